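"""Synthetic reaction tables, networks, expression matrices and known-gene
lists with planted, hand-computable ground truth.

Construction (documented so downstream ground truth is computable by hand):

* The planted module is a clique over ``planted_module_size`` genes, so it
  survives any k-core filter up to size-1 and is mined as a dense module.
* The first two module genes are the planted *core* genes. Every known
  gene is attached to both core genes and to nothing else, so every
  geodesic between two known genes has length 2 and runs through a core
  gene: B(core) = C(known_gene_count, 2) and B = 0 for all other module
  genes.
* ``n_decoy_modules`` cliques of the same size, with two "hub" members
  given the same number of extra spoke edges as the core genes, are planted
  among background genes. They match the planted module's degree multiset
  but carry no correlation or DEG structure, so degree-conserved nulls have
  honest competitors instead of being forced back onto the planted genes.
* Each target-graph edge (u, v) becomes a private metabolite m plus two
  reactions u: src -> m and v: m -> sink, so the substrate-product chaining
  rule reproduces the target graph exactly. Background reactions draw
  random genes and metabolites from shared pools, giving an organic sparse
  background graph. Currency metabolites are sprinkled into >= 10% of
  reactions and must not create edges.
* Expression is drawn on log2 scale from a single-factor model: in the
  "correlated" state (the second state label) module genes share a latent
  factor with loading sqrt(corr_within_planted); elsewhere the loading is
  sqrt(corr_background). DEGs of a contrast (s1, s2) get +deg_effect added
  in s2. The differential-correlation contrast is (states[1], states[2]).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from coremod.metnet import Reaction, ReactionTable
from coremod.prep import ExpressionDataset


class ConfigError(ValueError):
    """Raised for infeasible synthetic configurations."""


DEFAULT_CURRENCY = ["h2o", "co2", "adp"]


@dataclass
class SyntheticConfig:
    n_genes: int = 120
    n_reactions: int = 200
    n_samples_per_state: int = 25
    states: tuple[str, str, str] = ("A", "B", "C")
    planted_module_size: int = 8
    corr_within_planted: float = 0.9
    corr_background: float = 0.0
    deg_effect: float = 2.0
    deg_fraction_planted: float = 0.5
    currency_metabolites: list[str] = field(default_factory=lambda: list(DEFAULT_CURRENCY))
    known_gene_count: int = 5
    n_decoy_modules: int = 3
    noise_sd: float = 0.5
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_module_size < 4:
            raise ConfigError("planted_module_size must be >= 4")
        if (self.planted_module_size * (1 + self.n_decoy_modules)
                + self.known_gene_count > self.n_genes):
            raise ConfigError(
                "planted module, decoy modules and known genes exceed the gene universe")
        if not (0.0 <= self.corr_background <= self.corr_within_planted <= 1.0):
            raise ConfigError("need 0 <= corr_background <= corr_within_planted <= 1")
        if self.known_gene_count < 2:
            raise ConfigError("need at least 2 known genes")
        if len(self.states) != 3 or len(set(self.states)) != 3:
            raise ConfigError("states must be 3 distinct labels")

    @property
    def diff_contrast(self) -> tuple[str, str]:
        """The state pair carrying the planted differential correlation."""
        return (self.states[1], self.states[2])

    @property
    def corr_state(self) -> str:
        return self.states[1]

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    planted_module_genes: set[str]
    planted_deg_sets: dict[tuple[str, str], set[str]]
    planted_known_genes: set[str]
    planted_core_genes: set[str]

    def to_json(self, path) -> None:
        data = {
            "planted_module_genes": sorted(self.planted_module_genes),
            "planted_deg_sets": {f"{a}_vs_{b}": sorted(v)
                                 for (a, b), v in self.planted_deg_sets.items()},
            "planted_known_genes": sorted(self.planted_known_genes),
            "planted_core_genes": sorted(self.planted_core_genes),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    reaction_table: ReactionTable
    truth: GroundTruth
    dataset: ExpressionDataset


def _decoy_slice(cfg: SyntheticConfig, background: list[str]) -> list[str]:
    return background[: cfg.n_decoy_modules * cfg.planted_module_size]


def _plan_truth(cfg: SyntheticConfig, rng: np.random.Generator) -> GroundTruth:
    """DEG plan: module DEGs are shifted in the third state only, so they
    are DEGs of (states[1], states[2]) and (states[0], states[2]);
    background "disease" DEGs are shifted in BOTH disease states, so they
    are DEGs of the two disease-vs-normal contrasts but cancel out of the
    disease-vs-disease contrast. Decoy-module genes never carry DEGs."""
    genes = cfg.gene_ids()
    module = genes[: cfg.planted_module_size]
    known = genes[cfg.planted_module_size: cfg.planted_module_size + cfg.known_gene_count]
    background = genes[cfg.planted_module_size + cfg.known_gene_count:]
    core = set(module[:2])

    n_planted_degs = max(1, round(cfg.deg_fraction_planted * cfg.planted_module_size))
    module_degs = {str(g) for g in
                   rng.choice(module, size=n_planted_degs, replace=False)}
    free_bg = [g for g in background if g not in set(_decoy_slice(cfg, background))]
    rng.shuffle(free_bg)
    n_bg = min(n_planted_degs, max(len(free_bg) // 3, 1))
    disease_degs = set(free_bg[:n_bg])
    s = cfg.states
    deg_sets = {
        (s[1], s[2]): set(module_degs),
        (s[0], s[1]): set(disease_degs),
        (s[0], s[2]): set(disease_degs) | set(module_degs),
    }
    return GroundTruth(
        planted_module_genes=set(module),
        planted_deg_sets=deg_sets,
        planted_known_genes=set(known),
        planted_core_genes=core,
    )


def generate_reaction_table(
    cfg: SyntheticConfig,
) -> tuple[ReactionTable, GroundTruth]:
    """Build the reaction table whose reconstructed network realizes the
    planted structure; see the module docstring for the construction."""
    rng = np.random.default_rng(cfg.seed)
    truth = _plan_truth(cfg, rng)
    genes = cfg.gene_ids()
    module = sorted(truth.planted_module_genes)
    known = sorted(truth.planted_known_genes)
    core = sorted(truth.planted_core_genes)
    background = [g for g in genes
                  if g not in truth.planted_module_genes
                  and g not in truth.planted_known_genes]

    target_edges: list[tuple[str, str]] = []
    for i, u in enumerate(module):
        for v in module[i + 1:]:
            target_edges.append((u, v))
    for k in known:
        for c in core:
            target_edges.append((k, c))

    # decoy cliques with hub spokes: same degree multiset as the planted
    # module, but no correlation or DEG structure
    size = cfg.planted_module_size
    decoy_genes = _decoy_slice(cfg, background)
    free = [g for g in background if g not in set(decoy_genes)]
    for d in range(cfg.n_decoy_modules):
        members = decoy_genes[d * size:(d + 1) * size]
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                target_edges.append((u, v))
        for hub in members[:2]:
            leaves = rng.choice(free, size=min(len(known), len(free)), replace=False)
            for leaf in leaves:
                target_edges.append((str(leaf), hub))
    background = free or module

    reactions: list[Reaction] = []
    for e_idx, (u, v) in enumerate(target_edges):
        met = f"pm_{e_idx:04d}"
        reactions.append(Reaction(f"RP{2 * e_idx:05d}", [f"src_{e_idx:04d}"], [met], [u]))
        reactions.append(Reaction(f"RP{2 * e_idx + 1:05d}", [met], [f"snk_{e_idx:04d}"], [v]))

    # organic background: random reactions over shared metabolite pools
    n_bg_mets = max(20, cfg.n_reactions // 2)
    bg_mets = [f"bm_{j:04d}" for j in range(n_bg_mets)]
    for r_idx in range(cfg.n_reactions):
        gene = background[int(rng.integers(len(background)))] if background else \
            module[int(rng.integers(len(module)))]
        subs = list(rng.choice(bg_mets, size=int(rng.integers(1, 3)), replace=False))
        prods = list(rng.choice(bg_mets, size=int(rng.integers(1, 3)), replace=False))
        reactions.append(Reaction(f"RB{r_idx:05d}", subs, prods, [gene]))

    # currency metabolites in >= 10% of reactions; they never add edges
    if cfg.currency_metabolites:
        step = 6  # ~17% of reactions
        for i in range(0, len(reactions), step):
            cm = cfg.currency_metabolites[
                int(rng.integers(len(cfg.currency_metabolites)))]
            if rng.random() < 0.5:
                reactions[i].substrates.append(cm)
            else:
                reactions[i].products.append(cm)
    return ReactionTable(reactions), truth


def generate_expression(
    cfg: SyntheticConfig, truth: GroundTruth
) -> ExpressionDataset:
    """Three-state log2 expression with the planted factor structure."""
    universe = set(cfg.gene_ids())
    for name, gs in (("module", truth.planted_module_genes),
                     ("known", truth.planted_known_genes)):
        if not gs <= universe:
            raise ConfigError(f"planted {name} genes outside the gene universe")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = cfg.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    module_idx = [gene_index[g] for g in sorted(truth.planted_module_genes)]
    n_genes, n_per = cfg.n_genes, cfg.n_samples_per_state

    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    state_of: dict[str, str] = {}
    for state in cfg.states:
        block = rng.standard_normal((n_genes, n_per))
        rho = cfg.corr_within_planted if state == cfg.corr_state else cfg.corr_background
        if rho > 0.0:
            factor = rng.standard_normal(n_per)
            block[module_idx, :] = (
                math.sqrt(rho) * factor
                + math.sqrt(1.0 - rho) * block[module_idx, :]
            )
        block = cfg.baseline + cfg.noise_sd * block
        # module DEGs are shifted in the third state only; disease DEGs in
        # both disease states (see _plan_truth)
        module_degs = truth.planted_deg_sets.get((cfg.states[1], cfg.states[2]), set())
        disease_degs = truth.planted_deg_sets.get((cfg.states[0], cfg.states[1]), set())
        if state == cfg.states[2]:
            rows = [gene_index[g] for g in sorted(module_degs)]
            block[rows, :] += cfg.deg_effect
        if state in (cfg.states[1], cfg.states[2]):
            rows = [gene_index[g] for g in sorted(disease_degs)]
            block[rows, :] += cfg.deg_effect
        cols.append(block)
        for i in range(n_per):
            sid = f"{state}_{i + 1:02d}"
            sample_ids.append(sid)
            state_of[sid] = state
    matrix = np.concatenate(cols, axis=1)
    return ExpressionDataset(matrix, genes, sample_ids, state_of)


def generate(cfg: SyntheticConfig) -> SyntheticBundle:
    rt, truth = generate_reaction_table(cfg)
    ds = generate_expression(cfg, truth)
    return SyntheticBundle(cfg, rt, truth, ds)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write all artifacts as plain text (TSV / TXT / JSON)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    bundle.reaction_table.to_tsv(os.path.join(outdir, "reactions.tsv"))
    bundle.dataset.to_tsv(os.path.join(outdir, "expression.tsv"),
                          os.path.join(outdir, "sample_states.tsv"))
    with open(os.path.join(outdir, "known_genes.txt"), "w") as fh:
        for g in sorted(bundle.truth.planted_known_genes):
            fh.write(g + "\n")
    bundle.truth.to_json(os.path.join(outdir, "ground_truth.json"))
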