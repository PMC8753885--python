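"""End-to-end orchestration: prep -> DEGs -> network -> dense modules ->
differential-correlation candidates -> MRF risk modules -> core genes ->
classification, with per-stage artifacts and a machine-readable report.
"""

from __future__ import annotations

import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import yaml

from coremod import classify as clf
from coremod import coregenes, diffcorr, mcode, metnet, mrf, prep, synth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs (ignored when simulate=True)
    expression_tsv: str | None = None
    states_tsv: str | None = None
    reactions_tsv: str | None = None
    known_genes_txt: str | None = None
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    # stage parameters; defaults follow the published protocol where stated
    max_missing_fraction: float = 0.5
    knn_k: int = 10
    fc_threshold: float = 1.0
    q_threshold: float = 0.05
    sam_n_perm: int = 1000
    s0_quantile: float = 0.05
    currency_metabolites: list[str] = field(
        default_factory=lambda: sorted(metnet.DEFAULT_CURRENCY))
    mcode_degree_cutoff: int = 2
    mcode_k_core: int = 3
    mcode_node_score_cutoff: float = 0.2
    min_module_size: int = 4
    n_rand: int = 1000
    alpha: float = 0.05
    e_transform: str = "normal_quantile"
    mi_bins: int | None = None
    quartile: float = 0.25
    n_reps: int = 100
    svm_c: float = 1.0
    run_classification: bool = True
    seed: int = 0
    outdir: str = "coremod_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG derived from the global seed."""
        return np.random.default_rng(
            (self.seed * 2**32 + zlib.crc32(stage.encode())) % 2**63)


def _contrasts(states: list[str]) -> list[tuple[str, str]]:
    return [(states[0], states[1]), (states[0], states[2]),
            (states[1], states[2])]


def _ckey(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}_vs_{contrast[1]}"


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and persists) the pipeline report."""
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    t0 = time.monotonic()

    def stage_done(name: str) -> None:
        logger.info("stage %-10s done at %.1fs", name, time.monotonic() - t0)

    # ---- inputs -----------------------------------------------------------
    if cfg.simulate:
        syn_cfg = synth.SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
        bundle = synth.generate(syn_cfg)
        synth.write_bundle(bundle, os.path.join(cfg.outdir, "inputs"))
        rt, ds = bundle.reaction_table, bundle.dataset
        known_genes = set(bundle.truth.planted_known_genes)
        report["stages"]["simulate"] = {
            "n_genes": syn_cfg.n_genes,
            "n_reactions": len(rt),
            "planted_module_size": syn_cfg.planted_module_size,
        }
    else:
        for p, what in ((cfg.expression_tsv, "expression_tsv"),
                        (cfg.states_tsv, "states_tsv"),
                        (cfg.reactions_tsv, "reactions_tsv"),
                        (cfg.known_genes_txt, "known_genes_txt")):
            if not p:
                raise ValueError(f"{what} is required when simulate=False")
        ds = prep.ExpressionDataset.from_tsv(cfg.expression_tsv, cfg.states_tsv)
        rt = metnet.ReactionTable.from_tsv(cfg.reactions_tsv)
        with open(cfg.known_genes_txt) as fh:
            known_genes = {l.strip() for l in fh if l.strip()}
    stage_done("inputs")

    # ---- prep -------------------------------------------------------------
    mat, kept = prep.filter_missing(ds.matrix, cfg.max_missing_fraction)
    if np.isnan(mat).any():
        mat = prep.knn_impute(mat, cfg.knn_k)
    ds = prep.ExpressionDataset(mat, [ds.gene_ids[i] for i in kept],
                                ds.sample_ids, ds.state_of)
    states = ds.states
    if len(states) != 3:
        raise ValueError(f"expected 3 sample states, found {states}")
    report["stages"]["prep"] = {"n_genes": len(ds.gene_ids),
                                "n_samples": len(ds.sample_ids)}
    stage_done("prep")

    # ---- DEGs -------------------------------------------------------------
    contrasts = _contrasts(states)
    deg_sets: dict[tuple[str, str], set[str]] = {}
    deg_frames = []
    for c in contrasts:
        recs = prep.sam_degs(ds, c, n_perm=cfg.sam_n_perm,
                             s0_quantile=cfg.s0_quantile,
                             fc_threshold=cfg.fc_threshold,
                             q_threshold=cfg.q_threshold,
                             rng=cfg.stage_rng(f"deg:{_ckey(c)}"))
        deg_sets[c] = prep.deg_gene_set(recs)
        deg_frames.append(prep.degs_to_frame(recs))
    import pandas as pd

    pd.concat(deg_frames).to_csv(os.path.join(cfg.outdir, "degs.tsv"),
                                 sep="\t", index=False)
    report["stages"]["degs"] = {_ckey(c): len(deg_sets[c]) for c in contrasts}
    stage_done("degs")

    # ---- network ----------------------------------------------------------
    net = metnet.build_network(rt, set(cfg.currency_metabolites))
    metnet.write_edge_list(net, os.path.join(cfg.outdir, "network_edges.tsv"))
    in_net = metnet.annotate_degs(net, {_ckey(c): deg_sets[c] for c in contrasts})
    report["stages"]["network"] = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "degs_in_network": {k: len(v) for k, v in in_net.items()},
    }
    stage_done("network")

    # ---- dense modules ----------------------------------------------------
    params = mcode.MCODEParams(
        degree_cutoff=cfg.mcode_degree_cutoff, k_core=cfg.mcode_k_core,
        node_score_cutoff=cfg.mcode_node_score_cutoff,
        min_module_size=cfg.min_module_size)
    modules = mcode.predict_complexes(net, params=params)
    initial = mcode.classify_initial(
        modules, {_ckey(c): deg_sets[c] for c in contrasts})
    mcode.modules_to_json(initial, os.path.join(cfg.outdir, "initial_modules.json"))
    report["stages"]["modules"] = {
        "mined": len(modules),
        "initial": len(initial),
        "initial_per_tag": {
            _ckey(c): sum(1 for m in initial if _ckey(c) in m.contrast_tags)
            for c in contrasts},
    }
    stage_done("modules")

    # statistics are evaluated on network nodes; they need expression rows
    scored_net = net.subgraph([n for n in net.nodes if ds.has_gene(n)])
    if scored_net.number_of_nodes() < net.number_of_nodes():
        logger.warning("%d network genes lack expression; excluded from nulls",
                       net.number_of_nodes() - scored_net.number_of_nodes())

    # ---- differential-correlation candidates ------------------------------
    w_rows, candidates = [], []
    for m in initial:
        for ck in sorted(m.contrast_tags):
            contrast = next(c for c in contrasts if _ckey(c) == ck)
            genes = {g for g in m.genes if ds.has_gene(g)}
            if len(genes) < 2:
                continue
            score = diffcorr.w_score(sorted(genes), ds, contrast, m.module_id)
            res = diffcorr.permutation_pvalues(
                genes,
                lambda gs, c=contrast: diffcorr.w_score(sorted(gs), ds, c).W,
                scored_net, n_rand=cfg.n_rand,
                rng=cfg.stage_rng(f"wperm:{m.module_id}:{ck}"),
                module_id=m.module_id)
            is_cand = res.p_degree < cfg.alpha and res.p_size < cfg.alpha
            w_rows.append({"module_id": m.module_id, "contrast": ck,
                           "H": score.H, "H_prime": score.H_prime, "W": score.W,
                           "p_degree": res.p_degree, "p_size": res.p_size,
                           "candidate": is_cand})
            if is_cand:
                candidates.append((m, contrast))
    pd.DataFrame(w_rows).to_csv(os.path.join(cfg.outdir, "w_scores.tsv"),
                                sep="\t", index=False)
    report["stages"]["candidates"] = {
        "evaluations": len(w_rows),
        "candidate_module_contrasts": sorted(
            f"{m.module_id}:{_ckey(c)}" for m, c in candidates),
    }
    stage_done("candidates")

    # ---- MRF risk modules -------------------------------------------------
    risk: list[tuple[mcode.Module, tuple[str, str]]] = []
    mrf_rows = []
    for m, contrast in candidates:
        model = mrf.MRFModel(net=scored_net, ds=ds, contrast=contrast,
                             deg_genes=deg_sets[contrast],
                             e_transform=cfg.e_transform, mi_bins=cfg.mi_bins)
        genes = {g for g in m.genes if ds.has_gene(g)}
        score = mrf.mrfms(genes, model, m.module_id)
        res = diffcorr.permutation_pvalues(
            genes, lambda gs: mrf.mrfms(gs, model).mrfms, scored_net,
            n_rand=cfg.n_rand,
            rng=cfg.stage_rng(f"mrfperm:{m.module_id}:{_ckey(contrast)}"),
            module_id=m.module_id, statistic_name="MRFms")
        is_risk = res.p_degree < cfg.alpha and res.p_size < cfg.alpha
        mrf_rows.append({"module_id": m.module_id, "contrast": _ckey(contrast),
                         "mrfms": score.mrfms, "term1": score.term1,
                         "term2": score.term2, "p_degree": res.p_degree,
                         "p_size": res.p_size, "risk": is_risk})
        if is_risk:
            risk.append((m, contrast))
    pd.DataFrame(mrf_rows).to_csv(os.path.join(cfg.outdir, "mrf_scores.tsv"),
                                  sep="\t", index=False)
    report["stages"]["risk_modules"] = {
        "risk_module_contrasts": sorted(
            f"{m.module_id}:{_ckey(c)}" for m, c in risk)}
    stage_done("risk")

    # ---- core genes -------------------------------------------------------
    risk_genes = sorted({g for m, _ in risk for g in m.genes})
    core: set[str] = set()
    candidate_genes: list[str] = []
    if risk_genes:
        known = coregenes.KnownGeneSet.from_network(known_genes, net)
        if len(known.in_network) >= 2:
            scores = coregenes.pair_linkage_scores(net, risk_genes, known)
            core = coregenes.select_core(scores, cfg.quartile)
            candidate_genes = [s.gene_id for s in scores if s.is_candidate]
            coregenes.scores_to_frame(scores).to_csv(
                os.path.join(cfg.outdir, "core_genes.tsv"), sep="\t", index=False)
        else:
            logger.warning("fewer than 2 known genes in the network; "
                           "no core genes can be scored")
    report["stages"]["core_genes"] = {
        "risk_module_genes": len(risk_genes),
        "candidate_genes": len(candidate_genes),
        "core_genes": sorted(core),
    }
    stage_done("core")

    # ---- classification ---------------------------------------------------
    if cfg.run_classification and core:
        cls_report: dict = {"auc": {}}
        for c in contrasts:
            usable = [g for g in sorted(core) if ds.has_gene(g)]
            if not usable:
                continue
            res = clf.svm_loocv_auc(ds, usable, c, C=cfg.svm_c)
            cls_report["auc"][_ckey(c)] = res.auc
        diff_c = contrasts[2]
        pool1 = set(candidate_genes)
        usable_core = {g for g in core if ds.has_gene(g)}
        if len(pool1 - usable_core) >= len(usable_core) and usable_core:
            cmp1 = clf.random_set_comparison(
                ds, usable_core, pool1, deg_sets[diff_c],
                "candidates_minus_core", diff_c,
                cfg.stage_rng("classify:scheme1"), n_reps=cfg.n_reps, C=cfg.svm_c)
            cls_report["scheme1_wilcoxon_p"] = cmp1.wilcoxon_p
        pool2 = set(risk_genes) & {g for g in risk_genes if ds.has_gene(g)}
        try:
            cmp2 = clf.random_set_comparison(
                ds, usable_core, pool2, deg_sets[diff_c],
                "composition_matched", diff_c,
                cfg.stage_rng("classify:scheme2"), n_reps=cfg.n_reps, C=cfg.svm_c)
            cls_report["scheme2_wilcoxon_p"] = cmp2.wilcoxon_p
        except ValueError as exc:
            logger.warning("composition-matched comparison skipped: %s", exc)
        report["stages"]["classification"] = cls_report
        stage_done("classify")

    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
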