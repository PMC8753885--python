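# coremod

Core-gene discovery from metabolic gene networks and three-state expression
data. The pipeline:

1. **prep** — missing-value filtering (rows with >50% missing dropped), kNN
   imputation (distance-weighted average over co-observed columns), probe
   collapsing, and SAM-style differential expression (moderated d-statistic,
   permutation FDR, `|log2FC| > 1`, `q < 0.05`).
2. **metnet** — reconstructs an undirected gene–gene network from a reaction
   table: two genes are linked when the product of one gene's reaction is a
   substrate of the other's, with currency metabolites (H2O, CO2, ADP, ...)
   excluded.
3. **mcode** — mines dense modules with a re-implementation of the MCODE
   algorithm (degree cutoff 2, k-core 3, node score cutoff 0.2, ≥4 nodes),
   then tags modules by the DEG contrasts they contain ("initial modules").
4. **diffcorr** — scores each initial module with `W = |H − H'|`, the absolute
   difference of its mean absolute pairwise Pearson correlation between two
   sample states, and tests it against 1000 degree-conserved and 1000
   size-conserved random modules (`p = 1 − t/1000`); modules significant
   under both nulls become candidates.
5. **mrf** — scores candidates with an MRF-based statistic
   `MRFms = g^(−1/2) Σ_{u∈G1} E_u − b^(−1) Σ_{(v,z)∈G2-edges}
   (E_v/√d_v − E_z/√d_z)² · MI(v,z)` (E = normal quantile of a Welch-test
   p-value, MI = equal-frequency-binned mutual information), under the same
   two permutation nulls; survivors are risk modules.
6. **coregenes** — every risk-module gene x gets `B(x)`, the number of
   known-disease-gene pairs whose shortest paths pass through x; the top
   upper quartile (ties included) are the core genes.
7. **classify** — radial-SVM leave-one-out AUC of any gene set, plus
   comparisons against size- and composition-matched random gene sets
   (one-sample Wilcoxon signed-rank).

A synthetic-data generator (`coremod.synth`) plants a correlated clique
module, DEGs, decoy modules, and known genes whose geodesics are forced
through designated core genes, so the whole pipeline has recoverable ground
truth without any external download. Real data in the supported TSV formats
(expression + sample states, reaction table, known-gene list) can be
substituted for the synthetic inputs.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, formula identities, permutation-null calibration, parameter
recovery, determinism); the rest are unit/property tests per module.

## CLI

```sh
coremod run-all --seed 1 --outdir out            # synthetic end-to-end run
coremod run-all --config cfg.yaml --outdir out   # custom/real inputs
coremod simulate --seed 1 --outdir inputs        # just the synthetic bundle
coremod net --reactions inputs/reactions.tsv --out edges.tsv
coremod mine --edges edges.tsv --degs degs.tsv --out modules.json
coremod deg --expression inputs/expression.tsv --states inputs/sample_states.tsv \
    --contrast B,C --out degs.tsv
coremod score --edges edges.tsv --modules modules.json \
    --expression inputs/expression.tsv --states inputs/sample_states.tsv \
    --contrast B,C --out w_scores.tsv
coremod core --edges edges.tsv --modules risk_modules.json \
    --known inputs/known_genes.txt --out core_genes.tsv
```

`run-all` writes per-stage TSV/JSON artifacts and a `report.json` with every
intermediate count; the same config and seed reproduce the report
byte-identically. The YAML config mirrors `coremod.pipeline.PipelineConfig`
(thresholds, permutation counts, MCODE parameters, currency-metabolite list,
E-transform, MI bins, quartile, SVM settings).

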