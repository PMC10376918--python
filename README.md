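# evcargo

Ageing-trajectory analysis of small non-coding RNA cargo in two mouse plasma
fractions: extracellular-vesicle-bound (EV) and free-circulating (fc) RNA.
The package re-implements, as a tested and reusable pipeline, the
computational stages of a small-RNA ageing study:

- **core_io** — TSV expression-matrix IO and validation, reads-per-million
  normalization, the 5-RPM expression filter, and per-class summaries
  (read shares, detection curves, EV/fc overlap).
- **synthetic** — seeded synthetic cohort generator: five age groups
  (2/6/8/12/18 months), two fractions, ten RNA classes, planted linear and
  purely nonlinear trajectories with fraction-specific sign structure,
  gamma-Poisson (negative-binomial) count noise, plus a miRNA→target atlas
  with planted repression and synthetic qPCR Ct tables.
- **trajectory** — per-feature Pearson and distance correlation with age,
  the spline-residual nonlinearity rule (|dcor − spline| ≥ 0.15 at 7 df),
  cross-fraction sign-quadrant concordance against the uniform 25% null,
  the permutation test of the mean-correlation shift between fractions, and
  baseline-relative class expression.
- **age_nmf** — constrained non-negative matrix factorization age-group
  classifier: D ≈ TP with 0 ≤ T,P ≤ 1 and column-stochastic P, solved by
  alternating projected least squares; labels by argmax of P, accuracy
  maximized over label permutations.
- **clustering** — z-scored feature clustering (Euclidean, complete
  linkage), dendrogram cut at 1/1.25 of the maximal height, cluster-level
  ageing summaries and cross-fraction cluster mapping.
- **variance** — PVCA-style attribution of expression variance to age,
  fraction, and mouse via eigenvalue-weighted per-component
  method-of-moments variance components.
- **enrichment** — unweighted running-sum miRNA set enrichment over
  correlation-ranked lists, permutation p-values, Benjamini–Hochberg
  adjustment, and the EV-vs-fc orders-of-magnitude contrast.
- **target_network** — strong-evidence miRNA→gene network, hub genes
  (in-degree ≥ 3), per-tissue target-age concordance, and direct
  miRNA–target correlation distributions.
- **qpcr** — ΔΔCt relative quantification with two conjoint endogenous
  controls.
- **pipeline / cli** — stage orchestration with YAML config, seeded
  determinism and a checksummed run manifest.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, one test per
criterion.

## CLI

Generate a complete synthetic input set and run every stage:

```sh
evcargo simulate --preset tiny --seed 1 --out fixtures/
evcargo run --config fixtures/config.yaml
```

Presets: `tiny` (≤50 features, seconds), `default`, `stress`. Single-stage
verbs (`trajectory`, `nmf`, `cluster`, `variance`, `enrich`, `network`,
`qpcr`) accept the same `--config/--seed/--out` options. All outputs are
TSV; the run manifest (`manifest.json`) records every output file with a
SHA-256 checksum, so reruns with the same config and seed are byte-identical.

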