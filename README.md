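# cnakit

Correlation-based network analysis (CNA) for multi-group biomarker panels.

Given a samples × biomarkers table of continuous measurements, a
biomarker → variable-group assignment, and a cohort label per sample,
cnakit:

- applies an explicit, recorded log transform and a complete-case rule
  (any biomarker with missing data is excluded entirely; samples are kept);
- computes all pairwise Pearson correlations and hard-thresholds them at
  |ρ| ≥ 0.7 (inclusive by default, configurable) into an edge list;
- builds the biomarker network (only biomarkers with at least one strong
  correlation appear), computes node degree, normalized betweenness
  centrality, per-group network density, and detects hubs (normalized
  betweenness strictly above 0.1);
- collapses the network to a group-level view where any number of
  cross-group edges renders a single connector between two variable groups;
- compares two cohort networks descriptively (edge differences, connector
  differences, hub overlap) and runs unpaired t-tests per biomarker, both
  from raw data and from printed summary statistics (mean ± SD, n);
- ships a synthetic-data module that generates two-cohort tables with
  planted correlation blocks and hubs via a Gaussian copula, so the entire
  pipeline is testable without any external data.

## CLI

```bash
# generate the two-cohort study emulation (tables + ground truth)
cnakit simulate --out sim/ --seed 1

# single-cohort pipeline: edge list, GraphML, per-group summary table
cnakit build sim/disease.csv sim/groups.csv --log --out results_disease/

# two-cohort comparison: comparison JSON, per-cohort artifacts, t-tests
cnakit compare sim/disease.csv sim/control.csv sim/groups.csv --log \
    --label-a disease --label-b control --out comparison/

# render a comparison JSON as a readable report
cnakit report comparison/comparison.json
```

`--config analysis.yaml` supplies an analysis configuration (threshold
`rho0`, threshold strictness, hub cutoff, density universe convention,
betweenness scope, t-test variant); individual flags override the file.
Every verb writes a `manifest.json` recording the config, input digests,
per-stage counts, seed and tool version. Exit codes: 0 success,
2 validation error, 1 internal error.

### Conventions worth knowing

- **Density denominator** defaults to the full measured roster of a group,
  including biomarkers dropped by the complete-case rule — e.g. 11 edges
  over a 16-member roster gives 11/C(16,2) = 0.09. Set
  `density_universe: connected_nodes` to use only connected biomarkers.
- **Betweenness scope** for hub detection defaults to the within-group
  induced subgraph (`bc_scope: within_group`); `full_network` scores nodes
  on the whole graph instead.
- **Thresholding is inclusive** (|ρ| ≥ ρ₀) by default so a correlation of
  exactly 0.70 counts as an edge; `--strict-threshold` switches to >.
- Edges are never filtered by p-value; a Fisher-z p-value is available as
  an optional annotation only.

## Library use

```python
from cnakit import (
    AnalysisConfig, make_study_emulation, log_transform,
    run_pipeline, compare_cohorts,
)

disease, control, truth = make_study_emulation(seed=1)
report = compare_cohorts(
    log_transform(disease), log_transform(control),
    AnalysisConfig(), label_a="disease", label_b="control",
)
print(report.connectors_only_in_a)   # group pairs connected only in disease
```
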