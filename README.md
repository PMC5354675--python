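# melafidelity

**How faithfully do melanoma cell lines model melanoma tumours?**

Cell lines are the workhorse of melanoma research, but they are pure
malignant populations growing without the immune and stromal compartments
that shape a tumour *in vivo*. `melafidelity` is an analysis pipeline for
quantifying that gap and for choosing the cell line that best fits a
research question. It provides:

- **Cohort harmonization** — RPKM→TPM conversion, log2(TPM+1) scaling (with
  the ÷10 variant for low-complexity single-cell libraries), gene-universe
  intersection, variance filtering and PCA.
- **Immune divergence** — per-gene Welch *t* tests with Benjamini–Hochberg
  correction between cell lines and tumours; partition of the top 5%
  differentially expressed genes by their Pearson correlation (*r* > 0.4)
  with immune/stromal admixture scores; a per-tumour *immune DEG value*
  (summed per-gene Z-scores over the immune-correlated genes) tested against
  ten-year overall survival by median split, Kaplan–Meier and log-rank.
- **Fidelity ranking** — mean Pearson correlation of each cell line with
  single malignant cells over all shared genes, optionally restricted to
  the cells most extreme for the MITF or AXL transcriptional program;
  program cell scores use expression-bin-matched control gene sets, and
  lines are assigned MITF / AXL / intermediate states by mode-seeking on a
  2-D Gaussian kernel density of the two program enrichments.
- **UV mutational signature** — strand-collapsed substitution spectra at
  dipyrimidine vs non-dipyrimidine sites; a sample is UV-signature positive
  when its fraction of C>T-at-dipyrimidine SNVs exceeds 0.6; exact two-sided
  binomial tests compare per-gene alteration frequencies.
- **Tissue of origin** — a skin score per sample, Σ<sub>g</sub> expr<sub>g</sub> ·
  EE<sub>g</sub>²/Σ EE², combined with the UV call and Ward (ward.D2)
  hierarchical clustering to flag probable melanoma-origin lines.
- **A seeded synthetic-cohort generator** — tumours are convex mixtures of a
  malignant archetype with immune/stromal contamination at variable purity,
  cell lines are pure noisy archetypes, single cells come from MITF-high /
  AXL-high archetypes, SNV catalogs have tunable UV fractions, and survival
  follows an exponential model tied to the immune score. Every downstream
  stage is testable against the generator's truth labels without any
  external download.

All inputs and outputs are plain text: TSV expression/score/survival/copy-
number tables, GMT gene sets and MAF-like mutation tables.

## Worked example

```python
import numpy as np
from melafidelity import harmonize as hz
from melafidelity.synthetic_cohort import (
    CohortParams, simulate_expression_cohort, simulate_mutation_catalog,
    simulate_survival,
)
from melafidelity.immune_divergence import (
    differential_expression, select_top_degs, correlate_genes_with_scores,
    partition_degs, immune_deg_values, survival_logrank,
)
from melafidelity.mutation_signature import uv_signature_calls

params = CohortParams(seed=1)           # 2,000 genes, 120 tumours, 30 lines
tumours, lines, imm, stro, truth = simulate_expression_cohort(params)
tum, cl = hz.to_log_tpm(tumours), hz.to_log_tpm(lines)

print("mean-profile r:", round(hz.mean_profile_correlation(cl, tum), 3))
table = differential_expression(cl, tum)
top = select_top_degs(table, 0.05)
part = partition_degs(
    correlate_genes_with_scores(tum, top, imm)["r"],
    correlate_genes_with_scores(tum, top, stro)["r"],
)
print("top DEGs:", len(top), "| IMMUNE:", (part.label == "IMMUNE").sum())

ideg = immune_deg_values(tum, list(part.index[part.label == "IMMUNE"]))
res = survival_logrank(ideg, simulate_survival(ideg, 2.0, seed=1))
print(f"log-rank chi2 = {res.chi_square:.2f}, p = {res.p_value:.2g}")

records, uv_truth = simulate_mutation_catalog(params, n_samples=30)
calls = uv_signature_calls(records)
print("UV-positive calls:", sum(c.uv_positive for c in calls), "of", len(calls))
```

This prints:

```
mean-profile r: 0.807
top DEGs: 100 | IMMUNE: 100
log-rank chi2 = 27.55, p = 1.5e-07
UV-positive calls: 15 of 30
```

Read: the simulated cell lines correlate strongly with tumours overall
(r = 0.81 on mean log profiles), yet every one of the top differentially
expressed genes is immune-correlated — the signal a tumour carries and a
monoculture cannot. High immune DEG values are strongly associated with
survival in the simulated cohort, and the UV classifier recovers exactly
the 15 samples simulated with a UV-dominated mutation catalog.

The same pipeline is available from the shell:

```bash
melafidelity run-all --seed 1 --out results/demo
```

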