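"""Differential expression between cell lines and tumours, and what drives it.

Cell lines lack the immune and stromal compartments of a tumour, so genes
over-expressed in tumours relative to culture are dominated by
microenvironment transcripts. This module computes per-gene Welch t
statistics with Benjamini-Hochberg correction, partitions the top
differentially expressed genes by their correlation with immune/stromal
admixture scores, summarises the immune-correlated genes into a per-tumour
"immune DEG value" (summed per-gene Z-scores) and tests that score's
association with overall survival via a median split and log-rank test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel_io import ExpressionMatrix, ScoreTable, SurvivalRecord, Unit

__all__ = [
    "differential_expression",
    "select_top_degs",
    "correlate_genes_with_scores",
    "partition_degs",
    "immune_deg_values",
    "survival_logrank",
    "LogRankResult",
]


def differential_expression(
    cell_lines: ExpressionMatrix, tumours: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene Welch t test (cell lines vs tumours) with BH adjustment.

    Expression must be on a log scale and share one gene universe. The
    returned frame is indexed by gene with columns ``mean_cell_line``,
    ``mean_tumour``, ``t_statistic``, ``p_value``, ``adjusted_p`` and
    ``rank`` (1 = most significant; ties broken by raw p, then |t|, then
    gene id). Genes with zero variance in both groups and equal means are
    assigned t=0, p=1; zero variance with unequal means yields p=0.
    """
    if not cell_lines.genes.equals(tumours.genes):
        raise ValueError("gene universes differ; intersect first")
    if cell_lines.values.shape[1] < 2 or tumours.values.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    if cell_lines.unit in (Unit.TPM, Unit.RPKM) or tumours.unit in (Unit.TPM, Unit.RPKM):
        raise ValueError("differential expression expects log-scale input")
    a = cell_lines.values.to_numpy()
    b = tumours.values.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes are re-assigned explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t = np.where(degenerate & equal_means, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "mean_cell_line": a.mean(axis=1),
            "mean_tumour": b.mean(axis=1),
            "t_statistic": t,
            "p_value": p,
            "adjusted_p": adj,
        },
        index=cell_lines.genes,
    )
    order = sorted(
        table.index,
        key=lambda g: (
            table.at[g, "adjusted_p"],
            table.at[g, "p_value"],
            -abs(table.at[g, "t_statistic"]),
            g,
        ),
    )
    table["rank"] = pd.Series(range(1, len(order) + 1), index=order)
    return table


def select_top_degs(table: pd.DataFrame, fraction: float = 0.05) -> list[str]:
    """The floor(fraction * m) genes with smallest adjusted p.

    Ties are broken by smaller raw p, then larger |t|, then gene id — the
    same ordering as the ``rank`` column of the DEG table.
    """
    if table.empty:
        raise ValueError("empty DEG table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.floor(fraction * len(table)))
    ranked = table.sort_values("rank")
    return list(ranked.index[:k])


def correlate_genes_with_scores(
    tumours: ExpressionMatrix, genes: list[str], score: ScoreTable
) -> pd.DataFrame:
    """Pearson r of each gene's tumour expression with a per-sample score.

    Zero-variance genes get r=0 with ``degenerate=True`` so downstream
    partitions stay total.
    """
    samples = tumours.samples
    if len(samples) < 3:
        raise ValueError("need at least 3 tumours")
    missing = set(samples) - set(score.samples)
    if missing:
        raise ValueError(f"score missing for samples: {sorted(missing)[:5]}")
    s = score.values.loc[samples].to_numpy()
    sc = s - s.mean()
    s_norm = np.sqrt((sc**2).sum())
    if s_norm == 0:
        raise ValueError(f"score {score.score_name!r} has zero variance")
    x = tumours.values.loc[genes].to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xc**2).sum(axis=1))
    degenerate = x_norm == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ sc) / (x_norm * s_norm)
    r = np.where(degenerate, 0.0, r)
    return pd.DataFrame({"r": r, "degenerate": degenerate}, index=pd.Index(genes, name="gene"))


def partition_degs(
    r_immune: pd.Series, r_stromal: pd.Series, threshold: float = 0.4
) -> pd.DataFrame:
    """Label each gene IMMUNE (r_immune > threshold, strict), else STROMAL
    (r_stromal > threshold), else NEITHER. Immune takes precedence when both
    correlations exceed the threshold."""
    if not r_immune.index.equals(r_stromal.index):
        raise ValueError("gene vectors are not aligned")
    label = np.where(
        r_immune.to_numpy() > threshold,
        "IMMUNE",
        np.where(r_stromal.to_numpy() > threshold, "STROMAL", "NEITHER"),
    )
    return pd.DataFrame(
        {"label": label, "r_immune": r_immune, "r_stromal": r_stromal}, index=r_immune.index
    )


def immune_deg_values(tumours: ExpressionMatrix, immune_genes: list[str]) -> ScoreTable:
    """Per-tumour sum of per-gene Z-scores over the immune-correlated DEGs.

    Z-scores are computed across tumours per gene (mean 0, SD 1, ddof=1);
    zero-SD genes contribute 0. The resulting values sum to 0 over tumours.
    """
    if not immune_genes:
        raise ValueError("empty immune gene list")
    if tumours.values.shape[1] < 2:
        raise ValueError("need at least 2 tumours")
    x = tumours.values.loc[list(immune_genes)].to_numpy()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z = np.where(sd == 0, 0.0, z)
    return ScoreTable("ImmuneDEGValue", pd.Series(z.sum(axis=0), index=tumours.samples))


@dataclass
class LogRankResult:
    groups: pd.Series  # sample -> "HIGH" / "LOW"
    km_curves: dict  # group -> DataFrame(time, survival)
    chi_square: float
    p_value: float
    n_events: int


def survival_logrank(
    values: ScoreTable, survival: list[SurvivalRecord], horizon: float = 120.0
) -> LogRankResult:
    """Median split of a score followed by Kaplan-Meier and a log-rank test.

    Samples must have both a score and survival information (the analysis is
    restricted to the intersection before the median is taken). HIGH is
    strictly above the median; ties at the median go to LOW. Events after
    ``horizon`` months are administratively censored at the horizon.
    """
    surv = {r.sample: r for r in survival}
    shared = [s for s in values.samples if s in surv]
    if len(shared) < 2:
        raise ValueError("need at least 2 samples with both score and survival")
    v = values.values.loc[shared]
    median = v.median()
    groups = pd.Series(np.where(v > median, "HIGH", "LOW"), index=v.index, name="group")
    if (groups == "HIGH").sum() == 0 or (groups == "LOW").sum() == 0:
        raise ValueError("one group empty after median split")
    times = np.array([min(surv[s].time, horizon) for s in shared])
    events = np.array([surv[s].event and surv[s].time <= horizon for s in shared])
    hi = groups == "HIGH"
    km_curves = {}
    for label, mask in (("HIGH", hi.to_numpy()), ("LOW", ~hi.to_numpy())):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=label)
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        km_curves[label] = curve
    n_events = int(events.sum())
    if n_events == 0:
        return LogRankResult(groups, km_curves, 0.0, 1.0, 0)
    res = logrank_test(
        times[hi.to_numpy()], times[~hi.to_numpy()], events[hi.to_numpy()], events[~hi.to_numpy()]
    )
    chi2 = float(res.test_statistic)
    if not np.isfinite(chi2):
        warnings.warn("log-rank variance degenerate; reporting chi-square 0")
        return LogRankResult(groups, km_curves, 0.0, 1.0, n_events)
    return LogRankResult(groups, km_curves, chi2, float(res.p_value), n_events)
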