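"""Rank cell lines against single malignant cells and score MITF/AXL states.

A cell line is a pure malignant population, so its transcriptome can be
compared directly to single malignant cells taken from tumours. Lines are
ranked by the mean Pearson correlation over all line-cell pairs (optionally
restricted to the cells most extreme for the MITF or AXL program). Program
activity per cell is scored as the mean relative expression of program genes
minus an expression-matched control gene score, which removes library-
complexity bias. Per-line program enrichment uses set-level t statistics,
and lines are assigned to MITF / AXL / intermediate states by mode-seeking
on a 2-D Gaussian kernel density of the two enrichments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import ExpressionMatrix, GeneSet

__all__ = [
    "rank_by_single_cell_correlation",
    "program_cell_scores",
    "select_extreme_cells",
    "gene_set_enrichment",
    "cluster_program_states",
    "StateClustering",
]


def rank_by_single_cell_correlation(
    cell_lines: ExpressionMatrix,
    cells: ExpressionMatrix,
    cell_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Mean Pearson correlation of every cell line with single cells.

    For each line, Pearson r is computed over all shared genes against each
    cell (optionally a subset), and the mean across cells is reported.
    Zero-variance lines or cells are skipped pair-wise with a warning; a
    line with no valid pairs raises. The result is sorted by mean r
    descending, ties broken by line id.
    """
    if not cell_lines.genes.equals(cells.genes):
        raise ValueError("gene universes differ; intersect first")
    cell_ids = cells.samples if cell_subset is None else pd.Index(cell_subset)
    if len(cell_ids) == 0:
        raise ValueError("no cells to correlate against")
    A = cell_lines.values.to_numpy()
    B = cells.values.loc[:, cell_ids].to_numpy()
    Ac = A - A.mean(axis=0, keepdims=True)
    Bc = B - B.mean(axis=0, keepdims=True)
    an = np.sqrt((Ac**2).sum(axis=0))
    bn = np.sqrt((Bc**2).sum(axis=0))
    bad_lines = an == 0
    bad_cells = bn == 0
    if bad_cells.any():
        warnings.warn(f"skipping {int(bad_cells.sum())} zero-variance cells")
    if bad_lines.any():
        raise ValueError(
            f"zero-variance cell line(s): {list(cell_lines.samples[bad_lines])[:5]}"
        )
    keep = ~bad_cells
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Ac[:, :].T @ Bc[:, keep]) / np.outer(an, bn[keep])
    mean_r = R.mean(axis=1)
    out = pd.DataFrame(
        {"mean_r": mean_r, "n_cells": int(keep.sum())},
        index=pd.Index(cell_lines.samples, name="cell_line"),
    )
    return out.sort_values("mean_r", ascending=False, kind="mergesort").loc[
        sorted(out.index, key=lambda c: (-out.at[c, "mean_r"], c))
    ]


def _present_members(gene_set: GeneSet, universe: pd.Index) -> list[str]:
    present = [g for g in universe if g in gene_set.members]
    dropped = len(gene_set.members) - len(present)
    if dropped:
        warnings.warn(f"{dropped} member(s) of {gene_set.name!r} absent from the universe")
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} empty after universe filtering")
    return present


def program_cell_scores(
    cells: ExpressionMatrix,
    mitf_set: GeneSet,
    axl_set: GeneSet,
    n_bins: int = 25,
    n_controls: int = 100,
    seed: int = 0,
    control_pools: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-cell MITF and AXL program scores with expression-matched controls.

    Relative expression centers each gene across cells (log scale expected).
    The raw program score of a cell is the mean relative expression of the
    program genes; the control score averages, for each program gene,
    ``n_controls`` genes drawn (seeded) from the same average-expression bin
    out of ``n_bins``. The reported score is raw minus control, and
    ``ratio_key`` = score_mitf - score_axl ranks cells from MITF-most to
    AXL-most. ``control_pools`` may override the drawn pools (mainly for
    testing the self-control identity).
    """
    expr = cells.values
    rel = expr.sub(expr.mean(axis=1), axis=0)
    avg = expr.mean(axis=1)
    # Equal-occupancy bins on average expression; rank first so ties split.
    bins = pd.qcut(avg.rank(method="first"), min(n_bins, len(avg)), labels=False)
    rng = np.random.default_rng(seed)
    out = {}
    for name, gene_set in (("mitf", mitf_set), ("axl", axl_set)):
        members = _present_members(gene_set, expr.index)
        raw = rel.loc[members].mean(axis=0)
        if control_pools is not None and name in control_pools:
            pool = list(control_pools[name])
        else:
            pool = []
            for g in members:
                bin_genes = avg.index[(bins == bins[g]).to_numpy()]
                replace = n_controls > len(bin_genes)
                pool.extend(rng.choice(bin_genes, size=n_controls, replace=replace))
        control = rel.loc[pool].mean(axis=0)
        out[f"raw_{name}"] = raw
        out[f"control_{name}"] = control
        out[f"score_{name}"] = raw - control
    table = pd.DataFrame(out, index=expr.columns)
    table["ratio_key"] = table["score_mitf"] - table["score_axl"]
    table.index.name = "cell"
    return table


def select_extreme_cells(scores: pd.DataFrame, k: int = 400) -> tuple[list[str], list[str]]:
    """Cells with the k largest / k smallest MITF-vs-AXL ratio keys.

    If fewer than 2k cells are available, k is reduced to floor(n/2) with a
    warning. The two groups are disjoint; ties at the boundary are broken by
    cell id.
    """
    n = len(scores)
    if 2 * k > n:
        k = n // 2
        warnings.warn(f"fewer than 2k cells; reducing k to {k}")
    if k == 0:
        raise ValueError("not enough cells to select extremes")
    key = scores["ratio_key"]
    desc = sorted(scores.index, key=lambda c: (-key[c], c))
    mitf_top = desc[:k]
    remaining = [c for c in desc if c not in set(mitf_top)]
    asc = sorted(remaining, key=lambda c: (key[c], c))
    axl_top = asc[:k]
    return mitf_top, axl_top


def gene_set_enrichment(
    expr: ExpressionMatrix,
    sets: list[GeneSet],
    mode: str = "single_sample",
    groups: pd.Series | None = None,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Signed set-level t statistics on expression data.

    single_sample mode: genes are Z-scored across samples (ddof=1) and, per
    sample and set, a one-sample t statistic of the set genes' Z-scores
    against 0 is returned (rows = sets, columns = samples). Sets reduced to a
    single present gene (or with zero Z spread in a sample) are flagged NaN.

    two_group mode: per-gene log-fold-changes between the two groups in
    ``groups`` (ordered by ``group_order`` or sorted labels) are compared
    between set genes and the non-set background with a Welch two-sample t;
    one signed statistic per set is returned with columns ``statistic``,
    ``n_genes`` and ``degenerate``.
    """
    values = expr.values
    if mode == "single_sample":
        mu = values.mean(axis=1)
        sd = values.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = values.sub(mu, axis=0).div(sd, axis=0)
        z = z.where(sd > 0, 0.0)
        rows = {}
        for gene_set in sets:
            members = _present_members(gene_set, values.index)
            zset = z.loc[members].to_numpy()
            m = len(members)
            if m < 2:
                warnings.warn(f"set {gene_set.name!r} has <2 genes; statistic undefined")
                rows[gene_set.name] = np.full(values.shape[1], np.nan)
                continue
            mean = zset.mean(axis=0)
            sdev = zset.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = mean / (sdev / np.sqrt(m))
            # zero spread with zero mean is a true 0; nonzero mean is undefined
            t = np.where((sdev == 0) & (mean == 0), 0.0, t)
            rows[gene_set.name] = np.where((sdev == 0) & (mean != 0), np.nan, t)
        return pd.DataFrame(rows, index=values.columns).T
    if mode == "two_group":
        if groups is None:
            raise ValueError("two_group mode requires a groups series")
        labels = group_order or tuple(sorted(pd.Series(groups).unique()))
        if len(labels) != 2:
            raise ValueError("two_group mode requires exactly two group labels")
        a_cols = [s for s in values.columns if groups[s] == labels[0]]
        b_cols = [s for s in values.columns if groups[s] == labels[1]]
        lfc = values[a_cols].mean(axis=1) - values[b_cols].mean(axis=1)
        rows = []
        for gene_set in sets:
            members = _present_members(gene_set, values.index)
            inside = lfc.loc[members].to_numpy()
            outside = lfc.drop(index=members).to_numpy()
            if len(inside) < 2 or len(outside) < 2:
                rows.append((gene_set.name, np.nan, len(inside), True))
                continue
            t, _ = stats.ttest_ind(inside, outside, equal_var=False)
            rows.append((gene_set.name, float(t), len(inside), False))
        return pd.DataFrame(
            rows, columns=["set", "statistic", "n_genes", "degenerate"]
        ).set_index("set")
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class StateClustering:
    labels: pd.Series  # line -> MITF / AXL / INTERMEDIATE
    modes: np.ndarray  # cluster modes in (mitf, axl) space
    assignments: pd.Series  # line -> mode index
    fallback: bool


def _mean_shift(points: np.ndarray, inv_cov: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Ascend each point to a mode of the Gaussian KDE (mean-shift fixed point)."""
    modes = points.copy()
    for i in range(points.shape[0]):
        x = points[i].copy()
        for _ in range(1000):
            d = points - x
            w = np.exp(-0.5 * np.einsum("ij,jk,ik->i", d, inv_cov, d))
            x_new = (w[:, None] * points).sum(axis=0) / w.sum()
            if np.linalg.norm(x_new - x) < tol:
                x = x_new
                break
            x = x_new
        modes[i] = x
    return modes


def cluster_program_states(
    mitf_enrichment: pd.Series, axl_enrichment: pd.Series
) -> StateClustering:
    """Density-mode clustering of lines in (MITF, AXL) enrichment space.

    A 2-D Gaussian KDE (Silverman bandwidth) is fit to the enrichment pairs;
    each line ascends the density to a mode, and modes closer than the
    kernel bandwidth are merged. The mode with the highest mean MITF-AXL
    difference is labelled MITF, the lowest AXL, and any remaining modes are
    pooled as INTERMEDIATE. With fewer than two modes (or degenerate input)
    every line is labelled by the sign of MITF-AXL, with a warning.

    The procedure has no internal randomness and is invariant to the input
    order of the lines.
    """
    if not mitf_enrichment.index.equals(axl_enrichment.index):
        raise ValueError("enrichment series are not aligned")
    if len(mitf_enrichment) < 3:
        raise ValueError("need at least 3 lines")
    ids = mitf_enrichment.index
    pts = np.column_stack([mitf_enrichment.to_numpy(), axl_enrichment.to_numpy()])
    diff = pts[:, 0] - pts[:, 1]

    def fallback() -> StateClustering:
        warnings.warn("fewer than two density modes; labelling by sign of MITF-AXL")
        labels = pd.Series(np.where(diff > 0, "MITF", "AXL"), index=ids, name="state")
        return StateClustering(labels, np.empty((0, 2)), pd.Series(0, index=ids), True)

    try:
        kde = stats.gaussian_kde(pts.T, bw_method="silverman")
    except np.linalg.LinAlgError:
        return fallback()
    inv_cov = kde.inv_cov
    bandwidth = float(np.sqrt(np.trace(kde.covariance) / 2.0))
    converged = _mean_shift(pts, inv_cov)
    # Register modes scanning converged points in lexicographic coordinate
    # order so the clustering is independent of input ordering.
    scan = sorted(range(len(ids)), key=lambda i: (converged[i, 0], converged[i, 1]))
    mode_list: list[np.ndarray] = []
    assign = np.empty(len(ids), dtype=int)
    for i in scan:
        for m, mode in enumerate(mode_list):
            if np.linalg.norm(converged[i] - mode) < bandwidth:
                assign[i] = m
                break
        else:
            mode_list.append(converged[i])
            assign[i] = len(mode_list) - 1
    n_modes = len(mode_list)
    if n_modes < 2:
        return fallback()
    mode_diff = [diff[assign == m].mean() for m in range(n_modes)]
    mitf_mode = int(np.argmax(mode_diff))
    axl_mode = int(np.argmin(mode_diff))
    labels = np.full(len(ids), "INTERMEDIATE", dtype=object)
    labels[assign == mitf_mode] = "MITF"
    labels[assign == axl_mode] = "AXL"
    return StateClustering(
        pd.Series(labels, index=ids, name="state"),
        np.array(mode_list),
        pd.Series(assign, index=ids),
        False,
    )
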