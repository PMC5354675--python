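"""Mutation-spectrum tabulation and UV-signature classification.

UV-induced DNA damage produces C>T transitions at dipyrimidine sites
(a mutated pyrimidine flanked by at least one other pyrimidine). Substitutions
are collapsed onto the pyrimidine strand (G>A on the reference strand is the
same lesion as C>T on the opposite strand), tabulated into the six collapsed
substitution classes split by dipyrimidine context, and a sample is called
UV-signature positive when the fraction of its SNVs that are C>T at a
dipyrimidine exceeds 0.6 (strictly).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import MutationRecord, PYRIMIDINES

__all__ = [
    "Context",
    "SUBSTITUTION_CLASSES",
    "UVCall",
    "normalize_substitution",
    "mutation_spectrum",
    "uv_signature_call",
    "uv_signature_calls",
    "compare_alteration_frequencies",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class Context(str, Enum):
    DIPYRIMIDINE = "DIPYRIMIDINE"
    NON_DIPYRIMIDINE = "NON_DIPYRIMIDINE"


def normalize_substitution(record: MutationRecord) -> tuple[str, Context]:
    """Collapse a record onto the pyrimidine strand and classify its context.

    Purine-reference records are reverse-complemented (ref/alt complemented,
    5'/3' neighbours swapped and complemented) so the reference base is C or
    T. The context is DIPYRIMIDINE iff at least one flanking base is a
    pyrimidine after collapse.
    """
    ref, alt = record.ref, record.alt
    five, three = record.five_prime, record.three_prime
    if ref not in PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    context = (
        Context.DIPYRIMIDINE
        if five in PYRIMIDINES or three in PYRIMIDINES
        else Context.NON_DIPYRIMIDINE
    )
    return f"{ref}>{alt}", context


_CELLS = [(c, ctx) for c in SUBSTITUTION_CLASSES for ctx in Context]
_CELL_NAMES = [f"{c}|{ctx.value}" for c, ctx in _CELLS]


def _per_sample_percentages(records: Iterable[MutationRecord]) -> pd.DataFrame:
    counts: dict[str, np.ndarray] = {}
    index = {cell: i for i, cell in enumerate(_CELL_NAMES)}
    for rec in records:
        cls, ctx = normalize_substitution(rec)
        row = counts.setdefault(rec.sample, np.zeros(len(_CELL_NAMES)))
        row[index[f"{cls}|{ctx.value}"]] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", columns=_CELL_NAMES)
    df.index.name = "sample"
    return df


def mutation_spectrum(
    records: Iterable[MutationRecord], group_map: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate the substitution spectrum per sample and per group.

    Returns ``(per_sample, per_group)``: per-sample percentages of that
    sample's SNVs in each of the 12 class x context cells (rows sum to 100),
    and per-group mean percentage and standard error of the mean across the
    group's samples. Samples in ``group_map`` without any SNVs are excluded
    from group means with a warning.
    """
    counts = _per_sample_percentages(records)
    unmapped = counts.index.difference(pd.Index(group_map.keys()))
    if len(unmapped):
        raise ValueError(f"samples without a group: {list(unmapped)[:5]}")
    empty = pd.Index(group_map.keys()).difference(counts.index)
    if len(empty):
        warnings.warn(f"excluding {len(empty)} sample(s) with 0 SNVs from group means")
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    rows = []
    groups = pd.Series({s: group_map[s] for s in pct.index})
    for group in sorted(groups.unique()):
        sub = pct.loc[groups[groups == group].index]
        mean = sub.mean(axis=0)
        sem = sub.std(axis=0, ddof=1) / np.sqrt(len(sub)) if len(sub) > 1 else mean * np.nan
        for cell in _CELL_NAMES:
            cls, ctx = cell.split("|")
            rows.append(
                {
                    "group": group,
                    "substitution": cls,
                    "context": ctx,
                    "mean_pct": float(mean[cell]),
                    "sem_pct": float(sem[cell]) if len(sub) > 1 else np.nan,
                    "n_samples": len(sub),
                }
            )
    return pct, pd.DataFrame(rows)


@dataclass(frozen=True)
class UVCall:
    sample: str
    n_snvs: int
    f_uv: float  # fraction of SNVs that are C>T at a dipyrimidine
    uv_positive: bool

    def __post_init__(self) -> None:
        if not 0 <= self.f_uv <= 1:
            raise ValueError("f_uv must lie in [0, 1]")
        if self.uv_positive != (self.f_uv > 0.6):
            raise ValueError("uv_positive inconsistent with f_uv > 0.6")


def uv_signature_call(records: Iterable[MutationRecord], sample: str | None = None) -> UVCall:
    """UV-signature call for one sample's SNV catalog (f_uv > 0.6, strict)."""
    records = list(records)
    if sample is not None:
        records = [r for r in records if r.sample == sample]
    if not records:
        raise ValueError("no SNVs; UV call undefined")
    samples = {r.sample for r in records}
    if len(samples) > 1:
        raise ValueError("records span multiple samples; use uv_signature_calls")
    qualifying = sum(
        1
        for r in records
        if normalize_substitution(r) == ("C>T", Context.DIPYRIMIDINE)
    )
    f_uv = qualifying / len(records)
    return UVCall(samples.pop(), len(records), f_uv, f_uv > 0.6)


def uv_signature_calls(records: Iterable[MutationRecord]) -> list[UVCall]:
    """Per-sample UV-signature calls, sorted by sample id."""
    by_sample: dict[str, list[MutationRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample, []).append(rec)
    return [uv_signature_call(recs) for _, recs in sorted(by_sample.items())]


def compare_alteration_frequencies(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p for k alteration hits in n cell lines vs a
    tumour rate p0 (two-sided by summing all outcomes at most as probable as
    the observed one)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
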