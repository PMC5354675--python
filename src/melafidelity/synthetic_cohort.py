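"""Seeded generators for synthetic expression cohorts, single cells,
mutation catalogs and survival tables.

The generator encodes the admixture model the analysis assumes: a tumour
transcriptome is a convex mixture of a malignant archetype with immune and
stromal contamination at variable purity, while a cell line is a pure (but
noisy) malignant archetype. Single malignant cells are drawn from two
antagonistic transcriptional archetypes (MITF-high vs AXL-high). Mutation
catalogs have a tunable fraction of C>T-at-dipyrimidine events (the UV
lesion class), and survival times follow an exponential model whose
log-hazard is linear in a standardized immune score.

Every generator is fully deterministic under a fixed seed; each operation
derives an independent random stream from ``CohortParams.seed`` so adding a
call to one generator never perturbs another.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import (
    ExpressionMatrix,
    MutationRecord,
    SampleClass,
    ScoreTable,
    SurvivalRecord,
    Unit,
)

__all__ = [
    "CohortParams",
    "simulate_expression_cohort",
    "simulate_single_cells",
    "simulate_state_cell_lines",
    "simulate_graded_cell_lines",
    "simulate_mutation_catalog",
    "simulate_survival",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale melanoma-like cohort: 2,000 genes with a
    100-gene immune block and a 40-gene stromal block (mirroring the strong
    immune/weak stromal asymmetry of tumour contamination), 120 tumours at
    purity 0.3-0.7, 30 cell lines, 200 single cells split between two
    transcriptional archetypes, UV-positive samples with 75% C>T-at-
    dipyrimidine mutations vs 30% for UV-negative ones, and a two-fold
    hazard ratio tied to the immune score.

    ``noise_sd`` is the standard deviation (log2 units) of multiplicative
    log-normal expression noise. ``block_shift`` is the log2 elevation of
    immune/stromal block genes in their contaminating archetype;
    ``program_shift`` the log2 elevation of MITF/AXL program genes in their
    single-cell archetype.
    """

    n_genes: int = 2000
    n_tumours: int = 120
    n_cell_lines: int = 30
    n_single_cells: int = 200
    n_immune_genes: int = 100
    n_stromal_genes: int = 40
    n_mitf_program: int = 50
    n_axl_program: int = 50
    purity_range: tuple[float, float] = (0.3, 0.7)
    noise_sd: float = 0.3
    uv_fraction_pos: float = 0.75
    uv_fraction_neg: float = 0.30
    mutations_per_sample: int = 100
    survival_hazard_ratio: float = 2.0
    program_shift: float = 2.0
    block_shift: float = 2.5
    background_log2_mean: float = 5.0
    background_log2_sd: float = 2.0
    block_floor_tpm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes,
            self.n_tumours,
            self.n_cell_lines,
            self.n_single_cells,
            self.n_immune_genes,
            self.n_stromal_genes,
            self.n_mitf_program,
            self.n_axl_program,
            self.mutations_per_sample,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("purity_range must be an interval within [0, 1]")
        for f in (self.uv_fraction_pos, self.uv_fraction_neg):
            if not 0 <= f <= 1:
                raise ValueError("uv fractions must lie in [0, 1]")
        n_special = (
            self.n_immune_genes + self.n_stromal_genes + self.n_mitf_program + self.n_axl_program
        )
        if n_special > self.n_genes:
            raise ValueError("gene blocks and programs exceed n_genes")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible random stream per generator operation."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


# Stream ids, one per generator operation.
_STREAM_BLUEPRINT = 0
_STREAM_COHORT = 1
_STREAM_CELLS = 2
_STREAM_MUTATIONS = 3
_STREAM_GRADED = 4
_STREAM_STATE_LINES = 5


@dataclass(frozen=True)
class _Blueprint:
    """Shared gene universe and archetype TPM profiles (each sums to 10^6)."""

    genes: pd.Index
    gene_labels: pd.Series  # IMMUNE / STROMAL / MITF_PROGRAM / AXL_PROGRAM / BACKGROUND
    malignant: np.ndarray
    immune: np.ndarray
    stromal: np.ndarray
    mitf: np.ndarray
    axl: np.ndarray


def _normalize(profile: np.ndarray, total: float = 1e6) -> np.ndarray:
    return profile / profile.sum() * total


def _blueprint(params: CohortParams) -> _Blueprint:
    rng = params.rng(_STREAM_BLUEPRINT)
    n = params.n_genes
    names = []
    labels = []
    blocks = (
        ("IMM", "IMMUNE", params.n_immune_genes),
        ("STR", "STROMAL", params.n_stromal_genes),
        ("MITFP", "MITF_PROGRAM", params.n_mitf_program),
        ("AXLP", "AXL_PROGRAM", params.n_axl_program),
    )
    for prefix, label, count in blocks:
        names += [f"{prefix}{i:04d}" for i in range(count)]
        labels += [label] * count
    n_bg = n - len(names)
    names += [f"BG{i:05d}" for i in range(n_bg)]
    labels += ["BACKGROUND"] * n_bg
    genes = pd.Index(names, name="gene")
    gene_labels = pd.Series(labels, index=genes, name="label")

    base = 2.0 ** rng.normal(params.background_log2_mean, params.background_log2_sd, size=n)
    imm = gene_labels.to_numpy() == "IMMUNE"
    stro = gene_labels.to_numpy() == "STROMAL"
    mitf = gene_labels.to_numpy() == "MITF_PROGRAM"
    axl = gene_labels.to_numpy() == "AXL_PROGRAM"

    shift = 2.0**params.block_shift
    floor = params.block_floor_tpm
    malignant = base.copy()
    malignant[imm | stro] = floor  # microenvironment transcripts absent in pure tumour cells
    immune_prof = malignant.copy()
    immune_prof[imm] = base[imm] * shift
    stromal_prof = malignant.copy()
    stromal_prof[stro] = base[stro] * shift
    pshift = 2.0**params.program_shift
    mitf_prof = malignant.copy()
    mitf_prof[mitf] = base[mitf] * pshift
    axl_prof = malignant.copy()
    axl_prof[axl] = base[axl] * pshift
    return _Blueprint(
        genes=genes,
        gene_labels=gene_labels,
        malignant=_normalize(malignant),
        immune=_normalize(immune_prof),
        stromal=_normalize(stromal_prof),
        mitf=_normalize(mitf_prof),
        axl=_normalize(axl_prof),
    )


def _noisy_tpm(
    profiles: np.ndarray, rng: np.random.Generator, noise_sd: float, total: float = 1e6
) -> np.ndarray:
    """Apply multiplicative log-normal noise, then re-normalize columns."""
    noisy = profiles * 2.0 ** rng.normal(0.0, noise_sd, size=profiles.shape)
    return noisy / noisy.sum(axis=0, keepdims=True) * total


def simulate_expression_cohort(params: CohortParams) -> tuple[
    ExpressionMatrix, ExpressionMatrix, ScoreTable, ScoreTable, dict
]:
    """Simulate tumours (malignant + admixture) and pure cell lines.

    Tumour TPM = purity x malignant + (1 - purity) x [w x immune +
    (1 - w) x stromal] with log-normal noise and re-normalization; the
    immune share ``w`` of the contamination is drawn once per cohort from
    U(0.5, 0.9), making immune contamination dominate. Immune/stromal score
    tables are the mean log2(TPM+1) of the true immune/stromal gene blocks
    per tumour — a purity-surrogate standing in for expression-based
    admixture scores, monotone in the respective cell fraction by
    construction.

    Returns (tumours, cell_lines, immune_scores, stromal_scores, truth)
    where ``truth`` carries gene labels, per-tumour purity and the immune
    mixture weight.
    """
    bp = _blueprint(params)
    rng = params.rng(_STREAM_COHORT)
    lo, hi = params.purity_range
    purity = rng.uniform(lo, hi, size=params.n_tumours)
    w = float(rng.uniform(0.5, 0.9))

    contamination = w * bp.immune + (1.0 - w) * bp.stromal
    tumour_profiles = np.outer(bp.malignant, purity) + np.outer(contamination, 1.0 - purity)
    tumour_tpm = _noisy_tpm(tumour_profiles, rng, params.noise_sd)
    line_profiles = np.tile(bp.malignant[:, None], (1, params.n_cell_lines))
    line_tpm = _noisy_tpm(line_profiles, rng, params.noise_sd)

    tumour_ids = pd.Index([f"T{i:04d}" for i in range(params.n_tumours)])
    line_ids = pd.Index([f"CL{i:03d}" for i in range(params.n_cell_lines)])
    tumours = ExpressionMatrix(
        pd.DataFrame(tumour_tpm, index=bp.genes, columns=tumour_ids),
        Unit.TPM,
        pd.Series(SampleClass.TUMOUR, index=tumour_ids),
    )
    cell_lines = ExpressionMatrix(
        pd.DataFrame(line_tpm, index=bp.genes, columns=line_ids),
        Unit.TPM,
        pd.Series(SampleClass.CELL_LINE, index=line_ids),
    )
    log_t = np.log2(tumour_tpm + 1.0)
    imm_mask = (bp.gene_labels == "IMMUNE").to_numpy()
    str_mask = (bp.gene_labels == "STROMAL").to_numpy()
    immune_scores = ScoreTable(
        "ImmuneScore", pd.Series(log_t[imm_mask].mean(axis=0), index=tumour_ids)
    )
    stromal_scores = ScoreTable(
        "StromalScore", pd.Series(log_t[str_mask].mean(axis=0), index=tumour_ids)
    )
    truth = {
        "gene_labels": bp.gene_labels,
        "purity": pd.Series(purity, index=tumour_ids, name="purity"),
        "immune_weight": w,
    }
    return tumours, cell_lines, immune_scores, stromal_scores, truth


def simulate_single_cells(params: CohortParams) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate single malignant cells from MITF-high or AXL-high archetypes.

    Each cell's archetype is drawn with probability 0.5; program genes are
    elevated by ``program_shift`` log2 units in their archetype. Cells are
    emitted at a x10 TPM scale (columns sum to ~10^7) so the single-cell
    branch of :func:`melafidelity.harmonize.to_log_tpm` is exercised.
    """
    bp = _blueprint(params)
    rng = params.rng(_STREAM_CELLS)
    states = np.where(rng.random(params.n_single_cells) < 0.5, "MITF", "AXL")
    profiles = np.where(states == "MITF", 1, 0) * bp.mitf[:, None] + np.where(
        states == "AXL", 1, 0
    ) * bp.axl[:, None]
    tpm = profiles * 10.0 * 2.0 ** rng.normal(0.0, params.noise_sd, size=profiles.shape)
    ids = pd.Index([f"SC{i:04d}" for i in range(params.n_single_cells)])
    cells = ExpressionMatrix(
        pd.DataFrame(tpm, index=bp.genes, columns=ids),
        Unit.TPM,
        pd.Series(SampleClass.SINGLE_CELL, index=ids),
    )
    return cells, pd.Series(states, index=ids, name="archetype")


def simulate_state_cell_lines(
    params: CohortParams, n_lines: int, state: str
) -> tuple[ExpressionMatrix, pd.Series]:
    """Cell lines drawn from one transcriptional archetype (MITF or AXL)."""
    if state not in ("MITF", "AXL"):
        raise ValueError("state must be 'MITF' or 'AXL'")
    bp = _blueprint(params)
    rng = params.rng(_STREAM_STATE_LINES)
    archetype = bp.mitf if state == "MITF" else bp.axl
    profiles = np.tile(archetype[:, None], (1, n_lines))
    tpm = _noisy_tpm(profiles, rng, params.noise_sd)
    ids = pd.Index([f"{state}L{i:03d}" for i in range(n_lines)])
    lines = ExpressionMatrix(
        pd.DataFrame(tpm, index=bp.genes, columns=ids),
        Unit.TPM,
        pd.Series(SampleClass.CELL_LINE, index=ids),
    )
    return lines, pd.Series(state, index=ids, name="archetype")


def simulate_graded_cell_lines(
    params: CohortParams, n_lines: int = 20, max_alpha: float = 0.9
) -> tuple[ExpressionMatrix, pd.Series]:
    """Cell lines at graded transcriptional distances from the malignant archetype.

    Line ``i`` mixes the malignant log-profile with an unrelated decoy
    log-profile at weight ``alpha_i`` (evenly spaced in [0, max_alpha]), then
    adds log-normal noise. The returned truth series holds ``alpha`` — larger
    alpha means a worse tumour model, so correlation-based fidelity rankings
    should decrease in alpha.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines for a graded panel")
    bp = _blueprint(params)
    rng = params.rng(_STREAM_GRADED)
    decoy = 2.0 ** rng.normal(
        params.background_log2_mean, params.background_log2_sd, size=params.n_genes
    )
    decoy = _normalize(decoy)
    alphas = np.linspace(0.0, max_alpha, n_lines)
    log_mal = np.log2(bp.malignant + 1.0)
    log_dec = np.log2(decoy + 1.0)
    log_mix = np.outer(log_mal, 1.0 - alphas) + np.outer(log_dec, alphas)
    profiles = 2.0**log_mix - 1.0
    profiles = np.clip(profiles, 0.0, None)
    tpm = _noisy_tpm(profiles, rng, params.noise_sd)
    ids = pd.Index([f"GL{i:03d}" for i in range(n_lines)])
    lines = ExpressionMatrix(
        pd.DataFrame(tpm, index=bp.genes, columns=ids),
        Unit.TPM,
        pd.Series(SampleClass.CELL_LINE, index=ids),
    )
    return lines, pd.Series(alphas, index=ids, name="alpha")


# Pyrimidine-collapsed substitution classes x contexts used when drawing
# non-UV events: every cell except (C>T, dipyrimidine).
_NON_UV_CELLS = [
    (ref, alt, dipy)
    for ref in "CT"
    for alt in "ACGT"
    if alt != ref
    for dipy in (True, False)
    if not (ref == "C" and alt == "T" and dipy)
]


def _draw_record(
    rng: np.random.Generator, sample: str, ref: str, alt: str, dipyrimidine: bool
) -> MutationRecord:
    if dipyrimidine:
        five = "CT"[rng.integers(2)]
        three = "ACGT"[rng.integers(4)]
    else:
        five = "AG"[rng.integers(2)]
        three = "AG"[rng.integers(2)]
    if rng.random() < 0.5:  # emit on the opposite strand to exercise collapse
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return MutationRecord(sample, ref, alt, five, three)


def simulate_mutation_catalog(
    params: CohortParams,
    n_samples: int | None = None,
    positive_labels: Mapping[str, bool] | Sequence[bool] | None = None,
) -> tuple[list[MutationRecord], pd.Series]:
    """Simulate per-sample SNV catalogs with a tunable UV lesion fraction.

    For a UV-positive sample each SNV is a C>T at a dipyrimidine site with
    probability ``uv_fraction_pos`` (otherwise drawn uniformly from the 11
    remaining substitution-class x context cells); UV-negative samples use
    ``uv_fraction_neg``. Records are emitted on a random strand, so purine-
    reference rows appear and downstream strand collapse is exercised.
    """
    rng = params.rng(_STREAM_MUTATIONS)
    if n_samples is None:
        n_samples = params.n_cell_lines
    ids = [f"S{i:04d}" for i in range(n_samples)]
    if positive_labels is None:
        labels = pd.Series([i < n_samples // 2 for i in range(n_samples)], index=ids)
    elif isinstance(positive_labels, Mapping):
        ids = list(positive_labels)
        labels = pd.Series({s: bool(v) for s, v in positive_labels.items()})
    else:
        labels = pd.Series([bool(v) for v in positive_labels], index=ids)
    labels.name = "uv_positive"
    records: list[MutationRecord] = []
    for sample in labels.index:
        f_uv = params.uv_fraction_pos if labels[sample] else params.uv_fraction_neg
        for _ in range(params.mutations_per_sample):
            if rng.random() < f_uv:
                records.append(_draw_record(rng, sample, "C", "T", True))
            else:
                ref, alt, dipy = _NON_UV_CELLS[rng.integers(len(_NON_UV_CELLS))]
                records.append(_draw_record(rng, sample, ref, alt, dipy))
    return records, labels


def simulate_survival(
    immune_values: ScoreTable,
    hazard_ratio: float,
    censor_time: float = 120.0,
    seed: int = 0,
    baseline_median: float = 60.0,
) -> list[SurvivalRecord]:
    """Exponential survival with log-hazard linear in the standardized score.

    The slope is scaled so that the above-median and below-median score
    groups differ in mean log-hazard by log(hazard_ratio); events after
    ``censor_time`` months are administratively censored. ``baseline_median``
    sets the median survival (months) of a sample at the cohort-average
    score.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    v = immune_values.values
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    z = (v - v.mean()) / sd if sd > 0 else pd.Series(0.0, index=v.index)
    median = v.median()
    hi, lo = z[v > median], z[v <= median]
    spread = hi.mean() - lo.mean() if len(hi) and len(lo) else 0.0
    beta = math.log(hazard_ratio) / spread if spread > 0 else 0.0
    lam = math.log(2.0) / baseline_median * np.exp(beta * z.to_numpy())
    times = rng.exponential(1.0 / lam)
    records = []
    for sample, t in zip(v.index, times):
        observed = t <= censor_time
        records.append(
            SurvivalRecord(str(sample), float(min(t, censor_time)), bool(observed))
        )
    return records
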