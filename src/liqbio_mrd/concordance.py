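"""PET/CT vs liquid-biopsy MRD concordance and cohort statistics.

PET/CT metabolic response is graded on the 5-point Deauville scale; scores
1-3 define the negative (complete-response) group and 4-5 the positive
group (partial metabolic response and progression both map to positive).
Both imaging and the molecular assay are compared against an adjudicated
clinical truth (later imaging / clinical follow-up, supplied as input) to
produce per-method confusion matrices, and against each other for
between-method concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NEGATIVE_DEAUVILLE = frozenset({1, 2, 3})
POSITIVE_DEAUVILLE = frozenset({4, 5})
CFDNA_CUTOFF_NG_ML = 5.0


@dataclass(frozen=True)
class ResponseRecord:
    """One patient-time-point response assessment with adjudicated truth."""

    patient_id: str
    timepoint: str
    deauville: int
    fdg_trend: str = "n/a"  # reduced | increased | n/a
    liqbio_positive: bool | None = None
    clinical_truth: str | None = None  # disease | no_disease

    @property
    def petct_group(self) -> str:
        return classify_petct(self.deauville, self.fdg_trend)


@dataclass(frozen=True)
class MethodConfusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionSummary:
    petct: MethodConfusion
    liqbio: MethodConfusion
    agree: int
    total: int
    n_excluded: int = 0

    @property
    def concordance(self) -> float:
        return self.agree / self.total if self.total else float("nan")


def classify_petct(deauville: int, fdg_trend: str = "n/a") -> str:
    """Map a Deauville score to the PET/CT response group.

    Scores 1-3 (complete response) are negative; 4-5 are positive whether
    the FDG intensity is reduced (partial metabolic response) or increased
    (progressive disease).
    """
    if deauville not in (1, 2, 3, 4, 5):
        raise ValueError(f"Deauville score must be 1..5, got {deauville}")
    return "negative" if deauville in NEGATIVE_DEAUVILLE else "positive"


def build_confusion(records: Iterable[ResponseRecord]) -> ConfusionSummary:
    """Per-method confusion matrices vs clinical truth plus between-method concordance.

    Records missing the adjudicated truth or the molecular result are
    excluded (with a logged count).  Concordance compares the PET/CT group
    (as a boolean) with molecular positivity, over all retained records.
    """
    kept: list[ResponseRecord] = []
    n_excluded = 0
    for rec in records:
        if rec.clinical_truth is None or rec.liqbio_positive is None:
            n_excluded += 1
            continue
        kept.append(rec)
    if n_excluded:
        logger.warning("excluded %d records lacking adjudicated truth or MRD result", n_excluded)

    def confusion(predicted: list[bool]) -> MethodConfusion:
        truth = [r.clinical_truth == "disease" for r in kept]
        tp = sum(p and t for p, t in zip(predicted, truth))
        fp = sum(p and not t for p, t in zip(predicted, truth))
        tn = sum(not p and not t for p, t in zip(predicted, truth))
        fn = sum(not p and t for p, t in zip(predicted, truth))
        return MethodConfusion(tp, fp, tn, fn)

    pet_pos = [r.petct_group == "positive" for r in kept]
    liq_pos = [bool(r.liqbio_positive) for r in kept]
    agree = sum(p == l for p, l in zip(pet_pos, liq_pos))
    return ConfusionSummary(
        petct=confusion(pet_pos),
        liqbio=confusion(liq_pos),
        agree=agree,
        total=len(kept),
        n_excluded=n_excluded,
    )


def compare_mrd_by_pet_group(
    negative_group: Sequence[float],
    positive_group: Sequence[float],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on MRD values between PET/CT groups.

    Returns (U, p) where U is the statistic for the PET-negative group.
    Ties receive average ranks; the exact distribution is used for small
    tie-free samples and the normal approximation otherwise (scipy's
    automatic policy).
    """
    x = np.asarray(negative_group, dtype=float)
    y = np.asarray(positive_group, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both PET/CT groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def dichotomize_cfdna(cfdna_ngml: Sequence[float], cutoff: float = CFDNA_CUTOFF_NG_ML) -> list[str]:
    """Split cfDNA concentrations at the cutoff; values == cutoff go to "low"."""
    return ["high" if v > cutoff else "low" for v in cfdna_ngml]


def contingency_chi2(table) -> tuple[float, float]:
    """Chi-square of independence on a ready-made contingency table.

    Yates' continuity correction is applied for 2x2 tables and omitted for
    larger tables.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=arr.shape == (2, 2))
    return float(chi2), float(p)


def cfdna_clinical_association(
    cfdna_ngml: Sequence[float],
    category: Sequence,
    cutoff: float = CFDNA_CUTOFF_NG_ML,
) -> tuple[float, float, pd.DataFrame]:
    """Chi-square independence test: dichotomized cfDNA level vs a clinical factor.

    cfDNA is split at ``cutoff`` ng/mL (strictly greater = "high").  For a
    2x2 table Yates' continuity correction is applied; for 2xK (K > 2) the
    uncorrected statistic is used.

    Returns (chi2, p, contingency table).
    """
    levels = dichotomize_cfdna(cfdna_ngml, cutoff)
    table = pd.crosstab(pd.Series(levels, name="cfdna"), pd.Series(list(category), name="factor"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table has an empty margin: need >= 2 levels per factor")
    chi2, p = contingency_chi2(table.to_numpy())
    return float(chi2), float(p), table
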