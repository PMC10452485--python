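"""Baseline genotyping: FFPE artifact filtering, biomarker selection, paired merging.

Formalin fixation deaminates cytosine, producing artifactual low-frequency
C>T (and G>A on the opposite strand) calls in FFPE tissue variant tables.
The filter implemented here removes exactly those calls whose allele
frequency falls below a threshold (default 20%) and whose caller-reported
transformed p-value exceeds a significance cutoff (default -2), unless the
change is a catalogued somatic aberration in lymphoma (COSMIC), in which
case it is rescued.  Plasma cfDNA is not formalin-exposed, so the filter
refuses plasma-compartment input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: substitution pairs attributable to cytosine deamination on either strand
DEAMINATION_CHANGES = {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class VariantCall:
    """One somatic mutation observation in one compartment.

    ``pvalue_transformed`` is the caller-supplied signed transformed
    significance score (more negative = more significant) and is consumed
    as-is; ``in_cosmic`` / ``described_in_lymphoma`` are input annotation
    flags, not live database queries.
    """

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    compartment: str  # "tissue" | "plasma"
    pvalue_transformed: float = -10.0
    in_cosmic: bool = False
    described_in_lymphoma: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.compartment not in ("tissue", "plasma"):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized identity used for paired-genotype merging."""
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class BiomarkerPanel:
    """Per-patient MRD tracking panel: selected mutations plus ±15 bp contexts."""

    patient_id: str
    mutations: tuple = ()  # tuple of (VariantCall, context | None)
    source: str = "both"

    @property
    def applicable(self) -> bool:
        return len(self.mutations) > 0


@dataclass(frozen=True)
class MergeSummary:
    n_both: int
    n_tissue_only: int
    n_plasma_only: int

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_tissue_only + self.n_plasma_only


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Left-align and trim an allele pair to a canonical (chrom, pos, ref, alt).

    Shared suffix bases are trimmed first, then shared prefix bases (advancing
    ``pos``), keeping at least one base on each allele.  SNVs pass through
    unchanged.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def _is_deamination_change(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in DEAMINATION_CHANGES


class FFPEArtifactFilter(BaseEstimator, TransformerMixin):
    """Deamination-artifact filter for FFPE tissue variant tables.

    A variant is removed iff it is a C>T or G>A change AND its allele
    frequency is strictly below ``vaf_max`` AND its transformed p-value is
    strictly above ``pvalue_min`` AND it is not rescued by the COSMIC flag.
    Boundary values (vaf == vaf_max, p == pvalue_min) are retained.

    The transformer is stateless (``fit`` is a no-op) and idempotent; it
    preserves input order.

    Parameters
    ----------
    vaf_max : float, default 0.20
        Allele-frequency ceiling below which a deamination change is suspect.
    pvalue_min : float, default -2.0
        Transformed p-value floor above which a deamination change is suspect.
    """

    def __init__(self, vaf_max: float = 0.20, pvalue_min: float = -2.0):
        self.vaf_max = vaf_max
        self.pvalue_min = pvalue_min

    def fit(self, X, y=None):  # noqa: D102 - stateless
        self.n_features_in_ = 0
        return self

    def _is_artifact(self, ref: str, alt: str, vaf: float, pvalue: float, in_cosmic: bool) -> bool:
        return (
            _is_deamination_change(ref, alt)
            and vaf < self.vaf_max
            and pvalue > self.pvalue_min
            and not in_cosmic
        )

    def transform(self, X):
        """Filter a list of :class:`VariantCall` or an equivalent DataFrame.

        Raises
        ------
        ValueError
            If any input variant is plasma-compartment (the filter is
            FFPE-tissue-specific).
        """
        if isinstance(X, pd.DataFrame):
            if "compartment" in X.columns and (X["compartment"] == "plasma").any():
                raise ValueError("FFPE deamination filter applies to tissue samples only")
            keep = ~X.apply(
                lambda row: self._is_artifact(
                    row["ref"], row["alt"], row["vaf"],
                    row["pvalue_transformed"], bool(row["in_cosmic"]),
                ),
                axis=1,
            )
            return X.loc[keep]
        variants = list(X)
        for v in variants:
            if v.compartment == "plasma":
                raise ValueError("FFPE deamination filter applies to tissue samples only")
        return [
            v for v in variants
            if not self._is_artifact(v.ref, v.alt, v.vaf, v.pvalue_transformed, v.in_cosmic)
        ]


def filter_ffpe_artifacts(
    variants: Sequence[VariantCall],
    vaf_max: float = 0.20,
    pvalue_min: float = -2.0,
) -> list[VariantCall]:
    """Remove FFPE deamination artifacts; see :class:`FFPEArtifactFilter`."""
    return FFPEArtifactFilter(vaf_max=vaf_max, pvalue_min=pvalue_min).fit(None).transform(variants)


def select_mrd_biomarkers(
    variants: Sequence[VariantCall],
    contexts: dict | None = None,
) -> BiomarkerPanel:
    """Select MRD tracking biomarkers from artifact-filtered variants.

    Only somatic mutations previously described in lymphoma or similar
    cancers (the ``described_in_lymphoma`` annotation flag) qualify.  An
    empty panel marks the patient as not MRD-applicable.

    Parameters
    ----------
    variants
        Artifact-filtered calls for one patient (any compartment mix).
    contexts
        Optional mapping from variant key to a flanking-context pair; attached
        to panel entries when present.
    """
    variants = list(variants)
    if not variants:
        return BiomarkerPanel(patient_id="", mutations=(), source="both")
    patient_ids = {v.patient_id for v in variants}
    if len(patient_ids) > 1:
        raise ValueError(f"panel selection expects one patient, got {sorted(patient_ids)}")
    selected = [v for v in variants if v.described_in_lymphoma]
    compartments = {v.compartment for v in selected}
    source = compartments.pop() if len(compartments) == 1 else "both"
    mutations = tuple(
        (v, contexts.get(v.key) if contexts else None) for v in selected
    )
    return BiomarkerPanel(patient_id=variants[0].patient_id, mutations=mutations, source=source)


def merge_paired_genotypes(
    tissue: Sequence[VariantCall],
    plasma: Sequence[VariantCall],
) -> tuple[MergeSummary, list[tuple[VariantCall, str]]]:
    """Merge one patient's tissue and plasma variant calls with source accounting.

    Variants are keyed by normalized (chrom, pos, ref, alt).  Each union
    member is labelled ``both`` / ``tissue_only`` / ``plasma_only``; the
    summary counts satisfy n_total = n_both + n_tissue_only + n_plasma_only.

    Returns
    -------
    (MergeSummary, list of (VariantCall, label))
        The annotated union keeps tissue-call objects for shared variants
        (tissue is the genotyping gold standard) ordered tissue-first.
    """
    tissue, plasma = list(tissue), list(plasma)
    pids = {v.patient_id for v in tissue} | {v.patient_id for v in plasma}
    if len(pids) > 1:
        raise ValueError(f"merge requires a single patient, got {sorted(pids)}")
    tissue_keys = {v.key: v for v in tissue}
    plasma_keys = {v.key: v for v in plasma}
    union: list[tuple[VariantCall, str]] = []
    n_both = n_tissue = n_plasma = 0
    for key in sorted(set(tissue_keys) | set(plasma_keys), key=lambda k: (k[0], k[1], k[2], k[3])):
        if key in tissue_keys and key in plasma_keys:
            union.append((tissue_keys[key], "both"))
            n_both += 1
        elif key in tissue_keys:
            union.append((tissue_keys[key], "tissue_only"))
            n_tissue += 1
        else:
            union.append((plasma_keys[key], "plasma_only"))
            n_plasma += 1
    return MergeSummary(n_both, n_tissue, n_plasma), union


def vaf_correlation(paired: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """Pearson correlation between paired tissue and plasma allele frequencies.

    Returns (r, two-sided p) via the standard t-approximation.  Requires at
    least 3 pairs and non-degenerate variance in both coordinates.
    """
    pairs = np.asarray(list(paired), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("Pearson correlation requires at least 3 (tissue, plasma) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in one coordinate")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
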