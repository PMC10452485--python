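"""Ultrasensitive triplicate-based MRD calling with healthy-control calibration.

Each tracked mutation is amplified in three biological replicates at very
high depth (targeting 500,000x per amplicon).  Per replicate, the MRD ratio
is mutant / (mutant + wild-type) matched reads.  PCR/sequencing noise is
controlled by discarding replicate ratios strictly above the triplicate
mean plus one standard deviation; the corrected mean of the retained
replicates is then compared against per-mutation detection limits derived
from healthy-donor replicates:

    LOD = mean(control ratios) + 3 * SD,   LOQ = mean + 10 * SD

A mutation below its LOD is eliminated; mutations whose own LOD exceeds
1e-4 are too noisy to contribute and are excluded from the patient-level
value.  The patient's MRD value at a time-point is the highest corrected
mean among eligible mutations; the assay's reporting sensitivity is 2e-4.

Sample standard deviations (n-1 denominator) are used throughout.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: replicate ratios above triplicate mean + ARTIFACT_SD_MULTIPLIER * SD are dropped
ARTIFACT_SD_MULTIPLIER = 1.0
LOD_MULTIPLIER = 3.0
LOQ_MULTIPLIER = 10.0
#: per-mutation LOD ceiling above which the mutation is excluded (too noisy)
LOD_CAP = 1e-4
#: assay-level reporting sensitivity
ASSAY_FLOOR = 2e-4


@dataclass(frozen=True)
class TriplicateMeasurement:
    """Read counts for one mutation at one time-point, three replicates."""

    mutation_id: str
    timepoint: str
    replicates: tuple  # exactly 3 of (mut_reads, wt_reads)

    def __post_init__(self) -> None:
        if len(self.replicates) != 3:
            raise ValueError(f"expected 3 replicates, got {len(self.replicates)}")
        for m, w in self.replicates:
            if m < 0 or w < 0:
                raise ValueError("read counts must be non-negative")
        if all(m + w == 0 for m, w in self.replicates):
            raise ValueError("all replicates empty: not a valid measurement")


@dataclass(frozen=True)
class ControlCalibration:
    """Per-mutation detection limits from healthy-donor background ratios."""

    mutation_id: str
    control_ratios: tuple
    lod: float
    loq: float


@dataclass(frozen=True)
class MutationMRD:
    mutation_id: str
    replicate_ratios: tuple
    retained_mask: tuple
    corrected_mean: float
    lod: float
    loq: float
    status: str  # below_LOD | detected | quantifiable
    lod_excluded: bool


@dataclass(frozen=True)
class MRDResult:
    """Patient-level MRD call at one time-point."""

    patient_id: str
    timepoint: str
    mutations: tuple  # of MutationMRD
    mrd_value: float
    positive: bool
    assay_floor: float = ASSAY_FLOOR

    @property
    def below_assay_floor(self) -> bool:
        """True when positive but beneath the assay's reporting sensitivity."""
        return self.positive and self.mrd_value < self.assay_floor


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _overlap_match(read: str, context: str) -> bool:
    # exact containment either way: amplicon reads may be shorter or longer
    # than the +/-15 bp context window
    return read in context or context in read


def match_reads(
    reads: Iterable[str],
    wt_context: str,
    mut_context: str,
) -> tuple[int, int, int]:
    """Assign amplicon reads to wild-type / mutant allele by exact context match.

    A read (or its reverse complement) counts for an allele when it matches
    that allele's ±15 bp context exactly over their overlap; a read matching
    neither or both contexts is unmatched.  No mismatch recovery is
    attempted: error-corrected amplicon reads are expected to be clean.

    Returns
    -------
    (mut_reads, wt_reads, unmatched) summing to the number of input reads.
    """
    wt_context, mut_context = wt_context.upper(), mut_context.upper()
    if wt_context == mut_context:
        raise ValueError("wild-type and mutant contexts are identical; alleles not distinguishable")
    n_mut = n_wt = n_un = 0
    for raw in reads:
        read = str(raw).upper()
        assigned = None
        # forward orientation first; reverse complement only as a fallback,
        # so a context pair that is its own reverse complement stays decidable
        for oriented in (read, reverse_complement(read)):
            hit_wt = _overlap_match(oriented, wt_context)
            hit_mut = _overlap_match(oriented, mut_context)
            if hit_mut and not hit_wt:
                assigned = "mut"
                break
            if hit_wt and not hit_mut:
                assigned = "wt"
                break
            if hit_wt and hit_mut:
                break  # ambiguous in this orientation -> unmatched
        if assigned == "mut":
            n_mut += 1
        elif assigned == "wt":
            n_wt += 1
        else:
            n_un += 1
    return n_mut, n_wt, n_un


def replicate_ratio(mut_reads: int, wt_reads: int) -> float:
    """Single-replicate MRD ratio: mutant / (mutant + wild-type)."""
    total = mut_reads + wt_reads
    if mut_reads < 0 or wt_reads < 0:
        raise ValueError("read counts must be non-negative")
    if total == 0:
        raise ValueError("replicate has zero matched reads: ratio undefined")
    return mut_reads / total


def correct_noise(
    ratios: Sequence[float],
    sd_multiplier: float = ARTIFACT_SD_MULTIPLIER,
) -> tuple[float, tuple[bool, bool, bool]]:
    """Remove artifact replicates strictly above mean + sd_multiplier * SD.

    Operates on exactly 3 replicate ratios (single pass, no re-iteration).
    The minimum ratio can never be removed (min <= mean <= mean + SD), so at
    least one replicate is always retained and the corrected mean never
    exceeds the raw mean.

    Returns
    -------
    (corrected_mean, retained_mask)
    """
    ratios = [float(r) for r in ratios]
    if len(ratios) != 3 or not all(np.isfinite(ratios)):
        raise ValueError("noise correction requires exactly 3 finite replicate ratios")
    m = sum(ratios) / 3
    s = math.sqrt(sum((r - m) ** 2 for r in ratios) / 2)  # sample SD, n-1
    threshold = m + sd_multiplier * s
    # the minimum is mathematically never above mean + SD; keep it explicitly
    # so float rounding at the boundary cannot empty the triplicate
    rmin = min(ratios)
    mask = tuple(r <= threshold or r == rmin for r in ratios)
    retained = [r for r, keep in zip(ratios, mask) if keep]
    return sum(retained) / len(retained), mask


def calibrate_lod_loq(
    control_ratios: Sequence[float],
    mutation_id: str = "",
    lod_multiplier: float = LOD_MULTIPLIER,
    loq_multiplier: float = LOQ_MULTIPLIER,
) -> ControlCalibration:
    """Compute per-mutation LOD/LOQ from healthy-control background ratios.

    The study design uses 9 control ratios (three triplicates of three
    healthy donors); any >= 2 ratios are accepted.
    """
    ratios = tuple(float(r) for r in control_ratios)
    if len(ratios) < 2:
        raise ValueError("calibration requires at least 2 control ratios")
    if any(r < 0 for r in ratios):
        raise ValueError("control ratios must be non-negative")
    m = statistics.fmean(ratios)
    s = statistics.stdev(ratios)
    return ControlCalibration(
        mutation_id=mutation_id,
        control_ratios=ratios,
        lod=m + lod_multiplier * s,
        loq=m + loq_multiplier * s,
    )


def call_mutation(
    corrected_mean: float,
    calib: ControlCalibration,
    replicate_ratios: Sequence[float] = (),
    retained_mask: Sequence[bool] = (),
    lod_cap: float = LOD_CAP,
) -> MutationMRD:
    """Classify one mutation's corrected mean ratio against its LOD/LOQ.

    below_LOD if corrected_mean < LOD (eliminated); quantifiable if
    corrected_mean >= LOQ; detected otherwise.  ``lod_excluded`` is set
    whenever the mutation's own LOD exceeds ``lod_cap`` — such noisy sites
    never contribute to the patient-level value regardless of their ratio.
    """
    if calib is None:
        raise ValueError("missing control calibration for mutation")
    if corrected_mean < calib.lod:
        status = "below_LOD"
    elif corrected_mean >= calib.loq:
        status = "quantifiable"
    else:
        status = "detected"
    return MutationMRD(
        mutation_id=calib.mutation_id,
        replicate_ratios=tuple(replicate_ratios),
        retained_mask=tuple(retained_mask),
        corrected_mean=float(corrected_mean),
        lod=calib.lod,
        loq=calib.loq,
        status=status,
        lod_excluded=calib.lod > lod_cap,
    )


def patient_mrd(
    calls: Sequence[MutationMRD],
    patient_id: str = "",
    timepoint: str = "",
    assay_floor: float = ASSAY_FLOOR,
) -> MRDResult:
    """Patient-level MRD value: the highest eligible corrected mean ratio.

    Eligible mutations are those not eliminated (status != below_LOD) and
    not excluded for a noisy LOD.  With no eligible mutation the result is
    negative with value 0.
    """
    calls = tuple(calls)
    if not calls:
        raise ValueError("patient has no trackable biomarkers")
    eligible = [c for c in calls if c.status != "below_LOD" and not c.lod_excluded]
    if eligible:
        mrd_value = max(c.corrected_mean for c in eligible)
        positive = True
    else:
        mrd_value, positive = 0.0, False
    return MRDResult(
        patient_id=patient_id,
        timepoint=timepoint,
        mutations=calls,
        mrd_value=mrd_value,
        positive=positive,
        assay_floor=assay_floor,
    )


def _ratios_from_counts(group: pd.DataFrame) -> list[float]:
    ratios = []
    for _, row in group.iterrows():
        total = row["mut_reads"] + row["wt_reads"]
        if total == 0:
            logger.warning("dropping zero-total replicate for %s", row.get("mutation_id", "?"))
            continue
        ratios.append(row["mut_reads"] / total)
    return ratios


class MRDCaller(BaseEstimator):
    """Triplicate MRD caller calibrated on healthy-control replicate counts.

    ``fit`` consumes control counts (long table: mutation_id, mut_reads,
    wt_reads — one row per control replicate) and stores per-mutation
    LOD/LOQ calibrations.  ``evaluate`` scores a follow-up count table
    (patient, timepoint, mutation_id, replicate, mut_reads, wt_reads) into
    per-mutation calls and per-patient-time-point :class:`MRDResult`s;
    ``predict`` returns the boolean positivity vector over the
    (patient, timepoint) groups in sorted order.

    Parameters
    ----------
    lod_multiplier, loq_multiplier : float
        SD multipliers for the detection / quantification limits (3 and 10).
    artifact_sd_multiplier : float
        Replicate ratios above mean + this * SD are removed as artifacts.
    lod_cap : float
        Mutations whose LOD exceeds this are excluded from the MRD value.
    assay_floor : float
        Reporting sensitivity annotation (2e-4); not a hard threshold.
    """

    def __init__(
        self,
        lod_multiplier: float = LOD_MULTIPLIER,
        loq_multiplier: float = LOQ_MULTIPLIER,
        artifact_sd_multiplier: float = ARTIFACT_SD_MULTIPLIER,
        lod_cap: float = LOD_CAP,
        assay_floor: float = ASSAY_FLOOR,
    ):
        self.lod_multiplier = lod_multiplier
        self.loq_multiplier = loq_multiplier
        self.artifact_sd_multiplier = artifact_sd_multiplier
        self.lod_cap = lod_cap
        self.assay_floor = assay_floor

    def fit(self, X: pd.DataFrame | Mapping[str, Sequence[float]], y=None) -> "MRDCaller":
        """Calibrate per-mutation LOD/LOQ from healthy-control replicates."""
        if self.loq_multiplier < self.lod_multiplier:
            raise ValueError("loq_multiplier must be >= lod_multiplier")
        calibrations: dict[str, ControlCalibration] = {}
        if isinstance(X, pd.DataFrame):
            for mutation_id, group in X.groupby("mutation_id", sort=True):
                ratios = _ratios_from_counts(group)
                calibrations[str(mutation_id)] = calibrate_lod_loq(
                    ratios, str(mutation_id), self.lod_multiplier, self.loq_multiplier
                )
        else:
            for mutation_id, ratios in X.items():
                calibrations[str(mutation_id)] = calibrate_lod_loq(
                    list(ratios), str(mutation_id), self.lod_multiplier, self.loq_multiplier
                )
        self.calibrations_ = calibrations
        self.n_mutations_ = len(calibrations)
        return self

    def call_measurement(self, measurement: TriplicateMeasurement) -> MutationMRD:
        """Score one triplicate measurement against its calibration."""
        calib = self.calibrations_.get(measurement.mutation_id)
        if calib is None:
            raise ValueError(f"no control calibration for {measurement.mutation_id}")
        ratios = []
        for m, w in measurement.replicates:
            if m + w == 0:
                logger.warning(
                    "dropping zero-total replicate for %s @ %s",
                    measurement.mutation_id, measurement.timepoint,
                )
                continue
            ratios.append(replicate_ratio(m, w))
        if len(ratios) == 3:
            corrected, mask = correct_noise(ratios, self.artifact_sd_multiplier)
        elif ratios:
            # fewer than 3 usable replicates: no outlier rule, plain mean
            corrected, mask = statistics.fmean(ratios), tuple(True for _ in ratios)
        else:
            raise ValueError(f"no usable replicates for {measurement.mutation_id}")
        return call_mutation(corrected, calib, ratios, mask, self.lod_cap)

    def evaluate(self, counts: pd.DataFrame) -> list[MRDResult]:
        """Call MRD for every (patient, timepoint) group in a count table."""
        results = []
        for (patient, timepoint), group in counts.groupby(["patient", "timepoint"], sort=True):
            calls = []
            for mutation_id, muts in group.groupby("mutation_id", sort=True):
                reps = tuple(
                    (int(r["mut_reads"]), int(r["wt_reads"]))
                    for _, r in muts.sort_values("replicate").iterrows()
                )
                if mutation_id not in self.calibrations_:
                    logger.warning("skipping %s: no calibration", mutation_id)
                    continue
                calls.append(
                    self.call_measurement(
                        TriplicateMeasurement(str(mutation_id), str(timepoint), reps)
                    )
                )
            if calls:
                results.append(
                    patient_mrd(calls, str(patient), str(timepoint), self.assay_floor)
                )
        return results

    def predict(self, counts: pd.DataFrame) -> np.ndarray:
        """Boolean MRD positivity per (patient, timepoint) group, sorted."""
        return np.array([r.positive for r in self.evaluate(counts)], dtype=bool)

    def results_frame(self, results: Sequence[MRDResult]) -> pd.DataFrame:
        """Flatten MRD results into the per-mutation report table."""
        rows = []
        for res in results:
            for c in res.mutations:
                r = list(c.replicate_ratios) + [np.nan] * (3 - len(c.replicate_ratios))
                rows.append({
                    "patient": res.patient_id,
                    "timepoint": res.timepoint,
                    "mutation_id": c.mutation_id,
                    "r1": r[0], "r2": r[1], "r3": r[2],
                    "retained_mask": "".join("1" if k else "0" for k in c.retained_mask),
                    "corrected_mean": c.corrected_mean,
                    "lod": c.lod, "loq": c.loq,
                    "status": c.status, "lod_excluded": c.lod_excluded,
                })
        return pd.DataFrame(rows)
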