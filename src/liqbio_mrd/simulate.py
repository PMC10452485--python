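"""Synthetic B-cell lymphoma cohort generator for end-to-end pipeline testing.

Emulates the statistical structure of a baseline-genotyped lymphoma cohort
with longitudinal liquid-biopsy follow-up:

* subtype-specific gene mutation spectra (FL / DLBCL / PMBCL / PCNSL),
* correlated tissue/plasma allele frequencies (plasma attenuated + noisy),
* per-patient ctDNA "shedding" so a configurable fraction of plasma
  samples carries no detectable mutations,
* FFPE deamination artifacts (low-frequency C>T/G>A calls) injected into
  tissue tables, a fraction of them COSMIC-catalogued,
* triplicate amplicon read counts at ~500,000x depth with a binomial
  per-position background error,
* healthy-control replicates (three triplicates of three donors) per
  tracked mutation, and
* follow-up trajectories (responders decay to zero; relapsers rebound)
  with PET/CT Deauville scores carrying configurable false-positive /
  false-negative rates.

All randomness flows from one master seed; per-patient streams are derived
deterministically so identical configurations reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .concordance import ResponseRecord
from .genotyping import VariantCall
from .mrd import TriplicateMeasurement

SUBTYPES = ("FL", "DLBCL", "PMBCL", "PCNSL")

#: per-subtype recurrent-gene mutation probabilities (cohort frequencies)
DEFAULT_GENE_FREQS: dict[str, dict[str, float]] = {
    "FL": {"KMT2D": 0.64, "CREBBP": 0.36, "BCL2": 0.32, "EZH2": 0.24},
    "DLBCL": {
        "KMT2D": 0.32, "TP53": 0.30, "MYD88": 0.22,
        "CARD11": 0.21, "CREBBP": 0.15, "BCL2": 0.15,
    },
    "PMBCL": {"STAT1": 0.83, "SOCS1": 0.66},
    "PCNSL": {"MYD88": 0.80},
}

#: per-subtype probability that plasma carries detectable ctDNA
DEFAULT_SHED_PROB = {"DLBCL": 0.82, "PMBCL": 0.86, "PCNSL": 0.43, "FL": 0.56}

#: approximate cohort subtype composition (FL 25, DLBCL-like 34, PMBCL 12, PCNSL 7 of 78)
DEFAULT_SUBTYPE_MIX = {"FL": 25 / 78, "DLBCL": 34 / 78, "PMBCL": 12 / 78, "PCNSL": 7 / 78}

#: synthetic per-gene anchor coordinates (chrom, base position)
GENE_LOCI: dict[str, tuple[str, int]] = {
    "KMT2D": ("chr12", 49_020_000),
    "TP53": ("chr17", 7_570_000),
    "MYD88": ("chr3", 38_180_000),
    "CARD11": ("chr7", 2_940_000),
    "CREBBP": ("chr16", 3_770_000),
    "BCL2": ("chr18", 60_790_000),
    "EZH2": ("chr7", 148_500_000),
    "STAT1": ("chr2", 191_830_000),
    "SOCS1": ("chr16", 11_250_000),
    "PIM1": ("chr6", 37_130_000),
    "CD79B": ("chr17", 62_000_000),
}

_BASES = np.array(list("ACGT"))
CONTEXT_MARGIN = 15


class SimulationConfig(BaseModel):
    """Parameters of the synthetic cohort; defaults mirror the study conditions."""

    n_patients: int = Field(default=20, ge=1)
    subtype_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX))
    gene_freqs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {s: dict(g) for s, g in DEFAULT_GENE_FREQS.items()}
    )
    shed_prob: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_SHED_PROB))
    depth: int = Field(default=500_000, ge=1)
    error_rate: float = Field(default=2e-5, ge=0.0, le=1.0)
    deamination_rate: float = Field(default=0.30, ge=0.0, le=1.0)
    n_artifact_sites: int = Field(default=4, ge=0)
    cosmic_rescue_prob: float = Field(default=0.15, ge=0.0, le=1.0)
    tissue_vaf_mean: float = Field(default=0.26, gt=0.0, lt=1.0)
    tissue_vaf_alpha: float = Field(default=2.0, gt=0.0)
    plasma_attenuation: float = Field(default=0.7, ge=0.0)
    plasma_noise_sd: float = Field(default=0.12, ge=0.0)
    plasma_only_prob: float = Field(default=0.08, ge=0.0, le=1.0)
    min_reported_vaf: float = Field(default=0.03, ge=0.0, le=1.0)
    lymphoma_described_prob: float = Field(default=0.85, ge=0.0, le=1.0)
    noisy_site_prob: float = Field(default=0.05, ge=0.0, le=1.0)
    noisy_site_error: float = Field(default=1e-3, ge=0.0, le=1.0)
    relapse_prob: float = Field(default=0.3, ge=0.0, le=1.0)
    relapse_fraction: float = Field(default=1e-2, ge=0.0, le=1.0)
    residual_fraction_c2: float = Field(default=0.02, ge=0.0, le=1.0)
    petct_fp_rate: float = Field(default=3 / 23, ge=0.0, le=1.0)
    petct_fn_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    n_control_donors: int = Field(default=3, ge=1)
    n_control_replicates_per_donor: int = Field(default=3, ge=1)
    seed: int = 0

    @field_validator("subtype_mix")
    @classmethod
    def _mix_sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError("subtype proportions must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"subtype_mix sums to {sum(v.values())}, expected 1")
        return v

    @field_validator("gene_freqs")
    @classmethod
    def _freqs_are_probs(cls, v):
        for subtype, genes in v.items():
            for gene, p in genes.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"gene_freqs[{subtype}][{gene}]={p} outside [0, 1]")
        return v

    @property
    def n_control_replicates(self) -> int:
        return self.n_control_donors * self.n_control_replicates_per_donor


@dataclass
class TrueMutation:
    mutation_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tissue_vaf: float
    plasma_vaf: float
    plasma_only: bool
    described_in_lymphoma: bool
    in_cosmic: bool
    background_error: float
    wt_context: str
    mut_context: str


@dataclass
class TruePatient:
    patient_id: str
    subtype: str
    sheds_ctdna: bool
    cfdna_ngml: float
    mutations: list[TrueMutation] = field(default_factory=list)
    artifact_ids: list[str] = field(default_factory=list)
    rescued_artifact_ids: list[str] = field(default_factory=list)
    relapser: bool = False
    trajectory: dict[str, float] = field(default_factory=dict)  # timepoint -> ct fraction


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    config: SimulationConfig
    patients: dict[str, TruePatient] = field(default_factory=dict)

    def tracked_mutations(self, patient_id: str) -> list[TrueMutation]:
        """The patient's true MRD biomarkers (lymphoma-described mutations)."""
        return [m for m in self.patients[patient_id].mutations if m.described_in_lymphoma]


def _rng_for(config: SimulationConfig, *stream: int) -> np.random.Generator:
    # fixed-offset derived streams: patient i always sees the same entropy
    return np.random.default_rng(np.random.SeedSequence((config.seed, *stream)))


def _random_context(rng: np.random.Generator, ref: str, alt: str) -> tuple[str, str]:
    flank_left = "".join(rng.choice(_BASES, size=CONTEXT_MARGIN))
    flank_right = "".join(rng.choice(_BASES, size=CONTEXT_MARGIN))
    return flank_left + ref + flank_right, flank_left + alt + flank_right


def _draw_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return ref, alt


def _beta_params(mean: float, alpha: float) -> tuple[float, float]:
    return alpha, alpha * (1.0 - mean) / mean


def simulate_baseline_genotypes(
    config: SimulationConfig,
) -> tuple[dict[str, tuple[list[VariantCall], list[VariantCall]]], SyntheticTruth]:
    """Generate per-patient baseline tissue and plasma variant tables.

    Tissue tables contain every true somatic mutation (except plasma-only
    clones) plus injected deamination artifacts; plasma tables contain the
    attenuated, noisy mirror of the truth for ctDNA-shedding patients only.

    Returns
    -------
    (genotypes, truth)
        ``genotypes`` maps patient_id -> (tissue calls, plasma calls);
        ``truth`` records everything the generator decided.
    """
    truth = SyntheticTruth(config=config)
    genotypes: dict[str, tuple[list[VariantCall], list[VariantCall]]] = {}
    subtype_names = sorted(config.subtype_mix)
    subtype_probs = np.array([config.subtype_mix[s] for s in subtype_names])
    a, b = _beta_params(config.tissue_vaf_mean, config.tissue_vaf_alpha)

    for i in range(config.n_patients):
        rng = _rng_for(config, 0, i)
        patient_id = f"SIM{i:04d}"
        subtype = subtype_names[rng.choice(len(subtype_names), p=subtype_probs)]
        sheds = bool(rng.random() < config.shed_prob.get(subtype, 0.5))
        # cfDNA yield: lognormal around the cohort-scale mean, heavier for LBCL
        scale = 2.6 if subtype in ("DLBCL", "PMBCL") else 2.1
        cfdna = float(np.round(rng.lognormal(mean=scale, sigma=0.9), 2))
        patient = TruePatient(patient_id, subtype, sheds, cfdna)

        tissue_calls: list[VariantCall] = []
        plasma_calls: list[VariantCall] = []
        for gene, p_hit in sorted(config.gene_freqs.get(subtype, {}).items()):
            if rng.random() >= p_hit:
                continue
            chrom, base = GENE_LOCI.get(gene, ("chr1", 1_000_000))
            pos = int(base + rng.integers(0, 10_000))
            ref, alt = _draw_snv(rng)
            tissue_vaf = float(np.clip(rng.beta(a, b), 0.01, 0.98))
            plasma_vaf = float(np.clip(
                tissue_vaf * config.plasma_attenuation + rng.normal(0.0, config.plasma_noise_sd),
                0.0, 1.0,
            ))
            plasma_only = bool(rng.random() < config.plasma_only_prob)
            described = bool(rng.random() < config.lymphoma_described_prob)
            in_cosmic = described or bool(rng.random() < 0.3)
            background = (
                config.noisy_site_error
                if rng.random() < config.noisy_site_prob
                else config.error_rate
            )
            wt_ctx, mut_ctx = _random_context(rng, ref, alt)
            mutation_id = f"{patient_id}:{gene}:{chrom}:{pos}:{ref}>{alt}"
            mut = TrueMutation(
                mutation_id, gene, chrom, pos, ref, alt, tissue_vaf, plasma_vaf,
                plasma_only, described, in_cosmic, background, wt_ctx, mut_ctx,
            )
            patient.mutations.append(mut)

            common = dict(
                patient_id=patient_id, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                in_cosmic=in_cosmic, described_in_lymphoma=described,
            )
            if not plasma_only:
                tissue_calls.append(VariantCall(
                    vaf=tissue_vaf, depth=2150, compartment="tissue",
                    pvalue_transformed=float(rng.uniform(-12.0, -3.0)), **common,
                ))
            plasma_detectable = (sheds or plasma_only) and plasma_vaf >= config.min_reported_vaf
            if plasma_detectable:
                plasma_calls.append(VariantCall(
                    vaf=plasma_vaf, depth=2150, compartment="plasma",
                    pvalue_transformed=float(rng.uniform(-12.0, -3.0)), **common,
                ))

        # deamination artifacts: low-VAF C>T / G>A tissue calls, weak p-values
        for k in range(config.n_artifact_sites):
            if rng.random() >= config.deamination_rate:
                continue
            gene = str(rng.choice(sorted(GENE_LOCI)))
            chrom, base = GENE_LOCI[gene]
            pos = int(base + 20_000 + rng.integers(0, 5_000))
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
            vaf = float(rng.uniform(0.01, 0.19))
            rescued = bool(rng.random() < config.cosmic_rescue_prob)
            artifact_id = f"{patient_id}:{gene}:{chrom}:{pos}:{ref}>{alt}"
            tissue_calls.append(VariantCall(
                patient_id=patient_id, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                vaf=vaf, depth=2150, compartment="tissue",
                pvalue_transformed=float(rng.uniform(-1.9, 0.0)),
                in_cosmic=rescued, described_in_lymphoma=False,
            ))
            patient.artifact_ids.append(artifact_id)
            if rescued:
                patient.rescued_artifact_ids.append(artifact_id)

        truth.patients[patient_id] = patient
        genotypes[patient_id] = (tissue_calls, plasma_calls)
    return genotypes, truth


def simulate_triplicate_counts(
    true_fraction: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mutation_id: str = "mut",
    timepoint: str = "t0",
    background_error: float | None = None,
) -> TriplicateMeasurement:
    """Draw one triplicate of (mutant, wild-type) counts at the configured depth.

    Mutant reads per replicate follow Binomial(depth, true_fraction +
    background error), independently across the three replicates; totals
    equal the depth.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError(f"true_fraction {true_fraction} outside [0, 1]")
    if rng is None:
        rng = _rng_for(config, 1)
    err = config.error_rate if background_error is None else background_error
    p = min(true_fraction + err, 1.0)
    muts = rng.binomial(config.depth, p, size=3)
    replicates = tuple((int(m), int(config.depth - m)) for m in muts)
    return TriplicateMeasurement(mutation_id, timepoint, replicates)


def simulate_control_replicates(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    background_error: float | None = None,
) -> list[float]:
    """Background ratios of the healthy-control replicates for one mutation.

    Draws n_control_donors x n_control_replicates_per_donor replicates with
    zero true allele fraction (background error only) and returns their
    mutant-read ratios.
    """
    if rng is None:
        rng = _rng_for(config, 2)
    err = config.error_rate if background_error is None else background_error
    n = config.n_control_replicates
    muts = rng.binomial(config.depth, min(err, 1.0), size=n)
    return [float(m) / config.depth for m in muts]


def simulate_control_counts(
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Healthy-control count table for every tracked mutation in the cohort."""
    rows = []
    for p_idx, (patient_id, patient) in enumerate(sorted(truth.patients.items())):
        rng = _rng_for(config, 3, p_idx)
        for mut in truth.tracked_mutations(patient_id):
            n = config.n_control_replicates
            draws = rng.binomial(config.depth, min(mut.background_error, 1.0), size=n)
            idx = 0
            for donor in range(config.n_control_donors):
                for rep in range(config.n_control_replicates_per_donor):
                    m = int(draws[idx]); idx += 1
                    rows.append({
                        "mutation_id": mut.mutation_id, "donor": f"HC{donor + 1}",
                        "replicate": rep + 1, "mut_reads": m,
                        "wt_reads": config.depth - m,
                    })
    return pd.DataFrame(rows, columns=["mutation_id", "donor", "replicate", "mut_reads", "wt_reads"])


def _trajectory(patient: TruePatient, timepoints: Sequence[str], config: SimulationConfig,
                rng: np.random.Generator) -> dict[str, float]:
    """Circulating tumor fraction per time-point.

    Responders decay to zero after the first on-treatment sample; relapsers
    decay then rebound to ``relapse_fraction`` at the final time-point.
    """
    shed_vafs = [m.plasma_vaf for m in patient.mutations if m.described_in_lymphoma]
    f0 = max(shed_vafs) if shed_vafs else 0.1
    traj: dict[str, float] = {}
    for k, tp in enumerate(timepoints):
        if k == 0:
            traj[tp] = f0 * config.residual_fraction_c2
        elif patient.relapser and k == len(timepoints) - 1:
            traj[tp] = config.relapse_fraction
        else:
            traj[tp] = 0.0
    return traj


def simulate_followup_course(
    truth: SyntheticTruth,
    timepoints: Sequence[str],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[ResponseRecord]]:
    """Follow-up triplicate counts and PET/CT response records for the cohort.

    The circulating-fraction trajectory drives per-mutation counts (each
    mutation scaled by its clonal share of the baseline plasma signal).
    Deauville scores follow the true disease state, flipped with the
    configured PET false-positive / false-negative rates; the adjudicated
    clinical truth column records the generating state.
    """
    timepoints = list(timepoints)
    rows = []
    records: list[ResponseRecord] = []
    for p_idx, (patient_id, patient) in enumerate(sorted(truth.patients.items())):
        rng = _rng_for(config, 4, p_idx)
        tracked = truth.tracked_mutations(patient_id)
        patient.relapser = bool(rng.random() < config.relapse_prob)
        patient.trajectory = _trajectory(patient, timepoints, config, rng)
        max_vaf = max((m.plasma_vaf for m in tracked), default=0.0)
        for tp in timepoints:
            fraction = patient.trajectory[tp]
            for mut in tracked:
                share = (mut.plasma_vaf / max_vaf) if max_vaf > 0 else 1.0
                meas = simulate_triplicate_counts(
                    min(fraction * share, 1.0), config, rng,
                    mutation_id=mut.mutation_id, timepoint=tp,
                    background_error=mut.background_error,
                )
                for rep, (m, w) in enumerate(meas.replicates, start=1):
                    rows.append({
                        "patient": patient_id, "timepoint": tp,
                        "mutation_id": mut.mutation_id, "replicate": rep,
                        "mut_reads": m, "wt_reads": w,
                    })
            diseased = fraction > 0.0
            if diseased:
                pet_positive = rng.random() >= config.petct_fn_rate
            else:
                pet_positive = rng.random() < config.petct_fp_rate
            if pet_positive:
                deauville = int(rng.choice([4, 5]))
                fdg = "increased" if diseased else "reduced"
            else:
                deauville = int(rng.choice([1, 2, 3]))
                fdg = "reduced"
            records.append(ResponseRecord(
                patient_id=patient_id, timepoint=tp, deauville=deauville,
                fdg_trend=fdg, liqbio_positive=None,
                clinical_truth="disease" if diseased else "no_disease",
            ))
    counts = pd.DataFrame(
        rows,
        columns=["patient", "timepoint", "mutation_id", "replicate", "mut_reads", "wt_reads"],
    )
    return counts, records


def simulate_cohort(config: SimulationConfig, timepoints: Sequence[str] = ("C2", "EOT", "FU1")):
    """One-call cohort simulation: baseline, controls, follow-up, responses."""
    genotypes, truth = simulate_baseline_genotypes(config)
    controls = simulate_control_counts(truth, config)
    counts, records = simulate_followup_course(truth, timepoints, config)
    return genotypes, truth, controls, counts, records
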