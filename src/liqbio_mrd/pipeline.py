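"""End-to-end pipeline: simulate -> genotype -> MRD -> concordance.

Every threshold used by any stage lives in :class:`PipelineConfig`, so a
run is fully described by one auditable document; the emitted
:class:`RunManifest` hashes the configuration and inputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as lio
from .concordance import (
    ResponseRecord, build_confusion, compare_mrd_by_pet_group,
    cfdna_clinical_association,
)
from .genotyping import (
    FFPEArtifactFilter, merge_paired_genotypes, select_mrd_biomarkers, vaf_correlation,
)
from .mrd import MRDCaller, MRDResult
from .simulate import SimulationConfig, simulate_baseline_genotypes, \
    simulate_control_counts, simulate_followup_course

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """All tunable constants of the pipeline in one place."""

    outdir: str = "liqbio_out"
    timepoints: list[str] = Field(default_factory=lambda: ["C2", "EOT", "FU1"])
    deamination_vaf: float = Field(default=0.20, gt=0.0)
    deamination_pvalue: float = -2.0
    lod_multiplier: float = Field(default=3.0, gt=0.0)
    loq_multiplier: float = Field(default=10.0, gt=0.0)
    artifact_sd_multiplier: float = Field(default=1.0, gt=0.0)
    lod_cap: float = Field(default=1e-4, gt=0.0)
    assay_floor: float = Field(default=2e-4, gt=0.0)
    cfdna_cutoff_ngml: float = Field(default=5.0, gt=0.0)
    seed: int = 0
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    @model_validator(mode="after")
    def _loq_dominates_lod(self) -> "PipelineConfig":
        if self.loq_multiplier < self.lod_multiplier:
            raise ValueError(
                f"loq_multiplier ({self.loq_multiplier}) must be >= "
                f"lod_multiplier ({self.lod_multiplier}): LOQ cannot fall below LOD"
            )
        return self

    @model_validator(mode="after")
    def _propagate_seed(self) -> "PipelineConfig":
        object.__setattr__(self.simulation, "seed", self.seed)
        return self


@dataclass
class RunManifest:
    config_hash: str
    input_checksums: dict[str, str]
    record_counts: dict[str, int]
    stage_versions: dict[str, str]
    timestamp: str = ""

    @property
    def manifest_hash(self) -> str:
        payload = json.dumps(
            [self.config_hash, self.input_checksums, self.record_counts, self.stage_versions],
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_swimmer_table(results: Sequence[MRDResult],
                         records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """Longitudinal per-patient table (tabular swimmer plot).

    One row per patient-time-point with the MRD value, positivity, PET/CT
    group and therapy phase; sorted by patient then time-point order of
    first appearance.
    """
    pet = {(r.patient_id, r.timepoint): r.petct_group for r in records}
    tp_order = {tp: k for k, tp in enumerate(dict.fromkeys(r.timepoint for r in results))}
    rows = [{
        "patient": r.patient_id,
        "timepoint": r.timepoint,
        "mrd_value": r.mrd_value,
        "liqbio_positive": r.positive,
        "below_assay_floor": r.below_assay_floor,
        "petct_group": pet.get((r.patient_id, r.timepoint), "n/a"),
        "therapy_phase": r.timepoint,
    } for r in results]
    df = pd.DataFrame(rows, columns=[
        "patient", "timepoint", "mrd_value", "liqbio_positive",
        "below_assay_floor", "petct_group", "therapy_phase",
    ])
    if len(df):
        df = df.sort_values(
            ["patient", "timepoint"],
            key=lambda col: col.map(tp_order) if col.name == "timepoint" else col,
        ).reset_index(drop=True)
    return df


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute simulate -> genotype -> mrd -> concord and write all outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_of: dict[str, int] = {}

    # --- simulate ---------------------------------------------------------
    sim = config.simulation
    genotypes, truth = simulate_baseline_genotypes(sim)
    controls = simulate_control_counts(truth, sim)
    followup_counts, records = simulate_followup_course(truth, config.timepoints, sim)
    all_tissue = [v for t, _ in genotypes.values() for v in t]
    all_plasma = [v for _, p in genotypes.values() for v in p]
    lio.write_variants_tsv(all_tissue, outdir / "tissue_variants.tsv")
    lio.write_variants_tsv(all_plasma, outdir / "plasma_variants.tsv")
    lio.write_counts_tsv(controls, outdir / "control_counts.tsv")
    lio.write_counts_tsv(followup_counts, outdir / "followup_counts.tsv")
    lio.write_truth_json(truth, outdir / "truth.json")
    metadata = pd.DataFrame([{
        "patient_id": pid, "subtype": p.subtype, "sheds_ctdna": p.sheds_ctdna,
        "cfdna_ngml": p.cfdna_ngml, "relapser": p.relapser,
    } for pid, p in sorted(truth.patients.items())])
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    counts_of["simulate.patients"] = len(truth.patients)
    counts_of["simulate.tissue_variants"] = len(all_tissue)
    counts_of["simulate.plasma_variants"] = len(all_plasma)
    logger.info("simulate: %d patients, %d tissue / %d plasma variants",
                len(truth.patients), len(all_tissue), len(all_plasma))

    # --- genotype ---------------------------------------------------------
    ffpe = FFPEArtifactFilter(
        vaf_max=config.deamination_vaf, pvalue_min=config.deamination_pvalue
    ).fit(None)
    panels = {}
    merge_rows = []
    pairs = []
    for pid, (tissue, plasma) in sorted(genotypes.items()):
        filtered = ffpe.transform(tissue)
        summary, union = merge_paired_genotypes(filtered, plasma)
        merge_rows.append({
            "patient_id": pid, "n_both": summary.n_both,
            "n_tissue_only": summary.n_tissue_only,
            "n_plasma_only": summary.n_plasma_only, "n_total": summary.n_total,
        })
        panels[pid] = select_mrd_biomarkers([v for v, _ in union])
        plasma_by_key = {v.key: v for v in plasma}
        for v, label in union:
            if label == "both":
                pairs.append((v.vaf, plasma_by_key[v.key].vaf))
    merge_df = pd.DataFrame(merge_rows)
    merge_df.to_csv(outdir / "merge_summary.tsv", sep="\t", index=False)
    panel_rows = [{
        "patient_id": pid, "mutation_id": f"{pid}:{v.gene}:{v.chrom}:{v.pos}:{v.ref}>{v.alt}",
        "gene": v.gene, "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
    } for pid, panel in sorted(panels.items()) for v, _ in panel.mutations]
    pd.DataFrame(panel_rows, columns=[
        "patient_id", "mutation_id", "gene", "chrom", "pos", "ref", "alt",
    ]).to_csv(outdir / "biomarker_panels.tsv", sep="\t", index=False)
    applicable = sum(1 for p in panels.values() if p.applicable)
    counts_of["genotype.applicable_patients"] = applicable
    counts_of["genotype.panel_mutations"] = len(panel_rows)
    report: dict = {
        "applicability": {"applicable": applicable, "total": len(panels)},
        "merge_totals": {
            k: int(merge_df[k].sum()) for k in ("n_both", "n_tissue_only", "n_plasma_only", "n_total")
        } if len(merge_df) else {},
    }
    if len(pairs) >= 3:
        try:
            r, p = vaf_correlation(pairs)
            report["vaf_correlation"] = {"r": r, "p": p, "n_pairs": len(pairs)}
        except ValueError:
            pass
    logger.info("genotype: %d/%d patients MRD-applicable", applicable, len(panels))

    # --- mrd --------------------------------------------------------------
    caller = MRDCaller(
        lod_multiplier=config.lod_multiplier, loq_multiplier=config.loq_multiplier,
        artifact_sd_multiplier=config.artifact_sd_multiplier,
        lod_cap=config.lod_cap, assay_floor=config.assay_floor,
    )
    panel_ids = {row["mutation_id"] for row in panel_rows}
    controls_panel = controls[controls["mutation_id"].isin(panel_ids)]
    tracked_counts = followup_counts[followup_counts["mutation_id"].isin(panel_ids)]
    results: list[MRDResult] = []
    if len(controls_panel):
        caller.fit(controls_panel)
        results = caller.evaluate(tracked_counts)
        caller.results_frame(results).to_csv(outdir / "mrd_report.tsv", sep="\t", index=False)
        lio.write_mrd_results_json(results, outdir / "mrd_results.json")
    counts_of["mrd.calls"] = len(results)
    logger.info("mrd: %d patient-time-point calls", len(results))

    # --- concord ----------------------------------------------------------
    positive_by_key = {(r.patient_id, r.timepoint): r.positive for r in results}
    annotated = [
        dataclasses.replace(rec, liqbio_positive=positive_by_key.get(
            (rec.patient_id, rec.timepoint)))
        for rec in records
    ]
    lio.write_responses_tsv(annotated, outdir / "responses.tsv")
    summary = build_confusion(annotated)
    concord_report = {
        "petct": {
            "tp": summary.petct.tp, "fp": summary.petct.fp,
            "tn": summary.petct.tn, "fn": summary.petct.fn,
            "sensitivity": summary.petct.sensitivity,
            "specificity": summary.petct.specificity,
        },
        "liqbio": {
            "tp": summary.liqbio.tp, "fp": summary.liqbio.fp,
            "tn": summary.liqbio.tn, "fn": summary.liqbio.fn,
            "sensitivity": summary.liqbio.sensitivity,
            "specificity": summary.liqbio.specificity,
        },
        "concordance": {"fraction": summary.concordance,
                        "agree": summary.agree, "total": summary.total},
    }
    mrd_by_group: dict[str, list[float]] = {"negative": [], "positive": []}
    for rec in annotated:
        key = (rec.patient_id, rec.timepoint)
        for res in results:
            if (res.patient_id, res.timepoint) == key:
                mrd_by_group[rec.petct_group].append(res.mrd_value)
    if mrd_by_group["negative"] and mrd_by_group["positive"]:
        u, p = compare_mrd_by_pet_group(mrd_by_group["negative"], mrd_by_group["positive"])
        concord_report["mannwhitney"] = {"U": u, "p": p}
    try:
        chi2, p, _ = cfdna_clinical_association(
            metadata["cfdna_ngml"], metadata["subtype"].isin(["DLBCL", "PMBCL"]),
            cutoff=config.cfdna_cutoff_ngml,
        )
        concord_report["cfdna_vs_subtype"] = {"chi2": chi2, "p": p}
    except ValueError:
        pass
    counts_of["concord.records"] = summary.total
    report["concordance"] = concord_report
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    swimmer = render_swimmer_table(results, annotated)
    swimmer.to_csv(outdir / "swimmer.tsv", sep="\t", index=False)
    logger.info("concord: concordance %.3f over %d records",
                summary.concordance if summary.total else float("nan"), summary.total)

    manifest = RunManifest(
        config_hash=_config_hash(config),
        input_checksums={
            name: _file_checksum(outdir / name)
            for name in ("tissue_variants.tsv", "plasma_variants.tsv",
                         "control_counts.tsv", "followup_counts.tsv")
        },
        record_counts=counts_of,
        stage_versions={"liqbio_mrd": _package_version()},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (outdir / "manifest.json").write_text(json.dumps({
        "config_hash": manifest.config_hash,
        "manifest_hash": manifest.manifest_hash,
        "input_checksums": manifest.input_checksums,
        "record_counts": manifest.record_counts,
        "stage_versions": manifest.stage_versions,
        "timestamp": manifest.timestamp,
    }, indent=1))
    return manifest


def _package_version() -> str:
    from . import __version__
    return __version__
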