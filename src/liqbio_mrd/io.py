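"""Readers and writers for the pipeline's on-disk formats.

Variant tables travel as uncompressed VCF v4.2 (1-based positions, INFO
keys VAF, PT, COSMIC, LYMPH, GENE) with a mirrored TSV; read counts,
controls, metadata and reports are TSV; ground truth and patient-level MRD
results are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .concordance import ResponseRecord
from .genotyping import VariantCall
from .mrd import MRDResult

VARIANT_TSV_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "vaf", "depth",
    "compartment", "pvalue_transformed", "in_cosmic", "described_in_lymphoma",
]

_VCF_HEADER_LINES = [
    ('INFO', 'GENE', '1', 'String', 'Gene symbol'),
    ('INFO', 'VAF', '1', 'Float', 'Variant allele frequency'),
    ('INFO', 'PT', '1', 'Float', 'Caller-reported transformed p-value'),
    ('INFO', 'COSMIC', '0', 'Flag', 'Catalogued somatic aberration (COSMIC)'),
    ('INFO', 'LYMPH', '0', 'Flag', 'Previously described in lymphoma or similar cancers'),
    ('INFO', 'COMPARTMENT', '1', 'String', 'Source compartment (tissue or plasma)'),
]


def write_variants_vcf(variants: Sequence[VariantCall], path: str | Path) -> None:
    """Write variant calls to an uncompressed VCF v4.2 file."""
    header = pysam.VariantHeader()
    for rec in _VCF_HEADER_LINES:
        header.add_meta(rec[0], items=[
            ("ID", rec[1]), ("Number", rec[2]), ("Type", rec[3]), ("Description", rec[4]),
        ])
    contigs = sorted({v.chrom for v in variants})
    for contig in contigs:
        header.contigs.add(contig)
    if variants:
        header.add_sample(variants[0].patient_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["GENE"] = v.gene
            rec.info["VAF"] = v.vaf
            rec.info["PT"] = v.pvalue_transformed
            rec.info["COMPARTMENT"] = v.compartment
            if v.in_cosmic:
                rec.info["COSMIC"] = True
            if v.described_in_lymphoma:
                rec.info["LYMPH"] = True
            vcf.write(rec)


def read_variants_vcf(path: str | Path, patient_id: str | None = None) -> list[VariantCall]:
    """Read variant calls back from a VCF written by :func:`write_variants_vcf`."""
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        pid = patient_id or (list(vcf.header.samples)[0] if vcf.header.samples else "unknown")
        for rec in vcf:
            calls.append(VariantCall(
                patient_id=pid,
                gene=str(rec.info.get("GENE", "")),
                chrom=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                vaf=float(rec.info["VAF"]),
                depth=2150,
                compartment=str(rec.info.get("COMPARTMENT", "tissue")),
                pvalue_transformed=float(rec.info.get("PT", -10.0)),
                in_cosmic=bool(rec.info.get("COSMIC", False)),
                described_in_lymphoma=bool(rec.info.get("LYMPH", False)),
            ))
    return calls


def variants_to_frame(variants: Iterable[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(v) for v in variants], columns=VARIANT_TSV_COLUMNS
    )


def frame_to_variants(df: pd.DataFrame) -> list[VariantCall]:
    return [
        VariantCall(
            patient_id=str(r.patient_id), gene=str(r.gene), chrom=str(r.chrom),
            pos=int(r.pos), ref=str(r.ref), alt=str(r.alt), vaf=float(r.vaf),
            depth=int(r.depth), compartment=str(r.compartment),
            pvalue_transformed=float(r.pvalue_transformed),
            in_cosmic=bool(r.in_cosmic), described_in_lymphoma=bool(r.described_in_lymphoma),
        )
        for r in df.itertuples(index=False)
    ]


def write_variants_tsv(variants: Sequence[VariantCall], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantCall]:
    return frame_to_variants(pd.read_csv(path, sep="\t"))


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_responses_tsv(records: Sequence[ResponseRecord], path: str | Path) -> None:
    rows = [{
        "patient_id": r.patient_id, "timepoint": r.timepoint, "deauville": r.deauville,
        "fdg_trend": r.fdg_trend,
        "liqbio_positive": "" if r.liqbio_positive is None else int(r.liqbio_positive),
        "clinical_truth": r.clinical_truth or "",
    } for r in records]
    pd.DataFrame(rows, columns=[
        "patient_id", "timepoint", "deauville", "fdg_trend", "liqbio_positive", "clinical_truth",
    ]).to_csv(path, sep="\t", index=False)


def read_responses_tsv(path: str | Path) -> list[ResponseRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"liqbio_positive": "object"})
    records = []
    for r in df.itertuples(index=False):
        liq = r.liqbio_positive
        liq = None if pd.isna(liq) or liq == "" else bool(int(float(liq)))
        truth = None if pd.isna(r.clinical_truth) or r.clinical_truth == "" else str(r.clinical_truth)
        records.append(ResponseRecord(
            patient_id=str(r.patient_id), timepoint=str(r.timepoint),
            deauville=int(r.deauville), fdg_trend=str(r.fdg_trend),
            liqbio_positive=liq, clinical_truth=truth,
        ))
    return records


def write_truth_json(truth, path: str | Path) -> None:
    payload = {
        "config": truth.config.model_dump(),
        "patients": {
            pid: {
                "subtype": p.subtype,
                "sheds_ctdna": p.sheds_ctdna,
                "cfdna_ngml": p.cfdna_ngml,
                "relapser": p.relapser,
                "trajectory": p.trajectory,
                "artifact_ids": p.artifact_ids,
                "rescued_artifact_ids": p.rescued_artifact_ids,
                "mutations": [dataclasses.asdict(m) for m in p.mutations],
            }
            for pid, p in sorted(truth.patients.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_mrd_results_json(results: Sequence[MRDResult], path: str | Path) -> None:
    payload = [{
        "patient_id": r.patient_id, "timepoint": r.timepoint,
        "mrd_value": r.mrd_value, "positive": r.positive,
        "below_assay_floor": r.below_assay_floor, "assay_floor": r.assay_floor,
    } for r in results]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_mrd_results_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
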