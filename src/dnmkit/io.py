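"""Readers and writers: PED pedigrees, multi-sample VCF, BED masks,
candidate tables and validation outcomes.

VCF input goes through cyvcf2 and VCF output through pysam; missing FORMAT
or INFO subfields are mapped to ``None`` (never to defaults), so downstream
filters always see explicit missingness.
"""

from __future__ import annotations

import csv
import warnings
from typing import Iterable, Iterator, Optional, Sequence

from .filters import ConfigurationError
from .model import (
    IndividualRecord,
    Pedigree,
    RegionMask,
    SampleCall,
    SiteAnnotations,
    TrioSiteRecord,
    ValidationOutcome,
)
from .pipeline import STAGES, CandidateDNM

_INFO_FIELDS = {
    "QD": "qd",
    "MQ": "mq",
    "FS": "fs",
    "SOR": "sor",
    "MQRankSum": "mq_rank_sum",
    "ReadPosRankSum": "read_pos_rank_sum",
    "BaseQRankSum": "base_q_rank_sum",
}


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path: str, ages_path: Optional[str] = None) -> Pedigree:
    """Read a 6-column PED file (family, id, father, mother, sex, phenotype).

    ``0`` (or ``.``) marks an unknown parent.  An optional sidecar table
    supplies per-individual ages at conception (two columns: id, years).
    """
    ages: dict[str, float] = {}
    if ages_path is not None:
        with open(ages_path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 2 and not line.startswith("#"):
                    ages[parts[0]] = float(parts[1])
    individuals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED row has {len(parts)} columns, expected 6: {line!r}")
            _, iid, father, mother, sex, _ = parts[:6]
            individuals.append(IndividualRecord(
                id=iid,
                father_id=None if father in ("0", ".") else father,
                mother_id=None if mother in ("0", ".") else mother,
                sex=int(sex) if sex in ("1", "2") else None,
                age_at_conception_years=ages.get(iid),
            ))
    if len(individuals) < 3:
        raise ValueError("pedigree must contain at least one trio (3 rows)")
    ped = Pedigree(individuals)
    if not ped.trios():
        from .model import PedigreeError

        raise PedigreeError("no complete (father, mother, child) trio derivable")
    return ped


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def _none_if_missing(value) -> Optional[float]:
    return None if value is None else float(value)


def read_variants(
    path: str,
    pedigree: Optional[Pedigree] = None,
    region: Optional[tuple[str, int, int]] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> Iterator[TrioSiteRecord]:
    """Stream TrioSiteRecords from a multi-sample VCF in coordinate order.

    Multi-allelic sites are yielded with all alternative alleles retained.
    ``region`` is (chrom, start, end) with 1-based inclusive bounds.  Sample
    ids named by the pedigree (or ``sample_ids``) must appear in the VCF
    header.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    header_samples = list(vcf.samples)
    wanted = list(sample_ids) if sample_ids is not None else (
        [m.id for m in pedigree] if pedigree is not None else header_samples
    )
    missing = [s for s in wanted if s not in header_samples]
    if missing:
        raise ConfigurationError(
            f"samples missing from VCF header: {', '.join(missing)}"
        )
    index = {s: header_samples.index(s) for s in wanted}

    for variant in vcf:
        if region is not None:
            chrom, start, end = region
            if variant.CHROM != chrom or not (start <= variant.POS <= end):
                continue
        ann = {"qual": _none_if_missing(variant.QUAL)}
        for key, attr in _INFO_FIELDS.items():
            ann[attr] = _none_if_missing(variant.INFO.get(key))
        annotations = SiteAnnotations(**ann)

        gts = variant.genotypes  # [allele0, allele1, phased] per sample

        def fmt(key):
            try:
                return variant.format(key)
            except KeyError:  # field not declared in the header
                return None

        depths = fmt("DP")
        ads = fmt("AD")
        gqs = fmt("GQ")
        pls = fmt("PL")
        calls = {}
        for s, j in index.items():
            a0, a1 = gts[j][0], gts[j][1]
            gt = None if (a0 < 0 or a1 < 0) else tuple(sorted((int(a0), int(a1))))
            dp = None
            if depths is not None and depths[j][0] >= 0:
                dp = int(depths[j][0])
            ad = None
            if ads is not None:
                row = [int(x) for x in ads[j]]
                if all(x >= 0 for x in row):
                    ad = tuple(row)
            gq = None
            if gqs is not None:
                v = gqs[j] if gqs.ndim == 1 else gqs[j][0]
                try:
                    v = float(v)
                    if v >= 0:
                        gq = int(v)
                except (TypeError, ValueError):
                    gq = None
            pl = None
            if pls is not None:
                row = [int(x) for x in pls[j]]
                if all(x >= 0 for x in row):
                    pl = tuple(row)
            calls[s] = SampleCall(gt=gt, dp=dp, ad=ad, gq=gq, pl=pl)

        yield TrioSiteRecord(
            chrom=variant.CHROM,
            pos=variant.POS,
            ref_allele=variant.REF,
            alt_alleles=tuple(variant.ALT),
            annotations=annotations,
            calls=calls,
        )


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_records_vcf(
    records: Iterable[TrioSiteRecord],
    path: str,
    sample_ids: Sequence[str],
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write TrioSiteRecords as an uncompressed multi-sample VCF."""
    import pysam

    header = pysam.VariantHeader()
    records = list(records)
    contigs = contig_lengths or {}
    seen = {r.chrom for r in records}
    for chrom in sorted(seen | set(contigs)):
        length = contigs.get(chrom)
        if length:
            header.contigs.add(chrom, length=length)
        else:
            header.contigs.add(chrom)
    for key in _INFO_FIELDS:
        header.info.add(key, 1, "Float", f"{key} site annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref first)")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    for s in sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref_allele,) + tuple(rec.alt_alleles),
            )
            a = rec.annotations
            if a.qual is not None:
                row.qual = a.qual
            for key, attr in _INFO_FIELDS.items():
                value = getattr(a, attr)
                if value is not None:
                    row.info[key] = value
            for s in sample_ids:
                call = rec.call(s)
                sample = row.samples[s]
                sample["GT"] = call.gt if call.gt is not None else (None, None)
                sample.phased = False
                if call.dp is not None:
                    sample["DP"] = call.dp
                if call.ad is not None:
                    sample["AD"] = list(call.ad)
                if call.gq is not None:
                    sample["GQ"] = min(call.gq, 99)
                if call.pl is not None:
                    sample["PL"] = list(call.pl)
            out.write(row)


# ---------------------------------------------------------------------------
# BED masks, position lists, validation tables
# ---------------------------------------------------------------------------

def read_mask(path: str, label: str = "") -> RegionMask:
    """Read a 3+-column BED file into a merged RegionMask.

    Rows with start >= end are rejected (counted in a warning), matching the
    0-based half-open BED convention.
    """
    intervals = []
    rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                rejected += 1
                continue
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                rejected += 1
                continue
            intervals.append((chrom, start, end))
    if rejected:
        warnings.warn(f"{path}: rejected {rejected} malformed BED row(s)")
    return RegionMask(intervals, label=label)


def read_positions(path: str) -> set[tuple[str, int]]:
    """Read a two-column (chrom, 1-based pos) site list, e.g. population SNPs."""
    out = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            out.add((parts[0], int(parts[1])))
    return out


def read_validation(path: str) -> list[ValidationOutcome]:
    """Read a validation-outcome TSV: chrom, pos, allele, status."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(ValidationOutcome(
                chrom=row["chrom"], pos=int(row["pos"]),
                allele=row["allele"], status=row["status"],
            ))
    return out


# ---------------------------------------------------------------------------
# candidate tables
# ---------------------------------------------------------------------------

_PROVENANCE_STAGES = [s for s in STAGES if s not in ("input", "mendelian_violation")]


def candidate_to_row(cand: CandidateDNM) -> dict[str, str]:
    row = {
        "chrom": cand.chrom,
        "pos": str(cand.pos),
        "ref": cand.ref_allele,
        "alt": cand.mutant_allele,
        "child": cand.child_id,
        "background": cand.background,
        "genotype_configuration": cand.genotype_configuration,
        "status": cand.status,
        "validation": cand.validation,
    }
    for stage in _PROVENANCE_STAGES:
        verdict = cand.verdicts.get(stage)
        if verdict is None:
            row[f"filter_{stage}"] = "not_run"
        elif verdict.passed:
            ne = ",".join(verdict.not_evaluable)
            row[f"filter_{stage}"] = f"pass({ne})" if ne else "pass"
        else:
            row[f"filter_{stage}"] = ";".join(str(r) for r in verdict.reasons)
    return row


def write_candidates(
    candidates: Sequence[CandidateDNM], path: str, format: str = "tsv",
    sample_order: Optional[Sequence[str]] = None,
) -> None:
    """Write candidates with full per-filter provenance (TSV or VCF)."""
    if format == "tsv":
        fields = [
            "chrom", "pos", "ref", "alt", "child", "background",
            "genotype_configuration", "status", "validation",
        ] + [f"filter_{s}" for s in _PROVENANCE_STAGES]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
            writer.writeheader()
            for cand in candidates:
                writer.writerow(candidate_to_row(cand))
    elif format == "vcf":
        records = [c.record for c in candidates if c.record is not None]
        if sample_order is None and records:
            sample_order = list(records[0].calls)
        write_records_vcf(records, path, sample_order or [])
    else:
        raise ValueError(f"unknown candidate output format {format!r}")


def read_candidate_rows(path: str) -> list[dict[str, str]]:
    """Read back a candidate TSV as the row dicts written by write_candidates."""
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
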