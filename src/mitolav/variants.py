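"""Variant data model, VCF/TSV readers and writers, and minor-allele adjustment.

Every downstream statistic works on diploid allele counts per group
(cases = centenarian probands, controls). Counts enter as ALT/REF counts
from the pooled-sequencing estimator (or from a VCF written by it) and are
adjusted so that the ALT slot always holds the cohort *minor* allele before
any frequency or association computation.

Coordinate conventions: VCF positions are 1-based and stay 1-based
internally; BED target files are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import pysam

log = logging.getLogger(__name__)

#: Controlled vocabulary for functional consequence classes.
CONSEQUENCE_CLASSES = frozenset({
    "nonsynonymous", "synonymous", "stop_gain", "frameshift", "inframe_indel",
    "utr3", "utr5", "intronic", "upstream", "downstream", "splice",
})

#: Classes whose variants lie in protein-coding sequence.
CODING_CLASSES = frozenset({
    "nonsynonymous", "synonymous", "stop_gain", "frameshift", "inframe_indel",
})


class VariantError(ValueError):
    """Raised for malformed variant inputs."""


@dataclass(frozen=True)
class AlleleCounts:
    """Diploid allele counts for a bi-allelic site, split by group.

    ``min_*`` holds the ALT (after adjustment: minor) allele count and
    ``maj_*`` the other allele, so ``min_case + maj_case == 2 * N_cases``.
    """

    min_case: int
    maj_case: int
    min_ctrl: int
    maj_ctrl: int

    def __post_init__(self) -> None:
        for name in ("min_case", "maj_case", "min_ctrl", "maj_ctrl"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                object.__setattr__(self, name, int(v))
            if getattr(self, name) < 0:
                raise VariantError(f"negative allele count: {name}={v}")

    @property
    def total_case(self) -> int:
        return self.min_case + self.maj_case

    @property
    def total_ctrl(self) -> int:
        return self.min_ctrl + self.maj_ctrl

    @property
    def minor_cohort(self) -> int:
        return self.min_case + self.min_ctrl

    @property
    def total_cohort(self) -> int:
        return self.total_case + self.total_ctrl

    def as_table(self) -> list[list[int]]:
        """2x2 contingency table [[min_case, maj_case], [min_ctrl, maj_ctrl]]."""
        return [[self.min_case, self.maj_case], [self.min_ctrl, self.maj_ctrl]]


@dataclass
class VariantRecord:
    """One bi-allelic site with per-group counts plus annotation payload."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence_class: str
    counts: AlleleCounts
    annotations: dict[str, Any] = field(default_factory=dict)
    swapped: bool = False  # set when adjust_minor_allele exchanged REF/ALT

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise VariantError(
                f"unknown consequence class {self.consequence_class!r}"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def adjust_minor_allele(record: VariantRecord) -> VariantRecord:
    """Return a record whose ALT slot holds the cohort minor allele.

    A swap is performed only when the ALT allele is a strict cohort majority;
    an exact 50/50 tie keeps ALT as the minor allele. Idempotent.
    """
    c = record.counts
    if 2 * c.minor_cohort > c.total_cohort:
        new = AlleleCounts(
            min_case=c.maj_case, maj_case=c.min_case,
            min_ctrl=c.maj_ctrl, maj_ctrl=c.min_ctrl,
        )
        return replace(record, ref=record.alt, alt=record.ref,
                       counts=new, swapped=True)
    return record


def maf(record: VariantRecord, group: str = "cohort") -> float:
    """Minor-allele frequency in ``cases``, ``controls`` or the ``cohort``.

    The cohort value of an adjusted record is <= 0.5 by construction; a
    single-group value may exceed 0.5 because adjustment is cohort-level.
    """
    c = record.counts
    if group == "cases":
        num, den = c.min_case, c.total_case
    elif group == "controls":
        num, den = c.min_ctrl, c.total_ctrl
    elif group == "cohort":
        num, den = c.minor_cohort, c.total_cohort
    else:
        raise VariantError(f"unknown group {group!r}")
    if den == 0:
        raise VariantError(f"zero allele total for group {group!r}")
    return num / den


def maf_exact(record: VariantRecord, group: str = "cohort") -> Fraction:
    """Exact rational MAF, for boundary comparisons free of float rounding."""
    c = record.counts
    if group == "cases":
        return Fraction(c.min_case, c.total_case)
    if group == "controls":
        return Fraction(c.min_ctrl, c.total_ctrl)
    if group == "cohort":
        return Fraction(c.minor_cohort, c.total_cohort)
    raise VariantError(f"unknown group {group!r}")


# ---------------------------------------------------------------------------
# VCF + annotation TSV I/O
# ---------------------------------------------------------------------------

_INFO_FIELDS = (
    ("MINC_CASE", "A", "Integer", "ALT allele count among case chromosomes"),
    ("MINC_CTRL", "A", "Integer", "ALT allele count among control chromosomes"),
    ("N_CASE", "1", "Integer", "Number of case individuals"),
    ("N_CTRL", "1", "Integer", "Number of control individuals"),
)

#: Annotation TSV columns that are parsed into typed record fields; any
#: extra column is carried through verbatim in ``annotations``.
_TYPED_ANN = {
    "gene": str,
    "consequence_class": str,
    "aa_change": str,
    "cadd_phred": float,
    "condel_label": str,
    "regulome_rank": int,
    "vert_conserved": int,
    "invert_conserved": int,
    "regulatory_evidence": int,
    "evidence_notes": int,
}


def write_variants(records: Iterable[VariantRecord], vcf_path: str | Path,
                   ann_path: str | Path | None = None) -> None:
    """Write records to an uncompressed VCF v4.2 plus an annotation TSV.

    Counts go into INFO as MINC_CASE/MINC_CTRL/N_CASE/N_CTRL; every entry of
    ``annotations`` (plus gene / consequence class) goes to the TSV keyed by
    CHROM:POS:REF:ALT so the pair round-trips bit-exactly.
    """
    records = list(records)
    header = pysam.VariantHeader()
    contigs = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    for c in contigs:
        header.contigs.add(c)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            c = r.counts
            rec.info["MINC_CASE"] = (c.min_case,)
            rec.info["MINC_CTRL"] = (c.min_ctrl,)
            rec.info["N_CASE"] = c.total_case // 2
            rec.info["N_CTRL"] = c.total_ctrl // 2
            vcf.write(rec)
    if ann_path is not None:
        rows = []
        for r in records:
            row: dict[str, Any] = {
                "variant_key": r.key,
                "gene": r.gene,
                "consequence_class": r.consequence_class,
            }
            row.update(r.annotations)
            rows.append(row)
        pd.DataFrame(rows).to_csv(ann_path, sep="\t", index=False)


def _parse_annotation_row(row: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in row.items():
        if k == "variant_key":
            continue
        if pd.isna(v):
            continue  # explicit missing state: key absent
        caster = _TYPED_ANN.get(k)
        if caster is not None:
            try:
                out[k] = caster(v)
            except (TypeError, ValueError):
                out[k] = v  # preserve verbatim rather than fail
        elif k.startswith("maf_"):
            out[k] = float(v)
        else:
            out[k] = v  # unknown keys pass through verbatim
    return out


def read_variants(vcf_path: str | Path,
                  ann_path: str | Path | None = None) -> list[VariantRecord]:
    """Read a VCF (with count INFO fields) and join its annotation TSV.

    Multi-allelic sites are split into one record per ALT with per-ALT
    counts (INFO Number=A). Records with no matching annotation row get an
    ``intronic`` placeholder class and empty payload; unmatched annotation
    rows are logged, never fatal.
    """
    ann_by_key: dict[str, dict[str, Any]] = {}
    if ann_path is not None:
        df = pd.read_csv(ann_path, sep="\t", dtype={"variant_key": str})
        if "variant_key" not in df.columns:
            raise VariantError(
                f"annotation file {ann_path} lacks a variant_key column"
            )
        for _, row in df.iterrows():
            ann_by_key[row["variant_key"]] = _parse_annotation_row(row)

    records: list[VariantRecord] = []
    matched: set[str] = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for site in vcf:
            alts = site.alts or ()
            try:
                minc_case = site.info["MINC_CASE"]
                minc_ctrl = site.info["MINC_CTRL"]
                n_case = site.info["N_CASE"]
                n_ctrl = site.info["N_CTRL"]
            except KeyError as exc:
                raise VariantError(
                    f"{vcf_path}:{site.chrom}:{site.pos}: missing count INFO "
                    f"field {exc}"
                ) from exc
            for i, alt in enumerate(alts):
                mc, mt = int(minc_case[i]), int(minc_ctrl[i])
                counts = AlleleCounts(
                    min_case=mc, maj_case=2 * n_case - mc,
                    min_ctrl=mt, maj_ctrl=2 * n_ctrl - mt,
                )
                key = f"{site.chrom}:{site.pos}:{site.ref}:{alt}"
                ann = ann_by_key.get(key, {})
                if ann:
                    matched.add(key)
                records.append(VariantRecord(
                    chrom=site.chrom, pos=site.pos, ref=site.ref, alt=alt,
                    gene=str(ann.get("gene", "")),
                    consequence_class=str(ann.get("consequence_class",
                                                  "intronic")),
                    counts=counts,
                    annotations={k: v for k, v in ann.items()
                                 if k not in ("gene", "consequence_class")},
                ))
    unmatched = set(ann_by_key) - matched
    if unmatched:
        log.warning("%d annotation rows had no matching VCF site (e.g. %s)",
                    len(unmatched), sorted(unmatched)[:3])
    return records


def read_variants_tsv(table_path: str | Path,
                      ann_path: str | Path | None = None
                      ) -> list[VariantRecord]:
    """Read a flat TSV variant table with per-group diploid counts.

    Required columns: chrom, pos, ref, alt, min_case, maj_case, min_ctrl,
    maj_ctrl; optional gene and consequence_class travel with the record.
    An annotation TSV (keyed by variant_key) may be joined exactly as for
    the VCF reader.
    """
    df = pd.read_csv(table_path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "min_case", "maj_case",
                "min_ctrl", "maj_ctrl"}
    missing = required - set(df.columns)
    if missing:
        raise VariantError(
            f"variant table {table_path} lacks columns: {sorted(missing)}")
    ann_by_key: dict[str, dict[str, Any]] = {}
    if ann_path is not None:
        ann_df = pd.read_csv(ann_path, sep="\t",
                             dtype={"variant_key": str})
        if "variant_key" not in ann_df.columns:
            raise VariantError(
                f"annotation file {ann_path} lacks a variant_key column")
        for _, row in ann_df.iterrows():
            ann_by_key[row["variant_key"]] = _parse_annotation_row(row)
    records = []
    for _, row in df.iterrows():
        key = f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
        ann = ann_by_key.get(key, {})
        records.append(VariantRecord(
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]),
            gene=str(ann.get("gene", row.get("gene", ""))),
            consequence_class=str(ann.get(
                "consequence_class",
                row.get("consequence_class", "intronic"))),
            counts=AlleleCounts(int(row["min_case"]), int(row["maj_case"]),
                                int(row["min_ctrl"]),
                                int(row["maj_ctrl"])),
            annotations={k: v for k, v in ann.items()
                         if k not in ("gene", "consequence_class")},
        ))
    return records


def read_targets_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene/target BED (0-based half-open) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"])
    if (df["end"] <= df["start"]).any():
        raise VariantError(f"BED {path}: interval with end <= start")
    return df
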