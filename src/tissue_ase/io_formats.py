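"""Readers, writers and the internal data model.

The pipeline's on-disk surface is deliberately plain: VCF v4.x for the
heterozygous site list, samtools-mpileup six-column text for per-base
evidence, TSV for count/call tables and annotations, and BED for gene
intervals (used by the intragenic filter). Coordinates are 1-based
inclusive everywhere except BED, which is 0-based half-open; conversion
happens inside the readers.
"""

from __future__ import annotations

import enum
import logging
import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger("tissue_ase")

_VALID_BASES = frozenset("ACGT")


class VariantClass(str, enum.Enum):
    """Functional class of a heterozygous variant."""

    CONTROL = "control"
    DELETERIOUS_NSSNP = "deleterious_nsSNP"
    NONSENSE = "nonsense"


class Assay(str, enum.Enum):
    """Sequencing assay that produced an allele-count record."""

    RNA_SEQ = "rna_seq"
    MMPCR = "mmpcr"
    EXOME_DNA = "exome_dna"


@dataclass(frozen=True)
class HetSite:
    """An annotated high-confidence heterozygous SNP.

    ``pos`` follows the VCF convention (1-based). ``maf`` is the minor
    allele frequency in reference panels, ``None`` when the variant was
    not observed there; ``is_private`` marks variants absent from all
    panels. A site is "rare" when maf < 0.05 or it is private.
    """

    site_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    gene_id: str | None = None
    variant_class: VariantClass = VariantClass.CONTROL
    maf: float | None = None
    is_private: bool = False
    is_intragenic: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.site_id}: pos must be >= 1, got {self.pos}")
        if self.ref_base not in _VALID_BASES or self.alt_base not in _VALID_BASES:
            raise ValueError(
                f"{self.site_id}: alleles must be single nucleotides, "
                f"got {self.ref_base!r}/{self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.site_id}: ref and alt alleles are identical")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"{self.site_id}: maf {self.maf} outside [0,1]")

    @property
    def is_rare(self) -> bool:
        """Rare = MAF below 5% or absent from reference panels."""
        return self.is_private or self.maf is None or self.maf < 0.05


@dataclass(frozen=True)
class AlleleCountRecord:
    """Filtered read counts at one site in one tissue/replicate/assay.

    ``other_count`` aggregates reads supporting any base other than the
    two expected alleles (after base-quality filtering); it feeds the
    bi-allelic expression filter downstream.
    """

    site_id: str
    tissue_id: str
    replicate_id: str
    assay: Assay
    ref_count: int
    alt_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        for name in ("ref_count", "alt_count", "other_count"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{self.site_id}: {name} is negative ({v})")

    @property
    def total(self) -> int:
        """Bi-allelic read total (reference + alternate)."""
        return self.ref_count + self.alt_count

    @property
    def key(self) -> tuple[str, str, str, Assay]:
        return (self.site_id, self.tissue_id, self.replicate_id, self.assay)


@dataclass(frozen=True)
class SampleManifest:
    """Declared tissue/replicate layout for one assay."""

    assay: Assay
    tissue_ids: tuple[str, ...]
    replicate_ids: tuple[str, ...] = ("rep1",)
    excluded_tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.tissue_ids)) != len(self.tissue_ids):
            raise ValueError("tissue_ids must be unique within an assay")
        if not self.replicate_ids:
            raise ValueError("at least one replicate per sample")


# ---------------------------------------------------------------------------
# VCF / annotation reading
# ---------------------------------------------------------------------------

def read_het_sites(
    vcf_path: str | Path,
    annotation_table_path: str | Path | None = None,
) -> list[HetSite]:
    """Read concordant heterozygous SNPs from a VCF with >=1 DNA sample.

    A site is kept only when every genotyped sample present in the VCF is
    heterozygous (0/1) for the same ref/alt pair — the genotype-concordance
    definition of a high-confidence site. Multi-allelic records and
    non-SNPs are skipped with a warning. If an annotation table is given
    (TSV with columns chrom, pos, ref, alt and any of gene_id,
    variant_class, maf, is_private, is_intragenic), annotations are joined
    on (chrom, pos, ref, alt); annotation rows matching no VCF site are
    skipped with a warning.
    """
    vcf_path = Path(vcf_path)
    sites: list[HetSite] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{vcf_path}: VCF has no genotype columns")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"{vcf_path}:{rec.chrom}:{rec.pos} multi-allelic or ALT-less "
                    "record skipped (bi-allelic SNP model)"
                )
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES:
                warnings.warn(
                    f"{vcf_path}:{rec.chrom}:{rec.pos} non-SNP record skipped"
                )
                continue
            gts = [rec.samples[s].get("GT") for s in samples]
            if not all(gt is not None and set(gt) == {0, 1} for gt in gts):
                continue  # not heterozygous-concordant across all DNA samples
            site_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
            sites.append(
                HetSite(site_id=site_id, chrom=rec.chrom, pos=rec.pos,
                        ref_base=ref, alt_base=alt)
            )
    if annotation_table_path is not None:
        sites = _join_annotations(sites, annotation_table_path)
    logger.info("read_het_sites: %d concordant heterozygous SNPs from %s",
                len(sites), vcf_path)
    return sites


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in {"1", "true", "yes", "t"}


def _join_annotations(sites: list[HetSite], path: str | Path) -> list[HetSite]:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {sorted(missing)}")
    by_key = {(s.chrom, s.pos, s.ref_base, s.alt_base): i for i, s in enumerate(sites)}
    out = list(sites)
    for _, row in ann.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        idx = by_key.get(key)
        if idx is None:
            warnings.warn(f"annotation for unknown site {key} skipped")
            continue
        kwargs = {}
        if "gene_id" in ann.columns and pd.notna(row.get("gene_id")):
            kwargs["gene_id"] = str(row["gene_id"])
        if "variant_class" in ann.columns and pd.notna(row.get("variant_class")):
            kwargs["variant_class"] = VariantClass(str(row["variant_class"]))
        if "maf" in ann.columns and pd.notna(row.get("maf")):
            kwargs["maf"] = float(row["maf"])
        if "is_private" in ann.columns and pd.notna(row.get("is_private")):
            kwargs["is_private"] = _parse_bool(row["is_private"])
        if "is_intragenic" in ann.columns and pd.notna(row.get("is_intragenic")):
            kwargs["is_intragenic"] = _parse_bool(row["is_intragenic"])
        out[idx] = replace(out[idx], **kwargs)
    return out


def annotate_intragenic(sites: Sequence[HetSite], bed_path: str | Path) -> list[HetSite]:
    """Set ``is_intragenic`` from a BED3+name file of gene intervals.

    BED is 0-based half-open; a site at 1-based position p falls inside
    [start, end) when start <= p-1 < end. Overlapping a named interval
    also fills ``gene_id`` when the site has none.
    """
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{line_no}: malformed BED line")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    out = []
    for s in sites:
        hits = trees.get(s.chrom, IntervalTree())[s.pos - 1]
        if hits:
            gene = s.gene_id or next(iter(hits)).data
            out.append(replace(s, is_intragenic=True, gene_id=gene))
        else:
            out.append(replace(s, is_intragenic=False))
    return out


# ---------------------------------------------------------------------------
# mpileup text -> allele counts
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


def _parse_pileup_bases(bases: str, quals: str, ref_base: str) -> list[tuple[str, int]]:
    """Expand a pileup base string into (base, phred_quality) pairs.

    Handles '.'/',' (reference match), ACGT/acgt, '*' (deletion
    placeholder, consumes a quality but yields no base), read start
    '^X' (skips the mapping-quality char), read end '$', and +N/-N
    indel insertions (skipped; they carry no per-base quality).
    """
    out: list[tuple[str, int]] = []
    i = 0
    q = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise ValueError(f"malformed indel spec at offset {i} in pileup bases")
            length = int(m.group(1))
            i = m.end() + length
            continue
        if q >= len(quals):
            raise ValueError("pileup base string longer than quality string")
        qual = ord(quals[q]) - 33
        q += 1
        i += 1
        if c in ".,":
            out.append((ref_base, qual))
        elif c.upper() in _VALID_BASES or c.upper() == "N":
            out.append((c.upper(), qual))
        elif c in "*<>":
            continue  # deletion/refskip placeholder: consumes quality, no base
        else:
            raise ValueError(f"unexpected pileup character {c!r}")
    return out


def pileup_to_counts(
    mpileup_text: str | Iterable[str],
    sites: Sequence[HetSite],
    min_base_quality: int = 10,
    tissue_id: str = "sample",
    replicate_id: str = "rep1",
    assay: Assay = Assay.RNA_SEQ,
) -> list[AlleleCountRecord]:
    """Count ref/alt/other bases per site from samtools-mpileup text.

    Bases with phred quality below ``min_base_quality`` are discarded
    before counting (the upstream base-quality filter). Pileup lines for
    positions not in ``sites`` are ignored; a pileup reference base that
    contradicts the site's ref allele raises.
    """
    by_pos: dict[tuple[str, int], HetSite] = {(s.chrom, s.pos): s for s in sites}
    if isinstance(mpileup_text, str):
        lines: Iterable[str] = mpileup_text.splitlines()
    else:
        lines = mpileup_text
    records: list[AlleleCountRecord] = []
    for line_no, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"mpileup line {line_no}: expected 6 columns, got {len(parts)}")
        chrom, pos_s, ref, _depth, bases, quals = parts[:6]
        site = by_pos.get((chrom, int(pos_s)))
        if site is None:
            continue
        if ref.upper() != site.ref_base and ref.upper() != "N":
            raise ValueError(
                f"mpileup line {line_no}: reference base {ref!r} inconsistent "
                f"with site {site.site_id} ref {site.ref_base!r}"
            )
        ref_n = alt_n = other_n = 0
        for base, qual in _parse_pileup_bases(bases, quals, site.ref_base):
            if qual < min_base_quality:
                continue
            if base == site.ref_base:
                ref_n += 1
            elif base == site.alt_base:
                alt_n += 1
            else:
                other_n += 1
        records.append(
            AlleleCountRecord(
                site_id=site.site_id, tissue_id=tissue_id,
                replicate_id=replicate_id, assay=assay,
                ref_count=ref_n, alt_count=alt_n, other_count=other_n,
            )
        )
    return records


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["site_id", "tissue_id", "replicate_id", "assay",
                  "ref_count", "alt_count", "other_count"]


def read_count_table(tsv_path: str | Path) -> list[AlleleCountRecord]:
    """Read an allele-count TSV; validates keys, counts and assay labels."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"site_id": str, "tissue_id": str,
                                                "replicate_id": str})
    missing = set(_COUNT_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"{tsv_path}: missing columns {sorted(missing)}")
    if "other_count" not in df.columns:
        warnings.warn(f"{tsv_path}: other_count column missing, defaulting to 0")
        df["other_count"] = 0
    if (df[["ref_count", "alt_count", "other_count"]] < 0).to_numpy().any():
        raise ValueError(f"{tsv_path}: negative counts")
    keys = df[["site_id", "tissue_id", "replicate_id", "assay"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"{tsv_path}: duplicate record key {tuple(dup)}")
    return [
        AlleleCountRecord(
            site_id=r.site_id, tissue_id=r.tissue_id, replicate_id=r.replicate_id,
            assay=Assay(r.assay), ref_count=int(r.ref_count),
            alt_count=int(r.alt_count), other_count=int(r.other_count),
        )
        for r in df.itertuples(index=False)
    ]


def write_count_table(records: Sequence[AlleleCountRecord], tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.site_id, r.tissue_id, r.replicate_id, r.assay.value,
          r.ref_count, r.alt_count, r.other_count) for r in records],
        columns=_COUNT_COLUMNS,
    )
    df.to_csv(tsv_path, sep="\t", index=False)


_SITE_COLUMNS = ["site_id", "chrom", "pos", "ref", "alt", "gene_id",
                 "variant_class", "maf", "is_private", "is_intragenic"]


def write_sites_table(sites: Sequence[HetSite], tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.site_id, s.chrom, s.pos, s.ref_base, s.alt_base,
          s.gene_id if s.gene_id is not None else "",
          s.variant_class.value,
          s.maf if s.maf is not None else "",
          s.is_private, s.is_intragenic) for s in sites],
        columns=_SITE_COLUMNS,
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def read_sites_table(tsv_path: str | Path) -> list[HetSite]:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"site_id": str, "chrom": str})
    return [
        HetSite(
            site_id=r.site_id, chrom=r.chrom, pos=int(r.pos),
            ref_base=r.ref, alt_base=r.alt,
            gene_id=None if pd.isna(r.gene_id) or r.gene_id == "" else str(r.gene_id),
            variant_class=VariantClass(r.variant_class),
            maf=None if pd.isna(r.maf) else float(r.maf),
            is_private=_parse_bool(r.is_private),
            is_intragenic=_parse_bool(r.is_intragenic),
        )
        for r in df.itertuples(index=False)
    ]


def write_ase_table(calls: Sequence["ASECall"], tsv_path: str | Path) -> None:  # noqa: F821
    """Write ASE calls as TSV, flags as a semicolon-joined list."""
    rows = []
    for c in calls:
        rows.append({
            "site_id": c.site_id, "tissue_id": c.tissue_id,
            "replicate_id": c.replicate_id, "assay": c.assay.value,
            "ref_count": c.ref_count, "alt_count": c.alt_count,
            "other_count": c.other_count,
            "allelic_ratio": "" if c.allelic_ratio is None else f"{c.allelic_ratio:.6g}",
            "p_value": "" if c.p_value is None else f"{c.p_value:.6g}",
            "filter_flags": ";".join(sorted(f.name for f in c.filter_flags)),
            "qc_pass": c.qc_pass, "is_ase": c.is_ase,
        })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_ase_table(tsv_path: str | Path) -> list["ASECall"]:  # noqa: F821
    from .ase_core import ASECall, FilterFlag

    df = pd.read_csv(tsv_path, sep="\t", dtype={"site_id": str, "tissue_id": str,
                                                "replicate_id": str},
                     keep_default_na=False, na_values=[""])
    calls = []
    for r in df.itertuples(index=False):
        flags = frozenset(
            FilterFlag[name] for name in str(r.filter_flags).split(";")
            if name and name != "nan"
        ) if pd.notna(r.filter_flags) else frozenset()
        calls.append(ASECall(
            site_id=r.site_id, tissue_id=r.tissue_id, replicate_id=r.replicate_id,
            assay=Assay(r.assay), ref_count=int(r.ref_count),
            alt_count=int(r.alt_count), other_count=int(r.other_count),
            allelic_ratio=None if pd.isna(r.allelic_ratio) else float(r.allelic_ratio),
            p_value=None if pd.isna(r.p_value) else float(r.p_value),
            filter_flags=flags, qc_pass=bool(r.qc_pass), is_ase=bool(r.is_ase),
        ))
    return calls
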