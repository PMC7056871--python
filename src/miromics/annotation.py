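"""miRNA-related genomic regions and SNP/CpG annotation.

Builds the candidate regions around precursor miRNAs (a symmetric flank,
default +/-2 kb, plus the precursor and mature sequences themselves), maps
SNPs and CpG probes into them, and merges region-scan SNP catalogs with
externally curated miR-eQTL catalogs into one deduplicated candidate set.

Coordinates: every input format that is 1-based inclusive (GFF3, Illumina
manifests, SNP catalog TSVs, VCF) is converted exactly once, at read time, to
the internal 0-based half-open convention; writers convert back. BED input is
already 0-based half-open and is passed through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pysam
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: region_class specificity used when one site hits several classes of the
#: same miRNA (most specific wins).
REGION_SPECIFICITY = {"mature": 3, "precursor": 2, "flank": 1, "eqtl": 0}


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open internally."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start < 0: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int, strand: str = "unknown"):
        """Build from 1-based inclusive coordinates (GFF3/manifest style)."""
        return cls(chrom, start1 - 1, end1, strand)

    def to_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end


@dataclass
class MirnaRecord:
    """One precursor miRNA with its mature products and genomic context."""

    mirna_id: str
    precursor_interval: GenomicInterval
    mature_ids: list[str] = field(default_factory=list)
    mature_intervals: list[GenomicInterval] = field(default_factory=list)
    genomic_context: str = "intergenic"

    def __post_init__(self) -> None:
        if self.mature_intervals and not self.mature_ids:
            raise ValueError(f"{self.mirna_id}: mature intervals without ids")
        for iv in self.mature_intervals:
            if not self.precursor_interval.contains_interval(iv):
                raise ValueError(
                    f"{self.mirna_id}: mature interval {iv} outside precursor"
                )


@dataclass
class SiteRecord:
    """A SNP or CpG site as read from an input catalog (pos is 1-based)."""

    site_id: str
    site_kind: str  # snp | cpg
    chrom: str
    pos: int
    alleles: tuple[str, str] | None = None
    sources: frozenset[str] = frozenset({"region_scan"})
    mirna_ids: tuple[str, ...] = ()  # used by eQTL catalogs (direct mapping)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.site_id}: pos must be >= 1")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class SiteAnnotation:
    """A site assigned to one or more miRNAs with its best region class."""

    site_id: str
    site_kind: str
    chrom: str
    pos: int
    mirna_ids: list[str]
    region_class: str
    distance_to_precursor: float  # signed bp; NaN for eqtl annotations


Region = tuple[str, str, GenomicInterval]  # (mirna_id, region_class, interval)


def build_mirna_regions(
    records: Iterable[MirnaRecord], flank_bp: int
) -> list[Region]:
    """Emit flank / precursor / mature regions for each miRNA record.

    The flank region is the precursor extended symmetrically by ``flank_bp``
    on both sides (strand-agnostic), clipped at position 0. Records with a
    malformed precursor interval are skipped with a warning rather than
    aborting the scan.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    regions: list[Region] = []
    for rec in records:
        iv = rec.precursor_interval
        try:
            flank = GenomicInterval(
                iv.chrom, max(0, iv.start - flank_bp), iv.end + flank_bp, iv.strand
            )
        except ValueError as exc:  # pragma: no cover - guarded by MirnaRecord
            log.warning("skipping %s: %s", rec.mirna_id, exc)
            continue
        regions.append((rec.mirna_id, "flank", flank))
        regions.append((rec.mirna_id, "precursor", iv))
        for mature_iv in rec.mature_intervals:
            regions.append((rec.mirna_id, "mature", mature_iv))
    return regions


def _check_chrom_schemes(site_chroms: set[str], region_chroms: set[str]) -> None:
    """Hard error when the two inputs use different chromosome dialects."""

    def norm(c: str) -> str:
        return c[3:] if c.lower().startswith("chr") else c

    if site_chroms & region_chroms:
        return
    norm_regions = {norm(c) for c in region_chroms}
    offending = sorted(c for c in site_chroms if norm(c) in norm_regions)
    if offending:
        raise ValueError(
            "chromosome naming mismatch between sites and regions: "
            f"site labels {offending} vs region labels {sorted(region_chroms)}"
        )


def _signed_distance(pos0: int, precursor: GenomicInterval) -> int:
    """Signed bp from a site to the precursor: negative upstream (by strand),
    0 inside."""
    if precursor.contains(pos0):
        return 0
    if pos0 < precursor.start:
        d = pos0 - precursor.start  # negative, upstream on + strand
    else:
        d = pos0 - (precursor.end - 1)  # positive, downstream on + strand
    if precursor.strand == "-":
        d = -d
    return d


def map_sites_to_regions(
    sites: Sequence[SiteRecord], regions: Sequence[Region]
) -> list[SiteAnnotation]:
    """Assign each site to the miRNA regions covering it.

    A site at 1-based ``pos`` hits a region iff ``start <= pos-1 < end``.
    Per miRNA the most specific class wins (mature > precursor > flank); a
    site covered by several miRNAs yields one annotation listing them all,
    carrying the most specific class reached for any of them. Sites outside
    every region are dropped.
    """
    if not sites:
        return []
    precursors = {
        mid: iv for mid, cls, iv in regions if cls == "precursor"
    }
    site_chroms = {s.chrom for s in sites}
    region_chroms = {iv.chrom for _, _, iv in regions}
    if regions:
        _check_chrom_schemes(site_chroms, region_chroms)

    trees: dict[str, IntervalTree] = {}
    for mid, cls, iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (mid, cls))

    out: list[SiteAnnotation] = []
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        best_per_mirna: dict[str, str] = {}
        for hit in tree.at(site.pos0):
            mid, cls = hit.data
            prev = best_per_mirna.get(mid)
            if prev is None or REGION_SPECIFICITY[cls] > REGION_SPECIFICITY[prev]:
                best_per_mirna[mid] = cls
        if not best_per_mirna:
            continue
        top_class = max(best_per_mirna.values(), key=REGION_SPECIFICITY.get)
        mirna_ids = sorted(best_per_mirna)
        # distance relative to the nearest precursor among the hit miRNAs
        dists = [
            _signed_distance(site.pos0, precursors[m])
            for m in mirna_ids
            if m in precursors
        ]
        distance = min(dists, key=abs) if dists else float("nan")
        out.append(
            SiteAnnotation(
                site_id=site.site_id,
                site_kind=site.site_kind,
                chrom=site.chrom,
                pos=site.pos,
                mirna_ids=mirna_ids,
                region_class=top_class,
                distance_to_precursor=distance,
            )
        )
    return out


def annotate_eqtl_sites(eqtl_snps: Sequence[SiteRecord]) -> list[SiteAnnotation]:
    """Annotations for eQTL-catalog SNPs: direct SNP-to-miRNA mapping, class
    ``eqtl``, no distance requirement (most miR-eQTLs are distal)."""
    return [
        SiteAnnotation(
            site_id=s.site_id,
            site_kind=s.site_kind,
            chrom=s.chrom,
            pos=s.pos,
            mirna_ids=sorted(s.mirna_ids),
            region_class="eqtl",
            distance_to_precursor=float("nan"),
        )
        for s in eqtl_snps
    ]


def merge_snp_catalogs(
    region_snps: Sequence[SiteRecord], eqtl_snps: Sequence[SiteRecord]
) -> list[SiteRecord]:
    """Union two SNP catalogs by rsID, deduplicating shared SNPs.

    A SNP present in both keeps both source tags (and the union of any
    direct miRNA assignments). Conflicting positions for one rsID raise.
    """
    merged: dict[str, SiteRecord] = {}
    conflicts: list[str] = []
    for snp in list(region_snps) + list(eqtl_snps):
        if snp.site_id not in merged:
            merged[snp.site_id] = snp
            continue
        prev = merged[snp.site_id]
        if (prev.chrom, prev.pos) != (snp.chrom, snp.pos):
            conflicts.append(snp.site_id)
            continue
        merged[snp.site_id] = SiteRecord(
            site_id=prev.site_id,
            site_kind=prev.site_kind,
            chrom=prev.chrom,
            pos=prev.pos,
            alleles=prev.alleles or snp.alleles,
            sources=prev.sources | snp.sources,
            mirna_ids=tuple(sorted(set(prev.mirna_ids) | set(snp.mirna_ids))),
        )
    if conflicts:
        raise ValueError(
            f"conflicting positions for rsIDs: {sorted(set(conflicts))}"
        )
    return list(merged.values())


# ---------------------------------------------------------------------------
# Readers / writers


def read_mirna_gff3(path: str | Path) -> list[MirnaRecord]:
    """Read a miRBase-dialect GFF3 (``miRNA_primary_transcript`` + ``miRNA``
    features with ``ID=``/``Name=`` attributes and ``Derives_from`` links)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    records: dict[str, MirnaRecord] = {}
    id_to_name: dict[str, str] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        fid = feat.attributes.get("ID", [feat.id])[0]
        id_to_name[fid] = name
        try:
            iv = GenomicInterval.from_1based(feat.seqid, feat.start, feat.end, feat.strand or "unknown")
        except ValueError as exc:
            log.warning("skipping precursor %s: %s", name, exc)
            continue
        records[name] = MirnaRecord(mirna_id=name, precursor_interval=iv)
    for feat in db.features_of_type("miRNA"):
        parent = feat.attributes.get("Derives_from", [None])[0]
        pname = id_to_name.get(parent)
        if pname is None or pname not in records:
            log.warning("mature %s has no known precursor", feat.id)
            continue
        rec = records[pname]
        name = feat.attributes.get("Name", [feat.id])[0]
        try:
            iv = GenomicInterval.from_1based(feat.seqid, feat.start, feat.end, feat.strand or "unknown")
            if not rec.precursor_interval.contains_interval(iv):
                raise ValueError("mature outside precursor")
        except ValueError as exc:
            log.warning("skipping mature %s: %s", name, exc)
            continue
        rec.mature_ids.append(name)
        rec.mature_intervals.append(iv)
    return list(records.values())


def read_snp_catalog_tsv(path: str | Path, default_source: str = "region_scan") -> list[SiteRecord]:
    """Read a SNP catalog TSV: ``rsid, chrom, pos, a1, a2[, source[, mirna]]``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        alleles = None
        if getattr(row, "a1", None) and isinstance(row.a1, str):
            alleles = (row.a1, row.a2)
        source = getattr(row, "source", default_source) or default_source
        mirna = getattr(row, "mirna", "")
        mirna_ids = tuple(str(mirna).split(";")) if isinstance(mirna, str) and mirna else ()
        out.append(
            SiteRecord(
                site_id=row.rsid,
                site_kind="snp",
                chrom=str(row.chrom),
                pos=int(row.pos),
                alleles=alleles,
                sources=frozenset({source}),
                mirna_ids=mirna_ids,
            )
        )
    return out


def read_snp_catalog_vcf(path: str | Path, source: str = "region_scan") -> list[SiteRecord]:
    """Read a sites-only VCF as a SNP catalog (REF/ALT become the alleles)."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            out.append(
                SiteRecord(
                    site_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    site_kind="snp",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    alleles=(alt, rec.ref),
                    sources=frozenset({source}),
                )
            )
    return out


def read_cpg_manifest(path: str | Path) -> list[SiteRecord]:
    """Read an Illumina-450K-like probe manifest TSV: ``probe_id, chrom, pos``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SiteRecord(site_id=r.probe_id, site_kind="cpg", chrom=str(r.chrom),
                   pos=int(r.pos), sources=frozenset({"manifest"}))
        for r in df.itertuples(index=False)
    ]


def read_gene_intervals_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read gene intervals from BED (0-based half-open; name in column 4)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str},
    )
    return [
        (str(r.name), GenomicInterval(str(r.chrom), int(r.start), int(r.end)))
        for r in df.itertuples(index=False)
    ]


def annotations_to_frame(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    """Long-format table with one row per (site, miRNA) pair."""
    rows = [
        {
            "site_id": a.site_id,
            "site_kind": a.site_kind,
            "chrom": a.chrom,
            "pos": a.pos,
            "mirna_id": mid,
            "region_class": a.region_class,
            "distance": a.distance_to_precursor,
        }
        for a in annotations
        for mid in a.mirna_ids
    ]
    return pd.DataFrame(
        rows,
        columns=["site_id", "site_kind", "chrom", "pos", "mirna_id",
                 "region_class", "distance"],
    )


def write_annotation_tsv(annotations: Sequence[SiteAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)
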