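"""Per-sample annotated variant calls: ingest and quality filtering.

Variants arrive already aligned, called and gene-annotated (the upstream
BWA/GATK/Strelka2/Annovar stages are out of scope). Two carriers are
supported: VCF v4.2 with per-sample GT/GQ/AD and a gene-symbol INFO tag, and
a flat annotated-variant TSV.

Quality filtering follows the WES convention for FFPE-derived calls:
genotype quality GQ strictly greater than 30 and alternate-allele read depth
AD strictly greater than 10. Formalin fixation induces artificial C>T (and
complementary G>A) miscalls; SNV records with those allele pairs are flagged
``ffpe_suspect`` and can optionally be dropped for sensitivity analysis.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)

_TSV_HEADER = ["sample_id", "chrom", "pos", "ref", "alt", "gene", "GQ", "AD"]


class VariantKey(NamedTuple):
    """Sample-independent identity of a variant; totally ordered for
    deterministic output (chrom lexicographic, then pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str


class AnnotatedVariant(NamedTuple):
    """One called, gene-annotated variant allele for one sample.

    Coordinates are 1-based (VCF convention). ``ffpe_suspect`` is true iff
    the record is an SNV with (ref, alt) equal to (C, T) or (G, A); indels
    always get False.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    gq: float
    ad_alt: int
    ffpe_suspect: bool

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


def is_ffpe_suspect(ref: str, alt: str) -> bool:
    """Formalin-artifact allele rule: single-nucleotide C>T or G>A."""
    return (ref, alt) in (("C", "T"), ("G", "A"))


def annotated_variant(
    sample_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: str,
    gq: float,
    ad_alt: int,
) -> AnnotatedVariant:
    """Validating constructor; derives ``ffpe_suspect`` from the alleles."""
    pos = int(pos)
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if not ref or not alt:
        raise ValueError("ref and alt alleles must be non-empty")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}) at {chrom}:{pos}")
    if gq < 0:
        raise ValueError(f"GQ must be non-negative, got {gq}")
    ad_alt = int(ad_alt)
    if ad_alt < 0:
        raise ValueError(f"AD must be non-negative, got {ad_alt}")
    return AnnotatedVariant(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene.upper(),
        gq=float(gq),
        ad_alt=ad_alt,
        ffpe_suspect=is_ffpe_suspect(ref, alt),
    )


def read_annotated_variants(
    path: str | Path, format: str = "tsv", gene_tag: str = "GENE"
) -> list[AnnotatedVariant]:
    """Read per-sample annotated variants from a TSV or VCF file.

    Multi-allelic VCF records are decomposed into one record per alternate
    allele a sample carries. Records without a gene annotation are dropped
    and the drop count logged.
    """
    if format == "tsv":
        return _read_tsv(Path(path))
    if format == "vcf":
        return _read_vcf(Path(path), gene_tag)
    raise ValueError(f"unknown variant format {format!r}; expected 'tsv' or 'vcf'")


def _read_tsv(path: Path) -> list[AnnotatedVariant]:
    out: list[AnnotatedVariant] = []
    dropped = 0
    with path.open("rt", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _TSV_HEADER:
            raise ValueError(
                f"{path}: expected header {_TSV_HEADER}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(_TSV_HEADER):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_TSV_HEADER)} fields, got {len(row)}"
                )
            sample_id, chrom, pos, ref, alt, gene, gq, ad = row
            if not gene.strip():
                dropped += 1
                continue
            try:
                out.append(
                    annotated_variant(
                        sample_id, chrom, int(pos), ref, alt, gene, float(gq), int(ad)
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if dropped:
        logger.info(
            "read_annotated_variants(%s): dropped %d records without gene annotation",
            path,
            dropped,
        )
    return out


def _read_vcf(path: Path, gene_tag: str) -> list[AnnotatedVariant]:
    import pysam

    out: list[AnnotatedVariant] = []
    dropped = 0
    with pysam.VariantFile(str(path)) as vf:
        if gene_tag not in vf.header.info:
            raise ValueError(
                f"{path}: INFO tag {gene_tag!r} not declared in the VCF header"
            )
        for rec in vf:
            gene = rec.info.get(gene_tag)
            if isinstance(gene, tuple):
                gene = gene[0] if gene else None
            if not gene:
                dropped += sum(
                    1 for s in rec.samples.values() if any(a for a in (s.get("GT") or ()))
                )
                continue
            alts = rec.alts or ()
            for sample_name, sample in rec.samples.items():
                gt = tuple(a for a in (sample.get("GT") or ()) if a is not None)
                if not gt:
                    continue
                gq = sample.get("GQ")
                ad = sample.get("AD")
                for alt_index, alt in enumerate(alts, start=1):
                    if alt_index not in gt:
                        continue
                    ad_alt = 0
                    if ad is not None and len(ad) > alt_index and ad[alt_index] is not None:
                        ad_alt = int(ad[alt_index])
                    out.append(
                        annotated_variant(
                            sample_name,
                            rec.chrom,
                            rec.pos,
                            rec.ref,
                            alt,
                            str(gene),
                            float(gq) if gq is not None else 0.0,
                            ad_alt,
                        )
                    )
    if dropped:
        logger.info(
            "read_annotated_variants(%s): dropped %d sample records without %s annotation",
            path,
            dropped,
            gene_tag,
        )
    return out


def write_variants_tsv(
    variants: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    """Write variants in the annotated-variant TSV dialect, sorted by
    (sample_id, VariantKey) for deterministic output."""
    rows = sorted(variants, key=lambda v: (v.sample_id, v.key))
    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for v in rows:
            gq = format(v.gq, ".17g")
            fh.write(
                f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}\t{gq}\t{v.ad_alt}\n"
            )


def apply_quality_filters(
    variants: Iterable[AnnotatedVariant],
    gq_min: float = 30.0,
    ad_min: int = 10,
    ffpe_mode: str = "flag",
) -> list[AnnotatedVariant]:
    """Retain records with GQ > gq_min and AD > ad_min (strict inequalities).

    ``ffpe_mode="flag"`` keeps formalin-artifact suspects (annotated);
    ``"drop"`` removes them. The operation is idempotent. Filter tallies are
    logged.
    """
    if gq_min < 0 or ad_min < 0:
        raise ValueError("quality thresholds must be non-negative")
    if ffpe_mode not in ("flag", "drop"):
        raise ValueError(f"unknown ffpe_mode {ffpe_mode!r}; expected 'flag' or 'drop'")
    kept: list[AnnotatedVariant] = []
    n_quality = n_ffpe = n_in = 0
    for v in variants:
        n_in += 1
        if not (v.gq > gq_min and v.ad_alt > ad_min):
            n_quality += 1
            continue
        if ffpe_mode == "drop" and v.ffpe_suspect:
            n_ffpe += 1
            continue
        kept.append(v)
    logger.info(
        "apply_quality_filters: %d in, %d failed GQ/AD, %d FFPE-dropped, %d kept",
        n_in,
        n_quality,
        n_ffpe,
        len(kept),
    )
    return kept
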