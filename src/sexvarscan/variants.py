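"""Genotype-pattern filtering of per-sample variant calls.

This is the core of the discovery design: per-sample variant-only VCFs are
quality-filtered (males) or deliberately left unfiltered (females), merged
on (contig, pos, ref, alt) keys, and screened for two genotype patterns:

* species-fixed variants - homozygous ALT (1/1) in every cohort sample, so
  AF = AC/AN = 1 relative to the cross-species reference;
* sex-associated variants - 1/1 in all males while every female is 0/1,
  0/0 or recordless, gated on per-sample read depth > 2 so that a missing
  female record reflects reference homozygosity rather than no coverage.

Spacing and 10 kb per-segment statistics summarise the genomic distribution
of any resulting site list.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from .depth import DepthMatrix

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

GT_MISSING = None
GT_HOM_REF = "0/0"
GT_HET = "0/1"
GT_HOM_ALT = "1/1"


class VariantFormatError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant call in one sample (multi-allelic records are
    split into per-ALT records with genotypes recoded against that ALT)."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotype: str  # "0/0", "0/1" or "1/1"
    sample: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt or self.ref == self.alt:
            raise VariantFormatError(
                f"{self.contig}:{self.pos}: ref/alt must be non-empty and differ"
            )
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise VariantFormatError(
                    f"{self.contig}:{self.pos}: non-ACGT allele {allele!r}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def read_vcf(path: str | Path, sample: str | None = None) -> Iterator[VariantRecord]:
    """Stream per-ALT :class:`VariantRecord` objects from a single-sample VCF.

    Multi-allelic rows are split: for ALT number k, the genotype is recoded
    by counting alleles equal to k (0 -> 0/0, 1 -> 0/1, 2 -> 1/1). Rows with
    missing or non-diploid genotypes are skipped.
    """
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if len(vcf_samples) != 1:
            raise VariantFormatError(f"{path}: expected a single-sample VCF")
        sample_name = sample or vcf_samples[0]
        for rec in vcf:
            gt = rec.samples[vcf_samples[0]].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                continue
            qual = float(rec.qual) if rec.qual is not None else 0.0
            for k, alt in enumerate(rec.alts or (), start=1):
                if alt is None or alt == "<*>" or alt == ".":
                    continue
                n_alt = sum(1 for a in gt if a == k)
                genotype = {0: GT_HOM_REF, 1: GT_HET, 2: GT_HOM_ALT}[n_alt]
                yield VariantRecord(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    qual=qual,
                    genotype=genotype,
                    sample=sample_name,
                )


def filter_quality(
    records: Iterable[VariantRecord], min_qual: float = 30.0
) -> Iterator[VariantRecord]:
    """Keep records with QUAL strictly greater than ``min_qual`` (a record
    at exactly the threshold is removed); input order preserved."""
    return (r for r in records if r.qual > min_qual)


@dataclass
class MergedSite:
    """One (contig, pos, ref, alt) key with genotypes across the cohort.

    Samples without a record at the key carry a missing genotype. Allele
    counts follow the merged-VCF convention: AC counts ALT alleles over
    called genotypes, AN counts called alleles (2 per non-missing sample),
    AF = AC/AN as an exact rational comparison.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, str | None] = field(default_factory=dict)

    _ALT_DOSE = {GT_HOM_REF: 0, GT_HET: 1, GT_HOM_ALT: 2}

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def ac(self) -> int:
        return sum(self._ALT_DOSE[g] for g in self.genotypes.values() if g is not None)

    @property
    def an(self) -> int:
        return 2 * sum(1 for g in self.genotypes.values() if g is not None)

    @property
    def af(self) -> float | None:
        return self.ac / self.an if self.an else None


def merge_samples(
    streams: Mapping[str, Iterable[VariantRecord]],
    samples: Sequence[str] | None = None,
) -> list[MergedSite]:
    """Merge per-sample record streams into one site list keyed by
    (contig, pos, ref, alt), sorted by genomic coordinate.

    Positions at which samples disagree on the REF allele cannot be merged
    onto a common key; all keys at such a position are excluded and the
    count of excluded positions is logged.
    """
    samples = list(samples) if samples is not None else list(streams)
    sites: dict[tuple[str, int, str, str], MergedSite] = {}
    refs_at: dict[tuple[str, int], set[str]] = defaultdict(set)
    for sample in samples:
        for rec in streams[sample]:
            refs_at[(rec.contig, rec.pos)].add(rec.ref)
            site = sites.get(rec.key)
            if site is None:
                site = MergedSite(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alt,
                    genotypes={s: GT_MISSING for s in samples},
                )
                sites[rec.key] = site
            site.genotypes[sample] = rec.genotype
    conflicted = {k for k, refs in refs_at.items() if len(refs) > 1}
    if conflicted:
        logger.warning(
            "merge_samples: excluded %d position(s) with conflicting REF alleles",
            len(conflicted),
        )
    merged = [
        s for k, s in sites.items() if (s.contig, s.pos) not in conflicted
    ]
    merged.sort(key=lambda s: s.key)
    return merged


def interspecies_fixed_variants(
    merged: Iterable[MergedSite], n_samples: int = 10
) -> list[MergedSite]:
    """Sites homozygous ALT (1/1) in every one of ``n_samples`` samples,
    i.e. AN = 2n and AF = AC/AN = 1 exactly; any missing genotype
    disqualifies the site."""
    out = []
    for site in merged:
        called = [g for g in site.genotypes.values() if g is not None]
        if len(called) == n_samples and all(g == GT_HOM_ALT for g in called):
            out.append(site)
    return out


def sex_associated_variants(
    male_merged: Iterable[MergedSite],
    female_merged: Iterable[MergedSite],
    depth: DepthMatrix,
    min_depth_exclusive: int = 2,
) -> list[MergedSite]:
    """Sites 1/1 in all males and 0/1, 0/0 or recordless in every female,
    with per-sample depth strictly greater than ``min_depth_exclusive`` in
    every cohort sample at the position.

    ``male_merged`` must come from quality-filtered male calls;
    ``female_merged`` from deliberately unfiltered female calls, so that a
    low-quality female ALT still vetoes the site. A female 1/1 at the
    position - at any ALT allele - disqualifies it. Sites absent from the
    depth matrix raise, because the coverage gate cannot be evaluated.
    """
    female_by_pos: dict[tuple[str, int], list[MergedSite]] = defaultdict(list)
    for site in female_merged:
        female_by_pos[(site.contig, site.pos)].append(site)

    out: list[MergedSite] = []
    for site in male_merged:
        called = [g for g in site.genotypes.values() if g is not None]
        if len(called) != len(site.genotypes) or any(g != GT_HOM_ALT for g in called):
            continue
        # rule (b): every female 0/1, 0/0 or absent; any female 1/1 at the
        # position (any ALT) vetoes
        female_ok = True
        for fsite in female_by_pos.get((site.contig, site.pos), []):
            if any(g == GT_HOM_ALT for g in fsite.genotypes.values() if g is not None):
                female_ok = False
                break
        if not female_ok:
            continue
        if site.contig not in depth.depth:
            raise KeyError(
                f"site {site.contig}:{site.pos} absent from depth matrix; "
                "coverage gate cannot be evaluated"
            )
        d = depth.depth_at(site.contig, site.pos)
        if (d > min_depth_exclusive).all():
            merged_gt = dict(site.genotypes)
            for fsite in female_by_pos.get((site.contig, site.pos), []):
                if fsite.key[2:] == site.key[2:]:
                    merged_gt.update(
                        {s: g for s, g in fsite.genotypes.items() if g is not None}
                    )
            out.append(
                MergedSite(
                    contig=site.contig,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alt,
                    genotypes=merged_gt,
                )
            )
    return out


class VariantClass(enum.Enum):
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"
    MNP_OTHER = "MNP-other"


def classify_variant(ref: str, alt: str) -> VariantClass:
    """SNP / insertion / deletion / MNP-other classification from alleles.

    Insertions and deletions follow VCF left-anchoring: the shorter allele
    is a prefix-sharing contraction of the longer one. Equal-length
    multi-base substitutions are MNP-other (excluded from SNP/indel pies).
    """
    for allele in (ref, alt):
        if not allele or not set(allele) <= _VALID_BASES:
            raise VariantFormatError(f"non-ACGT allele {allele!r}")
    if ref == alt:
        raise VariantFormatError("ref and alt must differ")
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNP
    if len(alt) > len(ref) and alt[0] == ref[0]:
        return VariantClass.INSERTION
    if len(ref) > len(alt) and ref[0] == alt[0]:
        return VariantClass.DELETION
    return VariantClass.MNP_OTHER


def variant_class_proportions(sites: Iterable[MergedSite]) -> dict[str, float]:
    """Percentage of SNP / insertion / deletion / MNP-other over a site
    list; percentages sum to 100 on non-empty input."""
    counts = {cls: 0 for cls in VariantClass}
    total = 0
    for site in sites:
        counts[classify_variant(site.ref, site.alt)] += 1
        total += 1
    if total == 0:
        return {cls.value: 0.0 for cls in VariantClass}
    return {cls.value: 100.0 * counts[cls] / total for cls in VariantClass}


@dataclass
class SpacingStats:
    """Distances between consecutive variants within each contig."""

    distances: dict[str, list[int]]
    mean_distance: float | None

    @property
    def n_distances(self) -> int:
        return sum(len(v) for v in self.distances.values())


def variant_spacing_stats(
    sites: Iterable[MergedSite] | Iterable[tuple[str, int]],
) -> SpacingStats:
    """Consecutive within-contig distances (bp) between variant positions.

    Cross-contig pairs contribute nothing; contigs with fewer than two
    variants contribute nothing; the mean is None when no distance exists.
    Duplicate positions (e.g. the same position under two ALT keys) are
    collapsed before differencing, so distances are strictly positive.
    """
    by_contig: dict[str, set[int]] = defaultdict(set)
    for site in sites:
        contig, pos = (site.contig, site.pos) if isinstance(site, MergedSite) else site
        by_contig[contig].add(pos)
    distances: dict[str, list[int]] = {}
    all_d: list[int] = []
    for contig, posset in sorted(by_contig.items()):
        pos = sorted(posset)
        d = [b - a for a, b in zip(pos, pos[1:])]
        if d:
            distances[contig] = d
            all_d.extend(d)
    mean = float(np.mean(all_d)) if all_d else None
    return SpacingStats(distances=distances, mean_distance=mean)


@dataclass
class SegmentCounts:
    """Variant counts in consecutive fixed-length windows over all contigs.

    Windows are anchored at position 1 of every contig, non-overlapping,
    ``window`` bp long; the final partial window is retained. The
    including-empty mean averages over every window implied by the contig
    lengths; the excluding-empty mean over windows with >= 1 variant.
    """

    window: int
    counts: dict[str, np.ndarray]

    @property
    def total_variants(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    @property
    def n_windows(self) -> int:
        return int(sum(len(c) for c in self.counts.values()))

    @property
    def n_nonempty_windows(self) -> int:
        return int(sum((c > 0).sum() for c in self.counts.values()))

    @property
    def n_contigs_with_variants(self) -> int:
        return sum(1 for c in self.counts.values() if (c > 0).any())

    @property
    def mean_including_empty(self) -> float | None:
        n = self.n_windows
        return self.total_variants / n if n else None

    @property
    def mean_excluding_empty(self) -> float | None:
        n = self.n_nonempty_windows
        return self.total_variants / n if n else None


def per_segment_counts(
    sites: Iterable[MergedSite] | Iterable[tuple[str, int]],
    contig_lengths: Mapping[str, int],
    window: int = 10_000,
) -> SegmentCounts:
    """Count variant sites per non-overlapping ``window`` bp segment.

    A site's window index is ``(pos - 1) // window``. Sites on unknown
    contigs or beyond the stated contig length raise, because the implied
    window grid would be wrong.
    """
    counts = {
        contig: np.zeros(-(-length // window), dtype=np.int64)
        for contig, length in contig_lengths.items()
    }
    for site in sites:
        contig, pos = (site.contig, site.pos) if isinstance(site, MergedSite) else site
        if contig not in counts:
            raise ValueError(f"site on contig {contig!r} absent from contig lengths")
        if not 1 <= pos <= contig_lengths[contig]:
            raise ValueError(
                f"site {contig}:{pos} beyond contig length {contig_lengths[contig]}"
            )
        counts[contig][(pos - 1) // window] += 1
    return SegmentCounts(window=window, counts=counts)
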