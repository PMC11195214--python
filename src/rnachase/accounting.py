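"""Fragment-level RNA-class accounting.

Two distinct counting procedures live here, mirroring two distinct needs:

* :func:`classify_fragment` assigns each whole fragment to one RNA class
  (exon / intron / antisense variants / intergenic / ambiguous); a fragment
  touching both exon and intron of its single gene counts as exonic.
* :func:`fractional_counts` splits each fragment's mass by aligned base, so
  a fragment contributes ``overlap / aligned_length`` to each feature; over
  any partition of the genome the per-fragment mass sums to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import FeatureSet, GeneModel
from .intervals import GenomicInterval, IntervalIndex, blocks_sorted_disjoint, merge_spans

logger = logging.getLogger(__name__)

EXON = "exon"
INTRON = "intron"
EXON_ANTISENSE = "exon_antisense"
INTRON_ANTISENSE = "intron_antisense"
INTERGENIC = "intergenic"
AMBIGUOUS = "ambiguous"
CLASSES = (EXON, INTRON, EXON_ANTISENSE, INTRON_ANTISENSE, INTERGENIC, AMBIGUOUS)

DEFAULT_MAPQ_MIN = 255


class EmptySampleError(ValueError):
    """Raised when a sample retains zero fragments after filtering."""


@dataclass(frozen=True, slots=True)
class AlignedFragment:
    """One sequenced paired-end fragment as genomic alignment blocks.

    ``blocks`` is the merged, sorted, non-overlapping union of both mates'
    aligned blocks (the unsequenced insert gap is excluded). ``mate_blocks``
    optionally preserves the per-mate block lists, which is needed to
    distinguish splice gaps from the insert gap (isoform compatibility).
    ``strand`` is the transcription strand after protocol decoding.
    """

    name: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str
    mapq: int = 255
    mate_blocks: tuple[tuple[tuple[int, int], ...], ...] | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"fragment {self.name}: no aligned blocks")
        if not blocks_sorted_disjoint(self.blocks):
            raise ValueError(
                f"fragment {self.name}: blocks must be sorted and non-overlapping"
            )

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


def merge_blocks(blocks: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and coalesce overlapping or touching blocks."""
    return tuple(merge_spans(blocks))


def _decode_strand(r1, r2, strandedness: str) -> str:
    """Transcription strand of a pair under the given protocol convention."""
    if strandedness == "reverse":  # dUTP-style: mate 2 carries the strand
        ref = r2 if r2 is not None else r1
        flip = ref is r1
    elif strandedness == "forward":
        ref = r1 if r1 is not None else r2
        flip = ref is r2
    else:
        raise ValueError(f"unknown strandedness {strandedness!r}")
    strand = "-" if ref.is_reverse else "+"
    if flip:
        strand = "-" if strand == "+" else "+"
    return strand


def read_fragments(
    path: str | Path,
    strandedness: str = "reverse",
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> tuple[list[AlignedFragment], int]:
    """Read a SAM/BAM file into fragments, pairing mates by name.

    Returns the retained fragments and the count excluded by the MAPQ
    threshold. Secondary/supplementary/unmapped records are skipped.
    """
    fragments: list[AlignedFragment] = []
    excluded = 0
    pending: dict[str, pysam.AlignedSegment] = {}
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for read in af:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if not read.is_paired:
                    frag = _build_fragment(read, None, strandedness)
                    if frag.mapq < mapq_min:
                        excluded += 1
                    else:
                        fragments.append(frag)
                    continue
                mate = pending.pop(read.query_name, None)
                if mate is None:
                    pending[read.query_name] = read
                    continue
                r1, r2 = (read, mate) if read.is_read1 else (mate, read)
                frag = _build_fragment(r1, r2, strandedness)
                if frag.mapq < mapq_min:
                    excluded += 1
                else:
                    fragments.append(frag)
    finally:
        pysam.set_verbosity(save)
    for read in pending.values():  # orphaned mates: keep as single-ended
        frag = _build_fragment(
            read if read.is_read1 else None,
            read if not read.is_read1 else None,
            strandedness,
        )
        if frag.mapq < mapq_min:
            excluded += 1
        else:
            fragments.append(frag)
    return fragments, excluded


def _build_fragment(r1, r2, strandedness: str) -> AlignedFragment:
    reads = [r for r in (r1, r2) if r is not None]
    blocks1 = tuple(r1.get_blocks()) if r1 is not None else ()
    blocks2 = tuple(r2.get_blocks()) if r2 is not None else ()
    merged = merge_blocks(list(blocks1) + list(blocks2))
    mate_blocks = tuple(b for b in (blocks1, blocks2) if b)
    return AlignedFragment(
        name=reads[0].query_name,
        chrom=reads[0].reference_name,
        blocks=merged,
        strand=_decode_strand(r1, r2, strandedness),
        mapq=min(r.mapping_quality for r in reads),
        mate_blocks=mate_blocks if len(mate_blocks) > 1 else None,
    )


class FeatureIndex:
    """Per-chromosome gene-span index plus per-gene union-exon lookup."""

    def __init__(self, features: FeatureSet):
        self.features = features
        by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
        self._exons: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for gene in features.genes.values():
            span = gene.span
            by_chrom.setdefault(gene.chrom, []).append((span.start, span.end, gene))
            starts = np.fromiter((s for s, _ in gene.union_exons), dtype=np.int64)
            ends = np.fromiter((e for _, e in gene.union_exons), dtype=np.int64)
            self._exons[gene.id] = (starts, ends)
        self._span_index = {
            chrom: IntervalIndex(recs) for chrom, recs in by_chrom.items()
        }

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        idx = self._span_index.get(chrom)
        return idx.overlapping(start, end) if idx is not None else []

    def block_hits_exon(self, gene_id: str, start: int, end: int) -> bool:
        """Does ``[start, end)`` overlap the gene's union-exon space?"""
        starts, ends = self._exons[gene_id]
        i = int(np.searchsorted(starts, end, side="left"))
        return i >= 1 and ends[i - 1] > start


def classify_fragment(
    frag: AlignedFragment,
    index: FeatureIndex,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> str:
    """Assign a fragment to one of the six RNA classes.

    Fragments overlapping the bodies of two or more same-strand genes are
    ambiguous; within a single gene, any exonic block overlap makes the
    fragment exonic.
    """
    if frag.mapq < mapq_min:
        raise ValueError(
            f"fragment {frag.name}: MAPQ {frag.mapq} below threshold {mapq_min}"
        )
    genes = index.genes_overlapping(frag.chrom, frag.start, frag.end)
    sense = [g for g in genes if g.strand == frag.strand]
    if len(sense) >= 2:
        return AMBIGUOUS
    if sense:
        gene = sense[0]
        exonic = any(
            index.block_hits_exon(gene.id, s, e) for s, e in frag.blocks
        )
        return EXON if exonic else INTRON
    antisense = [g for g in genes if g.strand != frag.strand]
    if antisense:
        exonic = any(
            index.block_hits_exon(g.id, s, e)
            for g in antisense
            for s, e in frag.blocks
        )
        return EXON_ANTISENSE if exonic else INTRON_ANTISENSE
    return INTERGENIC


@dataclass
class ClassProfile:
    """Per-sample counts and fractions over the six RNA classes."""

    counts: dict[str, int]
    n_excluded: int = 0
    sample: str | None = None

    @property
    def n_retained(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        total = self.n_retained
        return {cls: self.counts.get(cls, 0) / total for cls in CLASSES}


def class_profile(
    frags: Iterable[AlignedFragment],
    index: FeatureIndex,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    sample: str | None = None,
) -> ClassProfile:
    """Classify all fragments and normalise class counts to fractions."""
    counts = {cls: 0 for cls in CLASSES}
    excluded = 0
    for frag in frags:
        if frag.mapq < mapq_min:
            excluded += 1
            continue
        counts[classify_fragment(frag, index, mapq_min)] += 1
    profile = ClassProfile(counts=counts, n_excluded=excluded, sample=sample)
    if profile.n_retained == 0:
        raise EmptySampleError(
            f"sample {sample!r}: no fragments retained (excluded={excluded})"
        )
    return profile


def relative_class_stability(
    profile_0h: ClassProfile, profile_t: ClassProfile, cls: str
) -> float | None:
    """Fold change of a class fraction normalised to the exon-class fold.

    ``(frac_cls(t)/frac_cls(0h)) / (frac_exon(t)/frac_exon(0h))``; ``None``
    when a denominator is zero. Identically 1 for the exon class.
    """
    f0 = profile_0h.fractions
    ft = profile_t.fractions
    if f0[cls] == 0 or f0[EXON] == 0 or ft[EXON] == 0:
        return None
    return (ft[cls] / f0[cls]) / (ft[EXON] / f0[EXON])


def fractional_counts(
    frags: Iterable[AlignedFragment],
    feature_intervals: Mapping[str, Sequence[GenomicInterval]],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    stranded: bool = True,
) -> pd.Series:
    """Strand-specific fractional coverage counts summed per feature.

    Each fragment contributes ``bases inside feature / total aligned bases``
    to every feature it overlaps on its own strand, so fragment mass is
    conserved over any partition of the genome.
    """
    by_key: dict[tuple[str, str], list[tuple[int, int, tuple[str, int, int]]]] = {}
    for fid, ivs in feature_intervals.items():
        for iv in ivs:
            key = (iv.chrom, iv.strand if stranded else ".")
            by_key.setdefault(key, []).append((iv.start, iv.end, (fid, iv.start, iv.end)))
    indexes = {key: IntervalIndex(recs) for key, recs in by_key.items()}

    totals: dict[str, float] = {fid: 0.0 for fid in feature_intervals}
    for frag in frags:
        if frag.mapq < mapq_min:
            continue
        idx = indexes.get((frag.chrom, frag.strand if stranded else "."))
        if idx is None:
            continue
        total = frag.aligned_length
        for bs, be in frag.blocks:
            for fid, fs, fe in idx.overlapping(bs, be):
                ov = min(be, fe) - max(bs, fs)
                if ov > 0:
                    totals[fid] += ov / total
    return pd.Series(totals, name="count").sort_index()


def repeat_family_hits(
    frags: Iterable[AlignedFragment],
    repeats: Sequence[tuple[str, GenomicInterval]],
) -> dict[str, set[str]]:
    """Distinct repeat families overlapped per fragment name.

    Multiple alignments of one fragment (multimappers) share a name, so their
    family hits are pooled; strand is ignored, as is conventional for repeat
    accounting.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for family, iv in repeats:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, family))
    indexes = {chrom: IntervalIndex(recs) for chrom, recs in by_chrom.items()}
    hits: dict[str, set[str]] = {}
    for frag in frags:
        idx = indexes.get(frag.chrom)
        if idx is None:
            continue
        fams = {
            family for s, e in frag.blocks for family in idx.overlapping(s, e)
        }
        if fams:
            hits.setdefault(frag.name, set()).update(fams)
    return hits


def repeat_fractional_counts(
    frags: Iterable[AlignedFragment] | None = None,
    repeats: Sequence[tuple[str, GenomicInterval]] | None = None,
    hits: Mapping[str, set[str]] | None = None,
) -> pd.Series:
    """Fractional repeat-family counts: a fragment hitting ``n`` families
    contributes ``1/n`` to each; unique hits contribute 1."""
    if hits is None:
        if frags is None or repeats is None:
            raise ValueError("provide either precomputed hits or frags + repeats")
        hits = repeat_family_hits(frags, repeats)
    totals: dict[str, float] = {}
    if repeats is not None:
        for family, _iv in repeats:
            totals.setdefault(family, 0.0)
    for fams in hits.values():
        share = 1.0 / len(fams)
        for family in fams:
            totals[family] = totals.get(family, 0.0) + share
    return pd.Series(totals, name="count").sort_index()
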