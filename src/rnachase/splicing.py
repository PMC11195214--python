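"""Intron-centric splicing index and exon-spanning splicing patterns.

Junction evidence per intron comes in three kinds: ``a`` split fragments
whose block boundary pair spans exactly the intron; ``b`` contiguous blocks
crossing the intron start; ``c`` contiguous blocks crossing the intron end
(each with a minimum aligned overlap on both sides of the junction). The
splicing index is ``a / (a + (b + c) / 2)``: an unspliced molecule exposes
two crossable junctions, hence the halving of ``b + c``.

A fragment spanning an entire retained intron evidences both unspliced
junctions and counts once toward ``b`` and once toward ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .accounting import AlignedFragment
from .genome import GeneModel
from .intervals import GenomicInterval, IntervalIndex

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MIN_JRSUM = 5

SS = "SS"
SU = "SU"
US = "US"
UU = "UU"
UNINFORMATIVE = "uninformative"
PATTERNS = (SS, SU, US, UU)


@dataclass
class JunctionCounts:
    """Per-intron junction tallies feeding the splicing index."""

    intron_id: str
    a: int = 0
    b: int = 0
    c: int = 0

    @property
    def jrsum(self) -> int:
        return self.a + self.b + self.c


def classify_junction_fragment(
    frag: AlignedFragment,
    intron: GenomicInterval,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> frozenset[str]:
    """Junction evidence a fragment provides for one intron.

    Returns a subset of ``{"a", "b", "c"}`` (empty set when uninformative).
    ``b`` and ``c`` can co-occur for a fragment covering the whole intron.
    """
    labels = set()
    blocks = frag.blocks
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if (
            e1 == intron.start
            and s2 == intron.end
            and e1 - s1 >= min_overlap
            and e2 - s2 >= min_overlap
        ):
            labels.add("a")
    for s, e in blocks:
        if s <= intron.start - min_overlap and e >= intron.start + min_overlap:
            labels.add("b")
        if s <= intron.end - min_overlap and e >= intron.end + min_overlap:
            labels.add("c")
    return frozenset(labels)


def splicing_index(
    counts: JunctionCounts, min_jrsum: int = DEFAULT_MIN_JRSUM
) -> float | None:
    """``a / (a + (b + c) / 2)``; ``None`` when ``jrsum`` is below threshold."""
    if counts.jrsum < min_jrsum:
        return None
    return counts.a / (counts.a + (counts.b + counts.c) / 2)


def count_junctions(
    frags: Iterable[AlignedFragment],
    introns: Mapping[str, GenomicInterval],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dict[str, JunctionCounts]:
    """Tally a/b/c over all fragments for each (sense-strand) intron."""
    by_key: dict[tuple[str, str], list[tuple[int, int, tuple[str, GenomicInterval]]]] = {}
    for iid, iv in introns.items():
        by_key.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end, (iid, iv)))
    indexes = {key: IntervalIndex(recs) for key, recs in by_key.items()}

    counts = {iid: JunctionCounts(intron_id=iid) for iid in introns}
    for frag in frags:
        idx = indexes.get((frag.chrom, frag.strand))
        if idx is None:
            continue
        for iid, iv in idx.overlapping(frag.start, frag.end):
            labels = classify_junction_fragment(frag, iv, min_overlap)
            jc = counts[iid]
            if "a" in labels:
                jc.a += 1
            if "b" in labels:
                jc.b += 1
            if "c" in labels:
                jc.c += 1
    return counts


def si_table(
    samples: Mapping[str, Sequence[AlignedFragment]],
    introns: Mapping[str, GenomicInterval],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_jrsum: int = DEFAULT_MIN_JRSUM,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Splicing-index records for every (intron, sample) plus per-sample
    median SI over the introns where the SI is defined.

    Replicates intended to be merged should be merged into one fragment list
    per sample key before calling.
    """
    rows = []
    medians: dict[str, float] = {}
    for sample in sorted(samples):
        counts = count_junctions(samples[sample], introns, min_overlap)
        vals = []
        for iid in sorted(counts):
            jc = counts[iid]
            si = splicing_index(jc, min_jrsum)
            rows.append(
                {
                    "intron": iid,
                    "sample": sample,
                    "a": jc.a,
                    "b": jc.b,
                    "c": jc.c,
                    "jrsum": jc.jrsum,
                    "si": si,
                }
            )
            if si is not None:
                vals.append(si)
        medians[sample] = float(np.median(vals)) if vals else float("nan")
    return pd.DataFrame(rows), medians


@dataclass(frozen=True)
class SpannedExon:
    """An internal exon with its flanking introns, transcript-oriented.

    ``upstream`` is the intron on the 5' side of the exon in transcript
    orientation (left of the exon for + genes, right for - genes).
    """

    exon_id: str
    exon: GenomicInterval
    upstream: GenomicInterval
    downstream: GenomicInterval


def internal_exons(gene: GeneModel) -> list[SpannedExon]:
    """Spanned internal exons of a single-isoform gene."""
    if gene.n_transcripts != 1:
        raise ValueError(f"gene {gene.id}: exon-spanning patterns need a single isoform")
    tx = gene.transcripts[0]
    out = []
    for i in range(1, len(tx.exons) - 1):
        left, right = tx.introns[i - 1], tx.introns[i]
        up, down = (left, right) if gene.strand == "+" else (right, left)
        out.append(
            SpannedExon(
                exon_id=f"{gene.id}:exon{i}",
                exon=tx.exons[i],
                upstream=up,
                downstream=down,
            )
        )
    return out


def _junction_status(
    frag: AlignedFragment,
    intron: GenomicInterval,
    exon: GenomicInterval,
    min_overlap: int,
) -> str | None:
    """Status of the exon-adjacent junction of one flanking intron.

    The junction is the shared boundary between ``intron`` and ``exon``;
    a split exactly removing the intron reports it spliced, a contiguous
    block crossing that boundary reports it unspliced. Crossings of the
    intron's far boundary say nothing about this junction. Contradictory
    evidence (both) yields ``None``.
    """
    labels = classify_junction_fragment(frag, intron, min_overlap)
    crossing = "c" if intron.end == exon.start else "b"
    spliced = "a" in labels
    unspliced = crossing in labels
    if spliced == unspliced:
        return None
    return "spliced" if spliced else "unspliced"


def classify_exon_spanning(
    frag: AlignedFragment,
    spanned: SpannedExon,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> str:
    """Classify a fragment spanning an internal exon into one of the four
    splicing-pattern bins, or ``uninformative``.

    Informative fragments report both junctions flanking the exon, each as
    either a split (spliced) or a contiguous crossing (unspliced).
    """
    up = _junction_status(frag, spanned.upstream, spanned.exon, min_overlap)
    down = _junction_status(frag, spanned.downstream, spanned.exon, min_overlap)
    if up is None or down is None:
        return UNINFORMATIVE
    if up == "spliced":
        return SS if down == "spliced" else SU
    return US if down == "spliced" else UU


def pattern_fractions(
    samples: Mapping[str, Sequence[AlignedFragment]],
    genes: Iterable[GeneModel],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Splicing-pattern counts per (exon, sample) and summed per-sample
    fractions over all eligible internal exons.

    Returns ``(per_exon_counts, per_sample_fractions)``; fractions sum to 1
    for each sample with at least one informative fragment.
    """
    spanned = [se for gene in genes for se in internal_exons(gene)]
    by_key: dict[tuple[str, str], list[tuple[int, int, SpannedExon]]] = {}
    for se in spanned:
        key = (se.exon.chrom, se.exon.strand)
        by_key.setdefault(key, []).append((se.exon.start, se.exon.end, se))
    indexes = {key: IntervalIndex(recs) for key, recs in by_key.items()}

    exon_rows: list[dict] = []
    frac_rows: list[dict] = []
    for sample in sorted(samples):
        per_exon: dict[str, dict[str, int]] = {
            se.exon_id: {p: 0 for p in PATTERNS} for se in spanned
        }
        for frag in samples[sample]:
            idx = indexes.get((frag.chrom, frag.strand))
            if idx is None:
                continue
            for se in idx.overlapping(frag.start, frag.end):
                label = classify_exon_spanning(frag, se, min_overlap)
                if label != UNINFORMATIVE:
                    per_exon[se.exon_id][label] += 1
        totals = {p: 0 for p in PATTERNS}
        for exon_id in sorted(per_exon):
            row = {"exon": exon_id, "sample": sample}
            row.update(per_exon[exon_id])
            exon_rows.append(row)
            for p in PATTERNS:
                totals[p] += per_exon[exon_id][p]
        grand = sum(totals.values())
        frac = {
            p: (totals[p] / grand if grand else float("nan")) for p in PATTERNS
        }
        frac_rows.append(
            {"sample": sample, "informative": grand, **{f"frac_{p}": frac[p] for p in PATTERNS}}
        )
    return pd.DataFrame(exon_rows), pd.DataFrame(frac_rows)
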