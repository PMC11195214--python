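"""Shared test helpers: tiny model builders and brute-force per-base oracles.

The oracles deliberately reason over explicit base sets instead of block
arithmetic so they stay independent of the implementation they check.
"""

from __future__ import annotations

from rnachase.accounting import AlignedFragment
from rnachase.genome import FeatureSet, GeneModel, Transcript
from rnachase.intervals import GenomicInterval


def make_tx(tid, gid, chrom, strand, exon_spans):
    return Transcript(
        id=tid,
        gene_id=gid,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_spans),
    )


def make_gene(gid, chrom, strand, exon_spans, alt_exon_spans=None):
    txs = [make_tx(f"{gid}.t1", gid, chrom, strand, exon_spans)]
    if alt_exon_spans is not None:
        txs.append(make_tx(f"{gid}.t2", gid, chrom, strand, alt_exon_spans))
    return GeneModel(id=gid, transcripts=tuple(txs))


def make_features(*genes):
    return FeatureSet(genes={g.id: g for g in genes})


def frag(chrom, blocks, strand="+", name="f", mapq=255, mate_blocks=None):
    return AlignedFragment(
        name=name,
        chrom=chrom,
        blocks=tuple(tuple(b) for b in blocks),
        strand=strand,
        mapq=mapq,
        mate_blocks=mate_blocks,
    )


# ---------------------------------------------------------------------------
# brute-force per-base oracles


def fragment_bases(fragment) -> set[int]:
    return {p for s, e in fragment.blocks for p in range(s, e)}


def junction_labels_oracle(fragment, intron, min_overlap=10) -> frozenset[str]:
    """Per-base re-derivation of junction evidence for one intron."""
    bases = fragment_bases(fragment)
    labels = set()
    left_flank = set(range(intron.start - min_overlap, intron.start))
    right_flank = set(range(intron.end, intron.end + min_overlap))
    interior = set(range(intron.start, intron.end))
    if left_flank <= bases and right_flank <= bases and not (interior & bases):
        labels.add("a")
    start_window = set(range(intron.start - min_overlap, intron.start + min_overlap))
    if start_window <= bases:
        labels.add("b")
    end_window = set(range(intron.end - min_overlap, intron.end + min_overlap))
    if end_window <= bases:
        labels.add("c")
    return frozenset(labels)


def exon_pattern_oracle(fragment, spanned, min_overlap=10) -> str:
    """Per-base re-derivation of the exon-spanning splicing pattern."""

    def status(intron):
        labels = junction_labels_oracle(fragment, intron, min_overlap)
        crossing = "c" if intron.end == spanned.exon.start else "b"
        spliced = "a" in labels
        unspliced = crossing in labels
        if spliced == unspliced:
            return None
        return "spliced" if spliced else "unspliced"

    up, down = status(spanned.upstream), status(spanned.downstream)
    if up is None or down is None:
        return "uninformative"
    key = {"spliced": "S", "unspliced": "U"}
    return key[up] + key[down]


def classify_fragment_oracle(fragment, features: FeatureSet) -> str:
    """Per-base re-derivation of the six-way fragment class."""
    bases = fragment_bases(fragment)

    def body(gene):
        return set(range(gene.span.start, gene.span.end))

    def exonic(gene):
        return {p for s, e in gene.union_exons for p in range(s, e)}

    overlapped = [
        g
        for g in features.genes.values()
        if g.chrom == fragment.chrom and bases & body(g)
    ]
    sense = [g for g in overlapped if g.strand == fragment.strand]
    if len(sense) >= 2:
        return "ambiguous"
    if sense:
        return "exon" if bases & exonic(sense[0]) else "intron"
    anti = [g for g in overlapped if g.strand != fragment.strand]
    if anti:
        hit = any(bases & exonic(g) for g in anti)
        return "exon_antisense" if hit else "intron_antisense"
    return "intergenic"
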