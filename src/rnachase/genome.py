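"""Gene annotation model: GTF I/O, intron derivation and auxiliary features.

The model mirrors the gene/transcript/exon hierarchy of GENCODE-style GTF
files. Introns are derived per transcript as the gaps between consecutive
exons. Two auxiliary per-gene features are derived geometrically:

* a divergent upstream window on the antisense strand (promoter-upstream
  transcription), default 4 kb;
* a sense-strand readthrough window past the annotated 3' end, default
  10 kb, clipped at the next same-strand gene.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, merge_spans

logger = logging.getLogger(__name__)

DEFAULT_PROMPT_LENGTH = 4000
DEFAULT_READTHROUGH_LENGTH = 10000


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Transcript:
    """An ordered set of exons sharing a strand, with derived introns."""

    id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"transcript {self.id}: exons span multiple chromosomes/strands"
            )
        prev = None
        for exon in self.exons:
            if prev is not None and exon.start <= prev.end:
                raise AnnotationError(
                    f"transcript {self.id}: overlapping or touching exons "
                    f"at {prev.end} / {exon.start}"
                )
            prev = exon

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @cached_property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            out.append(
                GenomicInterval(self.chrom, left.end, right.start, self.strand)
            )
        return tuple(out)

    @cached_property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Total exonic (spliced) length."""
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts on a single strand."""

    id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.id}: no transcripts")
        strands = {t.strand for t in self.transcripts}
        chroms = {t.chrom for t in self.transcripts}
        if len(strands) != 1 or len(chroms) != 1:
            raise AnnotationError(
                f"gene {self.id}: transcripts disagree on chromosome or strand"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @cached_property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @cached_property
    def union_exons(self) -> tuple[tuple[int, int], ...]:
        """Merged exon spans across all transcripts (a base is exonic for the
        gene if it is exonic in any transcript)."""
        return tuple(
            merge_spans((e.start, e.end) for t in self.transcripts for e in t.exons)
        )

    @property
    def union_exon_length(self) -> int:
        return sum(e - s for s, e in self.union_exons)


@dataclass
class FeatureSet:
    """Genes plus derived/auxiliary feature regions used for counting."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    prompts: dict[str, GenomicInterval] = field(default_factory=dict)
    readthrough: dict[str, GenomicInterval] = field(default_factory=dict)
    enhancers: list[GenomicInterval] = field(default_factory=list)
    repeats: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def chromosomes(self) -> list[str]:
        return sorted({g.chrom for g in self.genes.values()})


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_annotation(path: str | Path) -> FeatureSet:
    """Parse a GTF file into a :class:`FeatureSet`.

    Only ``exon`` records are used; transcripts and genes are grouped via the
    ``transcript_id`` and ``gene_id`` attributes. GTF 1-based closed
    coordinates are converted to 0-based half-open.

    Raises
    ------
    AnnotationError
        Naming the offending line number for malformed records, or the
        transcript id for overlapping exons.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != "exon":
                continue
            try:
                start = int(start_s) - 1
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path.name}:{lineno}: non-numeric coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise AnnotationError(
                    f"{path.name}:{lineno}: invalid strand {strand!r}"
                )
            attr = dict(_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            tx_id = attr.get("transcript_id")
            if not gene_id or not tx_id:
                raise AnnotationError(
                    f"{path.name}:{lineno}: exon record lacks gene_id/transcript_id"
                )
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise AnnotationError(f"{path.name}:{lineno}: {exc}") from exc
            exons.setdefault(tx_id, []).append(iv)
            prior = tx_gene.setdefault(tx_id, gene_id)
            if prior != gene_id:
                raise AnnotationError(
                    f"{path.name}:{lineno}: transcript {tx_id} assigned to "
                    f"multiple genes ({prior}, {gene_id})"
                )

    by_gene: dict[str, list[Transcript]] = {}
    for tx_id in sorted(exons):
        tx = Transcript(
            id=tx_id,
            gene_id=tx_gene[tx_id],
            exons=tuple(sorted(exons[tx_id], key=lambda e: e.start)),
        )
        by_gene.setdefault(tx.gene_id, []).append(tx)

    genes = {
        gid: GeneModel(id=gid, transcripts=tuple(txs))
        for gid, txs in sorted(by_gene.items())
    }
    return FeatureSet(genes=genes)


def write_annotation(features: FeatureSet, path: str | Path) -> None:
    """Write gene/transcript/exon GTF records (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for gid in sorted(features.genes):
            gene = features.genes[gid]
            span = gene.span
            fh.write(
                _gtf_line(span, "gene", f'gene_id "{gid}";')
            )
            for tx in gene.transcripts:
                attrs = f'gene_id "{gid}"; transcript_id "{tx.id}";'
                fh.write(_gtf_line(tx.span, "transcript", attrs))
                for exon in tx.exons:
                    fh.write(_gtf_line(exon, "exon", attrs))


def _gtf_line(iv: GenomicInterval, ftype: str, attrs: str) -> str:
    return (
        f"{iv.chrom}\trnachase\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
        f"{iv.strand}\t.\t{attrs}\n"
    )


def load_bed6(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read a BED6 file into ``(name, interval)`` pairs (0-based half-open)."""
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{Path(path).name}:{lineno}: expected >=6 BED fields"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            out.append((name, GenomicInterval(chrom, int(start), int(end), strand)))
    return out


def derive_prompt(
    gene: GeneModel, length: int = DEFAULT_PROMPT_LENGTH
) -> GenomicInterval | None:
    """Antisense window of ``length`` bases immediately upstream of the TSS.

    Truncated (with a logged warning) when the TSS is closer than ``length``
    to the chromosome start; ``None`` when no valid window exists at all.
    """
    if gene.strand == "+":
        tss = gene.span.start
        start = tss - length
        if start < 0:
            logger.warning(
                "prompt window for %s truncated at chromosome start", gene.id
            )
            start = 0
        if start >= tss:
            return None
        return GenomicInterval(gene.chrom, start, tss, "-")
    tss = gene.span.end
    return GenomicInterval(gene.chrom, tss, tss + length, "+")


def derive_readthrough(
    gene: GeneModel,
    length: int = DEFAULT_READTHROUGH_LENGTH,
    features: FeatureSet | None = None,
    chrom_length: int | None = None,
) -> GenomicInterval | None:
    """Sense-strand window of ``length`` bases past the annotated gene end,
    clipped at the nearest same-strand neighbour gene (and chromosome bounds).
    """
    neighbours = []
    if features is not None:
        neighbours = [
            g
            for g in features.genes.values()
            if g.id != gene.id and g.chrom == gene.chrom and g.strand == gene.strand
        ]
    if gene.strand == "+":
        start = gene.span.end
        end = start + length
        for other in neighbours:
            if start <= other.span.start < end:
                end = other.span.start
        if chrom_length is not None:
            end = min(end, chrom_length)
        if end <= start:
            return None
        return GenomicInterval(gene.chrom, start, end, "+")
    end = gene.span.start
    start = max(0, end - length)
    for other in neighbours:
        if start < other.span.end <= end:
            start = other.span.end
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end, "-")


def attach_auxiliary_features(
    features: FeatureSet,
    prompt_length: int = DEFAULT_PROMPT_LENGTH,
    readthrough_length: int = DEFAULT_READTHROUGH_LENGTH,
    chrom_lengths: Mapping[str, int] | None = None,
) -> FeatureSet:
    """Populate per-gene prompt and readthrough windows in place."""
    for gid, gene in features.genes.items():
        prompt = derive_prompt(gene, prompt_length)
        if prompt is not None:
            features.prompts[gid] = prompt
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        rt = derive_readthrough(
            gene, readthrough_length, features=features, chrom_length=clen
        )
        if rt is not None:
            features.readthrough[gid] = rt
    return features


def select_single_isoform_multi_intron(
    features: FeatureSet, min_introns: int = 2
) -> list[str]:
    """Genes with exactly one annotated transcript and at least
    ``min_introns`` introns."""
    out = []
    for gid in sorted(features.genes):
        gene = features.genes[gid]
        if gene.n_transcripts != 1:
            continue
        if len(gene.transcripts[0].introns) >= min_introns:
            out.append(gid)
    return out


def feature_summary(features: FeatureSet) -> pd.DataFrame:
    """Per-gene summary table (one row per gene)."""
    rows = []
    for gid in sorted(features.genes):
        gene = features.genes[gid]
        rows.append(
            {
                "gene_id": gid,
                "chrom": gene.chrom,
                "strand": gene.strand,
                "start": gene.span.start,
                "end": gene.span.end,
                "n_transcripts": gene.n_transcripts,
                "n_introns": max(len(t.introns) for t in gene.transcripts),
                "union_exon_length": gene.union_exon_length,
                "has_prompt": gid in features.prompts,
                "has_readthrough": gid in features.readthrough,
            }
        )
    return pd.DataFrame(rows)
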