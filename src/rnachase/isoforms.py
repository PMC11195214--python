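"""Isoform quantification by equivalence-class EM and dominance dynamics.

A fragment is compatible with an isoform when every aligned block lies in
the isoform's exons, every within-mate alignment gap matches an isoform
junction chain, and the mates are colinear along the transcript. The set of
compatible isoforms is the fragment's equivalence class; classes are the
unit of a standard length-normalised mixture EM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .accounting import AlignedFragment
from .genome import GeneModel, Transcript

logger = logging.getLogger(__name__)

DEFAULT_FRAG_MEAN = 450.0
DEFAULT_TPM_MIN = 1.0
DEFAULT_DOMINANCE_THRESHOLD = 50.0
AD = "AD"
GD = "GD"
LD = "LD"
OTHER = "other"
UNCLASSIFIABLE = "unclassifiable"


def effective_length(length: float, frag_mean: float = DEFAULT_FRAG_MEAN) -> float:
    """Transcript length minus mean fragment length plus one, floored at 1."""
    return max(length - frag_mean + 1.0, 1.0)


class _TranscriptCoords:
    """Genome-to-transcript coordinate map over a transcript's exons."""

    def __init__(self, tx: Transcript):
        self.starts = np.fromiter((e.start for e in tx.exons), dtype=np.int64)
        self.ends = np.fromiter((e.end for e in tx.exons), dtype=np.int64)
        self.cum = np.concatenate(
            [[0], np.cumsum(self.ends - self.starts)]
        )

    def block_to_tx(self, s: int, e: int) -> tuple[int, int] | None:
        """Transcript interval of a genomic block fully inside one exon."""
        i = int(np.searchsorted(self.starts, s, side="right")) - 1
        if i < 0 or e > self.ends[i]:
            return None
        off = self.cum[i]
        return (off + s - self.starts[i], off + e - self.starts[i])


def fragment_compatible(frag: AlignedFragment, coords: _TranscriptCoords) -> bool:
    """Splice-structure consistency of a fragment with one isoform."""
    mates = frag.mate_blocks if frag.mate_blocks is not None else (frag.blocks,)
    spans: list[tuple[int, int]] = []
    for mate in mates:
        prev_end: int | None = None
        t_start: int | None = None
        for s, e in mate:
            t = coords.block_to_tx(s, e)
            if t is None:
                return False
            if prev_end is not None and t[0] != prev_end:
                return False  # alignment gap is not an isoform junction chain
            if t_start is None:
                t_start = t[0]
            prev_end = t[1]
        spans.append((t_start, prev_end))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:  # mates must be colinear, insert gap >= 0
            return False
    return True


@dataclass
class EquivalenceClassCounts:
    """Per-gene equivalence classes: isoform-id-set -> fragment count."""

    gene_id: str
    classes: dict[frozenset[str], int]
    effective_lengths: dict[str, float]
    incompatible: int = 0

    @property
    def total(self) -> int:
        return sum(self.classes.values())


def build_equivalence_classes(
    frags: Iterable[AlignedFragment],
    gene: GeneModel,
    frag_mean: float = DEFAULT_FRAG_MEAN,
) -> EquivalenceClassCounts:
    """Assign each fragment to the set of isoforms it is compatible with.

    Fragments compatible with no isoform (e.g. lying in a retained intron
    absent from the annotation) are tallied separately.
    """
    coords = {tx.id: _TranscriptCoords(tx) for tx in gene.transcripts}
    classes: dict[frozenset[str], int] = {}
    incompatible = 0
    for frag in frags:
        compatible = frozenset(
            tid for tid, c in coords.items() if fragment_compatible(frag, c)
        )
        if compatible:
            classes[compatible] = classes.get(compatible, 0) + 1
        else:
            incompatible += 1
    eff = {
        tx.id: effective_length(tx.length, frag_mean) for tx in gene.transcripts
    }
    return EquivalenceClassCounts(
        gene_id=gene.id,
        classes=classes,
        effective_lengths=eff,
        incompatible=incompatible,
    )


@dataclass
class EMResult:
    """Converged mixture estimate for one gene.

    ``theta`` are read-fraction mixture weights (the EM parameter);
    ``proportions`` are the molar isoform proportions
    ``theta_t / eff_len_t`` renormalised to the simplex.
    """

    gene_id: str
    theta: dict[str, float]
    proportions: dict[str, float]
    n_iter: int
    converged: bool


def ec_log_likelihood(
    ec: EquivalenceClassCounts, theta: Mapping[str, float]
) -> float:
    """Equivalence-class log-likelihood of read-fraction weights ``theta``."""
    ll = 0.0
    for cls, n in ec.classes.items():
        rate = sum(theta[t] / ec.effective_lengths[t] for t in cls)
        if rate <= 0:
            return -np.inf
        ll += n * np.log(rate)
    return ll


def em_quantify(
    ec: EquivalenceClassCounts,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> EMResult:
    """Length-normalised mixture EM over equivalence classes.

    Iterates ``theta_t <- (1/N) * sum_c n_c * (theta_t/l_t) / sum_{u in c}
    theta_u/l_u`` from a uniform start until ``max |d theta| < tol``.
    """
    tids = sorted(ec.effective_lengths)
    if ec.total <= 0:
        raise ValueError(f"gene {ec.gene_id}: no assigned fragments")
    inv_len = np.array([1.0 / ec.effective_lengths[t] for t in tids])
    pos = {t: i for i, t in enumerate(tids)}
    cls_idx = [
        (np.fromiter((pos[t] for t in cls), dtype=np.int64), n)
        for cls, n in sorted(ec.classes.items(), key=lambda kv: sorted(kv[0]))
    ]
    n_total = ec.total
    theta = np.full(len(tids), 1.0 / len(tids))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros_like(theta)
        for idx, n in cls_idx:
            w = theta[idx] * inv_len[idx]
            new[idx] += n * w / w.sum()
        new /= n_total
        delta = np.max(np.abs(new - theta))
        theta = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("gene %s: EM did not converge in %d iterations", ec.gene_id, max_iter)
    molar = theta * inv_len
    molar_sum = molar.sum()
    props = molar / molar_sum if molar_sum > 0 else molar
    return EMResult(
        gene_id=ec.gene_id,
        theta=dict(zip(tids, theta.tolist())),
        proportions=dict(zip(tids, props.tolist())),
        n_iter=it,
        converged=converged,
    )


def isoform_percentages(
    ec_by_timepoint: Mapping[str, Mapping[str, EquivalenceClassCounts]],
    tpm_min: float = DEFAULT_TPM_MIN,
    reference_timepoint: str = "0h",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Isoform TPM and percentage per gene and timepoint.

    Genes are retained only when they have at least 2 isoforms and a total
    expression of at least ``tpm_min`` TPM at the reference (0h) timepoint.
    Percentages within a gene/timepoint sum to 100.
    """
    if reference_timepoint not in ec_by_timepoint:
        raise ValueError(f"reference timepoint {reference_timepoint!r} missing")
    rows = []
    for tp in ec_by_timepoint:
        rates: dict[tuple[str, str], float] = {}
        props: dict[tuple[str, str], float] = {}
        for gid, ec in ec_by_timepoint[tp].items():
            if ec.total == 0:
                continue
            res = em_quantify(ec, tol=tol, max_iter=max_iter)
            for tid in res.theta:
                rates[(gid, tid)] = (
                    res.theta[tid] * ec.total / ec.effective_lengths[tid]
                )
                props[(gid, tid)] = res.proportions[tid]
        denom = sum(rates.values())
        for (gid, tid), rate in rates.items():
            rows.append(
                {
                    "gene": gid,
                    "isoform": tid,
                    "timepoint": tp,
                    "tpm": 1e6 * rate / denom if denom else 0.0,
                    "percent": 100.0 * props[(gid, tid)],
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    n_iso = df.groupby("gene")["isoform"].nunique()
    ref = df[df["timepoint"] == reference_timepoint].groupby("gene")["tpm"].sum()
    keep = set(n_iso.index[n_iso >= 2]) & set(ref.index[ref >= tpm_min])
    return (
        df[df["gene"].isin(keep)]
        .sort_values(["gene", "isoform", "timepoint"])
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class DominanceCall:
    """Dominance-trajectory classification for one gene.

    ``categories`` is a subset of ``{AD, GD, LD}``, ``{other}`` when no
    isoform meets any definition, or ``{unclassifiable}`` on missing data.
    """

    gene: str
    categories: frozenset[str]
    dominant: tuple[tuple[str, tuple[str, ...]], ...]  # (timepoint, isoform ids)


def dominance_classify(
    gene: str,
    percent_by_isoform: Mapping[str, Sequence[float]],
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    timepoints: Sequence[str] = ("0h", "2h", "6h"),
) -> DominanceCall:
    """Classify isoform-dominance dynamics over the chase.

    AD: some isoform at or above threshold at every timepoint. GD: some
    isoform below threshold at the first timepoint and at/above it at the
    last. LD: the converse. A gene can be both GD and LD via different
    isoforms. Missing values make the gene unclassifiable.
    """
    n_tp = len(timepoints)
    for tid, series in percent_by_isoform.items():
        if len(series) != n_tp or any(v is None or np.isnan(v) for v in series):
            return DominanceCall(
                gene=gene,
                categories=frozenset({UNCLASSIFIABLE}),
                dominant=(),
            )
    cats = set()
    for series in percent_by_isoform.values():
        first, last = series[0], series[-1]
        if all(v >= threshold for v in series):
            cats.add(AD)
        if first < threshold <= last:
            cats.add(GD)
        if first >= threshold > last:
            cats.add(LD)
    if not cats:
        cats = {OTHER}
    dominant = tuple(
        (
            tp,
            tuple(
                sorted(
                    tid
                    for tid, series in percent_by_isoform.items()
                    if series[i] >= threshold
                )
            ),
        )
        for i, tp in enumerate(timepoints)
    )
    return DominanceCall(gene=gene, categories=frozenset(cats), dominant=dominant)


def dominance_table(
    percent_df: pd.DataFrame,
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    timepoints: Sequence[str] = ("0h", "2h", "6h"),
) -> list[DominanceCall]:
    """Apply :func:`dominance_classify` to an isoform-percentage table
    (columns ``gene, isoform, timepoint, percent``)."""
    calls = []
    for gid, sub in percent_df.groupby("gene"):
        series: dict[str, list[float]] = {}
        pivot = sub.pivot_table(index="isoform", columns="timepoint", values="percent")
        for tid, row in pivot.iterrows():
            series[tid] = [row.get(tp, np.nan) for tp in timepoints]
        calls.append(dominance_classify(gid, series, threshold, timepoints))
    return calls


def dominance_summary(calls: Iterable[DominanceCall]) -> dict[str, float]:
    """Fraction of classified genes per category (AD/GD/LD/other).

    Fractions can sum to more than 1 because a gene may carry several
    categories.
    """
    classified = [c for c in calls if UNCLASSIFIABLE not in c.categories]
    n = len(classified)
    out = {cat: 0.0 for cat in (AD, GD, LD, OTHER)}
    if n == 0:
        return out
    for call in classified:
        for cat in call.categories:
            out[cat] += 1.0
    return {cat: v / n for cat, v in out.items()}
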