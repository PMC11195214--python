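"""Per-gene relative stability (log2 fold change) across chase intervals.

Normalisation is the median-of-ratios estimator; the differential test is a
Wald test on the log2 fold change under a negative-binomial error model with
a per-gene method-of-moments dispersion (floored), followed by
Benjamini-Hochberg correction. Shrinkage and independent filtering are
deliberately not implemented; the quantity of interest downstream is the
log2FC itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_RPKM_MIN = 0.5
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_DISPERSION_FLOOR = 0.01
TIMEPOINT_ORDER = ("0h", "2h", "6h")


@dataclass
class CountMatrix:
    """Gene-by-sample fractional exonic counts with sample metadata.

    ``samples`` is indexed by sample id with columns ``cell_line``,
    ``timepoint`` and ``replicate``; ``lengths`` holds union-exon lengths.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("cell_line", "timepoint", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        lens = self.lengths.reindex(self.counts.index)
        if lens.isna().any() or (lens <= 0).any():
            raise ValueError("every counted gene needs a positive length")

    def subset(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[list(sample_ids)],
            samples=self.samples.loc[list(sample_ids)],
            lengths=self.lengths,
        )

    def samples_at(self, timepoint: str, cell_line: str | None = None) -> list[str]:
        meta = self.samples
        mask = meta["timepoint"] == timepoint
        if cell_line is not None:
            mask &= meta["cell_line"] == cell_line
        return list(meta.index[mask])


def size_factors(
    counts: pd.DataFrame, reference_genes: Sequence[str] | None = None
) -> pd.Series:
    """Median-of-ratios per-sample normalisation factors.

    ``factor_s = median_g(count_gs / geometric_mean_g)`` over the genes with
    nonzero counts in every sample. When ``reference_genes`` is given the
    median is restricted to that subset (the control-gene/spike-in
    convention for experiments where most genes are expected to change).
    """
    if reference_genes is not None:
        counts = counts.loc[list(reference_genes)]
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; a pseudo-reference "
            "fallback would be required"
        )
    sub = arr[nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def rpkm(count: float, gene_length: float, library_size: float):
    """Reads per kilobase of feature per million library fragments."""
    return count / (gene_length / 1e3) / (library_size / 1e6)


def rpkm_table(cm: CountMatrix) -> pd.DataFrame:
    """RPKM per gene and sample, using raw per-sample totals as library sizes."""
    libsizes = cm.counts.sum(axis=0)
    lens = cm.lengths.reindex(cm.counts.index)
    return cm.counts.div(lens / 1e3, axis=0).div(libsizes / 1e6, axis=1)


def stability_log2fc(
    cm: CountMatrix,
    interval: tuple[str, str] = ("0h", "2h"),
    cell_line: str | None = None,
    rpkm_min: float = DEFAULT_RPKM_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    dispersion_floor: float = DEFAULT_DISPERSION_FLOOR,
    reference_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Relative stability per gene over one chase interval.

    For each gene passing the RPKM filter at the earlier timepoint:
    ``log2FC = log2((mean_norm_later + pc) / (mean_norm_earlier + pc))``
    with a Wald p-value from the NB model and BH-adjusted p across the
    reported genes. ``reference_genes`` optionally restricts the
    normalisation to a stable control set (spike-in-style).

    Returns a table with columns ``gene, interval, log2fc, se, p, padj,
    rpkm_earlier``.
    """
    earlier, later = interval
    ids_e = cm.samples_at(earlier, cell_line)
    ids_l = cm.samples_at(later, cell_line)
    if not ids_e or not ids_l:
        raise ValueError(f"missing samples for timepoints {earlier!r}/{later!r}")
    if len(ids_e) < 2 or len(ids_l) < 2:
        logger.warning(
            "fewer than 2 replicates for %s vs %s: p-values will be missing",
            earlier,
            later,
        )
    sub = cm.counts[ids_e + ids_l]
    sf = size_factors(sub, reference_genes=reference_genes)
    norm = sub / sf

    libsizes = sub.sum(axis=0)
    lens = cm.lengths.reindex(cm.counts.index)
    rpkm_e = (
        sub[ids_e].div(lens / 1e3, axis=0).div(libsizes[ids_e] / 1e6, axis=1).mean(axis=1)
    )
    keep = rpkm_e >= rpkm_min

    mean_e = norm.loc[keep, ids_e].mean(axis=1)
    mean_l = norm.loc[keep, ids_l].mean(axis=1)
    log2fc = np.log2((mean_l + pseudocount) / (mean_e + pseudocount))

    has_reps = len(ids_e) >= 2 and len(ids_l) >= 2
    if has_reps:
        var_e = norm.loc[keep, ids_e].var(axis=1, ddof=1)
        var_l = norm.loc[keep, ids_l].var(axis=1, ddof=1)
        pooled_mean = (mean_e + mean_l) / 2
        pooled_var = (var_e + var_l) / 2
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (pooled_var - pooled_mean) / pooled_mean**2
        alpha = alpha.clip(lower=dispersion_floor).fillna(dispersion_floor)
        se_e = np.sqrt((mean_e + alpha * mean_e**2) / len(ids_e))
        se_l = np.sqrt((mean_l + alpha * mean_l**2) / len(ids_l))
        se = (
            np.sqrt(
                (se_e / (mean_e + pseudocount)) ** 2
                + (se_l / (mean_l + pseudocount)) ** 2
            )
            / np.log(2)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = log2fc / se
        p = pd.Series(2 * sps.norm.sf(np.abs(z)), index=log2fc.index)
        reported = p.dropna()
        padj = pd.Series(np.nan, index=p.index)
        if len(reported):
            padj.loc[reported.index] = multipletests(
                reported.to_numpy(), method="fdr_bh"
            )[1]
    else:
        se = pd.Series(np.nan, index=log2fc.index)
        p = pd.Series(np.nan, index=log2fc.index)
        padj = pd.Series(np.nan, index=log2fc.index)

    return pd.DataFrame(
        {
            "gene": log2fc.index,
            "interval": f"{earlier}-{later}",
            "log2fc": log2fc.to_numpy(),
            "se": se.to_numpy(),
            "p": p.to_numpy(),
            "padj": padj.to_numpy(),
            "rpkm_earlier": rpkm_e[keep].to_numpy(),
        }
    ).reset_index(drop=True)


def rescale_unit(values) -> np.ndarray:
    """Affine rescale of a vector onto [0, 1]."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to rescale")
    lo, hi = np.min(arr), np.max(arr)
    if hi == lo:
        raise ValueError("cannot rescale a constant vector")
    return (arr - lo) / (hi - lo)


def trajectory_matrix(
    early: Mapping[str, pd.Series],
    late: Mapping[str, pd.Series],
) -> pd.DataFrame:
    """Two-interval stability trajectories across cell lines.

    ``early``/``late`` map cell line to a gene-indexed log2FC Series already
    restricted to filter-passing genes. Only genes present in every cell
    line for both intervals are used; log2FCs are rescaled to [0, 1] per
    cell line per interval, and an across-cell-line ``averaged`` point is
    appended per gene.
    """
    if set(early) != set(late) or not early:
        raise ValueError("early and late must cover the same non-empty cell lines")
    lines = sorted(early)
    common: set[str] | None = None
    for line in lines:
        genes = set(early[line].index) & set(late[line].index)
        common = genes if common is None else common & genes
    genes = sorted(common or [])
    if not genes:
        raise ValueError("no gene passes filters in all cell lines")

    rows = []
    scaled: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for line in lines:
        e = rescale_unit(early[line].loc[genes].to_numpy())
        l = rescale_unit(late[line].loc[genes].to_numpy())
        scaled[line] = (e, l)
        for g, se_, sl_ in zip(genes, e, l):
            rows.append(
                {"gene": g, "cell_line": line, "scaled_early": se_, "scaled_late": sl_}
            )
    mean_e = np.mean([scaled[line][0] for line in lines], axis=0)
    mean_l = np.mean([scaled[line][1] for line in lines], axis=0)
    for g, se_, sl_ in zip(genes, mean_e, mean_l):
        rows.append(
            {"gene": g, "cell_line": "averaged", "scaled_early": se_, "scaled_late": sl_}
        )
    return pd.DataFrame(rows)


def cellline_correlation(
    values: Mapping[str, pd.Series],
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation of per-gene log2FCs across cell lines,
    with an average-linkage dendrogram order on distance ``1 - r``.
    """
    lines = sorted(values)
    if len(lines) < 2:
        raise ValueError("need at least two cell lines")
    mat = pd.DataFrame({line: values[line] for line in lines}).dropna()
    corr = mat.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    order = [lines[i] for i in hierarchy.leaves_list(linkage)]
    return corr, order
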