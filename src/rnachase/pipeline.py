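"""End-to-end orchestration: simulate -> account -> splicing -> stability ->
isoforms, with a manifest and deterministic TSV outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .accounting import (
    AlignedFragment,
    FeatureIndex,
    class_profile,
    fractional_counts,
    read_fragments,
)
from .genome import FeatureSet, load_annotation, select_single_isoform_multi_intron
from .intervals import GenomicInterval
from .isoforms import (
    build_equivalence_classes,
    dominance_summary,
    dominance_table,
    isoform_percentages,
)
from .simulate import SimConfig, simulate_dataset, write_simulation
from .splicing import pattern_fractions, si_table
from .stability import CountMatrix, stability_log2fc, trajectory_matrix, cellline_correlation

logger = logging.getLogger(__name__)

_TSV_KWARGS = dict(sep="\t", index=False, float_format="%.6g")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the output directory."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str
    seed: int = 0
    simulate: SimConfig | None = None
    gtf: str | None = None
    samples: list[dict] = field(default_factory=list)
    strandedness: str = "reverse"
    mapq_min: int = 255
    min_overlap: int = 10
    min_jrsum: int = 5
    rpkm_min: float = 0.5
    tpm_min: float = 1.0
    dominance_threshold: float = 50.0
    frag_mean: float = 450.0
    alignment_format: str = "sam"

    def __post_init__(self) -> None:
        if self.simulate is None:
            if not self.gtf:
                raise ValueError("config needs either a simulate block or a gtf path")
            if not Path(self.gtf).exists():
                raise FileNotFoundError(f"annotation not found: {self.gtf}")
            for entry in self.samples:
                if not Path(entry["path"]).exists():
                    raise FileNotFoundError(f"alignment not found: {entry['path']}")
        if not 0 <= self.dominance_threshold <= 100:
            raise ValueError("dominance_threshold must be a percentage")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulate", None)
        if sim is not None:
            data["simulate"] = SimConfig.from_dict(sim)
        return cls(**data)

    def to_dict(self) -> dict:
        data = asdict(self)
        return data


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return run

    return wrap


def run_all(config: RunConfig) -> dict:
    """Execute all stages in dependency order and write the report bundle.

    Returns a dict of output paths. On stage failure a
    :class:`PipelineError` names the stage; earlier outputs remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    features, samples, meta = _stage("simulate")(_load_inputs)(config, outdir, outputs)
    index = FeatureIndex(features)

    counts = _stage("account")(_account)(config, features, index, samples, meta, outdir, outputs)
    _stage("splicing")(_splicing)(config, features, samples, meta, outdir, outputs)
    stab = _stage("stability")(_stability)(config, features, counts, meta, outdir, outputs)
    _stage("isoforms")(_isoforms)(config, features, index, samples, meta, outdir, outputs)
    _stage("report")(_report)(config, outdir, outputs, samples, stab)
    return outputs


def _load_inputs(config: RunConfig, outdir: Path, outputs: dict):
    if config.simulate is not None:
        sim_cfg = config.simulate
        if sim_cfg.seed != config.seed:
            sim_cfg = SimConfig.from_dict({**sim_cfg.to_dict(), "seed": config.seed})
        result = simulate_dataset(sim_cfg)
        paths = write_simulation(outdir / "sim", result, fmt=config.alignment_format)
        outputs.update({f"sim:{k}": str(v) for k, v in paths.items()})
        meta = pd.DataFrame.from_dict(result.sample_meta, orient="index")
        return result.features, result.samples, meta
    features = load_annotation(config.gtf)
    samples: dict[str, list[AlignedFragment]] = {}
    meta_rows = {}
    for entry in config.samples:
        name = entry["name"]
        frags, excluded = read_fragments(
            entry["path"], strandedness=config.strandedness, mapq_min=config.mapq_min
        )
        samples[name] = frags
        meta_rows[name] = {
            "cell_line": entry.get("cell_line", "cl1"),
            "timepoint": entry["timepoint"],
            "replicate": entry.get("replicate", 1),
            "depth": len(frags),
            "excluded": excluded,
        }
    return features, samples, pd.DataFrame.from_dict(meta_rows, orient="index")


def _account(config, features, index, samples, meta, outdir: Path, outputs: dict):
    rows = []
    for name in sorted(samples):
        profile = class_profile(
            samples[name], index, mapq_min=config.mapq_min, sample=name
        )
        row = {"sample": name, "retained": profile.n_retained, "excluded": profile.n_excluded}
        row.update({f"count_{c}": profile.counts[c] for c in profile.counts})
        row.update({f"frac_{c}": v for c, v in profile.fractions.items()})
        rows.append(row)
    profile_df = pd.DataFrame(rows)
    path = outdir / "class_profile.tsv"
    profile_df.to_csv(path, **_TSV_KWARGS)
    outputs["class_profile"] = str(path)

    exon_features = {
        gid: [
            GenomicInterval(g.chrom, s, e, g.strand) for s, e in g.union_exons
        ]
        for gid, g in features.genes.items()
    }
    counts = pd.DataFrame(
        {
            name: fractional_counts(samples[name], exon_features, mapq_min=config.mapq_min)
            for name in sorted(samples)
        }
    )
    counts.index.name = "gene"
    path = outdir / "gene_counts.tsv"
    counts.reset_index().to_csv(path, **_TSV_KWARGS)
    outputs["gene_counts"] = str(path)
    return counts


def _merged_by_condition(samples, meta) -> dict[str, list[AlignedFragment]]:
    merged: dict[str, list[AlignedFragment]] = {}
    for name in sorted(samples):
        key = f"{meta.loc[name, 'cell_line']}_{meta.loc[name, 'timepoint']}"
        merged.setdefault(key, []).extend(samples[name])
    return merged


def _splicing(config, features, samples, meta, outdir: Path, outputs: dict):
    eligible = select_single_isoform_multi_intron(features, min_introns=2)
    if not eligible:
        logger.info("no single-isoform multi-intron genes; skipping splicing stage")
        return
    introns = {}
    for gid in eligible:
        tx = features.genes[gid].transcripts[0]
        for i, iv in enumerate(tx.introns):
            introns[f"{gid}:i{i}"] = iv
    merged = _merged_by_condition(samples, meta)
    table, medians = si_table(
        merged, introns, min_overlap=config.min_overlap, min_jrsum=config.min_jrsum
    )
    path = outdir / "si.tsv"
    table.to_csv(path, **_TSV_KWARGS)
    outputs["si"] = str(path)
    med = pd.DataFrame(
        [{"sample": k, "median_si": v} for k, v in sorted(medians.items())]
    )
    path = outdir / "si_medians.tsv"
    med.to_csv(path, **_TSV_KWARGS)
    outputs["si_medians"] = str(path)

    genes = [features.genes[gid] for gid in eligible]
    _per_exon, fractions = pattern_fractions(merged, genes, min_overlap=config.min_overlap)
    path = outdir / "pattern_fractions.tsv"
    fractions.to_csv(path, **_TSV_KWARGS)
    outputs["pattern_fractions"] = str(path)


def _stability(config, features, counts, meta, outdir: Path, outputs: dict):
    lengths = pd.Series(
        {gid: g.union_exon_length for gid, g in features.genes.items()}, name="length"
    )
    cm = CountMatrix(counts=counts, samples=meta, lengths=lengths)
    timepoints = sorted(
        meta["timepoint"].unique(), key=lambda s: float(str(s).rstrip("h"))
    )
    if len(timepoints) < 2:
        logger.info("fewer than two timepoints; skipping stability stage")
        return None
    intervals = list(zip(timepoints, timepoints[1:]))
    tables = []
    per_line: dict[str, dict[str, pd.Series]] = {}
    for line in sorted(meta["cell_line"].unique()):
        for interval in intervals:
            tab = stability_log2fc(
                cm, interval=interval, cell_line=line, rpkm_min=config.rpkm_min
            )
            tab.insert(0, "cell_line", line)
            tables.append(tab)
            per_line.setdefault(f"{interval[0]}-{interval[1]}", {})[line] = tab.set_index(
                "gene"
            )["log2fc"]
    stab = pd.concat(tables, ignore_index=True)
    path = outdir / "stability.tsv"
    stab.to_csv(path, **_TSV_KWARGS)
    outputs["stability"] = str(path)

    if len(intervals) >= 2:
        early_key = f"{intervals[0][0]}-{intervals[0][1]}"
        late_key = f"{intervals[1][0]}-{intervals[1][1]}"
        try:
            traj = trajectory_matrix(per_line[early_key], per_line[late_key])
            path = outdir / "trajectory.tsv"
            traj.to_csv(path, **_TSV_KWARGS)
            outputs["trajectory"] = str(path)
        except ValueError as exc:
            logger.info("trajectory matrix skipped: %s", exc)
        if len(per_line[early_key]) >= 2:
            for key, label in ((early_key, "early"), (late_key, "late")):
                corr, order = cellline_correlation(per_line[key])
                path = outdir / f"correlation_{label}.tsv"
                corr.round(6).reset_index(names="cell_line").to_csv(path, **_TSV_KWARGS)
                outputs[f"correlation_{label}"] = str(path)
    return stab


def _isoforms(config, features, index, samples, meta, outdir: Path, outputs: dict):
    multi = {gid: g for gid, g in features.genes.items() if g.n_transcripts >= 2}
    if not multi:
        logger.info("no multi-isoform genes; skipping isoform stage")
        return
    merged = _merged_by_condition(samples, meta)
    timepoints = sorted(
        meta["timepoint"].unique(), key=lambda s: float(str(s).rstrip("h"))
    )
    pct_tables = []
    calls = []
    for line in sorted(meta["cell_line"].unique()):
        ec_by_tp: dict[str, dict] = {}
        for tp in timepoints:
            frag_by_gene: dict[str, list[AlignedFragment]] = {gid: [] for gid in multi}
            for frag in merged[f"{line}_{tp}"]:
                for gene in index.genes_overlapping(frag.chrom, frag.start, frag.end):
                    if gene.id in multi and gene.strand == frag.strand:
                        frag_by_gene[gene.id].append(frag)
            ec_by_tp[tp] = {
                gid: build_equivalence_classes(
                    frag_by_gene[gid], multi[gid], frag_mean=config.frag_mean
                )
                for gid in sorted(multi)
            }
        pct = isoform_percentages(
            ec_by_tp, tpm_min=config.tpm_min, reference_timepoint=timepoints[0]
        )
        if pct.empty:
            continue
        pct.insert(0, "cell_line", line)
        pct_tables.append(pct)
        for call in dominance_table(
            pct, threshold=config.dominance_threshold, timepoints=timepoints
        ):
            calls.append(
                {
                    "cell_line": line,
                    "gene": call.gene,
                    "categories": ",".join(sorted(call.categories)),
                }
            )
    if not pct_tables:
        logger.info("no gene passed isoform filters; skipping isoform outputs")
        return
    pct_all = pd.concat(pct_tables, ignore_index=True)
    path = outdir / "isoform_percent.tsv"
    pct_all.to_csv(path, **_TSV_KWARGS)
    outputs["isoform_percent"] = str(path)

    calls_df = pd.DataFrame(calls)
    path = outdir / "dominance.tsv"
    calls_df.to_csv(path, **_TSV_KWARGS)
    outputs["dominance"] = str(path)

    counted = calls_df[calls_df["categories"] != "unclassifiable"]
    n = len(counted)
    summary_rows = []
    for cat in ("AD", "GD", "LD", "other"):
        frac = (
            counted["categories"].str.split(",").apply(lambda cs: cat in cs).sum() / n
            if n
            else 0.0
        )
        summary_rows.append({"category": cat, "fraction": frac})
    path = outdir / "dominance_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(path, **_TSV_KWARGS)
    outputs["dominance_summary"] = str(path)


def _report(config, outdir: Path, outputs: dict, samples, stab):
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_fragments": {name: len(frags) for name, frags in sorted(samples.items())},
        "outputs": dict(sorted(outputs.items())),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = str(path)

    lines = ["# Run summary", "", f"- seed: {config.seed}"]
    lines.append(f"- samples: {len(samples)}")
    if stab is not None:
        sig = stab[(stab["padj"] < 0.01) & (stab["log2fc"].abs() > 1.5)]
        lines.append(f"- stability records: {len(stab)}")
        lines.append(f"- significant (padj<0.01, |log2FC|>1.5): {len(sig)}")
    for key in ("class_profile", "si_medians", "pattern_fractions", "dominance_summary"):
        if key in outputs:
            lines.append(f"- {key}: {Path(outputs[key]).name}")
    path = outdir / "summary.md"
    path.write_text("\n".join(lines) + "\n")
    outputs["summary"] = str(path)
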