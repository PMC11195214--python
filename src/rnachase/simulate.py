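"""Synthetic label-chase read simulator with closed-form expectations.

The generative model collapses the labeling window to an instantaneous
cohort born at t=0. Each molecule draws its splice state once at synthesis:
with probability ``p_allnone`` it follows the all-or-none mode (fully
spliced with probability ``q_spliced``, else fully unspliced); otherwise
each intron is spliced independently with probability ``s_i``. Molecules
then decay with state-specific first-order kinetics — mature molecules with
a biphasic rate (``k_early`` before the phase switch at 2 h, ``k_late``
after), incompletely spliced molecules with ``k_unspliced`` plus a
conversion flow ``r_post`` into the mature pool, and excised introns with
``k_intron``. All expected abundances have closed forms, so every sampled
population is Poisson around an analytically known mean.

Fragments are born aligned: paired 150-nt mates from a truncated-normal
fragment length, mapped through the molecule's splice state onto the
genome (spliced intron -> split blocks, retained intron -> contiguous).
"""

from __future__ import annotations

import itertools
import json
import math
from collections import Counter
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
import yaml
from scipy.stats import truncnorm

from .accounting import AlignedFragment
from .genome import (
    FeatureSet,
    GeneModel,
    Transcript,
    attach_auxiliary_features,
    write_annotation,
)
from .intervals import GenomicInterval, merge_spans

PHASE_SWITCH = 2.0  # hours: boundary between the early and late decay phases
MAX_ENUMERATED_INTRONS = 14


@dataclass(frozen=True)
class KineticParams:
    """Per-gene generative kinetic parameters.

    Rates are per hour; probabilities live in [0, 1]; ``isoform_props`` is a
    simplex over the gene's transcripts. ``s_intron`` must have one entry
    per intron of the (single) transcript when independent-mode splicing is
    in play.
    """

    synthesis_level: float
    k_early: float = 0.0
    k_late: float = 0.0
    k_unspliced: float = 0.0
    k_intron: float = 0.0
    r_post: float = 0.0
    p_allnone: float = 1.0
    q_spliced: float = 1.0
    s_intron: tuple[float, ...] = ()
    isoform_props: tuple[float, ...] = (1.0,)
    isoform_k: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        rates = (
            self.synthesis_level,
            self.k_early,
            self.k_late,
            self.k_unspliced,
            self.k_intron,
            self.r_post,
            *self.isoform_k,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates and levels must be non-negative")
        probs = (self.p_allnone, self.q_spliced, *self.s_intron)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.isoform_props) - 1.0) > 1e-9:
            raise ValueError("isoform_props must sum to 1")
        if len(self.isoform_props) != len(self.isoform_k):
            raise ValueError("isoform_props and isoform_k must align")


@dataclass(frozen=True, slots=True)
class MoleculeState:
    """Latent state of one labeled molecule class at a sampling time."""

    gene_id: str
    kind: str  # 'rna' | 'intron' | 'class'
    isoform: str = ""
    splice_state: tuple[bool, ...] = ()
    intron_index: int = -1
    label: str = ""


def _state_key(state: MoleculeState):
    return (
        state.gene_id,
        state.kind,
        state.isoform,
        state.intron_index,
        state.splice_state,
        state.label,
    )


# ---------------------------------------------------------------------------
# closed-form kinetics


def _exp_integral(decay: float, growth: float, a: float, b: float) -> float:
    """``int_a^b exp((growth - decay) * tau) d tau`` with a stable limit."""
    d = growth - decay
    span = b - a
    if span <= 0:
        return 0.0
    x = d * span
    if abs(x) < 1e-12:
        return span * math.exp(d * a)
    return math.exp(d * a) * math.expm1(x) / d


def mature_survival(
    a: float, t: float, k_early: float, k_late: float, t_switch: float = PHASE_SWITCH
) -> float:
    """Survival of a mature molecule from time ``a`` to ``t`` under the
    biphasic rate (``k_early`` before ``t_switch``, ``k_late`` after)."""
    early = max(0.0, min(t, t_switch) - min(a, t_switch))
    late = max(0.0, t - t_switch) - max(0.0, a - t_switch)
    return math.exp(-k_early * early - k_late * late)


def converted_surviving(
    u0: float,
    k_unspliced: float,
    r_post: float,
    t: float,
    k_early: float,
    k_late: float,
    t_switch: float = PHASE_SWITCH,
) -> float:
    """Expected molecules converted from the unspliced pool and still alive.

    Standard two-compartment closed form: conversions occur at rate
    ``r_post`` while the source decays at ``k_unspliced + r_post``; the
    converted molecule then follows the biphasic mature survival.
    """
    if u0 <= 0 or r_post <= 0 or t <= 0:
        return 0.0
    lam = k_unspliced + r_post
    m = min(t, t_switch)
    integral = math.exp(-k_early * m - k_late * max(0.0, t - t_switch)) * _exp_integral(
        lam, k_early, 0.0, m
    )
    if t > t_switch:
        integral += math.exp(-k_late * t) * _exp_integral(lam, k_late, t_switch, t)
    return u0 * r_post * integral


def _released_intron_surviving(
    u0: float, k_unspliced: float, r_post: float, k_intron: float, t: float
) -> float:
    """Introns released by post-transcriptional conversion, still alive at t."""
    if u0 <= 0 or r_post <= 0 or t <= 0:
        return 0.0
    lam = k_unspliced + r_post
    return u0 * r_post * math.exp(-k_intron * t) * _exp_integral(lam, k_intron, 0.0, t)


def splice_state_probs(
    params: KineticParams, n_introns: int
) -> dict[tuple[bool, ...], float]:
    """Probability of each splice state at synthesis."""
    if n_introns == 0:
        return {(): 1.0}
    if n_introns > MAX_ENUMERATED_INTRONS:
        raise ValueError(f"too many introns to enumerate ({n_introns})")
    if params.p_allnone < 1.0 and len(params.s_intron) != n_introns:
        raise ValueError(
            f"need one s_intron entry per intron "
            f"({len(params.s_intron)} != {n_introns})"
        )
    probs: dict[tuple[bool, ...], float] = {}
    full = (True,) * n_introns
    none = (False,) * n_introns
    if params.p_allnone > 0:
        probs[full] = params.p_allnone * params.q_spliced
        probs[none] = probs.get(none, 0.0) + params.p_allnone * (1.0 - params.q_spliced)
    if params.p_allnone < 1.0:
        w = 1.0 - params.p_allnone
        for pattern in itertools.product((False, True), repeat=n_introns):
            p = w
            for spliced, s in zip(pattern, params.s_intron):
                p *= s if spliced else (1.0 - s)
            if p > 0:
                probs[pattern] = probs.get(pattern, 0.0) + p
    return {k: v for k, v in probs.items() if v > 0}


def state_expectations(
    params: KineticParams,
    n_introns: int,
    t: float,
    t_switch: float = PHASE_SWITCH,
) -> dict[tuple[bool, ...], float]:
    """Expected molecule count per splice state at chase time ``t``.

    Mass converted post-transcriptionally is folded into the fully spliced
    state.
    """
    probs = splice_state_probs(params, n_introns)
    full = (True,) * n_introns
    n0 = params.synthesis_level
    out: dict[tuple[bool, ...], float] = {}
    mature = probs.get(full, 0.0) * n0 * mature_survival(
        0.0, t, params.k_early, params.k_late, t_switch
    )
    for pattern, p in probs.items():
        if pattern == full:
            continue
        u0 = n0 * p
        out[pattern] = u0 * math.exp(-(params.k_unspliced + params.r_post) * t)
        mature += converted_surviving(
            u0,
            params.k_unspliced,
            params.r_post,
            t,
            params.k_early,
            params.k_late,
            t_switch,
        )
    out[full] = mature
    return out


def expected_abundance(
    params: KineticParams,
    species: str,
    t: float,
    n_introns: int = 0,
    intron_index: int | None = None,
    t_switch: float = PHASE_SWITCH,
) -> float:
    """Closed-form expected molecule count for one species at time ``t``.

    ``species`` is one of ``mature``, ``unspliced``, ``excised_intron``
    (requires ``intron_index``) or ``class`` (single-rate decay using
    ``k_early`` as the class turnover rate).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if species == "class":
        return params.synthesis_level * math.exp(-params.k_early * t)
    states = state_expectations(params, n_introns, t, t_switch)
    full = (True,) * n_introns
    if species == "mature":
        return states.get(full, 0.0)
    if species == "unspliced":
        return sum(v for k, v in states.items() if k != full)
    if species == "excised_intron":
        if intron_index is None or not 0 <= intron_index < n_introns:
            raise ValueError("excised_intron needs a valid intron_index")
        probs = splice_state_probs(params, n_introns)
        p_spliced = sum(p for σ, p in probs.items() if σ[intron_index])
        n0 = params.synthesis_level
        born = n0 * p_spliced * math.exp(-params.k_intron * t)
        released = _released_intron_surviving(
            n0 * (1.0 - p_spliced),
            params.k_unspliced,
            params.r_post,
            params.k_intron,
            t,
        )
        return born + released
    raise ValueError(f"unknown species {species!r}")


# ---------------------------------------------------------------------------
# population sampling


def simulate_population(
    params: KineticParams,
    gene: GeneModel,
    t: float,
    rng: np.random.Generator,
    t_switch: float = PHASE_SWITCH,
) -> Counter:
    """Draw the surviving labeled molecule multiset of one gene at time ``t``.

    Counts are Poisson around the closed-form expectations (equivalent in
    distribution to per-molecule Bernoulli survival filtering of a Poisson
    cohort). Excised introns are tracked as separate molecules.
    """
    pop: Counter = Counter()
    if gene.n_transcripts > 1:
        for j, tx in enumerate(gene.transcripts):
            mean = (
                params.synthesis_level
                * params.isoform_props[j]
                * math.exp(-params.isoform_k[j] * t)
            )
            n = int(rng.poisson(mean))
            if n:
                pop[
                    MoleculeState(
                        gene_id=gene.id,
                        kind="rna",
                        isoform=tx.id,
                        splice_state=(True,) * len(tx.introns),
                    )
                ] = n
        return pop

    tx = gene.transcripts[0]
    n_introns = len(tx.introns)
    states = state_expectations(params, n_introns, t, t_switch)
    for pattern in sorted(states):
        n = int(rng.poisson(states[pattern]))
        if n:
            pop[
                MoleculeState(
                    gene_id=gene.id, kind="rna", isoform=tx.id, splice_state=pattern
                )
            ] = n
    for i in range(n_introns):
        mean = expected_abundance(
            params, "excised_intron", t, n_introns, intron_index=i, t_switch=t_switch
        )
        n = int(rng.poisson(mean))
        if n:
            pop[
                MoleculeState(gene_id=gene.id, kind="intron", isoform=tx.id, intron_index=i)
            ] = n
    return pop


def simulate_class_population(
    label: str, level: float, k: float, t: float, rng: np.random.Generator
) -> Counter:
    """Surviving molecules of one non-genic RNA class region at time ``t``."""
    n = int(rng.poisson(level * math.exp(-k * t)))
    pop: Counter = Counter()
    if n:
        pop[MoleculeState(gene_id=label, kind="class", label=label)] = n
    return pop


def molecule_blocks(
    state: MoleculeState,
    features: FeatureSet,
    class_regions: Mapping[str, GenomicInterval] | None = None,
) -> tuple[str, str, tuple[tuple[int, int], ...]]:
    """Genomic alignment segments of one molecule state."""
    if state.kind == "class":
        if class_regions is None or state.label not in class_regions:
            raise KeyError(f"unknown class region {state.label!r}")
        iv = class_regions[state.label]
        return iv.chrom, iv.strand, ((iv.start, iv.end),)
    gene = features.genes[state.gene_id]
    tx = next(t for t in gene.transcripts if t.id == state.isoform) if state.isoform else gene.transcripts[0]
    if state.kind == "intron":
        iv = tx.introns[state.intron_index]
        return gene.chrom, gene.strand, ((iv.start, iv.end),)
    spans = [(e.start, e.end) for e in tx.exons]
    for i, retained in enumerate(state.splice_state):
        if not retained:
            spans.append((tx.introns[i].start, tx.introns[i].end))
    return gene.chrom, gene.strand, tuple(merge_spans(spans))


def _map_span(
    segs: Sequence[tuple[int, int]], cum: np.ndarray, a: int, b: int
) -> tuple[tuple[int, int], ...]:
    """Map molecule-coordinate interval [a, b) onto genomic blocks."""
    out = []
    i = int(np.searchsorted(cum, a, side="right")) - 1
    pos = a
    while pos < b:
        seg_start, seg_end = segs[i]
        g = seg_start + (pos - int(cum[i]))
        take = min(b, int(cum[i + 1])) - pos
        out.append((g, g + take))
        pos += take
        i += 1
    return tuple(out)


def sample_fragments(
    population: Counter,
    features: FeatureSet,
    depth: int,
    rng: np.random.Generator,
    read_len: int = 150,
    frag_mean: float = 450.0,
    frag_sd: float = 25.0,
    class_regions: Mapping[str, GenomicInterval] | None = None,
    name_prefix: str = "frag",
) -> tuple[list[AlignedFragment], int]:
    """Sample ``depth`` paired-end fragments from a molecule population.

    Fragments are allocated across molecules proportional to the number of
    available start positions (length minus mean fragment length), starts
    are uniform, and lengths follow a truncated normal on
    ``[2*read_len, molecule length]``. Molecules shorter than two read
    lengths cannot yield a fragment; draws landing on them are skipped and
    tallied, so emitted + skipped == depth.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    states = sorted(population, key=_state_key)
    if not states:
        return [], depth

    resolved = []
    weights = np.empty(len(states))
    for i, state in enumerate(states):
        chrom, strand, segs = molecule_blocks(state, features, class_regions)
        lengths = np.fromiter((e - s for s, e in segs), dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lengths)])
        mol_len = int(cum[-1])
        resolved.append((chrom, strand, segs, cum, mol_len))
        weights[i] = population[state] * max(mol_len - frag_mean + 1.0, 1.0)

    alloc = rng.multinomial(depth, weights / weights.sum())
    frags: list[AlignedFragment] = []
    skipped = 0
    counter = 0
    lo = 2 * read_len
    for (chrom, strand, segs, cum, mol_len), n in zip(resolved, alloc):
        if n == 0:
            continue
        if mol_len < lo:
            skipped += int(n)
            continue
        if frag_sd > 0:
            a = (lo - frag_mean) / frag_sd
            b = (mol_len - frag_mean) / frag_sd
            ls = truncnorm.rvs(a, b, loc=frag_mean, scale=frag_sd, size=n, random_state=rng)
            ls = np.clip(np.rint(ls).astype(np.int64), lo, mol_len)
        else:
            ls = np.full(n, int(np.clip(round(frag_mean), lo, mol_len)), dtype=np.int64)
        starts = rng.integers(0, mol_len - ls + 1)
        for s, L in zip(starts.tolist(), ls.tolist()):
            b1 = _map_span(segs, cum, s, s + read_len)
            b2 = _map_span(segs, cum, s + L - read_len, s + L)
            merged = tuple(merge_spans(list(b1) + list(b2)))
            frags.append(
                AlignedFragment(
                    name=f"{name_prefix}{counter:08d}",
                    chrom=chrom,
                    blocks=merged,
                    strand=strand,
                    mapq=255,
                    mate_blocks=(b1, b2),
                )
            )
            counter += 1
    return frags, skipped


# ---------------------------------------------------------------------------
# dataset-level configuration and orchestration


@dataclass
class SimConfig:
    """Configuration for a full simulated label-chase dataset.

    Tuple-valued kinetic fields are ``(low, high)`` sampling ranges; scalar
    fields apply to every gene. The fragment-size default follows the
    sequencing description (400-500 bp fragments, 150 nt paired ends) and
    is configurable.
    """

    seed: int = 0
    chrom: str = "chrS"
    chrom_gap: int = 20000
    n_genes: int = 12
    cell_lines: tuple[str, ...] = ("simA",)
    timepoints: tuple[float, ...] = (0.0, 2.0, 6.0)
    replicates: int = 2
    depth: int = 20000
    depth_mode: str = "proportional"  # library size tracks surviving RNA mass
    read_len: int = 150
    frag_mean: float = 450.0
    frag_sd: float = 25.0
    exon_count: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (100, 300)
    # terminal exons can be drawn longer (UTR-like) so that junction sites
    # sit away from molecule ends; None -> same range as internal exons
    terminal_exon_length: tuple[int, int] | None = None
    intron_length: tuple[int, int] = (200, 800)
    multi_isoform_fraction: float = 0.0
    synthesis: tuple[float, float] = (100.0, 400.0)
    k_early: tuple[float, float] = (0.05, 0.5)
    k_late: tuple[float, float] = (0.05, 0.5)
    k_unspliced: tuple[float, float] = (0.5, 1.5)
    k_intron: tuple[float, float] = (1.0, 2.0)
    r_post: tuple[float, float] = (0.0, 0.3)
    p_allnone: float = 1.0
    q_spliced: tuple[float, float] = (0.4, 0.8)
    s_intron: tuple[float, float] = (0.3, 0.7)
    isoform_k: tuple[float, float] = (0.0, 0.8)
    include_classes: bool = False
    class_level: float = 200.0
    prompt_k: float = 1.5
    readthrough_k: float = 0.8
    repeat_k: float = 2.5

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        kwargs = {}
        for name, value in data.items():
            if name not in cls.__dataclass_fields__:
                raise ValueError(f"unknown simulation option {name!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Generative ground truth recorded for recovery tests."""

    seed: int
    genes: dict[str, KineticParams]
    class_params: dict[str, tuple[float, float]]  # label -> (level, rate)
    config: dict = field(default_factory=dict)
    expectations: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "genes": {gid: asdict(p) for gid, p in self.genes.items()},
            "class_params": {k: list(v) for k, v in self.class_params.items()},
            "config": self.config,
            "expectations": self.expectations,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        genes = {}
        for gid, fields_ in payload["genes"].items():
            for key in ("s_intron", "isoform_props", "isoform_k"):
                fields_[key] = tuple(fields_[key])
            genes[gid] = KineticParams(**fields_)
        config = payload["config"]
        try:  # restore tuple-valued fields lost to JSON lists
            config = SimConfig.from_dict(config).to_dict()
        except (ValueError, TypeError):
            pass
        return cls(
            seed=payload["seed"],
            genes=genes,
            class_params={k: tuple(v) for k, v in payload["class_params"].items()},
            config=config,
            expectations=payload["expectations"],
        )


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def random_feature_set(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[FeatureSet, dict[str, KineticParams], dict[str, int]]:
    """Lay out random gene models on one synthetic chromosome and sample
    kinetic parameters for each."""
    features = FeatureSet()
    params: dict[str, KineticParams] = {}
    pos = cfg.chrom_gap
    for i in range(cfg.n_genes):
        gid = f"g{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(cfg.exon_count[0], cfg.exon_count[1] + 1))
        exons = []
        cursor = pos
        for j in range(n_exons):
            rng_pair = (
                cfg.terminal_exon_length
                if cfg.terminal_exon_length is not None and j in (0, n_exons - 1)
                else cfg.exon_length
            )
            elen = int(rng.integers(rng_pair[0], rng_pair[1] + 1))
            exons.append(GenomicInterval(cfg.chrom, cursor, cursor + elen, strand))
            cursor += elen
            if j < n_exons - 1:
                cursor += int(
                    rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1)
                )
        transcripts = [Transcript(id=f"{gid}.t1", gene_id=gid, exons=tuple(exons))]
        multi = n_exons >= 3 and rng.random() < cfg.multi_isoform_fraction
        if multi:
            skip = int(rng.integers(1, n_exons - 1))
            alt = tuple(e for j, e in enumerate(exons) if j != skip)
            transcripts.append(Transcript(id=f"{gid}.t2", gene_id=gid, exons=alt))
        gene = GeneModel(id=gid, transcripts=tuple(transcripts))
        features.genes[gid] = gene

        n_introns = len(transcripts[0].introns)
        if multi:
            p1 = float(rng.uniform(0.2, 0.8))
            params[gid] = KineticParams(
                synthesis_level=_uniform(rng, cfg.synthesis),
                isoform_props=(p1, 1.0 - p1),
                isoform_k=(
                    _uniform(rng, cfg.isoform_k),
                    _uniform(rng, cfg.isoform_k),
                ),
            )
        else:
            params[gid] = KineticParams(
                synthesis_level=_uniform(rng, cfg.synthesis),
                k_early=_uniform(rng, cfg.k_early),
                k_late=_uniform(rng, cfg.k_late),
                k_unspliced=_uniform(rng, cfg.k_unspliced),
                k_intron=_uniform(rng, cfg.k_intron),
                r_post=_uniform(rng, cfg.r_post),
                p_allnone=cfg.p_allnone,
                q_spliced=_uniform(rng, cfg.q_spliced),
                s_intron=tuple(
                    _uniform(rng, cfg.s_intron) for _ in range(n_introns)
                ),
            )
        pos = cursor + cfg.chrom_gap
    chrom_lengths = {cfg.chrom: pos + cfg.chrom_gap}
    return features, params, chrom_lengths


def class_region_map(
    features: FeatureSet, cfg: SimConfig
) -> tuple[dict[str, GenomicInterval], dict[str, tuple[float, float]]]:
    """Non-genic class regions (prompt/readthrough per gene) and their
    simulation parameters."""
    regions: dict[str, GenomicInterval] = {}
    class_params: dict[str, tuple[float, float]] = {}
    if not cfg.include_classes:
        return regions, class_params
    for gid, iv in features.prompts.items():
        label = f"prompt:{gid}"
        regions[label] = iv
        class_params[label] = (cfg.class_level, cfg.prompt_k)
    for gid, iv in features.readthrough.items():
        label = f"rt:{gid}"
        regions[label] = iv
        class_params[label] = (cfg.class_level, cfg.readthrough_k)
    for family, iv in features.repeats:
        label = f"repeat:{family}:{iv.start}"
        regions[label] = iv
        class_params[label] = (cfg.class_level, cfg.repeat_k)
    return regions, class_params


def expected_population_weight(
    features: FeatureSet,
    params: Mapping[str, KineticParams],
    class_params: Mapping[str, tuple[float, float]],
    class_regions: Mapping[str, GenomicInterval],
    t: float,
    frag_mean: float,
) -> float:
    """Analytic expected fragment-sampling weight of a population at ``t``
    (used to scale library depth with surviving RNA mass)."""

    def w(length: int) -> float:
        return max(length - frag_mean + 1.0, 1.0)

    total = 0.0
    for gid, gene in features.genes.items():
        p = params[gid]
        if gene.n_transcripts > 1:
            for j, tx in enumerate(gene.transcripts):
                mean = p.synthesis_level * p.isoform_props[j] * math.exp(
                    -p.isoform_k[j] * t
                )
                total += mean * w(tx.length)
            continue
        tx = gene.transcripts[0]
        n_introns = len(tx.introns)
        intron_lens = [iv.length for iv in tx.introns]
        spliced_len = tx.length
        for pattern, mean in state_expectations(p, n_introns, t).items():
            mol_len = spliced_len + sum(
                l for retained, l in zip(pattern, intron_lens) if not retained
            )
            total += mean * w(mol_len)
        for i in range(n_introns):
            mean = expected_abundance(p, "excised_intron", t, n_introns, intron_index=i)
            total += mean * w(intron_lens[i])
    for label, (level, k) in class_params.items():
        total += level * math.exp(-k * t) * w(class_regions[label].length)
    return total


def timepoint_label(t: float) -> str:
    return f"{t:g}h"


@dataclass
class SimResult:
    """In-memory result of a dataset simulation."""

    features: FeatureSet
    truth: SimTruth
    chrom_lengths: dict[str, int]
    class_regions: dict[str, GenomicInterval]
    samples: dict[str, list[AlignedFragment]]
    skipped: dict[str, int]
    sample_meta: dict[str, dict]


def compute_expectations(
    features: FeatureSet,
    params: Mapping[str, KineticParams],
    timepoints: Sequence[float],
) -> dict:
    """Derived per-gene expectations frozen into the truth record."""
    out: dict = {}
    for gid, gene in features.genes.items():
        p = params[gid]
        entry: dict = {}
        if gene.n_transcripts > 1:
            entry["isoform_percent"] = {
                timepoint_label(t): {
                    tx.id: 100.0
                    * p.isoform_props[j]
                    * math.exp(-p.isoform_k[j] * t)
                    / sum(
                        p.isoform_props[m] * math.exp(-p.isoform_k[m] * t)
                        for m in range(gene.n_transcripts)
                    )
                    for j, tx in enumerate(gene.transcripts)
                }
                for t in timepoints
            }
        else:
            n_introns = len(gene.transcripts[0].introns)
            mature = {
                timepoint_label(t): expected_abundance(p, "mature", t, n_introns)
                for t in timepoints
            }
            entry["mature"] = mature
            ordered = sorted(timepoints)
            entry["log2fc"] = {
                f"{timepoint_label(a)}-{timepoint_label(b)}": math.log2(
                    mature[timepoint_label(b)] / mature[timepoint_label(a)]
                )
                if mature[timepoint_label(a)] > 0 and mature[timepoint_label(b)] > 0
                else None
                for a, b in zip(ordered, ordered[1:])
            }
            si: dict = {}
            for t in timepoints:
                states = state_expectations(p, n_introns, t)
                per_intron = []
                for i in range(n_introns):
                    spliced = sum(v for σ, v in states.items() if σ[i])
                    unspliced = sum(v for σ, v in states.items() if not σ[i])
                    per_intron.append(
                        spliced / (spliced + unspliced)
                        if spliced + unspliced > 0
                        else None
                    )
                si[timepoint_label(t)] = per_intron
            entry["si"] = si
        out[gid] = entry
    return out


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Simulate every sample of a label-chase dataset in memory."""
    ss = np.random.SeedSequence(cfg.seed)
    struct_seed, *sample_seeds = ss.spawn(
        1 + len(cfg.cell_lines) * len(cfg.timepoints) * cfg.replicates
    )
    rng = np.random.default_rng(struct_seed)
    features, params, chrom_lengths = random_feature_set(cfg, rng)
    if cfg.include_classes:
        attach_auxiliary_features(features, chrom_lengths=chrom_lengths)
    class_regions, class_params = class_region_map(features, cfg)
    w0 = expected_population_weight(
        features, params, class_params, class_regions, 0.0, cfg.frag_mean
    )
    truth = SimTruth(
        seed=cfg.seed,
        genes=params,
        class_params=class_params,
        config=cfg.to_dict(),
        expectations=compute_expectations(features, params, cfg.timepoints),
    )

    samples: dict[str, list[AlignedFragment]] = {}
    skipped: dict[str, int] = {}
    sample_meta: dict[str, dict] = {}
    seed_iter = iter(sample_seeds)
    for line in cfg.cell_lines:
        for t in cfg.timepoints:
            for rep in range(1, cfg.replicates + 1):
                srng = np.random.default_rng(next(seed_iter))
                name = f"{line}_{timepoint_label(t)}_r{rep}"
                pop: Counter = Counter()
                for gid in sorted(features.genes):
                    pop.update(
                        simulate_population(params[gid], features.genes[gid], t, srng)
                    )
                for label in sorted(class_params):
                    level, k = class_params[label]
                    pop.update(simulate_class_population(label, level, k, t, srng))
                if cfg.depth_mode == "proportional":
                    w_t = sum(
                        pop[state]
                        * max(
                            sum(
                                e - s
                                for s, e in molecule_blocks(
                                    state, features, class_regions
                                )[2]
                            )
                            - cfg.frag_mean
                            + 1.0,
                            1.0,
                        )
                        for state in pop
                    )
                    depth = max(1, round(cfg.depth * w_t / w0))
                else:
                    depth = cfg.depth
                frags, nskip = sample_fragments(
                    pop,
                    features,
                    depth,
                    srng,
                    read_len=cfg.read_len,
                    frag_mean=cfg.frag_mean,
                    frag_sd=cfg.frag_sd,
                    class_regions=class_regions,
                    name_prefix=f"{name}:",
                )
                samples[name] = frags
                skipped[name] = nskip
                sample_meta[name] = {
                    "cell_line": line,
                    "timepoint": timepoint_label(t),
                    "replicate": rep,
                    "depth": depth,
                }
    return SimResult(
        features=features,
        truth=truth,
        chrom_lengths=chrom_lengths,
        class_regions=class_regions,
        samples=samples,
        skipped=skipped,
        sample_meta=sample_meta,
    )


# ---------------------------------------------------------------------------
# output


def _sam_records(frag: AlignedFragment, strand: str):
    """Flags/blocks of the two mates in (leftmost, rightmost) order."""
    b1, b2 = frag.mate_blocks
    # protocol: mate 2 carries the transcription strand (dUTP-style)
    if strand == "+":
        left = (b1, 0x1 | 0x2 | 0x80)  # read2, forward
        right = (b2, 0x1 | 0x2 | 0x10 | 0x40)  # read1, reverse
    else:
        left = (b1, 0x1 | 0x2 | 0x40)  # read1, forward
        right = (b2, 0x1 | 0x2 | 0x10 | 0x80)  # read2, reverse
    return left, right


def _cigar(blocks: Sequence[tuple[int, int]]):
    ops = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                ops.append((3, gap))  # N
        ops.append((0, e - s))  # M
    return ops


def write_sample_alignments(
    path: str | Path,
    frags: Sequence[AlignedFragment],
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write fragments as a coordinate-sorted SAM/BAM of proper pairs
    (MAPQ 255, the unique-mapper convention)."""
    path = Path(path)
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    mode = "wb" if path.suffix == ".bam" else "w"
    tid = {c: i for i, c in enumerate(chroms)}
    records = []
    for frag in sorted(frags, key=lambda f: (f.chrom, f.start, f.name)):
        if frag.mate_blocks is None or len(frag.mate_blocks) != 2:
            raise ValueError(f"fragment {frag.name} lacks mate blocks")
        (lb, lflag), (rb, rflag) = _sam_records(frag, frag.strand)
        lflag |= 0x20  # mate of the left read is on the reverse strand
        tlen = frag.end - frag.start
        for blocks, flag, mate_start, tl in (
            (lb, lflag, rb[0][0], tlen),
            (rb, rflag, lb[0][0], -tlen),
        ):
            records.append((frag, blocks, flag, mate_start, tl))
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for frag, blocks, flag, mate_start, tl in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = frag.name
            seg.flag = flag
            seg.reference_id = tid[frag.chrom]
            seg.reference_start = blocks[0][0]
            seg.mapping_quality = frag.mapq
            seg.cigartuples = _cigar(blocks)
            seg.next_reference_id = tid[frag.chrom]
            seg.next_reference_start = mate_start
            seg.template_length = tl
            length = sum(e - s for s, e in blocks)
            seg.query_sequence = "N" * length
            seg.query_qualities = pysam.qualitystring_to_array("I" * length)
            out.write(seg)
    if mode == "wb":
        pysam.index(str(path))


def write_simulation(
    outdir: str | Path,
    result: SimResult,
    fmt: str = "sam",
) -> dict[str, Path]:
    """Write annotation, per-sample alignments and the truth record.

    Returns a mapping of logical names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gtf = outdir / "annotation.gtf"
    write_annotation(result.features, gtf)
    paths["annotation"] = gtf
    for name, frags in result.samples.items():
        path = outdir / f"{name}.{fmt}"
        write_sample_alignments(path, frags, result.chrom_lengths)
        paths[name] = path
    truth_path = outdir / "truth.json"
    truth_path.write_text(result.truth.to_json())
    paths["truth"] = truth_path
    meta = outdir / "samples.json"
    meta.write_text(json.dumps(result.sample_meta, indent=1, sort_keys=True))
    paths["samples"] = meta
    return paths
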