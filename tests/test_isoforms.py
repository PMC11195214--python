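import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from _util import frag, make_features, make_gene

from rnachase.isoforms import (
    DominanceCall,
    EquivalenceClassCounts,
    build_equivalence_classes,
    dominance_classify,
    dominance_summary,
    dominance_table,
    ec_log_likelihood,
    effective_length,
    em_quantify,
    isoform_percentages,
)
from rnachase.simulate import KineticParams, MoleculeState, sample_fragments

# two isoforms: t1 keeps the middle exon, t2 skips it
GENE = make_gene(
    "g1",
    "chr1",
    "+",
    [(0, 300), (500, 800), (1000, 1300)],
    alt_exon_spans=[(0, 300), (1000, 1300)],
)


def test_effective_length_floor():
    assert effective_length(900, 450) == 451
    assert effective_length(100, 450) == 1


class TestBuildEquivalenceClasses:
    def test_shared_exon_ambiguous(self):
        f = frag("chr1", [(50, 200)], mate_blocks=(((50, 200),),))
        ec = build_equivalence_classes([f], GENE)
        assert ec.classes == {frozenset({"g1.t1", "g1.t2"}): 1}

    def test_unique_junction_resolves(self):
        # split exactly over t2's skipped-exon junction
        f = frag(
            "chr1",
            [(260, 300), (1000, 1040)],
            mate_blocks=(((260, 300), (1000, 1040)),),
        )
        ec = build_equivalence_classes([f], GENE)
        assert ec.classes == {frozenset({"g1.t2"}): 1}

    def test_middle_exon_resolves_t1(self):
        f = frag("chr1", [(600, 700)], mate_blocks=(((600, 700),),))
        ec = build_equivalence_classes([f], GENE)
        assert ec.classes == {frozenset({"g1.t1"}): 1}

    def test_retained_intron_incompatible(self):
        f = frag("chr1", [(250, 420)], mate_blocks=(((250, 420),),))
        ec = build_equivalence_classes([f], GENE)
        assert ec.classes == {} and ec.incompatible == 1

    def test_mate_gap_must_be_colinear(self):
        # mate pair spanning t1's junction as an *insert* gap is fine for t1
        f = frag(
            "chr1",
            [(200, 300), (500, 600)],
            mate_blocks=(((200, 300),), ((500, 600),)),
        )
        ec = build_equivalence_classes([f], GENE)
        assert frozenset({"g1.t1"}) in ec.classes


class TestEmQuantify:
    def test_analytic_fixed_point(self):
        ec = EquivalenceClassCounts(
            gene_id="g",
            classes={
                frozenset({"t1"}): 80,
                frozenset({"t2"}): 20,
                frozenset({"t1", "t2"}): 100,
            },
            effective_lengths={"t1": 500.0, "t2": 500.0},
        )
        res = em_quantify(ec)
        assert res.converged
        assert res.theta["t1"] == pytest.approx(0.8, abs=1e-6)
        assert res.proportions["t1"] == pytest.approx(0.8, abs=1e-6)

    def test_single_isoform(self):
        ec = EquivalenceClassCounts(
            gene_id="g",
            classes={frozenset({"t1"}): 10},
            effective_lengths={"t1": 300.0},
        )
        res = em_quantify(ec)
        assert res.proportions == {"t1": 1.0}

    def test_no_reads_errors(self):
        ec = EquivalenceClassCounts(
            gene_id="g", classes={}, effective_lengths={"t1": 300.0}
        )
        with pytest.raises(ValueError, match="no assigned"):
            em_quantify(ec)

    def test_loglik_nondecreasing_and_simplex(self, rng):
        for _ in range(20):
            lens = {"t1": float(rng.integers(200, 800)), "t2": float(rng.integers(200, 800))}
            ec = EquivalenceClassCounts(
                gene_id="g",
                classes={
                    frozenset({"t1"}): int(rng.integers(1, 100)),
                    frozenset({"t2"}): int(rng.integers(1, 100)),
                    frozenset({"t1", "t2"}): int(rng.integers(1, 100)),
                },
                effective_lengths=lens,
            )
            lls = []
            for it in range(1, 30):
                res = em_quantify(ec, tol=0.0, max_iter=it)
                assert sum(res.theta.values()) == pytest.approx(1.0)
                lls.append(ec_log_likelihood(ec, res.theta))
            assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            lens = {"t1": float(rng.integers(200, 800)), "t2": float(rng.integers(200, 800))}
            ec = EquivalenceClassCounts(
                gene_id="g",
                classes={
                    frozenset({"t1"}): int(rng.integers(0, 100)) + 1,
                    frozenset({"t2"}): int(rng.integers(0, 100)) + 1,
                    frozenset({"t1", "t2"}): int(rng.integers(0, 100)),
                },
                effective_lengths=lens,
            )
            grid = np.linspace(1e-6, 1 - 1e-6, 10001)
            lls = [
                ec_log_likelihood(ec, {"t1": g, "t2": 1 - g}) for g in grid
            ]
            best = grid[int(np.argmax(lls))]
            res = em_quantify(ec)
            assert res.theta["t1"] == pytest.approx(best, abs=1e-3)


def _percent_df(rows):
    return pd.DataFrame(rows, columns=["gene", "isoform", "timepoint", "percent"])


class TestIsoformPercentages:
    def make_ec(self, n1, n2, shared=0):
        return EquivalenceClassCounts(
            gene_id="g",
            classes={
                k: v
                for k, v in {
                    frozenset({"t1"}): n1,
                    frozenset({"t2"}): n2,
                    frozenset({"t1", "t2"}): shared,
                }.items()
                if v
            },
            effective_lengths={"t1": 500.0, "t2": 500.0},
        )

    def test_percentages_sum_to_100(self):
        ec_by_tp = {tp: {"g": self.make_ec(400, 100)} for tp in ("0h", "2h", "6h")}
        df = isoform_percentages(ec_by_tp, tpm_min=0.0)
        for tp, sub in df.groupby("timepoint"):
            assert sub["percent"].sum() == pytest.approx(100.0, abs=1e-6)
        t1 = df[(df.isoform == "t1") & (df.timepoint == "0h")]["percent"].item()
        assert t1 == pytest.approx(80.0)

    def test_low_tpm_gene_excluded(self):
        ec_by_tp = {
            "0h": {"g": self.make_ec(400, 100), "big": None},
            "2h": {"g": self.make_ec(400, 100)},
            "6h": {"g": self.make_ec(400, 100)},
        }
        # a dominant competitor dilutes g below 1 TPM at 0h
        big = EquivalenceClassCounts(
            gene_id="big",
            classes={frozenset({"b1"}): 10**9},
            effective_lengths={"b1": 500.0, "b2": 500.0},
        )
        ec_by_tp["0h"]["big"] = big
        df = isoform_percentages(ec_by_tp, tpm_min=1.0)
        assert "g" not in set(df["gene"])

    def test_single_isoform_gene_excluded(self):
        single = EquivalenceClassCounts(
            gene_id="solo",
            classes={frozenset({"t1"}): 100},
            effective_lengths={"t1": 500.0},
        )
        ec_by_tp = {tp: {"solo": single} for tp in ("0h", "2h", "6h")}
        df = isoform_percentages(ec_by_tp, tpm_min=0.0)
        assert df.empty or "solo" not in set(df["gene"])


class TestDominanceClassify:
    def test_always_dominant(self):
        call = dominance_classify("g", {"a": [60, 70, 80], "b": [40, 30, 20]})
        assert call.categories == {"AD"}

    def test_gd_and_ld_together(self):
        call = dominance_classify("g", {"a": [30, 45, 60], "b": [70, 55, 40]})
        assert call.categories == {"GD", "LD"}

    def test_other_when_no_crossing(self):
        call = dominance_classify("g", {"a": [40, 45, 48], "b": [60, 55, 52]})
        # b holds >=50 throughout -> AD; make a truly undominated gene:
        call = dominance_classify("g", {"a": [40, 45, 48], "b": [45, 40, 42], "c": [15, 15, 10]})
        assert call.categories == {"other"}

    def test_missing_timepoint_unclassifiable(self):
        call = dominance_classify("g", {"a": [60, float("nan"), 80]})
        assert call.categories == {"unclassifiable"}

    def test_dominant_isoforms_recorded(self):
        call = dominance_classify("g", {"a": [60, 70, 80], "b": [40, 30, 20]})
        assert dict(call.dominant) == {"0h": ("a",), "2h": ("a",), "6h": ("a",)}


def test_dominance_summary_fractions():
    calls = [
        dominance_classify("g1", {"a": [60, 60, 60], "b": [40, 40, 40]}),
        dominance_classify("g2", {"a": [30, 50, 60], "b": [70, 50, 40]}),
        dominance_classify("g3", {"a": [40, 40, 40], "b": [45, 45, 45], "c": [15, 15, 15]}),
        dominance_classify("g4", {"a": [60, float("nan"), 80]}),
    ]
    summary = dominance_summary(calls)
    assert summary["AD"] == pytest.approx(1 / 3)
    assert summary["GD"] == pytest.approx(1 / 3)
    assert summary["LD"] == pytest.approx(1 / 3)
    assert summary["other"] == pytest.approx(1 / 3)


# isoforms with mutually exclusive middle exons: equal lengths, each with a
# unique distinguishing junction, and symmetric ambiguity classes (the
# equivalence-class likelihood is unbiased for this geometry)
MXE_GENE = make_gene(
    "mx",
    "chr1",
    "+",
    [(0, 300), (500, 800), (1300, 1600)],
    alt_exon_spans=[(0, 300), (900, 1200), (1300, 1600)],
)


def test_proportion_recovery_from_simulated_fragments(rng):
    feats = make_features(MXE_GENE)
    pop = Counter(
        {
            MoleculeState("mx", "rna", "mx.t1", (True, True)): int(0.8 * 20000),
            MoleculeState("mx", "rna", "mx.t2", (True, True)): int(0.2 * 20000),
        }
    )
    frags, _ = sample_fragments(pop, feats, 10000, rng)
    ec = build_equivalence_classes(frags, MXE_GENE, frag_mean=450.0)
    res = em_quantify(ec)
    assert res.proportions["mx.t1"] == pytest.approx(0.8, abs=0.03)


def test_dominance_flip_from_isoform_specific_decay(rng):
    # t2 starts minor (40%) but is stable; t1 starts major and decays fast
    feats = make_features(MXE_GENE)
    n0 = 30000
    k1, k2 = 0.4, 0.0
    ec_by_tp = {}
    for t, tp in ((0.0, "0h"), (2.0, "2h"), (6.0, "6h")):
        pop = Counter(
            {
                MoleculeState("mx", "rna", "mx.t1", (True, True)): int(
                    0.6 * n0 * math.exp(-k1 * t)
                ),
                MoleculeState("mx", "rna", "mx.t2", (True, True)): int(
                    0.4 * n0 * math.exp(-k2 * t)
                ),
            }
        )
        frags, _ = sample_fragments(pop, feats, 8000, rng)
        ec_by_tp[tp] = {"mx": build_equivalence_classes(frags, MXE_GENE)}
    pct = isoform_percentages(ec_by_tp, tpm_min=0.0)
    calls = dominance_table(pct)
    assert len(calls) == 1
    assert calls[0].categories == {"GD", "LD"}
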