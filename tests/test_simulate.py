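import math
from collections import Counter

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import truncnorm

from _util import make_features, make_gene

from rnachase.accounting import read_fragments
from rnachase.genome import load_annotation
from rnachase.simulate import (
    KineticParams,
    MoleculeState,
    SimConfig,
    SimTruth,
    expected_abundance,
    sample_fragments,
    simulate_dataset,
    simulate_population,
    splice_state_probs,
    state_expectations,
    write_simulation,
)

LN2 = math.log(2.0)


class TestKineticParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            KineticParams(synthesis_level=10, k_early=-0.1)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            KineticParams(synthesis_level=10, q_spliced=1.5)

    def test_isoform_props_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            KineticParams(
                synthesis_level=10, isoform_props=(0.5, 0.2), isoform_k=(0, 0)
            )


class TestExpectedAbundance:
    def test_half_life_two_hours(self):
        p = KineticParams(synthesis_level=1000, k_early=LN2 / 2, p_allnone=1, q_spliced=1)
        n2 = expected_abundance(p, "mature", 2)
        assert n2 == pytest.approx(500)
        assert math.log2(n2 / expected_abundance(p, "mature", 0)) == pytest.approx(-1)

    def test_all_rates_zero_conserves(self):
        p = KineticParams(synthesis_level=321, p_allnone=1, q_spliced=1)
        for t in (0, 2, 6):
            assert expected_abundance(p, "mature", t) == pytest.approx(321)

    def test_biphasic_late_phase(self):
        p = KineticParams(
            synthesis_level=1000, k_early=LN2 / 2, k_late=LN2 / 4, p_allnone=1, q_spliced=1
        )
        # x0.5 over 0-2h, then x0.5 over the 4h late phase
        assert expected_abundance(p, "mature", 6) == pytest.approx(250)

    def test_conversion_example(self):
        # all-unspliced cohort of 800, no decay, conversion half-life 2h
        p = KineticParams(
            synthesis_level=800,
            r_post=LN2 / 2,
            p_allnone=1,
            q_spliced=0,
            s_intron=(0.0,),
        )
        assert expected_abundance(p, "unspliced", 2, n_introns=1) == pytest.approx(400)
        assert expected_abundance(p, "mature", 2, n_introns=1) == pytest.approx(400)

    def test_conversion_matches_ode_integrator(self):
        # independent oracle: integrate the two-compartment ODE numerically
        p = KineticParams(
            synthesis_level=500,
            k_early=0.31,
            k_late=0.12,
            k_unspliced=0.8,
            r_post=0.45,
            p_allnone=1,
            q_spliced=0.25,
            s_intron=(0.5,),
        )
        u0 = 500 * 0.75
        m0 = 500 * 0.25

        def rhs(t, y):
            k_m = p.k_early if t < 2 else p.k_late
            u, m = y
            return [-(p.k_unspliced + p.r_post) * u, p.r_post * u - k_m * m]

        sol = solve_ivp(
            rhs, (0, 6), [u0, m0], t_eval=[2, 6], rtol=1e-10, atol=1e-10
        )
        for i, t in enumerate((2, 6)):
            assert expected_abundance(p, "unspliced", t, n_introns=1) == pytest.approx(
                sol.y[0][i], rel=1e-6
            )
            assert expected_abundance(p, "mature", t, n_introns=1) == pytest.approx(
                sol.y[1][i], rel=1e-6
            )

    def test_excised_intron_decay(self):
        p = KineticParams(
            synthesis_level=1000,
            k_intron=LN2,
            p_allnone=1,
            q_spliced=1,
            s_intron=(1.0, 1.0),
        )
        born = expected_abundance(p, "excised_intron", 0, n_introns=2, intron_index=0)
        after = expected_abundance(p, "excised_intron", 2, n_introns=2, intron_index=0)
        assert born == pytest.approx(1000)
        assert after == pytest.approx(250)

    def test_unknown_species(self):
        p = KineticParams(synthesis_level=10)
        with pytest.raises(ValueError, match="species"):
            expected_abundance(p, "plasmid", 0)


def test_splice_state_probs_mixture():
    p = KineticParams(
        synthesis_level=1,
        p_allnone=0.4,
        q_spliced=0.7,
        s_intron=(0.5, 0.5),
    )
    probs = splice_state_probs(p, 2)
    assert sum(probs.values()) == pytest.approx(1)
    assert probs[(True, True)] == pytest.approx(0.4 * 0.7 + 0.6 * 0.25)
    assert probs[(False, False)] == pytest.approx(0.4 * 0.3 + 0.6 * 0.25)
    assert probs[(True, False)] == pytest.approx(0.6 * 0.25)


def test_equal_rates_give_flat_class_fractions():
    # no differential turnover => state fractions invariant over time
    k = 0.37
    p = KineticParams(
        synthesis_level=100,
        k_early=k,
        k_late=k,
        k_unspliced=k,
        k_intron=k,
        r_post=0.0,
        p_allnone=0.0,
        q_spliced=0.5,
        s_intron=(0.3, 0.8),
    )
    ref = state_expectations(p, 2, 0.0)
    total0 = sum(ref.values())
    for t in (2.0, 6.0):
        states = state_expectations(p, 2, t)
        total = sum(states.values())
        for pattern, v in states.items():
            assert v / total == pytest.approx(ref[pattern] / total0, rel=1e-9)


GENE = make_gene("g1", "chrS", "+", [(1000, 1300), (1500, 1800), (2100, 2400)])
FEATURES = make_features(GENE)


class TestSimulatePopulation:
    def test_allnone_spliced_fraction(self, rng):
        p = KineticParams(
            synthesis_level=20000, p_allnone=1, q_spliced=0.7, s_intron=(0.5, 0.5)
        )
        pop = simulate_population(p, GENE, 0.0, rng)
        full = pop[MoleculeState("g1", "rna", "g1.t1", (True, True))]
        none = pop[MoleculeState("g1", "rna", "g1.t1", (False, False))]
        frac = full / (full + none)
        assert abs(frac - 0.7) < 3 * math.sqrt(0.7 * 0.3 / 20000)

    def test_unspliced_purged_by_6h(self, rng):
        p = KineticParams(
            synthesis_level=5000,
            k_early=0.01,
            k_late=0.01,
            k_unspliced=3.0,
            p_allnone=0,
            q_spliced=0,
            s_intron=(0.0, 0.0),
        )
        pop = simulate_population(p, GENE, 6.0, rng)
        unspliced = sum(
            n
            for state, n in pop.items()
            if state.kind == "rna" and not all(state.splice_state)
        )
        assert unspliced <= 2  # 5000 * exp(-18) is essentially zero

    def test_deterministic_under_seed(self):
        p = KineticParams(
            synthesis_level=500, p_allnone=0, q_spliced=0.5, s_intron=(0.4, 0.6)
        )
        pops = [
            simulate_population(p, GENE, 2.0, np.random.default_rng(5))
            for _ in range(2)
        ]
        assert pops[0] == pops[1]

    def test_excised_introns_tracked(self, rng):
        p = KineticParams(
            synthesis_level=2000, p_allnone=1, q_spliced=1, s_intron=(1.0, 1.0)
        )
        pop = simulate_population(p, GENE, 0.0, rng)
        intron_states = [s for s in pop if s.kind == "intron"]
        assert {s.intron_index for s in intron_states} == {0, 1}


class TestSampleFragments:
    def test_spliced_molecule_yields_split_blocks(self, rng):
        # short exons: with fragment length == molecule length, both mates
        # must cross a junction, producing split alignments at the introns
        gene = make_gene("s1", "chrS", "+", [(1000, 1100), (1500, 1600), (2100, 2200)])
        feats = make_features(gene)
        pop = Counter({MoleculeState("s1", "rna", "s1.t1", (True, True)): 50})
        frags, skipped = sample_fragments(
            pop, feats, 30, rng, read_len=150, frag_mean=300.0, frag_sd=0.0
        )
        assert skipped == 0
        for frag in frags:
            assert frag.blocks == ((1000, 1100), (1500, 1600), (2100, 2200))
            assert all(len(mate) == 2 for mate in frag.mate_blocks)

    def test_unspliced_molecule_contiguous(self, rng):
        pop = Counter({MoleculeState("g1", "rna", "g1.t1", (False, False)): 50})
        frags, _ = sample_fragments(
            pop, FEATURES, 30, rng, frag_mean=450.0, frag_sd=0.0
        )
        for frag in frags:
            # no splits at introns: every mate is one contiguous block
            assert all(len(mate) == 1 for mate in frag.mate_blocks)

    def test_fragment_length_mean_matches_truncnorm_oracle(self, rng):
        pop = Counter({MoleculeState("g1", "rna", "g1.t1", (False, False)): 1000})
        frags, _ = sample_fragments(
            pop, FEATURES, 10000, rng, frag_mean=450.0, frag_sd=25.0
        )
        mol_len = 1400
        a, b = (300 - 450) / 25, (mol_len - 450) / 25
        oracle_mean = truncnorm.mean(a, b, loc=450, scale=25)
        lengths = [f.aligned_length + (f.end - f.start) - f.aligned_length for f in frags]
        spans = [f.end - f.start for f in frags]
        assert np.mean(spans) == pytest.approx(oracle_mean, abs=5)
        assert abs(oracle_mean - 450) < 1  # sanity: truncation is negligible here

    def test_depth_conservation_with_short_molecules(self, rng):
        short_gene = make_gene("tiny", "chrS", "+", [(100, 280)])  # < 2*read_len
        feats = make_features(GENE, short_gene)
        pop = Counter(
            {
                MoleculeState("g1", "rna", "g1.t1", (True, True)): 20,
                MoleculeState("tiny", "rna", "tiny.t1", ()): 500,
            }
        )
        frags, skipped = sample_fragments(pop, feats, 2000, rng)
        assert len(frags) + skipped == 2000
        assert skipped > 0

    def test_mates_are_150nt(self, rng):
        pop = Counter({MoleculeState("g1", "rna", "g1.t1", (True, True)): 10})
        frags, _ = sample_fragments(pop, FEATURES, 50, rng)
        for frag in frags:
            for mate in frag.mate_blocks:
                assert sum(e - s for s, e in mate) == 150


def test_expected_si_equals_independent_splice_probability():
    cfg = SimConfig(seed=11, n_genes=4, p_allnone=0.0, s_intron=(0.2, 0.9))
    result = simulate_dataset(cfg)
    for gid, entry in result.truth.expectations.items():
        if "si" not in entry:
            continue
        s = result.truth.genes[gid].s_intron
        assert entry["si"]["0h"] == pytest.approx(list(s))


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    cfg = SimConfig(seed=3, n_genes=4, depth=2000, multi_isoform_fraction=0.3)
    result = simulate_dataset(cfg)
    outdir = tmp_path_factory.mktemp("sim")
    paths = write_simulation(outdir, result)
    return cfg, result, paths


class TestWriteSimulation:
    def test_annotation_parses_back(self, written):
        _cfg, result, paths = written
        fs = load_annotation(paths["annotation"])
        assert set(fs.genes) == set(result.features.genes)

    def test_alignments_round_trip(self, written):
        _cfg, result, paths = written
        for name, frags in result.samples.items():
            loaded, excluded = read_fragments(paths[name])
            assert excluded == 0
            assert len(loaded) == len(frags)
            orig = {f.name: f for f in frags}
            for frag in loaded:
                assert orig[frag.name].blocks == frag.blocks
                assert orig[frag.name].strand == frag.strand

    def test_record_counts_match_depth_minus_skips(self, written):
        _cfg, result, _paths = written
        for name, frags in result.samples.items():
            depth = result.sample_meta[name]["depth"]
            assert len(frags) + result.skipped[name] == depth

    def test_truth_json_round_trip(self, written):
        _cfg, result, paths = written
        reloaded = SimTruth.from_json(paths["truth"].read_text())
        assert reloaded == result.truth


def test_dataset_deterministic_under_seed():
    cfg = SimConfig(seed=9, n_genes=3, depth=1500)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    for name in a.samples:
        assert [f.blocks for f in a.samples[name]] == [f.blocks for f in b.samples[name]]
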