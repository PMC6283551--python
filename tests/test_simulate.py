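"""Simulator unit and property tests: library statistics, selection, kinetics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavemap import (
    AMINO_ACIDS,
    DisplayContext,
    Peptide,
    cleavage_probability,
    generate_library,
    motif_model,
    propagate_selection,
    sample_clones,
    simulate_biopanning,
    simulate_panel,
    simulate_timecourse,
    site_probabilities,
)
from cleavemap.peptides import AA_INDEX, total_multiplicity

from conftest import make_single_site_model


class TestGenerateLibrary:
    def test_degenerate_composition_yields_homopolymer(self, context):
        comp = np.zeros(20)
        comp[AA_INDEX["A"]] = 1.0
        lib = generate_library(1, context, comp, seed=0)
        assert lib == [Peptide("AAAAAAAAA", 1)]

    def test_uniform_library_has_uniform_positional_frequencies(self, context):
        lib = generate_library(10_000, context, "uniform", seed=1)
        counts = np.zeros((9, 20))
        for p in lib:
            for i, aa in enumerate(p.sequence):
                counts[i, AA_INDEX[aa]] += p.multiplicity
        freqs = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(freqs - 0.05).max() < 0.01

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            generate_library(0, seed=0)

    def test_bad_composition_names_offending_sum(self):
        comp = np.full(20, 0.06)  # sums to 1.2
        with pytest.raises(ValueError, match="1.2"):
            generate_library(10, composition=comp, seed=0)

    def test_reproducible_under_seed(self, context):
        assert generate_library(500, seed=7) == generate_library(500, seed=7)


def brute_force_cleavage(peptide, context, model):
    """Independent oracle: enumerate every per-site Bernoulli outcome."""
    p = site_probabilities(peptide, context, model)
    sites = np.nonzero(p > 0)[0]
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=len(sites)):
        prob = 1.0
        for o, s in zip(outcome, sites):
            prob *= p[s] if o else 1 - p[s]
        if any(outcome):
            total += prob
    return total


class TestCleavageProbability:
    def test_no_candidate_site_gives_zero(self, context):
        model = motif_model("F", saturation=0.5, background_release=0.0)
        assert cleavage_probability(Peptide("AAAAAAAAA"), context, model) == 0.0

    def test_single_site_equals_site_probability(self, context):
        model = make_single_site_model(0.5, "F")
        assert cleavage_probability(
            Peptide("AAAFAAAAA"), context, model
        ) == pytest.approx(0.5)

    def test_two_sites_combine_independently(self, context):
        model = make_single_site_model(0.5, "F")
        assert cleavage_probability(
            Peptide("AFAAAFAAA"), context, model
        ) == pytest.approx(0.75)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_enumeration_upto_4_sites(self, seed):
        context = DisplayContext()
        rng = np.random.default_rng(seed)
        model = motif_model("FYW", p2prime_acidic_mass=0.5, saturation=2.0)
        seq = "".join(rng.choice(list("ACDEGST"), 9))
        n_sites = int(rng.integers(0, 5))
        pos = rng.choice(9, size=n_sites, replace=False)
        chars = list(seq)
        for i in pos:
            chars[i] = str(rng.choice(list("FYW")))
        pep = Peptide("".join(chars))
        got = cleavage_probability(pep, context, model)
        assert got == pytest.approx(brute_force_cleavage(pep, context, model), abs=1e-12)
        assert 0.0 <= got <= 1.0


class TestBiopanning:
    def test_null_model_enrichment_is_one(self, context):
        # no admissible residue present in the library -> pure background release
        null = motif_model("F", background_release=0.05)
        lib = [Peptide("ADEGSTKLM", 5), Peptide("CCCDDDEEE", 3)]
        res = simulate_biopanning(lib, null, rounds=3, carryover=50, seed=0)
        assert res.per_round_enrichment == pytest.approx([1.0, 1.0, 1.0])

    def test_fixed_seed_reproducible(self, context, chymase_model):
        lib = generate_library(2000, seed=3)
        a = simulate_biopanning(lib, chymase_model, 3, 2000, seed=9, sample_size=50)
        b = simulate_biopanning(lib, chymase_model, 3, 2000, seed=9, sample_size=50)
        assert a == b
        c = simulate_biopanning(lib, chymase_model, 3, 2000, seed=10, sample_size=50)
        assert a != c

    def test_all_zero_weights_error_names_round(self, context):
        model = motif_model("F", background_release=0.0)
        lib = [Peptide("AAAAAAAAA", 10)]  # no F anywhere, no background
        with pytest.raises(ValueError, match="round 1"):
            simulate_biopanning(lib, model, rounds=2, carryover=10, seed=0)

    def test_finite_sampling_matches_infinite_recursion(self, context):
        """Mean motif prevalence over replicates agrees with the closed-form
        frequency recursion within 3 Monte Carlo standard errors."""
        model = make_single_site_model(0.4, "F")
        motif = Peptide("AAAFAAAAA", 20)  # 1% prevalence
        rest = [Peptide(s, 1) for s in _nonmotif_pool(1980)]
        lib = [motif] + rest
        seqs, freqs, _ = propagate_selection(lib, model, rounds=3)
        expected = freqs[-1][seqs.index("AAAFAAAAA")]
        prevs = []
        for seed in range(40):
            res = simulate_biopanning(lib, model, rounds=3, carryover=2000, seed=seed)
            final = res.per_round_libraries[-1]
            n = total_multiplicity(final)
            hit = sum(p.multiplicity for p in final if p.sequence == "AAAFAAAAA")
            prevs.append(hit / n)
        prevs = np.asarray(prevs)
        se = prevs.std(ddof=1) / np.sqrt(len(prevs))
        assert abs(prevs.mean() - expected) < 3 * se + 1e-12

    def test_motif_prevalence_nondecreasing_in_expectation(self, context):
        """A planted motif whose site beats background is enriched round on round."""
        model = make_single_site_model(0.4, "F")
        motif = Peptide("AAAFAAAAA", 20)
        lib = [motif] + [Peptide(s, 1) for s in _nonmotif_pool(1980)]
        seqs, freqs, _ = propagate_selection(lib, model, rounds=5)
        i = seqs.index("AAAFAAAAA")
        assert (np.diff(freqs[:, i]) > 0).all()


def _nonmotif_pool(n):
    """Deterministic filler sequences containing no F/Y/W."""
    rng = np.random.default_rng(123)
    alphabet = [a for a in AMINO_ACIDS if a not in "FYW"]
    seqs = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(alphabet, 9)))
    return sorted(seqs)


class TestSampleClones:
    def test_single_sequence_library(self):
        lib = [Peptide("AAAFAAAAA", 5)]
        assert sample_clones(lib, 96, seed=0) == [Peptide("AAAFAAAAA", 96)]

    def test_uniform_large_library_has_no_duplicates(self):
        # birthday problem: 96 draws from 1e6 clones -> expected collisions ~ 0.005
        lib = generate_library(10**6, seed=5)
        clones = sample_clones(lib, 96, seed=6)
        assert all(p.multiplicity == 1 for p in clones)
        assert total_multiplicity(clones) == 96

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            sample_clones([], 96, seed=0)

    def test_reproducible(self, chymase_model):
        lib = generate_library(5000, seed=1)
        res = simulate_biopanning(lib, chymase_model, 2, 5000, seed=2)
        assert sample_clones(res.per_round_libraries[-1], 96, 3) == sample_clones(
            res.per_round_libraries[-1], 96, 3
        )


class TestSimulateTimecourse:
    def test_zero_rate_gives_flat_zero(self):
        tc = simulate_timecourse(0.0, [0, 15, 45, 150], 0.0, seed=0)
        assert tc.values == pytest.approx([0, 0, 0, 0])

    def test_closed_form_values(self):
        tc = simulate_timecourse(0.02, [0, 15, 45, 150], 0.0, seed=0)
        assert tc.values == pytest.approx([0.0, 0.2592, 0.5934, 0.9502], abs=5e-5)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_timecourse(0.01, [0, 15], -0.1, seed=0)

    def test_noise_clipped_to_unit_interval(self):
        tc = simulate_timecourse(0.5, np.arange(0, 200, 5.0), 0.3, seed=4)
        assert (tc.values >= 0).all() and (tc.values <= 1).all()

    def test_absorbance_variant_scales_and_shifts(self):
        tc = simulate_timecourse(
            0.01, [0, 60, 120], 0.0, seed=0, kind="absorbance",
            baseline=0.1, amplitude=2.0,
        )
        f = 1 - np.exp(-0.01 * np.array([0, 60, 120]))
        assert tc.values == pytest.approx(0.1 + 2.0 * f)


def test_simulated_panel_rates_follow_p1_weights(elastase_model):
    times = np.arange(0, 361, 30.0)
    courses, p1_map = simulate_panel(elastase_model, times, 0.0, seed=0)
    by_res = {p1_map[tc.substrate_id]: tc for tc in courses}
    for res in "VAI":
        assert by_res[res].values[-1] > 0.5
    for res in "FYWLKRD":
        assert np.allclose(by_res[res].values, by_res[res].values[0])
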