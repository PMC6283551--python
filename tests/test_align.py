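"""Anchored-alignment tests: site enumeration, profiles, iterative placement.

The key correctness check compares the iterative placement against an
exhaustive enumeration of all joint offset assignments, using the same joint
log-likelihood functional, on small seeded instances.
"""

import itertools

import numpy as np
import pytest
from cleavemap import (
    AMINO_ACIDS,
    Peptide,
    align_unambiguous,
    build_profile,
    enumerate_sites,
    motif_model,
    place_peptide,
    resolve_and_iterate,
    score_offset,
    total_log_likelihood,
)
from cleavemap.peptides import AA_INDEX


class TestEnumerateSites:
    def test_unique_site(self):
        assert enumerate_sites(Peptide("AAAFAAAAA"), "F") == [3]

    def test_exhaustive_scan(self):
        assert enumerate_sites(Peptide("AFAAYAAAW"), "FYW") == [1, 4, 8]

    def test_no_sites(self):
        assert enumerate_sites(Peptide("AAAAAAAAA"), "FYW") == []

    def test_empty_p1_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_sites(Peptide("AAAFAAAAA"), "")


class TestPlacement:
    def test_interior_placement_reads_insert(self):
        ap = place_peptide(Peptide("AAAFCDEGH"), 3)
        by = {fr.subsite: fr for fr in ap.frame_residues}
        assert ap.p1_residue == "F"
        assert by["P1'"].residue == "C" and not by["P1'"].arm_derived
        assert by["P2'"].residue == "D"
        assert by["P4'"].residue == "G"

    def test_cterminal_placement_reads_his_arm(self):
        ap = place_peptide(Peptide("AAAAAAAAF"), 8)
        by = {fr.subsite: fr for fr in ap.frame_residues}
        assert by["P1'"].residue == "H" and by["P1'"].arm_derived
        assert by["P4'"].residue == "H" and by["P4'"].arm_derived

    def test_nterminal_placement_reads_pgg_arm_and_marks_missing(self):
        ap = place_peptide(Peptide("FAAAAAAAA"), 0)
        by = {fr.subsite: fr for fr in ap.frame_residues}
        assert by["P2"].residue == "G" and by["P2"].arm_derived
        assert by["P3"].residue == "G" and by["P3"].arm_derived
        assert by["P4"].residue == "P" and by["P4"].arm_derived
        assert by["P5"].residue is None

    def test_partitions_are_disjoint_and_exhaustive(self):
        peps = [Peptide("AAAFAAAAA"), Peptide("AFAFAAAAA"), Peptide("AAAAAAAAA")]
        aligned, amb, unal = align_unambiguous(peps, "F")
        assert [a.peptide.sequence for a in aligned] == ["AAAFAAAAA"]
        assert aligned[0].p1_offset == 3
        assert [p.sequence for p in amb] == ["AFAFAAAAA"]
        assert [p.sequence for p in unal] == ["AAAAAAAAA"]


class TestBuildProfile:
    def test_single_peptide_indicator_distributions(self):
        ap = place_peptide(Peptide("CDEFGHIKL"), 3)
        prof = build_profile([ap], pseudocount=0.0, arm_policy="include")
        for fr in ap.frame_residues:
            if fr.residue is not None:
                assert prof.prob(fr.subsite, fr.residue) == 1.0

    def test_multiplicity_equals_repetition(self):
        a = [
            place_peptide(Peptide("CDEFGHIKL"), 3),
            place_peptide(Peptide("CDEFGHIKL"), 3),
        ]
        b = [place_peptide(Peptide("CDEFGHIKL", 2), 3)]
        pa = build_profile(a, weighting="by_multiplicity")
        pb = build_profile(b, weighting="by_multiplicity")
        assert np.allclose(pa.probs, pb.probs)
        assert np.allclose(pa.effective_n, pb.effective_n)

    def test_pseudocount_lower_bound(self):
        aligned = [place_peptide(Peptide("CDEFGHIKL"), 3, ), place_peptide(Peptide("AAWFAADDA"), 3)]
        pc = 0.5
        prof = build_profile(aligned, pseudocount=pc)
        for j, n in enumerate(prof.effective_n):
            assert (prof.probs[j] >= pc / (n + 20 * pc) - 1e-12).all()

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])

    def test_mask_policy_excludes_arm_counts(self):
        ap = place_peptide(Peptide("AAAAAAAAF"), 8)  # primed side all His-arm
        prof = build_profile([ap], pseudocount=0.0, arm_policy="mask")
        j = prof.frame.labels.index("P1'")
        assert prof.effective_n[j] == 0


class TestScoreOffset:
    def test_profile_equal_to_background_scores_zero(self):
        pep = Peptide("AFAAAAFAA")
        aligned = [place_peptide(pep, 1)]
        prof = build_profile(aligned, pseudocount=1e9, arm_policy="include")
        bg = np.full(20, 1 / 20)
        for o in enumerate_sites(pep, "F"):
            assert score_offset(pep, o, prof, bg) == pytest.approx(0.0, abs=1e-6)

    def test_indicator_profile_closed_form(self):
        pep = Peptide("CDEFGHIKL")
        prof = build_profile(
            [place_peptide(pep, 3)], pseudocount=0.0, arm_policy="include"
        )
        bg = np.full(20, 1 / 20)
        assert score_offset(pep, 3, prof, bg) == pytest.approx(8 * np.log(20))

    def test_zero_probability_directs_to_pseudocount(self):
        prof = build_profile(
            [place_peptide(Peptide("CDEFGHIKL"), 3)], pseudocount=0.0,
            arm_policy="include",
        )
        with pytest.raises(ValueError, match="pseudocount"):
            score_offset(Peptide("WWWFWWWWW"), 3, prof, np.full(20, 1 / 20))

    def test_chosen_offset_is_argmax_by_exhaustive_scoring(self):
        rng = np.random.default_rng(5)
        anchors = [
            place_peptide(Peptide("".join(rng.choice(list("ACDEG"), 9))), 4)
            for _ in range(6)
        ]
        prof = build_profile(anchors)
        pep = Peptide("AFAAAAFAA")
        bg = np.full(20, 1 / 20)
        sites = enumerate_sites(pep, "F")
        scores = {o: score_offset(pep, o, prof, bg) for o in sites}
        best = max(sites, key=lambda o: (scores[o], -o))
        assert scores[best] == max(scores.values())


def random_instance(seed, n_pep=10, n_amb_max=7):
    """Small planted-motif instance with a mix of 1-3 candidate sites."""
    rng = np.random.default_rng(seed)
    filler = [a for a in AMINO_ACIDS if a not in "FYW"]
    peps = []
    for i in range(n_pep):
        seq = list(rng.choice(filler, 9))
        n_sites = 1 if i < n_pep - n_amb_max else int(rng.integers(1, 4))
        for pos in rng.choice(9, size=n_sites, replace=False):
            seq[pos] = str(rng.choice(list("FYW")))
        peps.append(Peptide("".join(seq), int(rng.integers(1, 3))))
    return peps


def exhaustive_optimum(unamb, amb, pseudocount=0.5):
    """Brute-force the best joint assignment over all ambiguous offsets."""
    site_lists = [enumerate_sites(p, "FYW") for p in amb]
    best = -np.inf
    for combo in itertools.product(*site_lists):
        aligned = list(unamb) + [
            place_peptide(p, o) for p, o in zip(amb, combo)
        ]
        best = max(best, total_log_likelihood(aligned, pseudocount))
    return best


class TestResolveAndIterate:
    def test_no_ambiguous_is_fixed_point(self):
        peps = [Peptide("AAAFAAAAA"), Peptide("CCCYCCCCC")]
        unamb, amb, _ = align_unambiguous(peps, "FY")
        res = resolve_and_iterate(unamb, amb, "FY")
        assert res.n_iterations == 1 and res.converged
        assert [a.p1_offset for a in res.aligned] == [3, 3]

    def test_requires_anchor_or_seed(self):
        with pytest.raises(ValueError, match="seed"):
            resolve_and_iterate([], [Peptide("AFAFAAAAA")], "F")

    def test_every_p1_in_candidate_set(self):
        peps = random_instance(11, n_pep=20, n_amb_max=12)
        unamb, amb, _ = align_unambiguous(peps, "FYW")
        res = resolve_and_iterate(unamb, amb, "FYW")
        assert all(a.p1_residue in "FYW" for a in res.aligned)

    def test_loglik_trace_nondecreasing(self):
        peps = random_instance(13, n_pep=25, n_amb_max=15)
        unamb, amb, _ = align_unambiguous(peps, "FYW")
        res = resolve_and_iterate(unamb, amb, "FYW")
        assert (np.diff(res.ll_trace) >= -1e-9).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_joint_optimum(self, seed):
        peps = random_instance(seed, n_pep=9, n_amb_max=6)
        unamb, amb, _ = align_unambiguous(peps, "FYW")
        if not unamb:
            pytest.skip("instance has no unambiguous anchor")
        res = resolve_and_iterate(unamb, amb, "FYW")
        ll = total_log_likelihood(res.aligned)
        assert ll >= exhaustive_optimum(unamb, amb) - 1e-9

    def test_tie_rule_validated_and_deterministic(self):
        peps = random_instance(5, n_pep=12, n_amb_max=8)
        unamb, amb, _ = align_unambiguous(peps, "FYW")
        with pytest.raises(ValueError, match="tie_rule"):
            resolve_and_iterate(unamb, amb, "FYW", tie_rule="bogus")
        res_c = resolve_and_iterate(unamb, amb, "FYW", tie_rule="cterminal")
        assert all(a.p1_residue in "FYW" for a in res_c.aligned)
        assert res_c.converged

    def test_input_order_invariance(self):
        peps = random_instance(21, n_pep=15, n_amb_max=9)
        unamb, amb, _ = align_unambiguous(peps, "FYW")
        res1 = resolve_and_iterate(unamb, amb, "FYW")
        rng = np.random.default_rng(0)
        perm_u = [unamb[i] for i in rng.permutation(len(unamb))]
        perm_a = [amb[i] for i in rng.permutation(len(amb))]
        res2 = resolve_and_iterate(perm_u, perm_a, "FYW")
        placed1 = {(a.peptide.sequence, a.peptide.multiplicity, a.p1_offset)
                   for a in res1.aligned}
        placed2 = {(a.peptide.sequence, a.peptide.multiplicity, a.p1_offset)
                   for a in res2.aligned}
        assert placed1 == placed2
        assert np.allclose(res1.profile.probs, res2.profile.probs)


class TestParameterRecovery:
    def test_planted_model_recovered_from_selected_clones(self):
        """Alignment of clones selected under a planted chymase-like model
        recovers an aromatic P1 and the planted P2' acidity (median of 5
        seeded replicates; the full 20-replicate check runs in acceptance)."""
        from cleavemap import generate_library, simulate_biopanning
        from cleavemap.profiles import p2prime_acidity

        model = motif_model("FYW", p2prime_acidic_mass=0.5)
        arom, acid = [], []
        for seed in range(5):
            lib = generate_library(30_000, seed=seed)
            res = simulate_biopanning(
                lib, model, rounds=5, carryover=30_000, seed=100 + seed,
                sample_size=96,
            )
            unamb, amb, _ = align_unambiguous(res.sampled_clones, "FYW")
            r = resolve_and_iterate(unamb, amb, "FYW")
            j = r.profile.frame.labels.index("P1")
            arom.append(
                sum(r.profile.probs[j, AA_INDEX[a]] for a in "FYW")
            )
            acid.append(p2prime_acidity(r.profile))
        assert np.median(arom) >= 0.9
        assert abs(np.median(acid) - 0.5) <= 0.15

    def test_masking_removes_arm_gly_excess(self):
        """Pooled upstream (P2-P4) Gly frequency under arm masking never
        exceeds the frequency with arms included, since the upstream arm ends
        in ...PGG."""
        peps = random_instance(31, n_pep=40, n_amb_max=20)
        unamb, amb, _ = align_unambiguous(peps, "FYW")
        res = resolve_and_iterate(unamb, amb, "FYW")
        for policy_pair in [("mask", "include")]:
            profs = {
                pol: build_profile(res.aligned, arm_policy=pol) for pol in policy_pair
            }
            g = AA_INDEX["G"]
            freqs = {}
            for pol, prof in profs.items():
                idx = [prof.frame.labels.index(s) for s in ("P2", "P3", "P4")]
                tot = prof.counts[idx].sum()
                freqs[pol] = prof.counts[idx, g].sum() / tot if tot else 0.0
            assert freqs["mask"] <= freqs["include"] + 1e-12
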