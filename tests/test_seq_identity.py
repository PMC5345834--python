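import itertools

import numpy as np
import pytest

from genospec.io_formats import AlignmentBlock, SequenceRecord
from genospec.seq_identity import (MLSA_CONCATENATION_ORDER, SaturationError,
                                   alignment_stats, concatenate_loci,
                                   genus_boundary_screen, k2p_distance,
                                   mlsa_species_screen, pairwise_identity)
from genospec.synthetic_data import (LOCUS_LENGTHS, simulate_marker_alignments)


def _block(seqs, locus="16S", ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return AlignmentBlock([SequenceRecord(i, s) for i, s in zip(ids, seqs)],
                          locus)


class TestPairwiseIdentity:
    def test_three_quarters_match(self):
        m = pairwise_identity(_block(["ACGT", "ACGA"]))
        assert m.loc("s0", "s1") == pytest.approx(75.0)

    def test_gap_policy_contrast(self):
        block = _block(["AC-T", "ACGT"])
        gaps_diff = pairwise_identity(block, "gaps-are-differences")
        excl = pairwise_identity(block, "exclude-pairwise")
        assert gaps_diff.loc("s0", "s1") == pytest.approx(75.0)
        assert excl.loc("s0", "s1") == pytest.approx(100.0)

    def test_matches_bruteforce_column_counter(self, rng):
        """Random 10x500 block equals an independent per-column counter."""
        chars = np.array(list("ACGT-N"))
        seqs = ["".join(rng.choice(chars, 500, p=[.22, .22, .22, .22, .06, .06]))
                for _ in range(10)]
        block = _block(seqs)
        m = pairwise_identity(block, "gaps-are-differences")
        for i, j in itertools.combinations(range(10), 2):
            matches = compared = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a == "N" or b == "N":
                    continue
                if a == "-" and b == "-":
                    continue
                compared += 1
                if a == b and a != "-":
                    matches += 1
            assert m.loc(f"s{i}", f"s{j}") == pytest.approx(
                100.0 * matches / compared)

    def test_symmetry_and_diagonal(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        m = pairwise_identity(_block(seqs))
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 100.0)


class TestK2P:
    def test_identical_sequences(self):
        est = k2p_distance("ACGTACGT", "ACGTACGT")
        assert est.P == est.Q == est.d == 0.0

    def test_closed_form_at_p01_q005(self):
        """A pair with exactly 10 transitions and 5 transversions in 100
        sites gives the closed-form K2P distance."""
        base = ("ACGT" * 25)
        mutated = list(base)
        ti = {"A": "G", "G": "A", "C": "T", "T": "C"}
        tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for k in range(10):
            mutated[k] = ti[base[k]]
        for k in range(10, 15):
            mutated[k] = tv[base[k]]
        est = k2p_distance(base, "".join(mutated))
        assert est.P == pytest.approx(0.10)
        assert est.Q == pytest.approx(0.05)
        assert est.d == pytest.approx(0.1701812, abs=1e-6)

    def test_counts_match_per_site_classification(self, rng):
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(c if rng.random() > 0.2 else
                    rng.choice([x for x in "ACGT" if x != c]) for c in a)
        est = k2p_distance(a, b)
        ti_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        ti = sum((x, y) in ti_pairs for x, y in zip(a, b))
        tv = sum(x != y and (x, y) not in ti_pairs for x, y in zip(a, b))
        assert est.P == pytest.approx(ti / 300)
        assert est.Q == pytest.approx(tv / 300)

    def test_gap_and_n_sites_excluded(self):
        est = k2p_distance("AC-TN", "ACGTA")
        assert est.n_sites == 3
        assert est.d == 0.0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("AAAA" * 25, "GGGG" * 25)

    def test_k2p_dominates_p_distance(self, rng):
        """K2P corrects for multiple hits, so d >= p-distance whenever any
        difference is observed."""
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 500))
            b = [c if rng.random() > 0.2 else
                 rng.choice([x for x in "ACGT" if x != c]) for c in a]
            est = k2p_distance(a, "".join(b))
            p_dist = est.P + est.Q
            if p_dist > 0:
                assert est.d >= p_dist


class TestAlignmentStats:
    def test_identical_pair(self):
        st = alignment_stats(_block(["ACGT", "ACGT"]))
        assert st.pct_polymorphic == 0.0
        assert st.mean_d == 0.0
        assert st.length == 4

    def test_one_polymorphic_column(self):
        st = alignment_stats(_block(["ACGT", "ACGA"]))
        assert st.pct_polymorphic == pytest.approx(25.0)

    def test_gc_content(self):
        st = alignment_stats(_block(["GGCC", "GGCC"]))
        assert st.mean_gc == pytest.approx(100.0)
        st2 = alignment_stats(_block(["GGAT", "GGAT"]))
        assert st2.mean_gc == pytest.approx(50.0)

    def test_min_le_mean_le_max(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(5)]
        st = alignment_stats(_block(seqs))
        assert st.min_d <= st.mean_d <= st.max_d

    def test_simulated_16s_matches_generator_expectation(self, small_complex):
        """Mean K2P distance of a simulated 16S block sits near the
        generator's planned divergence (16S multiplier x genomic bands)."""
        _, truth, _ = small_complex
        block = simulate_marker_alignments(truth, [("16S", 1360)], seed=5)[0]
        st = alignment_stats(block)
        mult = 0.15
        plan = list(truth.divergence_plan.values())
        # between-species pairs additionally carry the within-species edges
        expected = mult * np.mean([
            b + (truth.bands["within_species"]
                 if b == truth.bands["between_species"] else 0)
            for b in plan])
        assert st.mean_d == pytest.approx(expected, rel=0.35)


class TestConcatenation:
    def test_two_loci_order_respected(self):
        clpA = _block(["AAA", "CCC"], locus="clpA", ids=["x", "y"])
        atpD = _block(["GGGG", "TTTT"], locus="atpD", ids=["y", "x"])
        mlsa = concatenate_loci([atpD, clpA])
        assert mlsa.length == 7
        rec = {r.id: r.seq for r in mlsa.records}
        assert rec["x"] == "AAATTTT"   # clpA first, then atpD

    def test_input_order_irrelevant(self, small_complex):
        _, truth, _ = small_complex
        blocks = simulate_marker_alignments(
            truth, [(l, 60) for l in MLSA_CONCATENATION_ORDER], seed=2)
        fwd = concatenate_loci(blocks)
        rev = concatenate_loci(blocks[::-1])
        assert [(r.id, r.seq) for r in fwd.records] == \
            [(r.id, r.seq) for r in rev.records]

    def test_default_lengths_sum_to_mlsa_total(self, small_complex):
        """The eight housekeeping loci at their default lengths concatenate
        to the 12,283 bp MLSA alignment."""
        _, truth, _ = small_complex
        blocks = simulate_marker_alignments(
            truth, [(l, LOCUS_LENGTHS[l]) for l in MLSA_CONCATENATION_ORDER],
            seed=2)
        assert concatenate_loci(blocks).length == 12_283

    def test_missing_strain_named(self):
        clpA = _block(["AAA", "CCC"], locus="clpA", ids=["x", "y"])
        atpD = _block(["GGGG", "TTTT"], locus="atpD", ids=["x", "z"])
        with pytest.raises(ValueError, match="atpD"):
            concatenate_loci([clpA, atpD])

    def test_concatenated_identity_is_length_weighted(self, rng):
        """MLSA identity equals the column-count identity over all loci
        (brute-force oracle)."""
        ids = ["a", "b", "c"]
        blocks = []
        for locus, n in (("clpA", 30), ("atpD", 50)):
            seqs = ["".join(rng.choice(list("ACGT"), n)) for _ in ids]
            blocks.append(_block(seqs, locus=locus, ids=ids))
        mlsa = concatenate_loci(blocks)
        m = pairwise_identity(mlsa)
        seqs = {r.id: r.seq for r in mlsa.records}
        for i, j in itertools.combinations(ids, 2):
            matches = sum(a == b for a, b in zip(seqs[i], seqs[j]))
            assert m.loc(i, j) == pytest.approx(100.0 * matches / 80)


class TestScreens:
    @pytest.mark.parametrize("identity,verdict", [
        (99.0, "same-species"),
        (97.5, "different-species"),
        (98.0, "grey-zone"),
        (98.13, "grey-zone"),
        (97.77, "grey-zone"),
    ])
    def test_mlsa_screen(self, identity, verdict):
        assert mlsa_species_screen(identity).verdict == verdict

    def test_mlsa_screen_range_checked(self):
        with pytest.raises(ValueError):
            mlsa_species_screen(104.0)

    def _matrix(self, inter):
        from genospec.io_formats import LabeledMatrix
        v = np.full((4, 4), 99.0)
        v[:2, 2:] = inter
        v[2:, :2] = inter
        np.fill_diagonal(v, 100.0)
        return LabeledMatrix(["a", "b", "c", "d"], v, "16S-identity")

    def test_low_identities_support_separate_genera(self):
        rep = genus_boundary_screen(self._matrix(90.0), {"a", "b"}, {"c", "d"})
        assert rep["verdict"] == "separate-genera-supported"
        assert rep["mean"] == pytest.approx(90.0)

    def test_identical_groups_same_genus(self):
        rep = genus_boundary_screen(self._matrix(99.0), {"a", "b"}, {"c", "d"})
        assert rep["verdict"] == "same-genus-supported"

    def test_boundary_band_detected(self):
        rep = genus_boundary_screen(self._matrix(94.8), {"a", "b"}, {"c", "d"})
        assert rep["verdict"] == "within-band"

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            genus_boundary_screen(self._matrix(90.0), {"a", "b"}, {"b", "c"})
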