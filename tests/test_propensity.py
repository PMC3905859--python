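import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from autogeny import scales
from autogeny._pairing import nussinov_pair_count, paired_indicator
from autogeny.defaults import default_model
from autogeny.propensity import (
    InteractionModel,
    compress_profile,
    interaction_propensity,
    load_score_table,
    moving_average,
    protein_profiles,
    rna_profiles,
)

from conftest import make_protein, make_rna, random_protein_seq, random_rna_seq

# ---------------------------------------------------------------- profiles


class TestProteinProfiles:
    def test_homopolymer_tracks_constant(self):
        prof = protein_profiles("A" * 20)
        for name, scale in (
            ("helix", scales.HELIX),
            ("sheet", scales.SHEET),
            ("hbond", scales.HBOND),
            ("polar", scales.POLAR),
        ):
            assert np.allclose(prof.tracks[name], scale["A"])

    def test_reversal_symmetry(self):
        seq = "MKVLLAGDESRTW" * 4
        fwd = protein_profiles(seq)
        rev = protein_profiles(seq[::-1])
        for name in fwd.tracks:
            assert np.allclose(rev.tracks[name], fwd.tracks[name][::-1])

    def test_window_one_is_raw_lookup(self):
        seq = "MKVLLA"
        prof = protein_profiles(seq, window=1)
        assert np.allclose(
            prof.tracks["hbond"], [scales.HBOND[a] for a in seq]
        )

    def test_x_contributes_scale_mean(self):
        prof = protein_profiles("XXXX", window=1)
        assert np.allclose(prof.tracks["helix"], scales.scale_mean(scales.HELIX))

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            protein_profiles("MKB")


def brute_force_nussinov(seq, min_loop=3):
    """Exponential enumeration of non-crossing pairings (oracle, n <= ~16)."""
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

    def best(i, j):
        if j - i <= min_loop:
            return 0
        out = best(i, j - 1)
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in pairs:
                left = best(i, k - 1) if k > i else 0
                out = max(out, 1 + left + best(k + 1, j - 1))
        return out

    return best(0, len(seq) - 1)


class TestRnaProfiles:
    def test_poly_a_has_no_pairing(self):
        prof = rna_profiles("A" * 80)
        assert np.allclose(prof.tracks["pairing"], 0.0)

    def test_poly_n_has_no_pairing(self):
        prof = rna_profiles("N" * 60)
        assert np.allclose(prof.tracks["pairing"], 0.0)

    def test_hairpin_arms_paired_loop_not(self):
        arm = "GGGGGGGG"
        seq = arm + "AAAA" + "CCCCCCCC"
        ind = paired_indicator(seq)
        assert ind[:8].mean() == 1.0
        assert ind[8:12].mean() == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_max_pairing_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_rna_seq(rng, 14)
        assert nussinov_pair_count(seq) == brute_force_nussinov(seq)

    def test_gc_track_all_gc(self):
        prof = rna_profiles("GGCC", gc_window=4)
        assert np.allclose(prof.tracks["gc"], 1.0)

    def test_pairing_track_in_unit_interval(self):
        rng = np.random.default_rng(3)
        prof = rna_profiles(random_rna_seq(rng, 300))
        track = prof.tracks["pairing"]
        assert np.all((track >= 0) & (track <= 1))

    def test_illegal_nucleotide(self):
        with pytest.raises(ValueError):
            rna_profiles("ACGT")  # T is normalized upstream, not here


# --------------------------------------------------------------- compress


def naive_dct(track, n_coeff):
    n = len(track)
    out = np.zeros(min(n_coeff, n))
    for k in range(len(out)):
        out[k] = sum(
            track[i] * np.cos(np.pi * k * (2 * i + 1) / (2 * n)) for i in range(n)
        ) / n
    if n_coeff > n:
        out = np.concatenate([out, np.zeros(n_coeff - n)])
    return out


class TestCompressProfile:
    def test_constant_track_dc_only(self):
        c = compress_profile(np.full(37, 2.5), 8)
        assert c[0] == pytest.approx(2.5)
        assert np.allclose(c[1:], 0.0, atol=1e-12)

    def test_linearity_under_negation(self):
        rng = np.random.default_rng(0)
        track = rng.normal(size=40)
        assert np.allclose(
            compress_profile(-track, 10), -compress_profile(track, 10)
        )

    @given(st.integers(0, 1000))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        track = rng.normal(size=n)
        assert np.allclose(
            compress_profile(track, 12), naive_dct(track, 12), atol=1e-9
        )

    def test_zero_padding_when_short(self):
        c = compress_profile(np.ones(4), 9)
        assert len(c) == 9
        assert np.allclose(c[4:], 0.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            compress_profile(np.ones(5), 0)
        with pytest.raises(ValueError):
            compress_profile(np.array([]), 3)


# ------------------------------------------------------------ propensity


def unit_model(slope=1.0, intercept=0.0, track_pair=("hbond", "pairing"), k=0):
    w = np.zeros((4, 2, 50))
    i = ("helix", "sheet", "hbond", "polar").index(track_pair[0])
    j = ("pairing", "gc").index(track_pair[1])
    w[i, j, k] = 1.0
    return InteractionModel(n_coeff=50, weights=w, slope=slope, intercept=intercept)


class TestInteractionPropensity:
    def test_bitwise_deterministic(self, scorer):
        rng = np.random.default_rng(5)
        p = make_protein("p", "G", random_protein_seq(rng, 90))
        r = make_rna("r", "G", random_rna_seq(rng, 150))
        a = interaction_propensity(p, r, scorer.model).pi
        b = interaction_propensity(p, r, scorer.model).pi
        assert a == b

    def test_zero_weights_give_intercept(self):
        model = InteractionModel(
            n_coeff=50, weights=np.zeros((4, 2, 50)), slope=2.0, intercept=7.5
        )
        rng = np.random.default_rng(6)
        p = make_protein("p", "G", random_protein_seq(rng, 60))
        r = make_rna("r", "G", random_rna_seq(rng, 80))
        assert interaction_propensity(p, r, model).pi == pytest.approx(7.5)

    def test_single_dc_weight_equals_product_of_means(self):
        """With one unit weight on (hbond x pairing, k=0) the score is the
        product of the two track means, hand-computable from the profiles."""
        model = unit_model(slope=3.0, intercept=1.0)
        rng = np.random.default_rng(7)
        p = make_protein("p", "G", random_protein_seq(rng, 55))
        r = make_rna("r", "G", random_rna_seq(rng, 70))
        expected = (
            3.0
            * protein_profiles(p.sequence, 7).tracks["hbond"].mean()
            * rna_profiles(r.sequence).tracks["pairing"].mean()
            + 1.0
        )
        assert interaction_propensity(p, r, model).pi == pytest.approx(expected)

    def test_kind_check(self, scorer):
        rng = np.random.default_rng(8)
        p = make_protein("p", "G", random_protein_seq(rng, 60))
        r = make_rna("r", "G", random_rna_seq(rng, 60))
        with pytest.raises(ValueError):
            interaction_propensity(r, p, scorer.model)

    def test_score_matrix_matches_scalar_path(self, scorer):
        rng = np.random.default_rng(9)
        prots = [make_protein(f"p{i}", "G", random_protein_seq(rng, 60)) for i in range(3)]
        rnas = [make_rna(f"r{i}", "G", random_rna_seq(rng, 90)) for i in range(2)]
        mat = scorer.score_matrix(prots, rnas)
        for i, p in enumerate(prots):
            for j, r in enumerate(rnas):
                assert mat[i, j] == pytest.approx(scorer(p, r), abs=1e-9)

    def test_calibration_slope_must_be_positive(self):
        with pytest.raises(ValueError):
            InteractionModel(
                n_coeff=5, weights=np.zeros((4, 2, 5)), slope=0.0, intercept=0.0
            )


class TestScoreTable:
    def test_lookup_round_trip(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "protein_id\trna_id\tpropensity\nP1\tR1\t72.0\nP1\tR2\t10.0\nP2\tR1\t5.0\n"
        )
        table = load_score_table(path)
        assert table.query("P1", "R1") == 72.0
        assert len(table) == 3

    def test_absent_pair_raises(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("protein_id\trna_id\tpropensity\nP1\tR1\t72.0\n")
        with pytest.raises(KeyError, match="P9"):
            load_score_table(path).query("P9", "R1")

    def test_conflicting_duplicates_rejected(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "protein_id\trna_id\tpropensity\nP1\tR1\t72.0\nP1\tR1\t3.0\n"
        )
        with pytest.raises(ValueError, match="conflicting"):
            load_score_table(path)


class TestMovingAverage:
    @given(st.integers(0, 500))
    def test_preserves_mean_of_constant_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(2, 50)))
        w = int(rng.integers(1, 9))
        sm = moving_average(x, w)
        assert len(sm) == len(x)
        assert sm.min() >= x.min() - 1e-12 and sm.max() <= x.max() + 1e-12

    def test_default_model_shapes(self):
        m = default_model()
        assert m.weights.shape == (4, 2, m.n_coeff)
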