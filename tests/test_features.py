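"""Feature-extraction unit and property tests.

The moment operations are checked against the independent brute-force
oracles in ``oracles.py``; the incidence/position/frequency vectors against
hand-derived values and their defining symmetries.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutscan import (
    FEATURE_LENGTH,
    HahnParams,
    MomentFeaturizer,
    central_moments,
    compute_aapiv,
    compute_prim,
    compute_raapiv,
    compute_rprim,
    encode_sequence,
    extract_features,
    feature_layout,
    frequency_vector,
    hahn_moments,
    hahn_polynomial,
    raw_moments,
)
from mutscan.errors import ParameterError, SequenceValidationError
from mutscan.features import MOMENT_ORDERS

from oracles import (
    MOMENT_ORDERS as ORACLE_ORDERS,
    auc_pairwise,
    central_moment,
    hahn_moment,
    hahn_poly,
    raw_moment,
)


def random_sequences(rng, n, min_len=5, max_len=80, with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(list(alphabet), size=length)))
    return out


class TestEncoding:
    @pytest.mark.parametrize(
        "seq,side,grid",
        [
            ("ACGT", 2, [[1, 2], [3, 4]]),
            ("ACGTA", 3, [[1, 2, 3], [4, 1, 0], [0, 0, 0]]),
            ("N", 1, [[0]]),
        ],
    )
    def test_examples(self, seq, side, grid):
        m = encode_sequence(seq)
        assert m.side == side
        assert m.original_length == len(seq)
        np.testing.assert_array_equal(m.values, grid)

    def test_padding_count(self, rng):
        for seq in random_sequences(rng, 20):
            m = encode_sequence(seq)
            flat = m.values.ravel()
            assert m.side == int(np.ceil(np.sqrt(len(seq))))
            # trailing entries beyond L are exactly the zero pads
            assert (flat[len(seq):] == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(SequenceValidationError):
            encode_sequence("")


class TestMomentsAgainstOracle:
    def test_order_layout_matches_oracle(self):
        assert list(MOMENT_ORDERS) == ORACLE_ORDERS

    def test_raw_examples(self):
        grid = [[1, 2], [3, 4]]
        out = raw_moments(grid)
        assert out[MOMENT_ORDERS.index((0, 0))] == 10
        assert out[MOMENT_ORDERS.index((1, 0))] == 17  # 1*(1+2) + 2*(3+4)

    def test_central_basics(self, rng):
        grid = rng.integers(0, 5, (4, 4))
        out = central_moments(grid)
        # first-order central moments vanish by centroid definition
        assert out[MOMENT_ORDERS.index((1, 0))] == pytest.approx(0, abs=1e-9)
        assert out[MOMENT_ORDERS.index((0, 1))] == pytest.approx(0, abs=1e-9)
        assert central_moments([[1, 2], [3, 4]])[0] == pytest.approx(10)

    def test_constant_grid_symmetry(self):
        grid = np.full((5, 5), 3.0)
        out = central_moments(grid)
        for k, (a, b) in enumerate(MOMENT_ORDERS):
            if (a + b >= 1) and (a % 2 == 1 or b % 2 == 1 or a + b == 2):
                # odd orders vanish by symmetry about the center; C11 too
                if a % 2 == 1 or b % 2 == 1:
                    assert out[k] == pytest.approx(0, abs=1e-9)

    def test_zero_grid(self):
        with pytest.warns(UserWarning):
            out = central_moments(np.zeros((3, 3)))
        np.testing.assert_allclose(out, 0)
        np.testing.assert_allclose(raw_moments(np.zeros((3, 3))), 0)
        np.testing.assert_allclose(hahn_moments(np.zeros((3, 3))), 0)

    @pytest.mark.parametrize("side", [2, 3, 4, 5, 6])
    def test_random_grids_match_bruteforce(self, side, rng):
        """Raw, central and Hahn moments agree with the loop oracle."""
        for _ in range(8):
            grid = rng.integers(0, 5, (side, side)).astype(float)
            raw = raw_moments(grid)
            cen = central_moments(grid)
            hah = hahn_moments(grid)
            for k, (p, q) in enumerate(MOMENT_ORDERS):
                assert raw[k] == pytest.approx(
                    raw_moment(grid.tolist(), p, q), rel=1e-9, abs=1e-9
                )
                assert cen[k] == pytest.approx(
                    central_moment(grid.tolist(), p, q), rel=1e-9, abs=1e-9
                )
                assert hah[k] == pytest.approx(
                    hahn_moment(grid.tolist(), p, q), rel=1e-9, abs=1e-9
                )

    def test_hahn_nonzero_params_match_oracle(self, rng):
        grid = rng.integers(0, 5, (4, 4)).astype(float)
        params = HahnParams(a=2, b=1)
        out = hahn_moments(grid, params)
        for k, (p, q) in enumerate(MOMENT_ORDERS):
            assert out[k] == pytest.approx(
                hahn_moment(grid.tolist(), p, q, a=2, b=1), rel=1e-9, abs=1e-9
            )

    def test_hahn_linearity(self, rng):
        grid = rng.integers(0, 5, (4, 4)).astype(float)
        np.testing.assert_allclose(
            hahn_moments(2 * grid), 2 * hahn_moments(grid), rtol=1e-12
        )

    def test_hahn_tiny_grid_padded(self):
        with pytest.warns(UserWarning, match="padding"):
            out = hahn_moments([[5.0]])
        assert np.isfinite(out).all()


class TestHahnPolynomial:
    def test_order_zero_constant_in_x(self):
        values = {hahn_polynomial(0, x, 5) for x in range(5)}
        assert len(values) == 1

    @pytest.mark.parametrize("params", [HahnParams(0, 0), HahnParams(1, 3)])
    def test_matches_term_by_term_oracle(self, params):
        for m in range(4):
            for x in range(6):
                got = hahn_polynomial(m, x, 6, params)
                want = hahn_poly(m, x, 6, params.a, params.b)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)
                assert np.isfinite(got)

    def test_range_checks(self):
        with pytest.raises(ParameterError):
            hahn_polynomial(4, 0, 4)
        with pytest.raises(ParameterError):
            hahn_polynomial(0, 4, 4)
        with pytest.raises(ParameterError):
            HahnParams(-1, 0)


class TestIncidenceAndPositionVectors:
    def test_prim_hand_examples(self):
        p = compute_prim("AA").values
        assert p[0, 0] == 1  # (A->A) = 2 - 1
        assert p.sum() == 1
        p = compute_prim("ACGT").values
        assert p[0, 3] == 3  # A->T
        assert p[1, 2] == 1  # C->G
        assert p[3, 0] == 0  # T->A: nothing after T
        # absent nucleotide -> zero row
        assert (compute_prim("ACAC").values[2] == 0).all()
        assert (compute_prim("ACAC").values[3] == 0).all()

    def test_reversal_duality(self, rng):
        for seq in random_sequences(rng, 50, with_n=True):
            np.testing.assert_array_equal(
                compute_rprim(seq).values, compute_prim(seq[::-1]).values
            )
            np.testing.assert_array_equal(
                compute_raapiv(seq).values, compute_aapiv(seq[::-1]).values
            )

    def test_palindrome_symmetry(self):
        np.testing.assert_array_equal(
            compute_rprim("ACCA").values, compute_prim("ACCA").values
        )
        np.testing.assert_array_equal(
            compute_raapiv("ACCA").values, compute_aapiv("ACCA").values
        )

    @pytest.mark.parametrize(
        "seq,expect",
        [("ACGT", (1, 2, 3, 4)), ("AACG", (3, 3, 4, 0)), ("G", (0, 0, 1, 0))],
    )
    def test_aapiv_examples(self, seq, expect):
        np.testing.assert_array_equal(compute_aapiv(seq).values, expect)

    def test_raapiv_example(self):
        np.testing.assert_array_equal(compute_raapiv("ACGT").values, (4, 3, 2, 1))

    def test_conservation(self, rng):
        for seq in random_sequences(rng, 50):
            L = len(seq)
            assert compute_aapiv(seq).values.sum() == L * (L + 1) // 2
            assert compute_raapiv(seq).values.sum() == L * (L + 1) // 2
            assert frequency_vector(seq).values.sum() == L

    def test_frequency_with_n(self):
        np.testing.assert_array_equal(frequency_vector("AACGT").values, (2, 1, 1, 1))
        np.testing.assert_array_equal(frequency_vector("NNNN").values, (0, 0, 0, 0))
        assert frequency_vector("ANCGN").values.sum() == 3


class TestFeatureVector:
    def test_layout_and_length(self):
        names = feature_layout()
        assert len(names) == FEATURE_LENGTH == 102
        assert names[:4] == ["FV_A", "FV_C", "FV_G", "FV_T"]
        assert names[12] == "SEQ_raw_00"
        assert names[42] == "PRIM_raw_00"
        assert names[-1] == "RPRIM_hahn_30"

    def test_fixed_length_across_sequences(self, rng):
        for seq in random_sequences(rng, 10, min_len=3, max_len=200, with_n=True):
            v = extract_features(seq)
            assert v.shape == (FEATURE_LENGTH,)
            assert np.isfinite(v).all()

    def test_determinism_and_fv_block(self):
        v1 = extract_features("ACGT")
        v2 = extract_features("ACGT")
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(v1[:4], (1, 1, 1, 1))

    def test_featurizer_transform(self, rng):
        seqs = random_sequences(rng, 5)
        M = MomentFeaturizer().fit_transform(seqs)
        assert M.shape == (5, FEATURE_LENGTH)
        np.testing.assert_array_equal(M[0], extract_features(seqs[0]))
        assert list(MomentFeaturizer().fit(seqs).get_feature_names_out()) == feature_layout()

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=120))
    def test_reversal_duality_property(self, seq):
        np.testing.assert_array_equal(
            compute_rprim(seq).values, compute_prim(seq[::-1]).values
        )
        np.testing.assert_array_equal(
            compute_raapiv(seq).values, compute_aapiv(seq[::-1]).values
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=120))
    def test_conservation_property(self, seq):
        L = len(seq)
        assert frequency_vector(seq).values.sum() == L
        assert compute_aapiv(seq).values.sum() == L * (L + 1) // 2
        assert compute_raapiv(seq).values.sum() == L * (L + 1) // 2

    def test_translation_sensitivity(self):
        """Central moments see shape, raw moments see position.

        Shifting the mass block inside a larger zero grid changes raw
        moments but leaves central moments (about the re-centered centroid)
        unchanged.
        """
        base = np.zeros((6, 6))
        base[1:3, 1:3] = [[1, 2], [3, 4]]
        shifted = np.zeros((6, 6))
        shifted[3:5, 3:5] = [[1, 2], [3, 4]]
        np.testing.assert_allclose(
            central_moments(base), central_moments(shifted), atol=1e-9
        )
        assert not np.allclose(raw_moments(base), raw_moments(shifted))
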