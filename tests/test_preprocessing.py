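"""Pre-treatment identities: MC, SNV, MSC, Savitzky-Golay second derivative."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pelletchem.preprocessing import (
    build_chain,
    chain_from_state,
    chain_state,
    mean_center,
    msc,
    second_derivative,
    snv,
)


class TestMeanCenter:
    def test_hand_arithmetic(self):
        out = mean_center(np.array([[1.0, 3.0], [3.0, 5.0]]))
        np.testing.assert_allclose(out, [[-1.0, -1.0], [1.0, 1.0]])

    def test_column_means_zero(self, rng):
        out = mean_center(rng.normal(size=(12, 6)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent_on_centered(self, rng):
        once = mean_center(rng.normal(size=(8, 5)))
        np.testing.assert_allclose(mean_center(once), once, atol=1e-12)

    def test_stored_means_reused(self, rng):
        table = rng.normal(size=(8, 5))
        means = table.mean(axis=0)
        np.testing.assert_allclose(
            mean_center(table[:3], fitted_means=means), table[:3] - means
        )

    def test_single_sample_warns(self):
        with pytest.warns(UserWarning):
            out = mean_center(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, 0.0)


class TestSNV:
    def test_three_point_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_normalization(self, rng):
        out = np.asarray(snv(rng.uniform(size=(10, 30))))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(0.1, 10),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=20)
        np.testing.assert_allclose(snv(a + b * x), snv(x), atol=1e-9)

    def test_constant_spectrum_errors(self):
        with pytest.raises(ValueError, match="sd = 0"):
            snv(np.full(10, 3.0))


class TestMSC:
    def test_exact_inversion(self, rng):
        ref = rng.uniform(0.1, 0.9, size=40)
        table = np.vstack([ref, 2.0 * ref + 0.5])
        out = np.asarray(msc(table, reference=ref))
        np.testing.assert_allclose(out[1], ref, atol=1e-12)

    def test_reference_unchanged(self, rng):
        ref = rng.uniform(0.1, 0.9, size=40)
        out = np.asarray(msc(ref[np.newaxis, :], reference=ref))
        np.testing.assert_allclose(out[0], ref, atol=1e-12)

    def test_corrected_regression_is_identity(self, rng):
        # refit oracle: after correction, regressing on the reference
        # must give intercept 0 and slope 1 for every spectrum
        table = rng.uniform(0.1, 0.9, size=(8, 50))
        ref = table.mean(axis=0)
        out = np.asarray(msc(table))
        A = np.column_stack([np.ones_like(ref), ref])
        for row in out:
            (a, b), *_ = np.linalg.lstsq(A, row, rcond=None)
            assert abs(a) < 1e-10 and abs(b - 1) < 1e-10

    def test_flat_spectrum_errors(self, rng):
        ref = rng.uniform(size=30)
        with pytest.raises(ValueError, match="slope"):
            msc(np.full((1, 30), 0.4), reference=ref)


class TestSecondDerivative:
    def test_linear_and_constant_to_zero(self):
        i = np.arange(30, dtype=float)
        np.testing.assert_allclose(second_derivative(3 * i + 2), 0.0, atol=1e-10)
        np.testing.assert_allclose(second_derivative(np.full(30, 7.0)), 0.0, atol=1e-10)

    def test_quadratic_gives_two(self):
        # analytic oracle: d2/di2 of i^2 is exactly 2 everywhere a degree-2
        # Savitzky-Golay fit is exact
        i = np.arange(40, dtype=float)
        np.testing.assert_allclose(second_derivative(i**2), 2.0, atol=1e-8)

    def test_too_few_bands_errors(self):
        with pytest.raises(ValueError):
            second_derivative(np.arange(5, dtype=float), window=11)

    def test_bad_window_errors(self):
        with pytest.raises(ValueError):
            second_derivative(np.arange(30, dtype=float), window=4)


class TestChains:
    def test_rowwise_consistency(self, rng):
        table = rng.uniform(0.1, 0.9, size=(12, 40))
        chain = build_chain("snv+mc")
        chain.fit(table)
        full = np.asarray(chain.transform(table))
        row = np.asarray(chain.transform(table[3:4]))
        np.testing.assert_allclose(row[0], full[3], atol=1e-12)

    def test_band_reorder_commutes_with_snv_msc(self, rng):
        table = rng.uniform(0.1, 0.9, size=(6, 30))
        perm = rng.permutation(30)
        for name in ("snv", "msc"):
            chain = build_chain(name).fit(table)
            direct = np.asarray(chain.transform(table))[:, perm]
            chain_p = build_chain(name).fit(table[:, perm])
            reordered = np.asarray(chain_p.transform(table[:, perm]))
            np.testing.assert_allclose(reordered, direct, atol=1e-10)

    def test_state_round_trip(self, rng):
        table = rng.uniform(0.1, 0.9, size=(10, 40))
        chain = build_chain(["msc", "mc", "d2"], d2__window=9)
        chain.fit(table)
        rebuilt = chain_from_state(chain_state(chain))
        np.testing.assert_allclose(
            np.asarray(rebuilt.transform(table)),
            np.asarray(chain.transform(table)),
            atol=1e-12,
        )

    def test_order_is_configured_order(self, rng):
        from pelletchem.preprocessing import chain_steps

        chain = build_chain("msc+snv")
        assert chain_steps(chain) == ["msc", "snv"]
        assert chain_steps(build_chain("none")) == []
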