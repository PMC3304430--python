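"""Preprocessing: normexp correction, quantile normalisation, median polish."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from xenodissect import synthdata as sd
from xenodissect.iotables import MOUSE, ProbeIntensityMatrix, ProbesetMap
from xenodissect.preprocess import (
    NormexpParams,
    background_correct,
    estimate_normexp,
    median_polish,
    normexp_conditional_expectation,
    quantile_normalize,
    rma_pipeline,
    summarize_medianpolish,
)


def _matrix(values, species="human"):
    arr = np.asarray(values, dtype=float)
    return ProbeIntensityMatrix(
        species,
        pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
    )


def quadrature_conditional_expectation(x, mu, sigma, alpha):
    """Independent oracle: E[S|X=x] by numerical integration of the
    exponential-signal x gaussian-noise convolution density."""
    lo = max(0.0, x - mu - 10 * sigma)
    hi = x - mu + 10 * sigma
    num = quad(lambda s: s * alpha * np.exp(-alpha * s) * norm.pdf(x - s, mu, sigma),
               lo, hi, limit=400)[0]
    den = quad(lambda s: alpha * np.exp(-alpha * s) * norm.pdf(x - s, mu, sigma),
               lo, hi, limit=400)[0]
    return num / den


class TestNormexp:
    def test_matches_quadrature_oracle(self):
        params = NormexpParams(mu_bg=100.0, sigma_bg=10.0, alpha=0.01)
        grid = np.array([80.0, 90.0, 95.0, 100.0, 105.0, 110.0, 120.0,
                         150.0, 200.0, 300.0])
        got = normexp_conditional_expectation(grid, params)
        expected = [quadrature_conditional_expectation(x, 100.0, 10.0, 0.01)
                    for x in grid]
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-6)

    def test_noise_free_limit_subtracts_background(self):
        params = NormexpParams(mu_bg=100.0, sigma_bg=1e-4, alpha=0.01)
        x = np.array([150.0, 300.0, 1000.0])
        got = normexp_conditional_expectation(x, params)
        np.testing.assert_allclose(got, x - 100.0, rtol=0, atol=1e-3)

    def test_strictly_monotone_and_positive(self, rng):
        params = NormexpParams(mu_bg=80.0, sigma_bg=15.0, alpha=0.005)
        x = np.sort(rng.uniform(1.0, 2000.0, size=500))
        y = normexp_conditional_expectation(x, params)
        assert np.all(y > 0)
        assert np.all(np.diff(y) > 0)

    def test_degenerate_array_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_normexp(np.full(100, 7.0))

    def test_background_correct_recovers_parameters_roughly(self, rng):
        # mostly-background array with exponential signal: the robust fit
        # should land near the generating parameters
        n = 5000
        bg = rng.normal(100.0, 10.0, size=n)
        sig = rng.exponential(200.0, size=n)
        m = _matrix((bg + sig)[:, None])
        corrected, fits = background_correct(m)
        assert np.all(corrected.values.to_numpy() > 0)
        assert 80 < fits[0].mu_bg < 140
        assert 1.0 / fits[0].alpha == pytest.approx(200.0, rel=0.5)


class TestQuantileNormalize:
    def test_identical_arrays_unchanged(self):
        col = np.array([5.0, 1.0, 3.0])
        m = _matrix(np.column_stack([col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   np.column_stack([col, col]), atol=1e-12)

    def test_hand_computed_rank_means(self):
        # arrays [1,2] and [3,6]: sorted means (2, 4) assigned by rank
        m = _matrix([[1.0, 3.0], [2.0, 6.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   [[2.0, 2.0], [4.0, 4.0]], atol=1e-12)

    def test_ties_get_mean_of_rank_range(self):
        # col A = (1,1,2), col B = (10,20,30); reference = (5.5, 10.5, 16);
        # A's tied pair shares mean(5.5, 10.5) = 8
        m = _matrix([[1.0, 10.0], [1.0, 20.0], [2.0, 30.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   [[8.0, 5.5], [8.0, 10.5], [16.0, 16.0]],
                                   atol=1e-12)

    def test_sorted_columns_identical_and_sum_conserved(self, rng):
        vals = rng.lognormal(5, 1, size=(200, 6))
        out = quantile_normalize(_matrix(vals)).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
        assert out.sum() == pytest.approx(vals.sum(), abs=1e-9 * vals.sum())

    def test_single_array_identity_with_warning(self):
        m = _matrix([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single array"):
            out = quantile_normalize(m)
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())


def scratch_median_polish(mat, tol=0.01, max_iter=10):
    """Independent reference: plain nested-loop Tukey sweeps."""
    mat = [row[:] for row in np.asarray(mat, dtype=float).tolist()]
    nr, nc = len(mat), len(mat[0])
    overall, row_eff, col_eff = 0.0, [0.0] * nr, [0.0] * nc
    for _ in range(max_iter):
        delta = 0.0
        for i in range(nr):
            med = float(np.median(mat[i]))
            for j in range(nc):
                mat[i][j] -= med
            row_eff[i] += med
            delta = max(delta, abs(med))
        med = float(np.median(row_eff))
        row_eff = [r - med for r in row_eff]
        overall += med
        for j in range(nc):
            med = float(np.median([mat[i][j] for i in range(nr)]))
            for i in range(nr):
                mat[i][j] -= med
            col_eff[j] += med
            delta = max(delta, abs(med))
        med = float(np.median(col_eff))
        col_eff = [c - med for c in col_eff]
        overall += med
        if delta < tol:
            break
    return overall, np.array(row_eff), np.array(col_eff), np.array(mat)


class TestMedianPolish:
    def test_exact_additive_structure_recovered(self):
        row = np.array([0.0, 1.0, -0.5, 2.0])
        col = np.array([10.0, 11.0, 12.0])
        mat = row[:, None] + col[None, :]
        overall, r, c, resid = median_polish(mat)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)
        fitted = overall + r[:, None] + c[None, :]
        np.testing.assert_allclose(fitted, mat, atol=1e-12)
        # array effects reproduce the column structure up to centring
        np.testing.assert_allclose(c - c[0], col - col[0], atol=1e-12)

    def test_single_probe_set_equals_probe_value(self):
        vals = np.array([[4.0, 8.0, 16.0]])
        m = _matrix(2.0 ** vals)
        pm = ProbesetMap("human", {"p0": "psA"}, {"psA": None})
        expr = summarize_medianpolish(m, pm)
        np.testing.assert_allclose(expr.values.loc["psA"], vals[0], atol=1e-12)

    def test_matches_scratch_reference(self, rng):
        mat = rng.normal(8.0, 1.0, size=(11, 10))
        mine = median_polish(mat, tol=0.01, max_iter=10)
        ref = scratch_median_polish(mat, tol=0.01, max_iter=10)
        assert mine[0] == pytest.approx(ref[0], abs=1e-9)
        np.testing.assert_allclose(mine[1], ref[1], atol=1e-9)
        np.testing.assert_allclose(mine[2], ref[2], atol=1e-9)
        np.testing.assert_allclose(mine[3], ref[3], atol=1e-9)

    def test_residual_medians_below_tolerance_at_convergence(self, rng):
        mat = rng.normal(0.0, 1.0, size=(9, 7))
        _, _, _, resid = median_polish(mat, tol=1e-6, max_iter=200)
        assert np.max(np.abs(np.median(resid, axis=0))) <= 1e-5
        assert np.max(np.abs(np.median(resid, axis=1))) <= 1e-5


class TestRmaPipeline:
    def test_output_dimensions_and_determinism(self, small_universe):
        xeno, _ = sd.generate_xenograft_arrays(small_universe)
        pm = small_universe.probeset_maps[MOUSE]
        a, _ = rma_pipeline(xeno[MOUSE], pm)
        b, _ = rma_pipeline(xeno[MOUSE], pm)
        assert a.values.shape == (len(pm.probeset_ids), len(xeno[MOUSE].sample_ids))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_species_mismatch_rejected(self, small_universe):
        xeno, _ = sd.generate_xenograft_arrays(small_universe)
        with pytest.raises(ValueError, match="species differ"):
            rma_pipeline(xeno[MOUSE], small_universe.probeset_maps["human"])

    def test_noise_free_recovery_of_planted_effects(self):
        # no measurement noise, no affinity spread, a genuine absent-probe
        # background population and a sparse planted fraction: the pipeline's
        # group differences recover the planted log2 effects.  Individual
        # members landing in the sparse upper intensity tail can be slightly
        # attenuated by quantile normalisation (an inherent property of the
        # method), so the assertion is on the mean member error.
        cfg = sd.SynthConfig(
            seed=21, n_probesets=2000, n_per_group=3,
            noise_sd=0.0, affinity_sd=0.0, crosshyb_fraction=0.0,
            absent_fraction=0.4, baseline_log2_mean=10.0, baseline_log2_sd=1.0,
            treatment_sets=(sd.TreatmentSet("NFKB_TARGETS", 6, 1.5, 0.2),),
        )
        uni = sd.generate_universe(cfg)
        xeno, sheet = sd.generate_xenograft_arrays(uni)
        expr, _ = rma_pipeline(xeno[MOUSE], uni.probeset_maps[MOUSE])
        groups = sheet.groups(MOUSE)
        observed = (expr.values[groups["treated"]].mean(axis=1)
                    - expr.values[groups["untreated"]].mean(axis=1))
        truth = uni.truth.true_log2fc[MOUSE]
        member_errs = [abs(observed[ps] - v) for ps, v in truth.items() if v != 0]
        assert np.mean(member_errs) <= 0.05
        # unplanted, expressed probe sets stay flat
        flat_errs = [
            abs(observed[ps]) for ps, v in truth.items()
            if v == 0 and ps not in uni.truth.absent_sets[MOUSE]
        ]
        assert np.mean(flat_errs) <= 0.02

    def test_exclusion_filter_drops_probesets(self, small_universe):
        xeno, _ = sd.generate_xenograft_arrays(small_universe)
        pm = small_universe.probeset_maps[MOUSE]
        drop = set(pm.probeset_ids[:5])
        expr, _ = rma_pipeline(xeno[MOUSE], pm, exclude_probesets=drop)
        assert set(expr.probeset_ids) == set(pm.probeset_ids) - drop
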