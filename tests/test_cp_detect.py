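"""Sequential-search test parameters, combination and CP selection."""

import numpy as np
import pytest

from afmcp import (
    ForceCurve,
    SampleProfile,
    StrategySpec,
    candidate_range,
    combine_traces,
    find_cp,
    generate_curve,
    normalize_trace,
)
# aliased so pytest does not collect the library's test-parameter functions
from afmcp.cp_detect import testparam_delta_e as delta_e_trace
from afmcp.cp_detect import testparam_gof as gof_trace
from afmcp.cp_detect import testparam_rov as rov_trace
from afmcp.errors import (
    CombinationError,
    DetectionFailedError,
    InsufficientDataError,
    NoPeakWarning,
    SearchRangeError,
)


def _flat_noise_curve(n=1024, sd=1.0, seed=0, dz=1.0):
    """Approach-only curve that never touches the sample."""
    rng = np.random.default_rng(seed)
    return ForceCurve(
        Z=np.arange(n) * dz, d=rng.normal(0, sd, n), k=0.03, theta=35.0,
        Z_glass=float(n) * dz + 1000.0,
    )


class TestCandidateRange:
    def test_rov_window_margin_at_1nm_sampling(self):
        curve = _flat_noise_curve(n=512, dz=1.0)
        cands, mask = candidate_range(curve, StrategySpec(components=("rov",)))
        # 50 nm windows at 1 nm sampling: 50 samples on each side
        assert cands[mask][0] == 50
        assert cands[mask][-1] == 511 - 50

    def test_delta_e_stencil_margin(self):
        curve = _flat_noise_curve(n=512)
        spec = StrategySpec(components=("delta_e",), h=3000.0)
        cands, mask = candidate_range(curve, spec)
        assert cands[mask][0] == 3  # 3 candidates lost per side of the E series
        assert cands[mask][-1] == 511 - 10 - 3

    def test_combined_mask_is_intersection(self):
        curve = _flat_noise_curve(n=512)
        masks = {}
        for comps in (("rov",), ("delta_e",), ("ple",)):
            _, masks[comps] = candidate_range(
                curve, StrategySpec(components=comps, h=3000.0)
            )
        _, joint = candidate_range(
            curve, StrategySpec(components=("rov", "delta_e", "ple"), h=3000.0)
        )
        expected = masks[("rov",)] & masks[("delta_e",)] & masks[("ple",)]
        np.testing.assert_array_equal(joint, expected)

    def test_empty_intersection_raises(self):
        curve = _flat_noise_curve(n=120, dz=1.0)
        # 50-sample margins on both sides of a 120-sample curve: nothing left
        with pytest.raises(SearchRangeError):
            candidate_range(
                curve, StrategySpec(components=("rov",), search_range=(0, 40))
            )


class TestDeltaE:
    def test_constant_modulus_gives_zero(self):
        trace = delta_e_trace(np.full(20, 5.0))
        assert np.allclose(trace[3:-3], 0.0)
        assert np.isnan(trace[:3]).all() and np.isnan(trace[-3:]).all()

    def test_exact_for_exponential_series(self):
        # lnE linear in i: the 6th-order stencil is exact
        c = 0.17
        E = np.exp(-c * np.arange(30))
        trace = delta_e_trace(E)
        assert np.allclose(trace[3:-3], c, atol=1e-10)

    def test_scale_invariance(self, rng):
        E = np.exp(rng.normal(0, 0.3, 40)) * 5.0
        t1 = delta_e_trace(E)
        t2 = delta_e_trace(123.0 * E)
        np.testing.assert_allclose(t1[3:-3], t2[3:-3], atol=1e-12)

    def test_nonpositive_entries_invalidate_neighbourhood(self):
        E = np.full(20, 2.0)
        E[9] = 0.0
        trace = delta_e_trace(E)
        assert np.isnan(trace[6:13]).all()
        assert np.isfinite(trace[3:6]).all()


class TestRoV:
    def test_pure_noise_mean_near_one(self):
        # no contact anywhere: both windows see the same iid noise.
        # (With 20-sample windows the exact mean of the variance ratio is
        # 19/17 ~ 1.12, hence the asymmetric band.)
        means = []
        for seed in range(20):
            curve = _flat_noise_curve(n=1024, sd=1.0, seed=seed, dz=2.44)
            cands, mask = candidate_range(curve, StrategySpec(components=("rov",)))
            trace = rov_trace(curve, cands, mask)
            means.append(np.nanmean(trace))
        assert 0.8 < np.mean(means) < 1.25

    def test_deep_contact_ratio_near_one(self):
        # both windows on the rising contact flank: variances similar
        vals = []
        for seed in range(5):
            curve, truth = generate_curve(SampleProfile(noise_sd=1.0), seed=seed,
                                          h_true=5000.0)
            spec = StrategySpec(components=("rov",))
            cands, mask = candidate_range(curve, spec)
            trace = rov_trace(curve, cands, mask)
            deep = slice(truth.cp_index + 600, truth.cp_index + 750)
            vals.append(np.nanmean(trace[deep]))
        assert 0.7 < np.mean(vals) < 1.6

    def test_peak_in_vicinity_of_cp_at_low_noise(self):
        # the RoV peak sits within about one window of the true CP
        curve, truth = generate_curve(SampleProfile(noise_sd=0.1), seed=11,
                                      h_true=4000.0)
        res = find_cp(curve, StrategySpec(components=("rov",)))
        dz = curve.Z[1] - curve.Z[0]
        assert abs(res.cp_index - truth.cp_index) * dz < 60.0

    def test_noiseless_flat_region_uses_floor_not_nan(self):
        curve, truth = generate_curve(SampleProfile(noise_sd=0.0), seed=1,
                                      h_true=4000.0)
        cands, mask = candidate_range(curve, StrategySpec(components=("rov",)))
        trace = rov_trace(curve, cands, mask)
        assert np.isfinite(trace[mask]).all()


class TestNormalizeCombine:
    def test_minmax_example(self):
        np.testing.assert_allclose(normalize_trace(np.array([1.0, 3.0, 2.0])),
                                   [0.0, 1.0, 0.5])

    def test_argmax_preserved(self, rng):
        t = rng.normal(0, 1, 50)
        assert np.argmax(normalize_trace(t)) == np.argmax(t)

    def test_constant_trace_warns_and_zeroes(self):
        with pytest.warns(NoPeakWarning):
            out = normalize_trace(np.full(10, 3.0))
        assert np.all(out == 0.0)

    def test_too_few_valid_entries(self):
        with pytest.raises(InsufficientDataError):
            normalize_trace(np.array([np.nan, 1.0, np.nan]))

    def test_single_trace_identity(self):
        t = np.array([0.0, 0.5, 1.0])
        np.testing.assert_array_equal(combine_traces([t]), t)

    def test_self_product_squares_keeps_argmax(self):
        t = np.array([0.1, 0.9, 0.4])
        prod = combine_traces([t, t])
        np.testing.assert_allclose(prod, t**2)
        assert np.argmax(prod) == np.argmax(t)

    def test_disjoint_peaks_resolve_to_highest_joint_value(self):
        a = np.array([1.0, 0.2, 0.6, 0.1])
        b = np.array([0.1, 0.6, 0.5, 1.0])
        prod = combine_traces([a, b])
        assert np.argmax(prod) == 2  # neither individual peak wins

    def test_nan_propagates_and_empty_intersection_raises(self):
        a = np.array([np.nan, 1.0, 0.5])
        b = np.array([0.5, 0.5, np.nan])
        prod = combine_traces([a, b])
        np.testing.assert_array_equal(np.isfinite(prod), [False, True, False])
        with pytest.raises(CombinationError):
            combine_traces([np.array([np.nan, 1.0]), np.array([1.0, np.nan])])


class TestFindCP:
    @pytest.mark.parametrize("component, tol", [
        ("gof_whole", 1), ("gof_low", 1), ("ple", 2),
    ])
    def test_noiseless_localization(self, noiseless_curve, component, tol):
        curve, truth = noiseless_curve
        res = find_cp(curve, StrategySpec(components=(component,)))
        assert abs(res.cp_index - truth.cp_index) <= tol

    def test_gof_trace_bounded_by_one(self, noiseless_curve):
        curve, _ = noiseless_curve
        cands, mask = candidate_range(curve, StrategySpec(components=("gof_whole",)))
        r2, _ = gof_trace(curve, cands, mask, mode="whole", model="becc")
        assert np.nanmax(r2) <= 1.0

    def test_gof_low_uses_stated_fraction(self):
        curve, truth = generate_curve(SampleProfile(noise_sd=0.0), seed=5,
                                      h_true=5000.0)
        # a trial point with N_c points ahead fits ceil(N_c/3) of them; check
        # via the modulus of a truncated-window fit differing from whole-fit
        cands, mask = candidate_range(curve, StrategySpec(components=("gof_low",)))
        r2_low, E_low = gof_trace(curve, cands, mask, mode="low", model="becc")
        r2_whole, E_whole = gof_trace(curve, cands, mask, mode="whole",
                                          model="becc")
        i = truth.cp_index
        assert E_low[i] == pytest.approx(10.0, rel=1e-6)
        assert E_whole[i] == pytest.approx(10.0, rel=1e-6)
        # away from the CP the two window lengths disagree
        assert not np.allclose(E_low[mask], E_whole[mask])

    def test_combined_exhaustive_trace_lengths(self, noisy_curve):
        curve, _ = noisy_curve
        res = find_cp(curve, StrategySpec(components=("gof_low", "rov", "delta_e")))
        assert len(res.combined) == len(res.candidates)
        for trace in res.traces.values():
            assert len(trace) == len(res.candidates)

    def test_determinism_bit_for_bit(self, noisy_curve):
        curve, _ = noisy_curve
        spec = StrategySpec(components=("gof_low", "rov", "delta_e"))
        r1 = find_cp(curve, spec)
        r2 = find_cp(curve, spec)
        assert r1.cp_index == r2.cp_index
        np.testing.assert_array_equal(r1.combined, r2.combined)

    def test_translation_equivariance(self, noisy_curve):
        curve, _ = noisy_curve
        spec = StrategySpec(components=("gof_low", "rov", "delta_e"))
        shifted = ForceCurve(Z=curve.Z + 777.0, d=curve.d, k=curve.k,
                             theta=curve.theta, nu=curve.nu,
                             Z_glass=curve.Z_glass + 777.0, label=curve.label)
        r1 = find_cp(curve, spec)
        r2 = find_cp(shifted, spec)
        assert r2.cp_index == r1.cp_index
        assert r2.Z_cp == pytest.approx(r1.Z_cp + 777.0)

    def test_pure_noise_never_silent(self):
        # a curve that never touches the sample either fails detection or is
        # flagged low-confidence - but is never reported as a clean result
        curve = _flat_noise_curve(n=1024, sd=1.0, seed=2, dz=2.44)
        spec = StrategySpec(components=("gof_low", "rov", "delta_e"))
        try:
            res = find_cp(curve, spec)
        except DetectionFailedError:
            return
        assert res.flags, "pure-noise curve produced an unflagged CP"

    def test_search_range_restriction(self, noiseless_curve):
        curve, truth = noiseless_curve
        spec = StrategySpec(components=("gof_whole",),
                            search_range=(truth.cp_index - 50, truth.cp_index + 50))
        res = find_cp(curve, spec)
        assert abs(res.cp_index - truth.cp_index) <= 1
        assert res.candidates[0] == truth.cp_index - 50
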