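"""Sequential-search contact-point detection.

Every sample of the approach segment (or those inside a restricted search
range) is assessed as a trial contact point.  For each trial point a *test
parameter* is computed; each test parameter is designed to peak in the
vicinity of the true contact point, so the CP is the trial point that
maximizes it.  Four test parameters are implemented:

* ``gof_whole`` / ``gof_low`` - goodness of fit: transform the data to
  force-indentation assuming contact at the trial point, fit the contact
  model to the whole contact part (or only the low-indentation first
  fraction of it) and score the trial point by r^2.
* ``rov`` - ratio of variances of the deflection in two windows flanking
  the trial point (contact side over non-contact side); near 1 away from
  contact, peaked near the CP.
* ``delta_e`` - minus the index derivative of log-modulus, -d(lnE)/di,
  computed with a 6th-order central finite-difference stencil over the
  per-trial-point fitted moduli; the inflection of lnE(i) near the CP
  becomes a peak.
* ``ple`` - power-law exponent: fit F = A*delta^x over a small vicinity
  ahead of the trial point and score by -|x - 2|, peaking where the
  response is purely quadratic, i.e. at genuine incipient cone contact.

Traces are min-max normalized to [0, 1] (argmax-preserving, and it keeps
strictly negative raw scores valid as product factors) and combined as an
elementwise product; the CP is the global maximum of the combined trace.
The search is exhaustive - every candidate is evaluated - because combined
traces are in general multimodal, which rules out bracketing shortcuts
such as golden-section search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .contact_models import E_BOUNDS, _model_basis, fit_power_law
from .curves import ForceCurve, split_approach_withdraw
from .errors import (
    CombinationError,
    DetectionFailedError,
    DomainError,
    InsufficientDataError,
    NoPeakWarning,
    SearchRangeError,
)

#: 6th-order central first-derivative stencil (unit grid spacing).
DELTA_E_STENCIL = np.array([-1.0, 9.0, -45.0, 0.0, 45.0, -9.0, 1.0]) / 60.0
#: Half-width, in candidates, of the stencil.
DELTA_E_MARGIN = 3
#: Minimum number of samples ahead of a GoF trial point.
GOF_MIN_AHEAD = 10
#: Variance floor (nm^2) guarding the RoV denominator on noiseless data.
ROV_VARIANCE_FLOOR = 1e-6

ALL_COMPONENTS = ("gof_whole", "gof_low", "rov", "delta_e", "ple")


@dataclass(frozen=True)
class StrategySpec:
    """Configuration of one CP-detection strategy.

    Parameters
    ----------
    components : tuple of str
        Subset of ``{"gof_whole", "gof_low", "rov", "delta_e", "ple"}``;
        multiple components are combined multiplicatively.
    model : "becc" | "sneddon"
        Contact model used by the fit-based components (thin vs thick
        samples).
    rov_window : float
        Width (nm) of each variance window flanking the trial point.
    ple_vicinity : float
        Length (nm) of piezo travel ahead of the trial point fitted by the
        power law.
    gof_low_fraction : float
        Fraction of contact points fitted by ``gof_low``.
    search_range : (int, int), optional
        Half-open approach-index interval to restrict the candidate search;
        default is the full approach segment.
    step : int
        Candidate stride in samples (1 = every sample).
    h : float, optional
        Fixed sample thickness (nm) for the BECC fits; when absent the
        per-trial-point thickness |Z_glass - Z_i| from the curve's glass
        reference is used.
    """

    components: tuple[str, ...] = ("gof_low", "rov", "delta_e")
    model: str = "becc"
    rov_window: float = 50.0
    ple_vicinity: float = 250.0
    gof_low_fraction: float = 1.0 / 3.0
    search_range: tuple[int, int] | None = None
    step: int = 1
    h: float | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("strategy needs at least one component")
        unknown = set(self.components) - set(ALL_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        if not self.rov_window > 0:
            raise ValueError("rov_window must be positive")
        if not 0 < self.gof_low_fraction <= 1:
            raise ValueError("gof_low_fraction must lie in (0, 1]")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class CPResult:
    """Outcome of one sequential CP search.

    ``cp_index`` is the chosen trial point as an index into the curve's
    arrays (0-based, normalized orientation).  ``candidates`` holds the
    evaluated approach indices, ``traces`` the normalized per-component
    test-parameter arrays over them (NaN = not computable there), and
    ``combined`` their product.  ``n_peaks`` counts local maxima of the
    combined trace - more than one flags a multimodal search.
    """

    cp_index: int
    Z_cp: float
    d_cp: float
    candidates: np.ndarray
    traces: dict[str, np.ndarray]
    combined: np.ndarray
    n_peaks: int
    flags: list[str] = field(default_factory=list)

    @property
    def raw_traces(self) -> dict[str, np.ndarray]:
        return {k[4:]: v for k, v in self.traces.items() if k.startswith("raw_")}


# ---------------------------------------------------------------------------
# Candidate range
# ---------------------------------------------------------------------------

def _approach_arrays(curve: ForceCurve) -> tuple[np.ndarray, np.ndarray]:
    approach, _ = split_approach_withdraw(curve)
    return curve.Z[: approach.stop], curve.d[: approach.stop]


def _rov_window_samples(Z: np.ndarray, window_nm: float) -> int:
    dz = float(np.median(np.abs(np.diff(Z))))
    if dz <= 0:
        raise SearchRangeError("approach Z has no spread")
    w = int(round(window_nm / dz))
    if w < 5:
        raise SearchRangeError(
            f"RoV window of {window_nm} nm spans only {w} samples (< 5) at "
            f"the curve's {dz:.3g} nm sampling"
        )
    return w


def candidate_range(
    curve: ForceCurve, spec: StrategySpec
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate approach indices and their joint validity mask.

    Each component imposes an edge margin: RoV needs a full variance window
    on each side of the trial point, the log-modulus derivative needs three
    candidates on each side (6th-order stencil), the power-law exponent
    needs ``ple_vicinity`` of travel ahead, and the GoF fits need at least
    ``GOF_MIN_AHEAD`` samples ahead.  Returns ``(candidates, mask)`` where
    candidates covers the (possibly restricted) search range at the
    requested stride and ``mask`` marks candidates valid for *every*
    requested component.

    Raises :class:`SearchRangeError` when the intersection is empty.
    """
    Z, _ = _approach_arrays(curve)
    n = len(Z)
    lo, hi = 0, n
    if spec.search_range is not None:
        lo = max(lo, int(spec.search_range[0]))
        hi = min(hi, int(spec.search_range[1]))
        if hi <= lo:
            raise SearchRangeError("empty search range")
    candidates = np.arange(lo, hi, spec.step)
    mask = np.ones(len(candidates), dtype=bool)

    fit_based = {"gof_whole", "gof_low", "delta_e"} & set(spec.components)
    if fit_based:
        mask &= candidates <= n - 1 - GOF_MIN_AHEAD
    if "delta_e" in spec.components:
        # stencil consumes 3 candidates per side of the fitted-E series
        gof_ok = candidates <= n - 1 - GOF_MIN_AHEAD
        interior = np.zeros(len(candidates), dtype=bool)
        m = DELTA_E_MARGIN
        if len(candidates) > 2 * m:
            interior[m:-m] = gof_ok[m:-m] & gof_ok[: -2 * m] & gof_ok[2 * m :]
        mask &= interior
    if "rov" in spec.components:
        w = _rov_window_samples(Z, spec.rov_window)
        mask &= (candidates >= w) & (candidates <= n - 1 - w)
    if "ple" in spec.components:
        # vicinity of travel ahead, and at least 5 points in it
        reach = Z[candidates] + spec.ple_vicinity
        mask &= reach <= Z[-1]
        mask &= candidates <= n - 1 - 5
    if not mask.any():
        raise SearchRangeError(
            "no candidate satisfies every component's edge margin"
        )
    return candidates, mask


# ---------------------------------------------------------------------------
# Test parameters
# ---------------------------------------------------------------------------

def _trial_h(curve: ForceCurve, z0: float, spec_h: float | None) -> float | None:
    if spec_h is not None:
        return spec_h
    if curve.Z_glass is not None:
        return abs(curve.Z_glass - z0)
    return None


def testparam_gof(
    curve: ForceCurve,
    candidates: np.ndarray,
    mask: np.ndarray,
    mode: str = "whole",
    model: str = "becc",
    h: float | None = None,
    low_fraction: float = 1.0 / 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Goodness-of-fit trace (r^2) and the per-trial fitted moduli.

    For each valid trial point i the curve is re-zeroed there (delta_i = 0,
    F_i = 0), transformed to force-indentation over points i..apex, and the
    contact model fitted with the modulus as the only free parameter - one
    fit per candidate.  ``mode="whole"`` fits the whole contact part;
    ``mode="low"`` fits only the first ``low_fraction`` of the contact
    points (low indentations).  Trial points where the fit is impossible
    are NaN in both outputs.

    Returns ``(r2_trace, E_trace)`` aligned with ``candidates``.
    """
    if mode not in ("whole", "low"):
        raise ValueError(f"unknown GoF mode {mode!r}")
    Z, d = _approach_arrays(curve)
    k = curve.k
    r2 = np.full(len(candidates), np.nan)
    E = np.full(len(candidates), np.nan)
    for ci in np.nonzero(mask)[0]:
        i = int(candidates[ci])
        z0, d0 = Z[i], d[i]
        delta = (Z[i:] - z0) - (d[i:] - d0)
        F = k * (d[i:] - d0)
        n_c = len(delta)
        stop = n_c if mode == "whole" else max(5, math.ceil(low_fraction * n_c))
        delta = delta[:stop]
        F = F[:stop]
        sel = delta >= 0
        if sel.sum() < 5:
            continue
        dd, FF = delta[sel], F[sel]
        h_i = _trial_h(curve, z0, h)
        if model == "becc" and h_i is None:
            raise DomainError(
                "BECC goodness-of-fit needs a thickness: provide spec.h or a "
                "curve with Z_glass"
            )
        try:
            phi = _model_basis(dd, model, curve.theta, curve.nu, h_i)
        except DomainError:
            continue
        s2 = float(phi @ phi)
        if s2 == 0.0 or np.all(FF == 0):
            continue
        e_hat = float(phi @ FF) / s2
        e_hat = float(np.clip(e_hat, *E_BOUNDS))
        resid = FF - e_hat * phi
        ss_tot = float(np.sum((FF - FF.mean()) ** 2))
        if ss_tot == 0.0:
            continue
        # r^2 is unbounded below; one catastrophic trial fit would otherwise
        # stretch the min-max normalization and flatten the whole trace, so
        # "worse than the mean predictor" is floored to zero quality.
        r2[ci] = max(1.0 - float(resid @ resid) / ss_tot, 0.0)
        E[ci] = e_hat
    return r2, E


def testparam_rov(
    curve: ForceCurve,
    candidates: np.ndarray,
    mask: np.ndarray,
    window: float = 50.0,
) -> np.ndarray:
    """Ratio-of-variances trace over the candidates.

    RoV_i = var(d over (i, i+w]) / var(d over [i-w, i)), with the trial
    point itself excluded from both windows and the contact side (larger
    index in the normalized orientation) in the numerator, so the trace
    peaks near the CP and sits near 1 deep inside either region.  The
    denominator is floored at ``ROV_VARIANCE_FLOOR`` so noiseless flat
    baselines cannot divide by zero (floored entries are still reported).
    """
    Z, d = _approach_arrays(curve)
    w = _rov_window_samples(Z, window)
    n = len(d)
    # windowed sample variances via cumulative sums
    c1 = np.concatenate(([0.0], np.cumsum(d)))
    c2 = np.concatenate(([0.0], np.cumsum(d * d)))

    def window_var(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # sample variance (ddof=1) of d[a:b], vectorized over index arrays
        s1 = c1[b] - c1[a]
        s2 = c2[b] - c2[a]
        m = b - a
        return (s2 - s1 * s1 / m) / (m - 1)

    trace = np.full(len(candidates), np.nan)
    ok = mask & (candidates >= w) & (candidates <= n - 1 - w)
    idx = candidates[ok]
    var_right = window_var(idx + 1, idx + 1 + w)
    var_left = window_var(idx - w, idx)
    trace[ok] = var_right / np.maximum(var_left, ROV_VARIANCE_FLOOR)
    return trace


def testparam_delta_e(E_series: np.ndarray) -> np.ndarray:
    """-d(lnE)/di of a per-candidate modulus series, 6th-order stencil.

    The modulus drifts monotonically as the trial point marches through the
    true CP - downward when non-contact data dilute the fit, upward when
    contact data are truncated - and lnE(i) has an inflection near the CP.
    The minus sign turns that local minimum of d(lnE)/di into a local
    maximum.  Entries are NaN wherever any of the seven stencil nodes is
    missing or non-positive; by construction the trace is invariant under
    E -> lambda*E.
    """
    E_series = np.asarray(E_series, dtype=float)
    n = len(E_series)
    out = np.full(n, np.nan)
    if n < 2 * DELTA_E_MARGIN + 1:
        return out
    lnE = np.where(E_series > 0, np.log(np.where(E_series > 0, E_series, 1.0)), np.nan)
    m = DELTA_E_MARGIN
    window = np.lib.stride_tricks.sliding_window_view(lnE, 2 * m + 1)
    deriv = window @ DELTA_E_STENCIL
    out[m : n - m] = -deriv
    return out


def testparam_ple(
    curve: ForceCurve,
    candidates: np.ndarray,
    mask: np.ndarray,
    vicinity: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Power-law-exponent trace: -|x - 2| per trial point.

    For each valid trial point the force-indentation transform is applied
    and F = A*delta^x fitted over the points with Z in (Z_i, Z_i+vicinity].
    Restricting the fit to a small vicinity keeps the thin-film
    higher-order terms from dominating the exponent.  The raw score
    -|x - 2| is maximal (zero) where the response is purely quadratic.

    Returns ``(score_trace, x_trace)``.
    """
    Z, d = _approach_arrays(curve)
    k = curve.k
    score = np.full(len(candidates), np.nan)
    x_vals = np.full(len(candidates), np.nan)
    ends = np.searchsorted(Z, Z[candidates] + vicinity, side="right")
    for ci in np.nonzero(mask)[0]:
        i = int(candidates[ci])
        j_end = int(ends[ci])
        if j_end <= i + 5:
            continue
        z0, d0 = Z[i], d[i]
        delta = (Z[i + 1 : j_end] - z0) - (d[i + 1 : j_end] - d0)
        F = k * (d[i + 1 : j_end] - d0)
        try:
            fit = fit_power_law(delta, F)
        except InsufficientDataError:
            continue
        x_vals[ci] = fit.x
        score[ci] = -abs(fit.x - 2.0)
    return score, x_vals


# ---------------------------------------------------------------------------
# Normalization, combination, selection
# ---------------------------------------------------------------------------

def normalize_trace(trace: np.ndarray) -> np.ndarray:
    """Affine min-max map of the valid entries onto [0, 1].

    Argmax-preserving; NaN entries stay NaN.  A constant trace normalizes
    to all zeros and raises :class:`NoPeakWarning` (there is nothing to
    maximize).  Min-max rather than divide-by-max so that strictly negative
    raw scores (PLE, delta-E) become valid non-negative product factors.
    """
    trace = np.asarray(trace, dtype=float)
    valid = np.isfinite(trace)
    if valid.sum() < 2:
        raise InsufficientDataError("need at least 2 valid trace entries")
    t_min = trace[valid].min()
    t_max = trace[valid].max()
    out = np.full_like(trace, np.nan)
    if t_max == t_min:
        warnings.warn("constant test-parameter trace has no peak", NoPeakWarning)
        out[valid] = 0.0
        return out
    out[valid] = (trace[valid] - t_min) / (t_max - t_min)
    return out


def combine_traces(traces: list[np.ndarray]) -> np.ndarray:
    """Elementwise product of normalized traces sharing one candidate grid.

    An entry invalid (NaN) in any trace is invalid in the product.  Raises
    :class:`CombinationError` if no entry is valid everywhere.
    """
    if not traces:
        raise CombinationError("no traces to combine")
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise CombinationError("traces do not share a candidate grid")
    combined = np.ones(lengths.pop())
    for t in traces:
        combined = combined * np.asarray(t, dtype=float)
    if not np.isfinite(combined).any():
        raise CombinationError("no candidate is valid in every trace")
    return combined


def _count_peaks(trace: np.ndarray) -> int:
    t = np.asarray(trace, dtype=float)
    finite = np.isfinite(t)
    n = 0
    for i in range(1, len(t) - 1):
        if finite[i - 1] and finite[i] and finite[i + 1]:
            if t[i] > t[i - 1] and t[i] >= t[i + 1]:
                n += 1
    return n


def find_cp(curve: ForceCurve, spec: StrategySpec) -> CPResult:
    """Run one full sequential CP search on the approach segment.

    Evaluates every requested component over the candidate range,
    normalizes each trace, multiplies them and returns the global-maximum
    candidate (ties break toward the smaller index - the earlier,
    conservative contact point).  When both a GoF component and ``delta_e``
    are requested, the log-modulus derivative consumes the modulus series
    of the GoF fits, so one fitting pass per candidate serves both; a
    standalone ``delta_e`` performs whole-contact fits itself.

    Raises :class:`DetectionFailedError` when the combined trace is
    constant (no peak to report); a result whose fit quality or variance
    contrast is too weak to be trustworthy is returned but flagged
    ``low_confidence``.
    """
    Z, d = _approach_arrays(curve)
    candidates, mask = candidate_range(curve, spec)
    raw: dict[str, np.ndarray] = {}
    e_series: np.ndarray | None = None

    for comp, mode in (("gof_whole", "whole"), ("gof_low", "low")):
        if comp in spec.components:
            r2, E = testparam_gof(
                curve, candidates, mask, mode=mode, model=spec.model,
                h=spec.h, low_fraction=spec.gof_low_fraction,
            )
            raw[comp] = r2
            # delta_e reuses gof_low's moduli in preference to gof_whole's
            if e_series is None or comp == "gof_low":
                e_series = E
    if "delta_e" in spec.components:
        if e_series is None:
            _, e_series = testparam_gof(
                curve, candidates, mask, mode="whole", model=spec.model, h=spec.h
            )
        raw["delta_e"] = testparam_delta_e(e_series)
    if "rov" in spec.components:
        raw["rov"] = testparam_rov(curve, candidates, mask, spec.rov_window)
    if "ple" in spec.components:
        raw["ple"], _ = testparam_ple(curve, candidates, mask, spec.ple_vicinity)

    flags: list[str] = []
    normalized: dict[str, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("error", NoPeakWarning)
        for name, trace in raw.items():
            try:
                normalized[name] = normalize_trace(trace)
            except (NoPeakWarning, InsufficientDataError):
                raise DetectionFailedError(
                    f"test parameter {name!r} is constant or empty; no peak"
                ) from None

    combined = combine_traces([normalized[c] for c in spec.components if c in normalized])
    finite = np.isfinite(combined)
    if not finite.any() or combined[finite].max() == combined[finite].min():
        raise DetectionFailedError("combined trace has no peak")

    best = int(np.nanargmax(combined))  # first occurrence = smaller index
    cp_index = int(candidates[best])

    for name in ("gof_whole", "gof_low"):
        if name in raw and np.nanmax(raw[name]) < 0.5:
            flags.append("low_confidence:gof")
            break
    if "rov" in raw and np.nanmax(raw["rov"]) < 1.5:
        flags.append("low_confidence:rov")

    traces = {name: normalized[name] for name in normalized}
    traces.update({f"raw_{name}": trace for name, trace in raw.items()})
    return CPResult(
        cp_index=cp_index,
        Z_cp=float(Z[cp_index]),
        d_cp=float(d[cp_index]),
        candidates=candidates,
        traces=traces,
        combined=combined,
        n_peaks=_count_peaks(combined),
        flags=flags,
    )
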