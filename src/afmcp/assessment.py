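"""Distribution metrics for ranking CP-detection strategies.

A strategy is judged by the distribution of Young's moduli it produces
over a collection of curves obtained on a homogeneous sample of known
stiffness: it should be accurate, produce few outliers, leave no residual
dependence between modulus and local thickness once the thin-film model is
applied, and (for a homogeneous gel) no skew.  Four metrics operationalize
this - variance sigma^2(E), success rate SR, covariance sigma(E, h), and
skewness s(E) - and combine into one global figure of merit

    M = sigma^2(E) * |sigma(E, h)| * |s(E)| / SR      [kPa^3 * nm]

whose numerator collects everything a good strategy minimizes and whose
denominator is the one quantity it maximizes; lower M is better.

Curves whose analysis failed enter the success-rate denominator but are
excluded from the moment-based metrics, which are all computed on the same
valid subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError

#: Acceptance ranges (kPa) used for the success rate on gels of known
#: nominal stiffness.
SR_RANGES = {
    10.0: (0.3, 60.0),
    1.0: (0.15, 9.0),
    0.1: (0.02, 1.0),
}


@dataclass
class AssessmentMetrics:
    """Metric suite for one strategy over one curve collection."""

    mean_E: float  # kPa
    var_E: float  # kPa^2
    SR: float  # fraction in [0, 1]
    cov_Eh: float  # kPa*nm
    skew_E: float  # dimensionless
    M: float  # kPa^3*nm
    n_curves: int
    sr_range: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "mean_E": self.mean_E,
            "var_E": self.var_E,
            "SR": self.SR,
            "cov_Eh": self.cov_Eh,
            "skew_E": self.skew_E,
            "M": self.M,
            "n_curves": self.n_curves,
            "sr_range": list(self.sr_range),
        }


def success_rate(E_values, sr_range: tuple[float, float]) -> float:
    """Fraction of curves whose modulus falls inside the acceptance range.

    Bounds are inclusive.  Invalid entries (NaN, from failed detections)
    count in the denominator: a strategy that fails outright on a curve is
    not successful on it.
    """
    e_min, e_max = sr_range
    if not e_min < e_max:
        raise UndefinedMetricError(f"invalid acceptance range {sr_range}")
    E = np.asarray(E_values, dtype=float)
    if E.size == 0:
        raise UndefinedMetricError("success rate of an empty collection")
    inside = np.isfinite(E) & (E >= e_min) & (E <= e_max)
    return float(inside.sum()) / E.size


def covariance_Eh(E_values, h_values) -> float:
    """Sample covariance (n-1 denominator) of modulus and point thickness.

    Pairs with an invalid modulus are dropped.  A correctly corrected thin
    homogeneous sample shows no E-h dependence (covariance near zero); a
    residual bottom effect gives positive covariance, an overcorrection a
    negative one.
    """
    E = np.asarray(E_values, dtype=float)
    h = np.asarray(h_values, dtype=float)
    if E.shape != h.shape:
        raise UndefinedMetricError("E and h collections differ in length")
    valid = np.isfinite(E) & np.isfinite(h)
    if valid.sum() < 2:
        raise UndefinedMetricError("fewer than 2 valid (E, h) pairs")
    return float(np.cov(E[valid], h[valid], ddof=1)[0, 1])


def skewness(E_values) -> float:
    """Fisher-Pearson moment coefficient g1 = m3 / m2^(3/2)."""
    E = np.asarray(E_values, dtype=float)
    E = E[np.isfinite(E)]
    if E.size < 3:
        raise UndefinedMetricError("skewness needs at least 3 valid values")
    if np.var(E) == 0:
        raise UndefinedMetricError("skewness undefined for zero variance")
    return float(stats.skew(E, bias=True))


def global_metric(var_E: float, SR: float, cov_Eh: float, skew_E: float) -> float:
    """Global figure of merit M = var * |cov| * |skew| / SR (kPa^3*nm).

    Lower is better.  Absolute values keep rows with negative covariance
    or skew comparable.  SR = 0 returns +inf with a warning (the strategy
    produced no acceptable modulus at all).
    """
    if SR == 0:
        warnings.warn("success rate is zero; global metric is infinite")
        return float("inf")
    if SR < 0 or SR > 1:
        raise UndefinedMetricError(f"success rate {SR} outside [0, 1]")
    return float(var_E) * abs(float(cov_Eh)) * abs(float(skew_E)) / float(SR)


def compute_metrics(
    E_values, h_values, sr_range: tuple[float, float]
) -> AssessmentMetrics:
    """All four metrics plus M for one strategy's (E, h) collection.

    Failed curves are passed as NaN moduli; every moment-based metric is
    computed on the identical valid subset.
    """
    E = np.asarray(E_values, dtype=float)
    h = np.asarray(h_values, dtype=float)
    valid = np.isfinite(E) & np.isfinite(h)
    if valid.sum() < 2:
        raise UndefinedMetricError("fewer than 2 valid curves")
    Ev = E[valid]
    sr = success_rate(E, sr_range)
    var_E = float(np.var(Ev, ddof=1))
    cov = covariance_Eh(E, h)
    skew = skewness(Ev)
    return AssessmentMetrics(
        mean_E=float(Ev.mean()),
        var_E=var_E,
        SR=sr,
        cov_Eh=cov,
        skew_E=skew,
        M=global_metric(var_E, sr, cov, skew),
        n_curves=int(E.size),
        sr_range=(float(sr_range[0]), float(sr_range[1])),
    )


def rank_strategies(results: dict[str, AssessmentMetrics]) -> pd.DataFrame:
    """Strategies sorted ascending by M (best first), one row each.

    Columns mirror the metric suite: <E>, sigma^2(E), SR, sigma(E,h),
    s(E), M.  Deterministic: ties keep insertion order.
    """
    if not results:
        raise UndefinedMetricError("no strategy results to rank")
    rows = []
    for name, m in results.items():
        rows.append(
            {
                "strategy": name,
                "mean_E_kPa": m.mean_E,
                "var_E_kPa2": m.var_E,
                "SR": m.SR,
                "cov_Eh_kPa_nm": m.cov_Eh,
                "skew_E": m.skew_E,
                "M_kPa3_nm": m.M,
                "n_curves": m.n_curves,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values("M_kPa3_nm", kind="stable").reset_index(drop=True)
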