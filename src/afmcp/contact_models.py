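"""Forward contact-mechanics models and Young's-modulus fitting.

Three force-indentation models are provided:

* **Sneddon cone** - a rigid cone of half-angle theta indenting a linear
  elastic half-space:  F = (2/pi) * E/(1-nu^2) * tan(theta) * delta^2.
* **BECC** (bottom effect cone correction) - the thin-film correction for a
  sample of thickness h bonded to a rigid substrate.  The substrate's image
  stress field stiffens the apparent response, so BECC multiplies the
  Sneddon force by a polynomial in the dimensionless ratio
  chi = delta*tan(theta)/h (roughly contact radius over thickness):

      F = F_sneddon(delta) * B(chi),
      B(chi) = 1 + b1*chi + b2*chi^2,
      b1 = 4*1.7795/pi^2 ~ 0.7212,   b2 = b1^2 ~ 0.5201,

  valid for delta < h.  B(0) = 1 recovers the half-space limit; B is
  monotone increasing, so the bottom effect always raises the force and,
  at fixed force, thinner samples appear stiffer if left uncorrected.
* **Power law** - F = A * delta^x with both the prefactor and the exponent
  free; on true conical half-space contact x = 2, and deviations of the
  fitted exponent from 2 signal a mis-placed contact point or dominant
  thin-film terms.

Units: delta and h in nm, E in kPa, forces in nN (1 kPa * nm^2 = 1e-6 nN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateFitError, DomainError, InsufficientDataError

#: kPa * nm^2 -> nN
_KPA_NM2_TO_NN = 1e-6

#: Image-series constant of the bonded thin-film solution.
_BECC_ALPHA = 1.7795
#: First- and second-order correction coefficients of B(chi).
BECC_B1 = 4.0 * _BECC_ALPHA / math.pi**2
BECC_B2 = 16.0 * _BECC_ALPHA**2 / math.pi**4

#: Modulus search bounds (kPa) used by the fit; generous for soft matter.
E_BOUNDS = (1e-3, 1e4)


@dataclass
class EFit:
    """Result of a modulus (or power-law) fit.

    ``E`` is the Young's modulus in kPa (NaN for the power-law model, whose
    free parameters are the prefactor ``A`` in nN/nm^x and exponent ``x``).
    ``r2`` is the coefficient of determination computed on the fitted range
    only.  ``fit_range`` is the half-open index interval used.
    """

    E: float
    model: str  # "sneddon" | "becc" | "power_law"
    r2: float
    fit_range: tuple[int, int]
    x: float | None = None
    A: float | None = None
    h: float | None = None
    converged: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "E": self.E,
            "model": self.model,
            "r2": self.r2,
            "fit_range": list(self.fit_range),
            "x": self.x,
            "A": self.A,
            "h": self.h,
            "converged": self.converged,
            "message": self.message,
        }


def sneddon_force(
    delta: np.ndarray | float, E: float, theta: float, nu: float = 0.5
) -> np.ndarray | float:
    """Force (nN) of a rigid cone on an elastic half-space.

    F = (2/pi) * E/(1-nu^2) * tan(theta) * delta^2; quadratic, so
    F(2*delta) = 4*F(delta) and F(0) = 0.

    Raises :class:`DomainError` for negative indentation.
    """
    delta_arr = np.asarray(delta, dtype=float)
    if np.any(delta_arr < 0):
        raise DomainError("negative indentation; clamp or filter before calling")
    out = (
        (2.0 / math.pi)
        * (E / (1.0 - nu**2))
        * math.tan(math.radians(theta))
        * delta_arr**2
        * _KPA_NM2_TO_NN
    )
    return out if np.ndim(delta) else float(out)


def becc_correction(chi: np.ndarray | float) -> np.ndarray | float:
    """The bottom-effect multiplier B(chi), chi = delta*tan(theta)/h."""
    chi = np.asarray(chi, dtype=float)
    out = 1.0 + BECC_B1 * chi + BECC_B2 * chi**2
    return out if out.ndim else float(out)


def becc_force(
    delta: np.ndarray | float,
    E: float,
    theta: float,
    nu: float = 0.5,
    h: float = np.inf,
) -> np.ndarray | float:
    """Force (nN) of a cone on a thin elastic film bonded to a substrate.

    Multiplies the Sneddon force by B(delta*tan(theta)/h); requires h > 0
    and delta < h (the tip cannot indent past the substrate).
    """
    if not h > 0:
        raise DomainError(f"sample thickness must be positive, got {h}")
    delta_arr = np.asarray(delta, dtype=float)
    if np.any(delta_arr >= h):
        raise DomainError("indentation exceeds thickness (delta >= h)")
    chi = delta_arr * math.tan(math.radians(theta)) / h
    out = sneddon_force(delta_arr, E, theta, nu) * becc_correction(chi)
    return out if np.ndim(delta) else float(out)


def _model_basis(
    delta: np.ndarray, model: str, theta: float, nu: float, h: float | None
) -> np.ndarray:
    """phi(delta) such that F_model = E * phi(delta).

    Both contact models are linear in E.  Unlike the public forward models
    this helper evaluates B(chi) for any non-negative delta: during the
    sequential CP search trial points deep inside the contact region can
    transiently imply delta close to (or past) the trial thickness, and the
    polynomial extrapolation keeps those trial fits finite rather than
    fatal.
    """
    tan_t = math.tan(math.radians(theta))
    phi = (2.0 / math.pi) / (1.0 - nu**2) * tan_t * delta**2 * _KPA_NM2_TO_NN
    if model == "becc":
        if h is None or not h > 0:
            raise DomainError("model 'becc' requires a positive thickness h")
        phi = phi * becc_correction(delta * tan_t / h)
    elif model != "sneddon":
        raise ValueError(f"unknown contact model {model!r}")
    return phi


def _r_squared(F: np.ndarray, F_model: np.ndarray) -> float:
    ss_res = float(np.sum((F - F_model) ** 2))
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_modulus(
    delta: np.ndarray,
    F: np.ndarray,
    model: str = "becc",
    theta: float = 35.0,
    nu: float = 0.5,
    h: float | None = None,
    fit_range: tuple[int, int] | None = None,
) -> EFit:
    """Least-squares Young's modulus with E as the only free parameter.

    Minimizes sum((F - E*phi(delta))^2) over the fitted index range,
    excluding negative-indentation points (the contact models are defined
    for contact only).  Because the model is linear in E the minimizer is
    the closed-form projection E = <phi, F>/<phi, phi>, clipped to
    ``E_BOUNDS``; clipping a convex quadratic objective onto an interval
    preserves optimality, so this equals the bounded nonlinear
    least-squares solution exactly and deterministically.

    Parameters
    ----------
    delta, F : ndarray
        Indentation (nm) and force (nN) samples.
    model : "sneddon" | "becc"
    h : float, optional
        Sample thickness (nm); required iff ``model == "becc"``.
    fit_range : (int, int), optional
        Half-open index interval to fit; default is the full array.
    """
    delta = np.asarray(delta, dtype=float)
    F = np.asarray(F, dtype=float)
    if fit_range is None:
        fit_range = (0, len(delta))
    lo, hi = int(fit_range[0]), int(fit_range[1])
    d_sel = delta[lo:hi]
    F_sel = F[lo:hi]
    mask = d_sel >= 0
    d_sel, F_sel = d_sel[mask], F_sel[mask]
    if len(d_sel) < 5:
        raise InsufficientDataError(
            f"only {len(d_sel)} contact points in fit range; at least 5 required"
        )
    if np.all(F_sel == 0):
        raise DegenerateFitError("all-zero force in fit range")

    phi = _model_basis(d_sel, model, theta, nu, h)
    s2 = float(phi @ phi)
    if s2 == 0.0:
        raise DegenerateFitError("degenerate basis (all-zero indentation)")
    e_hat = float(phi @ F_sel) / s2
    converged = True
    message = ""
    if not E_BOUNDS[0] < e_hat <= E_BOUNDS[1]:
        e_clipped = float(np.clip(e_hat, E_BOUNDS[0], E_BOUNDS[1]))
        message = f"modulus {e_hat:.3g} kPa clipped to bounds {E_BOUNDS}"
        e_hat = e_clipped
        converged = False
    r2 = _r_squared(F_sel, e_hat * phi)
    return EFit(
        E=e_hat,
        model=model,
        r2=r2,
        fit_range=(lo, hi),
        h=h if model == "becc" else None,
        converged=converged,
        message=message,
    )


def fit_power_law(
    delta: np.ndarray,
    F: np.ndarray,
    fit_range: tuple[int, int] | None = None,
    x_bounds: tuple[float, float] = (0.2, 8.0),
) -> EFit:
    """Fit F = A * delta^x by least squares with A and x free.

    Points with delta <= 0 or F <= 0 are dropped (the power law is defined
    on the positive quadrant); at least 5 must remain.  The exponent search
    is initialized from the log-log linear regression, then refined on the
    profiled objective: for fixed x the optimal prefactor is the linear
    projection A(x) = <delta^x, F>/<delta^x, delta^x>, leaving a
    one-dimensional minimization in x.
    """
    delta = np.asarray(delta, dtype=float)
    F = np.asarray(F, dtype=float)
    if fit_range is None:
        fit_range = (0, len(delta))
    lo, hi = int(fit_range[0]), int(fit_range[1])
    d_sel = delta[lo:hi]
    F_sel = F[lo:hi]
    mask = (d_sel > 0) & (F_sel > 0)
    d_sel, F_sel = d_sel[mask], F_sel[mask]
    if len(d_sel) < 5:
        raise InsufficientDataError(
            f"only {len(d_sel)} positive (delta, F) points; at least 5 required"
        )

    log_d = np.log(d_sel)
    log_F = np.log(F_sel)
    x0, _ = np.polyfit(log_d, log_F, 1)
    x0 = float(np.clip(x0, *x_bounds))

    # Profile out A; scale delta to its geometric mean so delta^x stays
    # well-conditioned for large exponents.
    d_scale = float(np.exp(log_d.mean()))
    d_n = d_sel / d_scale

    def sse(x: float) -> float:
        basis = d_n**x
        a = float(basis @ F_sel) / float(basis @ basis)
        return float(np.sum((F_sel - a * basis) ** 2))

    lo_x = max(x_bounds[0], x0 - 2.0)
    hi_x = min(x_bounds[1], x0 + 2.0)
    res = minimize_scalar(sse, bounds=(lo_x, hi_x), method="bounded",
                          options={"xatol": 1e-5})
    x_hat = float(res.x)
    basis = d_n**x_hat
    a_n = float(basis @ F_sel) / float(basis @ basis)
    A_hat = a_n / d_scale**x_hat
    r2 = _r_squared(F_sel, a_n * basis)
    return EFit(
        E=float("nan"),
        model="power_law",
        r2=r2,
        fit_range=(lo, hi),
        x=x_hat,
        A=A_hat,
        converged=bool(res.success),
        message="" if res.success else str(res.message),
    )
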