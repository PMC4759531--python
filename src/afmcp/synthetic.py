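"""Ground-truthed synthetic force-curve generator.

Emulates the experimental regime the detection strategies are meant for:
triangular 5-um piezo ramps at 2048 samples per approach, a soft 0.03 N/m
cantilever with a 35-degree conical tip, incompressible (nu = 0.5) samples
of constant true modulus (~0.1-10 kPa) whose local thickness is graded
over 2-8 um, and Gaussian deflection noise.  Each curve carries its exact
contact-point index, modulus and thickness, so every downstream stage can
be tested against ground truth without instrument data.

The contact part is generated by solving the *implicit force balance* at
every piezo position: the cantilever deflection d satisfies

    k*d = F_becc(delta),   delta = (Z - Z_cp) - d,

rather than the small-deflection shortcut delta ~ Z - Z_cp.  At kPa-scale
moduli probed with a 0.03 N/m lever the deflection is a non-negligible
fraction of the travel, and the shortcut would bias the ground truth.  The
balance has a unique root because the thin-film force is strictly
increasing in indentation.

What this generator deliberately omits: adhesion snap-in, viscoelastic
approach/withdraw hysteresis (an optional stiffening factor can inject a
controlled elastic asymmetry instead), baseline drift (optional, off) and
heterogeneous stiffness fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_models import becc_correction, sneddon_force
from .curves import ForceCurve
from .errors import GenerationError

#: Indentation is capped at this fraction of the local thickness so the
#: generated contact stays inside the thin-film model's validity.
MAX_INDENTATION_FRACTION = 0.8

#: Residual tolerance (nN) of the implicit force balance.
FORCE_BALANCE_TOL = 1e-6


@dataclass(frozen=True)
class SampleProfile:
    """Experimental regime emulated by the generator.

    Defaults reproduce the thin-gel study conditions: 5-um ramps, 0.03 N/m
    lever, 35-degree half-angle cone, nu = 0.5, thickness graded 2-8 um,
    1 nm deflection noise, 2048 samples per approach, and a true contact
    point falling in the 30-60 % stretch of the ramp (thin spots push it
    later so the indentation cap can be honoured).
    """

    E_true: float = 10.0  # kPa
    h_range: tuple[float, float] = (2000.0, 8000.0)  # nm
    noise_sd: float = 1.0  # nm
    k: float = 0.03  # N/m
    theta: float = 35.0  # deg
    nu: float = 0.5
    ramp_size: float = 5000.0  # nm
    n_points: int = 2048
    cp_position_range: tuple[float, float] = (0.3, 0.6)  # fraction of ramp

    def __post_init__(self) -> None:
        if not self.E_true > 0:
            raise ValueError("E_true must be positive")
        lo, hi = self.h_range
        if not 0 < lo < hi:
            raise ValueError("h_range must satisfy 0 < low < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points < 64:
            raise ValueError("n_points must be at least 64")
        flo, fhi = self.cp_position_range
        if not 0 <= flo <= fhi < 1:
            raise ValueError("cp_position_range must satisfy 0 <= low <= high < 1")


@dataclass(frozen=True)
class GroundTruth:
    """Per-curve generation record."""

    cp_index: int  # approach index of true contact
    Z_cp: float  # nm
    E_true: float  # kPa
    h_true: float  # nm
    noise_sd: float  # nm
    seed: int


def _becc_force_raw(delta: np.ndarray, E: float, theta: float, nu: float,
                    h: float) -> np.ndarray:
    tan_t = math.tan(math.radians(theta))
    return sneddon_force(delta, E, theta, nu) * becc_correction(delta * tan_t / h)


def _becc_force_deriv(delta: np.ndarray, E: float, theta: float, nu: float,
                      h: float) -> np.ndarray:
    """dF/ddelta of the thin-film force (nN/nm)."""
    tan_t = math.tan(math.radians(theta))
    pref = (2.0 / math.pi) * (E / (1.0 - nu**2)) * tan_t * 1e-6
    from .contact_models import BECC_B1, BECC_B2

    chi = delta * tan_t / h
    b = 1.0 + BECC_B1 * chi + BECC_B2 * chi**2
    db = (BECC_B1 + 2.0 * BECC_B2 * chi) * tan_t / h
    return pref * (2.0 * delta * b + delta**2 * db)


def _solve_contact_deflection(travel: np.ndarray, E: float, k: float,
                              theta: float, nu: float, h: float) -> np.ndarray:
    """Solve k*d = F(travel - d) for each travel value past contact.

    g(d) = k*d - F(travel - d) is strictly increasing and concave in d, so
    Newton iteration from d = 0 converges monotonically from below; the
    residual of every sample is checked against ``FORCE_BALANCE_TOL``.
    """
    d = np.zeros_like(travel)
    for _ in range(60):
        delta = travel - d
        g = k * d - _becc_force_raw(delta, E, theta, nu, h)
        gp = k + _becc_force_deriv(delta, E, theta, nu, h)
        step = g / gp
        d = d - step
        if np.max(np.abs(step)) < 1e-12:
            break
    d = np.clip(d, 0.0, travel)
    resid = np.abs(k * d - _becc_force_raw(travel - d, E, theta, nu, h))
    if resid.size and resid.max() > FORCE_BALANCE_TOL:
        raise GenerationError(
            f"force balance residual {resid.max():.3g} nN exceeds tolerance"
        )
    return d


def generate_curve(
    profile: SampleProfile,
    seed: int,
    h_true: float | None = None,
    withdraw_stiffening: float = 1.0,
    baseline_slope: float = 0.0,
) -> tuple[ForceCurve, GroundTruth]:
    """Generate one triangular approach-withdraw ramp with ground truth.

    The approach samples Z uniformly over the ramp; the true CP index is
    drawn inside ``cp_position_range`` and then pushed later if needed so
    the final indentation stays below ``MAX_INDENTATION_FRACTION`` of the
    thickness.  Beyond the CP the noiseless deflection solves the implicit
    force balance; before it the deflection is flat (plus an optional
    linear baseline drift, off by default, which leaves the ground truth
    unchanged).  The withdraw retraces the approach elastically, times an
    optional modulus stiffening factor for controlled hysteresis studies.
    i.i.d. Gaussian noise of sd ``noise_sd`` is added to the whole
    deflection record, and the glass reference is placed consistently with
    the thickness: Z_glass = Z_cp + h.

    Same profile and seed give bit-identical curves.
    """
    rng = np.random.default_rng(seed)
    if h_true is None:
        h_true = float(rng.uniform(*profile.h_range))
    u = float(rng.uniform(*profile.cp_position_range))

    n = profile.n_points
    Z = np.linspace(0.0, profile.ramp_size, n)
    dz = Z[1] - Z[0]

    # indentation cap -> earliest admissible contact position
    delta_max = MAX_INDENTATION_FRACTION * h_true
    travel_max = delta_max + _becc_force_raw(
        np.asarray(delta_max), profile.E_true, profile.theta, profile.nu, h_true
    ) / profile.k
    z_cp_min = profile.ramp_size - float(travel_max)
    cp_index = int(round(u * (n - 1)))
    cp_index = max(cp_index, int(math.ceil(z_cp_min / dz)))
    if cp_index >= n - 8:
        raise GenerationError(
            "contact point pushed past the ramp end; thickness too small for "
            "this ramp"
        )
    Z_cp = float(Z[cp_index])

    d = np.zeros(n)
    travel = Z[cp_index + 1 :] - Z_cp
    d[cp_index + 1 :] = _solve_contact_deflection(
        travel, profile.E_true, profile.k, profile.theta, profile.nu, h_true
    )
    if baseline_slope != 0.0:
        d = d + baseline_slope * (Z - Z_cp) * (Z <= Z_cp)

    if withdraw_stiffening == 1.0:
        d_withdraw = d[-2::-1].copy()
    else:
        d_w = np.zeros(n)
        d_w[cp_index + 1 :] = _solve_contact_deflection(
            travel,
            profile.E_true * withdraw_stiffening,
            profile.k,
            profile.theta,
            profile.nu,
            h_true,
        )
        d_withdraw = d_w[-2::-1]

    Z_full = np.concatenate([Z, Z[-2::-1]])
    d_full = np.concatenate([d, d_withdraw])
    if profile.noise_sd > 0:
        d_full = d_full + rng.normal(0.0, profile.noise_sd, size=len(d_full))

    curve = ForceCurve(
        Z=Z_full,
        d=d_full,
        k=profile.k,
        theta=profile.theta,
        nu=profile.nu,
        Z_glass=Z_cp + h_true,
        label=f"synthetic-{seed}",
    )
    truth = GroundTruth(
        cp_index=cp_index,
        Z_cp=Z_cp,
        E_true=profile.E_true,
        h_true=h_true,
        noise_sd=profile.noise_sd,
        seed=int(seed),
    )
    return curve, truth


def generate_dataset(
    profile: SampleProfile,
    n_curves: int,
    seed: int,
    **curve_kwargs,
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Generate a batch of curves with a tidy ground-truth table.

    Thicknesses are drawn uniformly from the profile's ``h_range`` and
    per-curve seeds derive deterministically from the master seed, so
    distinct master seeds give disjoint noise realizations while one seed
    reproduces the batch exactly.
    """
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_curves)
    h_values = rng.uniform(*profile.h_range, size=n_curves)
    curves: list[ForceCurve] = []
    records = []
    for i in range(n_curves):
        curve, truth = generate_curve(
            profile, int(child_seeds[i]), h_true=float(h_values[i]), **curve_kwargs
        )
        curves.append(curve)
        records.append(
            {
                "label": curve.label,
                "cp_index": truth.cp_index,
                "Z_cp": truth.Z_cp,
                "E_true": truth.E_true,
                "h_true": truth.h_true,
                "noise_sd": truth.noise_sd,
                "seed": truth.seed,
            }
        )
    return curves, pd.DataFrame(records)


def write_dataset(curves: list[ForceCurve], truth: pd.DataFrame, directory) -> None:
    """Write a batch in the curve-file dialect plus a truth TSV."""
    from pathlib import Path

    from .curves import write_curve

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, curve in enumerate(curves):
        write_curve(curve, directory / f"curve_{i:04d}.tsv")
    truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
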