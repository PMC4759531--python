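"""Batch orchestration: per-curve analysis, summaries and strategy ranking.

`analyze_curve` chains the stages for one curve - CP detection on the
approach, thickness from the glass reference, modulus fit over the contact
region - and optionally fits the withdraw segment (reusing the approach CP;
no withdraw CP procedure is defined) and a depth-dependent modulus pair
obtained by splitting the N contact points at N/2.  `analyze_batch` maps
this over a directory or list of curves, never letting one bad curve kill
the run, and `rank_strategies_on_batch` produces the ranking table that
compares strategies by their modulus distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assessment
from .contact_models import EFit, fit_modulus
from .cp_detect import CPResult, StrategySpec, find_cp
from .curves import ForceCurve, read_curve, sample_height, split_approach_withdraw
from .errors import AfmcpError, HeightUnavailableError, UndefinedMetricError
from .assessment import AssessmentMetrics

logger = logging.getLogger("afmcp")

#: Cell-mode indentation ceiling (nm) avoiding non-linear elasticity.
CELL_MAX_INDENTATION = 600.0


@dataclass(frozen=True)
class FitConfig:
    """Modulus-fit configuration.

    ``mode="gel"`` fits the whole contact region; ``mode="cell"`` restricts
    the fit to indentations below ``max_indentation`` (600 nm by default).
    ``h`` supplies the thickness when no glass reference exists (e.g.
    measured optically); ignored for the Sneddon model.
    """

    model: str = "becc"  # "becc" | "sneddon"
    mode: str = "gel"  # "gel" | "cell"
    max_indentation: float = CELL_MAX_INDENTATION  # nm, cell mode only
    h: float | None = None
    fit_withdraw: bool = False
    depth_split: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("becc", "sneddon"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.mode not in ("gel", "cell"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CurveAnalysis:
    """Full analysis record for one curve."""

    label: str
    cp: CPResult | None
    h: float  # nm (NaN when unavailable)
    E_approach: EFit | None
    E_withdraw: EFit | None = None
    E_low: EFit | None = None
    E_high: EFit | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return self.cp is None or self.E_approach is None


def _contact_data(curve: ForceCurve, cp_index: int, start: int, stop: int):
    """Force-indentation transform of points start..stop re-zeroed at the CP."""
    z0 = curve.Z[cp_index]
    d0 = curve.d[cp_index]
    Z = curve.Z[start:stop]
    d = curve.d[start:stop]
    delta = (Z - z0) - (d - d0)
    F = curve.k * (d - d0)
    return delta, F


def _fit_segment(curve: ForceCurve, delta, F, config: FitConfig, h: float,
                 fit_range=None) -> EFit:
    return fit_modulus(
        delta,
        F,
        model=config.model,
        theta=curve.theta,
        nu=curve.nu,
        h=h if config.model == "becc" else None,
        fit_range=fit_range,
    )


def analyze_curve(
    curve: ForceCurve, spec: StrategySpec, config: FitConfig = FitConfig()
) -> CurveAnalysis:
    """Detect the CP and fit the modulus for one curve.

    The thickness used by the BECC fit comes from the glass reference at
    the detected CP, falling back to ``config.h``.  In cell mode the fit
    stops at the first sample whose indentation exceeds the ceiling.  A
    failed detection returns a flagged record rather than raising, so
    batches keep going.
    """
    try:
        cp = find_cp(curve, spec)
    except AfmcpError as exc:
        logger.warning("%s: CP detection failed: %s", curve.label, exc)
        return CurveAnalysis(
            label=curve.label, cp=None, h=float("nan"), E_approach=None,
            flags=[f"detection_failed: {exc}"],
        )

    flags = list(cp.flags)
    if config.model == "becc":
        try:
            h = sample_height(cp.Z_cp, curve.Z_glass)
        except HeightUnavailableError:
            if config.h is None:
                flags.append("no_thickness")
                return CurveAnalysis(
                    label=curve.label, cp=cp, h=float("nan"), E_approach=None,
                    flags=flags,
                )
            h = config.h
    else:
        h = float("nan")

    approach, withdraw = split_approach_withdraw(curve)
    delta, F = _contact_data(curve, cp.cp_index, cp.cp_index, approach.stop)
    fit_stop = len(delta)
    if config.mode == "cell":
        over = np.nonzero(delta > config.max_indentation)[0]
        if over.size:
            fit_stop = int(over[0])

    analysis = CurveAnalysis(label=curve.label, cp=cp, h=h, E_approach=None,
                             flags=flags)
    try:
        analysis.E_approach = _fit_segment(curve, delta, F, config, h,
                                           fit_range=(0, fit_stop))
    except AfmcpError as exc:
        logger.warning("%s: modulus fit failed: %s", curve.label, exc)
        analysis.flags.append(f"fit_failed: {exc}")
        return analysis

    if config.fit_withdraw and len(withdraw) >= 5:
        z0, d0 = cp.Z_cp, cp.d_cp
        Zw = curve.Z[withdraw.start : withdraw.stop]
        dw = curve.d[withdraw.start : withdraw.stop]
        delta_w = (Zw - z0) - (dw - d0)
        F_w = curve.k * (dw - d0)
        if config.mode == "cell":
            out = delta_w > config.max_indentation
            delta_w, F_w = delta_w[~out], F_w[~out]
        try:
            analysis.E_withdraw = _fit_segment(curve, delta_w, F_w, config, h)
        except AfmcpError as exc:
            analysis.flags.append(f"withdraw_fit_failed: {exc}")

    if config.depth_split:
        n_c = fit_stop
        half = n_c // 2
        try:
            analysis.E_low = _fit_segment(curve, delta, F, config, h,
                                          fit_range=(0, half))
            analysis.E_high = _fit_segment(curve, delta, F, config, h,
                                           fit_range=(half, n_c))
        except AfmcpError as exc:
            analysis.flags.append(f"depth_split_failed: {exc}")

    return analysis


def _analysis_row(a: CurveAnalysis) -> dict:
    return {
        "label": a.label,
        "cp_index": a.cp.cp_index if a.cp else -1,
        "Z_cp": a.cp.Z_cp if a.cp else float("nan"),
        "h": a.h,
        "E": a.E_approach.E if a.E_approach else float("nan"),
        "r2": a.E_approach.r2 if a.E_approach else float("nan"),
        "E_withdraw": a.E_withdraw.E if a.E_withdraw else float("nan"),
        "E_low": a.E_low.E if a.E_low else float("nan"),
        "E_high": a.E_high.E if a.E_high else float("nan"),
        "n_peaks": a.cp.n_peaks if a.cp else 0,
        "flags": ";".join(a.flags),
    }


def load_batch(directory, config_file: str = "batch.yaml") -> list[ForceCurve]:
    """Read every curve file in a directory, with optional shared metadata.

    A YAML sidecar (``batch.yaml``) may supply metadata shared by all
    curves; per-file headers win.  Unreadable files are skipped with a
    logged reason.
    """
    import yaml

    directory = Path(directory)
    shared: dict = {}
    cfg = directory / config_file
    if cfg.exists():
        shared = yaml.safe_load(cfg.read_text()) or {}
    curves = []
    for path in sorted(directory.glob("*.tsv")) + sorted(directory.glob("*.csv")):
        if path.name == "truth.tsv":
            continue
        try:
            curves.append(read_curve(path, metadata=shared or None))
        except AfmcpError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
    return curves


def analyze_batch(
    batch: list[ForceCurve] | str | Path,
    spec: StrategySpec,
    config: FitConfig = FitConfig(),
    sr_range: tuple[float, float] = (0.3, 60.0),
) -> tuple[pd.DataFrame, AssessmentMetrics | None]:
    """Analyze a curve collection with one strategy.

    Returns the per-curve results table (deterministic order: input order
    for lists, sorted filenames for directories) and the strategy's
    assessment metrics, with failed curves as NaN rows counted against the
    success rate.  Metrics are ``None`` when the collection is too small
    for the moment estimators (< 3 valid curves).
    """
    if not isinstance(batch, list):
        batch = load_batch(batch)
    if not batch:
        raise AfmcpError("no readable curves in batch")
    rows = []
    for curve in batch:
        analysis = analyze_curve(curve, spec, config)
        rows.append(_analysis_row(analysis))
        logger.info("%s: E=%.4g kPa%s", analysis.label,
                    rows[-1]["E"], " [FAILED]" if analysis.failed else "")
    table = pd.DataFrame(rows)
    if not np.isfinite(table["E"]).any():
        raise AfmcpError("every curve in the batch failed analysis")
    try:
        metrics = assessment.compute_metrics(table["E"], table["h"], sr_range)
    except UndefinedMetricError as exc:
        logger.warning("summary metrics unavailable: %s", exc)
        metrics = None
    return table, metrics


def rank_strategies_on_batch(
    batch: list[ForceCurve] | str | Path,
    specs: dict[str, StrategySpec],
    config: FitConfig = FitConfig(),
    sr_range: tuple[float, float] = (0.3, 60.0),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run several strategies over one batch and rank them by M.

    Returns the ranking table (ascending M) and the per-strategy result
    tables.
    """
    if not isinstance(batch, list):
        batch = load_batch(batch)
    metrics: dict[str, AssessmentMetrics] = {}
    tables: dict[str, pd.DataFrame] = {}
    for name, spec in specs.items():
        table, m = analyze_batch(batch, spec, config, sr_range)
        if m is None:
            raise AfmcpError("batch too small to rank strategies (< 3 valid curves)")
        metrics[name] = m
        tables[name] = table
    return assessment.rank_strategies(metrics), tables


def compare_approach_withdraw(results: pd.DataFrame) -> dict:
    """Per-curve withdraw/approach modulus ratios and their median.

    On purely elastic data the median ratio is 1 within noise; a genuine
    viscoelastic sample (or an injected stiffening factor) shifts it.
    Returns an empty summary with a warning when no withdraw fits exist.
    """
    if "E_withdraw" not in results or not np.isfinite(results["E_withdraw"]).any():
        logger.warning("no withdraw fits in results table")
        return {"ratios": np.array([]), "median": float("nan"), "n": 0}
    valid = np.isfinite(results["E_withdraw"]) & np.isfinite(results["E"])
    ratios = (results.loc[valid, "E_withdraw"] / results.loc[valid, "E"]).to_numpy()
    return {"ratios": ratios, "median": float(np.median(ratios)), "n": int(valid.sum())}
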