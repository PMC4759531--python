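"""Force-displacement curve container, file I/O and coordinate transforms.

A force curve is the raw record of one approach-withdraw ramp of the AFM
piezo: piezo displacement ``Z`` and cantilever deflection ``d``, both in nm,
plus the acquisition metadata needed to turn them into force-indentation
data (spring constant ``k`` in N/m, tip half-opening angle ``theta`` in
degrees, Poisson ratio ``nu``, and optionally the piezo position of contact
on bare glass ``Z_glass`` used as the zero-height reference).

Orientation convention
----------------------
Internally the approach segment always has ``Z`` increasing toward the
sample, so "later index" means "closer to / deeper into the sample".  Files
recorded with a decreasing-Z approach are flipped (sign inverted) on read;
all indices are reported in this normalized frame.

Canonical units are nm for lengths, nN for force, kPa for moduli and N/m
for the spring constant (1 N/m x 1 nm = 1 nN).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateSegmentError,
    FormatError,
    HeightUnavailableError,
    MetadataError,
    ParseError,
)

MIN_CURVE_LENGTH = 16
MIN_APPROACH_LENGTH = 16

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


@dataclass
class ForceCurve:
    """One recorded force-displacement ramp with acquisition metadata.

    Parameters
    ----------
    Z : ndarray
        Piezo displacement samples (nm), normalized so the approach
        increases toward the sample.
    d : ndarray
        Cantilever deflection samples (nm), same length as ``Z``.
    k : float
        Cantilever spring constant (N/m).
    theta : float
        Tip half-opening angle (degrees), in (0, 90).
    nu : float
        Poisson ratio of the sample, in [0, 0.5].
    Z_glass : float or None
        Piezo position of contact on bare glass (nm), used to compute the
        local sample height. ``None`` when not recorded.
    label : str
        Free-text curve identifier.
    """

    Z: np.ndarray
    d: np.ndarray
    k: float
    theta: float
    nu: float = 0.5
    Z_glass: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.Z.ndim != 1 or self.d.ndim != 1:
            raise FormatError("Z and d must be one-dimensional arrays")
        if len(self.Z) != len(self.d):
            raise FormatError(
                f"Z and d lengths differ ({len(self.Z)} vs {len(self.d)})"
            )
        if len(self.Z) < MIN_CURVE_LENGTH:
            raise FormatError(
                f"curve has {len(self.Z)} samples; at least "
                f"{MIN_CURVE_LENGTH} required"
            )
        if not self.k > 0:
            raise MetadataError(f"spring constant must be positive, got {self.k}")
        if not 0 < self.theta < 90:
            raise MetadataError(
                f"tip half-angle must lie in (0, 90) degrees, got {self.theta}"
            )
        if not 0 <= self.nu <= 0.5:
            raise MetadataError(f"Poisson ratio must lie in [0, 0.5], got {self.nu}")

    def __len__(self) -> int:
        return len(self.Z)

    @property
    def force(self) -> np.ndarray:
        """Cantilever force F = k*d (nN) for every sample."""
        return deflection_to_force(self.d, self.k)


@dataclass(frozen=True)
class CurveSegment:
    """A contiguous index range of a :class:`ForceCurve`.

    ``start`` is inclusive, ``stop`` exclusive (half-open, like slices).
    For the approach segment, index 0 of the parent curve is the point
    furthest from the sample surface.
    """

    start: int
    stop: int
    direction: str  # "approach" | "withdraw"

    def __post_init__(self) -> None:
        if self.direction not in ("approach", "withdraw"):
            raise ValueError(f"unknown segment direction {self.direction!r}")
        if self.stop < self.start:
            raise ValueError("segment stop precedes start")

    def __len__(self) -> int:
        return self.stop - self.start

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


def deflection_to_force(d: np.ndarray | float, k: float) -> np.ndarray | float:
    """Hooke's law: F = k * d, with 1 N/m x 1 nm = 1 nN."""
    if not k > 0:
        raise MetadataError(f"spring constant must be positive, got {k}")
    return k * np.asarray(d, dtype=float) if np.ndim(d) else k * float(d)


def split_approach_withdraw(curve: ForceCurve) -> tuple[CurveSegment, CurveSegment]:
    """Split a ramp at the point of closest approach (global maximum of Z).

    The approach segment runs up to and including the apex; the withdraw
    segment is the remainder (possibly empty).  Apex ties resolve to the
    earliest index so the split is deterministic.

    Raises
    ------
    DegenerateSegmentError
        If fewer than 16 approach samples exist.
    """
    apex = int(np.argmax(curve.Z))  # np.argmax returns the first maximum
    approach = CurveSegment(0, apex + 1, "approach")
    withdraw = CurveSegment(apex + 1, len(curve), "withdraw")
    if len(approach) < MIN_APPROACH_LENGTH:
        raise DegenerateSegmentError(
            f"approach segment has {len(approach)} samples; "
            f"at least {MIN_APPROACH_LENGTH} required"
        )
    return approach, withdraw


def indentation(curve: ForceCurve, cp_index: int) -> np.ndarray:
    """Sample indentation for the approach points at/after contact.

    With the contact point at index ``cp_index`` of the (normalized)
    approach segment, the indentation of every later approach sample j is

        delta_j = (Z_j - Z_cp) - (d_j - d_cp)

    i.e. piezo travel past contact minus the extra cantilever bending; by
    construction delta = 0 exactly at the contact point.

    Returns the indentation array for indices ``cp_index .. apex``.
    """
    approach, _ = split_approach_withdraw(curve)
    if not approach.start <= cp_index < approach.stop:
        raise IndexError(
            f"cp_index {cp_index} outside approach segment "
            f"[{approach.start}, {approach.stop})"
        )
    Z = curve.Z[cp_index : approach.stop]
    d = curve.d[cp_index : approach.stop]
    return (Z - Z[0]) - (d - d[0])


def sample_height(Z_cp: float, Z_glass: float | None) -> float:
    """Local sample height h = |Z_cp - Z_glass| (nm).

    In the normalized orientation the tip travels h further before touching
    bare glass than before touching the sample surface, so the (absolute)
    difference of the two contact positions is the local thickness.

    Raises
    ------
    HeightUnavailableError
        If no glass reference is available; the caller may supply a
        thickness measured by other means (e.g. optically for thick gels).
    """
    if Z_glass is None:
        raise HeightUnavailableError(
            "no glass reference position; supply the sample height directly"
        )
    return abs(float(Z_cp) - float(Z_glass))


# ---------------------------------------------------------------------------
# File I/O
#
# Dialect: two numeric columns "Z" and "d" (nm), tab- or comma-separated,
# preceded by "#"-prefixed metadata lines of the form "# key = value".
# ---------------------------------------------------------------------------

_METADATA_FLOAT_KEYS = ("k", "theta", "nu", "Z_glass")


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in _DIALECT_SEP:
            raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
        return dialect
    return "csv" if path.suffix.lower() == ".csv" else "tsv"


def read_curve(
    path: str | Path,
    dialect: str | None = None,
    metadata: dict | None = None,
) -> ForceCurve:
    """Read a force curve from a TSV/CSV file.

    Metadata comes from "#"-prefixed header lines (``# k = 0.03``) and may
    be overridden/supplemented by the ``metadata`` mapping (used for batch
    directories with one shared sidecar config).  Curves recorded with a
    decreasing-Z approach are flipped to the normalized orientation.

    Raises
    ------
    FormatError / ParseError / MetadataError
        On missing columns, non-numeric rows (with line number) and missing
        required metadata respectively.
    """
    path = Path(path)
    sep = _DIALECT_SEP[_infer_dialect(path, dialect)]

    meta: dict = {}
    header_names: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                elif ":" in body:
                    key, _, value = body.partition(":")
                else:
                    continue
                meta[key.strip()] = value.strip()
                continue
            fields = [f.strip() for f in line.split(sep)]
            if header_names is None:
                header_names = fields
                continue
            try:
                rows.append([float(f) for f in fields])
            except ValueError:
                raise ParseError(
                    f"{path.name}: non-numeric value on line {lineno}: {line!r}"
                ) from None

    if header_names is None:
        raise FormatError(f"{path.name}: no column header found")
    for col in ("Z", "d"):
        if col not in header_names:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    if any(len(r) != len(header_names) for r in rows):
        raise FormatError(f"{path.name}: ragged rows do not match header")

    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise FormatError(f"{path.name}: no data rows")
    Z = data[:, header_names.index("Z")]
    d = data[:, header_names.index("d")]

    if metadata:
        meta.update({k: v for k, v in metadata.items() if v is not None})

    kwargs: dict = {"label": str(meta.get("label", path.stem))}
    for key in _METADATA_FLOAT_KEYS:
        if key in meta and meta[key] not in ("", "None"):
            kwargs[key] = float(meta[key])
    for required in ("k", "theta"):
        if required not in kwargs:
            raise MetadataError(f"{path.name}: missing metadata {required!r}")

    curve = ForceCurve(Z=Z, d=d, **kwargs)
    return normalize_orientation(curve)


def normalize_orientation(curve: ForceCurve) -> ForceCurve:
    """Return a curve whose approach has Z increasing toward the sample.

    The initial (approach) segment ends at the sample turnaround, i.e. the
    extremum of Z furthest from the starting value; if Z decreases toward
    it, the sign of Z (and of the glass reference) is inverted.  Sign
    inversion is a rigid transform: all differences, and therefore forces,
    indentations and heights, are unchanged.
    """
    turnaround = int(np.argmax(np.abs(curve.Z - curve.Z[0])))
    if curve.Z[turnaround] >= curve.Z[0]:
        return curve
    return replace(
        curve,
        Z=-curve.Z,
        Z_glass=None if curve.Z_glass is None else -curve.Z_glass,
    )


def write_curve(curve: ForceCurve, path: str | Path, dialect: str | None = None) -> None:
    """Write a curve in the package dialect, lossless for finite values."""
    path = Path(path)
    sep = _DIALECT_SEP[_infer_dialect(path, dialect)]
    lines = [
        f"# k = {curve.k!r}",
        f"# theta = {curve.theta!r}",
        f"# nu = {curve.nu!r}",
    ]
    if curve.Z_glass is not None:
        lines.append(f"# Z_glass = {curve.Z_glass!r}")
    if curve.label:
        lines.append(f"# label = {curve.label}")
    lines.append(sep.join(("Z", "d")))
    for z, dd in zip(curve.Z, curve.d):
        lines.append(sep.join((f"{z:.17g}", f"{dd:.17g}")))
    path.write_text("\n".join(lines) + "\n")
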