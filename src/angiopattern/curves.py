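"""Virtual pullback curves and per-vessel records.

A *virtual pullback* is the angiography-derived pressure-ratio surrogate
(μFR) plotted against distance from the vessel ostium, mimicking a
motorized pressure-wire pullback.  Curves live on a uniform along-vessel
grid (default spacing 0.35 mm) together with optional co-registered
lumen-diameter traces from quantitative coronary analysis (QCA): the
minimal lumen diameter (MLD) and the reference vessel diameter (RVD).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

DEFAULT_SPACING_MM = 0.35

#: the four physiological disease patterns
PATTERNS = ("focal", "diffuse", "mixed", "serial")

_SPACING_RTOL = 1e-6


class InvalidCurveError(ValueError):
    """Raised when raw input cannot form a valid pullback curve."""


@dataclass(frozen=True)
class PullbackCurve:
    """μFR (and optional diameter) values on a uniform along-vessel grid.

    Parameters
    ----------
    positions
        Distance from the ostium in mm, strictly increasing with constant
        spacing.  0-based at the proximal analysis start.
    mufr
        Unitless pressure-ratio values in [0, 1], one per position.
    mld, rvd
        Optional minimal lumen diameter and reference vessel diameter in
        mm (strictly positive where present).
    """

    positions: np.ndarray
    mufr: np.ndarray
    mld: Optional[np.ndarray] = None
    rvd: Optional[np.ndarray] = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        mufr = np.asarray(self.mufr, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "mufr", mufr)
        if pos.ndim != 1 or pos.size < 2:
            raise InvalidCurveError("need at least 2 grid points")
        if mufr.shape != pos.shape:
            raise InvalidCurveError("mufr and positions differ in length")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise InvalidCurveError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_SPACING_RTOL, atol=1e-9):
            raise InvalidCurveError("positions must be uniformly spaced")
        if np.any(mufr < -1e-12) or np.any(mufr > 1 + 1e-12):
            raise InvalidCurveError("mufr values must lie in [0, 1]")
        for name in ("mld", "rvd"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                object.__setattr__(self, name, arr)
                if arr.shape != pos.shape:
                    raise InvalidCurveError(f"{name} and positions differ in length")
                if np.any(arr <= 0):
                    raise InvalidCurveError(f"{name} values must be > 0")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def total_length(self) -> float:
        """Total interrogated vessel length in mm."""
        return float(self.positions[-1] - self.positions[0])

    @property
    def n_points(self) -> int:
        return int(self.positions.size)

    def with_mufr(self, mufr: np.ndarray) -> "PullbackCurve":
        return replace(self, mufr=np.asarray(mufr, dtype=float))


@dataclass(frozen=True)
class VesselRecord:
    """A vessel's pullback curve plus the scalar descriptors used downstream."""

    vessel_id: str
    patient_id: str
    curve: PullbackCurve
    distal_mufr: float
    reference_diameter: float
    label: Optional[str] = None

    def __post_init__(self):
        if abs(self.distal_mufr - float(self.curve.mufr[-1])) > 1e-9:
            raise ValueError(
                "distal_mufr must equal the last value of the μFR curve"
            )
        if self.label is not None and self.label not in PATTERNS:
            raise ValueError(f"label must be one of {PATTERNS}, got {self.label!r}")


def _interp_to_grid(raw_positions, raw_values, spacing):
    pos = np.asarray(raw_positions, dtype=float)
    vals = np.asarray(raw_values, dtype=float)
    if pos.size < 2 or vals.size != pos.size:
        raise InvalidCurveError("need at least 2 (position, value) pairs")
    if np.any(np.diff(pos) <= 0):
        raise InvalidCurveError("raw positions must be strictly increasing")
    if spacing <= 0:
        raise InvalidCurveError("spacing must be > 0")
    n = int(np.floor((pos[-1] - pos[0]) / spacing + 1e-9)) + 1
    grid = pos[0] + spacing * np.arange(n)
    return grid, np.interp(grid, pos, vals)


def resample_curve(raw_positions, raw_values, spacing: float = DEFAULT_SPACING_MM) -> PullbackCurve:
    """Linearly interpolate a raw μFR trace onto a uniform grid.

    The grid starts at the first raw position and extends in steps of
    ``spacing`` as far as the last raw position allows; raw samples that
    already sit on the grid are reproduced exactly.
    """
    grid, vals = _interp_to_grid(raw_positions, raw_values, spacing)
    return PullbackCurve(positions=grid, mufr=np.clip(vals, 0.0, 1.0))


def monotonize(curve: PullbackCurve) -> PullbackCurve:
    """Non-increasing least-squares projection of the μFR trace.

    Pressure ratios cannot physiologically recover along a pullback, so
    small upward wobbles are measurement noise.  The pool-adjacent-violators
    projection removes them before any drop or gradient is measured; it is
    idempotent and preserves monotone inputs exactly.
    """
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    fitted = iso.fit_transform(curve.positions, curve.mufr)
    return curve.with_mufr(fitted)


def read_curves_csv(path) -> dict[str, PullbackCurve]:
    """Read curves from long-format CSV (vessel_id,position_mm,mufr,mld,rvd)."""
    df = pd.read_csv(path)
    required = {"vessel_id", "position_mm", "mufr"}
    if not required.issubset(df.columns):
        raise InvalidCurveError(f"curve CSV must have columns {sorted(required)}")
    out = {}
    for vid, grp in df.groupby("vessel_id", sort=False):
        grp = grp.sort_values("position_mm")
        kwargs = {}
        for col in ("mld", "rvd"):
            if col in grp.columns and grp[col].notna().all():
                kwargs[col] = grp[col].to_numpy(float)
        out[str(vid)] = PullbackCurve(
            positions=grp["position_mm"].to_numpy(float),
            mufr=grp["mufr"].to_numpy(float),
            **kwargs,
        )
    return out


def write_curves_csv(curves: dict[str, PullbackCurve], path) -> None:
    """Write curves to the long-format CSV dialect read by :func:`read_curves_csv`."""
    frames = []
    for vid, c in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "vessel_id": vid,
                    "position_mm": c.positions,
                    "mufr": c.mufr,
                    "mld": c.mld if c.mld is not None else np.nan,
                    "rvd": c.rvd if c.rvd is not None else np.nan,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
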