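"""Sucrose-gradient sedimentation calibration and distribution transforms.

Ferritin cages sediment deeper into a 1-25% sucrose gradient the more iron
they carry, following a non-linear, saturating relationship between gradient
fraction index and Fe/ferritin ratio.  This module treats that calibration
curve as a black-box monotone mapping: it fits user-supplied (fraction,
ratio) points, generates a synthetic stand-in curve when no measured points
are available, and converts simulated iron-load distributions to
per-fraction protein profiles and back.  Both transforms conserve protein
mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .experiments import IronDistribution

__all__ = [
    "CalibrationCurve",
    "FractionProfile",
    "fit_calibration",
    "synthetic_calibration",
    "distribution_to_fractions",
    "fractions_to_distribution",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Strictly monotone mapping between gradient fraction index (1..F) and
    Fe/ferritin atom ratio.

    Between knots the curve is piecewise linear, which keeps the mapping
    exactly invertible over its range.
    """

    fraction_axis: np.ndarray
    ratio_knots: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fraction_axis", np.asarray(self.fraction_axis, dtype=int)
        )
        object.__setattr__(
            self, "ratio_knots", np.asarray(self.ratio_knots, dtype=float)
        )
        if self.fraction_axis.shape != self.ratio_knots.shape:
            raise ValueError("fraction_axis and ratio_knots must align")
        if len(self.fraction_axis) < 2:
            raise ValueError("a calibration curve needs at least two knots")
        if np.any(np.diff(self.fraction_axis) <= 0):
            raise ValueError("fraction indices must be strictly increasing")
        if np.any(np.diff(self.ratio_knots) <= 0):
            raise ValueError("ratio knots must be strictly increasing")

    @property
    def f_count(self) -> int:
        return len(self.fraction_axis)

    @property
    def min_ratio(self) -> float:
        return float(self.ratio_knots[0])

    @property
    def max_ratio(self) -> float:
        return float(self.ratio_knots[-1])

    def ratio_at(self, fraction) -> np.ndarray | float:
        """Fe/ferritin ratio at a (possibly fractional) fraction index."""
        f = np.asarray(fraction, dtype=float)
        if np.any(f < self.fraction_axis[0]) or np.any(f > self.fraction_axis[-1]):
            raise ValueError("fraction index outside the calibrated range")
        out = np.interp(f, self.fraction_axis, self.ratio_knots)
        return float(out) if np.ndim(fraction) == 0 else out

    def fraction_of(self, ratio) -> np.ndarray | float:
        """Inverse mapping: gradient position of a given Fe/ferritin ratio."""
        r = np.asarray(ratio, dtype=float)
        if np.any(r < self.min_ratio) or np.any(r > self.max_ratio):
            raise ValueError("ratio outside the calibrated range")
        out = np.interp(r, self.ratio_knots, self.fraction_axis.astype(float))
        return float(out) if np.ndim(ratio) == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fraction_axis, "ratio": self.ratio_knots}
        )


@dataclass
class FractionProfile:
    """Protein mass collected in each gradient fraction."""

    fraction_axis: np.ndarray
    protein_mass: np.ndarray

    def __post_init__(self) -> None:
        self.fraction_axis = np.asarray(self.fraction_axis, dtype=int)
        self.protein_mass = np.asarray(self.protein_mass, dtype=float)
        if self.fraction_axis.shape != self.protein_mass.shape:
            raise ValueError("fraction_axis and protein_mass must align")

    @property
    def total_mass(self) -> float:
        return float(self.protein_mass.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fraction_axis, "mass": self.protein_mass}
        )


def fit_calibration(points) -> CalibrationCurve:
    """Fit a monotone calibration curve through measured (fraction, ratio)
    points.

    Points already strictly monotone in ratio are interpolated exactly;
    otherwise an isotonic (pool-adjacent-violators) adjustment is applied and
    flat runs are broken by a negligible ramp so the curve stays invertible.
    """
    pts = [(int(f), float(r)) for f, r in points]
    if len(pts) < 3:
        raise ValueError("at least 3 calibration points are required")
    fracs = np.array([p[0] for p in pts])
    if len(np.unique(fracs)) != len(fracs):
        raise ValueError("fraction indices must be distinct")
    order = np.argsort(fracs)
    fracs = fracs[order]
    ratios = np.array([p[1] for p in pts])[order]
    if np.all(ratios == ratios[0]):
        raise ValueError("degenerate curve: all calibration ratios are equal")
    if np.any(np.diff(ratios) <= 0):
        ratios = isotonic_regression(ratios, increasing=True).x.copy()
        span = ratios[-1] - ratios[0]
        if span <= 0:
            raise ValueError(
                "degenerate curve: isotonic fit collapsed to a constant"
            )
        eps = 1e-9 * span
        for k in range(1, len(ratios)):
            if ratios[k] <= ratios[k - 1]:
                ratios[k] = ratios[k - 1] + eps
    return CalibrationCurve(fraction_axis=fracs, ratio_knots=ratios)


def synthetic_calibration(
    f_count: int = 20,
    max_ratio: float = 2500.0,
    shape: dict | None = None,
    seed: int = 0,
) -> CalibrationCurve:
    """Synthetic stand-in for a measured sedimentation calibration curve.

    Deterministic for a given seed: a saturating-exponential ratio profile
    over fractions 1..``f_count`` spanning [0, ``max_ratio``], with mild
    multiplicative jitter on the knot spacings to mimic experimental
    scatter.  ``shape`` accepts ``steepness`` (> 0, how quickly the ratio
    saturates along the gradient) and ``jitter`` (in [0, 1), relative
    spacing noise).  The default 20 fractions correspond to a 5 mL gradient
    collected in 250 uL aliquots.
    """
    if f_count < 5:
        raise ValueError("f_count must be at least 5")
    if max_ratio <= 0:
        raise ValueError("max_ratio must be positive")
    shape = dict(shape or {})
    steepness = float(shape.pop("steepness", 2.5))
    jitter = float(shape.pop("jitter", 0.08))
    if shape:
        raise ValueError(f"unknown shape parameters: {sorted(shape)}")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    if not 0 <= jitter < 1:
        raise ValueError("jitter must lie in [0, 1)")

    x = np.linspace(0.0, 1.0, f_count)
    base = (1.0 - np.exp(-steepness * x)) / (1.0 - np.exp(-steepness))
    increments = np.diff(base)
    rng = np.random.default_rng(seed)
    increments = increments * (1.0 + jitter * rng.uniform(-1.0, 1.0, len(increments)))
    ratios = np.concatenate(([0.0], np.cumsum(increments)))
    ratios *= max_ratio / ratios[-1]
    return CalibrationCurve(
        fraction_axis=np.arange(1, f_count + 1), ratio_knots=ratios
    )


def distribution_to_fractions(
    dist: IronDistribution, curve: CalibrationCurve
) -> FractionProfile:
    """Assign each load class's protein mass to the gradient fraction whose
    calibration ratio is nearest (interval bracketing with midpoint
    boundaries).  Mass is conserved exactly.
    """
    atoms = dist.load_atoms
    if np.any(atoms < curve.min_ratio) or np.any(atoms > curve.max_ratio):
        bad = atoms[(atoms < curve.min_ratio) | (atoms > curve.max_ratio)]
        raise ValueError(
            f"load classes at {bad[:5].tolist()} atoms/cage fall outside the "
            f"calibrated range [{curve.min_ratio}, {curve.max_ratio}]"
        )
    midpoints = 0.5 * (curve.ratio_knots[:-1] + curve.ratio_knots[1:])
    idx = np.searchsorted(midpoints, atoms, side="right")
    mass = np.bincount(idx, weights=dist.mass_per_load, minlength=curve.f_count)
    return FractionProfile(
        fraction_axis=curve.fraction_axis.copy(), protein_mass=mass
    )


def fractions_to_distribution(
    profile: FractionProfile, curve: CalibrationCurve
) -> IronDistribution:
    """Inverse transform: each fraction's protein mass is placed at the
    Fe/ferritin ratio of its calibration knot."""
    if len(profile.fraction_axis) != curve.f_count or np.any(
        profile.fraction_axis != curve.fraction_axis
    ):
        raise ValueError("profile fraction axis does not match the curve")
    return IronDistribution(
        load_atoms=curve.ratio_knots.copy(),
        mass_per_load=profile.protein_mass.copy(),
    )
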