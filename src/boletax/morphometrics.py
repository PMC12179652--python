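"""Spore and pileipellis morphometrics.

Implements the mycological summary conventions: the [n/m/p] bookkeeping
(n structures from m basidiomes of p collections), the
``(min of averages) average ± sd (max of averages)`` interval convention
computed over per-collection means, the length/width quotient Q, the
rotation-ellipsoid spore volume Vm = πLW²/6, and 68% isoprobability
(confidence) ellipses of the bivariate Gaussian fitted to (length, width)
pairs.

Q and Vm are computed per spore and then averaged per collection, so the
printed Vm is the mean of per-spore volumes, not π·L̄·W̄²/6 of the grand
means (Jensen's inequality makes the former at least as large).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasurementSet",
    "SummaryStats",
    "Ellipse",
    "spore_volume",
    "summarize_structure",
    "isoprobability_ellipse",
    "ellipse_from_points",
    "ellipse_coverage",
    "collection_means",
]

_EN_DASH = "–"


@dataclass
class MeasurementSet:
    """Length/width observations of one structure type.

    ``data`` columns: collection, basidiome, length_um, width_um.
    """

    structure: str
    data: pd.DataFrame

    def __post_init__(self):
        required = {"collection", "basidiome", "length_um", "width_um"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"measurement table missing columns {sorted(missing)}")
        if (self.data["length_um"] <= 0).any() or (self.data["width_um"] <= 0).any():
            raise ValueError("lengths and widths must be positive")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def m(self) -> int:
        return self.data.groupby(["collection", "basidiome"]).ngroups

    @property
    def p(self) -> int:
        return self.data["collection"].nunique()


@dataclass
class Block:
    """(min of collection means, grand mean, sd of means, max of means)."""

    min: float
    mean: float
    sd: float
    max: float

    def __iter__(self):
        return iter((self.min, self.mean, self.sd, self.max))


@dataclass
class SummaryStats:
    n: int
    m: int
    p: int
    length: Block
    width: Block
    q: Block
    vm: Block
    flags: list[str] = field(default_factory=list)


def spore_volume(length: float, width: float) -> float:
    """Rotation-ellipsoid volume πLW²/6 in μm³."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return math.pi * length * width * width / 6.0


def collection_means(ms: MeasurementSet) -> pd.DataFrame:
    """Per-collection means of length, width, Q and Vm (per-spore values
    averaged within each collection)."""
    df = ms.data.copy()
    df["q"] = df["length_um"] / df["width_um"]
    df["vm"] = np.pi * df["length_um"] * df["width_um"] ** 2 / 6.0
    return df.groupby("collection")[["length_um", "width_um", "q", "vm"]].mean()


def _block(values: np.ndarray) -> Block:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return Block(float(values.min()), mean, sd, float(values.max()))


def _fmt(block: Block, nd: int) -> str:
    f = f"{{:.{nd}f}}"
    return (
        f"({f.format(block.min)}{_EN_DASH})"
        f"{f.format(block.mean)} ± {f.format(block.sd)}"
        f"({_EN_DASH}{f.format(block.max)})"
    )


def summarize_structure(ms: MeasurementSet) -> tuple[SummaryStats, str]:
    """Summary statistics plus the formatted description line, e.g.
    ``[561/19/19] (10.3–)11.6 ± 0.6(–12.8) × (4.7–)5.0 ± 0.2(–5.5) μm,
    Q = …, Vm = … μm³``."""
    if ms.n == 0:
        raise ValueError("empty measurement set")
    cm = collection_means(ms)
    stats_ = SummaryStats(
        n=ms.n,
        m=ms.m,
        p=ms.p,
        length=_block(cm["length_um"].to_numpy()),
        width=_block(cm["width_um"].to_numpy()),
        q=_block(cm["q"].to_numpy()),
        vm=_block(cm["vm"].to_numpy()),
    )
    if ms.p == 1:
        stats_.flags.append("single_collection_sd_zero")
    text = (
        f"[{ms.n}/{ms.m}/{ms.p}] "
        f"{_fmt(stats_.length, 1)} × {_fmt(stats_.width, 1)} μm, "
        f"Q = {_fmt(stats_.q, 2)}, "
        f"Vm = {stats_.vm.mean:.0f} ± {stats_.vm.sd:.0f} μm³"
    )
    return stats_, text


@dataclass
class Ellipse:
    """Isoprobability ellipse of a bivariate Gaussian.

    Semi-axes lie along the covariance eigenvectors; ``k2`` is the
    chi-square(2) quantile at the probability level, so a point is inside
    iff its squared Mahalanobis distance from the centre is <= k2
    (boundary counts as inside).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the major axis
    level: float
    k2: float
    _cov_inv: np.ndarray

    def mahalanobis_sq(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - np.asarray(self.center)
        return np.einsum("ij,jk,ik->i", d, self._cov_inv, d)

    def contains(self, points) -> np.ndarray:
        return self.mahalanobis_sq(points) <= self.k2 + 1e-12


def isoprobability_ellipse(
    mean, covariance, level: float = 0.68
) -> Ellipse:
    """Ellipse enclosing ``level`` probability mass of N(mean, covariance).

    For level 0.68 and identity covariance the radius is
    sqrt(-2 ln 0.32) ≈ 1.5096 (the chi-square(2) quantile in closed
    form)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be a symmetric 2x2 matrix")
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals.min() <= 0:
        raise ValueError("covariance must be positive definite")
    k2 = float(stats.chi2.ppf(level, df=2))  # == -2 ln(1 - level)
    order = np.argsort(eigvals)[::-1]  # major axis first
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return Ellipse(
        center=(float(mean[0]), float(mean[1])),
        semi_axes=(
            float(np.sqrt(eigvals[0] * k2)),
            float(np.sqrt(eigvals[1] * k2)),
        ),
        angle=angle,
        level=level,
        k2=k2,
        _cov_inv=np.linalg.inv(cov),
    )


def ellipse_from_points(
    points, level: float = 0.68
) -> Ellipse:
    """Fit N(mean, sample covariance) to (length, width) points (n-1
    denominator) and build the isoprobability ellipse."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 bivariate points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    return isoprobability_ellipse(mean, cov, level)


def ellipse_coverage(points, ellipse: Ellipse) -> float:
    """Percentage of points inside the ellipse (boundary inclusive)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one point")
    return float(ellipse.contains(pts).mean() * 100.0)
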