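"""Relative survival-probability surfaces over the outlier-genotype space.

Individuals are placed in the plane of the two leading PCs of the outlier
loci.  For each habitat, the post-selection (juvenile) kernel-density
estimate minus the pre-selection (larval) estimate over a shared lattice
yields a relative survival surface: positive where multilocus genotypes
were enriched by selection, negative where depleted.  Projecting an
individual's coordinates onto the surface gives its relative survival score
in that habitat.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import norm

from .phenotypes import AncovaFit, ancova_interaction


def nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference-rule Gaussian bandwidth (sd units) for one axis.

    ``1.06 · min(sd, IQR/1.34) · n^(−1/5)``; falls back to the sd when the
    IQR is zero, and errors on a zero-variance axis.
    """
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0 or len(x) < 2:
        raise ValueError("zero variance on an axis; bandwidth undefined")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 1.06 * spread * len(x) ** (-1 / 5)


@dataclass
class KDE2DResult:
    x: np.ndarray          # lattice axis values, length grid_n
    y: np.ndarray
    density: np.ndarray    # (grid_n, grid_n), indexed [ix, iy]
    bandwidth: tuple[float, float]

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.y, axis=1), self.x))


# lattice padding in bandwidth units; 3 keeps >99.7% of every kernel's mass
# inside the grid so densities integrate to ~1 even for small samples
PAD_BANDWIDTHS = 3.0


def _grid(points: np.ndarray, bw: tuple[float, float], grid_n: int):
    px, py = PAD_BANDWIDTHS * bw[0], PAD_BANDWIDTHS * bw[1]
    gx = np.linspace(points[:, 0].min() - px, points[:, 0].max() + px, grid_n)
    gy = np.linspace(points[:, 1].min() - py, points[:, 1].max() + py, grid_n)
    return gx, gy


def _eval_kde(points: np.ndarray, gx: np.ndarray, gy: np.ndarray,
              bw: tuple[float, float]) -> np.ndarray:
    kx = norm.pdf((gx[:, None] - points[None, :, 0]) / bw[0]) / bw[0]
    ky = norm.pdf((gy[:, None] - points[None, :, 1]) / bw[1]) / bw[1]
    return kx @ ky.T / len(points)


def kde2d(points, grid_n: int = 100, bandwidth=None, extent=None) -> KDE2DResult:
    """Product-Gaussian 2D kernel density on a regular lattice.

    The lattice spans the data range padded by three bandwidths on each side
    (or the supplied ``extent`` as ``(gx, gy)`` axis arrays), wide enough
    that the density integrates to ~1 by the trapezoid rule.  Default
    bandwidths follow the normal reference rule per axis.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("points must be an (n>=2, 2) array")
    if bandwidth is None:
        bw = (nrd_bandwidth(pts[:, 0]), nrd_bandwidth(pts[:, 1]))
    else:
        bw = (float(bandwidth[0]), float(bandwidth[1])) if np.ndim(bandwidth) else (float(bandwidth),) * 2
    if bw[0] <= 0 or bw[1] <= 0:
        raise ValueError("bandwidths must be positive")
    if extent is None:
        gx, gy = _grid(pts, bw, grid_n)
    else:
        gx, gy = (np.asarray(e, float) for e in extent)
    return KDE2DResult(gx, gy, _eval_kde(pts, gx, gy, bw), bw)


@dataclass
class SurvivalSurface:
    """Difference of post- and pre-selection densities on a shared lattice."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray                       # juvenile density − larval density
    bandwidth: tuple[float, float]
    density_post: np.ndarray
    density_pre: np.ndarray
    habitat: str | None = None

    def z_integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.z, self.y, axis=1), self.x))


def survival_surface(coords_post, coords_pre, grid_n: int = 100,
                     bandwidth=None, habitat: str | None = None) -> SurvivalSurface:
    """Survival surface from post- and pre-selection PC coordinates.

    Bandwidths (shared so that the subtraction compares like with like) and
    the lattice extent come from the pooled samples.
    """
    post = np.asarray(coords_post, float)
    pre = np.asarray(coords_pre, float)
    if len(post) == 0 or len(pre) == 0:
        raise ValueError("both coordinate sets must be non-empty")
    pooled = np.vstack([post, pre])
    if bandwidth is None:
        bw = (nrd_bandwidth(pooled[:, 0]), nrd_bandwidth(pooled[:, 1]))
    else:
        bw = (float(bandwidth[0]), float(bandwidth[1])) if np.ndim(bandwidth) else (float(bandwidth),) * 2
    gx, gy = _grid(pooled, bw, grid_n)
    d_post = _eval_kde(post, gx, gy, bw)
    d_pre = _eval_kde(pre, gx, gy, bw)
    return SurvivalSurface(gx, gy, d_post - d_pre, bw, d_post, d_pre, habitat)


def project_survival_scores(coords, surface: SurvivalSurface):
    """Bilinear interpolation of the surface at individual coordinates.

    Points outside the lattice hull are clipped to its edge and flagged.
    Returns ``(scores, clipped)`` arrays.
    """
    pts = np.atleast_2d(np.asarray(coords, float))
    lo = np.array([surface.x[0], surface.y[0]])
    hi = np.array([surface.x[-1], surface.y[-1]])
    clipped = ((pts < lo) | (pts > hi)).any(axis=1)
    pts_c = np.clip(pts, lo, hi)
    interp = RegularGridInterpolator((surface.x, surface.y), surface.z,
                                     method="linear")
    return interp(pts_c), clipped


def positive_fraction(scores) -> float:
    """Fraction of individuals with a strictly positive survival score."""
    s = np.asarray(scores, float)
    return float((s > 0).mean())


def survival_tradeoff_ancova(scores_by_habitat: dict, polygenic_score) -> AncovaFit:
    """ANCOVA of survival score on habitat × polygenic score.

    ``scores_by_habitat`` maps each habitat label to the per-individual
    survival scores on that habitat's surface (same individuals, same
    order); each individual contributes one row per habitat surface.
    Antagonistic selection shows up as opposite-sign slopes.
    """
    ps = np.asarray(polygenic_score, float)
    ys, xs, gs = [], [], []
    for hab, sc in scores_by_habitat.items():
        sc = np.asarray(sc, float)
        if len(sc) != len(ps):
            raise ValueError("survival scores and polygenic scores misaligned")
        ys.append(sc)
        xs.append(ps)
        gs.extend([hab] * len(ps))
    return ancova_interaction(np.concatenate(ys), np.concatenate(xs), gs)
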