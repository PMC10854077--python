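"""Derived quantities: central-crop summaries, section slices, FSS band
proportions, time-in-band fractions and peak timing.

Field statistics are computed over the central sub-cube of the solid core
(default fraction 0.875 of the core edge, i.e. a 0.7 mm window in a 0.8 mm
cube) to suppress boundary artefacts, mirroring standard practice for
micro-FE samples.  FSS bands follow the osteocyte/osteoblast literature:
below 0.1 Pa (osteoclast recruitment), 0.1-1, 1-3 (osteoblast activation)
and above 3 Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VoxelDomain
from .stokes import InterfaceFSS

__all__ = [
    "FieldSummary",
    "BinProportions",
    "FSS_BANDS",
    "crop_center",
    "crop_center_mask",
    "section_slices",
    "fss_bin_proportions",
    "time_fraction_in_band",
    "summarize",
    "peak_time",
]

#: FSS band edges (Pa), half-open [low, high)
FSS_BANDS = ((0.0, 0.1), (0.1, 1.0), (1.0, 3.0), (3.0, np.inf))


@dataclass
class FieldSummary:
    """Mean, population SD, median and quartiles of one scalar field."""

    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n: int
    region_label: str = ""
    time: float = 0.0


@dataclass
class BinProportions:
    """Fraction of interface faces per FSS band at one time."""

    proportions: np.ndarray  # (4,)
    n_faces: int
    time: float


def _round_half_down(x: float) -> int:
    """Nearest integer, ties toward the lower index (bit-reproducible)."""
    return int(np.ceil(x - 0.5))


def crop_center_mask(points_um: np.ndarray, domain: VoxelDomain,
                     core_fraction: float = 0.875) -> np.ndarray:
    """Boolean mask of entities whose centroids fall in the centered sub-cube.

    The sub-cube edge is ``round(core_fraction * grid_n)`` voxels (ties to
    the lower integer), centered in the core with the same tie rule.
    """
    if not 0.0 < core_fraction <= 1.0:
        raise ValueError("core_fraction must lie in (0, 1]")
    gn = domain.grid_n
    sub = _round_half_down(core_fraction * gn)
    start = domain.margin_vox + (gn - sub) // 2
    lo = start * domain.pitch
    hi = (start + sub) * domain.pitch
    pts = np.asarray(points_um)
    return np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)


def crop_center(values: np.ndarray, points_um: np.ndarray, domain: VoxelDomain,
                core_fraction: float = 0.875) -> np.ndarray:
    """Restrict a scalar field to the central sub-cube of the core."""
    mask = crop_center_mask(points_um, domain, core_fraction)
    if not mask.any():
        raise ValueError("central crop is empty")
    return np.asarray(values)[mask]


def section_slices(values: np.ndarray, points_um: np.ndarray,
                   domain: VoxelDomain,
                   fractions=(0.25, 0.5, 0.75)) -> dict:
    """Voxel-layer slices at fractional heights along the loading axis.

    Layer index = ``round(fraction * grid_n)`` with ties toward the lower
    layer; entities whose centroid lies in that core layer are returned.
    """
    ax = domain.loading_axis
    gn = domain.grid_n
    pts = np.asarray(points_um)
    out = {}
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise ValueError("section fractions must lie in (0, 1)")
        layer = min(_round_half_down(f * gn), gn - 1)
        lo = (domain.margin_vox + layer) * domain.pitch
        hi = lo + domain.pitch
        m = (pts[:, ax] >= lo - 1e-9) & (pts[:, ax] < hi - 1e-9)
        out[f] = np.asarray(values)[m]
    return out


def fss_bin_proportions(iface: InterfaceFSS, t: float) -> BinProportions:
    """Proportion of wall faces per FSS band at sample time t."""
    if iface.fss is None or iface.times is None:
        raise ValueError("interface carries no FSS time series")
    if iface.n_faces == 0:
        raise ValueError("empty interface")
    ti = int(np.argmin(np.abs(iface.times - t)))
    if not np.isclose(iface.times[ti], t):
        raise ValueError(f"t={t} is not among the sampled times")
    vals = iface.fss[:, ti]
    props = np.array([np.mean((vals >= lo) & (vals < hi)) for lo, hi in FSS_BANDS])
    return BinProportions(proportions=props, n_faces=iface.n_faces, time=float(t))


def time_fraction_in_band(iface: InterfaceFSS, band=(1.0, 3.0),
                          min_fraction: float = 0.5) -> float:
    """Fraction of wall faces in the band for more than ``min_fraction`` of
    the sampled times (strict inequality)."""
    lo, hi = band
    if not lo < hi:
        raise ValueError("band low must be below high")
    if not 0.0 < min_fraction < 1.0:
        raise ValueError("min_fraction must lie in (0, 1)")
    if iface.fss is None:
        raise ValueError("interface carries no FSS time series")
    in_band = (iface.fss >= lo) & (iface.fss < hi)
    frac = in_band.mean(axis=1)
    return float(np.mean(frac > min_fraction))


def summarize(values: np.ndarray, region_label: str = "",
              time: float = 0.0) -> FieldSummary:
    """Mean, population SD, median, Q1/Q3 (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError(f"empty region {region_label!r}")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return FieldSummary(
        mean=float(v.mean()), sd=float(v.std(ddof=0)),
        median=float(med), q1=float(q1), q3=float(q3),
        n=int(v.size), region_label=region_label, time=float(time),
    )


def peak_time(times: np.ndarray, series: np.ndarray, period: float | None = None) -> float:
    """Quadratic-interpolated argmax of a periodic time series.

    Fits a parabola through the maximum sample and its two cyclic
    neighbours; a flat (constant) series returns the first sample time.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(series, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 samples over the period")
    i = int(np.argmax(y))
    if np.allclose(y, y[0]):
        return float(t[0])
    n = len(t)
    dt = t[1] - t[0]
    ym, y0, yp = y[(i - 1) % n], y[i], y[(i + 1) % n]
    denom = ym - 2 * y0 + yp
    if denom == 0:
        return float(t[i])
    shift = 0.5 * (ym - yp) / denom
    T = period if period is not None else n * dt
    return float((t[i] + shift * dt) % T)
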