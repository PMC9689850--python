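"""Geometric descriptors of the second-order difference plot (SODP).

The SODP of a signal ``s`` is the scatter of successive first differences,

    x(i) = s(i+1) - s(i),    y(i) = s(i+2) - s(i+1),

a Poincare-style representation of signal variability.  Epileptic-seizure
EEG spreads over a much larger region of this plane than seizure-free
background, so the shape of the point cloud carries discriminative
information.  This module computes the ten geometric descriptors used by
the detection pipeline -- ellipse dispersion (STD1/STD2 and the fitted
ellipse area), the sum of cosines of inter-vector angles (SAV), distances
to the ``y = x`` diagonal (SSHD), triangle areas of consecutive triples
(STA), the central tendency measure at three radii (CTM), radial distances
to the origin (SDC), the trajectory polyline length (SSVL) and successive
triangle-centroid distances (SCC) -- plus eight conventional time-domain
features kept for comparison.

All descriptors are plain sums or population moments over the SODP points;
none involves fitting.  Homogeneity under amplitude scaling ``a > 0``:
SAV and CTM are scale-invariant; SSHD, SDC, SSVL, SCC, STD1 and STD2 scale
by ``a``; the ellipse area STD and STA scale by ``a**2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SODP",
    "GEO_FEATURE_NAMES",
    "TimeDomainFeatures",
    "compute_sodp",
    "std_descriptors",
    "sav",
    "sshd",
    "sta",
    "ctm",
    "sdc",
    "ssvl",
    "scc",
    "geo_feature_vector",
    "extract_features",
    "time_domain_features",
]

#: Canonical feature order used for particle encoding: one block of ten
#: per frequency band.
GEO_FEATURE_NAMES = (
    "STD",
    "SAV",
    "SDC",
    "STA",
    "SSHD",
    "SCC",
    "SSVL",
    "CTM03",
    "CTM04",
    "CTM05",
)

CTM_RADII = (0.3, 0.4, 0.5)


@dataclass(frozen=True)
class SODP:
    """Second-order difference plot of a 1-D signal.

    ``y`` is the one-sample lag of the first-difference series, so
    ``y[i] == x[i+1]`` whenever both are defined.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("SODP coordinates must be 1-D arrays of equal length")

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def radii(self) -> np.ndarray:
        """Euclidean distance of every SODP point from the origin."""
        return np.hypot(self.x, self.y)


def compute_sodp(signal: Sequence[float]) -> SODP:
    """Build the SODP of a 1-D signal of length ``n >= 3``.

    Returns ``n - 2`` points ``(x(i), y(i))`` of successive first
    differences.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1:
        raise ValueError("signal must be 1-D")
    if s.size < 3:
        raise ValueError(f"need at least 3 samples to form an SODP, got {s.size}")
    d = np.diff(s)
    return SODP(x=d[:-1], y=d[1:])


def std_descriptors(p: SODP) -> tuple[float, float, float]:
    """Dispersion along the 45/135-degree axes and the fitted ellipse area.

    ``STD1 = sqrt(Var((x - y)/sqrt(2)))`` measures spread across the
    ``y = x`` diagonal, ``STD2 = sqrt(Var((x + y)/sqrt(2)))`` spread along
    it, and ``STD = pi * STD1 * STD2`` is the area of the fitted ellipse.
    Population (1/n) variances are used: these are descriptors of the
    realized point cloud, not estimators of an underlying process.
    """
    if p.n_points < 2:
        raise ValueError("std_descriptors needs at least 2 SODP points")
    u = (p.x - p.y) / np.sqrt(2.0)
    v = (p.x + p.y) / np.sqrt(2.0)
    std1 = float(np.sqrt(np.mean((u - u.mean()) ** 2)))
    std2 = float(np.sqrt(np.mean((v - v.mean()) ** 2)))
    return std1, std2, float(np.pi * std1 * std2)


def sav(p: SODP, denominator: str = "product") -> float:
    """Sum of cosines of the angles between consecutive SODP vectors.

    Each term is ``<v_i, v_{i+1}> / (|v_i| |v_{i+1}|)``, the cosine of the
    angle between consecutive position vectors, so the sum is bounded by
    the number of pairs and is invariant to amplitude scaling.  A pair
    involving a zero-length vector has no defined angle and contributes 0.

    ``denominator="sum"`` switches to dividing by ``|v_i|^2 + |v_{i+1}|^2``
    instead of the product of norms, an alternative normalisation seen in
    the descriptor literature (not scale-invariant).
    """
    if p.n_points < 2:
        raise ValueError("sav needs at least 2 SODP points")
    if denominator not in ("product", "sum"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    dots = p.x[:-1] * p.x[1:] + p.y[:-1] * p.y[1:]
    r = p.radii
    if denominator == "product":
        den = r[:-1] * r[1:]
    else:
        den = r[:-1] ** 2 + r[1:] ** 2
    terms = np.zeros_like(dots)
    ok = den > 0
    terms[ok] = dots[ok] / den[ok]
    return float(terms.sum())


def sshd(p: SODP) -> float:
    """Sum of shortest distances of SODP points to the ``y = x`` line."""
    if p.n_points < 1:
        raise ValueError("sshd needs at least 1 SODP point")
    return float(np.sum(np.abs(p.x - p.y)) / np.sqrt(2.0))


def sta(p: SODP) -> float:
    """Sum of triangle areas over consecutive point triples.

    The area of the triangle with vertices ``P_i, P_{i+1}, P_{i+2}`` is
    half the absolute determinant of the homogeneous-coordinate matrix
    (the shoelace formula).
    """
    if p.n_points < 3:
        raise ValueError("sta needs at least 3 SODP points")
    x0, x1, x2 = p.x[:-2], p.x[1:-1], p.x[2:]
    y0, y1, y2 = p.y[:-2], p.y[1:-1], p.y[2:]
    det = x0 * (y1 - y2) - x1 * (y0 - y2) + x2 * (y0 - y1)
    return float(0.5 * np.sum(np.abs(det)))


def ctm(p: SODP, rho: float) -> float:
    """Central tendency measure: fraction of points inside a central disk.

    The disk radius is ``rho`` times the radial extent of this SODP
    (``max sqrt(x^2 + y^2)`` over its own points), so the measure is
    scale-invariant and lies in [0, 1].  A low CTM means the plot spreads
    out towards its extremes.  An all-zero SODP has radius 0 and every
    point trivially inside, giving CTM 1.
    """
    if p.n_points < 1:
        raise ValueError("ctm needs at least 1 SODP point")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    r = p.radii
    return float(np.mean(r <= rho * r.max()))


def sdc(p: SODP) -> float:
    """Sum of radial distances of all SODP points from the origin."""
    if p.n_points < 1:
        raise ValueError("sdc needs at least 1 SODP point")
    return float(p.radii.sum())


def ssvl(p: SODP) -> float:
    """Polyline length of the SODP trajectory (sum of successive steps)."""
    if p.n_points < 1:
        raise ValueError("ssvl needs at least 1 SODP point")
    return float(np.sum(np.hypot(np.diff(p.x), np.diff(p.y))))


def scc(p: SODP) -> float:
    """Sum of distances between centroids of successive point triples.

    Centroid ``C_i`` is the mean of points ``i, i+1, i+2``; the sum of
    ``|C_{i+1} - C_i|`` quantifies drift of the local centre of mass and
    hence the self-similarity of the plot.
    """
    if p.n_points < 4:
        raise ValueError("scc needs at least 4 SODP points")
    kernel = np.ones(3) / 3.0
    cx = np.convolve(p.x, kernel, mode="valid")
    cy = np.convolve(p.y, kernel, mode="valid")
    return float(np.sum(np.hypot(np.diff(cx), np.diff(cy))))


def geo_feature_vector(signal: Sequence[float], sav_denominator: str = "product") -> np.ndarray:
    """All ten geometric descriptors of one 1-D signal, in canonical order.

    Order: STD, SAV, SDC, STA, SSHD, SCC, SSVL, CTM-0.3, CTM-0.4, CTM-0.5.
    """
    p = compute_sodp(signal)
    _, _, std_area = std_descriptors(p)
    return np.array(
        [
            std_area,
            sav(p, denominator=sav_denominator),
            sdc(p),
            sta(p),
            sshd(p),
            scc(p),
            ssvl(p),
            ctm(p, 0.3),
            ctm(p, 0.4),
            ctm(p, 0.5),
        ]
    )


def extract_features(segments: Iterable, sav_denominator: str = "product") -> pd.DataFrame:
    """Per-segment geometric feature table for band-filtered segments.

    Features are computed per channel and averaged over channels, yielding
    one 10-vector per segment per band: the particle encoding carries ten
    bits per band, so the classifier consumes segment-level, not
    channel-level, vectors.

    Parameters
    ----------
    segments
        Iterable of :class:`~sodpeeg.eeg_io.Segment` (or anything with
        ``signal`` (channels x samples), ``label``, ``band`` and
        ``start_s`` attributes).  All segments should already be filtered
        to a single band each.

    Returns
    -------
    pandas.DataFrame
        Columns ``segment_id, band, label, start_s`` plus the ten feature
        columns of :data:`GEO_FEATURE_NAMES`.
    """
    rows = []
    for seg_id, seg in enumerate(segments):
        sig = np.atleast_2d(np.asarray(seg.signal, dtype=float))
        feats = np.mean(
            [geo_feature_vector(ch, sav_denominator=sav_denominator) for ch in sig],
            axis=0,
        )
        rows.append(
            {
                "segment_id": seg_id,
                "band": seg.band,
                "label": seg.label,
                "start_s": getattr(seg, "start_s", float(seg_id)),
                **dict(zip(GEO_FEATURE_NAMES, feats)),
            }
        )
    if not rows:
        raise ValueError("extract_features requires at least one segment")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TimeDomainFeatures:
    """Eight conventional time-domain features used for comparison."""

    rms: float
    peak_peak: float
    skewness: float
    kurtosis: float
    shape_indicator: float
    crest_indicator: float
    impulse_indicator: float
    clearance_indicator: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.rms,
                self.peak_peak,
                self.skewness,
                self.kurtosis,
                self.shape_indicator,
                self.crest_indicator,
                self.impulse_indicator,
                self.clearance_indicator,
            ]
        )


def time_domain_features(signal: Sequence[float]) -> TimeDomainFeatures:
    """RMS, peak-peak, sample skewness/kurtosis and four shape indicators.

    shape = rms / mean|x|, crest = max|x| / rms, impulse = max|x| / mean|x|,
    clearance = max|x| / (mean sqrt|x|)^2.  For an all-zero signal the
    indicator ratios are undefined and are reported as 0 with a warning.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    rms = float(np.sqrt(np.mean(s**2)))
    peak_peak = float(s.max() - s.min())
    mu = s.mean()
    sd = float(np.sqrt(np.mean((s - mu) ** 2)))
    if sd > 0:
        skew = float(np.mean((s - mu) ** 3) / sd**3)
        kurt = float(np.mean((s - mu) ** 4) / sd**4)
    else:
        skew = 0.0
        kurt = 0.0
    abs_mean = float(np.mean(np.abs(s)))
    sqrt_mean = float(np.mean(np.sqrt(np.abs(s))))
    peak = float(np.max(np.abs(s)))
    if rms == 0.0:
        warnings.warn("all-zero signal: indicator ratios undefined, returning 0")
        shape = crest = impulse = clearance = 0.0
    else:
        shape = rms / abs_mean
        crest = peak / rms
        impulse = peak / abs_mean
        clearance = peak / sqrt_mean**2
    return TimeDomainFeatures(
        rms=rms,
        peak_peak=peak_peak,
        skewness=skew,
        kurtosis=kurt,
        shape_indicator=shape,
        crest_indicator=crest,
        impulse_indicator=impulse,
        clearance_indicator=clearance,
    )
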