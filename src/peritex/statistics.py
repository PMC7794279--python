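"""Portilla-Simoncelli summary statistics over a pooling window.

This module computes the texture summary-statistics (SS) vector that forms
the representation stage of the SS model of peripheral vision: statistics
of the steerable-pyramid coefficients of an image, every averaging
operation weighted by a circular pooling window whose diameter follows
Bouma's law (window radius = 0.5 x target eccentricity).

Statistic groups and counts at the defaults (4 scales, 4 orientations,
7-pixel correlation neighborhood), after removing symmetric duplicates:

====================================================  =====
pixel marginals (mean, var, skew, kurt, min, max)         6
skew + kurtosis of lowpass reconstructions (5 levels)    10
lowpass autocorrelations (25 unique lags x 5 levels)    125
band-magnitude autocorrelations (25 x 16 bands)         400
band-magnitude means (16 bands)                          16
within-scale magnitude covariances (10 x 4 scales)       40
cross-scale magnitude correlations (16 x 3 pairs)        48
within-scale real-part covariances (10 x 4 scales)       40
cross-scale phase correlations (4 x 8 x 3 pairs)         96
highpass variance                                         1
====================================================  =====
total                                                   782

Autocorrelations are centrally symmetric, so only the lexicographic half
of the Na x Na lag neighborhood (including zero lag) is retained; the
zero-lag entry stores the window-weighted variance and all other lags are
normalized by it.  Symmetric covariance matrices keep the upper triangle
including the diagonal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .image import GrayImage
from .pyramid import build_pyramid, _polar_grids, _lo_mask

__all__ = [
    "PSParams",
    "PSStatVector",
    "PoolingWindow",
    "bouma_pooling_diameter",
    "marginal_stats",
    "compute_ps_statistics",
    "statistic_difference",
]


@dataclass
class PSParams:
    """Parameters of the summary-statistic computation.

    ``neighborhood`` (Na) is the side of the square lag neighborhood for
    spatial autocorrelations, in pixels of the relevant pyramid level
    (odd, >= 3).  ``pooling_diameter_px`` is the diameter of the circular
    pooling window; the default of 360 px corresponds to Bouma's law at
    12 degrees eccentricity and 30 px/deg.
    """

    n_scales: int = 4
    n_orientations: int = 4
    neighborhood: int = 7
    pooling_diameter_px: int = 360

    def __post_init__(self) -> None:
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValueError("neighborhood must be odd and >= 3")
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("n_scales and n_orientations must be >= 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PSParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class PSStatVector:
    """Named, ordered vector of summary statistics."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "value"])
            for n, v in zip(self.names, self.values):
                writer.writerow([n, repr(float(v))])

    @classmethod
    def from_csv(cls, path) -> "PSStatVector":
        names, values = [], []
        with open(path) as fh:
            reader = csv.reader(fh)
            next(reader)
            for n, v in reader:
                names.append(n)
                values.append(float(v))
        return cls(names, np.array(values))


@dataclass
class PoolingWindow:
    """Circular pooling window: center, diameter and full-resolution weights."""

    center: tuple[int, int]
    diameter_px: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.sum() <= 0:
            raise ValueError("window weights must have positive sum")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("window weights must lie in [0, 1]")

    @classmethod
    def disk(
        cls,
        shape: tuple[int, int],
        diameter_px: int,
        center: tuple[int, int] | None = None,
        edge_width_px: int = 0,
    ) -> "PoolingWindow":
        """Binary disk window (optionally with a raised-cosine edge).

        ``edge_width_px > 0`` replaces the hard edge with a raised-cosine
        ramp of that width just inside the nominal radius.
        """
        h, w = shape
        if center is None:
            center = (h // 2, w // 2)
        cy, cx = center
        yy, xx = np.ogrid[:h, :w]
        r = np.hypot(yy - cy, xx - cx)
        radius = diameter_px / 2.0
        if edge_width_px <= 0:
            weights = (r <= radius).astype(float)
        else:
            t = np.clip((radius - r) / edge_width_px, 0.0, 1.0)
            weights = 0.5 - 0.5 * np.cos(np.pi * t)
        return cls(center=(cy, cx), diameter_px=diameter_px, weights=weights)

    def at_scale(self, factor: int) -> np.ndarray:
        """Window weights box-averaged down to resolution ``1/factor``."""
        if factor == 1:
            return self.weights
        h, w = self.weights.shape
        if h % factor or w % factor:
            raise ValueError("window shape not divisible by scale factor")
        return (
            self.weights.reshape(h // factor, factor, w // factor, factor)
            .mean(axis=(1, 3))
        )


def bouma_pooling_diameter(
    eccentricity_deg: float, bouma_factor: float, px_per_deg: float
) -> int:
    """Pooling-window diameter in pixels from Bouma's law.

    The window radius is ``bouma_factor x eccentricity`` (in degrees), the
    critical distance within which surrounding stimuli interfere with
    target identification; the returned diameter is twice that, in pixels.
    """
    if eccentricity_deg <= 0 or bouma_factor <= 0 or px_per_deg <= 0:
        raise ValueError("all arguments must be > 0")
    return int(round(2 * bouma_factor * eccentricity_deg * px_per_deg))


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float, float]:
    """Weighted mean, variance, skewness, kurtosis; skew/kurt -> 0 at zero variance."""
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("degenerate window: weights sum to zero")
    mean = float((w * x).sum() / wsum)
    xc = x - mean
    var = float((w * xc**2).sum() / wsum)
    if var <= np.finfo(float).eps * max(1.0, mean**2):
        return mean, 0.0, 0.0, 0.0
    skew = float((w * xc**3).sum() / wsum / var**1.5)
    kurt = float((w * xc**4).sum() / wsum / var**2)
    return mean, var, skew, kurt


def marginal_stats(
    img: GrayImage, window: PoolingWindow
) -> tuple[float, float, float, float, float, float]:
    """Window-weighted pixel marginals: mean, var, skew, kurt, min, max.

    Min and max are taken over the window support (weights > 0).  For a
    zero-variance region skewness and kurtosis are reported as 0 by
    convention (no exception raised).
    """
    x = img.pixels
    w = window.weights
    if w.shape != x.shape:
        raise ValueError("window does not fit image")
    mean, var, skew, kurt = _weighted_moments(x, w)
    support = w > 0
    lo = float(x[support].min())
    hi = float(x[support].max())
    return mean, var, skew, kurt, lo, hi


def _half_lags(na: int) -> list[tuple[int, int]]:
    """Lexicographic half of the Na x Na lag neighborhood, zero lag first."""
    m = na // 2
    lags = [(0, 0)]
    for dy in range(0, m + 1):
        for dx in range(-m, m + 1):
            if (dy, dx) > (0, 0):
                lags.append((dy, dx))
    return lags


def _weighted_autocorr(
    x: np.ndarray, w: np.ndarray, lags: list[tuple[int, int]]
) -> list[float]:
    """Centrally symmetric window-weighted autocorrelation.

    Uses the symmetrized weight (w(p) + w(p+tau))/2 so that ac(tau) equals
    ac(-tau) exactly.  Entry for lag (0, 0) is the weighted variance; all
    other lags are covariances normalized by that variance (0 if the
    variance vanishes).
    """
    wsum = w.sum()
    mean = (w * x).sum() / wsum
    xc = x - mean
    var = float((w * xc**2).sum() / wsum)
    out = []
    wxc = w * xc
    for dy, dx in lags:
        if dy == 0 and dx == 0:
            out.append(var)
            continue
        if var <= 0:
            out.append(0.0)
            continue
        shifted = np.roll(xc, (dy, dx), axis=(0, 1))
        wshift = np.roll(w, (dy, dx), axis=(0, 1))
        cov = float(((w + wshift) / 2 * xc * shifted).sum() / wsum)
        out.append(cov / var)
    return out


def _weighted_cov_matrix(cols: list[np.ndarray], w: np.ndarray) -> np.ndarray:
    """Window-weighted covariance matrix of flattened maps (mean-removed)."""
    wsum = w.sum()
    centered = []
    for c in cols:
        centered.append(c - (w * c).sum() / wsum)
    n = len(centered)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = (w * centered[i] * centered[j]).sum() / wsum
    return out


def _weighted_cross(
    a: list[np.ndarray], b: list[np.ndarray], w: np.ndarray
) -> np.ndarray:
    """Window-weighted cross-covariance matrix between two map lists."""
    wsum = w.sum()
    ac = [x - (w * x).sum() / wsum for x in a]
    bc = [x - (w * x).sum() / wsum for x in b]
    out = np.empty((len(ac), len(bc)))
    for i, x in enumerate(ac):
        for j, y in enumerate(bc):
            out[i, j] = (w * x * y).sum() / wsum
    return out


def _upsample2(band: np.ndarray) -> np.ndarray:
    """Upsample a complex band by 2 via central spectral zero-padding."""
    h, w = band.shape
    spec = np.fft.fftshift(np.fft.fft2(band))
    pad = np.zeros((2 * h, 2 * w), dtype=complex)
    pad[h // 2 : h // 2 + h, w // 2 : w // 2 + w] = spec
    return np.fft.ifft2(np.fft.ifftshift(pad)) * 4.0


def _lowpass_reconstructions(img: GrayImage, n_scales: int) -> list[np.ndarray]:
    """Partial lowpass reconstructions at levels 1..n_scales+1.

    Level ``i`` is the image content below band ``i`` (synthesis-consistent
    squared filters), downsampled to the resolution of scale ``i``;
    level ``n_scales + 1`` is the lowpass residual.
    """
    h, w = img.shape
    spec = np.fft.fftshift(np.fft.fft2(img.pixels))
    r, _ = _polar_grids((h, w))
    cum = _lo_mask(r, np.pi)
    recons = []
    for level in range(1, n_scales + 2):
        factor = 2 ** (level - 1)
        masked = spec * cum**2
        ch, cw = h // factor, w // factor
        cropped = masked[(h - ch) // 2 : (h + ch) // 2, (w - cw) // 2 : (w + cw) // 2]
        recons.append(np.fft.ifft2(np.fft.ifftshift(cropped)).real / factor**2)
        if level <= n_scales:
            cum = cum * _lo_mask(r, np.pi / 2**level)
    return recons


def compute_ps_statistics(
    img: GrayImage, params: PSParams, window: PoolingWindow
) -> PSStatVector:
    """Full PS summary-statistic vector over a pooling window.

    See the module docstring for the statistic groups; at the default
    parameters (4, 4, Na=7) the vector has exactly 782 entries.
    """
    h, w = img.shape
    if window.weights.shape != (h, w):
        raise ValueError("window shape does not match image")
    if window.diameter_px > min(h, w):
        raise ValueError("pooling window larger than image")

    nsc, nor, na = params.n_scales, params.n_orientations, params.neighborhood
    lags = _half_lags(na)
    pyr = build_pyramid(img, nsc, nor)

    windows = {}
    for s in range(0, nsc + 1):
        ws = window.at_scale(2**s) if s else window.weights
        if ws.sum() <= 0:
            raise ValueError(f"degenerate window at scale factor 2**{s}")
        windows[s] = ws

    names: list[str] = []
    values: list[float] = []

    def emit(name: str, value: float) -> None:
        names.append(name)
        values.append(float(value))

    # --- pixel marginals -------------------------------------------------
    mean, var, skew, kurt, lo, hi = marginal_stats(img, window)
    for n, v in zip(
        ("mean", "var", "skew", "kurt", "min", "max"),
        (mean, var, skew, kurt, lo, hi),
    ):
        emit(f"pix_{n}", v)

    # --- lowpass reconstructions: skew/kurt + autocorrelation ------------
    recons = _lowpass_reconstructions(img, nsc)
    for level, rec in enumerate(recons, start=1):
        wlev = windows[level - 1]
        _, _, sk, ku = _weighted_moments(rec, wlev)
        emit(f"lp_skew_l{level}", sk)
        emit(f"lp_kurt_l{level}", ku)
    for level, rec in enumerate(recons, start=1):
        wlev = windows[level - 1]
        for (dy, dx), v in zip(lags, _weighted_autocorr(rec, wlev, lags)):
            emit(f"lp_acorr_l{level}_dy{dy}_dx{dx}", v)

    # --- band magnitudes -------------------------------------------------
    mags = {
        (s, o): np.abs(pyr.band(s, o)) for s in range(1, nsc + 1) for o in range(nor)
    }
    for s in range(1, nsc + 1):
        wlev = windows[s - 1]
        for o in range(nor):
            for (dy, dx), v in zip(
                lags, _weighted_autocorr(mags[(s, o)], wlev, lags)
            ):
                emit(f"mag_acorr_s{s}_o{o}_dy{dy}_dx{dx}", v)
    for s in range(1, nsc + 1):
        wlev = windows[s - 1]
        wsum = wlev.sum()
        for o in range(nor):
            emit(f"mag_mean_s{s}_o{o}", (wlev * mags[(s, o)]).sum() / wsum)

    # --- within-scale magnitude covariances (upper triangle) -------------
    for s in range(1, nsc + 1):
        cov = _weighted_cov_matrix([mags[(s, o)] for o in range(nor)], windows[s - 1])
        for i in range(nor):
            for j in range(i, nor):
                emit(f"mag_cov_s{s}_o{i}_o{j}", cov[i, j])

    # --- cross-scale magnitude correlations ------------------------------
    parents_mag = {}
    parents_phase = {}
    for s in range(1, nsc):
        up = [_upsample2(pyr.band(s + 1, o)) for o in range(nor)]
        parents_mag[s] = [np.abs(u) for u in up]
        doubled = [np.where(np.abs(u) > 0, u**2 / np.maximum(np.abs(u), 1e-300), 0.0) for u in up]
        parents_phase[s] = doubled
    for s in range(1, nsc):
        cross = _weighted_cross(
            [mags[(s, o)] for o in range(nor)], parents_mag[s], windows[s - 1]
        )
        for i in range(nor):
            for j in range(nor):
                emit(f"mag_xscale_s{s}_o{i}_po{j}", cross[i, j])

    # --- within-scale real-part covariances ------------------------------
    for s in range(1, nsc + 1):
        cov = _weighted_cov_matrix(
            [pyr.band(s, o).real for o in range(nor)], windows[s - 1]
        )
        for i in range(nor):
            for j in range(i, nor):
                emit(f"real_cov_s{s}_o{i}_o{j}", cov[i, j])

    # --- cross-scale phase correlations ----------------------------------
    # child real parts against real and imaginary parts of the
    # phase-doubled parents (the classic relative-phase statistic)
    for s in range(1, nsc):
        pcols = [p.real for p in parents_phase[s]] + [p.imag for p in parents_phase[s]]
        cross = _weighted_cross(
            [pyr.band(s, o).real for o in range(nor)], pcols, windows[s - 1]
        )
        for i in range(nor):
            for j in range(nor):
                emit(f"phase_xscale_s{s}_o{i}_pre{j}", cross[i, j])
            for j in range(nor):
                emit(f"phase_xscale_s{s}_o{i}_pim{j}", cross[i, nor + j])

    # --- highpass variance ------------------------------------------------
    _, hp_var, _, _ = _weighted_moments(pyr.highpass, windows[0])
    emit("hp_var", hp_var)

    return PSStatVector(names, np.array(values))


def statistic_difference(a: PSStatVector, b: PSStatVector) -> PSStatVector:
    """Element-wise ``a - b`` of two aligned statistic vectors."""
    if a.names != b.names:
        raise ValueError("statistic vectors are not aligned (name mismatch)")
    return PSStatVector(list(a.names), a.values - b.values)
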