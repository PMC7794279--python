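"""Complex steerable pyramid (frequency-domain construction).

Multi-scale, multi-orientation decomposition with polar-separable filters
whose squared amplitude responses tile the Fourier plane: a raised-cosine
radial profile (one-octave transition bands) and ``cos^(K-1)`` angular
lobes restricted to a half-plane, which makes the oriented bands analytic
(complex-valued), so the band magnitude is a local, translation-covariant
energy measure and the real part an even-phase filter response.

Conventions
-----------
* Circular (periodic) boundary handling, as implied by the FFT.
* Downsampling by spectral cropping (alias-free).  Each octave of cropping
  divides the spectrum by 4 so the coefficients keep the *signal* scaling:
  the lowpass of a constant image ``c`` is a constant image ``c``.  With
  this convention a band at scale ``s`` carries a known frame weight of
  ``4**(s-1)`` in energy bookkeeping; :meth:`PyramidCoeffs.total_energy`
  applies the weights so that the frame energy equals the input energy
  exactly (Parseval), which is how the tight-frame property is tested.
* Orientation ``k`` has preferred angle ``pi*k/K``; the angular lobes use
  the normalization that makes the squared responses of the ``K``
  orientations sum to 1 over the full circle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image import GrayImage

__all__ = ["PyramidCoeffs", "build_pyramid", "filter_stack"]


def _polar_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Centered (fftshift layout) radial and angular frequency grids."""
    h, w = shape
    fy = np.fft.fftshift(np.fft.fftfreq(h)) * 2 * np.pi
    fx = np.fft.fftshift(np.fft.fftfreq(w)) * 2 * np.pi
    wy, wx = np.meshgrid(fy, fx, indexing="ij")
    r = np.hypot(wy, wx)
    r[h // 2, w // 2] = np.finfo(float).tiny  # avoid log2(0) at DC
    theta = np.arctan2(wy, wx)
    return r, theta


def _hi_mask(r: np.ndarray, rc: float) -> np.ndarray:
    """Raised-cosine highpass: 0 below rc/2, 1 above rc, cosine in log2(r)."""
    with np.errstate(divide="ignore"):
        u = np.log2(r / rc)
    u = np.clip(u, -1.0, 0.0)
    return np.cos(np.pi / 2 * u)


def _lo_mask(r: np.ndarray, rc: float) -> np.ndarray:
    """Quadrature complement of :func:`_hi_mask` (lo**2 + hi**2 == 1)."""
    with np.errstate(divide="ignore"):
        u = np.log2(r / rc)
    u = np.clip(u, -1.0, 0.0)
    return np.abs(np.sin(np.pi / 2 * u))


def _angular_masks(theta: np.ndarray, n_orientations: int) -> list[np.ndarray]:
    """Half-plane cos^(K-1) lobes with unit tiling of squared responses.

    The constant ``c`` satisfies ``sum_k c^2 cos^(2K-2)(theta - pi k/K) = 1``
    for every angle; the sqrt(2) factor compensates for the half-plane
    (analytic) restriction so that the symmetrized squared responses of the
    complex bands still tile to 1.
    """
    k = n_orientations
    c = math.sqrt(
        (2 ** (2 * k - 2)) * math.factorial(k - 1) ** 2
        / (k * math.factorial(2 * k - 2))
    )
    phase = (-1j) ** (k - 1)
    masks = []
    for o in range(k):
        d = np.cos(theta - np.pi * o / k)
        lobe = np.where(d > 0, d, 0.0) ** (k - 1)
        masks.append(np.sqrt(2.0) * c * phase * lobe)
    return masks


@dataclass
class PyramidCoeffs:
    """Coefficients of a complex steerable pyramid.

    Attributes
    ----------
    bands : dict[(int, int), ndarray]
        Complex oriented bands keyed by ``(scale, orientation)`` with
        ``scale`` in ``1..n_scales`` and ``orientation`` in
        ``0..n_orientations-1``.  The band at scale ``s`` is downsampled by
        ``2**(s-1)`` relative to the input.
    highpass : ndarray
        Real highpass residual at full resolution.
    lowpass : ndarray
        Real lowpass residual at the coarsest resolution.
    """

    bands: dict[tuple[int, int], np.ndarray]
    highpass: np.ndarray
    lowpass: np.ndarray
    n_scales: int
    n_orientations: int

    def band(self, scale: int, orientation: int) -> np.ndarray:
        return self.bands[(scale, orientation)]

    def total_energy(self) -> float:
        """Frame energy of all coefficients (equals input energy exactly).

        Complex bands are single-sided in frequency; with the signal
        scaling convention their spatial energy times ``4**(s-1)`` equals
        the symmetrized spectral energy share, so the weighted sum below
        reproduces ``sum(pixels**2)`` of the input (Parseval).
        """
        e = float(np.sum(self.highpass**2))
        for (s, _o), b in self.bands.items():
            e += 4.0 ** (s - 1) * float(np.sum(np.abs(b) ** 2))
        e += 4.0**self.n_scales * float(np.sum(self.lowpass**2))
        return e

    def save(self, directory) -> None:
        """Write per-band arrays (``.npy``) plus a JSON manifest for debugging."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "highpass.npy", self.highpass)
        np.save(d / "lowpass.npy", self.lowpass)
        for (s, o), b in self.bands.items():
            np.save(d / f"band_s{s}_o{o}.npy", b)
        manifest = {
            "n_scales": self.n_scales,
            "n_orientations": self.n_orientations,
            "bands": {f"s{s}_o{o}": list(b.shape) for (s, o), b in self.bands.items()},
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def build_pyramid(
    img: GrayImage, n_scales: int = 4, n_orientations: int = 4
) -> PyramidCoeffs:
    """Decompose an image into a complex steerable pyramid.

    Parameters
    ----------
    img : GrayImage
        Input image; both dimensions must be divisible by ``2**n_scales``.
    n_scales, n_orientations : int
        Number of radial scales and angular orientations (defaults 4, 4).
    """
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    h, w = img.shape
    div = 2**n_scales
    if h % div or w % div:
        raise ValueError(
            f"image dimensions {h}x{w} not divisible by 2**n_scales = {div}"
        )

    spec = np.fft.fftshift(np.fft.fft2(img.pixels))
    r, theta = _polar_grids((h, w))
    highpass = np.fft.ifft2(np.fft.ifftshift(spec * _hi_mask(r, np.pi))).real
    lodft = spec * _lo_mask(r, np.pi)

    bands: dict[tuple[int, int], np.ndarray] = {}
    for s in range(1, n_scales + 1):
        ch, cw = lodft.shape
        r, theta = _polar_grids((ch, cw))
        him = _hi_mask(r, np.pi / 2)
        for o, ang in enumerate(_angular_masks(theta, n_orientations)):
            band = np.fft.ifft2(np.fft.ifftshift(lodft * him * ang))
            bands[(s, o)] = band
        lodft = lodft * _lo_mask(r, np.pi / 2)
        # alias-free downsampling: central spectral crop, signal scaling
        lodft = lodft[ch // 4 : 3 * ch // 4, cw // 4 : 3 * cw // 4] / 4.0

    lowpass = np.fft.ifft2(np.fft.ifftshift(lodft)).real
    return PyramidCoeffs(bands, highpass, lowpass, n_scales, n_orientations)


def filter_stack(
    shape: tuple[int, int], n_scales: int = 4, n_orientations: int = 4
) -> dict:
    """Full-resolution amplitude masks of every filter in the pyramid.

    Returns a dict with keys ``highpass``, ``lowpass`` (real masks) and
    ``bands`` (dict keyed by ``(scale, orientation)`` of complex masks,
    all at full resolution, fftshift layout).  Used to assert the
    tight-frame identity: ``hp^2 + sum_sym |band|^2 + lp^2 == 1`` at every
    frequency, where ``sum_sym`` averages each band's response at ``w``
    and ``-w`` (the bands are analytic, hence one-sided).
    """
    r, theta = _polar_grids(shape)
    hp = _hi_mask(r, np.pi)
    cumlo = _lo_mask(r, np.pi)
    bands: dict[tuple[int, int], np.ndarray] = {}
    for s in range(1, n_scales + 1):
        rc = np.pi / 2**s
        him = _hi_mask(r, rc)
        for o, ang in enumerate(_angular_masks(theta, n_orientations)):
            bands[(s, o)] = cumlo * him * ang
        cumlo = cumlo * _lo_mask(r, rc)
    return {"highpass": hp, "bands": bands, "lowpass": cumlo}
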