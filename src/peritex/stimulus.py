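"""Stimulus construction: scrambling, matching, sampling, compositing.

Implements the texture-control procedures and stimulus geometries of the
3-AFC texture-discrimination task:

* **Phase scrambling** -- replace an image's Fourier phases with those of
  a seeded uniform-noise image while keeping its Fourier amplitude
  spectrum (FAS), destroying the higher-order statistics (HOS) that give
  naturalistic textures their structure.
* **Histogram matching** -- rank-order substitution of pixel values, used
  to co-match a naturalistic/scrambled pair to the average of their
  histograms so brightness cues cannot drive the task.
* **Iterative FAS + histogram matching** -- alternate spectrum
  substitution and histogram matching (30 rounds by default) to build
  surround textures dissimilar in HOS only (FAS matched to the target) or
  in both FAS and HOS.
* **Patch sampling** -- seeded random 90-degree rotation followed by a
  uniform random crop, the trial-by-trial texture sampling of the task.
* **Stimulus compositing** -- disk or split targets with ring / half-ring
  surrounds, background-colored gaps, and linear alpha gradients at every
  texture boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .image import GrayImage

__all__ = [
    "StimulusSpec",
    "TexturePair",
    "phase_scramble",
    "histogram_match",
    "iterative_fas_hist_match",
    "MatchResult",
    "sample_patch",
    "compose_stimulus",
]

logger = logging.getLogger(__name__)

TARGET_SHAPES = ("disk", "split")
SURROUND_KINDS = ("none", "ring", "half_ring_inward", "half_ring_outward")
GAP_MODES = ("shrink_target", "enlarge_surround")
SURROUND_CONTENTS = ("same_texture", "hos_dissimilar", "fas_hos_dissimilar", "phase_scrambled")


@dataclass
class StimulusSpec:
    """Geometry and content description of one stimulus.

    Angles and sizes are in degrees of visual field; conversion to pixels
    uses the ``px_per_deg`` of the source textures at composition time.
    ``gap_mode`` selects how a nonzero gap is realized: by shrinking the
    target while keeping the surround fixed, or by enlarging the surround
    while keeping the target fixed.
    """

    eccentricity_deg: float = 12.0
    target_shape: str = "disk"
    target_diameter_deg: float = 3.7
    surround_kind: str = "ring"
    surround_width_factor: float = 1.0
    gap_deg: float = 0.5
    gap_mode: str = "shrink_target"
    surround_content: str = "same_texture"
    edge_gradient_px: int = 4
    canvas_px: int | None = None

    def __post_init__(self) -> None:
        if self.target_shape not in TARGET_SHAPES:
            raise ValueError(f"unknown target_shape {self.target_shape!r}")
        if self.surround_kind not in SURROUND_KINDS:
            raise ValueError(f"unknown surround_kind {self.surround_kind!r}")
        if self.gap_mode not in GAP_MODES:
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")
        if self.surround_content not in SURROUND_CONTENTS:
            raise ValueError(f"unknown surround_content {self.surround_content!r}")
        if self.target_diameter_deg <= 0:
            raise ValueError("target_diameter_deg must be > 0")
        if self.gap_deg < 0:
            raise ValueError("gap_deg must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StimulusSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class TexturePair:
    """A naturalistic texture and its phase-scrambled counterpart.

    After histogram co-matching the two share their FAS (to numerical
    precision) and approximately share their sorted pixel values, so they
    differ only in higher-order statistics.
    """

    naturalistic: GrayImage
    scrambled: GrayImage


def fourier_amplitude(img: GrayImage) -> np.ndarray:
    """Fourier amplitude spectrum (FAS) of an image."""
    return np.abs(np.fft.fft2(img.pixels))


def phase_scramble(img: GrayImage, rng_seed: int) -> GrayImage:
    """Replace the image's Fourier phases with seeded uniform-noise phases.

    A uniform[0, 1] noise image is generated from ``rng_seed`` and its
    phase spectrum is combined with the input's amplitude spectrum; the
    output therefore has exactly the input's FAS but no higher-order
    structure.  Only the noise phases matter, so the choice of a uniform
    amplitude distribution for the noise is immaterial.
    """
    rng = np.random.default_rng(rng_seed)
    noise = rng.random(img.shape)
    amp = np.abs(np.fft.fft2(img.pixels))
    phase = np.angle(np.fft.fft2(noise))
    out = np.fft.ifft2(amp * np.exp(1j * phase)).real
    return GrayImage(out, img.px_per_deg)


def histogram_match(img: GrayImage, reference_sorted_values: np.ndarray) -> GrayImage:
    """Rank-order substitution of pixel values.

    The sorted pixels of the output equal ``reference_sorted_values``
    exactly; the spatial rank order of the input is preserved, with ties
    broken by row-major scan order (stable sort).
    """
    ref = np.asarray(reference_sorted_values, dtype=np.float64).ravel()
    flat = img.pixels.ravel()
    if ref.size != flat.size:
        raise ValueError(
            f"reference length {ref.size} != pixel count {flat.size}"
        )
    order = np.argsort(flat, kind="stable")
    out = np.empty_like(flat)
    out[order] = np.sort(ref)
    return GrayImage(out.reshape(img.shape), img.px_per_deg)


class MatchResult(NamedTuple):
    image: GrayImage
    fas_error: float
    hist_error: float
    converged: bool


def iterative_fas_hist_match(
    img: GrayImage,
    fas_reference: GrayImage,
    hist_reference: np.ndarray,
    n_iter: int = 30,
) -> MatchResult:
    """Alternate FAS substitution and histogram matching.

    Runs ``n_iter`` rounds of (impose the reference FAS, then match the
    reference histogram), ending on the histogram step, and reports the
    final relative FAS error and histogram error.  If either error fails
    to decrease monotonically over the last five iterations a convergence
    warning is logged (convergence is reported, not enforced).
    """
    if img.shape != fas_reference.shape:
        raise ValueError("images must share a shape")
    ref_amp = np.abs(np.fft.fft2(fas_reference.pixels))
    ref_sorted = np.sort(np.asarray(hist_reference, dtype=np.float64).ravel())
    amp_norm = np.linalg.norm(ref_amp)
    hist_norm = max(np.linalg.norm(ref_sorted), np.finfo(float).tiny)

    current = img
    fas_hist_errors: list[tuple[float, float]] = []
    for _ in range(n_iter):
        spec = np.fft.fft2(current.pixels)
        phase = np.angle(spec)
        current = GrayImage(
            np.fft.ifft2(ref_amp * np.exp(1j * phase)).real, img.px_per_deg
        )
        current = histogram_match(current, ref_sorted)
        fas_err = float(
            np.linalg.norm(np.abs(np.fft.fft2(current.pixels)) - ref_amp) / amp_norm
        )
        hist_err = float(
            np.linalg.norm(np.sort(current.pixels.ravel()) - ref_sorted) / hist_norm
        )
        fas_hist_errors.append((fas_err, hist_err))

    converged = True
    tail = fas_hist_errors[-5:]
    for i in range(1, len(tail)):
        if tail[i][0] > tail[i - 1][0] * (1 + 1e-9):
            converged = False
    if not converged:
        logger.warning(
            "iterative_fas_hist_match: FAS error not monotonically decreasing "
            "over the last iterations (final %.3g)", tail[-1][0]
        )
    return MatchResult(current, *fas_hist_errors[-1], converged)


def sample_patch(
    source: GrayImage, size_px: tuple[int, int], rng_seed: int
) -> GrayImage:
    """Seeded 90-degree rotation followed by a uniform random crop."""
    h, w = size_px
    rng = np.random.default_rng(rng_seed)
    k = int(rng.integers(4))
    rotated = np.rot90(source.pixels, k)
    sh, sw = rotated.shape
    if h > sh or w > sw:
        raise ValueError(f"patch {h}x{w} larger than source {sh}x{sw}")
    top = int(rng.integers(sh - h + 1))
    left = int(rng.integers(sw - w + 1))
    return GrayImage(rotated[top : top + h, left : left + w], source.px_per_deg)


def _linear_ramp_inside(mask: np.ndarray, gradient_px: float) -> np.ndarray:
    """Alpha map: 1 deep inside ``mask``, linear ramp to 0 at its boundary."""
    if gradient_px <= 0:
        return mask.astype(float)
    dist = ndimage.distance_transform_edt(mask)
    return np.clip(dist / gradient_px, 0.0, 1.0)


def stimulus_geometry(spec: StimulusSpec, px_per_deg: float) -> dict:
    """Resolve a StimulusSpec into pixel-space geometry.

    Returns target radius as rendered, surround inner/outer radii, gap in
    pixels and canvas size.  The ring inner radius always exceeds the
    rendered target radius by the gap.
    """
    r_nominal = spec.target_diameter_deg / 2 * px_per_deg
    gap_px = spec.gap_deg * px_per_deg
    if spec.target_shape == "split":
        # split target: straight sides stay continuous with the surround
        # (inner radius = target radius); the gap is carved around the
        # curved sides only, so target area matches the continuous disk
        r_target = r_nominal
        r_inner = r_nominal
    elif spec.gap_mode == "shrink_target":
        r_target = r_nominal - gap_px
        r_inner = r_nominal
    else:  # enlarge_surround
        r_target = r_nominal
        r_inner = r_nominal + gap_px
    if r_target <= 0 or r_inner <= 0:
        raise ValueError("inconsistent geometry: non-positive radius")
    width = spec.surround_width_factor * 2 * r_nominal
    r_outer = r_inner + width
    canvas = spec.canvas_px
    if canvas is None:
        canvas = int(np.ceil((2 * r_outer + 2 * spec.edge_gradient_px + 8) / 16)) * 16
        canvas = max(canvas, 32)
    return {
        "r_target": r_target,
        "r_inner": r_inner,
        "r_outer": r_outer,
        "gap_px": gap_px,
        "canvas": canvas,
    }


def _target_mask(spec: StimulusSpec, geom: dict, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    cy, cx = h // 2, w // 2
    yy, xx = np.ogrid[:h, :w]
    if spec.target_shape == "disk":
        return np.hypot(yy - cy, xx - cx) <= geom["r_target"]
    # split target: two semicircles with straight sides facing outward.
    # Each half-disk of the original target is translated outward until its
    # straight edge aligns with the surround's inner edge; the curved sides
    # meet near the stimulus center, preserving texture area.
    r = geom["r_target"]
    d = geom["r_inner"]
    left = (np.hypot(yy - cy, xx - (cx - d)) <= r) & (xx >= cx - d)
    right = (np.hypot(yy - cy, xx - (cx + d)) <= r) & (xx <= cx + d)
    return left | right


def _surround_mask(spec: StimulusSpec, geom: dict, shape: tuple[int, int],
                   target: np.ndarray) -> np.ndarray:
    h, w = shape
    cy, cx = h // 2, w // 2
    yy, xx = np.ogrid[:h, :w]
    r = np.hypot(yy - cy, xx - cx)
    if spec.target_shape == "disk":
        mask = (r >= geom["r_inner"]) & (r <= geom["r_outer"])
    else:
        # surround wraps the split target: outer disk minus target minus a
        # gap band around the curved sides (between the straight edges);
        # surround touches the target at the straight edges (continuity).
        outer = r <= geom["r_outer"]
        dist_out = ndimage.distance_transform_edt(~target)
        between = np.abs(np.arange(w)[None, :] - cx) < geom["r_inner"]
        gap_band = (dist_out > 0) & (dist_out <= geom["gap_px"]) & between
        mask = outer & ~target & ~gap_band
    if spec.surround_kind == "half_ring_inward":
        mask = mask & (np.broadcast_to(xx, mask.shape) <= cx)
    elif spec.surround_kind == "half_ring_outward":
        mask = mask & (np.broadcast_to(xx, mask.shape) >= cx)
    return mask


def compose_stimulus(
    spec: StimulusSpec,
    target_src: GrayImage,
    surround_src: GrayImage,
    background: float,
    rng_seed: int,
    return_masks: bool = False,
):
    """Render one stimulus: target + surround over a gray background.

    Target and surround patches are sampled independently from their
    source textures (seeded rotation + crop).  The surround is composited
    first and the target on top, each with a linear alpha gradient of
    ``edge_gradient_px`` at its boundaries, so continuous target-surround
    boundaries crossfade while gaps show the background.  By convention
    the fixation point lies to the left of the canvas, so the inward
    half-ring is the left half.
    """
    px_per_deg = target_src.px_per_deg
    geom = stimulus_geometry(spec, px_per_deg)
    n = geom["canvas"]
    shape = (n, n)
    g = spec.edge_gradient_px

    rng = np.random.default_rng(rng_seed)
    t_seed, s_seed = [int(s) for s in rng.integers(2**31 - 1, size=2)]
    target_tex = sample_patch(target_src, shape, t_seed).pixels
    surround_tex = sample_patch(surround_src, shape, s_seed).pixels

    target = _target_mask(spec, geom, shape)
    a_target = _linear_ramp_inside(target, g)

    out = np.full(shape, float(background))
    a_surround = np.zeros(shape)
    if spec.surround_kind != "none":
        surround = _surround_mask(spec, geom, shape, target)
        a_surround = _linear_ramp_inside(surround, g)
        out = out * (1 - a_surround) + surround_tex * a_surround
    out = out * (1 - a_target) + target_tex * a_target

    img = GrayImage(out, px_per_deg)
    if return_masks:
        return img, {"target_alpha": a_target, "surround_alpha": a_surround,
                     "geometry": geom}
    return img
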