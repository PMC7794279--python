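"""Synthetic inputs: procedural textures and simulated behavioral data.

The package is exercised end-to-end without photographic sources or human
participants:

* :func:`generate_texture` builds large structured textures procedurally
  (sparse oriented strokes, blobs, or jittered grids).  Like naturalistic
  textures, they carry higher-order statistics (HOS) -- sparseness,
  oriented structure, phase alignment across scales, skewed pixel
  histograms -- that phase scrambling destroys while the Fourier
  amplitude spectrum (FAS) is preserved, which is exactly the dissociation
  the discrimination task rests on.
* :func:`simulate_behavior` is the generative twin of the binomial GLMM
  used for analysis: participant x texture random effects plus fixed
  condition log-odds ratios (LORs) produce Bernoulli trial outcomes, so
  recovery of known LORs can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import GrayImage
from .stimulus import TexturePair, histogram_match, iterative_fas_hist_match, phase_scramble

__all__ = [
    "ProceduralTextureParams",
    "BehavioralSimParams",
    "generate_texture",
    "make_texture_pair",
    "simulate_behavior",
]

ELEMENT_KINDS = ("oriented_edge", "blob", "grid")


@dataclass
class ProceduralTextureParams:
    """Parameters of the procedural texture generator.

    ``density`` is the expected number of texture elements per 64x64-pixel
    tile; ``orientation_bandwidth`` (degrees) is the spread of element
    orientations around horizontal for ``oriented_edge`` textures.
    Elements are placed by a clustered (Thomas) point process --
    ``cluster_size`` elements on average per cluster, scattered with SD
    ``cluster_sd_px`` around Poisson cluster centers -- because natural
    textures are spatially inhomogeneous, and that clumpiness is what
    makes crop-to-crop statistic variability higher for structured
    textures than for their phase-scrambled counterparts.  The default
    size of 1024 px matches the large source textures that stimuli are
    cropped from.
    """

    size_px: int = 1024
    element_kind: str = "oriented_edge"
    density: float = 6.0
    orientation_bandwidth_deg: float = 12.0
    contrast: float = 0.18
    cluster_size: float = 8.0
    cluster_sd_px: float = 20.0
    inhomogeneity: float = 0.6
    inhomogeneity_scale_px: float = 96.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.element_kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element_kind {self.element_kind!r}")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.size_px % 16:
            raise ValueError("size_px must be a multiple of 16")


def _stroke_kernel(length: float, width: float, angle_rad: float, size: int) -> np.ndarray:
    """Oriented Gaussian line element, zero-mean free (positive lobe only)."""
    half = size // 2
    yy, xx = np.mgrid[-half:half, -half:half]
    u = xx * np.cos(angle_rad) + yy * np.sin(angle_rad)
    v = -xx * np.sin(angle_rad) + yy * np.cos(angle_rad)
    return np.exp(-(u**2) / (2 * length**2) - (v**2) / (2 * width**2))


def generate_texture(params: ProceduralTextureParams) -> GrayImage:
    """Seeded structured texture with nonzero higher-order statistics.

    Sparse one-sided (bright-biased) elements produce a positively skewed
    pixel histogram and kurtotic, phase-aligned band activations; an
    ``oriented_edge`` texture concentrates band energy around horizontal.
    """
    n = params.size_px
    rng = np.random.default_rng(params.rng_seed)
    n_elements = int(params.density * (n / 64) ** 2)

    impulse_layers: dict[int, np.ndarray] = {}
    if params.element_kind == "oriented_edge":
        n_bins = 8
        bw = np.deg2rad(params.orientation_bandwidth_deg)
        angles = rng.normal(0.0, bw, size=n_elements)
        bins = np.clip(
            np.round((angles + 3 * bw) / (6 * bw) * (n_bins - 1)).astype(int), 0, n_bins - 1
        )
        bin_angle = (np.arange(n_bins) + 0.5) / n_bins * 6 * bw - 3 * bw
        kernels = {b: _stroke_kernel(9.0, 1.1, bin_angle[b], 48) for b in range(n_bins)}
    elif params.element_kind == "blob":
        bins = np.zeros(n_elements, dtype=int)
        kernels = {0: _stroke_kernel(3.0, 3.0, 0.0, 32)}
    else:  # grid: jittered lattice of blobs
        spacing = max(8, int(round(64 / np.sqrt(params.density))))
        ys, xs = np.meshgrid(
            np.arange(0, n, spacing), np.arange(0, n, spacing), indexing="ij"
        )
        pos = np.stack([ys.ravel(), xs.ravel()], axis=1)
        pos = (pos + rng.normal(0, spacing * 0.08, size=pos.shape)).astype(int) % n
        n_elements = len(pos)
        bins = np.zeros(n_elements, dtype=int)
        kernels = {0: _stroke_kernel(2.5, 2.5, 0.0, 32)}

    if params.element_kind == "grid":
        positions = pos
    else:
        # Thomas process: Poisson cluster centers, Gaussian offsets
        n_clusters = max(1, int(round(n_elements / params.cluster_size)))
        centers = rng.integers(0, n, size=(n_clusters, 2))
        owner = rng.integers(0, n_clusters, size=n_elements)
        offsets = rng.normal(0.0, params.cluster_sd_px, size=(n_elements, 2))
        positions = (centers[owner] + offsets).astype(int) % n
    # bright-biased amplitudes -> positive pixel skewness
    amplitudes = rng.exponential(1.0, size=n_elements) * np.where(
        rng.random(n_elements) < 0.8, 1.0, -0.6
    )

    canvas = np.zeros((n, n))
    for b, kernel in kernels.items():
        sel = bins == b
        if not np.any(sel):
            continue
        impulses = np.zeros((n, n))
        np.add.at(impulses, (positions[sel, 0], positions[sel, 1]), amplitudes[sel])
        spec = np.fft.fft2(impulses) * np.fft.fft2(
            np.fft.ifftshift(np.pad(kernel, ((0, n - kernel.shape[0]),
                                             (0, n - kernel.shape[1])))),
        )
        canvas += np.fft.ifft2(spec).real

    if params.inhomogeneity > 0:
        # smooth multiplicative contrast field: natural textures vary in
        # local contrast/density over large scales; phase scrambling
        # homogenizes this, which is what makes crop statistics of
        # structured textures more variable than those of their scrambles
        f = np.fft.fft2(rng.standard_normal((n, n)))
        fy = np.fft.fftfreq(n)[:, None]
        fx = np.fft.fftfreq(n)[None, :]
        lowpass = np.exp(-((fy**2 + fx**2) * (params.inhomogeneity_scale_px**2) * 2))
        field = np.fft.ifft2(f * lowpass).real
        field /= max(field.std(), 1e-12)
        canvas = canvas * np.exp(params.inhomogeneity * field)

    canvas -= canvas.mean()
    sd = canvas.std()
    if sd > 0:
        canvas = canvas / sd * params.contrast
    return GrayImage(np.clip(canvas + 0.5, 0.0, 1.0), px_per_deg=30.0)


def make_texture_pair(
    params: ProceduralTextureParams, n_match_iter: int = 10
) -> TexturePair:
    """Structured texture plus phase-scrambled counterpart, co-matched.

    The scrambled image is built from the texture's FAS with seeded random
    phases; both images are then iteratively matched to the average of
    their pixel histograms while re-imposing the texture's original FAS,
    ending on the FAS step so the pair shares its amplitude spectrum to
    numerical precision while the histograms agree approximately.
    """
    nat = generate_texture(params)
    scr = phase_scramble(nat, params.rng_seed + 1)
    avg_sorted = (
        np.sort(nat.pixels.ravel()) + np.sort(scr.pixels.ravel())
    ) / 2.0

    ref_amp = np.abs(np.fft.fft2(nat.pixels))

    def _match(img: GrayImage) -> GrayImage:
        res = iterative_fas_hist_match(img, nat, avg_sorted, n_iter=n_match_iter)
        # end on the FAS step so the pair's spectra agree exactly
        spec = np.fft.fft2(res.image.pixels)
        out = np.fft.ifft2(ref_amp * np.exp(1j * np.angle(spec))).real
        return GrayImage(out, img.px_per_deg)

    return TexturePair(naturalistic=_match(nat), scrambled=_match(scr))


@dataclass
class BehavioralSimParams:
    """Parameters of the behavioral-data generator.

    ``fixed_lors`` maps factor names to their true log-odds ratios (the
    effect of that factor's level-1 condition relative to level 0);
    ``baseline_logit`` is the logit of the success probability in the
    all-zeros condition; ``random_sd`` maps grouping names ("texture",
    "participant") to the SD of their random intercepts and slopes
    (independent, shared SD within a grouping).  The default of 90 trials
    per condition matches a typical experimental session.
    """

    n_participants: int = 10
    n_textures: int = 1
    trials_per_condition: int = 90
    fixed_lors: dict = field(default_factory=lambda: {"surround": -1.0})
    baseline_logit: float = 1.0
    random_sd: dict = field(default_factory=lambda: {"texture": 0.0, "participant": 0.3})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if any(sd < 0 for sd in self.random_sd.values()):
            raise ValueError("random-effect SDs must be >= 0")


_CLASSES = np.array(["scr_left", "scr_right", "none"])
_RESPONSES = {"scr_left": "left", "scr_right": "right", "none": "none"}


def simulate_behavior(params: BehavioralSimParams) -> pd.DataFrame:
    """Simulate trial records from the generative logistic model.

    Each participant runs one session per texture; a session visits every
    combination of factor levels (the conditions) with
    ``trials_per_condition`` trials each.  Per-trial success probability
    is the inverse logit of baseline + fixed LORs + random effects, and
    the 3-AFC response is reconstructed to be consistent with the Bernoulli
    ``correct`` outcome (errors pick one of the two wrong responses).
    """
    rng = np.random.default_rng(params.rng_seed)
    factors = list(params.fixed_lors)
    n_cond = 2 ** len(factors)
    levels = [
        [(c >> i) & 1 for i in range(len(factors))] for c in range(n_cond)
    ]

    sd_tex = params.random_sd.get("texture", 0.0)
    sd_par = params.random_sd.get("participant", 0.0)

    rows = []
    for t in range(params.n_textures):
        tex_int = rng.normal(0, sd_tex)
        tex_slopes = rng.normal(0, sd_tex, size=len(factors))
        for p in range(params.n_participants):
            par_int = rng.normal(0, sd_par)
            par_slopes = rng.normal(0, sd_par, size=len(factors))
            session = f"P{p:02d}-T{t:02d}"
            for lev in levels:
                eta = params.baseline_logit + tex_int + par_int
                for i, f in enumerate(factors):
                    eta += lev[i] * (
                        params.fixed_lors[f] + tex_slopes[i] + par_slopes[i]
                    )
                prob = 1.0 / (1.0 + np.exp(-eta))
                correct = rng.random(params.trials_per_condition) < prob
                true_class = rng.choice(_CLASSES, size=params.trials_per_condition)
                for k in range(params.trials_per_condition):
                    tc = true_class[k]
                    if correct[k]:
                        resp = _RESPONSES[tc]
                    else:
                        wrong = [r for c, r in _RESPONSES.items() if c != tc]
                        resp = wrong[int(rng.integers(2))]
                    row = {
                        "participant_id": f"P{p:02d}",
                        "session_id": session,
                        "texture_id": f"T{t:02d}",
                        "true_class": tc,
                        "response": resp,
                        "correct": bool(correct[k]),
                    }
                    for i, f in enumerate(factors):
                        row[f"cond_{f}"] = lev[i]
                    rows.append(row)
    return pd.DataFrame(rows)
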