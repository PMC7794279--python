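"""Summary-statistics model observer for the 3-AFC texture task.

The observer sees a pair of stimuli (left, right) and must report where
the phase-scrambled target is ({Scr, Nat} -> "scr_left", {Nat, Scr} ->
"scr_right", {Nat, Nat} -> "none").  Its pipeline mirrors the
summary-statistics account of peripheral vision:

1. compute the PS statistic vector of each stimulus over a fixed
   circular pooling window centered on the target (Bouma's-law size);
2. take the difference (first minus second) -> 782 predictors per pair;
3. add Gaussian noise per predictor, with SD equal to that predictor's
   SD over the whole training set (all conditions pooled) -- the noise
   level that brings model performance into the human range;
4. normalize predictors to unit variance (divisors frozen from the noisy
   training set) and classify with L2-penalized multinomial logistic
   regression, the penalty chosen by 10-fold cross-validation;
5. at test time, draw fresh noise, apply the frozen normalization, and
   take the arg-max class (ties broken by fixed class order).

:func:`simulate_experiment` reproduces the surround manipulations of the
four experiments with procedural textures, training several observer
replicates (different training draws and noise) and emitting trial
records compatible with the behavioral analysis module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import KFold

from .image import GrayImage
from .statistics import (
    PSParams,
    PoolingWindow,
    bouma_pooling_diameter,
    compute_ps_statistics,
    statistic_difference,
)
from .stimulus import StimulusSpec, compose_stimulus, histogram_match, iterative_fas_hist_match
from .synth import ProceduralTextureParams, generate_texture, make_texture_pair

logger = logging.getLogger(__name__)

__all__ = [
    "TrialStimulusPair",
    "ObserverModel",
    "build_predictors",
    "calibrate_noise",
    "train_observer",
    "evaluate_observer",
    "simulate_experiment",
    "EXPERIMENTS",
]

CLASSES = ("scr_left", "scr_right", "none")
_RESPONSE = {"scr_left": "left", "scr_right": "right", "none": "none"}

FULL_SCALE_TRAIN_PER_CLASS = 250
FULL_SCALE_TEST_PER_CLASS = 500
DEFAULT_BACKGROUND = 0.1


@dataclass
class TrialStimulusPair:
    """One ordered stimulus pair of the 3-AFC task."""

    left: GrayImage
    right: GrayImage
    true_class: str
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")


@dataclass
class ObserverModel:
    """Trained observer: classifier weights plus noise/normalization state."""

    weights: np.ndarray  # (3, p) in CLASSES order
    intercepts: np.ndarray  # (3,)
    noise_sd: np.ndarray  # (p,)
    scale: np.ndarray  # (p,) unit-variance divisors
    penalty: float  # selected L2 penalty (1 / C)
    rng_seed: int

    def decision_values(self, predictors: np.ndarray) -> np.ndarray:
        return predictors @ self.weights.T + self.intercepts

    def predict(self, predictors: np.ndarray) -> np.ndarray:
        """Arg-max class per row; ties resolve to the first class in order."""
        dv = self.decision_values(predictors)
        return np.asarray(CLASSES)[np.argmax(dv, axis=1)]


def build_predictors(
    pair: TrialStimulusPair, params: PSParams, window: PoolingWindow
) -> np.ndarray:
    """Difference of the pair's statistic vectors (first minus second)."""
    a = compute_ps_statistics(pair.left, params, window)
    b = compute_ps_statistics(pair.right, params, window)
    return statistic_difference(a, b).values


def calibrate_noise(training_predictors: np.ndarray) -> np.ndarray:
    """Per-predictor SD over the pooled training set (all conditions).

    A constant predictor gets SD 0 and therefore receives no noise.
    """
    P = np.asarray(training_predictors, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need at least 2 training rows to calibrate noise")
    return P.std(axis=0, ddof=0)


def _fit_classifier(
    P_noisy: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    n_lambdas: int,
    cv_folds: int,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Normalize and fit the CV-penalized multinomial classifier."""
    scale = P_noisy.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    Pn = P_noisy / scale
    Cs = np.logspace(-3, 3, n_lambdas)
    clf = LogisticRegressionCV(
        Cs=Cs,
        cv=KFold(cv_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))),
        penalty="l2",
        max_iter=2000,
        tol=1e-4,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", FutureWarning)
        clf.fit(Pn, labels)
    order = [list(clf.classes_).index(c) for c in CLASSES]
    weights = clf.coef_[order]
    intercepts = clf.intercept_[order]
    penalty = float(1.0 / clf.C_[0])
    return weights, intercepts, penalty, scale


def _train_from_predictors(
    P: np.ndarray,
    labels: np.ndarray,
    rng_seed: int,
    n_lambdas: int = 10,
    cv_folds: int = 10,
    noise_factor: float = 1.0,
) -> ObserverModel:
    """Train on raw (noise-free) predictors: noise -> normalize -> fit.

    ``noise_factor`` rescales the calibrated noise SDs (1 = the default
    SD-matched level; 0 = noiseless, for robustness probes).
    """
    labels = np.asarray(labels)
    if set(labels) != set(CLASSES):
        raise ValueError("all three classes must be present in training data")
    rng = np.random.default_rng(rng_seed)
    noise_sd = calibrate_noise(P) * noise_factor
    P_noisy = P + rng.standard_normal(P.shape) * noise_sd
    weights, intercepts, penalty, scale = _fit_classifier(
        P_noisy, labels, rng, n_lambdas, cv_folds
    )
    return ObserverModel(weights, intercepts, noise_sd, scale, penalty, rng_seed)


def train_observer(
    train_pairs: list[TrialStimulusPair],
    params: PSParams,
    window: PoolingWindow,
    rng_seed: int,
    n_lambdas: int = 10,
    cv_folds: int = 10,
) -> ObserverModel:
    """Train an observer from stimulus pairs (image pipeline)."""
    P = np.stack([build_predictors(p, params, window) for p in train_pairs])
    labels = np.array([p.true_class for p in train_pairs])
    return _train_from_predictors(P, labels, rng_seed, n_lambdas, cv_folds)


def _evaluate_from_predictors(
    model: ObserverModel,
    P: np.ndarray,
    labels: np.ndarray,
    conditions: np.ndarray,
    rng_seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fresh test noise, frozen normalization, per-condition accuracy."""
    rng = np.random.default_rng(rng_seed)
    P_noisy = P + rng.standard_normal(P.shape) * model.noise_sd
    pred = model.predict(P_noisy / model.scale)
    correct = pred == labels
    rows = []
    for cond in pd.unique(conditions):
        sel = conditions == cond
        rows.append({"condition": cond, "accuracy": float(correct[sel].mean()),
                     "n": int(sel.sum())})
    return pd.DataFrame(rows), pred


def evaluate_observer(
    model: ObserverModel,
    test_pairs: list[TrialStimulusPair],
    params: PSParams,
    window: PoolingWindow,
    rng_seed: int,
) -> pd.DataFrame:
    """Per-condition accuracy of a trained observer on stimulus pairs."""
    P = np.stack([build_predictors(p, params, window) for p in test_pairs])
    labels = np.array([p.true_class for p in test_pairs])
    conditions = np.array([p.condition_label for p in test_pairs])
    table, _ = _evaluate_from_predictors(model, P, labels, conditions, rng_seed)
    return table


# ---------------------------------------------------------------------------
# experiment definitions
# ---------------------------------------------------------------------------

def _spec(**kw) -> dict:
    base = dict(
        eccentricity_deg=12.0,
        target_shape="disk",
        target_diameter_deg=3.7,
        surround_kind="ring",
        surround_width_factor=1.0,
        gap_deg=0.0,
        gap_mode="shrink_target",
        surround_content="same_texture",
    )
    base.update(kw)
    return base

# Condition lists per experiment: (label, stimulus spec kwargs, factor levels).
# Factor columns are what the GLMM sees downstream.
EXPERIMENTS: dict[int, dict] = {
    1: {
        "factors": ["surround"],
        "conditions": [
            ("no_surround", _spec(surround_kind="none", surround_width_factor=1.4),
             {"surround": 0}),
            ("surround", _spec(surround_width_factor=1.4), {"surround": 1}),
        ],
    },
    2: {
        "factors": ["discont"],
        "conditions": [
            ("continuous", _spec(surround_width_factor=1.4), {"discont": 0}),
            ("discontinuous",
             _spec(surround_width_factor=1.4, gap_deg=0.35, gap_mode="shrink_target"),
             {"discont": 1}),
        ],
    },
    3: {
        "factors": ["hos", "fas"],
        "conditions": [
            ("same", _spec(), {"hos": 0, "fas": 0}),
            ("hos_dissimilar", _spec(surround_content="hos_dissimilar"),
             {"hos": 1, "fas": 0}),
            ("fas_hos_dissimilar", _spec(surround_content="fas_hos_dissimilar"),
             {"hos": 1, "fas": 1}),
        ],
    },
    4: {
        "factors": ["nat"],
        "conditions": [
            ("scrambled_surround", _spec(surround_content="phase_scrambled"),
             {"nat": 0}),
            ("natural_surround", _spec(), {"nat": 1}),
        ],
    },
}


def _surround_source(content: str, pair, alt_texture: GrayImage | None) -> GrayImage:
    if content == "same_texture":
        return pair.naturalistic
    if content == "phase_scrambled":
        return pair.scrambled
    if alt_texture is None:
        raise ValueError("dissimilar surround requested without an alternate texture")
    ref_sorted = np.sort(pair.naturalistic.pixels.ravel())
    if content == "fas_hos_dissimilar":
        return histogram_match(alt_texture, ref_sorted)
    # hos_dissimilar: FAS and histogram matched to the target texture
    res = iterative_fas_hist_match(alt_texture, pair.naturalistic, ref_sorted, n_iter=30)
    return res.image


def _stimulus_pool(
    spec: StimulusSpec,
    target_src: GrayImage,
    surround_src: GrayImage,
    n_stimuli: int,
    params: PSParams,
    window: PoolingWindow,
    background: float,
    seed_seq: np.random.SeedSequence,
) -> np.ndarray:
    seeds = seed_seq.generate_state(n_stimuli) % (2**31 - 1)
    out = []
    for s in seeds:
        stim = compose_stimulus(spec, target_src, surround_src, background, int(s))
        out.append(compute_ps_statistics(stim, params, window).values)
    return np.stack(out)


def _draw_pairs(
    rng: np.random.Generator,
    nat: np.ndarray,
    scr: np.ndarray,
    n_per_class: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble predictor rows for n pairs of each class from stat pools."""
    rows, labels = [], []
    for cls in CLASSES:
        for _ in range(n_per_class):
            if cls == "scr_left":
                a = scr[rng.integers(len(scr))]
                b = nat[rng.integers(len(nat))]
            elif cls == "scr_right":
                a = nat[rng.integers(len(nat))]
                b = scr[rng.integers(len(scr))]
            else:
                a = nat[rng.integers(len(nat))]
                b = nat[rng.integers(len(nat))]
            rows.append(a - b)
            labels.append(cls)
    return np.stack(rows), np.array(labels)


def simulate_experiment(
    experiment_id: int,
    n_observers: int = 8,
    scale_factor: float = 1.0,
    master_seed: int = 0,
    px_per_deg: float = 7.5,
    background: float = DEFAULT_BACKGROUND,
    texture_kind: str = "oriented_edge",
    n_lambdas: int = 10,
    test_draw_factor: int = 1,
):
    """Simulate one experiment: stimuli, observer replicates, trial records.

    ``scale_factor`` scales the full-scale train/test composition (250 /
    500 pairs per class per condition) down for desk-scale runs; the
    stimulus canvas scales through ``px_per_deg`` (the pooling window
    keeps its 12-degree Bouma size in degrees).  Observer replicates
    share per-condition stimulus statistic pools but draw their own
    training subsets and noise.  Returns ``(trials, accuracy, metadata)``
    where ``trials`` feeds the behavioral analysis and ``accuracy`` has
    one row per observer x condition.
    """
    if experiment_id not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment_id}; choose 1-4")
    exp = EXPERIMENTS[experiment_id]
    n_train = max(3, int(round(FULL_SCALE_TRAIN_PER_CLASS * scale_factor)))
    n_test = max(3, int(round(FULL_SCALE_TEST_PER_CLASS * scale_factor)))

    pooling_px = bouma_pooling_diameter(12.0, 0.5, px_per_deg)
    canvas = int(np.ceil(max(pooling_px * 1.35, pooling_px + 8) / 16)) * 16
    grad_px = max(1, int(round(4 * px_per_deg / 30.0)))
    params = PSParams(pooling_diameter_px=pooling_px)
    window = PoolingWindow.disk((canvas, canvas), pooling_px)

    ss = np.random.SeedSequence(master_seed)
    tex_ss, alt_ss, pool_ss, obs_ss = ss.spawn(4)
    tex_seed = int(tex_ss.generate_state(1)[0] % (2**31 - 1))
    pair = make_texture_pair(
        ProceduralTextureParams(size_px=1024, element_kind=texture_kind, rng_seed=tex_seed)
    )
    alt_texture = None
    if any(c[1]["surround_content"].endswith("dissimilar") for c in exp["conditions"]):
        alt_seed = int(alt_ss.generate_state(1)[0] % (2**31 - 1))
        # the dissimilar-surround texture must stay strongly structured
        # after FAS matching (as the study's retained surrounds did); a
        # regular lattice carries that structure in its phases
        alt_kind = "grid" if texture_kind != "grid" else "oriented_edge"
        alt_texture = generate_texture(
            ProceduralTextureParams(size_px=1024, element_kind=alt_kind, rng_seed=alt_seed)
        )

    # per-condition stat pools (shared across observer replicates)
    pool_nat_train = max(24, 2 * n_train)
    pool_scr_train = max(16, n_train)
    pool_nat_test = max(24, 2 * n_test)
    pool_scr_test = max(16, n_test)
    pools = {}
    cond_seqs = pool_ss.spawn(len(exp["conditions"]))
    for (label, spec_kw, _levels), cseq in zip(exp["conditions"], cond_seqs):
        spec = StimulusSpec(canvas_px=canvas, edge_gradient_px=grad_px, **spec_kw)
        surround_src = _surround_source(spec.surround_content, pair, alt_texture)
        sub = cseq.spawn(4)
        pools[label] = {
            "nat_train": _stimulus_pool(spec, pair.naturalistic, surround_src,
                                        pool_nat_train, params, window, background, sub[0]),
            "scr_train": _stimulus_pool(spec, pair.scrambled, surround_src,
                                        pool_scr_train, params, window, background, sub[1]),
            "nat_test": _stimulus_pool(spec, pair.naturalistic, surround_src,
                                       pool_nat_test, params, window, background, sub[2]),
            "scr_test": _stimulus_pool(spec, pair.scrambled, surround_src,
                                       pool_scr_test, params, window, background, sub[3]),
        }

    cond_labels = [c[0] for c in exp["conditions"]]
    cond_levels = {c[0]: c[2] for c in exp["conditions"]}
    acc_rows, trial_rows = [], []
    lambdas_used, noise_scales = [], []
    for i, oseq in enumerate(obs_ss.spawn(n_observers)):
        s_train, s_noise, s_test = [int(s.generate_state(1)[0] % (2**31 - 1))
                                    for s in oseq.spawn(3)]
        rng = np.random.default_rng(s_train)
        P_list, y_list, c_list = [], [], []
        for label in cond_labels:
            P, y = _draw_pairs(rng, pools[label]["nat_train"],
                               pools[label]["scr_train"], n_train)
            P_list.append(P)
            y_list.append(y)
            c_list.append(np.full(len(y), label))
        model = _train_from_predictors(
            np.concatenate(P_list), np.concatenate(y_list), s_noise,
            n_lambdas=n_lambdas,
        )
        lambdas_used.append(model.penalty)
        noise_scales.append(float(model.noise_sd.mean()))

        rng_t = np.random.default_rng(s_test)
        P_list, y_list, c_list = [], [], []
        for label in cond_labels:
            P, y = _draw_pairs(rng_t, pools[label]["nat_test"],
                               pools[label]["scr_test"], n_test * test_draw_factor)
            P_list.append(P)
            y_list.append(y)
            c_list.append(np.full(len(y), label))
        P_test = np.concatenate(P_list)
        y_test = np.concatenate(y_list)
        c_test = np.concatenate(c_list)
        table, pred = _evaluate_from_predictors(model, P_test, y_test, c_test, s_test)
        for _, row in table.iterrows():
            acc_rows.append({"observer": f"M{i}", "condition": row["condition"],
                             "accuracy": row["accuracy"], "n": row["n"]})
        for k in range(len(y_test)):
            r = {
                "participant_id": f"M{i}",
                "session_id": f"M{i}-exp{experiment_id}",
                "texture_id": f"SYN{tex_seed % 1000:03d}",
                "condition": c_test[k],
                "true_class": y_test[k],
                "response": _RESPONSE[pred[k]],
                "correct": bool(pred[k] == y_test[k]),
            }
            for f in exp["factors"]:
                r[f"cond_{f}"] = cond_levels[c_test[k]][f]
            trial_rows.append(r)

    metadata = {
        "experiment": experiment_id,
        "n_observers": n_observers,
        "scale_factor": scale_factor,
        "master_seed": master_seed,
        "px_per_deg": px_per_deg,
        "canvas_px": canvas,
        "pooling_diameter_px": pooling_px,
        "train_pairs_per_class": n_train,
        "test_pairs_per_class": n_test,
        "texture_seed": tex_seed,
        "penalties": lambdas_used,
        "mean_noise_sd": noise_scales,
        "conditions": cond_labels,
    }
    return pd.DataFrame(trial_rows), pd.DataFrame(acc_rows), metadata
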