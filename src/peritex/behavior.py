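"""Log-odds-ratio analysis of trial data.

Trial records (one row per 3-AFC trial, with a binary ``correct``
outcome, condition factor columns prefixed ``cond_`` coded 0/1, and
``participant_id`` / ``session_id`` / ``texture_id`` identifiers) are
analyzed with:

* a session-exclusion filter (sessions below threshold accuracy in every
  condition are dropped to avoid floor effects);
* per-participant binomial GLMs (Wald intervals and p-values), used to
  display individual effects;
* binomial GLMMs with a random intercept and a random slope per fixed
  effect for each grouping factor (texture, and participants nested
  within texture, or participants only), with all random-effect
  correlations fixed at zero; effects are reported in log-odds-ratio
  (LOR) units with likelihood-ratio-test p-values and profile-likelihood
  confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glmm import RandomTerm, fit_laplace_glmm, lrt_pvalue, profile_ci

logger = logging.getLogger(__name__)

__all__ = [
    "GLMMFit",
    "FixedEffect",
    "exclusion_filter",
    "fit_participant_glm",
    "fit_glmm",
    "lor_to_probability",
    "read_trials_csv",
]


class FixedEffect(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    p_lrt: float
    ci_is_profile: bool = True


@dataclass
class GLMMFit:
    """Fitted mixed model: LORs, intervals, p-values, random-effect SDs."""

    fixed_effects: dict[str, FixedEffect]
    random_sd: dict[str, float]
    loglik: float
    converged: bool
    model_desc: str = ""


class ExclusionResult(NamedTuple):
    kept: pd.DataFrame
    excluded: pd.DataFrame
    excluded_sessions: list[str]


def _condition_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("cond_")]
    if not cols:
        raise ValueError("no condition columns (prefix 'cond_') found")
    return cols


def exclusion_filter(
    records: pd.DataFrame, threshold: float = 0.45
) -> ExclusionResult:
    """Drop sessions performing below ``threshold`` in *every* condition.

    A session is excluded iff its accuracy is strictly below the
    threshold in each of its conditions (floor-effect guard); a session
    above threshold in at least one condition is kept.  Empty sessions
    are ignored with a warning.  The filter is idempotent and
    order-independent.
    """
    cond_cols = _condition_columns(records)
    excluded_sessions = []
    for session, grp in records.groupby("session_id", sort=True):
        if len(grp) == 0:  # pragma: no cover - defensive
            warnings.warn(f"session {session} has no trials; ignored")
            continue
        acc = grp.groupby(cond_cols, sort=False)["correct"].mean()
        if (acc < threshold).all():
            excluded_sessions.append(session)
    mask = records["session_id"].isin(excluded_sessions)
    return ExclusionResult(
        kept=records[~mask].reset_index(drop=True),
        excluded=records[mask].reset_index(drop=True),
        excluded_sessions=excluded_sessions,
    )


def fit_participant_glm(
    records: pd.DataFrame, factors: list[str]
) -> pd.DataFrame:
    """Per-factor LOR from a binomial GLM on one participant's trials.

    Fits ``correct ~ 1 + factors`` with a logit link; returns a frame
    with the LOR estimate, Wald 95% CI and Wald p-value per factor.
    Perfect separation is flagged with infinite CIs rather than raised.
    """
    X = sm.add_constant(records[[f"cond_{f}" for f in factors]].astype(float))
    y = records["correct"].astype(float)
    for f in factors:
        if records[f"cond_{f}"].nunique() < 2:
            raise ValueError(f"factor {f} has a single level in these records")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    rows = []
    ci = fit.conf_int()
    separated = bool(np.any(np.abs(fit.params) > 15))
    for f in factors:
        name = f"cond_{f}"
        lo, hi = (-np.inf, np.inf) if separated else (ci.loc[name, 0], ci.loc[name, 1])
        rows.append(
            {
                "factor": f,
                "lor": float(fit.params[name]),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_wald": float(fit.pvalues[name]),
                "separated": separated,
            }
        )
    return pd.DataFrame(rows)


def _aggregate(
    df: pd.DataFrame, factors: list[str], group_cols: list[str]
) -> pd.DataFrame:
    cols = group_cols + [f"cond_{f}" for f in factors]
    agg = (
        df.groupby(cols, sort=True)["correct"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    return agg


def fit_glmm(
    records: pd.DataFrame,
    fixed: list[str],
    random_structure: str = "texture_participant",
    compute_ci: bool = True,
) -> GLMMFit:
    """Binomial GLMM of ``correct`` on the given condition factors.

    ``random_structure`` is either ``"texture_participant"`` (a random
    effect for texture plus one for participants nested within texture,
    each with an intercept and a slope per fixed effect, all independent)
    or ``"participant"`` (participant random effects only, used when a
    single texture is analyzed).  Groupings with fewer than two levels
    are dropped with a warning; with no grouping left the fit reduces to
    a plain GLM.
    """
    if random_structure not in ("texture_participant", "participant"):
        raise ValueError(f"unknown random_structure {random_structure!r}")
    df = records.copy()
    df["_unit"] = df["texture_id"].astype(str) + ":" + df["participant_id"].astype(str)

    groupings = []
    if random_structure == "texture_participant":
        groupings = [("texture", "texture_id"), ("participant_in_texture", "_unit")]
    else:
        groupings = [("participant", "_unit")]

    agg = _aggregate(df, fixed, ["texture_id", "_unit"])
    n = len(agg)
    X = np.column_stack(
        [np.ones(n)] + [agg[f"cond_{f}"].to_numpy(float) for f in fixed]
    )
    beta_names = ["(Intercept)"] + list(fixed)
    y = agg["successes"].to_numpy(float)
    m = agg["trials"].to_numpy(float)

    terms = []
    design = X  # random intercept + slope per fixed effect
    col_names = ["(Intercept)"] + list(fixed)
    for label, col in groupings:
        codes, levels = pd.factorize(agg[col])
        if len(levels) < 2:
            warnings.warn(
                f"grouping {label} has fewer than 2 levels; dropped from the model"
            )
            continue
        terms.append(
            RandomTerm(name=label, groups=codes, design=design, col_names=col_names)
        )

    full = fit_laplace_glmm(X, y, m, terms, beta_names=beta_names)
    effects = {}
    for j, f in enumerate(fixed, start=1):
        p = lrt_pvalue(X, y, m, terms, full, j)
        if compute_ci:
            lo, hi, is_profile = profile_ci(X, y, m, terms, full, j)
        else:
            se = float(np.sqrt(max(full.beta_cov[j, j], 1e-12)))
            lo, hi, is_profile = full.beta[j] - 1.96 * se, full.beta[j] + 1.96 * se, False
        effects[f] = FixedEffect(float(full.beta[j]), lo, hi, p, is_profile)
    effects["(Intercept)"] = FixedEffect(
        float(full.beta[0]), np.nan, np.nan, np.nan, False
    )
    random_sd = dict(zip(full.sigma_names, full.sigma.tolist()))
    desc = (
        f"correct ~ {' + '.join(fixed)} with independent random "
        f"(intercept + slopes) for {', '.join(t.name for t in terms) or 'none (GLM)'}"
    )
    return GLMMFit(
        fixed_effects=effects,
        random_sd=random_sd,
        loglik=full.loglik,
        converged=full.converged,
        model_desc=desc,
    )


def lor_to_probability(baseline_p: float, lor: float) -> float:
    """Success probability after adding a log-odds ratio to a baseline."""
    if not 0 < baseline_p < 1:
        raise ValueError("baseline_p must lie strictly between 0 and 1")
    logit = np.log(baseline_p / (1 - baseline_p)) + lor
    return float(1.0 / (1.0 + np.exp(-logit)))


def read_trials_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a trial CSV, optionally translating foreign column names.

    ``column_map`` maps the file's column names to the package schema
    (``participant_id``, ``session_id``, ``texture_id``, ``correct``,
    ``cond_<factor>`` ...), which isolates external deposits with
    different layouts from the analysis code.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"participant_id", "session_id", "correct"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if "texture_id" not in df.columns:
        df["texture_id"] = "T00"
    df["correct"] = df["correct"].astype(bool)
    return df
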