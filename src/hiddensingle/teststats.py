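"""Transfer-phase effect estimation and rater agreement.

Accuracy effects use the in-package Laplace logistic mixed model; response
time effects use a linear mixed model on log2 seconds (statsmodels
MixedLM, correct trials only). Each feature is entered one at a time
together with a log2(trial) practice-effect term, with a per-participant
random intercept and log2(trial) slope and an automatic fallback to an
intercept-only random structure if the full fit does not converge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .glmm import fit_logistic_glmm

Z95 = 1.959963984540054

WINDOWS = {"1-16": (1, 16), "17-64": (17, 64)}
FEATURES = ("ds_changed", "ht_changed", "gp_changed")


class InestimableTermError(ValueError):
    """The requested feature column is constant within the window."""


@dataclass
class EffectEstimate:
    term: str
    dv: str  # "accuracy" (logits) or "rt" (log2 seconds)
    window: str
    estimate: float
    ci_low: float
    ci_high: float
    n_obs: int
    converged: bool
    random_slopes: bool

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "dv": self.dv,
            "window": self.window,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "random_slopes": self.random_slopes,
        }


def recode_goal_position(records: pd.DataFrame) -> pd.DataFrame:
    """Add gp_changed = hi_changed OR ci_changed (record count preserved)."""
    out = records.copy()
    out["gp_changed"] = (
        out["hi_changed"].astype(bool) | out["ci_changed"].astype(bool)
    ).astype(int)
    return out


def _window_slice(records: pd.DataFrame, window: str) -> pd.DataFrame:
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {sorted(WINDOWS)}, got {window!r}")
    lo, hi = WINDOWS[window]
    return records[(records["trial"] >= lo) & (records["trial"] <= hi)].copy()


def fit_accuracy_model(
    records: pd.DataFrame, window: str, feature: str = "ht_changed"
) -> EffectEstimate:
    """Logistic mixed model: correct ~ feature + log2(trial), per-window."""
    df = _window_slice(records, window)
    if feature not in df.columns:
        raise KeyError(f"missing feature column {feature!r}")
    if df[feature].nunique() < 2:
        raise InestimableTermError(f"feature {feature!r} is constant in window {window}")

    pids = sorted(df["participant_id"].unique())
    lo, hi = WINDOWS[window]
    T = hi - lo + 1
    n = len(pids)
    df = df.sort_values(["participant_id", "trial"])
    if len(df) != n * T:
        raise ValueError("accuracy model requires one record per participant and trial")

    y = df["correct"].to_numpy(dtype=float).reshape(n, T)
    feat = df[feature].to_numpy(dtype=float).reshape(n, T)
    logt = np.log2(df["trial"].to_numpy(dtype=float)).reshape(n, T)
    ones = np.ones_like(feat)
    X = np.stack([ones, feat, logt], axis=2)

    for random_slopes in (True, False):
        Z = np.stack([ones, logt], axis=2) if random_slopes else ones[..., None]
        fit = fit_logistic_glmm(
            y, X, Z, pids, fixed_names=["intercept", feature, "log2_trial"]
        )
        ok = fit.converged and np.all(np.isfinite(fit.beta_se))
        if ok or not random_slopes:
            est = float(fit.beta[1])
            se = float(fit.beta_se[1])
            return EffectEstimate(
                term=feature,
                dv="accuracy",
                window=window,
                estimate=est,
                ci_low=est - Z95 * se,
                ci_high=est + Z95 * se,
                n_obs=int(y.size),
                converged=ok,
                random_slopes=random_slopes,
            )
    raise AssertionError("unreachable")


def fit_rt_model(
    records: pd.DataFrame, window: str, feature: str = "ht_changed"
) -> EffectEstimate:
    """Linear mixed model: log2(rt) ~ feature + log2(trial), correct trials only."""
    df = _window_slice(records, window)
    df = df[(df["correct"].astype(bool)) & df["rt_seconds"].notna()].copy()
    if df.empty:
        raise ValueError(f"no correct trials with RTs in window {window}")
    if df[feature].nunique() < 2:
        raise InestimableTermError(f"feature {feature!r} is constant in window {window}")
    df["log2_rt"] = np.log2(df["rt_seconds"].astype(float))
    df["log2_trial"] = np.log2(df["trial"].astype(float))
    df["feat"] = df[feature].astype(float)

    for re_formula, random_slopes in (("~log2_trial", True), ("~1", False)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "log2_rt ~ feat + log2_trial",
                data=df,
                groups=df["participant_id"],
                re_formula=re_formula,
            )
            try:
                res = model.fit(reml=True, method="lbfgs")
            except Exception:
                continue
        if res.converged or not random_slopes:
            est = float(res.params["feat"])
            se = float(res.bse["feat"])
            return EffectEstimate(
                term=feature,
                dv="rt",
                window=window,
                estimate=est,
                ci_low=est - Z95 * se,
                ci_high=est + Z95 * se,
                n_obs=int(len(df)),
                converged=bool(res.converged),
                random_slopes=random_slopes,
            )
    raise RuntimeError(f"RT model failed to fit in window {window}")


def fit_all_effects(records: pd.DataFrame, windows=("1-16", "17-64")) -> pd.DataFrame:
    """Tidy table of accuracy and RT effects for ds/ht/gp in each window."""
    if "gp_changed" not in records.columns:
        records = recode_goal_position(records)
    rows = []
    for window in windows:
        for feature in FEATURES:
            rows.append(fit_accuracy_model(records, window, feature).to_dict())
            rows.append(fit_rt_model(records, window, feature).to_dict())
    return pd.DataFrame(rows)


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    p_observed: float
    p_expected: float
    n: int
    defined: bool = True


def cohen_kappa(ratings_a, ratings_b) -> KappaResult:
    """Cohen's kappa with a 95% asymptotic confidence interval."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D vectors")
    n = len(a)
    if n == 0:
        raise ValueError("ratings must be non-empty")
    cats = sorted(set(a.tolist()) | set(b.tolist()))
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0:  # single shared category: chance correction undefined
        return KappaResult(float("nan"), float("nan"), float("nan"), p_o, p_e, n, False)
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(kappa - Z95 * se),
        ci_high=float(kappa + Z95 * se),
        p_observed=p_o,
        p_expected=p_e,
        n=n,
    )
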