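"""Sample-wise mixed-model sweep and the consecutive-samples reliability rule.

The central analysis fits, at every time sample of the mid-saccade-locked
grid, a linear mixed-effects model of normalized pupil size on the trial
factors, with a by-participant random intercept and by-participant random
slopes for all predictors.  No p-values are estimated for the sweep; an
effect counts as *reliable* where |t| exceeds a threshold for a minimum run
of consecutive samples (t > 2 for 200 consecutive 1-ms samples by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

CONDITIONS = ("no_percept", "intrasaccadic_percept")


# ---------------------------------------------------------------------------
# Reliability rule
# ---------------------------------------------------------------------------

def reliable_intervals(
    t_values: np.ndarray,
    times: Optional[np.ndarray] = None,
    threshold: float = 2.0,
    min_run_ms: float = 200.0,
    two_sided: bool = True,
) -> List[Tuple[float, float]]:
    """Maximal runs where the t-series exceeds the threshold long enough.

    Returns half-open intervals [start_ms, end_ms) on the series' own grid.
    ``min_run_ms`` is converted to a sample count via the grid step, so a
    decimated grid needs proportionally fewer consecutive samples.
    Non-finite t-values (non-converged fits) never exceed the threshold and
    therefore break runs.
    """
    tv = np.asarray(t_values, dtype=float)
    if tv.size == 0:
        return []
    if times is None:
        times = np.arange(tv.size, dtype=float)
    times = np.asarray(times, dtype=float)
    step = float(times[1] - times[0]) if times.size > 1 else 1.0
    min_run = int(np.ceil(min_run_ms / step))

    with np.errstate(invalid="ignore"):
        exceed = (np.abs(tv) > threshold) if two_sided else (tv > threshold)
    exceed &= np.isfinite(tv)

    intervals: List[Tuple[float, float]] = []
    edges = np.diff(exceed.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if exceed.size and exceed[0]:
        starts.insert(0, 0)
    if exceed.size and exceed[-1]:
        stops.append(exceed.size)
    for a, b in zip(starts, stops):
        if b - a >= min_run:
            intervals.append((float(times[a]), float(times[b - 1] + step)))
    return intervals


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def build_design(factors: pd.DataFrame, model: str) -> Tuple[np.ndarray, List[str]]:
    """Treatment-coded design matrix for the supported model formulas.

    ``model`` is 'condition' or 'condition*direction'.  Condition reference
    is no_percept; direction enters as a two-level axis factor with
    reference horizontal, since the experimental question contrasts
    horizontal with vertical saccades.
    """
    cond = (factors["condition"] == "intrasaccadic_percept").to_numpy(float)
    n = len(factors)
    if model == "condition":
        X = np.column_stack([np.ones(n), cond])
        names = ["Intercept", "condition[percept]"]
    elif model == "condition+direction":
        # condition effect with direction as a nuisance factor: measured
        # pupil size depends on gaze angle, so saccades toward different
        # screen positions carry different position artifacts
        cols, names = [np.ones(n), cond], ["Intercept", "condition[percept]"]
        present = [d for d in ("left", "right", "up", "down")
                   if (factors["direction"] == d).any()]
        for d in present[1:]:
            cols.append((factors["direction"] == d).to_numpy(float))
            names.append(f"direction[{d}]")
        X = np.column_stack(cols)
    elif model in ("condition*direction", "condition*axis"):
        if "axis" in factors:
            vert = (factors["axis"] == "vertical").to_numpy(float)
        else:
            vert = factors["direction"].isin(["up", "down"]).to_numpy(float)
        X = np.column_stack([np.ones(n), cond, vert, cond * vert])
        names = ["Intercept", "condition[percept]", "axis[vertical]",
                 "condition:axis"]
    else:
        raise ValueError(f"unsupported model {model!r}")
    return X, names


# ---------------------------------------------------------------------------
# The sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-sample fixed-effect estimates, t-values, and reliable intervals."""

    times: np.ndarray                       # ms (relative to mid-saccade)
    effect_names: List[str]
    coef: np.ndarray                        # (n_times, n_effects)
    tval: np.ndarray                        # (n_times, n_effects)
    converged: np.ndarray                   # (n_times,) bool
    intervals: Dict[str, List[Tuple[float, float]]]
    model: str
    threshold: float
    min_run_ms: float
    two_sided: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.effect_names):
            rows.append(pd.DataFrame({
                "t_ms": self.times,
                "effect": name,
                "coef": self.coef[:, j],
                "tval": self.tval[:, j],
                "converged": self.converged,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_json(self) -> str:
        return json.dumps({
            "model": self.model,
            "threshold": self.threshold,
            "min_run_ms": self.min_run_ms,
            "two_sided": self.two_sided,
            "effects": self.effect_names,
            "times_ms": self.times.tolist(),
            "coef": self.coef.tolist(),
            "tval": self.tval.tolist(),
            "converged": self.converged.tolist(),
            "reliable_intervals": {k: [list(iv) for iv in v]
                                   for k, v in self.intervals.items()},
        }, indent=2)


def _fit_one(y, X, groups, exog_re, free, reml, start):
    model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(free=free, reml=reml, method="lbfgs",
                            maxiter=75, disp=False, start_params=start)
            fe = np.asarray(res.fe_params, dtype=float)
            se = np.asarray(res.bse_fe, dtype=float)
        except (np.linalg.LinAlgError, ValueError):
            return None
    if not (np.all(np.isfinite(fe)) and np.all(np.isfinite(se)) and np.all(se > 0)):
        return None
    return res, fe, fe / se


def lme_sweep(
    values: np.ndarray,
    times: np.ndarray,
    factors: pd.DataFrame,
    model: str = "condition*direction",
    threshold: float = 2.0,
    min_run_ms: float = 200.0,
    two_sided: bool = True,
    reml: bool = True,
) -> SweepResult:
    """Fit the mixed model at every time sample of an epoch matrix.

    Parameters
    ----------
    values:
        (n_epochs, n_times) normalized pupil values; NaN marks masked
        samples, which are dropped row-wise per time point.
    times:
        The epochs' shared (possibly decimated) time grid in ms.
    factors:
        One row per epoch with columns ``participant``, ``condition`` and —
        for the interaction model — ``direction`` (or ``axis``).

    Each sample is fit by REML with a by-participant random intercept and
    random slopes for all fixed-effect columns, with a diagonal
    (uncorrelated) random-effects covariance.  Optimizations are
    warm-started from the neighbouring sample.  Samples whose full model
    does not converge are refit with the random slopes dropped; if that
    also fails the sample is flagged non-converged and its t-values are NaN
    (so it can never enter a reliable interval).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    participants = factors["participant"].to_numpy()
    uniq = np.unique(participants)
    if uniq.size < 3:
        raise ValueError(f"need >= 3 participants, got {uniq.size}")
    if "condition" in factors:
        tab = pd.crosstab(factors["participant"], factors["condition"])
        if (tab == 0).to_numpy().any():
            warnings.warn("some participants lack a condition level",
                          stacklevel=2)

    X_full, names = build_design(factors, model)
    k = X_full.shape[1]
    free_full = MixedLMParams.from_components(
        fe_params=np.ones(k), cov_re=np.eye(k))
    free_int = MixedLMParams.from_components(
        fe_params=np.ones(k), cov_re=np.eye(1))

    n_t = times.size
    coef = np.full((n_t, k), np.nan)
    tval = np.full((n_t, k), np.nan)
    converged = np.zeros(n_t, dtype=bool)
    warm_full = None
    warm_int = None

    for j in range(n_t):
        y = values[:, j]
        ok = np.isfinite(y)
        if ok.sum() < k + 2 or np.unique(participants[ok]).size < 3:
            continue
        yj, Xj, gj = y[ok], X_full[ok], participants[ok]
        fit = _fit_one(yj, Xj, gj, Xj, free_full, reml, warm_full)
        if fit is None and warm_full is not None:
            # warm starts can land on a degenerate boundary; retry cold
            fit = _fit_one(yj, Xj, gj, Xj, free_full, reml, None)
        if fit is not None:
            res, fe, tv = fit
            warm_full = res.params_object
            converged[j] = True
        else:
            fit = _fit_one(yj, Xj, gj, Xj[:, :1], free_int, reml, warm_int)
            if fit is None:
                continue
            res, fe, tv = fit
            warm_int = res.params_object
            converged[j] = False  # degraded fit: flagged, never reliable
        coef[j] = fe
        tval[j] = tv

    # flagged (non-converged) samples are treated as unreliable
    tval_for_rule = np.where(converged[:, None], tval, np.nan)
    intervals = {
        name: reliable_intervals(tval_for_rule[:, i], times, threshold,
                                 min_run_ms, two_sided)
        for i, name in enumerate(names)
    }
    return SweepResult(times=times, effect_names=names, coef=coef, tval=tval,
                       converged=converged, intervals=intervals, model=model,
                       threshold=threshold, min_run_ms=min_run_ms,
                       two_sided=two_sided)


# ---------------------------------------------------------------------------
# Post-hoc helpers
# ---------------------------------------------------------------------------

def median_split_select(
    df: pd.DataFrame,
    metric: str,
    by: Sequence[str] = ("participant", "direction"),
    side: str = "below",
) -> pd.DataFrame:
    """Keep rows whose metric is strictly below their group median.

    Groups are formed by ``by`` (participant x saccade direction in the
    post-hoc analyses).  With an even group the median is the midpoint of
    the two central values, so exactly half the rows survive; with all-equal
    values nothing survives (strict inequality).  Empty groups are skipped
    with a warning.
    """
    if side != "below":
        raise ValueError("only side='below' is defined")
    out = []
    for key, grp in df.groupby(list(by), observed=True):
        if len(grp) < 2:
            warnings.warn(f"group {key} has <2 trials; skipped", stacklevel=2)
            continue
        med = grp[metric].median()
        out.append(grp[grp[metric] < med])
    if not out:
        return df.iloc[0:0]
    return pd.concat(out).sort_index()


def paired_t(values_a: Sequence[float], values_b: Sequence[float]
             ) -> Tuple[float, int, float]:
    """Two-sided paired-samples t-test; returns (t, df, p).

    Values are paired by participant; df = n - 1.  Zero variance of the
    differences is an error (t undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, a.size - 1, 1.0
        raise ValueError("zero variance of differences")
    t, p = sps.ttest_rel(a, b)
    return float(t), a.size - 1, float(p)


def dispersion_metrics(
    df: pd.DataFrame,
    value: str,
    participant: str = "participant",
) -> pd.DataFrame:
    """Per-participant sample SD (ddof=1) and mean of a per-trial metric.

    Participants with fewer than 2 trials are skipped with a warning.
    These are the dependent measures of the direction post-hocs:
    SD of peak velocity, mean peak orthogonal velocity.
    """
    rows = []
    for pid, grp in df.groupby(participant, observed=True):
        vals = grp[value].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"participant {pid} has <2 trials; skipped",
                          stacklevel=2)
            continue
        rows.append({participant: pid,
                     "sd": float(np.std(vals, ddof=1)),
                     "mean": float(np.mean(vals)),
                     "n": int(vals.size)})
    return pd.DataFrame(rows)
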