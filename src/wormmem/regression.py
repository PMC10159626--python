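"""Linear-combination modelling of interneuron activity.

The AIY interneuron integrates several chemosensory inputs (AWA, AWC, ASE,
ASG, AWB).  To quantify each input's contribution per training condition,
neuronal activities are averaged across animals for each of the six
stimulus-exchange trials within a 15-s post-switch window; the six averaged
vectors per neuron are concatenated and the interneuron's vector regressed
on the sensory vectors by ordinary least squares.  R², adjusted R²,
per-coefficient t statistics, p-values and confidence intervals come from
the OLS fit; a 50/50 split cross-validates against overfitting.  The
coefficients describe communication-route weights in a statistical sense
only — they are not synaptic weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import StimulusSchedule
from .traces import NormalizedTrace

__all__ = [
    "TrialAveragedActivity",
    "RegressionFit",
    "trial_average",
    "fit_linear_combo",
    "incremental_fit",
    "crossval_fit",
    "within_animal_R2",
    "PAPER_REGRESSOR_SET",
]

#: The canonical sensory regressor set for the AIY model.
PAPER_REGRESSOR_SET = ("AWA", "AWC", "ASE", "ASG", "AWB")


@dataclass
class TrialAveragedActivity:
    """Across-animal mean activity per trial in the post-switch window.

    ``values`` has shape (n_trials, n_time): one row per stimulus exchange,
    each the pointwise mean over animals within [switch, switch + window).
    """

    neuron_id: str
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def concatenated(self) -> np.ndarray:
        return self.values.ravel()


@dataclass
class RegressionFit:
    response: str
    regressors: tuple[str, ...]
    condition: str
    beta: np.ndarray
    intercept: float
    R2: float
    adjusted_R2: float
    coef_p: np.ndarray
    coef_CI: np.ndarray  # (k, 2)
    n_obs: int


def trial_average(
    traces: Sequence[NormalizedTrace],
    schedule: StimulusSchedule,
    window_s: float = 15.0,
    neuron_id: str = "",
    condition: str = "",
) -> TrialAveragedActivity:
    """Average one neuron's traces over animals, per trial.

    All traces must share a uniform common time base (resample first).
    Raises if any trial window has no animals.
    """
    if not traces:
        raise ValueError("trial_average needs at least one trace")
    t = traces[0].time
    for tr in traces[1:]:
        if tr.time.shape != t.shape or not np.allclose(tr.time, t):
            raise ValueError("traces must share a common time base; resample first")
    rows = []
    for i, sw in enumerate(schedule.switch_times):
        mask = (t >= sw) & (t < sw + window_s)
        if not mask.any():
            raise ValueError(f"trial {i}: window [{sw}, {sw + window_s}) is empty")
        stacked = np.stack([tr.values[mask] for tr in traces])
        rows.append(stacked.mean(axis=0))
    return TrialAveragedActivity(
        neuron_id=neuron_id or (traces[0].neuron_id or ""),
        condition=condition,
        values=np.stack(rows),
    )


def _design(
    response: TrialAveragedActivity, regressors: Sequence[TrialAveragedActivity]
) -> tuple[np.ndarray, np.ndarray]:
    y = response.concatenated
    cols = []
    for reg in regressors:
        x = reg.concatenated
        if x.shape != y.shape:
            raise ValueError(
                f"regressor {reg.neuron_id!r} is not on the response's time base"
            )
        cols.append(x)
    X = np.column_stack(cols)
    return y, X


def fit_linear_combo(
    response: TrialAveragedActivity,
    regressors: Sequence[TrialAveragedActivity],
) -> RegressionFit:
    """OLS fit of the interneuron on the sensory neurons (intercept included).

    Observations are the concatenated six trial-mean vectors.  A
    rank-deficient design raises, naming the collinear regressors.
    """
    y, X = _design(response, regressors)
    names = tuple(r.neuron_id for r in regressors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank, in order
        collinear = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear regressors: {collinear}")
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    ci = np.asarray(fit.conf_int())[1:]  # drop intercept row
    return RegressionFit(
        response=response.neuron_id,
        regressors=names,
        condition=response.condition,
        beta=np.asarray(fit.params[1:]),
        intercept=float(fit.params[0]),
        R2=float(fit.rsquared),
        adjusted_R2=float(fit.rsquared_adj),
        coef_p=np.asarray(fit.pvalues[1:]),
        coef_CI=ci,
        n_obs=int(y.size),
    )


def incremental_fit(
    response: TrialAveragedActivity,
    ordered_regressors: Sequence[TrialAveragedActivity],
) -> pd.DataFrame:
    """R² / adjusted R² for each prefix of the regressor ordering.

    Because the models are nested, R² is non-decreasing in prefix length.
    """
    rows = []
    for k in range(1, len(ordered_regressors) + 1):
        fit = fit_linear_combo(response, ordered_regressors[:k])
        rows.append(
            dict(
                n_regressors=k,
                last_added=ordered_regressors[k - 1].neuron_id,
                R2=fit.R2,
                adjusted_R2=fit.adjusted_R2,
            )
        )
    return pd.DataFrame(rows)


def crossval_fit(
    response: TrialAveragedActivity,
    regressors: Sequence[TrialAveragedActivity],
    seed: int = 0,
    test_fraction: float = 0.5,
) -> tuple[float, float]:
    """Train/test R² under a random 50/50 observation split.

    Test R² is 1 − SS_res/SS_tot with SS_tot around the held-out mean; it can
    be negative when the model generalizes worse than the test mean.
    """
    y, X = _design(response, regressors)
    n = y.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test, train = perm[:n_test], perm[n_test:]
    if train.size < X.shape[1] + 2 or test.size < 4:
        raise ValueError("too few observations for a 50/50 cross-validation")
    Xtr = sm.add_constant(X[train], has_constant="add")
    fit = sm.OLS(y[train], Xtr).fit()
    train_R2 = float(fit.rsquared)
    Xte = sm.add_constant(X[test], has_constant="add")
    pred = Xte @ np.asarray(fit.params)
    resid = y[test] - pred
    ss_tot = float(np.sum((y[test] - y[test].mean()) ** 2))
    test_R2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return train_R2, test_R2


def within_animal_R2(
    paired_traces: Mapping[str, Sequence[tuple[NormalizedTrace, NormalizedTrace]]],
    schedule: StimulusSchedule,
    window_s: float = 15.0,
) -> pd.DataFrame:
    """Variance in AIY explained by AWA recorded in the same animal.

    ``paired_traces`` maps condition → list of (awa_trace, aiy_trace) pairs,
    one per animal (simultaneous recordings).  Per condition, the 15-s
    post-switch windows of all animals are pooled and AIY regressed on AWA by
    simple OLS; the returned table holds one R² per condition.
    """
    rows = []
    for condition, pairs in paired_traces.items():
        xs, ys = [], []
        for awa, aiy in pairs:
            if awa.animal_id != aiy.animal_id:
                raise ValueError(
                    f"unpaired traces: {awa.animal_id!r} vs {aiy.animal_id!r}"
                )
            if awa.time.shape != aiy.time.shape or not np.allclose(awa.time, aiy.time):
                raise ValueError("paired traces must share a time base")
            for sw in schedule.switch_times:
                mask = (awa.time >= sw) & (awa.time < sw + window_s)
                xs.append(awa.values[mask])
                ys.append(aiy.values[mask])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append(dict(condition=condition, R2=float(fit.rsquared), n_obs=y.size))
    return pd.DataFrame(rows)
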