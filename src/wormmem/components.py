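"""PCA-based filtering of experience-component activity deltas.

Training-induced activity changes are expressed as *activity deltas*:
differences of across-animal trial-mean activity between pairs of groups
chosen so that each difference isolates one experience component — the
conditioned stimulus (CS, trained − mock, per valence), the unconditioned
treatment itself (US+/US−, mock − naive), and valence (appetitive − aversive
at matched treatment).  Concatenating all neurons' time points per
(component, trial) gives a 36-row delta matrix (6 components × 6 trials)
which is denoised by reconstructing it from a chosen subset of principal
components.  The reconstructed deltas are summed per neuron, scaled by the
neuron's mean response amplitude, and summarized as a per-(neuron,
component) signed change (mean ± SD over the six trials); a two-cluster
1-D k-means on the absolute changes separates significant from
insignificant ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regression import TrialAveragedActivity

logger = logging.getLogger(__name__)

__all__ = [
    "DELTA_COMPONENTS",
    "DeltaMatrix",
    "build_delta_matrix",
    "pca_filter",
    "arrow_map",
    "kmeans_threshold",
]

#: Delta components and the group contrasts defining them.
DELTA_COMPONENTS: dict[str, tuple[str, str]] = {
    "CS(AP)": ("STAP-T", "STAP-M"),
    "CS(AV)": ("STAV-T", "STAV-M"),
    "US+": ("STAP-M", "NAIVE"),
    "US-": ("STAV-M", "NAIVE"),
    "VAL(T)": ("STAP-T", "STAV-T"),
    "VAL(M)": ("STAP-M", "STAV-M"),
}


@dataclass
class DeltaMatrix:
    """(component, trial) × concatenated-neuron-time activity-delta matrix."""

    data: np.ndarray  # (n_components * n_trials, n_neurons * n_time)
    row_labels: list[tuple[str, int]]  # (component, trial)
    neurons: list[str]
    n_time: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("delta matrix entries must be finite")
        if self.data.shape[0] != len(self.row_labels):
            raise ValueError("row label count mismatch")
        if self.data.shape[1] != len(self.neurons) * self.n_time:
            raise ValueError("column count != n_neurons * n_time")

    def neuron_slice(self, neuron: str) -> slice:
        j = self.neurons.index(neuron)
        return slice(j * self.n_time, (j + 1) * self.n_time)


def build_delta_matrix(
    trial_averaged: Mapping[str, Mapping[str, TrialAveragedActivity]],
    components: Mapping[str, tuple[str, str]] | None = None,
) -> DeltaMatrix:
    """Assemble the delta matrix from per-condition trial-averaged activity.

    ``trial_averaged`` maps condition short label ('STAP-T', ..., 'NAIVE') →
    neuron → :class:`TrialAveragedActivity` with six trial rows on a common
    time base.  Each delta row is (condition_a − condition_b) for one trial,
    all neurons concatenated; the full design yields 36 rows.
    """
    components = dict(components or DELTA_COMPONENTS)
    needed = {g for pair in components.values() for g in pair}
    for g in sorted(needed):
        if g not in trial_averaged:
            raise ValueError(f"missing condition {g!r} in trial-averaged input")
    any_cond = next(iter(trial_averaged.values()))
    neurons = sorted(any_cond)
    n_trials = any_cond[neurons[0]].values.shape[0]
    n_time = any_cond[neurons[0]].values.shape[1]
    for cond, per_neuron in trial_averaged.items():
        if sorted(per_neuron) != neurons:
            raise ValueError(f"condition {cond!r} has a different neuron set")
        for nm, ta in per_neuron.items():
            if ta.values.shape != (n_trials, n_time):
                raise ValueError(
                    f"{cond}/{nm}: shape {ta.values.shape} != {(n_trials, n_time)}"
                )
    rows, labels = [], []
    for comp, (ga, gb) in components.items():
        for trial in range(n_trials):
            row = np.concatenate(
                [
                    trial_averaged[ga][nm].values[trial]
                    - trial_averaged[gb][nm].values[trial]
                    for nm in neurons
                ]
            )
            rows.append(row)
            labels.append((comp, trial))
    return DeltaMatrix(
        data=np.asarray(rows), row_labels=labels, neurons=neurons, n_time=n_time
    )


def pca_filter(
    matrix: DeltaMatrix, keep: Sequence[int] = (1, 2, 3, 5)
) -> tuple[DeltaMatrix, dict]:
    """Reconstruct the delta matrix from selected principal components.

    Rows (component × trial observations) are column-mean-centered and
    decomposed by SVD; the reconstruction uses the scores and loadings of
    the 1-based component indices in ``keep`` (ordered by descending
    eigenvalue) with the column means added back.  The variance report gives
    the retained and filtered variance fractions (eigenvalue ratios, summing
    to 1) plus the per-component spectrum and the loadings for inspection —
    selecting which components carry the experience structure is the
    analyst's call, made by examining loadings, not automated.
    """
    X = matrix.data
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2
    n_comp = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    keep0 = sorted({int(k) - 1 for k in keep})
    if any(k < 0 for k in keep0):
        raise ValueError("component indices are 1-based")
    if keep0 and keep0[-1] >= n_comp:
        raise ValueError(
            f"component index {keep0[-1] + 1} exceeds the {n_comp} "
            "non-degenerate components available"
        )
    idx = np.asarray(keep0, dtype=int)
    recon = (U[:, idx] * s[idx]) @ Vt[idx] + mu
    total = float(eig.sum())
    retained = float(eig[idx].sum() / total) if total > 0 else 1.0
    report = {
        "retained_fraction": retained,
        "filtered_fraction": 1.0 - retained,
        "eigenvalue_fractions": (eig / total).tolist() if total > 0 else [],
        "n_components": n_comp,
        "kept": [int(k) + 1 for k in keep0],
        "loadings": Vt,
        "scores": U * s,
    }
    out = DeltaMatrix(
        data=recon,
        row_labels=list(matrix.row_labels),
        neurons=list(matrix.neurons),
        n_time=matrix.n_time,
    )
    return out, report


def arrow_map(
    reconstructed: DeltaMatrix,
    mean_amplitudes: Mapping[str, float],
    weighting: str = "divide",
) -> pd.DataFrame:
    """Per-(neuron, component) signed change summary.

    For each neuron, component, and trial the reconstructed deltas are summed
    over the neuron's time points and scaled by the neuron's mean response
    amplitude — divided by it by default (``weighting='divide'``), or
    multiplied (``weighting='multiply'``) to weight high-amplitude neurons
    more.  Returns mean and SD over the six trials per (neuron, component);
    neurons with nonpositive amplitude are excluded with a warning.
    """
    if weighting not in ("divide", "multiply"):
        raise ValueError("weighting must be 'divide' or 'multiply'")
    comps = sorted({c for c, _ in reconstructed.row_labels})
    rows = []
    for nm in reconstructed.neurons:
        amp = float(mean_amplitudes.get(nm, 0.0))
        if amp <= 0:
            logger.warning("neuron %s has nonpositive mean amplitude; excluded", nm)
            continue
        sl = reconstructed.neuron_slice(nm)
        for comp in comps:
            trial_vals = []
            for (c, _t), row in zip(reconstructed.row_labels, reconstructed.data):
                if c == comp:
                    summed = float(np.sum(row[sl]))
                    trial_vals.append(
                        summed / amp if weighting == "divide" else summed * amp
                    )
            trial_vals = np.asarray(trial_vals)
            rows.append(
                dict(
                    neuron=nm,
                    component=comp,
                    mean=float(trial_vals.mean()),
                    sd=float(trial_vals.std(ddof=1)) if trial_vals.size > 1 else 0.0,
                    n_trials=trial_vals.size,
                )
            )
    return pd.DataFrame(rows)


def kmeans_threshold(magnitudes: np.ndarray) -> tuple[np.ndarray, float]:
    """Two-cluster 1-D k-means split of absolute change magnitudes.

    The optimal 1-D two-means partition is a contiguous split of the sorted
    values, found exactly by sweeping all split points and minimizing the
    within-cluster sum of squares.  The cluster with the larger centroid is
    labelled significant; the reported boundary is the midpoint between the
    two centroids.  All-equal input → nothing significant (warning).
    """
    mags = np.abs(np.asarray(magnitudes, dtype=float))
    if mags.size < 2:
        raise ValueError("k-means thresholding needs at least 2 values")
    if np.all(mags == mags[0]):
        logger.warning("all magnitudes equal; no significant changes")
        return np.zeros(mags.size, dtype=bool), float(mags[0])
    order = np.argsort(mags, kind="mergesort")
    x = mags[order]
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def wss(i: int, j: int) -> float:  # within-SS of x[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / m

    best_k, best = 1, np.inf
    for k in range(1, n):
        val = wss(0, k) + wss(k, n)
        if val < best - 1e-15:
            best, best_k = val, k
    lo_mean = (csum[best_k]) / best_k
    hi_mean = (csum[n] - csum[best_k]) / (n - best_k)
    boundary = 0.5 * (lo_mean + hi_mean)
    labels_sorted = np.zeros(n, dtype=bool)
    labels_sorted[best_k:] = True
    labels = np.empty(n, dtype=bool)
    labels[order] = labels_sorted
    return labels, float(boundary)
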