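"""Comparison design, test selection, pFDR adjustment, behavioral indices.

The experimental design compares post-switch integrated activity between
training groups in a fixed table of pairwise contrasts.  Each contrast is
labelled by the experience component it isolates: CS (trained vs mock within
a paradigm — the stimulus-specific effect), US+ / US− (mock vs naive — the
appetitive / aversive treatment itself), VAL (appetitive vs aversive at
matched treatment — valence), TR (trained vs naive — the whole training
effect), and SL (short- vs long-term at matched valence).

Test selection follows the usual parametric/non-parametric switch: per-group
normality (Shapiro–Wilk for small n, Kolmogorov–Smirnov against a fitted
normal for large n), then t-test if both groups pass, else Wilcoxon rank-sum
(unpaired) or signed-rank (paired).  Families of p-values are adjusted by
Storey's positive false discovery rate (q-values) with Benjamini–Hochberg
available as a cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import EndpointCounts, GroupLabel

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonSpec",
    "ComparisonResult",
    "BehaviorIndices",
    "comparison_table",
    "ci_filter",
    "pairwise_test",
    "pfdr_adjust",
    "behavior_indices",
    "one_sample_vs_zero",
    "classify_responders",
    "omnibus_gate",
]


class StatTest(str, Enum):
    t = "t"
    rank_sum = "rank_sum"
    signed_rank = "signed_rank"


@dataclass(frozen=True)
class ComparisonSpec:
    group_a: GroupLabel
    group_b: GroupLabel
    component_label: str = "none"

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("a comparison needs two distinct groups")

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.group_a.short} vs {self.group_b.short} [{self.component_label}]"


@dataclass
class ComparisonResult:
    spec: ComparisonSpec
    neuron_id: str
    switch_index: int
    test_used: StatTest
    statistic: float
    p: float
    q: float = float("nan")


@dataclass(frozen=True)
class BehaviorIndices:
    """Choice Index and the three Learning Indices derived from it.

    CI = (n_cs − n_alt)/(n_cs + n_alt) ∈ [−1, +1]: −1 is complete aversion to
    the conditioned stimulus, +1 full attraction.  The LIs isolate the
    stimulus-specific (trained − mock), training-specific (trained − naive),
    and treatment-specific (mock − naive) parts of the behavioral change.
    """

    CI_trained: float
    CI_mock: float
    CI_naive: float

    @property
    def LI_stimulus(self) -> float:
        return self.CI_trained - self.CI_mock

    @property
    def LI_training(self) -> float:
        return self.CI_trained - self.CI_naive

    @property
    def LI_treatment(self) -> float:
        return self.CI_mock - self.CI_naive


_SHORT_BLOCK = [
    ("STAP-T", "STAV-T", "VAL"),
    ("STAP-M", "STAV-M", "VAL"),
    ("STAP-T", "STAP-M", "CS"),
    ("STAV-T", "STAV-M", "CS"),
    ("STAP-M", "NAIVE", "US+"),
    ("STAV-M", "NAIVE", "US-"),
    ("STAP-T", "NAIVE", "TR"),
    ("STAV-T", "NAIVE", "TR"),
]

_LONG_BLOCK = [
    ("STAP-T", "LTAP-T", "SL"),
    ("STAV-T", "LTAV-T", "SL"),
    ("LTAP-T", "LTAV-T", "VAL"),
    ("LTAP-M", "LTAV-M", "VAL"),
    ("LTAP-T", "LTAP-M", "CS"),
    ("LTAV-T", "LTAV-M", "CS"),
    ("LTAP-T", "NAIVE", "TR"),
    ("LTAV-T", "NAIVE", "TR"),
    ("LTAP-M", "NAIVE", "US+"),
    ("LTAV-M", "NAIVE", "US-"),
]


def comparison_table(dataset_kind: str) -> list[ComparisonSpec]:
    """The fixed table of pairwise group contrasts.

    ``but_da_exchange`` (short-term exchange recordings) uses the first eight
    rows; ``but_exposure`` (the full four-paradigm exposure dataset) uses all
    eighteen.
    """
    if dataset_kind == "but_da_exchange":
        rows = _SHORT_BLOCK
    elif dataset_kind == "but_exposure":
        rows = _SHORT_BLOCK + _LONG_BLOCK
    else:
        raise ValueError(f"unknown dataset_kind {dataset_kind!r}")
    return [
        ComparisonSpec(GroupLabel.from_short(a), GroupLabel.from_short(b), c)
        for a, b, c in rows
    ]


def ci_filter(
    values: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, list[int]]:
    """Confidence-interval outlier filter on summed activities.

    Retains values within mean ± z(level)·SD of their group; returns the
    retained values and the indices of the excluded ones.  With fewer than 3
    values no filtering is applied (warning).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        logger.warning("ci_filter: fewer than 3 values, no filtering applied")
        return values, []
    z = sps.norm.ppf(0.5 + level / 2.0)
    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    lo, hi = mu - z * sd, mu + z * sd
    keep = (values >= lo) & (values <= hi)
    excluded = [int(i) for i in np.nonzero(~keep)[0]]
    return values[keep], excluded


def _is_normal(x: np.ndarray, n_threshold: int, alpha: float = 0.05) -> bool:
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        return False  # degenerate; fall through to rank-based tests
    if x.size < n_threshold:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = sps.shapiro(x).pvalue
    else:
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        p = sps.kstest(x, "norm", args=(mu, sd)).pvalue
    return p > alpha


def pairwise_test(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool = False,
    n_threshold: int = 50,
) -> tuple[StatTest, float, float]:
    """Distribution-aware two-group test.

    Returns ``(test_used, statistic, p)``.  Both groups normal → t-test
    (paired or two-sample); otherwise Wilcoxon rank-sum (unpaired) or
    signed-rank (paired).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if paired and a.size != b.size:
        raise ValueError("paired test requires equal-length groups")
    normal = _is_normal(a, n_threshold) and _is_normal(b, n_threshold)
    if normal:
        res = sps.ttest_rel(a, b) if paired else sps.ttest_ind(a, b)
        return StatTest.t, float(res.statistic), float(res.pvalue)
    if paired:
        d = a - b
        if np.all(d == 0):
            return StatTest.signed_rank, 0.0, 1.0
        res = sps.wilcoxon(a, b)
        return StatTest.signed_rank, float(res.statistic), float(res.pvalue)
    res = sps.ranksums(a, b)
    return StatTest.rank_sum, float(res.statistic), float(res.pvalue)


def pfdr_adjust(pvalues: Sequence[float], method: str = "storey") -> np.ndarray:
    """q-values controlling the (positive) false discovery rate.

    ``storey``: q-values with the null proportion π₀ estimated at λ = 0.5,
    π₀ = min(1, #{p > λ} / ((1 − λ) m)); q_(i) = min_{j ≥ i} π₀ m p_(j) / j.
    ``bh``: Benjamini–Hochberg step-up (equivalent to Storey with π₀ = 1).
    q is monotone in p in both methods.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey":
        raise ValueError(f"unknown method {method!r}")
    m = p.size
    lam = 0.5
    # floor the null-proportion estimate at 1/m: with tiny families of
    # uniformly strong effects the raw estimator hits 0, which would assign
    # q = 0 to every p
    pi0 = min(1.0, max(np.sum(p > lam) / ((1.0 - lam) * m), 1.0 / m))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def adjust_family(results: Iterable[ComparisonResult], method: str = "storey") -> None:
    """Assign q-values across a family of comparison results, in place."""
    results = list(results)
    if not results:
        return
    q = pfdr_adjust([r.p for r in results], method=method)
    for r, qi in zip(results, q):
        r.q = float(qi)


def behavior_indices(
    counts_trained: EndpointCounts,
    counts_mock: EndpointCounts,
    counts_naive: EndpointCounts,
) -> BehaviorIndices:
    """Choice and Learning Indices from endpoint counts of the two-choice assay."""

    def ci(c: EndpointCounts) -> float:
        if c.total <= 0:
            raise ValueError("choice index requires at least one scored worm")
        return (c.n_cs - c.n_alt) / c.total

    return BehaviorIndices(
        CI_trained=ci(counts_trained),
        CI_mock=ci(counts_mock),
        CI_naive=ci(counts_naive),
    )


def one_sample_vs_zero(values: np.ndarray) -> float:
    """Two-sided one-sample t-test of LI replicates against zero."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("one-sample test needs at least 3 replicates")
    if np.std(values, ddof=1) == 0:
        if np.mean(values) == 0:
            return 1.0
        logger.warning("one_sample_vs_zero: zero variance with nonzero mean")
        return 0.0
    return float(sps.ttest_1samp(values, 0.0).pvalue)


def count_upward_crossings(values: np.ndarray, threshold: float) -> int:
    """Number of upward threshold crossings (below→above transitions)."""
    above = np.asarray(values, dtype=float) > threshold
    if above.size < 2:
        return 0
    return int(np.sum(~above[:-1] & above[1:]))


def classify_responders(
    traces: Sequence[np.ndarray],
    threshold: float,
    mode: str = "trial",
) -> list[bool] | bool:
    """Responding / non-responding classification against an activity threshold.

    ``trial`` mode labels each trial's trace responding iff it crosses the
    threshold upward at least once and returns one flag per trace.  ``animal``
    mode requires the six-trial exchange structure and labels the animal
    responding iff its traces cross the threshold at least twice in total
    across the six consecutive trials.
    """
    crossings = [count_upward_crossings(t, threshold) for t in traces]
    if mode == "trial":
        return [c >= 1 for c in crossings]
    if mode == "animal":
        if len(traces) != 6:
            raise ValueError("animal mode requires exactly 6 trials")
        return sum(crossings) >= 2
    raise ValueError(f"unknown mode {mode!r}")


def run_comparison_suite(
    records,
    schedule,
    dataset_kind: str = "but_da_exchange",
    window_s: float = 10.0,
    per_neuron_overrides: Mapping[str, float] | None = None,
    ci_level: float = 0.95,
    fdr_method: str = "storey",
    paired: bool = False,
) -> "pd.DataFrame":
    """Full group-comparison stage: integrate, filter, test, adjust.

    For every trace record, activity is ground-state normalized and summed
    in the post-switch windows; per (neuron, group, switch) the summed
    activities are CI-filtered; each contrast in the design table is then
    tested per neuron and switch, and q-values assigned across the whole
    family.  Returns a long-format table (neuron, switch, groups, component,
    test, statistic, p, q, group sizes).
    """
    import pandas as pd

    from .traces import detect_ground_state, integrate_post_switch, normalize

    specs = comparison_table(dataset_kind)
    sums: dict[tuple[str, str, int], list[float]] = {}
    for rec in records:
        f_g = detect_ground_state(rec.intensity)
        tr = normalize(
            rec.intensity, rec.time, "ground_state", F_G=f_g,
            neuron_id=rec.neuron_id, animal_id=rec.animal_id,
        )
        for win in integrate_post_switch(
            tr, schedule, window_s=window_s, per_neuron_overrides=per_neuron_overrides
        ):
            key = (rec.neuron_id, rec.group.short, win.switch_index)
            sums.setdefault(key, []).append(win.integrated_activity)

    neurons = sorted({k[0] for k in sums})
    switches = sorted({k[2] for k in sums})
    rows: list[dict] = []
    pvals: list[float] = []
    for spec in specs:
        ga, gb = spec.group_a.short, spec.group_b.short
        for nm in neurons:
            for sw in switches:
                a = sums.get((nm, ga, sw))
                b = sums.get((nm, gb, sw))
                if a is None or b is None:
                    continue
                a_f, _ = ci_filter(np.asarray(a), level=ci_level)
                b_f, _ = ci_filter(np.asarray(b), level=ci_level)
                if a_f.size < 3 or b_f.size < 3:
                    continue
                test, stat, p = pairwise_test(a_f, b_f, paired=paired)
                rows.append(
                    dict(
                        neuron=nm, switch=sw, group_a=ga, group_b=gb,
                        component=spec.component_label, test=test.value,
                        statistic=stat, p=p, n_a=int(a_f.size), n_b=int(b_f.size),
                    )
                )
                pvals.append(p)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = pfdr_adjust(df["p"].to_numpy(), method=fdr_method)
    return df


def omnibus_gate(
    groups: Sequence[np.ndarray], n_threshold: int = 50, alpha: float = 0.05
) -> tuple[bool, float]:
    """Optional omnibus gate before pairwise contrasts.

    One-way ANOVA when every group passes the normality check, otherwise
    Kruskal–Wallis (ANOVA on ranks).  Returns (significant, p).
    """
    if len(groups) < 2:
        raise ValueError("omnibus test needs >= 2 groups")
    normal = all(_is_normal(np.asarray(g, float), n_threshold) for g in groups)
    res = sps.f_oneway(*groups) if normal else sps.kruskal(*groups)
    p = float(res.pvalue)
    return p < alpha, p
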