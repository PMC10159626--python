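"""Locomotion metrics from 2-D worm tracks.

Center-of-mass tracks from the two-choice chemotaxis assay are cut into
non-overlapping 24-frame segments.  Per segment we compute the *deviation
angle* — the unsigned angle between the segment's net displacement vector
and the vector from the segment start toward the target endpoint (0° is
motion straight at the target, 180° straight away) — the speed (path length
over duration, cm/min), and the distance to the target at the segment
midpoint.  Reversals (episodes of backward motion) are detected from the
projection of the instantaneous displacement onto the recent heading and
reported as events per centimeter of worm track, binned by distance to the
target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "Track",
    "SegmentMetrics",
    "segment_metrics",
    "detect_reversals",
    "distance_profile",
    "PROXIMAL_INTERVAL_CM",
]

#: Distance band used for proximal-region summaries (cm from the target).
PROXIMAL_INTERVAL_CM = (1.2, 3.5)


@dataclass(frozen=True)
class Arena:
    """Rectangular assay plate with two absorbing endpoints (cm)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    cs_endpoint: tuple[float, float]
    alt_endpoint: tuple[float, float]
    start_point: tuple[float, float]
    endpoint_radius: float = 0.5

    def contains(self, pt: Sequence[float]) -> bool:
        x, y = pt
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def endpoint(self, which: str) -> np.ndarray:
        if which == "cs":
            return np.asarray(self.cs_endpoint, float)
        if which == "alt":
            return np.asarray(self.alt_endpoint, float)
        raise ValueError(f"unknown endpoint {which!r}")


@dataclass
class Track:
    """One animal's center-of-mass trajectory."""

    animal_id: str
    positions: np.ndarray  # (n_frames, 2) in cm
    frame_rate: float
    arena: Arena | None = None
    group: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    def truncated(self, max_duration_s: float) -> "Track":
        """First ``max_duration_s`` of the track (odor gradients degrade later)."""
        n = int(round(max_duration_s * self.frame_rate)) + 1
        if n >= self.n_frames:
            return self
        return Track(
            animal_id=self.animal_id, positions=self.positions[:n],
            frame_rate=self.frame_rate, arena=self.arena, group=self.group,
        )


@dataclass(frozen=True)
class SegmentMetrics:
    segment_index: int
    deviation_angle_deg: float
    speed_cm_min: float
    distance_to_target_cm: float


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    cosang = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def segment_metrics(
    track: Track,
    segment_frames: int = 24,
    target: str | Sequence[float] = "cs",
    max_duration_s: float | None = 600.0,
) -> pd.DataFrame:
    """Per-segment deviation angle, speed, and distance to target.

    Non-overlapping ``segment_frames``-frame segments; the segment vector is
    end − start position; speed is the polyline path length over the segment
    duration.  Segments with zero net displacement have an undefined angle
    and are skipped (count in ``df.attrs['skipped_segments']``).  By default
    only the first 10 min of the track are analyzed.
    """
    if max_duration_s is not None:
        track = track.truncated(max_duration_s)
    pos = track.positions
    if pos.shape[0] < segment_frames + 1:
        raise ValueError(
            f"track has {pos.shape[0]} frames; need at least {segment_frames + 1}"
        )
    if isinstance(target, str):
        if track.arena is None:
            raise ValueError("named target requires the track to carry an arena")
        tgt = track.arena.endpoint(target)
    else:
        tgt = np.asarray(target, float)
    dur_s = segment_frames / track.frame_rate
    n_segments = (pos.shape[0] - 1) // segment_frames
    rows, skipped = [], 0
    for i in range(n_segments):
        a, b = i * segment_frames, (i + 1) * segment_frames
        start, end = pos[a], pos[b]
        seg_vec = end - start
        if np.linalg.norm(seg_vec) == 0.0:
            skipped += 1
            continue
        to_target = tgt - start
        angle = _angle_between_deg(seg_vec, to_target)
        path_cm = float(np.sum(np.linalg.norm(np.diff(pos[a : b + 1], axis=0), axis=1)))
        midpoint = pos[a + segment_frames // 2]
        rows.append(
            dict(
                animal_id=track.animal_id,
                group=track.group,
                segment_index=i,
                deviation_angle_deg=angle,
                speed_cm_min=path_cm / dur_s * 60.0,
                distance_to_target_cm=float(np.linalg.norm(midpoint - tgt)),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "animal_id", "group", "segment_index", "deviation_angle_deg",
            "speed_cm_min", "distance_to_target_cm",
        ],
    )
    df.attrs["skipped_segments"] = skipped
    return df


def detect_reversals(
    track: Track,
    displacement_threshold_cm: float = 0.01,
    heading_window_frames: int = 24,
    target: str | Sequence[float] = "cs",
    bin_width_cm: float = 0.25,
    max_duration_s: float | None = 600.0,
) -> tuple[list[tuple[int, int]], pd.DataFrame]:
    """Reversal events and their rate per cm of track, binned by distance.

    An event starts at the first frame whose displacement projects onto the
    recent heading (mean displacement over the preceding
    ``heading_window_frames``) more negatively than
    ``displacement_threshold_cm``, and ends when forward motion resumes.
    Returns ``(events, profile)`` where events are (start_frame, end_frame)
    pairs and the profile gives events per cm of path in each
    distance-to-target bin.
    """
    if displacement_threshold_cm <= 0 or heading_window_frames <= 0:
        raise ValueError("thresholds must be positive")
    if max_duration_s is not None:
        track = track.truncated(max_duration_s)
    pos = track.positions
    if pos.shape[0] < 3:
        raise ValueError("reversal detection needs at least 3 frames")
    disp = np.diff(pos, axis=0)  # (n-1, 2)
    n = disp.shape[0]
    events: list[tuple[int, int]] = []
    in_event = False
    start = 0
    for i in range(n):
        lo = max(0, i - heading_window_frames)
        if i == 0:
            heading = disp[0]
        else:
            heading = disp[lo:i].mean(axis=0)
        hnorm = np.linalg.norm(heading)
        proj = float(np.dot(disp[i], heading) / hnorm) if hnorm > 0 else 0.0
        if not in_event and proj < -displacement_threshold_cm:
            in_event, start = True, i
        elif in_event and proj >= 0.0:
            events.append((start, i))
            in_event = False
    if in_event:
        events.append((start, n - 1))

    if isinstance(target, str):
        tgt = track.arena.endpoint(target) if track.arena is not None else None
    else:
        tgt = np.asarray(target, float)
    step_len = np.linalg.norm(disp, axis=1)
    if tgt is None:
        profile = pd.DataFrame(
            columns=["bin_lo", "bin_hi", "events", "path_cm", "rate_per_cm"]
        )
        return events, profile
    dist = np.linalg.norm(pos[:-1] - tgt, axis=1)
    max_d = float(dist.max()) if n else 0.0
    edges = np.arange(0.0, max_d + bin_width_cm, bin_width_cm)
    which = np.digitize(dist, edges) - 1
    ev_bins = [which[s] for s, _ in events]
    rows = []
    for b in range(len(edges) - 1):
        path_cm = float(step_len[which == b].sum())
        n_ev = int(sum(1 for eb in ev_bins if eb == b))
        rows.append(
            dict(
                bin_lo=edges[b], bin_hi=edges[b + 1], events=n_ev,
                path_cm=path_cm,
                rate_per_cm=(n_ev / path_cm) if path_cm > 0 else np.nan,
            )
        )
    return events, pd.DataFrame(rows)


def distance_profile(
    metrics: pd.DataFrame,
    value_col: str = "deviation_angle_deg",
    bin_width_cm: float = 0.25,
    proximal: tuple[float, float] = PROXIMAL_INTERVAL_CM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric vs distance-to-target profile plus a proximal-region summary.

    Returns ``(profile, proximal_summary)``: the profile holds per-bin mean
    and SEM across animals; the summary holds one mean per animal over
    segments whose distance lies in the proximal interval (default
    1.2–3.5 cm), the unit entering group comparisons (rank-sum + pFDR,
    delegated to :mod:`wormmem.stats`).  Animals with no proximal segments
    are flagged with NaN.
    """
    df = metrics.copy()
    max_d = float(df["distance_to_target_cm"].max())
    edges = np.arange(0.0, max_d + bin_width_cm, bin_width_cm)
    df["bin"] = np.digitize(df["distance_to_target_cm"], edges) - 1
    per_animal_bin = (
        df.groupby(["animal_id", "bin"])[value_col].mean().reset_index()
    )
    prof = (
        per_animal_bin.groupby("bin")[value_col]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    prof["bin_lo"] = edges[prof["bin"].to_numpy()]
    prof["bin_hi"] = prof["bin_lo"] + bin_width_cm

    lo, hi = proximal
    prox = df[(df["distance_to_target_cm"] >= lo) & (df["distance_to_target_cm"] <= hi)]
    summary = (
        prox.groupby("animal_id")[value_col].mean().rename("proximal_mean").reset_index()
    )
    all_animals = df["animal_id"].unique()
    missing = sorted(set(all_animals) - set(summary["animal_id"]))
    if missing:
        summary = pd.concat(
            [summary, pd.DataFrame({"animal_id": missing, "proximal_mean": np.nan})],
            ignore_index=True,
        )
    return prof, summary
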