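"""Synthetic calcium-trace and locomotion-track datasets with planted truth.

Every analysis stage in the pipeline is validated against data whose latent
structure is known.  The trace generator emulates the butanone/diacetyl
exchange recordings: one minute of diacetyl then six 30-s exchanges, with
GCaMP-like stimulus-locked transients (difference-of-exponentials kernel),
ON-type neurons responding to butanone onset and OFF-type to its removal,
additive Gaussian noise, slow baseline drift, and bimodal animal-to-animal
responsiveness (some neurons respond in only ~half the animals).  Group
structure is planted through a neuron × experience-component effect matrix
whose entries multiply response amplitudes.

The track generator emulates the two-choice chemotaxis recordings: agents
start 3.5 cm from the endpoints and move in 24-frame segments whose
deviation angle, speed, and reversal statistics are drawn from configured
group distributions, so the locomotion metrics have known expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    GROUP_LABELS,
    GroupLabel,
    StimulusSchedule,
    TraceRecord,
    exchange_protocol,
)
from .locomotion import Arena, Track

__all__ = [
    "COMPONENTS",
    "EffectMatrix",
    "NeuronSpec",
    "TraceGenConfig",
    "TraceGroundTruth",
    "gen_trace_dataset",
    "GroupLocomotion",
    "TrackGenConfig",
    "TrackGroundTruth",
    "gen_track_dataset",
    "default_arena",
]

#: Experience components of the effect matrix.  US+ / US− are the appetitive
#: and aversive treatments themselves (mock vs naive); CS(AP) / CS(AV) the
#: stimulus-specific effects (trained vs mock); VAL a pure valence term.
COMPONENTS = ("US+", "US-", "CS(AP)", "CS(AV)", "VAL")


@dataclass
class EffectMatrix:
    """Signed amplitude multipliers, neurons × experience components.

    A zero entry means the neuron's expected response is identical across the
    groups that define that component.  Group amplitude multipliers derive
    from the components as::

        NAIVE  = 1
        STAP-M = 1 + US+
        STAV-M = 1 + US-
        STAP-T = 1 + US+ + CS(AP) + VAL
        STAV-T = 1 + US- + CS(AV) - VAL
    """

    table: pd.DataFrame  # index: neuron ids, columns: COMPONENTS

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENTS if c not in self.table.columns]
        if missing:
            raise ValueError(f"effect matrix missing components {missing}")
        if not np.all(np.isfinite(self.table[list(COMPONENTS)].to_numpy(float))):
            raise ValueError("effect matrix entries must be finite")

    @classmethod
    def zeros(cls, neurons: Sequence[str]) -> "EffectMatrix":
        return cls(pd.DataFrame(0.0, index=list(neurons), columns=list(COMPONENTS)))

    @classmethod
    def from_dict(
        cls, effects: Mapping[str, Mapping[str, float]], neurons: Sequence[str]
    ) -> "EffectMatrix":
        em = cls.zeros(neurons)
        for neuron, comps in effects.items():
            for comp, val in comps.items():
                if comp not in COMPONENTS:
                    raise ValueError(f"unknown component {comp!r}")
                em.table.loc[neuron, comp] = float(val)
        return em

    def group_multiplier(self, neuron: str, group: GroupLabel | str) -> float:
        if isinstance(group, str):
            group = GroupLabel.from_short(group)
        e = self.table.loc[neuron]
        short = group.short
        if short == "NAIVE":
            return 1.0
        if short == "STAP-M":
            return 1.0 + e["US+"]
        if short == "STAV-M":
            return 1.0 + e["US-"]
        if short == "STAP-T":
            return 1.0 + e["US+"] + e["CS(AP)"] + e["VAL"]
        if short == "STAV-T":
            return 1.0 + e["US-"] + e["CS(AV)"] - e["VAL"]
        raise ValueError(f"no multiplier defined for group {short}")

    def expected_contrast(self, neuron: str, component: str) -> float:
        """Expected group-mean amplitude difference for a delta-matrix row.

        The six delta-matrix components are contrasts of group multipliers;
        e.g. CS(AP) = STAP-T − STAP-M.  This is the generator's bookkeeping
        used as ground truth for recovery tests.
        """
        m = lambda g: self.group_multiplier(neuron, g)
        contrasts = {
            "CS(AP)": m("STAP-T") - m("STAP-M"),
            "CS(AV)": m("STAV-T") - m("STAV-M"),
            "US+": m("STAP-M") - m("NAIVE"),
            "US-": m("STAV-M") - m("NAIVE"),
            "VAL(T)": m("STAP-T") - m("STAV-T"),
            "VAL(M)": m("STAP-M") - m("STAV-M"),
        }
        if component not in contrasts:
            raise ValueError(f"unknown contrast component {component!r}")
        return contrasts[component]


@dataclass
class NeuronSpec:
    """One simulated neuron class."""

    name: str
    responder_type: str = "ON"  # ON: butanone onset; OFF: butanone removal
    base_amplitude: float = 1.0  # peak ΔF as a fraction of baseline F
    #: P(respond) at the animal (or trial) level; a scalar, or a mapping
    #: group-short-label -> probability for bimodal, group-specific
    #: responsiveness (e.g. ASER responding in only ~50% of naive animals)
    responder_probability: float | Mapping[str, float] = 1.0

    def __post_init__(self) -> None:
        if self.responder_type not in ("ON", "OFF"):
            raise ValueError("responder_type must be 'ON' or 'OFF'")
        probs = (
            self.responder_probability.values()
            if isinstance(self.responder_probability, Mapping)
            else [self.responder_probability]
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("responder_probability must lie in [0, 1]")

    def prob_for(self, group_short: str) -> float:
        if isinstance(self.responder_probability, Mapping):
            return float(self.responder_probability.get(group_short, 1.0))
        return float(self.responder_probability)


@dataclass
class TraceGenConfig:
    """Study conditions for the synthetic exchange-protocol dataset.

    Defaults mirror the recordings the pipeline targets: six 30-s exchanges
    after a 60-s diacetyl prelude, 2 Hz soma-level sampling, 15 animals per
    group, GCaMP-like kinetics (1 s rise, 8 s decay), noise at 10% of the
    response amplitude and baseline drift up to 5% of baseline.
    """

    neurons: Sequence[NeuronSpec]
    frame_rate: float = 2.0
    n_animals: int = 15
    groups: Sequence[str] = GROUP_LABELS
    rise_s: float = 1.0
    decay_s: float = 8.0
    noise_sd: float = 0.1  # fraction of the neuron's response amplitude
    drift_amplitude: float = 0.05  # fraction of baseline F
    drift_period_s: float = 200.0
    baseline_f: float = 100.0
    responder_mode: str = "animal"  # or "trial"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.neurons:
            raise ValueError("need at least one neuron")
        if self.frame_rate <= 0 or self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("rates and time constants must be positive")
        if self.decay_s <= self.rise_s:
            raise ValueError("decay must be slower than rise")
        if self.responder_mode not in ("animal", "trial"):
            raise ValueError("responder_mode must be 'animal' or 'trial'")


@dataclass
class TraceGroundTruth:
    """Latent values drawn by the trace generator."""

    effects: EffectMatrix
    group_multipliers: pd.DataFrame  # neurons × groups
    expected_contrasts: pd.DataFrame  # neurons × six delta components
    responders: pd.DataFrame  # neuron, group, animal, (trial,) responding
    config: TraceGenConfig


def _transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient, normalized to peak 1."""
    k = np.where(t >= 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def _onset_times(schedule: StimulusSchedule, responder_type: str) -> np.ndarray:
    """Stimulus-event times for a neuron type: BUT onsets (ON) or removals (OFF)."""
    times = []
    for (a0, _, s0), (a1, _, s1) in zip(schedule.epochs, schedule.epochs[1:]):
        if responder_type == "ON" and s1 == "BUT" and s0 != "BUT":
            times.append(a1)
        if responder_type == "OFF" and s0 == "BUT" and s1 != "BUT":
            times.append(a1)
    return np.array(times)


def gen_trace_dataset(
    config: TraceGenConfig, effects: EffectMatrix
) -> tuple[list[TraceRecord], StimulusSchedule, TraceGroundTruth]:
    """Generate the full synthetic exchange dataset.

    Returns the trace records (raw-F scale), the stimulus schedule, and a
    ground-truth record of every latent draw.  Fixing ``config.seed`` makes
    the output bit-identical.
    """
    for spec in config.neurons:
        if spec.name not in effects.table.index:
            raise ValueError(f"effect matrix missing configured neuron {spec.name!r}")

    schedule = exchange_protocol()
    rng = np.random.default_rng(config.seed)
    n = int(round(schedule.end * config.frame_rate))
    t = np.arange(n) / config.frame_rate

    kernels = {
        rt: np.stack(
            [
                _transient_kernel(t - ev, config.rise_s, config.decay_s)
                for ev in _onset_times(schedule, rt)
            ]
        )
        for rt in ("ON", "OFF")
    }

    records: list[TraceRecord] = []
    resp_rows: list[dict] = []
    B = config.baseline_f

    for group_short in config.groups:
        group = GroupLabel.from_short(group_short)
        for animal_idx in range(config.n_animals):
            animal_id = f"{group_short}_a{animal_idx:03d}"
            for spec in config.neurons:
                mult = effects.group_multiplier(spec.name, group)
                amp = spec.base_amplitude * B * mult
                ev_kernels = kernels[spec.responder_type]
                n_events = ev_kernels.shape[0]
                p_resp = spec.prob_for(group_short)
                if config.responder_mode == "animal":
                    responding = rng.random() < p_resp
                    weights = np.full(n_events, float(responding))
                    resp_rows.append(
                        dict(
                            neuron=spec.name, group=group_short,
                            animal=animal_id, trial=-1, responding=bool(responding),
                        )
                    )
                else:
                    flags = rng.random(n_events) < p_resp
                    weights = flags.astype(float)
                    for trial_i, fl in enumerate(flags):
                        resp_rows.append(
                            dict(
                                neuron=spec.name, group=group_short,
                                animal=animal_id, trial=trial_i,
                                responding=bool(fl),
                            )
                        )
                signal = amp * (weights @ ev_kernels)
                phase = rng.uniform(0, 2 * np.pi)
                drift = (
                    config.drift_amplitude
                    * B
                    * np.sin(2 * np.pi * t / config.drift_period_s + phase)
                )
                noise = rng.normal(
                    0.0, config.noise_sd * spec.base_amplitude * B, size=n
                )
                f = np.maximum(B + signal + drift + noise, 0.0)
                records.append(
                    TraceRecord(
                        neuron_id=spec.name,
                        animal_id=animal_id,
                        paradigm=group.paradigm,
                        treatment=group.treatment,
                        time=t.copy(),
                        intensity=f,
                        frame_rate=config.frame_rate,
                    )
                )

    neurons = [s.name for s in config.neurons]
    mult_df = pd.DataFrame(
        {
            g: [effects.group_multiplier(nm, g) for nm in neurons]
            for g in config.groups
        },
        index=neurons,
    )
    comp6 = ("CS(AP)", "CS(AV)", "US+", "US-", "VAL(T)", "VAL(M)")
    contrast_df = pd.DataFrame(
        {c: [effects.expected_contrast(nm, c) for nm in neurons] for c in comp6},
        index=neurons,
    )
    truth = TraceGroundTruth(
        effects=effects,
        group_multipliers=mult_df,
        expected_contrasts=contrast_df,
        responders=pd.DataFrame(resp_rows),
        config=config,
    )
    return records, schedule, truth


# ---------------------------------------------------------------------------
# Locomotion tracks


@dataclass
class GroupLocomotion:
    """Planted per-group locomotion statistics.

    Deviation angles are drawn from a normal truncated to [0, 180] degrees;
    speeds from a normal truncated to positive values (cm/min); reversals as
    a Poisson process along the path (events/cm).
    """

    angle_mean_deg: float = 60.0
    angle_sd_deg: float = 30.0
    speed_mean_cm_min: float = 0.8
    speed_sd_cm_min: float = 0.2
    reversal_rate_per_cm: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.angle_mean_deg <= 180:
            raise ValueError("angle mean must lie in [0, 180] degrees")
        if self.speed_mean_cm_min <= 0:
            raise ValueError("speed mean must be positive")
        if self.reversal_rate_per_cm < 0:
            raise ValueError("reversal rate must be non-negative")


def default_arena() -> Arena:
    """Two-choice assay plate: endpoints 3.5 cm from the central start point."""
    return Arena(
        x_min=0.0, x_max=9.0, y_min=0.0, y_max=6.0,
        cs_endpoint=(8.0, 3.0), alt_endpoint=(1.0, 3.0),
        start_point=(4.5, 3.0), endpoint_radius=0.5,
    )


@dataclass
class TrackGenConfig:
    group_params: Mapping[str, GroupLocomotion]
    arena: Arena = field(default_factory=default_arena)
    n_tracks_per_group: int = 50
    # 1 Hz keeps per-frame displacements at ordinary crawl speeds (~0.8
    # cm/min -> ~0.13 mm/frame) above the 0.1 mm reversal-detection threshold
    frame_rate: float = 1.0
    duration_s: float = 600.0
    segment_frames: int = 24
    reversal_frames: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        a = self.arena
        for name, pt in (("start_point", a.start_point),
                         ("cs_endpoint", a.cs_endpoint),
                         ("alt_endpoint", a.alt_endpoint)):
            if not a.contains(pt):
                raise ValueError(f"{name} {pt} lies outside the arena")
        sx, sy = a.start_point
        if self.frame_rate <= 0 or self.duration_s <= 0:
            raise ValueError("frame_rate and duration must be positive")


@dataclass
class TrackGroundTruth:
    """Per-segment latent draws of the track generator."""

    segments: pd.DataFrame  # animal, group, segment, angle, speed, n_reversals
    reversal_events: pd.DataFrame  # animal, segment, frame


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (fast enough at these scales)."""
    out = rng.normal(mean, sd, size=size)
    scalar = np.isscalar(out)
    out = np.atleast_1d(out)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return float(out[0]) if scalar else out


def _rotate(vec: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def gen_track_dataset(
    config: TrackGenConfig,
) -> tuple[list[Track], TrackGroundTruth]:
    """Generate 2-D worm tracks with planted locomotion statistics.

    Motion is built segment-wise: per 24-frame segment the agent draws a
    deviation angle (random sign), a speed, and a Poisson number of reversal
    events; it then steps along the rotated direction-to-target with constant
    per-frame step length, reversing direction for ``reversal_frames`` frames
    at each event.  Path length per segment therefore equals speed × duration
    exactly, and the measured per-segment statistics recover the planted
    distributions.  Agents stop (are absorbed) at either endpoint; walls
    reflect.
    """
    rng = np.random.default_rng(config.seed)
    arena = config.arena
    cs = np.asarray(arena.cs_endpoint, float)
    alt = np.asarray(arena.alt_endpoint, float)
    dt = 1.0 / config.frame_rate
    n_frames = int(round(config.duration_s * config.frame_rate))
    seg = config.segment_frames

    tracks: list[Track] = []
    seg_rows: list[dict] = []
    ev_rows: list[dict] = []

    for group in sorted(config.group_params):
        params = config.group_params[group]
        for k in range(config.n_tracks_per_group):
            animal_id = f"{group}_w{k:03d}"
            pos = np.asarray(arena.start_point, float).copy()
            positions = [pos.copy()]
            seg_idx = 0
            frame = 0
            absorbed = False
            while frame < n_frames and not absorbed:
                to_target = cs - pos
                dist = np.linalg.norm(to_target)
                direction = to_target / dist if dist > 0 else np.array([1.0, 0.0])
                angle = _truncated_normal(
                    rng, params.angle_mean_deg, params.angle_sd_deg, 0.0, 180.0
                )
                sign = 1.0 if rng.random() < 0.5 else -1.0
                heading = _rotate(direction, sign * np.radians(angle))
                speed = _truncated_normal(
                    rng, params.speed_mean_cm_min, params.speed_sd_cm_min,
                    1e-6, np.inf,
                )
                step = speed / 60.0 * dt  # cm per frame
                seg_len_cm = step * seg
                n_rev = rng.poisson(params.reversal_rate_per_cm * seg_len_cm)
                rev_starts: set[int] = set()
                if n_rev > 0:
                    lo, hi = 4, seg - config.reversal_frames - 1
                    starts = sorted(
                        rng.choice(
                            np.arange(lo, hi),
                            size=min(n_rev, (hi - lo) // (config.reversal_frames + 2)),
                            replace=False,
                        )
                    )
                    # enforce a forward gap between events so each is distinct
                    kept, last_end = [], -10
                    for s0 in starts:
                        if s0 > last_end + 1:
                            kept.append(int(s0))
                            last_end = s0 + config.reversal_frames - 1
                    rev_starts = set(kept)
                    n_rev = len(kept)
                seg_rows.append(
                    dict(
                        animal=animal_id, group=group, segment=seg_idx,
                        angle_deg=angle, speed_cm_min=speed, n_reversals=n_rev,
                    )
                )
                backward_until = -1
                for j in range(seg):
                    if frame >= n_frames or absorbed:
                        break
                    if j in rev_starts:
                        backward_until = j + config.reversal_frames - 1
                        ev_rows.append(
                            dict(animal=animal_id, segment=seg_idx, frame=frame)
                        )
                    direction_sign = -1.0 if j <= backward_until else 1.0
                    new_pos = pos + direction_sign * step * heading
                    # reflecting walls
                    if new_pos[0] < arena.x_min or new_pos[0] > arena.x_max:
                        heading[0] = -heading[0]
                        new_pos = pos + direction_sign * step * heading
                    if new_pos[1] < arena.y_min or new_pos[1] > arena.y_max:
                        heading[1] = -heading[1]
                        new_pos = pos + direction_sign * step * heading
                    new_pos[0] = np.clip(new_pos[0], arena.x_min, arena.x_max)
                    new_pos[1] = np.clip(new_pos[1], arena.y_min, arena.y_max)
                    pos = new_pos
                    positions.append(pos.copy())
                    frame += 1
                    if (
                        np.linalg.norm(pos - cs) <= arena.endpoint_radius
                        or np.linalg.norm(pos - alt) <= arena.endpoint_radius
                    ):
                        absorbed = True
                seg_idx += 1
            tracks.append(
                Track(
                    animal_id=animal_id,
                    positions=np.asarray(positions),
                    frame_rate=config.frame_rate,
                    arena=arena,
                    group=group,
                )
            )
    truth = TrackGroundTruth(
        segments=pd.DataFrame(seg_rows),
        reversal_events=pd.DataFrame(ev_rows),
    )
    return tracks, truth
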