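"""Shared data model for the associative-memory imaging/behavior pipeline.

The pipeline analyzes calcium-imaging recordings of *C. elegans* chemosensory
and inter- neurons across associative training paradigms, together with
two-choice chemotaxis behavior.  All stages key on a closed set of group
labels: a training *paradigm* (short/long-term, appetitive/aversive) crossed
with a *treatment* (trained, mock-trained, or naive).  Naive animals have no
paradigm, encoded as ``Paradigm.NONE``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import numpy as np

__all__ = [
    "Paradigm",
    "Treatment",
    "GroupLabel",
    "TraceRecord",
    "StimulusSchedule",
    "EndpointCounts",
    "exchange_protocol",
    "GROUP_LABELS",
]


class Paradigm(str, Enum):
    """Training paradigm: short/long-term (ST/LT), appetitive/aversive (AP/AV)."""

    STAP = "STAP"
    STAV = "STAV"
    LTAP = "LTAP"
    LTAV = "LTAV"
    NONE = "NONE"


class Treatment(str, Enum):
    trained = "trained"
    mock = "mock"
    naive = "naive"


@dataclass(frozen=True)
class GroupLabel:
    """A (paradigm, treatment) pair identifying an experimental group."""

    paradigm: Paradigm
    treatment: Treatment

    def __post_init__(self) -> None:
        p = Paradigm(self.paradigm)
        t = Treatment(self.treatment)
        object.__setattr__(self, "paradigm", p)
        object.__setattr__(self, "treatment", t)
        if (p is Paradigm.NONE) != (t is Treatment.naive):
            raise ValueError(
                f"paradigm NONE iff treatment naive; got ({p.value}, {t.value})"
            )

    @property
    def short(self) -> str:
        """Compact label, e.g. 'STAP-T', 'STAV-M', 'NAIVE'."""
        if self.treatment is Treatment.naive:
            return "NAIVE"
        suffix = "T" if self.treatment is Treatment.trained else "M"
        return f"{self.paradigm.value}-{suffix}"

    @classmethod
    def from_short(cls, label: str) -> "GroupLabel":
        label = label.strip().upper().replace("_", "-")
        if label == "NAIVE":
            return cls(Paradigm.NONE, Treatment.naive)
        base = label.replace("-", "")
        paradigm, suffix = base[:-1], base[-1]
        treatment = {"T": Treatment.trained, "M": Treatment.mock}.get(suffix)
        if treatment is None:
            raise ValueError(f"unknown group label {label!r}")
        return cls(Paradigm(paradigm), treatment)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.short


NAIVE = GroupLabel(Paradigm.NONE, Treatment.naive)

#: Groups of the short-term exchange design, in canonical order.
GROUP_LABELS: tuple[str, ...] = ("STAP-T", "STAP-M", "STAV-T", "STAV-M", "NAIVE")


@dataclass
class TraceRecord:
    """One neuron's raw fluorescence time series in one animal.

    ``intensity`` is raw F (arbitrary fluorescence units, pre-normalization);
    ``time`` is seconds from recording start and must be strictly increasing.
    """

    neuron_id: str
    animal_id: str
    paradigm: Paradigm
    treatment: Treatment
    time: np.ndarray
    intensity: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.paradigm = Paradigm(self.paradigm)
        self.treatment = Treatment(self.treatment)
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError(
                f"time must be strictly increasing (record {self.neuron_id}/{self.animal_id})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(
                f"intensity must be finite (record {self.neuron_id}/{self.animal_id})"
            )
        if np.any(self.intensity < 0):
            raise ValueError(
                f"intensity must be non-negative (record {self.neuron_id}/{self.animal_id})"
            )
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        # paradigm NONE iff naive, enforced via GroupLabel
        GroupLabel(self.paradigm, self.treatment)

    @property
    def group(self) -> GroupLabel:
        return GroupLabel(self.paradigm, self.treatment)

    @property
    def n_frames(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class StimulusSchedule:
    """Contiguous stimulus epochs and the switch times between them.

    ``epochs`` is an ordered list of ``(start_s, end_s, stimulus)`` with
    stimulus one of {'BUT', 'DA', 'buffer'}; epochs must tile the recording
    without gaps or overlap.  ``switch_times`` are the interior epoch
    boundaries, i.e. the stimulus-exchange instants.
    """

    epochs: tuple[tuple[float, float, str], ...]

    VALID_STIMULI = frozenset({"BUT", "DA", "buffer"})

    def __post_init__(self) -> None:
        eps = tuple((float(a), float(b), str(s)) for a, b, s in self.epochs)
        object.__setattr__(self, "epochs", eps)
        if not eps:
            raise ValueError("schedule needs at least one epoch")
        for a, b, s in eps:
            if s not in self.VALID_STIMULI:
                raise ValueError(f"unknown stimulus {s!r}")
            if not b > a:
                raise ValueError(f"epoch ({a}, {b}) has nonpositive duration")
        for (_, b0, _), (a1, _, _) in zip(eps, eps[1:]):
            if not np.isclose(b0, a1):
                raise ValueError("epochs must be contiguous and non-overlapping")

    @property
    def switch_times(self) -> np.ndarray:
        return np.array([a for a, _, _ in self.epochs[1:]], dtype=float)

    @property
    def start(self) -> float:
        return self.epochs[0][0]

    @property
    def end(self) -> float:
        return self.epochs[-1][1]

    def stimulus_at(self, t: float) -> str:
        for a, b, s in self.epochs:
            if a <= t < b:
                return s
        if np.isclose(t, self.end):
            return self.epochs[-1][2]
        raise ValueError(f"t={t} outside schedule [{self.start}, {self.end}]")


def exchange_protocol(
    da_prelude_s: float = 60.0, step_s: float = 30.0, n_exchanges: int = 6
) -> StimulusSchedule:
    """The butanone/diacetyl exchange protocol: one minute of diacetyl (DA)
    followed by six 30-s butanone (BUT)/DA alternations.

    Each BUT/DA exchange is one *trial*; the default yields six switch times
    at 60, 90, ..., 210 s and a 240-s recording.
    """
    epochs: list[tuple[float, float, str]] = [(0.0, da_prelude_s, "DA")]
    t = da_prelude_s
    for i in range(n_exchanges):
        stim = "BUT" if i % 2 == 0 else "DA"
        epochs.append((t, t + step_s, stim))
        t += step_s
    return StimulusSchedule(tuple(epochs))


@dataclass(frozen=True)
class EndpointCounts:
    """Worm counts at the conditioned-stimulus endpoint vs the alternative."""

    n_cs: int
    n_alt: int

    def __post_init__(self) -> None:
        if self.n_cs < 0 or self.n_alt < 0:
            raise ValueError("endpoint counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_cs + self.n_alt
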