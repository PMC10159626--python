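"""Canonical synthetic study conditions.

One place defines the synthetic dataset every analysis stage, test, and the
acceptance script run on: the neuron panel with ON/OFF response types and
heterogeneous amplitudes, the planted neuron × experience-component effect
matrix, bimodal ASER responsiveness (~50% of naive and aversively trained
animals respond), 15 animals per group over the five short-term groups, and
the locomotion groups for the chemotaxis analyses (directed appetitively
trained worms, undirected aversively trained worms, naive in between, with
speed and reversal statistics shared — the planted analog of training
modulating directionality but not speed or reversals).
"""

from __future__ import annotations

from .synthetic import (
    EffectMatrix,
    GroupLocomotion,
    NeuronSpec,
    TraceGenConfig,
    TrackGenConfig,
)

__all__ = [
    "study_neurons",
    "study_effects",
    "study_trace_config",
    "study_track_config",
    "NEURON_ORDER",
]

#: Neuron ordering used for the decoding scaling curve.
NEURON_ORDER = ("AWA", "AWCON", "AWCOFF", "ASER", "ASEL", "AWB")


def study_neurons() -> list[NeuronSpec]:
    """The six-neuron chemosensory panel.

    Response types follow the known classes (AWC-OFF, ASER and AWB respond
    to butanone removal; the rest to its onset); base amplitudes are
    heterogeneous, as across real neuron classes; ASER responds in only
    half of the naive and aversively trained animals.
    """
    return [
        NeuronSpec("AWA", responder_type="ON", base_amplitude=1.2),
        NeuronSpec("AWCON", responder_type="ON", base_amplitude=0.8),
        NeuronSpec("AWCOFF", responder_type="OFF", base_amplitude=1.0),
        NeuronSpec(
            "ASER",
            responder_type="OFF",
            base_amplitude=0.9,
            responder_probability={"NAIVE": 0.5, "STAV-T": 0.5},
        ),
        NeuronSpec("ASEL", responder_type="ON", base_amplitude=0.6),
        NeuronSpec("AWB", responder_type="OFF", base_amplitude=0.7),
    ]


def study_effects() -> EffectMatrix:
    """Planted effect matrix: every nonzero entry is ≥ 2× the noise SD (0.1).

    The pattern sketches the recorded phenomenology — AWA suppressed by
    training of either valence, ASER and AWB modulated by aversive
    experience, AWC split between its ON and OFF classes — without claiming
    the measured magnitudes.
    """
    return EffectMatrix.from_dict(
        {
            "AWA": {"CS(AP)": -0.5, "CS(AV)": -0.4, "US+": 0.3},
            "AWCON": {"CS(AP)": 0.4, "US-": 0.3},
            "AWCOFF": {"CS(AV)": 0.5, "US+": -0.3},
            "ASER": {"CS(AV)": 0.6, "US-": 0.4},
            "ASEL": {"CS(AP)": 0.3, "US+": 0.4},
            "AWB": {"CS(AV)": -0.4, "US-": -0.3},
        },
        list(NEURON_ORDER),
    )


def study_trace_config(seed: int = 0, n_animals: int = 15) -> TraceGenConfig:
    return TraceGenConfig(neurons=study_neurons(), n_animals=n_animals, seed=seed)


def study_track_config(seed: int = 0, n_tracks_per_group: int = 40) -> TrackGenConfig:
    """Locomotion groups: training modulates directionality only.

    Appetitively trained animals are more directed toward the conditioned
    stimulus (smaller deviation angles), aversively trained ones less
    directed; speed and reversal statistics are identical across groups.
    Speeds sit well above the reversal-perceptibility threshold.
    """
    shared = dict(speed_mean_cm_min=1.2, speed_sd_cm_min=0.15, reversal_rate_per_cm=0.5)
    return TrackGenConfig(
        group_params={
            "naive": GroupLocomotion(angle_mean_deg=70, angle_sd_deg=25, **shared),
            "STAP-T": GroupLocomotion(angle_mean_deg=40, angle_sd_deg=20, **shared),
            "STAV-T": GroupLocomotion(angle_mean_deg=100, angle_sd_deg=25, **shared),
        },
        n_tracks_per_group=n_tracks_per_group,
        seed=seed,
    )
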