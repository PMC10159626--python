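"""Generate the canonical synthetic study: calcium traces and worm tracks.

Produces the exchange-protocol trace dataset (5 short-term groups x 15
animals x 6 neurons, planted neuron x experience-component effects) and the
two-choice locomotion tracks (3 groups x 40 animals, training modulating
directionality only).  Bulky tidy tables go to scratch/; the ground truth
and small summaries go to results/.
"""

import argparse
from pathlib import Path

import yaml

from wormmem.io import save_schedule, save_track_table, save_trace_table
from wormmem.study import study_effects, study_trace_config, study_track_config
from wormmem.synthetic import gen_trace_dataset, gen_track_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    results = ROOT / "results"
    scratch = ROOT / "scratch" / "data"
    results.mkdir(exist_ok=True)
    scratch.mkdir(parents=True, exist_ok=True)

    effects = study_effects()
    records, schedule, truth = gen_trace_dataset(
        study_trace_config(seed=args.seed), effects
    )
    save_trace_table(records, scratch / "traces.csv")
    save_schedule(schedule, scratch / "schedule.csv")

    tracks, track_truth = gen_track_dataset(study_track_config(seed=args.seed))
    save_track_table(tracks, scratch / "tracks.csv")

    truth_doc = {
        "seed": args.seed,
        "effects": {n: effects.table.loc[n].to_dict() for n in effects.table.index},
        "group_multipliers": truth.group_multipliers.round(6).to_dict(),
        "expected_contrasts": truth.expected_contrasts.round(6).to_dict(),
        "responder_fraction": float(truth.responders["responding"].mean()),
        "n_trace_records": len(records),
        "n_tracks": len(tracks),
        "planted_track_segment_means": (
            track_truth.segments.groupby("group")[["angle_deg", "speed_cm_min"]]
            .mean().round(3).to_dict()
        ),
    }
    (results / "ground_truth.yaml").write_text(yaml.safe_dump(truth_doc, sort_keys=False))

    print(f"traces: {len(records)} records "
          f"({len({r.animal_id for r in records})} animals, "
          f"{len({r.neuron_id for r in records})} neurons) -> scratch/data/")
    print(f"tracks: {len(tracks)} -> scratch/data/tracks.csv")
    print(f"ground truth -> results/ground_truth.yaml")


if __name__ == "__main__":
    main()
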