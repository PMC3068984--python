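"""Event-history metrics per animal and interval from the scored hypnograms.

Reads the scored hypnograms written by 01_simulate_and_score.py, averages
the two recording days per animal, and writes tidy tables of normed state
durations, normed transition frequencies and REMS episode statistics for
the L1/L2/D1/D2 intervals under results/.

Run from the repository root:  python analysis/02_hypnogram_metrics.py
"""

import argparse
from pathlib import Path

from srsleep.io import read_hypnogram_csv
from srsleep.pipeline import (
    _durations_long,
    _episodes_long,
    _transitions_long,
    summarize_cohort,
)


class _Animal:
    def __init__(self, animal_id, hypnograms):
        self.animal_id = animal_id
        self.line = animal_id.split("_")[0]
        self.hypnograms = sorted(hypnograms, key=lambda h: h.day_index)
        self.recordings = []


def load_animals(csv_path):
    by_animal = {}
    for h in read_hypnogram_csv(csv_path):
        by_animal.setdefault(h.animal_id, []).append(h)
    return [_Animal(aid, hs) for aid, hs in sorted(by_animal.items())]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--hypnograms", type=Path,
                    default=Path("scratch/analysis/hypnograms_scored.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    animals = load_animals(args.hypnograms)
    summaries = summarize_cohort(animals)

    dur = _durations_long(summaries)
    tra = _transitions_long(summaries)
    epi = _episodes_long(summaries)
    dur.to_csv(args.out / "normed_durations.csv", index=False)
    tra.to_csv(args.out / "normed_transitions.csv", index=False)
    epi.to_csv(args.out / "rems_episodes.csv", index=False)

    rems_l1 = (dur[(dur.interval == "L1") & (dur.state == "REMS")]
               .groupby("line")["normed_duration"].mean())
    print("FINDING: mean L1 REMS normed duration per line:")
    for line, v in rems_l1.sort_index().items():
        print(f"  {line}: {100 * v:.2f}%")
    n2r = (tra[(tra.interval == "L1") & (tra.transition == "NREMS->REMS")]
           .groupby("line")["normed"].mean())
    print("FINDING: mean L1 normed NREMS->REMS transition frequency per line:")
    for line, v in n2r.sort_index().items():
        print(f"  {line}: {100 * v:.2f}%")
    print(f"wrote normed_durations / normed_transitions / rems_episodes under {args.out}/")


if __name__ == "__main__":
    main()
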