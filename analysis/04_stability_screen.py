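"""Stability screen: which line's curves lie constantly above/below others?

Tests, for every pair of lines, whether the group-mean hourly curves of
(a) each ordered state-transition frequency and (b) each NREMS band's
relative power lie stably above or below one another across the 23 ZT
points (Wilcoxon matched-pairs on per-ZT excesses over the common median).
Writes the full screen to results/stability_screen.csv.

Run from the repository root:  python analysis/04_stability_screen.py
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from srsleep.pipeline import band_stability_series, transition_stability_series
from srsleep.stability import stability_screen

_here = Path(__file__).parent
spec = importlib.util.spec_from_file_location("metrics_stage", _here / "02_hypnogram_metrics.py")
metrics_stage = importlib.util.module_from_spec(spec)
spec.loader.exec_module(metrics_stage)


def load_band_profiles(csv_path):
    df = pd.read_csv(csv_path)
    out = {}
    for aid, g in df.groupby("animal_id"):
        prof = g.set_index("zt_hour").drop(columns="animal_id")
        out[aid] = (aid.split("_")[0], prof)
    return out


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--hypnograms", type=Path,
                    default=Path("scratch/analysis/hypnograms_scored.csv"))
    ap.add_argument("--band-profiles", type=Path,
                    default=Path("scratch/analysis/band_profiles_nrems.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    animals = metrics_stage.load_animals(args.hypnograms)
    series = transition_stability_series(animals)
    if args.band_profiles.exists():
        series.update(band_stability_series(load_band_profiles(args.band_profiles), "NREMS"))
    else:
        print(f"note: {args.band_profiles} not found; screening transitions only")

    table = stability_screen(series)
    table.to_csv(args.out / "stability_screen.csv", index=False)
    stable = table[table.stable]
    print(f"FINDING: {len(stable)} of {len(table)} quantity x pair comparisons are "
          "stable (significant and sign-constant in >= 90% of ZT points):")
    for _, row in stable.iterrows():
        print(f"  {row.quantity:18s} {row.direction:8s} p = {row.p:.2e}")
    print(f"wrote full screen to {args.out}/stability_screen.csv")


if __name__ == "__main__":
    main()
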