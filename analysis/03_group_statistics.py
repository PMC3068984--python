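"""Interval-wise group statistics: MANOVAs, univariate F tests, LSD contrasts.

For each interval (L1, L2, D1, D2): a MANOVA over normed state durations
(WAKE dropped — the three fractions sum to 1), a MANOVA over the six normed
transition frequencies, Bonferroni-modified LSD contrasts where the global
test is significant, and a one-way ANOVA of mean REMS episode length.
Writes results/group_stats.csv and a readable report.

Run from the repository root:  python analysis/03_group_statistics.py
"""

import argparse
import importlib.util
import sys
from pathlib import Path

from srsleep.pipeline import PipelineConfig, _stats_battery, summarize_cohort

_here = Path(__file__).parent
spec = importlib.util.spec_from_file_location("metrics_stage", _here / "02_hypnogram_metrics.py")
metrics_stage = importlib.util.module_from_spec(spec)
spec.loader.exec_module(metrics_stage)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--hypnograms", type=Path,
                    default=Path("scratch/analysis/hypnograms_scored.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    animals = metrics_stage.load_animals(args.hypnograms)
    summaries = summarize_cohort(animals)
    report: list = []
    table = _stats_battery(summaries, PipelineConfig(), report)
    table.to_csv(args.out / "group_stats.csv", index=False)
    (args.out / "stats_report.txt").write_text("\n".join(report) + "\n")
    print("\n".join(report))
    sig = table[table.p < 0.05]
    print(f"\nFINDING: {len(sig)} of {len(table)} interval x family tests significant "
          f"at the nominal 0.05 level (see {args.out}/stats_report.txt).")


if __name__ == "__main__":
    main()
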