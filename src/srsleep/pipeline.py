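"""End-to-end orchestration: simulate -> features -> score -> metrics -> stats -> stability.

The pipeline operates on a cohort of animals (three breeding lines), each
with one hypnogram per recording day, optionally backed by raw signals.
Stages write tidy CSVs into a run directory together with a manifest
(config hash, row counts), so every figure-equivalent table — normed
durations, normed transition frequencies, REMS episode lengths, hourly
band profiles and the stability screen — can be re-plotted from artifacts
alone.  A run is reproducible bit-for-bit from its config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from srsleep import io as sio
from srsleep.features import BandScheme, bandpass_filter, epoch_features, hourly_band_profile
from srsleep.metrics import (
    INTERVALS,
    TRANSITION_PAIRS,
    hourly_transition_counts,
    summarize_animal,
)
from srsleep.scoring import ScoringThresholds, calibrate, score_epochs
from srsleep.simulate import SimConfig, default_presets, simulate_cohort
from srsleep.states import STATE_NAMES, VigilanceState
from srsleep.stats import band_auc, manova, oneway_anova
from srsleep.stability import stability_screen

__all__ = [
    "PipelineConfig",
    "run",
    "summarize_cohort",
    "duration_table",
    "transition_table",
    "episode_length_table",
    "score_cohort",
    "scoring_agreement",
    "transition_stability_series",
    "band_stability_series",
    "cohort_band_profiles",
]

_PAIR_LABELS = {p: f"{p[0].name}->{p[1].name}" for p in TRANSITION_PAIRS}


# ---------------------------------------------------------------------------
# cohort-level tables


def summarize_cohort(animals) -> dict:
    """Per-animal interval summaries for a list of AnimalRecord-like objects.

    Returns ``{animal_id: (line, {interval_name: IntervalSummary})}``.
    """
    out = {}
    for a in animals:
        out[a.animal_id] = (a.line, summarize_animal(a.hypnograms))
    return out


def duration_table(summaries: dict, interval: str):
    """Normed durations as (responses DataFrame, group labels) for one interval."""
    rows, groups, idx = [], [], []
    for animal_id, (line, per_iv) in summaries.items():
        d = per_iv[interval].normed_duration
        rows.append([d[s] for s in VigilanceState])
        groups.append(line)
        idx.append(animal_id)
    df = pd.DataFrame(rows, columns=list(STATE_NAMES), index=idx)
    return df, np.array(groups)


def transition_table(summaries: dict, interval: str):
    """Normed transition frequencies (6 ordered pairs) per animal for one interval."""
    rows, groups, idx = [], [], []
    for animal_id, (line, per_iv) in summaries.items():
        nt = per_iv[interval].normed_transitions
        rows.append([np.nan] * len(TRANSITION_PAIRS) if nt is None
                    else [nt[p] for p in TRANSITION_PAIRS])
        groups.append(line)
        idx.append(animal_id)
    df = pd.DataFrame(rows, columns=[_PAIR_LABELS[p] for p in TRANSITION_PAIRS], index=idx)
    return df, np.array(groups)


def episode_length_table(summaries: dict, interval: str):
    """Mean REMS episode length (s) per animal; NaN when no episode occurred."""
    vals, groups, idx = [], [], []
    for animal_id, (line, per_iv) in summaries.items():
        m = per_iv[interval].mean_rems_episode_length
        vals.append(np.nan if m is None else m)
        groups.append(line)
        idx.append(animal_id)
    return pd.Series(vals, index=idx, name="mean_rems_episode_length"), np.array(groups)


# ---------------------------------------------------------------------------
# signal-backed stages


def score_cohort(animals, scheme: BandScheme | None = None,
                 thresholds: ScoringThresholds | None = None,
                 *, filter_signals: bool = False) -> dict:
    """Extract features and score every recording; returns scored hypnograms.

    ``{animal_id: [Hypnogram per day]}``.  EMG cutoffs are calibrated per
    recording.  ``filter_signals`` applies the 0.5-29 Hz band-pass first
    (appropriate for real recordings; synthetic signals are already band
    limited).
    """
    if scheme is None:
        scheme = BandScheme()
    base = thresholds if thresholds is not None else ScoringThresholds()
    out = {}
    for a in animals:
        scored = []
        for rec in a.recordings:
            if filter_signals:
                rec = bandpass_filter(rec)
            feats = epoch_features(rec, scheme)
            th = calibrate(feats, base)
            scored.append(score_epochs(feats, th))
        out[a.animal_id] = scored
    return out


def scoring_agreement(animals, scored: dict) -> float:
    """Epoch-level agreement between generated and recovered hypnograms."""
    hits = total = 0
    for a in animals:
        for truth, est in zip(a.hypnograms, scored[a.animal_id]):
            hits += int((truth.states == est.states).sum())
            total += truth.n_epochs
    return hits / total


def cohort_band_profiles(animals, scheme: BandScheme | None = None,
                         restrict_to: VigilanceState | None = None) -> dict:
    """Per-animal hourly band profiles (days averaged).

    Returns ``{animal_id: (line, DataFrame hour x band)}``.  Features are
    computed from each animal's recordings; epochs are conditioned on the
    animal's hypnogram when ``restrict_to`` is given.
    """
    if scheme is None:
        scheme = BandScheme()
    out = {}
    for a in animals:
        profs = []
        for rec, hyp in zip(a.recordings, a.hypnograms):
            feats = epoch_features(rec, scheme)
            profs.append(hourly_band_profile(feats, hyp, restrict_to))
        out[a.animal_id] = (a.line, sum(profs) / len(profs))
    return out


# ---------------------------------------------------------------------------
# stability-series assembly


def transition_stability_series(animals) -> dict:
    """Group-mean hourly transition counts per ordered pair.

    For each animal the per-hour counts are averaged across days; the group
    curve is the mean across the line's animals.  Returns
    ``{"NREMS->REMS": DataFrame(index=zt_hour, columns=lines), ...}``.
    """
    per_line: dict = {}
    hours = None
    for a in animals:
        day_counts = [hourly_transition_counts(h) for h in a.hypnograms]
        hours = day_counts[0]["hours"]
        animal_mean = {
            p: np.mean([dc[p] for dc in day_counts], axis=0) for p in TRANSITION_PAIRS
        }
        per_line.setdefault(a.line, []).append(animal_mean)
    out = {}
    for p in TRANSITION_PAIRS:
        df = pd.DataFrame(
            {line: np.mean([am[p] for am in members], axis=0)
             for line, members in per_line.items()},
            index=pd.Index(hours, name="zt_hour"),
        )
        out[_PAIR_LABELS[p]] = df
    return out


def band_stability_series(profiles: dict, state_label: str = "NREMS") -> dict:
    """Group-mean hourly band-power curves from :func:`cohort_band_profiles`.

    Returns ``{f"{state_label}/{band}": DataFrame(index=zt_hour, columns=lines)}``.
    """
    per_line: dict = {}
    for _, (line, prof) in profiles.items():
        per_line.setdefault(line, []).append(prof)
    line_means = {line: sum(ps) / len(ps) for line, ps in per_line.items()}
    bands = next(iter(line_means.values())).columns
    out = {}
    for band in bands:
        df = pd.DataFrame({line: m[band] for line, m in line_means.items()})
        out[f"{state_label}/{band}"] = df
    return out


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    """Serialisable configuration of a full pipeline run."""

    out_dir: str = "run"
    input_hypnograms: str | None = None  # CSV path; None -> simulate
    include_signals: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)
    alpha: float = 0.05
    drop_duration_response: str = "WAKE"  # durations sum to 1; drop one for MANOVA
    stability_sign_fraction: float = 0.9
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = ScoringThresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path and logging excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _durations_long(summaries: dict) -> pd.DataFrame:
    rows = []
    for animal_id, (line, per_iv) in summaries.items():
        for iv, s in per_iv.items():
            for st, v in s.normed_duration.items():
                rows.append({"animal_id": animal_id, "line": line, "interval": iv,
                             "state": st.name, "normed_duration": v})
    return pd.DataFrame(rows)


def _transitions_long(summaries: dict) -> pd.DataFrame:
    rows = []
    for animal_id, (line, per_iv) in summaries.items():
        for iv, s in per_iv.items():
            for p in TRANSITION_PAIRS:
                rows.append({
                    "animal_id": animal_id, "line": line, "interval": iv,
                    "transition": _PAIR_LABELS[p],
                    "count": s.transition_counts[p],
                    "normed": np.nan if s.normed_transitions is None else s.normed_transitions[p],
                })
    return pd.DataFrame(rows)


def _episodes_long(summaries: dict) -> pd.DataFrame:
    rows = []
    for animal_id, (line, per_iv) in summaries.items():
        for iv, s in per_iv.items():
            rows.append({
                "animal_id": animal_id, "line": line, "interval": iv,
                "n_episodes": len(s.rems_episode_lengths),
                "mean_rems_episode_length_s": (np.nan if s.mean_rems_episode_length is None
                                               else s.mean_rems_episode_length),
            })
    return pd.DataFrame(rows)


def _stats_battery(summaries: dict, cfg: PipelineConfig, report_lines: list) -> pd.DataFrame:
    """MANOVAs on durations and transitions plus episode-length ANOVAs."""
    rows = []
    for iv in INTERVALS:
        dur, groups = duration_table(summaries, iv)
        dur = dur.drop(columns=[cfg.drop_duration_response])
        res = manova(dur, groups, alpha=cfg.alpha)
        report_lines.append(f"[{iv}] normed durations ({', '.join(dur.columns)}): {res}")
        rows.append({"interval": iv, "family": "durations", "wilks_lambda": res.wilks_lambda,
                     "F": res.F_approx, "df1": res.df1, "df2": res.df2, "p": res.p,
                     "n": res.n_used})
        tra, tg = transition_table(summaries, iv)
        tra = tra.dropna(axis=1, how="all")
        # normed transitions are compositional (rows sum to 1): drop structurally
        # constant pairs, then the rarest pair, mirroring the durations treatment
        tra = tra.loc[:, tra.std() > 0]
        if len(tra.columns) > 1 and np.allclose(tra.sum(axis=1).dropna(), 1.0):
            tra = tra.drop(columns=[tra.mean().idxmin()])
        try:
            res_t = manova(tra, tg, alpha=cfg.alpha)
            report_lines.append(f"[{iv}] normed transitions: {res_t}")
            rows.append({"interval": iv, "family": "transitions",
                         "wilks_lambda": res_t.wilks_lambda, "F": res_t.F_approx,
                         "df1": res_t.df1, "df2": res_t.df2, "p": res_t.p, "n": res_t.n_used})
        except np.linalg.LinAlgError as e:
            report_lines.append(f"[{iv}] normed transitions: MANOVA skipped ({e})")
        ep, eg = episode_length_table(summaries, iv)
        try:
            res_e = oneway_anova(ep, eg, alpha=cfg.alpha)
            report_lines.append(f"[{iv}] mean REMS episode length: {res_e}")
            rows.append({"interval": iv, "family": "rems_episode_length",
                         "wilks_lambda": np.nan, "F": res_e.F, "df1": res_e.df1,
                         "df2": res_e.df2, "p": res_e.p, "n": res_e.n_used})
        except ValueError as e:
            report_lines.append(f"[{iv}] mean REMS episode length: ANOVA skipped ({e})")
    return pd.DataFrame(rows)


def run(config: PipelineConfig):
    """Execute all applicable stages; returns the run directory path.

    With ``input_hypnograms`` set, signal synthesis, feature extraction and
    scoring are skipped and metrics onward run on the provided labels.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash(), "rows": {}}

    if config.input_hypnograms:
        hyps = sio.read_hypnogram_csv(config.input_hypnograms)
        by_animal: dict = {}
        for h in hyps:
            by_animal.setdefault(h.animal_id, []).append(h)
        # line label = prefix of the animal id before the underscore
        animals = [
            type("Rec", (), {"animal_id": aid, "line": aid.split("_")[0],
                             "hypnograms": sorted(v, key=lambda h: h.day_index),
                             "recordings": []})()
            for aid, v in sorted(by_animal.items())
        ]
        scored_agreement = None
    else:
        cohort = simulate_cohort(default_presets(), config.sim,
                                 include_signals=config.include_signals)
        animals = cohort.animals
        sio.write_hypnogram_csv(
            [h for a in animals for h in a.hypnograms], out / "hypnograms_true.csv")
        scored_agreement = None
        if config.include_signals:
            scored = score_cohort(animals, thresholds=config.thresholds)
            scored_agreement = scoring_agreement(animals, scored)
            sio.write_hypnogram_csv(
                [h for hs in scored.values() for h in hs], out / "hypnograms_scored.csv")
            manifest["scoring_agreement"] = scored_agreement
            # downstream metrics run on the scored labels, as in the source protocol
            for a in animals:
                a.hypnograms = scored[a.animal_id]

    summaries = summarize_cohort(animals)
    report: list = []
    _durations_long(summaries).to_csv(out / "normed_durations.csv", index=False)
    _transitions_long(summaries).to_csv(out / "normed_transitions.csv", index=False)
    _episodes_long(summaries).to_csv(out / "rems_episodes.csv", index=False)
    stats_df = _stats_battery(summaries, config, report)
    stats_df.to_csv(out / "group_stats.csv", index=False)

    series = transition_stability_series(animals)
    if (not config.input_hypnograms) and config.include_signals:
        profiles = cohort_band_profiles(animals, restrict_to=VigilanceState.NREMS)
        series.update(band_stability_series(profiles, "NREMS"))
        pd.concat({aid: prof for aid, (_, prof) in profiles.items()},
                  names=["animal_id", "zt_hour"]).to_csv(out / "band_profiles_nrems.csv")
    stab = stability_screen(series, alpha=config.alpha,
                            sign_fraction=config.stability_sign_fraction)
    stab.to_csv(out / "stability_screen.csv", index=False)

    for name, df in [("normed_durations", _durations_long(summaries)),
                     ("stability_screen", stab), ("group_stats", stats_df)]:
        manifest["rows"][name] = int(len(df))
    (out / "report.txt").write_text("\n".join(report) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    config.to_yaml(out / "config.yaml")
    return out
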