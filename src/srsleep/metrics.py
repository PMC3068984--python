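"""Event-history metrics of hypnograms: normed durations, transitions, episodes.

All quantities are computed per animal within the four standard intervals
of the 23-h recording day: L1 = ZT0-6 and L2 = ZT6-12 (light phase halves),
D1 = ZT12-18 and D2 = ZT18-23 (dark phase; D2 spans only five hours because
recordings stop at ZT23).  Normed durations express time in a state as a
fraction of the interval; normed transition frequencies express each of the
six ordered state-pair transition counts as a fraction of all transitions
in the interval, which makes the unequal interval lengths comparable.

Conventions (the analysis is insensitive to reasonable alternatives, but
these are fixed for reproducibility): an epoch belongs to the interval
containing its start time; a transition between consecutive differing
epochs is attributed to the interval in which the LATER epoch starts; a
REMS episode is a maximal run of consecutive REMS epochs and belongs to
the interval of its FIRST epoch (episodes spanning a boundary are not
split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from srsleep.states import Hypnogram, N_STATES, STATE_NAMES, VigilanceState

__all__ = [
    "TimeInterval",
    "INTERVALS",
    "TRANSITION_PAIRS",
    "IntervalSummary",
    "normed_durations",
    "transition_frequencies",
    "rems_episodes",
    "summarize_animal",
]


@dataclass(frozen=True)
class TimeInterval:
    """Half-open ZT interval [start, end), in hours."""

    name: str
    start: float
    end: float

    def contains(self, zt: np.ndarray) -> np.ndarray:
        return (zt >= self.start) & (zt < self.end)


INTERVALS = {
    "L1": TimeInterval("L1", 0.0, 6.0),
    "L2": TimeInterval("L2", 6.0, 12.0),
    "D1": TimeInterval("D1", 12.0, 18.0),
    "D2": TimeInterval("D2", 18.0, 23.0),
}

#: the six ordered off-diagonal state pairs, as (from, to)
TRANSITION_PAIRS = [
    (VigilanceState(i), VigilanceState(j))
    for i in range(N_STATES)
    for j in range(N_STATES)
    if i != j
]


def _interval_mask(hypnogram: Hypnogram, interval: TimeInterval) -> np.ndarray:
    zt = hypnogram.zt
    if interval.start < zt[0] - 1e-9 or interval.end > zt[-1] + hypnogram.epoch_seconds / 3600.0 + 1e-9:
        raise ValueError(
            f"interval {interval.name} [{interval.start}, {interval.end}) outside the "
            f"recording span [{zt[0]}, {zt[-1] + hypnogram.epoch_seconds / 3600.0})"
        )
    return interval.contains(zt)


def normed_durations(hypnogram: Hypnogram, interval: TimeInterval) -> dict:
    """Fraction of interval epochs spent in each state (sums to 1)."""
    mask = _interval_mask(hypnogram, interval)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"interval {interval.name} contains no epochs")
    sub = hypnogram.states[mask]
    return {s: float(np.count_nonzero(sub == int(s))) / n for s in VigilanceState}


def transition_frequencies(hypnogram: Hypnogram, interval: TimeInterval):
    """Counts and normed frequencies of the six ordered transitions.

    Returns ``(counts, normed)``: dicts keyed by ``(from, to)`` pairs.  When
    the interval contains no transition, ``normed`` is None (undefined, not
    zero) while counts of 0 are still returned for all six pairs.
    """
    mask = _interval_mask(hypnogram, interval)
    s = hypnogram.states
    # boundary between epoch i-1 and i belongs to the interval of epoch i
    later = np.flatnonzero(mask)
    later = later[later > 0]
    frm = s[later - 1]
    to = s[later]
    diff = frm != to
    counts = {pair: 0 for pair in TRANSITION_PAIRS}
    for a, b in zip(frm[diff], to[diff]):
        counts[(VigilanceState(int(a)), VigilanceState(int(b)))] += 1
    total = sum(counts.values())
    if total == 0:
        return counts, None
    normed = {pair: c / total for pair, c in counts.items()}
    return counts, normed


def rems_episodes(hypnogram: Hypnogram, interval: TimeInterval) -> list:
    """Lengths (seconds) of REMS episodes whose first epoch starts in the interval.

    An episode is a maximal run of consecutive REMS epochs; single-epoch
    episodes count.  An empty list (no episode) is a valid result; its mean
    is undefined, not zero.
    """
    _interval_mask(hypnogram, interval)  # validates coverage
    s = hypnogram.states
    is_r = (s == int(VigilanceState.REMS)).astype(np.int8)
    d = np.diff(np.concatenate(([0], is_r, [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    zt = hypnogram.zt
    out = []
    for a, b in zip(starts, ends):
        if interval.contains(np.array([zt[a]]))[0]:
            out.append(float((b - a) * hypnogram.epoch_seconds))
    return out


@dataclass
class IntervalSummary:
    """Per-animal, per-interval event-history summary (averaged over days)."""

    animal_id: str
    interval: str
    normed_duration: dict
    transition_counts: dict
    normed_transitions: dict | None
    rems_episode_lengths: list
    mean_rems_episode_length: float | None
    n_days: int = 1


def summarize_animal(hypnograms, intervals=None) -> dict:
    """Combine one animal's recording days into per-interval summaries.

    Normed durations and the mean REMS episode length are computed per day
    and averaged with equal weight across days (days on which an interval
    has no REMS episode are excluded from that interval's episode-length
    average); transition counts are summed across days and normed
    transition frequencies recomputed from the summed counts.
    """
    hyps = list(hypnograms)
    if not hyps:
        raise ValueError("need at least one recording day")
    n0 = hyps[0].n_epochs
    if any(h.n_epochs != n0 for h in hyps):
        raise ValueError("recording days have unequal epoch counts")
    if intervals is None:
        intervals = INTERVALS
    animal_id = hyps[0].animal_id
    out = {}
    for name, iv in intervals.items():
        dur = {s: np.mean([normed_durations(h, iv)[s] for h in hyps]) for s in VigilanceState}
        counts = {pair: 0 for pair in TRANSITION_PAIRS}
        for h in hyps:
            c, _ = transition_frequencies(h, iv)
            for pair in TRANSITION_PAIRS:
                counts[pair] += c[pair]
        total = sum(counts.values())
        normed = {p: c / total for p, c in counts.items()} if total else None
        lengths = []
        day_means = []
        for h in hyps:
            ep = rems_episodes(h, iv)
            lengths.extend(ep)
            if ep:
                day_means.append(float(np.mean(ep)))
        mean_len = float(np.mean(day_means)) if day_means else None
        out[name] = IntervalSummary(
            animal_id=animal_id,
            interval=name,
            normed_duration={s: float(v) for s, v in dur.items()},
            transition_counts=counts,
            normed_transitions=normed,
            rems_episode_lengths=lengths,
            mean_rems_episode_length=mean_len,
            n_days=len(hyps),
        )
    return out


def hourly_transition_counts(hypnogram: Hypnogram) -> dict:
    """Transition counts of each ordered pair per ZT hour (hour h = [h-1, h)).

    Feeds the stability screen, which compares group-mean per-hour
    transition frequencies across the 23 recording hours.
    """
    zt = hypnogram.zt
    hours = np.arange(int(np.floor(zt[0])) + 1, int(np.floor(zt[-1])) + 2)
    s = hypnogram.states
    out = {pair: np.zeros(hours.size) for pair in TRANSITION_PAIRS}
    later = np.arange(1, hypnogram.n_epochs)
    diff = s[later] != s[later - 1]
    idx = later[diff]
    hr = np.floor(zt[idx]).astype(int) + 1
    for i, h in zip(idx, hr):
        out[(VigilanceState(int(s[i - 1])), VigilanceState(int(s[i])))][h - hours[0]] += 1
    return {"hours": hours, **out}
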