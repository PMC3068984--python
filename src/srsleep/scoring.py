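"""Rule-based vigilance-state scoring of 4-s epochs.

A transparent threshold cascade over the spectral features stands in for
the semi-automatic scorer used at acquisition time, with every threshold
exposed in configuration and a manual-override channel replacing
interactive rescoring:

1. high EMG (above the calibrated wake cutoff)          -> WAKE
2. theta-dominant EEG with muscle atonia (EMG below the
   sleep cutoff and theta/delta above a ratio threshold) -> REMS
3. delta-dominant EEG                                    -> NREMS
4. otherwise the previous epoch's label (first epoch: WAKE).

EMG cutoffs are calibrated per recording from quantiles of the epoch EMG
RMS distribution, standing in for the experimenter's per-animal tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from srsleep.states import Hypnogram, PROVENANCE_OVERRIDE, VigilanceState

__all__ = [
    "ScoringThresholds",
    "CalibrationError",
    "calibrate",
    "score_epochs",
    "apply_overrides",
    "Hypnogram",
]


class CalibrationError(ValueError):
    """EMG distribution unusable for quantile calibration."""


@dataclass
class ScoringThresholds:
    """Thresholds of the scoring cascade.

    ``emg_wake_quantile`` / ``emg_sleep_quantile`` are quantiles of the
    per-recording EMG RMS distribution from which absolute cutoffs are
    calibrated; ``emg_wake_cutoff`` / ``emg_sleep_cutoff`` may instead be
    given explicitly (then calibration is the identity).
    """

    emg_wake_quantile: float = 0.60
    emg_sleep_quantile: float = 0.40
    delta_fraction_min: float = 0.35
    theta_delta_ratio_min: float = 1.5
    emg_wake_cutoff: float | None = None
    emg_sleep_cutoff: float | None = None

    def __post_init__(self) -> None:
        for q in (self.emg_wake_quantile, self.emg_sleep_quantile):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie strictly between 0 and 1")
        if self.theta_delta_ratio_min <= 0:
            raise ValueError("theta/delta ratio threshold must be positive")

    @property
    def calibrated(self) -> bool:
        return self.emg_wake_cutoff is not None and self.emg_sleep_cutoff is not None


def calibrate(features: pd.DataFrame, thresholds: ScoringThresholds | None = None) -> ScoringThresholds:
    """Fill in absolute EMG cutoffs from the recording's EMG RMS quantiles.

    Explicit cutoffs already present are kept (identity).  A degenerate,
    effectively constant EMG distribution cannot separate wake from sleep
    and raises :class:`CalibrationError` advising explicit cutoffs.
    """
    if thresholds is None:
        thresholds = ScoringThresholds()
    if thresholds.calibrated:
        return thresholds
    if len(features) < 100:
        raise CalibrationError("need at least 100 epochs to calibrate EMG cutoffs")
    emg = np.asarray(features["emg_rms"], dtype=float)
    if emg.max() - emg.min() <= 1e-12 * max(1.0, abs(emg.max())):
        raise CalibrationError(
            "EMG RMS is constant over the recording; supply explicit emg_wake_cutoff "
            "and emg_sleep_cutoff instead of quantile calibration"
        )
    wake = thresholds.emg_wake_cutoff
    sleep = thresholds.emg_sleep_cutoff
    if wake is None:
        wake = float(np.quantile(emg, thresholds.emg_wake_quantile))
    if sleep is None:
        sleep = float(np.quantile(emg, thresholds.emg_sleep_quantile))
    if wake <= 0 or sleep <= 0:
        raise CalibrationError("calibrated EMG cutoffs must be strictly positive")
    return replace(thresholds, emg_wake_cutoff=wake, emg_sleep_cutoff=sleep)


def score_epochs(features: pd.DataFrame, thresholds: ScoringThresholds) -> Hypnogram:
    """Label every epoch WAKE/NREMS/REMS via the threshold cascade.

    Epochs with undefined relative powers (zero total power) fall through
    to the previous-state rule, so the output is always total.
    """
    if not thresholds.calibrated:
        raise ValueError("thresholds not calibrated; call calibrate() first")
    emg = np.asarray(features["emg_rms"], dtype=float)
    delta = np.asarray(features["rel_delta"], dtype=float)
    theta = np.asarray(features["rel_theta"], dtype=float)
    defined = np.asarray(features["power_defined"], dtype=bool)
    n = emg.size

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = theta / delta
    is_wake = emg > thresholds.emg_wake_cutoff
    is_rems = (
        ~is_wake
        & defined
        & (emg < thresholds.emg_sleep_cutoff)
        & (ratio > thresholds.theta_delta_ratio_min)
    )
    is_nrems = ~is_wake & ~is_rems & defined & (delta > thresholds.delta_fraction_min)

    states = np.full(n, -1, dtype=np.int8)
    states[is_wake] = VigilanceState.WAKE
    states[is_rems] = VigilanceState.REMS
    states[is_nrems] = VigilanceState.NREMS
    # rule 4: undecided epochs inherit the previous decided label (seed WAKE)
    if (states < 0).any():
        s = pd.Series(states.astype(float)).replace(-1.0, np.nan)
        states = s.ffill().fillna(float(VigilanceState.WAKE)).to_numpy().astype(np.int8)

    zt0 = float(features["zt"].iloc[0]) if n else 0.0
    return Hypnogram(
        states=states,
        zt_start=zt0,
        animal_id=features.attrs.get("animal_id", ""),
        day_index=features.attrs.get("day_index", 0),
    )


def apply_overrides(hypnogram: Hypnogram, overrides) -> Hypnogram:
    """Replace listed epochs with manually assigned states.

    ``overrides`` is an iterable of ``(epoch_index, state)`` pairs (state as
    :class:`VigilanceState` or its name).  Out-of-range indices raise with
    the offending indices listed; all untouched epochs keep their label and
    AUTO provenance.
    """
    out = hypnogram.copy()
    pairs = [(int(i), VigilanceState[s] if isinstance(s, str) else VigilanceState(s))
             for i, s in overrides]
    bad = [i for i, _ in pairs if not 0 <= i < out.n_epochs]
    if bad:
        raise IndexError(f"override epoch indices out of range: {sorted(set(bad))}")
    for i, s in pairs:
        out.states[i] = int(s)
        out.provenance[i] = PROVENANCE_OVERRIDE
    return out
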