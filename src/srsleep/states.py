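"""Vigilance states and the hypnogram container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class VigilanceState(IntEnum):
    """The three rodent vigilance states, scored per 4-s epoch."""

    WAKE = 0
    NREMS = 1
    REMS = 2


STATE_NAMES = tuple(s.name for s in VigilanceState)
N_STATES = len(VigilanceState)

#: provenance codes for each scored epoch
PROVENANCE_AUTO = 0
PROVENANCE_OVERRIDE = 1


@dataclass
class Hypnogram:
    """ZT-aligned sequence of vigilance-state labels for one animal-day.

    Parameters
    ----------
    states
        Integer-coded states (``VigilanceState``), one per epoch.
    zt_start
        Zeitgeber time of the first epoch in hours (lights-on = ZT0).
    epoch_seconds
        Epoch length; 4 s throughout this pipeline.
    provenance
        Per-epoch origin: ``PROVENANCE_AUTO`` or ``PROVENANCE_OVERRIDE``.
    """

    states: np.ndarray
    zt_start: float = 0.0
    epoch_seconds: float = 4.0
    animal_id: str = ""
    day_index: int = 0
    provenance: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-D sequence")
        if self.states.size and not np.isin(self.states, list(VigilanceState)).all():
            raise ValueError("states contains values outside {WAKE, NREMS, REMS}")
        if self.provenance is None:
            self.provenance = np.full(self.states.size, PROVENANCE_AUTO, dtype=np.int8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.int8)
            if self.provenance.shape != self.states.shape:
                raise ValueError("provenance and states must have equal length")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def zt(self) -> np.ndarray:
        """ZT (hours) of each epoch's start."""
        return self.zt_start + np.arange(self.n_epochs) * (self.epoch_seconds / 3600.0)

    def copy(self) -> "Hypnogram":
        return Hypnogram(
            states=self.states.copy(),
            zt_start=self.zt_start,
            epoch_seconds=self.epoch_seconds,
            animal_id=self.animal_id,
            day_index=self.day_index,
            provenance=self.provenance.copy(),
        )
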