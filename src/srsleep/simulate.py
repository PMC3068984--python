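"""Synthetic sleep-EEG cohorts for the stress-reactivity (HR/IR/LR) mouse lines.

Hypnograms are first-order Markov chains on 4-s epochs, piecewise-homogeneous
by light phase (LIGHT = ZT0-12, DARK = ZT12-23).  The shipped presets encode
the qualitative line differences: HR mice enter REMS from NREMS more often
than IR and LR in both phases (raising REMS time through episode *count*,
not episode length), and LR mice carry depressed theta/alpha relative power
in NREMS.  EEG signals are built per epoch as spectrally shaped noise with
exact band-power fractions; EMG is white noise with state-dependent
amplitude obeying the atonia ordering REMS < NREMS < WAKE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from srsleep.features import BandScheme, RawRecording
from srsleep.states import Hypnogram, N_STATES, VigilanceState

__all__ = [
    "VigilanceState",
    "LinePreset",
    "SimConfig",
    "CohortDataset",
    "AnimalRecord",
    "ConfigurationError",
    "default_presets",
    "stationary_distribution",
    "simulate_hypnogram",
    "synthesize_signals",
    "simulate_cohort",
]

LIGHT = "LIGHT"
DARK = "DARK"

_ROW_SUM_TOL = 1e-12


class ConfigurationError(ValueError):
    """Raised for invalid presets or simulation configuration."""


@dataclass
class SimConfig:
    """Recording-session geometry shared by simulation and analysis.

    Defaults mirror the experimental protocol: two successive 23-h sessions
    per animal, 64 Hz sampling, 4-s scoring epochs, lights off at ZT12,
    eight animals per breeding line.
    """

    n_animals_per_line: int = 8
    n_days: int = 2
    epoch_seconds: float = 4.0
    sample_rate: float = 64.0
    recording_hours: float = 23.0
    lights_off_zt: float = 12.0
    seed: int = 20110324

    def __post_init__(self) -> None:
        if self.recording_hours <= 0 or self.epoch_seconds <= 0:
            raise ConfigurationError("recording_hours and epoch_seconds must be positive")
        n = self.recording_hours * 3600.0 / self.epoch_seconds
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("recording length must be divisible by the epoch length")
        spe = self.sample_rate * self.epoch_seconds
        if abs(spe - round(spe)) > 1e-9:
            raise ConfigurationError("epoch length must hold a whole number of samples")

    @property
    def epochs_per_day(self) -> int:
        return int(round(self.recording_hours * 3600.0 / self.epoch_seconds))

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.sample_rate * self.epoch_seconds))


@dataclass
class LinePreset:
    """Generative parameters of one breeding line.

    ``phase_transition_matrices`` maps light phase (LIGHT/DARK) to a 3x3
    row-stochastic matrix of per-epoch transition probabilities, rows and
    columns ordered WAKE, NREMS, REMS.  ``band_profile`` maps each state to
    target relative powers over the five analysis bands (delta, theta,
    alpha, eta, beta); the remainder up to 1 is placed in the inter-band
    gap bins.  ``emg_level`` and ``eeg_amplitude`` are RMS amplitudes in
    arbitrary uV units.
    """

    line_id: str
    phase_transition_matrices: dict
    band_profile: dict
    emg_level: dict
    eeg_amplitude: dict

    def __post_init__(self) -> None:
        for phase in (LIGHT, DARK):
            if phase not in self.phase_transition_matrices:
                raise ConfigurationError(f"preset {self.line_id!r}: missing {phase} matrix")
            P = np.asarray(self.phase_transition_matrices[phase], dtype=float)
            self.phase_transition_matrices[phase] = P
            if P.shape != (N_STATES, N_STATES):
                raise ConfigurationError(f"preset {self.line_id!r}: {phase} matrix must be 3x3")
            if (P < 0).any():
                raise ConfigurationError(f"preset {self.line_id!r}: negative probability in {phase}")
            if np.abs(P.sum(axis=1) - 1.0).max() > _ROW_SUM_TOL:
                raise ConfigurationError(
                    f"preset {self.line_id!r}: {phase} matrix rows must sum to 1"
                )
        for state in VigilanceState:
            prof = np.asarray(self.band_profile[state], dtype=float)
            self.band_profile[state] = prof
            if (prof < 0).any() or prof.sum() > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"preset {self.line_id!r}: band profile of {state.name} must be "
                    "non-negative and sum to at most 1"
                )
        emg = self.emg_level
        if not (emg[VigilanceState.REMS] < emg[VigilanceState.NREMS] < emg[VigilanceState.WAKE]):
            raise ConfigurationError(
                f"preset {self.line_id!r}: EMG atonia ordering REMS < NREMS < WAKE violated"
            )


def _preset(line_id, light, dark, nrems_theta_alpha=(0.15, 0.10)):
    theta_n, alpha_n = nrems_theta_alpha
    # NREMS delta absorbs what theta/alpha give up so total in-band power is constant
    delta_n = 0.90 - theta_n - alpha_n - 0.06 - 0.04
    band_profile = {
        VigilanceState.WAKE: np.array([0.30, 0.25, 0.12, 0.10, 0.08]),
        VigilanceState.NREMS: np.array([delta_n, theta_n, alpha_n, 0.06, 0.04]),
        VigilanceState.REMS: np.array([0.15, 0.55, 0.10, 0.06, 0.04]),
    }
    return LinePreset(
        line_id=line_id,
        phase_transition_matrices={LIGHT: np.array(light), DARK: np.array(dark)},
        band_profile=band_profile,
        emg_level={VigilanceState.WAKE: 30.0, VigilanceState.NREMS: 10.0, VigilanceState.REMS: 2.0},
        eeg_amplitude={VigilanceState.WAKE: 40.0, VigilanceState.NREMS: 80.0, VigilanceState.REMS: 50.0},
    )


def default_presets() -> dict:
    """Shipped HR/IR/LR presets.

    Ordering of the NREMS->REMS entry probability is HR > IR > LR in both
    phases, with identical REMS exit rows, so HR gains REMS time through
    more episodes of unchanged length.  LR carries depressed theta/alpha
    relative power in NREMS.
    """
    hr_light = [[0.960, 0.040, 0.000], [0.016, 0.965, 0.019], [0.058, 0.002, 0.940]]
    ir_light = [[0.960, 0.040, 0.000], [0.016, 0.971, 0.013], [0.058, 0.002, 0.940]]
    lr_light = [[0.960, 0.040, 0.000], [0.016, 0.974, 0.010], [0.058, 0.002, 0.940]]
    hr_dark = [[0.985, 0.015, 0.000], [0.034, 0.956, 0.010], [0.070, 0.002, 0.928]]
    ir_dark = [[0.985, 0.015, 0.000], [0.034, 0.960, 0.006], [0.070, 0.002, 0.928]]
    lr_dark = [[0.985, 0.015, 0.000], [0.034, 0.961, 0.005], [0.070, 0.002, 0.928]]
    return {
        "HR": _preset("HR", hr_light, hr_dark),
        "IR": _preset("IR", ir_light, ir_dark),
        "LR": _preset("LR", lr_light, lr_dark, nrems_theta_alpha=(0.11, 0.07)),
    }


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _phase_of_epoch(config: SimConfig, epoch_index: int, zt_start: float = 0.0) -> str:
    zt = (zt_start + epoch_index * config.epoch_seconds / 3600.0) % 24.0
    return LIGHT if zt < config.lights_off_zt else DARK


def simulate_hypnogram(
    preset: LinePreset,
    config: SimConfig,
    animal_seed: int,
    *,
    initial_state: VigilanceState | None = None,
    animal_id: str = "",
    day_index: int = 0,
) -> Hypnogram:
    """Simulate one 23-h day of 4-s vigilance-state epochs.

    The LIGHT matrix governs epochs starting in ZT0-12, the DARK matrix
    those in ZT12-23.  The initial state is drawn from the stationary
    distribution of the LIGHT matrix unless ``initial_state`` is given
    (used to chain successive recording days).
    """
    n = config.epochs_per_day
    if n <= 0:
        raise ValueError("zero-length recording")
    rng = np.random.default_rng(animal_seed)

    mats = {p: preset.phase_transition_matrices[p] for p in (LIGHT, DARK)}
    cum = {p: np.cumsum(mats[p], axis=1) for p in mats}
    # epoch index at which the phase flips (recording starts at ZT0)
    flip = int(round(config.lights_off_zt * 3600.0 / config.epoch_seconds))

    if initial_state is None:
        pi_light = stationary_distribution(mats[LIGHT])
        state = int(rng.choice(N_STATES, p=pi_light))
    else:
        state = int(initial_state)

    u = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    cl, cd = cum[LIGHT], cum[DARK]
    for i in range(n):
        c = cl if i < flip else cd
        row = c[state]
        state = 0 if u[i] < row[0] else (1 if u[i] < row[1] else 2)
        states[i] = state
    return Hypnogram(states=states, zt_start=0.0, epoch_seconds=config.epoch_seconds,
                     animal_id=animal_id, day_index=day_index)


def synthesize_signals(
    hypnogram: Hypnogram,
    preset: LinePreset,
    config: SimConfig,
    seed: int,
    scheme: BandScheme | None = None,
) -> RawRecording:
    """Generate state-conditioned EEG/EMG for a hypnogram.

    Each 4-s epoch of EEG is spectrally shaped noise: the target relative
    power of each analysis band (within 0.75-31.75 Hz) equals the preset's
    band profile for the epoch's state, with the remainder placed in the
    inter-band gap bins; phases are random per epoch, and the epoch RMS is
    scaled exactly to the state's EEG amplitude.  EMG is white noise with
    the state's RMS level.
    """
    if scheme is None:
        scheme = BandScheme()
    n_epochs = hypnogram.n_epochs
    if n_epochs != config.epochs_per_day:
        raise ValueError(
            f"hypnogram has {n_epochs} epochs but config implies {config.epochs_per_day}"
        )
    rng = np.random.default_rng(seed)
    nsamp = config.samples_per_epoch
    freqs = np.fft.rfftfreq(nsamp, d=1.0 / config.sample_rate)
    nbins = freqs.size

    band_bins = [scheme.band_bin_indices(name, freqs) for name in scheme.band_names]
    in_range = scheme.analysis_bin_mask(freqs)
    gap = in_range.copy()
    for idx in band_bins:
        gap[idx] = False
    gap_idx = np.flatnonzero(gap)

    # per-state one-sided power templates, unit total power
    templates = np.zeros((N_STATES, nbins))
    for s in VigilanceState:
        prof = preset.band_profile[s]
        t = np.zeros(nbins)
        for frac, idx in zip(prof, band_bins):
            t[idx] = frac / len(idx)
        rem = 1.0 - prof.sum()
        if gap_idx.size:
            t[gap_idx] += rem / gap_idx.size
        templates[int(s)] = t

    states = hypnogram.states.astype(int)
    amp = np.array([preset.eeg_amplitude[VigilanceState(k)] for k in range(N_STATES)])
    power = templates[states] * (amp[states] ** 2)[:, None]  # (n_epochs, nbins)

    # one-sided power P_k -> complex rfft coefficients with random phases;
    # interior bins carry half the power in each of the two sides
    mag = nsamp * np.sqrt(power / 2.0)
    mag[:, 0] = 0.0
    if nsamp % 2 == 0:
        mag[:, -1] = nsamp * np.sqrt(power[:, -1])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=mag.shape)
    spec = mag * np.exp(1j * phases)
    spec[:, 0] = 0.0
    if nsamp % 2 == 0:
        spec[:, -1] = mag[:, -1]  # Nyquist bin must be real
    eeg = np.fft.irfft(spec, n=nsamp, axis=1).reshape(-1)

    emg_amp = np.array([preset.emg_level[VigilanceState(k)] for k in range(N_STATES)])
    emg = rng.standard_normal(n_epochs * nsamp) * np.repeat(emg_amp[states], nsamp)

    return RawRecording(
        eeg=eeg,
        emg=emg,
        sample_rate=config.sample_rate,
        zt_start=hypnogram.zt_start,
        animal_id=hypnogram.animal_id,
        day_index=hypnogram.day_index,
    )


@dataclass
class AnimalRecord:
    animal_id: str
    line: str
    hypnograms: list  # one Hypnogram per recording day
    recordings: list = field(default_factory=list)  # optional RawRecording per day


@dataclass
class CohortDataset:
    config: SimConfig
    animals: list

    @property
    def animal_ids(self) -> list:
        return [a.animal_id for a in self.animals]


def simulate_cohort(
    presets: dict,
    config: SimConfig,
    *,
    include_signals: bool = False,
    n_animals_per_line: dict | None = None,
) -> CohortDataset:
    """Simulate a full cohort: ``n_animals_per_line`` animals per breeding line.

    Animal seeds derive deterministically from ``config.seed`` via
    ``numpy.random.SeedSequence``, so a master seed reproduces the cohort
    exactly.  Successive days chain the Markov state (day 2 starts where
    day 1 ended).
    """
    animals = []
    seen = set()
    for line_idx, (line, preset) in enumerate(sorted(presets.items())):
        n_line = (n_animals_per_line or {}).get(line, config.n_animals_per_line)
        for a in range(n_line):
            animal_id = f"{line}_{a + 1:02d}"
            if animal_id in seen:
                raise ConfigurationError(f"duplicate animal identifier {animal_id!r}")
            seen.add(animal_id)
            hyps, recs = [], []
            prev_state = None
            for day in range(config.n_days):
                ss = np.random.SeedSequence([config.seed, line_idx, a, day])
                hyp_seed, sig_seed = ss.generate_state(2)
                hyp = simulate_hypnogram(
                    preset, config, int(hyp_seed),
                    initial_state=prev_state, animal_id=animal_id, day_index=day,
                )
                prev_state = VigilanceState(int(hyp.states[-1]))
                hyps.append(hyp)
                if include_signals:
                    recs.append(synthesize_signals(hyp, preset, config, int(sig_seed)))
            animals.append(AnimalRecord(animal_id=animal_id, line=line,
                                        hypnograms=hyps, recordings=recs))
    return CohortDataset(config=config, animals=animals)
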