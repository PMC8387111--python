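"""Synthetic visual-stream experiment: design tables and sensor epochs.

The generator emulates the structure of a rapid serial visual presentation
study: each subject watches 672 trials of 8 oriented Gabor patches flashed
every 250 ms (the flanking masks evoke no modelled response), for 5376
oriented stimuli per subject.  Orientations are i.i.d. uniform on the
orientation half-circle [0, pi); the analysis features are the doubled
angle alpha = 2*theta (sine/cosine regression needs a full-circle
variable) and delta, the circular orientation distance to the previous
item (undefined at position 1).

Evoked activity is produced by a hierarchical dynamical system
(:mod:`streamwaves.dynamics`): each stimulus injects a step input of 58
samples (~233 ms at 250 Hz) into the network, and the per-level observable
profiles are amplitude-modulated by the stimulus features (sin alpha,
cos alpha, mean-centred delta).  Per-stimulus responses superpose
additively, are projected through a random subject-specific matrix onto 32
virtual sensors, and receive i.i.d. Gaussian sensor noise (SD 1 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import NetworkSpec, StepInput, simulate

__all__ = [
    "FS",
    "SOA",
    "N_SENSORS",
    "STIM_DURATION_SAMPLES",
    "DESIGN_COLUMNS",
    "circular_orientation_distance",
    "sample_design",
    "default_network",
    "TuningProjection",
    "SensorEpochs",
    "render_subject",
    "epoch",
    "simulate_subject",
    "sequence_epochs",
]

FS = 250.0  # sensor sampling rate, Hz
SOA = 0.25  # stimulus onset asynchrony, s
N_SENSORS = 32
N_POSITIONS = 8
N_TRIALS = 672
N_SUBJECTS = 15
STIM_DURATION_SAMPLES = 58  # ~233 ms stimulus duration at 250 Hz
#: Two leading masks precede the first oriented item in every trial.
SEQUENCE_LEAD = 2 * SOA
#: Trial period: 2 masks + 8 items + 1 mask (11 x 250 ms) + 1.25 s intertrial.
TRIAL_PERIOD = 11 * SOA + 1.25

DESIGN_COLUMNS = (
    "subject",
    "trial",
    "position",
    "theta_rad",
    "alpha_rad",
    "delta_rad",
    "onset_s",
)


def circular_orientation_distance(a, b):
    """Absolute circular distance between orientations (period pi).

    The result lies in [0, pi/2]; orthogonal orientations are maximally
    distant.
    """
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), np.pi)
    return np.minimum(d, np.pi - d)


def sample_design(
    n_trials: int = N_TRIALS,
    n_subjects: int = N_SUBJECTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample the per-stimulus design table for every subject.

    Orientations are i.i.d. uniform on [0, pi) across all stimuli;
    ``alpha_rad`` doubles them onto the full circle and ``delta_rad`` is
    the circular orientation distance to the preceding item within the
    trial (NaN at position 1).  Onsets are spaced by the SOA, with the
    first oriented item ``SEQUENCE_LEAD`` after the trial start.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for subject in range(n_subjects):
        theta = rng.uniform(0.0, np.pi, size=(n_trials, N_POSITIONS))
        delta = np.full_like(theta, np.nan)
        delta[:, 1:] = circular_orientation_distance(theta[:, 1:], theta[:, :-1])
        trial = np.repeat(np.arange(1, n_trials + 1), N_POSITIONS)
        position = np.tile(np.arange(1, N_POSITIONS + 1), n_trials)
        onset = (
            (trial - 1) * TRIAL_PERIOD + SEQUENCE_LEAD + (position - 1) * SOA
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "trial": trial,
                    "position": position,
                    "theta_rad": theta.ravel(),
                    "alpha_rad": 2.0 * theta.ravel(),
                    "delta_rad": delta.ravel(),
                    "onset_s": onset,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_network(n_levels: int = 10) -> NetworkSpec:
    """The updating hierarchy used as the default signal generator.

    A chain of negative feedback loops in which the hidden units maintain
    and propagate the stimulus drive while each observable unit reads out
    the difference between its level's content and the level below:
    observables emit a transient at stimulus onset and an opposite
    transient at offset, and the waves widen as they travel up the
    hierarchy.  The weights are a valid exemplar found by the
    architecture search on its reduced grid.
    """
    return NetworkSpec.from_weights(
        {
            ("y", "x", 0): -0.5,
            ("y", "y", 0): 0.5,
            ("y", "x", 1): 1.0,
            ("y", "y", 1): 1.0,
        },
        n_levels=n_levels,
        activation_x="satlin",
    )


@dataclass(frozen=True)
class TuningProjection:
    """Random linear projection of observable activity onto sensors.

    ``F`` has shape (n_sensors, n_levels * 3): each of the three feature
    dimensions (delta, sin alpha, cos alpha) of each level's observable
    unit projects to every sensor with an independent standard-normal
    coefficient.  Fixed per subject.
    """

    F: np.ndarray
    noise_sd: float = 1.0

    @classmethod
    def sample(
        cls,
        n_levels: int,
        n_sensors: int = N_SENSORS,
        noise_sd: float = 1.0,
        seed: int = 0,
    ) -> "TuningProjection":
        rng = np.random.default_rng(seed)
        return cls(F=rng.standard_normal((n_sensors, n_levels * 3)), noise_sd=noise_sd)

    @property
    def n_levels(self) -> int:
        return self.F.shape[1] // 3


@dataclass
class SensorEpochs:
    """Stimulus-locked sensor data: (stimuli, sensors, samples).

    ``times`` is the common time axis in seconds relative to stimulus
    onset; ``design`` holds the matching per-stimulus rows.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.design):
            raise ValueError("epochs and design rows must align")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample count inconsistent with time axis")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def _onset_samples(onset_s: np.ndarray, fs: float) -> np.ndarray:
    # Half-sample onsets (SOA = 62.5 samples at 250 Hz) round half-up, so
    # successive intervals alternate 63/62 samples and the long-run rate
    # stays exact.
    return np.floor(np.asarray(onset_s) * fs + 0.5).astype(int)


def render_subject(
    design: pd.DataFrame,
    net: NetworkSpec,
    tuning: TuningProjection,
    seed: int = 0,
    fs: float = FS,
    stim_duration_samples: int = STIM_DURATION_SAMPLES,
    profile_samples: int = 340,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one subject's continuous sensor recording.

    ``design`` must hold a single subject's rows.  Each stimulus drives
    the network with a step of ``stim_duration_samples``; the per-level
    observable profiles, scaled by the stimulus features (mean-centred
    delta — zero at position 1 — sin alpha, cos alpha), superpose
    additively into the continuous recording, are projected through the
    tuning matrix and topped with Gaussian sensor noise.

    Returns ``(series, events)``: the (n_sensors, n_samples) recording and
    the per-stimulus onset sample indices aligned with ``design`` rows.
    """
    if design["subject"].nunique() > 1:
        raise ValueError("render_subject expects a single subject's design")
    trace = simulate(
        net, StepInput(n_samples=profile_samples, on_start=0, on_end=stim_duration_samples)
    )
    if not trace.stable:
        raise ValueError("network is unstable; refusing to render")
    profile = trace.x  # (n_levels, profile_samples)
    L = net.n_levels
    if tuning.n_levels != L:
        raise ValueError("tuning projection does not match network depth")

    delta = design["delta_rad"].to_numpy()
    defined = ~np.isnan(delta)
    dmean = delta[defined].mean() if defined.any() else 0.0
    dcent = np.where(defined, delta - dmean, 0.0)
    alpha = design["alpha_rad"].to_numpy()
    feats = np.column_stack([dcent, np.sin(alpha), np.cos(alpha)])  # (q, 3)

    events = _onset_samples(design["onset_s"].to_numpy(), fs)
    n_total = int(events.max()) + max(profile_samples, int(1.25 * fs)) + 1
    series = np.zeros((tuning.F.shape[0], n_total))
    # Per-feature sensor profiles: G[f] = F[:, :, f] @ profile, (3, m, P).
    F3 = tuning.F.reshape(tuning.F.shape[0], L, 3)
    G = np.stack([F3[:, :, f] @ profile for f in range(3)])
    for onset, feat in zip(events, feats):
        series[:, onset : onset + profile.shape[1]] += np.tensordot(
            feat, G, axes=(0, 0)
        )
    if tuning.noise_sd > 0:
        rng = np.random.default_rng(seed)
        series += rng.normal(0.0, tuning.noise_sd, size=series.shape)
    return series, events


def epoch(
    series: np.ndarray,
    events: np.ndarray,
    design: pd.DataFrame,
    window: tuple[float, float] = (-0.25, 1.0),
    fs: float = FS,
) -> SensorEpochs:
    """Cut stimulus-locked epochs out of a continuous recording.

    The window is inclusive of both endpoints: (-0.25, 1.0) at 250 Hz
    yields 313 samples.  No baseline correction is applied.  An event
    whose window leaves the recording raises an error naming it.
    """
    events = np.asarray(events, dtype=int)
    lo = int(np.floor(window[0] * fs + 0.5))
    hi = int(np.floor(window[1] * fs + 0.5))
    n = hi - lo + 1
    times = (np.arange(n) + lo) / fs
    if events.size == 0:
        return SensorEpochs(
            data=np.empty((0, series.shape[0], n)),
            times=times,
            sfreq=fs,
            design=design.iloc[:0],
        )
    bad = np.nonzero((events + lo < 0) | (events + hi >= series.shape[1]))[0]
    if bad.size:
        raise ValueError(
            f"epoch window out of recording bounds for event {bad[0]} "
            f"(onset sample {events[bad[0]]})"
        )
    idx = events[:, None] + np.arange(lo, hi + 1)[None, :]
    data = series[:, idx].transpose(1, 0, 2)
    return SensorEpochs(data=data, times=times, sfreq=fs, design=design.reset_index(drop=True))


def simulate_subject(
    design: pd.DataFrame,
    subject: int,
    net: NetworkSpec | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    window: tuple[float, float] = (-0.25, 1.0),
) -> SensorEpochs:
    """Design -> continuous render -> stimulus-locked epochs for one subject.

    The tuning projection and the noise stream are drawn from streams
    keyed by ``(seed, subject)`` so subjects are independent but
    reproducible.
    """
    if net is None:
        net = default_network()
    sub = design[design["subject"] == subject]
    if sub.empty:
        raise ValueError(f"subject {subject} not present in design")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(subject,))
    s_tune, s_noise = ss.generate_state(2)
    tuning = TuningProjection.sample(net.n_levels, noise_sd=noise_sd, seed=s_tune)
    series, events = render_subject(sub, net, tuning, seed=s_noise)
    return epoch(series, events, sub, window=window)


def sequence_epochs(
    series: np.ndarray,
    events: np.ndarray,
    design: pd.DataFrame,
    window: tuple[float, float] = (-0.25, 2.75),
    fs: float = FS,
) -> SensorEpochs:
    """Cut sequence-locked epochs (one per trial, locked to the first item).

    The returned design holds the position-1 rows; all eight items of each
    trial fall inside the default window.
    """
    first = design["position"].to_numpy() == 1
    return epoch(series, np.asarray(events)[first], design[first], window=window, fs=fs)
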