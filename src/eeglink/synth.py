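"""Synthetic multichannel EEG with subject- and task-specific structure.

Each synthetic subject owns a spectral signature: per-channel stationary AR(p)
backbones (broadband colour), a subject-specific alpha-band oscillation
(peak frequency stratified over 8-13 Hz so subjects stay identifiable) with a
per-channel amplitude pattern, and additive white sensor noise.  A task
modulates the oscillation amplitude multiplicatively on a subset of channels,
which is the kind of band-power modulation motor-imagery protocols produce.

Seeds fan out hierarchically (dataset seed -> subject -> task), so generating
more subjects or tasks never perturbs recordings already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from .eeg_io import DatasetManifest, EEGRecording, write_manifest, write_matrix

__all__ = [
    "SubjectProfile",
    "TaskEffect",
    "make_profiles",
    "simulate_recording",
    "generate_dataset",
    "stable_ar_coefficients",
]

ALPHA_BAND = (8.0, 13.0)


def stable_ar_coefficients(rng: np.random.Generator, p: int, kappa: float = 0.7) -> np.ndarray:
    """Draw AR(p) coefficients guaranteed stationary.

    Reflection (partial autocorrelation) coefficients are drawn uniformly in
    (-kappa, kappa) and converted to AR coefficients by the inverse
    Levinson-Durbin recursion; |reflection| < 1 for every order is equivalent
    to all roots of the AR polynomial lying inside the unit circle.
    """
    if p == 0:
        return np.zeros(0)
    refl = rng.uniform(-kappa, kappa, size=p)
    a = np.array([refl[0]])
    for m in range(1, p):
        k = refl[m]
        a = np.concatenate([a - k * a[::-1], [k]])
    return a


@dataclass
class SubjectProfile:
    """Generative fingerprint of one synthetic subject."""

    subject_id: int
    ar_coeffs: np.ndarray          # (K, p) per-channel AR backbone
    peak_freq: float               # Hz, alpha-band oscillation frequency
    osc_amplitude: np.ndarray      # (K,) per-channel oscillation amplitude
    ar_scale: np.ndarray           # (K,) innovation std of the AR backbone
    noise_std: float               # additive white sensor noise

    def __post_init__(self) -> None:
        self.ar_coeffs = np.atleast_2d(np.asarray(self.ar_coeffs, dtype=float))
        for k, a in enumerate(self.ar_coeffs):
            if a.size and np.any(np.abs(np.roots(np.concatenate([[1.0], -a]))) >= 1.0):
                raise ValueError(f"channel {k + 1}: AR polynomial not stationary")

    @property
    def n_channels(self) -> int:
        return self.ar_coeffs.shape[0]

    @property
    def order(self) -> int:
        return self.ar_coeffs.shape[1]


@dataclass
class TaskEffect:
    """Multiplicative modulation a task applies to the subject oscillation."""

    class_id: int
    gain: float = 1.0
    channels: np.ndarray | None = None   # indices affected; None = all

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if self.channels is not None:
            self.channels = np.asarray(self.channels, dtype=int)
            if self.channels.size == 0:
                raise ValueError("affected channel subset must be non-empty")


def _subject_rng(seed: int, subject_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subject_idx]))


def make_profiles(
    n_subjects: int,
    K: int = 8,
    p: int = 6,
    seed: int = 0,
    noise_std: float = 0.3,
) -> list[SubjectProfile]:
    """Create ``n_subjects`` pairwise-distinct subject profiles.

    Peak frequencies sit at evenly spaced centres across the alpha band
    (8-13 Hz), so any 10 subjects are >= 0.5 Hz apart; the dataset rng only
    permutes which subject gets which centre.
    """
    if n_subjects < 1 or K < 1 or p < 1:
        raise ValueError("need n_subjects >= 1, K >= 1, p >= 1")
    lo, hi = ALPHA_BAND
    centres = lo + (np.arange(n_subjects) + 0.5) * (hi - lo) / n_subjects
    perm = np.random.default_rng(np.random.SeedSequence([seed])).permutation(n_subjects)
    profiles = []
    for i in range(n_subjects):
        rng = _subject_rng(seed, i)
        ar = np.stack([stable_ar_coefficients(rng, p) for _ in range(K)])
        # modest spatial jitter: the task's band gain must stay decodable
        # from a single channel, as it is in real motor-imagery recordings
        amp = rng.uniform(0.8, 1.2, size=K)
        scale = rng.uniform(0.3, 0.7, size=K)
        profiles.append(
            SubjectProfile(
                subject_id=i + 1,
                ar_coeffs=ar,
                peak_freq=float(centres[perm[i]]),
                osc_amplitude=amp,
                ar_scale=scale,
                noise_std=noise_std,
            )
        )
    return profiles


def simulate_recording(
    profile: SubjectProfile,
    effect: TaskEffect,
    L: int,
    fs: float,
    seed: int = 0,
) -> EEGRecording:
    """Simulate one K x L recording of ``profile`` performing a task.

    Each channel is an AR(p) process driven by Gaussian innovations (with a
    burn-in of 10p samples discarded), plus the subject's alpha oscillation
    scaled by the task gain on affected channels, plus white noise.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, profile.subject_id, effect.class_id, int(effect.gain * 1000)])
    )
    K, p = profile.n_channels, profile.order
    burn = 10 * p
    t = np.arange(L) / fs
    affected = (
        np.arange(K) if effect.channels is None else effect.channels
    )
    data = np.empty((K, L))
    for k in range(K):
        innov = rng.normal(0.0, profile.ar_scale[k], size=L + burn)
        ar_poly = np.concatenate([[1.0], -profile.ar_coeffs[k]])
        x = _signal.lfilter([1.0], ar_poly, innov)[burn:]
        # alpha rhythm as a narrowband process: the instantaneous phase
        # diffuses (Wiener phase noise, ~0.3 Hz linewidth) and the envelope
        # waxes and wanes slowly, as scalp alpha does; a constant-phase
        # sinusoid would make the cross-channel phase pattern a recording
        # fingerprint instead of a subject trait.
        phase0 = rng.uniform(0, 2 * np.pi)
        drift = np.cumsum(rng.normal(0.0, 2 * np.pi * 0.3 / np.sqrt(fs), size=L))
        phase = 2 * np.pi * profile.peak_freq * t + phase0 + drift
        env_lp = _signal.butter(2, 0.5, btype="low", fs=fs, output="sos")
        env = 1.0 + 0.5 * _signal.sosfilt(env_lp, rng.normal(0, 1, size=L)) * np.sqrt(fs)
        env = np.clip(env, 0.2, None)
        amp = profile.osc_amplitude[k]
        if k in affected:
            amp = amp * effect.gain
        x = x + amp * env * np.sin(phase)
        x = x + rng.normal(0.0, profile.noise_std, size=L)
        data[k] = x
    return EEGRecording(
        data=data,
        fs=fs,
        subject_id=profile.subject_id,
        task_id=effect.class_id,
        channel_names=[f"sim{k + 1}" for k in range(K)],
    )


def task_effects(n_tasks: int, n_classes: int, gain_ratio: float = 3.0) -> list[TaskEffect]:
    """Round-robin class assignment over tasks with geometric band gains.

    Adjacent classes differ by a factor ``gain_ratio`` in oscillation
    amplitude; the gains are centred at 1 (class q gets
    ratio^(q - (Q+1)/2)), so modulation stays in a physiological range
    instead of growing unboundedly with the class count.
    """
    if n_tasks % n_classes != 0:
        raise ValueError(
            f"n_tasks={n_tasks} not divisible by n_classes={n_classes} (balanced design)"
        )
    effects = []
    for task in range(1, n_tasks + 1):
        cls = (task - 1) % n_classes + 1
        gain = gain_ratio ** (cls - (n_classes + 1) / 2)
        effects.append(TaskEffect(class_id=cls, gain=gain))
    return effects


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset: recordings plus labels."""

    recordings: list[EEGRecording]
    manifest: DatasetManifest
    fs: float
    task_to_class: dict[int, int] = field(default_factory=dict)


def generate_dataset(
    n_subjects: int = 10,
    n_tasks: int = 4,
    classes: int | None = None,
    K: int = 8,
    p: int = 6,
    L: int = 1600,
    fs: float = 160.0,
    seed: int = 0,
    gain_ratio: float = 3.0,
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a balanced synthetic dataset of N subjects x M tasks.

    Tasks are assigned to ``classes`` round-robin (default: every task its own
    class).  When ``outdir`` is given, recordings are written as CSV matrices
    plus a TSV manifest in the dialect :mod:`eeglink.eeg_io` reads.
    """
    n_classes = classes if classes is not None else n_tasks
    effects = task_effects(n_tasks, n_classes, gain_ratio)
    profiles = make_profiles(n_subjects, K=K, p=p, seed=seed)
    recordings = []
    entries = []
    t2c = {}
    for prof in profiles:
        for task in range(1, n_tasks + 1):
            eff = effects[task - 1]
            rec_seed = int(
                np.random.SeedSequence([seed, prof.subject_id, task]).generate_state(1)[0]
                % (2**31)
            )
            rec = simulate_recording(prof, eff, L=L, fs=fs, seed=rec_seed)
            rec.task_id = task
            recordings.append(rec)
            entries.append((f"s{prof.subject_id:03d}_t{task:02d}.csv", prof.subject_id, task))
            t2c[task] = eff.class_id
    manifest = DatasetManifest(entries=entries, root=Path(outdir) if outdir else None)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec, (rel, _, _) in zip(recordings, entries):
            write_matrix(rec, outdir / rel)
        write_manifest(manifest, outdir / "manifest.tsv", fs=fs)
    return SyntheticDataset(recordings=recordings, manifest=manifest, fs=fs, task_to_class=t2c)
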