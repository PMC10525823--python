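"""Reading and writing EEG recordings, dataset manifests and label schemes.

An :class:`EEGRecording` is a channels x samples matrix plus sampling rate and
subject/task labels.  Recordings come either from EDF/EDF+ files (the format of
the PhysioNet 64-channel motor movement/imagery corpus: 109 subjects, 14 task
runs each, 160 Hz) or from plain comma-delimited text with one channel per row.
A dataset is described by a TSV manifest (path, subject, task), which lets
synthetic and real data flow through a single loader.

The module also encodes the task -> activity and task -> class label schemes of
the 14-run motor-imagery protocol: six activities (rest open/closed eyes, real
and imagined single-fist movement, real and imagined both-fists/feet movement),
coarsened into 5-class and 3-class task-classification schemes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "DatasetManifest",
    "ClassScheme",
    "FormatError",
    "read_edf",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "write_manifest",
    "map_task_to_activity",
    "map_task_to_class",
    "parse_task_id",
    "ACTIVITY_OF_TASK",
    "CLASS5_OF_TASK",
    "CLASS3_OF_TASK",
]


class FormatError(ValueError):
    """A file violated its declared format (EDF header, CSV matrix, manifest)."""


@dataclass
class EEGRecording:
    """A single multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (K, L)
        Signal matrix, one row per channel.  Units are whatever the source
        used (microvolts for real EDF data); none of the downstream math
        depends on the physical scale.
    fs : float
        Sampling rate in Hz.
    subject_id : int
        1-based subject label.
    task_id : int
        1-based task label.
    channel_names : list of str
        One name per channel.
    """

    data: np.ndarray
    fs: float
    subject_id: int = 0
    task_id: int = 0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        k, l = self.data.shape
        if k < 1 or l < 1:
            raise ValueError(f"need at least one channel and one sample, got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(k)]
        if len(self.channel_names) != k:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {k} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class DatasetManifest:
    """Index of a dataset: one (path, subject, task) row per recording."""

    entries: list[tuple[str, int, int]]
    root: Path | None = None

    def __post_init__(self) -> None:
        pairs = [(s, t) for _, s, t in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (subject, task) pair in manifest")
        subjects = sorted({s for s, _ in pairs})
        if subjects and subjects != list(range(1, len(subjects) + 1)):
            raise ValueError(f"subject ids must be contiguous from 1, got {subjects}")

    @property
    def n_subjects(self) -> int:
        return len({s for _, s, _ in self.entries})

    @property
    def n_tasks_per_subject(self) -> int:
        return len({t for _, _, t in self.entries})

    @property
    def subjects(self) -> list[int]:
        return sorted({s for _, s, _ in self.entries})

    @property
    def tasks(self) -> list[int]:
        return sorted({t for _, _, t in self.entries})

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p


# Task -> activity map of the 14-run motor-imagery protocol.  Activities:
# a1 rest/eyes-open, a2 rest/eyes-closed, a3 open-close one fist,
# a4 imagine a3, a5 open-close both fists or feet, a6 imagine a5.
ACTIVITY_OF_TASK: dict[int, int] = {
    1: 1,
    2: 2,
    3: 3, 7: 3, 11: 3,
    4: 4, 8: 4, 12: 4,
    5: 5, 9: 5, 13: 5,
    6: 6, 10: 6, 14: 6,
}

# 5-class scheme: the two resting activities merge; each movement activity is
# its own class.
CLASS5_OF_TASK: dict[int, int] = {
    1: 1, 2: 1,
    3: 2, 7: 2, 11: 2,
    4: 3, 8: 3, 12: 3,
    5: 4, 9: 4, 13: 4,
    6: 5, 10: 5, 14: 5,
}

# 3-class scheme: rest / single-fist (real+imagined) / both-fists-feet
# (real+imagined).
CLASS3_OF_TASK: dict[int, int] = {
    1: 1, 2: 1,
    3: 2, 7: 2, 11: 2, 4: 2, 8: 2, 12: 2,
    5: 3, 9: 3, 13: 3, 6: 3, 10: 3, 14: 3,
}

_SCHEME_TABLES = {
    "activity6": ACTIVITY_OF_TASK,
    "class5": CLASS5_OF_TASK,
    "class3": CLASS3_OF_TASK,
}


@dataclass(frozen=True)
class ClassScheme:
    """A task -> class mapping.

    ``activity6``, ``class5`` and ``class3`` are the built-in schemes of the
    14-run protocol; ``identity(M)`` treats each task as its own class, which
    is what synthetic datasets with explicit per-task classes use.
    """

    name: str
    mapping: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mapping:
            if self.name not in _SCHEME_TABLES:
                raise ValueError(
                    f"unknown scheme {self.name!r}; built-ins: {sorted(_SCHEME_TABLES)}"
                )
            object.__setattr__(self, "mapping", dict(_SCHEME_TABLES[self.name]))
        labels = sorted(set(self.mapping.values()))
        if labels != list(range(1, len(labels) + 1)):
            raise ValueError(f"class labels must be contiguous from 1, got {labels}")

    @classmethod
    def identity(cls, n_tasks: int) -> "ClassScheme":
        return cls("identity", {t: t for t in range(1, n_tasks + 1)})

    @classmethod
    def from_classes(cls, task_to_class: dict[int, int], name: str = "custom") -> "ClassScheme":
        return cls(name, dict(task_to_class))

    @property
    def n_classes(self) -> int:
        return len(set(self.mapping.values()))

    def __call__(self, task_id: int) -> int:
        try:
            return self.mapping[task_id]
        except KeyError:
            raise KeyError(
                f"task t{task_id} not covered by scheme {self.name!r}"
            ) from None


_TASK_RE = re.compile(r"^t?(\d+)$")


def parse_task_id(token: int | str) -> int:
    """Accept ``5`` or ``"t5"`` / ``"5"`` and return the integer task id."""
    if isinstance(token, (int, np.integer)):
        tid = int(token)
    else:
        m = _TASK_RE.match(str(token).strip())
        if not m:
            raise ValueError(f"cannot parse task id {token!r}")
        tid = int(m.group(1))
    if tid < 1:
        raise ValueError(f"task id must be >= 1, got {tid}")
    return tid


def map_task_to_activity(task_id: int | str) -> int:
    """Map a task run (t1..t14) to its activity (a1..a6)."""
    tid = parse_task_id(task_id)
    try:
        return ACTIVITY_OF_TASK[tid]
    except KeyError:
        raise KeyError(f"task t{tid} outside t1..t14") from None


def map_task_to_class(task_id: int | str, scheme: ClassScheme | str) -> int:
    """Map a task run to its class under ``class5`` or ``class3`` (or any scheme)."""
    if isinstance(scheme, str):
        scheme = ClassScheme(scheme)
    return scheme(parse_task_id(task_id))


def read_edf(path: str | Path, subject_id: int = 0, task_id: int = 0) -> EEGRecording:
    """Read all channels of an EDF/EDF+ file at native sampling rate.

    Sample values are converted to physical units by the EDF header scaling;
    annotation channels are dropped.  A malformed header raises
    :class:`FormatError` naming the problem.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types for bad headers
        raise FormatError(f"{path.name}: not a readable EDF file ({exc})") from exc
    picks = [i for i, ch in enumerate(raw.ch_names) if "annot" not in ch.lower()]
    if not picks:
        raise FormatError(f"{path.name}: no signal channels")
    # mne rescales to SI volts internally; EEG headers store microvolts
    data = raw.get_data(picks=picks, units="uV")
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path.name}: non-finite samples after scaling")
    names = [raw.ch_names[i] for i in picks]
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        subject_id=subject_id,
        task_id=task_id,
        channel_names=names,
    )


def read_matrix(
    path: str | Path,
    fs: float,
    subject_id: int = 0,
    task_id: int = 0,
) -> EEGRecording:
    """Read a comma-delimited channels x samples matrix (one channel per row)."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            vals = []
            for colno, tok in enumerate(line.split(","), start=1):
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise FormatError(
                        f"{path.name}: non-numeric token {tok!r} at row {lineno}, column {colno}"
                    ) from None
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path.name}: empty matrix file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path.name}: ragged rows (widths {sorted(widths)})")
    return EEGRecording(
        data=np.array(rows, dtype=float),
        fs=fs,
        subject_id=subject_id,
        task_id=task_id,
    )


def write_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as the CSV dialect :func:`read_matrix` consumes."""
    np.savetxt(path, rec.data, delimiter=",", fmt="%.10g")


_MANIFEST_COLUMNS = ("path", "subject", "task")


def write_manifest(manifest: DatasetManifest, path: str | Path, fs: float) -> None:
    """Write a TSV manifest with a ``# fs=<Hz>`` header comment."""
    with open(path, "w") as fh:
        fh.write(f"# fs={fs:g}\n")
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for rel, subj, task in manifest.entries:
            fh.write(f"{rel}\t{subj}\t{task}\n")


def read_manifest(path: str | Path) -> tuple[DatasetManifest, float]:
    """Read a TSV manifest; returns (manifest, sampling rate)."""
    path = Path(path)
    fs = 0.0
    entries: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"fs\s*=\s*([\d.eE+-]+)", line)
                if m:
                    fs = float(m.group(1))
                continue
            parts = line.split("\t")
            if parts == list(_MANIFEST_COLUMNS):
                continue
            if len(parts) != 3:
                raise FormatError(f"{path.name}: manifest row needs 3 columns, got {parts!r}")
            entries.append((parts[0], parse_task_id(parts[1]), parse_task_id(parts[2])))
    if not entries:
        raise FormatError(f"{path.name}: empty manifest")
    if fs <= 0:
        raise FormatError(f"{path.name}: manifest missing '# fs=' header")
    return DatasetManifest(entries=entries, root=path.parent), fs


def load_recording(manifest: DatasetManifest, entry: tuple[str, int, int], fs: float) -> EEGRecording:
    """Load one manifest entry, dispatching on file extension (.edf or CSV)."""
    rel, subj, task = entry
    p = manifest.resolve(rel)
    if p.suffix.lower() == ".edf":
        return read_edf(p, subject_id=subj, task_id=task)
    return read_matrix(p, fs=fs, subject_id=subj, task_id=task)
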