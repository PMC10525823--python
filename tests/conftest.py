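"""Shared fixtures: tiny synthetic datasets and an independent EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from eeglink import synth


def write_minimal_edf(
    path: Path,
    data: np.ndarray,
    fs: float,
    phys_range: tuple[float, float] = (-200.0, 200.0),
    n_signals_header: int | None = None,
) -> np.ndarray:
    """Write a minimal EDF file by direct struct packing (independent of any
    EDF library).  Returns the quantized data actually stored, so round-trip
    tests can compare against what the 16-bit digitization preserves.

    ``n_signals_header`` can override the signal count to forge a degenerate
    header.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ns, total = data.shape
    rec_dur = 1.0
    spr = int(round(fs * rec_dur))  # samples per record per signal
    n_rec = total // spr
    assert n_rec * spr == total, "length must be a whole number of 1 s records"
    pmin, pmax = phys_range
    dmin, dmax = -32768, 32767
    ns_hdr = ns if n_signals_header is None else n_signals_header

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate 01-JAN-2000 X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (ns_hdr + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad(f"{rec_dur:g}", 8),
        pad(str(ns_hdr), 4),
    ])
    fields = []
    fields.append(b"".join(pad(f"EEG C{i:02d}", 16) for i in range(ns_hdr)))
    fields.append(b"".join(pad("AgAgCl electrode", 80) for _ in range(ns_hdr)))
    fields.append(b"".join(pad("uV", 8) for _ in range(ns_hdr)))
    fields.append(b"".join(pad(f"{pmin:g}", 8) for _ in range(ns_hdr)))
    fields.append(b"".join(pad(f"{pmax:g}", 8) for _ in range(ns_hdr)))
    fields.append(b"".join(pad(str(dmin), 8) for _ in range(ns_hdr)))
    fields.append(b"".join(pad(str(dmax), 8) for _ in range(ns_hdr)))
    fields.append(b"".join(pad("", 80) for _ in range(ns_hdr)))
    fields.append(b"".join(pad(str(spr), 8) for _ in range(ns_hdr)))
    fields.append(b"".join(pad("", 32) for _ in range(ns_hdr)))
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data - pmin) * gain + dmin), dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(b"".join(fields))
        for r in range(n_rec):
            for s in range(ns):
                fh.write(digital[s, r * spr:(r + 1) * spr].tobytes())
    quantized = (digital.astype(float) - dmin) / gain + pmin
    return quantized


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 4 tasks, 6 channels, 4 s at 160 Hz; fast to make."""
    return synth.generate_dataset(
        n_subjects=3, n_tasks=4, classes=2, K=6, L=640, fs=160.0, seed=7,
        gain_ratio=2.0,
    )


@pytest.fixture(scope="session")
def id_dataset():
    """10-subject subject-identification dataset used by feature-level tests."""
    return synth.generate_dataset(
        n_subjects=10, n_tasks=4, classes=4, K=8, L=1600, fs=160.0, seed=11,
        gain_ratio=2.0,
    )
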