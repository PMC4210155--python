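"""Reading and writing multichannel gait recordings.

Recordings are plain-ASCII numeric matrices, one row per sample, matching
the convention of treadmill acquisition software that saves "MATLAB
compatible" text files.  The canonical dialect written here is
comma-delimited with a single ``#``-prefixed header line naming the
channels; whitespace-delimited files (with or without the header) are also
accepted on read.  Time is implicit: row index divided by the sampling
rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "DEFAULT_CHANNELS", "read_recording", "write_recording"]

log = logging.getLogger("reflexgait")

#: Default 16-channel schema: 8 surface-EMG channels (left/right x tibialis
#: anterior, lateral gastrocnemius, rectus femoris, biceps femoris) followed
#: by 8 force-sensing-resistor channels (left/right x heel, first and fifth
#: metatarsal, big toe).  The acquisition column order is not standardised,
#: so readers accept a user-supplied schema; this is the documented default
#: used by the synthetic generator.
DEFAULT_CHANNELS = tuple(
    [f"EMG_{side}_{mus}" for side in "LR" for mus in ("TA", "LG", "RF", "BF")]
    + [f"FSR_{side}_{site}" for side in "LR" for site in ("heel", "mt1", "mt5", "toe")]
)


@dataclass
class Recording:
    """Uniformly sampled multichannel time series (time x channel)."""

    samples: np.ndarray
    rate_hz: float
    channels: tuple[str, ...]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channels = tuple(self.channels)
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D time x channel array")
        if self.samples.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[1]} columns but {len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def t(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[:, self.channels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channels}") from None


def read_recording(
    path: str | Path,
    rate_hz: float,
    channels: tuple[str, ...] | None = None,
) -> Recording:
    """Read a delimited-ASCII recording.

    A ``#``-prefixed header line, when present, supplies the channel labels;
    otherwise ``channels`` must be given and its length must match the
    column count.  Ragged rows, non-numeric cells or missing values raise.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    header = None
    data_lines = []
    for ln in lines:
        if not ln:
            continue
        if ln.startswith("#"):
            if header is None:
                header = [c.strip() for c in ln.lstrip("#").replace(",", " ").split()]
            continue
        data_lines.append(ln)
    if header is not None:
        if channels is not None and tuple(channels) != tuple(header):
            raise ValueError("supplied channel schema disagrees with file header")
        channels = tuple(header)
    if channels is None:
        raise ValueError("file has no header; a channel schema must be supplied")
    if not data_lines and header is None:
        raise ValueError(f"{path} is empty")

    ncol = len(channels)
    rows = np.empty((len(data_lines), ncol), dtype=float)
    for i, ln in enumerate(data_lines):
        cells = ln.replace(",", " ").split()
        if len(cells) != ncol:
            raise ValueError(
                f"{path}:{i + 1}: expected {ncol} columns, found {len(cells)}"
            )
        try:
            rows[i] = [float(c) for c in cells]
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: non-numeric cell ({exc})") from None
    if not np.isfinite(rows).all():
        raise ValueError(f"{path}: recording contains non-finite values")
    log.debug("read %d samples x %d channels from %s", len(rows), ncol, path)
    return Recording(samples=rows, rate_hz=rate_hz, channels=channels)


def write_recording(rec: Recording, path: str | Path, precision: int = 9) -> Path:
    """Write a recording as comma-delimited ASCII with a ``#`` header.

    Deterministic formatting (``%.{precision}g``) so identical recordings
    produce byte-identical files; round trips are lossless to ~1e-9
    relative at the default precision.
    """
    path = Path(path)
    fmt = f"%.{precision}g"
    with path.open("w") as fh:
        fh.write("# " + ",".join(rec.channels) + "\n")
        np.savetxt(fh, rec.samples, fmt=fmt, delimiter=",")
    return path
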