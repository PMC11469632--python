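"""WAV and annotation file I/O for phonocardiogram segmentation.

Time is in seconds everywhere outside raw sample buffers; intervals are
half-open ``[onset, offset)``; sample indices are 0-based.

Annotation files follow the CirCor DigiScope convention: three tab-separated
columns ``onset<TAB>offset<TAB>state`` with no header, where the state code is
0 (noise / unlabeled), 1 (S1), 2 (systole), 3 (S2) or 4 (diastole).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path


import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger("pcgseg")

#: Annotation state codes (CirCor dialect).
STATE_NOISE = 0
STATE_S1 = 1
STATE_SYSTOLE = 2
STATE_S2 = 3
STATE_DIASTOLE = 4
VALID_STATES = frozenset({STATE_NOISE, STATE_S1, STATE_SYSTOLE, STATE_S2, STATE_DIASTOLE})


@dataclass(frozen=True)
class PCGRecording:
    """A single-channel heart sound recording at any pipeline stage.

    Parameters
    ----------
    samples:
        Real-valued amplitude sequence (dimensionless).
    rate:
        Sampling frequency in Hz; must be positive.
    source_id:
        Free-text identifier carried through the pipeline.
    """

    samples: np.ndarray
    rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def with_samples(self, samples: np.ndarray) -> "PCGRecording":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class StateAnnotation:
    """Ground-truth (or predicted) segmentation as (onset, offset, state) rows.

    Rows are sorted by onset, non-overlapping, with ``onset < offset``.
    """

    onsets: np.ndarray
    offsets: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=np.float64)
        offsets = np.asarray(self.offsets, dtype=np.float64)
        states = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "states", states)
        if not (onsets.shape == offsets.shape == states.shape):
            raise ValueError("onsets, offsets and states must have equal length")
        if onsets.size:
            if np.any(offsets <= onsets):
                raise ValueError("every row must satisfy onset < offset")
            if np.any(np.diff(onsets) < 0):
                raise ValueError("rows must be sorted by onset")
            if np.any(onsets[1:] < offsets[:-1] - 1e-9):
                raise ValueError("rows must be non-overlapping")
            unknown = set(np.unique(states)) - VALID_STATES
            if unknown:
                raise ValueError(f"unknown state codes: {sorted(unknown)}")

    def __len__(self) -> int:
        return int(self.onsets.size)

    def rows(self) -> list[tuple[float, float, int]]:
        return list(zip(self.onsets.tolist(), self.offsets.tolist(), self.states.tolist()))

    def intervals_for(self, state: int) -> np.ndarray:
        """(n, 2) array of [onset, offset) intervals carrying ``state``."""
        mask = self.states == state
        return np.column_stack([self.onsets[mask], self.offsets[mask]])

    @property
    def span(self) -> tuple[float, float]:
        """[first onset, last offset] of the annotated region."""
        if not len(self):
            raise ValueError("empty annotation has no span")
        return float(self.onsets[0]), float(self.offsets[-1])


def empty_annotation() -> StateAnnotation:
    z = np.empty(0)
    return StateAnnotation(z, z, z.astype(np.int64))


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 2.0**15, np.dtype(np.int32): 2.0**31, np.dtype(np.uint8): 2.0**7}


def read_wav(path: str | Path) -> PCGRecording:
    """Read a WAV file as a :class:`PCGRecording`.

    Multi-channel files keep only the first channel (a warning is logged).
    Integer PCM is rescaled to [-1, 1]; float data is kept in native scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        logger.warning("%s has %d channels; using first channel only", path.name, data.shape[1])
        data = data[:, 0]
    if data.size == 0:
        raise ValueError(f"{path} contains no audio samples")
    dtype = data.dtype
    data = data.astype(np.float64)
    if dtype in _PCM_SCALE:
        if dtype == np.dtype(np.uint8):
            data = data - 128.0
        data = data / _PCM_SCALE[dtype]
    return PCGRecording(samples=data, rate=float(rate), source_id=path.stem)


def write_wav(rec: PCGRecording, path: str | Path) -> None:
    """Write a recording as float-32 WAV."""
    wavfile.write(Path(path), int(round(rec.rate)), rec.samples.astype(np.float32))


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> StateAnnotation:
    """Read a tab-separated (onset, offset, state) annotation file.

    Extra columns beyond the first three are ignored with a warning, so CirCor
    files with trailing fields load directly. Unknown state codes are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return empty_annotation()
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 tab-separated columns, found {df.shape[1]}")
    if df.shape[1] > 3:
        logger.warning("%s: ignoring %d extra columns", path.name, df.shape[1] - 3)
        df = df.iloc[:, :3]
    onsets = df.iloc[:, 0].to_numpy(dtype=np.float64)
    offsets = df.iloc[:, 1].to_numpy(dtype=np.float64)
    states = df.iloc[:, 2].to_numpy()
    if not np.all(states == states.astype(np.int64)):
        raise ValueError(f"{path}: non-integer state codes")
    return StateAnnotation(onsets, offsets, states.astype(np.int64))


def write_annotation(annotation, path: str | Path) -> None:
    """Write an annotation (or a ``Segmentation``) as tab-separated rows.

    Onset/offset are written with microsecond precision so a write-then-read
    round trip is an identity to 1e-6 s.
    """
    rows = _as_rows(annotation)
    with open(path, "w") as fh:
        for onset, offset, state in rows:
            fh.write(f"{onset:.6f}\t{offset:.6f}\t{int(state)}\n")


def _as_rows(annotation) -> list[tuple[float, float, int]]:
    if isinstance(annotation, StateAnnotation):
        return annotation.rows()
    # duck-typed Segmentation: has .to_annotation()
    to_ann = getattr(annotation, "to_annotation", None)
    if to_ann is not None:
        return to_ann().rows()
    raise TypeError(f"cannot write annotation of type {type(annotation)!r}")


# ---------------------------------------------------------------------------
# Parameter config files
# ---------------------------------------------------------------------------

def read_params_file(path: str | Path) -> dict[str, float]:
    """Parse a ``key = value`` parameter file into a dict of floats.

    Blank lines and ``#`` comments are ignored. Keys must match fields of
    ``SegmentationParams`` (validated by the caller when constructing params).
    """
    out: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = float(value)
    return out
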