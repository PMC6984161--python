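"""Raw-signal input, MAD standardization, and sliding-window segmentation.

A nanopore sequencer stores each read as a long vector of current samples
(the "squiggle").  Before inference the squiggle is standardized per read
with the median absolute deviation (a robust scale, insensitive to the
outlier spikes typical of pore current) and cut into fixed-length,
overlapping windows that are batched through the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "RawRead",
    "StandardizedSignal",
    "SegmentationConfig",
    "SignalSegment",
    "DegenerateSignalError",
    "Fast5FormatError",
    "mad_standardize",
    "segment_signal",
    "read_fast5",
    "write_fast5",
    "read_signal_txt",
    "write_signal_txt",
]

DEFAULT_SEGMENT_LENGTH = 512
# The experiments run with a sliding-window stride of 118 samples (a 512-long
# window therefore overlaps its successor by 394 samples).
DEFAULT_STRIDE = 118


class DegenerateSignalError(ValueError):
    """Raised when a signal's MAD is zero and cannot be used as a scale."""


class Fast5FormatError(ValueError):
    """Raised when an HDF5 file does not contain a recognizable raw-signal layout."""


@dataclass
class RawRead:
    """One sequencing read's raw current samples plus identity metadata."""

    read_id: str
    samples: np.ndarray
    sampling_rate: float = 4000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.read_id:
            raise ValueError("read_id must be non-empty")


@dataclass
class StandardizedSignal:
    """MAD-standardized signal: zero median, median absolute value equal to ``c``."""

    values: np.ndarray
    c: float


@dataclass
class SegmentationConfig:
    """Sliding-window parameters: window length T and stride d (d <= T)."""

    segment_length: int = DEFAULT_SEGMENT_LENGTH
    stride: int = DEFAULT_STRIDE

    def __post_init__(self) -> None:
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")
        if not 1 <= self.stride <= self.segment_length:
            raise ValueError("stride must satisfy 1 <= stride <= segment_length")


@dataclass
class SignalSegment:
    """A window of exactly ``segment_length`` samples cut from one signal.

    ``valid_length`` counts the non-padded samples; it is smaller than the
    window length only when the whole signal is shorter than one window.
    """

    values: np.ndarray
    offset: int
    valid_length: int


def mad_standardize(raw: Sequence[float] | np.ndarray, c: float = 1.0) -> StandardizedSignal:
    """Standardize a raw current trace by median and median absolute deviation.

    Computes ``c * (x - median(x)) / median(|x - median(x)|)``.  The result is
    invariant to affine rescaling of the input (gain and offset drift between
    pores), and idempotent up to the constant ``c``.

    Raises
    ------
    DegenerateSignalError
        If the MAD is zero (more than half the samples identical), which
        would otherwise silently divide by zero.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    x = np.asarray(raw, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("raw signal must be a non-empty 1-D sequence")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        raise DegenerateSignalError(
            "signal MAD is zero (over half of the samples are identical); "
            "cannot standardize"
        )
    return StandardizedSignal(values=c * (x - med) / mad, c=float(c))


def segment_signal(
    signal: StandardizedSignal | np.ndarray | Sequence[float],
    config: SegmentationConfig,
    tail: str = "anchor",
) -> list[SignalSegment]:
    """Cut a signal into overlapping windows of length T with the given stride.

    Windows start at offsets 0, d, 2d, ...  Two tail policies exist:

    * ``"anchor"`` (default, used for basecalling): if the final stride step
      would overrun the end of the signal, one extra full window anchored at
      ``L - T`` is emitted, so the tail is covered without padding and the
      extra overlap is resolved downstream by overlap assembly.
    * ``"pad"`` (used to build training examples): the final partial window
      is zero-padded with ``valid_length`` recording the real sample count,
      so a stride-T segmentation partitions the signal exactly and window
      labels never overlap.

    A signal shorter than one window yields a single zero-padded segment
    under either policy.
    """
    if tail not in ("anchor", "pad"):
        raise ValueError("tail must be 'anchor' or 'pad'")
    values = signal.values if isinstance(signal, StandardizedSignal) else np.asarray(signal, dtype=np.float64)
    T = config.segment_length
    L = len(values)
    if L <= T:
        padded = np.zeros(T, dtype=np.float64)
        padded[:L] = values
        return [SignalSegment(values=padded, offset=0, valid_length=L)]
    if tail == "anchor":
        offsets = list(range(0, L - T + 1, config.stride))
        if offsets[-1] != L - T:
            offsets.append(L - T)
        return [
            SignalSegment(values=values[o : o + T].copy(), offset=o, valid_length=T)
            for o in offsets
        ]
    segments = []
    for o in range(0, L, config.stride):
        if o >= L:
            break
        chunk = values[o : o + T]
        if len(chunk) == T:
            segments.append(SignalSegment(values=chunk.copy(), offset=o, valid_length=T))
        else:
            padded = np.zeros(T, dtype=np.float64)
            padded[: len(chunk)] = chunk
            segments.append(SignalSegment(values=padded, offset=o, valid_length=len(chunk)))
        if o + T >= L:
            break
    return segments


# --------------------------------------------------------------------------
# fast5 (HDF5) I/O.  Two layouts exist in the wild and both are supported:
#   single-read:  /Raw/Reads/Read_<n>/Signal        (one read per file)
#   multi-read:   /read_<id>/Raw/Signal             (many reads per file)
# Layout is auto-detected from the root groups.
# --------------------------------------------------------------------------

def read_fast5(path: str | Path) -> list[RawRead]:
    """Read all raw reads from a fast5 file (single- or multi-read layout)."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open {path} as HDF5: {exc}") from exc
    with f:
        root_keys = list(f.keys())
        multi = [k for k in root_keys if k.startswith("read_")]
        if multi:
            return [_read_from_group(f[k], default_id=k[len("read_") :]) for k in sorted(multi)]
        if "Raw" in f:
            raw = f["Raw"]
            if "Reads" not in raw:
                raise Fast5FormatError(f"{path}: group 'Raw' lacks a 'Reads' subgroup")
            reads = []
            for name in sorted(raw["Reads"].keys()):
                grp = raw["Reads"][name]
                if "Signal" not in grp:
                    raise Fast5FormatError(f"{path}: group 'Raw/Reads/{name}' lacks a 'Signal' dataset")
                reads.append(_read_from_signal_group(grp, default_id=name))
            if not reads:
                raise Fast5FormatError(f"{path}: 'Raw/Reads' contains no read groups")
            return reads
        raise Fast5FormatError(
            f"{path}: no 'read_*' groups and no 'Raw' group; not a recognized fast5 layout"
        )


def _read_from_group(grp: h5py.Group, default_id: str) -> RawRead:
    if "Raw" not in grp or "Signal" not in grp["Raw"]:
        raise Fast5FormatError(f"read group '{grp.name}' lacks a 'Raw/Signal' dataset")
    return _read_from_signal_group(grp["Raw"], default_id)


def _read_from_signal_group(grp: h5py.Group, default_id: str) -> RawRead:
    signal = np.asarray(grp["Signal"][()], dtype=np.float64)
    read_id = grp.attrs.get("read_id", default_id)
    if isinstance(read_id, bytes):
        read_id = read_id.decode()
    rate = float(grp.attrs.get("sampling_rate", 4000.0))
    return RawRead(read_id=str(read_id), samples=signal, sampling_rate=rate)


def write_fast5(path: str | Path, reads: Sequence[RawRead], layout: str = "multi") -> None:
    """Write reads to a fast5 file in the single- or multi-read layout."""
    if layout not in ("single", "multi"):
        raise ValueError("layout must be 'single' or 'multi'")
    if layout == "single" and len(reads) != 1:
        raise ValueError("single-read layout holds exactly one read per file")
    with h5py.File(path, "w") as f:
        if layout == "multi":
            for read in reads:
                grp = f.create_group(f"read_{read.read_id}/Raw")
                grp.create_dataset("Signal", data=read.samples)
                grp.attrs["read_id"] = read.read_id
                grp.attrs["sampling_rate"] = read.sampling_rate
        else:
            read = reads[0]
            grp = f.create_group("Raw/Reads/Read_0")
            grp.create_dataset("Signal", data=read.samples)
            grp.attrs["read_id"] = read.read_id
            grp.attrs["sampling_rate"] = read.sampling_rate


def read_signal_txt(path: str | Path, read_id: str | None = None) -> RawRead:
    """Read a plain-text one-sample-per-line signal (fixture format)."""
    path = Path(path)
    samples = np.loadtxt(path, dtype=np.float64, ndmin=1)
    return RawRead(read_id=read_id or path.stem, samples=samples)


def write_signal_txt(path: str | Path, read: RawRead) -> None:
    np.savetxt(path, read.samples, fmt="%.6f")
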