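"""End-to-end basecalling: raw signal -> standardize -> window -> network ->
decode -> overlap-assemble -> FASTA/FASTQ.

Per read, the standardized signal is cut into overlapping windows, windows
are batched through the network, each window's probability matrix is decoded
independently (greedy by default, prefix beam search on request), and the
per-window fragments are merged at their overlaps into the final sequence.
The model emits no per-base quality estimates, so FASTQ output carries a
constant placeholder quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .assembly import SegmentCall, assemble_read
from .ctc import DEFAULT_BEAM_WIDTH, beam_search_decode, greedy_decode
from .model import TCNModel
from .signal_io import RawRead, SegmentationConfig, mad_standardize, segment_signal

__all__ = ["BasecallConfig", "basecall_signal", "basecall_reads", "write_fasta", "write_fastq"]

PLACEHOLDER_PHRED = 10  # constant FASTQ quality; the model emits none


@dataclass
class BasecallConfig:
    segmentation: SegmentationConfig = None
    decoder: str = "greedy"
    beam_width: int = DEFAULT_BEAM_WIDTH
    batch_size: int = 256
    mad_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.segmentation is None:
            self.segmentation = SegmentationConfig()
        if self.decoder not in ("greedy", "beam"):
            raise ValueError("decoder must be 'greedy' or 'beam'")


def basecall_signal(
    samples: np.ndarray | Sequence[float],
    model: TCNModel,
    config: BasecallConfig | None = None,
) -> str:
    """Basecall one raw signal vector into a base string."""
    cfg = config or BasecallConfig()
    std = mad_standardize(samples, c=cfg.mad_scale)
    segments = segment_signal(std, cfg.segmentation)
    calls: list[SegmentCall] = []
    for start in range(0, len(segments), cfg.batch_size):
        batch = segments[start : start + cfg.batch_size]
        probs = model.forward_probs(np.stack([s.values for s in batch]))
        for i, seg in enumerate(batch):
            O = probs[i, : seg.valid_length]
            if cfg.decoder == "beam":
                bases, _ = beam_search_decode(O, cfg.beam_width)
            else:
                bases = greedy_decode(O)
            calls.append(SegmentCall(bases=bases, segment_index=start + i, offset=seg.offset))
    return assemble_read(calls)


def basecall_reads(
    reads: Iterable[RawRead],
    model: TCNModel,
    config: BasecallConfig | None = None,
) -> list[tuple[str, str]]:
    """Basecall many reads; returns (read_id, sequence) pairs in input order."""
    return [(r.read_id, basecall_signal(r.samples, model, config)) for r in reads]


def _records(calls: Sequence[tuple[str, str]], with_quality: bool):
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    for read_id, seq in calls:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        if with_quality:
            rec.letter_annotations["phred_quality"] = [PLACEHOLDER_PHRED] * len(seq)
        yield rec


def write_fasta(calls: Sequence[tuple[str, str]], path: str | Path) -> None:
    from Bio import SeqIO

    SeqIO.write(_records(calls, with_quality=False), str(path), "fasta")


def write_fastq(calls: Sequence[tuple[str, str]], path: str | Path) -> None:
    from Bio import SeqIO

    SeqIO.write(_records(calls, with_quality=True), str(path), "fastq")
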