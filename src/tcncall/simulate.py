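"""Synthetic squiggle generator with ground-truth base/sample boundaries.

The simulator emulates the physics that make basecalling a sequence-labeling
problem: the pore holds k nucleotides at a time, the measured current level is
a function of the resident k-mer, and each base dwells in the pore for a
variable number of samples because strand translocation is slower and less
regular than the fixed sampling clock.  Every simulated read carries its true
base sequence and the exact half-open sample interval of each base, standing
in for the re-squiggle alignments used to label real training data.

The simulator is deliberately simple: it does not model methylation-shifted
levels, baseline drift, stalls, or adapter signal.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .signal_io import (
    RawRead,
    SegmentationConfig,
    SignalSegment,
    mad_standardize,
    segment_signal,
)

__all__ = [
    "BASES",
    "PoreModel",
    "DwellModel",
    "SimulatedRead",
    "LabeledExample",
    "random_genome",
    "generate_pore_model",
    "simulate_read",
    "simulate_reads",
    "make_labeled_examples",
    "write_truth_fasta",
    "write_boundaries_tsv",
    "write_training_archive",
    "read_training_archive",
]

BASES = "ACGT"


@dataclass
class PoreModel:
    """Current level model: one mean level and noise sd per k-mer."""

    k: int
    level_mean: dict[str, float]
    level_sd: dict[str, float]

    def __post_init__(self) -> None:
        n = 4 ** self.k
        if len(self.level_mean) != n or len(self.level_sd) != n:
            raise ValueError(f"pore model must have exactly 4^k = {n} entries")
        if any(sd <= 0 for sd in self.level_sd.values()):
            raise ValueError("all k-mer noise scales must be positive")


@dataclass
class DwellModel:
    """Distribution of per-base dwell lengths, in samples.

    ``fixed`` emits exactly round(mean_dwell) samples per base; ``geometric``
    draws min_dwell + Geometric shifted so the mean equals ``mean_dwell``,
    which reproduces the heavy right tail of real translocation times.
    """

    mean_dwell: float = 8.0
    distribution: str = "geometric"
    min_dwell: int = 2

    def __post_init__(self) -> None:
        if self.distribution not in ("fixed", "geometric"):
            raise ValueError("distribution must be 'fixed' or 'geometric'")
        if not (self.mean_dwell >= self.min_dwell >= 1):
            raise ValueError("require mean_dwell >= min_dwell >= 1")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "fixed":
            return np.full(n, int(round(self.mean_dwell)), dtype=np.int64)
        # shifted geometric: support {min_dwell, min_dwell+1, ...}, mean mean_dwell
        p = 1.0 / (self.mean_dwell - self.min_dwell + 1.0)
        return self.min_dwell + rng.geometric(p, size=n) - 1


@dataclass
class SimulatedRead:
    """Synthetic signal plus its ground truth.

    ``sequence`` contains only the bases actually emitted: bases at the read
    edges lacking a complete k-mer context are trimmed, so truth, boundaries
    and training labels stay mutually consistent.  ``boundaries[i]`` is the
    half-open sample interval [start, end) during which ``sequence[i]``
    occupied the pore's central position.
    """

    read_id: str
    sequence: str
    signal: np.ndarray
    boundaries: np.ndarray  # (n_bases, 2) int array of [start, end)
    seed: int

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        if len(self.boundaries) != len(self.sequence):
            raise ValueError("one boundary interval per emitted base required")
        if len(self.boundaries):
            starts, ends = self.boundaries[:, 0], self.boundaries[:, 1]
            if starts[0] != 0 or ends[-1] != len(self.signal):
                raise ValueError("boundaries must cover [0, len(signal))")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError("boundaries must be contiguous and non-overlapping")


@dataclass
class LabeledExample:
    """A standardized signal window paired with the bases it contains."""

    segment: SignalSegment
    labels: str


def random_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. random base string; deterministic in the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def generate_pore_model(
    k: int,
    seed: int,
    level_range: tuple[float, float] = (60.0, 140.0),
    sd_range: tuple[float, float] = (1.5, 3.5),
) -> PoreModel:
    """Draw a reproducible synthetic pore model.

    Levels are uniform on ``level_range`` (picoamp-like units spanning the
    range typical of a real pore table) and per-k-mer noise scales uniform on
    ``sd_range``; the wide level range relative to the noise keeps distinct
    k-mers typically separable.
    """
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")
    rng = np.random.default_rng(seed)
    kmers = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    means = rng.uniform(*level_range, size=len(kmers))
    sds = rng.uniform(*sd_range, size=len(kmers))
    return PoreModel(
        k=k,
        level_mean=dict(zip(kmers, means.tolist())),
        level_sd=dict(zip(kmers, sds.tolist())),
    )


def simulate_read(
    sequence: str,
    pore: PoreModel,
    dwell: DwellModel | None = None,
    noise_sd_scale: float = 1.0,
    seed: int = 0,
    read_id: str | None = None,
    anchor: str = "end",
) -> SimulatedRead:
    """Simulate the squiggle of one known sequence.

    One dwell is emitted per k-mer of the sequence, in order: a dwell length
    is drawn, then that many samples ~ Normal(level_mean[kmer],
    noise_sd_scale * level_sd[kmer]).  ``anchor`` controls which base of the
    resident k-mer names each dwell in the ground-truth boundaries:

    * ``"end"`` (default): the k-mer's last base — the base about to be
      shifted out of the pore.  This mirrors re-squiggle labeling, where a
      boundary is labeled with the shifted base, and means a base's full
      k-mer context lies at or before its labeled interval, so a causal
      decoder needs no future signal.
    * ``"center"``: the central base (odd k) — labels are synchronous with
      the pore's geometric center, at the cost of making each base's level
      depend on a not-yet-labeled future base.
    * ``"start"``: the k-mer's first base.

    Bases at the read edge without a full k-mer under the chosen anchoring
    are not emitted; the recorded truth is trimmed accordingly (k-1 bases in
    total).  Fully deterministic in ``seed``.
    """
    if dwell is None:
        dwell = DwellModel()
    if noise_sd_scale < 0:
        raise ValueError("noise_sd_scale must be non-negative")
    k = pore.k
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} shorter than k={k}")
    if anchor not in ("start", "center", "end"):
        raise ValueError("anchor must be 'start', 'center', or 'end'")
    rng = np.random.default_rng(seed)
    # offset of the labeling base within each k-mer
    h = {"start": 0, "center": (k - 1) // 2, "end": k - 1}[anchor]
    emitted = sequence[h : len(sequence) - (k - 1 - h)]
    n = len(emitted)
    kmers = [sequence[i : i + k] for i in range(n)]
    levels = np.array([pore.level_mean[km] for km in kmers])
    sds = np.array([pore.level_sd[km] for km in kmers])
    dwells = dwell.draw(n, rng)
    ends = np.cumsum(dwells)
    starts = ends - dwells
    signal = np.repeat(levels, dwells)
    if noise_sd_scale > 0:
        signal = signal + rng.normal(0.0, 1.0, size=len(signal)) * np.repeat(
            noise_sd_scale * sds, dwells
        )
    return SimulatedRead(
        read_id=read_id or f"sim_{seed}",
        sequence=emitted,
        signal=signal,
        boundaries=np.column_stack([starts, ends]),
        seed=seed,
    )


def simulate_reads(
    n_reads: int,
    read_length: int,
    pore: PoreModel,
    dwell: DwellModel | None = None,
    noise_sd_scale: float = 1.0,
    seed: int = 0,
    anchor: str = "end",
) -> list[SimulatedRead]:
    """Simulate a batch of reads with independent random sequences.

    Per-read seeds are derived from ``seed`` so the batch is reproducible and
    individual reads can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_reads)]
    reads = []
    for i in range(n_reads):
        seq = random_genome(read_length, child_seeds[2 * i])
        reads.append(
            simulate_read(
                seq,
                pore,
                dwell,
                noise_sd_scale,
                seed=child_seeds[2 * i + 1],
                read_id=f"sim_{seed}_{i:05d}",
                anchor=anchor,
            )
        )
    return reads


def make_labeled_examples(
    read: SimulatedRead,
    config: SegmentationConfig,
    c: float = 1.0,
    standardize: bool = True,
) -> list[LabeledExample]:
    """Cut one simulated read into (standardized window, label string) pairs.

    A base belongs to a window when the midpoint of its sample interval lies
    inside the window's valid span — an unambiguous rule that assigns every
    base to exactly one window of a stride-T (non-overlapping) segmentation,
    preserving sequence order.  Windows use the padded-tail segmentation
    policy so a stride-T label set partitions the read's bases exactly.
    Every base over a window's valid span is labeled: the network's
    emissions are translation-equivariant, so position-dependent label
    exclusions (say, in a window's low-context head) would demand a function
    the architecture cannot represent.
    """
    values = read.signal
    if standardize:
        values = mad_standardize(values, c=c).values
    segments = segment_signal(values, config, tail="pad")
    mids = read.boundaries.mean(axis=1)  # (start + end) / 2
    bases = np.array(list(read.sequence))
    out = []
    for seg in segments:
        lo, hi = seg.offset, seg.offset + seg.valid_length
        mask = (mids >= lo) & (mids < hi)
        labels = "".join(bases[mask]) if mask.any() else ""
        out.append(LabeledExample(segment=seg, labels=labels))
    return out


# --------------------------------------------------------------------------
# On-disk artifacts: truth FASTA, boundaries TSV, and training archives.
# --------------------------------------------------------------------------

def write_truth_fasta(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def write_boundaries_tsv(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Write per-base sample intervals: read_id, base index, base, start, end."""
    with open(path, "w") as fh:
        fh.write("read_id\tbase_index\tbase\tstart\tend\n")
        for r in reads:
            for i, (b, (s, e)) in enumerate(zip(r.sequence, r.boundaries)):
                fh.write(f"{r.read_id}\t{i}\t{b}\t{s}\t{e}\n")


_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}


def write_training_archive(
    path: str | Path,
    examples: Sequence[LabeledExample],
) -> None:
    """Write labeled windows as a single .npz archive.

    Layout (all arrays named): ``signals`` float32 (N, T); ``labels`` int8
    concatenation of base indices (A=0, C=1, G=2, T=3); ``label_lengths``
    int32 (N,), from which per-example slices are recovered by cumulative sum;
    ``valid_lengths`` int32 (N,); ``meta`` JSON string with T and the
    alphabet.
    """
    if not examples:
        raise ValueError("cannot write an empty training archive")
    T = len(examples[0].segment.values)
    signals = np.stack([ex.segment.values for ex in examples]).astype(np.float32)
    label_lengths = np.array([len(ex.labels) for ex in examples], dtype=np.int32)
    labels = np.array(
        [_BASE_TO_INT[b] for ex in examples for b in ex.labels], dtype=np.int8
    )
    valid_lengths = np.array(
        [ex.segment.valid_length for ex in examples], dtype=np.int32
    )
    meta = json.dumps({"segment_length": T, "alphabet": BASES})
    np.savez_compressed(
        path,
        signals=signals,
        labels=labels,
        label_lengths=label_lengths,
        valid_lengths=valid_lengths,
        meta=np.bytes_(meta.encode()),
    )


def read_training_archive(
    path: str | Path,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Load an archive: (signals (N, T) float32, per-example int label arrays,
    valid_lengths (N,))."""
    with np.load(path) as data:
        signals = data["signals"]
        flat = data["labels"].astype(np.int64)
        lengths = data["label_lengths"]
        valid = data["valid_lengths"]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    labels = [flat[offsets[i] : offsets[i + 1]] for i in range(len(lengths))]
    return signals, labels, valid
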