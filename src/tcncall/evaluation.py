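"""Basecalling evaluation: per-read error rates, cross-caller common-error
overlap, and a six-way error taxonomy aware of homopolymers and Dcm motifs.

Rates follow the standard alignment-based definitions: with a read aligned to
its reference, the identity rate is matched bases over reference bases in the
aligned span, and insertion/deletion/mismatch rates are the corresponding
event base counts over the same denominator, so identity + mismatch +
deletion = 1 for an alignment covering its reference span and the total error
rate is the sum of the three error rates.

Errors are localized to 0-based reference coordinates (insertions anchored to
the reference position they precede).  An error site is "common" to a set of
callers when every caller makes that error type at the same coordinate; the
taxonomy assigns each error to exactly one of homopolymer_deletion,
homopolymer_insertion, dcm_error, deletion, insertion, or substitution, where
homopolymers are reference runs of more than two identical bases and Dcm
motifs are CCTGG/CCAGG occurrences (a reverse-complement-closed pair, so a
forward-strand scan covers both strands).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

__all__ = [
    "Alignment",
    "ErrorProfile",
    "SiteError",
    "TaxonomyCounts",
    "align",
    "error_rates",
    "site_errors",
    "common_error_proportion",
    "classify_errors",
    "read_sam_alignments",
    "write_error_report_tsv",
]

DCM_MOTIFS = ("CCTGG", "CCAGG")
MIN_HOMOPOLYMER_RUN = 3  # "more than two bases"

_CIGAR_RE = re.compile(r"(\d+)([=XID])")
ORDINARY_TYPES = ("insertion", "deletion", "mismatch")
TAXONOMY_TYPES = (
    "homopolymer_deletion",
    "homopolymer_insertion",
    "dcm_error",
    "deletion",
    "insertion",
    "substitution",
)


@dataclass
class Alignment:
    """A read/reference pair with an explicit per-column operation string.

    ``ops`` is over '=' (match), 'X' (mismatch), 'I' (base present only in
    the read), 'D' (reference base missing from the read); ``ref_start`` is
    the 0-based reference coordinate of the first aligned reference base.
    """

    query: str
    reference: str
    ops: str
    ref_start: int = 0

    def __post_init__(self) -> None:
        q = sum(1 for o in self.ops if o in "=XI")
        r = sum(1 for o in self.ops if o in "=XD")
        if q != len(self.query) or r != len(self.reference):
            raise ValueError("operation string inconsistent with sequence lengths")


def align(query: str, reference: str) -> Alignment:
    """Global (end-to-end) edit alignment of a read against its reference."""
    if not query or not reference:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(query, reference, task="path", mode="NW")
    ops = "".join(
        op * int(n) for n, op in _CIGAR_RE.findall(res["cigar"])
    )
    return Alignment(query=query, reference=reference, ops=ops, ref_start=0)


@dataclass
class ErrorProfile:
    """Alignment-derived rates, all as fractions of the aligned reference span."""

    identity_rate: float
    insertion_rate: float
    deletion_rate: float
    mismatch_rate: float
    total_error_rate: float
    reference_span: int


def _op_counts(ops: str) -> dict[str, int]:
    return {o: ops.count(o) for o in "=XID"}


def error_rates(alignment: Alignment) -> ErrorProfile:
    """Identity/insertion/deletion/mismatch rates of one alignment."""
    if not alignment.ops:
        raise ValueError("empty alignment")
    c = _op_counts(alignment.ops)
    span = c["="] + c["X"] + c["D"]
    if span == 0:
        raise ValueError("alignment covers no reference bases")
    return ErrorProfile(
        identity_rate=c["="] / span,
        insertion_rate=c["I"] / span,
        deletion_rate=c["D"] / span,
        mismatch_rate=c["X"] / span,
        total_error_rate=(c["I"] + c["D"] + c["X"]) / span,
        reference_span=span,
    )


@dataclass(frozen=True)
class SiteError:
    """One basecalling error at a 0-based reference coordinate."""

    reference_position: int
    error_type: str  # insertion | deletion | mismatch
    caller_id: str = ""


def site_errors(alignment: Alignment, caller_id: str = "") -> list[SiteError]:
    """Project an alignment's errors onto reference coordinates.

    Mismatches and deletions sit on the reference base they touch; an
    insertion is anchored to the reference position it precedes.
    """
    out: list[SiteError] = []
    pos = alignment.ref_start
    for op in alignment.ops:
        if op == "X":
            out.append(SiteError(pos, "mismatch", caller_id))
            pos += 1
        elif op == "D":
            out.append(SiteError(pos, "deletion", caller_id))
            pos += 1
        elif op == "I":
            out.append(SiteError(pos, "insertion", caller_id))
        else:
            pos += 1
    return out


def common_error_proportion(
    errors_by_caller: Mapping[str, Iterable[SiteError]],
    caller: str,
) -> dict[str, float | None]:
    """Fraction of a caller's errors that every caller shares, per type.

    A site is common for a type when all callers have that error type at the
    same reference coordinate.  A caller with zero errors of some type gets
    ``None`` for that type (undefined), and those errors are excluded from
    the overall aggregate.
    """
    if len(errors_by_caller) < 2:
        raise ValueError("common-error analysis needs at least two callers")
    if caller not in errors_by_caller:
        raise KeyError(f"unknown caller {caller!r}")
    sites = {
        name: {
            t: {e.reference_position for e in errs if e.error_type == t}
            for t in ORDINARY_TYPES
        }
        for name, errs in (
            (name, list(errs)) for name, errs in errors_by_caller.items()
        )
    }
    result: dict[str, float | None] = {}
    common_total = 0
    own_total = 0
    for t in ORDINARY_TYPES:
        common = set.intersection(*(sites[name][t] for name in sites))
        own = sites[caller][t]
        if not own:
            result[t] = None
            continue
        result[t] = len(common & own) / len(own)
        common_total += len(common & own)
        own_total += len(own)
    result["overall"] = common_total / own_total if own_total else None
    return result


@dataclass
class TaxonomyCounts:
    """Six-way error classification; counts partition the total error set."""

    counts: dict[str, int]
    reference_length: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def rates(self) -> dict[str, float]:
        return {k: v / self.reference_length for k, v in self.counts.items()}


def _homopolymer_mask(reference: str) -> np.ndarray:
    """True at positions inside a run of >= MIN_HOMOPOLYMER_RUN identical bases."""
    mask = np.zeros(len(reference), dtype=bool)
    i = 0
    n = len(reference)
    while i < n:
        j = i
        while j < n and reference[j] == reference[i]:
            j += 1
        if j - i >= MIN_HOMOPOLYMER_RUN:
            mask[i:j] = True
        i = j
    return mask


def _dcm_mask(reference: str) -> np.ndarray:
    """True inside any CCTGG/CCAGG occurrence (the motif pair is its own
    reverse complement, so one forward scan covers both strands)."""
    mask = np.zeros(len(reference), dtype=bool)
    for motif in DCM_MOTIFS:
        start = 0
        while True:
            hit = reference.find(motif, start)
            if hit < 0:
                break
            mask[hit : hit + len(motif)] = True
            start = hit + 1
    return mask


def classify_errors(
    alignment: Alignment,
    reference: str | None = None,
    caller_id: str = "",
) -> TaxonomyCounts:
    """Assign each alignment error to exactly one taxonomy class.

    Precedence: homopolymer context first (insertions/deletions only), then
    Dcm motif context, then the ordinary class.  An insertion is judged by
    the run/motif touching either side of its anchor point.
    """
    ref = reference if reference is not None else alignment.reference
    homo = _homopolymer_mask(ref)
    dcm = _dcm_mask(ref)

    def in_mask(mask: np.ndarray, err: SiteError) -> bool:
        p = err.reference_position
        if err.error_type == "insertion":
            candidates = [p - 1, p]
        else:
            candidates = [p]
        return any(0 <= c < len(mask) and mask[c] for c in candidates)

    counts = {t: 0 for t in TAXONOMY_TYPES}
    for err in site_errors(alignment, caller_id):
        if err.error_type == "deletion" and in_mask(homo, err):
            counts["homopolymer_deletion"] += 1
        elif err.error_type == "insertion" and in_mask(homo, err):
            counts["homopolymer_insertion"] += 1
        elif in_mask(dcm, err):
            counts["dcm_error"] += 1
        elif err.error_type == "deletion":
            counts["deletion"] += 1
        elif err.error_type == "insertion":
            counts["insertion"] += 1
        else:
            counts["substitution"] += 1
    return TaxonomyCounts(counts=counts, reference_length=len(ref))


def read_sam_alignments(path: str | Path) -> list[tuple[str, Alignment]]:
    """Load alignments from a SAM file (CIGAR + MD) for parity with external
    aligners.  Returns (query_name, Alignment) pairs for mapped records."""
    import pysam

    out: list[tuple[str, Alignment]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            pairs = rec.get_aligned_pairs(with_seq=True)
            query = rec.query_sequence
            ops = []
            ref_bases = []
            q_bases = []
            ref_start = rec.reference_start
            for qpos, rpos, rbase in pairs:
                if qpos is None and rpos is None:
                    continue
                if qpos is None:
                    ops.append("D")
                    ref_bases.append(rbase.upper())
                elif rpos is None:
                    ops.append("I")
                    q_bases.append(query[qpos])
                else:
                    qb = query[qpos]
                    rb = rbase.upper() if rbase else "N"
                    # pysam lower-cases reference bases at mismatches (from MD)
                    ops.append("=" if rbase is not None and rbase.isupper() else "X")
                    q_bases.append(qb)
                    ref_bases.append(rb)
            # soft-clipped query bases are outside the alignment
            aln = Alignment(
                query="".join(q_bases),
                reference="".join(ref_bases),
                ops="".join(ops),
                ref_start=ref_start,
            )
            out.append((rec.query_name, aln))
    return out


def write_error_report_tsv(
    rows: Sequence[tuple[str, ErrorProfile]], path: str | Path
) -> None:
    """Per-read error profile table plus a span-weighted aggregate row."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tidentity_rate\tinsertion_rate\tdeletion_rate\t"
            "mismatch_rate\ttotal_error_rate\treference_span\n"
        )
        for read_id, prof in rows:
            fh.write(
                f"{read_id}\t{prof.identity_rate:.6f}\t{prof.insertion_rate:.6f}\t"
                f"{prof.deletion_rate:.6f}\t{prof.mismatch_rate:.6f}\t"
                f"{prof.total_error_rate:.6f}\t{prof.reference_span}\n"
            )
        if rows:
            spans = np.array([p.reference_span for _, p in rows], dtype=float)
            w = spans / spans.sum()
            agg = {
                name: float(np.sum(w * np.array([getattr(p, name) for _, p in rows])))
                for name in (
                    "identity_rate", "insertion_rate", "deletion_rate",
                    "mismatch_rate", "total_error_rate",
                )
            }
            fh.write(
                f"__aggregate__\t{agg['identity_rate']:.6f}\t{agg['insertion_rate']:.6f}\t"
                f"{agg['deletion_rate']:.6f}\t{agg['mismatch_rate']:.6f}\t"
                f"{agg['total_error_rate']:.6f}\t{int(spans.sum())}\n"
            )
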