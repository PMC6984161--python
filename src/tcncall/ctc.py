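"""Connectionist temporal classification: probability, loss, and decoders.

The network emits a T x 5 row-stochastic matrix O over the symbols
(A, C, G, T, blank).  A frame-level symbol sequence s collapses to a base
sequence through the many-to-one mapping B, which first merges consecutive
repeats and then removes blanks; the probability of a base sequence Y is the
sum of the path products over every s with B(s) = Y:

    P(Y|X) = sum_{s in B^-1(Y)} prod_t O_t[s_t]

Training minimizes -log P(Y|X).  The sum is computed with the standard
forward recursion over the blank-interleaved extended label in log space (so
T = 512 windows do not underflow); a literal enumeration oracle over all 5^T
symbol sequences is provided for small T.  Decoding is either greedy
(framewise argmax, then collapse) or a prefix beam search that merges all
symbol paths collapsing to the same prefix, approximating the full sum.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import BLANK, N_SYMBOLS, SYMBOLS

__all__ = [
    "collapse",
    "ctc_probability",
    "ctc_log_probability",
    "brute_force_probability",
    "ctc_loss",
    "ctc_loss_and_grad",
    "greedy_decode",
    "beam_search_decode",
    "ZeroProbabilityError",
    "DEFAULT_BEAM_WIDTH",
]

DEFAULT_BEAM_WIDTH = 20

_NEG_INF = -np.inf
_BASE_TO_INT = {b: i for i, b in enumerate(SYMBOLS[:4])}


class ZeroProbabilityError(ValueError):
    """Raised when a label has zero probability and the loss would be infinite."""


def _as_label_array(y: str | Sequence[int]) -> np.ndarray:
    if isinstance(y, str):
        try:
            return np.array([_BASE_TO_INT[b] for b in y], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"label contains non-base symbol {exc}") from exc
    arr = np.asarray(y, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() >= 4):
        raise ValueError("label indices must be in 0..3 (A, C, G, T)")
    return arr


def _as_symbol_array(s: str | Sequence[int]) -> np.ndarray:
    if isinstance(s, str):
        idx = {c: i for i, c in enumerate(SYMBOLS)}
        return np.array([idx[c] for c in s], dtype=np.int64)
    return np.asarray(s, dtype=np.int64)


def collapse(s: str | Sequence[int]) -> str:
    """Apply the mapping B: merge consecutive repeats, then drop blanks.

    Accepts a string over "ACGT-" or a sequence of symbol indices; returns the
    base string.  E.g. collapse("AA--G-C") == "AGC".
    """
    arr = _as_symbol_array(s)
    if arr.size == 0:
        return ""
    keep = np.concatenate([[True], arr[1:] != arr[:-1]])
    merged = arr[keep]
    return "".join(SYMBOLS[i] for i in merged if i != BLANK)


def _extended_label(y: np.ndarray) -> np.ndarray:
    """Blank-interleaved label: [-, y1, -, y2, ..., -], length 2M+1."""
    z = np.full(2 * len(y) + 1, BLANK, dtype=np.int64)
    z[1::2] = y
    return z


def ctc_log_probability(O: np.ndarray, y: str | Sequence[int]) -> float:
    """log P(Y|X) by the forward recursion (log space); -inf if impossible."""
    O = np.asarray(O, dtype=np.float64)
    if O.ndim != 2 or O.shape[1] != N_SYMBOLS:
        raise ValueError(f"O must be (T, {N_SYMBOLS}), got {O.shape}")
    T = O.shape[0]
    label = _as_label_array(y)
    z = _extended_label(label)
    S = len(z)
    with np.errstate(divide="ignore"):
        lp = np.log(O)
    # alpha[s]: log-prob of all prefixes of extended-label paths ending in
    # state s after emitting frame t.
    alpha = np.full(S, _NEG_INF)
    alpha[0] = lp[0, z[0]]
    if S > 1:
        alpha[1] = lp[0, z[1]]
    # a state may skip its predecessor's predecessor only across a blank
    # between two distinct bases
    can_skip = np.zeros(S, dtype=bool)
    if S > 2:
        can_skip[2:] = (z[2:] != BLANK) & (z[2:] != z[:-2])
    for t in range(1, T):
        prev = alpha
        shifted1 = np.concatenate([[_NEG_INF], prev[:-1]])
        shifted2 = np.concatenate([[_NEG_INF, _NEG_INF], prev[:-2]])
        shifted2 = np.where(can_skip, shifted2, _NEG_INF)
        alpha = lp[t, z] + np.logaddexp(np.logaddexp(prev, shifted1), shifted2)
    if S == 1:
        return float(alpha[0])
    return float(np.logaddexp(alpha[-1], alpha[-2]))


def ctc_probability(O: np.ndarray, y: str | Sequence[int]) -> float:
    """P(Y|X) per the collapsed-path sum; 0 when no path can produce Y."""
    return float(np.exp(ctc_log_probability(O, y)))


def brute_force_probability(O: np.ndarray, y: str | Sequence[int]) -> float:
    """Literal enumeration of the collapsed-path sum (test oracle, T <= 8).

    Sums prod_t O_t[s_t] over every one of the 5^T frame sequences s whose
    collapse equals Y.  Exponential: refuses T > 8.
    """
    O = np.asarray(O, dtype=np.float64)
    T = O.shape[0]
    if T > 8:
        raise ValueError(f"brute force enumeration refused for T={T} > 8")
    target = tuple(_as_label_array(y).tolist())
    rows = [tuple(row) for row in O]
    total = 0.0
    import itertools

    for s in itertools.product(range(N_SYMBOLS), repeat=T):
        # inline collapse: merge consecutive repeats, drop blanks
        collapsed = []
        prev = -1
        for sym in s:
            if sym != prev and sym != BLANK:
                collapsed.append(sym)
            prev = sym
        if tuple(collapsed) != target:
            continue
        p = 1.0
        for t, sym in enumerate(s):
            p *= rows[t][sym]
        total += p
    return total


def ctc_loss(O: np.ndarray, y: str | Sequence[int]) -> float:
    """-log P(Y|X); raises ZeroProbabilityError when P(Y|X) = 0."""
    logp = ctc_log_probability(O, y)
    if not np.isfinite(logp):
        label = y if isinstance(y, str) else "".join(SYMBOLS[i] for i in y)
        raise ZeroProbabilityError(
            f"label {label!r} (length {len(label)}) has zero probability under a "
            f"{O.shape[0]}-frame output; the loss is infinite"
        )
    return -logp


def ctc_loss_and_grad(
    log_probs: np.ndarray,
    labels: Sequence[np.ndarray | str],
    input_lengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched CTC loss and its gradient with respect to the logits.

    Parameters
    ----------
    log_probs : (B, T, 5) log-softmax outputs.
    labels : per-example base index arrays (or strings).
    input_lengths : optional per-example number of valid frames (<= T);
        padded frames contribute nothing and receive zero gradient.

    Returns
    -------
    losses : (B,) per-example -log P(Y|X) (inf where no path exists).
    grad : (B, T, 5) d(loss)/d(logits), i.e. softmax(logits) minus the
        posterior symbol occupancy from the forward-backward recursion.
        Examples with impossible labels get zero gradient.
    """
    lp = np.asarray(log_probs, dtype=np.float64)
    B, T, K = lp.shape
    if K != N_SYMBOLS:
        raise ValueError(f"expected {N_SYMBOLS} symbol channels, got {K}")
    labs = [_as_label_array(y) for y in labels]
    if len(labs) != B:
        raise ValueError("one label per batch element required")
    if input_lengths is None:
        input_lengths = np.full(B, T, dtype=np.int64)
    else:
        input_lengths = np.asarray(input_lengths, dtype=np.int64)

    S_max = 2 * max((len(y) for y in labs), default=0) + 1
    z = np.full((B, S_max), BLANK, dtype=np.int64)
    s_len = np.zeros(B, dtype=np.int64)
    for b, y in enumerate(labs):
        s_len[b] = 2 * len(y) + 1
        z[b, 1 : 2 * len(y) : 2] = y
    valid_s = np.arange(S_max)[None, :] < s_len[:, None]

    can_skip = np.zeros((B, S_max), dtype=bool)
    if S_max > 2:
        can_skip[:, 2:] = (z[:, 2:] != BLANK) & (z[:, 2:] != z[:, :-2]) & valid_s[:, 2:]

    # per-state emission probabilities: (B, T, S); strictly positive because
    # they come from a log-softmax, so only structural zeros appear below
    p_z = np.exp(np.take_along_axis(lp, z[:, None, :].repeat(T, axis=1), axis=2))
    p_z[~valid_s[:, None, :].repeat(T, axis=1)] = 0.0

    # Scaled linear-space forward-backward: each frame's state vector is
    # renormalized to sum 1 and the log of the normalizer accumulated, which
    # avoids both underflow on long windows and the cost of log-space ops.
    no_skip = ~can_skip
    invalid = ~valid_s
    idx_b = np.arange(B)
    last_t = input_lengths - 1

    alpha = np.zeros((B, T, S_max))
    alpha[:, 0, 0] = p_z[:, 0, 0]
    has2 = s_len > 1
    alpha[has2, 0, 1] = p_z[has2, 0, 1]
    log_c = np.zeros(B)
    norm0 = alpha[:, 0, :].sum(axis=1)
    dead = norm0 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha[:, 0, :] /= norm0[:, None]
        log_c += np.where(dead, _NEG_INF, np.log(np.where(dead, 1.0, norm0)))
    pad_prev = np.zeros((B, S_max + 2))
    for t in range(1, T):
        prev = alpha[:, t - 1, :]
        pad_prev[:, 2:] = prev
        acc = prev + pad_prev[:, 1:-1]
        s2 = pad_prev[:, :-2].copy()
        s2[no_skip] = 0.0
        acc += s2
        acc *= p_z[:, t, :]
        norm = acc.sum(axis=1)
        live = t < input_lengths
        ok = live & (norm > 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(ok[:, None], acc / np.where(norm == 0.0, 1.0, norm)[:, None], 0.0)
        alpha[:, t, :] = np.where(live[:, None], scaled, prev)
        log_c += np.where(live, np.where(ok, np.log(np.where(norm == 0.0, 1.0, norm)), _NEG_INF), 0.0)

    final = alpha[idx_b, T - 1, s_len - 1]
    if S_max > 1:
        final = final + np.where(s_len > 1, alpha[idx_b, T - 1, np.maximum(s_len - 2, 0)], 0.0)
    with np.errstate(divide="ignore"):
        log_p = np.where(final > 0.0, np.log(np.maximum(final, 1e-300)), _NEG_INF) + log_c
    losses = -log_p

    # beta[t, s]: (scaled) probability of completing the path from state s
    # using frames t+1 .. L-1 (exclusive of frame t's emission).
    beta = np.zeros((B, T, S_max))
    beta[idx_b, last_t, s_len - 1] = 1.0
    beta[idx_b[has2], last_t[has2], s_len[has2] - 2] = 1.0
    pad_nxt = np.zeros((B, S_max + 2))
    no_skip_next = np.ones((B, S_max), dtype=bool)
    no_skip_next[:, :-2] = no_skip[:, 2:]
    for t in range(T - 2, -1, -1):
        nxt = beta[:, t + 1, :] * p_z[:, t + 1, :]
        pad_nxt[:, :S_max] = nxt
        acc = nxt + pad_nxt[:, 1 : S_max + 1]
        s2 = pad_nxt[:, 2 : S_max + 2].copy()
        s2[no_skip_next] = 0.0
        acc += s2
        norm = acc.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(norm[:, None] > 0.0, acc / np.where(norm == 0.0, 1.0, norm)[:, None], 0.0)
        before_last = (t < last_t)[:, None]
        at_last = (t == last_t)[:, None]
        beta[:, t, :] = np.where(
            before_last, scaled, np.where(at_last, beta[:, t, :], beta[:, t + 1, :])
        )

    # posterior state occupancy: alpha*beta renormalized per frame (the true
    # posterior sums to 1 over states at every valid frame, so per-frame
    # normalization cancels all scale factors at once)
    gamma = alpha * beta
    gsum = gamma.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(gsum > 0.0, gamma / np.where(gsum == 0.0, 1.0, gsum), 0.0)

    occupancy = np.zeros((B, T, K))
    flat_idx = (
        np.arange(B)[:, None, None] * (T * K)
        + np.arange(T)[None, :, None] * K
        + z[:, None, :]
    )
    np.add.at(occupancy.reshape(-1), flat_idx.ravel(), gamma.ravel())

    grad = np.exp(lp) - occupancy
    # zero out gradient beyond valid frames and for impossible labels
    frame_mask = (np.arange(T)[None, :] < input_lengths[:, None])[:, :, None]
    grad = np.where(frame_mask, grad, 0.0)
    bad = ~np.isfinite(log_p)
    if bad.any():
        grad[bad] = 0.0
    return losses, grad


def greedy_decode(O: np.ndarray) -> str:
    """Collapse the framewise argmax path; ties go to the lowest symbol index."""
    O = np.asarray(O, dtype=np.float64)
    if O.ndim != 2 or O.shape[1] != N_SYMBOLS:
        raise ValueError(f"O must be (T, {N_SYMBOLS}), got {O.shape}")
    return collapse(np.argmax(O, axis=1))


def beam_search_decode(O: np.ndarray, beam_width: int = DEFAULT_BEAM_WIDTH) -> tuple[str, float]:
    """Prefix beam search over collapsed sequences.

    Maintains, for each candidate collapsed prefix, the total log-probability
    of all symbol paths ending in blank (p_b) and in the prefix's last base
    (p_nb); merging paths per prefix makes the score approximate the full
    collapsed-path sum, and it is exact when the beam holds every prefix.

    Returns (base sequence, log-probability score of that sequence).
    """
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    O = np.asarray(O, dtype=np.float64)
    if O.ndim != 2 or O.shape[1] != N_SYMBOLS:
        raise ValueError(f"O must be (T, {N_SYMBOLS}), got {O.shape}")
    with np.errstate(divide="ignore"):
        lp = np.log(O)
    # prefix (tuple of base indices) -> [log p_blank, log p_nonblank]
    beams: dict[tuple[int, ...], list[float]] = {(): [0.0, _NEG_INF]}
    for t in range(O.shape[0]):
        new: dict[tuple[int, ...], list[float]] = {}

        def add(prefix: tuple[int, ...], which: int, logp: float) -> None:
            if logp == _NEG_INF:
                return
            entry = new.setdefault(prefix, [_NEG_INF, _NEG_INF])
            entry[which] = np.logaddexp(entry[which], logp)

        for prefix, (pb, pnb) in beams.items():
            total = np.logaddexp(pb, pnb)
            add(prefix, 0, total + lp[t, BLANK])
            for c in range(4):
                if prefix and prefix[-1] == c:
                    # repeat frame merges into the same prefix ...
                    add(prefix, 1, pnb + lp[t, c])
                    # ... unless separated by a blank, which extends it
                    add(prefix + (c,), 1, pb + lp[t, c])
                else:
                    add(prefix + (c,), 1, total + lp[t, c])
        if len(new) > beam_width:
            ranked = sorted(
                new.items(), key=lambda kv: np.logaddexp(kv[1][0], kv[1][1]), reverse=True
            )
            new = dict(ranked[:beam_width])
        beams = new
    best_prefix, (pb, pnb) = max(
        beams.items(), key=lambda kv: np.logaddexp(kv[1][0], kv[1][1])
    )
    return "".join(SYMBOLS[i] for i in best_prefix), float(np.logaddexp(pb, pnb))
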