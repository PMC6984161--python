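"""Exact Viterbi decoder over the true k-mer chain — an independent oracle.

This is the classical HMM view of nanopore decoding: hidden states are
k-mers, transitions advance the strand by one base (or stay, modeling dwell),
and emissions are Gaussian at the pore model's levels.  Decoding with the
*true* simulator parameters bounds what any basecaller could recover from a
simulated squiggle, independent of the network implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

from tcncall.simulate import PoreModel


def viterbi_decode(signal: np.ndarray, pore: PoreModel, mean_dwell: float) -> str:
    """Most likely base sequence given the true pore model.

    Consecutive identical states are collapsed to one base each, so run
    lengths inside homopolymers longer than the k-mer span are not recovered
    — an intrinsic ambiguity shared by every level-based decoder.
    """
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=pore.k)]
    kidx = {k: i for i, k in enumerate(kmers)}
    mu = np.array([pore.level_mean[k] for k in kmers])
    sd = np.array([pore.level_sd[k] for k in kmers])
    succ = np.array([[kidx[k[1:] + b] for b in "ACGT"] for k in kmers])
    n = len(kmers)
    p_adv = 1.0 / mean_dwell
    log_stay = np.log(1.0 - p_adv)
    log_adv = np.log(p_adv / 4.0)

    em = -0.5 * ((signal[:, None] - mu[None, :]) / sd[None, :]) ** 2 - np.log(sd[None, :])
    T = len(signal)
    V = em[0].copy()
    back = np.zeros((T, n), dtype=np.int32)
    for t in range(1, T):
        best = V + log_stay
        bptr = np.arange(n)
        for i in range(n):
            sc = V[i] + log_adv
            for j in succ[i]:
                if sc > best[j]:
                    best[j] = sc
                    bptr[j] = i
        V = best + em[t]
        back[t] = bptr
    j = int(np.argmax(V))
    path = [j]
    for t in range(T - 1, 0, -1):
        j = back[t][j]
        path.append(j)
    path.reverse()
    out = []
    prev = -1
    for j in path:
        if j != prev:
            # report the base shifted out of the pore (matches the simulator's
            # default end-anchored truth)
            out.append(kmers[j][-1])
            prev = j
    return "".join(out)
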