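"""Low-level Smith-Waterman kernels and k-mer utilities.

Sequences are handled as uint8 code arrays (A=0, C=1, G=2, T=3, N=4).
Code 4 never matches anything, including itself.

Gap convention (Gotoh affine): a gap of length L costs
``gap_open + (L - 1) * gap_extend`` with both penalties negative,
i.e. ``gap_open`` already includes the first gapped base.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (anything outside ACGTacgt -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (N stays N)."""
    out = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)
    return out[::-1]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer integer codes for every window; second array flags
    windows free of ambiguous bases."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win.astype(np.int64) @ powers
    valid = win.max(axis=1) < 4
    return vals, valid


@njit(cache=True)
def sw_align(q, r, match, mismatch, gap_open, gap_extend):
    """Full affine-gap local alignment with traceback.

    Returns int64 array [score, q_start, q_end, r_start, r_end,
    n_match, n_cols]; spans are 0-based half-open. Score 0 means no
    positive-scoring alignment exists.
    """
    m = len(q)
    n = len(r)
    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    # ptrH: 0 stop, 1 diag, 2 from E (gap consuming r), 3 from F
    ptrH = np.zeros((m + 1, n + 1), np.uint8)
    ptrE = np.zeros((m + 1, n + 1), np.uint8)  # 1 open, 0 extend
    ptrF = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qc = q[i - 1]
        for j in range(1, n + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 0
            rc = r[j - 1]
            if qc == rc and qc < 4:
                sub = match
            else:
                sub = mismatch
            h = H[i - 1, j - 1] + sub
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    out = np.zeros(7, np.int64)
    if best == 0:
        return out
    # traceback
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    n_match = 0
    n_cols = 0
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                n_cols += 1
                if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            p = ptrE[i, j]
            n_cols += 1
            j -= 1
            if p == 1:
                state = 0
        else:
            p = ptrF[i, j]
            n_cols += 1
            i -= 1
            if p == 1:
                state = 0
    out[0] = best
    out[1] = i
    out[2] = bi
    out[3] = j
    out[4] = bj
    out[5] = n_match
    out[6] = n_cols
    return out


@njit(cache=True)
def sw_score(q, r, match, mismatch, gap_open, gap_extend):
    """Score-only affine local alignment (two rolling rows).

    Returns (best_score, q_end, r_end) with 0-based exclusive ends of the
    best-scoring cell.
    """
    m = len(q)
    n = len(r)
    NEG = -(10 ** 9)
    Hrow = np.zeros(n + 1, np.int32)   # H[i-1, :] entering the loop body
    Frow = np.full(n + 1, NEG, np.int32)  # F[i-1, :]
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qc = q[i - 1]
        hdiag = 0       # H[i-1, j-1]
        hleft = 0       # H[i, j-1]
        eleft = NEG     # E[i, j-1]
        for j in range(1, n + 1):
            e = hleft + gap_open
            ee = eleft + gap_extend
            if ee > e:
                e = ee
            f = Hrow[j] + gap_open
            fe = Frow[j] + gap_extend
            if fe > f:
                f = fe
            rc = r[j - 1]
            if qc == rc and qc < 4:
                sub = match
            else:
                sub = mismatch
            h = hdiag + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            hdiag = Hrow[j]
            Hrow[j] = h
            Frow[j] = f
            hleft = h
            eleft = e
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj
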