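"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (plain-Python Gotoh dynamic program,
direct rule application) kept separate from the package so they cannot
share code paths with what they check.
"""

from __future__ import annotations


def sw_best_score(
    q: str,
    r: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Best affine-gap local alignment score, plain-Python Gotoh.

    Gap of length L costs gap_open + (L-1)*gap_extend.
    """
    m, n = len(q), len(r)
    NEG = -(10 ** 9)
    Hp = [0] * (n + 1)
    Fp = [NEG] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        qc = q[i - 1]
        hd = 0
        hl = 0
        el = NEG
        Hc = [0] * (n + 1)
        Fc = [NEG] * (n + 1)
        for j in range(1, n + 1):
            e = max(hl + gap_open, el + gap_extend)
            f = max(Hp[j] + gap_open, Fp[j] + gap_extend)
            sub = match if (qc == r[j - 1] and qc in "ACGT") else mismatch
            h = max(0, hd + sub, e, f)
            hd = Hp[j]
            Hc[j] = h
            Fc[j] = f
            hl = h
            el = e
            if h > best:
                best = h
        Hp, Fp = Hc, Fc
    return best


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def sw_best_score_bothstrands(q: str, r: str, **kw) -> int:
    return max(sw_best_score(q, r, **kw), sw_best_score(revcomp(q), r, **kw))
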