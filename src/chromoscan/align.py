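"""Affine-gap local alignment with a k-mer seed prefilter.

The quantification in this package is defined by "fraction of reads with
a qualifying local alignment", not by any particular external mapper, so
the aligner lives in the repo: a Gotoh affine-gap Smith-Waterman kernel
(numba-compiled, see _sw.py) driven by an 11-mer seed index.  The seed
stage is lossless for any alignment that contains at least one exact
k-mer; callers that cannot tolerate even the residual seed misses use
``exhaustive=True`` to run the full dynamic program against every
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _sw
from .library import RepeatLibrary, RepeatRecord


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring: match/mismatch, affine gaps, and the
    score / alignment-length floors below which a hit is discarded."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 40
    min_aln_len: int = 20

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a query against one reference.

    Spans are 0-based half-open.  For strand '-', the query was
    reverse-complemented before alignment but q_start/q_end refer to the
    original query coordinates; reference coordinates are always on the
    forward reference.
    """

    score: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    strand: str
    n_match: int
    n_cols: int

    @property
    def identity(self) -> float:
        """Percent identical columns over all alignment columns."""
        return 100.0 * self.n_match / self.n_cols if self.n_cols else 0.0


def _run_sw(qcodes, rcodes, scheme) -> tuple | None:
    res = _sw.sw_align(
        qcodes, rcodes, scheme.match, scheme.mismatch,
        scheme.gap_open, scheme.gap_extend,
    )
    if res[0] == 0:
        return None
    return tuple(int(x) for x in res)


def _flip_q(qs: int, qe: int, qlen: int) -> tuple[int, int]:
    return qlen - qe, qlen - qs


def align_local(
    query: str,
    reference: str,
    scheme: ScoringScheme = ScoringScheme(),
    both_strands: bool = True,
) -> LocalAlignment | None:
    """Best affine-gap local alignment of query vs reference.

    Tries both query strands (unless disabled) and returns the better
    one, or None when the best score is below ``scheme.min_score`` or the
    alignment spans fewer than ``scheme.min_aln_len`` columns.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    q = _sw.encode(query)
    r = _sw.encode(reference)
    best: LocalAlignment | None = None
    strands = [("+", q)]
    if both_strands:
        strands.append(("-", _sw.revcomp_codes(q)))
    for strand, qc in strands:
        res = _run_sw(qc, r, scheme)
        if res is None:
            continue
        score, qs, qe, rs, re, nm, nc = res
        if strand == "-":
            qs, qe = _flip_q(qs, qe, len(q))
        cand = LocalAlignment(score, qs, qe, rs, re, strand, nm, nc)
        if best is None or cand.score > best.score:
            best = cand
    if best is None:
        return None
    if best.score < scheme.min_score or best.n_cols < scheme.min_aln_len:
        return None
    return best


# ---------------------------------------------------------------------------
# seed-indexed search against a reference set

class SeedIndex:
    """k-mer index over a set of reference sequences.

    Tandem records are indexed via their duplicated consensus so
    junction-spanning reads align contiguously; the caller reduces the
    resulting coordinates modulo the monomer length.
    """

    K = 11

    def __init__(
        self,
        refs: Sequence[tuple[str, str]],
        scheme: ScoringScheme = ScoringScheme(),
        k: int = K,
        window_pad: int = 15,
        diag_tol: int = 5,
        max_clusters_per_ref: int = 8,
    ):
        self.scheme = scheme
        self.k = k
        self.window_pad = window_pad
        self.diag_tol = diag_tol
        self.max_clusters_per_ref = max_clusters_per_ref
        self.names = [n for n, _ in refs]
        self.enc = [_sw.encode(s) for _, s in refs]
        self.lengths = np.array([len(e) for e in self.enc], dtype=np.int64)
        sep = np.full(k, 4, dtype=np.uint8)  # N spacer kills boundary k-mers
        chunks = []
        offsets = []
        pos = 0
        for e in self.enc:
            offsets.append(pos)
            chunks.append(e)
            chunks.append(sep)
            pos += len(e) + k
        self.offsets = np.array(offsets, dtype=np.int64)
        concat = np.concatenate(chunks) if chunks else np.empty(0, np.uint8)
        vals, valid = _sw.kmer_codes(concat, k)
        gpos = np.nonzero(valid)[0]
        vals = vals[valid]
        order = np.argsort(vals, kind="stable")
        self._codes = vals[order]
        self._gpos = gpos[order]

    def _seed_clusters(self, qcodes: np.ndarray):
        """Yield (ref_idx, dmin, dmax, support) diagonal clusters."""
        vals, valid = _sw.kmer_codes(qcodes, self.k)
        if not valid.any():
            return []
        qp = np.nonzero(valid)[0]
        vals = vals[valid]
        lo = np.searchsorted(self._codes, vals, side="left")
        hi = np.searchsorted(self._codes, vals, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return []
        gpos = np.empty(total, np.int64)
        qpos = np.empty(total, np.int64)
        at = 0
        for t in range(len(qp)):
            c = int(counts[t])
            if c:
                gpos[at:at + c] = self._gpos[lo[t]:hi[t]]
                qpos[at:at + c] = qp[t]
                at += c
        ref = np.searchsorted(self.offsets, gpos, side="right") - 1
        diag = gpos - self.offsets[ref] - qpos
        order = np.lexsort((diag, ref))
        ref = ref[order]
        diag = diag[order]
        gq = gpos[order] - self.offsets[ref]  # local ref position of seed
        clusters = []
        start = 0
        n = len(ref)
        for i in range(1, n + 1):
            new = (
                i == n
                or ref[i] != ref[i - 1]
                or diag[i] - diag[i - 1] > self.diag_tol
            )
            if new:
                clusters.append(
                    (
                        int(ref[start]),
                        int(diag[start]),
                        int(diag[i - 1]),
                        i - start,
                    )
                )
                start = i
        return clusters

    def _align_cluster(self, qcodes, ref_idx, dmin, dmax):
        e = self.enc[ref_idx]
        qlen = len(qcodes)
        ws = max(0, dmin - self.window_pad)
        we = min(len(e), dmax + qlen + self.window_pad)
        if we - ws < self.scheme.min_aln_len:
            return None
        res = _run_sw(qcodes, e[ws:we], self.scheme)
        if res is None:
            return None
        score, qs, qe, rs, re, nm, nc = res
        return score, qs, qe, rs + ws, re + ws, nm, nc

    def best_per_ref(
        self, query: str, exhaustive: bool = False, fallback: bool = True
    ) -> dict[int, LocalAlignment]:
        """Best qualifying alignment per reference index.

        With ``exhaustive=False`` (default) only seed-supported candidate
        windows are aligned; if none yields a qualifying alignment and
        ``fallback`` is on, the query is rescanned exhaustively, so a
        query is only ever called unaligned after a full scan.  Callers
        that tolerate seed misses (e.g. dense coverage profiling) disable
        the fallback for speed.
        """
        q = _sw.encode(query)
        if exhaustive:
            return self._scan_all(q)
        best: dict[int, LocalAlignment] = {}
        for strand, qc in (("+", q), ("-", _sw.revcomp_codes(q))):
            clusters = self._seed_clusters(qc)
            per_ref: dict[int, list] = {}
            for ref_idx, dmin, dmax, support in clusters:
                per_ref.setdefault(ref_idx, []).append((support, dmin, dmax))
            for ref_idx, cls in per_ref.items():
                cls.sort(reverse=True)
                for support, dmin, dmax in cls[: self.max_clusters_per_ref]:
                    res = self._align_cluster(qc, ref_idx, dmin, dmax)
                    if res is None:
                        continue
                    score, qs, qe, rs, re, nm, nc = res
                    if strand == "-":
                        qs, qe = _flip_q(qs, qe, len(q))
                    cand = LocalAlignment(score, qs, qe, rs, re, strand, nm, nc)
                    cur = best.get(ref_idx)
                    if cur is None or cand.score > cur.score:
                        best[ref_idx] = cand
        best = {
            i: a
            for i, a in best.items()
            if a.score >= self.scheme.min_score
            and a.n_cols >= self.scheme.min_aln_len
        }
        if not best and fallback:
            return self._scan_all(q)
        return best

    def _scan_all(self, q: np.ndarray) -> dict[int, LocalAlignment]:
        """Score-only scan of every reference/strand; best hit refined
        with a traceback pass on a bounded window."""
        best: dict[int, LocalAlignment] = {}
        s = self.scheme
        for ref_idx, e in enumerate(self.enc):
            top: LocalAlignment | None = None
            for strand, qc in (("+", q), ("-", _sw.revcomp_codes(q))):
                score, bi, bj = _sw.sw_score(
                    qc, e, s.match, s.mismatch, s.gap_open, s.gap_extend
                )
                if score < s.min_score:
                    continue
                ws = max(0, bj - 2 * len(qc))
                res = _run_sw(qc, e[ws:bj], s)
                if res is None:
                    continue
                sc, qs, qe, rs, re, nm, nc = res
                if strand == "-":
                    qs, qe = _flip_q(qs, qe, len(q))
                cand = LocalAlignment(sc, qs, qe, rs + ws, re + ws, strand, nm, nc)
                if top is None or cand.score > top.score:
                    top = cand
            if top is not None and top.n_cols >= s.min_aln_len:
                best[ref_idx] = top
        return best


def library_index(
    lib: RepeatLibrary, scheme: ScoringScheme = ScoringScheme(), **kw
) -> SeedIndex:
    """SeedIndex over a library; tandem consensuses are duplicated."""
    refs = []
    for rec in lib.records:
        seq = rec.seq + rec.seq if rec.is_tandem else rec.seq
        refs.append((rec.name, seq))
    return SeedIndex(refs, scheme=scheme, **kw)


# ---------------------------------------------------------------------------
# multi-hit search of one query along a contig

_MAX_EXHAUSTIVE_CELLS = 5_000_000
_OVERLAP_TOL = 10  # bp of overlap tolerated between accepted hits


def find_local_hits(
    query: str,
    contig: str,
    scheme: ScoringScheme = ScoringScheme(),
    min_identity: float = 0.0,
    overlap_tol: int = _OVERLAP_TOL,
) -> list[LocalAlignment]:
    """All non-overlapping qualifying local alignments of ``query`` along
    ``contig`` (both strands), greedily selected by descending score.

    Accepted hits may overlap by at most ``overlap_tol`` bases so that
    indel-jittered boundaries of adjacent tandem copies do not discard
    whole copies.  Queries too short to seed (shorter than the k-mer) fall
    back to exhaustive align-and-mask when the problem is small enough.
    """
    q = _sw.encode(query)
    cands: list[LocalAlignment] = []
    if len(q) >= SeedIndex.K:
        idx = SeedIndex([("contig", contig)], scheme=scheme, window_pad=20)
        e = idx.enc[0]
        for strand, qc in (("+", q), ("-", _sw.revcomp_codes(q))):
            for _ref, dmin, dmax, _sup in idx._seed_clusters(qc):
                res = idx._align_cluster(qc, 0, dmin, dmax)
                if res is None:
                    continue
                score, qs, qe, rs, re, nm, nc = res
                if strand == "-":
                    qs, qe = _flip_q(qs, qe, len(q))
                cands.append(
                    LocalAlignment(score, qs, qe, rs, re, strand, nm, nc)
                )
    else:
        cands = _exhaustive_hits(q, _sw.encode(contig), scheme)
    cands = [
        c
        for c in cands
        if c.score >= scheme.min_score
        and c.n_cols >= scheme.min_aln_len
        and c.identity >= min_identity
    ]
    cands.sort(key=lambda c: (-c.score, c.r_start))
    accepted: list[LocalAlignment] = []
    for c in cands:
        clash = False
        for a in accepted:
            ov = min(c.r_end, a.r_end) - max(c.r_start, a.r_start)
            if ov > overlap_tol:
                clash = True
                break
        if not clash:
            accepted.append(c)
    accepted.sort(key=lambda c: c.r_start)
    return accepted


def _exhaustive_hits(q, r, scheme) -> list[LocalAlignment]:
    if len(q) * len(r) > _MAX_EXHAUSTIVE_CELLS:
        raise ValueError(
            "query too short to seed and contig too long for exhaustive "
            f"search ({len(q)} x {len(r)} cells)"
        )
    hits = []
    for strand, qc in (("+", q), ("-", _sw.revcomp_codes(q))):
        work = r.copy()
        for _ in range(1000):
            res = _run_sw(qc, work, scheme)
            if res is None or res[0] < scheme.min_score:
                break
            score, qs, qe, rs, re, nm, nc = res
            if strand == "-":
                qs, qe = _flip_q(qs, qe, len(q))
            hits.append(LocalAlignment(score, qs, qe, rs, re, strand, nm, nc))
            work[rs:re] = 4  # mask and rescan
    return hits
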