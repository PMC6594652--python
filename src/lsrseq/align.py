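"""Seed-and-extend local alignment of reads against reference regions.

Candidate (region, orientation) pairs are nominated by exact k-mer seeds,
then scored with an exact affine-gap Smith-Waterman (numba kernel). A gap
of length L costs ``gap_open + L * gap_extend``. Secondary segments on the
same read are recovered by masking already-aligned read bases and
re-aligning, so a junction-spanning read yields one segment per flank.

Tie-breaking is deterministic: among equal-scoring end cells the smallest
reference coordinate wins and the segment is flagged ``multi_mapped``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .reference import PrimerPair, ReferenceRegion, reverse_complement

#: default alignment parameters; min length / identity echo the 20 bp / 90%
#: repeat criterion used for the reference dot plots
DEFAULT_PARAMS = {
    "seed_k": 12,
    "min_seg_len": 20,
    "min_identity": 0.90,
    "match": 2,
    "mismatch": -3,
    "gap_open": -5,
    "gap_extend": -2,
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_MASK = 5  # sentinel for masked read bases: matches nothing, scored as mismatch


@dataclass(frozen=True)
class AlignedSegment:
    read_id: str
    read_interval: tuple[int, int]
    region_id: str
    ref_interval: tuple[int, int]
    orientation: str  # "forward" | "reverse"
    score: int
    identity: float
    cigar: str  # over =, X, I (read insertion), D (read deletion)
    multi_mapped: bool = False

    @property
    def read_start(self) -> int:
        return self.read_interval[0]

    @property
    def read_end(self) -> int:
        return self.read_interval[1]

    @property
    def length(self) -> int:
        return self.read_interval[1] - self.read_interval[0]


def encode_dna(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


@njit(cache=True)
def _sw_fill(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    # trace flags: bits 0-1 pointer (0 stop, 1 diag, 2 up/F, 3 left/E),
    # bit 4 E opened from H, bit 5 F opened from H
    n = q.shape[0]
    m = r.shape[0]
    neg = -(10 ** 8)
    trace = np.zeros((n + 1, m + 1), np.uint8)
    h_prev = np.zeros(m + 1, np.int32)
    h_cur = np.zeros(m + 1, np.int32)
    f_col = np.full(m + 1, neg, np.int32)
    best = 0
    bi = 0
    bj = 0
    n_best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        e = neg
        h_left = 0
        h_cur[0] = 0
        for j in range(1, m + 1):
            flags = 0
            open_e = h_left + gap_open + gap_extend
            ext_e = e + gap_extend
            if open_e >= ext_e:
                e = open_e
                flags |= 16
            else:
                e = ext_e
            open_f = h_prev[j] + gap_open + gap_extend
            ext_f = f_col[j] + gap_extend
            if open_f >= ext_f:
                f_col[j] = open_f
                flags |= 32
            else:
                f_col[j] = ext_f
            if qi == r[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            diag = h_prev[j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if f_col[j] > h:
                h = f_col[j]
                p = 2
            if e > h:
                h = e
                p = 3
            trace[i, j] = flags | p
            h_cur[j] = h
            h_left = h
            if h > best:
                best = h
                bi = i
                bj = j
                n_best = 1
            elif h == best and h > 0:
                n_best += 1
                if j < bj:
                    bi = i
                    bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj, n_best, trace


def smith_waterman(
    query: str | np.ndarray, ref: str | np.ndarray, params: dict | None = None
):
    """Exact affine-gap local alignment.

    Returns ``None`` when the best score is 0, else a dict with keys
    ``score``, ``query_interval``, ``ref_interval``, ``cigar``,
    ``identity``, ``n_max_cells``.
    """
    p = dict(DEFAULT_PARAMS, **(params or {}))
    q = encode_dna(query) if isinstance(query, str) else query
    r = encode_dna(ref) if isinstance(ref, str) else ref
    if len(q) == 0 or len(r) == 0:
        return None
    score, i, j, n_max, trace = _sw_fill(
        q, r, p["match"], p["mismatch"], p["gap_open"], p["gap_extend"]
    )
    score = int(score)
    if score <= 0:
        return None
    # end cell is deterministic: max score, smallest ref coord, then row
    i, j = int(i), int(j)

    ops = []
    matches = 0
    ii, jj = i, j
    while trace[ii, jj] & 3 != 0:
        p_ = trace[ii, jj] & 3
        if p_ == 1:
            ops.append("=" if (q[ii - 1] == r[jj - 1] and q[ii - 1] < 4) else "X")
            if ops[-1] == "=":
                matches += 1
            ii -= 1
            jj -= 1
        elif p_ == 2:  # vertical: consumes query -> insertion relative to ref
            while True:
                ops.append("I")
                stop = trace[ii, jj] & 32 != 0
                ii -= 1
                if stop:
                    break
        else:  # horizontal: consumes ref -> deletion
            while True:
                ops.append("D")
                stop = trace[ii, jj] & 16 != 0
                jj -= 1
                if stop:
                    break
    ops.reverse()
    cigar = _compress_cigar(ops)
    aln_len = len(ops)
    return {
        "score": score,
        "query_interval": (ii, i),
        "ref_interval": (jj, j),
        "cigar": cigar,
        "ops": ops,
        "identity": matches / aln_len if aln_len else 0.0,
        "n_max_cells": n_max,
    }


def _split_alignment(aln: dict, params: dict):
    """Decompose one local alignment into maximal high-identity
    subsegments (the HSPs junction assembly needs).

    A junction-spanning read can yield a single best local alignment that
    crosses the joint into pseudo-homologous repeat sequence; splitting on
    sliding-window identity recovers the clean flank as its own segment.
    Yields dicts shaped like :func:`smith_waterman` results.
    """
    ops = aln["ops"]
    win = params["min_seg_len"]
    match = np.array([op == "=" for op in ops])
    q0, _ = aln["query_interval"]
    r0, _ = aln["ref_interval"]
    dq = np.cumsum([op in "=XI" for op in ops])  # query consumed through col i
    dr = np.cumsum([op in "=XD" for op in ops])
    if len(ops) >= win and aln["identity"] >= params["min_identity"]:
        # already clean: keep whole alignment intact
        yield aln
        return
    for s, e, _ident in _identity_windows_ops(match, win, params["min_identity"]):
        while s < e and ops[s] != "=":
            s += 1
        while e > s and ops[e - 1] != "=":
            e -= 1
        if e - s < win:
            continue
        seg_ops = ops[s:e]
        qs = int(q0 + (dq[s - 1] if s else 0))
        qe = int(q0 + dq[e - 1])
        rs = int(r0 + (dr[s - 1] if s else 0))
        re_ = int(r0 + dr[e - 1])
        n_match = sum(op == "=" for op in seg_ops)
        score = 0
        i = 0
        while i < len(seg_ops):
            op = seg_ops[i]
            if op == "=":
                score += params["match"]
                i += 1
            elif op == "X":
                score += params["mismatch"]
                i += 1
            else:
                j = i
                while j < len(seg_ops) and seg_ops[j] == op:
                    j += 1
                score += params["gap_open"] + (j - i) * params["gap_extend"]
                i = j
        yield {
            "score": score,
            "query_interval": (qs, qe),
            "ref_interval": (rs, re_),
            "cigar": _compress_cigar(seg_ops),
            "ops": seg_ops,
            "identity": n_match / len(seg_ops),
            "n_max_cells": aln["n_max_cells"],
        }


def _identity_windows_ops(match: np.ndarray, window: int, min_identity: float):
    n = len(match)
    if n < window:
        return
    need = int(np.ceil(min_identity * window))
    counts = np.convolve(match.astype(int), np.ones(window, dtype=int), "valid")
    ok = counts >= need
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            yield (start, i - 1 + window, counts[start:i].max() / window)
            start = None
    if start is not None:
        yield (start, len(ok) - 1 + window, counts[start:].max() / window)


def _compress_cigar(ops: list[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


class ReadAligner:
    """Aligner with per-region k-mer indexes cached across reads."""

    def __init__(self, regions, params: dict | None = None):
        self.params = dict(DEFAULT_PARAMS, **(params or {}))
        self.regions = list(regions)
        k = self.params["seed_k"]
        self._encoded = {r.region_id: encode_dna(r.sequence) for r in self.regions}
        self._kmers = {}
        for r in self.regions:
            seq = r.sequence.upper()
            self._kmers[r.region_id] = {
                seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]
            }

    def _has_seed(self, read_seq: str, region_id: str) -> bool:
        k = self.params["seed_k"]
        kmers = self._kmers[region_id]
        for i in range(len(read_seq) - k + 1):
            if read_seq[i : i + k] in kmers:
                return True
        return False

    def align(self, read_seq: str, read_id: str = "") -> list[AlignedSegment]:
        p = self.params
        read_seq = read_seq.upper()
        n = len(read_seq)
        if n < max(p["min_seg_len"], p["seed_k"]):
            return []
        min_score = int(
            p["min_seg_len"]
            * (p["min_identity"] * p["match"] + (1 - p["min_identity"]) * p["mismatch"])
        )
        rc_seq = reverse_complement(read_seq)
        segments: list[AlignedSegment] = []
        for region in self.regions:
            ref = self._encoded[region.region_id]
            for orientation, oriented in (("forward", read_seq), ("reverse", rc_seq)):
                if not self._has_seed(oriented, region.region_id):
                    continue
                q = encode_dna(oriented)
                for it in range(3):  # at most a few segments per read/region
                    aln = smith_waterman(q, ref, p)
                    if aln is None or aln["score"] < min_score:
                        break
                    if it and aln["identity"] < p["min_identity"]:
                        break  # leftover pseudo-homology only
                    for sub in _split_alignment(aln, p):
                        qs, qe = sub["query_interval"]
                        if orientation == "forward":
                            read_iv = (qs, qe)
                        else:
                            read_iv = (n - qe, n - qs)
                        seg = AlignedSegment(
                            read_id=read_id,
                            read_interval=read_iv,
                            region_id=region.region_id,
                            ref_interval=sub["ref_interval"],
                            orientation=orientation,
                            score=sub["score"],
                            identity=sub["identity"],
                            cigar=sub["cigar"],
                            multi_mapped=sub["n_max_cells"] > 1,
                        )
                        if (
                            seg.length >= p["min_seg_len"]
                            and seg.identity >= p["min_identity"]
                        ):
                            segments.append(seg)
                    q = q.copy()
                    qs, qe = aln["query_interval"]
                    q[qs:qe] = _MASK
        segments = _drop_contained(segments)
        segments.sort(key=lambda s: (s.read_interval, s.region_id, s.orientation))
        return segments


def _drop_contained(segments: list[AlignedSegment]) -> list[AlignedSegment]:
    """Drop segments whose read interval is contained in a higher-scoring
    segment's read interval (redundant placements of the same read span)."""
    kept: list[AlignedSegment] = []
    for seg in sorted(segments, key=lambda s: -s.score):
        contained = any(
            seg.read_start >= k.read_start
            and seg.read_end <= k.read_end
            and seg.score <= k.score
            and (seg.region_id != k.region_id or seg.orientation != k.orientation
                 or seg.ref_interval != k.ref_interval)
            and _overlap_frac(seg, k) >= 0.9
            for k in kept
        )
        if not contained:
            kept.append(seg)
    return kept


def _overlap_frac(a: AlignedSegment, b: AlignedSegment) -> float:
    lo = max(a.read_start, b.read_start)
    hi = min(a.read_end, b.read_end)
    return max(0, hi - lo) / max(1, a.length)


def align_read(read_seq: str, regions, params: dict | None = None, read_id: str = "") -> list[AlignedSegment]:
    """One-shot convenience wrapper around :class:`ReadAligner`."""
    return ReadAligner(regions, params).align(read_seq, read_id)


def trim_primers(
    read_seq: str, primer_pair: PrimerPair | None, max_mismatches: int = 2
) -> tuple[str, dict]:
    """Strip a terminal primer match (<= ``max_mismatches`` Hamming) from
    either end: the forward primer at the 5' end and the reverse-complement
    of the reverse primer at the 3' end."""
    flags = {"forward_trimmed": False, "reverse_trimmed": False}
    if primer_pair is None:
        return read_seq, flags
    read_seq = read_seq.upper()
    fwd = primer_pair.forward_seq
    if len(read_seq) >= len(fwd):
        mism = sum(a != b for a, b in zip(read_seq[: len(fwd)], fwd))
        if mism <= max_mismatches:
            read_seq = read_seq[len(fwd) :]
            flags["forward_trimmed"] = True
    rev = reverse_complement(primer_pair.reverse_seq)
    if len(read_seq) >= len(rev):
        tail = read_seq[-len(rev) :]
        mism = sum(a != b for a, b in zip(tail, rev))
        if mism <= max_mismatches:
            read_seq = read_seq[: -len(rev)]
            flags["reverse_trimmed"] = True
    return read_seq, flags
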