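"""Sequence-feature tracks: deaminase hotspot motifs, run-based
G-quadruplex propensity scores, and gapless direct/inverted repeats.

Motif classes
-------------
``AID_WRCY`` / ``AID_RGYW``
    4-mer deaminase hotspots, IUPAC W={A,T}, R={A,G}, Y={C,T}. A WRCY match
    on the stored strand is an RGYW site on the opposite strand and vice
    versa, so the two classes mirror under reverse complement.
``APOBEC3_TC`` / ``APOBEC3_GA``
    2-mer TC on the stored strand; GA is the opposite-strand TC.

N never matches a motif, scores 0 in the G4 track, and breaks repeat
diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import ReferenceRegion, reverse_complement

G4_WINDOW_DEFAULT = 25
G4_THRESHOLD_DEFAULT = 1.2

_IUPAC = {
    "W": set("AT"),
    "R": set("AG"),
    "Y": set("CT"),
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
}

_MOTIF_PATTERNS = {
    "AID_WRCY": "WRCY",
    "AID_RGYW": "RGYW",
    "APOBEC3_TC": "TC",
    "APOBEC3_GA": "GA",
}


@dataclass(frozen=True)
class MotifOccurrence:
    region_id: str
    interval: tuple[int, int]
    motif_class: str
    strand_spelling: str

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if hi - lo != len(_MOTIF_PATTERNS[self.motif_class]):
            raise ValueError("interval length inconsistent with motif class")


@dataclass
class G4Track:
    region_id: str
    scores: np.ndarray          # per-base run score, +G / -C
    window: int
    threshold: float
    window_means: np.ndarray    # length len(seq) - window + 1
    tracts: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, sign)


@dataclass(frozen=True)
class RepeatHit:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    orientation: str  # "direct" | "inverted"
    identity: float
    length: int


def _matches(seq: str, pos: int, pattern: str) -> bool:
    return all(seq[pos + i] in _IUPAC[p] for i, p in enumerate(pattern))


def scan_aid_hotspots(seq: str, region_id: str = "") -> list[MotifOccurrence]:
    """Report every WRCY and RGYW 4-mer; overlaps allowed, and a 4-mer
    matching both patterns yields one occurrence per class."""
    seq = seq.upper()
    out = []
    for cls in ("AID_WRCY", "AID_RGYW"):
        pattern = _MOTIF_PATTERNS[cls]
        for i in range(len(seq) - 3):
            if _matches(seq, i, pattern):
                out.append(MotifOccurrence(region_id, (i, i + 4), cls, seq[i : i + 4]))
    out.sort(key=lambda m: (m.interval, m.motif_class))
    return out


def scan_apobec3(seq: str, region_id: str = "") -> list[MotifOccurrence]:
    """Report every TC (stored strand) and GA (opposite-strand TC)."""
    seq = seq.upper()
    out = []
    for cls in ("APOBEC3_TC", "APOBEC3_GA"):
        pattern = _MOTIF_PATTERNS[cls]
        for i in range(len(seq) - 1):
            if seq[i : i + 2] == pattern:
                out.append(MotifOccurrence(region_id, (i, i + 2), cls, pattern))
    out.sort(key=lambda m: (m.interval, m.motif_class))
    return out


def g4_base_scores(seq: str) -> np.ndarray:
    """Per-base run scores: a G in a maximal run of k consecutive G
    scores +min(k, 4); a C in a run of k scores -min(k, 4); A/T/N 0."""
    seq = seq.upper()
    scores = np.zeros(len(seq), dtype=float)
    i = 0
    while i < len(seq):
        base = seq[i]
        j = i
        while j < len(seq) and seq[j] == base:
            j += 1
        if base == "G":
            scores[i:j] = min(j - i, 4)
        elif base == "C":
            scores[i:j] = -min(j - i, 4)
        i = j
    return scores


def g4hunter_scores(
    seq: str,
    window: int = G4_WINDOW_DEFAULT,
    threshold: float = G4_THRESHOLD_DEFAULT,
    region_id: str = "",
) -> G4Track:
    """Run-based G4 propensity track with sliding-window means.

    Tracts are maximal unions of overlapping windows whose |mean| >=
    ``threshold``, tagged +1 (G4 on the stored strand) or -1 (opposite
    strand).
    """
    seq = seq.upper()
    if window < 1 or window > len(seq):
        raise ValueError(f"window {window} outside [1, {len(seq)}]")
    scores = g4_base_scores(seq)
    cums = np.concatenate([[0.0], np.cumsum(scores)])
    means = (cums[window:] - cums[:-window]) / window

    tracts: list[tuple[int, int, int]] = []
    for sign in (1, -1):
        hot = sign * means >= threshold
        start = None
        for i, flag in enumerate(hot):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                tracts.append((start, i - 1 + window, sign))
                start = None
        if start is not None:
            tracts.append((start, len(hot) - 1 + window, sign))
    tracts.sort()
    return G4Track(region_id, scores, window, threshold, means, tracts)


def _identity_windows(match: np.ndarray, window: int, min_identity: float):
    """Yield merged (start, end, best_window_identity) spans of qualifying
    sliding windows on a boolean match vector."""
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


def _diagonal_hits(a: np.ndarray, b: np.ndarray, window: int, min_identity: float,
                   skip_main_diagonal: bool):
    la, lb = len(a), len(b)
    for d in range(-(la - window), lb - window + 1):
        if skip_main_diagonal and d == 0:
            continue
        a0 = max(0, -d)
        b0 = max(0, d)
        length = min(la - a0, lb - b0)
        if length < window:
            continue
        seg_a = a[a0 : a0 + length]
        seg_b = b[b0 : b0 + length]
        match = (seg_a == seg_b) & (seg_a < 4) & (seg_b < 4)
        for s, e, ident in _identity_windows(match, window, min_identity):
            yield (a0 + s, a0 + e), (b0 + s, b0 + e), float(ident), e - s


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)


def scan_repeats(
    seq_a: str,
    seq_b: str | None = None,
    window: int = 20,
    min_identity: float = 0.90,
) -> list[RepeatHit]:
    """Gapless dot-plot repeat survey.

    Reports merged spans of sliding ``window``-bp diagonal windows at
    >= ``min_identity``, in direct (seq_a vs seq_b) and inverted
    (seq_a vs revcomp(seq_b)) orientation. Self-comparison (``seq_b``
    omitted or equal to ``seq_a``) excludes the trivial main diagonal and
    reports each off-diagonal pair once (interval_a start < interval_b
    start for direct, <= for inverted).
    """
    if window < 8:
        raise ValueError("window must be >= 8")
    self_cmp = seq_b is None or seq_b == seq_a
    if seq_b is None:
        seq_b = seq_a
    a = encode(seq_a)
    b = encode(seq_b)
    b_rc = encode(reverse_complement(seq_b))
    lb = len(seq_b)

    hits: list[RepeatHit] = []
    for ia, ib, ident, length in _diagonal_hits(a, b, window, min_identity, self_cmp):
        if self_cmp and ia[0] >= ib[0]:
            continue  # mirror duplicate
        hits.append(RepeatHit(ia, ib, "direct", ident, length))
    for ia, ib_rc, ident, length in _diagonal_hits(a, b_rc, window, min_identity, False):
        ib = (lb - ib_rc[1], lb - ib_rc[0])  # back to seq_b coordinates
        if self_cmp and ia[0] > ib[0]:
            continue
        hits.append(RepeatHit(ia, ib, "inverted", ident, length))
    hits.sort(key=lambda h: (h.orientation, h.interval_a, h.interval_b))
    return hits


def region_feature_summary(
    region: ReferenceRegion,
    motifs: list[MotifOccurrence] | None = None,
    g4track: G4Track | None = None,
) -> dict:
    """Per-region counts, densities and per-strand G-richness."""
    if motifs is None:
        motifs = scan_aid_hotspots(region.sequence, region.region_id) + scan_apobec3(
            region.sequence, region.region_id
        )
    for m in motifs:
        if m.region_id and m.region_id != region.region_id:
            raise ValueError("motif does not belong to region")
    if g4track is None:
        window = min(G4_WINDOW_DEFAULT, len(region.sequence))
        g4track = g4hunter_scores(region.sequence, window=window, region_id=region.region_id)
    length = len(region.sequence)
    counts = {cls: 0 for cls in _MOTIF_PATTERNS}
    for m in motifs:
        counts[m.motif_class] += 1
    g = region.sequence.count("G")
    c = region.sequence.count("C")
    row = {
        "region_id": region.region_id,
        "length": length,
        "g_richness_stored": g / length,
        "g_richness_opposite": c / length,
        "g4_tract_count": len(g4track.tracts),
    }
    for cls, n in counts.items():
        row[f"{cls}_count"] = n
        row[f"{cls}_density"] = n / length
    return row
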