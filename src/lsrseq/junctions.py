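"""Per-read junction assembly and structure classification.

A junction-spanning read carries a donor-region flank toward its 5' end
and an acceptor-region flank toward its 3' end (optionally with an
intermediate switch-region remnant between them -> a *complex*, i.e.
post-switch, junction). The junction is classified as

``blunt``
    broken ends directly joined, no shared bases, no inserted bases;
``microhomology``
    >= 1 nt perfectly shared by both references at the joint;
``insertion``
    >= 1 nt at the joint matching neither flank.

Canonicalization: each flank is maximally extended toward the joint by
perfect matches against its own reference. Microhomology is the resulting
overlap (perfect on both references) and is assigned to *both* flanks:
``donor_break`` is the rightmost donor-matching reference position and
``acceptor_break`` the leftmost acceptor-matching one, so the joint
reconstructs as ``donor[:donor_break] + insertion +
acceptor[acceptor_break + mh_len:]``. This single fixed convention makes
deduplication keys stable; ambiguity exists only inside the
microhomology, which the convention resolves.

Only donor-forward / acceptor-forward (deletional) junctions are
accepted; inverted configurations are tallied as rejections.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import AlignedSegment, ReadAligner, trim_primers
from .reference import ReferenceSet, reverse_complement

STRUCTURES = ("blunt", "microhomology", "insertion")

REJECTION_REASONS = (
    "no_donor",
    "no_acceptor",
    "orientation_conflict",
    "chimera_ambiguous",
)


@dataclass(frozen=True)
class JunctionCall:
    read_id: str
    donor_region: str
    donor_break: int
    acceptor_region: str
    acceptor_break: int
    structure: str
    mh_len: int
    insertion_seq: str
    junction_type: str  # "direct" | "complex"
    intermediate_region: str | None = None
    intermediate_breaks: tuple[int, int] | None = None
    orientation_consistent: bool = True
    ambiguous_acceptor: bool = False

    def __post_init__(self) -> None:
        if self.structure == "blunt" and not (self.mh_len == 0 and not self.insertion_seq):
            raise ValueError("blunt requires mh_len=0 and empty insertion")
        if self.structure == "microhomology" and not (self.mh_len >= 1 and not self.insertion_seq):
            raise ValueError("microhomology requires mh_len>=1 and empty insertion")
        if self.structure == "insertion" and not (self.insertion_seq and self.mh_len == 0):
            raise ValueError("insertion requires non-empty insertion and mh_len=0")
        if self.junction_type == "complex" and self.intermediate_region is None:
            raise ValueError("complex junction requires intermediate_region")


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


def resolve_joint(
    read: str,
    left_ref: str,
    left_read_anchor: int,
    left_ref_anchor: int,
    right_ref: str,
    right_read_anchor: int,
    right_ref_anchor: int,
) -> dict:
    """Canonicalize one joint between a left (donor-side) and right
    (acceptor-side) flank.

    Anchors are exclusive-end / inclusive-start matched columns: read
    position ``left_read_anchor - 1`` matches ``left_ref[left_ref_anchor - 1]``
    and read position ``right_read_anchor`` matches
    ``right_ref[right_ref_anchor]``. Both flanks are assumed gapless on
    their diagonal near the joint.
    """
    diag_l = left_ref_anchor - left_read_anchor
    diag_r = right_ref_anchor - right_read_anchor

    # maximal perfect extension of the left flank toward 3'
    d_end = left_read_anchor
    while (
        d_end < len(read)
        and 0 <= d_end + diag_l < len(left_ref)
        and read[d_end] == left_ref[d_end + diag_l]
    ):
        d_end += 1
    # maximal perfect extension of the right flank toward 5'
    a_start = right_read_anchor
    while (
        a_start > 0
        and 0 <= a_start - 1 + diag_r < len(right_ref)
        and read[a_start - 1] == right_ref[a_start - 1 + diag_r]
    ):
        a_start -= 1

    if d_end <= a_start:
        insertion = read[d_end:a_start]
        structure = "insertion" if insertion else "blunt"
        mh_len = 0
        left_break = d_end + diag_l
        right_break = a_start + diag_r
    else:
        overlap = d_end - a_start
        # perfect run lengths into the overlap on each diagonal
        p_l = 0
        while (
            p_l < overlap
            and d_end - p_l - 1 >= 0
            and 0 <= d_end - p_l - 1 + diag_l < len(left_ref)
            and read[d_end - p_l - 1] == left_ref[d_end - p_l - 1 + diag_l]
        ):
            p_l += 1
        p_r = 0
        while (
            p_r < overlap
            and a_start + p_r < len(read)
            and 0 <= a_start + p_r + diag_r < len(right_ref)
            and read[a_start + p_r] == right_ref[a_start + p_r + diag_r]
        ):
            p_r += 1
        # maximal perfectly-shared core; with error-free flanks this is the
        # whole overlap, otherwise shrink (never both mh and insertion)
        core = min(overlap, p_l, p_r)
        mh_len = core
        insertion = ""
        left_break = d_end + diag_l
        right_break = a_start + diag_r
        if core < overlap:
            left_break = a_start + core + diag_l
            right_break = d_end - core + diag_r
            mh_len = core

    return {
        "structure": structure if d_end <= a_start else "microhomology",
        "mh_len": mh_len,
        "insertion_seq": insertion,
        "left_break": left_break,
        "right_break": right_break,
        "left_read_end": d_end,
        "right_read_start": a_start,
    }


def _major_diag(seg: AlignedSegment) -> int:
    """Diagonal (ref - read) carrying the most matched columns of the
    segment's alignment; robust when one end overran a joint via a gap."""
    import re

    diag = seg.ref_interval[0] - seg.read_interval[0]
    counts: dict[int, int] = {}
    for num, op in re.findall(r"(\d+)([=XID])", seg.cigar):
        n = int(num)
        if op == "=":
            counts[diag] = counts.get(diag, 0) + n
        elif op == "I":
            diag -= n
        elif op == "D":
            diag += n
    if not counts:
        return seg.ref_interval[0] - seg.read_interval[0]
    return max(counts.items(), key=lambda kv: kv[1])[0]


def classify_structure(
    donor_seg: AlignedSegment,
    acceptor_seg: AlignedSegment,
    read: str,
    donor_ref: str,
    acceptor_ref: str,
    left_diag: int | None = None,
    right_diag: int | None = None,
) -> dict:
    """Canonical structure of the joint between two read segments.

    Anchored on each segment's *distal* diagonal (donor 5' start,
    acceptor 3' end): a local alignment can overrun the joint into
    pseudo-homologous repeat sequence, but its distal end always sits in
    clean flank. The joint is located by maximizing donor-vs-acceptor
    match counts over every split point on those diagonals, then
    canonicalized by maximal perfect extension.
    """
    if donor_seg.orientation != acceptor_seg.orientation:
        raise ValueError("segments must share orientation")
    diag_l = (
        left_diag
        if left_diag is not None
        else donor_seg.ref_interval[0] - donor_seg.read_interval[0]
    )
    diag_r = (
        right_diag
        if right_diag is not None
        else acceptor_seg.ref_interval[1] - acceptor_seg.read_interval[1]
    )
    lo = donor_seg.read_start
    hi = acceptor_seg.read_end

    def _m(i: int, ref: str, diag: int) -> int:
        j = i + diag
        return 1 if 0 <= j < len(ref) and read[i] == ref[j] else 0

    m_d = [_m(i, donor_ref, diag_l) for i in range(lo, hi)]
    m_a = [_m(i, acceptor_ref, diag_r) for i in range(lo, hi)]
    # best split s: read[lo:s] credited to donor, read[s:hi] to acceptor
    suffix_a = [0] * (len(m_a) + 1)
    for i in range(len(m_a) - 1, -1, -1):
        suffix_a[i] = suffix_a[i + 1] + m_a[i]
    best_s, best_score, prefix_d = lo, suffix_a[0], 0
    for k in range(1, len(m_d) + 1):
        prefix_d += m_d[k - 1]
        score = prefix_d + suffix_a[k]
        if score > best_score:
            best_score, best_s = score, lo + k
    # anchor each flank on its nearest *solid* matched run (>= 4
    # consecutive matches) on its side of the split: isolated chance
    # matches inside an inserted stretch must not capture the anchor
    run = 4
    d_anchor = best_s
    while d_anchor > lo:
        k = d_anchor - lo
        if all(m_d[k - run : k]) and k >= run:
            break
        d_anchor -= 1
    a_anchor = best_s
    while a_anchor < hi:
        k = a_anchor - lo
        if all(m_a[k : k + run]) and k + run <= len(m_a):
            break
        a_anchor += 1
    return resolve_joint(
        read,
        donor_ref,
        d_anchor,
        d_anchor + diag_l,
        acceptor_ref,
        a_anchor,
        a_anchor + diag_r,
    )


def _pick_best(segments: list[AlignedSegment]) -> tuple[AlignedSegment, bool]:
    """Highest score wins; ties -> longer segment, then lexicographic
    region id. Returns (segment, had_ambiguous_tie)."""
    ranked = sorted(segments, key=lambda s: (-s.score, -s.length, s.region_id))
    best = ranked[0]
    ambiguous = (
        len(ranked) > 1
        and ranked[1].score == best.score
        and ranked[1].length == best.length
        and ranked[1].region_id != best.region_id
    )
    return best, ambiguous


def assemble_junction(
    segments: list[AlignedSegment],
    read: str,
    roles: dict[str, str],
    regions: ReferenceSet,
) -> JunctionCall | Rejection:
    """Assemble one read's segments into a junction call or a coded
    rejection (rejections are data, not errors)."""
    read_id = segments[0].read_id if segments else ""
    fwd = [s for s in segments if s.orientation == "forward"]
    donor_f = [s for s in fwd if roles.get(s.region_id) == "donor"]
    acceptor_f = [s for s in fwd if roles.get(s.region_id) == "acceptor"]

    donor_any = [s for s in segments if roles.get(s.region_id) == "donor"]
    acceptor_any = [s for s in segments if roles.get(s.region_id) == "acceptor"]
    if not donor_any:
        return Rejection(read_id, "no_donor")
    if not acceptor_any:
        return Rejection(read_id, "no_acceptor")
    if not donor_f or not acceptor_f:
        # pairs exist but not both forward on this read orientation
        return Rejection(read_id, "orientation_conflict")

    donor, _ = _pick_best(donor_f)
    acceptor, ambiguous = _pick_best(
        [s for s in acceptor_f if s.read_start >= donor.read_start] or acceptor_f
    )
    if not (donor.read_start < acceptor.read_start and donor.read_end < acceptor.read_end):
        return Rejection(read_id, "chimera_ambiguous")

    intermediates = [
        s
        for s in fwd
        if roles.get(s.region_id) == "intermediate"
        and s.read_start >= donor.read_start
        and s.read_end <= acceptor.read_end
        and s.read_start > donor.read_start
        and s.read_end < acceptor.read_end
    ]

    donor_ref = regions[donor.region_id].sequence
    acceptor_ref = regions[acceptor.region_id].sequence

    if intermediates:
        inter, _ = _pick_best(intermediates)
        inter_ref = regions[inter.region_id].sequence
        inter_diag = _major_diag(inter)
        j1 = classify_structure(
            donor, inter, read, donor_ref, inter_ref, right_diag=inter_diag
        )
        j2 = classify_structure(
            inter, acceptor, read, inter_ref, acceptor_ref, left_diag=inter_diag
        )
        return JunctionCall(
            read_id=read_id,
            donor_region=donor.region_id,
            donor_break=j1["left_break"],
            acceptor_region=acceptor.region_id,
            acceptor_break=j2["right_break"],
            structure=j1["structure"],
            mh_len=j1["mh_len"],
            insertion_seq=j1["insertion_seq"],
            junction_type="complex",
            intermediate_region=inter.region_id,
            intermediate_breaks=(j1["right_break"], j2["left_break"]),
            ambiguous_acceptor=ambiguous,
        )

    j = classify_structure(donor, acceptor, read, donor_ref, acceptor_ref)
    return JunctionCall(
        read_id=read_id,
        donor_region=donor.region_id,
        donor_break=j["left_break"],
        acceptor_region=acceptor.region_id,
        acceptor_break=j["right_break"],
        structure=j["structure"],
        mh_len=j["mh_len"],
        insertion_seq=j["insertion_seq"],
        junction_type="direct",
        ambiguous_acceptor=ambiguous,
    )


def call_junctions(
    reads,
    regions: ReferenceSet,
    params: dict | None = None,
    primer_pair=None,
) -> tuple[list[JunctionCall], Counter, int]:
    """Run trim -> align -> assemble -> classify over an iterable of
    ``(read_id, sequence)`` pairs.

    Returns accepted calls, a rejection tally, and the total read count.
    Deterministic given inputs and params.
    """
    aligner = ReadAligner(regions, params)
    roles = regions.roles()
    calls: list[JunctionCall] = []
    tally: Counter = Counter()
    n_reads = 0
    for read_id, seq in reads:
        n_reads += 1
        seq, _flags = trim_primers(seq, primer_pair)
        segments = aligner.align(seq, read_id)
        if not segments:
            tally["no_alignment"] += 1
            continue
        if all(s.orientation == "reverse" for s in segments):
            # read sequenced from the other strand: normalize and redo
            seq = reverse_complement(seq)
            segments = aligner.align(seq, read_id)
        result = assemble_junction(segments, seq, roles, regions)
        if isinstance(result, Rejection):
            tally[result.reason] += 1
        else:
            calls.append(result)
            tally["accepted"] += 1
    return calls, tally, n_reads


def verify_reconstruction(call: JunctionCall, read: str, regions: ReferenceSet,
                          window: int = 10) -> bool:
    """Check that donor[:donor_break] + insertion + acceptor[acceptor_break
    + mh_len:] reproduces the read across the junction window."""
    donor = regions[call.donor_region].sequence
    if call.junction_type == "complex":
        other = regions[call.intermediate_region].sequence
        other_from = call.intermediate_breaks[0] + call.mh_len
    else:
        other = regions[call.acceptor_region].sequence
        other_from = call.acceptor_break + call.mh_len
    probe = (
        donor[max(0, call.donor_break - window) : call.donor_break]
        + call.insertion_seq
        + other[other_from : other_from + window]
    )
    return probe in read
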