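"""Breakpoint maps, break-to-feature distances with an exact
random-break null, and junction-structure summaries.

The null is *exact*: the expected distance under uniform break placement
is the arithmetic mean of the distance-to-nearest-feature profile over
every inter-base position of the amplifiable interval (not Monte Carlo).
The null is restricted to the amplifiable interval because PCR cannot
observe breaks beyond the primers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .quantify import UniqueJunction
from .reference import ReferenceRegion


@dataclass
class BreakDistanceReport:
    region_id: str
    feature_class: str
    observed_distances: list[int]
    observed_mean: float
    expected_mean: float
    profile: np.ndarray
    statistic: float
    p_value: float
    mean_difference: float  # observed - expected


@dataclass
class StructureSummary:
    n_junctions: int
    counts: dict
    percentages: dict
    mean_mh_len: float | None
    mean_insertion_len: float | None


def distance_to_nearest(break_pos: int, occurrences: list[tuple[int, int]]) -> int:
    """0 if the break lies within or on the boundary of an occurrence,
    else the gap to the nearest interval edge."""
    if not occurrences:
        raise ValueError("no feature occurrences in region")
    best = None
    for start, end in occurrences:
        if start <= break_pos <= end:
            return 0
        d = start - break_pos if break_pos < start else break_pos - end
        if best is None or d < best:
            best = d
    return best


def distance_profile(
    occurrences: list[tuple[int, int]], interval: tuple[int, int]
) -> np.ndarray:
    """Distance to nearest feature for every inter-base break position in
    the half-open interval (positions lo..hi inclusive)."""
    lo, hi = interval
    if not occurrences:
        raise ValueError("no feature occurrences in region")
    starts = np.array([s for s, _ in occurrences])
    ends = np.array([e for _, e in occurrences])
    positions = np.arange(lo, hi + 1)
    d_left = starts[None, :] - positions[:, None]   # >0 when break left of start
    d_right = positions[:, None] - ends[None, :]    # >0 when break right of end
    d = np.maximum(np.maximum(d_left, d_right), 0).min(axis=1)
    return d


def expected_random_distance(
    region: ReferenceRegion | None,
    occurrences: list[tuple[int, int]],
    interval: tuple[int, int] | None = None,
) -> tuple[float, np.ndarray]:
    """Exact mean distance to the nearest feature for a uniformly placed
    break, plus the per-position profile it averages."""
    if interval is None:
        if region is None:
            raise ValueError("need a region or an explicit interval")
        interval = region.amplifiable_interval
    if region is not None:
        lo, hi = interval
        if not (0 <= lo <= hi <= len(region.sequence)):
            raise ValueError("interval outside region")
    profile = distance_profile(occurrences, interval)
    return float(profile.mean()), profile


def compare_observed_vs_null(
    observed: list[int], profile: np.ndarray
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U of observed distances against the
    per-position null profile; also reports the mean difference."""
    observed = np.asarray(observed, dtype=float)
    if len(observed) == 0:
        raise ValueError("no observed distances")
    stat, p = stats.mannwhitneyu(observed, profile, alternative="two-sided")
    return float(stat), float(p), float(observed.mean() - profile.mean())


def break_distance_report(
    region: ReferenceRegion,
    feature_class: str,
    occurrences: list[tuple[int, int]],
    breaks: list[int],
    interval: tuple[int, int] | None = None,
) -> BreakDistanceReport:
    expected, profile = expected_random_distance(region, occurrences, interval)
    observed = [distance_to_nearest(b, occurrences) for b in breaks]
    stat, p, diff = compare_observed_vs_null(observed, profile)
    return BreakDistanceReport(
        region_id=region.region_id,
        feature_class=feature_class,
        observed_distances=observed,
        observed_mean=float(np.mean(observed)),
        expected_mean=expected,
        profile=profile,
        statistic=stat,
        p_value=p,
        mean_difference=diff,
    )


def summarize_structures(uniques: list[UniqueJunction]) -> StructureSummary:
    """Blunt / microhomology / insertion counts, percentages (sum to 100),
    and subclass means. Means are None when the subclass is empty."""
    counts = {"blunt": 0, "microhomology": 0, "insertion": 0}
    mh_lens: list[int] = []
    ins_lens: list[int] = []
    for u in uniques:
        counts[u.structure] += 1
        if u.structure == "microhomology":
            mh_lens.append(u.mh_len)
        elif u.structure == "insertion":
            ins_lens.append(len(u.insertion_seq))
    n = len(uniques)
    percentages = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
    return StructureSummary(
        n_junctions=n,
        counts=counts,
        percentages=percentages,
        mean_mh_len=float(np.mean(mh_lens)) if mh_lens else None,
        mean_insertion_len=float(np.mean(ins_lens)) if ins_lens else None,
    )


def chi_square_structures(
    a: StructureSummary, b: StructureSummary
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on the structure-class
    x sample count table. Falls back to a 2x2 Fisher exact test when a
    class margin is empty."""
    classes = [
        c for c in ("blunt", "microhomology", "insertion")
        if a.counts[c] + b.counts[c] > 0
    ]
    table = np.array([[a.counts[c] for c in classes], [b.counts[c] for c in classes]])
    if len(classes) < 2:
        raise ValueError("need at least two populated structure classes")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("each sample needs at least one junction")
    if len(classes) == 2 and (table < 1).any():
        _, p = stats.fisher_exact(table)
        return float("nan"), 1, float(p)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def breakpoint_map(
    uniques: list[UniqueJunction],
    regions,
    bin_width: int = 50,
) -> dict:
    """Binned break-position histograms per region plus a 2D donor-break x
    acceptor-break count matrix per acceptor region. Plain counts; any log
    scaling is a rendering concern."""
    per_region: dict[str, np.ndarray] = {}
    edges: dict[str, np.ndarray] = {}
    for region in regions:
        bins = np.arange(0, len(region.sequence) + bin_width, bin_width)
        edges[region.region_id] = bins
        per_region[region.region_id] = np.zeros(len(bins) - 1, dtype=int)

    def _add(region_id: str, pos: int) -> None:
        if region_id in per_region:
            idx = min(pos // bin_width, len(per_region[region_id]) - 1)
            per_region[region_id][idx] += 1

    pair_counts: dict[str, np.ndarray] = {}
    donor_id = next(r.region_id for r in regions if r.role == "donor")
    n_donor_bins = len(per_region[donor_id])
    for u in uniques:
        _add(u.donor_region, u.donor_break)
        _add(u.acceptor_region, u.acceptor_break)
        if u.acceptor_region not in pair_counts:
            pair_counts[u.acceptor_region] = np.zeros(
                (n_donor_bins, len(per_region[u.acceptor_region])), dtype=int
            )
        di = min(u.donor_break // bin_width, n_donor_bins - 1)
        ai = min(u.acceptor_break // bin_width, pair_counts[u.acceptor_region].shape[1] - 1)
        pair_counts[u.acceptor_region][di, ai] += 1
    return {
        "bin_width": bin_width,
        "bin_edges": edges,
        "histograms": per_region,
        "donor_acceptor_counts": pair_counts,
    }
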