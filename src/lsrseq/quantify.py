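"""Unique-junction deduplication and per-million semi-quantification.

Uniqueness is defined on junction coordinates plus inserted sequence, not
on the raw read string, so redundant reads differing only by sequencing
error outside the joint collapse to one unique junction. The per-million
denominator is the total number of reads entering the caller (pre-filter);
``junction_reads_denominator=True`` switches to accepted junction reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .junctions import JunctionCall

JunctionKey = tuple


def junction_key(call: JunctionCall) -> JunctionKey:
    return (
        call.donor_region,
        call.donor_break,
        call.acceptor_region,
        call.acceptor_break,
        call.insertion_seq,
        call.junction_type,
        call.intermediate_region,
    )


@dataclass
class UniqueJunction:
    key: JunctionKey
    read_count: int
    structure: str
    mh_len: int

    @property
    def donor_region(self) -> str:
        return self.key[0]

    @property
    def donor_break(self) -> int:
        return self.key[1]

    @property
    def acceptor_region(self) -> str:
        return self.key[2]

    @property
    def acceptor_break(self) -> int:
        return self.key[3]

    @property
    def insertion_seq(self) -> str:
        return self.key[4]

    @property
    def junction_type(self) -> str:
        return self.key[5]

    @property
    def intermediate_region(self) -> str | None:
        return self.key[6]


@dataclass
class SampleQuant:
    sample_id: str
    total_reads: int
    unique_junction_count: int
    junctions_per_million: float
    per_acceptor: dict = field(default_factory=dict)
    complex_fraction: float = 0.0


def dedupe(calls: list[JunctionCall]) -> list[UniqueJunction]:
    """Group calls by junction key; read counts are conserved and output
    order is the sorted key order (deterministic)."""
    groups: dict[JunctionKey, list[JunctionCall]] = defaultdict(list)
    for call in calls:
        groups[junction_key(call)].append(call)
    out = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        members = groups[key]
        out.append(
            UniqueJunction(
                key=key,
                read_count=len(members),
                structure=members[0].structure,
                mh_len=members[0].mh_len,
            )
        )
    return out


def per_million(unique_count: int, total_reads: int) -> float:
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    return unique_count / total_reads * 1e6


def quantify_sample(
    sample_id: str,
    uniques: list[UniqueJunction],
    total_reads: int,
) -> SampleQuant:
    per_acceptor: dict[str, int] = defaultdict(int)
    n_complex = 0
    for u in uniques:
        per_acceptor[u.acceptor_region] += 1
        if u.junction_type == "complex":
            n_complex += 1
    n = len(uniques)
    return SampleQuant(
        sample_id=sample_id,
        total_reads=total_reads,
        unique_junction_count=n,
        junctions_per_million=per_million(n, total_reads),
        per_acceptor=dict(sorted(per_acceptor.items())),
        complex_fraction=(n_complex / n) if n else 0.0,
    )


def merge_primer_libraries(
    libraries: dict[str, list[UniqueJunction]],
    total_reads: int,
    sample_id: str = "merged",
) -> tuple[list[UniqueJunction], SampleQuant, dict]:
    """Union of unique junctions across per-primer amplicon libraries.

    A key present in several libraries counts once with read counts
    summed; provenance (which libraries saw each key) is returned.
    """
    merged: dict[JunctionKey, UniqueJunction] = {}
    provenance: dict[JunctionKey, list[str]] = defaultdict(list)
    for lib_name in sorted(libraries):
        for u in libraries[lib_name]:
            provenance[u.key].append(lib_name)
            if u.key in merged:
                merged[u.key].read_count += u.read_count
            else:
                merged[u.key] = UniqueJunction(u.key, u.read_count, u.structure, u.mh_len)
    uniques = [merged[k] for k in sorted(merged, key=lambda k: tuple(str(x) for x in k))]
    quant = quantify_sample(sample_id, uniques, total_reads)
    return uniques, quant, dict(provenance)


def dilution_response(
    calls: list[JunctionCall],
    total_reads: int,
    fractions: list[float],
    seed: int,
) -> list[dict]:
    """Binomially thin junction-bearing reads at each dilution fraction
    against a constant background read count, recomputing per-million.

    Per-million is monotone non-increasing in expectation as the fraction
    decreases (the semi-quantitativity property).
    """
    rng = np.random.default_rng(seed)
    background = total_reads - len(calls)
    if background < 0:
        raise ValueError("total_reads smaller than number of junction reads")
    rows = []
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
        keep = rng.random(len(calls)) < frac if frac < 1.0 else np.ones(len(calls), bool)
        kept = [c for c, k in zip(calls, keep) if k]
        uniques = dedupe(kept)
        total = background + len(kept)
        rows.append(
            {
                "fraction": frac,
                "junction_reads": len(kept),
                "unique_junctions": len(uniques),
                "total_reads": total,
                "per_million": per_million(len(uniques), total) if total else 0.0,
            }
        )
    return rows
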