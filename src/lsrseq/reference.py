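"""Reference segments and coordinate conventions.

All coordinates downstream are 0-based, half-open. A *break* is an
inter-base position in ``[0, len(sequence)]``. Regions are stored in the
transcriptional orientation of the IgH constant genes; strand-aware scans
handle the opposite strand explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ROLES = ("donor", "acceptor", "intermediate")


class ConfigError(ValueError):
    """Fatal problem in the reference FASTA / manifest pair."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement ``seq`` over {A,C,G,T,N}.

    Raises ``ValueError`` on any other character. Involution:
    ``reverse_complement(reverse_complement(s)) == s``.
    """
    seq = seq.upper()
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceRegion:
    """A named reference segment against which reads are aligned."""

    region_id: str
    sequence: str
    role: str
    genomic_offset: int = 0
    locus_label: str = ""
    #: half-open interval of positions reachable by the primer pair in use
    amplifiable_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ConfigError(f"region {self.region_id!r}: empty sequence")
        if not set(self.sequence) <= DNA_ALPHABET:
            raise ConfigError(
                f"region {self.region_id!r}: non-DNA characters in sequence"
            )
        if self.role not in ROLES:
            raise ConfigError(
                f"region {self.region_id!r}: role {self.role!r} not in {ROLES}"
            )
        if self.amplifiable_interval is None:
            object.__setattr__(
                self, "amplifiable_interval", (0, len(self.sequence))
            )
        lo, hi = self.amplifiable_interval
        if not (0 <= lo < hi <= len(self.sequence)):
            raise ConfigError(
                f"region {self.region_id!r}: amplifiable_interval {self.amplifiable_interval}"
                f" outside [0, {len(self.sequence)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A nested-PCR primer pair; reverse primer is spelled 5'->3' on the
    strand it anneals to (i.e. the bottom strand of the amplicon)."""

    forward_seq: str
    reverse_seq: str
    forward_region: str = ""
    reverse_region: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if len(seq) < 15:
                raise ConfigError(f"{label} primer {seq!r} shorter than 15 nt")
            if not set(seq.upper()) <= DNA_ALPHABET:
                raise ConfigError(f"{label} primer {seq!r} not DNA")
        object.__setattr__(self, "forward_seq", self.forward_seq.upper())
        object.__setattr__(self, "reverse_seq", self.reverse_seq.upper())


class ReferenceSet:
    """Validated, ordered collection of :class:`ReferenceRegion`."""

    def __init__(self, regions: Iterable[ReferenceRegion], require_single_donor: bool = True):
        self._regions: dict[str, ReferenceRegion] = {}
        for region in regions:
            if region.region_id in self._regions:
                raise ConfigError(f"duplicate region id {region.region_id!r}")
            self._regions[region.region_id] = region
        if require_single_donor:
            donors = [r for r in self if r.role == "donor"]
            if len(donors) != 1:
                raise ConfigError(
                    f"expected exactly one donor region, found {len(donors)}"
                )

    def __iter__(self) -> Iterator[ReferenceRegion]:
        return iter(self._regions.values())

    def __len__(self) -> int:
        return len(self._regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._regions

    def __getitem__(self, region_id: str) -> ReferenceRegion:
        return self._regions[region_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def donor(self) -> ReferenceRegion:
        return next(r for r in self if r.role == "donor")

    def by_role(self, role: str) -> list[ReferenceRegion]:
        return [r for r in self if r.role == role]

    def roles(self) -> dict[str, str]:
        return {r.region_id: r.role for r in self}


def load_regions(
    fasta_path: str | Path,
    manifest: str | Path | Mapping,
    require_single_donor: bool = True,
) -> ReferenceSet:
    """Load reference regions from a FASTA plus a YAML/dict manifest.

    The manifest maps ``region_id -> {role, offset?, locus?, interval?}``
    either at top level or under a ``regions`` key. Every manifest id must
    be present in the FASTA; FASTA records absent from the manifest are
    ignored. Sequences are uppercased; N is allowed.
    """
    if not isinstance(manifest, Mapping):
        with open(manifest) as handle:
            manifest = yaml.safe_load(handle)
    spec = manifest.get("regions", manifest)

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ConfigError(f"duplicate FASTA record id {rec.id!r}")
        records[rec.id] = str(rec.seq)

    regions = []
    for region_id, meta in spec.items():
        if region_id not in records:
            raise ConfigError(f"manifest region {region_id!r} absent from FASTA")
        interval = meta.get("interval")
        regions.append(
            ReferenceRegion(
                region_id=region_id,
                sequence=records[region_id],
                role=meta["role"],
                genomic_offset=int(meta.get("offset", 0)),
                locus_label=str(meta.get("locus", "")),
                amplifiable_interval=tuple(interval) if interval else None,
            )
        )
    return ReferenceSet(regions, require_single_donor=require_single_donor)


def load_primers(manifest: str | Path | Mapping) -> list[PrimerPair]:
    """Read primer pairs from the ``primers`` list of a manifest."""
    if not isinstance(manifest, Mapping):
        with open(manifest) as handle:
            manifest = yaml.safe_load(handle)
    out = []
    for entry in manifest.get("primers", []):
        out.append(
            PrimerPair(
                forward_seq=entry["forward_seq"],
                reverse_seq=entry["reverse_seq"],
                forward_region=entry.get("forward_region", ""),
                reverse_region=entry.get("reverse_region", ""),
                name=entry.get("name", ""),
            )
        )
    return out


def write_regions(
    regions: ReferenceSet, fasta_path: str | Path, manifest_path: str | Path
) -> None:
    """Write a ReferenceSet back to FASTA + YAML so it round-trips."""
    with open(fasta_path, "w") as fa:
        for r in regions:
            fa.write(f">{r.region_id}\n")
            for i in range(0, len(r.sequence), 70):
                fa.write(r.sequence[i : i + 70] + "\n")
    spec = {
        r.region_id: {
            "role": r.role,
            "offset": r.genomic_offset,
            "locus": r.locus_label,
            "interval": list(r.amplifiable_interval),
        }
        for r in regions
    }
    with open(manifest_path, "w") as mh:
        yaml.safe_dump({"regions": spec}, mh, sort_keys=False)
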