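"""Synthetic-data engine: switch-like reference fixtures and
junction-bearing amplicon reads with a known truth table.

Every emitted truth record stores the *canonical* junction description
(the same maximal-perfect-extension convention the caller uses), derived
from the clean read before sequencing error is applied, so end-to-end
recovery can be asserted exactly.

The error model is substitution-only by default (homopolymer indels of
the sequencing chemistry are out of scope); an optional indel rate exists
for robustness experiments. Identical configs (same seed) regenerate
byte-identical read sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .junctions import resolve_joint
from .motifs import scan_aid_hotspots
from .reference import PrimerPair, ReferenceRegion, ReferenceSet, reverse_complement

_BASES = np.array(list("ACGT"))

#: length-distribution means follow reported junction repertoires
#: (microhomology ~4 bp, insertions ~5 bp); realism defaults only, never
#: asserted as outputs.
DEFAULT_MIX = {"blunt": 0.3, "microhomology": 0.5, "insertion": 0.2}


@dataclass
class SimConfig:
    seed: int = 0
    read_length: int = 200
    n_junctions: int = 100
    structure_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    mh_mean: float = 4.1
    mh_max: int = 8
    insertion_mean: float = 4.9
    insertion_max: int = 15
    complex_fraction: float = 0.0
    break_mode: str = "uniform"  # "uniform" | "motif_targeted"
    motif_sigma: float = 3.0
    clone_mean: float = 1.0
    error_rate: float = 0.0
    indel_rate: float = 0.0
    background_fraction: float = 0.0
    min_flank: int = 30
    primer_pair: PrimerPair | None = None

    def __post_init__(self) -> None:
        total = sum(self.structure_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"structure_mix fractions sum to {total}, not 1")
        if self.break_mode not in ("uniform", "motif_targeted"):
            raise ValueError(f"unknown break_mode {self.break_mode!r}")
        for name in ("read_length", "n_junctions", "mh_max", "insertion_max", "min_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        primer = raw.pop("primer_pair", None)
        cfg = cls(**raw)
        if primer:
            cfg.primer_pair = PrimerPair(**primer)
        return cfg


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    clone_id: int
    donor_region: str
    donor_break: int
    acceptor_region: str
    acceptor_break: int
    structure: str
    mh_len: int
    insertion_seq: str
    junction_type: str
    intermediate_region: str | None = None
    intermediate_breaks: tuple[int, int] | None = None


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_switch_like_region(
    length: int,
    repeat_unit: str = "GAGCTGGGGT",
    seed: int = 0,
    region_id: str = "LS",
    role: str = "acceptor",
    divergence: float = 0.02,
    flank: int = 50,
) -> ReferenceRegion:
    """Tandem copies of a hotspot-bearing repeat unit with seeded point
    divergence, flanked by random sequence. Defaults give 0.5-2 kb
    repetitive stretches resembling switch-region DNA."""
    rng = np.random.default_rng(seed)
    core_len = max(0, length - 2 * flank)
    n_copies = -(-core_len // len(repeat_unit))
    core = list((repeat_unit * n_copies)[:core_len])
    for i in range(len(core)):
        if rng.random() < divergence:
            core[i] = str(rng.choice([b for b in "ACGT" if b != core[i]]))
    seq = random_dna(rng, flank) + "".join(core) + random_dna(rng, flank)
    seq = seq[:length]
    return ReferenceRegion(
        region_id=region_id,
        sequence=seq,
        role=role,
        locus_label=f"synthetic switch-like ({repeat_unit})",
    )


def default_reference_set(seed: int = 0) -> ReferenceSet:
    """A desk-scale donor + two acceptor windows + one intermediate."""
    return ReferenceSet(
        [
            make_switch_like_region(
                1200, "GAGCTGAGCTGGGGTGAGCT", seed, "Smu", "donor", 0.12
            ),
            make_switch_like_region(
                900, "GGGCTGGAATGAGCTGGGTC", seed + 1, "RR1_hs4", "acceptor", 0.10
            ),
            make_switch_like_region(
                900, "GGAGCTAGGCTGAGGGTTGA", seed + 2, "RR2_hs4", "acceptor", 0.10
            ),
            make_switch_like_region(
                700, "GGGTAGCTAAGGTTGGGCAT", seed + 3, "Sg1", "intermediate", 0.08
            ),
        ]
    )


def _draw_truncated_geometric(rng, mean: float, max_val: int) -> int:
    p = min(1.0, 1.0 / max(mean, 1.0))
    val = int(rng.geometric(p))
    return min(val, max_val)


def _motif_edges(region: ReferenceRegion) -> np.ndarray:
    occ = scan_aid_hotspots(region.sequence, region.region_id)
    if not occ:
        return np.array([], dtype=int)
    return np.array(sorted({m.interval[0] for m in occ}), dtype=int)


class _BreakSampler:
    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self._edges: dict[str, np.ndarray] = {}

    def sample(self, region: ReferenceRegion, lo: int, hi: int) -> int:
        """Break position in [lo, hi] per the configured placement mode."""
        if hi < lo:
            raise ValueError("empty break window")
        if self.cfg.break_mode == "uniform":
            return int(self.rng.integers(lo, hi + 1))
        if region.region_id not in self._edges:
            self._edges[region.region_id] = _motif_edges(region)
        edges = self._edges[region.region_id]
        edges = edges[(edges >= lo) & (edges <= hi)]
        if len(edges) == 0:
            return int(self.rng.integers(lo, hi + 1))
        center = int(self.rng.choice(edges))
        offset = int(round(self.rng.normal(0.0, self.cfg.motif_sigma)))
        return int(np.clip(center + offset, lo, hi))


def _apply_errors(seq: str, rng: np.random.Generator, cfg: SimConfig) -> str:
    chars = list(seq)
    if cfg.error_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < cfg.error_rate)[0]
        for i in hits:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    if cfg.indel_rate > 0:
        out = []
        for c in chars:
            r = rng.random()
            if r < cfg.indel_rate / 2:
                continue  # deletion
            out.append(c)
            if cfg.indel_rate / 2 <= r < cfg.indel_rate:
                out.append(str(rng.choice(list("ACGT"))))
        chars = out
    return "".join(chars)


def _build_direct(
    cfg: SimConfig,
    rng: np.random.Generator,
    sampler: _BreakSampler,
    donor: ReferenceRegion,
    acceptor: ReferenceRegion,
    structure: str,
):
    """One clean junction read plus its canonical description, or None
    when the draw cannot be realized (caller retries)."""
    dlo, dhi = donor.amplifiable_interval
    alo, ahi = acceptor.amplifiable_interval
    payload = cfg.read_length
    if cfg.primer_pair is not None:
        payload -= len(cfg.primer_pair.forward_seq) + len(cfg.primer_pair.reverse_seq)
    min_flank = cfg.min_flank

    bd = sampler.sample(donor, dlo + min_flank, dhi)
    insertion = ""
    mh = 0
    if structure == "microhomology":
        mh = _draw_truncated_geometric(rng, cfg.mh_mean, cfg.mh_max)
        target_ab = sampler.sample(acceptor, alo + mh, ahi - min_flank)
        motif = donor.sequence[bd - mh : bd]
        acc = acceptor.sequence
        while mh >= 1:
            motif = donor.sequence[bd - mh : bd]
            candidates = [
                q + mh
                for q in _find_all(acc, motif, alo, ahi - min_flank - mh)
            ]
            if candidates:
                ab = min(candidates, key=lambda q: abs(q - target_ab))
                break
            mh -= 1
        else:
            return None
    elif structure == "insertion":
        ins_len = _draw_truncated_geometric(rng, cfg.insertion_mean, cfg.insertion_max)
        insertion = random_dna(rng, ins_len)
        ab = sampler.sample(acceptor, alo, ahi - min_flank)
    else:
        ab = sampler.sample(acceptor, alo, ahi - min_flank)

    max_df = payload - min_flank - len(insertion)
    if max_df < min_flank:
        return None
    df = int(rng.integers(min_flank, min(max_df, bd - dlo) + 1))
    af = payload - df - len(insertion)
    af = min(af, len(acceptor.sequence) - ab)
    if af < min_flank:
        return None
    read = donor.sequence[bd - df : bd] + insertion + acceptor.sequence[ab : ab + af]
    if not _unique_at(donor.sequence, read[:df], bd - df):
        return None
    if not _unique_at(acceptor.sequence, acceptor.sequence[ab : ab + af], ab):
        return None

    joint = resolve_joint(
        read, donor.sequence, df, bd, acceptor.sequence, df + len(insertion), ab
    )
    if joint["structure"] != structure:
        return None
    truth = {
        "donor_region": donor.region_id,
        "donor_break": joint["left_break"],
        "acceptor_region": acceptor.region_id,
        "acceptor_break": joint["right_break"],
        "structure": joint["structure"],
        "mh_len": joint["mh_len"],
        "insertion_seq": joint["insertion_seq"],
        "junction_type": "direct",
        "intermediate_region": None,
        "intermediate_breaks": None,
    }
    return read, truth


def _unique_at(seq: str, sub: str, pos: int, slack: int = 3) -> bool:
    """True when ``sub`` matches ``seq`` exactly at ``pos`` and every
    other placement has > ``slack`` mismatches.

    Junction flanks are required to place essentially uniquely in their
    reference so the canonical breakpoints of the truth table are well
    defined even in repetitive regions; near-duplicate placements could
    outscore the true one once extension across the joint is counted.
    Draws violating this are rejected and retried."""
    a = np.frombuffer(seq.encode(), np.uint8)
    s = np.frombuffer(sub.encode(), np.uint8)
    if len(s) == 0 or len(a) < len(s):
        return False
    windows = np.lib.stride_tricks.sliding_window_view(a, len(s))
    mism = (windows != s).sum(axis=1)
    if mism[pos] != 0:
        return False
    mism[pos] = len(s)
    return int(mism.min()) > slack


def _find_all(seq: str, motif: str, lo: int, hi: int) -> list[int]:
    """Start positions of motif occurrences with start in [lo, hi]."""
    out = []
    pos = seq.find(motif, lo)
    while pos != -1 and pos <= hi:
        out.append(pos)
        pos = seq.find(motif, pos + 1)
    return out


def _build_complex(
    cfg: SimConfig,
    rng: np.random.Generator,
    sampler: _BreakSampler,
    donor: ReferenceRegion,
    intermediate: ReferenceRegion,
    acceptor: ReferenceRegion,
):
    """Donor + intermediate remnant + acceptor with blunt joints."""
    dlo, dhi = donor.amplifiable_interval
    ilo, ihi = intermediate.amplifiable_interval
    alo, ahi = acceptor.amplifiable_interval
    payload = cfg.read_length
    if cfg.primer_pair is not None:
        payload -= len(cfg.primer_pair.forward_seq) + len(cfg.primer_pair.reverse_seq)
    min_flank = cfg.min_flank

    bd = sampler.sample(donor, dlo + min_flank, dhi)
    remnant_len = int(rng.integers(40, 81))
    if ihi - ilo <= remnant_len:
        return None
    ib1 = int(rng.integers(ilo, ihi - remnant_len))
    ib2 = ib1 + remnant_len
    ab = sampler.sample(acceptor, alo, ahi - min_flank)

    max_df = payload - min_flank - remnant_len
    if max_df < min_flank:
        return None
    df = int(rng.integers(min_flank, min(max_df, bd - dlo) + 1))
    af = payload - df - remnant_len
    af = min(af, len(acceptor.sequence) - ab)
    if af < min_flank:
        return None
    read = (
        donor.sequence[bd - df : bd]
        + intermediate.sequence[ib1:ib2]
        + acceptor.sequence[ab : ab + af]
    )
    if not _unique_at(donor.sequence, read[:df], bd - df):
        return None
    if not _unique_at(intermediate.sequence, intermediate.sequence[ib1:ib2], ib1):
        return None
    if not _unique_at(acceptor.sequence, acceptor.sequence[ab : ab + af], ab):
        return None
    j1 = resolve_joint(read, donor.sequence, df, bd, intermediate.sequence, df, ib1)
    j2 = resolve_joint(
        read,
        intermediate.sequence,
        df + remnant_len,
        ib2,
        acceptor.sequence,
        df + remnant_len,
        ab,
    )
    if j1["structure"] != "blunt" or j2["structure"] != "blunt":
        return None
    truth = {
        "donor_region": donor.region_id,
        "donor_break": j1["left_break"],
        "acceptor_region": acceptor.region_id,
        "acceptor_break": j2["right_break"],
        "structure": "blunt",
        "mh_len": 0,
        "insertion_seq": "",
        "junction_type": "complex",
        "intermediate_region": intermediate.region_id,
        "intermediate_breaks": (j1["right_break"], j2["left_break"]),
    }
    return read, truth


def simulate_reads(
    config: SimConfig, regions: ReferenceSet
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Generate amplicon reads plus their truth table.

    Returns ``([(read_id, sequence), ...], [TruthRecord, ...])``; reads
    are shuffled with background reads. Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    sampler = _BreakSampler(config, rng)
    donor = regions.donor
    acceptors = regions.by_role("acceptor")
    intermediates = regions.by_role("intermediate")
    if not acceptors:
        raise ValueError("need at least one acceptor region")

    classes = sorted(config.structure_mix)
    probs = np.array([config.structure_mix[c] for c in classes])

    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    for idx in range(config.n_junctions):
        acceptor = acceptors[int(rng.integers(len(acceptors)))]
        is_complex = (
            bool(intermediates) and rng.random() < config.complex_fraction
        )
        built = None
        for _attempt in range(60):
            if is_complex:
                inter = intermediates[int(rng.integers(len(intermediates)))]
                built = _build_complex(config, rng, sampler, donor, inter, acceptor)
            else:
                structure = str(rng.choice(classes, p=probs))
                built = _build_direct(config, rng, sampler, donor, acceptor, structure)
            if built is not None:
                break
        if built is None:
            raise RuntimeError("could not realize a junction draw; check config")
        clean_read, t = built
        if config.primer_pair is not None:
            clean_read = (
                config.primer_pair.forward_seq
                + clean_read
                + reverse_complement(config.primer_pair.reverse_seq)
            )
        n_copies = (
            int(rng.geometric(min(1.0, 1.0 / config.clone_mean)))
            if config.clone_mean > 1
            else 1
        )
        for copy in range(n_copies):
            read_id = f"j{idx:05d}_c{copy}"
            seq = _apply_errors(clean_read, rng, config)
            reads.append((read_id, seq))
            truth.append(TruthRecord(read_id=read_id, clone_id=idx, **t))

    bf = config.background_fraction
    n_bg = int(round(bf / (1.0 - bf) * len(reads))) if bf > 0 else 0
    for i in range(n_bg):
        reads.append((f"bg{i:05d}", random_dna(rng, config.read_length)))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, truth


def simulate_dilution_series(
    config: SimConfig, regions: ReferenceSet, fractions: list[float]
) -> list[dict]:
    """Thin junction reads of one master sample at each fraction against a
    constant total read count (dropped junction reads are replaced by
    background reads). Seeds derive deterministically from the master."""
    reads, truth = simulate_reads(config, regions)
    truth_by_id = {t.read_id: t for t in truth}
    junction_reads = [r for r in reads if r[0] in truth_by_id]
    background = [r for r in reads if r[0] not in truth_by_id]
    out = []
    for i, frac in enumerate(fractions):
        rng = np.random.default_rng((config.seed + 1) * 100_003 + i)
        keep = rng.random(len(junction_reads)) < frac
        kept = [r for r, k in zip(junction_reads, keep) if k]
        n_pad = len(junction_reads) - len(kept)
        pad = [
            (f"pad{i}_{j:05d}", random_dna(rng, config.read_length))
            for j in range(n_pad)
        ]
        sample_reads = kept + background + pad
        order = rng.permutation(len(sample_reads))
        out.append(
            {
                "fraction": frac,
                "reads": [sample_reads[k] for k in order],
                "truth": [truth_by_id[r[0]] for r in kept],
            }
        )
    return out
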