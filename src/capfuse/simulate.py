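"""Synthetic capture-sequencing data with machine-readable truth.

Emulates the assay the caller is built for: random toy chromosomes with
centromeres and capture target regions, derivative chromosomes built
from junction specifications (optionally with engineered microhomology
or untemplated insertions), and paired-end reads with a unimodal
(truncated-normal) insert-size distribution enriched around the targets.

Defaults mirror the study conditions: 100 bp paired reads from 350-400 bp
library fragments (insert mean 375 bp, SD 35 bp) at 30-fold target
coverage.  Capture is modeled as pair-level rejection sampling -- a
fragment is kept when it overlaps a target interval (padded by
``capture_margin``) on its source molecule -- which is sufficient to
create the on-target pile-up the caller consumes; probe hybridization
chemistry is not modeled.  All randomness flows from the mandatory seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .rearrange import (Breakend, GenomeModel, Junction, Segment, canonical,
                        derivative_sequence, junction_segments,
                        normalize_junction, revcomp)

__all__ = ["SimulationConfig", "TruthSet", "DerivativeRecord",
           "make_toy_genome", "apply_junctions", "simulate_reads",
           "preset_scenario", "SCENARIOS"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Knobs of the read simulator; rates are probabilities in [0, 1]."""

    seed: int
    read_len: int = 100
    insert_mean: float = 375.0
    insert_sd: float = 35.0
    depth: float = 30.0
    base_error_rate: float = 0.002
    capture_margin: int = 200
    off_target_rate: float = 0.01
    base_quality: int = 35

    def __post_init__(self):
        if self.insert_mean <= 0 or self.insert_sd < 0:
            raise ValueError("insert_mean must be > 0 and insert_sd >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for name in ("base_error_rate", "off_target_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class DerivativeRecord:
    """A derivative chromosome with its coordinate map back to the genome."""

    name: str
    seq: str
    #: (segment, start offset of the segment inside the derivative, 0-based)
    layout: list[tuple[Segment, int]]
    #: 0-based index in ``seq`` where the acceptor part begins
    junction_offset: int
    junction: Junction = None

    def projected_targets(self, targets) -> list[tuple[int, int]]:
        """Genome target intervals mapped into derivative coordinates (1-based)."""
        out = []
        for seg, off in self.layout:
            for chrom, ts, te in targets:
                if chrom != seg.chrom:
                    continue
                lo, hi = max(ts, seg.start), min(te, seg.end)
                if lo > hi:
                    continue
                if seg.orient == "+":
                    a = off + (lo - seg.start) + 1
                    b = off + (hi - seg.start) + 1
                else:
                    a = off + (seg.end - hi) + 1
                    b = off + (seg.end - lo) + 1
                out.append((a, b))
        return sorted(out)


@dataclass
class TruthSet:
    """Edited genome, normalized truth junctions, derivative sequences."""

    genome: GenomeModel
    junctions: list[Junction]
    derivatives: list[DerivativeRecord] = field(default_factory=list)


def make_toy_genome(chrom_specs, seed: int, gc: float = 0.41,
                    target_regions=None) -> GenomeModel:
    """Random toy genome: ``chrom_specs`` is (name, length, centromere|None).

    Deterministic for a fixed seed; base composition follows ``gc``.
    """
    rng = np.random.default_rng(seed)
    lengths, seqs, cens = {}, {}, {}
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for spec in chrom_specs:
        name, length, cen = (list(spec) + [None])[:3]
        if length < 1:
            raise ValueError(f"zero-length chromosome {name}")
        lengths[name] = int(length)
        seqs[name] = np.frombuffer(
            rng.choice(_BASES, size=int(length), p=p).tobytes(), dtype=np.uint8
        ).tobytes().decode()
        if cen is not None:
            cens[name] = tuple(cen)
    return GenomeModel(lengths=lengths, sequences=seqs, centromeres=cens,
                       target_regions=list(target_regions or []))


def _engineer_homology(genome: GenomeModel, junction: Junction, h: int):
    """Copy donor-end bases just outside the acceptor start so that the
    junction acquires >= h bp of genuine microhomology."""
    from .rearrange import _donor_tail  # shared index arithmetic

    donor_tail = "".join(
        _donor_tail(junction, genome, k) for k in range(h, 0, -1))
    a = junction.acceptor
    seq = list(genome.sequences[a.chrom])
    if a.strand == "F":
        lo = a.pos - h - 1  # 0-based start of the window [pos-h, pos-1]
        if lo < 0:
            raise ValueError("homology window runs off chromosome start")
        seq[lo:lo + h] = list(donor_tail)
    else:
        hi = a.pos + h  # window [pos+1, pos+h] holds revcomp(tail) reversed
        if hi > len(seq):
            raise ValueError("homology window runs off chromosome end")
        seq[a.pos:hi] = list(revcomp(donor_tail))
    genome.sequences[a.chrom] = "".join(seq)


def apply_junctions(genome: GenomeModel, junctions, homology_len: int = 0,
                    insertion_seq: str = "") -> TruthSet:
    """Build derivative chromosomes and the matching truth records.

    Microhomology is engineered by editing the acceptor chromosome so the
    homologous bases genuinely flank both sides; requesting both a
    homology and an insertion is contradictory and raises.  Truth
    junctions are re-normalized after the edit, so they record the
    leftmost-donor convention and the *actual* homology (engineered plus
    any incidental extension).
    """
    if homology_len and insertion_seq:
        raise ValueError("cannot engineer microhomology around an insertion")
    if homology_len < 0:
        raise ValueError("homology_len must be >= 0")
    genome = copy.deepcopy(genome)
    derivatives = []
    truth = []
    for i, j in enumerate(junctions):
        genome.check_breakend(j.donor)
        genome.check_breakend(j.acceptor)
        j = replace(j, inserted_seq=insertion_seq or j.inserted_seq)
        if homology_len:
            _engineer_homology(genome, j, homology_len)
    for i, j in enumerate(junctions):
        j = replace(j, inserted_seq=insertion_seq or j.inserted_seq)
        donor_seg, acceptor_seg = junction_segments(j, genome)
        seq = derivative_sequence(j, genome)
        layout = [(donor_seg, 0),
                  (acceptor_seg, len(donor_seg) + len(j.inserted_seq))]
        norm = normalize_junction(j, genome)
        derivatives.append(DerivativeRecord(
            name=f"der{i + 1}_{j.donor.chrom}_{j.acceptor.chrom}",
            seq=seq, layout=layout, junction_offset=len(donor_seg),
            junction=norm))
        # truth records use the caller's convention: canonical orientation,
        # breakpoint leftmost on the canonical donor
        truth.append(normalize_junction(canonical(norm), genome))
    return TruthSet(genome=genome, junctions=truth, derivatives=derivatives)


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str
    source: str
    frag_start: int  # 1-based on source
    frag_len: int


def _apply_errors(rng, seqs: list[str], rate: float) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    L = len(seqs[0])
    mask = rng.random((len(seqs), L)) < rate
    rows = np.nonzero(mask.any(axis=1))[0]
    out = list(seqs)
    for r in rows:
        s = bytearray(out[r], "ascii")
        for c in np.nonzero(mask[r])[0]:
            cur = s[c]
            choices = [b for b in b"ACGT" if b != cur]
            s[c] = choices[rng.integers(0, 3)]
        out[r] = s.decode()
    return out


def simulate_reads(truth: TruthSet, config: SimulationConfig) -> list[ReadPair]:
    """Capture-enriched FR read pairs from natives plus derivatives.

    Per source molecule the pair count is ``depth * on_target_bp /
    (2 * read_len)``; fragment lengths are Normal(insert_mean, insert_sd)
    truncated below at ``2 * read_len``; fragments are placed uniformly
    subject to overlapping a (margin-padded) target interval.  A further
    ``off_target_rate`` fraction of pairs is drawn genome-wide.
    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    genome = truth.genome
    rl = config.read_len

    sources: list[tuple[str, str, list[tuple[int, int]]]] = []
    for name in genome.lengths:
        targets = [(s, e) for c, s, e in genome.target_regions if c == name]
        sources.append((name, genome.seq(name), _merge(targets)))
    for der in truth.derivatives:
        sources.append((der.name, der.seq,
                        _merge(der.projected_targets(genome.target_regions))))

    pairs: list[ReadPair] = []
    n_on_total = 0
    for name, seq, targets in sources:
        tbp = sum(e - s + 1 for s, e in targets)
        if tbp == 0:
            continue
        n = int(round(config.depth * tbp / (2 * rl)))
        n_on_total += n
        pairs.extend(_draw_pairs(rng, name, seq, targets, n, config))
    if n_on_total == 0:
        raise ValueError("no on-target pairs: empty targets or depth too low")

    n_off = int(round(config.off_target_rate * n_on_total))
    if n_off:
        natives = [(n, genome.seq(n)) for n in genome.lengths]
        weights = np.array([len(s) for _, s in natives], dtype=float)
        counts = rng.multinomial(n_off, weights / weights.sum())
        for (name, seq), k in zip(natives, counts):
            if k:
                pairs.extend(_draw_pairs(rng, name, seq,
                                         [(1, len(seq))], int(k), config,
                                         tag="off"))
    # apply base errors in one deterministic sweep
    seqs1 = _apply_errors(rng, [p.seq1 for p in pairs], config.base_error_rate)
    seqs2 = _apply_errors(rng, [p.seq2 for p in pairs], config.base_error_rate)
    for p, s1, s2 in zip(pairs, seqs1, seqs2):
        p.seq1, p.seq2 = s1, s2
    return pairs


def _draw_pairs(rng, name, seq, targets, n, config, tag="on"):
    rl = config.read_len
    L = len(seq)
    ext = _merge([(max(1, s - config.capture_margin),
                   min(L, e + config.capture_margin)) for s, e in targets])
    weights = np.array([e - s + 1 for s, e in ext], dtype=float)
    out = []
    flens = rng.normal(config.insert_mean, config.insert_sd, size=n)
    flens = np.maximum(np.round(flens), 2 * rl).astype(int)
    which = rng.choice(len(ext), size=n, p=weights / weights.sum())
    u = rng.random(n)
    flip = rng.random(n) < 0.5
    for i in range(n):
        flen = min(int(flens[i]), L)
        ts, te = ext[which[i]]
        lo = max(1, ts - flen + 1)
        hi = min(L - flen + 1, te)
        if hi < lo:
            lo, hi = max(1, min(lo, L - flen + 1)), max(1, min(hi, L - flen + 1))
            if hi < lo:
                continue
        start = lo + int(u[i] * (hi - lo + 1))
        frag = seq[start - 1: start - 1 + flen]
        r1, r2 = frag[:rl], revcomp(frag)[:rl]
        if flip[i]:
            r1, r2 = r2, r1
        out.append(ReadPair(f"{tag}_{name}_{len(out)}_{start}", r1, r2,
                            name, start, flen))
    return out


def write_fastq_pair(pairs: list[ReadPair], path1, path2, base_quality=35):
    from . import io as _io
    q = chr(base_quality + 33)
    _io.write_fastq([(f"{p.name}/1", p.seq1, q * len(p.seq1)) for p in pairs], path1)
    _io.write_fastq([(f"{p.name}/2", p.seq2, q * len(p.seq2)) for p in pairs], path2)


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("sv_free", "c_only", "c_d_reciprocal", "b_d_homologous",
             "three_way", "microhomology", "insertion")


def preset_scenario(name: str, seed: int,
                    config: SimulationConfig | None = None):
    """A ready-made simulation: (truth set, read pairs, config).

    Two 60 kbp chromosomes carry 6 kbp capture targets; junction
    positions jitter within the targets per seed.  ``microhomology``
    engineers 0-8 bp of homology and ``insertion`` 0-10 bp of untemplated
    sequence, both cycling deterministically with the seed.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    import zlib
    rng = np.random.default_rng(
        (seed * 1_000_003 + zlib.crc32(name.encode()) % 65_536) % 2**31)
    gseed = int(rng.integers(0, 2**31 - 1))
    chroms = [("chrA", 60_000, (40_000, 41_000)),
              ("chrB", 60_000, (8_000, 9_000))]
    targets = [("chrA", 23_001, 29_000), ("chrB", 31_001, 37_000)]
    if name == "three_way":
        chroms.append(("chrC", 60_000, (30_000, 31_000)))
    genome = make_toy_genome(chroms, gseed, target_regions=targets)

    p1 = 25_000 + int(rng.integers(0, 2_000))
    p2 = 33_000 + int(rng.integers(0, 2_000))
    c = Junction(Breakend("chrA", p1, "F"), Breakend("chrB", p2, "R"))
    homology, insertion = 0, ""
    if name == "sv_free":
        junctions = []
    elif name == "c_only":
        junctions = [c]
    elif name == "c_d_reciprocal":
        d = Junction(Breakend("chrA", p1 + int(rng.integers(0, 40)), "R"),
                     Breakend("chrB", p2 - int(rng.integers(0, 40)), "F"))
        junctions = [c, d]
    elif name == "b_d_homologous":
        b = Junction(Breakend("chrA", p1, "R"), Breakend("chrB", p2, "R"))
        d = Junction(Breakend("chrA", p1 + 500 + int(rng.integers(0, 1_500)), "R"),
                     Breakend("chrB", p2 - 500 - int(rng.integers(0, 1_500)), "F"))
        junctions = [b, d]
    elif name == "three_way":
        pc = 30_000 + int(rng.integers(0, 2_000))
        j2 = Junction(Breakend("chrC", pc, "F"),
                      Breakend("chrB", p2 + 150 + int(rng.integers(0, 300)), "F"))
        j3 = Junction(Breakend("chrC", pc - 200, "R"),
                      Breakend("chrA", p1 + 150 + int(rng.integers(0, 300)), "F"))
        junctions = [c, j2, j3]
    elif name == "microhomology":
        homology = seed % 9
        junctions = [c]
    else:  # insertion
        k = seed % 11
        insertion = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
        junctions = [c]

    truth = apply_junctions(genome, junctions, homology_len=homology,
                            insertion_seq=insertion)
    cfg = config or SimulationConfig(seed=int(rng.integers(0, 2**31 - 1)))
    reads = simulate_reads(truth, cfg)
    return truth, reads, cfg
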