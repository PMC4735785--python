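"""Breakpoint caller: discordant pairs -> clusters -> contigs -> junctions.

The calling chain mirrors targeted-capture SV detection practice:

1. read pairs are classified against the insert-size model; pairs with
   both mates above the mapping-quality floor that are inter-chromosomal
   or otherwise discordant are clustered by chromosome pair and
   orientation (single linkage, positional gap <= center + 3*spread);
2. every mapped read within a window (500-1000 bp) of each predicted
   breakpoint is extracted, together with unmapped reads whose mates map
   inside the window;
3. split-read candidates (soft-clipped or unmapped) are assembled into a
   junction contig by greedy overlap-consensus;
4. the contig is resolved to base-pair precision by maximal exact prefix
   and suffix matching against the reference (either strand), yielding
   the microhomology window or untemplated insertion;
5. reads support the junction when they cross the breakpoint with at
   least ``min_cross_bases`` extra bases on both sides, leave fewer than
   ``max_unaligned_end_bp`` unaligned bases at each end, and are not
   fully explained by a single reference locus.

Junctions with enough split support are emitted with fused flanking
sequence and evidence counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align_ingest import (AlignedPair, InsertSizeModel, ReadAlignment,
                           ReferenceIndex, builtin_map, classify_pair,
                           estimate_insert_model)
from .rearrange import (Breakend, GenomeModel, Junction, SampleCallset,
                        canonical, chrom_sort_key, fused_flank,
                        normalize_junction, revcomp)

__all__ = ["SvCallingParams", "DiscordantCluster", "cluster_discordant",
           "extract_window_reads", "assemble_contig", "resolve_junction",
           "count_support", "call_sample", "ResolvedJunction"]


@dataclass
class SvCallingParams:
    """All numeric thresholds of the calling procedure.

    ``max_unaligned_end_bp`` is an exclusive bound: a read with >= 5
    unaligned end bases is rejected.  ``window_bp`` must stay within
    500-1000 bp.
    """

    mq_min: int = 30
    k_sd: float = 4.0
    window_bp: int = 750
    max_unaligned_end_bp: int = 5
    min_cross_bases: int = 2
    min_cluster_pairs: int = 3
    min_support_reads: int = 2
    min_overlap: int = 30
    min_identity: float = 0.95
    flank_bp: int = 300
    max_assembly_reads: int = 120
    min_insert_pairs: int = 100

    def __post_init__(self):
        if not 500 <= self.window_bp <= 1000:
            raise ValueError("window_bp must lie in [500, 1000]")
        for name in ("max_unaligned_end_bp", "min_cross_bases",
                     "min_cluster_pairs", "min_support_reads", "min_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class DiscordantCluster:
    """A group of discordant pairs sharing chromosome pair and orientation."""

    chrom1: str
    chrom2: str
    pattern: tuple[str, str]  # observed mate strands on (chrom1, chrom2)
    pairs: list[AlignedPair]
    breakend1: Breakend = None  # predicted, approximate
    breakend2: Breakend = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# a mate observed on strand F points rightward at the joint -> its side
# retains sequence left of the breakpoint (donor F / acceptor R); strand R
# points leftward -> the side retains sequence right of the breakpoint.
_DONOR_STRAND = {"F": "F", "R": "R"}
_ACCEPTOR_STRAND = {"F": "R", "R": "F"}


def _sides(pair: AlignedPair):
    """Order the two mates by (chromosome, position)."""
    a, b = pair.r1, pair.r2
    if (chrom_sort_key(a.chrom), a.pos) > (chrom_sort_key(b.chrom), b.pos):
        a, b = b, a
    return a, b


def cluster_discordant(pairs, model: InsertSizeModel,
                       params: SvCallingParams | None = None,
                       classes: dict | None = None) -> list[DiscordantCluster]:
    """Single-linkage clustering of discordant evidence pairs.

    Only inter-chromosomal or distance/orientation-discordant pairs with
    both mates above the MQ floor participate; linkage distance is
    ``center + 3 * spread`` on both footprints simultaneously.  Clusters
    smaller than ``min_cluster_pairs`` are dropped.  Predicted breakends
    are the innermost mate-end coordinates implied by the strand pattern.
    """
    params = params or SvCallingParams()
    linkage = model.center + 3.0 * model.spread
    groups: dict[tuple, list[AlignedPair]] = {}
    for p in pairs:
        cls = (classes or {}).get(id(p)) or classify_pair(
            p, model, mq_min=params.mq_min, k_sd=params.k_sd)
        if cls not in ("interchromosomal", "discordant_distance",
                       "discordant_orientation"):
            continue
        a, b = _sides(p)
        groups.setdefault((a.chrom, b.chrom, a.strand, b.strand), []).append(p)

    clusters = []
    for (c1, c2, s1, s2), members in sorted(groups.items()):
        members.sort(key=lambda p: _sides(p)[0].pos)
        # union-find single linkage on both footprints
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        pos = [(_sides(p)[0].pos, _sides(p)[1].pos) for p in members]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if pos[j][0] - pos[i][0] > linkage:
                    break
                if abs(pos[j][1] - pos[i][1]) <= linkage:
                    parent[find(j)] = find(i)
        buckets: dict[int, list[int]] = {}
        for i in range(len(members)):
            buckets.setdefault(find(i), []).append(i)
        for idxs in buckets.values():
            if len(idxs) < params.min_cluster_pairs:
                continue
            group = [members[i] for i in idxs]
            side1 = [_sides(p)[0] for p in group]
            side2 = [_sides(p)[1] for p in group]
            bp1 = max(r.end for r in side1) if s1 == "F" else min(r.pos for r in side1)
            bp2 = max(r.end for r in side2) if s2 == "F" else min(r.pos for r in side2)
            clusters.append(DiscordantCluster(
                c1, c2, (s1, s2), group,
                Breakend(c1, bp1, _DONOR_STRAND[s1]),
                Breakend(c2, bp2, _ACCEPTOR_STRAND[s2])))
    clusters.sort(key=lambda c: (chrom_sort_key(c.chrom1), c.breakend1.pos,
                                 chrom_sort_key(c.chrom2), c.breakend2.pos))
    return clusters


def extract_window_reads(pairs, breakend: Breakend,
                         params: SvCallingParams | None = None,
                         genome: GenomeModel | None = None) -> list[ReadAlignment]:
    """All mapped reads within ``window_bp`` of a predicted breakpoint,
    plus unmapped reads whose mates map inside the window."""
    params = params or SvCallingParams()
    if genome is not None:
        genome.check_breakend(breakend)
    lo, hi = breakend.pos - params.window_bp, breakend.pos + params.window_bp
    out = []
    for p in pairs:
        for aln, mate in ((p.r1, p.r2), (p.r2, p.r1)):
            if aln.chrom == breakend.chrom and aln.pos <= hi and aln.end >= lo:
                out.append(aln)
            elif (aln.chrom is None and mate.chrom == breakend.chrom
                  and mate.pos <= hi and mate.end >= lo):
                out.append(aln)
    return out


# ---------------------------------------------------------------------------
# greedy overlap-consensus assembly
# ---------------------------------------------------------------------------

def _overlap_shifts(a: str, b: str, k: int = 16):
    """Candidate relative offsets of b against a from shared k-mers."""
    if len(a) < k or len(b) < k:
        return set()
    pos_a: dict[str, int] = {}
    for i in range(0, len(a) - k + 1):
        pos_a.setdefault(a[i:i + k], i)
    shifts = set()
    for i in range(0, len(b) - k + 1):
        j = pos_a.get(b[i:i + k])
        if j is not None:
            shifts.add(j - i)
    return shifts


def _score_overlap(a: str, b: str, shift: int):
    """(matches, overlap_len) of b placed at offset ``shift`` along a."""
    start = max(0, shift)
    end = min(len(a), shift + len(b))
    if end <= start:
        return 0, 0
    sa = np.frombuffer(a[start:end].encode(), np.uint8)
    sb = np.frombuffer(b[start - shift:end - shift].encode(), np.uint8)
    return int((sa == sb).sum()), end - start


@dataclass
class _Unit:
    seq: str
    support: np.ndarray  # per-base read multiplicity

    @classmethod
    def from_read(cls, seq: str, count: int):
        return cls(seq, np.full(len(seq), count, dtype=np.int32))


def _merge_units(a: _Unit, b: _Unit, shift: int) -> _Unit:
    if shift < 0:
        return _merge_units(b, a, -shift)
    length = max(len(a.seq), shift + len(b.seq))
    seq = bytearray(b"N" * length)
    sup = np.zeros(length, dtype=np.int32)
    seq[:len(a.seq)] = a.seq.encode()
    sup[:len(a.seq)] = a.support
    bseq = b.seq.encode()
    for i in range(len(b.seq)):
        p = shift + i
        if sup[p] == 0:
            seq[p] = bseq[i]
            sup[p] = b.support[i]
        elif seq[p] == bseq[i]:
            sup[p] += b.support[i]
        elif b.support[i] > sup[p]:  # majority base wins
            seq[p] = bseq[i]
            sup[p] = b.support[i]
    return _Unit(seq.decode(), sup)


def assemble_contig(reads, params: SvCallingParams | None = None):
    """Greedy overlap-consensus assembly of a read set.

    Repeatedly merges the highest-scoring overlap of length >=
    ``min_overlap`` at identity >= ``min_identity`` (either orientation),
    consensus by support-weighted majority; ties break lexicographically
    by sequence, so the result is deterministic.  Returns ``(contig,
    support, flag)`` where ``flag`` is True when not all input could be
    joined into one contig (or no overlap existed at all).
    """
    params = params or SvCallingParams()
    seqs: dict[str, int] = {}
    for r in reads:
        s = r.seq if isinstance(r, ReadAlignment) else str(r)
        if s:
            seqs[s.upper()] = seqs.get(s.upper(), 0) + 1
    units = [_Unit.from_read(s, c) for s, c in sorted(seqs.items())]
    if not units:
        raise ValueError("no reads to assemble")

    while len(units) > 1:
        best = None  # (score, -overlap, seqkey, i, j, shift, rc)
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                for rc in (False, True):
                    bseq = revcomp(units[j].seq) if rc else units[j].seq
                    for shift in _overlap_shifts(units[i].seq, bseq):
                        m, ov = _score_overlap(units[i].seq, bseq, shift)
                        if ov < params.min_overlap or m < params.min_identity * ov:
                            continue
                        cand = (m, -ov, units[i].seq, bseq, i, j, shift, rc)
                        if best is None or cand > best:
                            best = cand
        if best is None:
            break
        m, _, _, _, i, j, shift, rc = best
        bunit = units[j]
        if rc:
            bunit = _Unit(revcomp(bunit.seq), bunit.support[::-1].copy())
        merged = _merge_units(units[i], bunit, shift)
        units = [u for idx, u in enumerate(units) if idx not in (i, j)]
        units.append(merged)

    units.sort(key=lambda u: (-len(u.seq), u.seq))
    top = units[0]
    return top.seq, top.support, len(units) > 1


# ---------------------------------------------------------------------------
# junction resolution
# ---------------------------------------------------------------------------

def polish_contig(contig: str, reads, k: int = 15):
    """Column-majority consensus polish of a contig against its reads.

    Every read is realigned to the contig at its best-scoring placement
    (either orientation) and votes per column; the majority base replaces
    the greedy consensus.  Returns ``(polished, coverage)``.  Low-coverage
    contig ends keep their bases but report their true depth, so callers
    can trim columns supported by fewer than two reads.
    """
    carr = np.frombuffer(contig.upper().encode(), np.uint8)
    kmap: dict[str, list[int]] = {}
    for i in range(0, len(contig) - k + 1):
        kmap.setdefault(contig[i:i + k], []).append(i)
    votes = np.zeros((len(contig), 256), dtype=np.int32)
    for r in reads:
        seq = (r.seq if isinstance(r, ReadAlignment) else str(r)).upper()
        hit = _align_to_contig(contig, carr, kmap, seq)
        if hit is None:
            continue
        nm, _, strand, shift, _ = hit
        q = seq if strand == "F" else revcomp(seq)
        start, end = max(0, shift), min(len(contig), shift + len(q))
        if end <= start or nm < 0.9 * (end - start):
            continue  # reads sharing only one flank with the contig may
            # place poorly; their votes would corrupt thin columns
        qarr = np.frombuffer(q.encode(), np.uint8)[start - shift:end - shift]
        votes[np.arange(start, end), qarr] += 1
    coverage = votes.sum(axis=1)
    best = votes.argmax(axis=1).astype(np.uint8)
    cur = votes[np.arange(len(contig)), carr]
    top = votes.max(axis=1)
    # override the assembly base only on a strict majority against it
    out = np.where(top > cur, best, carr).tobytes().decode()
    return out, coverage


@dataclass
class ResolvedJunction:
    junction: Junction
    contig: str
    #: 0-based contig interval [window_left, window_right] bounding the
    #: breakpoint (ambiguous under microhomology, spans the insertion)
    window_left: int
    window_right: int


def _find_all(haystack: str, needle: str):
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _anchor_hits(genome: GenomeModel, anchor: str):
    """(chrom, 0-based pos, strand) of every exact occurrence of anchor."""
    hits = []
    for name in genome.lengths:
        seq = genome.seq(name)
        for i in _find_all(seq, anchor):
            hits.append((name, i, "F"))
        for i in _find_all(seq, revcomp(anchor)):
            hits.append((name, i, "R"))
    return hits


def _max_prefix(genome, contig, anchor_len=24, offsets=(0, 6, 12, 18)):
    """Longest exact prefix-side match: (length, chrom, strand, map) or None.

    ``map(i)`` gives the 1-based reference position of contig index i.
    The anchor may start a few bases into the contig (``offsets``) so
    that a stray base at a low-coverage contig end cannot mask the whole
    donor side; ``length`` is always the rightmost matched contig index
    (exclusive).  Longer matches anchored closer to the start win.
    """
    best = None
    for o in offsets:
        anchor = contig[o:o + anchor_len]
        if len(anchor) < anchor_len:
            break
        for chrom, i, strand in _anchor_hits(genome, anchor):
            seq = genome.seq(chrom)
            if strand == "F":
                length = o + anchor_len
                while (length < len(contig) and i + length - o < len(seq)
                       and contig[length] == seq[i + length - o]):
                    length += 1
                mapper = (lambda x, i=i, o=o: i + 1 + x - o)
            else:
                # contig[o:] == revcomp(seq[...]); rightward contig extension
                # walks leftward on the reference
                length = o + anchor_len
                while (length < len(contig)
                       and i + anchor_len + o - length - 1 >= 0
                       and contig[length] == revcomp(seq[i + anchor_len + o - length - 1])):
                    length += 1
                mapper = (lambda x, i=i, o=o: i + anchor_len + o - x)
            cand = (length, -o, chrom, strand, mapper)
            if best is None or (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
                best = cand
        if best is not None and best[0] >= len(contig):
            break
    if best is None:
        return None
    length, _, chrom, strand, mapper = best
    return (length, chrom, strand, mapper)


def _max_suffix(genome, contig, anchor_len=24):
    """Longest exact suffix match, as (chrom, strand, length, map)."""
    rc = revcomp(contig)
    hit = _max_prefix(genome, rc, anchor_len)
    if hit is None:
        return None
    length, chrom, strand, rcmap = hit
    flip = {"F": "R", "R": "F"}[strand]
    mapper = (lambda x, n=len(contig), rcmap=rcmap: rcmap(n - 1 - x))
    return (length, chrom, flip, mapper)


def resolve_junction(contig: str, genome: GenomeModel,
                     params: SvCallingParams | None = None,
                     anchor_len: int = 24) -> ResolvedJunction | None:
    """Resolve a junction contig to base-pair precision.

    The maximal exact prefix of the contig matching one reference locus
    (either strand) and the maximal exact suffix matching another define
    the joint; their overlap is the microhomology window, any gap the
    untemplated insertion.  The breakpoint is reported leftmost on the
    donor.  Returns ``None`` when the contig is fully explained by a
    single locus (reference allele) or no two-sided match exists.
    """
    params = params or SvCallingParams()
    if len(contig) < 2 * params.min_cross_bases + 20:
        return None
    contig = contig.upper()
    pre = _max_prefix(genome, contig, anchor_len)
    suf = _max_suffix(genome, contig, anchor_len)
    if pre is None or suf is None:
        return None
    lp, chrom_p, strand_p, map_p = pre
    ls, chrom_s, strand_s, map_s = suf
    n = len(contig)
    if lp >= n or ls >= n:
        return None  # single-locus (reference) contig
    if lp + ls < n - 1000:
        return None

    a_start = n - ls  # first contig index of the suffix match
    if lp >= a_start:  # microhomology (or blunt) joint
        d_end = a_start  # split at the leftmost acceptor-consistent point
        ins = ""
    else:
        d_end = lp
        ins = contig[lp:a_start]
    # donor side from the prefix match, acceptor from the suffix match
    donor_pos = map_p(d_end - 1)
    donor_strand = "F" if strand_p == "F" else "R"
    acc_pos = map_s(a_start)
    # suffix matched forward -> acceptor segment extends right (F);
    # matched reverse -> acceptor is a reverse-complement prefix (R)
    acc_strand = "F" if strand_s == "F" else "R"
    try:
        junction = Junction(Breakend(chrom_p, donor_pos, donor_strand),
                            Breakend(chrom_s, acc_pos, acc_strand),
                            inserted_seq=ins)
        genome.check_breakend(junction.donor)
        genome.check_breakend(junction.acceptor)
        # canonicalize first: leftmost-donor is defined on the canonical donor
        junction = normalize_junction(canonical(junction), genome)
    except ValueError:
        return None
    window_left = min(d_end, a_start)
    window_right = max(min(lp, n), a_start)
    return ResolvedJunction(junction, contig, window_left, window_right)


# ---------------------------------------------------------------------------
# split-read support
# ---------------------------------------------------------------------------

def _align_to_contig(contig: str, carr: np.ndarray, kmap: dict, seq: str,
                     k: int = 15):
    """Best placement of a read on the contig: (shift, strand, match array)."""
    best = None
    for strand, q in (("F", seq), ("R", revcomp(seq))):
        cands = set()
        for off in {0, max(0, len(q) // 2 - k // 2), max(0, len(q) - k)}:
            for j in kmap.get(q[off:off + k], ()):
                cands.add(j - off)
        qarr = np.frombuffer(q.encode(), np.uint8)
        for shift in cands:
            start, end = max(0, shift), min(len(contig), shift + len(q))
            if end <= start:
                continue
            m = carr[start:end] == qarr[start - shift:end - shift]
            nm = int(m.sum())
            cand = (nm, -abs(shift), strand, shift, m)
            if best is None or cand[:2] > best[:2]:
                best = cand
    return best


def count_support(reads, contig: str, resolved: ResolvedJunction,
                  genome: GenomeModel | None = None,
                  params: SvCallingParams | None = None):
    """Count reads supporting a resolved junction on its contig.

    A read supports when its contig alignment (i) crosses the whole
    breakpoint window with >= ``min_cross_bases`` extra bases on both
    sides, (ii) leaves fewer than ``max_unaligned_end_bp`` unaligned
    bases at each read end, and (iii) is not fully explained by a single
    reference locus (its reference alignment retains clipped bases).
    Returns ``(n_support, rejected-by-reason dict)``.
    """
    params = params or SvCallingParams()
    contig = contig.upper()
    carr = np.frombuffer(contig.encode(), np.uint8)
    k = 15
    kmap: dict[str, list[int]] = {}
    for i in range(0, len(contig) - k + 1):
        kmap.setdefault(contig[i:i + k], []).append(i)
    wl, wr = resolved.window_left, resolved.window_right
    n_support = 0
    reasons = {"no_contig_alignment": 0, "insufficient_cross": 0,
               "unaligned_ends": 0, "reference_explained": 0}
    for r in reads:
        seq = (r.seq if isinstance(r, ReadAlignment) else str(r)).upper()
        hit = _align_to_contig(contig, carr, kmap, seq)
        if hit is None:
            reasons["no_contig_alignment"] += 1
            continue
        nm, _, strand, shift, m = hit
        # matched span within the read, after trimming end mismatch runs
        idx = np.nonzero(m)[0]
        if idx.size == 0:
            reasons["no_contig_alignment"] += 1
            continue
        start, end = max(0, shift), min(len(contig), shift + len(seq))
        span_lo = start + int(idx[0])
        span_hi = start + int(idx[-1]) + 1  # contig coords, exclusive
        # unaligned bases at each read end: overhang beyond the contig
        # plus trimmed mismatching ends
        left_un = (start - shift) + int(idx[0])
        right_un = (shift + len(seq) - end) + (m.size - 1 - int(idx[-1]))
        crosses = (span_lo <= wl - params.min_cross_bases
                   and span_hi >= wr + params.min_cross_bases)
        if not crosses:
            reasons["insufficient_cross"] += 1
            continue
        if max(left_un, right_un) >= params.max_unaligned_end_bp:
            reasons["unaligned_ends"] += 1
            continue
        if (isinstance(r, ReadAlignment) and r.chrom is not None
                and r.total_clip == 0):
            reasons["reference_explained"] += 1
            continue
        n_support += 1
    return n_support, reasons


# ---------------------------------------------------------------------------
# whole-sample calling
# ---------------------------------------------------------------------------

def _assembly_candidates(window_reads, params: SvCallingParams,
                         cluster: DiscordantCluster,
                         boundary_tol: int = 150):
    """Split-read candidates for targeted assembly of one cluster.

    A mate observed on strand F points rightward at the joint, so a read
    crossing it is soft-clipped on its right end (left end for strand R);
    candidate reads must carry the expected clip on the expected side
    with the clip boundary near the predicted breakend.  Unmapped reads
    from the windows join unconditionally.  This keeps reads from a
    second nearby junction (e.g. the reciprocal partner) out of the
    contig.
    """
    sides = ((cluster.breakend1.chrom, cluster.breakend1.pos, cluster.pattern[0]),
             (cluster.breakend2.chrom, cluster.breakend2.pos, cluster.pattern[1]))
    picked = []
    for r in window_reads:
        if r.chrom is None:
            picked.append(r)
            continue
        for chrom, bp, strand in sides:
            if r.chrom != chrom:
                continue
            clip = r.clip_right if strand == "F" else r.clip_left
            boundary = r.end if strand == "F" else r.pos
            if clip >= params.min_cross_bases and abs(boundary - bp) <= boundary_tol:
                picked.append(r)
                break
    picked.sort(key=lambda r: (r.name, r.mate))
    seen = set()
    out = []
    for r in picked:
        if (r.name, r.mate) in seen:
            continue
        seen.add((r.name, r.mate))
        out.append(r)
        if len(out) >= params.max_assembly_reads:
            break
    return out


def call_sample(genome: GenomeModel, params: SvCallingParams | None = None,
                pairs: list[AlignedPair] | None = None,
                fastq_pairs=None, sample: str = "sample",
                index: ReferenceIndex | None = None) -> SampleCallset:
    """Run the full calling chain on one sample.

    Input is either pre-aligned ``pairs`` (from any aligner via
    :func:`capfuse.align_ingest.read_sam`) or raw read pairs mapped with
    the built-in mapper.  Emitted junctions carry split and pair support
    and fused flanking sequence, sorted canonically.
    """
    params = params or SvCallingParams()
    if pairs is None:
        if fastq_pairs is None:
            return SampleCallset(sample, [])
        pairs = builtin_map(fastq_pairs, genome, index=index)
    if not pairs:
        return SampleCallset(sample, [])
    model = estimate_insert_model(pairs, min_pairs=params.min_insert_pairs)
    clusters = cluster_discordant(pairs, model, params)
    found: dict[tuple, Junction] = {}
    for cl in clusters:
        reads = []
        seen = set()
        for be in (cl.breakend1, cl.breakend2):
            for r in extract_window_reads(pairs, be, params, genome):
                if (r.name, r.mate) not in seen:
                    seen.add((r.name, r.mate))
                    reads.append(r)
        cands = _assembly_candidates(reads, params, cl)
        if len(cands) < 2:
            continue
        contig, _support, _flag = assemble_contig(cands, params)
        # polish against the candidate reads, then trim single-read ends:
        # low-coverage columns may carry sequencing errors
        contig, coverage = polish_contig(contig, cands)
        solid = np.nonzero(coverage >= 2)[0]
        if solid.size:
            contig = contig[solid[0]: solid[-1] + 1]
        resolved = resolve_junction(contig, genome, params)
        if resolved is None:
            continue
        n_split, _reasons = count_support(reads, resolved.contig, resolved,
                                          genome, params)
        if n_split < params.min_support_reads:
            continue
        j = resolved.junction
        j.support_split = n_split
        j.support_pairs = cl.n_pairs
        j.sample = sample
        j.flank_seq = fused_flank(j, genome, params.flank_bp)[0]
        key = j.key()
        if key not in found or found[key].support_split < n_split:
            found[key] = j
    callset = SampleCallset(sample, list(found.values()),
                            metadata={"insert_model": model,
                                      "n_clusters": len(clusters)})
    callset.junctions = callset.sorted()
    return callset
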