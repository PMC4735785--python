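"""Core domain model for inter-chromosomal fusion junctions.

A translocation is represented as a :class:`Junction` between two
:class:`Breakend` s.  The *donor* is the chromosomal segment that flows
into the fused joint, the *acceptor* the segment that flows out of it.
Strand semantics are fixed throughout the package:

* donor ``F``   -- forward prefix of the chromosome ending at ``pos``;
* donor ``R``   -- reverse complement of the suffix starting at ``pos``;
* acceptor ``F`` -- forward suffix starting at ``pos``;
* acceptor ``R`` -- reverse complement of the prefix ending at ``pos``.

For a chr12-donor / chr21-acceptor junction the four strand combinations
define the four orientation types of the classic ETV6-RUNX1 fusion:
``(F,F) -> a``, ``(R,R) -> b``, ``(F,R) -> c`` (the productive in-frame
fusion), ``(R,F) -> d`` (its reciprocal product).  The derivative
chromosome of a type-a junction carries no centromere (acentric, not
mitotically viable), type b carries two (dicentric), types c and d one
each -- which is why type a is never observed in patients.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Breakend",
    "Junction",
    "GenomeModel",
    "DerivativeChromosome",
    "RearrangementEvent",
    "FishProbePanel",
    "SampleCallset",
    "CloneComparison",
    "revcomp",
    "chrom_sort_key",
    "mirror",
    "canonical",
    "classify_type",
    "junction_segments",
    "build_derivative",
    "derivative_sequence",
    "normalize_junction",
    "fused_flank",
    "interpret_events",
    "predict_fish_pattern",
    "probe_fragments",
    "compare_clones",
    "HG19_MODEL",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STRAND_TYPE = {("F", "F"): "a", ("R", "R"): "b", ("F", "R"): "c", ("R", "F"): "d"}
_FLIP = {"F": "R", "R": "F"}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def chrom_sort_key(name: str):
    """Natural chromosome ordering: chr1 < ... < chr22 < chrX < chrY."""
    m = re.fullmatch(r"(?:chr)?(\w+)", name)
    token = m.group(1) if m else name
    if token.isdigit():
        return (0, int(token), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if token.upper() in special:
        return (0, special[token.upper()], "")
    return (1, 0, token)


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a fused joint: chromosome, 1-based position, strand flag."""

    chrom: str
    pos: int
    strand: str  # "F" or "R"

    def __post_init__(self):
        if self.strand not in ("F", "R"):
            raise ValueError(f"strand must be F or R, got {self.strand!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class Junction:
    """A fused joint between a donor and an acceptor breakend.

    ``microhomology_len`` is the number of bases shared by both sides at
    the joint (breakpoint ambiguous within that window);
    ``inserted_seq`` holds untemplated bases between the two segments.
    """

    donor: Breakend
    acceptor: Breakend
    microhomology_len: int = 0
    inserted_seq: str = ""
    support_pairs: int = 0
    support_split: int = 0
    flank_seq: str | None = None
    sample: str | None = None

    def __post_init__(self):
        if self.microhomology_len < 0:
            raise ValueError("microhomology_len must be >= 0")

    def key(self):
        j = canonical(self)
        return (
            j.donor.chrom, j.donor.pos, j.donor.strand,
            j.acceptor.chrom, j.acceptor.pos, j.acceptor.strand,
            j.inserted_seq.upper(),
        )

    def chrom_pair(self):
        return tuple(sorted({self.donor.chrom, self.acceptor.chrom},
                            key=chrom_sort_key))


def mirror(junction: Junction) -> Junction:
    """The same joint read from the other derivative strand.

    ``((c1,p1,s1),(c2,p2,s2)) -> ((c2,p2,flip s2),(c1,p1,flip s1))``;
    an involution.
    """
    d, a = junction.donor, junction.acceptor
    return replace(
        junction,
        donor=Breakend(a.chrom, a.pos, _FLIP[a.strand]),
        acceptor=Breakend(d.chrom, d.pos, _FLIP[d.strand]),
        inserted_seq=revcomp(junction.inserted_seq),
    )


def canonical(junction: Junction) -> Junction:
    """Canonical representation: donor chromosome first in natural order.

    For intra-chromosomal joints the smaller donor position wins; exact
    ties fall back to a full lexicographic comparison with the mirror so
    every junction has one unique canonical form.
    """
    m = mirror(junction)

    def rank(j):
        return (chrom_sort_key(j.donor.chrom), j.donor.pos, j.donor.strand,
                chrom_sort_key(j.acceptor.chrom), j.acceptor.pos,
                j.acceptor.strand, j.inserted_seq.upper())

    return junction if rank(junction) <= rank(m) else m


def classify_type(junction: Junction,
                  primary_pair: tuple[str, str] = ("chr12", "chr21")) -> str:
    """Orientation type (a/b/c/d) of a primary-pair junction.

    The junction is canonicalized so the donor lies on the first
    chromosome of ``primary_pair``; the (donor strand, acceptor strand)
    pair then maps FF/RR/FR/RF to a/b/c/d.
    """
    j = canonical(junction)
    if {j.donor.chrom, j.acceptor.chrom} != set(primary_pair):
        raise ValueError(
            f"not a primary-pair junction: {j.donor.chrom}/{j.acceptor.chrom}"
        )
    if j.donor.chrom != primary_pair[0]:
        j = mirror(j)
    return STRAND_TYPE[(j.donor.strand, j.acceptor.strand)]


# ---------------------------------------------------------------------------
# genome model and derivative chromosomes
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Chromosome lengths, optional sequences, centromeres, target regions.

    All intervals are 1-based inclusive.  ``target_regions`` are the
    hybridization-capture intervals that the sequencing enriches for.
    """

    lengths: dict[str, int]
    sequences: dict[str, str] = field(default_factory=dict)
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    target_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for name, (s, e) in self.centromeres.items():
            if not (1 <= s <= e <= self.lengths.get(name, 0)):
                raise ValueError(f"centromere {name}:{s}-{e} outside chromosome")
        for chrom, s, e in self.target_regions:
            if not (1 <= s <= e <= self.lengths.get(chrom, 0)):
                raise ValueError(f"target {chrom}:{s}-{e} outside chromosome")
        for name, seq in self.sequences.items():
            if len(seq) != self.lengths.get(name):
                raise ValueError(f"sequence length mismatch for {name}")

    def seq(self, chrom: str) -> str:
        try:
            return self.sequences[chrom]
        except KeyError:
            raise KeyError(f"no sequence loaded for {chrom}") from None

    def check_breakend(self, be: Breakend):
        if be.chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {be.chrom}")
        if not (1 <= be.pos <= self.lengths[be.chrom]):
            raise ValueError(f"{be.chrom}:{be.pos} outside chromosome")


#: hg19 coordinates of the chromosomes this assay touches: lengths,
#: centromere gap intervals, and the two capture regions around
#: ETV6 intron 5 (chr12) and RUNX1 introns 1-3 (chr21).
HG19_MODEL = GenomeModel(
    lengths={
        "chr5": 180_915_260,
        "chr6": 171_115_067,
        "chr8": 146_364_022,
        "chr12": 133_851_895,
        "chr15": 102_531_392,
        "chr21": 48_129_895,
    },
    centromeres={
        "chr5": (46_405_641, 49_405_641),
        "chr6": (58_830_166, 61_830_166),
        "chr8": (43_838_887, 46_838_887),
        "chr12": (34_856_694, 37_856_694),
        "chr15": (15_933_768, 18_933_768),
        "chr21": (11_288_129, 14_288_129),
    },
    target_regions=[
        ("chr12", 12_022_748, 12_037_521),
        ("chr21", 36_259_140, 36_425_395),
    ],
)


@dataclass
class Segment:
    """A stretch of reference sequence inside a derivative chromosome."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    orient: str  # "+" forward, "-" reverse complement

    def __len__(self):
        return self.end - self.start + 1


@dataclass
class DerivativeChromosome:
    segments: list[Segment]
    centromere_count: int
    viable: bool

    def __len__(self):
        return sum(len(s) for s in self.segments)


def junction_segments(junction: Junction, genome: GenomeModel) -> list[Segment]:
    """The two reference segments fused by a junction, in derivative order."""
    d, a = junction.donor, junction.acceptor
    genome.check_breakend(d)
    genome.check_breakend(a)
    if d.strand == "F":
        donor = Segment(d.chrom, 1, d.pos, "+")
    else:
        donor = Segment(d.chrom, d.pos, genome.lengths[d.chrom], "-")
    if a.strand == "F":
        acceptor = Segment(a.chrom, a.pos, genome.lengths[a.chrom], "+")
    else:
        acceptor = Segment(a.chrom, 1, a.pos, "-")
    return [donor, acceptor]


def build_derivative(junction: Junction, genome: GenomeModel) -> DerivativeChromosome:
    """Derivative chromosome implied by a junction, with centromere census.

    Counting requires centromere annotation for both chromosomes; a
    segment overlapping a centromere interval by >= 1 bp contributes one
    centromere.  ``viable`` means at least one centromere (dicentrics are
    flagged by ``centromere_count == 2`` but considered viable).
    """
    segments = junction_segments(junction, genome)
    count = 0
    for seg in segments:
        if seg.chrom not in genome.centromeres:
            raise ValueError(f"no centromere annotation for {seg.chrom}")
        cs, ce = genome.centromeres[seg.chrom]
        if seg.start <= ce and seg.end >= cs:
            count += 1
    return DerivativeChromosome(segments, count, viable=count >= 1)


def _segment_seq(seg: Segment, genome: GenomeModel) -> str:
    s = genome.seq(seg.chrom)[seg.start - 1: seg.end]
    return revcomp(s) if seg.orient == "-" else s


def derivative_sequence(junction: Junction, genome: GenomeModel) -> str:
    """Full nucleotide sequence of the derivative chromosome."""
    donor, acceptor = junction_segments(junction, genome)
    return (_segment_seq(donor, genome)
            + junction.inserted_seq
            + _segment_seq(acceptor, genome))


# ---------------------------------------------------------------------------
# breakpoint normalization under microhomology
# ---------------------------------------------------------------------------

def _donor_tail(j: Junction, genome: GenomeModel, k: int) -> str | None:
    """k-th base from the end of the donor segment (segment orientation)."""
    d = j.donor
    seq = genome.seq(d.chrom)
    if d.strand == "F":
        i = d.pos - k + 1  # 1-based; k=1 is the base at pos itself
        return seq[i - 1] if i >= 1 else None
    i = d.pos + k - 1
    return revcomp(seq[i - 1]) if i <= len(seq) else None


def _donor_next(j: Junction, genome: GenomeModel, k: int) -> str | None:
    """k-th base past the donor segment end, extending it."""
    d = j.donor
    seq = genome.seq(d.chrom)
    if d.strand == "F":
        i = d.pos + k
        return seq[i - 1] if i <= len(seq) else None
    i = d.pos - k
    return revcomp(seq[i - 1]) if i >= 1 else None


def _acceptor_head(j: Junction, genome: GenomeModel, k: int) -> str | None:
    """k-th base of the acceptor segment."""
    a = j.acceptor
    seq = genome.seq(a.chrom)
    if a.strand == "F":
        i = a.pos + k - 1
        return seq[i - 1] if i <= len(seq) else None
    i = a.pos - k + 1
    return revcomp(seq[i - 1]) if i >= 1 else None


def _acceptor_prev(j: Junction, genome: GenomeModel, k: int) -> str | None:
    """k-th base before the acceptor segment start."""
    a = j.acceptor
    seq = genome.seq(a.chrom)
    if a.strand == "F":
        i = a.pos - k
        return seq[i - 1] if i >= 1 else None
    i = a.pos + k
    return revcomp(seq[i - 1]) if i <= len(seq) else None


def _shift(j: Junction, k: int) -> Junction:
    """Move the joint by k derivative positions (positive = rightward)."""
    d, a = j.donor, j.acceptor
    dd = k if d.strand == "F" else -k
    da = k if a.strand == "F" else -k
    return replace(j,
                   donor=Breakend(d.chrom, d.pos + dd, d.strand),
                   acceptor=Breakend(a.chrom, a.pos + da, a.strand))


def normalize_junction(junction: Junction, genome: GenomeModel,
                       max_homology: int = 200) -> Junction:
    """Leftmost-donor canonical form of a junction, with true microhomology.

    Untemplated inserted bases matching the adjacent reference are first
    absorbed into the flanking segments; the remaining homology window is
    scanned in both directions and the split with the smallest donor
    coordinate is reported, ``microhomology_len`` set to the window size.
    The derivative sequence is invariant under this renaming.
    """
    j = replace(junction)
    # absorb insertion bases into donor (from the left) ...
    ins = j.inserted_seq.upper()
    while ins and _donor_next(j, genome, 1) == ins[0]:
        d = j.donor
        step = 1 if d.strand == "F" else -1
        j = replace(j, donor=Breakend(d.chrom, d.pos + step, d.strand))
        ins = ins[1:]
    # ... and into acceptor (from the right)
    while ins and _acceptor_prev(j, genome, 1) == ins[-1]:
        a = j.acceptor
        step = -1 if a.strand == "F" else 1
        j = replace(j, acceptor=Breakend(a.chrom, a.pos + step, a.strand))
        ins = ins[:-1]
    j = replace(j, inserted_seq=ins)
    if ins:
        return replace(j, microhomology_len=0)

    hl = 0
    while hl < max_homology:
        t = _donor_tail(j, genome, hl + 1)
        p = _acceptor_prev(j, genome, hl + 1)
        if t is None or p is None or t != p:
            break
        hl += 1
    hr = 0
    while hr < max_homology:
        n = _donor_next(j, genome, hr + 1)
        h = _acceptor_head(j, genome, hr + 1)
        if n is None or h is None or n != h:
            break
        hr += 1
    homology = hl + hr
    # smallest donor coordinate inside the ambiguity window
    if j.donor.strand == "F":
        j = _shift(j, -hl)
    else:
        j = _shift(j, hr)
    return replace(j, microhomology_len=homology)


def fused_flank(junction: Junction, genome: GenomeModel,
                flank_bp: int = 300) -> tuple[str, int, bool]:
    """Fused sequence around the joint: donor flank + insertion + acceptor flank.

    Returns ``(sequence, junction_offset, clipped)`` where ``offset`` is
    the length of the donor-side part and ``clipped`` flags truncation at
    a chromosome end.
    """
    donor, acceptor = junction_segments(junction, genome)
    dseq = _segment_seq(donor, genome)
    aseq = _segment_seq(acceptor, genome)
    clipped = len(dseq) < flank_bp or len(aseq) < flank_bp
    dflank = dseq[-flank_bp:]
    aflank = aseq[:flank_bp]
    return dflank + junction.inserted_seq + aflank, len(dflank), clipped


# ---------------------------------------------------------------------------
# event interpretation
# ---------------------------------------------------------------------------

@dataclass
class RearrangementEvent:
    junctions: list[Junction]
    event_class: str  # two_way_simple | two_way_reciprocal | three_way | homologous_joint | other
    partner_chromosomes: set[str] = field(default_factory=set)
    derivatives: list[DerivativeChromosome] = field(default_factory=list)


def _safe_type(j: Junction, primary_pair) -> str | None:
    try:
        return classify_type(j, primary_pair)
    except ValueError:
        return None


def interpret_events(junctions: list[Junction],
                     primary_pair: tuple[str, str] = ("chr12", "chr21"),
                     genome: GenomeModel | None = None
                     ) -> list[RearrangementEvent]:
    """Group one sample's junctions into rearrangement events.

    * junctions touching a chromosome beyond the primary pair, together
      with the sample's productive (type-c) junction, form a
      ``three_way`` event whose partners are those extra chromosomes;
    * a complementary c+d (or a+b) pair on the primary pair is a
      reciprocal two-way translocation;
    * a b+d pair with distinct breakpoint pairs marks joint breaks of
      both homologous chromosomes (``homologous_joint``);
    * anything left over is a simple two-way event.
    """
    if not junctions:
        return []
    primary = set(primary_pair)
    on_pair, off_pair = [], []
    for j in junctions:
        jc = canonical(j)
        if {jc.donor.chrom, jc.acceptor.chrom} <= primary:
            on_pair.append(jc)
        else:
            off_pair.append(jc)

    events: list[RearrangementEvent] = []
    remaining = list(on_pair)

    if off_pair:
        partners = set()
        for j in off_pair:
            partners |= {j.donor.chrom, j.acceptor.chrom} - primary
        members = list(off_pair)
        for j in list(remaining):
            if _safe_type(j, primary_pair) == "c":
                members.append(j)
                remaining.remove(j)
        events.append(RearrangementEvent(members, "three_way", partners))

    by_type: dict[str, list[Junction]] = {}
    for j in remaining:
        by_type.setdefault(_safe_type(j, primary_pair) or "?", []).append(j)

    # joint breaks of both homologs: b + d with distinct breakpoint pairs
    while by_type.get("b") and by_type.get("d"):
        b = by_type["b"].pop(0)
        d = by_type["d"].pop(0)
        distinct = (b.donor.pos, b.acceptor.pos) != (d.donor.pos, d.acceptor.pos)
        events.append(RearrangementEvent(
            [b, d], "homologous_joint" if distinct else "two_way_reciprocal"))
    # reciprocal pairs
    for t1, t2 in (("c", "d"), ("a", "b")):
        while by_type.get(t1) and by_type.get(t2):
            events.append(RearrangementEvent(
                [by_type[t1].pop(0), by_type[t2].pop(0)], "two_way_reciprocal"))
    for t, rest in sorted(by_type.items()):
        for j in rest:
            cls = "two_way_simple" if t in "abcd" else "other"
            events.append(RearrangementEvent([j], cls))

    if genome is not None:
        for ev in events:
            ev.derivatives = [build_derivative(j, genome) for j in ev.junctions
                              if j.donor.chrom in genome.centromeres
                              and j.acceptor.chrom in genome.centromeres]
    return events


# ---------------------------------------------------------------------------
# FISH pattern prediction
# ---------------------------------------------------------------------------

@dataclass
class FishProbePanel:
    """Dual-color probe panel; probes are (color, chromosome, interval)."""

    probes: list[tuple[str, str, tuple[int, int]]]
    min_detectable_bp: int = 50_000

    def __post_init__(self):
        if self.min_detectable_bp <= 0:
            raise ValueError("min_detectable_bp must be > 0")
        for color, _, (s, e) in self.probes:
            if color not in ("green", "red"):
                raise ValueError(f"probe color must be green or red, got {color}")
            if s > e:
                raise ValueError("probe interval start > end")


def _chromosome_copies(events, genome: GenomeModel, homozygous: bool):
    """Diploid chromosome complement after applying events.

    Each event consumes one homolog of every chromosome it touches and
    contributes the derivative of each of its junctions; in a
    ``homologous_joint`` event each junction consumes its own homolog
    pair.  With ``homozygous=True`` both homologs are consumed and every
    derivative is duplicated.
    """
    copies: list[tuple[str, list[Segment]]] = []
    natives: dict[str, int] = {}
    for name, length in genome.lengths.items():
        natives[name] = 2

    def consume(chroms):
        for c in chroms:
            if natives.get(c, 0) > 0:
                natives[c] -= 1

    derived: list[tuple[str, list[Segment]]] = []
    for ev in events or []:
        groups = ([[j] for j in ev.junctions]
                  if ev.event_class == "homologous_joint" else [ev.junctions])
        for junctions in groups:
            involved = set()
            for j in junctions:
                involved |= {j.donor.chrom, j.acceptor.chrom}
            consume(sorted(involved))
            if homozygous:
                consume(sorted(involved))
            for j in junctions:
                segs = junction_segments(j, genome)
                derived.append((f"der({'/'.join(sorted(involved))})", segs))
                if homozygous:
                    derived.append((f"der({'/'.join(sorted(involved))})'", segs))
    for name in genome.lengths:
        for _ in range(natives[name]):
            copies.append((name, [Segment(name, 1, genome.lengths[name], "+")]))
    copies.extend(derived)
    return copies


def probe_fragments(events, genome: GenomeModel, panel: FishProbePanel,
                    homozygous: bool = False):
    """Per-chromosome-copy probe fragments with their detectability."""
    out = []
    for copy_name, segments in _chromosome_copies(events, genome, homozygous):
        for color, chrom, (ps, pe) in panel.probes:
            for seg in segments:
                if seg.chrom != chrom:
                    continue
                lo, hi = max(ps, seg.start), min(pe, seg.end)
                if lo > hi:
                    continue
                length = hi - lo + 1
                out.append({
                    "copy": copy_name,
                    "color": color,
                    "chrom": chrom,
                    "length": length,
                    "detected": length >= panel.min_detectable_bp,
                })
    return out


def predict_fish_pattern(events, genome: GenomeModel, panel: FishProbePanel,
                         homozygous: bool = False) -> dict[str, int]:
    """Predicted interphase signal multiset {green, red, yellow}.

    Detectable green and red fragments colocalized on the same derivative
    fuse into a single yellow signal; everything else signals in its own
    color.  The genome is assumed diploid.
    """
    counts = {"green": 0, "red": 0, "yellow": 0}
    for copy_name, segments in _chromosome_copies(events, genome, homozygous):
        g = r = 0
        for color, chrom, (ps, pe) in panel.probes:
            for seg in segments:
                if seg.chrom != chrom:
                    continue
                lo, hi = max(ps, seg.start), min(pe, seg.end)
                if lo > hi or hi - lo + 1 < panel.min_detectable_bp:
                    continue
                if color == "green":
                    g += 1
                else:
                    r += 1
        y = min(g, r)
        counts["yellow"] += y
        counts["green"] += g - y
        counts["red"] += r - y
    return counts


# ---------------------------------------------------------------------------
# clonal comparison
# ---------------------------------------------------------------------------

@dataclass
class SampleCallset:
    """All junctions called for one sample, with evidence and provenance."""

    sample: str
    junctions: list[Junction] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def sorted(self):
        return sorted(self.junctions,
                      key=lambda j: (chrom_sort_key(j.donor.chrom), j.donor.pos,
                                     chrom_sort_key(j.acceptor.chrom), j.acceptor.pos))


@dataclass
class CloneComparison:
    relation: str  # identical | shared_subset | disjoint
    shared: list[Junction]
    lost: list[Junction]
    gained: list[Junction]
    coordinate_only: bool = False


def compare_clones(diagnosis: SampleCallset, relapse: SampleCallset,
                   flank_bp: int = 300) -> CloneComparison:
    """Clonal relation between diagnosis and relapse callsets.

    Two junctions are the same clone marker when their canonical
    breakends agree *and* their fused flank sequences are identical.
    When either side lacks flank sequences the comparison degrades to
    coordinates only and is flagged ``coordinate_only``.
    """
    coordinate_only = False

    def ident(j: Junction):
        nonlocal coordinate_only
        flank = j.flank_seq
        if flank is None:
            coordinate_only = True
            return j.key()
        return j.key() + (flank[:2 * flank_bp + len(j.inserted_seq)].upper(),)

    dmap = {ident(j): j for j in diagnosis.junctions}
    rmap = {ident(j): j for j in relapse.junctions}
    if coordinate_only:
        # degrade *both* sides to coordinates so keys stay comparable
        dmap = {j.key(): j for j in diagnosis.junctions}
        rmap = {j.key(): j for j in relapse.junctions}
    shared = [dmap[k] for k in dmap.keys() & rmap.keys()]
    lost = [dmap[k] for k in dmap.keys() - rmap.keys()]
    gained = [rmap[k] for k in rmap.keys() - dmap.keys()]
    if not lost and not gained:
        relation = "identical"
    elif shared:
        relation = "shared_subset"
    else:
        relation = "disjoint"
    order = lambda js: sorted(js, key=lambda j: j.key())
    return CloneComparison(relation, order(shared), order(lost), order(gained),
                           coordinate_only)
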