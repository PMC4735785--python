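"""Read-pair ingestion and concordance classification.

External alignments (SAM/BAM from any aligner, read via pysam) are the
first-class input; a minimal built-in k-mer seed-and-extend mapper is
provided so the whole pipeline can run self-contained on toy references
of up to ~1 Mbp.  Pairs are classified against a robust insert-size
model: evidence pairs must have mapping quality strictly greater than 30
and either map to two chromosomes, deviate from the median insert by
more than four standard deviations, or sit in an unexpected (non-FR)
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rearrange import GenomeModel, revcomp

__all__ = ["ReadAlignment", "AlignedPair", "InsertSizeModel", "ReferenceIndex",
           "builtin_map", "estimate_insert_model", "classify_pair",
           "read_sam", "write_sam"]

PAIR_CLASSES = ("proper", "discordant_distance", "discordant_orientation",
                "interchromosomal", "low_quality")


@dataclass
class ReadAlignment:
    """One mate's best placement; ``chrom is None`` means unmapped.

    ``pos`` is the 1-based reference start of the aligned span,
    ``clip_left``/``clip_right`` count soft-clipped bases at the read's
    ends *in reference orientation*.
    """

    name: str
    mate: int  # 1 or 2
    seq: str
    chrom: str | None = None
    pos: int = 0
    strand: str = "F"
    clip_left: int = 0
    aligned_len: int = 0
    clip_right: int = 0
    mapq: int = 0
    matches: int = 0

    @property
    def end(self) -> int:
        """1-based inclusive end of the aligned span."""
        return self.pos + self.aligned_len - 1

    @property
    def total_clip(self) -> int:
        return self.clip_left + self.clip_right


@dataclass
class AlignedPair:
    name: str
    r1: ReadAlignment
    r2: ReadAlignment

    def mates(self):
        return (self.r1, self.r2)

    @property
    def separation(self) -> int | None:
        """Outer span of the two mates when co-chromosomal and mapped."""
        a, b = self.r1, self.r2
        if a.chrom is None or b.chrom is None or a.chrom != b.chrom:
            return None
        return max(a.end, b.end) - min(a.pos, b.pos) + 1

    @property
    def fr_inward(self) -> bool:
        a, b = sorted((self.r1, self.r2), key=lambda r: (r.pos, r.strand))
        return a.strand == "F" and b.strand == "R"


# ---------------------------------------------------------------------------
# built-in mapper
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Exact k-mer index over a concatenated reference (forward strand)."""

    def __init__(self, genome: GenomeModel, k: int = 21):
        if not genome.lengths:
            raise ValueError("empty reference")
        self.k = k
        self.genome = genome
        offsets = {}
        parts = []
        off = 0
        for name in genome.lengths:
            seq = genome.seq(name)
            offsets[name] = off
            parts.append(seq)
            off += len(seq) + k  # k-spacer of 'N' prevents cross-chrom k-mers
            parts.append("N" * k)
        self.offsets = offsets
        self.concat = "".join(parts)
        self.arr = np.frombuffer(self.concat.encode(), dtype=np.uint8)
        self.bounds = sorted((v, name) for name, v in offsets.items())
        index: dict[str, list[int]] = {}
        cat = self.concat
        for name in genome.lengths:
            start = offsets[name]
            stop = start + genome.lengths[name] - k + 1
            for i in range(start, max(start, stop)):
                km = cat[i:i + k]
                if "N" in km:
                    continue
                index.setdefault(km, []).append(i)
        self.index = index

    def locate(self, gpos: int) -> tuple[str, int]:
        """Concatenated position -> (chrom, 1-based position)."""
        lo = None
        for off, name in self.bounds:
            if gpos >= off:
                lo = (off, name)
            else:
                break
        off, name = lo
        return name, gpos - off + 1


def _best_span(match: np.ndarray, mismatch_penalty: int = 3):
    """Maximal-scoring contiguous window of a match/mismatch vector."""
    scores = np.where(match, 1, -mismatch_penalty).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(scores)))
    mins = np.minimum.accumulate(cs[:-1])
    gains = cs[1:] - mins
    e = int(np.argmax(gains))
    s = int(np.argmin(cs[:e + 1]))
    return s, e + 1, int(gains[e])  # [s, e) and score


def _map_one(idx: ReferenceIndex, seq: str):
    k = idx.k
    L = len(seq)
    if L < k:
        return None
    candidates = set()
    for query, strand in ((seq, "F"), (revcomp(seq), "R")):
        for off in {0, max(0, L // 2 - k // 2), L - k}:
            for g in idx.index.get(query[off:off + k], ()):
                candidates.add((g - off, strand))
    if not candidates:
        return None
    best = []
    rarr = {s: np.frombuffer(q.encode(), dtype=np.uint8)
            for q, s in ((seq, "F"), (revcomp(seq), "R"))}
    for g, strand in candidates:
        if g < 0 or g + L > len(idx.arr):
            continue
        ref = idx.arr[g:g + L]
        match = ref == rarr[strand]
        nm = int(match.sum())
        best.append((nm, g, strand, match))
    if not best:
        return None
    best.sort(key=lambda t: (-t[0], t[1], t[2]))
    nm, g, strand, match = best[0]
    tied = len(best) > 1 and best[1][0] == nm
    if nm < k:
        return None
    s, e, _ = _best_span(match)
    chrom, pos = idx.locate(g + s)
    if strand == "F":
        clip_left, clip_right = s, L - e
    else:  # clips reported in reference orientation
        clip_left, clip_right = s, L - e
    return dict(chrom=chrom, pos=pos, strand=strand,
                clip_left=clip_left, aligned_len=e - s, clip_right=clip_right,
                mapq=3 if tied else 60, matches=nm)


def builtin_map(pairs, genome: GenomeModel, k: int = 21,
                index: ReferenceIndex | None = None) -> list[AlignedPair]:
    """Map (name, seq1, seq2) tuples or simulator ReadPairs to the reference.

    Best placement per read; MQ 60 for a unique best hit, 3 for ties,
    unmapped when no seed matches.  Ungapped extension with soft clips at
    the maximal-scoring span (match +1 / mismatch -3).
    """
    idx = index or ReferenceIndex(genome, k)
    out = []
    for item in pairs:
        if hasattr(item, "seq1"):
            name, s1, s2 = item.name, item.seq1, item.seq2
        else:
            name, s1, s2 = item
        mates = []
        for mate, seq in ((1, s1), (2, s2)):
            hit = _map_one(idx, seq)
            aln = ReadAlignment(name=name, mate=mate, seq=seq)
            if hit:
                for key, val in hit.items():
                    setattr(aln, key, val)
            mates.append(aln)
        out.append(AlignedPair(name, mates[0], mates[1]))
    return out


# ---------------------------------------------------------------------------
# insert-size model
# ---------------------------------------------------------------------------

@dataclass
class InsertSizeModel:
    """Robust location/scale of the concordant insert-size distribution."""

    center: float  # median separation
    spread: float  # 1.4826 * MAD
    n_pairs: int
    unimodal: bool = True


def estimate_insert_model(pairs, min_pairs: int = 100) -> InsertSizeModel:
    """Median/MAD insert model from co-chromosomal inward-FR pairs.

    ``spread = 1.4826 * MAD`` (consistent for a normal scale); a coarse
    histogram dip check sets the unimodality flag.
    """
    seps = [p.separation for p in pairs
            if p.separation is not None and p.fr_inward]
    if len(seps) < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} co-chromosomal FR pairs to fit the insert "
            f"model, got {len(seps)}; provide more input")
    seps = np.asarray(seps, dtype=float)
    center = float(np.median(seps))
    spread = float(1.4826 * np.median(np.abs(seps - center)))
    hist, _ = np.histogram(seps, bins=20)
    # half-height contiguity: one mode iff the bins above half maximum
    # form a single contiguous run
    above = hist >= 0.5 * hist.max()
    runs = int(np.count_nonzero(np.diff(above.astype(int)) == 1)) + int(above[0])
    return InsertSizeModel(center=center, spread=spread, n_pairs=len(seps),
                           unimodal=runs <= 1)


def classify_pair(pair: AlignedPair, model: InsertSizeModel,
                  mq_min: int = 30, k_sd: float = 4.0) -> str:
    """One of proper / discordant_distance / discordant_orientation /
    interchromosomal / low_quality.

    Mapping quality must be *strictly* greater than ``mq_min`` on both
    mates for the pair to serve as SV evidence; the distance rule is
    two-sided: ``|separation - center| > k_sd * spread``.
    """
    a, b = pair.r1, pair.r2
    if (a.chrom is None or b.chrom is None
            or a.mapq <= mq_min or b.mapq <= mq_min):
        return "low_quality"
    if a.chrom != b.chrom:
        return "interchromosomal"
    if not pair.fr_inward:
        return "discordant_orientation"
    if abs(pair.separation - model.center) > k_sd * model.spread:
        return "discordant_distance"
    return "proper"


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

def _from_pysam(rec) -> ReadAlignment:
    name = rec.query_name
    mate = 2 if rec.is_read2 else 1
    seq = rec.query_sequence or ""
    if rec.is_unmapped:
        return ReadAlignment(name, mate, seq)
    clip_left = clip_right = 0
    cig = rec.cigartuples or []
    if cig and cig[0][0] in (4, 5):
        clip_left = cig[0][1]
    if len(cig) > 1 and cig[-1][0] in (4, 5):
        clip_right = cig[-1][1]
    return ReadAlignment(
        name, mate, seq, chrom=rec.reference_name,
        pos=rec.reference_start + 1, strand="R" if rec.is_reverse else "F",
        clip_left=clip_left, clip_right=clip_right,
        aligned_len=rec.reference_end - rec.reference_start,
        mapq=rec.mapping_quality)


def read_sam(path) -> list[AlignedPair]:
    """Primary alignments from SAM/BAM (auto-detected), paired by name."""
    import pysam

    by_name: dict[str, dict[int, ReadAlignment]] = {}
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                aln = _from_pysam(rec)
                by_name.setdefault(aln.name, {})[aln.mate] = aln
    finally:
        pysam.set_verbosity(save)
    out = []
    for name, mates in by_name.items():
        r1 = mates.get(1) or ReadAlignment(name, 1, "")
        r2 = mates.get(2) or ReadAlignment(name, 2, "")
        out.append(AlignedPair(name, r1, r2))
    return out


def write_sam(pairs: list[AlignedPair], genome: GenomeModel, path):
    """Write pairs as SAM with a header derived from the reference."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": l} for n, l in genome.lengths.items()]}
    refs = {n: i for i, n in enumerate(genome.lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for pair in pairs:
            for aln, flag_mate in ((pair.r1, 0x40), (pair.r2, 0x80)):
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = aln.name
                rec.query_sequence = (
                    aln.seq if aln.strand == "F" or aln.chrom is None
                    else revcomp(aln.seq))
                rec.flag = 0x1 | flag_mate
                if aln.chrom is None:
                    rec.flag |= 0x4
                    rec.reference_id = -1
                else:
                    rec.reference_id = refs[aln.chrom]
                    rec.reference_start = aln.pos - 1
                    rec.mapping_quality = aln.mapq
                    if aln.strand == "R":
                        rec.flag |= 0x10
                    cig = []
                    if aln.clip_left:
                        cig.append((4, aln.clip_left))
                    cig.append((0, aln.aligned_len))
                    if aln.clip_right:
                        cig.append((4, aln.clip_right))
                    rec.cigartuples = cig
                rec.next_reference_id = -1
                fh.write(rec)
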