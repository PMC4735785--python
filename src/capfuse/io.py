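"""Format readers and writers shared across the package.

External coordinates are 1-based inclusive everywhere (the junction TSV
dialect and VCF); BED input is 0-based half-open per the standard and is
converted at this boundary.  Thousands separators are tolerated when
reading breakpoint tables and never written.
"""

from __future__ import annotations

import importlib.resources
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rearrange import (Breakend, GenomeModel, Junction, canonical,
                        chrom_sort_key, mirror)

JUNCTION_COLUMNS = [
    "Sample", "Left_chr", "Left_str", "Left_breakpoint", "Gene_left",
    "Right_chr", "Right_str", "Right_breakpoint", "Gene_right", "Mode",
]


def parse_position(value) -> int:
    """Parse a 1-based coordinate, tolerating thousands separators."""
    if pd.isna(value):
        raise ValueError("missing position")
    s = str(value).strip().replace(",", "").replace(" ", "")
    if not re.fullmatch(r"\d+", s):
        raise ValueError(f"malformed position {value!r}")
    return int(s)


def fixture_path(name: str) -> Path:
    """Path to a packaged table fixture (e.g. ``table2_junctions.tsv``)."""
    return Path(importlib.resources.files("capfuse").joinpath("data").joinpath(name))


def read_junction_table(path=None) -> pd.DataFrame:
    """Read a breakpoint table in the junction TSV dialect.

    Defaults to the packaged 26-patient cohort table.  Positions keep
    their printed form; use :func:`junctions_from_table` for typed access.
    """
    if path is None:
        path = fixture_path("table2_junctions.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"junction table missing columns: {missing}")
    return df


def junctions_from_table(df: pd.DataFrame) -> list[Junction]:
    """Typed junctions from a table; left/right columns are donor/acceptor."""
    out = []
    for idx, row in df.iterrows():
        try:
            for col in ("Left_str", "Right_str"):
                if row[col] not in ("F", "R"):
                    raise ValueError(f"strand must be F or R, got {row[col]!r}")
            j = Junction(
                donor=Breakend(row["Left_chr"], parse_position(row["Left_breakpoint"]),
                               row["Left_str"]),
                acceptor=Breakend(row["Right_chr"], parse_position(row["Right_breakpoint"]),
                                  row["Right_str"]),
                sample=row["Sample"],
            )
        except ValueError as exc:
            raise ValueError(f"row {idx} ({row.get('Sample', '?')}): {exc}") from None
        out.append(j)
    return out


def write_junction_table(junctions: list[Junction], path,
                         genes: dict | None = None):
    """Write junctions in the TSV dialect (no thousands separators)."""
    rows = []
    for j in junctions:
        rows.append({
            "Sample": j.sample or "",
            "Left_chr": j.donor.chrom, "Left_str": j.donor.strand,
            "Left_breakpoint": j.donor.pos,
            "Gene_left": (genes or {}).get((j.donor.chrom, j.donor.pos), ""),
            "Right_chr": j.acceptor.chrom, "Right_str": j.acceptor.strand,
            "Right_breakpoint": j.acceptor.pos,
            "Gene_right": (genes or {}).get((j.acceptor.chrom, j.acceptor.pos), ""),
            "Mode": "",
            "Microhomology": j.microhomology_len,
            "Inserted_seq": j.inserted_seq,
            "Support_pairs": j.support_pairs,
            "Support_split": j.support_split,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_patient_table(path=None) -> pd.DataFrame:
    if path is None:
        path = fixture_path("table1_patients.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"POND_id": str})
    return df


def read_relapse_table(path=None) -> pd.DataFrame:
    if path is None:
        path = fixture_path("table3_relapse.tsv")
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# BED / FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int]]:
    """BED intervals converted to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out


def write_bed(regions: list[tuple[str, int, int]], path):
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path):
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta")


def genome_from_files(fasta_path, bed_path=None,
                      centromeres: dict | None = None) -> GenomeModel:
    seqs = read_fasta(fasta_path)
    targets = read_bed(bed_path) if bed_path else []
    return GenomeModel(
        lengths={n: len(s) for n, s in seqs.items()},
        sequences=seqs,
        centromeres=centromeres or {},
        target_regions=targets,
    )


def write_fastq(reads: list[tuple[str, str, str]], path):
    """Write (name, sequence, quality-string) records."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


# ---------------------------------------------------------------------------
# VCF 4.2 breakend notation
# ---------------------------------------------------------------------------

def _bnd_alt(donor_strand: str, acceptor: Breakend, base: str = "N") -> str:
    """ALT string for the record written at the donor breakend.

    Donor F joins the mate *after* the REF base; donor R before it.
    Acceptor F extends right of its position (square brackets opening
    right), acceptor R is the reverse-complement piece extending left
    (closing brackets).
    """
    mate = f"{acceptor.chrom}:{acceptor.pos}"
    if donor_strand == "F":
        return f"{base}[{mate}[" if acceptor.strand == "F" else f"{base}]{mate}]"
    return f"[{mate}[{base}" if acceptor.strand == "F" else f"]{mate}]{base}"


def write_vcf_bnd(junctions: list[Junction], lengths: dict[str, int], path,
                  seed: int | None = None, sample: str | None = None):
    """Write junctions as paired VCF 4.2 BND records (two mates each)."""
    lines = ["##fileformat=VCFv4.2"]
    if seed is not None:
        lines.append(f"##seed={seed}")
    for name in sorted(lengths, key=chrom_sort_key):
        lines.append(f"##contig=<ID={name},length={lengths[name]}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">',
        '##INFO=<ID=SUPPORT_PAIRS,Number=1,Type=Integer,Description="Discordant pair support">',
        '##INFO=<ID=SUPPORT_SPLIT,Number=1,Type=Integer,Description="Split read support">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Untemplated inserted sequence">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    records = []
    for i, j in enumerate(sorted(junctions, key=lambda x: x.key()), start=1):
        jc = canonical(j)
        for tag, side in (("a", jc), ("b", mirror(jc))):
            info = [
                "SVTYPE=BND",
                f"MATEID=bnd_{i}{'b' if tag == 'a' else 'a'}",
                f"HOMLEN={jc.microhomology_len}",
                f"SUPPORT_PAIRS={jc.support_pairs}",
                f"SUPPORT_SPLIT={jc.support_split}",
            ]
            ins = side.inserted_seq
            if ins:
                info.append(f"INSSEQ={ins}")
            records.append((
                chrom_sort_key(side.donor.chrom), side.donor.pos,
                f"{side.donor.chrom}\t{side.donor.pos}\tbnd_{i}{tag}\tN\t"
                f"{_bnd_alt(side.donor.strand, side.acceptor)}\t.\tPASS\t"
                + ";".join(info)))
    records.sort(key=lambda r: (r[0], r[1]))
    lines += [r[2] for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


_BND_RE = re.compile(
    r"^(?P<b1>[\[\]])?(?:(?P<mate1>[\w.]+):(?P<pos1>\d+))?(?P<b2>[\[\]])?"
    r"(?P<base>[ACGTNacgtn]+)"
    r"(?P<b3>[\[\]])?(?:(?P<mate2>[\w.]+):(?P<pos2>\d+))?(?P<b4>[\[\]])?$")


def parse_bnd_alt(chrom: str, pos: int, alt: str) -> Junction:
    """Reconstruct a junction from one BND record's locus and ALT."""
    m = _BND_RE.match(alt)
    if not m or (m.group("mate1") is None and m.group("mate2") is None):
        raise ValueError(f"not a breakend ALT: {alt!r}")
    base = m.group("base")
    if m.group("mate2"):  # t[...[ or t]...] : donor F
        donor = Breakend(chrom, pos, "F")
        acc_strand = "F" if m.group("b3") == "[" else "R"
        acceptor = Breakend(m.group("mate2"), int(m.group("pos2")), acc_strand)
    else:  # [...[t or ]...]t : donor R
        donor = Breakend(chrom, pos, "R")
        acc_strand = "F" if m.group("b1") == "[" else "R"
        acceptor = Breakend(m.group("mate1"), int(m.group("pos1")), acc_strand)
    ins = base[1:] if len(base) > 1 else ""
    return Junction(donor, acceptor, inserted_seq=ins)


def read_vcf_bnd(path) -> list[Junction]:
    """Read BND records back into canonical junctions (mates deduplicated)."""
    import pysam

    seen: dict[tuple, Junction] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.info.get("SVTYPE") != "BND":
                continue
            j = parse_bnd_alt(rec.chrom, rec.pos, rec.alts[0])
            j.microhomology_len = int(rec.info.get("HOMLEN", 0))
            j.support_pairs = int(rec.info.get("SUPPORT_PAIRS", 0))
            j.support_split = int(rec.info.get("SUPPORT_SPLIT", 0))
            ins = rec.info.get("INSSEQ")
            if ins and not j.inserted_seq:
                j.inserted_seq = str(ins)
            jc = canonical(j)
            seen.setdefault(jc.key(), jc)
    return list(seen.values())
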