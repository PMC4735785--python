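"""Patient-specific genomic fusion sequences for MRD assay design.

The fused breakpoint-flanking sequence is unique to each leukemic clone,
which makes it a stable quantitative PCR target for minimal residual
disease monitoring -- unlike fusion-transcript levels, which fluctuate
with expression.  This module emits one FASTA record per called junction
(donor flank + untemplated insertion + acceptor flank) together with a
TSV manifest locating the junction inside each record.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .rearrange import (GenomeModel, Junction, SampleCallset, canonical,
                        chrom_sort_key, classify_type, fused_flank)

__all__ = ["MrdTarget", "export_mrd_targets"]


@dataclass
class MrdTarget:
    """One exportable fusion sequence around a junction."""

    record_id: str
    sample: str
    junction: Junction
    sequence: str
    flank_bp: int
    offset: int  # donor-side length; the junction sits right after it
    clipped: bool


def _record_id(sample: str, j: Junction, i: int) -> str:
    try:
        label = classify_type(j)
    except ValueError:
        label = f"{j.donor.chrom.replace('chr', '')}-{j.acceptor.chrom.replace('chr', '')}"
    return f"{sample}_j{i}_{label}"


def export_mrd_targets(callset: SampleCallset, genome: GenomeModel,
                       flank_bp: int = 300, fasta_path=None,
                       manifest_path=None) -> list[MrdTarget]:
    """Fusion sequences (breakpoint +/- ``flank_bp``) for every junction.

    Records are deterministic: junctions are canonicalized and sorted
    before numbering.  A flank running past a chromosome end is clipped
    and flagged in the manifest.  Optionally writes FASTA and a TSV
    manifest.
    """
    ordered = sorted((canonical(j) for j in callset.junctions),
                     key=lambda j: j.key())
    targets = []
    for i, j in enumerate(ordered, start=1):
        seq, offset, clipped = fused_flank(j, genome, flank_bp)
        targets.append(MrdTarget(
            record_id=_record_id(callset.sample, j, i),
            sample=callset.sample, junction=j, sequence=seq,
            flank_bp=flank_bp, offset=offset, clipped=clipped))
    if fasta_path is not None:
        from . import io as _io
        _io.write_fasta({t.record_id: t.sequence for t in targets}, fasta_path)
    if manifest_path is not None:
        rows = []
        for t in targets:
            j = t.junction
            rows.append({
                "record_id": t.record_id, "sample": t.sample,
                "donor_chrom": j.donor.chrom, "donor_pos": j.donor.pos,
                "donor_strand": j.donor.strand,
                "acceptor_chrom": j.acceptor.chrom, "acceptor_pos": j.acceptor.pos,
                "acceptor_strand": j.acceptor.strand,
                "microhomology_len": j.microhomology_len,
                "inserted_len": len(j.inserted_seq),
                "flank_bp": t.flank_bp, "junction_offset": t.offset,
                "seq_len": len(t.sequence), "clipped": t.clipped,
            })
        pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return targets
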