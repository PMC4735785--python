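"""Caller mechanics: clustering, windows, assembly, resolution, support."""

import numpy as np
import pytest

from capfuse.align_ingest import (AlignedPair, InsertSizeModel, ReadAlignment,
                                  builtin_map, estimate_insert_model)
from capfuse.rearrange import Breakend, Junction, derivative_sequence, revcomp
from capfuse.simulate import (SimulationConfig, apply_junctions,
                              make_toy_genome, preset_scenario, simulate_reads)
from capfuse.sv_call import (DiscordantCluster, ResolvedJunction,
                             SvCallingParams, assemble_contig, call_sample,
                             cluster_discordant, count_support,
                             extract_window_reads, resolve_junction)

MODEL = InsertSizeModel(center=375.0, spread=35.0, n_pairs=1000)


def _evidence_pair(name, pos1, pos2, chrom1="cA", chrom2="cB",
                   strands=("F", "F"), mq=60):
    r1 = ReadAlignment(name, 1, "A" * 100, chrom=chrom1, pos=pos1,
                       strand=strands[0], aligned_len=100, mapq=mq)
    r2 = ReadAlignment(name, 2, "A" * 100, chrom=chrom2, pos=pos2,
                       strand=strands[1], aligned_len=100, mapq=mq)
    return AlignedPair(name, r1, r2)


class TestParams:
    def test_window_bounds_enforced(self):
        SvCallingParams(window_bp=500)
        SvCallingParams(window_bp=1000)
        with pytest.raises(ValueError, match="window_bp"):
            SvCallingParams(window_bp=1200)


class TestClusterDiscordant:
    def test_below_minimum_yields_no_cluster(self):
        pairs = [_evidence_pair(f"p{i}", 5000 + 40 * i, 8000 - 40 * i)
                 for i in range(2)]
        assert cluster_discordant(pairs, MODEL,
                                  SvCallingParams(min_cluster_pairs=3)) == []

    def test_two_distant_junctions_make_two_clusters(self):
        near = [_evidence_pair(f"a{i}", 5000 + 30 * i, 8000 + 30 * i)
                for i in range(5)]
        far = [_evidence_pair(f"b{i}", 55_000 + 30 * i, 58_000 + 30 * i)
               for i in range(5)]
        clusters = cluster_discordant(near + far, MODEL, SvCallingParams())
        assert len(clusters) == 2
        assert all(c.n_pairs == 5 for c in clusters)

    def test_predicted_breakends_are_innermost_coordinates(self):
        pairs = [_evidence_pair(f"p{i}", 5000 + 40 * i, 8000 + 40 * i)
                 for i in range(5)]
        (cl,) = cluster_discordant(pairs, MODEL, SvCallingParams())
        # both sides observed F: innermost = rightmost alignment end
        assert cl.breakend1.pos == 5000 + 160 + 99
        assert cl.breakend2.pos == 8000 + 160 + 99
        assert (cl.breakend1.strand, cl.breakend2.strand) == ("F", "R")

    def test_orientation_patterns_separate(self):
        a = [_evidence_pair(f"a{i}", 5000 + i, 8000 + i) for i in range(4)]
        b = [_evidence_pair(f"b{i}", 5000 + i, 8000 + i, strands=("R", "R"))
             for i in range(4)]
        clusters = cluster_discordant(a + b, MODEL, SvCallingParams())
        assert sorted(c.pattern for c in clusters) == [("F", "F"), ("R", "R")]

    def test_low_mq_pairs_excluded(self):
        pairs = [_evidence_pair(f"p{i}", 5000, 8000, mq=30) for i in range(5)]
        assert cluster_discordant(pairs, MODEL, SvCallingParams()) == []


class TestExtractWindowReads:
    def _pairs(self):
        out = []
        for i, pos in enumerate((4900, 5000 - 750 - 99, 5000 - 750 - 100)):
            out.append(_evidence_pair(f"p{i}", pos, 9000))
        # unmapped mate anchored inside the window
        anchored = ReadAlignment("u", 1, "A" * 100, chrom="cA", pos=5100,
                                 strand="F", aligned_len=100, mapq=60)
        floating = ReadAlignment("u", 2, "C" * 100)
        out.append(AlignedPair("u", anchored, floating))
        return out

    def test_window_boundary_inclusive_exclusive(self):
        params = SvCallingParams(window_bp=750)
        reads = extract_window_reads(self._pairs(), Breakend("cA", 5000, "F"),
                                     params)
        names = {(r.name, r.mate) for r in reads}
        assert ("p0", 1) in names          # well inside
        assert ("p1", 1) in names          # read end exactly at window edge
        assert ("p2", 1) not in names      # one base beyond the window
        assert ("u", 2) in names           # unmapped read, mate in window

    def test_empty_input(self):
        assert extract_window_reads([], Breakend("cA", 5000, "F"),
                                    SvCallingParams()) == []

    def test_breakend_outside_reference(self):
        g = make_toy_genome([("cA", 1000)], seed=1)
        with pytest.raises(ValueError):
            extract_window_reads([], Breakend("cA", 5000, "F"),
                                 SvCallingParams(), genome=g)


class TestAssembleContig:
    def test_tiling_reads_reconstruct_fused_sequence(self):
        g = make_toy_genome([("cA", 4000), ("cB", 4000)], seed=21)
        truth = apply_junctions(g, [Junction(Breakend("cA", 2000, "F"),
                                             Breakend("cB", 1500, "R"))])
        der = truth.derivatives[0].seq
        reads = [der[i:i + 100] for i in range(1800, 2100, 20)]
        contig, support, flag = assemble_contig(reads, SvCallingParams())
        region = der[1900:2000]  # junction at offset 2000
        assert region in contig or revcomp(region) in contig
        assert not flag

    def test_disjoint_groups_flagged(self):
        g = make_toy_genome([("cA", 4000)], seed=22)
        s = g.seq("cA")
        reads = [s[0:100], s[20:120], s[2000:2100], s[2020:2120]]
        contig, _, flag = assemble_contig(reads, SvCallingParams())
        assert flag
        assert len(contig) == 120

    def test_duplicate_reads_idempotent(self):
        contig, support, flag = assemble_contig(["ACGTACGTGGA" * 10] * 4,
                                                SvCallingParams())
        assert contig == "ACGTACGTGGA" * 10
        assert int(support.min()) == 4

    def test_no_reads_rejected(self):
        with pytest.raises(ValueError):
            assemble_contig([], SvCallingParams())


class TestResolveJunction:
    def test_forward_reverse_junction(self, small_seq_genome):
        g = small_seq_genome
        truth = apply_junctions(g, [Junction(Breakend("cA", 2000, "F"),
                                             Breakend("cB", 1500, "R"))])
        j = truth.derivatives[0].junction
        der = truth.derivatives[0].seq
        res = resolve_junction(der[1850:2150], g, SvCallingParams())
        assert res is not None
        assert res.junction.donor == j.donor
        assert res.junction.acceptor == j.acceptor

    def test_engineered_microhomology_reported_leftmost(self, small_seq_genome):
        truth = apply_junctions(small_seq_genome,
                                [Junction(Breakend("cA", 2000, "F"),
                                          Breakend("cB", 1500, "F"))],
                                homology_len=4)
        j = truth.derivatives[0].junction
        der = truth.derivatives[0].seq
        res = resolve_junction(der[1850:2150], truth.genome, SvCallingParams())
        assert res.junction.microhomology_len == j.microhomology_len >= 4
        assert res.junction.donor.pos == j.donor.pos  # leftmost convention

    def test_untemplated_insertion_recovered(self, small_seq_genome):
        truth = apply_junctions(small_seq_genome,
                                [Junction(Breakend("cA", 2000, "F"),
                                          Breakend("cB", 1500, "F"))],
                                insertion_seq="GGTACC")
        der = truth.derivatives[0].seq
        res = resolve_junction(der[1850:2160], truth.genome, SvCallingParams())
        assert res.junction.inserted_seq == truth.derivatives[0].junction.inserted_seq

    def test_pure_reference_contig_is_no_junction(self, small_seq_genome):
        g = small_seq_genome
        assert resolve_junction(g.seq("cA")[1000:1300], g,
                                SvCallingParams()) is None

    def test_too_short_contig(self, small_seq_genome):
        assert resolve_junction("ACGTACGT", small_seq_genome,
                                SvCallingParams()) is None


class TestCountSupport:
    @pytest.fixture()
    def resolved(self, small_seq_genome):
        g = small_seq_genome
        truth = apply_junctions(g, [Junction(Breakend("cA", 2000, "F"),
                                             Breakend("cB", 1500, "R"))])
        der = truth.derivatives[0].seq
        contig = der[1900:2100]  # junction at contig offset 100
        res = resolve_junction(contig, g, SvCallingParams())
        return g, der, contig, res

    def _read(self, seq, clipped=True):
        # clipped=True mimics a read whose reference alignment left clips
        return ReadAlignment("r", 1, seq, chrom="cA", pos=1, strand="F",
                             aligned_len=len(seq) - (5 if clipped else 0),
                             clip_right=5 if clipped else 0, mapq=60)

    def test_two_extra_bases_support_boundary(self, resolved):
        g, der, contig, res = resolved
        wl, wr = res.window_left, res.window_right
        # read ending exactly min_cross bases past the junction window
        read2 = self._read(contig[40:wr + 2])
        read1 = self._read(contig[40:wr + 1])
        n2, _ = count_support([read2], contig, res, g, SvCallingParams())
        n1, reasons1 = count_support([read1], contig, res, g, SvCallingParams())
        assert n2 == 1
        assert n1 == 0 and reasons1["insufficient_cross"] == 1

    def test_unaligned_end_bases_boundary(self, resolved):
        g, der, contig, res = resolved
        core = contig[40:160]
        ok = self._read(core + "NNNN")      # 4 unaligned end bases: accepted
        bad = self._read(core + "NNNNN")    # 5: rejected
        n_ok, _ = count_support([ok], contig, res, g, SvCallingParams())
        n_bad, reasons = count_support([bad], contig, res, g, SvCallingParams())
        assert n_ok == 1
        assert n_bad == 0 and reasons["unaligned_ends"] == 1

    def test_reference_explained_read_rejected(self, resolved):
        g, der, contig, res = resolved
        read = self._read(contig[40:160], clipped=False)
        n, reasons = count_support([read], contig, res, g, SvCallingParams())
        assert n == 0 and reasons["reference_explained"] == 1

    def test_support_partition(self, resolved):
        g, der, contig, res = resolved
        reads = [self._read(contig[i:i + 100]) for i in range(0, 100, 10)]
        n, reasons = count_support(reads, contig, res, g, SvCallingParams())
        assert n + sum(reasons.values()) == len(reads)


@pytest.fixture(scope="module")
def reciprocal_case():
    truth, reads, cfg = preset_scenario("c_d_reciprocal", seed=5)
    return truth, reads


class TestCallSample:

    def test_reciprocal_recovered_exactly(self, reciprocal_case):
        truth, reads = reciprocal_case
        cs = call_sample(truth.genome, SvCallingParams(), fastq_pairs=reads)
        assert len(cs.junctions) == 2
        got = {(j.donor.chrom, j.donor.pos, j.donor.strand,
                j.acceptor.chrom, j.acceptor.pos, j.acceptor.strand)
               for j in cs.junctions}
        want = {(j.donor.chrom, j.donor.pos, j.donor.strand,
                 j.acceptor.chrom, j.acceptor.pos, j.acceptor.strand)
                for j in truth.junctions}
        assert got == want
        assert all(j.support_split >= 2 and j.support_pairs >= 3
                   for j in cs.junctions)

    def test_raising_min_support_never_adds_junctions(self, reciprocal_case):
        truth, reads = reciprocal_case
        base = call_sample(truth.genome, SvCallingParams(min_support_reads=2),
                           fastq_pairs=reads)
        strict = call_sample(truth.genome,
                             SvCallingParams(min_support_reads=25),
                             fastq_pairs=reads)
        keys = lambda cs: {j.key() for j in cs.junctions}
        assert keys(strict) <= keys(base)

    def test_widening_window_keeps_junctions(self, reciprocal_case):
        truth, reads = reciprocal_case
        narrow = call_sample(truth.genome, SvCallingParams(window_bp=500),
                             fastq_pairs=reads)
        wide = call_sample(truth.genome, SvCallingParams(window_bp=1000),
                           fastq_pairs=reads)
        keys = lambda cs: {j.key() for j in cs.junctions}
        assert keys(narrow) <= keys(wide)

    def test_empty_input_empty_callset(self):
        g = make_toy_genome([("cA", 10_000)], seed=1)
        assert call_sample(g, SvCallingParams(), pairs=[]).junctions == []
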