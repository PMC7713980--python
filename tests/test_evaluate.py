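import numpy as np
import pytest

from _oracles import brute_force_metrics
from paleoref.evaluate import (
    MappingMetrics,
    ToyMapper,
    metrics_from_sam_text,
    sam_header,
    toy_map,
)
from paleoref.maf_io import Genome, revcomp
from paleoref.simulate import FastqRecord


def sam_text(ref: Genome, body_lines: list[str]) -> str:
    return "\n".join(sam_header(ref) + body_lines) + "\n"


def rec(name="r", flag=0, ref="c1", pos=1, mapq=60, cigar="4M", seq="ACGT"):
    return (f"{name}\t{flag}\t{ref}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
            f"{seq}\t{'I' * len(seq)}")


class TestFilters:
    def ref(self):
        return Genome({"c1": "ACGTACGTAC"})

    def metrics(self, lines, total=1):
        return metrics_from_sam_text(sam_text(self.ref(), lines), self.ref(), total)

    def test_mapq_20_passes(self):
        m = self.metrics([rec(mapq=20)])
        assert m.mapped_pct == 100.0

    def test_mapq_19_fails(self):
        assert self.metrics([rec(mapq=19)]).mapped_pct == 0.0

    @pytest.mark.parametrize("flag", [0x100, 0x200, 0x800])
    def test_excluded_flags(self, flag):
        assert self.metrics([rec(flag=flag)]).mapped_pct == 0.0

    def test_duplicate_flag_not_filtered(self):
        assert self.metrics([rec(flag=0x400)]).mapped_pct == 100.0

    def test_unmapped_fails(self):
        lines = ["r\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII"]
        assert self.metrics(lines).mapped_pct == 0.0


class TestComputeMetrics:
    def test_mapped_pct_example(self):
        ref = Genome({"c1": "ACGTACGTAC"})
        lines = [rec(name=f"p{i}", pos=1) for i in range(6)]
        lines += [rec(name=f"l{i}", pos=1, mapq=5) for i in range(2)]
        lines += ["u%d\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII" % i for i in range(2)]
        m = metrics_from_sam_text(sam_text(ref, lines), ref, 10)
        assert m.mapped_pct == 60.0

    def test_breadth_and_depth(self):
        ref = Genome({"c1": "ACGTACGTAC"})
        lines = [rec(name="a", pos=1), rec(name="b", pos=3)]
        m = metrics_from_sam_text(sam_text(ref, lines), ref, 2)
        assert m.breadth_pct == pytest.approx(60.0)
        assert m.mean_depth == pytest.approx(0.8)

    def test_n_exclusion(self):
        ref = Genome({"c1": "ACGTNNACGT"})
        lines = [rec(name="a", pos=1, cigar="10M", seq="ACGTAAACGT")]
        m = metrics_from_sam_text(sam_text(ref, lines), ref, 1)
        assert m.breadth_pct == pytest.approx(100.0)
        assert m.mean_depth == pytest.approx(1.0)
        assert m.ref_missing == 2

    def test_deletion_consumes_reference(self):
        ref = Genome({"c1": "ACGTACGTAC"})
        lines = [rec(name="a", pos=1, cigar="2M3D2M", seq="ACGT")]
        m = metrics_from_sam_text(sam_text(ref, lines), ref, 1)
        assert m.breadth_pct == pytest.approx(70.0)

    def test_insertion_and_clip_do_not_consume(self):
        ref = Genome({"c1": "ACGTACGTAC"})
        lines = [rec(name="a", pos=1, cigar="2M3I2M2S", seq="ACAAAGTAC")]
        m = metrics_from_sam_text(sam_text(ref, lines), ref, 1)
        assert m.breadth_pct == pytest.approx(40.0)

    def test_header_mismatch_error(self):
        ref = Genome({"c1": "ACGTACGTAC"})
        bad_header = ["@HD\tVN:1.6", "@SQ\tSN:c1\tLN:99"]
        text = "\n".join(bad_header + [rec()]) + "\n"
        with pytest.raises(ValueError, match="length mismatch"):
            metrics_from_sam_text(text, ref, 1)

    def test_total_reads_too_small_error(self):
        ref = Genome({"c1": "ACGTACGTAC"})
        with pytest.raises(ValueError):
            metrics_from_sam_text(sam_text(ref, [rec(), rec(name="b")]), ref, 1)

    def test_monotone_in_added_records(self):
        ref = Genome({"c1": "ACGTACGTAC"})
        lines = [rec(name="a", pos=1)]
        m1 = metrics_from_sam_text(sam_text(ref, lines), ref, 10)
        lines.append(rec(name="b", pos=5))
        m2 = metrics_from_sam_text(sam_text(ref, lines), ref, 10)
        assert m2.breadth_pct >= m1.breadth_pct
        assert m2.mean_depth >= m1.mean_depth

    def test_matches_brute_force_fuzz(self):
        rng = np.random.default_rng(50)
        for case in range(10):
            n = int(rng.integers(20, 60))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.22, 0.22, 0.22, 0.22, 0.12]))
            ref = Genome({"c1": seq})
            lines = []
            total = int(rng.integers(1, 15))
            for i in range(total):
                if rng.random() < 0.3:
                    lines.append(f"u{i}\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII")
                    continue
                pos = int(rng.integers(0, n - 10))
                cigar = str(rng.choice(["8M", "3M2D3M", "3M2I3M", "2S4M2S"]))
                import re
                read_len = sum(int(x) for x, op in re.findall(r"(\d+)(\w)", cigar)
                               if op in "MIS")
                mapq = int(rng.choice([0, 19, 20, 60]))
                flag = int(rng.choice([0, 0x100, 0x400]))
                lines.append(rec(name=f"r{i}", flag=flag, pos=pos + 1,
                                 mapq=mapq, cigar=cigar, seq="A" * read_len))
            text = sam_text(ref, lines)
            m = metrics_from_sam_text(text, ref, total)
            exp = brute_force_metrics(text.splitlines(), {"c1": seq}, total)
            assert m.mapped_pct == pytest.approx(exp[0], abs=1e-12)
            assert m.breadth_pct == pytest.approx(exp[1], abs=1e-12)
            assert m.mean_depth == pytest.approx(exp[2], abs=1e-12)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MappingMetrics(10, 120.0, 50.0, 1.0, 100, 0)


class TestToyMapper:
    def ref(self):
        rng = np.random.default_rng(60)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        return Genome({"c1": seq})

    def test_unique_substring_maps_mapq60(self):
        ref = self.ref()
        read = FastqRecord("q/1", ref["c1"][500:600], "I" * 100)
        sam = toy_map([read], ref)
        line = [l for l in sam.splitlines() if not l.startswith("@")][0]
        f = line.split("\t")
        assert (int(f[1]), f[2], int(f[3]), int(f[4]), f[5]) == (0, "c1", 501, 60, "100M")

    def test_duplicated_substring_mapq0(self):
        seq = self.ref()["c1"]
        dup = seq[:200]
        ref = Genome({"c1": dup + seq[200:1000] + dup})
        read = FastqRecord("q", dup[50:150], "I" * 100)
        sam = toy_map([read], ref)
        line = [l for l in sam.splitlines() if not l.startswith("@")][0]
        assert int(line.split("\t")[4]) == 0

    def test_too_many_mismatches_unmapped(self):
        ref = self.ref()
        rng = np.random.default_rng(61)
        read = "".join(rng.choice(list("ACGT"), size=100))
        sam = toy_map([FastqRecord("q", read, "I" * 100)], ref, max_mismatch=3)
        line = [l for l in sam.splitlines() if not l.startswith("@")][0]
        assert int(line.split("\t")[1]) & 0x4

    def test_reverse_complement_maps_flag16(self):
        ref = self.ref()
        read = FastqRecord("q", revcomp(ref["c1"][700:800]), "I" * 100)
        sam = toy_map([read], ref)
        line = [l for l in sam.splitlines() if not l.startswith("@")][0]
        f = line.split("\t")
        assert int(f[1]) == 16
        assert int(f[3]) == 701
        assert f[9] == ref["c1"][700:800]  # SEQ stored on forward strand

    def test_few_mismatches_still_map(self):
        ref = self.ref()
        read = list(ref["c1"][1000:1100])
        read[50] = "A" if read[50] != "A" else "C"
        sam = toy_map([FastqRecord("q", "".join(read), "I" * 100)], ref, max_mismatch=3)
        line = [l for l in sam.splitlines() if not l.startswith("@")][0]
        f = line.split("\t")
        assert int(f[3]) == 1001
        assert "NM:i:1" in line

    def test_deterministic(self):
        ref = self.ref()
        reads = [FastqRecord(f"q{i}", ref["c1"][i * 30:i * 30 + 100], "I" * 100)
                 for i in range(20)]
        assert toy_map(reads, ref) == toy_map(reads, ref)

    def test_mapper_reuse(self):
        ref = self.ref()
        mapper = ToyMapper(ref)
        reads = [FastqRecord("q", ref["c1"][10:110], "I" * 100)]
        assert toy_map(reads, ref, mapper=mapper) == toy_map(reads, ref)
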