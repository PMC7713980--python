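"""Mapping-efficiency metrics from SAM alignments, plus a toy read mapper.

Metrics follow the usual depth conventions: depth is counted at reference
positions consumed by M/=/X/D CIGAR operations of records that pass the
MAPQ/flag filters, and breadth and mean depth are computed over non-N
reference positions only.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .maf_io import Genome
from .simulate import FastqRecord

FILTER_FLAGS = 0x100 | 0x200 | 0x800  # secondary, QC-fail, supplementary
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X


@dataclass
class MappingMetrics:
    total_reads: int
    mapped_pct: float
    breadth_pct: float
    mean_depth: float
    ref_total_length: int
    ref_missing: int

    def __post_init__(self) -> None:
        if not (0 <= self.mapped_pct <= 100 and 0 <= self.breadth_pct <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if self.mean_depth < 0 or self.ref_missing > self.ref_total_length:
            raise ValueError("inconsistent metrics")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_alignments(
    records: Iterable[pysam.AlignedSegment], min_mapq: int = 20
) -> Iterator[pysam.AlignedSegment]:
    """Mapped records with MAPQ >= min_mapq and secondary/QC-fail/supplementary
    flags all clear."""
    for rec in records:
        if rec.is_unmapped:
            continue
        if rec.mapping_quality < min_mapq:
            continue
        if rec.flag & FILTER_FLAGS:
            continue
        yield rec


def _open_sam(sam) -> pysam.AlignmentFile:
    if isinstance(sam, pysam.AlignmentFile):
        return sam
    return pysam.AlignmentFile(str(sam), "r")


def compute_metrics(
    sam,
    reference: Genome,
    total_reads: int,
    min_mapq: int = 20,
) -> MappingMetrics:
    """Mapped-read %, breadth >= 1X and mean depth over non-N positions."""
    handle = _open_sam(sam)
    header = handle.header
    for name in header.references:
        if name not in reference:
            raise ValueError(f"SAM reference {name!r} absent from the genome")
        if header.get_reference_length(name) != len(reference[name]):
            raise ValueError(
                f"length mismatch for {name!r}: SAM header says "
                f"{header.get_reference_length(name)}, genome has {len(reference[name])}"
            )
    diffs = {name: np.zeros(len(reference[name]) + 1, dtype=np.int64)
             for name in reference.names}
    n_passing = 0
    for rec in filter_alignments(handle, min_mapq):
        n_passing += 1
        name = rec.reference_name
        pos = rec.reference_start
        d = diffs[name]
        for op, length in rec.cigartuples or ():
            if op in _REF_CONSUMING:
                d[pos] += 1
                d[pos + length] -= 1
                pos += length
            elif op == 3:  # N skips the reference without covering it
                pos += length
    covered = 0
    depth_sum = 0
    n_valid = 0
    for name in reference.names:
        depth = np.cumsum(diffs[name][:-1])
        valid = ~reference.missing_mask(name)
        n_valid += int(valid.sum())
        covered += int((depth[valid] >= 1).sum())
        depth_sum += int(depth[valid].sum())
    if total_reads < n_passing:
        raise ValueError("total_reads smaller than the number of passing records")
    mapped_pct = 100.0 * n_passing / total_reads if total_reads else 0.0
    breadth_pct = 100.0 * covered / n_valid if n_valid else 0.0
    mean_depth = depth_sum / n_valid if n_valid else 0.0
    return MappingMetrics(
        total_reads=total_reads,
        mapped_pct=mapped_pct,
        breadth_pct=breadth_pct,
        mean_depth=mean_depth,
        ref_total_length=reference.total_length,
        ref_missing=reference.n_missing,
    )


# ---------------------------------------------------------------------------
# Toy mapper: exact k-mer seeds + Hamming extension.  A stand-in for a real
# short-read mapper so the pipeline and its tests need no external binary.

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[ord(chr(_b).lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _pack_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mers at every start position, plus a validity mask."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    kmers = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        kmers = (kmers << np.uint64(2)) | c.astype(np.uint64)
        valid &= c < 4
    return kmers, valid


class ToyMapper:
    """Deterministic exact-seed / Hamming-extension mapper.

    Unique best hit gets MAPQ 60, tied best hits MAPQ 0, no hit within
    ``max_mismatch`` mismatches is reported unmapped.
    """

    def __init__(self, reference: Genome, seed_len: int = 16, max_hits: int = 32):
        if not 4 <= seed_len <= 31:
            raise ValueError("seed_len must be in [4, 31]")
        self.reference = reference
        self.seed_len = seed_len
        self.max_hits = max_hits
        self.names = reference.names
        lengths = [len(reference[n]) for n in self.names]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.codes = np.concatenate(
            [_encode(reference[n]) for n in self.names]
        ) if self.names else np.empty(0, dtype=np.uint8)
        kmers, valid = _pack_kmers(self.codes, seed_len)
        # invalidate k-mers crossing contig boundaries
        for off in self.offsets[1:-1]:
            lo = max(0, off - seed_len + 1)
            valid[lo:off] = False
        positions = np.flatnonzero(valid)
        order = np.argsort(kmers[positions], kind="stable")
        self._sorted_kmers = kmers[positions][order]
        self._sorted_pos = positions[order]

    def _contig_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def map_reads(
        self, reads: Sequence[FastqRecord], max_mismatch: int = 8
    ) -> list[str]:
        """Map reads; returns SAM body lines (no header)."""
        lines: list[str] = []
        if not reads:
            return lines
        read_len = len(reads[0].sequence)
        k = self.seed_len
        offsets = list(range(0, max(read_len - k, 0) + 1, k))
        fwd = np.stack([_encode(r.sequence) for r in reads])
        rev = 3 - fwd[:, ::-1]
        rev[fwd[:, ::-1] == 4] = 4
        n = len(reads)

        # gather candidate (read, strand, start) triples
        cand_read: list[np.ndarray] = []
        cand_start: list[np.ndarray] = []
        cand_strand: list[np.ndarray] = []
        for strand, mat in ((0, fwd), (1, rev)):
            for off in offsets:
                seg = mat[:, off:off + k]
                kmers = np.zeros(n, dtype=np.uint64)
                ok = np.ones(n, dtype=bool)
                for j in range(k):
                    kmers = (kmers << np.uint64(2)) | seg[:, j].astype(np.uint64)
                    ok &= seg[:, j] < 4
                lo = np.searchsorted(self._sorted_kmers, kmers, side="left")
                hi = np.searchsorted(self._sorted_kmers, kmers, side="right")
                counts = np.where(ok, hi - lo, 0)
                counts = np.minimum(counts, self.max_hits)
                total = int(counts.sum())
                if total == 0:
                    continue
                ridx = np.repeat(np.arange(n), counts)
                cs = np.concatenate([[0], np.cumsum(counts)])
                within = np.arange(total) - np.repeat(cs[:-1], counts)
                gpos = self._sorted_pos[np.repeat(lo, counts) + within]
                start = gpos - off
                cand_read.append(ridx)
                cand_start.append(start)
                cand_strand.append(np.full(total, strand, dtype=np.int8))
        if cand_read:
            ridx = np.concatenate(cand_read)
            start = np.concatenate(cand_start)
            strand = np.concatenate(cand_strand)
            # discard candidates whose read window leaves the contig
            contig = self._contig_of(np.clip(start, 0, len(self.codes) - 1))
            in_bounds = (
                (start >= self.offsets[contig])
                & (start + read_len <= self.offsets[contig + 1])
            )
            ridx, start, strand, contig = (
                ridx[in_bounds], start[in_bounds], strand[in_bounds], contig[in_bounds]
            )
            # dedupe
            key = np.stack([ridx, strand.astype(np.int64), start], axis=1)
            key = np.unique(key, axis=0)
            ridx, strand, start = key[:, 0], key[:, 1], key[:, 2]
            mism = np.empty(len(ridx), dtype=np.int64)
            span = np.arange(read_len)
            for lo_c in range(0, len(ridx), 100_000):  # bound peak memory
                sl = slice(lo_c, lo_c + 100_000)
                windows = self.codes[start[sl, None] + span]
                query = np.where(
                    (strand[sl] == 0)[:, None], fwd[ridx[sl]], rev[ridx[sl]]
                )
                mism[sl] = (windows != query).sum(axis=1)
        else:
            ridx = np.empty(0, dtype=np.int64)
            start = strand = mism = ridx

        # best hit per read
        best: dict[int, tuple[int, int, int, int]] = {}  # read -> (mm, start, strand, ties)
        order = np.lexsort((start, strand, mism, ridx)) if len(ridx) else []
        for idx in order:
            r = int(ridx[idx])
            mm = int(mism[idx])
            if mm > max_mismatch:
                continue
            if r not in best:
                best[r] = (mm, int(start[idx]), int(strand[idx]), 1)
            elif mm == best[r][0]:
                b = best[r]
                if (int(start[idx]), int(strand[idx])) != (b[1], b[2]):
                    best[r] = (b[0], b[1], b[2], b[3] + 1)

        for r, rec in enumerate(reads):
            name = rec.name.split("/")[0].split()[0]
            if r not in best:
                lines.append(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{rec.sequence}\t{rec.quality}")
                continue
            mm, gstart, st, ties = best[r]
            ci = int(np.searchsorted(self.offsets, gstart, side="right") - 1)
            ref_name = self.names[ci]
            pos1 = gstart - int(self.offsets[ci]) + 1
            mapq = 60 if ties == 1 else 0
            flag = 16 if st == 1 else 0
            seq = rec.sequence
            if st == 1:
                from .maf_io import revcomp

                seq = revcomp(seq)
            lines.append(
                f"{name}\t{flag}\t{ref_name}\t{pos1}\t{mapq}\t{read_len}M\t*\t0\t0\t"
                f"{seq}\t{rec.quality}\tNM:i:{mm}"
            )
        return lines


def sam_header(reference: Genome) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in reference.names:
        lines.append(f"@SQ\tSN:{name}\tLN:{len(reference[name])}")
    return lines


def toy_map(
    reads: Sequence[FastqRecord],
    reference: Genome,
    seed_len: int = 16,
    max_mismatch: int = 8,
    mapper: ToyMapper | None = None,
) -> str:
    """Map reads against a reference; returns complete SAM text."""
    if mapper is None:
        mapper = ToyMapper(reference, seed_len=seed_len)
    body = mapper.map_reads(reads, max_mismatch=max_mismatch)
    return "\n".join(sam_header(reference) + body) + "\n"


def metrics_from_sam_text(
    sam_text: str, reference: Genome, total_reads: int, min_mapq: int = 20
) -> MappingMetrics:
    """Convenience wrapper parsing in-memory SAM text via a temp file."""
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(sam_text)
        path = fh.name
    try:
        return compute_metrics(path, reference, total_reads, min_mapq)
    finally:
        os.unlink(path)
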