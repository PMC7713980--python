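"""MAF and FASTA I/O with block-level filtering.

MAF blocks are stored with their original strand-relative coordinates
(UCSC dialect); forward-strand 0-based half-open coordinates are exposed
as properties so downstream interval logic never has to reason about
strand arithmetic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN-")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MafParseError(ValueError):
    """Raised on malformed MAF input; message carries the line number."""


def _clean_text(text: str) -> str:
    """Uppercase and collapse non-ACGTN characters (IUPAC ambiguity) to N."""
    text = text.upper()
    if set(text) <= _VALID:
        return text
    return "".join(c if c in _VALID else "N" for c in text)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentRow:
    """One "s" line of a MAF block.

    ``start`` is strand-relative, 0-based, as in the MAF standard: on the
    minus strand it counts from the start of the reverse-complemented
    source sequence.
    """

    species_id: str
    seq_name: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def __post_init__(self) -> None:
        self.text = _clean_text(self.text)
        ungapped = len(self.text) - self.text.count("-")
        if ungapped != self.size:
            raise MafParseError(
                f"row {self.species_id}.{self.seq_name}: size={self.size} but "
                f"{ungapped} non-gap characters"
            )
        if self.start + self.size > self.src_size:
            raise MafParseError(
                f"row {self.species_id}.{self.seq_name}: start+size "
                f"({self.start + self.size}) exceeds src_size {self.src_size}"
            )
        if self.strand not in "+-":
            raise MafParseError(f"bad strand {self.strand!r}")

    @property
    def src(self) -> str:
        return f"{self.species_id}.{self.seq_name}"

    @property
    def fwd_start(self) -> int:
        """Forward-strand 0-based start."""
        if self.strand == "+":
            return self.start
        return self.src_size - self.start - self.size

    @property
    def fwd_end(self) -> int:
        """Forward-strand 0-based half-open end."""
        return self.fwd_start + self.size

    def ungapped(self) -> str:
        return self.text.replace("-", "")

    def positions(self) -> np.ndarray:
        """Strand-relative source offset of every non-gap column (-1 at gaps)."""
        isbase = np.frombuffer(self.text.encode(), dtype=np.uint8) != ord("-")
        pos = np.cumsum(isbase) - 1 + self.start
        pos[~isbase] = -1
        return pos


@dataclass
class AlignmentBlock:
    """A MAF alignment block; the first row is the anchor species."""

    rows: list[AlignmentRow]
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise MafParseError("block with no rows")
        widths = {len(r.text) for r in self.rows}
        if len(widths) != 1:
            raise MafParseError("ragged block: unequal row text lengths")
        species = [r.species_id for r in self.rows]
        if len(species) != len(set(species)):
            raise MafParseError("block with more than one row for a species")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].text)

    @property
    def anchor(self) -> AlignmentRow:
        return self.rows[0]

    @property
    def species(self) -> list[str]:
        return [r.species_id for r in self.rows]

    def row_for(self, species_id: str) -> AlignmentRow | None:
        for r in self.rows:
            if r.species_id == species_id:
                return r
        return None

    @property
    def effective_score(self) -> float:
        """Block score, falling back to width for unscored blocks."""
        return self.score if self.score is not None else float(self.n_columns)


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        sp, _, name = src.partition(".")
        return sp, name
    return src, src


def read_maf(stream: TextIO | str) -> list[AlignmentBlock]:
    """Parse a MAF file (UCSC dialect) into blocks, in file order."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    blocks: list[AlignmentBlock] = []
    cur_rows: list[AlignmentRow] = []
    cur_score: float | None = None
    in_block = False

    def flush(lineno: int) -> None:
        nonlocal cur_rows, cur_score, in_block
        if in_block:
            if not cur_rows:
                raise MafParseError(f"line {lineno}: 'a' line with no 's' rows")
            blocks.append(AlignmentBlock(rows=cur_rows, score=cur_score))
        cur_rows, cur_score, in_block = [], None, False

    lineno = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if line.startswith("#"):
            continue
        if not line.strip():
            flush(lineno)
            continue
        fields = line.split()
        if fields[0] == "a":
            flush(lineno)
            in_block = True
            for f in fields[1:]:
                if f.startswith("score="):
                    try:
                        cur_score = float(f[6:])
                    except ValueError as e:
                        raise MafParseError(f"line {lineno}: bad score {f!r}") from e
        elif fields[0] == "s":
            if not in_block:
                raise MafParseError(f"line {lineno}: 's' line outside a block")
            if len(fields) != 7:
                raise MafParseError(f"line {lineno}: expected 7 fields on 's' line")
            sp, name = _split_src(fields[1])
            try:
                row = AlignmentRow(
                    species_id=sp,
                    seq_name=name,
                    start=int(fields[2]),
                    size=int(fields[3]),
                    strand=fields[4],
                    src_size=int(fields[5]),
                    text=fields[6],
                )
            except MafParseError as e:
                raise MafParseError(f"line {lineno}: {e}") from None
            if cur_rows and len(row.text) != len(cur_rows[0].text):
                raise MafParseError(f"line {lineno}: ragged block (unequal text lengths)")
            cur_rows.append(row)
        # other line types (i/e/q, track) are ignored
    flush(lineno + 1)
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], stream: TextIO) -> None:
    stream.write("##maf version=1\n")
    for block in blocks:
        if block.score is not None:
            stream.write(f"a score={block.score:g}\n")
        else:
            stream.write("a\n")
        src_w = max(len(r.src) for r in block.rows)
        for r in block.rows:
            stream.write(
                f"s {r.src:<{src_w}} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n"
            )
        stream.write("\n")


def filter_min_columns(
    blocks: Iterable[AlignmentBlock], min_col: int = 100
) -> list[AlignmentBlock]:
    """Keep blocks with at least ``min_col`` columns (inclusive boundary)."""
    if min_col < 1:
        raise ValueError("min_col must be >= 1")
    return [b for b in blocks if b.n_columns >= min_col]


def dedupe_best_hit(blocks: Sequence[AlignmentBlock]) -> list[AlignmentBlock]:
    """Resolve anchor-interval overlaps, keeping the best-scoring block.

    Candidates are visited in descending score (ties: input order); a block
    is retained only if its anchor interval does not overlap any retained
    block on the same anchor sequence.  Output is sorted by anchor
    coordinate.
    """
    order = sorted(range(len(blocks)), key=lambda i: (-blocks[i].effective_score, i))
    kept: list[int] = []
    kept_ivals: dict[str, list[tuple[int, int]]] = {}
    for i in order:
        a = blocks[i].anchor
        iv = (a.fwd_start, a.fwd_end)
        clashes = any(
            iv[0] < e and s < iv[1] for s, e in kept_ivals.get(a.seq_name, ())
        )
        if not clashes:
            kept.append(i)
            kept_ivals.setdefault(a.seq_name, []).append(iv)
    kept_blocks = [blocks[i] for i in kept]
    kept_blocks.sort(key=lambda b: (b.anchor.seq_name, b.anchor.fwd_start))
    return kept_blocks


class Genome:
    """A set of named uppercase sequences over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate sequence name {name!r}")
            self.sequences[name] = _clean_text(seq).replace("-", "")

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.sequences == other.sequences

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def n_missing(self) -> int:
        return sum(s.count("N") for s in self.sequences.values())

    def missing_mask(self, name: str) -> np.ndarray:
        arr = np.frombuffer(self.sequences[name].encode(), dtype=np.uint8)
        return arr == ord("N")


def read_fasta(stream: TextIO | str) -> Genome:
    """Read FASTA into a Genome; duplicate record ids are an error."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return Genome(seqs)


def write_fasta(genome: Genome, stream: TextIO, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    writer = SeqIO.FastaIO.FastaWriter(stream, wrap=width)
    writer.write_file(records)
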