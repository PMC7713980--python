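"""Reference genome flavors: aligned fractions and the hybrid genome.

The hybrid genome is the sister-species genome with each alignable
interval replaced by the reconstructed ancestral sequence for that block;
everything outside the replaced intervals is untouched sister sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO

from .asr import AncestralSegment, mask_columns, segment_contig_name
from .maf_io import AlignmentBlock, Genome, revcomp


@dataclass
class ReplacementInterval:
    """One sister-genome interval to replace, with its ancestral string."""

    start: int
    end: int
    strand: str
    replacement: str  # in block orientation; reverse-complemented at build if '-'
    block_index: int
    node_id: str
    score: float


@dataclass
class ReplacementPlan:
    intervals: dict[str, list[ReplacementInterval]] = field(default_factory=dict)
    n_skipped: int = 0  # segments without a sister placement
    n_dropped_overlap: int = 0


def plan_replacements(
    segments: Sequence[AncestralSegment], sister: Genome
) -> ReplacementPlan:
    """Resolve segment placements into disjoint per-sequence intervals.

    Overlaps keep the segment from the higher-scoring block (ties: input
    order).  Segments without a sister placement are skipped and counted.
    """
    plan = ReplacementPlan()
    candidates: list[tuple[AncestralSegment]] = []
    for seg in segments:
        if seg.sister_placement is None or len(seg) == 0:
            plan.n_skipped += 1
            continue
        p = seg.sister_placement
        if p.seq_name not in sister:
            raise ValueError(
                f"block {seg.block_index}: sister sequence {p.seq_name!r} not found"
            )
        if p.start < 0 or p.end > len(sister[p.seq_name]):
            raise ValueError(
                f"block {seg.block_index}: placement {p.start}-{p.end} outside "
                f"{p.seq_name} (length {len(sister[p.seq_name])})"
            )
        candidates.append(seg)

    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].block_score, i))
    kept: dict[str, list[ReplacementInterval]] = {}
    for i in order:
        seg = candidates[i]
        p = seg.sister_placement
        existing = kept.setdefault(p.seq_name, [])
        if any(p.start < r.end and r.start < p.end for r in existing):
            plan.n_dropped_overlap += 1
            continue
        existing.append(
            ReplacementInterval(
                start=p.start,
                end=p.end,
                strand=p.strand,
                replacement=seg.sequence,
                block_index=seg.block_index,
                node_id=seg.node_id,
                score=seg.block_score,
            )
        )
    for name, ivals in kept.items():
        plan.intervals[name] = sorted(ivals, key=lambda r: r.start)
    return plan


@dataclass
class IntervalMapping:
    """BED-like row mapping sister coordinates to hybrid coordinates."""

    seq_name: str
    old_start: int
    old_end: int
    new_start: int
    new_end: int
    kind: str  # "kept" or "replaced"
    node_id: str | None = None
    block_index: int | None = None


def build_hybrid(
    sister: Genome, plan: ReplacementPlan
) -> tuple[Genome, list[IntervalMapping]]:
    """Splice ancestral replacements into the sister genome.

    Minus-strand replacements are reverse-complemented so the spliced text
    reads on the sister's forward strand.
    """
    out: dict[str, str] = {}
    table: list[IntervalMapping] = []
    for name, seq in sister.sequences.items():
        ivals = plan.intervals.get(name, [])
        parts: list[str] = []
        cursor = 0
        new_pos = 0
        for r in ivals:
            if cursor < r.start:
                parts.append(seq[cursor:r.start])
                table.append(
                    IntervalMapping(name, cursor, r.start,
                                    new_pos, new_pos + (r.start - cursor), "kept")
                )
                new_pos += r.start - cursor
            rep = revcomp(r.replacement) if r.strand == "-" else r.replacement
            parts.append(rep)
            table.append(
                IntervalMapping(name, r.start, r.end, new_pos, new_pos + len(rep),
                                "replaced", r.node_id, r.block_index)
            )
            new_pos += len(rep)
            cursor = r.end
        if cursor < len(seq):
            parts.append(seq[cursor:])
            table.append(
                IntervalMapping(name, cursor, len(seq),
                                new_pos, new_pos + len(seq) - cursor, "kept")
            )
        out[name] = "".join(parts)
    return Genome(out), table


def write_interval_table(table: Sequence[IntervalMapping], stream: TextIO) -> None:
    stream.write(
        "#seq\told_start\told_end\tnew_start\tnew_end\tkind\tnode\tblock\n"
    )
    for r in table:
        stream.write(
            f"{r.seq_name}\t{r.old_start}\t{r.old_end}\t{r.new_start}\t{r.new_end}\t"
            f"{r.kind}\t{r.node_id or '.'}\t{'.' if r.block_index is None else r.block_index}\n"
        )


def aligned_fraction_species(
    blocks: Sequence[AlignmentBlock],
    species_id: str,
    species_set: Sequence[str] | None = None,
    max_missing_frac: float = 0.9,
) -> Genome:
    """Per-block ungapped species sequence restricted to retained columns.

    One contig per block (block adjacency does not imply genomic
    adjacency, so contigs are never merged).
    """
    contigs: dict[str, str] = {}
    found = False
    for i, block in enumerate(blocks):
        row = block.row_for(species_id)
        if row is None:
            continue
        found = True
        sset = list(species_set) if species_set is not None else block.species
        retained = mask_columns(block, sset, max_missing_frac)
        if len(retained) == 0:
            continue
        text = "".join(row.text[c] for c in retained).replace("-", "")
        if not text:
            continue
        a = block.anchor
        name = f"{species_id}|{a.seq_name}:{a.fwd_start}-{a.fwd_end}|block{i}"
        contigs[name] = text
    if not found:
        raise ValueError(f"species {species_id!r} absent from every block")
    return Genome(contigs)


def aligned_fraction_node(segments: Sequence[AncestralSegment]) -> Genome:
    """Ancestral segment per block as one contig each."""
    contigs: dict[str, str] = {}
    any_seen = False
    for seg in segments:
        any_seen = True
        if len(seg) == 0:
            continue
        contigs[segment_contig_name(seg)] = seg.sequence
    if not any_seen:
        raise ValueError("no ancestral segments given")
    return Genome(contigs)


def build_aligned_fraction(
    blocks: Sequence[AlignmentBlock] | None = None,
    *,
    species_id: str | None = None,
    segments: Sequence[AncestralSegment] | None = None,
    species_set: Sequence[str] | None = None,
    max_missing_frac: float = 0.9,
) -> Genome:
    """Dispatch to the species-row or ancestral-segment aligned fraction."""
    if species_id is not None:
        if blocks is None:
            raise ValueError("species mode requires blocks")
        return aligned_fraction_species(blocks, species_id, species_set, max_missing_frac)
    if segments is not None:
        return aligned_fraction_node(segments)
    raise ValueError("give either species_id (with blocks) or segments")
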