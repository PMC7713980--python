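"""Marginal (empirical-Bayes) ancestral state reconstruction over MAF blocks.

Per-column state posteriors at internal nodes come from the up-down message
scheme in :mod:`paleoref.phylo`; this module adds allele calling, the
missing-data column mask, and assembly of per-block ancestral segments with
anchor/sister genome placements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence, TextIO

import numpy as np

from .maf_io import AlignmentBlock
from .phylo import (
    BASES,
    MISSING_CODE,
    PhyloTree,
    PruningEngine,
    SubstitutionModel,
    encode_columns,
)


class Placement(NamedTuple):
    """Forward-strand 0-based half-open interval on a source sequence."""

    seq_name: str
    start: int
    end: int
    strand: str


@dataclass
class SitePosterior:
    node_id: str
    probs: np.ndarray  # over ACGT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4,) or np.any(self.probs < 0):
            raise ValueError("posterior must be 4 non-negative probabilities")
        if abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("posterior must sum to 1")


@dataclass
class AncestralSegment:
    """Reconstructed sequence for one internal node over one block."""

    node_id: str
    block_index: int
    columns: np.ndarray  # retained column indices of the source block
    sequence: str  # called bases, one per retained column
    posteriors: np.ndarray  # (n_retained, 4)
    anchor_placement: Placement | None
    sister_placement: Placement | None
    block_score: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.columns) == len(self.posteriors)):
            raise ValueError("sequence, columns and posteriors must align")

    def __len__(self) -> int:
        return len(self.sequence)


def marginal_posteriors(
    tree: PhyloTree, model: SubstitutionModel, column: Mapping[str, str]
) -> dict[str, SitePosterior]:
    """Posterior state distribution at every internal node for one column."""
    leaves = tree.leaf_labels
    for sp in column:
        if sp not in tree or not tree.node(sp).is_leaf:
            raise ValueError(f"column references unknown species {sp!r}")
    mat = encode_columns([column], leaves)
    engine = PruningEngine(tree, model, leaves)
    posts = engine.node_posteriors(mat)
    return {label: SitePosterior(label, probs[0]) for label, probs in posts.items()}


def call_allele(
    posterior: SitePosterior | np.ndarray, base_freqs: np.ndarray | None = None
) -> str:
    """Highest-posterior base; ties broken by higher stationary frequency,
    then alphabetically."""
    probs = posterior.probs if isinstance(posterior, SitePosterior) else np.asarray(posterior)
    pi = np.full(4, 0.25) if base_freqs is None else np.asarray(base_freqs)
    best = probs.max()
    tied = [i for i in range(4) if probs[i] == best]
    tied.sort(key=lambda i: (-pi[i], BASES[i]))
    return BASES[tied[0]]


def block_code_matrix(block: AlignmentBlock, species: Sequence[str]) -> np.ndarray:
    """(n_columns, n_species) code matrix; species absent from the block are
    missing in every column."""
    mat = np.full((block.n_columns, len(species)), MISSING_CODE, dtype=np.uint8)
    lut = np.full(256, MISSING_CODE, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    for j, sp in enumerate(species):
        row = block.row_for(sp)
        if row is not None:
            mat[:, j] = lut[np.frombuffer(row.text.encode(), dtype=np.uint8)]
    return mat


def mask_columns(
    block: AlignmentBlock,
    species_set: Sequence[str],
    max_missing_frac: float = 0.9,
) -> np.ndarray:
    """Indices of columns whose missing fraction is <= ``max_missing_frac``.

    Missing means gap or N; species in ``species_set`` absent from the block
    count as missing in every column.  The boundary is strict: a column is
    dropped only when missing/|species_set| exceeds the threshold.
    """
    species = list(species_set)
    mat = block_code_matrix(block, species)
    missing_frac = (mat == MISSING_CODE).sum(axis=1) / len(species)
    return np.flatnonzero(missing_frac <= max_missing_frac)


def _row_placement(
    block: AlignmentBlock, species_id: str, retained: np.ndarray
) -> Placement | None:
    """Sub-interval of a species' block row spanned by the retained columns,
    snapped inward past gaps; forward-strand coordinates."""
    row = block.row_for(species_id)
    if row is None or len(retained) == 0:
        return None
    pos = row.positions()[retained]
    pos = pos[pos >= 0]
    if len(pos) == 0:
        return None
    lo, hi = int(pos.min()), int(pos.max()) + 1  # strand-relative half-open
    if row.strand == "+":
        start, end = lo, hi
    else:
        start, end = row.src_size - hi, row.src_size - lo
    return Placement(row.seq_name, start, end, row.strand)


def reconstruct_node_over_block(
    block: AlignmentBlock,
    tree: PhyloTree,
    model: SubstitutionModel,
    node_id: str,
    *,
    block_index: int = 0,
    sister_species: str | None = None,
    max_missing_frac: float = 0.9,
    engine: PruningEngine | None = None,
) -> AncestralSegment:
    """Call the ancestral sequence of one internal node over one block.

    The species set for masking and likelihood is the tree's leaf set;
    leaves absent from the block contribute missing data.
    """
    if node_id not in tree or tree.node(node_id).is_leaf:
        raise ValueError(f"{node_id!r} is not an internal node of the tree")
    species = tree.leaf_labels
    retained = mask_columns(block, species, max_missing_frac)
    anchor_sp = block.anchor.species_id
    if len(retained) == 0:
        return AncestralSegment(
            node_id, block_index, retained, "", np.zeros((0, 4)),
            None, None, block.effective_score,
        )
    mat = block_code_matrix(block, species)[retained]
    # collapse to unique patterns for the posterior computation
    patterns, inverse = np.unique(mat, axis=0, return_inverse=True)
    if engine is None:
        engine = PruningEngine(tree, model, species)
    posts = engine.node_posteriors(patterns)[node_id][inverse]
    pi = model.base_freqs
    calls = "".join(call_allele(p, pi) for p in posts)
    return AncestralSegment(
        node_id=node_id,
        block_index=block_index,
        columns=retained,
        sequence=calls,
        posteriors=posts,
        anchor_placement=_row_placement(block, anchor_sp, retained),
        sister_placement=(
            _row_placement(block, sister_species, retained) if sister_species else None
        ),
        block_score=block.effective_score,
    )


def reconstruct_node(
    blocks: Sequence[AlignmentBlock],
    tree: PhyloTree,
    model: SubstitutionModel,
    node_id: str,
    *,
    sister_species: str | None = None,
    max_missing_frac: float = 0.9,
) -> list[AncestralSegment]:
    """Reconstruct one node over every block, sharing one pruning engine."""
    engine = PruningEngine(tree.copy(), model, tree.leaf_labels)
    return [
        reconstruct_node_over_block(
            block, tree, model, node_id,
            block_index=i, sister_species=sister_species,
            max_missing_frac=max_missing_frac, engine=engine,
        )
        for i, block in enumerate(blocks)
    ]


def segment_contig_name(seg: AncestralSegment) -> str:
    if seg.anchor_placement is not None:
        p = seg.anchor_placement
        locus = f"{p.seq_name}:{p.start}-{p.end}"
    else:
        locus = "unplaced"
    return f"{seg.node_id}|{locus}|block{seg.block_index}"


def write_posterior_table(segments: Sequence[AncestralSegment], stream: TextIO) -> None:
    stream.write("contig\tpos\tpA\tpC\tpG\tpT\tcall\n")
    for seg in segments:
        name = segment_contig_name(seg)
        for i, (base, probs) in enumerate(zip(seg.sequence, seg.posteriors)):
            p = "\t".join(f"{x:.6g}" for x in probs)
            stream.write(f"{name}\t{i}\t{p}\t{base}\n")
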