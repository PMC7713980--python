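"""Synthetic clade generator and error-free paired-end read simulator.

``evolve_clade`` walks a rooted tree from a random root sequence, applying
per-site substitutions (with site-specific discrete-gamma rates inherited
from the root) and non-overlapping indels per branch, while tracking a
global column registry so the exact multiple alignment — and hence a truth
MAF — can be reconstructed afterwards.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np

from .maf_io import AlignmentBlock, AlignmentRow, Genome, revcomp
from .phylo import BASES, PhyloTree, SubstitutionModel, build_rate_matrix, _Propagator


@dataclass
class BranchEvents:
    n_subs: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    bases_inserted: int = 0
    bases_deleted: int = 0


@dataclass
class CladeSimulation:
    """Full truth record of one simulated clade."""

    tree: PhyloTree
    model: SubstitutionModel
    seed: int
    node_genomes: dict[str, Genome]
    truth_maf: list[AlignmentBlock]
    alignment: dict[str, str]  # node label -> gapped row over the global columns
    block_spans: list[tuple[int, int]]  # global column span of each truth block
    event_log: dict[str, BranchEvents]
    anchor_species: str
    seq_name: str = "chr1"

    @property
    def root_genome(self) -> Genome:
        return self.node_genomes[self.tree.root.label]

    def node_block_sequence(self, node_label: str, block_index: int) -> str:
        """Gapped truth sequence of any node over one truth-MAF block."""
        lo, hi = self.block_spans[block_index]
        return self.alignment[node_label][lo:hi]

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "tree": self.tree.to_newick(),
            "model": self.model.to_dict(),
            "anchor_species": self.anchor_species,
            "n_blocks": len(self.truth_maf),
            "events": {
                k: vars(v) for k, v in sorted(self.event_log.items())
            },
        }


def _draw_states(
    rng: np.random.Generator, parent: np.ndarray, cats: np.ndarray, P: np.ndarray
) -> np.ndarray:
    """Sample child states given parent states and per-site categories.

    ``P`` is (K, 4, 4); vectorized inverse-CDF draw per site.
    """
    probs = P[cats, parent]  # (L, 4)
    cum = np.cumsum(probs, axis=1)
    r = rng.random(len(parent))
    return (r[:, None] > cum).sum(axis=1).astype(np.uint8)


def _sample_indels(
    rng: np.random.Generator,
    length: int,
    expected_events: float,
    mean_len: float,
    max_attempts: int = 1000,
) -> list[tuple[int, int, int]]:
    """Non-overlapping indel events: (position, signed_length, kind).

    kind +1 insertion after position, -1 deletion starting at position.
    Rejection-sampled so deletion footprints never overlap.
    """
    n = rng.poisson(expected_events)
    events: list[tuple[int, int, int]] = []
    taken: list[tuple[int, int]] = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            size = int(rng.geometric(1.0 / mean_len))
            is_ins = bool(rng.random() < 0.5)
            if is_ins:
                pos = int(rng.integers(0, length + 1))
                span = (pos, pos)
            else:
                if length < size:
                    continue
                pos = int(rng.integers(0, length - size + 1))
                span = (pos, pos + size)
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            taken.append(span)
            events.append((pos, size, 1 if is_ins else -1))
            break
    events.sort()
    return events


def evolve_clade(
    tree: PhyloTree,
    model: SubstitutionModel,
    root_length: int,
    indel_rate: float = 0.0,
    indel_mean_len: float = 3.0,
    seed: int = 0,
    anchor_species: str | None = None,
    seq_name: str = "chr1",
) -> CladeSimulation:
    """Evolve genomes along ``tree`` from a stationary root sequence.

    ``indel_rate`` is the expected number of indel events per site per unit
    branch length.  Identical seed and parameters give bit-identical output.
    """
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    if indel_rate < 0:
        raise ValueError("indel_rate must be >= 0")
    rng = np.random.default_rng(seed)
    pi = model.base_freqs
    rates = model.category_rates()
    K = len(rates)
    rm = build_rate_matrix(model)
    prop = _Propagator(rm)

    root_codes = rng.choice(4, size=root_length, p=pi).astype(np.uint8)
    root_cats = rng.integers(0, K, size=root_length).astype(np.int64)
    next_id = root_length
    root_ids = np.arange(root_length, dtype=np.int64)

    node_state: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {
        tree.root.label: (root_ids, root_codes, root_cats)
    }
    event_log: dict[str, BranchEvents] = {}

    order = [n for n in reversed(tree.postorder())]  # preorder
    for node in order:
        if node.parent is None:
            continue
        ids, codes, cats = node_state[node.parent.label]
        t = node.length
        ev = BranchEvents()
        P = np.stack([prop(t * r) for r in rates])
        child_codes = _draw_states(rng, codes, cats, P)
        ev.n_subs = int((child_codes != codes).sum())
        child_ids = ids.copy()
        child_cats = cats.copy()

        if indel_rate > 0 and t > 0:
            events = _sample_indels(rng, len(child_codes), indel_rate * t * len(child_codes), indel_mean_len)
            # apply right-to-left so earlier positions stay valid
            for pos, size, kind in reversed(events):
                if kind > 0:
                    ins_codes = rng.choice(4, size=size, p=pi).astype(np.uint8)
                    ins_cats = rng.integers(0, K, size=size).astype(np.int64)
                    ins_ids = np.arange(next_id, next_id + size, dtype=np.int64)
                    next_id += size
                    child_codes = np.concatenate(
                        [child_codes[:pos], ins_codes, child_codes[pos:]]
                    )
                    child_ids = np.concatenate([child_ids[:pos], ins_ids, child_ids[pos:]])
                    child_cats = np.concatenate([child_cats[:pos], ins_cats, child_cats[pos:]])
                    ev.n_insertions += 1
                    ev.bases_inserted += size
                else:
                    child_codes = np.concatenate([child_codes[:pos], child_codes[pos + size:]])
                    child_ids = np.concatenate([child_ids[:pos], child_ids[pos + size:]])
                    child_cats = np.concatenate([child_cats[:pos], child_cats[pos + size:]])
                    ev.n_deletions += 1
                    ev.bases_deleted += size
        node_state[node.label] = (child_ids, child_codes, child_cats)
        event_log[node.label] = ev

    # --- global column order: merge the per-node orderings (Kahn on the
    # successor DAG, smallest ready id first for determinism) -------------
    edge_chunks = [
        np.stack([ids[:-1], ids[1:]], axis=1)
        for ids, _, _ in node_state.values()
        if len(ids) > 1
    ]
    live_ids = np.unique(np.concatenate([ids for ids, _, _ in node_state.values()]))
    if edge_chunks:
        edges = np.unique(np.concatenate(edge_chunks), axis=0)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    indeg = np.zeros(next_id, dtype=np.int64)
    np.add.at(indeg, edges[:, 1], 1)
    # successors of id a: edges[succ_lo[a]:succ_hi[a], 1] (edges sorted by a)
    succ_lo = np.searchsorted(edges[:, 0], np.arange(next_id), side="left")
    succ_hi = np.searchsorted(edges[:, 0], np.arange(next_id), side="right")
    heap = [int(i) for i in live_ids if indeg[i] == 0]
    heapq.heapify(heap)
    col_order = np.empty(len(live_ids), dtype=np.int64)
    k = 0
    succ_col = edges[:, 1]
    while heap:
        i = heapq.heappop(heap)
        col_order[k] = i
        k += 1
        for j in succ_col[succ_lo[i]:succ_hi[i]]:
            j = int(j)
            indeg[j] -= 1
            if indeg[j] == 0:
                heapq.heappush(heap, j)
    if k != len(live_ids):
        raise RuntimeError("column ordering failed (cyclic constraints)")
    col_index = np.empty(next_id, dtype=np.int64)
    col_index[col_order] = np.arange(len(live_ids))
    n_cols = len(live_ids)

    # --- gapped alignment rows for every node ----------------------------
    labels = [n.label for n in tree.postorder()]
    aln_codes = np.full((len(labels), n_cols), 4, dtype=np.uint8)  # 4 = gap
    label_row = {lab: i for i, lab in enumerate(labels)}
    for lab, (ids, codes, _) in node_state.items():
        aln_codes[label_row[lab], col_index[ids]] = codes
    gapped = np.frombuffer(b"ACGT-", dtype=np.uint8)
    alignment = {
        lab: gapped[aln_codes[label_row[lab]]].tobytes().decode()
        for lab in labels
    }

    node_genomes = {
        lab: Genome({seq_name: alignment[lab].replace("-", "")}) for lab in labels
    }

    # --- truth MAF: maximal runs of constant leaf presence, anchor present
    leaf_labels = tree.leaf_labels
    if anchor_species is None:
        anchor_species = leaf_labels[0]
    if anchor_species not in leaf_labels:
        raise ValueError(f"anchor species {anchor_species!r} is not a leaf")
    row_order = [anchor_species] + [l for l in leaf_labels if l != anchor_species]
    presence = np.stack(
        [aln_codes[label_row[l]] != 4 for l in row_order]
    )  # (n_leaves, n_cols)
    # species genome position before each column
    cum_pos = np.cumsum(presence, axis=1)
    change = np.any(presence[:, 1:] != presence[:, :-1], axis=0)
    boundaries = np.concatenate([[0], np.flatnonzero(change) + 1, [n_cols]])

    blocks: list[AlignmentBlock] = []
    block_spans: list[tuple[int, int]] = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        lo, hi = int(lo), int(hi)
        if not presence[0, lo]:  # anchor absent
            continue
        rows = []
        for ri, lab in enumerate(row_order):
            if not presence[ri, lo]:
                continue
            start = int(cum_pos[ri, lo]) - 1
            text = alignment[lab][lo:hi]
            rows.append(
                AlignmentRow(
                    species_id=lab,
                    seq_name=seq_name,
                    start=start,
                    size=hi - lo,
                    strand="+",
                    src_size=node_genomes[lab].total_length,
                    text=text,
                )
            )
        blocks.append(AlignmentBlock(rows=rows, score=float(hi - lo)))
        block_spans.append((lo, hi))

    return CladeSimulation(
        tree=tree,
        model=model,
        seed=seed,
        node_genomes=node_genomes,
        truth_maf=blocks,
        alignment=alignment,
        block_spans=block_spans,
        event_log=event_log,
        anchor_species=anchor_species,
        seq_name=seq_name,
    )


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class FastqRecord:
    name: str
    sequence: str
    quality: str


def simulate_reads(
    genome: Genome,
    n_pairs: int,
    read_len: int = 100,
    fragment_mean: float = 300.0,
    fragment_sd: float = 50.0,
    error_rate: float = 0.0,
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Paired-end reads from uniformly placed fragments.

    Read names encode the truth as ``{seq}:{frag_start}:{frag_end}:{i}``
    (0-based half-open fragment coordinates).  Fragments containing N are
    rejected and resampled (up to ``max_attempts`` tries).  Mate 2 is the
    reverse complement of the fragment's 3' end.
    """
    if fragment_mean < read_len:
        raise ValueError("fragment_mean must be >= read_len")
    names = [n for n in genome.names if len(genome[n]) >= read_len]
    if not names:
        raise ValueError("genome has no sequence long enough for a read")
    lengths = np.array([len(genome[n]) for n in names], dtype=float)
    weights = lengths / lengths.sum()
    rng = np.random.default_rng(seed)
    qual = "I" * read_len
    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    for i in range(n_pairs):
        for _attempt in range(max_attempts):
            ci = int(rng.choice(len(names), p=weights))
            seq = genome[names[ci]]
            frag_len = int(round(rng.normal(fragment_mean, fragment_sd)))
            frag_len = max(read_len, min(frag_len, len(seq)))
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start:start + frag_len]
            if "N" not in frag:
                break
        else:
            raise RuntimeError("could not sample an N-free fragment")
        fwd = frag[:read_len]
        rev = revcomp(frag[-read_len:])
        if error_rate > 0:
            fwd = _apply_errors(rng, fwd, error_rate)
            rev = _apply_errors(rng, rev, error_rate)
        name = f"{names[ci]}:{start}:{start + frag_len}:{i}"
        r1.append(FastqRecord(f"{name}/1", fwd, qual))
        r2.append(FastqRecord(f"{name}/2", rev, qual))
    return r1, r2


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alts = [b for b in BASES if b != out[i]]
        out[i] = alts[int(rng.integers(0, 3))]
    return "".join(out)


def write_fastq(records: Sequence[FastqRecord], stream: TextIO) -> None:
    for rec in records:
        stream.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")


def read_fastq(stream: TextIO) -> list[FastqRecord]:
    records = []
    lines = [l.rstrip("\n") for l in stream]
    for i in range(0, len(lines) - 3, 4):
        records.append(FastqRecord(lines[i][1:], lines[i + 1], lines[i + 3]))
    return records
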