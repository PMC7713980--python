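"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/pileup code paths: the
likelihood oracle enumerates every internal-state assignment, the posterior
oracle applies Bayes' rule over that enumeration, and the pileup oracle
walks CIGARs position by position.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
from scipy.linalg import expm

from paleoref.phylo import (
    PhyloTree,
    SubstitutionModel,
    build_rate_matrix,
    gamma_category_rates,
)


def _branch_matrices(tree: PhyloTree, model: SubstitutionModel, rate: float):
    rm = build_rate_matrix(model)
    mats = {}
    for node in tree.postorder():
        if node.parent is not None:
            mats[node.label] = expm(rm.Q * node.length * rate)
    return mats


def enumerate_column_likelihood(
    tree: PhyloTree, model: SubstitutionModel, column: dict[str, str]
) -> float:
    """Likelihood of one column by exhaustive summation over internal states,
    averaged over gamma categories with equal weights."""
    rates = (
        gamma_category_rates(model.gamma_shape, model.n_categories)
        if model.gamma_shape is not None
        else np.ones(1)
    )
    internals = [n.label for n in tree.postorder() if not n.is_leaf]
    leaves = {n.label for n in tree.postorder() if n.is_leaf}
    pi = model.base_freqs
    total = 0.0
    for rate in rates:
        mats = _branch_matrices(tree, model, rate)
        cat_lik = 0.0
        for assignment in itertools.product(range(4), repeat=len(internals)):
            states = dict(zip(internals, assignment))
            prob = pi[states[tree.root.label]]
            for node in tree.postorder():
                if node.parent is None:
                    continue
                parent_state = states[node.parent.label]
                if node.label in leaves:
                    obs = column.get(node.label, "N").upper()
                    if obs in "ACGT":
                        prob *= mats[node.label][parent_state, "ACGT".index(obs)]
                    # N/-: sums to 1 over all child states -> factor 1
                else:
                    prob *= mats[node.label][parent_state, states[node.label]]
            cat_lik += prob
        total += cat_lik / len(rates)
    return total


def enumerate_node_posterior(
    tree: PhyloTree, model: SubstitutionModel, column: dict[str, str], node_id: str
) -> np.ndarray:
    """P(state at node | column) by Bayes over the exhaustive enumeration,
    with gamma categories integrated out (equal priors)."""
    rates = (
        gamma_category_rates(model.gamma_shape, model.n_categories)
        if model.gamma_shape is not None
        else np.ones(1)
    )
    internals = [n.label for n in tree.postorder() if not n.is_leaf]
    leaves = {n.label for n in tree.postorder() if n.is_leaf}
    pi = model.base_freqs
    joint = np.zeros(4)
    for rate in rates:
        mats = _branch_matrices(tree, model, rate)
        for assignment in itertools.product(range(4), repeat=len(internals)):
            states = dict(zip(internals, assignment))
            prob = pi[states[tree.root.label]]
            for node in tree.postorder():
                if node.parent is None:
                    continue
                parent_state = states[node.parent.label]
                if node.label in leaves:
                    obs = column.get(node.label, "N").upper()
                    if obs in "ACGT":
                        prob *= mats[node.label][parent_state, "ACGT".index(obs)]
                else:
                    prob *= mats[node.label][parent_state, states[node.label]]
            joint[states[node_id]] += prob / len(rates)
    return joint / joint.sum()


def random_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """Random rooted binary tree by sequential joins, with random lengths."""
    from paleoref.phylo import TreeNode

    nodes = [TreeNode(f"L{i}", float(rng.uniform(0.01, 0.5))) for i in range(n_leaves)]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        parent = TreeNode(f"I{counter}", float(rng.uniform(0.01, 0.5)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    nodes[0].length = 0.0
    return PhyloTree(nodes[0])


def random_model(rng: np.random.Generator, gamma: bool = True) -> SubstitutionModel:
    exch = rng.uniform(0.3, 3.0, size=6)
    freqs = rng.dirichlet(np.full(4, 5.0))
    freqs = freqs / freqs.sum()
    alpha = float(rng.uniform(0.3, 3.0)) if gamma else None
    return SubstitutionModel("GTR", exch, freqs, alpha, 4 if gamma else 1)


def random_column(rng: np.random.Generator, leaves: list[str]) -> dict[str, str]:
    alphabet = "ACGTN-"
    return {l: alphabet[int(rng.integers(0, 6))] for l in leaves}


# ---------------------------------------------------------------------------
# SAM pileup oracle

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def brute_force_metrics(
    sam_lines: list[str],
    ref_seqs: dict[str, str],
    total_reads: int,
    min_mapq: int = 20,
) -> tuple[float, float, float]:
    """(mapped_pct, breadth_pct, mean_depth) from raw SAM text, walking each
    CIGAR one position at a time and counting depth in plain dicts."""
    depth = {name: [0] * len(seq) for name, seq in ref_seqs.items()}
    n_pass = 0
    for line in sam_lines:
        if line.startswith("@") or not line.strip():
            continue
        f = line.split("\t")
        flag, ref, pos, mapq, cigar = int(f[1]), f[2], int(f[3]) - 1, int(f[4]), f[5]
        if flag & 0x4:
            continue
        if mapq < min_mapq:
            continue
        if flag & (0x100 | 0x200 | 0x800):
            continue
        n_pass += 1
        cursor = pos
        for count, op in _CIGAR_RE.findall(cigar):
            count = int(count)
            if op in "M=XD":
                for p in range(cursor, cursor + count):
                    depth[ref][p] += 1
                cursor += count
            elif op == "N":
                cursor += count
    covered = valid = depth_total = 0
    for name, seq in ref_seqs.items():
        for p, base in enumerate(seq):
            if base == "N":
                continue
            valid += 1
            depth_total += depth[name][p]
            if depth[name][p] >= 1:
                covered += 1
    mapped_pct = 100.0 * n_pass / total_reads if total_reads else 0.0
    breadth_pct = 100.0 * covered / valid if valid else 0.0
    mean_depth = depth_total / valid if valid else 0.0
    return mapped_pct, breadth_pct, mean_depth
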