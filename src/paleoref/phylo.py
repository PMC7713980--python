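"""Nucleotide substitution models and fixed-topology likelihood machinery.

GTR / HKY85 rate matrices with discrete-gamma rate heterogeneity,
Felsenstein-pruning log-likelihoods vectorized over site patterns, and
coordinate-ascent estimation of branch lengths and model parameters on a
fixed rooted topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, gammaincinv, logsumexp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING_CODE = 4  # N or gap
#: order of the six exchangeability parameters
EXCH_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")

# pair index -> (i, j) in base order
_PAIR_IJ = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

BRANCH_MIN = 1e-8
BRANCH_MAX = 20.0


def encode_base(state: str) -> int:
    """Map a single character to {0..3}, with N/- (and anything else) -> 4."""
    return BASE_INDEX.get(state.upper(), MISSING_CODE)


@dataclass
class SubstitutionModel:
    """GTR or HKY85 model, optionally with discrete-gamma rate variation."""

    family: str
    exchangeabilities: np.ndarray  # 6 rates, order EXCH_PAIRS
    base_freqs: np.ndarray  # pi over ACGT
    gamma_shape: float | None = None
    n_categories: int = 1

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.family not in ("GTR", "HKY85"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.exchangeabilities.shape != (6,):
            raise ValueError("need exactly 6 exchangeabilities")
        if np.any(self.exchangeabilities <= 0):
            raise ValueError("exchangeabilities must be positive")
        if self.base_freqs.shape != (4,):
            raise ValueError("need exactly 4 base frequencies")
        if np.any(self.base_freqs <= 0):
            raise ValueError("base frequencies must be positive")
        if abs(self.base_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if self.family == "HKY85":
            s = self.exchangeabilities
            tv = s[[0, 2, 3, 5]]  # AC, AT, CG, GT
            ts = s[[1, 4]]  # AG, CT
            if not (np.allclose(tv, tv[0]) and np.allclose(ts, ts[0])):
                raise ValueError("HKY85 requires AG=CT and AC=AT=CG=GT")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        return cls("GTR", np.ones(6), np.full(4, 0.25))

    @classmethod
    def hky85(
        cls,
        kappa: float = 2.0,
        base_freqs: Sequence[float] | None = None,
        gamma_shape: float | None = None,
        n_categories: int = 1,
    ) -> "SubstitutionModel":
        freqs = np.full(4, 0.25) if base_freqs is None else np.asarray(base_freqs)
        exch = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("HKY85", exch, freqs, gamma_shape, n_categories)

    @classmethod
    def gtr(
        cls,
        exchangeabilities: Sequence[float],
        base_freqs: Sequence[float],
        gamma_shape: float | None = None,
        n_categories: int = 1,
    ) -> "SubstitutionModel":
        return cls(
            "GTR",
            np.asarray(exchangeabilities),
            np.asarray(base_freqs),
            gamma_shape,
            n_categories,
        )

    @property
    def kappa(self) -> float:
        """Transition/transversion rate ratio (exact for HKY85)."""
        s = self.exchangeabilities
        return float((s[1] + s[4]) / (s[0] + s[2] + s[3] + s[5]) * 2)

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None or self.n_categories == 1:
            return np.ones(max(self.n_categories, 1))
        return gamma_category_rates(self.gamma_shape, self.n_categories)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "exchangeabilities": self.exchangeabilities.tolist(),
            "base_freqs": self.base_freqs.tolist(),
            "gamma_shape": self.gamma_shape,
            "n_categories": self.n_categories,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubstitutionModel":
        return cls(
            d["family"],
            np.asarray(d["exchangeabilities"]),
            np.asarray(d["base_freqs"]),
            d.get("gamma_shape"),
            d.get("n_categories", 1),
        )


@dataclass
class RateMatrix:
    """Normalized reversible instantaneous rate matrix with its stationary pi."""

    Q: np.ndarray
    base_freqs: np.ndarray


def build_rate_matrix(model: SubstitutionModel) -> RateMatrix:
    """Q_ij = s_ij * pi_j, diagonal set so rows sum to 0, scaled to unit mean rate."""
    pi = model.base_freqs
    if np.any(pi <= 0):
        raise ValueError("base frequencies must be positive")
    Q = np.zeros((4, 4))
    for k, (i, j) in enumerate(_PAIR_IJ):
        s = model.exchangeabilities[k]
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return RateMatrix(Q / mu, pi.copy())


class _Propagator:
    """Eigendecomposition of a reversible Q for fast P(t) evaluation.

    Symmetrizes via pi^(1/2) so a real symmetric eigensolver applies.
    """

    def __init__(self, rm: RateMatrix):
        sqrt_pi = np.sqrt(rm.base_freqs)
        B = sqrt_pi[:, None] * rm.Q / sqrt_pi[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2)
        self._w = w
        self._left = V / sqrt_pi[:, None]
        self._right = V.T * sqrt_pi[None, :]
        # rows of P(t): D^-1/2 V exp(wt) V^T D^1/2

    def __call__(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._w * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        return P


def transition_matrix(Q: RateMatrix, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * t * rate); rows sum to 1, entries in [0, 1]."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if rate <= 0:
        raise ValueError("rate multiplier must be positive")
    return _Propagator(Q)(t * rate)


def gamma_category_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Discrete-gamma rates: equal-probability categories, category means.

    Renormalized so the rates average exactly 1; sorted ascending.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    K = n_categories
    if K == 1:
        return np.ones(1)
    # quantile boundaries of Gamma(alpha, rate=alpha) (mean 1)
    probs = np.arange(1, K) / K
    bounds = gammaincinv(alpha, probs) / alpha
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    # mean within each slice via the regularized incomplete gamma of shape alpha+1
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = K * (upper - lower)
    rates = np.sort(rates)
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# Trees


class TreeNode:
    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str, length: float = 0.0):
        self.label = label
        self.length = length
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> None:
        node.parent = self
        self.children.append(node)


class PhyloTree:
    """Rooted tree with labelled internal nodes and branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._index.clear()
        counter = 0
        for node in self.postorder():
            if not node.label:
                counter += 1
                label = f"N{counter}"
                while label in self._index:
                    counter += 1
                    label = f"N{counter}"
                node.label = label
            if node.label in self._index:
                raise ValueError(f"duplicate node label {node.label!r}")
            self._index[node.label] = node
            if not np.isfinite(node.length) or node.length < 0:
                raise ValueError(f"bad branch length on {node.label!r}")

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                out.append(node)
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))
        return out

    def node(self, label: str) -> TreeNode:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def internal_labels(self) -> list[str]:
        return [n.label for n in self.postorder() if not n.is_leaf]

    def branch_lengths(self) -> dict[str, float]:
        return {n.label: n.length for n in self.postorder() if n.parent is not None}

    def copy(self) -> "PhyloTree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return PhyloTree(rec(self.root))

    def prune_leaf(self, label: str) -> "PhyloTree":
        """Return a copy with one leaf removed; unary nodes are collapsed
        (their branch length added to the surviving child)."""
        tree = self.copy()
        leaf = tree.node(label)
        if not leaf.is_leaf:
            raise ValueError(f"{label!r} is not a leaf")
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.children.remove(leaf)
        if len(parent.children) == 1:
            child = parent.children[0]
            grand = parent.parent
            if grand is None:
                child.parent = None
                child.length = 0.0
                return PhyloTree(child)
            child.length += parent.length
            grand.children[grand.children.index(parent)] = child
            child.parent = grand
        return PhyloTree(tree.root)

    # -- Newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def rec(dnode) -> TreeNode:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            else:
                label = dnode.label or ""
            node = TreeNode(label, float(dnode.edge.length or 0.0))
            for c in dnode.child_nodes():
                node.add_child(rec(c))
            return node

        return cls(rec(dtree.seed_node))

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.10g}"
            inner = ",".join(rec(c) for c in node.children)
            if node.parent is None:
                return f"({inner}){node.label}"
            return f"({inner}){node.label}:{node.length:.10g}"

        return rec(self.root) + ";"


def read_newick(stream) -> PhyloTree:
    data = stream.read() if hasattr(stream, "read") else stream
    return PhyloTree.from_newick(data)


def write_newick(tree: PhyloTree, stream) -> None:
    stream.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Site patterns


def encode_columns(
    columns: Iterable[Mapping[str, str]], species: Sequence[str]
) -> np.ndarray:
    """Encode per-species column dicts into an (n_columns, n_species) code matrix."""
    cols = list(columns)
    mat = np.full((len(cols), len(species)), MISSING_CODE, dtype=np.uint8)
    for i, col in enumerate(cols):
        for j, sp in enumerate(species):
            if sp in col:
                mat[i, j] = encode_base(col[sp])
    return mat


def site_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse alignment columns to unique patterns with multiplicities."""
    patterns, counts = np.unique(matrix, axis=0, return_counts=True)
    return patterns, counts.astype(float)


# ---------------------------------------------------------------------------
# Pruning engine


class PruningEngine:
    """Vectorized pruning over site patterns and gamma categories.

    Patterns are (P, S) uint8 code matrices with columns in ``species``
    order; tree leaves absent from ``species`` raise.
    """

    def __init__(
        self, tree: PhyloTree, model: SubstitutionModel, species: Sequence[str]
    ):
        self.tree = tree
        self.model = model
        self.species = list(species)
        sp_index = {s: i for i, s in enumerate(self.species)}
        self.nodes = tree.postorder()
        self.node_pos = {id(n): i for i, n in enumerate(self.nodes)}
        self.leaf_col: dict[int, int] = {}
        for n in self.nodes:
            if n.is_leaf:
                if n.label not in sp_index:
                    raise ValueError(f"tree leaf {n.label!r} missing from species list")
                self.leaf_col[id(n)] = sp_index[n.label]
        self.rates = model.category_rates()
        self.K = len(self.rates)
        self.pi = model.base_freqs
        self.rm = build_rate_matrix(model)
        self.prop = _Propagator(self.rm)
        # per-node (K,4,4) transition matrices
        self._P: list[np.ndarray | None] = [None] * len(self.nodes)
        for i, n in enumerate(self.nodes):
            if n.parent is not None:
                self._set_P(i, n.length)

    def _set_P(self, idx: int, t: float) -> None:
        self._P[idx] = np.stack([self.prop(t * r) for r in self.rates])

    def set_branch_length(self, label: str, t: float) -> None:
        node = self.tree.node(label)
        node.length = t
        self._set_P(self.node_pos[id(node)], t)

    def _tips(self, patterns: np.ndarray) -> list[np.ndarray]:
        cached = getattr(self, "_tips_cache", None)
        if cached is not None and cached[0] is patterns:
            return cached[1]
        eye5 = np.vstack([np.eye(4), np.ones(4)])  # code 4 -> all-ones
        tips = [
            eye5[patterns[:, self.leaf_col[id(n)]]] if n.is_leaf else None
            for n in self.nodes
        ]
        self._tips_cache = (patterns, tips)
        return tips

    def _uppass(
        self, patterns: np.ndarray
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Return per-node partials U[i] of shape (K, P, 4) and a per-pattern
        logscale (P,) shared across categories."""
        P_count = patterns.shape[0]
        K = self.K
        tips = self._tips(patterns)
        partials: list[np.ndarray] = [None] * len(self.nodes)  # type: ignore
        logscale = np.zeros(P_count)
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                partials[i] = np.broadcast_to(tips[i], (K, P_count, 4))
            else:
                acc = None
                for child in node.children:
                    ci = self.node_pos[id(child)]
                    # (K,P,4) @ (K,4,4)^T -> (K,P,4)
                    msg = partials[ci] @ self._P[ci].transpose(0, 2, 1)
                    acc = msg if acc is None else acc * msg
                smax = acc.max(axis=(0, 2))  # one scale per pattern
                safe = np.where(smax > 0, smax, 1.0)
                acc /= safe[None, :, None]
                with np.errstate(divide="ignore"):
                    logscale += np.where(smax > 0, np.log(safe), -np.inf)
                partials[i] = acc
        return partials, logscale

    def site_log_likelihoods(self, patterns: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood, gamma mixture with equal category weights."""
        partials, logscale = self._uppass(patterns)
        root_lik = partials[-1] @ self.pi  # (K,P)
        with np.errstate(divide="ignore"):
            per_cat = np.log(root_lik)
        return logsumexp(per_cat, axis=0) - np.log(self.K) + logscale

    def log_likelihood(self, patterns: np.ndarray, weights: np.ndarray) -> float:
        return float(np.dot(self.site_log_likelihoods(patterns), weights))

    def node_posteriors(self, patterns: np.ndarray) -> dict[str, np.ndarray]:
        """Marginal state posteriors at internal nodes, (P, 4) per node.

        Gamma categories are mixed by their per-pattern posterior
        probability (empirical-Bayes weighting).
        """
        partials, _ = self._uppass(patterns)
        K, P_count = self.K, patterns.shape[0]
        root_lik = partials[-1] @ self.pi  # (K,P)
        # posterior category weights (equal priors); the shared per-pattern
        # scale cancels in the softmax
        with np.errstate(divide="ignore"):
            per_cat_ll = np.log(root_lik)  # (K,P)
        w = np.exp(per_cat_ll - logsumexp(per_cat_ll, axis=0, keepdims=True))  # (K,P)

        down: list[np.ndarray] = [None] * len(self.nodes)  # type: ignore
        down[-1] = np.broadcast_to(self.pi, (K, P_count, 4)).copy()
        result: dict[str, np.ndarray] = {}
        for i in range(len(self.nodes) - 1, -1, -1):
            node = self.nodes[i]
            if node.is_leaf:
                continue
            # per-category posterior at this node
            post = down[i] * partials[i]
            norm = post.sum(axis=2, keepdims=True)
            post = post / np.where(norm > 0, norm, 1.0)
            mixed = np.einsum("kp,kpx->px", w, post)
            mixed /= mixed.sum(axis=1, keepdims=True)
            result[node.label] = mixed
            # messages to children, excluding each child's own contribution
            msgs = []
            for child in node.children:
                ci = self.node_pos[id(child)]
                msgs.append(partials[ci] @ self._P[ci].transpose(0, 2, 1))
            for ck, child in enumerate(node.children):
                ci = self.node_pos[id(child)]
                excl = down[i].copy()
                for mk, m in enumerate(msgs):
                    if mk != ck:
                        excl = excl * m
                d = excl @ self._P[ci]
                dmax = d.max(axis=2, keepdims=True)
                down[ci] = d / np.where(dmax > 0, dmax, 1.0)
        return result


def column_log_likelihood(
    tree: PhyloTree, model: SubstitutionModel, column: Mapping[str, str]
) -> float:
    """Log-likelihood of one alignment column (missing leaves allowed)."""
    leaves = tree.leaf_labels
    for sp in column:
        if sp not in tree or not tree.node(sp).is_leaf:
            raise ValueError(f"column references unknown species {sp!r}")
    mat = encode_columns([column], leaves)
    engine = PruningEngine(tree, model, leaves)
    return float(engine.site_log_likelihoods(mat)[0])


def _usable(patterns: np.ndarray, weights: np.ndarray) -> bool:
    return patterns.size > 0 and bool(np.any(patterns != MISSING_CODE))


def optimize_branch_lengths(
    tree: PhyloTree,
    model: SubstitutionModel,
    patterns: np.ndarray,
    weights: np.ndarray,
    species: Sequence[str] | None = None,
    *,
    bounds: tuple[float, float] = (BRANCH_MIN, BRANCH_MAX),
    tol: float = 1e-6,
    max_rounds: int = 50,
) -> PhyloTree:
    """Per-branch Brent line search cycling branches in post-order."""
    if species is None:
        species = tree.leaf_labels
    if not _usable(patterns, weights):
        raise ValueError("no usable alignment columns")
    tree = tree.copy()
    engine = PruningEngine(tree, model, species)
    branch_nodes = [n.label for n in tree.postorder() if n.parent is not None]
    best_ll = engine.log_likelihood(patterns, weights)
    for _ in range(max_rounds):
        max_delta = 0.0
        for label in branch_nodes:
            old = tree.node(label).length

            def nll(t: float, _label=label) -> float:
                engine.set_branch_length(_label, t)
                return -engine.log_likelihood(patterns, weights)

            res = minimize_scalar(
                nll, bounds=bounds, method="bounded", options={"xatol": tol}
            )
            if -res.fun >= best_ll:
                best_ll = -res.fun
                engine.set_branch_length(label, float(res.x))
                max_delta = max(max_delta, abs(float(res.x) - old))
            else:
                engine.set_branch_length(label, old)
        if max_delta < tol:
            break
    return tree


def empirical_base_freqs(patterns: np.ndarray, weights: np.ndarray) -> np.ndarray:
    counts = np.zeros(4)
    for b in range(4):
        counts[b] = ((patterns == b) * weights[:, None]).sum()
    if counts.sum() == 0:
        raise ValueError("no usable alignment columns")
    counts = np.maximum(counts, 0.5)  # floor so frequencies stay positive
    return counts / counts.sum()


def estimate_model_params(
    tree: PhyloTree,
    patterns: np.ndarray,
    weights: np.ndarray,
    family: str = "GTR",
    species: Sequence[str] | None = None,
    *,
    gamma: bool = True,
    n_categories: int = 4,
    tol: float = 1e-6,
    max_rounds: int = 50,
) -> SubstitutionModel:
    """Estimate exchangeabilities (GT fixed at 1) and gamma shape.

    Base frequencies are fixed to empirical counts; free parameters are
    optimized by coordinate ascent with Brent line searches on a log scale.
    """
    if species is None:
        species = tree.leaf_labels
    if not _usable(patterns, weights):
        raise ValueError("no usable alignment columns")
    pi = empirical_base_freqs(patterns, weights)

    if family == "GTR":
        free = [0, 1, 2, 3, 4]  # GT (index 5) is the reference rate
    elif family == "HKY85":
        free = ["kappa"]
    else:
        raise ValueError(f"unknown family {family!r}")

    exch = np.ones(6)
    alpha = 1.0 if gamma else None

    def make_model(exch_v: np.ndarray, alpha_v: float | None) -> SubstitutionModel:
        return SubstitutionModel(
            family, exch_v.copy(), pi, alpha_v, n_categories if gamma else 1
        )

    def ll_of(exch_v: np.ndarray, alpha_v: float | None) -> float:
        eng = PruningEngine(tree, make_model(exch_v, alpha_v), species)
        return eng.log_likelihood(patterns, weights)

    for _ in range(max_rounds):
        max_delta = 0.0
        for p in free:
            if p == "kappa":

                def nll(logk: float) -> float:
                    k = 10.0**logk
                    e = np.array([1.0, k, 1.0, 1.0, k, 1.0])
                    return -ll_of(e, alpha)

                cur = np.log10(exch[1])
                res = minimize_scalar(
                    nll, bounds=(-3, 3), method="bounded", options={"xatol": 1e-5}
                )
                k = 10.0 ** float(res.x)
                exch = np.array([1.0, k, 1.0, 1.0, k, 1.0])
                max_delta = max(max_delta, abs(float(res.x) - cur))
            else:

                def nll(logv: float, _p=p) -> float:
                    e = exch.copy()
                    e[_p] = 10.0**logv
                    return -ll_of(e, alpha)

                cur = np.log10(exch[p])
                res = minimize_scalar(
                    nll, bounds=(-3, 3), method="bounded", options={"xatol": 1e-5}
                )
                exch[p] = 10.0 ** float(res.x)
                max_delta = max(max_delta, abs(float(res.x) - cur))
        if gamma:

            def nll_a(loga: float) -> float:
                return -ll_of(exch, 10.0**loga)

            cur = np.log10(alpha)
            res = minimize_scalar(
                nll_a,
                bounds=(np.log10(0.02), 2.0),
                method="bounded",
                options={"xatol": 1e-5},
            )
            alpha = 10.0 ** float(res.x)
            max_delta = max(max_delta, abs(float(res.x) - cur))
        if max_delta < tol:
            break
    return make_model(exch, alpha)


def fit(
    tree: PhyloTree,
    patterns: np.ndarray,
    weights: np.ndarray,
    family: str = "GTR",
    species: Sequence[str] | None = None,
    *,
    gamma: bool = True,
    n_categories: int = 4,
    rounds: int = 3,
) -> tuple[PhyloTree, SubstitutionModel]:
    """Alternate branch-length and model-parameter estimation."""
    pi = empirical_base_freqs(patterns, weights)
    if family == "HKY85":
        model = SubstitutionModel.hky85(2.0, pi, 1.0 if gamma else None,
                                        n_categories if gamma else 1)
    else:
        model = SubstitutionModel("GTR", np.ones(6), pi, 1.0 if gamma else None,
                                  n_categories if gamma else 1)
    for _ in range(rounds):
        tree = optimize_branch_lengths(tree, model, patterns, weights, species)
        model = estimate_model_params(
            tree, patterns, weights, family, species,
            gamma=gamma, n_categories=n_categories,
        )
    tree = optimize_branch_lengths(tree, model, patterns, weights, species)
    return tree, model
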