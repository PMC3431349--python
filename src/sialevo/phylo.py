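"""WAG+Gamma protein phylogenetics: maximum-likelihood distances,
between-subgroup divergence, pruning likelihood, NJ/BioNJ starting trees,
NNI search and bootstrap supports.

Model
-----
Amino-acid substitution follows a reversible continuous-time Markov chain
with rate matrix ``Q_ij = S_ij * pi_j`` (i != j), where ``S`` is the WAG
exchangeability matrix and ``pi`` its stationary frequencies; ``Q`` is
scaled so the expected substitution rate at stationarity is one, making
branch lengths expected substitutions per site.  Rate variation across sites
uses Yang's discrete-gamma approximation: K equiprobable categories whose
rates are the category means (or medians) of a Gamma(alpha, alpha)
distribution, normalised to mean one.

Gaps and ambiguity codes are treated as missing data (partial likelihood one)
everywhere; they are never a 21st state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize, special, stats

from .alignment import AA20, Alignment, AlignmentError
from .wag import AA_INDEX, AA_ORDER, WAG_FREQS, wag_exchangeabilities

# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionModel:
    """Reversible amino-acid rate matrix with cached symmetric eigensystem."""

    exchangeabilities: np.ndarray
    freqs: np.ndarray
    name: str = "custom"
    Q: np.ndarray = field(init=False, repr=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if S.shape != (20, 20) or pi.shape != (20,):
            raise AlignmentError("model requires a 20x20 matrix and 20 frequencies")
        if not np.allclose(S, S.T):
            raise AlignmentError("exchangeability matrix must be symmetric")
        if np.any(pi <= 0):
            raise AlignmentError("stationary frequencies must be positive")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))  # expected rate before scaling
        Q /= mu
        self.freqs = pi
        self.Q = Q
        # symmetric similarity transform: B = D Q D^-1 with D = diag(sqrt(pi))
        d = np.sqrt(pi)
        B = (d[:, None] * Q) / d[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._right = V / d[:, None]   # D^-1 V
        self._left = V.T * d[None, :]  # V^T D

    @classmethod
    def wag(cls) -> "SubstitutionModel":
        return cls(wag_exchangeabilities(), WAG_FREQS.copy(), name="WAG")

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P = exp(Q * t * rate); tiny negative round-off entries clamped to 0."""
        if t < 0:
            raise AlignmentError("branch length must be non-negative")
        if rate <= 0:
            raise AlignmentError("rate multiplier must be positive")
        e = np.exp(self._eigvals * (t * rate))
        P = (self._right * e[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        return P

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stacked (K, 20, 20) transition matrices for K rate multipliers."""
        return np.stack([self.transition_matrix(t, r) for r in rates])


def transition_matrix(model: SubstitutionModel, t: float, rate: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rate)


# ---------------------------------------------------------------------------
# Discrete gamma rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaRates:
    """Equal-probability discrete-gamma rate categories (mean rate one)."""

    shape: float
    rates: np.ndarray
    probs: np.ndarray

    @property
    def n_categories(self) -> int:
        return len(self.rates)

    @classmethod
    def discrete(cls, shape: float, n_categories: int = 5,
                 method: str = "mean") -> "GammaRates":
        """Discretise Gamma(shape, shape) into equiprobable categories.

        ``method='mean'`` uses the conditional category means (via the
        incomplete gamma function); ``'median'`` uses category medians
        rescaled to unit mean.
        """
        if shape <= 0:
            raise AlignmentError("gamma shape must be positive")
        if n_categories < 1:
            raise AlignmentError("need at least one rate category")
        K = n_categories
        if K == 1:
            rates = np.array([1.0])
        elif method == "mean":
            edges = stats.gamma.ppf(np.arange(1, K) / K, a=shape, scale=1.0 / shape)
            edges = np.concatenate([[0.0], edges, [np.inf]])
            # E[X | a<X<b] * P = (I(b; a+1) - I(a; a+1)) since E[X] = 1
            upper = special.gammainc(shape + 1, shape * edges[1:])
            lower = special.gammainc(shape + 1, shape * edges[:-1])
            rates = K * (upper - lower)
        elif method == "median":
            q = (2 * np.arange(K) + 1) / (2 * K)
            rates = stats.gamma.ppf(q, a=shape, scale=1.0 / shape)
            rates = rates / rates.mean()
        else:
            raise AlignmentError(f"unknown discretisation method {method!r}")
        probs = np.full(K, 1.0 / K)
        return cls(shape=float(shape), rates=rates, probs=probs)


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

MISSING = -1


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned row: 0..19 for residues, -1 for gap/ambiguity."""
    return np.array([AA_INDEX.get(c, MISSING) if c in AA20 else MISSING
                     for c in seq], dtype=np.int16)


def encode_alignment(aln: Alignment, columns: Sequence[int] | None = None) -> np.ndarray:
    """(n_seqs, n_cols) integer matrix in alignment id order."""
    M = np.stack([encode_sequence(s) for s in aln.seqs])
    if columns is not None:
        M = M[:, np.asarray(columns, dtype=int) - 1]
    return M


# ---------------------------------------------------------------------------
# Pairwise ML distances
# ---------------------------------------------------------------------------

_D_BOUNDS = (1e-8, 50.0)


def _pair_count_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """20x20 counts of aligned residue pairs over columns where both present."""
    keep = (x >= 0) & (y >= 0)
    if not keep.any():
        raise AlignmentError("sequence pair shares no unambiguous columns")
    flat = x[keep].astype(np.int64) * 20 + y[keep]
    return np.bincount(flat, minlength=400).reshape(20, 20).astype(float)


def _pair_neg_loglik(d: float, C: np.ndarray, model: SubstitutionModel,
                     gamma: GammaRates) -> float:
    K = gamma.n_categories
    mix = np.zeros((20, 20))
    for r in gamma.rates:
        mix += model.transition_matrix(d, r)
    mix /= K
    joint = model.freqs[:, None] * mix
    with np.errstate(divide="ignore"):
        logJ = np.log(joint)
    mask = C > 0
    if np.any(np.isneginf(logJ[mask])):
        return np.inf
    return -float(np.sum(C[mask] * logJ[mask]))


def pairwise_ml_distance(a, b, model: SubstitutionModel, gamma: GammaRates) -> float:
    """ML distance (expected substitutions/site) between two aligned rows.

    Accepts aligned strings or encoded integer arrays; columns where either
    row is gapped/ambiguous are skipped pairwise.
    """
    x = encode_sequence(a) if isinstance(a, str) else np.asarray(a)
    y = encode_sequence(b) if isinstance(b, str) else np.asarray(b)
    if x.shape != y.shape:
        raise AlignmentError("aligned rows must have equal length")
    C = _pair_count_matrix(x, y)
    if np.trace(C) == C.sum():  # identical on all shared columns
        return 0.0
    res = optimize.minimize_scalar(
        _pair_neg_loglik, args=(C, model, gamma), bounds=_D_BOUNDS,
        method="bounded", options={"xatol": 1e-6},
    )
    return float(res.x)


def distance_matrix(aln: Alignment, model: SubstitutionModel, gamma: GammaRates,
                    columns: Sequence[int] | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise ML distances in alignment id order."""
    M = encode_alignment(aln, columns)
    n = M.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_ml_distance(M[i], M[j], model, gamma)
    return D


def between_group_divergence(aln: Alignment, group_a: Sequence[str],
                             group_b: Sequence[str], model: SubstitutionModel,
                             gamma: GammaRates, min_coverage: float = 0.70,
                             n_bootstrap: int = 500,
                             seed: int | None = None) -> tuple[float, float]:
    """Mean ML distance over all between-group pairs, with a site-bootstrap SE.

    Columns with site coverage <= ``min_coverage`` are dropped first (strictly
    more-than threshold).  The SE resamples the retained columns with
    replacement ``n_bootstrap`` times, recomputing the mean each time; pass
    ``n_bootstrap=0`` to skip it (SE returned as NaN).
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise AlignmentError("groups must be non-empty")
    if set(ga) & set(gb):
        raise AlignmentError("groups must be disjoint")
    cols = aln.filter_columns(min_coverage, strict=True)
    if not cols:
        raise AlignmentError("no columns pass the coverage filter")
    idx = {sid: i for i, sid in enumerate(aln.ids)}
    M = encode_alignment(aln, cols)
    rows_a = [M[idx[i]] for i in ga]
    rows_b = [M[idx[i]] for i in gb]

    def mean_distance(col_sel: np.ndarray | None) -> float:
        ds = []
        for xa in rows_a:
            for xb in rows_b:
                x = xa if col_sel is None else xa[col_sel]
                y = xb if col_sel is None else xb[col_sel]
                try:
                    ds.append(pairwise_ml_distance(x, y, model, gamma))
                except AlignmentError:
                    continue  # pair with no shared sites in this resample
        if not ds:
            raise AlignmentError("no sequence pair shares sites")
        return float(np.mean(ds))

    mean_d = mean_distance(None)
    if n_bootstrap <= 0:
        return mean_d, float("nan")
    rng = np.random.default_rng(seed)
    S = len(cols)
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sel = rng.integers(0, S, size=S)
        reps[b] = mean_distance(sel)
    return mean_d, float(reps.std(ddof=1))


# ---------------------------------------------------------------------------
# Neighbour joining / BioNJ
# ---------------------------------------------------------------------------


def _check_distance_matrix(D: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise AlignmentError("distance matrix shape does not match labels")
    if np.max(np.abs(D - D.T)) > 1e-8:
        raise AlignmentError("distance matrix must be symmetric")
    if np.max(np.abs(np.diag(D))) > 1e-12:
        raise AlignmentError("distance matrix must have zero diagonal")
    return (D + D.T) / 2.0


def _agglomerate(D: np.ndarray, labels: Sequence[str], bionj: bool) -> str:
    """Shared NJ/BioNJ agglomeration; returns an unrooted newick string.

    Both variants select the pair minimising the standard NJ Q criterion;
    they differ in the reduction step: NJ averages the two distances, BioNJ
    uses the variance-weighted combination of Gascuel (1997).
    """
    nodes = [f"{lab}" for lab in labels]
    D = D.copy()
    V = D.copy()  # variance estimates (BioNJ); unused by plain NJ
    lengths: dict[int, float] = {}

    def fmt(i: int, bl: float) -> str:
        return f"{nodes[i]}:{max(bl, 0.0):.10g}"

    active = list(range(len(nodes)))
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qc = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qc, np.inf)
        k = int(np.argmin(Qc))
        ai, aj = divmod(k, n)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        others = [a for a in active if a not in (i, j)]
        if bionj and V[i, j] > 1e-12:
            lam = 0.5 + sum(V[j, m] - V[i, m] for m in others) / (
                2.0 * (n - 2) * V[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        new = f"({fmt(i, li)},{fmt(j, lj)})"
        # reuse slot i for the merged node
        for m in others:
            if bionj:
                dm = lam * D[i, m] + (1 - lam) * D[j, m] - lam * li - (1 - lam) * lj
                vm = lam * V[i, m] + (1 - lam) * V[j, m] - lam * (1 - lam) * V[i, j]
            else:
                dm = (D[i, m] + D[j, m] - dij) / 2.0
                vm = dm
            D[i, m] = D[m, i] = dm
            V[i, m] = V[m, i] = max(vm, 0.0)
        nodes[i] = new
        active.remove(j)

    if len(active) == 3:
        a, b, c = active
        la = max((D[a, b] + D[a, c] - D[b, c]) / 2.0, 0.0)
        lb = max((D[a, b] + D[b, c] - D[a, c]) / 2.0, 0.0)
        lc = max((D[a, c] + D[b, c] - D[a, b]) / 2.0, 0.0)
        return f"({fmt(a, la)},{fmt(b, lb)},{fmt(c, lc)});"
    a, b = active
    half = max(D[a, b] / 2.0, 0.0)
    return f"({fmt(a, half)},{fmt(b, half)});"


def nj_tree(D: np.ndarray, labels: Sequence[str],
            taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Neighbour-joining tree from a symmetric distance matrix (unrooted)."""
    D = _check_distance_matrix(D, labels)
    if len(labels) < 3:
        raise AlignmentError("need at least 3 taxa")
    newick = _agglomerate(D, labels, bionj=False)
    return dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=taxon_namespace,
                             preserve_underscores=True)


def bionj_tree(D: np.ndarray, labels: Sequence[str],
               taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """BioNJ tree: NJ with variance-weighted distance reduction."""
    D = _check_distance_matrix(D, labels)
    if len(labels) < 3:
        raise AlignmentError("need at least 3 taxa")
    newick = _agglomerate(D, labels, bionj=True)
    return dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=taxon_namespace,
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# Felsenstein pruning likelihood
# ---------------------------------------------------------------------------

_BL_MIN = 1e-9
_BL_MAX = 20.0


class TreeLikelihood:
    """Pruning likelihood of an alignment on a (possibly unrooted) tree.

    Site patterns are compressed; per-site scaling guards against underflow.
    Gamma-category likelihoods are averaged per site with equal weights.
    """

    def __init__(self, tree: dendropy.Tree, aln: Alignment,
                 model: SubstitutionModel, gamma: GammaRates,
                 columns: Sequence[int] | None = None):
        self.tree = tree
        self.model = model
        self.gamma = gamma
        leaf_labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        if leaf_labels != sorted(aln.ids):
            raise AlignmentError("tree leaves do not match alignment ids")
        M = encode_alignment(aln, columns)
        idx = {sid: i for i, sid in enumerate(aln.ids)}
        patterns, weights = np.unique(M, axis=1, return_counts=True)
        self.patterns = patterns      # (n_seqs, S)
        self.weights = weights.astype(float)
        self.leaf_row = {lf: idx[lf.taxon.label] for lf in tree.leaf_node_iter()}
        for e in tree.preorder_edge_iter():
            if e.tail_node is not None and (e.length is None or e.length < _BL_MIN):
                e.length = _BL_MIN

    # -- core passes -------------------------------------------------------
    def _leaf_partial(self, node) -> tuple[np.ndarray, np.ndarray]:
        s = self.patterns[self.leaf_row[node]]
        S = s.shape[0]
        D = np.zeros((S, 20))
        present = s >= 0
        D[present, s[present]] = 1.0
        D[~present, :] = 1.0
        K = self.gamma.n_categories
        return np.broadcast_to(D, (K, S, 20)).copy(), np.zeros(S)

    def _postorder(self):
        """Compute D (below-partials) and M (messages to parent) per node."""
        K = self.gamma.n_categories
        down: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                D, ls = self._leaf_partial(node)
            else:
                children = node.child_nodes()
                D = None
                ls = None
                for c in children:
                    Mc, lsc = down[c]["M"], down[c]["lsM"]
                    if D is None:
                        D, ls = Mc.copy(), lsc.copy()
                    else:
                        D *= Mc
                        ls = ls + lsc
                scale = D.max(axis=(0, 2))
                scale[scale == 0.0] = 1.0
                D /= scale[None, :, None]
                ls = ls + np.log(scale)
            entry = {"D": D, "lsD": ls}
            if node.parent_node is not None:
                t = node.edge.length
                P = self.model.transition_matrices(t, self.gamma.rates)
                entry["M"] = np.einsum("kij,ksj->ksi", P, D)
                entry["lsM"] = ls
            down[node] = entry
        return down

    def log_likelihood(self) -> float:
        down = self._postorder()
        root = self.tree.seed_node
        D, ls = down[root]["D"], down[root]["lsD"]
        site = np.einsum("j,ksj->ks", self.model.freqs, D).mean(axis=0)
        if np.any(site <= 0):
            return -np.inf
        return float(np.dot(self.weights, np.log(site) + ls))

    # -- branch-length optimization ----------------------------------------
    def _edge_arrays(self, down):
        """(node, W, lsW, D, lsD) per non-root node: W is the upper partial at
        the parent end of the node's edge (pi included), siblings folded in."""
        root = self.tree.seed_node
        K = self.gamma.n_categories
        S = self.patterns.shape[1]
        up: dict = {root: (np.broadcast_to(self.model.freqs, (K, S, 20)).copy(),
                           np.zeros(S))}
        out = []
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            parent = node.parent_node
            A, lsA = up[parent]
            W = A.copy()
            lsW = lsA.copy()
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                W *= down[sib]["M"]
                lsW = lsW + down[sib]["lsM"]
            scale = W.max(axis=(0, 2))
            scale[scale == 0.0] = 1.0
            W /= scale[None, :, None]
            lsW = lsW + np.log(scale)
            out.append((node, W, lsW, down[node]["D"], down[node]["lsD"]))
            if not node.is_leaf():
                t = node.edge.length
                P = self.model.transition_matrices(t, self.gamma.rates)
                A_node = np.einsum("ksi,kij->ksj", W, P)
                up[node] = (A_node, lsW)
        return out

    def _edge_loglik(self, t, W, lsW, D, lsD):
        P = self.model.transition_matrices(t, self.gamma.rates)
        PD = np.einsum("kij,ksj->ksi", P, D)
        site = np.einsum("ksi,ksi->ks", W, PD).mean(axis=0)
        if np.any(site <= 0):
            return -np.inf
        return float(np.dot(self.weights, np.log(site) + lsW + lsD))

    def optimize_branch_lengths(self, tol: float = 1e-4,
                                max_sweeps: int = 20) -> float:
        """Coordinate-wise branch-length optimization.

        Each sweep refreshes all messages, then Brent-optimizes every edge
        against messages from the sweep start; a sweep that fails to improve
        the exact log-likelihood is rolled back, guaranteeing monotonicity.
        """
        best = self.log_likelihood()
        for _ in range(max_sweeps):
            down = self._postorder()
            edges = self._edge_arrays(down)
            old = {node: node.edge.length for node, *_ in edges}
            for node, W, lsW, D, lsD in edges:
                res = optimize.minimize_scalar(
                    lambda t: -self._edge_loglik(t, W, lsW, D, lsD),
                    bounds=(_BL_MIN, _BL_MAX), method="bounded",
                    options={"xatol": 1e-7},
                )
                node.edge.length = float(res.x)
            new = self.log_likelihood()
            if new < best:
                for node, t in old.items():
                    node.edge.length = t
                break
            if new - best < tol:
                best = max(new, best)
                break
            best = new
        return best


def tree_log_likelihood(tree: dendropy.Tree, aln: Alignment,
                        model: SubstitutionModel, gamma: GammaRates,
                        columns: Sequence[int] | None = None) -> float:
    """Felsenstein pruning log-likelihood of the alignment on the tree."""
    return TreeLikelihood(tree, aln, model, gamma, columns).log_likelihood()


# ---------------------------------------------------------------------------
# Topology search
# ---------------------------------------------------------------------------


def _nni_candidates(tree: dendropy.Tree):
    """Internal edges eligible for NNI: both endpoints internal."""
    for edge in tree.preorder_edge_iter():
        u, v = edge.tail_node, edge.head_node
        if u is None or v.is_leaf():
            continue
        siblings = [c for c in u.child_nodes() if c is not v]
        if u.parent_node is None and len(siblings) < 1:
            continue
        if siblings:
            yield u, v, siblings[0]


def _apply_nni(u, v, s, a) -> None:
    """Swap child ``a`` of ``v`` with child ``s`` of ``u`` (lengths travel)."""
    u.remove_child(s)
    v.remove_child(a)
    u.add_child(a)
    v.add_child(s)


def optimize_tree(aln: Alignment, model: SubstitutionModel, gamma: GammaRates,
                  start: str = "both", columns: Sequence[int] | None = None,
                  nni: bool = True, max_nni_rounds: int = 10,
                  bl_tol: float = 1e-4, optimize_lengths: bool = True,
                  D: np.ndarray | None = None,
                  taxon_namespace: dendropy.TaxonNamespace | None = None
                  ) -> tuple[dendropy.Tree, float]:
    """Heuristic ML tree: NJ/BioNJ start, branch-length optimization, NNI.

    ``start`` is 'nj', 'bionj' or 'both' (the higher-likelihood result wins).
    Returns (tree, log-likelihood); the tree also carries the value as the
    attribute ``log_likelihood``.  Deterministic given inputs.
    """
    if aln.n_seqs < 4:
        raise AlignmentError("tree search needs at least 4 taxa")
    if D is None:
        D = distance_matrix(aln, model, gamma, columns)
    builders = {"nj": nj_tree, "bionj": bionj_tree}
    if start == "both":
        starts = ["nj", "bionj"]
    elif start in builders:
        starts = [start]
    else:
        raise AlignmentError("start must be 'nj', 'bionj' or 'both'")

    best_tree, best_ll = None, -np.inf
    for s in starts:
        tree = builders[s](D, aln.ids, taxon_namespace=taxon_namespace)
        engine = TreeLikelihood(tree, aln, model, gamma, columns)
        if optimize_lengths:
            ll = engine.optimize_branch_lengths(tol=bl_tol)
        else:
            ll = engine.log_likelihood()
        if nni:
            for _round in range(max_nni_rounds):
                improved = False
                for u, v, sib in list(_nni_candidates(tree)):
                    children = list(v.child_nodes())
                    best_swap = None
                    for a in children:
                        _apply_nni(u, v, sib, a)
                        cand = TreeLikelihood(tree, aln, model, gamma, columns)
                        cll = cand.log_likelihood()
                        _apply_nni(u, v, a, sib)  # undo
                        if cll > ll + 1e-9 and (best_swap is None or cll > best_swap[1]):
                            best_swap = (a, cll)
                    if best_swap is not None:
                        _apply_nni(u, v, sib, best_swap[0])
                        engine = TreeLikelihood(tree, aln, model, gamma, columns)
                        ll = engine.optimize_branch_lengths(tol=bl_tol)
                        improved = True
                        break  # candidate list is stale after a swap
                if not improved:
                    break
        if ll > best_ll:
            best_tree, best_ll = tree, ll
    best_tree.log_likelihood = best_ll
    return best_tree, best_ll


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(aln: Alignment, model: SubstitutionModel, gamma: GammaRates,
                      n_replicates: int = 1000, seed: int | None = None,
                      columns: Sequence[int] | None = None,
                      point_tree: dendropy.Tree | None = None,
                      nni: bool = True,
                      optimize_replicate_lengths: bool = True) -> dendropy.Tree:
    """Non-parametric bootstrap: resample columns, rebuild a tree per
    replicate, and label the point tree's internal nodes with the percentage
    of replicates containing each bipartition.
    """
    if n_replicates < 1:
        raise AlignmentError("need at least one bootstrap replicate")
    cols = list(columns) if columns is not None else list(range(1, aln.n_cols + 1))
    ns = dendropy.TaxonNamespace([str(i) for i in aln.ids])
    if point_tree is None:
        point_tree, _ = optimize_tree(aln, model, gamma, columns=cols, nni=nni,
                                      taxon_namespace=ns)
    elif point_tree.taxon_namespace is not ns:
        point_tree = dendropy.Tree.get(
            data=point_tree.as_string(schema="newick"), schema="newick",
            taxon_namespace=ns, preserve_underscores=True)
    point_tree.encode_bipartitions()
    counts = {b.split_bitmask: 0 for b in point_tree.bipartition_encoding}

    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        sel = rng.integers(0, len(cols), size=len(cols))
        rep_cols = [cols[i] for i in sel]
        rep_tree, _ll = optimize_tree(aln, model, gamma, columns=rep_cols,
                                      nni=nni, taxon_namespace=ns,
                                      optimize_lengths=optimize_replicate_lengths)
        rep_tree.encode_bipartitions()
        rep_masks = {b.split_bitmask for b in rep_tree.bipartition_encoding}
        for mask in counts:
            if mask in rep_masks:
                counts[mask] += 1

    for node in point_tree.preorder_node_iter():
        if node.is_leaf() or node.edge.bipartition is None:
            continue
        pct = 100.0 * counts[node.edge.bipartition.split_bitmask] / n_replicates
        node.label = f"{pct:.0f}"
        node.support = pct
    return point_tree


# ---------------------------------------------------------------------------
# Gamma shape estimation
# ---------------------------------------------------------------------------


def estimate_gamma_shape(tree: dendropy.Tree, aln: Alignment,
                         model: SubstitutionModel, n_categories: int = 5,
                         columns: Sequence[int] | None = None,
                         bounds: tuple[float, float] = (0.05, 50.0)) -> float:
    """Gamma shape maximizing the pruning likelihood on a fixed tree."""

    def neg(alpha: float) -> float:
        g = GammaRates.discrete(alpha, n_categories)
        return -tree_log_likelihood(tree, aln, model, g, columns)

    res = optimize.minimize_scalar(neg, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-4})
    return float(res.x)
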