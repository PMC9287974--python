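"""Sample-relationship analyses on β-value profiles.

Per patient, the most variable probes (variance over the patient's tumour
samples only; a normal reference participates in distances but never in
probe selection) define a Euclidean distance matrix, from which an unrooted
minimal-evolution tree is built: neighbour-joining start, ordinary
least-squares (OLS) branch lengths, then a nearest-neighbour-interchange
hill climb accepting moves that strictly reduce the OLS total tree length.
Negative OLS lengths are clamped to zero only after the search converges, so
the criterion is always evaluated on unclamped fits.

Cohort-level views (hierarchical clustering, classical metric MDS) and the
SNP-probe sample-identity check live here too.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .exceptions import IdentityError, ValidationError
from .io_formats import BetaMatrix, ProbeManifest, SampleSheet

logger = logging.getLogger(__name__)

_QUOTE_TRIGGERS = set("(),:;'[] \t\n")


def _format_label(label: str) -> str:
    if any(ch in _QUOTE_TRIGGERS for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_key(node: Hashable):
    return (0, node) if isinstance(node, str) else (1, node)


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distance matrix contains non-finite values")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def select_top_variable_probes(
    beta: BetaMatrix,
    samples: Sequence[str],
    k: int,
    exclude_from_selection: Iterable[str] = (),
) -> list[str]:
    """Top-k probes by sample variance (ddof=1), ranked over ``samples`` minus
    ``exclude_from_selection`` (typically the normal reference, which enters
    the distance computation but not the ranking).

    Only probes measured in every one of ``samples`` are eligible, so the
    resulting selection is always usable for distances. Ties break by probe
    id, lexicographically.
    """
    samples = list(samples)
    selection_samples = [s for s in samples if s not in set(exclude_from_selection)]
    if len(selection_samples) < 2:
        raise ValidationError("variance ranking needs >= 2 selection samples")
    sub = beta.values[samples]
    usable = sub.notna().all(axis=1)
    sub = sub[usable]
    if k > len(sub):
        raise ValidationError(
            f"requested top {k} probes but only {len(sub)} are measured in all samples"
        )
    var = sub[selection_samples].var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda p: (-var[p], p))
    return order[:k]


def euclidean_distances(
    beta: BetaMatrix, samples: Sequence[str], probes: Sequence[str]
) -> DistanceMatrix:
    """Pairwise Euclidean distances over the given probes."""
    samples = list(samples)
    sub = beta.values.loc[list(probes), samples]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()][0]
        raise ValidationError(
            f"missing β among selected probes (sample {bad!r}); "
            "probe selection should have excluded them"
        )
    d = squareform(pdist(sub.to_numpy().T, metric="euclidean"))
    return DistanceMatrix(samples, d)


# ---------------------------------------------------------------------------
# Unrooted trees


class PhyloTree:
    """Unrooted tree with branch lengths: leaves are string labels, internal
    nodes integers of degree 3. Serialization is canonical (children ordered
    by their smallest leaf label), so equal trees give equal Newick text."""

    def __init__(self, adjacency: Mapping[Hashable, Mapping[Hashable, float]]):
        self.adj: dict[Hashable, dict[Hashable, float]] = {
            u: dict(nbrs) for u, nbrs in adjacency.items()
        }
        self.ols_total_length: float | None = None  # unclamped OLS criterion value
        self._validate()

    def _validate(self) -> None:
        for u, nbrs in self.adj.items():
            for v, ln in nbrs.items():
                if not np.isfinite(ln):
                    raise ValidationError(f"non-finite branch length on edge {u}-{v}")
                if v not in self.adj or u not in self.adj[v]:
                    raise ValidationError("adjacency is not symmetric")
        if len(self.leaves()) < 3:
            raise ValidationError("tree must have >= 3 leaves")

    def leaves(self) -> list[str]:
        return sorted(n for n in self.adj if isinstance(n, str))

    def internal_nodes(self) -> list[Hashable]:
        return sorted((n for n in self.adj if not isinstance(n, str)))

    def edges(self) -> list[tuple[Hashable, Hashable]]:
        out = []
        for u in self.adj:
            for v in self.adj[u]:
                if _node_key(u) < _node_key(v):
                    out.append((u, v))
        return sorted(out, key=lambda e: (_node_key(e[0]), _node_key(e[1])))

    @property
    def total_length(self) -> float:
        return float(sum(self.adj[u][v] for u, v in self.edges()))

    def copy_topology(self) -> dict[Hashable, dict[Hashable, float]]:
        return {u: dict(nbrs) for u, nbrs in self.adj.items()}

    def leaf_path_lengths(self) -> pd.DataFrame:
        """Sum of branch lengths along the path between every leaf pair."""
        leaves = self.leaves()
        dist = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for src in leaves:
            seen = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, ln in self.adj[u].items():
                    if v not in seen:
                        seen[v] = seen[u] + ln
                        stack.append(v)
            for dst in leaves:
                dist.loc[src, dst] = seen[dst]
        return dist

    def _min_leaf(self, node: Hashable, parent: Hashable) -> str:
        if isinstance(node, str):
            return node
        return min(
            self._min_leaf(v, node) for v in self.adj[node] if v != parent
        )

    def _newick_subtree(self, node: Hashable, parent: Hashable) -> str:
        length = self.adj[parent][node]
        if isinstance(node, str):
            return f"{_format_label(node)}:{length:g}"
        children = sorted(
            (v for v in self.adj[node] if v != parent),
            key=lambda v: self._min_leaf(v, node),
        )
        inner = ",".join(self._newick_subtree(c, node) for c in children)
        return f"({inner}):{length:g}"

    def to_newick(self) -> str:
        """Unrooted Newick: the basal trifurcation sits at the internal node
        adjacent to the smallest leaf label (for a 3-leaf star, the centre)."""
        smallest = self.leaves()[0]
        root = next(iter(self.adj[smallest]))
        children = sorted(self.adj[root], key=lambda v: self._min_leaf(v, root))
        inner = ",".join(self._newick_subtree(c, root) for c in children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# Neighbour joining


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining with deterministic first-minimum
    tie-breaking (scan order = current node ordering)."""
    ids = list(dist.sample_ids)
    n = len(ids)
    if n < 3:
        raise ValidationError("neighbour joining needs >= 3 samples")
    nodes: list[Hashable] = list(ids)
    D = dist.values.astype(float).copy()
    adj: dict[Hashable, dict[Hashable, float]] = {u: {} for u in nodes}
    next_internal = 0

    def connect(u, v, ln):
        adj.setdefault(u, {})[v] = ln
        adj.setdefault(v, {})[u] = ln

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - row_sums[i] - row_sums[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        u = next_internal
        next_internal += 1
        li = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        connect(nodes[i], u, li)
        connect(nodes[j], u, lj)
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        nodes = [nodes[x] for x in keep] + [u]
        D = D2

    u = next_internal
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    connect(a, u, la)
    connect(b, u, lb)
    connect(c, u, lc)
    return PhyloTree(adj)


# ---------------------------------------------------------------------------
# OLS branch lengths and the minimal-evolution search


def _paths_incidence(
    adj: Mapping[Hashable, Mapping[Hashable, float]],
    leaves: Sequence[str],
    edges: Sequence[tuple[Hashable, Hashable]],
) -> np.ndarray:
    edge_index = {}
    for k, (u, v) in enumerate(edges):
        edge_index[(u, v)] = k
        edge_index[(v, u)] = k
    pairs = list(itertools.combinations(leaves, 2))
    A = np.zeros((len(pairs), len(edges)))
    for r, (a, b) in enumerate(pairs):
        parent = {a: None}
        stack = [a]
        while stack:
            x = stack.pop()
            if x == b:
                break
            for y in adj[x]:
                if y not in parent:
                    parent[y] = x
                    stack.append(y)
        node = b
        while parent[node] is not None:
            A[r, edge_index[(node, parent[node])]] = 1.0
            node = parent[node]
    return A


def ols_branch_lengths(
    adj: Mapping[Hashable, Mapping[Hashable, float]], dist: DistanceMatrix
) -> tuple[dict[tuple[Hashable, Hashable], float], float, float]:
    """Unconstrained OLS fit of branch lengths to pairwise distances on a
    fixed topology. Returns (edge lengths, total length, residual SSQ)."""
    leaves = sorted(n for n in adj if isinstance(n, str))
    edges = sorted(
        ((u, v) for u in adj for v in adj[u] if _node_key(u) < _node_key(v)),
        key=lambda e: (_node_key(e[0]), _node_key(e[1])),
    )
    A = _paths_incidence(adj, leaves, edges)
    d = np.array([dist.get(a, b) for a, b in itertools.combinations(leaves, 2)])
    lengths, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = float(np.sum((A @ lengths - d) ** 2))
    return dict(zip(edges, lengths)), float(lengths.sum()), resid


def _nni_moves(adj: Mapping[Hashable, Mapping[Hashable, float]]):
    """All NNI rearrangements, in deterministic edge-scan order.

    For an internal edge (u, v) with u-side subtrees (a1, a2) and v-side
    (c1, c2), the two alternatives swap a2 with c1 and a2 with c2.
    """
    internal_edges = sorted(
        (
            (u, v)
            for u in adj
            for v in adj[u]
            if not isinstance(u, str) and not isinstance(v, str)
            and _node_key(u) < _node_key(v)
        ),
        key=lambda e: (_node_key(e[0]), _node_key(e[1])),
    )
    for u, v in internal_edges:
        a_side = sorted((x for x in adj[u] if x != v), key=_node_key)
        c_side = sorted((x for x in adj[v] if x != u), key=_node_key)
        a2 = a_side[1]
        for c in c_side:
            new = {x: dict(nbrs) for x, nbrs in adj.items()}
            for node, old_parent, new_parent in ((a2, u, v), (c, v, u)):
                ln = new[old_parent].pop(node)
                new[node].pop(old_parent)
                new[new_parent][node] = ln
                new[node][new_parent] = ln
            yield new


def build_me_tree(dist: DistanceMatrix, max_iter: int = 10000) -> PhyloTree:
    """Minimal-evolution tree: NJ start, OLS lengths, first-improvement NNI
    hill climb on the OLS total tree length. Negative branch lengths are
    clamped to zero after convergence; the unclamped criterion value is kept
    on ``tree.ols_total_length``.
    """
    if not np.all(np.isfinite(dist.values)):
        raise ValidationError("non-finite distances")
    start = neighbor_joining(dist)
    adj = start.copy_topology()
    _, total, _ = ols_branch_lengths(adj, dist)
    for _ in range(max_iter):
        improved = False
        for candidate in _nni_moves(adj):
            _, cand_total, _ = ols_branch_lengths(candidate, dist)
            if cand_total < total:
                adj, total = candidate, cand_total
                improved = True
                break
        if not improved:
            break
    lengths, total, _ = ols_branch_lengths(adj, dist)
    final = {u: {} for u in adj}
    for (u, v), ln in lengths.items():
        clamped = max(0.0, float(ln))
        final[u][v] = clamped
        final[v][u] = clamped
    tree = PhyloTree(final)
    tree.ols_total_length = total
    return tree


# ---------------------------------------------------------------------------
# Rooted rendering


@dataclass
class RootedNode:
    """Rooted rendering of an unrooted tree (used for display only)."""

    name: str | None
    length: float
    children: list["RootedNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves()]

    def _min_leaf(self) -> str:
        return min(self.leaves())

    def _newick(self) -> str:
        if not self.children:
            return f"{_format_label(self.name)}:{self.length:g}"
        inner = ",".join(
            c._newick() for c in sorted(self.children, key=RootedNode._min_leaf)
        )
        return f"({inner}):{self.length:g}"

    def to_newick(self) -> str:
        inner = ",".join(
            c._newick() for c in sorted(self.children, key=RootedNode._min_leaf)
        )
        return f"({inner});"


def attach_reference_and_root(tree: PhyloTree, reference_id: str) -> RootedNode:
    """Root the rendering on the edge leading to the reference leaf.

    The root is placed at the reference leaf's attachment point: one child is
    the reference leaf carrying its full branch length, the other the rest of
    the tree at length 0 — every leaf-to-leaf path length is preserved.
    """
    if reference_id not in tree.adj or not isinstance(reference_id, str):
        raise ValidationError(f"unknown reference leaf {reference_id!r}")

    def build(node: Hashable, parent: Hashable, length: float) -> RootedNode:
        if isinstance(node, str):
            return RootedNode(name=node, length=length)
        children = [
            build(v, node, ln) for v, ln in tree.adj[node].items() if v != parent
        ]
        return RootedNode(name=None, length=length, children=children)

    attach = next(iter(tree.adj[reference_id]))
    ref_len = tree.adj[reference_id][attach]
    ref_child = RootedNode(name=reference_id, length=ref_len)
    rest = build(attach, reference_id, 0.0)
    return RootedNode(name=None, length=0.0, children=[ref_child, rest])


# ---------------------------------------------------------------------------
# Cohort views


@dataclass
class Dendrogram:
    sample_ids: list[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))


def hierarchical_clustering(dist: DistanceMatrix, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the distance matrix (complete or average
    linkage; the merge heights of both are monotonically non-decreasing)."""
    if method not in ("complete", "average"):
        raise ValidationError(f"unsupported linkage {method!r}")
    Z = scipy_linkage(dist.condensed(), method=method)
    return Dendrogram(list(dist.sample_ids), Z, method)


def classical_mds(dist: DistanceMatrix, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) scaling: double-centre −½D², eigendecompose, and
    scale eigenvectors by the square roots of the top eigenvalues.

    Returns (coordinates n×dims, all eigenvalues in descending order).
    Negative eigenvalues (non-Euclidean input) are truncated with a warning;
    asking for more dimensions than there are positive eigenvalues is an
    error. Output is centred at the origin; axis signs are fixed so the
    largest-magnitude loading on each axis is positive.
    """
    D = dist.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    if dims > int(positive.sum()):
        raise ValidationError(
            f"requested {dims} dimensions but only {int(positive.sum())} "
            "positive eigenvalues"
        )
    if (eigval < -1e-9 * max(1.0, abs(eigval[0]))).any():
        logger.warning("classical MDS: negative eigenvalues truncated")
    coords = eigvec[:, :dims] * np.sqrt(eigval[:dims])
    for j in range(dims):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, eigval


# ---------------------------------------------------------------------------
# SNP-probe identity verification


@dataclass
class IdentityReport:
    records: pd.DataFrame  # per sample: nearest neighbour and distance margins
    violations: list[str]
    n_snp_probes: int

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_sample_identity(
    beta: BetaMatrix, sheet: SampleSheet, manifest: ProbeManifest
) -> IdentityReport:
    """Check that every sample's nearest neighbour (Euclidean distance on the
    SNP probes only) comes from the same patient.

    A sample is flagged when it lies strictly nearer to another patient's
    sample than to any sample sharing its own patient label (the tie-robust
    reading of the nearest-neighbour rule: an exact tie that includes an
    own-patient sample is not a violation). Samples whose patient contributed
    only one sample cannot have a same-patient neighbour and are never
    flagged. The report carries, per sample, the nearest same-patient and
    nearest other-patient distances and their margin (inter − intra;
    positive = comfortably verified).
    """
    snp_ids = [p for p in manifest.snp_probe_ids if p in beta.probe_ids]
    if not snp_ids:
        raise IdentityError("no SNP probes available for identity verification")
    samples = [s for s in sheet.sample_ids if s in set(beta.sample_ids)]
    sub = beta.values.loc[snp_ids, samples]
    sub = sub[sub.notna().all(axis=1)]
    if sub.empty:
        raise IdentityError("no SNP probe is measured in every sample")
    D = squareform(pdist(sub.to_numpy().T, metric="euclidean"))
    patient_of = {s: sheet.row(s)["patient_id"] for s in samples}
    counts = pd.Series(list(patient_of.values())).value_counts()

    rows = []
    violations: list[str] = []
    for i, s in enumerate(samples):
        d = D[i].copy()
        d[i] = np.inf
        nearest_i = int(np.argmin(d))
        same = np.array([patient_of[t] == patient_of[s] for t in samples])
        same[i] = False
        other = ~same
        other[i] = False
        intra = float(d[same].min()) if same.any() else np.nan
        inter = float(d[other].min()) if other.any() else np.nan
        multi = counts[patient_of[s]] > 1
        flagged = bool(multi and intra > inter)
        if flagged:
            violations.append(s)
        rows.append(
            dict(sample_id=s, patient_id=patient_of[s],
                 nearest=samples[nearest_i],
                 nearest_patient=patient_of[samples[nearest_i]],
                 intra_min=intra, inter_min=inter,
                 margin=inter - intra if multi else np.nan,
                 flagged=flagged)
        )
    return IdentityReport(pd.DataFrame(rows), violations, len(sub))
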