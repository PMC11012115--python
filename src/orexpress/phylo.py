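"""Gene tree over intact ORs: alignment, distances, NJ, bootstrap, rooting.

The intact OR coding sequences are aligned progressively (pairwise global
alignments with match +1 / mismatch -1 / gap open -4 / extend -1, a UPGMA
guide tree on pairwise distances, then profile-profile merges along the
guide tree).  Input order never matters: sequences are sorted by id before
anything else.

Distances are Jukes-Cantor, ``d = -(3/4) ln(1 - (4/3) p)`` with ``p`` the
mismatch proportion over pairwise-ungapped columns (pairwise deletion);
saturated pairs (p >= 0.75) are capped at a large constant with a warning.
The tree is built with canonical neighbor joining (Saitou-Nei Q matrix,
ties broken by the lexicographically smallest taxon pair, negative branch
lengths clamped to zero with the deficit moved to the sister branch).
Column-bootstrap replicates give percent support per internal edge, and the
tree is rooted on the branch separating the non-class-2 leaves from the
rest (falling back to the maximum-purity branch, flagged, if non-class-2 is
not monophyletic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import linkage

__all__ = [
    "MultipleAlignment",
    "PhyloTree",
    "RootedNode",
    "UnrootedTree",
    "align",
    "distance_matrix",
    "jukes_cantor",
    "neighbor_joining",
    "bootstrap_and_root",
    "write_fasta_alignment",
    "write_phylip",
]

SATURATION_CAP = 10.0

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -4.0, -1.0

_ALPHA = "ACGT"
_A2I = {c: i for i, c in enumerate(_ALPHA)}


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def as_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            len(self.rows), self.n_columns
        )


# ---------------------------------------------------------------------------
# progressive alignment


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _profile(rows: list[str]) -> np.ndarray:
    """(columns x 4) base counts; gaps and ambiguous bases contribute zero."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    prof = np.zeros((arr.shape[1], 4), dtype=np.float64)
    for base, i in _A2I.items():
        prof[:, i] = (arr == ord(base)).sum(axis=0)
    return prof


def _profile_dp(profA: np.ndarray, profB: np.ndarray) -> list[str]:
    """Global affine-gap profile-profile alignment; returns the op string.

    Ops: 'M' consume a column of both profiles, 'A' consume a column of A
    against a gap, 'B' consume a column of B against a gap.  Vectorized row
    by row; the horizontal gap state uses the prefix-max identity
    ``E[j] = ext*j + max_{k<j}(M[k] + open - ext*(k+1))`` so no inner loop
    over columns is needed.
    """
    la, lb = profA.shape[0], profB.shape[0]
    nA = max(profA.sum(axis=1).max(), 1.0)
    nB = max(profB.sum(axis=1).max(), 1.0)
    Mscore = np.full((4, 4), MISMATCH)
    np.fill_diagonal(Mscore, MATCH)
    S = (profA @ Mscore @ profB.T) / (nA * nB)

    NEG = -1e30
    Mm = np.full((la + 1, lb + 1), NEG, dtype=np.float64)
    Em = np.full((la + 1, lb + 1), NEG, dtype=np.float64)
    Fm = np.full((la + 1, lb + 1), NEG, dtype=np.float64)
    Mm[0, 0] = 0.0
    j = np.arange(1, lb + 1)
    Em[0, 1:] = GAP_OPEN + GAP_EXTEND * (j - 1)
    i = np.arange(1, la + 1)
    Fm[1:, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)

    for r in range(1, la + 1):
        prev_best = np.maximum(np.maximum(Mm[r - 1], Em[r - 1]), Fm[r - 1])
        Mm[r, 1:] = S[r - 1] + prev_best[:-1]
        Fm[r, 1:] = np.maximum(Mm[r - 1, 1:] + GAP_OPEN, Fm[r - 1, 1:] + GAP_EXTEND)
        g = np.maximum(Mm[r, :-1], Fm[r, :-1]) + GAP_OPEN - GAP_EXTEND * np.arange(1, lb + 1)
        Em[r, 1:] = GAP_EXTEND * np.arange(1, lb + 1) + np.maximum.accumulate(g)

    ops: list[str] = []
    r, c = la, lb
    state = int(np.argmax([Mm[r, c], Em[r, c], Fm[r, c]]))
    while r > 0 or c > 0:
        if r == 0:
            ops.append("B")
            c -= 1
            continue
        if c == 0:
            ops.append("A")
            r -= 1
            continue
        if state == 0:  # M
            prev = [Mm[r - 1, c - 1], Em[r - 1, c - 1], Fm[r - 1, c - 1]]
            state = int(np.argmax(prev))
            ops.append("M")
            r -= 1
            c -= 1
        elif state == 1:  # E: gap in A, consumed B column c
            opened = max(Mm[r, c - 1], Fm[r, c - 1]) + GAP_OPEN
            state = 1 if Em[r, c] != opened and Em[r, c - 1] + GAP_EXTEND >= opened else (
                0 if Mm[r, c - 1] >= Fm[r, c - 1] else 2
            )
            ops.append("B")
            c -= 1
        else:  # F: gap in B, consumed A row r
            opened = Mm[r - 1, c] + GAP_OPEN
            state = 2 if Fm[r, c] != opened and Fm[r - 1, c] + GAP_EXTEND >= opened else 0
            ops.append("A")
            r -= 1
    ops.reverse()
    return ops


def _merge(rowsA: list[str], rowsB: list[str]) -> tuple[list[str], list[str]]:
    ops = _profile_dp(_profile(rowsA), _profile(rowsB))
    outA = ["" for _ in rowsA]
    outB = ["" for _ in rowsB]
    ia = ib = 0
    colsA = [[r[i] for r in rowsA] for i in range(len(rowsA[0]))]
    colsB = [[r[i] for r in rowsB] for i in range(len(rowsB[0]))]
    bufA: list[list[str]] = []
    bufB: list[list[str]] = []
    gapA = ["-"] * len(rowsA)
    gapB = ["-"] * len(rowsB)
    for op in ops:
        if op == "M":
            bufA.append(colsA[ia])
            bufB.append(colsB[ib])
            ia += 1
            ib += 1
        elif op == "A":
            bufA.append(colsA[ia])
            bufB.append(gapB)
            ia += 1
        else:
            bufA.append(gapA)
            bufB.append(colsB[ib])
            ib += 1
    for k in range(len(rowsA)):
        outA[k] = "".join(col[k] for col in bufA)
    for k in range(len(rowsB)):
        outB[k] = "".join(col[k] for col in bufB)
    return outA, outB


def align(seqs: dict[str, str]) -> MultipleAlignment:
    """Progressive multiple alignment of coding nucleotide sequences.

    Requires at least three sequences.  Deterministic: input is sorted by id,
    the guide tree is UPGMA on pairwise alignment distances, and merges
    follow the guide tree bottom-up.
    """
    if len(seqs) < 3:
        raise ValueError("alignment needs at least 3 sequences")
    ids = sorted(seqs)
    n = len(ids)
    aligner = _pairwise_aligner()
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[ids[i]], seqs[ids[j]])[0]
            a, b = str(aln[0]), str(aln[1])
            cols = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
            mism = sum(1 for x, y in zip(a, b) if x != "-" and y != "-" and x != y)
            dist[i, j] = dist[j, i] = mism / cols if cols else 1.0
    condensed = dist[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(n)
    }
    for step, (a, b, _d, _cnt) in enumerate(Z):
        ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
        rowsA, rowsB = _merge(ca[1], cb[1])
        clusters[n + step] = (ca[0] + cb[0], rowsA + rowsB)
    (final_ids, final_rows) = clusters.popitem()[1]
    order = {gid: k for k, gid in enumerate(final_ids)}
    return MultipleAlignment(ids=ids, rows=[final_rows[order[g]] for g in ids])


# ---------------------------------------------------------------------------
# distances


def jukes_cantor(p: float) -> float:
    """JC69 distance from a mismatch proportion (capped at saturation)."""
    if p >= 0.75:
        warnings.warn(f"saturated distance (p={p:.3f}); capping at {SATURATION_CAP}")
        return SATURATION_CAP
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def distance_matrix(aln: MultipleAlignment) -> np.ndarray:
    """Pairwise Jukes-Cantor distances with pairwise deletion of gap columns."""
    arr = aln.as_array()
    n = len(aln.ids)
    valid = np.zeros(arr.shape, dtype=bool)
    for base in _ALPHA:
        valid |= arr == ord(base)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                D[i, j] = D[j, i] = SATURATION_CAP
                continue
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            D[i, j] = D[j, i] = jukes_cantor(p)
    return D


# ---------------------------------------------------------------------------
# trees


@dataclass
class UnrootedTree:
    """Adjacency-list unrooted tree; leaves carry names."""

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_names: dict[int, str]

    def leaves_beyond(self, start: int, avoid: int) -> frozenset[str]:
        """Leaf names reachable from ``start`` without crossing ``avoid``."""
        seen = {avoid, start}
        stack = [start]
        out = []
        while stack:
            u = stack.pop()
            if u in self.leaf_names:
                out.append(self.leaf_names[u])
            for v, _l in self.adjacency[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(out)

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v, l in nbrs:
                if u < v:
                    out.append((u, v, l))
        return sorted(out)

    def bipartitions(self) -> dict[frozenset[str], tuple[int, int]]:
        """Canonical (smaller-or-lexicographic side) split per internal edge."""
        all_leaves = frozenset(self.leaf_names.values())
        out: dict[frozenset[str], tuple[int, int]] = {}
        for u, v, _l in self.edges():
            side = self.leaves_beyond(v, u)
            out[_canonical_split(side, all_leaves)] = (u, v)
        return out


def _canonical_split(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def neighbor_joining(D: np.ndarray, ids: list[str]) -> UnrootedTree:
    """Canonical Saitou-Nei neighbor joining.

    Tie-breaking: among minimal Q entries, the lexicographically smallest
    (sorted) pair of cluster labels wins, where a cluster's label is its
    smallest member taxon.  Negative branch lengths are clamped to zero and
    the deficit is transferred to the sister branch.
    """
    n = len(ids)
    if n < 2 or D.shape != (n, n):
        raise ValueError("need a square distance matrix over >= 2 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaf_names = {i: ids[i] for i in range(n)}
    active = list(range(n))
    labels = {i: ids[i] for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(n)}
    next_id = n

    def d(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    def connect(u: int, v: int, length: float) -> None:
        adjacency.setdefault(u, []).append((v, length))
        adjacency.setdefault(v, []).append((u, length))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _key, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        u = next_id
        next_id += 1
        connect(u, i, li)
        connect(u, j, lj)
        for k in active:
            if k in (i, j):
                continue
            dist[tuple(sorted((u, k)))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        labels[u] = min(labels[i], labels[j])
        active = [k for k in active if k not in (i, j)] + [u]

    if len(active) == 3:
        a, b, c = active
        u = next_id
        la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
        lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
        lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        for node, l in ((a, la), (b, lb), (c, lc)):
            connect(u, node, max(l, 0.0))
    elif len(active) == 2:
        a, b = active
        connect(a, b, d(a, b))
    return UnrootedTree(adjacency=adjacency, leaf_names=leaf_names)


@dataclass
class RootedNode:
    name: str | None
    length: float
    support: float | None
    children: list["RootedNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"


@dataclass
class PhyloTree:
    root: RootedNode
    monophyletic_outgroup: bool
    n_replicates: int

    def newick(self) -> str:
        inner = ",".join(c.newick() for c in self.root.children)
        return f"({inner});"

    def leaves(self) -> list[str]:
        return self.root.leaves()


def _root_on_edge(
    tree: UnrootedTree,
    edge: tuple[int, int, float],
    supports: dict[frozenset[str], float],
) -> RootedNode:
    u, v, length = edge
    all_leaves = frozenset(tree.leaf_names.values())

    def build(node: int, parent: int, branch: float) -> RootedNode:
        children = [(w, l) for w, l in tree.adjacency[node] if w != parent]
        if not children:
            return RootedNode(tree.leaf_names[node], branch, None)
        side = tree.leaves_beyond(node, parent)
        support = supports.get(_canonical_split(side, all_leaves))
        kids = [build(w, node, l) for w, l in sorted(children, key=lambda t: t[0])]
        return RootedNode(None, branch, support, kids)

    half = length / 2.0
    return RootedNode(None, 0.0, None, [build(u, v, half), build(v, u, half)])


def _resolve_root_edge(tree: UnrootedTree, outgroup: frozenset[str]):
    """Edge separating the outgroup exactly, else the maximum-purity edge."""
    best = None
    for u, v, l in tree.edges():
        for a, b in ((u, v), (v, u)):
            side = tree.leaves_beyond(b, a)
            if side == outgroup:
                return (a, b, l), True
            inter = len(side & outgroup)
            if inter == 0:
                continue
            purity = inter / len(side)
            key = (purity, inter, -len(side))
            if best is None or key > best[0]:
                best = (key, (a, b, l))
    return best[1], False


def bootstrap_and_root(
    aln: MultipleAlignment,
    n_replicates: int,
    seed: int,
    nonclass2_ids: list[str],
) -> PhyloTree:
    """NJ tree with column-bootstrap supports, rooted on non-class-2 ORs.

    Supports are the percentage of replicates whose NJ tree contains each
    original internal bipartition.  The root goes on the branch separating
    the non-class-2 leaves; if they are not monophyletic the branch with the
    highest non-class-2 purity on one side is used and the tree is flagged.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    outgroup = frozenset(nonclass2_ids)
    missing = outgroup - set(aln.ids)
    if not outgroup or missing:
        raise ValueError(f"non-class-2 ids absent from alignment: {sorted(missing)}")

    D = distance_matrix(aln)
    tree = neighbor_joining(D, aln.ids)
    splits = tree.bipartitions()
    trivial = {s for s in splits if len(s) <= 1 or len(s) >= len(aln.ids) - 1}
    hits = {s: 0 for s in splits}

    rng = np.random.default_rng(seed)
    arr = aln.as_array()
    n_cols = aln.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = MultipleAlignment(
            ids=aln.ids,
            rows=["".join(chr(b) for b in arr[i, cols]) for i in range(len(aln.ids))],
        )
        rep_splits = neighbor_joining(distance_matrix(rep), rep.ids).bipartitions()
        for s in hits:
            if s in rep_splits or s in trivial:
                hits[s] += 1

    supports = {s: 100.0 * c / n_replicates for s, c in hits.items()}
    edge, mono = _resolve_root_edge(tree, outgroup)
    u, v, l = edge
    root = _root_on_edge(tree, (u, v, l), supports)
    return PhyloTree(root=root, monophyletic_outgroup=mono, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# export


def write_fasta_alignment(aln: MultipleAlignment, path: str) -> None:
    with open(path, "w") as fh:
        for gid, row in zip(aln.ids, aln.rows):
            fh.write(f">{gid}\n{row}\n")


def write_phylip(aln: MultipleAlignment, path: str) -> None:
    """Relaxed PHYLIP (name, two spaces, row)."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.ids)} {aln.n_columns}\n")
        for gid, row in zip(aln.ids, aln.rows):
            fh.write(f"{gid}  {row}\n")
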