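"""Distance-based phylogenetics: p/Poisson distances, neighbor joining,
bootstrap supports, and clade-monophyly testing.

Neighbor joining is the Saitou-Nei agglomeration on the Q-criterion with a
deterministic tie-break (lowest label pair, lexicographically), so results
are invariant to the input ordering of taxa.  Negative branch lengths -- an
artifact NJ can produce on non-additive input -- are clamped to zero with
the deficit moved to the sibling branch; this never changes topology.

Poisson-corrected distances, -ln(1 - p), diverge as p approaches the
20-state saturation ceiling; pairs at p >= 0.95 are capped at -ln(0.05) and
reported as saturated, because no correction is reliable out there.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skbio import TreeNode

from .seqio import GAP, AlignedSet

SATURATION_P = 0.95

DistanceModel = Literal["p_distance", "poisson_corrected"]


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered label set."""

    labels: list[str]
    data: np.ndarray
    saturated: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise PhyloError("distance matrix diagonal is not zero")
        if not np.isfinite(self.data).all():
            raise PhyloError("distance matrix contains non-finite entries")
        if (self.data < 0).any():
            raise PhyloError("distance matrix contains negative entries")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.data[i, j])


def distance_matrix(aln: AlignedSet, model: DistanceModel = "p_distance") -> DistanceMatrix:
    """Pairwise distances over columns where both sequences have residues."""
    if len(aln.records) < 3:
        raise PhyloError("need >= 3 sequences for a distance matrix")
    ids = aln.ids
    rows = np.array([list(seq) for _, seq in aln.records])
    present = rows != GAP
    n = len(ids)
    d = np.zeros((n, n))
    saturated: set[frozenset[str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            ncomp = int(both.sum())
            if ncomp == 0:
                raise PhyloError(
                    f"pair ({ids[i]}, {ids[j]}) shares no comparable columns"
                )
            p = float((rows[i, both] != rows[j, both]).sum()) / ncomp
            if model == "p_distance":
                dist = p
            else:
                if p >= SATURATION_P:
                    dist = -np.log(1.0 - SATURATION_P)
                    saturated.add(frozenset((ids[i], ids[j])))
                else:
                    dist = -np.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    if saturated:
        warnings.warn(
            f"{len(saturated)} pair(s) at or beyond p={SATURATION_P} saturation; "
            "Poisson correction capped",
            stacklevel=2,
        )
    return DistanceMatrix(labels=list(ids), data=d, saturated=saturated)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; returned as a trifurcating root).

    Vectorized Saitou-Nei agglomeration; ties in the Q-criterion are broken
    on the lexicographically lowest label pair, with internal nodes named
    from their children so the result is invariant to input taxon order.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")
    labels = list(dm.labels)
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    d = dm.data.astype(float).copy()

    while len(labels) > 3:
        m = len(labels)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # q[i,j] and q[j,i] can differ by one ulp (subtraction order), so
        # canonicalize tie pairs rather than assuming the min lands at i<j
        ties = {
            (min(int(x), int(y)), max(int(x), int(y)))
            for x, y in np.argwhere(q == qmin)
            if x != y
        }
        i, j = min(
            ((tuple(sorted((labels[x], labels[y]))), (x, y)) for x, y in ties)
        )[1]
        a, b = labels[i], labels[j]
        dab = d[i, j]
        la = 0.5 * dab + (totals[i] - totals[j]) / (2 * (m - 2))
        lb = dab - la
        # clamp negatives, moving the deficit to the sibling branch
        if la < 0:
            lb, la = lb - la, 0.0
        elif lb < 0:
            la, lb = la - lb, 0.0
        parent = TreeNode()
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length, cb.length = la, lb
        parent.extend([ca, cb])
        new = f"\x00{a}|{b}"  # internal label, never collides with taxa
        nodes[new] = parent
        dnew = np.maximum(0.5 * (d[i, :] + d[j, :] - dab), 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack(
            [
                np.hstack([d[np.ix_(keep, keep)], dnew[keep][:, None]]),
                np.hstack([dnew[keep], [0.0]]),
            ]
        )
        labels = [labels[k] for k in keep] + [new]

    (a, b, c), dd = labels, d
    la = 0.5 * (dd[0, 1] + dd[0, 2] - dd[1, 2])
    lb = 0.5 * (dd[0, 1] + dd[1, 2] - dd[0, 2])
    lc = 0.5 * (dd[0, 2] + dd[1, 2] - dd[0, 1])
    root = TreeNode()
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(lab)
        child.length = max(ln, 0.0)
        root.append(child)
    for node in root.non_tips(include_self=True):
        node.name = None
    return root


def _bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Internal-edge bipartitions, keyed by the side not containing the
    reference taxon (canonical for unrooted comparison)."""
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    out: dict[frozenset[str], TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = tips - side
        if 1 < len(side) < len(tips) - 1:
            out[side] = node
    return out


def bootstrap_supports(
    aln: AlignedSet,
    n_reps: int = 100,
    seed: int = 0,
    model: DistanceModel = "p_distance",
) -> TreeNode:
    """NJ tree on the full alignment with column-bootstrap supports.

    Supports are the percentage of replicates (columns resampled with
    replacement, tree rebuilt) whose topology contains each internal
    bipartition of the full-data tree.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    if aln.n_columns < 2:
        raise PhyloError("alignment too short to bootstrap")
    full = neighbor_joining(distance_matrix(aln, model))
    target = _bipartitions(full)
    counts = {bip: 0 for bip in target}
    rng = np.random.default_rng(seed)
    ids = aln.ids
    cols = np.array([list(seq) for _, seq in aln.records])
    for _ in range(n_reps):
        pick = rng.integers(0, aln.n_columns, size=aln.n_columns)
        rep_rows = tuple(
            (rid, "".join(cols[i, pick])) for i, rid in enumerate(ids)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_aln = AlignedSet(records=rep_rows)
            rep_tree = neighbor_joining(distance_matrix(rep_aln, model))
        rep_bips = _bipartitions(rep_tree)
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for bip, node in target.items():
        node.support = 100.0 * counts[bip] / n_reps
    return full


def is_monophyletic(tree: TreeNode, taxa: set[str]) -> tuple[bool, float | None]:
    """Is ``taxa`` separated from all other leaves by a single edge?

    Returns the verdict and, when available, that edge's bootstrap support.
    """
    tips = {t.name for t in tree.tips()}
    taxa = set(taxa)
    if not taxa or not taxa < tips:
        raise PhyloError("taxa must be a non-empty proper subset of the leaf set")
    all_tips = frozenset(tips)
    ref = min(all_tips)
    query = frozenset(taxa)
    if ref in query:
        query = all_tips - query
    if len(query) == 1:
        return True, None  # a single leaf (or its complement) is trivially a clade
    bips = _bipartitions(tree)
    node = bips.get(query)
    if node is None:
        return False, None
    return True, getattr(node, "support", None)


def tree_from_newick_string(s: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(s), format="newick")
    tree.assign_supports()
    return tree
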