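"""Module detection: average-linkage dendrogram plus dynamic tree cutting.

The network (TOM or powered adjacency) is converted to a dissimilarity
d = 1 - w and clustered by UPGMA (unweighted pair-group average linkage).
Modules are then detected by a dynamic, shape-aware cut of the dendrogram:

1. *Branch detection* — a single bottom-up pass over the merge sequence.
   Branches are finalized wherever a merge height exceeds the static cut
   (interpreted, as in the standard dynamic-cut tooling, relative to the
   dendrogram's height range: the absolute threshold is
   ``q05 + cut_height * (h_max - q05)`` with ``q05`` the 5th percentile
   of merge heights), or where two module-sized branches join with a
   clear height gap above their internal cores; anything attaching to an
   already-finalized component is finalized on the spot, so diffusely
   attaching genes cannot swallow the clusters below them.
2. *Refinement* — a branch large enough to hide two modules is bisected
   (Ward 2-cut of its sub-dissimilarity); the split is kept only if the
   halves are *distinct*: the mean cross dissimilarity exceeds at least
   one half's admission radius (median + nmads x MAD of member-to-module
   distances).  Noise substructure inside a single module fails this
   test and is never split.
3. *Trim/attach (PAM-style)* — every gene joins the nearest module among
   those whose admission radius admits it, or becomes unassigned.
4. *Fragment merge* — module pairs that are mutually within each other's
   admission radius are fragments of one module and are merged (closest
   pair first), followed by a final trim/attach pass and size filter.

``deep_split`` (0-4) scales both the gap threshold and the admission
radii: higher values split more aggressively and attach more liberally.
Labels are renumbered 1..n_modules by decreasing module size; 0 is the
unassigned label.  The procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ModuleAssignment, ValidationError
from .network import AdjacencyMatrix, TOMMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "Dendrogram",
    "dissimilarity",
    "average_linkage",
    "dynamic_tree_cut",
    "detect_modules",
]

DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.99
DEFAULT_DEEP_SPLIT = 2

# deep_split -> gap threshold as a fraction of the dendrogram height range.
_GAP_FRACTION = {0: 0.40, 1: 0.30, 2: 0.20, 3: 0.10, 4: 0.05}
# deep_split -> multiple of the (scaled) median absolute deviation of
# member-to-module distances defining the assignment radius of the
# hybrid stage; higher deep_split attaches genes more liberally.
_ASSIGN_NMADS = {0: 1.0, 1: 1.5, 2: 2.0, 3: 2.5, 4: 3.0}


@dataclass
class Dendrogram:
    """UPGMA merge history in scipy linkage form plus the leaf order."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    gene_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.gene_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.linkage)


def dissimilarity(net) -> np.ndarray:
    """d = 1 - w with zero diagonal, for any [0, 1] symmetric network."""
    if isinstance(net, (SimilarityMatrix, TOMMatrix, AdjacencyMatrix)):
        W = net.values
    else:
        W = np.asarray(net, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"network must be square, got shape {W.shape}")
    if not np.array_equal(W, W.T):
        raise ValidationError("network must be symmetric")
    if np.any(W < 0) or np.any(W > 1):
        raise ValidationError("network entries must lie in [0, 1]")
    D = 1.0 - W
    np.fill_diagonal(D, 0.0)
    return D


def average_linkage(d: np.ndarray, gene_ids: list[str] | None = None) -> Dendrogram:
    """UPGMA merge tree of a dissimilarity matrix (deterministic)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 genes to cluster")
    if gene_ids is None:
        gene_ids = [str(i) for i in range(n)]
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, gene_ids=list(gene_ids))


def _candidate_branches(
    Z: np.ndarray,
    n: int,
    h_cut: float,
    min_gap: float,
    min_module_size: int,
) -> list[np.ndarray]:
    """Bottom-up pass over the merge sequence returning candidate branches.

    Merges are processed in height order.  A merge *locks* its two sides
    into final branches when (a) the merge height exceeds the static cut,
    or (b) both sides are large enough to be modules and the merge height
    jumps by at least ``min_gap`` above both sides' internal top heights —
    the shape-aware criterion that separates tight branches joined by a
    long stem.  Anything merging into an already-locked component is
    finalized on the spot, so diffuse genes that attach near the top of
    the dendrogram end up as small (later unassigned) branches instead of
    swallowing the clusters below them.
    """
    n_internal = Z.shape[0]
    # component bookkeeping per scipy node id; "core" is the running mean
    # of a component's internal merge heights, a scatter estimate that is
    # robust to late accretion of stray genes (which raises the top height
    # but barely moves the mean).
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    h_sum: dict[int, float] = {i: 0.0 for i in range(n)}
    h_cnt: dict[int, int] = {i: 0 for i in range(n)}
    locked: dict[int, bool] = {i: False for i in range(n)}
    finals: list[np.ndarray] = []

    def finalize(node: int) -> None:
        finals.append(np.array(sorted(members[node]), dtype=int))
        members[node] = []

    def core(node: int) -> float:
        return h_sum[node] / h_cnt[node] if h_cnt[node] else 0.0

    for row in range(n_internal):
        a, b = int(Z[row, 0]), int(Z[row, 1])
        h = float(Z[row, 2])
        new = n + row
        la, lb = locked[a], locked[b]
        split = h > h_cut or la or lb
        if not split and (
            len(members[a]) >= min_module_size
            and len(members[b]) >= min_module_size
            and h - max(core(a), core(b)) >= min_gap
        ):
            split = True
        if split:
            if not la:
                finalize(a)
            if not lb:
                finalize(b)
            members[new], locked[new] = [], True
            h_sum[new], h_cnt[new] = 0.0, 0
        else:
            members[new] = members[a] + members[b]
            members[a] = members[b] = []
            h_sum[new] = h_sum[a] + h_sum[b] + h
            h_cnt[new] = h_cnt[a] + h_cnt[b] + 1
            locked[new] = False
    root = n + n_internal - 1
    if not locked[root]:
        finalize(root)
    return finals


def _radius(own_dists: np.ndarray, nmads: float) -> float:
    """Robust envelope of member-to-module distances: median + nmads * MAD.

    Tight and loose modules each get an admission radius matched to their
    own internal spread.
    """
    med = float(np.median(own_dists))
    mad = 1.4826 * float(np.median(np.abs(own_dists - med)))
    return med + nmads * mad


def _own_dists(d: np.ndarray, members: np.ndarray) -> np.ndarray:
    m = members.size
    if m < 2:
        return np.zeros(m)
    return d[np.ix_(members, members)].sum(axis=1) / (m - 1)


def _distinct(d: np.ndarray, a: np.ndarray, b: np.ndarray, nmads: float) -> bool:
    """Are two gene sets separated relative to their internal spreads?

    The same admission-radius rule the assignment stage uses: the sets
    are indistinct (fragments of one module) only when the mean cross
    dissimilarity lies within both radii — each side would admit the
    typical gene of the other.  One-sided admission (a loose module
    reaching a tight neighbour) does not merge them.
    """
    cross = float(d[np.ix_(a, b)].mean())
    return cross > _radius(_own_dists(d, a), nmads) or cross > _radius(
        _own_dists(d, b), nmads
    )


def _refine_branches(
    d: np.ndarray,
    modules: list[np.ndarray],
    min_module_size: int,
    nmads: float,
) -> list[np.ndarray]:
    """Recursively split branches that hide more than one module.

    A branch big enough to contain two modules is bisected by a Ward
    2-cut of its own sub-dissimilarity (Ward resists the gradual
    accretion of diffuse genes that defeats height-based cuts) — but the
    split is accepted only when the two halves are distinct under the
    admission-radius rule, so genuine single modules are never fragmented
    by noise substructure.
    """
    out: list[np.ndarray] = []
    stack = list(modules)
    while stack:
        members = stack.pop(0)
        if members.size < 2 * min_module_size:
            out.append(members)
            continue
        sub = d[np.ix_(members, members)]
        Z = hierarchy.linkage(squareform(sub, checks=False), method="ward")
        halves = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        a = members[halves == 1]
        b = members[halves == 2]
        if (
            a.size >= min_module_size
            and b.size >= min_module_size
            and _distinct(d, a, b, nmads)
        ):
            stack.extend((a, b))
        else:
            out.append(members)
    return out


def _assign(d: np.ndarray, modules: list[np.ndarray], nmads: float) -> np.ndarray:
    """PAM-style assignment: every gene joins the nearest admitting module.

    A gene's average dissimilarity to each module's (fixed) core is
    compared to that module's admission radius; the gene takes the
    nearest module among those that admit it, or label 0 if none does.
    This both trims stray genes accreted into a branch and attaches
    outlying singletons.
    """
    n = d.shape[0]
    if not modules:
        return np.zeros(n, dtype=int)
    avg = np.stack([d[:, members].mean(axis=1) for members in modules], axis=1)
    radius = np.empty(len(modules))
    for k, members in enumerate(modules):
        m = members.size
        if m > 1:
            # a gene's distance to its own core excludes itself
            avg[members, k] = avg[members, k] * m / (m - 1)
        radius[k] = _radius(avg[members, k], nmads)
    admitted = avg <= radius[None, :]
    if len(modules) > 1:
        # clear-margin rule: a gene much closer to one module than to any
        # other belongs there even if it sits past the radius envelope
        # (the envelope is a scatter estimate, not a hard boundary)
        part = np.partition(avg, 1, axis=1)
        clear = part[:, 0] <= 0.5 * part[:, 1]
        admitted |= clear[:, None] & (avg == part[:, [0]])
    masked = np.where(admitted, avg, np.inf)
    nearest = masked.argmin(axis=1)
    return np.where(admitted.any(axis=1), nearest + 1, 0).astype(int)


def _merge_indistinct(
    d: np.ndarray, modules: list[np.ndarray], nmads: float
) -> list[np.ndarray]:
    """Greedily merge module pairs that fail the distinctness rule.

    Fragments of one underlying module sit within each other's admission
    radius; true neighbouring modules do not.  Closest indistinct pair
    first, repeated until all pairs are distinct.
    """
    mods = [np.asarray(m) for m in modules]
    changed = True
    while changed and len(mods) > 1:
        changed = False
        best: tuple[float, int, int] | None = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if not _distinct(d, mods[i], mods[j], nmads):
                    cross = float(d[np.ix_(mods[i], mods[j])].mean())
                    if best is None or cross < best[0]:
                        best = (cross, i, j)
        if best is not None:
            _, i, j = best
            merged = np.sort(np.concatenate([mods[i], mods[j]]))
            mods = [m for k, m in enumerate(mods) if k not in (i, j)] + [merged]
            changed = True
    return mods


def dynamic_tree_cut(
    dend: Dendrogram,
    d: np.ndarray,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    deep_split: int = DEFAULT_DEEP_SPLIT,
    hybrid: bool = True,
) -> ModuleAssignment:
    """Detect modules by a dynamic, shape-aware cut of the dendrogram.

    Parameters
    ----------
    dend
        Dendrogram from :func:`average_linkage` over ``d``.
    d
        The dissimilarity matrix the tree was built from (used by the
        hybrid assignment stage).
    min_module_size
        Smallest branch size that qualifies as a module.
    cut_height
        Relative static cut height in (0, 1]; see module docstring.
    deep_split
        0-4; higher splits branches more aggressively and attaches
        outlying genes more liberally.
    hybrid
        If False, skip the dissimilarity-aware assignment stage (pure
        tree-shape variant): genes in undersized branches stay unassigned.
    """
    if min_module_size < 1:
        raise ValidationError(f"min_module_size must be >= 1, got {min_module_size}")
    if deep_split not in _GAP_FRACTION:
        raise ValidationError(f"deep_split must be in 0..4, got {deep_split}")
    if not (0.0 < cut_height <= 1.0):
        raise ValidationError(f"cut_height must be in (0, 1], got {cut_height}")
    d = np.asarray(d, dtype=float)
    n = dend.n_leaves
    if d.shape != (n, n):
        raise ValidationError("dissimilarity shape does not match dendrogram")

    heights = dend.heights
    q05 = float(np.percentile(heights, 5))
    h_max = float(heights.max())
    h_range = max(h_max - q05, np.finfo(float).eps)
    h_cut = q05 + cut_height * h_range
    min_gap = _GAP_FRACTION[deep_split] * h_range

    nmads = _ASSIGN_NMADS[deep_split]
    branches = _candidate_branches(dend.linkage, n, h_cut, min_gap, min_module_size)
    modules = [b for b in branches if b.size >= min_module_size]

    if hybrid and modules:
        # split hidden multi-module branches, then trim/attach, then merge
        # fragments (on the trimmed modules) and reassign once more
        modules = _refine_branches(d, modules, min_module_size, nmads)
        labels = _assign(d, modules, nmads)
        trimmed = [np.flatnonzero(labels == k) for k in range(1, len(modules) + 1)]
        trimmed = [m for m in trimmed if m.size >= min_module_size]
        merged = _merge_indistinct(d, trimmed, nmads)
        labels = _assign(d, merged, nmads)
        for lab in range(1, len(merged) + 1):
            if (labels == lab).sum() < min_module_size:
                labels[labels == lab] = 0
    else:
        labels = np.zeros(n, dtype=int)
        for lab, members in enumerate(modules, start=1):
            labels[members] = lab

    # Renumber 1..n_modules by decreasing size (stable on ties).
    nonzero = [lab for lab in np.unique(labels) if lab > 0]
    sizes = {lab: int((labels == lab).sum()) for lab in nonzero}
    order = sorted(nonzero, key=lambda lab: (-sizes[lab], lab))
    remap = {old: new for new, old in enumerate(order, start=1)}
    relabeled = np.array([remap.get(v, 0) for v in labels], dtype=int)
    return ModuleAssignment({g: int(v) for g, v in zip(dend.gene_ids, relabeled)})


def detect_modules(
    net,
    gene_ids: list[str] | None = None,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    deep_split: int = DEFAULT_DEEP_SPLIT,
    hybrid: bool = True,
) -> ModuleAssignment:
    """Convenience wrapper: network -> dissimilarity -> UPGMA -> dynamic cut."""
    if gene_ids is None and hasattr(net, "gene_ids"):
        gene_ids = list(net.gene_ids)
    D = dissimilarity(net)
    dend = average_linkage(D, gene_ids=gene_ids)
    return dynamic_tree_cut(
        dend,
        D,
        min_module_size=min_module_size,
        cut_height=cut_height,
        deep_split=deep_split,
        hybrid=hybrid,
    )
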