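"""Lineage reconstruction from single-cell tape tables.

The unit of analysis is a cell carrying a fixed panel of tapes (one per
target barcode, each with a known site capacity).  Pairwise similarity is
the number of *order-aware* shared edits: per tape, matching insert
barcodes are counted only along the identical prefix of edited sites, so a
coincident match downstream of any disagreement (or unedited site) is
discounted.  The distance is the panel's total site count minus the shared
count.  Trees are built by UPGMA (deterministic tie-breaking) or
neighbour joining, assessed by Fitch parsimony, and supported by a
tape-block bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from dnatape.tape_sim import CellRecord

__all__ = [
    "CellRecord",
    "CohortMatrix",
    "LineageTreeResult",
    "correct_targetbc",
    "collapse_umis",
    "select_complete_cells",
    "shared_edits_order_aware",
    "pairwise_shared_matrix",
    "distance_matrix",
    "build_tree",
    "fitch_parsimony",
    "bootstrap_support",
    "cohort_summaries",
    "robinson_foulds",
    "tree_bipartitions",
    "tree_clades",
]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def correct_targetbc(
    observed: str,
    whitelist: Sequence[str],
    max_dist: int = 1,
) -> Tuple[Optional[str], str]:
    """Correct an observed target barcode against an approved list.

    Exact match returns itself; a unique match within ``max_dist``
    substitutions (default 1) is corrected; anything else is dropped.
    Returns ``(corrected_or_None, reason)``.
    """
    wl = list(whitelist)
    lens = {len(w) for w in wl}
    if len(lens) != 1:
        raise ValueError("whitelist barcodes must share one length")
    for i, a in enumerate(wl):
        for b in wl[i + 1 :]:
            if _hamming(a, b) < 3:
                warnings.warn(
                    f"whitelist pair {a}/{b} closer than Hamming 3; "
                    "correction may be ambiguous",
                    stacklevel=2,
                )
    if len(observed) != lens.pop():
        return None, "length-mismatch"
    if observed in wl:
        return observed, "exact"
    hits = [w for w in wl if _hamming(observed, w) <= max_dist]
    if len(hits) == 1:
        return hits[0], "corrected"
    if len(hits) > 1:
        return None, "ambiguous"
    return None, "too-distant"


def collapse_umis(
    rows: Iterable[Tuple[str, str, str, str]],
    min_umis: int = 2,
) -> List[Tuple[str, str, str, int]]:
    """Collapse (cell_id, umi, target_bc, tape_string) rows to consensus.

    Distinct UMIs are counted per (cell, target_bc, tape_string).  Groups
    with fewer than ``min_umis`` total UMIs are dropped; conflicting tape
    strings resolve to the one with more UMIs (ties drop the group).
    Returns (cell_id, target_bc, tape_string, n_umis) rows, sorted.
    """
    umis: Dict[Tuple[str, str], Dict[str, Set[str]]] = {}
    for cell, umi, tbc, tape in rows:
        umis.setdefault((cell, tbc), {}).setdefault(tape, set()).add(umi)
    out: List[Tuple[str, str, str, int]] = []
    for (cell, tbc), by_tape in umis.items():
        counts = {tape: len(u) for tape, u in by_tape.items()}
        if sum(counts.values()) < min_umis:
            continue
        best = max(counts.values())
        winners = [t for t, c in counts.items() if c == best]
        if len(winners) != 1:
            continue
        out.append((cell, tbc, winners[0], counts[winners[0]]))
    return sorted(out)


@dataclass
class CohortMatrix:
    """Cells over a fixed panel of (target_bc, site capacity)."""

    cells: List[CellRecord]
    panel: List[Tuple[str, int]]

    def __post_init__(self) -> None:
        for cell in self.cells:
            for tbc, cap in self.panel:
                if tbc not in cell.tapes:
                    raise ValueError(f"cell {cell.cell_id} missing tape {tbc}")
                if len(cell.tapes[tbc]) > cap:
                    raise ValueError(
                        f"cell {cell.cell_id} tape {tbc} exceeds capacity {cap}"
                    )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_sites(self) -> int:
        return sum(cap for _, cap in self.panel)

    @property
    def cell_ids(self) -> List[str]:
        return [c.cell_id for c in self.cells]

    def encode(self) -> Tuple[np.ndarray, List[str]]:
        """Integer site matrix (0 = unedited) and the symbol lookup table."""
        symbols = sorted(
            {s for c in self.cells for t in c.tapes.values() for s in t}
        )
        code = {s: i + 1 for i, s in enumerate(symbols)}
        mat = np.zeros((self.n_cells, self.total_sites), dtype=np.int32)
        for r, cell in enumerate(self.cells):
            col = 0
            for tbc, cap in self.panel:
                for s, sym in enumerate(cell.tapes[tbc]):
                    mat[r, col + s] = code[sym]
                col += cap
        return mat, symbols

    def tape_slices(self) -> List[slice]:
        out, col = [], 0
        for _, cap in self.panel:
            out.append(slice(col, col + cap))
            col += cap
        return out


def select_complete_cells(
    records: Sequence[CellRecord],
    targetbc_panel: Mapping[str, int],
    insertbc_whitelist: Optional[Sequence[str]] = None,
) -> Tuple[CohortMatrix, Dict[str, str]]:
    """Keep cells with every panel tape present and all inserts whitelisted.

    Returns the cohort plus a per-dropped-cell reason map.
    """
    wl = set(insertbc_whitelist) if insertbc_whitelist is not None else None
    panel = sorted(targetbc_panel.items())
    kept: List[CellRecord] = []
    dropped: Dict[str, str] = {}
    for cell in records:
        missing = [tbc for tbc, _ in panel if tbc not in cell.tapes]
        if missing:
            dropped[cell.cell_id] = f"missing-tape:{','.join(missing)}"
            continue
        if wl is not None:
            off = {
                s
                for tbc, _ in panel
                for s in cell.tapes[tbc]
                if s not in wl
            }
            if off:
                dropped[cell.cell_id] = f"off-whitelist:{','.join(sorted(off))}"
                continue
        kept.append(
            CellRecord(
                cell_id=cell.cell_id,
                tapes={tbc: tuple(cell.tapes[tbc]) for tbc, _ in panel},
                capacities=dict(panel),
            )
        )
    if not kept:
        raise ValueError("no cells pass the completeness filters")
    return CohortMatrix(cells=kept, panel=panel), dropped


def shared_edits_order_aware(
    a: CellRecord, b: CellRecord, panel: Sequence[Tuple[str, int]]
) -> int:
    """Order-aware shared edit count between two cells.

    Per tape, sites are scanned from site 1 while both cells carry the
    identical insert at every site so far; the scan ends at the first
    unedited site or mismatch.  The count is summed over the panel.
    """
    total = 0
    for tbc, _cap in panel:
        if tbc not in a.tapes or tbc not in b.tapes:
            raise ValueError(f"panel tape {tbc} missing from a cell")
        for x, y in zip(a.tapes[tbc], b.tapes[tbc]):
            if x != y:
                break
            total += 1
    return total


def pairwise_shared_matrix(
    cohort: CohortMatrix, chunk: int = 128
) -> np.ndarray:
    """All-pairs order-aware shared edit counts (vectorized, chunked).

    The shared count per tape is the length of the common prefix over which
    both cells are edited and identical, computed as the row sum of the
    cumulative product of per-site agreement indicators.
    """
    mat, _ = cohort.encode()
    n = cohort.n_cells
    out = np.zeros((n, n), dtype=np.int64)
    slices = cohort.tape_slices()
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block = mat[lo:hi]  # (b, S)
        for sl in slices:
            a = block[:, None, sl]  # (b, 1, m)
            b = mat[None, :, sl]  # (1, n, m)
            eq = (a == b) & (a != 0)
            out[lo:hi] += np.cumprod(eq, axis=2).sum(axis=2)
    return out


def distance_matrix(cohort: CohortMatrix) -> np.ndarray:
    """d(i, j) = total panel sites - shared(i, j); diagonal forced to 0."""
    shared = pairwise_shared_matrix(cohort)
    d = cohort.total_sites - shared.astype(float)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class LineageTreeResult:
    tree: TreeNode
    method: str
    support: Optional[Dict[int, float]] = None


def _upgma(dist: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Average-linkage ultrametric tree with deterministic tie-breaking.

    Among minimum-distance cluster pairs, the pair whose (smallest leaf
    label, other smallest leaf label) is lexicographically least is merged.
    """
    n = len(labels)
    total = 2 * n - 1
    d = np.full((total, total), np.inf)
    d[:n, :n] = dist.astype(float)
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    nodes: Dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    reps = {i: labels[i] for i in range(n)}  # smallest leaf label per cluster
    nxt = n
    while len(active) > 1:
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        m = sub.min()
        ii, jj = np.nonzero(sub == m)
        cands = [
            (tuple(sorted((reps[idx[a]], reps[idx[b]]))), idx[a], idx[b])
            for a, b in zip(ii, jj)
            if a < b
        ]
        _, i, j = min(cands)
        h = m / 2.0
        node = TreeNode()
        for c in (i, j):
            child = nodes.pop(c)
            child.length = h - heights[c]
            node.append(child)
        for k in active:
            if k in (i, j):
                continue
            v = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (sizes[i] + sizes[j])
            d[nxt, k] = v
            d[k, nxt] = v
        nodes[nxt] = node
        sizes[nxt] = sizes[i] + sizes[j]
        heights[nxt] = h
        reps[nxt] = min(reps[i], reps[j])
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    root = nodes[active[0]]
    if root.length is None:
        root.length = 0.0
    return root


def build_tree(
    dist: np.ndarray, labels: Sequence[str], method: str = "upgma"
) -> LineageTreeResult:
    """Build a lineage tree from a distance matrix.

    ``upgma`` gives a rooted ultrametric tree; ``nj`` a standard
    neighbour-joining (unrooted) tree.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if dist.shape[0] != len(labels):
        raise ValueError("labels do not match matrix size")
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 leaves")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValueError("distances must be nonnegative")
    if method == "upgma":
        tree = _upgma(dist, labels)
    elif method == "nj":
        dm = DistanceMatrix(dist, ids=list(labels))
        tree = nj(dm)
    else:
        raise ValueError(f"unknown method {method!r}")
    return LineageTreeResult(tree=tree, method=method)


def _binarize(tree: TreeNode) -> TreeNode:
    """Copy of ``tree`` with polytomies resolved to arbitrary caterpillars."""
    tree = tree.copy()
    poly = [
        node
        for node in tree.traverse(include_self=True)
        if len(node.children) > 2
    ]
    if poly:
        warnings.warn(
            f"resolved {len(poly)} polytomies arbitrarily for parsimony",
            stacklevel=2,
        )
    for node in poly:
        while len(node.children) > 2:
            a, b = node.children[0], node.children[1]
            node.remove(a)
            node.remove(b)
            joint = TreeNode(length=0.0)
            joint.append(a)
            joint.append(b)
            node.append(joint)
    return tree


def fitch_parsimony(tree: TreeNode, cohort: CohortMatrix) -> int:
    """Fitch small-parsimony change count summed over all panel sites.

    Characters are the panel sites; states are insert identities plus
    'unedited' (encoded 0), treated as unordered.  Polytomies are resolved
    arbitrarily (with a warning); leaf names must match cohort cell ids.
    """
    mat, _ = cohort.encode()
    row = {cid: mat[i] for i, cid in enumerate(cohort.cell_ids)}
    btree = _binarize(tree)
    leaves = [t.name for t in btree.tips()]
    if set(leaves) != set(cohort.cell_ids):
        raise ValueError("tree leaves do not match cohort cells")
    total = 0
    state_sets: Dict[int, List[Set[int]]] = {}
    for node in btree.postorder(include_self=True):
        if node.is_tip():
            state_sets[id(node)] = [{int(s)} for s in row[node.name]]
            continue
        kids = [state_sets.pop(id(c)) for c in node.children]
        merged: List[Set[int]] = []
        for site_sets in zip(*kids):
            inter = set.intersection(*site_sets)
            if inter:
                merged.append(inter)
            else:
                merged.append(set.union(*site_sets))
                total += len(site_sets) - 1
        state_sets[id(node)] = merged
    return total


def tree_clades(tree: TreeNode) -> Set[frozenset]:
    """Leaf sets of all internal (non-root) nodes of a rooted tree."""
    return {
        frozenset(t.name for t in node.tips())
        for node in tree.non_tips(include_self=False)
    }


def tree_bipartitions(tree: TreeNode) -> Set[frozenset]:
    """Non-trivial leaf bipartitions, orientation-free."""
    all_leaves = frozenset(t.name for t in tree.tips())
    parts: Set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        other = all_leaves - clade
        if len(clade) > 1 and len(other) > 1:
            parts.add(frozenset((clade, other)))
    return parts


def robinson_foulds(a: TreeNode, b: TreeNode, normalized: bool = True) -> float:
    """(Normalized) Robinson-Foulds distance via bipartition symmetric difference."""
    pa, pb = tree_bipartitions(a), tree_bipartitions(b)
    rf = len(pa ^ pb)
    if not normalized:
        return float(rf)
    denom = len(pa) + len(pb)
    return rf / denom if denom else 0.0


def bootstrap_support(
    cohort: CohortMatrix,
    n_reps: int = 100,
    seed: Optional[int] = None,
    method: str = "upgma",
) -> LineageTreeResult:
    """Tape-block bootstrap support for the cohort tree.

    Each replicate resamples whole tapes (target-barcode blocks) with
    replacement, rebuilds the order-aware distance (maximum shared count =
    resampled site total) and the tree; support on each internal node of
    the original tree is the percentage of replicates containing the same
    leaf bipartition, written into the node name.
    """
    rng = np.random.default_rng(seed)
    result = build_tree(distance_matrix(cohort), cohort.cell_ids, method)
    all_leaves = frozenset(cohort.cell_ids)
    rooted = method == "upgma"
    orig_parts = {}
    for node in result.tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        orig_parts[id(node)] = (
            clade if rooted else frozenset((clade, all_leaves - clade))
        )
    hits = {k: 0 for k in orig_parts}
    n_tapes = len(cohort.panel)
    for _ in range(n_reps):
        pick = rng.integers(0, n_tapes, size=n_tapes)
        panel = [
            (f"{cohort.panel[t][0]}#{k}", cohort.panel[t][1])
            for k, t in enumerate(pick)
        ]
        cells = [
            CellRecord(
                cell_id=c.cell_id,
                tapes={
                    f"{cohort.panel[t][0]}#{k}": c.tapes[cohort.panel[t][0]]
                    for k, t in enumerate(pick)
                },
                capacities=dict(panel),
            )
            for c in cohort.cells
        ]
        rep = CohortMatrix(cells=cells, panel=panel)
        rep_tree = build_tree(distance_matrix(rep), rep.cell_ids, method).tree
        rep_parts = (
            tree_clades(rep_tree) if rooted else tree_bipartitions(rep_tree)
        )
        for node_id, part in orig_parts.items():
            if part in rep_parts:
                hits[node_id] += 1
    support: Dict[int, float] = {}
    for node in result.tree.non_tips(include_self=False):
        pct = 100.0 * hits[id(node)] / n_reps
        support[id(node)] = pct
        node.name = f"{pct:g}"
    result.support = support
    return result


def cohort_summaries(cohort: CohortMatrix) -> Dict:
    """Cohort-level editing statistics.

    Includes per-tape per-site cumulative edit fractions (and the cross-tape
    mean per site index), the mean/variance of edits per cell, the all-pairs
    site-difference mean and sd (edited-vs-unedited counts as a difference),
    each cell's nearest-neighbour difference, active tape counts (tapes with
    spare capacity) and the unique-pattern census.
    """
    mat, _ = cohort.encode()
    n = cohort.n_cells
    slices = cohort.tape_slices()

    per_tape_site = {}
    for (tbc, cap), sl in zip(cohort.panel, slices):
        per_tape_site[tbc] = ((mat[:, sl] != 0).mean(axis=0)).tolist()
    max_cap = max(cap for _, cap in cohort.panel)
    site_means = []
    for s in range(max_cap):
        vals = [v[s] for v in per_tape_site.values() if len(v) > s]
        site_means.append(float(np.mean(vals)))

    edits = (mat != 0).sum(axis=1)
    mean_edits = float(edits.mean())
    var_edits = float(edits.var(ddof=1)) if n > 1 else 0.0

    # all-pairs site differences, chunked
    diff_sum = 0.0
    diff_sumsq = 0.0
    n_pairs = 0
    nn = np.full(n, np.inf)
    for lo in range(0, n, 128):
        hi = min(lo + 128, n)
        diffs = (mat[lo:hi, None, :] != mat[None, :, :]).sum(axis=2)
        for r in range(hi - lo):
            i = lo + r
            rowv = diffs[r].astype(float)
            rowv[i] = np.inf
            nn[i] = min(nn[i], rowv.min())
            upper = diffs[r, i + 1 :]
            diff_sum += float(upper.sum())
            diff_sumsq += float((upper.astype(float) ** 2).sum())
            n_pairs += upper.size
    if n_pairs:
        mean_diff = diff_sum / n_pairs
        var_diff = diff_sumsq / n_pairs - mean_diff**2
        sd_diff = float(np.sqrt(max(var_diff, 0.0)))
    else:
        mean_diff, sd_diff = 0.0, 0.0

    active = np.zeros(n, dtype=int)
    for (tbc, cap), sl in zip(cohort.panel, slices):
        active += (mat[:, sl] != 0).sum(axis=1) < cap

    patterns: Dict[bytes, int] = {}
    for r in range(n):
        key = mat[r].tobytes()
        patterns[key] = patterns.get(key, 0) + 1
    unique_cells = sum(c for c in patterns.values() if c == 1)

    return {
        "n_cells": n,
        "total_sites": cohort.total_sites,
        "per_tape_site_fractions": per_tape_site,
        "site_mean_fractions": site_means,
        "edits_per_cell_mean": mean_edits,
        "edits_per_cell_var": var_edits,
        "pairwise_diff_mean": float(mean_diff),
        "pairwise_diff_sd": sd_diff,
        "nearest_neighbour_mean": float(nn.mean()) if n > 1 else 0.0,
        "active_tapes_mean": float(active.mean()),
        "n_fully_edited_cells": int((edits == cohort.total_sites).sum()),
        "n_unique_patterns": int(len(patterns)),
        "n_cells_with_unique_pattern": int(unique_cells),
    }
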