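"""Topology classification, hybrid-origin calling and branch contrasts.

The 15 labeled rooted 5-taxon topologies partition into six classes under
exchangeability of {A1, A2} and of {S1, S2}:

====  =====================  ============  ============
id    shape                  multiplicity  origin call
====  =====================  ============  ============
H1    (A,(A,(S,S)))          2             hybrid
H2    (A,(S,(A,S)))          4             hybrid
P1    (S,(S,(A,A)))          2             pure
C4    (S,(A,(A,S)))          4             ambiguous
B1    ((A,A),(S,S))          1             ambiguous
B2    ((A,S),(A,S))          2             ambiguous
====  =====================  ============  ============

Derived mutations are assigned to branches by parsimony on the fixed,
outgroup-rooted tree, binned into the five annotation categories, and
contrasted between the conspecific-derived apomict terminal branch and
the sexual terminal branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .diversity import fisher_pair_test
from .trees import (
    FiveTaxonAlignment,
    TreeResult,
    clade_tips,
    topology_edges,
    _Tree,
)
from .variants import CATEGORIES, NEUTRAL

TOPOLOGY_CLASS_IDS = ("H1", "H2", "P1", "C4", "B1", "B2")
ORIGIN_OF_CLASS = {
    "H1": "hybrid",
    "H2": "hybrid",
    "P1": "pure",
    "C4": "ambiguous",
    "B1": "ambiguous",
    "B2": "ambiguous",
}


@dataclass(frozen=True)
class TopologyClass:
    class_id: str
    origin: str


def _tip_type(label: str) -> str:
    if label in ("A1", "A2"):
        return "A"
    if label in ("S1", "S2"):
        return "S"
    raise ValueError(f"unexpected tip label {label!r}")


def classify_topology(topology) -> TopologyClass:
    """Map a labeled rooted ingroup topology to its class and origin call.

    Accepts the nested-tuple ingroup topology used by :mod:`mutacc.trees`
    (a pair of subtrees hanging off the OUT-rooted trifurcation).  The
    mapping is invariant under swapping A1/A2 and S1/S2.
    """
    if isinstance(topology, TreeResult):
        topology = topology.topology
    try:
        c1, c2 = topology
    except (TypeError, ValueError):
        raise ValueError("expected a rooted 5-taxon ingroup topology") from None
    if sorted(clade_tips(topology[0]) + clade_tips(topology[1])) != list(
        ("A1", "A2", "S1", "S2")
    ):
        raise ValueError("topology must contain exactly A1, A2, S1, S2")

    def types(node) -> tuple[str, ...]:
        return tuple(sorted(_tip_type(t) for t in clade_tips(node)))

    if not isinstance(c1, str) and not isinstance(c2, str):
        # balanced: two cherries off the root
        if types(c1) in (("A", "A"), ("S", "S")):
            class_id = "B1"
        else:
            class_id = "B2"
    else:
        basal, sub = (c1, c2) if isinstance(c1, str) else (c2, c1)
        mid, cherry = (
            (sub[0], sub[1]) if isinstance(sub[0], str) else (sub[1], sub[0])
        )
        key = (_tip_type(basal), _tip_type(mid), types(cherry))
        class_id = {
            ("A", "A", ("S", "S")): "H1",
            ("A", "S", ("A", "S")): "H2",
            ("S", "S", ("A", "A")): "P1",
            ("S", "A", ("A", "S")): "C4",
        }[key]
    return TopologyClass(class_id, ORIGIN_OF_CLASS[class_id])


def summarize_topologies(classes: list[TopologyClass]) -> dict:
    """Counts and proportions per class and per origin call."""
    if not classes:
        raise ValueError("no classified trees")
    n = len(classes)
    by_class = {c: 0 for c in TOPOLOGY_CLASS_IDS}
    by_origin = {"hybrid": 0, "pure": 0, "ambiguous": 0}
    for cl in classes:
        by_class[cl.class_id] += 1
        by_origin[cl.origin] += 1
    return {
        "n_trees": n,
        "class_counts": by_class,
        "class_proportions": {k: v / n for k, v in by_class.items()},
        "origin_counts": by_origin,
        "origin_proportions": {k: v / n for k, v in by_origin.items()},
    }


# ---------------------------------------------------------------------------
# conspecific tip identification
# ---------------------------------------------------------------------------

def _patristic(tree: _Tree, lengths, a: str, b: str) -> float:
    """Path length between two tips, summing branch lengths."""
    def path_to_root(lab):
        n = next(i for i, l in enumerate(tree.label) if l == lab)
        edges = []
        while n != tree.root:
            edges.append(tree.edge_id[n])
            n = tree.parent[n]
        return edges

    pa, pb = path_to_root(a), path_to_root(b)
    shared = set(pa) & set(pb)
    return sum(lengths[e] for e in pa + pb if e not in shared)


def identify_conspecific_tip(result: TreeResult) -> str | None:
    """Apomict tip closest (mean patristic distance) to the sexual tips.

    Only meaningful for hybrid-class trees; an exact tie is flagged by
    returning None so the tree can be excluded from contrasts.
    """
    cl = classify_topology(result.topology)
    if cl.origin != "hybrid":
        raise ValueError("conspecific tip is defined for hybrid-class trees only")
    tree = _Tree(result.topology)
    bl = result.branch_lengths
    d = {
        a: np.mean([_patristic(tree, bl, a, s) for s in ("S1", "S2")])
        for a in ("A1", "A2")
    }
    if math.isclose(d["A1"], d["A2"], rel_tol=0.0, abs_tol=1e-12):
        return None
    return "A1" if d["A1"] < d["A2"] else "A2"


# ---------------------------------------------------------------------------
# parsimony branch-mutation assignment
# ---------------------------------------------------------------------------

@dataclass
class BranchMutationTable:
    """Per-branch derived-mutation counts by category for one tree."""

    class_id: str
    conspecific_tip: str | None
    terminal: dict[str, dict[str, int]]
    internal: dict[frozenset, dict[str, int]]
    n_placed: int = 0
    n_ambiguous: int = 0
    n_skipped: int = 0
    n_variant_columns: int = 0
    region: tuple | None = None

    def terminal_total(self, tip: str) -> int:
        return sum(self.terminal[tip].values())


def assign_branch_mutations(
    result: TreeResult, aln: FiveTaxonAlignment
) -> BranchMutationTable:
    """Place derived mutations on the fixed outgroup-rooted tree by parsimony.

    A column's ancestral state is the outgroup base; any differing base is
    derived.  Internal-node states are enumerated exhaustively; columns
    whose minimal-cost placement is not unique (as a set of edge changes)
    are discarded and counted.  Columns with an uncalled outgroup are
    skipped.
    """
    cl = classify_topology(result.topology)
    tree = _Tree(result.topology)
    conspecific = None
    if cl.origin == "hybrid":
        conspecific = identify_conspecific_tip(result)

    table = BranchMutationTable(
        class_id=cl.class_id,
        conspecific_tip=conspecific,
        terminal={t: {c: 0 for c in CATEGORIES} for t in ("A1", "A2", "S1", "S2")},
        internal={
            e: {c: 0 for c in CATEGORIES}
            for e in topology_edges(result.topology)
            if isinstance(e, frozenset)
        },
        region=result.region,
    )

    internal_nodes = [
        n for n in tree.postorder if tree.children[n] and n != tree.root
    ] + [tree.root]
    tip_nodes = {
        tree.label[n]: n for n in range(len(tree.label)) if tree.label[n]
    }
    # edges as (parent_node, child_node) pairs
    edge_list = [
        (tree.parent[n], n) for n in tree.postorder if n != tree.root
    ]

    cols = np.stack([aln.seqs[l] for l in ("A1", "A2", "S1", "S2", "OUT")])
    cats = aln.categories
    cat_order = {c: i for i, c in enumerate(CATEGORIES)}
    cat_codes = np.fromiter((cat_order[c] for c in cats), dtype=np.int64, count=len(cats))
    key = np.vstack([cols, cat_codes])
    patterns, first_idx, counts = np.unique(
        key, axis=1, return_index=True, return_counts=True
    )

    state_assignments = list(product(range(4), repeat=len(internal_nodes)))

    for p in range(patterns.shape[1]):
        col = patterns[:5, p]
        cat = str(cats[first_idx[p]])
        count = int(counts[p])
        out_base = int(col[4])
        if out_base >= 4:
            table.n_skipped += count
            continue
        ingroup = {lab: int(col[i]) for i, lab in enumerate(("A1", "A2", "S1", "S2"))}
        if all(v == out_base or v >= 4 for v in ingroup.values()):
            continue  # no derived state
        table.n_variant_columns += count

        def node_state(n, assign) -> int | None:
            lab = tree.label[n]
            if lab == "OUT":
                return out_base
            if lab is not None:
                v = ingroup[lab]
                return None if v >= 4 else v
            return assign[internal_nodes.index(n)]

        best_cost = None
        best_changes: set[frozenset] | None = None
        unique = True
        for assign in state_assignments:
            cost = 0
            changes = []
            for pa, ch in edge_list:
                sa, sc = node_state(pa, assign), node_state(ch, assign)
                if sa is None or sc is None:
                    continue
                if sa != sc:
                    cost += 1
                    changes.append((tree.edge_id[ch], sa, sc))
            if best_cost is None or cost < best_cost:
                best_cost = cost
                best_changes = frozenset(changes)
                unique = True
            elif cost == best_cost and frozenset(changes) != best_changes:
                unique = False
        if not unique:
            table.n_ambiguous += count
            continue
        table.n_placed += count
        for edge_id, _, _ in best_changes:
            if edge_id == "OUT":
                continue
            target = (
                table.terminal[edge_id]
                if isinstance(edge_id, str)
                else table.internal[edge_id]
            )
            target[cat] += count
    return table


# ---------------------------------------------------------------------------
# terminal-branch contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    name: str
    table: np.ndarray  # 2x2: [[apo_constrained, apo_neutral], [sex_constrained, sex_neutral]]
    odds_ratio: float
    log_odds_se: float
    p_value: float


def _contrast(name: str, apo: tuple[int, int], sex: tuple[int, int]) -> ContrastResult:
    t = np.array([[apo[0], apo[1]], [sex[0], sex[1]]], dtype=np.int64)
    odds, p = fisher_pair_test(t)
    se = math.sqrt((1.0 / t).sum()) if np.all(t > 0) else math.nan
    return ContrastResult(name, t, odds, se, p)


def terminal_contrasts(
    tables: list[BranchMutationTable],
    constrained: str = "0fold",
    neutral: str = NEUTRAL,
) -> dict[str, ContrastResult]:
    """Fisher contrasts of constrained vs neutral terminal-branch mutations.

    H1-class trees contribute three contrasts of the conspecific apomict
    tip against S1, S2 and the pooled sexual tips (C1-C3); H2-class trees
    contribute one pooled contrast (C4).  The combined test pools cells
    across all contrasts.
    """
    usable = [
        t for t in tables if t.class_id in ("H1", "H2") and t.conspecific_tip
    ]
    if not usable:
        raise ValueError("no hybrid-class trees with an identified conspecific tip")

    def cells(ts, tips) -> tuple[int, int]:
        c = sum(t.terminal[tip][constrained] for t in ts for tip in tips(t))
        n = sum(t.terminal[tip][neutral] for t in ts for tip in tips(t))
        return c, n

    h1 = [t for t in usable if t.class_id == "H1"]
    h2 = [t for t in usable if t.class_id == "H2"]
    out: dict[str, ContrastResult] = {}
    if h1:
        apo = cells(h1, lambda t: (t.conspecific_tip,))
        out["C1"] = _contrast("C1", apo, cells(h1, lambda t: ("S1",)))
        out["C2"] = _contrast("C2", apo, cells(h1, lambda t: ("S2",)))
        out["C3"] = _contrast("C3", apo, cells(h1, lambda t: ("S1", "S2")))
    if h2:
        apo = cells(h2, lambda t: (t.conspecific_tip,))
        out["C4"] = _contrast("C4", apo, cells(h2, lambda t: ("S1", "S2")))
    combined = sum(
        (c.table for c in out.values()), np.zeros((2, 2), dtype=np.int64)
    )
    odds, p = fisher_pair_test(combined)
    se = math.sqrt((1.0 / combined).sum()) if np.all(combined > 0) else math.nan
    out["combined"] = ContrastResult("combined", combined, odds, se, p)
    return out


@dataclass
class RatioTestResult:
    apomict_count: int
    sexual_count: int
    ratio: float
    null_ratio: float
    p_value: float


def branch_length_ratio_test(
    tables: list[BranchMutationTable], null_ratio: float = 2.0
) -> RatioTestResult:
    """Test apomict terminal mutations against the conservative 2x null.

    Because sexual pseudo-haplotypes split heterozygous variation across
    two tips, equal per-lineage accumulation predicts the conspecific
    apomict terminal branch to carry up to ``null_ratio`` (default 2)
    times the summed sexual terminal mutations.  The test is an exact
    one-sided binomial on the apomict count out of all terminal-branch
    mutations with null p0 = null_ratio / (null_ratio + 1).
    """
    usable = [
        t for t in tables if t.class_id in ("H1", "H2") and t.conspecific_tip
    ]
    apo = sum(t.terminal_total(t.conspecific_tip) for t in usable)
    sex = sum(
        t.terminal_total(s) for t in usable for s in ("S1", "S2")
    )
    if apo + sex == 0:
        return RatioTestResult(0, 0, math.nan, null_ratio, math.nan)
    p0 = null_ratio / (null_ratio + 1.0)
    res = stats.binomtest(apo, apo + sex, p0, alternative="greater")
    ratio = apo / sex if sex else math.inf
    return RatioTestResult(apo, sex, ratio, null_ratio, float(res.pvalue))
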