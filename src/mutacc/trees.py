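"""Five-taxon maximum-likelihood haplotype trees under GTR+Gamma.

Alignments carry two apomict haplotypes (A1, A2), two sexual
pseudo-haplotypes (S1, S2) and an outgroup (OUT).  With only five taxa
the 15 rooted-by-OUT topologies are evaluated exhaustively: no heuristic
tree search is needed.  The likelihood engine uses Felsenstein pruning
over compressed site patterns with an eigendecomposition of the
reversible rate matrix, and caches inside/outside partials so that
per-branch optimization is a cheap one-dimensional problem.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .variants import GenotypeTable, HET, HOMALT, MISSING, PhasedBlock, SiteAnnotation

log = logging.getLogger(__name__)

LABELS = ("A1", "A2", "S1", "S2", "OUT")
INGROUP = ("A1", "A2", "S1", "S2")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MIN_LEN, _MAX_LEN = 1e-9, 8.0


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 (A=0..T=3; N/gap/other=4)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.uint8)
    for b, c in _CODE.items():
        out[arr == ord(b)] = c
    return out


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete Gamma categories.

    Mean-1 Gamma with shape ``alpha``; the returned rates are normalized
    to average exactly 1.
    """
    if alpha <= 0 or k < 1:
        raise ValueError("alpha must be > 0 and k >= 1")
    if k == 1:
        return np.ones(1)
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    upper = special.gammainc(alpha + 1.0, alpha * edges[1:])
    lower = special.gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """GTR+Gamma parameters: stationary frequencies, exchangeabilities,
    gamma shape ``alpha`` and ``k`` discrete rate categories."""

    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    exchangeabilities: np.ndarray = field(default_factory=lambda: np.ones(6))
    alpha: float = 1.0
    k: int = 4

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.pi.shape != (4,) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be 4 frequencies summing to 1")
        if np.any(self.pi <= 0):
            raise ValueError("pi entries must be positive")
        if self.exchangeabilities.shape != (6,) or np.any(
            self.exchangeabilities <= 0
        ):
            raise ValueError("need 6 positive exchangeabilities")
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError("alpha must be positive and finite")

    def rate_matrix(self) -> np.ndarray:
        """Reversible rate matrix scaled to one expected change per unit time."""
        s = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        s[iu] = self.exchangeabilities
        s = s + s.T
        q = s * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(self.pi * np.diag(q)).sum()
        return q / scale

    def gamma_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.k)

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Decomposition ``P(t) = U @ diag(exp(w t)) @ V`` of the rate matrix."""
        q = self.rate_matrix()
        sq = np.sqrt(self.pi)
        b = (q * sq[:, None]) / sq[None, :]
        w, evec = np.linalg.eigh((b + b.T) / 2.0)
        u = evec / sq[:, None]
        v = evec.T * sq[None, :]
        return w, u, v


def empirical_model(aln: "FiveTaxonAlignment", alpha: float = 1.0, k: int = 4) -> SubstitutionModel:
    """Model with base frequencies estimated from the alignment (+1 pseudocount)."""
    counts = np.ones(4)
    for codes in aln.seqs.values():
        counts += np.bincount(codes[codes < 4], minlength=4)
    return SubstitutionModel(pi=counts / counts.sum(), alpha=alpha, k=k)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class FiveTaxonAlignment:
    """Equal-length labeled sequences {A1, A2, S1, S2, OUT} over one region."""

    region: tuple[str, int, int]
    seqs: dict[str, np.ndarray]
    categories: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if set(self.seqs) != set(LABELS):
            raise ValueError(f"alignment must have exactly the labels {LABELS}")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal lengths")
        if len(self.categories) != lengths.pop():
            raise ValueError("categories must match alignment length")

    @property
    def n_columns(self) -> int:
        return len(self.categories)

    def sexual_divergence(self) -> float:
        """Proportion of columns at which S1 and S2 differ (both called)."""
        s1, s2 = self.seqs["S1"], self.seqs["S2"]
        ok = (s1 < 4) & (s2 < 4)
        return float((s1[ok] != s2[ok]).mean()) if ok.any() else math.nan


def make_pseudo_haplotypes(
    table: GenotypeTable,
    sample: str,
    region: tuple[str, int, int],
    seed: int,
    reference: Mapping[str, str],
) -> tuple[str, str]:
    """Split a diploid sample into two pseudo-haplotypes over a region.

    Homozygous positions are identical in both outputs; at each
    heterozygous position the two alleles are assigned to the two outputs
    in a seeded-uniform orientation.  Missing genotypes become N in both.
    Positions without a retained SNP take the reference base.
    """
    chrom, start, end = region
    rng = np.random.default_rng(seed)
    ref = reference[chrom]
    base = seq_to_codes(ref[start:end])
    haps = [base.copy(), base.copy()]
    row = table.sample_index(sample)
    sel = (table.chrom == chrom) & (table.pos >= start + 1) & (table.pos <= end)
    for j in np.flatnonzero(sel):
        off = int(table.pos[j]) - 1 - start
        g = int(table.gt[row, j])
        alt = _CODE.get(str(table.alt[j]), 4)
        refc = _CODE.get(str(table.ref[j]), 4)
        if g == MISSING:
            haps[0][off] = haps[1][off] = 4
        elif g == HOMALT:
            haps[0][off] = haps[1][off] = alt
        elif g == HET:
            first = int(rng.integers(0, 2))
            haps[first][off] = refc
            haps[1 - first][off] = alt
        else:  # homref: keep VCF REF allele explicitly
            haps[0][off] = haps[1][off] = refc
    return codes_to_seq(haps[0]), codes_to_seq(haps[1])


def assemble_alignment(
    block: PhasedBlock,
    pseudo_haplotypes: tuple[str, str],
    outgroup: Mapping[str, str],
    region: tuple[str, int, int],
    ann: SiteAnnotation,
) -> FiveTaxonAlignment | None:
    """Combine phased apomict haplotypes, sexual pseudo-haplotypes and the
    outgroup into a five-sequence alignment over ``region``.

    Columns with an uncalled base (N/gap) in any sequence are removed.
    Returns None (with a log entry) when no usable column remains.
    """
    chrom, start, end = region
    if block.chrom != chrom or block.start > start or block.end < end:
        raise ValueError("phased block does not span the requested region")
    off = start - block.start
    n = end - start
    seqs = {
        "A1": seq_to_codes(block.hap1[off : off + n]),
        "A2": seq_to_codes(block.hap2[off : off + n]),
        "S1": seq_to_codes(pseudo_haplotypes[0]),
        "S2": seq_to_codes(pseudo_haplotypes[1]),
        "OUT": seq_to_codes(outgroup[chrom][start:end]),
    }
    if any(len(s) != n for s in seqs.values()):
        raise ValueError("sequences do not span the region")
    usable = np.ones(n, dtype=bool)
    for s in seqs.values():
        usable &= s < 4
    if not usable.any():
        log.info("assemble_alignment: region %s:%d-%d has no usable columns", *region)
        return None
    positions = np.arange(start + 1, end + 1)[usable]
    cats = ann.category_of(chrom, positions)
    return FiveTaxonAlignment(
        region=region,
        seqs={k: v[usable] for k, v in seqs.items()},
        categories=cats,
        positions=positions,
    )


# ---------------------------------------------------------------------------
# topologies
# ---------------------------------------------------------------------------

def _canon(node):
    if isinstance(node, str):
        return node
    a, b = (_canon(node[0]), _canon(node[1]))
    return (a, b) if repr(a) <= repr(b) else (b, a)


def _rooted_trees(labels: tuple[str, ...]):
    if len(labels) == 1:
        yield labels[0]
        return
    first = labels[0]
    rest = labels[1:]
    for mask in range(2 ** len(rest)):
        left = [first] + [r for i, r in enumerate(rest) if mask >> i & 1]
        right = [r for i, r in enumerate(rest) if not mask >> i & 1]
        if not right:
            continue
        for lt in _rooted_trees(tuple(left)):
            for rt in _rooted_trees(tuple(right)):
                yield _canon((lt, rt))


def enumerate_topologies() -> list[tuple]:
    """All 15 rooted-by-OUT labeled topologies (canonical, deterministic order)."""
    trees = sorted(set(_rooted_trees(INGROUP)), key=repr)
    assert len(trees) == 15
    return trees


TOPOLOGIES: list[tuple] = enumerate_topologies()


def clade_tips(node) -> tuple[str, ...]:
    if isinstance(node, str):
        return (node,)
    return tuple(sorted(clade_tips(node[0]) + clade_tips(node[1])))


def topology_edges(topology) -> tuple:
    """Edge identifiers: tip labels, internal clades (frozensets) and 'OUT'."""
    edges: list = ["OUT"]

    def walk(node):
        if isinstance(node, str):
            edges.append(node)
        else:
            edges.append(frozenset(clade_tips(node)))
            walk(node[0])
            walk(node[1])

    walk(topology[0])
    walk(topology[1])
    # the two root-child edges: drop the 4-tip clade id duplication is
    # impossible here because root children partition the 4 ingroup tips
    return tuple(edges)


def internal_edges(topology) -> list[frozenset]:
    return [e for e in topology_edges(topology) if isinstance(e, frozenset)]


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------

class _Tree:
    """Indexed tree over a topology: root is a trifurcation (OUT, c1, c2)."""

    def __init__(self, topology):
        self.topology = topology
        self.children: list[list[int]] = []
        self.parent: list[int] = []
        self.label: list[str | None] = []
        self.edge_id: list = []  # id of the edge above each node

        def new_node(label, parent, edge_id):
            self.children.append([])
            self.parent.append(parent)
            self.label.append(label)
            self.edge_id.append(edge_id)
            return len(self.parent) - 1

        self.root = new_node(None, -1, None)

        def build(node, parent):
            if isinstance(node, str):
                i = new_node(node, parent, node)
            else:
                i = new_node(None, parent, frozenset(clade_tips(node)))
                build(node[0], i)
                build(node[1], i)
            self.children[parent].append(i)
            return i

        build("OUT", self.root)
        build(topology[0], self.root)
        build(topology[1], self.root)
        self.postorder = self._postorder()

    def _postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(self.children[n])
        return order[::-1]

    @property
    def edges(self) -> tuple:
        return tuple(self.edge_id[n] for n in self.postorder if n != self.root)


class TreeLikelihood:
    """Per-alignment GTR+Gamma likelihood over compressed site patterns."""

    def __init__(self, aln: FiveTaxonAlignment, model: SubstitutionModel,
                 pattern_counts: np.ndarray | None = None):
        self.aln = aln
        self.model = model
        cols = np.stack([aln.seqs[l] for l in LABELS])
        self.patterns, counts = np.unique(cols, axis=1, return_counts=True)
        self.counts = counts.astype(float) if pattern_counts is None else pattern_counts
        self.n_patterns = self.patterns.shape[1]
        self.rates = model.gamma_rates()
        self.w, self.u, self.v = model.eigen()
        self.tipdata = {}
        eye = np.eye(4)
        for i, lab in enumerate(LABELS):
            codes = self.patterns[i]
            td = np.ones((self.n_patterns, 4))
            known = codes < 4
            td[known] = eye[codes[known]]
            self.tipdata[lab] = td
        self._trees: dict = {}

    def _tree(self, topology) -> _Tree:
        if topology not in self._trees:
            self._trees[topology] = _Tree(topology)
        return self._trees[topology]

    def pmat(self, t: float) -> np.ndarray:
        """(k, 4, 4) transition matrices for branch length t at each rate."""
        ew = np.exp(self.w[None, :] * (t * self.rates)[:, None])
        p = np.einsum("ij,kj,jl->kil", self.u, ew, self.v)
        return np.clip(p, 0.0, None)

    def _messages(self, tree: _Tree, lengths: Mapping) -> list:
        """Inside pass; returns per-node messages toward the parent."""
        k = len(self.rates)
        inside = [None] * len(tree.parent)
        msg = [None] * len(tree.parent)
        for n in tree.postorder:
            if not tree.children[n]:
                inside[n] = np.broadcast_to(
                    self.tipdata[tree.label[n]], (k, self.n_patterns, 4)
                )
            else:
                parts = [msg[c] for c in tree.children[n]]
                inside[n] = parts[0] if len(parts) == 1 else np.prod(parts, axis=0)
            if n != tree.root:
                p = self.pmat(float(lengths[tree.edge_id[n]]))
                msg[n] = np.einsum("kij,kpj->kpi", p, inside[n])
        self._inside = inside
        return msg

    def site_loglik(self, topology, lengths: Mapping) -> np.ndarray:
        tree = self._tree(topology)
        msg = self._messages(tree, lengths)
        root = np.prod([msg[c] for c in tree.children[tree.root]], axis=0)
        lik = np.einsum("kpi,i->p", root, self.model.pi) / len(self.rates)
        return np.log(np.clip(lik, 1e-300, None))

    def loglik(self, topology, lengths: Mapping) -> float:
        return float(self.counts @ self.site_loglik(topology, lengths))

    # -- per-edge profile for fast coordinate-wise optimization ------------
    def edge_profiles(self, topology, lengths: Mapping) -> dict:
        """For each edge, (outside, inside) partials such that the site
        likelihood is ``einsum('kpi,kij,kpj->p', O, P(t), I) / k``."""
        tree = self._tree(topology)
        msg = self._messages(tree, lengths)
        inside = self._inside
        k = len(self.rates)
        outside = [None] * len(tree.parent)
        pi = self.model.pi[None, None, :]
        for n in tree.postorder[::-1]:  # preorder
            for c in tree.children[n]:
                sibs = [msg[s] for s in tree.children[n] if s != c]
                sib = sibs[0] if len(sibs) == 1 else np.prod(sibs, axis=0)
                if n == tree.root:
                    above = pi
                else:
                    p = self.pmat(float(lengths[tree.edge_id[n]]))
                    above = np.einsum("kpi,kij->kpj", outside[n], p)
                outside[c] = above * sib
        return {
            tree.edge_id[n]: (outside[n], inside[n])
            for n in tree.postorder
            if n != tree.root
        }

    def edge_loglik(self, profile, t: float) -> float:
        o, i = profile
        p = self.pmat(t)
        lik = np.einsum("kpi,kij,kpj->p", o, p, i) / len(self.rates)
        return float(self.counts @ np.log(np.clip(lik, 1e-300, None)))


def gtr_gamma_loglik(
    aln: FiveTaxonAlignment,
    topology,
    branch_lengths: Mapping,
    model: SubstitutionModel,
) -> float:
    """Log-likelihood of a topology with given branch lengths under GTR+Gamma.

    ``branch_lengths`` maps edge identifiers (tip labels, internal-clade
    frozensets, 'OUT') to lengths in substitutions/site.  N/gap characters
    contribute through marginalization.
    """
    for e in topology_edges(topology):
        t = branch_lengths[e]
        if not (np.isfinite(t) and t >= 0):
            raise ValueError(f"branch length for {e} must be finite and >= 0")
    return TreeLikelihood(aln, model).loglik(topology, branch_lengths)


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

@dataclass
class TopologyFit:
    topology: tuple
    loglik: float
    branch_lengths: dict
    site_logliks: np.ndarray


@dataclass
class TreeResult:
    """Result of exhaustive ML topology evaluation for one alignment."""

    topology: tuple
    topology_index: int
    branch_lengths: dict
    loglik: float
    model: SubstitutionModel
    per_topology: list[TopologyFit]
    pattern_counts: np.ndarray
    n_columns: int
    sexual_divergence: float
    region: tuple[str, int, int]
    converged: bool = True
    supports: dict | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def min_support(self) -> float:
        if not self.supports:
            return math.nan
        return min(self.supports.values())


def _optimize_lengths(
    tl: TreeLikelihood,
    topology,
    init: Mapping,
    max_sweeps: int,
    tol: float,
    xatol: float,
) -> tuple[dict, float, bool]:
    edges = topology_edges(topology)
    lengths = {e: float(init[e]) for e in edges}
    best = tl.loglik(topology, lengths)
    converged = False
    for _ in range(max_sweeps):
        prev = best
        for e in edges:
            profiles = tl.edge_profiles(topology, lengths)
            prof = profiles[e]
            res = optimize.minimize_scalar(
                lambda t: -tl.edge_loglik(prof, t),
                bounds=(_MIN_LEN, _MAX_LEN),
                method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun >= best:
                best = -res.fun
                lengths[e] = float(res.x)
        if best - prev < tol:
            converged = True
            break
    return lengths, best, converged


def fit_ml_tree(
    aln: FiveTaxonAlignment,
    model: SubstitutionModel | None = None,
    *,
    optimize_alpha: bool | None = None,
    max_sweeps: int = 3,
    tol: float = 1e-6,
    xatol: float = 1e-6,
    init_length: float = 0.02,
) -> TreeResult:
    """Exhaustively evaluate all 15 rooted-by-OUT topologies by ML.

    Base frequencies default to empirical values; the gamma shape is
    estimated by a 1-D search when ``optimize_alpha`` (default: only for
    k > 1).  Branch lengths are optimized coordinate-wise with a bounded
    scalar search.  Ties break deterministically toward the canonical
    topology order.
    """
    if aln.n_columns < 1:
        raise ValueError("alignment must have at least one usable column")
    if model is None:
        model = empirical_model(aln)
    if optimize_alpha is None:
        optimize_alpha = model.k > 1

    tl = TreeLikelihood(aln, model)
    init = {e: init_length for t in TOPOLOGIES for e in topology_edges(t)}

    if optimize_alpha:
        # provisional topology: best at the initial branch lengths
        prov = max(TOPOLOGIES, key=lambda t: tl.loglik(t, init))
        lengths, _, _ = _optimize_lengths(tl, prov, init, 1, tol, 1e-3)

        def neg_alpha(log_a: float) -> float:
            m = SubstitutionModel(
                pi=model.pi,
                exchangeabilities=model.exchangeabilities,
                alpha=float(np.exp(log_a)),
                k=model.k,
            )
            return -TreeLikelihood(aln, m).loglik(prov, lengths)

        res = optimize.minimize_scalar(
            neg_alpha, bounds=(math.log(0.05), math.log(100.0)), method="bounded",
            options={"xatol": 1e-2},
        )
        model = SubstitutionModel(
            pi=model.pi,
            exchangeabilities=model.exchangeabilities,
            alpha=float(np.exp(res.x)),
            k=model.k,
        )
        tl = TreeLikelihood(aln, model)

    fits: list[TopologyFit] = []
    all_converged = True
    for topo in TOPOLOGIES:
        lengths, ll, conv = _optimize_lengths(tl, topo, init, max_sweeps, tol, xatol)
        all_converged &= conv
        fits.append(
            TopologyFit(topo, ll, lengths, tl.site_loglik(topo, lengths))
        )
    best_idx = int(np.argmax([round(f.loglik, 9) for f in fits]))
    best = fits[best_idx]
    flags = [] if all_converged else ["optimizer_not_converged"]
    return TreeResult(
        topology=best.topology,
        topology_index=best_idx,
        branch_lengths=best.branch_lengths,
        loglik=best.loglik,
        model=model,
        per_topology=fits,
        pattern_counts=tl.counts.copy(),
        n_columns=aln.n_columns,
        sexual_divergence=aln.sexual_divergence(),
        region=aln.region,
        converged=all_converged,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# bootstrap and filters
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: FiveTaxonAlignment,
    model: SubstitutionModel | None = None,
    n_reps: int = 100,
    seed: int = 0,
    *,
    method: str = "rell",
    fit: TreeResult | None = None,
) -> dict[frozenset, float]:
    """Bootstrap supports (%) for the internal edges of the ML topology.

    Columns are resampled with replacement (as multinomial draws over
    site patterns).  ``method='rell'`` re-scores each topology at its
    fitted branch lengths (fast); ``method='refit'`` re-optimizes branch
    lengths per replicate.  If ``fit`` is given its ``supports`` field is
    filled in.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if fit is None:
        fit = fit_ml_tree(aln, model)
    rng = np.random.default_rng(seed)
    counts = fit.pattern_counts
    total = int(counts.sum())
    probs = counts / total
    edges = internal_edges(fit.topology)
    topo_internal = [set(internal_edges(t)) for t in TOPOLOGIES]
    hits = {e: 0 for e in edges}

    if method == "rell":
        site_ll = np.stack([f.site_logliks for f in fit.per_topology])
        reps = rng.multinomial(total, probs, size=n_reps).astype(float)
        winners = np.argmax(np.round(site_ll @ reps.T, 9), axis=0)
        for w in winners:
            for e in edges:
                if e in topo_internal[w]:
                    hits[e] += 1
    elif method == "refit":
        tl_model = fit.model
        for _ in range(n_reps):
            cnt = rng.multinomial(total, probs).astype(float)
            tl = TreeLikelihood(aln, tl_model, pattern_counts=cnt)
            lls = []
            for f in fit.per_topology:
                _, ll, _ = _optimize_lengths(
                    tl, f.topology, f.branch_lengths, 1, 1e-4, 1e-3
                )
                lls.append(ll)
            w = int(np.argmax(np.round(lls, 9)))
            for e in edges:
                if e in topo_internal[w]:
                    hits[e] += 1
    else:
        raise ValueError("method must be 'rell' or 'refit'")

    supports = {e: 100.0 * hits[e] / n_reps for e in edges}
    fit.supports = supports
    return supports


@dataclass
class TreeFilterLog:
    n_input: int = 0
    n_low_support: int = 0
    n_high_divergence: int = 0
    n_passing: int = 0


def filter_trees(
    results: Sequence[TreeResult],
    min_support: float = 70.0,
    z_max: float = 3.0,
) -> tuple[list[TreeResult], TreeFilterLog]:
    """Keep trees with adequate bootstrap support whose region does not show
    statistically elevated sexual pseudo-haplotype divergence.

    The divergence criterion is a z-score of the per-region S1-S2
    difference proportion across all input regions.
    """
    flog = TreeFilterLog(n_input=len(results))
    divs = np.array([r.sexual_divergence for r in results], dtype=float)
    mean = np.nanmean(divs) if len(divs) else math.nan
    std = np.nanstd(divs) if len(divs) else math.nan
    z = np.zeros(len(divs)) if not std or math.isnan(std) else (divs - mean) / std
    passing = []
    for r, zi in zip(results, z):
        if min_support > 0:
            if r.supports is None:
                raise ValueError("bootstrap supports required before filtering")
            if r.min_support < min_support:
                flog.n_low_support += 1
                continue
        if zi > z_max:
            flog.n_high_divergence += 1
            continue
        passing.append(r)
    flog.n_passing = len(passing)
    log.info(
        "filter_trees: %d in, %d low support, %d high divergence, %d pass",
        flog.n_input, flog.n_low_support, flog.n_high_divergence, flog.n_passing,
    )
    return passing, flog


def to_newick(result: TreeResult) -> str:
    """Newick string with branch lengths and internal support labels."""
    bl = result.branch_lengths
    sup = result.supports or {}

    def fmt(node) -> str:
        if isinstance(node, str):
            return f"{node}:{bl[node]:.6g}"
        cl = frozenset(clade_tips(node))
        label = f"{sup[cl]:.0f}" if cl in sup else ""
        return f"({fmt(node[0])},{fmt(node[1])}){label}:{bl[cl]:.6g}"

    c1, c2 = result.topology
    return f"(OUT:{bl['OUT']:.6g},{fmt(c1)},{fmt(c2)});"
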