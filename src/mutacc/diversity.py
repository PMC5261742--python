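"""Diversity and constraint statistics, with between-mating-system tests.

Implements per-sample observed heterozygosity ``H0`` (heterozygous calls
over cohort-polymorphic called sites) and derived-allele proportion ``D``
(``(0.5*het + hom_derived) / called``), the constrained/neutral ratio
built on ``D``, Fisher exact tests of paired 2x2 count tables, one-sided
Z-tests of log-odds-ratio differences, SNP-windowed profiles, derived
allele frequency binned ratios and a pairwise-distance minimum spanning
network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .variants import (
    CATEGORIES,
    GenotypeTable,
    HET,
    HOMALT,
    HOMREF,
    NEUTRAL,
    SiteAnnotation,
    site_categories,
)

ALL = "all"


@dataclass
class CategoryCounts:
    n_called: int = 0
    n_polymorphic: int = 0
    n_het: int = 0
    n_homalt: int = 0
    n_derived: int = 0  # derived allele count (het + 2 * hom-derived)

    @property
    def H0(self) -> float:
        return self.n_het / self.n_polymorphic if self.n_polymorphic else math.nan

    @property
    def D(self) -> float:
        if not self.n_called:
            return math.nan
        return (0.5 * self.n_het + self.n_hom_derived) / self.n_called

    @property
    def n_hom_derived(self) -> int:
        # derived alleles not carried by hets are homozygous-derived pairs
        return (self.n_derived - self.n_het) // 2

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_called


@dataclass
class DiversitySummary:
    """Per-sample, per-category diversity counts and statistics."""

    sample: str
    counts: dict[str, CategoryCounts]

    def H0(self, category: str = ALL) -> float:
        return self.counts[category].H0

    def D(self, category: str = ALL) -> float:
        return self.counts[category].D


@dataclass
class RatioStat:
    """d_constrained / d_neutral with the count cells behind it.

    Cells are derived / non-derived allele counts at the constrained and
    the 4-fold (neutral) category; ``log_odds`` and its standard error
    are defined only when all four cells are positive.
    """

    constrained: str
    derived_constrained: int
    nonderived_constrained: int
    derived_neutral: int
    nonderived_neutral: int

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.derived_constrained,
            self.nonderived_constrained,
            self.derived_neutral,
            self.nonderived_neutral,
        )

    @property
    def ratio(self) -> float:
        a, b, c, d = self.cells
        d_c = a / (a + b) if a + b else math.nan
        d_n = c / (c + d) if c + d else math.nan
        return d_c / d_n if d_n else math.nan

    @property
    def log_odds(self) -> float:
        a, b, c, d = self.cells
        if min(a, b, c, d) <= 0:
            return math.nan
        return math.log(a * d / (b * c))

    @property
    def log_odds_se(self) -> float:
        a, b, c, d = self.cells
        if min(a, b, c, d) <= 0:
            return math.nan
        return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def _derived_per_sample(table: GenotypeTable, row: int) -> np.ndarray:
    """Derived allele count (0/1/2, -1 missing) for one sample at each site."""
    g = table.gt[row]
    if table.alt_is_derived is None:
        derived_hom = g == HOMALT
    else:
        derived_hom = np.where(table.alt_is_derived, g == HOMALT, g == HOMREF)
    out = np.where(g == HET, 1, np.where(derived_hom, 2, 0)).astype(np.int64)
    out[g < 0] = -1
    return out


def diversity_summary(
    table: GenotypeTable, ann: SiteAnnotation, sample: str
) -> DiversitySummary:
    """Compute H0 and D for one sample, per category and overall.

    "Polymorphic" means segregating among all retained samples of the
    cohort (with a call in this sample), matching a pipeline that keeps
    only cohort-polymorphic SNPs.
    """
    row = table.sample_index(sample)
    cats = site_categories(table, ann)
    g = table.gt[row]
    called = g >= 0
    poly = table.is_polymorphic() & called
    der = _derived_per_sample(table, row)
    counts: dict[str, CategoryCounts] = {}
    for cat in CATEGORIES + (ALL,):
        m = np.ones(table.n_sites, bool) if cat == ALL else (cats == cat)
        counts[cat] = CategoryCounts(
            n_called=int((called & m).sum()),
            n_polymorphic=int((poly & m).sum()),
            n_het=int(((g == HET) & m).sum()),
            n_homalt=int(((g == HOMALT) & m).sum()),
            n_derived=int(der[called & m].sum()),
        )
    return DiversitySummary(sample=sample, counts=counts)


def constrained_neutral_ratio(
    summary: DiversitySummary, constrained: str
) -> RatioStat:
    """Ratio of D at a constrained category to D at 4-fold sites."""
    if constrained == NEUTRAL:
        raise ValueError("constrained category cannot be the neutral one")
    c = summary.counts[constrained]
    n = summary.counts[NEUTRAL]
    return RatioStat(
        constrained=constrained,
        derived_constrained=c.n_derived,
        nonderived_constrained=c.n_alleles - c.n_derived,
        derived_neutral=n.n_derived,
        nonderived_neutral=n.n_alleles - n.n_derived,
    )


def pooled_ratio(stats_: list[RatioStat]) -> RatioStat:
    """Cell-wise sum of ratio statistics (e.g. across samples)."""
    if not stats_:
        raise ValueError("no ratio statistics to pool")
    cat = stats_[0].constrained
    cells = np.sum([s.cells for s in stats_], axis=0)
    return RatioStat(cat, *[int(x) for x in cells])


def fisher_pair_test(counts: np.ndarray | list) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns the cross-product odds ratio ``(a*d)/(b*c)`` (nan on a zero
    cell) and the exact hypergeometric two-sided P value.
    """
    t = np.asarray(counts)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)) or np.any(t < 0):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    odds = (a * d) / (b * c) if b * c else math.nan
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return odds, float(p)


def odds_ratio_z_test(stat_a: RatioStat, stat_b: RatioStat) -> tuple[float, float]:
    """One-sided Z-test for log-odds-ratio of A exceeding that of B.

    ``Z = (logOR_A - logOR_B) / sqrt(SE_A^2 + SE_B^2)`` with the standard
    log-odds SE ``sqrt(sum 1/cell)``; P is the upper tail of the standard
    normal.  Any zero cell yields (nan, nan).
    """
    la, lb = stat_a.log_odds, stat_b.log_odds
    sa, sb = stat_a.log_odds_se, stat_b.log_odds_se
    if any(math.isnan(v) for v in (la, lb, sa, sb)):
        return math.nan, math.nan
    z = (la - lb) / math.sqrt(sa**2 + sb**2)
    return z, float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# windowed profiles
# ---------------------------------------------------------------------------

_DIFF_WEIGHT = 0.5  # |genotype difference| of 1 (het vs hom) counts half


def _pairwise_diff(gi: np.ndarray, gj: np.ndarray) -> float:
    """Mean per-site expected allele mismatch between two genotype vectors."""
    both = (gi >= 0) & (gj >= 0)
    if not both.any():
        return math.nan
    return float(np.abs(gi[both] - gj[both]).mean() * _DIFF_WEIGHT)


def window_profiles(
    table: GenotypeTable,
    ann: SiteAnnotation,
    sexual_samples: list[str],
    apomict_sample: str,
    window_snps: int = 20_000,
) -> pd.DataFrame:
    """Apomict H0 and mean sexual pairwise difference per SNP window.

    Windows hold ``window_snps`` consecutive retained SNPs; the trailing
    partial window is reported with its actual size.
    """
    if len(sexual_samples) < 2:
        raise ValueError("need >= 2 sexual samples for pairwise differences")
    apo = table.sample_index(apomict_sample)
    sex_rows = [table.sample_index(s) for s in sexual_samples]
    poly = table.is_polymorphic()
    rows = []
    for w_start in range(0, table.n_sites, window_snps):
        sl = slice(w_start, min(w_start + window_snps, table.n_sites))
        g_apo = table.gt[apo, sl]
        called = g_apo >= 0
        n_poly = int((poly[sl] & called).sum())
        h0 = float((g_apo == HET).sum() / n_poly) if n_poly else math.nan
        dij = [
            _pairwise_diff(table.gt[i, sl], table.gt[j, sl])
            for i, j in combinations(sex_rows, 2)
        ]
        rows.append(
            {
                "window": w_start // window_snps,
                "start_pos": int(table.pos[sl][0]),
                "end_pos": int(table.pos[sl][-1]),
                "n_snps": sl.stop - sl.start,
                "apomict_H0": h0,
                "sexual_dij": float(np.nanmean(dij)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# derived allele frequency binned ratios
# ---------------------------------------------------------------------------

def freq_binned_ratios(
    table: GenotypeTable,
    ann: SiteAnnotation,
    apomict_samples: list[str],
    sexual_samples: list[str],
    constrained: str = "0fold",
) -> pd.DataFrame:
    """Constrained/neutral ratios binned by derived-allele frequency.

    Each polarized site is assigned bin ``n`` = number of the designated
    apomict genotypes carrying at least one derived allele; sites with no
    apomict derived allele (``n = 0``) are excluded.  Per bin, the ratio
    is computed separately from the pooled apomict calls and the pooled
    sexual calls at those same sites.
    """
    if table.alt_is_derived is None:
        raise ValueError("table must be polarized first")
    cats = site_categories(table, ann)
    apo_der = np.stack(
        [_derived_per_sample(table, table.sample_index(s)) for s in apomict_samples]
    )
    sex_der = np.stack(
        [_derived_per_sample(table, table.sample_index(s)) for s in sexual_samples]
    )
    bins = (apo_der > 0).sum(axis=0)
    rows = []
    for n in range(1, len(apomict_samples) + 1):
        in_bin = bins == n
        row: dict = {"bin": n, "n_sites": int(in_bin.sum())}
        for label, der in (("apomict", apo_der), ("sexual", sex_der)):
            cells = {}
            for cat in (constrained, NEUTRAL):
                m = in_bin & (cats == cat)
                called = der[:, m] >= 0
                derived = int(np.where(called, der[:, m], 0).sum())
                alleles = int(2 * called.sum())
                cells[cat] = (derived, alleles - derived)
            stat = RatioStat(
                constrained,
                cells[constrained][0],
                cells[constrained][1],
                cells[NEUTRAL][0],
                cells[NEUTRAL][1],
            )
            row[f"{label}_ratio"] = stat.ratio
            row[f"{label}_log_odds"] = stat.log_odds
            row[f"{label}_stat"] = stat
        z, p = odds_ratio_z_test(row["apomict_stat"], row["sexual_stat"])
        row["z"] = z
        row["p_one_sided"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance network
# ---------------------------------------------------------------------------

def distance_network(
    table: GenotypeTable, samples: list[str] | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise allele-sharing distance matrix and its minimum spanning tree.

    Distance is the mean per-site expected allele mismatch (0 identical
    genotypes, 0.5 one shared allele, 1 none) over co-called sites.  Tie
    break is deterministic in sample order.
    """
    if samples is None:
        samples = list(table.samples)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    n = len(samples)
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = _pairwise_diff(
            table.gt[table.sample_index(samples[i])],
            table.gt[table.sample_index(samples[j])],
        )
        dist[i, j] = dist[j, i] = d
    dm = pd.DataFrame(dist, index=samples, columns=samples)
    g = nx.Graph()
    g.add_nodes_from(samples)
    for i, j in combinations(range(n), 2):
        if np.isfinite(dist[i, j]):
            g.add_edge(samples[i], samples[j], weight=float(dist[i, j]))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted(
        (u, v, float(d["weight"])) for u, v, d in mst.edges(data=True)
    )
    return dm, edges
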