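"""Synthetic cohort generator.

Produces cohorts of sympatric sexual/apomict pairs with the statistical
structure the downstream analysis assumes:

* sexual lineages radiate independently from a common ancestor and are
  highly selfing -- each mutation is collapsed to a homozygote with
  probability ``selfing_F``, depressing heterozygosity by ``1 - F``;
* apomicts are non-recombining hybrids carrying one conspecific-derived
  haplotype and one sister-species haplotype; founder divergence is
  planted as fixed heterozygous differences shared within each
  hybridization-origin group;
* post-origin apomict mutations accrue on a clonal genealogy per origin
  group (so derived alleles reach intermediate frequencies) and retain
  constrained-site mutations at ``relax_factor_rho`` times the sexual
  retention probability;
* every planted event is recorded in a truth log, enabling exact
  parameter-recovery tests.

An ``intraspecific`` origin mode plants a within-species apomict instead:
both haplotypes descend from a single conspecific founder haplotype that
shares one of the paired sexual's true haplotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .variants import (
    CATEGORIES,
    CONSTRAINED,
    GenotypeTable,
    HET,
    HOMALT,
    HOMREF,
    PhasedBlock,
    SiteAnnotation,
    write_bed,
    write_fasta,
    write_phased_blocks,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")

# truth-log event kinds
KIND_STEM = "stem_divergence"
KIND_SISTER = "sister_divergence"
KIND_FOUNDER = "founder_private"
KIND_SEX_MUT = "sexual_mutation"
KIND_APO_MUT = "apomict_mutation"


@dataclass
class SimParams:
    """Generating parameters for :func:`simulate_cohort`.

    ``mu`` is the expected number of derived mutations per site per
    haploid genome over one lineage lifetime; diploid lineages draw
    ``Poisson(2 * mu * L)`` candidate mutations before selective
    thinning.  ``hybrid_divergence`` is the total substitutions/site
    separating the two founder haplotypes of a hybrid apomict (half is
    planted on the conspecific species stem, half on the sister-species
    branch).
    """

    genome_length: int
    n_pops: int = 8
    annotation_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "0fold": 0.12,
            "4fold": 0.08,
            "CNS": 0.10,
            "CCS": 0.05,
            "other": 0.65,
        }
    )
    mu: float = 1e-3
    hybrid_divergence: float = 0.02
    selfing_F: float = 0.75
    relax_factor_rho: float = 1.0
    retain_constrained_sex: float = 0.5
    n_hybrid_origins: int = 2
    seed: int = 0
    origin_mode: str = "hybrid"
    annotation_block_bp: int = 300
    region_length: int = 2000
    filter_window_bp: int = 20_000
    chrom: str = "chr1"
    qual: float = 99.0
    gq: float = 99.0

    def __post_init__(self) -> None:
        fr = dict(self.annotation_fractions)
        if set(fr) != set(CATEGORIES):
            raise ValueError(f"annotation_fractions keys must be {CATEGORIES}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("annotation fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("annotation_fractions must sum to 1")
        if not 0.0 <= self.selfing_F <= 1.0:
            raise ValueError("selfing_F must be in [0, 1]")
        if self.relax_factor_rho < 0:
            raise ValueError("relax_factor_rho must be >= 0")
        if not 0.0 <= self.retain_constrained_sex <= 1.0:
            raise ValueError("retain_constrained_sex must be in [0, 1]")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not 1 <= self.n_hybrid_origins <= self.n_pops:
            raise ValueError("n_hybrid_origins must be in [1, n_pops]")
        if self.origin_mode not in ("hybrid", "intraspecific"):
            raise ValueError("origin_mode must be 'hybrid' or 'intraspecific'")
        if self.genome_length < 10 * self.filter_window_bp:
            raise ValueError(
                "genome_length must be >= 10 * filter_window_bp so the "
                "window filter is exercisable"
            )
        if self.genome_length < self.region_length:
            raise ValueError("genome_length must cover at least one region")
        self.annotation_fractions = fr

    @property
    def apomict_retention(self) -> float:
        """Realized constrained-site retention probability in apomicts."""
        return min(1.0, self.relax_factor_rho * self.retain_constrained_sex)


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort.

    Per-site arrays are parallel to the cohort's :class:`GenotypeTable`
    sites; every polymorphic site corresponds to exactly one planted
    event.
    """

    seed: int
    origin_of: dict[str, int]
    lineage_counts: dict[str, dict[str, int]]
    lineage_hap_counts: dict[str, list[dict[str, int]]]
    kind: np.ndarray
    owner: np.ndarray
    category: np.ndarray
    derived: np.ndarray
    conspecific_hap: dict[str, dict[int, str]]

    def to_dict(self, table: GenotypeTable) -> dict:
        events = [
            {
                "chrom": str(table.chrom[i]),
                "pos": int(table.pos[i]),
                "kind": str(self.kind[i]),
                "owner": None if self.owner[i] is None else str(self.owner[i]),
                "category": str(self.category[i]),
                "derived": str(self.derived[i]),
            }
            for i in range(table.n_sites)
        ]
        return {
            "seed": self.seed,
            "origin_of": self.origin_of,
            "lineage_counts": self.lineage_counts,
            "lineage_hap_counts": self.lineage_hap_counts,
            "conspecific_hap": {
                s: {str(k): v for k, v in d.items()}
                for s, d in self.conspecific_hap.items()
            },
            "events": events,
        }


@dataclass
class Cohort:
    """In-memory simulated cohort; phased blocks are built lazily."""

    params: SimParams
    reference: dict[str, np.ndarray]  # chrom -> uint8 base codes
    annotation: SiteAnnotation
    table: GenotypeTable
    truth: SimTruth
    sample_sheet: pd.DataFrame
    _hap_variants: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(seq) for c, seq in self.reference.items()}

    @property
    def reference_seqs(self) -> dict[str, str]:
        return {c: _codes_to_str(codes) for c, codes in self.reference.items()}

    @property
    def sexual_samples(self) -> list[str]:
        return list(self.sample_sheet["sexual"])

    @property
    def apomict_samples(self) -> list[str]:
        return list(self.sample_sheet["apomict"])

    def regions(self) -> list[tuple[str, int, int]]:
        rl = self.params.region_length
        L = self.params.genome_length
        return [
            (self.params.chrom, s, min(s + rl, L)) for s in range(0, L, rl)
        ]

    def phased_block(self, sample: str, region_index: int) -> PhasedBlock:
        """Phased haplotype block for one apomict over one region.

        The emitted hap1/hap2 order is randomized per (sample, region) at
        simulation time; the truth log records which label carries the
        conspecific-derived haplotype.
        """
        chrom, start, end = self.regions()[region_index]
        pos, base, on0, on1 = self._hap_variants[sample]
        sel = (pos >= start + 1) & (pos <= end)
        haps = []
        for on in (on0, on1):
            codes = self.reference[chrom][start:end].copy()
            m = sel & on
            codes[pos[m] - 1 - start] = base[m]
            haps.append(_codes_to_str(codes))
        consp, sister = haps  # internal hap 0 is always the conspecific one
        if self.truth.conspecific_hap[sample][region_index] == "hap1":
            return PhasedBlock(chrom, start, end, consp, sister)
        return PhasedBlock(chrom, start, end, sister, consp)

    def phased_blocks(self, sample: str) -> list[PhasedBlock]:
        return [self.phased_block(sample, i) for i in range(len(self.regions()))]


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

class _SitePool:
    """Infinite-sites position allocator (collisions re-drawn)."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.length = length
        self.used = np.zeros(length, dtype=bool)
        self.rng = rng

    def draw(self, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0, dtype=np.int64)
        if n > self.length - int(self.used.sum()):
            raise ValueError("genome too short for the requested mutation load")
        out: list[int] = []
        seen: set[int] = set()
        while len(out) < n:
            cand = self.rng.integers(0, self.length, size=2 * (n - len(out)) + 8)
            for p in cand:
                p = int(p)
                if not self.used[p] and p not in seen:
                    seen.add(p)
                    out.append(p)
                    if len(out) == n:
                        break
        pos = np.array(out, dtype=np.int64)
        self.used[pos] = True
        return pos


def _intervals_from_codes(cat_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode a per-base category-code array into BED intervals."""
    change = np.flatnonzero(np.diff(cat_codes)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(cat_codes)]])
    cats = np.array([CATEGORIES[c] for c in cat_codes[starts]], dtype=object)
    return starts.astype(np.int64), ends.astype(np.int64), cats


def _clonal_branches(
    members: list[str], rng: np.random.Generator
) -> list[tuple[float, tuple[str, ...]]]:
    """Random ultrametric clonal genealogy; every tip sits at depth 1.

    Returns (branch_length, tips_below) pairs whose per-tip path lengths
    sum to exactly 1, so expected per-lineage mutation counts are
    independent of the group's sharing structure.
    """
    if len(members) == 1:
        return [(1.0, (members[0],))]
    times = np.sort(rng.uniform(0.05, 0.75, size=len(members) - 1))
    subtrees: list[tuple[tuple[str, ...], float]] = [((m,), 0.0) for m in members]
    branches: list[tuple[float, tuple[str, ...]]] = []
    for t in times:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        tips_j, h_j = subtrees.pop(j)
        tips_i, h_i = subtrees.pop(i)
        branches.append((float(t - h_i), tips_i))
        branches.append((float(t - h_j), tips_j))
        subtrees.append((tips_i + tips_j, float(t)))
    tips, h = subtrees[0]
    branches.append((1.0 - h, tips))
    return branches


class _EventLog:
    def __init__(self) -> None:
        self.pos: list[np.ndarray] = []
        self.kind: list[str] = []
        self.owner: list[object] = []
        self.apps: list[dict] = []
        self.n = 0

    def add(self, pos: np.ndarray, kind: str, owner: object) -> np.ndarray:
        idx = np.arange(self.n, self.n + len(pos))
        self.pos.append(pos)
        self.kind.extend([kind] * len(pos))
        self.owner.extend([owner] * len(pos))
        self.n += len(pos)
        return idx

    def carry(
        self,
        ev: np.ndarray,
        sample: str,
        gt,
        hap0=False,
        hap1=False,
    ) -> None:
        self.apps.append(
            {"ev": ev, "sample": sample, "gt": gt, "hap0": hap0, "hap1": hap1}
        )


def simulate_cohort(params: SimParams) -> Cohort:
    """Generate a full synthetic cohort from ``params`` (seeded, deterministic)."""
    rng = np.random.default_rng(params.seed)
    L = params.genome_length
    chrom = params.chrom

    # reference / ancestral / outgroup sequence
    ref_codes = rng.integers(0, 4, size=L).astype(np.uint8)

    # annotation: contiguous category blocks
    n_blocks = (L + params.annotation_block_bp - 1) // params.annotation_block_bp
    fracs = np.array([params.annotation_fractions[c] for c in CATEGORIES])
    block_cats = rng.choice(len(CATEGORIES), size=n_blocks, p=fracs).astype(np.uint8)
    cat_codes = np.repeat(block_cats, params.annotation_block_bp)[:L]
    intervals = _intervals_from_codes(cat_codes)
    pool = _SitePool(L, rng)

    # samples
    pops = [f"pop{i}" for i in range(params.n_pops)]
    sexuals = [f"sex_{i}" for i in range(params.n_pops)]
    apomicts = [f"apo_{i}" for i in range(params.n_pops)]
    samples = sexuals + apomicts
    sheet = pd.DataFrame(
        {"population": pops, "sexual": sexuals, "apomict": apomicts}
    )
    origin_of = {a: i % params.n_hybrid_origins for i, a in enumerate(apomicts)}

    p_sex = params.retain_constrained_sex
    p_apo = params.apomict_retention
    ev = _EventLog()

    def plant(rate: float, kind: str, owner: object, retention: float) -> np.ndarray:
        """Draw Poisson(rate * L) sites, thin constrained ones by ``retention``."""
        n = rng.poisson(rate * L)
        pos = pool.draw(n)
        cats = cat_codes[pos]
        constrained = np.isin(np.array(CATEGORIES, dtype=object)[cats], CONSTRAINED)
        keep = ~constrained | (rng.random(len(pos)) < retention)
        return ev.add(pos[keep], kind, owner)

    # --- species-stem divergence (shared ancestry of all conspecific genomes)
    stem_rate = params.hybrid_divergence / 2.0
    stem_idx = plant(stem_rate, KIND_STEM, None, p_sex)
    if params.origin_mode == "hybrid":
        for s in sexuals:
            ev.carry(stem_idx, s, HOMALT)
        for a in apomicts:
            ev.carry(stem_idx, a, HET, hap0=True)
    else:
        for s in samples:
            hap = s in apomicts
            ev.carry(stem_idx, s, HOMALT, hap0=hap, hap1=hap)

    # --- sexual lineage mutations (zygosity thinned by selfing)
    sex_het_events: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in sexuals:
        idx = plant(2.0 * params.mu, KIND_SEX_MUT, s, p_sex)
        hom = rng.random(len(idx)) < params.selfing_F
        gt = np.where(hom, HOMALT, HET).astype(np.int8)
        ev.carry(idx, s, gt)
        truehap = rng.integers(0, 2, size=len(idx))
        sex_het_events[s] = (idx, np.where(hom, -1, truehap))

    if params.origin_mode == "hybrid":
        # --- sister-species founder divergence, shared within origin groups
        for o in range(params.n_hybrid_origins):
            members = [a for a in apomicts if origin_of[a] == o]
            sis_idx = plant(stem_rate, KIND_SISTER, o, p_sex)
            for a in members:
                ev.carry(sis_idx, a, HET, hap1=True)
            # --- post-origin mutations on a clonal genealogy
            for length, tips in _clonal_branches(members, rng):
                idx = plant(length * 2.0 * params.mu, KIND_APO_MUT, o, p_apo)
                hap = rng.integers(0, 2, size=len(idx)).astype(bool)
                for a in tips:
                    ev.carry(idx, a, HET, hap0=~hap, hap1=hap)
    else:
        # --- intraspecific origin: founder captures one haplotype of the
        # paired sexual, then both apomict haplotypes descend from it
        for pop_i, a in enumerate(apomicts):
            partner = sexuals[pop_i]
            idx, truehap = sex_het_events[partner]
            captured = int(rng.integers(0, 2))
            shared = idx[(truehap == -1) | (truehap == captured)]
            ev.carry(shared, a, HOMALT, hap0=True, hap1=True)
            fp_idx = plant(params.hybrid_divergence, KIND_FOUNDER, a, p_sex)
            ev.carry(fp_idx, a, HOMALT, hap0=True, hap1=True)
            for h in (0, 1):
                idx = plant(params.mu, KIND_APO_MUT, a, p_apo)
                ev.carry(idx, a, HET, hap0=(h == 0), hap1=(h == 1))

    # --- assemble the table, sorted by position
    pos_all = (
        np.concatenate(ev.pos) if ev.pos else np.empty(0, dtype=np.int64)
    )
    order = np.argsort(pos_all, kind="stable")
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    pos_sorted = pos_all[order]

    n_sites = len(pos_sorted)
    kind_arr = np.array(ev.kind, dtype=object)[order]
    owner_arr = np.array(ev.owner, dtype=object)[order]
    cat_arr = np.array(CATEGORIES, dtype=object)[cat_codes[pos_sorted]]

    ref_b = _BASES[ref_codes[pos_sorted]]
    shift = rng.integers(1, 4, size=n_sites).astype(np.uint8)
    alt_codes = (ref_codes[pos_sorted] + shift) % 4
    alt_b = _BASES[alt_codes]

    sample_row = {s: i for i, s in enumerate(samples)}
    gt = np.zeros((len(samples), n_sites), dtype=np.int8)
    hap_present = {
        a: (np.zeros(n_sites, dtype=bool), np.zeros(n_sites, dtype=bool))
        for a in apomicts
    }
    for app in ev.apps:
        cols = rank[app["ev"]]
        gt[sample_row[app["sample"]], cols] = app["gt"]
        if app["sample"] in hap_present:
            for h, key in ((0, "hap0"), (1, "hap1")):
                v = app[key]
                if np.any(v):
                    mask = v if isinstance(v, np.ndarray) else np.full(len(cols), v)
                    hap_present[app["sample"]][h][cols[mask]] = True

    table = GenotypeTable(
        samples=samples,
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=pos_sorted + 1,
        ref=ref_b,
        alt=alt_b,
        qual=np.full(n_sites, params.qual),
        gt=gt,
        gq=np.full((len(samples), n_sites), params.gq),
    )
    table.validate()

    # --- truth bookkeeping
    lineage_counts: dict[str, dict[str, int]] = {}
    lineage_hap_counts: dict[str, list[dict[str, int]]] = {}
    for s in sexuals:
        own = (kind_arr == KIND_SEX_MUT) & (owner_arr == s)
        lineage_counts[s] = {
            c: int(((cat_arr == c) & own).sum()) for c in CATEGORIES
        }
    for a in apomicts:
        mut = (kind_arr == KIND_APO_MUT) & (gt[sample_row[a]] != HOMREF)
        lineage_counts[a] = {
            c: int(((cat_arr == c) & mut).sum()) for c in CATEGORIES
        }
        lineage_hap_counts[a] = [
            {
                c: int(((cat_arr == c) & mut & hap_present[a][h]).sum())
                for c in CATEGORIES
            }
            for h in (0, 1)
        ]

    n_regions = (L + params.region_length - 1) // params.region_length
    conspecific_hap = {
        a: {
            int(i): ("hap1" if keep else "hap2")
            for i, keep in enumerate(rng.random(n_regions) < 0.5)
        }
        for a in apomicts
    }

    truth = SimTruth(
        seed=params.seed,
        origin_of=origin_of,
        lineage_counts=lineage_counts,
        lineage_hap_counts=lineage_hap_counts,
        kind=kind_arr,
        owner=owner_arr,
        category=cat_arr,
        derived=alt_b.astype(object),
        conspecific_hap=conspecific_hap,
    )

    hap_variants = {
        a: (pos_sorted + 1, alt_codes, hap_present[a][0], hap_present[a][1])
        for a in apomicts
    }

    ann = SiteAnnotation(
        intervals={chrom: intervals},
        ancestral={chrom: _codes_to_str(ref_codes)},
    )
    return Cohort(
        params=params,
        reference={chrom: ref_codes},
        annotation=ann,
        table=table,
        truth=truth,
        sample_sheet=sheet,
        _hap_variants=hap_variants,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as a text file set (VCF, FASTA, BED, TSV, JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "fasta": out / "reference.fa",
        "bed": out / "annotation.bed",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
        "phased_dir": out / "phased",
    }
    write_vcf(cohort.table, paths["vcf"], contig_lengths=cohort.chrom_lengths)
    write_fasta(cohort.reference_seqs, paths["fasta"])
    write_bed(cohort.annotation.intervals, paths["bed"])
    cohort.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.to_dict(cohort.table), fh, indent=1, sort_keys=True)
    paths["phased_dir"].mkdir(exist_ok=True)
    for a in cohort.apomict_samples:
        write_phased_blocks(
            cohort.phased_blocks(a), paths["phased_dir"] / f"{a}.blocks.tsv"
        )
    return paths
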