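"""Variant, annotation and sequence input/output plus site filtering.

The central data structure is :class:`GenotypeTable`, a samples x sites
matrix of diploid genotype calls backed by numpy arrays.  Readers accept
the standard text formats (VCF 4.2, BED, FASTA, TSV sample sheets) and
writers round-trip them losslessly for the simulator's cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: site-annotation categories, in canonical order
CATEGORIES = ("0fold", "4fold", "CNS", "CCS", "other")
#: categories treated as phylogenetically constrained
CONSTRAINED = ("0fold", "CNS", "CCS")
#: neutral reference category
NEUTRAL = "4fold"

HOMREF, HET, HOMALT, MISSING = 0, 1, 2, -1

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


class EmptyResultError(RuntimeError):
    """Raised when a filtering stage leaves no usable data (not a crash)."""


# ---------------------------------------------------------------------------
# GenotypeTable
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Biallelic SNP genotype matrix with per-site and per-call metadata.

    Attributes
    ----------
    samples:
        Sample names, one per row of ``gt``/``gq``.
    chrom, pos:
        Site coordinates; ``pos`` is 1-based and strictly increasing
        within each chromosome.
    ref, alt:
        Single-character reference and alternate alleles.
    qual:
        Site quality scores.
    gt:
        ``(n_samples, n_sites)`` int8 matrix of genotype calls coded
        ``0`` homref, ``1`` het, ``2`` homalt, ``-1`` missing.
    gq:
        Per-call genotype qualities, same shape as ``gt``.
    alt_is_derived:
        Set by :func:`polarize_derived`; ``True`` where the alternate
        allele is the derived one.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    gt: np.ndarray
    gq: np.ndarray
    alt_is_derived: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in table") from None

    def take(self, mask: np.ndarray) -> "GenotypeTable":
        """Return a new table restricted to the sites selected by ``mask``."""
        idx = np.asarray(mask)
        derived = None if self.alt_is_derived is None else self.alt_is_derived[idx]
        return GenotypeTable(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            gt=self.gt[:, idx],
            gq=self.gq[:, idx],
            alt_is_derived=derived,
        )

    def is_polymorphic(self) -> np.ndarray:
        """Sites segregating among the non-missing calls of the cohort."""
        called = self.gt >= 0
        has_alt = ((self.gt > 0) & called).any(axis=0)
        has_ref = (((self.gt == HOMREF) | (self.gt == HET)) & called).any(axis=0)
        return has_alt & has_ref

    def validate(self) -> None:
        if self.gt.shape != (self.n_samples, self.n_sites):
            raise ValueError("gt shape does not match samples x sites")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        for arr, name in ((self.ref, "ref"), (self.alt, "alt")):
            bad = ~np.isin(arr, list(_BASES))
            if bad.any():
                raise ValueError(f"non-ACGT {name} allele at {self.pos[bad][:3]}")

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.allclose(self.qual, other.qual, equal_nan=True)
            and np.array_equal(self.gt, other.gt)
            and np.allclose(self.gq, other.gq, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# SiteAnnotation
# ---------------------------------------------------------------------------

@dataclass
class SiteAnnotation:
    """Maps genomic positions to constraint categories and ancestral alleles.

    ``intervals`` holds, per chromosome, parallel arrays of BED-style
    0-based half-open ``starts``/``ends`` and a category per interval.
    ``ancestral`` holds the outgroup/ancestral sequence per chromosome.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    ancestral: dict[str, str] = field(default_factory=dict)

    def category_of(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Category for each 1-based position; ``other`` where unannotated."""
        pos0 = np.asarray(pos) - 1
        out = np.full(len(pos0), "other", dtype=object)
        if chrom not in self.intervals:
            return out
        starts, ends, cats = self.intervals[chrom]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        out[ok] = cats[idx[ok]]
        return out

    def ancestral_base(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Ancestral allele per 1-based position ('' when unavailable)."""
        out = np.full(len(pos), "", dtype=object)
        seq = self.ancestral.get(chrom)
        if seq is None:
            return out
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        pos0 = np.asarray(pos) - 1
        ok = (pos0 >= 0) & (pos0 < len(arr))
        bases = arr[pos0[ok]]
        valid = np.isin(bases, list(_BASES))
        vals = np.where(valid, bases, "")
        out[ok] = vals
        return out


def site_categories(table: GenotypeTable, ann: SiteAnnotation) -> np.ndarray:
    """Per-site category array for a table (vectorised per chromosome)."""
    out = np.empty(table.n_sites, dtype=object)
    for c in np.unique(table.chrom):
        m = table.chrom == c
        out[m] = ann.category_of(c, table.pos[m])
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as fh:
        return {name.split()[0]: seq.upper() for name, seq in SimpleFastaParser(fh)}


def read_bed(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a 4-column BED of annotation categories (0-based half-open)."""
    rows: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 BED columns")
            chrom, start, end, cat = parts[:4]
            if cat not in CATEGORIES:
                raise ValueError(f"{path}:{ln}: malformed category {cat!r}")
            rows.setdefault(chrom, []).append((int(start), int(end), cat))
    out = {}
    for chrom, ivs in rows.items():
        ivs.sort()
        starts = np.array([i[0] for i in ivs], dtype=np.int64)
        ends = np.array([i[1] for i in ivs], dtype=np.int64)
        cats = np.array([i[2] for i in ivs], dtype=object)
        out[chrom] = (starts, ends, cats)
    return out


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet pairing one sexual and one apomict genotype per population."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"population", "sexual", "apomict"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return df


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a multi-sample VCF keeping only biallelic SNP records.

    Non-SNP and multiallelic records are dropped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, qual = [], [], [], [], []
    gts, gqs = [], []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_dropped += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        # gts012: 0 homref, 1 het, 2 homalt, 3 unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        q = np.asarray(v.gt_quals, dtype=float)
        q[g == MISSING] = np.nan
        gqs.append(q)
    vcf.close()
    if n_dropped:
        log.info("read_vcf: dropped %d non-SNP/multiallelic records", n_dropped)
    n = len(pos)
    table = GenotypeTable(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype="U1"),
        alt=np.array(alt, dtype="U1"),
        qual=np.array(qual, dtype=float),
        gt=(np.stack(gts, axis=1) if n else np.zeros((len(samples), 0), np.int8)),
        gq=(np.stack(gqs, axis=1) if n else np.zeros((len(samples), 0), float)),
    )
    table.validate()
    return table


def read_inputs(
    vcf: str | Path, bed: str | Path, fasta: str | Path, samples: str | Path
) -> tuple[GenotypeTable, SiteAnnotation, pd.DataFrame]:
    """Read the four standard inputs and cross-check the sample sheet."""
    table = read_vcf(vcf)
    ann = SiteAnnotation(intervals=read_bed(bed), ancestral=read_fasta(fasta))
    sheet = read_sample_sheet(samples)
    wanted = set(sheet["sexual"]) | set(sheet["apomict"])
    missing = wanted - set(table.samples)
    if missing:
        raise ValueError(f"sample-sheet samples absent from VCF: {sorted(missing)}")
    return table, ann, sheet


@dataclass
class PhasedBlock:
    """A phased region: two haploid sequences over [start, end) (0-based)."""

    chrom: str
    start: int
    end: int
    hap1: str
    hap2: str


def read_phased_blocks(path: str | Path) -> list[PhasedBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, h1, h2 = line.split("\t")
            blocks.append(PhasedBlock(chrom, int(start), int(end), h1, h2))
    return blocks


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(
    intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            starts, ends, cats = intervals[chrom]
            for s, e, c in zip(starts, ends, cats):
                fh.write(f"{chrom}\t{s}\t{e}\t{c}\n")


_GT_STR = {HOMREF: "0/0", HET: "0/1", HOMALT: "1/1", MISSING: "./."}


def write_vcf(
    table: GenotypeTable,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 with QUAL and per-genotype GQ populated."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutacc\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in sorted(set(table.chrom.tolist())):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for j in range(table.n_sites):
            calls = []
            for i in range(table.n_samples):
                g = int(table.gt[i, j])
                gq = table.gq[i, j]
                gq_str = "." if not np.isfinite(gq) else str(int(round(gq)))
                calls.append(f"{_GT_STR[g]}:{gq_str}")
            q = table.qual[j]
            q_str = "." if not np.isfinite(q) else f"{q:g}"
            fh.write(
                f"{table.chrom[j]}\t{table.pos[j]}\t.\t{table.ref[j]}\t"
                f"{table.alt[j]}\t{q_str}\t.\t.\tGT:GQ\t" + "\t".join(calls) + "\n"
            )


def write_phased_blocks(blocks: Iterable[PhasedBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.hap1}\t{b.hap2}\n")


# ---------------------------------------------------------------------------
# filtering and polarization
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    """Per-stage record counts emitted by :func:`filter_sites`."""

    n_input: int = 0
    n_low_site_qual: int = 0
    n_genotypes_masked: int = 0
    n_monomorphic: int = 0
    n_windows_total: int = 0
    n_windows_dropped: int = 0
    n_sites_in_dropped_windows: int = 0
    n_output: int = 0
    missingness: dict[str, float] = field(default_factory=dict)

    def lines(self) -> list[str]:
        return [
            f"input sites: {self.n_input}",
            f"removed (site quality): {self.n_low_site_qual}",
            f"genotype calls masked (genotype quality): {self.n_genotypes_masked}",
            f"removed (monomorphic among samples): {self.n_monomorphic}",
            f"windows dropped: {self.n_windows_dropped}/{self.n_windows_total}",
            f"removed (sites in dropped windows): {self.n_sites_in_dropped_windows}",
            f"output sites: {self.n_output}",
        ]


def filter_sites(
    table: GenotypeTable,
    site_qual_min: float = 15.0,
    gt_qual_min: float = 40.0,
    window_bp: int = 20_000,
    min_callable_frac: float = 0.30,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[GenotypeTable, FilterLog]:
    """Apply site-quality, genotype-quality, window and polymorphism filters.

    Sites with quality below ``site_qual_min`` are removed and genotype
    calls below ``gt_qual_min`` set to missing.  Non-overlapping windows
    of ``window_bp`` (0-based, anchored at position 0 of each chromosome)
    are dropped entirely when the fraction of window bases holding a
    retained, callable site falls below ``min_callable_frac``.  Only sites
    polymorphic among the retained samples are kept.

    The callable-fraction numerator counts sites that survive the quality
    and polymorphism filters; this makes the operation idempotent.

    Raises
    ------
    EmptyResultError
        If no site survives; a distinct, catchable condition.
    """
    if site_qual_min < 0 or gt_qual_min < 0:
        raise ValueError("quality thresholds must be >= 0")
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")

    flog = FilterLog(n_input=table.n_sites)

    # stage 1: site quality
    keep_q = np.nan_to_num(table.qual, nan=-np.inf) >= site_qual_min
    flog.n_low_site_qual = int((~keep_q).sum())
    out = table.take(keep_q)

    # stage 2: genotype quality -> missing
    gt = out.gt.copy()
    gq = out.gq.copy()
    low = (gt != MISSING) & ~(np.nan_to_num(gq, nan=-np.inf) >= gt_qual_min)
    flog.n_genotypes_masked = int(low.sum())
    gt[low] = MISSING
    gq[low] = np.nan
    out = replace(out, gt=gt, gq=gq)

    # stage 3: retain only cohort-polymorphic sites
    poly = out.is_polymorphic()
    flog.n_monomorphic = int((~poly).sum())
    out = out.take(poly)

    # stage 4: window filter on the surviving, callable sites
    keep = np.ones(out.n_sites, dtype=bool)
    for c in np.unique(out.chrom):
        m = out.chrom == c
        win = (out.pos[m] - 1) // window_bp
        uniq, counts = np.unique(win, return_counts=True)
        if chrom_lengths and c in chrom_lengths:
            clen = chrom_lengths[c]
            denom = np.minimum(window_bp, clen - uniq * window_bp)
        else:
            denom = np.full(len(uniq), window_bp)
        bad = counts / denom < min_callable_frac
        flog.n_windows_total += len(uniq)
        flog.n_windows_dropped += int(bad.sum())
        bad_windows = set(uniq[bad].tolist())
        if bad_windows:
            drop = np.isin(win, list(bad_windows))
            idx = np.where(m)[0][drop]
            keep[idx] = False
    flog.n_sites_in_dropped_windows = int((~keep).sum())
    out = out.take(keep)

    flog.n_output = out.n_sites
    called = out.gt >= 0
    for i, s in enumerate(out.samples):
        flog.missingness[s] = (
            float(1.0 - called[i].mean()) if out.n_sites else float("nan")
        )
    for line in flog.lines():
        log.info("filter_sites: %s", line)
    if out.n_sites == 0:
        raise EmptyResultError("no sites remain after filtering")
    return out, flog


def polarize_derived(
    table: GenotypeTable, ann: SiteAnnotation
) -> tuple[GenotypeTable, int]:
    """Orient each site's alleles as ancestral/derived using the outgroup.

    The allele not present in the ancestral (outgroup) reference is
    derived.  Sites whose ancestral allele matches neither ref nor alt,
    or is absent, are excluded; the count of exclusions is returned and
    logged.
    """
    anc = np.empty(table.n_sites, dtype=object)
    for c in np.unique(table.chrom):
        m = table.chrom == c
        anc[m] = ann.ancestral_base(c, table.pos[m])
    anc_is_ref = anc == table.ref.astype(object)
    anc_is_alt = anc == table.alt.astype(object)
    usable = anc_is_ref | anc_is_alt
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("polarize_derived: excluded %d unpolarizable sites", n_excluded)
    out = table.take(usable)
    out.alt_is_derived = anc_is_ref[usable]
    return out, n_excluded
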