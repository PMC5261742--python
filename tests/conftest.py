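"""Shared fixtures and independent-oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mutacc.variants import GenotypeTable, SiteAnnotation


def make_table(
    samples: list[str],
    pos: list[int],
    gt: list[list[int]],
    *,
    chrom: str = "chr1",
    ref: str | list[str] = "A",
    alt: str | list[str] = "G",
    qual: float | list[float] = 99.0,
    gq: float | np.ndarray = 99.0,
) -> GenotypeTable:
    """Build a GenotypeTable from plain lists (gt rows are samples)."""
    n = len(pos)
    pos_arr = np.asarray(pos, dtype=np.int64)
    refs = np.full(n, ref, dtype="U1") if isinstance(ref, str) else np.asarray(ref, "U1")
    alts = np.full(n, alt, dtype="U1") if isinstance(alt, str) else np.asarray(alt, "U1")
    quals = (
        np.full(n, qual, dtype=float)
        if np.isscalar(qual)
        else np.asarray(qual, dtype=float)
    )
    gts = np.asarray(gt, dtype=np.int8)
    gqs = (
        np.full(gts.shape, gq, dtype=float)
        if np.isscalar(gq)
        else np.asarray(gq, dtype=float)
    )
    t = GenotypeTable(
        samples=list(samples),
        chrom=np.full(n, chrom, dtype=object),
        pos=pos_arr,
        ref=refs,
        alt=alts,
        qual=quals,
        gt=gts,
        gq=gqs,
    )
    t.validate()
    return t


def uniform_annotation(length: int, category: str = "other", chrom: str = "chr1",
                       ancestral: str | None = None) -> SiteAnnotation:
    intervals = {
        chrom: (
            np.array([0], dtype=np.int64),
            np.array([length], dtype=np.int64),
            np.array([category], dtype=object),
        )
    }
    anc = {chrom: ancestral} if ancestral is not None else {}
    return SiteAnnotation(intervals=intervals, ancestral=anc)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def small_cohort():
    """A small hybrid cohort reused by several read-only tests."""
    from mutacc.simulate import SimParams, simulate_cohort

    params = SimParams(
        genome_length=30_000,
        n_pops=2,
        filter_window_bp=3000,
        region_length=2500,
        mu=4e-3,
        hybrid_divergence=0.02,
        retain_constrained_sex=0.5,
        relax_factor_rho=2.0,
        seed=42,
    )
    return simulate_cohort(params)
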