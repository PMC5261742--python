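"""End-to-end orchestration: simulate/read -> filter -> statistics -> trees
-> classification -> contrasts, with per-stage reports and a deterministic
summary bundle."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import simulate as sim
from . import topology as tp
from . import trees as tr
from . import variants as vr

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; either ``sim`` parameters or input paths."""

    out_dir: str = "mutacc_out"
    # inputs (exclusive with sim)
    vcf: str | None = None
    bed: str | None = None
    fasta: str | None = None
    samples: str | None = None
    phased_dir: str | None = None
    # simulation parameters (passed to SimParams)
    sim: dict | None = None
    # filters
    site_qual_min: float = 15.0
    gt_qual_min: float = 40.0
    window_bp: int = 20_000
    min_callable_frac: float = 0.30
    # analysis
    window_snps: int = 20_000
    constrained_categories: tuple[str, ...] = ("0fold", "CNS", "CCS")
    min_support: float = 70.0
    z_max: float = 3.0
    bootstrap_reps: int = 100
    bootstrap_method: str = "rell"
    gamma_categories: int = 4
    max_tree_regions: int | None = None
    min_alignment_columns: int = 500
    # seeds
    seed: int = 0

    def validate(self) -> None:
        have_paths = all(
            getattr(self, k) for k in ("vcf", "bed", "fasta", "samples")
        )
        if self.sim is None and not have_paths:
            missing = [
                k for k in ("vcf", "bed", "fasta", "samples")
                if not getattr(self, k)
            ]
            raise ValueError(
                f"config needs either 'sim' parameters or input paths; "
                f"missing: {missing}"
            )
        for k in ("site_qual_min", "gt_qual_min", "min_callable_frac"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be non-negative")
        if self.window_bp <= 0 or self.window_snps <= 0:
            raise ValueError("window sizes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _seed_for(master: int, *key: int) -> int:
    """Deterministic child seed derived from the master seed and a key."""
    ss = np.random.SeedSequence(entropy=(int(master),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0])


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; writes reports under ``config.out_dir`` and
    returns the summary dict (also written as ``summary.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_snapshot.yaml")
    summary: dict = {"seed": config.seed}

    # ---- stage 1: inputs -------------------------------------------------
    if config.sim is not None:
        params = sim.SimParams(**{**config.sim, "seed": _seed_for(config.seed, 0)})
        cohort = sim.simulate_cohort(params)
        paths = sim.write_cohort(cohort, out / "cohort")
        vcf, bed, fasta, samples = (
            paths["vcf"], paths["bed"], paths["fasta"], paths["samples"],
        )
        phased_dir = paths["phased_dir"]
    else:
        vcf, bed, fasta, samples = (
            config.vcf, config.bed, config.fasta, config.samples,
        )
        phased_dir = config.phased_dir

    table, ann, sheet = vr.read_inputs(vcf, bed, fasta, samples)
    chrom_lengths = {c: len(s) for c, s in ann.ancestral.items()}
    summary["n_input_sites"] = table.n_sites

    # ---- stage 2: filtering and polarization -----------------------------
    table, flog = vr.filter_sites(
        table,
        site_qual_min=config.site_qual_min,
        gt_qual_min=config.gt_qual_min,
        window_bp=config.window_bp,
        min_callable_frac=config.min_callable_frac,
        chrom_lengths=chrom_lengths,
    )
    table, n_unpolarizable = vr.polarize_derived(table, ann)
    summary["filter"] = {
        "n_retained_sites": table.n_sites,
        "n_unpolarizable": n_unpolarizable,
        "missingness": flog.missingness,
        "log": flog.lines(),
    }

    sexuals = list(sheet["sexual"])
    apomicts = list(sheet["apomict"])

    # ---- stage 3: diversity statistics -----------------------------------
    summaries = {
        s: dv.diversity_summary(table, ann, s) for s in sexuals + apomicts
    }
    rows = []
    for s, summ in summaries.items():
        for cat, c in summ.counts.items():
            rows.append(
                {
                    "sample": s,
                    "category": cat,
                    "n_called": c.n_called,
                    "n_polymorphic": c.n_polymorphic,
                    "n_het": c.n_het,
                    "n_homalt": c.n_homalt,
                    "H0": c.H0,
                    "D": c.D,
                }
            )
    pd.DataFrame(rows).to_csv(out / "diversity_summary.tsv", sep="\t", index=False)

    pair_rows = []
    for _, pr in sheet.iterrows():
        sx, ap = summaries[pr["sexual"]], summaries[pr["apomict"]]
        a, s = ap.counts["all"], sx.counts["all"]
        h0_or, h0_p = dv.fisher_pair_test(
            [[a.n_het, a.n_polymorphic - a.n_het],
             [s.n_het, s.n_polymorphic - s.n_het]]
        )
        d_or, d_p = dv.fisher_pair_test(
            [[a.n_derived, a.n_alleles - a.n_derived],
             [s.n_derived, s.n_alleles - s.n_derived]]
        )
        row = {
            "population": pr["population"],
            "apomict_H0": a.H0, "sexual_H0": s.H0,
            "H0_odds_ratio": h0_or, "H0_p": h0_p,
            "apomict_D": a.D, "sexual_D": s.D,
            "D_odds_ratio": d_or, "D_p": d_p,
        }
        for cat in config.constrained_categories:
            za = dv.constrained_neutral_ratio(ap, cat)
            zs = dv.constrained_neutral_ratio(sx, cat)
            z, p = dv.odds_ratio_z_test(za, zs)
            row[f"{cat}_apomict_ratio"] = za.ratio
            row[f"{cat}_sexual_ratio"] = zs.ratio
            row[f"{cat}_Z"] = z
            row[f"{cat}_p_one_sided"] = p
        pair_rows.append(row)
    pair_df = pd.DataFrame(pair_rows)
    pair_df.to_csv(out / "pair_tests.tsv", sep="\t", index=False)

    pooled = {}
    for cat in config.constrained_categories:
        apo_stat = dv.pooled_ratio(
            [dv.constrained_neutral_ratio(summaries[s], cat) for s in apomicts]
        )
        sex_stat = dv.pooled_ratio(
            [dv.constrained_neutral_ratio(summaries[s], cat) for s in sexuals]
        )
        z, p = dv.odds_ratio_z_test(apo_stat, sex_stat)
        pooled[cat] = {
            "apomict_ratio": apo_stat.ratio,
            "sexual_ratio": sex_stat.ratio,
            "Z": z,
            "p_one_sided": p,
        }
    summary["pooled_ratio_tests"] = pooled
    summary["mean_apomict_H0"] = float(
        np.nanmean([summaries[s].H0() for s in apomicts])
    )
    summary["mean_sexual_H0"] = float(
        np.nanmean([summaries[s].H0() for s in sexuals])
    )
    summary["mean_apomict_D"] = float(
        np.nanmean([summaries[s].D() for s in apomicts])
    )
    summary["mean_sexual_D"] = float(
        np.nanmean([summaries[s].D() for s in sexuals])
    )

    if len(sexuals) >= 2:
        profiles = []
        for _, pr in sheet.iterrows():
            wp = dv.window_profiles(
                table, ann, sexuals, pr["apomict"], config.window_snps
            )
            wp.insert(0, "population", pr["population"])
            profiles.append(wp)
        pd.concat(profiles).to_csv(out / "window_profiles.tsv", sep="\t", index=False)

    if len(apomicts) >= 2:
        fb = dv.freq_binned_ratios(table, ann, apomicts, sexuals)
        fb.drop(columns=["apomict_stat", "sexual_stat"]).to_csv(
            out / "freq_binned_ratios.tsv", sep="\t", index=False
        )

    dm, edges = dv.distance_network(table)
    dm.to_csv(out / "distance_matrix.tsv", sep="\t")
    pd.DataFrame(edges, columns=["from", "to", "distance"]).to_csv(
        out / "network_edges.tsv", sep="\t", index=False
    )

    # ---- stage 4: haplotype trees ----------------------------------------
    tree_summary: dict = {}
    if phased_dir is not None:
        reference = ann.ancestral
        results: list[tr.TreeResult] = []
        alignments: dict[int, tr.FiveTaxonAlignment] = {}
        idx = 0
        for pair_i, pr in sheet.iterrows():
            blocks_path = Path(phased_dir) / f"{pr['apomict']}.blocks.tsv"
            if not blocks_path.exists():
                raise FileNotFoundError(f"no phased blocks for {pr['apomict']}")
            blocks = vr.read_phased_blocks(blocks_path)
            if config.max_tree_regions is not None:
                blocks = blocks[: config.max_tree_regions]
            for block in blocks:
                region = (block.chrom, block.start, block.end)
                pseudo = tr.make_pseudo_haplotypes(
                    table, pr["sexual"], region,
                    _seed_for(config.seed, 1, pair_i, block.start), reference,
                )
                aln = tr.assemble_alignment(block, pseudo, reference, region, ann)
                if aln is None or aln.n_columns < config.min_alignment_columns:
                    continue
                model = tr.empirical_model(aln, k=config.gamma_categories)
                fit = tr.fit_ml_tree(aln, model)
                tr.bootstrap_support(
                    aln,
                    n_reps=config.bootstrap_reps,
                    seed=_seed_for(config.seed, 2, pair_i, block.start),
                    method=config.bootstrap_method,
                    fit=fit,
                )
                alignments[idx] = aln
                results.append(fit)
                idx += 1
        passing, tlog = tr.filter_trees(
            results, min_support=config.min_support, z_max=config.z_max
        )
        with open(out / "trees.nwk", "w") as fh:
            for r in passing:
                fh.write(tr.to_newick(r) + "\n")
        tree_summary["n_trees_fit"] = tlog.n_input
        tree_summary["n_trees_passing"] = tlog.n_passing
        tree_summary["n_low_support"] = tlog.n_low_support
        tree_summary["n_high_divergence"] = tlog.n_high_divergence

        # ---- stage 5: classification and contrasts -----------------------
        if passing:
            tables = []
            class_rows = []
            for r in passing:
                aln = alignments[results.index(r)]
                bt = tp.assign_branch_mutations(r, aln)
                tables.append(bt)
                class_rows.append(
                    {
                        "chrom": r.region[0],
                        "start": r.region[1],
                        "end": r.region[2],
                        "class": bt.class_id,
                        "origin": tp.ORIGIN_OF_CLASS[bt.class_id],
                        "conspecific_tip": bt.conspecific_tip,
                        "loglik": r.loglik,
                        "min_support": r.min_support,
                    }
                )
            pd.DataFrame(class_rows).to_csv(
                out / "tree_classes.tsv", sep="\t", index=False
            )
            classes = [
                tp.TopologyClass(t.class_id, tp.ORIGIN_OF_CLASS[t.class_id])
                for t in tables
            ]
            tree_summary["topologies"] = tp.summarize_topologies(classes)
            hybrid = [
                t for t in tables
                if t.class_id in ("H1", "H2") and t.conspecific_tip
            ]
            if hybrid:
                contrasts = tp.terminal_contrasts(tables)
                tree_summary["contrasts"] = {
                    name: {
                        "table": c.table.tolist(),
                        "odds_ratio": c.odds_ratio,
                        "log_odds_se": c.log_odds_se,
                        "p": c.p_value,
                    }
                    for name, c in contrasts.items()
                }
                rt = tp.branch_length_ratio_test(tables)
                tree_summary["ratio_test"] = {
                    "apomict_count": rt.apomict_count,
                    "sexual_count": rt.sexual_count,
                    "ratio": rt.ratio,
                    "null_ratio": rt.null_ratio,
                    "p": rt.p_value,
                }
    summary["trees"] = tree_summary

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    return summary
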