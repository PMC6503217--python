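"""End-to-end orchestration of the comparative-genomics analysis.

One TOML config drives the whole workflow in the analysis order: input
(load or simulate) -> collection filter -> marker phylogenetics -> ANI ->
continuum/cluster diagnostics -> pangenome & profiles -> replicon families
-> Ks contrasts. Every stage writes its tables under its own subdirectory
of the run directory, and the machine-readable report records input/output
counts, the thresholds used, a checksum manifest, and the seed registry;
rerunning an identical config reproduces the manifest byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ani_engine, cluster_diagnostics, collection_filter, ks_transfer, orthology, phylo
from . import replicon_families as repfam
from .io_core import (
    get_logger,
    load_config,
    read_genome_collection,
    write_collection,
    write_matrix,
    write_tree,
)
from .synthetic_data import PlasmidPlan, SimConfig, evolve_collection

_log = get_logger("pipeline")

STAGES = ("filter", "markers", "ani", "continuum", "pangenome", "replicon_families", "ks_contrast")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config_from_table(table: dict, seed: int | None) -> SimConfig:
    kwargs = dict(table)
    if "plasmid_plan" in kwargs:
        kwargs["plasmid_plan"] = [PlasmidPlan(**p) for p in kwargs["plasmid_plan"]]
    if seed is not None:
        kwargs["seed"] = seed
    return SimConfig(**kwargs)


def run_pipeline(config: str | Path | dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the full analysis; returns the report (also written as JSON).

    ``config`` is a TOML path or an equivalent dict. It must contain either
    a ``[simulate]`` table (SimConfig fields) or an ``[input]`` table
    (``fasta`` list + ``gene_table``), plus one table per stage — missing
    stage tables are an error naming the block. ``seed`` overrides the
    config seeds.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in cfg:
            raise PipelineError(stage, "missing config block")

    report: dict = {"stages": [], "seeds": {}, "thresholds": {}, "manifest": {}}

    # ---- input
    if "simulate" in cfg:
        sim_cfg = _sim_config_from_table(cfg["simulate"], seed)
        report["seeds"]["simulate"] = sim_cfg.seed
        genomes, truth = evolve_collection(sim_cfg)
        input_dir = outdir / "input"
        write_collection(genomes, input_dir)
        write_tree(truth.tree, input_dir / "true_tree.nwk")
        truth.true_pairwise_distance.write(input_dir / "true_distances.tsv")
        if truth.psym_distance is not None:
            truth.psym_distance.write(input_dir / "true_psym_distances.tsv")
    elif "input" in cfg:
        genomes = read_genome_collection(cfg["input"]["fasta"], cfg["input"].get("gene_table"))
        truth = None
    else:
        raise PipelineError("input", "config needs a [simulate] or [input] block")
    report["n_input_genomes"] = len(genomes)

    def _stage_dir(name: str) -> Path:
        d = outdir / "stages" / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _finish(name: str, **counts) -> None:
        report["stages"].append({"name": name, **counts})

    try:
        # ---- 1 filter
        fcfg = cfg["filter"]
        rep = collection_filter.filter_collection(
            genomes,
            min_draft_length=int(fcfg.get("min_draft_length", collection_filter.MIN_DRAFT_LENGTH)),
            required_tags=set(fcfg.get("required_tags", sorted(collection_filter.REQUIRED_SYMBIOSIS_TAGS))),
        )
        genomes = rep.kept_genomes(genomes)
        d = _stage_dir("filter")
        pd.DataFrame(
            [(g, "kept", "") for g in rep.kept] + [(g, "excluded", r) for g, r in rep.excluded],
            columns=["genome_id", "status", "reason"],
        ).to_csv(d / "filter_report.tsv", sep="\t", index=False)
        report["thresholds"]["filter"] = rep.thresholds
        _finish("filter", n_in=report["n_input_genomes"], n_kept=len(rep.kept), n_excluded=len(rep.excluded))
        if len(genomes) < 2:
            raise PipelineError("filter", "fewer than 2 genomes kept")

        # ---- 2 markers
        mcfg = cfg["markers"]
        markers = phylo.extract_markers(
            genomes,
            role_tag=mcfg.get("role_tag", "ribosomal"),
            min_identity=float(mcfg.get("min_identity", 60.0)),
            min_cov_largest=float(mcfg.get("min_cov_largest", 60.0)),
        )
        if bool(mcfg.get("congruence_filter", True)) and len(genomes) >= 4 and len(markers) >= 3:
            fres = phylo.filter_markers(
                markers,
                max_rf_quantile=float(mcfg.get("max_rf_quantile", 0.75)),
                min_len=int(mcfg.get("min_len", 50)),
            )
            sm = fres.supermatrix
            n_dropped = len(fres.dropped)
        else:
            sm = phylo.concatenate([phylo.trim_columns(m) for m in markers])
            n_dropped = 0
        distances = phylo.pairwise_distance(sm, model=mcfg.get("model", "poisson"))
        d = _stage_dir("markers")
        distances.write(d / "genetic_distance.tsv")
        if len(distances.labels) >= 3 and distances.saturated is None:
            tree = phylo.nj_tree(distances)
            write_tree(tree, d / "marker_tree.nwk")
        _finish(
            "markers",
            n_markers=len(markers),
            n_dropped=n_dropped,
            supermatrix_positions=sm.length,
        )

        # ---- 3 ani
        acfg = cfg["ani"]
        ani_df, gcov_df, pairs = ani_engine.ani_matrix(
            genomes,
            frag_len=int(acfg.get("frag_len", ani_engine.DEFAULT_FRAG_LEN)),
            min_frag_identity=float(acfg.get("min_frag_identity", ani_engine.DEFAULT_MIN_FRAG_IDENTITY)),
            min_frag_aln_cov=float(acfg.get("min_frag_aln_cov", ani_engine.DEFAULT_MIN_FRAG_ALN_COV)),
            return_pairs=True,
        )
        d = _stage_dir("ani")
        write_matrix((tuple(ani_df.index), ani_df.to_numpy()), d / "ani.tsv")
        write_matrix((tuple(gcov_df.index), gcov_df.to_numpy()), d / "gcov.tsv")
        pd.DataFrame(
            [
                (p.genome_a, p.genome_b, p.ani_pct, p.gcov_pct, p.ani_ab_pct, p.ani_ba_pct, p.ani_weighted_pct)
                for p in pairs
            ],
            columns=["genome_a", "genome_b", "ani", "gcov", "ani_ab", "ani_ba", "ani_weighted"],
        ).to_csv(d / "pairs.tsv", sep="\t", index=False, float_format="%.6f")
        _finish("ani", n_pairs=len(pairs))

        # ---- 4 continuum
        ccfg = cfg["continuum"]
        pair_recs = cluster_diagnostics.pair_table(ani_df, gcov_df, distances)
        x = [p.ani_pct for p in pair_recs]
        yd = [p.genetic_distance for p in pair_recs]
        rho, pval = cluster_diagnostics.spearman(x, yd)
        call = cluster_diagnostics.call_clusters(
            ani_df,
            gcov_df,
            ani_min=float(ccfg.get("ani_min", 96.0)),
            gcov_min=float(ccfg.get("gcov_min", 90.0)),
        )
        lefts, counts = ani_engine.ani_histogram(
            x, bin_width=float(ccfg.get("bin_width", 2.0))
        )
        d = _stage_dir("continuum")
        pd.DataFrame(
            [(p.genome_a, p.genome_b, p.ani_pct, p.gcov_pct, p.genetic_distance) for p in pair_recs],
            columns=["genome_a", "genome_b", "ani", "gcov", "genetic_distance"],
        ).to_csv(d / "pair_table.tsv", sep="\t", index=False, float_format="%.6f")
        pd.DataFrame(
            [(cid, ",".join(sorted(m))) for cid, m in sorted(call.clusters.items())],
            columns=["cluster_id", "members"],
        ).to_csv(d / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame({"bin_left": lefts, "count": counts}).to_csv(
            d / "ani_histogram.tsv", sep="\t", index=False
        )
        if len(pair_recs) >= 10:
            prof = cluster_diagnostics.continuum_profile(
                pair_recs, window=float(ccfg.get("window", 0.005))
            )
            prof.to_frame().to_csv(d / "continuum_profile.tsv", sep="\t", index=False, float_format="%.6f")
        report["thresholds"]["continuum"] = {"ani_min": call.ani_min, "gcov_min": call.gcov_min}
        _finish("continuum", spearman_rho=rho, spearman_p=pval, n_clusters=call.n_clusters)

        # ---- 5 pangenome
        pcfg = cfg["pangenome"]
        proteomes = {g.genome_id: g.proteome() for g in genomes}
        ft_mcl = orthology.cluster_proteomes(
            proteomes,
            "mcl",
            min_identity=float(pcfg.get("min_identity", 50.0)),
            min_coverage=float(pcfg.get("min_coverage", 50.0)),
            inflation=float(pcfg.get("inflation", 1.5)),
        )
        ft_bdbh = orthology.cluster_proteomes(proteomes, "bdbh")
        core = orthology.consensus_core(ft_bdbh, ft_mcl, sorted(proteomes))
        pa = ft_mcl.presence_absence()
        curves = orthology.pangenome_curves(
            pa, n_perm=int(pcfg.get("n_perm", 20)), seed=int(cfg.get("seed", 0) if seed is None else seed)
        )
        order, _linkage = orthology.order_profiles(pa)
        d = _stage_dir("pangenome")
        pa.to_csv(d / "presence_absence.tsv", sep="\t")
        pd.DataFrame(
            {"n": curves.n, "core_median": curves.core_median, "pan_median": curves.pan_median}
        ).to_csv(d / "curves.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(curves.heaps_k, curves.heaps_gamma, curves.core_a, curves.core_tau, curves.core_c)],
            columns=["K", "gamma", "A", "tau", "C"],
        ).to_csv(d / "fits.tsv", sep="\t", index=False, float_format="%.6f")
        (d / "profile_order.txt").write_text("\n".join(order) + "\n")
        # symbiotic mapping: packaged reference = tagged symbiotic proteins
        refs = {}
        for g in genomes:
            for gene in g.genes():
                if "symbiotic" in gene.role_tags and gene.protein:
                    refs.setdefault(gene.family_truth or gene.gene_id, gene.protein)
        if refs:
            profile = orthology.map_symbiotic(proteomes, refs)
            profile.to_csv(d / "symbiotic_profile.tsv", sep="\t")
        _finish(
            "pangenome",
            n_families=ft_mcl.n_families,
            n_consensus_core=core.n_families,
            heaps_gamma=curves.heaps_gamma,
        )

        # ---- 6 replicon families
        rcfg = cfg["replicon_families"]
        reps = repfam.extract_rep_proteins(genomes)
        assign = repfam.family_clusters(reps, genomes, inflation=float(rcfg.get("inflation", 1.5)))
        d = _stage_dir("replicon_families")
        pd.DataFrame(
            [(r, c or "", b or "") for r, (c, b) in sorted(assign.assignment.items())],
            columns=["replicon_id", "repC_family", "repB_family"],
        ).to_csv(d / "assignments.tsv", sep="\t", index=False)
        for tag, trees in sorted(assign.trees.items()):
            for fid, tree in sorted(trees.items()):
                write_tree(tree, d / f"{fid}.nwk")
        _finish(
            "replicon_families",
            n_repC_families=len(assign.families.get("repC", {})),
            n_repB_families=len(assign.families.get("repB", {})),
            n_unassigned=len(assign.unassigned()),
        )

        # ---- 7 ks contrasts
        kcfg = cfg["ks_contrast"]
        with_psym = [g for g in genomes if g.psym is not None]
        max_pairs = int(kcfg.get("max_pairs", 10))
        contrasts = []
        for i in range(len(with_psym)):
            for j in range(i + 1, len(with_psym)):
                if len(contrasts) >= max_pairs:
                    break
                contrasts.append(
                    ks_transfer.compartment_contrast(
                        with_psym[i],
                        with_psym[j],
                        transfer_ratio_max=float(kcfg.get("transfer_ratio_max", 0.2)),
                        min_chr_ks=float(kcfg.get("min_chr_ks", 0.1)),
                        min_pairs=int(kcfg.get("min_pairs", 10)),
                    )
                )
        d = _stage_dir("ks_contrast")
        pd.DataFrame(
            [
                (
                    c.genome_a,
                    c.genome_b,
                    c.median_ks_chr,
                    c.median_ks_psym,
                    c.ratio,
                    {True: "transfer", False: "no", None: "indeterminate"}[c.transfer_flag],
                    c.reverse_flag,
                )
                for c in contrasts
            ],
            columns=["genome_a", "genome_b", "median_ks_chr", "median_ks_psym", "ratio", "transfer", "reverse"],
        ).to_csv(d / "contrasts.tsv", sep="\t", index=False, float_format="%.6f")
        _finish(
            "ks_contrast",
            n_pairs=len(contrasts),
            n_flagged=sum(1 for c in contrasts if c.transfer_flag is True),
        )
    except PipelineError:
        raise
    except Exception as exc:
        stage = report["stages"][-1]["name"] if report["stages"] else "input"
        raise PipelineError(f"after:{stage}", str(exc)) from exc

    # ---- manifest
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "report.json":
            report["manifest"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    _log.info("run_pipeline: %d stages complete", len(report["stages"]))
    return report
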