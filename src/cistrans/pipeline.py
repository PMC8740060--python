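"""End-to-end orchestration of the synthetic pipeline with a run manifest.

``run_pipeline`` executes the enabled stages in dependency order —
simulate -> classify / inherit -> distribution -> noncoding -> protein —
writing every result table to the output directory plus a machine-readable
``manifest.json`` (parameters, package version, SHA-256 of every output),
so two runs with the same configuration and seed produce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .ase import adjust_depth
from .distribution import chromosome_density, detect_clusters
from .divergence import classify_regulatory_divergence, summarize_cis_effects
from .inheritance import classify_inheritance_table, compare_inheritance_spectra
from .io import write_loci_bed, write_panel_fasta, write_table
from .noncoding import window_ladder_counts
from .protein import diagnostic_haplotypes, find_fixed_aa_substitutions
from .simulate import (
    GENERATIVE_CATEGORIES,
    SimulationConfig,
    simulate_alignment_panel,
    simulate_gene_annotation,
    simulate_inheritance_counts,
    simulate_regulatory_counts,
)

__all__ = ["default_config", "run_pipeline"]

log = logging.getLogger("cistrans")
_ALL_STAGES = ("simulate", "classify", "inherit", "distribution", "noncoding", "protein")


def default_config(seed: int = 42, out_dir: str = "cistrans_run") -> dict:
    """The packaged demo configuration: a full synthetic run."""
    return {
        "out_dir": out_dir,
        "seed": seed,
        "stages": list(_ALL_STAGES),
        "alpha": 0.005,
        "de_alpha": 0.05,
        "lfc_threshold": 1.0,
        "min_reads": 20,
        "max_gap": 5500,
        "window_ladder": [500, 1000, 2000, 3000],
        "simulate": {
            "n_genes": 300,
            "category_proportions": {k: 0.2 for k in GENERATIVE_CATEGORIES},
            "cis_fold_range": [4.0, 4.0],
            "trans_fold_range": [4.0, 4.0],
            "base_mean_range": [500.0, 500.0],
            "dispersion": 0.05,
            "n_replicates": 3,
        },
        "annotation": {
            "n_genes": 60,
            "chromosome_lengths": {"X": 20_000_000, "2": 12_000_000},
            "planted_clusters": [["X", 1251], ["2", 5202]],
        },
        "inheritance": {
            "n_genes": 100,
            "mode_proportions": {
                "transgressive_up": 0.25,
                "transgressive_down": 0.25,
                "additive": 0.25,
                "non_differential": 0.25,
            },
            "fold": 4.0,
            "depth": 500.0,
        },
        "panels": {
            "noncoding": {"n_strains_a": 31, "n_strains_b": 5, "length": 3200,
                          "n_fixed": 6, "n_poly_a": 8, "n_poly_b": 3},
            "protein": {"n_strains_a": 31, "n_strains_b": 5, "length": 199,
                        "n_fixed": 7, "n_poly_a": 4, "n_poly_b": 2},
        },
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_log(stage: str, n_in: int, n_out: int) -> None:
    log.info("stage %-12s in=%d out=%d", stage, n_in, n_out)


def run_pipeline(config: dict) -> dict:
    """Run the enabled stages and return the manifest dict."""
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", _ALL_STAGES))
    unknown = set(stages) - set(_ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outputs: dict[str, Path] = {}

    counts = truth = None
    if "simulate" in stages:
        sim = SimulationConfig(seed=seed, **config["simulate"])
        counts, truth = simulate_regulatory_counts(sim)
        truth_df = pd.DataFrame(
            [(t.gene_id, t.true_category, t.c, t.t) for t in truth],
            columns=["gene_id", "true_category", "c", "t"],
        )
        write_table(counts, out_dir / "gene_allele_counts.tsv")
        write_table(truth_df, out_dir / "truth_regulatory.tsv")
        outputs["gene_allele_counts"] = out_dir / "gene_allele_counts.tsv"
        outputs["truth_regulatory"] = out_dir / "truth_regulatory.tsv"
        _stage_log("simulate", sim.n_genes, len(counts))

    if "classify" in stages:
        if counts is None:
            counts_path = config.get("counts_path")
            if not counts_path or not Path(counts_path).exists():
                raise ValueError(
                    "stage 'classify' needs stage 'simulate' or a counts_path"
                )
            counts = pd.read_csv(counts_path, sep="\t")
        # synthetic libraries share one depth: equal class totals, so the
        # adjustment reduces to the 0 -> 1 floor.  Real runs read library
        # totals from a class-total table (see the `ase` CLI subcommand).
        totals = config.get(
            "class_totals", {c: 1.0 for c in ("P_pse", "P_bog", "H_pse", "H_bog")}
        )
        adjusted = adjust_depth(counts, totals)
        adjusted = adjusted[adjusted["raw_total"] >= config.get("min_reads", 20)]
        tests, calls = classify_regulatory_divergence(adjusted, alpha=config.get("alpha", 0.005))
        fraction, tallies = summarize_cis_effects(calls)
        results = tests.merge(calls, on="gene_id")
        write_table(results, out_dir / "regulatory_divergence.tsv")
        summary = tallies.rename_axis("category").reset_index(name="n_genes")
        summary["cis_effect_fraction"] = fraction
        write_table(summary, out_dir / "category_summary.tsv")
        outputs["regulatory_divergence"] = out_dir / "regulatory_divergence.tsv"
        outputs["category_summary"] = out_dir / "category_summary.tsv"
        _stage_log("classify", len(adjusted), len(calls))

    if "inherit" in stages:
        inh = config["inheritance"]
        pa, pb, hy, modes = simulate_inheritance_counts(
            n_genes=inh["n_genes"],
            mode_proportions=inh["mode_proportions"],
            fold=inh.get("fold", 4.0),
            depth=inh.get("depth", 500.0),
            dispersion=inh.get("dispersion", 0.05),
            n_replicates=inh.get("n_replicates", 3),
            seed=seed,
        )
        calls = classify_inheritance_table(
            hy, pa, pb,
            alpha=config.get("de_alpha", 0.05),
            lfc_threshold=config.get("lfc_threshold", 1.0),
        )
        calls["true_mode"] = modes
        write_table(calls, out_dir / "inheritance_calls.tsv")
        outputs["inheritance_calls"] = out_dir / "inheritance_calls.tsv"
        table, p = compare_inheritance_spectra(
            calls["mode"], calls["true_mode"], collapse="three-way"
        )
        report = table.reset_index(names="group")
        report["fisher_p"] = p
        write_table(report, out_dir / "inheritance_spectrum.tsv")
        outputs["inheritance_spectrum"] = out_dir / "inheritance_spectrum.tsv"
        _stage_log("inherit", inh["n_genes"], len(calls))

    if "distribution" in stages:
        ann = config["annotation"]
        loci = simulate_gene_annotation(
            n_genes=ann["n_genes"],
            chromosome_lengths=ann["chromosome_lengths"],
            planted_clusters=[tuple(c) for c in ann.get("planted_clusters", [])],
            seed=seed,
        )
        write_loci_bed(loci, out_dir / "loci.bed")
        outputs["loci"] = out_dir / "loci.bed"
        clusters = detect_clusters(loci, max_gap=config.get("max_gap", 5500))
        cdf = pd.DataFrame(
            [
                (";".join(c.gene_ids), c.chromosome, ";".join(map(str, c.gaps)))
                for c in clusters
            ],
            columns=["gene_ids", "chromosome", "gaps_bp"],
        )
        write_table(cdf, out_dir / "clusters.tsv")
        outputs["clusters"] = out_dir / "clusters.tsv"
        obs = {}
        for l in loci:
            obs[l.chromosome] = obs.get(l.chromosome, 0) + 1
        lengths_mb = {k: v / 1e6 for k, v in ann["chromosome_lengths"].items()}
        dens = chromosome_density(obs, lengths_mb)
        write_table(
            pd.DataFrame(sorted(dens.items()), columns=["chromosome", "targets_per_mb"]),
            out_dir / "density.tsv",
        )
        outputs["density"] = out_dir / "density.tsv"
        _stage_log("distribution", len(loci), len(clusters))

    if "noncoding" in stages:
        panel_cfg = config["panels"]["noncoding"]
        panel, nc_truth = simulate_alignment_panel(
            alphabet="nucleotide", seed=seed, **panel_cfg
        )
        write_panel_fasta(panel, out_dir / "noncoding_panel.fasta")
        outputs["noncoding_panel"] = out_dir / "noncoding_panel.fasta"
        tss_column = panel_cfg["length"] - 200 + 1  # panel built to -upstream..+200
        ladder = window_ladder_counts(
            panel, tss_column, ladder=config.get("window_ladder", [500, 1000, 2000, 3000])
        )
        write_table(ladder, out_dir / "noncoding_windows.tsv")
        outputs["noncoding_windows"] = out_dir / "noncoding_windows.tsv"
        _stage_log("noncoding", panel.length, len(ladder))

    if "protein" in stages:
        panel_cfg = config["panels"]["protein"]
        panel, _ = simulate_alignment_panel(alphabet="protein", seed=seed + 1, **panel_cfg)
        write_panel_fasta(panel, out_dir / "protein_panel.fasta")
        outputs["protein_panel"] = out_dir / "protein_panel.fasta"
        subs = find_fixed_aa_substitutions(panel, protein_id="candidate")
        separating, positions = diagnostic_haplotypes(panel)
        sdf = pd.DataFrame(
            [(s.protein_id, s.position, s.residue_pse, s.residue_bog, s.label) for s in subs],
            columns=["protein_id", "position", "residue_pse", "residue_bog", "label"],
        )
        sdf["haplotypes_separate"] = separating
        write_table(sdf, out_dir / "protein_substitutions.tsv")
        outputs["protein_substitutions"] = out_dir / "protein_substitutions.tsv"
        _stage_log("protein", panel.length, len(subs))

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "parameters": {
            k: v for k, v in config.items() if k not in ("out_dir", "stages")
        },
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
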