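"""End-to-end synthetic-mode pipeline driver.

Chains every stage on generated data with known ground truth: time-series
panels -> FDR-thresholded Fisher-z graphs -> merging trajectories and
segregator/integrator maps -> region-level S-I phenotype map -> planted
expression screen with variogram-matched surrogate nulls -> surrogate-
calibrated enrichment with kappa clustering -> dN/dS curve regression with
a gene-list permutation null. A single master seed determines every
stochastic stage through per-stage derived sub-seeds, and a manifest of
config, seeds and output checksums makes runs byte-reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .connectivity import subject_graph
from .enrichment import cluster_terms, enrich, kappa_matrix
from .evolution import (
    annotation_species_means,
    compute_ratios,
    fit_curve_families,
    permutation_corrected_p,
)
from .merging import (
    PhenotypeMap,
    fit_trajectory_models,
    group_classification,
    group_maps,
    run_merging,
)
from .synthetic import (
    SimDnDsSpec,
    SimExpressionSpec,
    aggregate_node_map,
    assign_nodes_to_regions,
    gen_dnds_table,
    gen_expression_matrix,
    gen_gene_sets,
    gen_region_geometry,
    gen_timeseries_panel,
    modular_panel_spec,
)
from .transcriptome import make_surrogates, screen_genes, surrogate_selections

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Reproducible, stage-independent sub-seed from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    """All thresholds and scales of the analysis chain.

    Statistical defaults mirror the study constants (edge FDR q, the
    +/-1.96 SD gene selection, 1000 surrogate maps, term-size bounds
    [5, 2000], minimum overlap 3, enrichment prefilter p 0.01, kappa 0.3,
    100 permutations); synthetic-scale defaults are the package's
    desk-scale study conditions.
    """

    seed: int = 0
    # connectivity
    q_fdr: float = 0.001
    # gene screen
    sd_multiplier: float = 1.96
    n_surrogates: int = 1000
    # enrichment
    kappa_threshold: float = 0.3
    term_size_min: int = 5
    term_size_max: int = 2000
    min_overlap: int = 3
    prefilter_p: float = 0.01
    enrichment_fdr_q: float = 0.05
    # evolution
    n_permutations: int = 100
    # synthetic scale
    n_modules: int = 8
    module_size: int = 20
    n_integrators: int = 8
    n_background: int = 32
    n_subjects: int = 10
    n_timepoints: int = 300
    n_regions: int = 68
    n_genes: int = 2000
    n_planted_pos: int = 25
    n_planted_neg: int = 25
    target_abs_r: float = 0.8
    n_terms: int = 100
    term_size_range: tuple[int, int] = (10, 200)
    planted_term_background: int = 15

    def validate(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if not (0 < self.q_fdr < 1):
            raise ValueError("q_fdr must be in (0,1)")
        if not (0 < self.enrichment_fdr_q < 1):
            raise ValueError("enrichment_fdr_q must be in (0,1)")
        if not (0 < self.prefilter_p < 1):
            raise ValueError("prefilter_p must be in (0,1)")
        if not (-1 < self.kappa_threshold < 1):
            raise ValueError("kappa_threshold must be in (-1,1)")
        if self.n_surrogates < 1 or self.n_permutations < 1:
            raise ValueError("n_surrogates and n_permutations must be >= 1")
        if self.term_size_min < 1 or self.term_size_max < self.term_size_min:
            raise ValueError("invalid term size bounds")
        n_nodes = self.n_modules * self.module_size + self.n_integrators + self.n_background
        if n_nodes < self.n_regions:
            raise ValueError("need at least one node per region")

    @property
    def n_nodes(self) -> int:
        return self.n_modules * self.module_size + self.n_integrators + self.n_background


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: derive_seed(config.seed, stage)
        for stage in ("panel", "geometry", "expression", "genesets", "surrogates",
                      "enrichment", "dnds", "permutation")
    }
    written: list[Path] = []

    def save(fn, *args):
        fn(*args)
        written.append(Path(args[-1]))

    # --- stage 1: synthetic panels -------------------------------------
    spec = modular_panel_spec(
        n_modules=config.n_modules,
        module_size=config.module_size,
        n_integrators=config.n_integrators,
        n_background=config.n_background,
        n_timepoints=config.n_timepoints,
        n_subjects=config.n_subjects,
        seed=seeds["panel"],
    )
    panels, node_truth = gen_timeseries_panel(spec)
    (out / "panels").mkdir(exist_ok=True)
    for p in panels:
        save(io.write_panel, p, out / "panels" / f"{p.subject_id}.tsv")
    save(io.write_json, node_truth, out / "node_truth.json")

    # --- stage 2+3: graphs, merging, classification --------------------
    (out / "graphs").mkdir(exist_ok=True)
    (out / "classification").mkdir(exist_ok=True)
    classifications = []
    for p in panels:
        g = subject_graph(p, q=config.q_fdr)
        save(io.write_edge_list, g, out / "graphs" / f"{p.subject_id}_edges.tsv")
        traj = run_merging(g)
        cls = fit_trajectory_models(traj)
        classifications.append(cls)
        df = pd.DataFrame(
            {
                "node": cls.node_ids,
                "r2_log": cls.r2_log,
                "r2_exp": cls.r2_exp,
                "score": cls.score,
                "label": cls.labels,
            }
        )
        save(lambda d, pth: d.to_csv(pth, sep="\t", index=False), df,
             out / "classification" / f"{p.subject_id}.tsv")
    s_map, i_map, si_map = group_maps(classifications)
    group_labels = group_classification(classifications)
    (out / "maps").mkdir(exist_ok=True)
    save(io.write_map, s_map, out / "maps" / "S_nodes.tsv")
    save(io.write_map, i_map, out / "maps" / "I_nodes.tsv")
    save(io.write_map, si_map, out / "maps" / "S_minus_I_nodes.tsv")

    # --- stage 4: region geometry and region-level phenotype map -------
    geom = gen_region_geometry(config.n_regions, seed=seeds["geometry"])
    save(io.write_geometry, geom, out / "geometry.tsv")
    assignment = assign_nodes_to_regions(si_map.region_ids, geom.region_ids)
    region_map = aggregate_node_map(si_map, assignment, geom.region_ids)
    save(io.write_map, region_map, out / "maps" / "S_minus_I_regions.tsv")

    # --- stage 5: expression with planted genes ------------------------
    expr_spec = SimExpressionSpec(
        n_genes=config.n_genes,
        planted_pos=config.n_planted_pos,
        planted_neg=config.n_planted_neg,
        target_abs_r=config.target_abs_r,
        seed=seeds["expression"],
    )
    expr, gene_truth = gen_expression_matrix(region_map, geom, expr_spec)
    save(io.write_matrix, expr, out / "expression.tsv")
    save(io.write_json, gene_truth, out / "gene_truth.json")

    # --- stage 6: gene sets with one planted term ----------------------
    planted_pos = [g for g, lab in gene_truth.items() if lab == "planted_pos"]
    background = [g for g, lab in gene_truth.items() if lab == "background"]
    planted_term = planted_pos + background[: config.planted_term_background]
    collection = gen_gene_sets(
        list(expr.index),
        n_terms=config.n_terms,
        size_range=config.term_size_range,
        planted_term_genes=planted_term,
        seed=seeds["genesets"],
    )
    save(io.write_gmt, collection, out / "genesets.gmt")

    # --- stage 7: gene screen with surrogate calibration ----------------
    screen, ensemble = screen_genes(
        region_map,
        expr,
        geom,
        sd_multiplier=config.sd_multiplier,
        n_surrogates=config.n_surrogates,
        seed=seeds["surrogates"],
    )
    (out / "screen").mkdir(exist_ok=True)
    screen_df = pd.DataFrame(
        {
            "gene": screen.r.index,
            "r": screen.r.to_numpy(),
            "empirical_p": screen.empirical_p.reindex(screen.r.index).to_numpy(),
        }
    )
    screen_df["tail"] = np.where(
        screen_df["gene"].isin(screen.upper_genes), "upper",
        np.where(screen_df["gene"].isin(screen.lower_genes), "lower", "none"),
    )
    save(lambda d, pth: d.to_csv(pth, sep="\t", index=False), screen_df,
         out / "screen" / "gene_screen.tsv")
    screen_summary = {
        "mean_r": screen.mean_r,
        "sd_r": screen.sd_r,
        "sd_multiplier": screen.sd_multiplier,
        "upper_cutoff": screen.upper_cutoff,
        "lower_cutoff": screen.lower_cutoff,
        "null_upper_cutoff": screen.null_upper_cutoff,
        "null_lower_cutoff": screen.null_lower_cutoff,
        "cutoffs_exceed_null": screen.cutoffs_exceed_null,
        "n_upper": len(screen.upper_genes),
        "n_lower": len(screen.lower_genes),
        "n_surrogates": screen.n_surrogates,
        "surrogate_smoothing_scale_mm": ensemble.smoothing_scale_mm,
    }
    save(io.write_json, screen_summary, out / "screen" / "summary.json")

    # --- stage 8: enrichment (upper and lower lists separately) ---------
    surr_upper, surr_lower = surrogate_selections(
        ensemble, expr, geom.region_ids, screen.upper_cutoff, screen.lower_cutoff
    )
    (out / "enrichment").mkdir(exist_ok=True)
    enrichment_results = {}
    clusters_out = {}
    for tail, selection, surr in (
        ("upper", screen.upper_genes, surr_upper),
        ("lower", screen.lower_genes, surr_lower),
    ):
        if not selection:
            logger.warning("no genes selected on the %s tail; skipping enrichment", tail)
            enrichment_results[tail] = pd.DataFrame(
                columns=["term", "size", "overlap", "fold", "fisher_p",
                         "prefiltered", "empirical_p", "fdr_p", "passed"]
            )
            save(lambda d, pth: d.to_csv(pth, sep="\t", index=False),
                 enrichment_results[tail], out / "enrichment" / f"{tail}.tsv")
            clusters_out[tail] = {"clusters": [], "representatives": []}
            continue
        res = enrich(
            selection,
            collection,
            surrogate_selections=surr,
            min_size=config.term_size_min,
            max_size=config.term_size_max,
            min_overlap=config.min_overlap,
            prefilter_p=config.prefilter_p,
            fdr_q=config.enrichment_fdr_q,
            seed=seeds["enrichment"],
        )
        enrichment_results[tail] = res
        save(lambda d, pth: d.to_csv(pth, sep="\t", index=False), res,
             out / "enrichment" / f"{tail}.tsv")
        passed = res[res.passed]["term"].tolist()
        if len(passed) >= 2:
            kap = kappa_matrix(collection, passed)
            term_p = res.set_index("term")["empirical_p"]
            cl = cluster_terms(kap, term_p, kappa_threshold=config.kappa_threshold)
            clusters_out[tail] = {
                "clusters": cl.clusters,
                "representatives": cl.representatives,
            }
        else:
            clusters_out[tail] = {"clusters": [passed] if passed else [],
                                  "representatives": passed}
    save(io.write_json, clusters_out, out / "enrichment" / "clusters.json")

    # --- stage 9: dN/dS evolution regression ----------------------------
    dnds_spec = SimDnDsSpec(seed=seeds["dnds"])
    dnds = gen_dnds_table(dnds_spec, list(expr.index))
    (out / "evolution").mkdir(exist_ok=True)
    save(lambda d, pth: d.to_csv(pth, sep="\t", index=False), dnds,
         out / "evolution" / "dnds.tsv")
    ratios = compute_ratios(dnds)
    species = sorted(dnds_spec.species_times)
    times = np.array([dnds_spec.species_times[s] for s in species])
    fit_rows = []
    for tail in ("upper", "lower"):
        for term in clusters_out[tail]["representatives"]:
            genes = collection.terms[term]
            means = annotation_species_means(ratios, genes).reindex(species)
            fit = fit_curve_families(times, means.to_numpy())
            perm = permutation_corrected_p(
                fit, ratios, genes, collection.universe, dnds_spec.species_times,
                n_iter=config.n_permutations, seed=seeds["permutation"],
            )
            best = fit.best
            fit_rows.append(
                {
                    "tail": tail,
                    "term": term,
                    "n_genes": len(genes),
                    "best_family": fit.best_family,
                    "coefficients": ",".join(f"{c:.8g}" for c in best.coef),
                    "r2": best.r2,
                    "f_stat": best.f_stat,
                    "p": best.p,
                    "perm_z": perm.z,
                    "perm_corrected_p": perm.corrected_p,
                    "n_permutations": perm.n_iterations,
                }
            )
    fits_df = pd.DataFrame(fit_rows)
    save(lambda d, pth: d.to_csv(pth, sep="\t", index=False), fits_df,
         out / "evolution" / "fits.tsv")

    # --- manifest --------------------------------------------------------
    n_correct = int(
        sum(
            group_labels[i] == node_truth[nid]
            for i, nid in enumerate(si_map.region_ids)
            if node_truth[nid] in ("segregator", "integrator")
        )
    )
    n_labeled = sum(1 for v in node_truth.values() if v in ("segregator", "integrator"))
    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stage_seeds": seeds,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
        "summary": {
            "n_nodes": config.n_nodes,
            "node_label_accuracy": n_correct / max(n_labeled, 1),
            "screen": screen_summary,
            "n_terms_passed": {t: int(enrichment_results[t].passed.sum())
                               for t in ("upper", "lower")},
            "representatives": {t: clusters_out[t]["representatives"]
                                for t in ("upper", "lower")},
            "evolution": fit_rows,
        },
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
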