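"""End-to-end pipeline driver.

Chains the analysis stages in the order of the underlying study design —
count filter, normalisation, diversity/NMDS/ANOSIM, expressed-gene filter,
differential expression, co-expression network and seed neighbourhoods,
molar proportions, the OTU-SCFA screen, CCA, genus centroids, and the
headline association signs — writing every intermediate artifact plus a
machine-readable manifest.  Runs are idempotent for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import __version__, io
from .abundance import aggregate_taxa, detectable_otus, filter_min_count, group_overlap, relative_abundance
from .coexpression import coexpression_network, seed_neighborhood
from .diversity import alpha_diversity, anosim, bray_curtis, diversity_group_test, nmds
from .errors import PipelineStageError, RumenomicsError
from .expression import differential_expression, expressed_genes, family_expression_summary
from .integration import (
    association_signs,
    cca,
    genus_centroids,
    molar_proportions,
    otu_scfa_screen,
    scfa_group_stats,
)
from .synthetic import simulate_study

logger = logging.getLogger(__name__)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except RumenomicsError:
                raise
            except Exception as exc:  # attribute unexpected failures to the stage
                raise PipelineStageError(name, str(exc)) from exc
        inner.__name__ = fn.__name__
        return inner
    return wrap


def run_pipeline(cfg: io.PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json`` in the output directory).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "rumenomics",
        "version": __version__,
        "config": cfg.to_dict(),
        "stages": {},
        "outputs": [],
    }

    def emit(name, writer):
        writer(out / name)
        manifest["outputs"].append(name)

    # ---- inputs ---------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.simulate is not None:
            study = simulate_study(cfg.simulate)
            table, expr, scfa = study.otu_table, study.expression, study.scfa
            emit("otu_counts.tsv", lambda p: io.write_otu_counts(table, p))
            emit("taxonomy.tsv", lambda p: io.write_taxonomy(table.taxonomy, p))
            emit("metadata.tsv", lambda p: io.write_metadata(table.groups, p))
            emit("expression.tsv", lambda p: io.write_expression(
                expr, p, out / "gene_families.tsv"))
            manifest["outputs"].append("gene_families.tsv")
            emit("scfa.csv", lambda p: io.write_scfa(scfa, p))
            emit("truth.json", lambda p: io.write_json(study.truth.to_dict(), p))
            seeds = sorted(
                g for g, fam in expr.families.items() if fam in ("GPR", "HDAC")
            )
        else:
            try:
                table = io.read_otu_table(cfg.otu_counts, cfg.taxonomy, cfg.metadata)
            except (RumenomicsError, OSError) as exc:
                raise PipelineStageError("otu_table", str(exc)) from exc
            try:
                expr = io.read_expression(cfg.expression, cfg.gene_families, cfg.metadata)
            except (RumenomicsError, OSError) as exc:
                raise PipelineStageError("expression", str(exc)) from exc
            try:
                scfa = io.read_scfa(cfg.scfa, cfg.metadata)
            except (RumenomicsError, OSError) as exc:
                raise PipelineStageError("scfa", str(exc)) from exc
            ids = set(table.sample_ids)
            for name, other in (("expression", set(expr.sample_ids)),
                                ("scfa", set(scfa.sample_ids))):
                if other != ids:
                    raise PipelineStageError(
                        name,
                        f"sample-id mismatch vs OTU table: missing {sorted(ids - other)}, "
                        f"extra {sorted(other - ids)}",
                    )
            seeds = sorted(
                g for g, fam in expr.families.items() if fam in ("GPR", "HDAC")
            )
        manifest["stages"][stage] = {
            "n_samples": len(table.sample_ids),
            "n_otus": len(table.otu_ids),
            "n_genes": len(expr.gene_ids),
        }
    except PipelineStageError:
        raise
    except RumenomicsError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- community structure -------------------------------------------
    stage = "abundance"
    try:
        filtered = filter_min_count(table, cfg.min_count)
        abund = relative_abundance(filtered)
        detectable = detectable_otus(abund, cfg.detectable_threshold)
        by_genus = aggregate_taxa(abund, "genus")
        by_phylum = aggregate_taxa(abund, "phylum")
        overlap = group_overlap(by_genus)
        manifest["stages"][stage] = {
            "otus_in": len(table.otu_ids),
            "otus_after_count_filter": len(filtered.otu_ids),
            "n_detectable": len(detectable),
            "genus_overlap": {k: len(v) for k, v in overlap.items()},
        }
        emit("abundance_otu.tsv", lambda p: abund.fractions.to_csv(p, sep="\t"))
        emit("abundance_genus.tsv", lambda p: by_genus.fractions.to_csv(p, sep="\t"))
        emit("abundance_phylum.tsv", lambda p: by_phylum.fractions.to_csv(p, sep="\t"))
    except RumenomicsError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- diversity and ordination ---------------------------------------
    stage = "diversity"
    try:
        alpha = alpha_diversity(abund)
        alpha_p = diversity_group_test(alpha, abund.groups)
        dist = bray_curtis(abund)
        ordination = nmds(dist, k=cfg.nmds_k, n_starts=cfg.nmds_starts, seed=cfg.seed)
        sep = anosim(dist, abund.groups, n_perm=cfg.anosim_permutations, seed=cfg.seed)
        manifest["stages"][stage] = {
            "shannon_p": float(alpha_p.loc["shannon", "p"]),
            "simpson_p": float(alpha_p.loc["simpson", "p"]),
            "nmds_stress": ordination.stress,
            "anosim_r": sep.r,
            "anosim_p": sep.p_value,
        }
        emit("alpha_diversity.tsv", lambda p: alpha.to_csv(p, sep="\t"))
        emit("bray_curtis.tsv", lambda p: io.write_distance_matrix(dist, p))
        emit("nmds_coordinates.tsv",
             lambda p: ordination.coordinates.to_csv(p, sep="\t"))
    except RumenomicsError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- expression ------------------------------------------------------
    stage = "expression"
    try:
        expressed = expressed_genes(expr, cfg.min_rpkm)
        g1, g2 = sorted(set(expr.groups))
        de = differential_expression(
            expr, numerator=g2, reference=g1,
            alpha=cfg.de_alpha, adjust=cfg.de_adjust, expressed=expressed,
        )
        summary = family_expression_summary(expr, expressed)
        manifest["stages"][stage] = {
            "n_expressed": len(expressed),
            "n_significant": int(de["significant"].sum()),
            "comparison": f"{g2} vs {g1}",
        }
        emit("differential_expression.tsv", lambda p: de.to_csv(p, sep="\t"))
        emit("family_summary.tsv", lambda p: summary.to_csv(p, sep="\t"))
    except RumenomicsError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- co-expression network ------------------------------------------
    stage = "coexpression"
    try:
        net = coexpression_network(
            expr, rho_min=cfg.coexpr_rho_min, p_max=cfg.coexpr_p_max,
            absolute=cfg.coexpr_absolute, min_rpkm=cfg.min_rpkm,
        )
        neighborhood = seed_neighborhood(net, seeds, de)
        manifest["stages"][stage] = {
            "n_nodes": len(net.nodes),
            "n_edges": net.n_edges,
            "n_seed_genes": len(seeds),
            "neighborhood_nodes": neighborhood.number_of_nodes(),
            "neighborhood_edges": neighborhood.number_of_edges(),
        }
        emit("coexpression_edges.tsv",
             lambda p: io.write_network(net, p, out / "coexpression.graphml"))
        manifest["outputs"].append("coexpression.graphml")
        rows = [{"gene1": u, "gene2": v, **d} for u, v, d in neighborhood.edges(data=True)]
        emit("seed_neighborhood_edges.tsv", lambda p: pd.DataFrame(
            rows, columns=["gene1", "gene2", "rho", "p", "method"]).to_csv(
            p, sep="\t", index=False))
    except RumenomicsError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- integration -----------------------------------------------------
    stage = "integration"
    try:
        props = molar_proportions(scfa, cfg.proportion_time)
        stats = scfa_group_stats(scfa, cfg.proportion_time)
        screen = otu_scfa_screen(
            abund, props, rho_min=cfg.screen_rho_min, p_max=cfg.screen_p_max,
            absolute=cfg.screen_absolute,
        )
        de_seeds = [g for g in seeds if g in de.index and bool(de.loc[g, "significant"])]
        constraint_genes = de_seeds if de_seeds else [g for g in seeds if g in expr.rpkm.index]
        constraints = pd.concat(
            [props, expr.rpkm.loc[constraint_genes].T.reindex(props.index)], axis=1
        )
        retained = sorted(screen.retained)
        manifest["stages"][stage] = {
            "otus_screened": screen.n_input,
            "otus_retained": screen.n_retained,
            "removed_fraction": screen.removed_fraction,
            "n_constraints": constraints.shape[1],
        }
        emit("molar_proportions.tsv", lambda p: props.to_csv(p, sep="\t"))
        emit("scfa_stats.tsv", lambda p: stats.to_csv(p, sep="\t", index=False))
        emit("screen_retained.tsv", lambda p: screen.best.to_csv(p, sep="\t", index=False))
        if retained:
            y = abund.fractions[retained]
            result = cca(y, constraints.loc[y.index], standardize=cfg.cca_standardize)
            centroids = genus_centroids(result, table.taxonomy)
            manifest["stages"][stage].update(
                {
                    "cca_rank": result.rank,
                    "total_inertia": result.total_inertia,
                    "constrained_inertia": result.constrained_inertia,
                    "unconstrained_inertia": result.unconstrained_inertia,
                }
            )
            emit("cca_eigenvalues.tsv", lambda p: pd.Series(
                result.eigenvalues,
                index=[f"CCA{i + 1}" for i in range(len(result.eigenvalues))],
                name="eigenvalue").to_csv(p, sep="\t"))
            emit("cca_site_scores_lc.tsv",
                 lambda p: result.site_scores_lc.to_csv(p, sep="\t"))
            emit("cca_site_scores_wa.tsv",
                 lambda p: result.site_scores_wa.to_csv(p, sep="\t"))
            emit("cca_species_scores.tsv",
                 lambda p: result.species_scores.to_csv(p, sep="\t"))
            emit("cca_biplot_scores.tsv",
                 lambda p: result.biplot_scores.to_csv(p, sep="\t"))
            emit("cca_genus_centroids.tsv", lambda p: centroids.to_csv(p, sep="\t"))
        by_genus_named = by_genus
        pairs = []
        if "HDAC1" in expr.rpkm.index:
            pairs.append(("butyrate", "HDAC1"))
        if "GPR1" in expr.rpkm.index and "Clostridium_IV" in by_genus_named.fractions.columns:
            pairs.append(("Clostridium_IV", "GPR1"))
        if pairs:
            assoc = association_signs(props, expr, by_genus_named, pairs)
            manifest["stages"][stage]["associations"] = {
                f"{r.var1}~{r.var2}": {"rho": r.rho, "p": r.p, "sign": int(r.sign)}
                for r in assoc.itertuples()
            }
            emit("association_signs.tsv", lambda p: assoc.to_csv(p, sep="\t", index=False))
    except RumenomicsError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    io.write_json(manifest, out / "manifest.json")
    manifest["outputs"].append("manifest.json")
    logger.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest
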