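"""End-to-end driver: simulate inputs, run every analysis stage, summarise.

This is the orchestration layer the command line, the analysis scripts
and the acceptance checks all share. It generates the synthetic inputs
(or reuses a directory of them), runs each stage *from the files on
disk* — so the format round trip is exercised, not just the in-memory
objects — and writes one results directory plus a machine-readable
summary.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .express import ExpressionTable, fold_change, hypergeom_enrich, set_mean_fold
from .famdom import FamilyMatrix, domain_census, family_venn, group_specific_families
from .phylostrat import PhylostrataLadder, aggregate_eras, assign_all, default_eras
from .rare import bin_distances, genes_near_rare, rare_summary, scan_rare, tss_distances
from .seqstats import dense_ranks, gc3_records, rank_gc3, scaffold_stats
from .synthio import SyntheticManifest, simulate

__all__ = ["run_pipeline"]


def run_pipeline(
    config: Mapping | None = None,
    seed: int = 0,
    outdir: str | Path = "pipeline_out",
) -> dict:
    """Run the whole synthetic analysis and return headline numbers.

    Inputs are written under ``outdir/inputs`` and stage outputs under
    ``outdir/results``; the returned dict is also saved as
    ``results/summary.json``.
    """
    outdir = Path(outdir)
    simdir = outdir / "inputs"
    resdir = outdir / "results"
    resdir.mkdir(parents=True, exist_ok=True)

    manifest = simulate(config, seed=seed, outdir=simdir)
    results: dict[str, float | int] = {}

    # ------------------------------------------------------------------
    # assembly summary
    genome = mio.read_fasta(simdir / "genome.fasta")
    stats = scaffold_stats(genome.values())
    pd.DataFrame(
        [
            {
                "n_scaffolds": stats.n_scaffolds,
                "total_bp": stats.total_bp,
                "n50": stats.n50,
                "gap_fraction": stats.gap_fraction,
                "gc_overall": stats.gc_overall,
            }
        ]
    ).to_csv(resdir / "assembly_stats.tsv", sep="\t", index=False)
    results["n_scaffolds"] = stats.n_scaffolds
    results["assembly_mbp"] = stats.total_bp / 1e6
    results["n50_mbp"] = stats.n50 / 1e6
    results["gap_pct"] = 100.0 * stats.gap_fraction

    # ------------------------------------------------------------------
    # GC3 ranking
    cds = mio.read_fasta(simdir / "cds.fasta")
    records = gc3_records(cds)
    ranks = dense_ranks(records)
    table = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_codons_used": r.n_codons_used,
                "gc3": r.gc3,
                "rank": ranks.get(r.gene_id),
            }
            for r in records
        ]
    ).sort_values(["rank", "gene_id"])
    table.to_csv(resdir / "gc3.tsv", sep="\t", index=False, float_format="%.6f")
    planted_high = set(manifest.extras["gc3_high_set"])
    top = rank_gc3(records, top_n=len(planted_high))
    (resdir / "gc3_top.txt").write_text("\n".join(top) + "\n")
    results["gc3_top100_planted_recovery_pct"] = (
        100.0 * len(set(top) & planted_high) / len(planted_high)
    )

    # ------------------------------------------------------------------
    # phylostratigraphy
    ladder = PhylostrataLadder.from_yaml(simdir / "ladder.yaml")
    hits = mio.read_tsv(simdir / "hits.tsv")
    lengths = dict(
        mio.read_tsv(simdir / "protein_lengths.tsv").itertuples(index=False)
    )
    assignments = assign_all(hits, lengths, ladder)
    pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "length_aa": a.length_aa,
                "ps_index": "EXCLUDED" if a.excluded else a.ps_index,
                "basis_species": a.basis_hit[0] if a.basis_hit else "",
                "basis_e_value": a.basis_hit[1] if a.basis_hit else "",
            }
            for a in assignments
        ]
    ).to_csv(resdir / "age_assignments.tsv", sep="\t", index=False)
    era = aggregate_eras(assignments, default_eras())
    pd.DataFrame(
        [
            {
                "era": e.label,
                "ps_range": f"{e.ps_min}-{e.ps_max}",
                "start_mya": e.start_mya,
                "end_mya": e.end_mya,
                "count": era.counts[e.label],
                "proportion": era.proportions[e.label],
                "genes_per_my": era.rates[e.label],
            }
            for e in era.eras
        ]
    ).to_csv(resdir / "era_summary.tsv", sep="\t", index=False, float_format="%.8g")
    truth_ages = manifest.gene_ages
    assessed = [a for a in assignments if not a.excluded]
    n_match = sum(1 for a in assessed if truth_ages[a.protein_id] == a.ps_index)
    results["phylostrat_planted_age_recovery_pct"] = 100.0 * n_match / len(assessed)
    results["pct_ancient"] = 100.0 * era.proportions["ancient"]
    results["pct_middle"] = 100.0 * era.proportions["middle"]
    results["pct_young"] = 100.0 * era.proportions["young"]
    results["n_proteins_excluded_short"] = era.n_excluded
    results["young_turnover_genes_per_my"] = era.rates["young"]
    results["ancient_turnover_genes_per_my"] = era.rates["ancient"]

    # ------------------------------------------------------------------
    # response-element scan and TSS proximity
    genes = mio.read_gff3_genes(simdir / "genes.gff3")
    sites = scan_rare(genome)
    mio.write_bed6(resdir / "rare_sites.bed", sites)
    prox = tss_distances(sites, genes)
    pd.DataFrame(
        [
            {
                "chrom": p.site.chrom,
                "start": p.site.start,
                "end": p.site.end,
                "strand": p.site.strand,
                "motif_class": p.site.motif_class,
                "nearest_gene": p.nearest_gene,
                "signed_distance": p.signed_distance,
            }
            for p in prox
        ]
    ).to_csv(resdir / "rare_proximity.tsv", sep="\t", index=False)
    hist = bin_distances([p.signed_distance for p in prox if p.signed_distance is not None])
    pd.DataFrame(
        {
            "bin_lo": [lo for lo, _ in hist.bin_edges()],
            "bin_hi": [hi for _, hi in hist.bin_edges()],
            "count": hist.counts,
        }
    ).to_csv(resdir / "rare_histogram.tsv", sep="\t", index=False)
    near = genes_near_rare(sites, genes, window=10_000)
    pd.DataFrame(near, columns=["gene_id", "signed_distance"]).to_csv(
        resdir / "genes_near_rare.tsv", sep="\t", index=False
    )
    n_sites, mean_abs = rare_summary(prox)
    truth = {
        (p["chrom"], p["start"], p["end"], p["strand"], p["motif_class"])
        for p in manifest.planted_rares
    }
    found = {(s.chrom, s.start, s.end, s.strand, s.motif_class) for s in sites}
    results["n_rare_sites"] = len(sites)
    results["rare_site_recovery_pct"] = 100.0 * len(found & truth) / len(truth)
    results["mean_abs_tss_distance_kb"] = mean_abs / 1000.0
    planted_mean = np.mean([abs(p["signed_tss_distance"]) for p in manifest.planted_rares])
    results["planted_mean_abs_tss_distance_kb"] = float(planted_mean) / 1000.0
    results["n_genes_with_rare_within_10kb"] = len(near)

    # ------------------------------------------------------------------
    # family Venn and domain census
    fam_table = mio.read_tsv(simdir / "families.tsv")
    matrix = FamilyMatrix.from_long_table(fam_table)
    groups = manifest.extras["species_groups"]
    venn = family_venn(matrix, groups)
    pd.DataFrame(sorted(venn.items()), columns=["region", "n_families"]).to_csv(
        resdir / "family_venn.tsv", sep="\t", index=False
    )
    labels = list(groups)
    focal_label = "Scyphozoa" if "Scyphozoa" in groups else labels[0]
    specific = group_specific_families(
        matrix, groups[focal_label], {k: v for k, v in groups.items() if k != focal_label}
    )
    (resdir / f"{focal_label.lower()}_specific_families.txt").write_text(
        "\n".join(sorted(specific)) + ("\n" if specific else "")
    )
    results["n_families"] = len(matrix.families)
    results["n_families_shared_all_groups"] = venn["&".join(labels)]
    results[f"n_{focal_label.lower()}_specific_families"] = len(specific)

    dom_table = mio.read_tsv(simdir / "domains.tsv")
    targets = manifest.extras["target_domains"]
    focal_sp = manifest.extras["focal_species"]
    census = domain_census(dom_table, targets, focal_sp)
    census.counts.rename_axis("species").reset_index().to_csv(
        resdir / "domain_counts.tsv", sep="\t", index=False
    )
    results["n_target_domains"] = len(targets)
    results["n_target_domains_in_any_species"] = census.n_targets_in_any_species
    results["n_target_domains_in_focal"] = census.n_targets_in_focal

    # ------------------------------------------------------------------
    # expression: FPKM fold-change classes, set means, enrichment
    counts = mio.read_tsv(simdir / "counts.tsv").set_index("gene")
    glengths = mio.read_tsv(simdir / "gene_lengths.tsv").set_index("gene")["length"]
    totals = mio.read_tsv(simdir / "totals.tsv").set_index("tissue")["total"]
    table = ExpressionTable(counts=counts, lengths=glengths, totals=totals)
    folds = fold_change(table, "bell", "tentacle")
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "fc": "" if r.fc is None else r.fc,
                "status": r.status,
                "class": r.fold_class,
            }
            for r in folds
        ]
    ).to_csv(resdir / "fold_changes.tsv", sep="\t", index=False, float_format="%.6g")
    set_rows = []
    membership = manifest.extras["expression_sets"]
    for label, members in membership.items():
        summary = set_mean_fold(folds, set(members))
        set_rows.append(
            {
                "set": label,
                "n_members": len(members),
                "mean_fc": summary.mean_fc,
                "n_finite": summary.n_finite,
                "n_infinite": summary.n_infinite,
                "n_excluded": summary.n_excluded,
            }
        )
        results[f"mean_fold_{label}"] = (
            float("nan") if summary.mean_fc is None else summary.mean_fc
        )
    pd.DataFrame(set_rows).to_csv(
        resdir / "set_folds.tsv", sep="\t", index=False, float_format="%.6g"
    )

    population = {r.gene for r in folds if r.status == "OK"}
    study = {r.gene for r in folds if r.fold_class in ("GE2", "GE4")} & population
    term_rng = np.random.default_rng([seed, 104729])
    term_map: dict[str, set[str]] = {
        f"term_{label}": set(members) & population
        for label, members in membership.items()
    }
    pool = sorted(population)
    for i in range(20):  # background terms, should not be enriched
        term_map[f"term_random_{i:02d}"] = set(
            term_rng.choice(pool, size=25, replace=False)
        )
    enrich = hypergeom_enrich(study, population, term_map)
    pd.DataFrame(
        [
            {"term": r.term, "k": r.k, "n": r.n, "K": r.K, "M": r.M,
             "p": r.p, "q": r.q}
            for r in enrich
        ]
    ).to_csv(resdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    by_term = {r.term: r for r in enrich}
    for label in membership:
        r = by_term[f"term_{label}"]
        results[f"enrich_neglog10p_{label}"] = (
            300.0 if r.p == 0 else -math.log10(r.p)
        )

    with open(resdir / "summary.json", "w") as fh:
        json.dump(results, fh, sort_keys=True, indent=1, default=float)
        fh.write("\n")
    return results
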