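#!/usr/bin/env python
"""Direct-repeat response-element scan and TSS proximity profile.

Scans the synthetic genome for DR1/DR2/DR5 elements on both strands,
computes signed midpoint-to-TSS distances, bins them in 1-kb windows
over ±100 kb, and lists genes with an element within ±10 kb of their
TSS — then verifies everything against the planted truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from medusa_kit.io import read_fasta, read_gff3_genes, write_bed6
from medusa_kit.rare import (
    bin_distances,
    genes_near_rare,
    rare_summary,
    scan_rare,
    tss_distances,
)
from medusa_kit.synthio import SyntheticManifest

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SIM / "manifest.json").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    RESULTS.mkdir(exist_ok=True)
    manifest = SyntheticManifest.load(SIM / "manifest.json")

    genome = read_fasta(SIM / "genome.fasta")
    genes = read_gff3_genes(SIM / "genes.gff3")
    sites = scan_rare(genome)
    write_bed6(RESULTS / "04_rare_sites.bed", sites)

    prox = tss_distances(sites, genes)
    pd.DataFrame(
        [{"chrom": p.site.chrom, "start": p.site.start, "end": p.site.end,
          "strand": p.site.strand, "motif_class": p.site.motif_class,
          "nearest_gene": p.nearest_gene, "signed_distance": p.signed_distance}
         for p in prox]
    ).to_csv(RESULTS / "04_rare_proximity.tsv", sep="\t", index=False)

    hist = bin_distances([p.signed_distance for p in prox
                          if p.signed_distance is not None])
    pd.DataFrame(
        {"bin_lo": [a for a, _ in hist.bin_edges()],
         "bin_hi": [b for _, b in hist.bin_edges()],
         "count": hist.counts}
    ).to_csv(RESULTS / "04_distance_histogram.tsv", sep="\t", index=False)

    near = genes_near_rare(sites, genes, window=10_000)
    pd.DataFrame(near, columns=["gene_id", "signed_distance"]).to_csv(
        RESULTS / "04_genes_near_rare.tsv", sep="\t", index=False
    )

    n_sites, mean_abs = rare_summary(prox)
    truth = {(p["chrom"], p["start"], p["end"], p["strand"], p["motif_class"])
             for p in manifest.planted_rares}
    found = {(s.chrom, s.start, s.end, s.strand, s.motif_class) for s in sites}
    planted_mean = np.mean([abs(p["signed_tss_distance"])
                            for p in manifest.planted_rares])
    print(f"{n_sites} merged element regions "
          f"({100 * len(found & truth) / len(truth):.0f}% of planted sites "
          f"recovered exactly)")
    print(f"mean |distance| to nearest TSS: {mean_abs / 1000:.2f} kb "
          f"(planted {planted_mean / 1000:.2f} kb)")
    print(f"{len(near)} genes carry an element within ±10 kb of their TSS "
          f"(the planted Hox-like set)")


if __name__ == "__main__":
    main()
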