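# medusa-kit

Downstream comparative-genomic analyses for a scyphozoan (jellyfish)
genome, packaged as one tested pipeline: phylostratigraphic gene-age
dating, GC3 codon-bias ranking, retinoic-acid-response-element (RARE)
scanning with TSS-proximity statistics, ortholog-family and
toxin-domain censuses, and medusa-bell vs tentacle expression
fold-change profiling. Because the real inputs (a full assembly, an nr
homology search, deposited transcriptomes) are not desk-scale, the
package ships a synthetic-data generator that fabricates every input
with planted, machine-readable ground truth — so each stage is
validated by exact recovery of what was planted, not by eyeballing.

It is aimed at comparative genomicists who want these classic analyses
as importable, testable functions rather than one-off scripts.

## The statistics at the core

* **Phylostratigraphy** — a gene's age is the oldest phylostratum among
  its qualifying homology hits: `PS(g) = min { ps(species(h)) :
  e(h) ≤ 10⁻³, species(h) ≠ focal }`, proteins < 40 aa excluded, no
  qualifying hit ⇒ species-specific. Strata aggregate into ancient /
  middle / young eras (4204–741, 741–239, 239–0 Mya) with turnover
  rate = genes / era duration (My).
* **GC3** — fraction of G/C at unambiguous third codon positions,
  terminal stop excluded; genes ranked by descending GC3 (top-N sets
  feed enrichment).
* **RARE scan** — IUPAC grammar `RGKTCA + spacer + RGKTCA` (DR1/DR2/DR5)
  on both strands, overlapping matches merged; signed distance from the
  region midpoint to the nearest TSS (negative = upstream), 1-kb bins
  over ±100 kb, and gene calls within ±10 kb.
* **FPKM** — `C·10⁹ / (N·L)`; fold change is the FPKM ratio with strict
  >2×/>4× classes, both-zero genes excluded, one-sided zeros reported
  as +inf.
* **Enrichment** — one-sided hypergeometric upper tail with
  Benjamini–Hochberg adjustment.
* **Set algebra** — family Venn regions over species groups and
  lineage-specific family extraction; domain-occurrence censuses against
  a target accession list.

See `docs/methods.md` for assumptions, parameters and limitations.

## Layout

```
src/medusa_kit/     library: synthio, seqstats, phylostrat, rare,
                    famdom, express, io, pipeline, cli
analysis/           numbered drivers 01–06 (simulate → expression)
configs/            default.yaml (full study), small.yaml (quick run)
scripts/acceptance.py
```

## Worked example

Generate the default synthetic study and run every stage (writes inputs
under `scratch/synthetic`, tables under `results/`):

```sh
python analysis/01_simulate.py --seed 42
python analysis/03_gene_ages.py
python analysis/04_rare_elements.py
```

which prints (seed 42):

```
10000 proteins dated (10 excluded < 40 aa); planted ages recovered for 100.0%
  ancient:  7984 genes (79.8%), 2.31 genes/My over 4204-741 Mya
   middle:   309 genes (3.1%), 0.62 genes/My over 741-239 Mya
    young:  1707 genes (17.1%), 7.14 genes/My over 239-0 Mya
500 merged element regions (100% of planted sites recovered exactly)
mean |distance| to nearest TSS: 13.93 kb (planted 13.93 kb)
4 genes carry an element within ±10 kb of their TSS (the planted Hox-like set)
```

Reading: the hit-table assignment reproduced every planted gene age, so
the era split equals the planted 80/3/17% mix; normalising by era
duration shows turnover is highest in the young era even though ancient
genes dominate the raw counts. The motif scan found exactly the 500
planted elements, their recovered TSS distances average the planted
13.93 kb, and the four genes planted with elements inside ±10 kb are
exactly the four returned.

The same run is available as one command:

```sh
medusa-kit pipeline --config configs/small.yaml --seed 5 --outdir out/
```

Individual stages are exposed as `medusa-kit simulate | asm-stats | gc3 |
phylostrat | rare-scan | rare-dist | rare-near | venn | domains | fpkm |
fold | enrich` for use on real files.

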