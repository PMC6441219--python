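# Methods

`medusa-kit` re-implements the downstream, desk-scale analyses that sit
between a finished cnidarian genome assembly and its biological
conclusions: gene-age dating, codon-bias ranking, response-element
scanning with TSS proximity statistics, ortholog-family and domain
censuses, and tissue fold-change profiling. All stages run end to end
on synthetic data with planted ground truth, so every statistic the
package reports can be checked against what was actually put in.

## Phylostratigraphic gene ages (`phylostrat`)

A gene is dated by the most distant lineage in which a homolog is
detectable: subject species of its homology hits are mapped onto an
ordered ladder of phylostrata (PS1 = cellular organisms … PSk = the
focal species), and the gene's stratum is the minimum stratum index
over qualifying hits. Qualifying means e-value ≤ 1e-3, species present
in the ladder, and not the focal species itself — a self-hit carries no
age information, so it never ages a gene (without this rule every gene
would trivially receive the youngest stratum). Proteins shorter than
40 aa are excluded outright, since similarity search is unreliable at
those lengths; both thresholds are parameters. A protein with no
qualifying hit is species-specific (youngest stratum).

Strata aggregate into three eras bounded by divergence ages — ancient
(PS1–5, 4204–741 Mya), middle (PS6–7, 741–239 Mya), young (PS8–11,
239–0 Mya). Era proportions are over non-excluded proteins only, and
the per-era turnover rate divides the gene count by the era duration in
My, which is what makes recent turnover visible despite the ancient
era's much larger raw count.

The bundled 11-stratum example ladder is honest only at the three
anchor ages; intermediate stratum ages are evenly interpolated
placeholders and intermediate clade names are generic labels. Real
analyses must supply their own ladder (YAML); nothing in the code
depends on the placeholder values.

## GC3 and assembly statistics (`seqstats`)

GC3 is the fraction of G/C at third codon positions. The trailing
incomplete codon is dropped; the terminal stop codon is excluded
(stops are not under synonymous-site selection); codons whose third
base is not an unambiguous A/C/G/T are excluded from numerator and
denominator, which makes GC3 invariant under padding with
ambiguous-third-base codons. Ranking is by descending GC3 with a
lexicographic tie-break on gene id and a minimum of 30 usable codons
(configurable) — short CDS make the fraction too noisy to rank. When a
transcriptome carries isoforms, `longest_cds_per_gene` picks one
representative CDS per locus (longest, ties to the smaller id).

N50 is the scaffold length at which descending cumulative length first
reaches half the assembly; it is always a member of the length multiset.
Gap fraction counts N/n bases; GC is over non-gap bases, and
soft-masked lowercase counts as its base identity, not as a gap.

## Response-element scanning (`rare`)

The grammar is two copies of an IUPAC half-site separated by a fixed
spacer. Defaults are the canonical nuclear-receptor arrangement:
half-site RGKTCA, direct repeats with spacers 1/2/5 (DR1/DR2/DR5), zero
mismatches. These defaults are this package's assumption, documented as
canonical rather than taken from any particular study; the half-site,
spacer set, per-half-site mismatch budget and repeat geometry (direct,
everted, inverted — the latter two behind a flag) are all configurable.
Everted/inverted patterns equal their own reverse complement, so they
are scanned on one strand only to avoid double reporting.

Both strands are scanned (minus-strand matches via the
reverse-complemented pattern, coordinates on the forward axis), and
overlapping raw matches merge into maximal regions regardless of strand
or class, keeping the leftmost contributor's strand/class and a
contributor count. Coordinates are 0-based half-open internally; GFF3
converts at the boundary; BED output stays 0-based half-open.

Distance to a gene is measured from the region midpoint (integer floor)
to the TSS — the strand-aware first transcribed base — signed in the
gene's orientation (negative = upstream). Midpoint rather than edge
gives one distance per region; a `reference="span"` option measures to
the gene body instead. Histogram bins are half-open `[lo, lo+1000)`
over −100 kb … +100 kb with an overflow tally, so counts always
conserve. The ±10 kb gene-call window is inclusive (|d| ≤ window).

## Family and domain censuses (`famdom`)

A family is present in a species group if at least one member species
has a count ≥ 1; a `require_all` flag gives the stricter rule (the
choice matters when groups are taxonomic classes containing multiple
genomes; any-member is the default because class-level repertoires are
unions). All 2^g − 1 Venn regions are reported and sum to the number of
families present anywhere. Domain occurrences count annotated regions
(a protein with two copies of a domain contributes 2), with a
`per_protein` presence mode.

## Expression (`express`)

FPKM = C·10⁹/(N·L) with C the gene's fragment count, L its exon-model
length in bp, N the tissue's total mapped fragments. Fold change is the
FPKM ratio between two tissues. Genes with zero FPKM in both tissues
are excluded — they carry no contrast information; a zero denominator
against a nonzero numerator is reported as an explicit +inf sentinel
rather than hidden behind a pseudocount (pseudocount configurable,
default 0). Classes use strict inequalities (> 2-fold, > 4-fold, the
latter nested), so a gene at exactly 2.0 is unclassified. Set summaries
average only finite OK members and tally infinite/excluded members
separately.

Term enrichment is the one-sided hypergeometric upper tail
P(X ≥ k | M, K, n) with Benjamini–Hochberg adjustment — the standard
over-representation test; this is the package's choice of test, made
explicit because published P values rarely name one. Exact
hypergeometric p-values are discrete and conservative; the null
uniformity check therefore uses a mixture over many term sizes
(population 20 000, study 2 000, term sizes 500–5000), which brings the
p-value distribution close enough to continuous for a
Kolmogorov–Smirnov check at α = 0.01.

## Synthetic data (`synthio`)

The generator fabricates every input with recorded truth in one JSON
manifest per run; identical (config, seed) reproduce byte-identical
files.

*Genome/motifs.* Genes occupy private equal-width slots (round-robin
over chromosomes), so genes never overlap and each planted element is
nearest to its own gene's TSS. Sites are planted so the region midpoint
sits at the requested signed distance from the TSS. Incidental grammar
matches in the random background are removed by scan-and-disrupt — one
half-site base of each incidental match is mutated, avoiding planted
half-sites (planted spacers may be touched; spacers are wildcards) —
rather than rejection sampling, which need not terminate on long
chromosomes. A final re-scan must find exactly the planted sites or the
generator fails loudly. Infeasible geometry raises, never truncates.

*CDS.* Exactly round(target·m) of m third positions are G/C, so the
realised GC3 is within 1/m of the target; first codon positions avoid T,
so no stop codon can occur.

*Hits.* Each gene receives a qualifying hit in its true stratum and all
younger non-focal strata, a self-hit, and sometimes an above-threshold
distractor in an older stratum; noise-free assignment is therefore
exact by construction. False-negative noise drops each qualifying hit
with probability f (recorded); spurious noise adds a qualifying older
hit per gene with probability s (recorded). Random draws are consumed
independently of the rates, so the noisy table differs from the clean
one by exactly the recorded perturbations.

*Expression.* Counts are Poisson around expectations whose FPKM ratio
equals the planted multiplier (equal library totals in both tissues);
negative-binomial dispersion is deliberately omitted because
differential-expression testing is out of scope and the fold-change
statistics only need a count-noise model. Noise-free mode emits the
exact expectations (possibly non-integer) so folds recover exactly.

*Families/domains.* Independent per-species presence (p = 0.55, at
least one species), counts 1–5; per-(species, domain) occurrence counts
with presence probability 0.5.

## Default study conditions

The default configuration emulates the biological setting the pipeline
was built for, at desk scale: a 30 Mb genome (6 × 5 Mb) with 540 genes
and 500 planted elements — four "Hox-like" genes at |d| ≤ 8 kb and the
rest with |d| drawn from a normal(13 kb, 3 kb) truncated to
[10.5, 24] kb (the truncation keeps exactly four genes inside the
±10 kb window and shifts the realised mean |d| to ≈ 14 kb; recovery is
always judged against the planted empirical values, not the nominal
mean); 10 000 proteins with ages drawn 80 / 3 / 17 % across
ancient/middle/young eras plus 10 sub-40-aa proteins to exercise the
exclusion; 600 CDS of 300 codons with 100 planted high-GC3 (0.85–0.95)
over a 0.2–0.7 background; bell-vs-tentacle expression for 500 genes
with 7 genes at 8.8× and 21 at 17× under Poisson noise; three
two-species class-like groups over 2000 families; 20 target domain
accessions among 30. These sizes keep the full run under ~20 s on one
CPU while leaving every statistical check well-powered.

## What passing tests do and do not show

The synthetic data are clean by design: no assembly error, no
misannotated TSSs, no BLAST score noise beyond the configured rates, no
isoform ambiguity, Poisson (not overdispersed) counts, and planted
effects much larger than noise. Exact recovery therefore validates the
*computations* — coordinate conventions, thresholds, set algebra,
normalisations — not the robustness of the biology to real data
artefacts. The noise knobs (false-negative/spurious hit rates, Poisson
counts) probe first-order sensitivity only.

## Numerical and degenerate-input choices

Ties everywhere break lexicographically (gene ids, term ids) so output
is platform-independent. Empty inputs fail loudly (empty genome,
empty ladder, zero-length assembly, empty population). Zero usable
codons flags the record rather than producing NaN. Histogram values
outside range are tallied, never dropped. e-values must be
non-negative; era ranges must partition 1..k exactly.
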