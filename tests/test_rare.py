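"""Motif scanning conventions: strands, merging, distances, bins, windows."""

import numpy as np
import pytest

from medusa_kit.rare import (
    GeneModel,
    MotifSpec,
    RareSite,
    bin_distances,
    genes_near_rare,
    rare_summary,
    reverse_complement,
    scan_rare,
    tss_distances,
)

DR5 = "AGGTCAGGGGGAGGTCA"  # RGKTCA + 5-bp spacer + RGKTCA


class TestScan:
    def test_constructed_dr5_match(self):
        sites = scan_rare({"c": DR5})
        assert sites == [RareSite("c", 0, 17, "+", "DR5", 1)]

    def test_reverse_complement_found_on_minus_strand(self):
        sites = scan_rare({"c": reverse_complement(DR5)})
        assert sites == [RareSite("c", 0, 17, "-", "DR5", 1)]

    def test_strand_symmetry(self):
        seq = "TTTT" + DR5 + "ACACAC" + reverse_complement(DR5) + "GG"
        fwd = scan_rare({"c": seq})
        rev = scan_rare({"c": reverse_complement(seq)})
        L = len(seq)
        mirrored = sorted(
            (L - s.end, L - s.start, {"+": "-", "-": "+"}[s.strand], s.motif_class)
            for s in rev
        )
        assert mirrored == sorted(
            (s.start, s.end, s.strand, s.motif_class) for s in fwd
        )

    def test_overlapping_matches_merge_and_merge_is_idempotent(self):
        half = "AGGTCA"
        seq = half + "T" + half + "T" + half  # two overlapping DR1 matches
        sites = scan_rare({"c": seq})
        assert len(sites) == 1
        assert sites[0].merged_from == 2
        assert (sites[0].start, sites[0].end) == (0, len(seq))
        for a, b in zip(sites, sites[1:]):
            assert b.start >= a.end

    def test_n_runs_cannot_match(self):
        assert scan_rare({"c": "AGGTCANNNNNAGGTCA"}) == []

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            MotifSpec(half_site="RGXTCA")

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            scan_rare({})

    def test_mismatch_tolerance_widens_the_match_set(self):
        seq = "CGGTCAGGGGGAGGTCA"  # first half-site has R->C at position 1
        assert scan_rare({"c": seq}) == []
        lenient = MotifSpec(max_mismatches_per_half_site=1)
        sites = scan_rare({"c": seq}, lenient)
        assert any(s.start == 0 and s.motif_class == "DR5" for s in sites)

    def test_everted_and_inverted_geometries_behind_flag(self):
        half = "AGGTCA"
        rc = reverse_complement(half)
        everted = {"c": rc + "GGGGG" + half}
        inverted = {"c": half + "GGGGG" + rc}
        assert scan_rare(everted) == []
        assert scan_rare(inverted) == []
        spec = MotifSpec(geometries=("direct", "everted", "inverted"))
        [s_ev] = scan_rare(everted, spec)
        assert s_ev.motif_class == "DR5-ev"
        [s_inv] = scan_rare(inverted, spec)
        assert s_inv.motif_class == "DR5-inv"

    def test_planted_sites_recovered_exactly(self, sim_dir, manifest):
        from medusa_kit.io import read_fasta

        sites = scan_rare(read_fasta(sim_dir / "genome.fasta"))
        got = {(s.chrom, s.start, s.end, s.strand, s.motif_class) for s in sites}
        want = {
            (p["chrom"], p["start"], p["end"], p["strand"], p["motif_class"])
            for p in manifest.planted_rares
        }
        assert got == want


def site(mid, chrom="c", width=17):
    start = mid - width // 2
    return RareSite(chrom, start, start + width, "+", "DR5", 1)


class TestTssDistance:
    def test_plus_strand_sign(self):
        genes = [GeneModel("g", "c", 1000, 2000, "+")]
        [p] = tss_distances([site(1500)], genes)
        assert (p.nearest_gene, p.signed_distance) == ("g", 500)

    def test_minus_strand_sign(self):
        # minus-strand gene with TSS at 2000: a site at 1500 lies downstream
        genes = [GeneModel("g", "c", 1000, 2001, "-")]
        [p] = tss_distances([site(1500)], genes)
        assert (p.nearest_gene, p.signed_distance) == ("g", 500)

    def test_site_at_tss_is_zero(self):
        genes = [GeneModel("g", "c", 1500, 2000, "+")]
        [p] = tss_distances([site(1500)], genes)
        assert p.signed_distance == 0

    def test_tie_prefers_smaller_gene_id(self):
        genes = [
            GeneModel("gb", "c", 1000, 1500, "+"),
            GeneModel("ga", "c", 2000, 2500, "+"),
        ]
        [p] = tss_distances([site(1500)], genes)
        assert p.nearest_gene == "ga"

    def test_geneless_chromosome_gives_null(self):
        [p] = tss_distances([site(100, chrom="empty")],
                            [GeneModel("g", "c", 0, 10, "+")])
        assert p.nearest_gene is None and p.signed_distance is None

    def test_span_reference_is_zero_inside_gene_body(self):
        genes = [GeneModel("g", "c", 1000, 2000, "+")]
        inside = tss_distances([site(1500)], genes, reference="span")
        assert inside[0].signed_distance == 0
        upstream = tss_distances([site(800)], genes, reference="span")
        assert upstream[0].signed_distance == -200
        downstream = tss_distances([site(2500)], genes, reference="span")
        assert downstream[0].signed_distance == 501  # from last base, 1999

    def test_planted_signed_distances_recovered(self, sim_dir, manifest):
        from medusa_kit.io import read_fasta, read_gff3_genes

        sites = scan_rare(read_fasta(sim_dir / "genome.fasta"))
        genes = read_gff3_genes(sim_dir / "genes.gff3")
        got = {
            (p.site.chrom, p.site.start): (p.nearest_gene, p.signed_distance)
            for p in tss_distances(sites, genes)
        }
        for truth in manifest.planted_rares:
            assert got[(truth["chrom"], truth["start"])] == (
                truth["gene_id"], truth["signed_tss_distance"],
            )


class TestBins:
    def test_single_value(self):
        h = bin_distances([-500])
        assert h.counts[h.n_bins // 2 - 1] == 1  # the [-1000, 0) bin
        assert sum(h.counts) == 1

    def test_half_open_boundaries(self):
        h = bin_distances([-100_000, 100_000])
        assert h.counts[0] == 1       # lower edge is included
        assert h.overflow == 1        # upper edge is outside [lo, hi)

    def test_conservation_and_loop_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.integers(-150_000, 150_001, size=10_000)
        h = bin_distances(vals)
        assert sum(h.counts) + h.overflow == len(vals)
        counts = [0] * h.n_bins
        overflow = 0
        for v in vals:  # naive per-value oracle
            placed = False
            for i, (lo, hi) in enumerate(h.bin_edges()):
                if lo <= v < hi:
                    counts[i] += 1
                    placed = True
                    break
            overflow += not placed
        assert list(h.counts) == counts and h.overflow == overflow

    def test_non_divisible_range_rejected(self):
        with pytest.raises(ValueError):
            bin_distances([0], bin_width=3000, lo=-100_000, hi=100_000)


class TestNearWindow:
    def test_window_boundary_is_inclusive(self):
        genes = [GeneModel("in", "c", 20_000, 21_000, "+"),
                 GeneModel("out", "c", 60_000, 61_000, "+")]
        sites = [site(29_999), site(70_001)]
        near = genes_near_rare(sites, genes, window=10_000)
        assert near == [("in", 9_999)]
        assert genes_near_rare([site(30_000)],
                               [genes[0]], window=10_000) == [("in", 10_000)]

    def test_no_sites_means_no_genes(self):
        assert genes_near_rare([], [GeneModel("g", "c", 0, 10, "+")]) == []

    def test_planted_proximal_genes_recovered(self, sim_dir, manifest):
        from medusa_kit.io import read_fasta, read_gff3_genes

        sites = scan_rare(read_fasta(sim_dir / "genome.fasta"))
        genes = read_gff3_genes(sim_dir / "genes.gff3")
        near = dict(genes_near_rare(sites, genes, window=10_000))
        want = {
            p["gene_id"]: p["signed_tss_distance"]
            for p in manifest.planted_rares
            if abs(p["signed_tss_distance"]) <= 10_000
        }
        assert near == want


class TestSummary:
    def test_mean_of_absolute_distances(self):
        genes = [GeneModel("g", "c", 10_000, 11_000, "+")]
        prox = tss_distances([site(10_500), site(8_500)], genes)
        n, mean = rare_summary(prox)
        assert (n, mean) == (2, 1000.0)

    def test_requires_a_site_with_a_gene(self):
        prox = tss_distances([site(10, chrom="empty")],
                             [GeneModel("g", "c", 0, 10, "+")])
        with pytest.raises(ValueError):
            rare_summary(prox)
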