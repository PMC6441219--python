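"""The generators must provably plant what they claim to plant."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from medusa_kit.phylostrat import assign_all, default_ladder
from medusa_kit.rare import IUPAC, MotifSpec, reverse_complement
from medusa_kit.express import ExpressionTable, fold_change, set_mean_fold
from medusa_kit.synthio import (
    PlacementError,
    make_cds_set,
    make_expression,
    make_families_and_domains,
    make_genome,
    make_hit_table,
    simulate,
)

SPEC = MotifSpec()


def regex_free_scan(seq, spec=SPEC):
    """Oracle: test every offset on both strands with direct IUPAC logic."""
    found = []
    seq = seq.upper()
    for spacer, label in spec.spacers.items():
        for strand in "+-":
            pat = (spec.forward_pattern(spacer) if strand == "+"
                   else spec.reverse_pattern(spacer))
            w = len(pat)
            for i in range(len(seq) - w + 1):
                window = seq[i : i + w]
                if all(b in IUPAC[p] and b in "ACGT"
                       for b, p in zip(window, pat)):
                    found.append((i, i + w, strand, label))
    return sorted(found)


class TestMakeGenome:
    def test_empty_case(self):
        genome, genes, planted = make_genome(1, 5000, 0, [], seed=0)
        assert genes == [] and planted == []
        assert regex_free_scan(genome["chr01"]) == []

    def test_placement_is_definitional(self):
        genome, genes, planted = make_genome(1, 100_000, 1, [("DR5", -5000)], seed=2)
        [g] = genes
        [p] = planted
        mid = (p["start"] + p["end"]) // 2
        tss = g.start if g.strand == "+" else g.end - 1
        expected = mid - tss if g.strand == "+" else tss - mid
        assert expected == -5000 == p["signed_tss_distance"]

    def test_oracle_rescan_finds_exactly_the_planted_sites(self):
        plan = [("DR5", d) for d in
                (-9000, -7000, -5000, -3000, -1000, 1000, 3000, 5000, 7000, 9000)]
        genome, genes, planted = make_genome(2, 300_000, 10, plan, seed=1)
        found = sorted(
            (chrom, *m)
            for chrom, seq in genome.items()
            for m in regex_free_scan(seq)
        )
        want = sorted(
            (p["chrom"], p["start"], p["end"], p["strand"], p["motif_class"])
            for p in planted
        )
        assert found == want

    def test_infeasible_placement_raises(self):
        with pytest.raises(PlacementError):
            make_genome(1, 1000, 5, [], seed=0, gene_length=400)
        with pytest.raises(PlacementError):
            make_genome(1, 100_000, 2, [("DR5", 90_000)], seed=0)
        with pytest.raises(PlacementError):
            make_genome(1, 100_000, 0, [("DR5", 100)], seed=0)


class TestMakeCds:
    def test_extreme_targets(self):
        seqs, realized = make_cds_set(2, [1.0, 0.0], 50, seed=0)
        s_hi, s_lo = seqs["cds_0000"], seqs["cds_0001"]
        assert all(b in "GC" for b in s_hi[2::3])
        assert all(b in "AT" for b in s_lo[2::3])
        assert realized == {"cds_0000": 1.0, "cds_0001": 0.0}

    def test_recount_oracle_within_codon_resolution(self):
        rng = np.random.default_rng(7)
        targets = rng.uniform(0, 1, size=100)
        m = 60
        seqs, realized = make_cds_set(100, list(targets), m, seed=7)
        for cid, target in zip(seqs, targets):
            third = seqs[cid][2::3]
            frac = sum(b in "GC" for b in third) / m
            assert frac == realized[cid]
            assert abs(frac - target) <= 1 / m

    def test_no_internal_stop_codons(self):
        seqs, _ = make_cds_set(20, list(np.linspace(0, 1, 20)), 100, seed=3)
        for seq in seqs.values():
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & {"TAA", "TAG", "TGA"}

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            make_cds_set(1, [1.5], 10, seed=0)
        with pytest.raises(ValueError):
            make_cds_set(1, [0.5], 0, seed=0)


class TestMakeHitTable:
    def ages(self, ladder, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return {f"p{i:03d}": int(rng.integers(1, ladder.youngest + 1))
                for i in range(n)}

    def test_noise_free_assignment_recovers_truth(self, ladder):
        ages = self.ages(ladder)
        hits, dropped, spurious = make_hit_table(ladder, ages, 0.0, 0.0, seed=5)
        assert dropped == [] and spurious == []
        lengths = {g: 100 for g in ages}
        for a in assign_all(hits, lengths, ladder):
            assert a.ps_index == ages[a.protein_id]

    def test_species_specific_gene_has_no_foreign_hits(self, ladder):
        hits, _, _ = make_hit_table(ladder, {"p": ladder.youngest}, 0.0, 0.0, seed=1)
        subjects = set(hits["subject_species"])
        assert subjects == {ladder.focal_species}

    def test_dropped_hits_are_exactly_the_noise_free_diff(self, ladder):
        ages = self.ages(ladder, seed=2)
        clean, _, _ = make_hit_table(ladder, ages, 0.0, 0.0, seed=3)
        noisy, dropped, _ = make_hit_table(ladder, ages, 0.1, 0.0, seed=3)
        assert len(dropped) > 0
        key = ["query_id", "subject_species", "e_value"]
        merged = clean.merge(noisy, on=key, how="left", indicator=True)
        diff = merged[merged["_merge"] == "left_only"][key]
        want = pd.DataFrame(dropped)[key]
        got = diff.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got, want.sort_values(key).reset_index(drop=True)
        )

    def test_misassignment_rate_tracks_false_negative_rate(self, ladder):
        # genes with a single informative oldest-stratum hit lose it with
        # probability f and then look younger
        rng = np.random.default_rng(44)
        ages = {f"p{i:04d}": 10 for i in range(2000)}  # PS10: one aging hit
        f = 0.2
        hits, dropped, _ = make_hit_table(ladder, ages, f, 0.0, seed=44)
        lengths = {g: 100 for g in ages}
        assigns = assign_all(hits, lengths, ladder)
        mis = sum(1 for a in assigns if a.ps_index != 10) / len(assigns)
        assert mis == pytest.approx(f, abs=0.03)


class TestMakeExpression:
    def fold_records(self, counts, lengths, totals):
        t = ExpressionTable(counts=counts, lengths=lengths, totals=totals)
        return fold_change(t, "bell", "tentacle")

    def test_unit_multiplier_no_noise_gives_fold_one(self):
        counts, lengths, totals, effects, _ = make_expression(
            50, {}, 1_000_000, seed=0, noise=False
        )
        for r in self.fold_records(counts, lengths, totals):
            assert r.fc == pytest.approx(1.0)

    def test_planted_eightfold_no_noise_is_exact(self):
        counts, lengths, totals, effects, sets = make_expression(
            1, {"s": (1, 8.0)}, 1_000_000, seed=1, noise=False
        )
        [r] = self.fold_records(counts, lengths, totals)
        assert r.fc == pytest.approx(8.0)

    def test_poisson_noise_recovers_planted_fold_within_15pct(self):
        counts, lengths, totals, effects, sets = make_expression(
            500, {"biased": (20, 8.0)}, 5_000_000, seed=11, noise=True
        )
        records = self.fold_records(counts, lengths, totals)
        s = set_mean_fold(records, set(sets["biased"]))
        assert s.mean_fc == pytest.approx(8.0, rel=0.15)

    def test_bad_multiplier_rejected(self):
        with pytest.raises(ValueError):
            make_expression(10, {"s": (2, -1.0)}, 1000, seed=0)


class TestFamiliesAndDomains:
    GROUPS = {"G1": ["s1", "s2"], "G2": ["s3"], "G3": ["s4", "s5"]}

    def test_presence_patterns_recorded_exactly(self):
        fams, doms, fam_truth, dom_truth = make_families_and_domains(
            self.GROUPS, 50, ["PF00001", "PF00002"], seed=9
        )
        observed = fams.groupby("family_id")["species"].apply(
            lambda s: sorted(set(s))
        )
        assert dict(observed) == fam_truth
        counts = doms.groupby(["species", "accession"]).size()
        for sp, accs in dom_truth.items():
            for acc, c in accs.items():
                assert counts.get((sp, acc), 0) == c

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            make_families_and_domains(
                {"G1": ["s1"], "G2": ["s1"]}, 5, ["PF00001"], seed=0
            )


class TestSimulateDeterminism:
    CFG = {
        "genome": {"n_chrom": 2, "chrom_len": 400_000, "n_genes": 20},
        "rare": {"n_sites": 12, "distal_abs_max": 9000.0,
                 "distal_abs_min": 2000.0, "distal_abs_mean": 5000.0,
                 "distal_abs_sd": 2000.0, "proximal_distances": [1500]},
        "cds": {"n": 30, "n_high": 5, "codons_per_cds": 100},
        "phylostrat": {"n_proteins": 200, "n_short": 2},
        "expression": {"n_genes": 50,
                       "sets": {"s": {"size": 5, "multiplier": 4.0}}},
        "families": {"n_families": 40},
    }

    @staticmethod
    def digest(d):
        return {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(d).rglob("*")) if p.is_file()
        }

    def test_same_seed_same_bytes_different_seed_different_bytes(self, tmp_path):
        simulate(self.CFG, seed=7, outdir=tmp_path / "a")
        simulate(self.CFG, seed=7, outdir=tmp_path / "b")
        simulate(self.CFG, seed=8, outdir=tmp_path / "c")
        a, b, c = (self.digest(tmp_path / x) for x in "abc")
        assert a == b
        assert a != c

    def test_manifest_references_existing_entities(self, sim_dir, manifest):
        from medusa_kit.io import read_fasta, read_gff3_genes, read_tsv

        genome = read_fasta(sim_dir / "genome.fasta")
        gene_ids = {g.gene_id for g in read_gff3_genes(sim_dir / "genes.gff3")}
        for p in manifest.planted_rares:
            assert p["chrom"] in genome
            assert 0 <= p["start"] < p["end"] <= len(genome[p["chrom"]])
            assert p["gene_id"] in gene_ids
        cds_ids = set(read_fasta(sim_dir / "cds.fasta"))
        assert set(manifest.gc3_targets) == cds_ids
        hit_genes = set(read_tsv(sim_dir / "hits.tsv")["query_id"])
        assert hit_genes <= set(manifest.gene_ages)
        expr_genes = set(read_tsv(sim_dir / "counts.tsv")["gene"])
        assert set(manifest.tissue_effects) == expr_genes
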