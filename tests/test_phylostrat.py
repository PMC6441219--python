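"""Gene-age assignment vs a brute-force oracle, and era aggregation."""

import numpy as np
import pytest

from medusa_kit.io import read_tsv
from medusa_kit.phylostrat import (
    EraDef,
    PhylostrataLadder,
    Stratum,
    aggregate_eras,
    assign_all,
    assign_phylostratum,
    default_eras,
    default_ladder,
)


def oracle_assign(length, hits, ladder, thr=1e-3, min_len=40):
    """Independent min-scan over the full hit list."""
    if length < min_len:
        return None
    best = None
    for sp, e in hits:
        if e > thr or sp == ladder.focal_species or sp not in ladder.species_map:
            continue
        ps = ladder.species_map[sp]
        best = ps if best is None else min(best, ps)
    return ladder.youngest if best is None else best


class TestAssign:
    def test_minimum_stratum_wins(self, ladder):
        hits = [("sp_ps07_a", 1e-20), ("sp_ps03_a", 1e-5)]
        a = assign_phylostratum("p", 100, hits, ladder)
        assert a.ps_index == 3
        assert a.basis_hit == ("sp_ps03_a", 1e-5)

    def test_length_cutoff_excludes_regardless_of_hits(self, ladder):
        a = assign_phylostratum("p", 39, [("sp_ps03_a", 1e-30)], ladder)
        assert a.excluded
        assert assign_phylostratum("p", 40, [("sp_ps03_a", 1e-30)], ladder).ps_index == 3

    def test_threshold_failure_falls_to_youngest(self, ladder):
        a = assign_phylostratum("p", 100, [("sp_ps03_a", 1e-2)], ladder)
        assert a.ps_index == ladder.youngest

    def test_self_hits_never_age_a_gene(self, ladder):
        a = assign_phylostratum("p", 100, [(ladder.focal_species, 1e-80)], ladder)
        assert a.ps_index == ladder.youngest

    def test_unknown_species_ignored_and_tallied(self, ladder):
        diag = {}
        a = assign_phylostratum(
            "p", 100, [("martian", 1e-30), ("sp_ps05_a", 1e-9)], ladder,
            diagnostics=diag,
        )
        assert a.ps_index == 5
        assert diag["unknown_species"] == 1

    def test_matches_bruteforce_oracle_on_random_tables(self, ladder):
        rng = np.random.default_rng(21)
        species = list(ladder.species_map) + ["unknown_sp"]
        for _ in range(150):
            n_hits = int(rng.integers(0, 12))
            hits = [
                (species[rng.integers(0, len(species))],
                 float(10.0 ** -rng.uniform(0, 20)))
                for _ in range(n_hits)
            ]
            length = int(rng.integers(10, 200))
            got = assign_phylostratum("p", length, hits, ladder)
            want = oracle_assign(length, hits, ladder)
            assert got.ps_index == want

    def test_adding_a_qualifying_hit_never_makes_gene_younger(self, ladder):
        rng = np.random.default_rng(3)
        non_focal = [s for s in ladder.species_map if s != ladder.focal_species]
        for _ in range(60):
            hits = [
                (non_focal[rng.integers(0, len(non_focal))],
                 float(10.0 ** -rng.uniform(2, 20)))
                for _ in range(rng.integers(0, 6))
            ]
            base = assign_phylostratum("p", 100, hits, ladder).ps_index
            extra = hits + [(non_focal[rng.integers(0, len(non_focal))], 1e-9)]
            assert assign_phylostratum("p", 100, extra, ladder).ps_index <= base

    def test_raising_threshold_only_moves_assignments_older(self, ladder):
        rng = np.random.default_rng(4)
        non_focal = [s for s in ladder.species_map if s != ladder.focal_species]
        for _ in range(60):
            hits = [
                (non_focal[rng.integers(0, len(non_focal))],
                 float(10.0 ** -rng.uniform(0, 8)))
                for _ in range(rng.integers(1, 8))
            ]
            loose = assign_phylostratum("p", 100, hits, ladder, e_threshold=1e-2)
            strict = assign_phylostratum("p", 100, hits, ladder, e_threshold=1e-4)
            assert loose.ps_index <= strict.ps_index

    def test_noise_free_synthetic_recovery_is_exact(self, sim_dir, manifest):
        ladder = PhylostrataLadder.from_yaml(sim_dir / "ladder.yaml")
        hits = read_tsv(sim_dir / "hits.tsv")
        lengths = dict(read_tsv(sim_dir / "protein_lengths.tsv").itertuples(index=False))
        short = {p for p, L in lengths.items() if L < 40}
        for a in assign_all(hits, lengths, ladder):
            if a.protein_id in short:
                assert a.excluded
            else:
                assert a.ps_index == manifest.gene_ages[a.protein_id]


class TestEras:
    def test_all_ancient(self, ladder):
        assigns = [
            assign_phylostratum(f"p{i}", 100, [("sp_ps01_a", 1e-9)], ladder)
            for i in range(100)
        ]
        s = aggregate_eras(assigns, default_eras())
        assert s.proportions["ancient"] == 1.0
        assert s.counts["middle"] == s.counts["young"] == 0

    def test_turnover_rate_is_count_over_duration(self, ladder):
        assigns = [
            assign_phylostratum(f"p{i}", 100, [], ladder) for i in range(100)
        ]  # no hits -> youngest stratum, young era
        s = aggregate_eras(assigns, default_eras())
        assert s.rates["young"] == pytest.approx(100 / 239)

    def test_proportions_sum_to_one(self, ladder):
        rng = np.random.default_rng(8)
        species = [s for s in ladder.species_map if s != ladder.focal_species]
        assigns = [
            assign_phylostratum(
                f"p{i}", int(rng.integers(10, 200)),
                [(species[rng.integers(0, len(species))], 1e-9)], ladder,
            )
            for i in range(500)
        ]
        s = aggregate_eras(assigns, default_eras())
        assert sum(s.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(s.counts.values()) + s.n_excluded == s.n_total

    def test_overlapping_or_gapped_eras_rejected(self, ladder):
        assigns = [assign_phylostratum("p", 100, [], ladder)]
        with pytest.raises(ValueError):
            aggregate_eras(assigns, [
                EraDef("a", 1, 6, 4204, 741), EraDef("b", 6, 11, 741, 0),
            ])
        with pytest.raises(ValueError):
            aggregate_eras(assigns, [
                EraDef("a", 1, 4, 4204, 741), EraDef("b", 6, 11, 741, 0),
            ])


class TestLadder:
    def test_default_ladder_is_valid(self):
        ladder = default_ladder()
        assert ladder.n_strata == 11
        assert ladder.strata[0].age_mya == 4204.0
        assert ladder.species_map[ladder.focal_species] == 11

    def test_yaml_round_trip(self, tmp_path, ladder):
        path = tmp_path / "ladder.yaml"
        ladder.to_yaml(path)
        again = PhylostrataLadder.from_yaml(path)
        assert again == ladder

    def test_invalid_ladders_rejected(self):
        with pytest.raises(ValueError):
            PhylostrataLadder(
                strata=(Stratum(1, "old", 100.0), Stratum(2, "young", 200.0)),
                species_map={"me": 2},
                focal_species="me",
            )
        with pytest.raises(ValueError):
            PhylostrataLadder(
                strata=(Stratum(1, "old", 200.0), Stratum(2, "young", 100.0)),
                species_map={"me": 1},
                focal_species="me",
            )
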