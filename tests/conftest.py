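import pytest

from medusa_kit.phylostrat import default_ladder
from medusa_kit.synthio import SyntheticManifest, simulate

# A compact but complete synthetic study: every stage has planted truth.
# Expression is noise-free here so recovery checks can be exact; the
# stochastic checks generate their own noisy data.
SIM_CONFIG = {
    "genome": {"n_chrom": 3, "chrom_len": 1_000_000, "n_genes": 60,
               "gene_length": 800},
    "rare": {
        "n_sites": 40,
        "proximal_distances": [2000, -4000, 6000, -8000],
        "distal_abs_mean": 13000.0,
        "distal_abs_sd": 2000.0,
        "distal_abs_min": 10500.0,
        "distal_abs_max": 15000.0,
    },
    "cds": {"n": 150, "n_high": 30, "codons_per_cds": 200},
    "phylostrat": {"n_proteins": 2000, "n_short": 5},
    "expression": {
        "n_genes": 200,
        "noise": False,
        "sets": {
            "myosin_heavy_like": {"size": 7, "multiplier": 8.8},
            "myosin_light_like": {"size": 21, "multiplier": 17.0},
        },
    },
    "families": {"n_families": 300},
}

SIM_SEED = 11


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("synthetic")
    simulate(SIM_CONFIG, seed=SIM_SEED, outdir=out)
    return out


@pytest.fixture(scope="session")
def manifest(sim_dir) -> SyntheticManifest:
    return SyntheticManifest.load(sim_dir / "manifest.json")


@pytest.fixture(scope="session")
def ladder():
    return default_ladder()
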