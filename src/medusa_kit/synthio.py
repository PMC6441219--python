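"""Synthetic pipeline inputs with a machine-readable planted truth.

Every downstream stage of the pipeline (motif scanning, GC3 ranking,
phylostratigraphy, family/domain censuses, tissue fold-change) is
testable without any external download because this module fabricates
its inputs with known ground truth:

* a genome with gene models and response-element motifs planted at
  chosen signed distances from TSSs, where every *incidental* match to
  the motif grammar in the random background is disrupted by a
  single-base substitution in one of its half-sites, so the planted
  sites are provably the only matches;
* coding sequences whose third-codon GC content hits chosen targets to
  within one codon's resolution, with no internal stop codons;
* homology hit tables that encode chosen gene ages exactly in
  noise-free mode, with optional recorded false-negative and spurious
  hits;
* two-tissue fragment-count tables whose expected FPKM ratios equal
  chosen multipliers, with optional Poisson count noise;
* ortholog-family membership and protein-domain tables with recorded
  presence patterns and occurrence counts.

All truth lives in a single JSON manifest per run. Identical
(config, seed) reproduce byte-identical files.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylostrat import PhylostrataLadder, default_ladder
from .rare import IUPAC, GeneModel, MotifSpec, RareSite, raw_matches, reverse_complement
from . import io as mio

__all__ = [
    "PlacementError",
    "SyntheticManifest",
    "make_genome",
    "make_cds_set",
    "make_hit_table",
    "make_expression",
    "make_families_and_domains",
    "default_config",
    "simulate",
]


class PlacementError(ValueError):
    """Requested genes/motifs cannot be placed without violating bounds."""


@dataclass
class SyntheticManifest:
    """Single source of ground truth for one synthetic run."""

    seed: int
    planted_rares: list[dict] = field(default_factory=list)
    gene_ages: dict[str, int] = field(default_factory=dict)
    gc3_targets: dict[str, float] = field(default_factory=dict)
    tissue_effects: dict[str, float] = field(default_factory=dict)
    family_truth: dict[str, list[str]] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SyntheticManifest":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)


_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    idx = rng.integers(0, 4, size=length, dtype=np.uint8)
    return bytearray(_BASE_BYTES[idx].tobytes())


def _concrete_instance(rng: np.random.Generator, spec: MotifSpec, spacer: int) -> str:
    """One concrete sequence matching half + spacer + half."""
    def concrete(pattern: str) -> str:
        return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)

    return (
        concrete(spec.half_site)
        + "".join(_BASES[rng.integers(0, 4)] for _ in range(spacer))
        + concrete(spec.half_site)
    )


def make_genome(
    n_chrom: int,
    chrom_len: int,
    n_genes: int,
    rare_plan: Sequence[tuple[str, int]],
    seed: int,
    spec: MotifSpec | None = None,
    gene_length: int = 1000,
) -> tuple[dict[str, str], list[GeneModel], list[dict]]:
    """Genome + gene models with motifs planted at signed TSS distances.

    Genes are laid out in private, equal-width slots (round-robin over
    chromosomes) so that genes never overlap each other and a planted
    site stays nearest to its own gene's TSS. ``rare_plan`` entries
    (motif_class, signed_distance) are assigned to genes in order; the
    signed distance follows the gene's orientation (negative =
    upstream). After planting, the background is repeatedly scanned and
    every incidental grammar match is disrupted by mutating one
    half-site base that does not fall in a planted half-site; a final
    re-scan verifies that the planted sites are the only matches left.

    Raises :class:`PlacementError` when the geometry does not fit —
    never silently truncates.
    """
    spec = spec or MotifSpec()
    if n_chrom < 1 or chrom_len < 1:
        raise PlacementError("need at least one chromosome of positive length")
    if len(rare_plan) > n_genes:
        raise PlacementError(
            f"{len(rare_plan)} planted sites but only {n_genes} genes"
        )
    label_to_spacer = {label: sp for sp, label in spec.spacers.items()}
    for label, _ in rare_plan:
        if label not in label_to_spacer:
            raise PlacementError(f"motif class {label!r} not in the active grammar")

    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    h = len(spec.half_site)

    genes: list[GeneModel] = []
    planted: list[dict] = []
    # (chrom, start, end, strand, class, instance string) to embed later
    embeds: list[tuple[str, int, int, str, str, str]] = []

    gene_idx = 0
    for ci, chrom in enumerate(chrom_names):
        m = per_chrom[ci]
        if m == 0:
            continue
        slot = chrom_len // m
        for si in range(m):
            slot_lo, slot_hi = si * slot, (si + 1) * slot
            center = slot_lo + slot // 2
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            if strand == "+":
                gstart, gend = center, center + gene_length
            else:
                gend = center + 1
                gstart = gend - gene_length
            if gstart < slot_lo or gend > slot_hi or gend > chrom_len:
                raise PlacementError(
                    f"gene of length {gene_length} does not fit slot of {slot} bp"
                )
            gid = f"gene_{gene_idx:05d}"
            genes.append(GeneModel(gid, chrom, gstart, gend, strand))

            if gene_idx < len(rare_plan):
                label, dist = rare_plan[gene_idx]
                spacer = label_to_spacer[label]
                w = spec.width(spacer)
                tss = center
                mid = tss + dist if strand == "+" else tss - dist
                sstart = mid - w // 2
                send = sstart + w
                if sstart < slot_lo or send > slot_hi or send > chrom_len:
                    raise PlacementError(
                        f"site for {gid} at signed distance {dist} leaves its "
                        f"{slot}-bp slot"
                    )
                site_strand = "+" if rng.integers(0, 2) == 0 else "-"
                instance = _concrete_instance(rng, spec, spacer)
                if site_strand == "-":
                    instance = reverse_complement(instance)
                embeds.append((chrom, sstart, send, site_strand, label, instance))
                planted.append(
                    {
                        "chrom": chrom,
                        "start": int(sstart),
                        "end": int(send),
                        "strand": site_strand,
                        "motif_class": label,
                        "signed_tss_distance": int(dist),
                        "gene_id": gid,
                    }
                )
            gene_idx += 1

    # pairwise non-overlap of planted sites (guaranteed by slots, but checked)
    by_start = sorted(planted, key=lambda p: (p["chrom"], p["start"]))
    for a, b in zip(by_start, by_start[1:]):
        if a["chrom"] == b["chrom"] and b["start"] < a["end"]:
            raise PlacementError("planted sites overlap")

    genome: dict[str, str] = {}
    for chrom in chrom_names:
        seq = _random_sequence(rng, chrom_len)
        chrom_embeds = [e for e in embeds if e[0] == chrom]
        for _, s, e, _, _, inst in chrom_embeds:
            seq[s:e] = inst.encode()
        planted_here = [
            (p["start"], p["end"], p["strand"], p["motif_class"])
            for p in planted
            if p["chrom"] == chrom
        ]
        planted_intervals = {(s, e) for s, e, _, _ in planted_here}
        protected = set()
        for s, e, _, _ in planted_here:
            protected.update(range(s, s + h))
            protected.update(range(e - h, e))

        for _ in range(30):
            matches = raw_matches(seq.decode(), spec)
            incidental = [m for m in matches if (m[0], m[1]) not in planted_intervals]
            if not incidental:
                break
            for ms, me, strand, label in incidental:
                cands = [
                    p
                    for p in list(range(ms, ms + h)) + list(range(me - h, me))
                    if p not in protected
                ]
                if not cands:
                    raise PlacementError(
                        "incidental match cannot be disrupted without touching "
                        "a planted half-site"
                    )
                pos = cands[0]
                spacer = (me - ms) - 2 * h
                geometry = ("everted" if label.endswith("-ev")
                            else "inverted" if label.endswith("-inv")
                            else "direct")
                pattern = spec.pattern(spacer, geometry, strand)
                allowed = IUPAC[pattern[pos - ms]]
                choices = [b for b in _BASES if b not in allowed]
                seq[pos] = ord(choices[rng.integers(0, len(choices))])
        else:
            raise PlacementError("incidental-match disruption did not converge")

        final = {(m[0], m[1], m[2], m[3]) for m in raw_matches(seq.decode(), spec)}
        if final != set(planted_here):
            raise PlacementError(
                "post-disruption scan does not reproduce exactly the planted sites"
            )
        genome[chrom] = seq.decode()

    return genome, genes, planted


def planted_sites_as_rare(planted: Sequence[dict]) -> list[RareSite]:
    """Manifest planted-site dicts viewed as RareSite objects."""
    return [
        RareSite(p["chrom"], p["start"], p["end"], p["strand"], p["motif_class"], 1)
        for p in sorted(planted, key=lambda p: (p["chrom"], p["start"]))
    ]


def make_cds_set(
    n: int,
    gc3_targets: Sequence[float],
    codons_per_cds: int,
    seed: int,
) -> tuple[dict[str, str], dict[str, float]]:
    """CDS set whose per-sequence GC3 hits each target within 1/m.

    Third-position bases are allocated exactly round(target * m) G/C
    out of m codons and shuffled; first bases are drawn from {A,C,G} so
    no codon can be a stop (stops all begin with T). Returns the
    sequences and the realised GC3 per CDS.
    """
    if len(gc3_targets) != n:
        raise ValueError("need exactly one GC3 target per CDS")
    if codons_per_cds < 1:
        raise ValueError("codons_per_cds must be >= 1")
    for t in gc3_targets:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"GC3 target {t} outside [0, 1]")
    rng = np.random.default_rng(seed)
    m = codons_per_cds
    seqs: dict[str, str] = {}
    realized: dict[str, float] = {}
    for i, target in enumerate(gc3_targets):
        n_gc = int(round(target * m))
        is_gc = np.zeros(m, dtype=bool)
        is_gc[:n_gc] = True
        rng.shuffle(is_gc)
        first = rng.integers(0, 3, size=m)        # A/C/G: no stop codons possible
        second = rng.integers(0, 4, size=m)
        third_gc = rng.integers(0, 2, size=m)     # G or C
        third_at = rng.integers(0, 2, size=m)     # A or T
        codons = []
        for j in range(m):
            third = "GC"[third_gc[j]] if is_gc[j] else "AT"[third_at[j]]
            codons.append("ACG"[first[j]] + _BASES[second[j]] + third)
        cid = f"cds_{i:04d}"
        seqs[cid] = "".join(codons)
        realized[cid] = n_gc / m
    return seqs, realized


def make_hit_table(
    ladder: PhylostrataLadder,
    gene_ages: Mapping[str, int],
    fn_rate: float,
    spurious_rate: float,
    seed: int,
    distractor_rate: float = 0.3,
) -> tuple[pd.DataFrame, list[dict], list[dict]]:
    """Homology hit table encoding the given gene ages.

    In noise-free mode (both rates 0) each gene receives one qualifying
    hit (e <= 1e-3, here e in [1e-30, 1e-4]) in its true stratum and in
    every younger stratum up to (not including) the focal species'
    stratum, plus a self-hit and, sometimes, a non-qualifying distractor
    (e > 1e-3) in an older stratum. Downstream assignment therefore
    recovers the planted ages exactly.

    With noise, each qualifying hit is dropped with probability
    ``fn_rate`` and a spurious qualifying hit in a stratum older than
    the truth is added with probability ``spurious_rate`` per gene;
    both perturbations are returned so tests can diff against them.
    """
    for name, rate in (("fn_rate", fn_rate), ("spurious_rate", spurious_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    youngest = ladder.youngest
    valid = {s.ps_index for s in ladder.strata}
    species_by_stratum: dict[int, list[str]] = {ps: [] for ps in valid}
    for sp, ps in sorted(ladder.species_map.items()):
        if sp != ladder.focal_species:
            species_by_stratum[ps].append(sp)

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, float]] = []
    dropped: list[dict] = []
    spurious: list[dict] = []

    def qualifying_e() -> float:
        return float(10.0 ** -rng.uniform(4.0, 30.0))

    for gene in sorted(gene_ages):
        true_ps = gene_ages[gene]
        if true_ps not in valid:
            raise ValueError(f"gene {gene!r} assigned unknown stratum {true_ps}")
        rows.append((gene, ladder.focal_species, 1e-50))  # self-hit, never ages
        for ps in range(true_ps, youngest):
            pool = species_by_stratum[ps]
            if not pool:
                raise ValueError(f"stratum {ps} has no non-focal species")
            sp = pool[rng.integers(0, len(pool))]
            e = qualifying_e()
            # the draw happens regardless of the rate, so the noisy table is
            # the noise-free one minus exactly the dropped rows
            if rng.random() < fn_rate:
                dropped.append({"query_id": gene, "subject_species": sp, "e_value": e})
            else:
                rows.append((gene, sp, e))
        if true_ps > 1 and rng.random() < distractor_rate:
            ps = int(rng.integers(1, true_ps))
            pool = species_by_stratum[ps]
            if pool:
                # fails the 1e-3 threshold by construction
                rows.append(
                    (gene, pool[rng.integers(0, len(pool))],
                     float(10.0 ** -rng.uniform(0.0, 2.5)))
                )
        if rng.random() < spurious_rate and true_ps > 1:
            ps = int(rng.integers(1, true_ps))
            pool = species_by_stratum[ps]
            if pool:
                sp = pool[rng.integers(0, len(pool))]
                e = qualifying_e()
                rows.append((gene, sp, e))
                spurious.append(
                    {"query_id": gene, "subject_species": sp, "e_value": e,
                     "stratum": ps}
                )

    table = pd.DataFrame(rows, columns=["query_id", "subject_species", "e_value"])
    return table, dropped, spurious


def make_expression(
    n_genes: int,
    biased_sets: Mapping[str, tuple[int | Sequence[str], float]],
    total_fragments: int,
    seed: int,
    noise: bool = True,
    tissues: tuple[str, str] = ("bell", "tentacle"),
) -> tuple[pd.DataFrame, pd.Series, pd.Series, dict[str, float], dict[str, list[str]]]:
    """Two-tissue fragment counts with planted fold-change multipliers.

    Each biased set is (member genes or a member count, multiplier m):
    its genes get expected first-tissue counts m times their
    second-tissue expectation, so — with equal library totals — the
    expected FPKM ratio is exactly m. Counts are Poisson around the
    expectation when ``noise`` is true, else the exact expectation.

    Returns (counts, lengths, totals, per-gene effect multipliers,
    set membership).
    """
    num_t, den_t = tissues
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    membership: dict[str, list[str]] = {}
    effects = {g: 1.0 for g in genes}
    cursor = 0
    for label, (members, mult) in biased_sets.items():
        if mult <= 0:
            raise ValueError(f"set {label!r}: multiplier must be > 0")
        if isinstance(members, int):
            ids = genes[cursor : cursor + members]
            if len(ids) < members:
                raise ValueError("more biased genes requested than genes exist")
            cursor += members
        else:
            ids = list(members)
            unknown = set(ids) - set(genes)
            if unknown:
                raise ValueError(f"unknown genes in set {label!r}: {sorted(unknown)[:5]}")
        membership[label] = ids
        for g in ids:
            effects[g] = float(mult)

    lengths = pd.Series(
        rng.integers(500, 5001, size=n_genes).astype(int), index=genes, name="length"
    )
    lam_den = rng.integers(50, 501, size=n_genes).astype(float)
    lam_num = lam_den * np.array([effects[g] for g in genes])
    if noise:
        c_num = rng.poisson(lam_num).astype(float)
        c_den = rng.poisson(lam_den).astype(float)
    else:
        c_num, c_den = lam_num, lam_den
    counts = pd.DataFrame({num_t: c_num, den_t: c_den}, index=genes)
    totals = pd.Series(
        {num_t: float(total_fragments), den_t: float(total_fragments)}, name="total"
    )
    if (counts.sum(axis=0) > total_fragments).any():
        raise ValueError("planted expression exceeds the library fragment total")
    return counts, lengths, totals, effects, membership


def make_families_and_domains(
    species_groups: Mapping[str, Sequence[str]],
    n_families: int,
    domain_vocab: Sequence[str],
    seed: int,
    presence_prob: float = 0.55,
    domain_presence_prob: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], dict[str, dict[str, int]]]:
    """Ortholog-family membership and domain tables with recorded truth.

    Each family's species-presence pattern is drawn independently per
    species (guaranteed non-empty) and recorded; each (species, domain)
    pair carries a planted occurrence count. Venn regions, specific
    families and census matrices are then computable from the returned
    truth by plain set algebra.
    """
    seen: set[str] = set()
    for label, members in species_groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"species group {label!r} is empty")
        if seen & set(members):
            raise ValueError("species groups must be disjoint")
        seen |= set(members)
    all_species = [sp for members in species_groups.values() for sp in members]

    rng = np.random.default_rng(seed)
    fam_rows: list[tuple[str, str, str]] = []
    family_truth: dict[str, list[str]] = {}
    for i in range(n_families):
        fam = f"fam_{i:05d}"
        present = rng.random(len(all_species)) < presence_prob
        if not present.any():
            present[rng.integers(0, len(all_species))] = True
        members = [sp for sp, p in zip(all_species, present) if p]
        family_truth[fam] = sorted(members)
        for sp in members:
            for j in range(int(rng.integers(1, 6))):
                fam_rows.append((fam, sp, f"{sp}|{fam}|g{j}"))
    families = pd.DataFrame(fam_rows, columns=["family_id", "species", "gene_id"])

    dom_rows: list[tuple[str, str, str, int, int]] = []
    domain_truth: dict[str, dict[str, int]] = {}
    for sp in all_species:
        domain_truth[sp] = {}
        serial = 0
        for acc in domain_vocab:
            if rng.random() >= domain_presence_prob:
                continue
            count = int(rng.integers(1, 5))
            domain_truth[sp][acc] = count
            for _ in range(count):
                start = int(rng.integers(1, 200))
                dom_rows.append((sp, f"{sp}|p{serial:05d}", acc, start,
                                 start + int(rng.integers(30, 120))))
                serial += 1
    domains = pd.DataFrame(
        dom_rows, columns=["species", "protein_id", "accession", "start", "end"]
    )
    return families, domains, family_truth, domain_truth


# ---------------------------------------------------------------------------
# Config-driven end-to-end simulation


def default_config() -> dict:
    """The default synthetic study conditions.

    These mirror the biological setting the pipeline was built for: a
    multi-megabase genome with ~500 response elements averaging ~13 kb
    from the nearest TSS and a handful of Hox-like genes with elements
    inside ±10 kb; a gene cohort that is ~80% ancient, ~3% middle-aged
    and ~17% young; a CDS set with 100 strongly GC3-biased genes; bell
    vs tentacle expression with myosin-heavy-chain-like (~8.8x) and
    myosin-light-chain-like (~17x) biased sets; and three two-species
    cnidarian-class-like groups for the family Venn.
    """
    return {
        "genome": {
            "n_chrom": 6,
            "chrom_len": 5_000_000,
            "n_genes": 540,
            "gene_length": 1000,
        },
        "rare": {
            "n_sites": 500,
            "proximal_distances": [2000, -4000, 6000, -8000],
            "distal_abs_mean": 13000.0,
            "distal_abs_sd": 3000.0,
            "distal_abs_min": 10500.0,
            "distal_abs_max": 24000.0,
            "class_weights": {"DR5": 0.6, "DR1": 0.2, "DR2": 0.2},
        },
        "cds": {
            "n": 600,
            "n_high": 100,
            "high_range": [0.85, 0.95],
            "background_range": [0.2, 0.7],
            "codons_per_cds": 300,
        },
        "phylostrat": {
            "n_proteins": 10_000,
            "era_probs": {"ancient": 0.80, "middle": 0.03, "young": 0.17},
            "n_short": 10,
            "fn_rate": 0.0,
            "spurious_rate": 0.0,
        },
        "expression": {
            "n_genes": 500,
            "total_fragments": 5_000_000,
            "noise": True,
            "sets": {
                "myosin_heavy_like": {"size": 7, "multiplier": 8.8},
                "myosin_light_like": {"size": 21, "multiplier": 17.0},
            },
        },
        "families": {
            "groups": {
                "Scyphozoa": ["Nemopilema_synthetica", "Aurelia_synthetica"],
                "Hydrozoa": ["Hydra_synthetica", "Clytia_synthetica"],
                "Anthozoa": ["Acropora_synthetica", "Nematostella_synthetica"],
            },
            "n_families": 2000,
        },
        "domains": {
            "focal_species": "Nemopilema_synthetica",
            "target_domains": [
                "PF01421", "PF01549", "PF06607", "PF00068", "PF05826",
            ] + [f"PF9{i:04d}" for i in range(15)],
            "extra_domains": [f"PF8{i:04d}" for i in range(10)],
        },
    }


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _build_rare_plan(cfg: dict, rng: np.random.Generator) -> list[tuple[str, int]]:
    classes = list(cfg["class_weights"])
    weights = np.array([cfg["class_weights"][c] for c in classes], dtype=float)
    weights /= weights.sum()
    plan: list[tuple[str, int]] = []
    for d in cfg["proximal_distances"]:
        plan.append((classes[rng.choice(len(classes), p=weights)], int(d)))
    n_distal = int(cfg["n_sites"]) - len(plan)
    if n_distal < 0:
        raise ValueError("n_sites smaller than the proximal distance list")
    lo, hi = float(cfg["distal_abs_min"]), float(cfg["distal_abs_max"])
    for _ in range(n_distal):
        while True:  # rejection sampling within the |distance| band
            mag = rng.normal(cfg["distal_abs_mean"], cfg["distal_abs_sd"])
            if lo <= mag <= hi:
                break
        sign = 1 if rng.integers(0, 2) == 0 else -1
        plan.append((classes[rng.choice(len(classes), p=weights)], int(sign * round(mag))))
    return plan


def simulate(
    config: Mapping | None = None,
    seed: int = 0,
    outdir: str | os.PathLike = "synthetic",
) -> SyntheticManifest:
    """Generate every pipeline input under ``outdir`` with one manifest.

    Writes genome.fasta, genes.gff3, cds.fasta, hits.tsv,
    protein_lengths.tsv, counts.tsv, gene_lengths.tsv, totals.tsv,
    families.tsv, domains.tsv, ladder.yaml and manifest.json. The same
    (config, seed) always reproduces byte-identical files.
    """
    cfg = _merge(default_config(), config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    sub = {name: int(s) for name, s in zip(
        ("plan", "genome", "cds", "hits", "ages", "expr", "fam"),
        master.integers(0, 2**31 - 1, size=7),
    )}

    manifest = SyntheticManifest(seed=int(seed))

    # --- genome with planted response elements
    plan_rng = np.random.default_rng(sub["plan"])
    rare_plan = _build_rare_plan(cfg["rare"], plan_rng)
    g = cfg["genome"]
    genome, genes, planted = make_genome(
        g["n_chrom"], g["chrom_len"], g["n_genes"], rare_plan,
        seed=sub["genome"], gene_length=g["gene_length"],
    )
    mio.write_fasta(outdir / "genome.fasta", genome)
    mio.write_gff3_genes(outdir / "genes.gff3", genes)
    manifest.planted_rares = planted

    # --- CDS set with planted GC3 levels
    c = cfg["cds"]
    cds_rng = np.random.default_rng(sub["cds"])
    n_high, n_bg = int(c["n_high"]), int(c["n"]) - int(c["n_high"])
    targets = list(cds_rng.uniform(*c["high_range"], size=n_high)) + list(
        cds_rng.uniform(*c["background_range"], size=n_bg)
    )
    cds, realized = make_cds_set(c["n"], targets, c["codons_per_cds"], seed=sub["cds"])
    mio.write_fasta(outdir / "cds.fasta", cds)
    manifest.gc3_targets = realized
    manifest.extras["gc3_high_set"] = sorted(list(cds)[:n_high])

    # --- gene ages and homology hits
    p = cfg["phylostrat"]
    ladder = default_ladder()
    ladder.to_yaml(outdir / "ladder.yaml")
    age_rng = np.random.default_rng(sub["ages"])
    era_ranges = {"ancient": (1, 5), "middle": (6, 7), "young": (8, 11)}
    labels = list(era_ranges)
    probs = np.array([p["era_probs"][lb] for lb in labels], dtype=float)
    probs /= probs.sum()
    ages: dict[str, int] = {}
    lengths: dict[str, int] = {}
    n_prot, n_short = int(p["n_proteins"]), int(p["n_short"])
    for i in range(n_prot):
        pid = f"prot_{i:05d}"
        lo, hi = era_ranges[labels[age_rng.choice(len(labels), p=probs)]]
        ages[pid] = int(age_rng.integers(lo, hi + 1))
        lengths[pid] = int(age_rng.integers(40, 1001))
    for i in range(n_short):  # below the 40-aa cutoff: excluded downstream
        pid = f"prot_{n_prot + i:05d}"
        lo, hi = era_ranges[labels[age_rng.choice(len(labels), p=probs)]]
        ages[pid] = int(age_rng.integers(lo, hi + 1))
        lengths[pid] = int(age_rng.integers(10, 40))
    hits, dropped, spurious = make_hit_table(
        ladder, ages, p["fn_rate"], p["spurious_rate"], seed=sub["hits"]
    )
    mio.write_tsv(hits, outdir / "hits.tsv")
    mio.write_tsv(
        pd.DataFrame(
            sorted(lengths.items()), columns=["protein_id", "length_aa"]
        ),
        outdir / "protein_lengths.tsv",
    )
    manifest.gene_ages = ages
    manifest.extras["protein_lengths"] = lengths
    manifest.extras["dropped_hits"] = dropped
    manifest.extras["spurious_hits"] = spurious

    # --- expression
    e = cfg["expression"]
    sets = {
        label: (int(spec["size"]) if "size" in spec else list(spec["genes"]),
                float(spec["multiplier"]))
        for label, spec in e["sets"].items()
    }
    counts, glengths, totals, effects, membership = make_expression(
        int(e["n_genes"]), sets, int(e["total_fragments"]),
        seed=sub["expr"], noise=bool(e["noise"]),
    )
    mio.write_tsv(counts.rename_axis("gene").reset_index(), outdir / "counts.tsv")
    mio.write_tsv(
        glengths.rename_axis("gene").reset_index(), outdir / "gene_lengths.tsv"
    )
    mio.write_tsv(
        totals.rename_axis("tissue").reset_index(), outdir / "totals.tsv"
    )
    manifest.tissue_effects = effects
    manifest.extras["expression_sets"] = membership
    manifest.extras["expression_noise"] = bool(e["noise"])

    # --- families and domains
    f = cfg["families"]
    d = cfg["domains"]
    vocab = list(d["target_domains"]) + list(d["extra_domains"])
    families, domains, fam_truth, dom_truth = make_families_and_domains(
        f["groups"], int(f["n_families"]), vocab, seed=sub["fam"]
    )
    mio.write_tsv(families, outdir / "families.tsv")
    mio.write_tsv(domains, outdir / "domains.tsv")
    manifest.family_truth = fam_truth
    manifest.extras["domain_truth"] = dom_truth
    manifest.extras["species_groups"] = {k: list(v) for k, v in f["groups"].items()}
    manifest.extras["target_domains"] = list(d["target_domains"])
    manifest.extras["focal_species"] = d["focal_species"]
    manifest.extras["config"] = cfg

    manifest.save(outdir / "manifest.json")
    return manifest
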