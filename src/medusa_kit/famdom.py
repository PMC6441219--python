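"""Ortholog-family set algebra and protein-domain censuses.

Comparative genomics of gene content starts from an ortholog family
membership table (family x species gene counts, typically produced by
OrthoMCL-style clustering, which is an input here, not a computation).
Two standard summaries are provided:

* Venn-region counts of families across species *groups* (e.g.
  taxonomic classes each containing several genomes), where a family is
  present in a group if at least one member species carries it (or all
  members, under the stricter rule).
* Lineage-specific families: present in a focal group, absent from all
  others.

The domain census counts occurrences of a target list of domain
accessions (e.g. Pfam toxin domains) in per-species protein->domain
annotation tables, summarising how many targets appear anywhere and how
many in a focal species.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "FamilyMatrix",
    "family_venn",
    "group_specific_families",
    "domain_census",
    "DomainCensus",
]


@dataclass(frozen=True)
class FamilyMatrix:
    """family_id -> {species: gene count}; presence means count >= 1."""

    families: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for fam, counts in self.families.items():
            for sp, c in counts.items():
                if c < 0 or int(c) != c:
                    raise ValueError(
                        f"family {fam!r} species {sp!r}: counts must be "
                        f"non-negative integers, got {c!r}"
                    )

    @classmethod
    def from_long_table(cls, table: pd.DataFrame) -> "FamilyMatrix":
        """Build from a long (family_id, species, gene_id) table."""
        required = {"family_id", "species", "gene_id"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"family table missing columns: {sorted(missing)}")
        counts = (
            table.groupby(["family_id", "species"], sort=True)["gene_id"]
            .nunique()
        )
        fams: dict[str, dict[str, int]] = {}
        for (fam, sp), c in counts.items():
            fams.setdefault(str(fam), {})[str(sp)] = int(c)
        return cls(fams)

    def species(self) -> set[str]:
        out: set[str] = set()
        for counts in self.families.values():
            out |= set(counts)
        return out

    def present_in(self, family_id: str, species: Sequence[str],
                   require_all: bool = False) -> bool:
        counts = self.families[family_id]
        quant = all if require_all else any
        return quant(counts.get(sp, 0) >= 1 for sp in species)


def _check_groups(matrix: FamilyMatrix, groups: Mapping[str, Sequence[str]]) -> None:
    seen: set[str] = set()
    known = matrix.species()
    for label, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {label!r} is empty")
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"groups share species: {sorted(overlap)}")
        seen |= set(members)
        unknown = set(members) - known
        if unknown:
            raise ValueError(
                f"group {label!r} lists species absent from the matrix: "
                f"{sorted(unknown)}"
            )


def region_label(group_subset: Sequence[str]) -> str:
    return "&".join(group_subset)


def family_venn(
    matrix: FamilyMatrix,
    groups: Mapping[str, Sequence[str]],
    require_all: bool = False,
) -> dict[str, int]:
    """Counts of families in every Venn region over species groups.

    A family belongs to the region of exactly the set of groups it is
    present in. All 2^g - 1 non-empty regions are reported (keys join
    group labels with ``&`` in the order given), and the region counts
    sum to the number of families present in at least one group.
    """
    _check_groups(matrix, groups)
    labels = list(groups)
    regions = {
        region_label(sub): 0
        for r in range(1, len(labels) + 1)
        for sub in combinations(labels, r)
    }
    for fam in matrix.families:
        present = tuple(
            lb for lb in labels if matrix.present_in(fam, groups[lb], require_all)
        )
        if present:
            regions[region_label(present)] += 1
    return regions


def group_specific_families(
    matrix: FamilyMatrix,
    focal_group: Sequence[str],
    other_groups: Mapping[str, Sequence[str]],
    require_all: bool = False,
) -> set[str]:
    """Families present in the focal group and absent from every other."""
    groups = {"__focal__": list(focal_group), **{k: list(v) for k, v in other_groups.items()}}
    _check_groups(matrix, groups)
    out: set[str] = set()
    for fam in matrix.families:
        if not matrix.present_in(fam, focal_group, require_all):
            continue
        if any(matrix.present_in(fam, members) for members in other_groups.values()):
            continue
        out.add(fam)
    return out


@dataclass(frozen=True)
class DomainCensus:
    counts: pd.DataFrame  # species x target accession occurrence counts
    n_targets_in_any_species: int
    n_targets_in_focal: int


def domain_census(
    domain_table: pd.DataFrame,
    targets: Sequence[str],
    focal_species: str,
    per_protein: bool = False,
) -> DomainCensus:
    """Occurrence counts of target domain accessions per species.

    ``domain_table`` is long format with columns species, protein_id,
    accession (start/end columns optional and ignored). By default a
    protein annotated with the same domain twice contributes 2; with
    ``per_protein=True`` it contributes 1 (presence/absence per
    protein). The summary reports how many of the targets occur at
    least once in any species, and in the focal species.
    """
    required = {"species", "protein_id", "accession"}
    missing = required - set(domain_table.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    targets = list(dict.fromkeys(targets))  # keep order, drop dups
    sub = domain_table[domain_table["accession"].isin(targets)]
    if per_protein:
        sub = sub.drop_duplicates(subset=["species", "protein_id", "accession"])
    pivot = (
        sub.groupby(["species", "accession"]).size().unstack(fill_value=0)
        if len(sub)
        else pd.DataFrame()
    )
    species = sorted(domain_table["species"].unique())
    counts = pivot.reindex(index=species, columns=targets, fill_value=0).fillna(0).astype(int)
    any_present = int((counts.sum(axis=0) >= 1).sum())
    focal_present = (
        int((counts.loc[focal_species] >= 1).sum()) if focal_species in counts.index else 0
    )
    return DomainCensus(counts, any_present, focal_present)
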