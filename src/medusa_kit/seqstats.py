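"""Assembly summary statistics and the GC3 codon-usage statistic.

GC3 — the fraction of G or C at the third position of codons — is a
classic codon-bias measure: synonymous third positions are largely free
of amino-acid constraint, so persistent G/C enrichment there reflects
mutational bias and/or selection on codon usage. Ranking genes by GC3
and asking what the top of the ranking is enriched for is the standard
downstream use, and :func:`rank_gc3` supports exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AssemblyStats",
    "Gc3Record",
    "scaffold_stats",
    "gc3",
    "gc3_records",
    "rank_gc3",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_GC = frozenset("GC")
_UNAMBIGUOUS = frozenset("ACGT")
_GAP = frozenset("Nn")


@dataclass(frozen=True)
class AssemblyStats:
    """Scaffold-level summary of an assembly."""

    n_scaffolds: int
    total_bp: int
    n50: int
    gap_fraction: float
    gc_overall: float


@dataclass(frozen=True)
class Gc3Record:
    """Per-gene GC3 measurement.

    ``gc3`` is None when the CDS has no usable codon (e.g. every third
    base ambiguous); such records never enter a ranking.
    """

    gene_id: str
    n_codons_used: int
    gc3: float | None


def scaffold_stats(sequences: Iterable[str]) -> AssemblyStats:
    """Compute scaffold count, total size, N50, gap fraction and GC.

    N50 is the length L such that scaffolds of length >= L, taken in
    descending order of length, cumulatively cover at least half of the
    assembly; it is always a member of the scaffold length multiset.
    Gap bases are N/n; GC is computed over non-gap bases only, with
    soft-masked (lowercase) bases counted as their base identity.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("scaffold_stats requires at least one sequence")
    lengths = sorted((len(s) for s in seqs), reverse=True)
    total = sum(lengths)
    if total == 0:
        raise ValueError("scaffold_stats requires at least one non-empty sequence")

    half = total / 2
    cum = 0
    n50 = lengths[-1]
    for length in lengths:
        cum += length
        if cum >= half:
            n50 = length
            break

    gap = 0
    gc = 0
    for s in seqs:
        u = s.upper()
        gap += u.count("N")
        gc += u.count("G") + u.count("C")
    non_gap = total - gap
    return AssemblyStats(
        n_scaffolds=len(seqs),
        total_bp=total,
        n50=n50,
        gap_fraction=gap / total,
        gc_overall=(gc / non_gap) if non_gap else 0.0,
    )


def gc3(cds: str) -> tuple[int, float | None]:
    """GC fraction at third codon positions of a coding sequence.

    The trailing incomplete codon (if any) is dropped, a terminal stop
    codon is excluded, and codons whose third base is not an unambiguous
    A/C/G/T are excluded from both numerator and denominator. Returns
    ``(n_codons_used, gc3)``; ``gc3`` is None when no codon is usable.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    seq = cds.upper()
    n_codons = len(seq) // 3
    if seq[(n_codons - 1) * 3 : n_codons * 3] in STOP_CODONS:
        n_codons -= 1
    used = 0
    gc_count = 0
    for i in range(n_codons):
        third = seq[i * 3 + 2]
        if third in _UNAMBIGUOUS:
            used += 1
            if third in _GC:
                gc_count += 1
    if used == 0:
        return 0, None
    return used, gc_count / used


def gc3_records(cds_by_gene: Mapping[str, str]) -> list[Gc3Record]:
    """Compute a :class:`Gc3Record` for every CDS in a mapping."""
    out = []
    for gene_id, seq in cds_by_gene.items():
        used, frac = gc3(seq)
        out.append(Gc3Record(gene_id=gene_id, n_codons_used=used, gc3=frac))
    return out


def rank_gc3(
    records: Sequence[Gc3Record], top_n: int, min_codons: int = 30
) -> list[str]:
    """Return the gene ids of the ``top_n`` most GC3-biased genes.

    Records with fewer than ``min_codons`` usable codons (or none at
    all) are excluded before ranking. Order is by descending GC3 with
    ties broken lexicographically by gene id, so the selection is
    deterministic across platforms. Returns min(top_n, available) ids.
    """
    if not records:
        raise ValueError("rank_gc3 requires at least one record")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    eligible = [
        r for r in records if r.gc3 is not None and r.n_codons_used >= min_codons
    ]
    eligible.sort(key=lambda r: (-r.gc3, r.gene_id))
    return [r.gene_id for r in eligible[:top_n]]


def longest_cds_per_gene(
    cds_by_id: Mapping[str, str], gene_of
) -> dict[str, str]:
    """Pick one representative (longest) CDS per gene.

    ``gene_of`` maps a CDS id to its gene id. Length ties go to the
    lexicographically smaller CDS id, for reproducibility. Use this
    when a transcriptome carries several isoforms per locus and GC3
    should be computed once per gene.
    """
    best: dict[str, tuple[int, str]] = {}
    for cds_id in sorted(cds_by_id):
        gene = gene_of(cds_id)
        key = (-len(cds_by_id[cds_id]), cds_id)
        if gene not in best or key < best[gene]:
            best[gene] = key
    return {gene: cds_by_id[cds_id] for gene, (_, cds_id) in best.items()}


def dense_ranks(records: Sequence[Gc3Record]) -> dict[str, int]:
    """1-based dense rank by descending GC3 (equal GC3 -> equal rank)."""
    usable = sorted(
        (r for r in records if r.gc3 is not None),
        key=lambda r: (-r.gc3, r.gene_id),
    )
    ranks: dict[str, int] = {}
    rank = 0
    prev: float | None = None
    for r in usable:
        if r.gc3 != prev:
            rank += 1
            prev = r.gc3
        ranks[r.gene_id] = rank
    return ranks
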