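"""FPKM expression, tissue fold-change classes, and term enrichment.

FPKM (fragments per kilobase of exon model per million mapped
fragments) normalises a gene's fragment count C by its exon-model
length L (bp) and the tissue's total mapped fragments N:

    FPKM = C * 1e9 / (N * L)

Tissue contrast (e.g. medusa bell vs tentacle) is summarised per gene
as the FPKM ratio, with genes unexpressed in both tissues excluded and
one-sided zeros reported as an explicit infinity sentinel rather than
hidden behind a pseudocount. Classification uses strict thresholds:
"greater than twofold" (fc > 2) and "greater than fourfold" (fc > 4),
with the fourfold class nested in the twofold class.

Term enrichment (GO-style over-representation) is the one-sided
hypergeometric upper-tail test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionTable",
    "FoldChangeRecord",
    "SetFoldSummary",
    "EnrichmentResult",
    "fpkm",
    "fold_change",
    "set_mean_fold",
    "hypergeom_enrich",
]

EXCLUDED_BOTH_ZERO = "EXCLUDED_BOTH_ZERO"
OK = "OK"


def fpkm(C, L, N):
    """FPKM = C * 1e9 / (N * L); vectorised over array-like inputs."""
    C = np.asarray(C, dtype=float)
    L = np.asarray(L, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("total mapped fragments N must be positive")
    if np.any(L <= 0):
        raise ValueError("exon-model lengths L must be positive")
    if np.any(C < 0):
        raise ValueError("fragment counts C must be non-negative")
    out = C * 1e9 / (N * L)
    return float(out) if out.ndim == 0 else out


@dataclass
class ExpressionTable:
    """Gene x tissue fragment counts with lengths and library totals."""

    counts: pd.DataFrame           # genes x tissues
    lengths: pd.Series             # per gene, bp
    totals: pd.Series              # per tissue, total mapped fragments

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index.tolist()[:5]
            raise ValueError(f"genes missing a length, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("lengths must be positive")
        self.totals = self.totals.reindex(self.counts.columns)
        if self.totals.isna().any() or (self.totals <= 0).any():
            raise ValueError("every tissue needs a positive fragment total")
        col_sums = self.counts.sum(axis=0)
        if (self.totals + 1e-9 < col_sums).any():
            raise ValueError("tissue totals must be >= assigned fragment sums")

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        lengths: pd.Series,
        totals: pd.Series | None = None,
    ) -> "ExpressionTable":
        """Build a table; with no totals given, use column sums (flagged
        by the caller-facing CLI as inferred)."""
        if totals is None:
            totals = counts.sum(axis=0)
        return cls(counts=counts, lengths=lengths, totals=totals)

    def fpkm_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            fpkm(
                self.counts.to_numpy(),
                self.lengths.to_numpy()[:, None],
                self.totals.to_numpy()[None, :],
            ),
            index=self.counts.index,
            columns=self.counts.columns,
        )


@dataclass(frozen=True)
class FoldChangeRecord:
    gene: str
    fc: float | None           # None when excluded; math.inf for one-sided zero
    status: str                # OK | EXCLUDED_BOTH_ZERO
    fold_class: str            # NONE | GE2 | GE4


def _classify(fc: float) -> str:
    if fc > 4:
        return "GE4"
    if fc > 2:
        return "GE2"
    return "NONE"


def fold_change(
    table: ExpressionTable,
    num_tissue: str,
    den_tissue: str,
    pseudocount: float = 0.0,
) -> list[FoldChangeRecord]:
    """Per-gene FPKM ratio num/den with strict >2x / >4x classes.

    Genes with zero FPKM in both tissues are excluded (they carry no
    contrast information). With the default zero pseudocount, a zero
    denominator against a nonzero numerator yields an infinite fold
    change, which by construction exceeds any finite threshold and is
    classed GE4.
    """
    for t in (num_tissue, den_tissue):
        if t not in table.counts.columns:
            raise ValueError(f"tissue {t!r} not in table")
    f = table.fpkm_table()
    out: list[FoldChangeRecord] = []
    for gene in table.counts.index:
        a = float(f.at[gene, num_tissue])
        b = float(f.at[gene, den_tissue])
        if a == 0 and b == 0:
            out.append(FoldChangeRecord(gene, None, EXCLUDED_BOTH_ZERO, "NONE"))
            continue
        num, den = a + pseudocount, b + pseudocount
        fc = math.inf if den == 0 else num / den
        out.append(FoldChangeRecord(gene, fc, OK, _classify(fc)))
    return out


@dataclass(frozen=True)
class SetFoldSummary:
    mean_fc: float | None      # None when no finite member exists
    n_finite: int
    n_infinite: int
    n_excluded: int


def set_mean_fold(
    records: Sequence[FoldChangeRecord], gene_set: set[str]
) -> SetFoldSummary:
    """Arithmetic mean fold change over a gene set.

    Only members with OK status and a finite fold change enter the
    mean; infinite and excluded members are tallied but never averaged.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    finite: list[float] = []
    n_inf = n_exc = 0
    for r in records:
        if r.gene not in gene_set:
            continue
        if r.status == EXCLUDED_BOTH_ZERO:
            n_exc += 1
        elif math.isinf(r.fc):
            n_inf += 1
        else:
            finite.append(r.fc)
    mean = sum(finite) / len(finite) if finite else None
    return SetFoldSummary(mean, len(finite), n_inf, n_exc)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int      # term genes in the study set
    n: int      # study set size
    K: int      # term genes in the population
    M: int      # population size
    p: float    # hypergeometric upper-tail P(X >= k)
    q: float    # adjusted


def hypergeom_enrich(
    study: set[str],
    population: set[str],
    term_map: Mapping[str, set[str]],
    adjust: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per term.

    For each term with K genes in a population of M, the probability of
    observing at least k term genes in a study draw of size n is the
    hypergeometric upper tail. Term gene sets are intersected with the
    population first. Adjusted values use the given method from
    statsmodels ("fdr_bh" by default; "none" disables adjustment).
    Results are sorted by (p, term).
    """
    if not population:
        raise ValueError("population must be non-empty")
    extra = study - population
    if extra:
        raise ValueError(f"study genes outside population, e.g. {sorted(extra)[:5]}")
    M = len(population)
    n = len(study)
    rows: list[tuple[str, int, int]] = []
    for term, genes in term_map.items():
        in_pop = genes & population
        rows.append((term, len(in_pop & study), len(in_pop)))
    if not rows:
        return []
    ps = np.array([hypergeom.sf(k - 1, M, K, n) for _, k, K in rows])
    ps = np.clip(ps, 0.0, 1.0)
    if adjust == "none":
        qs = ps
    else:
        qs = multipletests(ps, method=adjust)[1]
    results = [
        EnrichmentResult(term, k, n, K, M, float(p), float(q))
        for (term, k, K), p, q in zip(rows, ps, qs)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results
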