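"""Direct-repeat response-element scanning and TSS proximity statistics.

Retinoic-acid response elements (RAREs) are composite nuclear-receptor
binding sites: two copies of a hexameric half-site (canonically RGKTCA
in IUPAC notation) arranged as a direct repeat separated by a short
spacer. The spacer length names the element class — DR1, DR2 and DR5
(5-bp spacer) are the classes bound by RAR/RXR heterodimers.

This module scans a genome for such elements on both strands, merges
overlapping raw matches into maximal regions, and relates the merged
regions to gene models: the signed distance from a region's midpoint to
the nearest transcription start site (negative = upstream in the gene's
own orientation), a fixed-width histogram of those distances, and the
set of genes with an element within a window of their TSS.

Coordinates are 0-based half-open internally; GFF3 input is 1-based
inclusive and converted at the boundary; BED output is 0-based
half-open.

The default grammar (RGKTCA half-site, DR1/DR2/DR5 spacing, zero
mismatches, direct repeats only) is the canonical one from the nuclear
receptor literature and is fully configurable; everted/inverted repeat
geometries are deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "IUPAC",
    "GeneModel",
    "MotifSpec",
    "RareSite",
    "TssProximity",
    "DistanceHistogram",
    "scan_rare",
    "tss_distances",
    "bin_distances",
    "genes_near_rare",
    "rare_summary",
    "reverse_complement",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_BASE_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene's location; coordinates 0-based half-open on the chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("gene span must satisfy 0 <= start < end")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


_GEOMETRIES = ("direct", "everted", "inverted")


@dataclass(frozen=True)
class MotifSpec:
    """Composite-element grammar: half-site, spacer classes, mismatches.

    ``geometries`` selects the half-site arrangements scanned for:
    direct repeats (>> , the default), everted repeats (<<ward-facing,
    i.e. revcomp(half) + spacer + half) and inverted repeats
    (half + spacer + revcomp(half)). Non-direct matches carry a
    ``-ev`` / ``-inv`` suffix on their spacer-class label.
    """

    half_site: str = "RGKTCA"
    spacers: Mapping[int, str] = field(
        default_factory=lambda: {1: "DR1", 2: "DR2", 5: "DR5"}
    )
    max_mismatches_per_half_site: int = 0
    geometries: tuple[str, ...] = ("direct",)

    def __post_init__(self) -> None:
        if len(self.half_site) < 4:
            raise ValueError("half_site must be at least 4 bases")
        bad = set(self.half_site.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters in half_site: {sorted(bad)}")
        if any(s < 0 for s in self.spacers):
            raise ValueError("spacer lengths must be non-negative")
        if self.max_mismatches_per_half_site < 0:
            raise ValueError("max_mismatches_per_half_site must be >= 0")
        unknown = set(self.geometries) - set(_GEOMETRIES)
        if unknown or not self.geometries:
            raise ValueError(f"geometries must be a non-empty subset of {_GEOMETRIES}")
        object.__setattr__(self, "half_site", self.half_site.upper())

    def width(self, spacer: int) -> int:
        return 2 * len(self.half_site) + spacer

    def pattern(self, spacer: int, geometry: str = "direct",
                strand: str = "+") -> str:
        """IUPAC pattern shown on the forward axis by a match."""
        h = self.half_site
        rc = h.translate(_COMPLEMENT)[::-1]
        gap = "N" * spacer
        base = {"direct": h + gap + h,
                "everted": rc + gap + h,
                "inverted": h + gap + rc}[geometry]
        return base if strand == "+" else base.translate(_COMPLEMENT)[::-1]

    def forward_pattern(self, spacer: int) -> str:
        """Direct-repeat pattern of a plus-strand match on the forward axis."""
        return self.pattern(spacer, "direct", "+")

    def reverse_pattern(self, spacer: int) -> str:
        """Direct-repeat pattern a minus-strand match shows on the forward axis."""
        return self.pattern(spacer, "direct", "-")

    def class_label(self, spacer: int, geometry: str) -> str:
        label = self.spacers[spacer]
        return {"direct": label, "everted": f"{label}-ev",
                "inverted": f"{label}-inv"}[geometry]


@dataclass(frozen=True)
class RareSite:
    """A maximal merged region of raw direct-repeat matches."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_class: str
    merged_from: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("site must have end > start")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TssProximity:
    site: RareSite
    nearest_gene: str | None
    signed_distance: int | None


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def matches_iupac(seq: str, pattern: str, max_mm_per_half: int = 0,
                  half_len: int | None = None) -> bool:
    """Does ``seq`` match the IUPAC ``pattern`` exactly in length?

    Mismatches are budgeted per half-site: the first ``half_len`` and
    last ``half_len`` pattern positions each tolerate up to
    ``max_mm_per_half`` mismatches; spacer positions (pattern N) always
    match A/C/G/T and never N in the subject.
    """
    if len(seq) != len(pattern):
        return False
    if half_len is None:
        half_len = len(pattern) // 2
    mm_first = mm_second = 0
    for i, (base, pat) in enumerate(zip(seq.upper(), pattern)):
        if base in IUPAC[pat] and base in "ACGT":
            continue
        if i < half_len:
            mm_first += 1
        elif i >= len(pattern) - half_len:
            mm_second += 1
        else:
            return False  # spacer position holding a non-ACGT base
        if mm_first > max_mm_per_half or mm_second > max_mm_per_half:
            return False
    return True


def raw_matches(
    chrom_seq: str, spec: MotifSpec
) -> list[tuple[int, int, str, str]]:
    """All unmerged matches in one sequence as (start, end, strand, class).

    Both strands are scanned; minus-strand matches are reported on the
    forward axis. With zero mismatches the scan is a compiled-regex
    pass per (spacer, strand); with mismatches allowed it falls back to
    an explicit sliding window.
    """
    seq = chrom_seq.upper()
    h = len(spec.half_site)
    out: list[tuple[int, int, str, str]] = []
    for spacer in spec.spacers:
        w = spec.width(spacer)
        for geometry in spec.geometries:
            label = spec.class_label(spacer, geometry)
            # everted/inverted patterns are their own reverse complement,
            # so a minus-strand pass would only duplicate every match
            strands = ("+", "-") if geometry == "direct" else ("+",)
            for strand in strands:
                pattern = spec.pattern(spacer, geometry, strand)
                if spec.max_mismatches_per_half_site == 0:
                    rx = _iupac_regex(pattern)
                    for m in rx.finditer(seq):
                        out.append((m.start(), m.start() + w, strand, label))
                else:
                    for i in range(len(seq) - w + 1):
                        if matches_iupac(
                            seq[i : i + w], pattern,
                            spec.max_mismatches_per_half_site, h,
                        ):
                            out.append((i, i + w, strand, label))
    out.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return out


def scan_rare(genome: Mapping[str, str], spec: MotifSpec | None = None) -> list[RareSite]:
    """Scan a genome for direct-repeat elements and merge overlaps.

    Overlapping raw matches are merged into maximal regions regardless
    of strand or spacer class; the merged region keeps the strand and
    class of its first (leftmost) contributor and records how many raw
    matches it absorbed. Output is sorted by (chrom, start).
    """
    if not genome:
        raise ValueError("scan_rare requires a non-empty genome")
    spec = spec or MotifSpec()
    sites: list[RareSite] = []
    for chrom in sorted(genome):
        raw = raw_matches(genome[chrom], spec)
        cur: list | None = None
        for start, end, strand, label in raw:
            if cur is not None and start < cur[1]:
                cur[1] = max(cur[1], end)
                cur[4] += 1
            else:
                if cur is not None:
                    sites.append(RareSite(chrom, cur[0], cur[1], cur[2], cur[3], cur[4]))
                cur = [start, end, strand, label, 1]
        if cur is not None:
            sites.append(RareSite(chrom, cur[0], cur[1], cur[2], cur[3], cur[4]))
    return sites


def _signed_distance(midpoint: int, gene: GeneModel) -> int:
    if gene.strand == "+":
        return midpoint - gene.tss
    return gene.tss - midpoint


def _signed_span_distance(midpoint: int, gene: GeneModel) -> int:
    """Distance to the gene body: 0 inside, signed in gene orientation."""
    if gene.start <= midpoint < gene.end:
        return 0
    if gene.strand == "+":
        return midpoint - gene.start if midpoint < gene.start else midpoint - (gene.end - 1)
    return (gene.end - 1) - midpoint if midpoint >= gene.end else gene.start - midpoint


def tss_distances(
    sites: Sequence[RareSite],
    genes: Sequence[GeneModel],
    reference: str = "tss",
) -> list[TssProximity]:
    """Signed distance of each site midpoint to its nearest gene.

    Distance is measured from the site midpoint (integer floor of the
    region centre) to the TSS by default, signed in the gene's
    orientation: negative = upstream of the TSS. With
    ``reference="span"`` the distance is to the gene body instead (zero
    inside the span, otherwise to the nearest gene edge, same sign
    convention). Nearest gene minimises |distance|, ties broken by
    lexicographically smaller gene id. Sites on a chromosome without
    genes get a null nearest gene.
    """
    if reference not in ("tss", "span"):
        raise ValueError("reference must be 'tss' or 'span'")
    dist = _signed_distance if reference == "tss" else _signed_span_distance
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[TssProximity] = []
    for site in sites:
        candidates = by_chrom.get(site.chrom)
        if not candidates:
            out.append(TssProximity(site, None, None))
            continue
        mid = site.midpoint
        best = min(candidates, key=lambda g: (abs(dist(mid, g)), g.gene_id))
        out.append(TssProximity(site, best.gene_id, dist(mid, best)))
    return out


@dataclass(frozen=True)
class DistanceHistogram:
    lo: int
    hi: int
    bin_width: int
    counts: tuple[int, ...]
    overflow: int

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_edges(self) -> list[tuple[int, int]]:
        return [
            (self.lo + i * self.bin_width, self.lo + (i + 1) * self.bin_width)
            for i in range(self.n_bins)
        ]


def bin_distances(
    distances: Iterable[int],
    bin_width: int = 1000,
    lo: int = -100_000,
    hi: int = 100_000,
) -> DistanceHistogram:
    """Histogram signed distances into half-open [lo, lo+width) bins.

    Values outside [lo, hi) land in a single overflow tally, so
    sum(counts) + overflow always equals the number of inputs. The bin
    width must divide the range exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if hi <= lo or (hi - lo) % bin_width != 0:
        raise ValueError("bin_width must divide the [lo, hi) range exactly")
    n_bins = (hi - lo) // bin_width
    counts = [0] * n_bins
    overflow = 0
    for d in distances:
        idx = (d - lo) // bin_width
        if 0 <= idx < n_bins:
            counts[idx] += 1
        else:
            overflow += 1
    return DistanceHistogram(lo, hi, bin_width, tuple(counts), overflow)


def genes_near_rare(
    sites: Sequence[RareSite],
    genes: Sequence[GeneModel],
    window: int = 10_000,
) -> list[tuple[str, int]]:
    """Genes with a site midpoint within ±window bp of their TSS.

    The window is inclusive (|distance| <= window). Each qualifying
    gene appears once with the signed distance of its nearest site
    (minimal |distance|, ties toward the more upstream site). Result
    sorted by gene id.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mids_by_chrom: dict[str, list[int]] = {}
    for s in sites:
        mids_by_chrom.setdefault(s.chrom, []).append(s.midpoint)
    out: list[tuple[str, int]] = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        mids = mids_by_chrom.get(g.chrom)
        if not mids:
            continue
        dists = [_signed_distance(m, g) for m in mids]
        best = min(dists, key=lambda d: (abs(d), d))
        if abs(best) <= window:
            out.append((g.gene_id, best))
    return out


def rare_summary(proximities: Sequence[TssProximity]) -> tuple[int, float]:
    """(number of sites, mean |distance| to the nearest gene's TSS).

    The mean is over sites that have a nearest gene; at least one such
    site is required.
    """
    dists = [p.signed_distance for p in proximities if p.nearest_gene is not None]
    if not dists:
        raise ValueError("no site has a nearest gene")
    return len(proximities), sum(abs(d) for d in dists) / len(dists)
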