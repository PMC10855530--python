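"""Genome-organization statistics: spacers, overlaps, partitions, gene order.

Adjacent annotated features on a circular mitogenome either abut, leave an
intergenic spacer (positive gap) or overlap (negative gap).  The boundary
after the last feature wraps around the circular origin back to the first.
For a fully tiled circular genome the accounting obeys a conservation law::

    sum(feature sizes) + total spacer bp - total overlap bp = genome length

which this module exposes as an executable check.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .mito_io import AnnotatedMitogenome, GeneTable, ValidationError
from .util import round_half_up

#: Ancestral teleost mitochondrial gene order (H-strand origin at trnF).
ANCESTRAL_TELEOST_ORDER: tuple[str, ...] = (
    "trnF", "12S", "trnV", "16S", "trnL2", "ND1", "trnI", "trnQ", "trnM",
    "ND2", "trnW", "trnA", "trnN", "trnC", "trnY", "COI", "trnS2", "trnD",
    "COII", "trnK", "atp8", "atp6", "COIII", "trnG", "ND3", "trnR", "ND4L",
    "ND4", "trnH", "trnS1", "trnL1", "ND5", "ND6", "trnE", "Cytb", "trnT",
    "trnP", "CR",
)


@dataclass
class BoundaryRecord:
    """Gap after ``upstream_gene``: + spacer, - overlap, 0 abutting."""

    upstream_gene: str
    downstream_gene: str
    gap_nt: int


@dataclass
class ArchitectureReport:
    genome_length: int
    spacer_count: int
    spacer_total_bp: int
    longest_spacer: tuple[str, str, int] | None
    overlap_count: int
    overlap_total_bp: int
    longest_overlap: tuple[str, str, int] | None
    class_total_bp: dict[str, int]
    class_pct: dict[str, float]
    strand_census: dict[str, dict[str, int]]
    feature_total_bp: int = 0
    boundaries: list[BoundaryRecord] = field(default_factory=list)

    def tiling_residual(self) -> int:
        """0 when the conservation law holds."""
        return (self.feature_total_bp + self.spacer_total_bp
                - self.overlap_total_bp - self.genome_length)

    def to_dict(self) -> dict:
        d = {
            "genome_length": self.genome_length,
            "spacer_count": self.spacer_count,
            "spacer_total_bp": self.spacer_total_bp,
            "longest_spacer": self.longest_spacer,
            "overlap_count": self.overlap_count,
            "overlap_total_bp": self.overlap_total_bp,
            "longest_overlap": self.longest_overlap,
            "feature_total_bp": self.feature_total_bp,
            "class_total_bp": self.class_total_bp,
            "class_pct": self.class_pct,
            "strand_census": self.strand_census,
        }
        return d


def _as_genome(obj: AnnotatedMitogenome | GeneTable) -> AnnotatedMitogenome:
    if isinstance(obj, GeneTable):
        g = obj.to_genome()
        # a gene table's genome length can exceed the last feature stop
        if obj.genome_length > g.length:
            raise ValidationError("gene table genome_length below last stop")
        return g
    return obj


def compute_boundaries(obj: AnnotatedMitogenome | GeneTable,
                       genome_length: int | None = None) -> list[BoundaryRecord]:
    """One record per adjacent feature pair in genome order, plus the
    circular wrap pair (last feature back to the first).

    ``gap_nt = downstream.start - upstream.stop - 1``; for the wrap pair the
    downstream start is lifted by the genome length.
    """
    genome = _as_genome(obj)
    feats = genome.features
    if len(feats) < 2:
        raise ValidationError("need at least 2 features to compute boundaries")
    n = genome_length or genome.length
    out: list[BoundaryRecord] = []
    for up, down in zip(feats, feats[1:]):
        if down.start < up.start:
            raise ValidationError(f"features unsorted at {up.name}/{down.name}")
        if down.stop <= up.stop:
            raise ValidationError(f"feature {down.name} nested inside {up.name}")
        out.append(BoundaryRecord(up.name, down.name,
                                  down.start - up.stop - 1))
    last, first = feats[-1], feats[0]
    out.append(BoundaryRecord(last.name, first.name,
                              first.start + n - last.stop - 1))
    return out


def summarize_architecture(obj: AnnotatedMitogenome | GeneTable,
                           genome_length: int | None = None) -> ArchitectureReport:
    """Counts, totals and extremes of spacers/overlaps plus partition and
    strand accounting.  Percentages are of genome length, rounded to two
    decimals half-up (printed-table convention)."""
    genome = _as_genome(obj)
    n = genome_length or (obj.genome_length if isinstance(obj, GeneTable)
                          else genome.length)
    bounds = compute_boundaries(genome, n)
    spacers = [b for b in bounds if b.gap_nt > 0]
    overlaps = [b for b in bounds if b.gap_nt < 0]
    longest_sp = max(spacers, key=lambda b: b.gap_nt, default=None)
    longest_ov = min(overlaps, key=lambda b: b.gap_nt, default=None)
    class_bp: dict[str, int] = {}
    strand: dict[str, dict[str, int]] = {}
    total = 0
    for f in genome.features:
        class_bp[f.gene_class] = class_bp.get(f.gene_class, 0) + f.size
        strand.setdefault(f.gene_class, {"H": 0, "L": 0})[f.strand] += 1
        total += f.size
    class_pct = {c: round_half_up(100.0 * bp / n, 2) for c, bp in class_bp.items()}
    return ArchitectureReport(
        genome_length=n,
        spacer_count=len(spacers),
        spacer_total_bp=sum(b.gap_nt for b in spacers),
        longest_spacer=(longest_sp.upstream_gene, longest_sp.downstream_gene,
                        longest_sp.gap_nt) if longest_sp else None,
        overlap_count=len(overlaps),
        overlap_total_bp=-sum(b.gap_nt for b in overlaps),
        longest_overlap=(longest_ov.upstream_gene, longest_ov.downstream_gene,
                         -longest_ov.gap_nt) if longest_ov else None,
        class_total_bp=class_bp,
        class_pct=class_pct,
        strand_census=strand,
        feature_total_bp=total,
        boundaries=bounds,
    )


@dataclass
class GeneOrderReport:
    identical: bool
    duplications: dict[str, int]
    missing: list[str]
    order_breaking: list[str]


def _lcs(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Longest common subsequence (classic DP)."""
    m, k = len(a), len(b)
    dp = [[0] * (k + 1) for _ in range(m + 1)]
    for i in range(m - 1, -1, -1):
        for j in range(k - 1, -1, -1):
            dp[i][j] = (dp[i + 1][j + 1] + 1 if a[i] == b[j]
                        else max(dp[i + 1][j], dp[i][j + 1]))
    out: list[str] = []
    i = j = 0
    while i < m and j < k:
        if a[i] == b[j]:
            out.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return out


def compare_gene_order(
    genome: AnnotatedMitogenome | GeneTable,
    reference_order: Sequence[str] = ANCESTRAL_TELEOST_ORDER,
) -> GeneOrderReport:
    """Compare a genome's gene order with a reference order.

    Reports (i) names present more than once, with counts, (ii) reference
    names missing from the genome, (iii) order-breaking names: occurrences
    not part of a longest common subsequence with the reference.
    """
    g = _as_genome(genome) if not isinstance(genome, AnnotatedMitogenome) else genome
    observed = [f.name for f in g.features]
    counts: dict[str, int] = {}
    for nm in observed:
        counts[nm] = counts.get(nm, 0) + 1
    duplications = {nm: c for nm, c in counts.items() if c > 1}
    missing = [nm for nm in reference_order if nm not in counts]
    # first-occurrence order vs reference
    first_order = list(dict.fromkeys(observed))
    keep = set(_lcs(first_order, list(reference_order)))
    order_breaking = [nm for nm in first_order if nm not in keep]
    identical = not duplications and not missing and not order_breaking and (
        first_order == list(reference_order)
    )
    return GeneOrderReport(identical, duplications, missing, order_breaking)
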