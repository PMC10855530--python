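"""Base composition and strand-skew statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), the standard
strand-asymmetry measures for mitochondrial genomes.  Percentages are
computed over unambiguous bases only (N excluded from every denominator).
"""
from __future__ import annotations

from dataclasses import dataclass

from .mito_io import AnnotatedMitogenome, ValidationError, concat_partition
from .util import round_half_up


@dataclass
class CompositionStats:
    n_sites: int          # unambiguous bases
    counts: dict[str, int]
    pct: dict[str, float]
    at_pct: float
    gc_pct: float
    at_skew: float
    gc_skew: float
    at_skew_degenerate: bool = False  # A+T == 0, skew reported as 0
    gc_skew_degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites, **{k: v for k, v in self.counts.items()},
            **{f"pct_{k}": v for k, v in self.pct.items()},
            "at_pct": self.at_pct, "gc_pct": self.gc_pct,
            "at_skew": self.at_skew, "gc_skew": self.gc_skew,
        }


def composition_stats(seq: str) -> CompositionStats:
    """Counts, percentages, AT/GC content and both skews for one sequence.

    A zero skew denominator (no A/T, or no G/C) yields skew 0 with the
    corresponding degenerate flag set, so tabular output stays rectangular.
    """
    if not seq:
        raise ValidationError("empty sequence")
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    n = sum(counts.values())
    if n == 0:
        raise ValidationError("sequence contains no unambiguous bases")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    at_deg = (a + t) == 0
    gc_deg = (g + c) == 0
    return CompositionStats(
        n_sites=n,
        counts=counts,
        pct={b: round_half_up(100.0 * counts[b] / n, 2) for b in "ACGT"},
        at_pct=round_half_up(100.0 * (a + t) / n, 2),
        gc_pct=round_half_up(100.0 * (g + c) / n, 2),
        at_skew=0.0 if at_deg else (a - t) / (a + t),
        gc_skew=0.0 if gc_deg else (g - c) / (g + c),
        at_skew_degenerate=at_deg,
        gc_skew_degenerate=gc_deg,
    )


PARTITIONS = ("whole", "PCG", "rRNA", "tRNA", "CR")


def partition_composition(genome: AnnotatedMitogenome) -> dict[str, CompositionStats]:
    """Composition per partition {whole, PCG, rRNA, tRNA, CR}.

    Partition rows are computed on the concatenation of sense-strand gene
    sequences in genome order; the whole-genome row uses the H strand as
    deposited.  Missing partitions are omitted (with a warning from the
    extraction layer).
    """
    if genome.sequence is None:
        raise ValidationError(f"{genome.accession}: sequence absent")
    out: dict[str, CompositionStats] = {"whole": composition_stats(genome.sequence)}
    for part in PARTITIONS[1:]:
        cat = concat_partition(genome, part)
        if cat:
            out[part] = composition_stats(cat)
    return out
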