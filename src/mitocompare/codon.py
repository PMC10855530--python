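"""Codon extraction, start/stop identification, RSCU and amino-acid usage
under the vertebrate mitochondrial genetic code (NCBI translation table 2).

Peculiarities of the code that matter here: AGA/AGG are stop codons, ATA is
Met and TGA is Trp.  Mitochondrial PCGs frequently end on incomplete stops
("T--" or "TA-") completed to TAA by post-transcriptional polyadenylation;
those trailing remnants are recorded but never enter usage counts.

Relative synonymous codon usage (RSCU) of a codon is its observed count
divided by the mean count of its synonymous family; 1 means no bias.
Leucine and serine are split into their two-fold and four-fold degeneracy
sub-families (Leu2 = TTA/TTG, Leu4 = CTN, Ser2 = AGT/AGC, Ser4 = TCN), the
convention used by per-codon usage panels.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[2]

#: codon -> one-letter amino acid, with '*' for stops
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

MITO_STOP_CODONS = frozenset(_TABLE.stop_codons)  # TAA, TAG, AGA, AGG
MITO_START_CODONS = frozenset(_TABLE.start_codons)

ALL_CODONS = tuple("".join(c) for c in itertools.product("TCAG", repeat=3))


def _build_families() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = CODON_TO_AA[codon]
        if aa == "*":
            continue
        if aa == "L":
            key = "Leu2" if codon[0] == "T" else "Leu4"
        elif aa == "S":
            key = "Ser2" if codon[0] == "A" else "Ser4"
        else:
            key = aa
        fams.setdefault(key, []).append(codon)
    return {k: tuple(v) for k, v in fams.items()}


#: degeneracy families used for RSCU (Leu/Ser split into 2- and 4-fold)
RSCU_FAMILIES: dict[str, tuple[str, ...]] = _build_families()
_CODON_TO_FAMILY = {c: fam for fam, cs in RSCU_FAMILIES.items() for c in cs}

#: family -> parent amino acid letter
FAMILY_TO_AA = {fam: CODON_TO_AA[cs[0]] for fam, cs in RSCU_FAMILIES.items()}


@dataclass
class CodonExtraction:
    gene: str
    codons: list[str]
    start_codon: str
    stop_codon: str          # complete triplet or incomplete "T--"/"TA-"
    remainder: int           # 0, 1 or 2 trailing bases
    warnings: list[str] = field(default_factory=list)


def extract_codons(gene_seq: str, gene: str = "",
                   declared_length: int | None = None) -> CodonExtraction:
    """Split a sense-strand PCG sequence into codons and classify its stop.

    Length mod 3 == 1 records an incomplete stop "T--" (the trailing base is
    expected to be T); mod 3 == 2 records a two-base remnant such as "TA-".
    A complete final triplet is checked against the mitochondrial stop set;
    inconsistencies raise warnings, never errors (real annotations contain
    them).
    """
    seq = gene_seq.upper()
    if declared_length is not None and declared_length != len(seq):
        raise ValueError(f"{gene}: declared length {declared_length} != "
                         f"sequence length {len(seq)}")
    if len(seq) < 6:
        raise ValueError(f"{gene}: sequence shorter than two codons")
    rem = len(seq) % 3
    n_full = len(seq) // 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_full)]
    warns: list[str] = []
    if rem == 0:
        stop = codons[-1]
        if stop not in MITO_STOP_CODONS:
            warns.append(f"{gene}: final codon {stop} is not a "
                         "mitochondrial stop codon")
    else:
        tail = seq[3 * n_full :]
        stop = tail + "-" * (3 - rem)
        # remnant must be completable to TAA by polyadenylation
        if not "TAA".startswith(tail):
            warns.append(f"{gene}: trailing remnant {tail!r} cannot be "
                         "poly-A-completed to TAA")
    for w in warns:
        warnings.warn(w)
    return CodonExtraction(gene, codons, codons[0], stop, rem, warns)


@dataclass
class CodonUsageTable:
    counts: dict[str, int]              # all 64 codons
    rscu: dict[str, float]
    rscu_undefined: frozenset[str]      # codons of unobserved families
    aa_counts: dict[str, int]           # per family (Leu2/Leu4/... keys)
    aa_abundance: dict[str, float]      # family count / total codons
    total_codons: int
    genetic_code_id: int = 2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for codon in ALL_CODONS:
            fam = _CODON_TO_FAMILY.get(codon)
            rows.append({
                "codon": codon,
                "amino_acid": CODON_TO_AA[codon],
                "family": fam or "stop",
                "count": self.counts[codon],
                "rscu": self.rscu.get(codon, float("nan")),
                "rscu_defined": codon not in self.rscu_undefined
                                 and fam is not None,
            })
        return pd.DataFrame(rows)

    def top_amino_acids(self, n: int = 4) -> list[str]:
        """Most abundant amino acids (one-letter), Leu/Ser families merged."""
        merged: dict[str, int] = {}
        for fam, cnt in self.aa_counts.items():
            merged[FAMILY_TO_AA[fam]] = merged.get(FAMILY_TO_AA[fam], 0) + cnt
        return [aa for aa, _ in sorted(merged.items(),
                                       key=lambda kv: (-kv[1], kv[0]))][:n]


def codon_usage_rscu(extractions: list[CodonExtraction],
                     include_start_codons: bool = True) -> CodonUsageTable:
    """Codon usage counts, RSCU and amino-acid relative abundance.

    Complete stop codons and incomplete stop remnants are excluded from the
    counts.  Start codons are genuine codons and included by default;
    ``include_start_codons=False`` drops each gene's first codon.

    RSCU(c) = count(c) / mean count of c's synonymous family.  Codons whose
    family was never observed get RSCU 0 and appear in ``rscu_undefined``.
    """
    if not extractions:
        raise ValueError("need at least one gene")
    counts = {c: 0 for c in ALL_CODONS}
    for ex in extractions:
        cods = ex.codons if include_start_codons else ex.codons[1:]
        if ex.remainder == 0 and cods and cods[-1] in MITO_STOP_CODONS:
            cods = cods[:-1]
        for c in cods:
            if c in counts:
                counts[c] += 1
    # stop codons never counted even if present mid-sequence by annotation error
    usable = {c: n for c, n in counts.items() if c in _CODON_TO_FAMILY}
    total = sum(usable.values())
    rscu: dict[str, float] = {}
    undefined: set[str] = set()
    aa_counts: dict[str, int] = {}
    for fam, codons in RSCU_FAMILIES.items():
        fam_total = sum(usable[c] for c in codons)
        aa_counts[fam] = fam_total
        if fam_total == 0:
            for c in codons:
                rscu[c] = 0.0
                undefined.add(c)
        else:
            mean = fam_total / len(codons)
            for c in codons:
                rscu[c] = usable[c] / mean
    aa_abundance = {fam: (cnt / total if total else 0.0)
                    for fam, cnt in aa_counts.items()}
    return CodonUsageTable(counts, rscu, frozenset(undefined), aa_counts,
                           aa_abundance, total)


def translate_codon(codon: str) -> str:
    """One-letter translation under the vertebrate mitochondrial code."""
    return CODON_TO_AA[codon.upper()]
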