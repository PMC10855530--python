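"""Reading and writing annotated mitochondrial genomes and gene tables.

Coordinates are 1-based and fully inclusive on both ends throughout the
public API, the convention used by printed mitogenome gene tables.  Internal
conversions to Python's 0-based half-open slices happen only inside this
module.

A vertebrate mitogenome is modelled as a circular sequence plus an ordered
list of gene features: 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and
the AT-rich control region (CR).  Features that would span the circular
origin are rejected: none occur in the genomes this package targets, and
accepting them silently is a classic source of off-by-one bugs.
"""
from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .util import clean_dna, reverse_complement

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "CR", "other")

PCG_NAMES = (
    "ND1", "ND2", "COI", "COII", "atp8", "atp6", "COIII",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "Cytb",
)
RRNA_NAMES = ("12S", "16S")
TRNA_NAMES = (
    "trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA",
    "trnN", "trnC", "trnY", "trnS2", "trnD", "trnK", "trnG", "trnR",
    "trnH", "trnS1", "trnL1", "trnE", "trnT", "trnP",
)

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# GenBank / annotation-server synonyms -> canonical labels
_SYNONYMS = {
    "COX1": "COI", "COXI": "COI", "CO1": "COI", "COI": "COI",
    "COX2": "COII", "COXII": "COII", "CO2": "COII", "COII": "COII",
    "COX3": "COIII", "COXIII": "COIII", "CO3": "COIII", "COIII": "COIII",
    "CYTB": "Cytb", "COB": "Cytb", "CYT B": "Cytb", "CYB": "Cytb",
    "ATP6": "atp6", "ATPASE6": "atp6", "ATPASE 6": "atp6",
    "ATP8": "atp8", "ATPASE8": "atp8", "ATPASE 8": "atp8",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "ND1": "ND1", "ND2": "ND2", "ND3": "ND3", "ND4": "ND4",
    "ND4L": "ND4L", "ND5": "ND5", "ND6": "ND6",
    "12S": "12S", "12S RRNA": "12S", "12S RIBOSOMAL RNA": "12S",
    "RRNS": "12S", "S-RRNA": "12S", "SMALL SUBUNIT RIBOSOMAL RNA": "12S",
    "16S": "16S", "16S RRNA": "16S", "16S RIBOSOMAL RNA": "16S",
    "RRNL": "16S", "L-RRNA": "16S", "LARGE SUBUNIT RIBOSOMAL RNA": "16S",
    "D-LOOP": "CR", "CONTROL REGION": "CR", "CONTROL REGION (CR)": "CR",
    "CR": "CR", "D LOOP": "CR",
}

# single-letter code -> trn label (Ser/Leu need an isoacceptor qualifier)
_TRNA_BY_LETTER = {
    "F": "trnF", "V": "trnV", "I": "trnI", "Q": "trnQ", "M": "trnM",
    "W": "trnW", "A": "trnA", "N": "trnN", "C": "trnC", "Y": "trnY",
    "D": "trnD", "K": "trnK", "G": "trnG", "R": "trnR", "H": "trnH",
    "E": "trnE", "T": "trnT", "P": "trnP",
    "S1": "trnS1", "S2": "trnS2", "L1": "trnL1", "L2": "trnL2",
}

# anticodons (either orientation as printed by different servers)
_SER_LEU_BY_ANTICODON = {
    "GCT": "trnS1", "AGC": "trnS1", "TGA": "trnS2", "TCA": "trnS2",
    "TAG": "trnL1", "CTA": "trnL1", "TAA": "trnL2", "TTA": "trnL2",
}


class MitoFormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input parsed but violates a structural invariant."""


def canonical_gene_name(raw: str, anticodon: str | None = None) -> tuple[str, str]:
    """Map a raw gene/product label to (canonical name, gene class).

    Unknown labels are passed through with gene class ``other``.
    """
    label = raw.strip().strip("*").strip()
    up = label.upper()
    if up in _SYNONYMS:
        name = _SYNONYMS[up]
        if name in PCG_NAMES:
            return name, "PCG"
        if name in RRNA_NAMES:
            return name, "rRNA"
        return name, "CR"
    m = re.match(r"(?:TRNA[- ]?|TRN)(\w+)\s*(?:\(([A-Z]\d?)\))?", up)
    if m:
        body, paren = m.groups()
        key = None
        if paren and paren in _TRNA_BY_LETTER:
            key = paren
        elif len(body) == 1 or (len(body) == 2 and body[1].isdigit()):
            key = body
        elif body[:3] in _AA3TO1:
            key = _AA3TO1[body[:3]]
            suffix = body[3:] if body[3:] in ("1", "2") else ""
            key += suffix
        if key in ("S", "L") and anticodon:
            hit = _SER_LEU_BY_ANTICODON.get(anticodon.upper())
            if hit:
                return hit, "tRNA"
        if key in _TRNA_BY_LETTER:
            return _TRNA_BY_LETTER[key], "tRNA"
        if key in ("S", "L"):
            warnings.warn(
                f"ambiguous {label!r}: Ser/Leu isoacceptor not identified"
            )
            return "trn" + key, "tRNA"
    warnings.warn(f"unrecognized gene label {label!r} kept with class 'other'")
    return label, "other"


@dataclass
class GeneFeature:
    """One annotated gene with 1-based inclusive boundaries."""

    name: str
    gene_class: str
    start: int
    stop: int
    strand: str = "H"
    anticodon: str | None = None  # stored verbatim as printed, not reoriented
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(f"unknown gene class {self.gene_class!r}")
        if self.strand not in ("H", "L"):
            raise ValidationError(f"strand must be H or L, got {self.strand!r}")
        if not (1 <= self.start <= self.stop):
            raise ValidationError(
                f"{self.name}: need 1 <= start <= stop, got {self.start}..{self.stop}"
            )

    @property
    def size(self) -> int:
        return self.stop - self.start + 1


@dataclass
class AnnotatedMitogenome:
    """Circular mitogenome: optional sequence plus ordered gene features."""

    accession: str
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.stop))
        if self.sequence is not None:
            n = len(self.sequence)
            for f in self.features:
                if f.stop > n:
                    raise ValidationError(
                        f"{self.accession}: feature {f.name} ends at {f.stop} "
                        f"beyond sequence length {n}"
                    )

    @property
    def length(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        return max((f.stop for f in self.features), default=0)

    def census(self) -> dict[str, int]:
        out = {c: 0 for c in GENE_CLASSES}
        for f in self.features:
            out[f.gene_class] += 1
        return out

    def get(self, name: str) -> GeneFeature:
        """First feature with the given canonical name."""
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_seq(self, feat: GeneFeature) -> str:
        """Sense-strand (reading-strand) subsequence of one feature."""
        if self.sequence is None:
            raise ValidationError(f"{self.accession}: no sequence attached")
        raw = self.sequence[feat.start - 1 : feat.stop]
        return reverse_complement(raw) if feat.strand == "L" else raw


@dataclass
class GeneTableRow:
    feature: GeneFeature
    intergenic: int | None = None  # spacer (+) / overlap (-) after this gene


@dataclass
class GeneTable:
    rows: list[GeneTableRow]
    genome_length: int

    def to_genome(self, accession: str = "gene-table") -> AnnotatedMitogenome:
        g = AnnotatedMitogenome(accession, None, [r.feature for r in self.rows])
        return g


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}


def read_genbank(path: str | Path) -> AnnotatedMitogenome:
    """Parse a GenBank flat file into an :class:`AnnotatedMitogenome`.

    Gene names are canonicalized (``COX1`` -> ``COI`` etc.); features on the
    complement strand get strand ``L``; a feature whose location wraps the
    circular origin raises :class:`MitoFormatError`.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise MitoFormatError(f"{path}: not a readable GenBank record: {exc}") from exc
    seq = clean_dna(str(record.seq)) if len(record.seq) else None
    feats: list[GeneFeature] = []
    for ft in record.features:
        if ft.type not in _GB_FEATURE_TYPES:
            continue
        label = (
            ft.qualifiers.get("gene", [None])[0]
            or ft.qualifiers.get("product", [None])[0]
            or ft.type
        )
        if ft.type == "D-loop":
            label = "D-loop"
        anticodon = None
        note = ft.qualifiers.get("note", [""])[0]
        m = re.search(r"anticodon[:=]?\s*([ACGTUacgtu]{3})", note)
        if m:
            anticodon = m.group(1).upper().replace("U", "T")
        if len(ft.location.parts) > 1:
            raise MitoFormatError(
                f"{record.id}: feature {label} has a compound location "
                "(possible origin-spanning feature); not supported"
            )
        start = int(ft.location.start) + 1
        stop = int(ft.location.end)
        strand = "L" if ft.location.strand == -1 else "H"
        name, gene_class = canonical_gene_name(label, anticodon)
        feats.append(GeneFeature(name, gene_class, start, stop, strand, anticodon))
    # CDS and gene records often duplicate one another; keep one per (name, start)
    seen: dict[tuple, GeneFeature] = {}
    for f in feats:
        seen.setdefault((f.name, f.start, f.stop), f)
    feats = list(seen.values())
    if not feats:
        warnings.warn(f"{record.id}: no gene features found")
    return AnnotatedMitogenome(record.id or str(path), seq, feats)


_CLASS_TO_GB = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop",
                "other": "misc_feature"}


def write_genbank(genome: AnnotatedMitogenome, path: str | Path) -> None:
    if genome.sequence is None:
        raise ValidationError("cannot write GenBank without a sequence")
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=re.sub(r"\W", "_", genome.accession)[:16],
        description=f"{genome.accession} mitochondrial genome",
        annotations={"molecule_type": "DNA",
                     "topology": "circular" if genome.circular else "linear"},
    )
    for f in genome.features:
        loc = FeatureLocation(f.start - 1, f.stop, strand=-1 if f.strand == "L" else 1)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        rec.features.append(SeqFeature(loc, type=_CLASS_TO_GB[f.gene_class],
                                       qualifiers=quals))
    SeqIO.write(rec, str(path), "genbank")


# ---------------------------------------------------------------------------
# Gene table (TSV)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("Genes", "Start", "Stop", "Strand", "Size (bp)",
                  "Intergenic Nucleotide", "Anticodon", "Start Codon",
                  "Stop Codon")


def _parse_int(text: str, *, row: int, col: str) -> int | None:
    t = text.strip().replace(",", "").replace("−", "-")
    if t in ("", "."):
        return None
    try:
        return int(t)
    except ValueError:
        raise MitoFormatError(f"row {row}: non-numeric {col} value {text!r}") from None


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a tab-separated gene table (printed-table layout).

    Required columns: Genes, Start, Stop, Strand.  Optional: Size (bp),
    Intergenic Nucleotide, Anticodon, Start Codon, Stop Codon.  Thousands
    separators and the typographic minus are tolerated.  A printed Size that
    disagrees with ``stop - start + 1`` raises :class:`ValidationError`.
    """
    rows: list[GeneTableRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "Genes" not in reader.fieldnames:
            raise MitoFormatError(f"{path}: missing header row with 'Genes' column")
        for i, rec in enumerate(reader, start=2):
            raw_name = rec["Genes"]
            start = _parse_int(rec["Start"], row=i, col="Start")
            stop = _parse_int(rec["Stop"], row=i, col="Stop")
            if start is None or stop is None:
                raise MitoFormatError(f"row {i}: missing coordinate")
            strand = (rec.get("Strand") or "H").strip()
            anticodon = (rec.get("Anticodon") or "").strip().strip(".") or None
            name, gene_class = canonical_gene_name(raw_name, anticodon)
            feat = GeneFeature(
                name, gene_class, start, stop, strand, anticodon,
                (rec.get("Start Codon") or "").strip().strip(".") or None,
                (rec.get("Stop Codon") or "").strip().strip(".") or None,
            )
            size = _parse_int(rec.get("Size (bp)") or "", row=i, col="Size")
            if size is not None and size != feat.size:
                raise ValidationError(
                    f"row {i} ({name}): printed size {size} != stop-start+1 "
                    f"= {feat.size}"
                )
            inter = _parse_int(rec.get("Intergenic Nucleotide") or "", row=i,
                               col="Intergenic Nucleotide")
            rows.append(GeneTableRow(feat, inter))
    if not rows:
        raise MitoFormatError(f"{path}: empty gene table")
    genome_length = max(r.feature.stop for r in rows)
    return GeneTable(rows, genome_length)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TABLE_COLUMNS)
        for r in table.rows:
            f = r.feature
            w.writerow([
                f.name, f.start, f.stop, f.strand, f.size,
                "." if r.intergenic is None else r.intergenic,
                f.anticodon or ".", f.start_codon or ".", f.stop_codon or ".",
            ])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = clean_dna(str(rec.seq))
    if not out:
        raise MitoFormatError(f"{path}: no FASTA records")
    return out


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Partition extraction
# ---------------------------------------------------------------------------

def extract_partition(
    genome: AnnotatedMitogenome,
    selector: str | Sequence[str],
) -> list[tuple[str, str]]:
    """Extract sense-strand subsequences for a gene class or list of names.

    ``selector`` is either one of {"PCG", "tRNA", "rRNA", "CR", "other"} or
    an explicit list of canonical gene names.  L-strand features are
    reverse-complemented so every returned sequence reads 5'->3' on its
    coding strand.  Output preserves genome order.
    """
    if genome.sequence is None:
        raise ValidationError(f"{genome.accession}: sequence absent")
    if isinstance(selector, str):
        chosen = [f for f in genome.features if f.gene_class == selector]
    else:
        wanted = set(selector)
        chosen = [f for f in genome.features if f.name in wanted]
    if not chosen:
        warnings.warn(f"{genome.accession}: selector {selector!r} matched nothing")
    return [(f.name, genome.feature_seq(f)) for f in chosen]


def concat_partition(genome: AnnotatedMitogenome, selector: str | Sequence[str]) -> str:
    """Concatenation (genome order) of :func:`extract_partition` output."""
    return "".join(seq for _, seq in extract_partition(genome, selector))
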