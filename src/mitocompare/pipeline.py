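"""Full comparative report over a family of annotated mitogenomes.

Runs every analysis stage in dependency order on N genomes: per-genome
architecture and partition composition, codon usage (RSCU), per-gene
pairwise Ka/Ks, sliding-window nucleotide diversity and saturation on the
concatenated protein-coding supermatrix, a K2P distance matrix, a
neighbor-joining tree with bootstrap supports, and the control-region
conserved-block / tandem-repeat table.

Genes are matched across genomes by canonical name (robust to duplications
and rearrangements; the first copy is used and duplicates are logged), and
genes missing from any taxon — or of unequal length, since no aligner is
run — are dropped from concatenations with a warning.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .architecture import (ANCESTRAL_TELEOST_ORDER, ArchitectureReport,
                           compare_gene_order, summarize_architecture)
from .codon import CodonUsageTable, codon_usage_rscu, extract_codons
from .composition import CompositionStats, partition_composition
from .divergence import (PairwiseDivergence, SlidingWindowProfile,
                         nei_gojobori_kaks, saturation_profile,
                         sliding_window_pi)
from .mito_io import AnnotatedMitogenome
from .phylogeny import (BootstrapResult, DistanceMatrix, bootstrap_support,
                        distance_matrix, write_charsets, write_newick,
                        write_phylip)
from .trna_cr import ConservedBlock, TandemRepeat, find_tandem_repeats, \
    scan_conserved_blocks

log = logging.getLogger("mitocompare")

PCG_ORDER = tuple(n for n in ANCESTRAL_TELEOST_ORDER
                  if n in {"ND1", "ND2", "COI", "COII", "atp8", "atp6",
                           "COIII", "ND3", "ND4L", "ND4", "ND5", "ND6",
                           "Cytb"})
RRNA_ORDER = ("12S", "16S")


@dataclass
class ReportConfig:
    """Thresholds and choices for :func:`run_report`; all defaults are the
    package's documented conventions."""

    dataset: str = "pcg"              # "pcg" or "pcg_rrna" concatenation
    window_bp: int = 200
    step_bp: int = 25
    bootstrap_replicates: int = 1000
    seed: int = 0
    cr_min_identity: float = 0.70
    repeat_min_identity: float = 0.80
    repeat_min_period: int = 10
    repeat_max_period: int = 60
    cr_skip: tuple[str, ...] = ()     # taxa excluded from CR block comparison
    include_start_codons: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReportConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "cr_skip" in doc:
            doc["cr_skip"] = tuple(doc["cr_skip"])
        return cls(**doc)


@dataclass
class ComparativeReport:
    taxa: list[str]
    architecture: dict[str, ArchitectureReport]
    gene_order: dict[str, object]
    composition: dict[str, dict[str, CompositionStats]]
    codon_usage: dict[str, CodonUsageTable]
    kaks: pd.DataFrame                   # gene, taxon_a, taxon_b, ka, ks, ...
    pi_profile: SlidingWindowProfile | None
    saturation: pd.DataFrame | None
    distances: DistanceMatrix | None
    tree: BootstrapResult | None
    cr_blocks: list[ConservedBlock]
    cr_repeats: dict[str, list[TandemRepeat]]
    charsets: list[tuple[str, int, int]]
    supermatrix: dict[str, str]
    provenance: dict
    warnings: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)


def _shared_genes(genomes: list[AnnotatedMitogenome], names: tuple[str, ...],
                  warnings: list[str]) -> dict[str, dict[str, str]]:
    """gene -> {taxon: sense-strand sequence}, keeping genes present in all
    taxa at one shared length."""
    out: dict[str, dict[str, str]] = {}
    for gene in names:
        seqs: dict[str, str] = {}
        missing = []
        for g in genomes:
            copies = [f for f in g.features if f.name == gene]
            if not copies:
                missing.append(g.accession)
                continue
            if len(copies) > 1:
                log.info("%s: %d copies of %s; using the first",
                         g.accession, len(copies), gene)
            seqs[g.accession] = g.feature_seq(copies[0])
        if missing:
            warnings.append(f"{gene}: missing in {missing}; dropped")
            continue
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            warnings.append(f"{gene}: unequal lengths {sorted(lengths)}; "
                            "dropped from concatenation (no aligner is run)")
            continue
        out[gene] = seqs
    return out


def run_report(genomes: list[AnnotatedMitogenome],
               config: ReportConfig | None = None) -> ComparativeReport:
    """Execute the full comparative analysis; independent stages that fail
    are reported in ``report.errors`` under their stage name while the rest
    of the run continues."""
    cfg = config or ReportConfig()
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    for g in genomes:
        if g.sequence is None:
            raise ValueError(f"{g.accession}: sequence required")
    taxa = [g.accession for g in genomes]
    warns: list[str] = []
    errors: dict[str, str] = {}

    arch: dict[str, ArchitectureReport] = {}
    order: dict[str, object] = {}
    comp: dict[str, dict[str, CompositionStats]] = {}
    usage: dict[str, CodonUsageTable] = {}
    for g in genomes:
        try:
            arch[g.accession] = summarize_architecture(g)
            order[g.accession] = compare_gene_order(g)
        except Exception as exc:
            errors[f"architecture:{g.accession}"] = str(exc)
        try:
            comp[g.accession] = partition_composition(g)
        except Exception as exc:
            errors[f"composition:{g.accession}"] = str(exc)
        try:
            pcgs = [f for f in g.features if f.gene_class == "PCG"]
            ext = [extract_codons(g.feature_seq(f), f.name) for f in pcgs]
            usage[g.accession] = codon_usage_rscu(
                ext, include_start_codons=cfg.include_start_codons)
        except Exception as exc:
            errors[f"codon_usage:{g.accession}"] = str(exc)

    genes = _shared_genes(genomes, PCG_ORDER, warns)
    if len(genes) < 2:
        raise ValueError(f"fewer than 2 PCGs shared across all taxa "
                         f"(got {sorted(genes)})")

    # per-gene pairwise Ka/Ks
    kaks_rows = []
    for gene, seqs in genes.items():
        # trim incomplete terminal codon bases
        L = min(len(s) for s in seqs.values())
        L -= L % 3
        for i, ta in enumerate(taxa):
            for tb in taxa[i + 1 :]:
                if ta not in seqs or tb not in seqs:
                    continue
                try:
                    r = nei_gojobori_kaks(seqs[ta][:L], seqs[tb][:L])
                except ValueError as exc:
                    errors[f"kaks:{gene}:{ta}-{tb}"] = str(exc)
                    continue
                kaks_rows.append({"gene": gene, "taxon_a": ta, "taxon_b": tb,
                                  "ka": r.ka, "ks": r.ks, "ka_ks": r.ka_ks,
                                  "flags": ";".join(r.flags)})
    kaks = pd.DataFrame(kaks_rows)

    # supermatrix (PCGs, optionally + rRNAs)
    concat_names = PCG_ORDER if cfg.dataset == "pcg" else PCG_ORDER + RRNA_ORDER
    concat_genes = dict(genes)
    if cfg.dataset == "pcg_rrna":
        concat_genes.update(_shared_genes(genomes, RRNA_ORDER, warns))
    charsets: list[tuple[str, int, int]] = []
    supermatrix: dict[str, str] = {t: "" for t in taxa}
    pos = 0
    for gene in concat_names:
        if gene not in concat_genes:
            continue
        L = len(next(iter(concat_genes[gene].values())))
        charsets.append((gene, pos + 1, pos + L))
        pos += L
        for t in taxa:
            supermatrix[t] += concat_genes[gene][t]

    pi_profile = None
    sat = None
    dm = None
    tree = None
    aln = [supermatrix[t] for t in taxa]
    try:
        pi_profile = sliding_window_pi(aln, cfg.window_bp, cfg.step_bp)
    except Exception as exc:
        errors["sliding_pi"] = str(exc)
    try:
        sat = saturation_profile(supermatrix)
    except Exception as exc:
        errors["saturation"] = str(exc)
    try:
        dm = distance_matrix(supermatrix)
    except Exception as exc:
        errors["distance_matrix"] = str(exc)
    if len(taxa) >= 3:
        try:
            tree = bootstrap_support(supermatrix, cfg.bootstrap_replicates,
                                     cfg.seed)
        except Exception as exc:
            errors["nj_tree"] = str(exc)

    # control region
    crs: dict[str, str] = {}
    for g in genomes:
        cr = [f for f in g.features if f.gene_class == "CR"]
        if cr:
            crs[g.accession] = g.feature_seq(cr[0])
    blocks: list[ConservedBlock] = []
    repeats: dict[str, list[TandemRepeat]] = {}
    if len(crs) >= 2:
        try:
            blocks = scan_conserved_blocks(crs, min_identity=cfg.cr_min_identity,
                                           skip=cfg.cr_skip)
        except Exception as exc:
            errors["cr_blocks"] = str(exc)
        for t, seq in crs.items():
            try:
                repeats[t] = find_tandem_repeats(
                    seq, cfg.repeat_min_period, cfg.repeat_max_period,
                    cfg.repeat_min_identity)
            except Exception as exc:
                errors[f"cr_repeats:{t}"] = str(exc)

    provenance = {
        "package": "mitocompare",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "taxa": taxa,
        "python": sys.version.split()[0],
    }
    return ComparativeReport(
        taxa=taxa, architecture=arch, gene_order=order, composition=comp,
        codon_usage=usage, kaks=kaks, pi_profile=pi_profile, saturation=sat,
        distances=dm, tree=tree, cr_blocks=blocks, cr_repeats=repeats,
        charsets=charsets, supermatrix=supermatrix, provenance=provenance,
        warnings=warns, errors=errors,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_report(report: ComparativeReport, outdir: str | Path) -> None:
    """Write the report as a directory of TSV/JSON/newick artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    arch_rows = []
    for t, a in report.architecture.items():
        row = {"taxon": t, "genome_length": a.genome_length,
               "spacer_count": a.spacer_count,
               "spacer_total_bp": a.spacer_total_bp,
               "overlap_count": a.overlap_count,
               "overlap_total_bp": a.overlap_total_bp}
        for cls, pct in a.class_pct.items():
            row[f"pct_{cls}"] = pct
        arch_rows.append(row)
    pd.DataFrame(arch_rows).to_csv(out / "architecture.tsv", sep="\t",
                                   index=False)

    comp_rows = []
    for t, parts in report.composition.items():
        for part, st in parts.items():
            comp_rows.append({"taxon": t, "partition": part, **st.to_dict()})
    pd.DataFrame(comp_rows).to_csv(out / "composition.tsv", sep="\t",
                                   index=False)

    for t, u in report.codon_usage.items():
        u.to_frame().to_csv(out / f"rscu_{t}.tsv", sep="\t", index=False)

    if len(report.kaks):
        report.kaks.to_csv(out / "kaks.tsv", sep="\t", index=False)
    if report.pi_profile is not None:
        p = report.pi_profile
        pd.DataFrame({"midpoint": p.midpoints, "pi": p.pi}).to_csv(
            out / "sliding_pi.tsv", sep="\t", index=False)
    if report.saturation is not None:
        report.saturation.to_csv(out / "saturation.tsv", sep="\t", index=False)
    if report.distances is not None:
        pd.DataFrame(report.distances.d, index=report.distances.taxa,
                     columns=report.distances.taxa).to_csv(
            out / "k2p_distances.tsv", sep="\t")
    if report.tree is not None:
        write_newick(report.tree.tree, str(out / "nj_tree.nwk"))
    if report.supermatrix:
        write_phylip(report.supermatrix, str(out / "supermatrix.phy"))
        write_charsets(report.charsets, str(out / "charsets.txt"))

    block_rows = []
    for b in report.cr_blocks:
        for sp, m in b.matches.items():
            block_rows.append({"block": b.label, "species": sp,
                               "start": m.start, "stop": m.stop,
                               "identity": m.identity,
                               "variable_columns": b.variable_columns,
                               "sequence": m.sequence})
        for sp in b.absent:
            block_rows.append({"block": b.label, "species": sp,
                               "start": None, "stop": None, "identity": None,
                               "variable_columns": b.variable_columns,
                               "sequence": "ABSENT"})
    if block_rows:
        pd.DataFrame(block_rows).to_csv(out / "cr_blocks.tsv", sep="\t",
                                        index=False)
    repeat_rows = []
    for t, reps in report.cr_repeats.items():
        for r in reps:
            repeat_rows.append({"taxon": t, "start": r.start, "stop": r.stop,
                                "period": r.period,
                                "copy_number": r.copy_number,
                                "identity": r.identity,
                                "consensus": r.consensus})
    pd.DataFrame(repeat_rows).to_csv(out / "cr_repeats.tsv", sep="\t",
                                     index=False)

    meta = {"provenance": report.provenance, "warnings": report.warnings,
            "errors": report.errors}
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
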