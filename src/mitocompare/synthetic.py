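"""Synthetic mitogenome families with known evolutionary truth.

Generates families of ~10 congeneric circular mitogenomes that share the
ancestral teleost gene order (13 PCGs, 22 tRNAs, 2 rRNAs, one control
region), with AT content around 55-57%, transition-biased substitution,
per-gene dN/dS in the strongly purifying range, a control region carrying
conserved blocks and optionally a tandem repeat, and (by default) one
genome with a trnD + CR duplication — the data structure every analysis
stage of this package consumes, with the generating parameters recorded so
estimates can be checked against truth.

Protein-coding genes evolve by acceptance thinning: mutation events are
proposed along each branch under an HKY-like scheme (stationary frequencies
matching the target composition, transitions favoured by kappa), proposals
creating stop codons are always rejected, nonsynonymous proposals are
accepted with probability omega, synonymous ones always.  This keeps exact
per-gene counts of realized synonymous/nonsynonymous substitutions — the
truth record against which NG86 estimates are tested.  Evolution is
indel-free, so homologous genes are born aligned across the family.
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .codon import CODON_TO_AA, MITO_STOP_CODONS
from .mito_io import AnnotatedMitogenome, GeneFeature
from .phylogeny import PhyloTree, TreeNode, write_newick
from .trna_cr import load_motif_library
from .util import reverse_complement

# gene order, class, per-gene default length (PCG lengths are multiples of
# three; other lengths follow typical grouper values), and strand
_T = [
    ("trnF", "tRNA", 70, "H"), ("12S", "rRNA", 953, "H"),
    ("trnV", "tRNA", 72, "H"), ("16S", "rRNA", 1712, "H"),
    ("trnL2", "tRNA", 75, "H"), ("ND1", "PCG", 975, "H"),
    ("trnI", "tRNA", 70, "H"), ("trnQ", "tRNA", 71, "L"),
    ("trnM", "tRNA", 70, "H"), ("ND2", "PCG", 1044, "H"),
    ("trnW", "tRNA", 71, "H"), ("trnA", "tRNA", 69, "L"),
    ("trnN", "tRNA", 73, "L"), ("trnC", "tRNA", 68, "L"),
    ("trnY", "tRNA", 71, "L"), ("COI", "PCG", 1551, "H"),
    ("trnS2", "tRNA", 71, "L"), ("trnD", "tRNA", 73, "H"),
    ("COII", "PCG", 690, "H"), ("trnK", "tRNA", 73, "H"),
    ("atp8", "PCG", 168, "H"), ("atp6", "PCG", 681, "H"),
    ("COIII", "PCG", 783, "H"), ("trnG", "tRNA", 72, "H"),
    ("ND3", "PCG", 348, "H"), ("trnR", "tRNA", 69, "H"),
    ("ND4L", "PCG", 297, "H"), ("ND4", "PCG", 1380, "H"),
    ("trnH", "tRNA", 70, "H"), ("trnS1", "tRNA", 72, "H"),
    ("trnL1", "tRNA", 73, "H"), ("ND5", "PCG", 1839, "H"),
    ("ND6", "PCG", 522, "L"), ("trnE", "tRNA", 69, "L"),
    ("Cytb", "PCG", 1141 - 1, "H"), ("trnT", "tRNA", 73, "H"),
    ("trnP", "tRNA", 70, "L"), ("CR", "CR", 873, "H"),
]
DEFAULT_TEMPLATE: tuple[tuple[str, str, int, str], ...] = tuple(_T)

#: default per-gene dN/dS: strong purifying selection spanning the range
#: observed in grouper mitogenomes, weakest constraint on COIII/Cytb and
#: strongest on ND5
DEFAULT_OMEGA: dict[str, float] = {
    "ND5": 0.011, "ND4L": 0.02, "ND3": 0.03, "ND1": 0.04, "ND6": 0.05,
    "ND4": 0.06, "COII": 0.08, "COI": 0.09, "atp8": 0.10, "ND2": 0.12,
    "atp6": 0.14, "Cytb": 0.17, "COIII": 0.199,
}

#: anticodon-loop triplets used when building tRNAs (trnS1 lacks a DHU arm)
TRNA_ANTICODONS: dict[str, str] = {
    "trnF": "GAA", "trnV": "TAC", "trnL2": "TAA", "trnI": "GAT",
    "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA", "trnA": "TGC",
    "trnN": "GTT", "trnC": "GCA", "trnY": "GTA", "trnS2": "TGA",
    "trnD": "GTC", "trnK": "TTT", "trnG": "TCC", "trnR": "TCG",
    "trnH": "GTG", "trnS1": "GCT", "trnL1": "TAG", "trnE": "TTC",
    "trnT": "TGT", "trnP": "TGG",
}

ETAS_REPEAT_MOTIF = "CATATATGTATAGTAAC"  # 17 bp grouper-style ETAS unit


@dataclass
class SimulationSpec:
    """Parameters of one simulated family; defaults mirror a small genus of
    grouper-like mitogenomes."""

    seed: int = 0
    n_taxa: int = 10
    tree_height: float = 0.2          # expected proposals/site root->tip
    tree_newick: str | None = None    # overrides the random ultrametric tree
    at_content: float = 0.56
    kappa: float = 2.0                # transition/transversion rate bias
    per_gene_omega: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OMEGA))
    genome_template: tuple[tuple[str, str, int, str], ...] = DEFAULT_TEMPLATE
    rna_rate_scale: float = 0.2       # tRNA/rRNA evolve slower than PCG sites
    cr_block_rate_scale: float = 0.1  # conserved CR blocks vs CR background
    cr_repeat_taxon: str | None = "taxon03"  # taxon receiving an ETAS repeat
    cr_repeat_motif: str = ETAS_REPEAT_MOTIF
    cr_repeat_copies: float = 2.7
    #: (taxon, feature names) duplications; default mirrors a genus where one
    #: member carries a trnD + CR duplication
    rearrangements: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("taxon10", ("trnD", "CR")),
    )

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        for g, w in self.per_gene_omega.items():
            if w < 0:
                raise ValueError(f"omega must be >= 0 ({g})")
        for name, cls, length, _ in self.genome_template:
            if cls == "PCG" and length % 3:
                raise ValueError(f"PCG {name} length {length} not divisible by 3")


@dataclass
class TruthRecord:
    seed: int
    taxa: list[str]
    tree_newick: str
    substitutions: dict[str, dict[str, int]]   # gene -> {syn, nonsyn, other}
    planted_repeat: dict | None
    planted_duplications: dict[str, list[str]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _base_probs(at: float) -> dict[str, float]:
    return {"A": at / 2, "T": at / 2, "G": (1 - at) / 2, "C": (1 - at) / 2}


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    p = _base_probs(at)
    return "".join(rng.choice(list("ATGC"), size=n,
                              p=[p["A"], p["T"], p["G"], p["C"]]))


def _random_codons(rng: np.random.Generator, n_codons: int, at: float) -> list[str]:
    out: list[str] = []
    while len(out) < n_codons:
        c = _random_seq(rng, 3, at)
        if c not in MITO_STOP_CODONS:
            out.append(c)
    return out


_PAIR_OF = {"A": "T", "T": "A", "G": "C", "C": "G"}


def build_trna(rng: np.random.Generator, anticodon: str, with_dhu: bool = True,
               n_wobble: int = 0, at: float = 0.56) -> str:
    """Construct a canonical cloverleaf tRNA with perfectly paired stems.

    ``n_wobble`` stem positions are converted to G.T pairs (placed in the
    acceptor stem 5'->3').  Without a DHU arm the D-domain collapses to a
    4-nt connector, the layout of mitochondrial trnS1.
    """
    def stem(n: int) -> tuple[str, str]:
        s5 = _random_seq(rng, n, at)
        return s5, "".join(_PAIR_OF[b] for b in reversed(s5))

    acc5, acc3 = stem(7)
    if n_wobble:
        # turn the first n_wobble acceptor pairs into G.T
        a5 = list(acc5)
        a3 = list(acc3)
        for i in range(min(n_wobble, 7)):
            a5[i] = "G"
            a3[6 - i] = "T"
        acc5, acc3 = "".join(a5), "".join(a3)
    d5, d3 = stem(4) if with_dhu else ("", "")
    ac5, ac3 = stem(5)
    t5, t3 = stem(5)
    dloop = _random_seq(rng, 7, at) if with_dhu else _random_seq(rng, 4, at)
    acloop = _random_seq(rng, 2, at) + anticodon.upper() + _random_seq(rng, 2, at)
    tloop = _random_seq(rng, 7, at)
    var = _random_seq(rng, 4, at)
    return (acc5 + "T" + d5 + dloop + d3 + "A" + ac5 + acloop + ac3
            + var + t5 + tloop + t3 + acc3)


def build_cr(rng: np.random.Generator, motifs: dict[str, str] | None = None,
             length: int = 873, at: float = 0.64,
             repeat: tuple[str, float] | None = None) -> tuple[str, dict]:
    """AT-rich control region containing the conserved blocks in order and,
    optionally, a 5' (ETAS-domain) tandem repeat.

    Returns (sequence, annotation dict with block and repeat coordinates).
    """
    lib = motifs or load_motif_library()
    blocks = list(lib.items())
    total_block = sum(len(m) for _, m in blocks)
    repeat_seq = ""
    ann: dict = {"blocks": {}, "repeat": None}
    if repeat is not None:
        motif, copies = repeat
        n = int(round(len(motif) * copies))
        repeat_seq = (motif * (int(copies) + 2))[:n]
    fixed = total_block + len(repeat_seq)
    if fixed + len(blocks) + 2 > length:
        raise ValueError(f"CR length {length} too short for motif library")
    n_gaps = len(blocks) + 1
    spacer_total = length - fixed
    cuts = sorted(rng.integers(0, spacer_total + 1, size=n_gaps - 1).tolist())
    gaps = np.diff([0] + cuts + [spacer_total]).tolist()
    parts = [repeat_seq, _random_seq(rng, gaps[0], at)]
    pos = len(repeat_seq) + gaps[0]
    if repeat_seq:
        ann["repeat"] = {"start": 1, "stop": len(repeat_seq),
                         "period": len(repeat[0]), "copies": repeat[1]}
    for (label, motif), gap in zip(blocks, gaps[1:]):
        ann["blocks"][label] = {"start": pos + 1, "stop": pos + len(motif)}
        parts.append(motif)
        pos += len(motif)
        parts.append(_random_seq(rng, gap, at))
        pos += gap
    seq = "".join(parts)
    assert len(seq) == length
    return seq, ann


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def random_ultrametric_tree(rng: np.random.Generator, taxa: Sequence[str],
                            height: float) -> PhyloTree:
    """Random ultrametric topology: recursive random bifurcation with child
    node heights at 35-65% of the parent's, so no internal branch is
    vanishingly short relative to the tree height."""

    def grow(names: list[str], h: float) -> TreeNode:
        if len(names) == 1:
            return TreeNode(name=names[0], length=h)
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        node = TreeNode()
        for part in (left, right):
            child_h = float(h * rng.uniform(0.35, 0.65)) if len(part) > 1 else 0.0
            sub = grow(part, child_h)
            sub.length = h - child_h
            node.children.append(sub)
        return node

    names = list(taxa)
    rng.shuffle(names)
    return PhyloTree(grow(names, height))


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def _propose(rng: np.random.Generator, base: str, kappa: float,
             pi: dict[str, float]) -> str:
    alts = [b for b in "ACGT" if b != base]
    purine = base in "AG"
    w = []
    for b in alts:
        ti = (b in "AG") == purine
        w.append(pi[b] * (kappa if ti else 1.0))
    w = np.asarray(w)
    return alts[int(rng.choice(3, p=w / w.sum()))]


def _evolve_nt(rng, seq: list[str], t: float, kappa: float, pi,
               site_weights: np.ndarray | None = None) -> int:
    """Neutral nucleotide evolution; optional per-site relative rates."""
    if site_weights is None:
        n_events = int(rng.poisson(t * len(seq)))
        for _ in range(n_events):
            i = int(rng.integers(len(seq)))
            seq[i] = _propose(rng, seq[i], kappa, pi)
        return n_events
    total = float(site_weights.sum())
    n_events = int(rng.poisson(t * total))
    p = site_weights / total
    for _ in range(n_events):
        i = int(rng.choice(len(seq), p=p))
        seq[i] = _propose(rng, seq[i], kappa, pi)
    return n_events


def _evolve_codons(rng, codons: list[str], t: float, omega: float,
                   kappa: float, pi, counts: dict[str, int]) -> None:
    L = 3 * len(codons)
    n_events = int(rng.poisson(t * L))
    for _ in range(n_events):
        pos = int(rng.integers(L))
        ci, off = divmod(pos, 3)
        cur = codons[ci]
        new = cur[:off] + _propose(rng, cur[off], kappa, pi) + cur[off + 1 :]
        if new in MITO_STOP_CODONS:
            continue
        if CODON_TO_AA[new] == CODON_TO_AA[cur]:
            codons[ci] = new
            counts["syn"] += 1
        elif rng.random() < omega:
            codons[ci] = new
            counts["nonsyn"] += 1


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

def simulate_family(spec: SimulationSpec) -> tuple[list[AnnotatedMitogenome], TruthRecord]:
    """Simulate an annotated mitogenome family with exact truth.

    Fully reproducible under ``spec.seed``.  Genes are evolved independently
    along the (given or randomly generated ultrametric) tree, then laid out
    abutting in template order, so the tiling conservation law holds by
    construction and homologous genes are mutually aligned.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = [f"taxon{i + 1:02d}" for i in range(spec.n_taxa)]
    if spec.tree_newick:
        from .phylogeny import read_newick

        tree = read_newick(spec.tree_newick)
    else:
        tree = random_ultrametric_tree(rng, taxa, spec.tree_height)
    pi = _base_probs(spec.at_content)

    # ancestral state per gene
    ancestors: dict[str, object] = {}
    for name, cls, length, _ in spec.genome_template:
        if cls == "PCG":
            codons = _random_codons(rng, length // 3 - 2, spec.at_content)
            ancestors[name] = ["ATG"] + codons + ["TAA"]
        elif cls == "tRNA":
            ancestors[name] = list(build_trna(
                rng, TRNA_ANTICODONS.get(name, "NNN"),
                with_dhu=(name != "trnS1"), at=spec.at_content))
        elif cls == "CR":
            seq, ann = build_cr(rng, length=length, at=min(spec.at_content + 0.08, 0.9))
            ancestors[name] = list(seq)
            ancestors["_cr_ann"] = ann
            # conserved blocks evolve slower than the CR background,
            # mirroring the conservation of real central conserved domains
            cr_weights = np.ones(length)
            for coords in ann["blocks"].values():
                cr_weights[coords["start"] - 1 : coords["stop"]] = \
                    spec.cr_block_rate_scale
        else:
            ancestors[name] = list(_random_seq(rng, length, spec.at_content))

    counts = {name: {"syn": 0, "nonsyn": 0, "other": 0}
              for name, *_ in spec.genome_template}
    leaf_states: dict[str, dict[str, object]] = {}

    def walk(node: TreeNode, state: dict[str, object]) -> None:
        for child in node.children:
            st = {k: (list(v) if isinstance(v, list) else v)
                  for k, v in state.items()}
            t = child.length
            for name, cls, _, _ in spec.genome_template:
                if t == 0:
                    continue
                if cls == "PCG":
                    omega = spec.per_gene_omega.get(name, 0.1)
                    body = st[name]
                    evolving = body[:-1]  # terminal stop codon frozen
                    _evolve_codons(rng, evolving, t, omega, spec.kappa, pi,
                                   counts[name])
                    st[name] = evolving + [body[-1]]
                elif cls == "CR":
                    counts[name]["other"] += _evolve_nt(
                        rng, st[name], t, spec.kappa, pi,
                        site_weights=cr_weights)
                else:
                    counts[name]["other"] += _evolve_nt(
                        rng, st[name], t * spec.rna_rate_scale,
                        spec.kappa, pi)
            if child.is_leaf:
                leaf_states[child.name] = st
            else:
                walk(child, st)

    init = {k: v for k, v in ancestors.items() if k != "_cr_ann"}
    walk(tree.root, init)
    if not leaf_states:  # single-taxon edge case
        leaf_states[taxa[0]] = init

    planted_repeat = None
    genomes: list[AnnotatedMitogenome] = []
    dup_map: dict[str, list[str]] = {}
    for taxon in taxa:
        st = leaf_states[taxon]
        if spec.cr_repeat_taxon == taxon:
            motif = spec.cr_repeat_motif
            n = int(round(len(motif) * spec.cr_repeat_copies))
            rep = (motif * (int(spec.cr_repeat_copies) + 2))[:n]
            st["CR"] = list(rep) + list(st["CR"])
            planted_repeat = {"taxon": taxon, "period": len(motif),
                              "copies": spec.cr_repeat_copies,
                              "cr_offset": 1, "length": n}
        feats: list[GeneFeature] = []
        parts: list[str] = []
        pos = 0
        for name, cls, _, strand in spec.genome_template:
            gene_seq = "".join(st[name])
            emit = reverse_complement(gene_seq) if strand == "L" else gene_seq
            feats.append(GeneFeature(name, cls, pos + 1, pos + len(emit),
                                     strand,
                                     TRNA_ANTICODONS.get(name) if cls == "tRNA" else None))
            parts.append(emit)
            pos += len(emit)
        genome = AnnotatedMitogenome(taxon, "".join(parts), feats)
        for rtaxon, names in spec.rearrangements:
            if rtaxon == taxon:
                genome = inject_rearrangement(genome, names)
                dup_map[taxon] = list(names)
        genomes.append(genome)

    truth = TruthRecord(
        seed=spec.seed,
        taxa=taxa,
        tree_newick=write_newick(tree),
        substitutions=counts,
        planted_repeat=planted_repeat,
        planted_duplications=dup_map,
    )
    return genomes, truth


def inject_rearrangement(genome: AnnotatedMitogenome,
                         names: Sequence[str]) -> AnnotatedMitogenome:
    """Duplicate the named features: each copy is inserted immediately
    downstream of its original, all coordinates re-laid, and the sequence
    spliced accordingly, so the tiling conservation law is preserved."""
    g = copy.deepcopy(genome)
    for name in names:
        try:
            f = g.get(name)
        except KeyError:
            raise KeyError(f"{genome.accession}: no feature named {name!r}") from None
        if g.sequence is None:
            raise ValueError("cannot duplicate features without a sequence")
        insert = g.sequence[f.start - 1 : f.stop]
        size = f.size
        new_seq = g.sequence[: f.stop] + insert + g.sequence[f.stop :]
        new_feats: list[GeneFeature] = []
        for feat in g.features:
            if feat.start > f.stop:
                new_feats.append(GeneFeature(feat.name, feat.gene_class,
                                             feat.start + size,
                                             feat.stop + size, feat.strand,
                                             feat.anticodon, feat.start_codon,
                                             feat.stop_codon))
            else:
                new_feats.append(feat)
        dup = GeneFeature(f.name, f.gene_class, f.stop + 1, f.stop + size,
                          f.strand, f.anticodon, f.start_codon, f.stop_codon)
        new_feats.append(dup)
        g = AnnotatedMitogenome(g.accession, new_seq, new_feats, g.circular)
    return g
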