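"""tRNA cloverleaf heuristics and control-region structure analysis.

The cloverleaf finder is a bounded exhaustive enumeration over arm-placement
grids within canonical mitochondrial tRNA length bounds — deliberately not a
thermodynamic folder.  Stems are scored by paired positions (Watson-Crick
pairs score 2, G.U/G.T wobble pairs 1); the best-scoring layout wins, with a
deterministic tie-break on the layout tuple.  This is enough to reproduce
the biological signal of interest: presence/absence of the DHU arm (the
mitochondrial trnS1 characteristically lacks it) and wobble-pair counts.

The control-region tools locate the conserved blocks of the teleost CR
(central conserved domains CSB-F/E/D/C/B/A and conserved sequence blocks
CSB-1/2/3) by best Hamming match against a packaged motif library, and
detect tandem repeats (typical of the ETAS domain) by rotated self-identity
with fractional copy numbers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product

import yaml

from .util import reverse_complement

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _pair_score(x: str, y: str) -> int:
    if (x, y) in _WC:
        return 2
    if (x, y) in _WOBBLE:
        return 1
    return 0


@dataclass
class Arm:
    name: str
    stem5: tuple[int, int]     # 0-based [start, stop) of 5' stem strand
    loop: tuple[int, int]
    stem3: tuple[int, int]
    paired: int                # positions with WC or wobble pair
    wobble: int


@dataclass
class CloverleafStructure:
    sequence: str
    score: int
    arms: dict[str, Arm]
    anticodon_triplet: str
    anticodon_position: int    # 1-based start of the anticodon
    wobble_pairs: int
    dhu_present: bool
    non_canonical: bool = False


def _stem_stats(seq: str, s5: tuple[int, int], s3: tuple[int, int]) -> tuple[int, int, int]:
    """(score, paired count, wobble count) for a stem; 3' strand read 3'->5'."""
    a = seq[s5[0] : s5[1]]
    b = seq[s3[0] : s3[1]][::-1]
    score = paired = wob = 0
    for x, y in zip(a, b):
        p = _pair_score(x, y)
        score += p
        if p:
            paired += 1
        if p == 1:
            wob += 1
    return score, paired, wob


def fold_cloverleaf(trna_seq: str, anticodon_hint: str | None = None) -> CloverleafStructure:
    """Best cloverleaf layout of a mitochondrial tRNA (55-95 nt).

    Enumerates acceptor (7 bp), DHU (0 or 2-4 bp), anticodon (5 bp) and
    TpsiC (4-5 bp) stem placements consistent with the sequence length and
    canonical spacer/loop bounds.  ``dhu_present`` is False when no DHU stem
    of >= 2 paired positions fits; fewer than 5 paired acceptor positions
    sets the ``non_canonical`` flag.  An ``anticodon_hint`` biases layout
    choice toward placements whose anticodon loop centre matches it.
    """
    seq = trna_seq.upper().replace("U", "T")
    n = len(seq)
    if not 55 <= n <= 95:
        raise ValueError(f"tRNA length {n} outside 55-95 nt")
    best: tuple | None = None
    ACC = 7
    AC = 5
    for s1, d, dloop, s2, t in product((1, 2), (0, 2, 3, 4),
                                       range(4, 10), (0, 1), (4, 5)):
        if d == 0 and dloop != 4:
            continue  # no DHU arm: collapse into a single spacer of s1+4+s2
        for acloop in (7,):
            fixed = ACC + s1 + 2 * d + (dloop if d else dloop) + s2 \
                + 2 * AC + acloop + 2 * t + ACC
            for tloop in range(3, 9):
                var = n - fixed - tloop
                if not 0 <= var <= 9:
                    continue
                pos = 0
                acc5 = (pos, pos + ACC); pos += ACC + s1
                dhu5 = (pos, pos + d); pos += d
                dl = (pos, pos + (dloop if d else dloop)); pos += (dloop if d else dloop)
                dhu3 = (pos, pos + d); pos += d + s2
                ac5 = (pos, pos + AC); pos += AC
                acl = (pos, pos + acloop); pos += acloop
                ac3 = (pos, pos + AC); pos += AC + var
                t5 = (pos, pos + t); pos += t
                tl = (pos, pos + tloop); pos += tloop
                t3 = (pos, pos + t); pos += t
                acc3 = (pos, pos + ACC); pos += ACC
                assert pos == n
                sc_a, pa_a, wo_a = _stem_stats(seq, acc5, acc3)
                sc_d, pa_d, wo_d = _stem_stats(seq, dhu5, dhu3) if d else (0, 0, 0)
                sc_c, pa_c, wo_c = _stem_stats(seq, ac5, ac3)
                sc_t, pa_t, wo_t = _stem_stats(seq, t5, t3)
                score = sc_a + sc_d + sc_c + sc_t
                mid = acl[0] + (acloop - 3) // 2
                anticodon = seq[mid : mid + 3]
                if anticodon_hint and anticodon == anticodon_hint.upper().replace("U", "T"):
                    score += 5
                key = (score, -abs(dloop - 7), d)  # prefer canonical-ish on ties
                if best is None or key > best[0]:
                    arms = {
                        "acceptor": Arm("acceptor", acc5, (0, 0), acc3, pa_a, wo_a),
                        "anticodon": Arm("anticodon", ac5, acl, ac3, pa_c, wo_c),
                        "TpsiC": Arm("TpsiC", t5, tl, t3, pa_t, wo_t),
                    }
                    if d:
                        arms["DHU"] = Arm("DHU", dhu5, dl, dhu3, pa_d, wo_d)
                    best = (key, arms, anticodon, mid,
                            wo_a + wo_d + wo_c + wo_t, pa_a, d, pa_d)
    assert best is not None
    _, arms, anticodon, mid, wobble, acc_paired, d, pa_d = best
    return CloverleafStructure(
        sequence=seq,
        score=best[0][0],
        arms=arms,
        anticodon_triplet=anticodon,
        anticodon_position=mid + 1,
        wobble_pairs=wobble,
        dhu_present=bool(d and pa_d >= 2),
        non_canonical=acc_paired < 5,
    )


# ---------------------------------------------------------------------------
# Conserved blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockMatch:
    species: str
    start: int      # 1-based on the species' ungapped CR
    stop: int
    sequence: str
    identity: float  # percent


@dataclass
class ConservedBlock:
    label: str
    expected_length: int
    matches: dict[str, BlockMatch]
    absent: list[str]
    variable_columns: int


def load_motif_library() -> dict[str, str]:
    """Packaged synthetic teleost-style CR motif library (ordered)."""
    text = (resources.files("mitocompare.data") / "cr_motifs_synthetic.yaml").read_text()
    doc = yaml.safe_load(text)
    return {label: doc["blocks"][label] for label in doc["order"]}


def _best_hamming_match(seq: str, motif: str) -> tuple[int, float]:
    """(0-based start, identity fraction) of the best gapless match."""
    m = len(motif)
    if len(seq) < m:
        return 0, 0.0
    best_pos, best_id = 0, -1.0
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        ident = sum(a == b for a, b in zip(window, motif)) / m
        if ident > best_id:
            best_pos, best_id = i, ident
    return best_pos, best_id


def scan_conserved_blocks(
    crs: dict[str, str],
    motif_library: dict[str, str] | None = None,
    min_identity: float = 0.70,
    skip: tuple[str, ...] = (),
) -> list[ConservedBlock]:
    """Locate each conserved block in each species' control region.

    ``crs`` maps species to (aligned or unaligned) CR sequences; gaps are
    removed before matching.  A block is reported absent in a species when
    its best gapless match falls below ``min_identity``.  Species listed in
    ``skip`` are excluded from the comparison (e.g. CRs with unprecedented
    length variation).  ``variable_columns`` counts positions at which the
    matched block sequences differ among the species carrying the block.
    """
    lib = motif_library or load_motif_library()
    species = [s for s in crs if s not in skip]
    if len(species) < 1:
        raise ValueError("no species left to scan")
    out: list[ConservedBlock] = []
    for label, motif in lib.items():
        motif = motif.upper()
        matches: dict[str, BlockMatch] = {}
        absent: list[str] = []
        for sp in species:
            seq = crs[sp].upper().replace("-", "")
            pos, ident = _best_hamming_match(seq, motif)
            if ident >= min_identity:
                matches[sp] = BlockMatch(sp, pos + 1, pos + len(motif),
                                         seq[pos : pos + len(motif)],
                                         100.0 * ident)
            else:
                absent.append(sp)
        var = 0
        if matches:
            seqs = [m.sequence for m in matches.values()]
            var = sum(1 for col in zip(*seqs) if len(set(col)) > 1)
        out.append(ConservedBlock(label, len(motif), matches, absent, var))
    return out


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

@dataclass
class TandemRepeat:
    start: int          # 1-based inclusive
    stop: int
    period: int
    copy_number: float  # region length / period, 1 decimal
    consensus: str
    identity: float     # percent rotated self-identity


def _consensus(region: str, period: int) -> str:
    cols: list[dict[str, int]] = [dict() for _ in range(period)]
    for i, base in enumerate(region):
        col = cols[i % period]
        col[base] = col.get(base, 0) + 1
    return "".join(max(sorted(c), key=lambda b: c[b]) for c in cols)


def find_tandem_repeats(seq: str, min_period: int = 10, max_period: int = 60,
                        min_identity: float = 0.80) -> list[TandemRepeat]:
    """Detect tandem repeats by rotated self-identity.

    For each candidate period p, positions where ``seq[i] == seq[i-p]``
    define a self-match profile; maximal segments whose match fraction stays
    at or above ``min_identity`` and that span at least two full copies
    become candidate repeats.  Overlapping candidates are resolved by
    highest identity, then smallest period.  The consensus is the
    column-majority over the aligned copies and the copy number is the
    region length divided by the period, to one decimal.
    """
    import numpy as np

    s = seq.upper()
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    cands: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        m = (arr[p:] == arr[:-p])
        if not m.any():
            continue
        cs = np.concatenate([[0], np.cumsum(m)])
        lengths = np.arange(1, len(m) + 1)
        i = 0
        while i < len(m):
            if not m[i]:
                i += 1
                continue
            # farthest j with running identity from i still >= threshold
            ident = (cs[i + 1 :] - cs[i]) / lengths[: len(m) - i]
            ok = np.where(ident >= min_identity)[0]
            if ok.size == 0:
                i += 1
                continue
            best_j = i + int(ok[-1])
            start, stop = i, best_j + p  # 0-based inclusive on seq
            region = s[start : stop + 1]
            if len(region) >= 2 * p:
                matched = float(cs[best_j + 1] - cs[i]) / (best_j - i + 1)
                cands.append(TandemRepeat(
                    start + 1, stop + 1, p,
                    round(len(region) / p, 1),
                    _consensus(region, p),
                    100.0 * matched,
                ))
            i = best_j + 1
    cands.sort(key=lambda r: (-r.identity, r.period, r.start))
    accepted: list[TandemRepeat] = []
    for c in cands:
        if all(c.stop < a.start or c.start > a.stop for a in accepted):
            accepted.append(c)
    accepted.sort(key=lambda r: r.start)
    return accepted
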