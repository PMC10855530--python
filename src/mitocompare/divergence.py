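"""Pairwise and multi-sequence divergence statistics.

Implements the classical distance machinery for mitochondrial comparative
work:

* transition/transversion counting with pairwise deletion of gap/N sites;
* Kimura 2-parameter distance  d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]  where P and
  Q are the transition and transversion proportions;
* Nei-Gojobori (1986) Ka/Ks: per-codon synonymous site fractions averaged
  over both sequences, multi-difference codons averaged over all minimal
  mutational pathways with pathways through stop codons excluded, and the
  Jukes-Cantor correction  K = -3/4 ln(1 - 4p/3);
* sliding-window nucleotide diversity (pi) with complete-column deletion,
  window 200 bp / step 25 bp by default;
* per-pair saturation profiles (distance vs transition and transversion
  proportions).

Site and pathway bookkeeping for NG86 is precomputed for all 64 codons and
64x64 codon pairs of the vertebrate mitochondrial code, so pairwise scans
are table lookups.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codon import CODON_TO_AA, MITO_STOP_CODONS

_PURINES = {"A", "G"}
_VALID = frozenset("ACGT")


class SaturatedPairError(ValueError):
    """K2P log argument non-positive: the pair is saturated."""


@dataclass
class PairwiseDivergence:
    sites_compared: int
    P: float                    # transition proportion
    Q: float                    # transversion proportion
    k2p: float | None
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None
    codons_compared: int = 0
    S: float = 0.0              # synonymous sites (mean of both sequences)
    N: float = 0.0
    Sd: float = 0.0             # synonymous differences
    Nd: float = 0.0
    flags: list[str] = field(default_factory=list)


def is_transition(x: str, y: str) -> bool:
    return x != y and ((x in _PURINES) == (y in _PURINES))


def pairwise_counts(a: str, b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) with pairwise deletion.

    Sites with a gap or ambiguous base in either sequence are excluded.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    sites = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        sites += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    return sites, ts, tv


def k2p_from_counts(sites: int, transitions: int, transversions: int) -> float:
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedPairError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f}"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance in substitutions/site."""
    return k2p_from_counts(*pairwise_counts(a, b))


def p_distance(a: str, b: str) -> float:
    sites, ts, tv = pairwise_counts(a, b)
    return (ts + tv) / sites


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986
# ---------------------------------------------------------------------------

def _syn_fraction_table() -> dict[str, float]:
    """Synonymous sites per codon: sum over the three positions of the
    fraction (out of 3 possible changes) that are synonymous.  Changes to
    stop codons are never counted as synonymous."""
    out: dict[str, float] = {}
    for codon, aa in CODON_TO_AA.items():
        if aa == "*":
            continue
        s = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if CODON_TO_AA[alt] == aa:
                    s += 1.0 / 3.0
        out[codon] = s
    return out


_SYN_SITES = _syn_fraction_table()


def _pathway_table() -> dict[tuple[str, str], tuple[float, float]]:
    """(Sd, Nd) per ordered codon pair, averaged over minimal mutational
    pathways; pathways whose intermediate codons are stops are excluded.
    If every pathway passes through a stop, all pathways are used (rare;
    keeps the statistic defined)."""
    out: dict[tuple[str, str], tuple[float, float]] = {}
    codons = [c for c, aa in CODON_TO_AA.items() if aa != "*"]
    for c1 in codons:
        for c2 in codons:
            if c1 == c2:
                out[(c1, c2)] = (0.0, 0.0)
                continue
            diff_pos = [i for i in range(3) if c1[i] != c2[i]]
            paths = []
            for order in itertools.permutations(diff_pos):
                cur = c1
                sd = nd = 0.0
                through_stop = False
                for pos in order:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if CODON_TO_AA[nxt] == "*" and nxt != c2:
                        through_stop = True
                    if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                paths.append((through_stop, sd, nd))
            valid = [(s, n) for stop, s, n in paths if not stop]
            if not valid:
                valid = [(s, n) for _, s, n in paths]
            sd = sum(v[0] for v in valid) / len(valid)
            nd = sum(v[1] for v in valid) / len(valid)
            out[(c1, c2)] = (sd, nd)
    return out


_PAIR_DIFFS = _pathway_table()


def nei_gojobori_kaks(a: str, b: str) -> PairwiseDivergence:
    """NG86 Ka/Ks between two codon-aligned sequences (vertebrate mito code).

    Codons containing gaps, ambiguity codes or stop codons in either
    sequence are skipped.  Jukes-Cantor correction is applied; p >= 3/4
    leaves the corresponding K undefined with a flag, and Ks = 0 leaves the
    ratio undefined with a flag.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if len(a) % 3:
        raise ValueError("length not divisible by 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca not in _SYN_SITES or cb not in _SYN_SITES:
            continue  # gap/N/stop codon
        n_codons += 1
        S += (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        sd, nd = _PAIR_DIFFS[(ca, cb)]
        Sd += sd
        Nd += nd
    N = 3.0 * n_codons - S
    flags: list[str] = []
    if n_codons == 0:
        raise ValueError("no comparable codons")

    def _jc(p: float, label: str) -> float | None:
        if p >= 0.75:
            flags.append(f"{label} correction undefined (p={p:.4f} >= 3/4)")
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = _jc(pS, "Ks")
    ka = _jc(pN, "Ka")
    ka_ks: float | None = None
    if ka is not None and ks is not None:
        if ks == 0.0:
            flags.append("Ka/Ks undefined (Ks = 0)")
        else:
            ka_ks = ka / ks
    sites, ts, tv = pairwise_counts(a, b)
    P, Q = ts / sites, tv / sites
    try:
        k2p = k2p_from_counts(sites, ts, tv)
    except SaturatedPairError:
        k2p = None
        flags.append("saturated pair")
    return PairwiseDivergence(sites, P, Q, k2p, ka, ks, ka_ks,
                              n_codons, S, N, Sd, Nd, flags)


def ng86_site_counts(seq: str) -> tuple[float, float]:
    """(S, N) synonymous/nonsynonymous site counts for one codon sequence."""
    S = 0.0
    n = 0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        c = seq[i : i + 3].upper()
        if c in _SYN_SITES:
            S += _SYN_SITES[c]
            n += 1
    return S, 3.0 * n - S


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class SlidingWindowProfile:
    window_bp: int
    step_bp: int
    midpoints: list[int]        # 1-based midpoint of each window
    pi: list[float]
    overall_pi: float
    polymorphic_sites: int
    n_sequences: int


_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _ENC[ord(_b)] = _i


def _encode(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(s.upper() for s in seqs).encode(),
                        dtype=np.uint8).reshape(len(seqs), -1)
    return _ENC[arr]  # 0 = gap/ambiguous


def sliding_window_pi(seqs: Sequence[str], window: int = 200,
                      step: int = 25) -> SlidingWindowProfile:
    """Sliding-window nucleotide diversity over an alignment.

    pi in a window is the mean, over all n(n-1)/2 sequence pairs, of
    pairwise differences per comparable site.  Columns with a gap or
    ambiguous base in any sequence are excluded everywhere (complete-column
    deletion).  Windows are anchored at position 1; a trailing partial
    window is dropped; the reported midpoint is window start + window/2 - 1.
    No multiple-hit correction is applied.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be aligned to equal length")
    if window > L:
        raise ValueError(f"window {window} longer than alignment {L}")
    mat = _encode(seqs)
    n = len(seqs)
    valid = (mat > 0).all(axis=0)
    # per-column sum of pairwise differences (only over valid columns)
    coldiff = np.zeros(L, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            coldiff += (mat[i] != mat[j])
    coldiff[~valid] = 0
    npairs = n * (n - 1) // 2
    # distinct-base count per valid column for segregating sites
    poly = 0
    vidx = np.where(valid)[0]
    sub = mat[:, vidx]
    poly = int((sub != sub[0]).any(axis=0).sum())

    cs_diff = np.concatenate([[0], np.cumsum(coldiff)])
    cs_valid = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    midpoints, pis = [], []
    start = 0
    while start + window <= L:
        d = cs_diff[start + window] - cs_diff[start]
        v = cs_valid[start + window] - cs_valid[start]
        pis.append(float(d / (npairs * v)) if v else 0.0)
        midpoints.append(start + window // 2)  # 1-based: start+1 + w/2 - 1
        start += step
    total_valid = int(valid.sum())
    overall = float(coldiff.sum() / (npairs * total_valid)) if total_valid else 0.0
    return SlidingWindowProfile(window, step, midpoints, pis, overall,
                                poly, n)


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

def saturation_profile(seqs: dict[str, str]) -> pd.DataFrame:
    """Per-pair table (taxon_a, taxon_b, distance, s, v, saturated).

    s and v are the transition and transversion proportions; distance is
    K2P (NaN for saturated pairs, which are flagged rather than dropped).
    Plotting s and v against distance diagnoses substitution saturation.
    """
    names = list(seqs)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            sites, ts, tv = pairwise_counts(seqs[na], seqs[nb])
            try:
                d = k2p_from_counts(sites, ts, tv)
                sat = False
            except SaturatedPairError:
                d = float("nan")
                sat = True
            rows.append({"taxon_a": na, "taxon_b": nb, "distance": d,
                         "s": ts / sites, "v": tv / sites, "saturated": sat})
    return pd.DataFrame(rows)
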