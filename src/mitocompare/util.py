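"""Small shared helpers."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def clean_dna(seq: str, *, allow_n: bool = True) -> str:
    """Uppercase and map IUPAC ambiguity codes (other than N) to N."""
    s = seq.upper().replace("U", "T")
    out = []
    dirty = False
    for c in s:
        if c in "ACGT" or (allow_n and c == "N"):
            out.append(c)
        else:
            out.append("N")
            dirty = True
    if dirty:
        import warnings

        warnings.warn("ambiguity codes other than A/C/G/T/N mapped to N")
    return "".join(out)
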