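"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def random_seq(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA of the given length."""
    return "".join(rng.choice(list(DNA), size=length))


def random_codons(n: int, rng: np.random.Generator) -> str:
    """n random sense (non-stop) codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(DNA), size=3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply uniform substitutions at the given per-base rate."""
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        base = arr[i].decode()
        choices = [c for c in DNA if c != base]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def format_sig(x: float, sig: int = 3) -> str:
    """Format a positive number to `sig` significant figures (no exponent for
    moderate magnitudes, matching bioassay-table conventions)."""
    if x == 0:
        return "0"
    from math import floor, log10

    ndigits = sig - int(floor(log10(abs(x)))) - 1
    y = round(x, ndigits)
    if ndigits <= 0:
        return f"{y:,.0f}"
    return f"{y:.{ndigits}f}"
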