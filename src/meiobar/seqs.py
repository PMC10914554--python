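"""Nucleotide helpers shared across the package.

IUPAC degeneracy tables, reverse complement, and the 18S-V4 primer pair used
throughout the study region (forward 18-mer, reverse 22-mer). Primer strings
may contain degenerate codes; references and reads are plain A/C/G/T/N.
"""

from __future__ import annotations

import numpy as np

# IUPAC nucleotide code -> set of plain bases it stands for
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)

#: 18S-V4 amplification primers (5'->3'), degenerate IUPAC strings.
FORWARD_PRIMER = "CCGCGGTAATWCCAGCHY"
REVERSE_PRIMER = "TTGGCAAATGCYTTCGCAKTHG"

BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    """True iff every character is a valid IUPAC nucleotide code."""
    return all(c in IUPAC for c in seq.upper())


def iupac_match(code: str, base: str) -> bool:
    """Does plain `base` satisfy degenerate `code`? N on either side matches."""
    if base == "N":
        return True
    return base in IUPAC.get(code, "")


def realize_degenerate(primer: str, rng: np.random.Generator) -> str:
    """Resolve each degenerate position to one concrete base (seeded)."""
    out = []
    for c in primer.upper():
        opts = IUPAC[c]
        out.append(opts if len(opts) == 1 else opts[rng.integers(len(opts))])
    return "".join(out)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute each given position with a different random base."""
    s = list(seq)
    for p in positions:
        old = s[p]
        choices = [b for b in BASES if b != old]
        s[p] = choices[rng.integers(3)]
    return "".join(s)
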