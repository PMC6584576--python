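"""Standard genetic code tables and codon neighborhood machinery.

Everything downstream (NG86 site counting, pathway classification, the
codon-evolution simulator) works on the 61 sense codons of the standard
nuclear code. Stop codons are excluded from the sense-codon index; single
nucleotide changes that would create a stop are tracked separately because
both the estimator and the simulator must refuse to pass through them.
"""

from __future__ import annotations

from itertools import product

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard code, T-notation. Built once; Biopython's table agrees but a flat
# dict keeps per-codon lookups allocation-free in inner loops.
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def translate(codon: str) -> str:
    """Amino acid (one-letter) for a codon; '*' for a stop."""
    return _CODE[codon.upper()]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    """True if the single-base change a->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return (a in _PURINES) == (b in _PURINES)


def codon_neighbors(codon: str) -> list[tuple[int, str, str]]:
    """All nine single-nucleotide mutations of a codon.

    Returns (position, new_base, mutant_codon) triples, including those that
    create stops — the caller decides how to treat them.
    """
    out = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base != codon[pos]:
                out.append((pos, base, codon[:pos] + base + codon[pos + 1:]))
    return out


def sense_neighbors(codon: str) -> list[str]:
    """Single-nucleotide mutants of a sense codon that are themselves sense."""
    return [m for _, _, m in codon_neighbors(codon) if m not in STOP_CODONS]
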