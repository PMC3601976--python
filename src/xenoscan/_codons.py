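"""Shared genetic-code tables and codon index helpers.

Standard genetic code (translation table 1). Sense codons are the 61
non-stop codons, in lexicographic order; this ordering is the state space of
the codon substitution model and of the counting routines.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCS = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCS)}

STOP_CODONS = frozenset(_TABLE.stop_codons)

ALL_CODONS = tuple("".join(c) for c in product(NUCS, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

AA_OF = dict(_TABLE.forward_table)  # sense codon -> amino acid


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    return AA_OF.get(codon, "*")


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return {a, b} in ({"A", "G"}, {"C", "T"})


def single_nt_neighbors(codon: str):
    """Yield (position, target_codon) for the 9 single-nucleotide mutations."""
    for pos in range(3):
        for b in NUCS:
            if b != codon[pos]:
                yield pos, codon[:pos] + b + codon[pos + 1 :]
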