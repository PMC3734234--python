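"""Standard genetic code constants shared across the package.

Codons are DNA triplets in the classical T/C/A/G table order. Synonymous
families are defined under the standard (NCBI table 1) code; the three stop
codons form their own family so that codon-usage vectors stay 64-dimensional.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"

#: All 64 codons in standard codon-table order (TTT, TTC, TTA, TTG, TCT, ...).
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid one-letter code, stops mapped to '*'.
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

#: amino acid (or '*') -> tuple of synonymous codons, in CODONS order.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TO_AA[_codon], ())
    SYNONYMOUS_FAMILIES[CODON_TO_AA[_codon]] += (_codon,)

#: Codons with no synonymous alternative (Met, Trp) — excluded from CAI.
SINGLE_MEMBER_CODONS: frozenset[str] = frozenset(
    codons[0] for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) == 1
)

VALID_BASES = frozenset("ACGT")


def is_unambiguous(codon: str) -> bool:
    return all(b in VALID_BASES for b in codon)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; ambiguous codons become 'X', stops '*'.

    The caller is responsible for frame validity (length divisible by 3).
    """
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aas.append(CODON_TO_AA.get(codon, "X") if is_unambiguous(codon) else "X")
    return "".join(aas)
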