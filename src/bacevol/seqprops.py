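"""Simple per-gene sequence properties: hydropathicity, aromaticity,
length, GC content and replication strand bias.

Strand bias follows replichore logic: a bacterial chromosome replicates
bidirectionally from the origin (oriC) to the terminus, splitting it into
two replichores. A gene is *leading* (RSB = 1) when its coding strand is
co-directional with the replication fork moving through it: genes on the
'+' strand are leading on the replichore running from ori forward (in
increasing coordinate, wrapping at the end) to ter, and genes on the '-'
strand are leading on the other replichore.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_core import GeneRecord

logger = logging.getLogger("bacevol")

# Kyte & Doolittle (1982) hydropathy indices; the same table CodonW's GRAVY
# uses.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")


def gravy(protein: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle index.

    Non-standard residues are skipped with a warning; a sequence with no
    standard residues raises ``ValueError``.
    """
    values = [KYTE_DOOLITTLE[aa] for aa in protein.upper()
              if aa in KYTE_DOOLITTLE]
    if not values:
        raise ValueError("no standard amino acids in protein sequence")
    if len(values) < len(protein):
        logger.warning("skipped %d non-standard residues in GRAVY",
                       len(protein) - len(values))
    return sum(values) / len(values)


def aromaticity(protein: str) -> float:
    """Frequency of aromatic residues (Phe, Tyr, Trp)."""
    if not protein:
        raise ValueError("empty protein sequence")
    p = protein.upper()
    return sum(1 for aa in p if aa in AROMATIC) / len(p)


def protein_length(protein: str) -> int:
    if not protein:
        raise ValueError("empty protein sequence")
    return len(protein)


def gc_content(cds: str) -> float:
    """G+C fraction over unambiguous bases."""
    s = cds.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases in sequence")
    return (counts["G"] + counts["C"]) / total


@dataclass(frozen=True)
class ReplichoreMap:
    """Origin/terminus positions on a circular chromosome (0-based bp)."""

    ori: int
    ter: int
    genome_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.ori < self.genome_length):
            raise ValueError("ori outside [0, genome_length)")
        if not (0 <= self.ter < self.genome_length):
            raise ValueError("ter outside [0, genome_length)")
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")

    def in_first_replichore(self, position: float) -> bool:
        """Is ``position`` on the replichore from ori (inclusive) forward,
        wrapping, to ter (exclusive)?"""
        pos = position % self.genome_length
        if self.ori < self.ter:
            return self.ori <= pos < self.ter
        return pos >= self.ori or pos < self.ter


def replication_strand(gene: GeneRecord, rep_map: ReplichoreMap,
                       by: str = "midpoint") -> int:
    """1 if the gene lies on the leading strand, 0 if lagging.

    The gene is located by its midpoint (or start codon with
    ``by='start'``). A position exactly at ori or ter is resolved by the
    half-open [ori, ter) convention and logged.
    """
    pos = gene.midpoint if by == "midpoint" else float(gene.start)
    pos %= rep_map.genome_length
    if pos in (float(rep_map.ori), float(rep_map.ter)):
        logger.info("gene %s midpoint at a replichore boundary; using the "
                    "half-open [ori, ter) convention", gene.gene_id)
    first = rep_map.in_first_replichore(pos)
    leading = first if gene.strand == "+" else not first
    return int(leading)
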