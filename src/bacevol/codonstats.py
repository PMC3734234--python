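"""Codon counting, RSCU vectors and the codon adaptation index (CAI).

RSCU (relative synonymous codon usage) is a codon's count divided by the
mean count of its synonymous family; values above 1 mark codons used more
often than expected under uniform synonymous usage. Vectors are kept
64-dimensional — stop codons and the single-member families (ATG, TGG) are
retained — so downstream ordination sees the full codon table.

CAI follows Sharp & Li: relative-adaptiveness weights ``w_c`` are the ratio
of a codon's RSCU to the maximum RSCU in its family, computed on counts
pooled over a reference set of highly expressed genes (ribosomal proteins),
and a gene's CAI is the geometric mean of the weights of its codons. Codons
with no synonymous alternative (ATG, TGG) and stop codons carry no signal
about synonymous choice and are excluded from the geometric mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetics import (
    CODONS,
    CODON_INDEX,
    SINGLE_MEMBER_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    is_unambiguous,
)

#: Weight assigned to codons never observed in the reference set — the usual
#: guard against a zero geometric mean.
UNOBSERVED_WEIGHT = 0.01


@dataclass(frozen=True)
class CodonCountVector:
    gene_id: str
    counts: tuple[int, ...]  # 64 entries, CODONS order
    skipped: int = 0  # codons containing non-ACGT symbols

    def __post_init__(self) -> None:
        if len(self.counts) != 64:
            raise ValueError("counts must have 64 entries")

    def __add__(self, other: "CodonCountVector") -> "CodonCountVector":
        return CodonCountVector(
            f"{self.gene_id}+{other.gene_id}",
            tuple(a + b for a, b in zip(self.counts, other.counts)),
            self.skipped + other.skipped,
        )


def count_codons(cds: str, gene_id: str = "") -> CodonCountVector:
    """Count the codons of an in-frame CDS.

    Codons containing non-ACGT symbols are skipped and tallied in
    ``skipped``. A length not divisible by 3 raises ``ValueError``.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    counts = [0] * 64
    skipped = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if is_unambiguous(codon):
            counts[CODON_INDEX[codon]] += 1
        else:
            skipped += 1
    return CodonCountVector(gene_id, tuple(counts), skipped)


def rscu(counts: CodonCountVector) -> np.ndarray:
    """RSCU vector (64 floats, CODONS order) of a codon-count vector.

    Within each synonymous family with at least one observed codon the RSCU
    values average exactly 1; families never observed are all-zero.
    """
    out = np.zeros(64)
    arr = np.asarray(counts.counts, dtype=float)
    for family in SYNONYMOUS_FAMILIES.values():
        idx = [CODON_INDEX[c] for c in family]
        total = arr[idx].sum()
        if total > 0:
            out[idx] = arr[idx] / (total / len(idx))
    return out


@dataclass(frozen=True)
class ReferenceWeights:
    """Relative-adaptiveness weights from a highly expressed reference set."""

    w: Mapping[str, float]  # sense codon -> weight in (0, 1]
    reference_ids: tuple[str, ...]


def cai_weights(reference: Sequence[CodonCountVector],
                unobserved_weight: float = UNOBSERVED_WEIGHT) -> ReferenceWeights:
    """Pool reference-gene codon counts and derive CAI weights.

    ``w_c = count_c / max_count_in_family`` on the pooled counts (identical
    to the RSCU ratio since the family mean cancels). Sense codons absent
    from the pooled reference receive ``unobserved_weight``.
    """
    if not reference:
        raise ValueError("reference set must contain at least one gene")
    pooled = np.zeros(64)
    for vec in reference:
        pooled += np.asarray(vec.counts, dtype=float)
    w: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if aa == "*":
            continue
        idx = [CODON_INDEX[c] for c in family]
        fam_max = pooled[idx].max()
        for codon, i in zip(family, idx):
            if pooled[i] > 0:
                w[codon] = pooled[i] / fam_max
            else:
                w[codon] = unobserved_weight
    return ReferenceWeights(w, tuple(v.gene_id for v in reference))


def cai(gene_counts: CodonCountVector, weights: ReferenceWeights) -> float:
    """Geometric mean of reference weights over a gene's codons.

    ATG, TGG and stop codons are excluded. Raises ``ValueError`` when no
    codon contributes.
    """
    log_sum = 0.0
    n = 0
    for codon, count in zip(CODONS, gene_counts.counts):
        if count == 0 or codon in STOP_CODONS or codon in SINGLE_MEMBER_CODONS:
            continue
        log_sum += count * math.log(weights.w[codon])
        n += count
    if n == 0:
        raise ValueError(f"gene {gene_counts.gene_id!r} has no codons "
                         "contributing to CAI")
    return math.exp(log_sum / n)


def rscu_matrix(count_vectors: Iterable[CodonCountVector]) -> np.ndarray:
    """Stack per-gene RSCU vectors into a genes x 64 matrix."""
    return np.array([rscu(v) for v in count_vectors])
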