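"""Ortholog detection, protein alignment, and NG86 evolutionary rates.

Orthologs between two proteomes are taken as reciprocal best hits (RBH)
under global protein alignment (BLOSUM62, affine gaps), filtered on
identity, alignment coverage, protein length and an optional
horizontal-gene-transfer exclusion list. Protein alignments are
back-translated onto the original codons, and the nonsynonymous and
synonymous substitution rates (Ka, Ks) are estimated with the
Nei-Gojobori (1986) counting method: per-codon synonymous/nonsynonymous
site fractions averaged over the two sequences, observed differences
averaged over all equally weighted minimal substitution paths, and a
Jukes-Cantor correction ``d = -(3/4) ln(1 - (4/3) p)`` applied separately
to the two proportions. The per-gene evolutionary rate is
``ER = ln(Ka + 0.001)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genetics import CODON_TO_AA, STOP_CODONS, is_unambiguous

GAP_CODON = "---"


# ---------------------------------------------------------------------------
# Protein alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinAlignment:
    a: str              # aligned sequence with '-' gaps
    b: str
    score: float
    identity: float     # identical residue pairs / aligned (gapless) columns
    coverage: float     # aligned (gapless) columns / shorter sequence length


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_proteins_global(a: str, b: str, gap_open: float = 11.0,
                          gap_extend: float = 1.0) -> ProteinAlignment:
    """Optimal global alignment under BLOSUM62 with affine gaps.

    The first alignment in Biopython's deterministic enumeration order is
    returned, so co-optimal alignments resolve reproducibly.
    """
    if not a or not b:
        raise ValueError("cannot align empty protein sequences")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    a_aln, b_aln = str(aln[0]), str(aln[1])
    aligned_cols = sum(1 for x, y in zip(a_aln, b_aln)
                       if x != "-" and y != "-")
    matches = sum(1 for x, y in zip(a_aln, b_aln)
                  if x == y and x != "-")
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = aligned_cols / min(len(a), len(b))
    return ProteinAlignment(a_aln, b_aln, float(aln.score), identity, coverage)


def alignment_score(a: str, b: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    aligner = _make_aligner(gap_open, gap_extend)
    return float(aligner.score(a, b))


def reciprocal_best_hits(scores_ab: Mapping[tuple[str, str], float],
                         scores_ba: Mapping[tuple[str, str], float],
                         ) -> list[tuple[str, str]]:
    """Pairs (a, b) where b is a's unique best hit and vice versa.

    A query whose best score is tied between several subjects has no unique
    best hit and contributes no pair.
    """

    def unique_best(scores: Mapping[tuple[str, str], float]) -> dict[str, str]:
        by_query: dict[str, list[tuple[str, float]]] = {}
        for (q, s), sc in scores.items():
            by_query.setdefault(q, []).append((s, sc))
        best: dict[str, str] = {}
        for q, hits in by_query.items():
            top = max(sc for _, sc in hits)
            top_subjects = [s for s, sc in hits if sc == top]
            if len(top_subjects) == 1:
                best[q] = top_subjects[0]
        return best

    best_ab = unique_best(scores_ab)
    best_ba = unique_best(scores_ba)
    return sorted((a, b) for a, b in best_ab.items()
                  if best_ba.get(b) == a)


def filter_pair(identity: float, coverage: float, len_a: int, len_b: int,
                gene_a: str = "", gene_b: str = "",
                min_identity: float = 0.30, min_coverage: float = 0.80,
                min_aa: int = 30, hgt_exclusion: Iterable[str] = (),
                evalue: float | None = None,
                max_evalue: float = 1e-5) -> tuple[bool, tuple[str, ...]]:
    """Apply the ortholog-pair retention filters; returns (keep, reasons).

    Proteins must be strictly longer than ``min_aa`` residues; identity and
    coverage thresholds are inclusive. The E-value filter only applies when
    an E-value is supplied (imported tabular hits)."""
    reasons = []
    if identity < min_identity:
        reasons.append("identity")
    if coverage < min_coverage:
        reasons.append("coverage")
    if len_a <= min_aa or len_b <= min_aa:
        reasons.append("length")
    hgt = set(hgt_exclusion)
    if gene_a in hgt or gene_b in hgt:
        reasons.append("hgt")
    if evalue is not None and evalue >= max_evalue:
        reasons.append("evalue")
    return (not reasons, tuple(reasons))


# ---------------------------------------------------------------------------
# Back-translation
# ---------------------------------------------------------------------------

def backtranslate(protein_alignment: ProteinAlignment, cds_a: str,
                  cds_b: str) -> tuple[str, str]:
    """Map an aligned protein pair back onto codons; gaps become '---'."""

    def one(aligned: str, cds: str) -> str:
        codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        if codons and CODON_TO_AA.get(codons[-1]) == "*":
            codons = codons[:-1]
        out = []
        pos = 0
        for col, aa in enumerate(aligned):
            if aa == "-":
                out.append(GAP_CODON)
                continue
            if pos >= len(codons):
                raise ValueError(f"protein longer than CDS at column {col}")
            codon = codons[pos]
            translated = CODON_TO_AA.get(codon, "X") if is_unambiguous(codon) else "X"
            if translated != aa:
                raise ValueError(
                    f"codon {codon} at residue {pos} translates to "
                    f"{translated}, alignment has {aa}")
            out.append(codon)
            pos += 1
        if pos != len(codons):
            raise ValueError("CDS longer than aligned protein")
        return "".join(out)

    return one(protein_alignment.a, cds_a), one(protein_alignment.b, cds_b)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of a codon.

    Each position contributes 1/3 site per possible point mutation;
    mutations creating a stop codon are excluded from both classes, so the
    codon's site total can fall below 3.
    """
    syn = nonsyn = 0.0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            if CODON_TO_AA[alt] == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


@lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    All minimal substitution paths (orderings of the differing positions)
    are enumerated with equal weight; paths passing through a stop codon
    are discarded (when every path is blocked, all paths are used, counting
    steps into or out of a stop as nonsynonymous).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            current = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if CODON_TO_AA[a] == CODON_TO_AA[b]:
                syn += 1
            else:
                nonsyn += 1
    return syn / len(usable), nonsyn / len(usable)


@dataclass(frozen=True)
class NGResult:
    ka: float | None
    ks: float | None
    pn: float | None
    ps: float | None
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    n_codons: int
    flags: tuple[str, ...] = ()


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    d = -0.75 * math.log(1 - 4 * p / 3)
    return abs(d) if d == 0 else d  # avoid -0.0 at p = 0


def ka_ng86(codon_a: str, codon_b: str) -> NGResult:
    """NG86 Ka/Ks from two gap-aligned codon strings of equal length.

    Columns with gaps, ambiguous bases or stop codons are excluded. A
    proportion of differences >= 3/4 leaves the corresponding rate missing
    with a ``saturated`` flag; zero sites of a class leave that rate
    missing with a ``no_*_sites`` flag.
    """
    if len(codon_a) != len(codon_b) or len(codon_a) % 3 != 0:
        raise ValueError("codon alignments must have equal length divisible by 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(codon_a), 3):
        ca, cb = codon_a[i : i + 3], codon_b[i : i + 3]
        if (GAP_CODON in (ca, cb) or "-" in ca or "-" in cb
                or not is_unambiguous(ca) or not is_unambiguous(cb)
                or ca in STOP_CODONS or cb in STOP_CODONS):
            continue
        n_codons += 1
        s1, n1 = _codon_sites(ca)
        s2, n2 = _codon_sites(cb)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _codon_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no ungapped, stop-free codon columns")
    flags: list[str] = []
    pn = Nd / N if N > 0 else None
    ps = Sd / S if S > 0 else None
    if pn is None:
        flags.append("no_nonsynonymous_sites")
        ka = None
    else:
        ka = _jukes_cantor(pn)
        if ka is None:
            flags.append("saturated_ka")
    if ps is None:
        flags.append("no_synonymous_sites")
        ks = None
    else:
        ks = _jukes_cantor(ps)
        if ks is None:
            flags.append("saturated_ks")
    return NGResult(ka, ks, pn, ps, N, S, Nd, Sd, n_codons, tuple(flags))


def er_transform(ka: float, c: float = 0.001, base: float = math.e) -> float:
    """Log-transformed evolutionary rate: ``ER = log(Ka + c)``."""
    if ka < 0:
        raise ValueError("ka must be non-negative")
    return math.log(ka + c) / math.log(base)


# ---------------------------------------------------------------------------
# Pair-level driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologKa:
    gene_a: str
    gene_b: str
    alignment: ProteinAlignment
    codon_a: str
    codon_b: str
    ng: NGResult | None
    er: float | None
    keep: bool
    filter_reasons: tuple[str, ...]


def ortholog_ka(rec_a, rec_b, min_identity: float = 0.30,
                min_coverage: float = 0.80, min_aa: int = 30,
                hgt_exclusion: Iterable[str] = (),
                ka_constant: float = 0.001) -> OrthologKa:
    """Full per-pair pipeline: align, filter, back-translate, NG86, ER."""
    aln = align_proteins_global(rec_a.protein, rec_b.protein)
    keep, reasons = filter_pair(
        aln.identity, aln.coverage, len(rec_a.protein), len(rec_b.protein),
        rec_a.gene_id, rec_b.gene_id, min_identity=min_identity,
        min_coverage=min_coverage, min_aa=min_aa,
        hgt_exclusion=hgt_exclusion)
    ng = er = None
    if keep:
        codon_a, codon_b = backtranslate(aln, rec_a.cds, rec_b.cds)
        ng = ka_ng86(codon_a, codon_b)
        if ng.ka is not None:
            er = er_transform(ng.ka, ka_constant)
    else:
        codon_a = codon_b = ""
    return OrthologKa(rec_a.gene_id, rec_b.gene_id, aln, codon_a, codon_b,
                      ng, er, keep, reasons)
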