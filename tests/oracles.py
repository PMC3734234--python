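"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration or naive definition,
sharing no code path with the package implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


# --- NG86 ------------------------------------------------------------------

def ng86_oracle(codons_a: list[str], codons_b: list[str]):
    """Naive NG86: (pn, ps) from explicit per-codon enumeration."""
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        for c in (ca, cb):
            s, n = _sites(c)
            S += s / 2
            N += n / 2
        sd, nd = _pair_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return (Nd / N if N else None), (Sd / S if S else None), N, S


def _sites(codon: str):
    syn = nonsyn = 0.0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt in STOPS:
            continue
        if translate_codon(alt) == translate_codon(codon):
            syn += 1 / 3
        else:
            nonsyn += 1 / 3
    return syn, nonsyn


def _pair_diffs(ca: str, cb: str):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    all_paths, open_paths = [], []
    for order in itertools.permutations(positions):
        steps, cur, through_stop = [], ca, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if nxt in STOPS and nxt != cb:
                through_stop = True
            cur = nxt
        all_paths.append(steps)
        if not through_stop:
            open_paths.append(steps)
    paths = open_paths or all_paths
    syn = sum(1 for steps in paths for a, b in steps
              if translate_codon(a) == translate_codon(b)) / len(paths)
    nonsyn = sum(1 for steps in paths for a, b in steps
                 if translate_codon(a) != translate_codon(b)) / len(paths)
    return syn, nonsyn


# --- RNA structure ---------------------------------------------------------

def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum base pairs over all valid structures, by full enumeration."""
    rna = seq.upper().replace("T", "U")
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}

    memo: dict[tuple[int, ...], int] = {}

    def best(positions: tuple[int, ...]) -> int:
        if not positions:
            return 0
        if positions in memo:
            return memo[positions]
        j = positions[-1]
        rest = positions[:-1]
        score = best(rest)  # j unpaired
        for idx, i in enumerate(rest):
            if j - i > min_loop and (rna[i], rna[j]) in pairs:
                inside = tuple(p for p in rest[idx + 1 :])
                outside = tuple(rest[:idx])
                # non-crossing: positions between i and j fold separately
                score = max(score, 1 + best(inside) + best(outside))
        memo[positions] = score
        return score

    return best(tuple(range(len(rna))))


# --- statistics ------------------------------------------------------------

def midrank(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


# --- alignment -------------------------------------------------------------

def global_alignment_oracle(a: str, b: str, score_fn, gap_open: float = 11.0,
                            gap_extend: float = 1.0) -> float:
    """Best global alignment score by enumerating all op paths.

    A gap run of length L costs ``gap_open + (L-1) * gap_extend``. Only
    practical for sequences of length <= ~6.
    """
    best = -np.inf

    def recurse(i: int, j: int, ops: list[str]):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, _score_ops(a, b, ops, score_fn, gap_open,
                                        gap_extend))
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, ops + ["M"])
        if i < len(a):
            recurse(i + 1, j, ops + ["D"])
        if j < len(b):
            recurse(i, j + 1, ops + ["I"])

    recurse(0, 0, [])
    return best


def _score_ops(a, b, ops, score_fn, gap_open, gap_extend):
    score = 0.0
    i = j = 0
    prev = None
    for op in ops:
        if op == "M":
            score += score_fn(a[i], b[j])
            i += 1
            j += 1
        else:
            score -= gap_open if op != prev else gap_extend
            if op == "D":
                i += 1
            else:
                j += 1
        prev = op
    return score


# --- replication strand ----------------------------------------------------

def leading_strand_oracle(position: int, strand: str, ori: int, ter: int,
                          length: int) -> int:
    """Walk from ori forward position by position to find the replichore."""
    pos = position % length
    first = set()
    p = ori
    while p != ter:
        first.add(p)
        p = (p + 1) % length
    on_first = pos in first
    if strand == "+":
        return 1 if on_first else 0
    return 0 if on_first else 1
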