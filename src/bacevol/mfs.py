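"""mRNA folding strength (MFS) from sliding-window secondary structure.

The coding sequence is scanned with 150-nt windows slid in 10-nt steps;
each window is folded, and a nucleotide's pairing probability is the number
of windows in which it pairs divided by the number of windows covering it.
MFS is the mean pairing probability over the mRNA — a proxy for how strongly
the transcript folds (in [0, 1]).

The built-in engine is base-pair maximization (Nussinov dynamic
programming) over Watson-Crick plus wobble pairs (AU/GC/GU, T read as U),
with a minimum hairpin loop of 3 unpaired nucleotides and a deterministic
traceback. Thermodynamic folding is deliberately out of this engine's
scope; per-window dot-bracket structures from any external folder can be
supplied through :class:`DotBracketEngine`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol

import numpy as np
from numba import njit

_WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
_PAIRS = _WC_PAIRS | {("G", "U"), ("U", "G")}

MIN_LOOP = 3  # unpaired nucleotides required inside a hairpin


def window_starts(seq_length: int, window: int = 150, step: int = 10) -> list[int]:
    """Start offsets of sliding windows over a sequence.

    Windows of ``window`` nt advance by ``step`` while they fit; when the
    last regular window stops short of the sequence end, a terminal window
    anchored at ``seq_length - window`` is appended so every nucleotide is
    covered. Sequences shorter than ``window`` get a single whole-sequence
    window.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if seq_length <= window:
        return [0]
    starts = list(range(0, seq_length - window + 1, step))
    if starts[-1] != seq_length - window:
        starts.append(seq_length - window)
    return starts


@njit(cache=False)
def _nussinov_fill(pair_ok: np.ndarray, min_loop: int) -> np.ndarray:  # pragma: no cover
    n = pair_ok.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i, j - 1]
            for k in range(i, j - min_loop):
                if pair_ok[k, j]:
                    left = M[i, k - 1] if k > i else 0
                    v = left + 1 + M[k + 1, j - 1]
                    if v > best:
                        best = v
            M[i, j] = best
    return M


def _pair_matrix(seq: str, min_loop: int = MIN_LOOP,
                 wobble: bool = True) -> np.ndarray:
    rna = seq.upper().replace("T", "U")
    pairs = _PAIRS if wobble else _WC_PAIRS
    n = len(rna)
    ok = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (rna[i], rna[j]) in pairs:
                ok[i, j] = True
    return ok


class FoldingEngine(Protocol):
    """Contract: fold a window into a non-crossing set of base pairs."""

    name: str

    def fold(self, window_seq: str, *, gene_id: str | None = None,
             start: int | None = None) -> tuple[tuple[int, int], ...]:
        ...


@dataclass
class NussinovEngine:
    """Base-pair maximization with deterministic traceback.

    Among co-optimal structures the traceback prefers pairing the window's
    right end over leaving it unpaired, and pairs it with the smallest
    admissible partner index — the result is a single reproducible
    structure per window. ``temperature`` is recorded for interface parity
    with thermodynamic folders and has no effect here.
    """

    name: str = "nussinov"
    min_loop: int = MIN_LOOP
    temperature: float = 30.0
    wobble: bool = True  # allow G-U pairs alongside Watson-Crick

    def fold(self, window_seq: str, *, gene_id: str | None = None,
             start: int | None = None) -> tuple[tuple[int, int], ...]:
        if not window_seq:
            raise ValueError("empty window")
        n = len(window_seq)
        if n <= self.min_loop + 1:
            return ()
        pair_ok = _pair_matrix(window_seq, self.min_loop, self.wobble)
        M = _nussinov_fill(pair_ok, self.min_loop)
        pairs: list[tuple[int, int]] = []
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if j - i <= self.min_loop:
                continue
            target = M[i, j]
            paired = False
            for k in range(i, j - self.min_loop):
                if pair_ok[k, j]:
                    left = M[i, k - 1] if k > i else 0
                    if left + 1 + M[k + 1, j - 1] == target:
                        pairs.append((k, j))
                        if k > i:
                            stack.append((i, k - 1))
                        stack.append((k + 1, j - 1))
                        paired = True
                        break
            if not paired:
                stack.append((i, j - 1))
        return tuple(sorted(pairs))


@dataclass
class DotBracketEngine:
    """Folds looked up from externally computed per-window structures.

    ``structures`` maps ``(gene_id, window_start)`` to a dot-bracket string
    of the window's length (as emitted by RNAfold and similar folders).
    """

    structures: Mapping[tuple[str, int], str]
    name: str = "external"

    def fold(self, window_seq: str, *, gene_id: str | None = None,
             start: int | None = None) -> tuple[tuple[int, int], ...]:
        db = self.structures[(gene_id, start)]
        if len(db) != len(window_seq):
            raise ValueError(f"dot-bracket length {len(db)} != window "
                             f"length {len(window_seq)} for {gene_id}@{start}")
        return parse_dot_bracket(db)


def parse_dot_bracket(structure: str) -> tuple[tuple[int, int], ...]:
    pairs = []
    stack = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


@dataclass(frozen=True)
class PairingProfile:
    """Per-nucleotide pairing probability across sliding windows."""

    gene_id: str
    p: np.ndarray             # pairing probability per nucleotide, in [0, 1]
    window_count: np.ndarray  # windows covering each nucleotide, >= 1


def pairing_profile(cds: str, engine: FoldingEngine | None = None,
                    window: int = 150, step: int = 10,
                    gene_id: str = "") -> PairingProfile:
    """Fold every sliding window and aggregate per-nucleotide pairing."""
    if engine is None:
        engine = NussinovEngine()
    n = len(cds)
    paired = np.zeros(n)
    covered = np.zeros(n)
    for start in window_starts(n, window, step):
        wseq = cds[start : start + window]
        covered[start : start + len(wseq)] += 1
        for i, j in engine.fold(wseq, gene_id=gene_id, start=start):
            paired[start + i] += 1
            paired[start + j] += 1
    return PairingProfile(gene_id, paired / covered, covered.astype(int))


def mfs_score(profile: PairingProfile) -> float:
    """Mean pairing probability over the mRNA."""
    if profile.p.size == 0:
        raise ValueError("empty pairing profile")
    return float(profile.p.mean())
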