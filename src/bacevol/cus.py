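"""Correspondence analysis of codon-usage tables and the CUS statistic.

Correspondence analysis (CA) decomposes a non-negative table under the
chi-square metric: with correspondence matrix ``P = T / n`` (``n`` the grand
total), row masses ``r`` and column masses ``c``, the matrix of standardized
residuals ``S = D_r^{-1/2} (P - r c') D_c^{-1/2}`` is factored by SVD and
rows are placed in principal coordinates ``F = D_r^{-1/2} U Sigma``. The sum
of squared singular values is the total inertia, equal to the table's
Pearson chi-square statistic divided by the grand total.

The codon-usage-separation statistic (CUS) measures how strongly ribosomal
proteins' codon usage departs from the rest of the genome: on the first two
CA axes, a two-sided 90% reference box (mean +/- 1.64 SD per axis) is drawn
around the non-ribosomal cloud, and CUS is the fraction of ribosomal genes
falling outside that box. CUS near 1 indicates strong translational
selection acting on highly expressed genes; near 0, none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger("bacevol")


@dataclass(frozen=True)
class CAResult:
    row_coords: np.ndarray      # kept_rows x K, principal coordinates
    col_coords: np.ndarray      # n_cols x K, principal coordinates
    singular_values: np.ndarray  # K, non-increasing
    total_inertia: float
    row_mask: np.ndarray        # original rows kept (all-zero rows dropped)
    row_masses: np.ndarray      # masses of kept rows


@dataclass(frozen=True)
class CUSResult:
    cus: float
    x_bar: float
    y_bar: float
    s_x: float
    s_y: float
    box: tuple[float, float, float, float]  # (x_lo, x_hi, y_lo, y_hi)
    n_ribo_outside: int
    n_ribo: int
    z: float


def correspondence_analysis(table: np.ndarray) -> CAResult:
    """Correspondence analysis of a genes x categories non-negative table.

    All-zero rows are dropped with a warning (they have no profile);
    all-zero columns get zero coordinates. Axes are ordered by singular
    value, and each axis is oriented so that the column coordinate of
    largest magnitude is positive — a deterministic sign convention.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (T < 0).any():
        raise ValueError("table entries must be non-negative")
    row_mask = T.sum(axis=1) > 0
    if row_mask.sum() < 3:
        raise ValueError("correspondence analysis needs at least 3 non-empty rows")
    if not row_mask.all():
        logger.warning("dropping %d all-zero rows from CA input",
                       int((~row_mask).sum()))
    T = T[row_mask]
    n = T.sum()
    P = T / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    col_mask = c > 0
    sr = np.sqrt(r)
    sc = np.sqrt(c[col_mask])
    S = (P[:, col_mask] - np.outer(r, c[col_mask])) / np.outer(sr, sc)
    U, sv, Vt = linalg.svd(S, full_matrices=False)
    K = min(S.shape[0] - 1, S.shape[1] - 1)
    U, sv, Vt = U[:, :K], sv[:K], Vt[:K]
    # principal coordinates
    F = (U * sv) / sr[:, None]
    G_kept = (Vt.T * sv) / sc[:, None]
    G = np.zeros((table.shape[1], K))
    G[col_mask] = G_kept
    # orient each axis: dominant column loading positive
    for k in range(K):
        if sv[k] <= 0:
            continue
        j = int(np.argmax(np.abs(G[:, k])))
        if G[j, k] < 0:
            G[:, k] *= -1
            F[:, k] *= -1
    return CAResult(F, G, sv, float((sv ** 2).sum()), row_mask, r)


def cus_statistic(row_coords: np.ndarray, ribosomal_flags: np.ndarray,
                  z: float = 1.64) -> CUSResult:
    """CUS from the first two CA axes and ribosomal membership flags.

    The reference box is mean +/- ``z`` standard deviations (sample SD,
    n-1 denominator) of the non-ribosomal genes on each axis. A ribosomal
    gene counts as outside when it exceeds the box on either axis; points
    exactly on the boundary count as inside.
    """
    coords = np.asarray(row_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] < 2:
        raise ValueError("row_coords must provide at least two axes")
    flags = np.asarray(ribosomal_flags, dtype=bool)
    if flags.shape[0] != coords.shape[0]:
        raise ValueError("ribosomal_flags length must match row count")
    non_ribo = coords[~flags, :2]
    ribo = coords[flags, :2]
    if len(ribo) < 1 or len(non_ribo) < 2:
        raise ValueError("need >=1 ribosomal and >=2 non-ribosomal genes")
    x_bar, y_bar = non_ribo.mean(axis=0)
    s_x, s_y = non_ribo.std(axis=0, ddof=1)
    if s_x == 0 and s_y == 0:
        raise ValueError("non-ribosomal coordinates have zero variance on "
                         "both axes")
    box = (x_bar - z * s_x, x_bar + z * s_x, y_bar - z * s_y, y_bar + z * s_y)
    inside = ((ribo[:, 0] >= box[0]) & (ribo[:, 0] <= box[1])
              & (ribo[:, 1] >= box[2]) & (ribo[:, 1] <= box[3]))
    n_out = int((~inside).sum())
    return CUSResult(n_out / len(ribo), float(x_bar), float(y_bar),
                     float(s_x), float(s_y), box, n_out, len(ribo), z)


def cus_from_rscu(rscu_table: np.ndarray, ribosomal_flags: np.ndarray,
                  z: float = 1.64) -> tuple[CAResult, CUSResult]:
    """CA of a genes x 64 RSCU table followed by the CUS statistic.

    Rows dropped by CA (all-zero) are dropped from the flags as well.
    """
    ca = correspondence_analysis(rscu_table)
    flags = np.asarray(ribosomal_flags, dtype=bool)[ca.row_mask]
    return ca, cus_statistic(ca.row_coords[:, :2], flags, z=z)
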