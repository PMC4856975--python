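"""Correspondence analysis of the MSA's indicator (one-hot) coding.

The MSA is coded as a 0/1 indicator table with one category per
(column, observed symbol) pair — multiple-correspondence-analysis style — and
decomposed under the chi-square metric. The joint map places sequences (rows)
and site-residue categories (columns) in the same principal-coordinate space,
so categories lying near a cluster of sequence points are the residues that
characterize that cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import MSA
from .errors import OrdinationError

logger = logging.getLogger(__name__)

_SV_TOL = 1e-12


@dataclass
class IndicatorMatrix:
    """0/1 sequence-by-category table; one category per (site, symbol) pair."""

    matrix: np.ndarray  # (n_seq, m) of 0/1
    col_labels: list[tuple[int, str]]
    row_labels: list[str]
    n_included_cols: int
    dropped_cols: list[int]

    @property
    def n_categories(self) -> int:
        return self.matrix.shape[1]


def build_indicator(msa: MSA, include_gap_category: bool = True) -> IndicatorMatrix:
    """Build the indicator coding of an MSA.

    Constant alignment columns (a single observed category) carry zero inertia
    and break the chi-square scaling, so they are dropped with a log notice.
    Gaps are a category of their own when ``include_gap_category`` is true;
    otherwise gap cells contribute no category (rows then may sum below the
    number of included columns).
    """
    if msa.n_seq < 2:
        raise OrdinationError("need at least 2 sequences")
    gap = msa.alphabet.gap_symbol
    order = {s: i for i, s in enumerate(msa.alphabet.symbols)}
    order[gap] = len(order)

    blocks, col_labels, included, dropped = [], [], 0, []
    for col in range(1, msa.n_col + 1):
        column = msa.column(col)
        observed = sorted(set(column), key=order.__getitem__)
        if not include_gap_category:
            observed = [s for s in observed if s != gap]
        if len(observed) <= 1:
            dropped.append(col)
            continue
        included += 1
        for s in observed:
            blocks.append([1 if ch == s else 0 for ch in column])
            col_labels.append((col, s))
    if dropped:
        logger.info(
            "dropped %d constant column(s) from indicator coding: %s",
            len(dropped), dropped,
        )
    if included == 0:
        raise OrdinationError("no variation: every column is constant")
    matrix = np.array(blocks, dtype=np.uint8).T
    return IndicatorMatrix(matrix, col_labels, list(msa.labels), included, dropped)


@dataclass
class CAResult:
    """Principal coordinates and spectrum of a correspondence analysis.

    ``row_coords`` / ``col_coords`` are truncated to the requested number of
    axes; ``singular_values`` holds the full positive spectrum, so
    ``total_inertia == sum(singular_values**2)`` always (it equals the
    chi-square statistic of the table divided by its grand total).
    """

    row_coords: np.ndarray       # (n_seq, n_axes)
    col_coords: np.ndarray       # (m, n_axes)
    singular_values: np.ndarray  # full positive spectrum, descending
    total_inertia: float
    row_masses: np.ndarray
    col_masses: np.ndarray
    row_labels: list[str]
    col_labels: list[tuple[int, str]]

    @property
    def n_axes(self) -> int:
        return self.row_coords.shape[1]


def correspondence_analysis(ind: IndicatorMatrix, n_axes: int = 2) -> CAResult:
    """Standard CA of a nonnegative table under the chi-square metric.

    P = N / grand total; S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}; SVD of S;
    principal coordinates F = D_r^{-1/2} U S, G = D_c^{-1/2} V S. Axes use a
    deterministic sign convention: each is oriented so its largest-|value|
    row coordinate is positive.
    """
    N = np.asarray(ind.matrix, dtype=float)
    if np.any(N < 0):
        raise OrdinationError("indicator table must be nonnegative")
    grand = N.sum()
    if grand <= 0:
        raise OrdinationError("indicator table has zero grand total")
    P = N / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r <= 0) or np.any(c <= 0):
        raise OrdinationError("zero row or column margin in indicator table")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > _SV_TOL
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    rank = sv.size

    F = (U * sv) / np.sqrt(r)[:, None]
    G = (Vt.T * sv) / np.sqrt(c)[:, None]
    # orient each axis: largest-|value| row coordinate positive
    for a in range(rank):
        i = int(np.argmax(np.abs(F[:, a])))
        if F[i, a] < 0:
            F[:, a] = -F[:, a]
            G[:, a] = -G[:, a]

    if n_axes > rank:
        logger.info("requested %d axes but rank is %d; truncating", n_axes, rank)
    d = min(n_axes, rank)
    return CAResult(
        row_coords=F[:, :d],
        col_coords=G[:, :d],
        singular_values=sv,
        total_inertia=float((sv ** 2).sum()),
        row_masses=r,
        col_masses=c,
        row_labels=list(ind.row_labels),
        col_labels=list(ind.col_labels),
    )


def nearest_categories(
    ca: CAResult, selection_rows: set[int], k: int
) -> list[tuple[int, str]]:
    """Categories ranked by distance to the centroid of selected sequence points.

    ``selection_rows`` are 1-based sequence indices. Distances are Euclidean in
    the retained principal coordinates; ties break by (column, symbol) order.
    """
    if not selection_rows:
        raise OrdinationError("selection is empty")
    for i in selection_rows:
        if not 1 <= i <= ca.row_coords.shape[0]:
            from .errors import BoundsError

            raise BoundsError(f"sequence index {i} out of range")
    idx = sorted(i - 1 for i in selection_rows)
    centroid = ca.row_coords[idx].mean(axis=0)
    dists = np.linalg.norm(ca.col_coords - centroid, axis=1)
    ranked = sorted(
        range(len(ca.col_labels)), key=lambda j: (dists[j], ca.col_labels[j])
    )
    k = min(k, len(ranked))
    return [ca.col_labels[j] for j in ranked[:k]]
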