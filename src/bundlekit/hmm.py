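"""Profile HMM match-state emissions and Fisher-score embedding of an MSA.

With a fixed alignment the state path of every sequence is known, so only the
match-state emission parameters carry per-sequence information; the embedding
is the gradient of each sequence's emission log-likelihood with respect to
those parameters under the natural (softmax) parameterization. For sequence
``x``, match column ``k`` and symbol ``b`` the score is::

    u_{k,b}(x) = 1[x_k = b] - e_k(b) * 1[x_k != gap]

i.e. indicator minus emission probability, and zero at gap positions. Scores
at a non-gap column therefore sum to zero over the alphabet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .alignment import MSA, Alphabet
from .errors import AlignmentShapeError, AlphabetError, ModelError, NumericalError


@dataclass
class ProfileHMM:
    """Match-column emission model with Laplace pseudocounts.

    ``emissions[k, b]`` is e_k(b) for the k-th match column (1-based alignment
    index ``match_columns[k]``) and the b-th alphabet symbol.
    """

    match_columns: tuple[int, ...]
    emissions: np.ndarray
    pseudocount: float
    alphabet: Alphabet
    n_col: int  # column count of the training MSA

    def __post_init__(self):
        if self.emissions.shape != (len(self.match_columns), self.alphabet.size):
            raise ModelError("emission matrix shape mismatch")
        sums = self.emissions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ModelError("emission rows must sum to 1")
        if list(self.match_columns) != sorted(set(self.match_columns)):
            raise ModelError("match_columns must be strictly increasing")


def train_profile_hmm(
    msa: MSA, gap_threshold: float = 0.5, pseudocount: float = 1.0
) -> ProfileHMM:
    """Train match-state emissions on an MSA.

    Match columns are those with gap fraction <= ``gap_threshold``;
    e_k(b) = (n_k(b) + alpha) / (n_k + alpha * |A|) with symmetric Laplace
    pseudocount alpha over non-gap characters.
    """
    if msa.n_seq < 2:
        raise ModelError("need at least 2 sequences to train a profile HMM")
    if not 0 <= gap_threshold < 1:
        raise ModelError(f"gap_threshold must be in [0, 1), got {gap_threshold}")
    if pseudocount < 0:
        raise ModelError(f"pseudocount must be nonnegative, got {pseudocount}")

    gap = msa.alphabet.gap_symbol
    sym_index = {s: i for i, s in enumerate(msa.alphabet.symbols)}
    match_cols, rows_e = [], []
    for col in range(1, msa.n_col + 1):
        column = msa.column(col)
        n_gap = column.count(gap)
        if n_gap / msa.n_seq > gap_threshold:
            continue
        counts = np.zeros(msa.alphabet.size)
        for ch in column:
            if ch != gap:
                counts[sym_index[ch]] += 1
        denom = counts.sum() + pseudocount * msa.alphabet.size
        rows_e.append((counts + pseudocount) / denom)
        match_cols.append(col)
    if not match_cols:
        raise ModelError("no match states: every column exceeds the gap threshold")
    return ProfileHMM(
        tuple(match_cols), np.array(rows_e), pseudocount, msa.alphabet, msa.n_col
    )


def emission_loglik(hmm: ProfileHMM, row: str) -> float:
    """Sum of log e_k(row_k) over match columns where ``row`` is non-gap."""
    if len(row) != hmm.n_col:
        raise AlignmentShapeError(
            f"row length {len(row)} != model column count {hmm.n_col}"
        )
    gap = hmm.alphabet.gap_symbol
    total = 0.0
    for k, col in enumerate(hmm.match_columns):
        ch = row[col - 1]
        if ch == gap:
            continue
        e = hmm.emissions[k, hmm.alphabet.index(ch)]
        if e <= 0:
            raise NumericalError(
                "zero emission probability; retrain with pseudocount > 0"
            )
        total += float(np.log(e))
    return total


@dataclass
class FisherEmbedding:
    """Per-sequence Fisher scores; one column per (match column, symbol) pair."""

    matrix: np.ndarray  # (n_seq, n_match * |A|)
    col_labels: list[tuple[int, str]]
    row_labels: list[str]

    def to_dataframe(self):
        import pandas as pd

        cols = [f"{c}:{s}" for c, s in self.col_labels]
        return pd.DataFrame(self.matrix, index=self.row_labels, columns=cols)


def fisher_scores(hmm: ProfileHMM, msa: MSA) -> FisherEmbedding:
    """Fisher-score embedding of every sequence in ``msa`` under ``hmm``."""
    if msa.n_col != hmm.n_col:
        raise AlignmentShapeError(
            f"MSA has {msa.n_col} columns but model was trained on {hmm.n_col}"
        )
    if np.any(hmm.emissions <= 0):
        raise NumericalError(
            "emissions contain zeros; Fisher scores require pseudocount > 0"
        )
    if tuple(msa.alphabet.symbols) != tuple(hmm.alphabet.symbols):
        raise AlphabetError("MSA and model alphabets differ")

    gap = hmm.alphabet.gap_symbol
    n_match, a = hmm.emissions.shape
    mat = np.zeros((msa.n_seq, n_match * a))
    sym_index = {s: i for i, s in enumerate(hmm.alphabet.symbols)}
    for i, row in enumerate(msa.rows):
        for k, col in enumerate(hmm.match_columns):
            ch = row[col - 1]
            if ch == gap:
                continue
            block = slice(k * a, (k + 1) * a)
            mat[i, block] = -hmm.emissions[k]
            mat[i, k * a + sym_index[ch]] += 1.0
    col_labels = [
        (col, s) for col in hmm.match_columns for s in hmm.alphabet.symbols
    ]
    return FisherEmbedding(mat, col_labels, list(msa.labels))


def export_embedding(emb: FisherEmbedding, path: str | os.PathLike) -> None:
    """Write the embedding as TSV (header of column:symbol labels, one row/seq)."""
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(f"{c}:{s}" for c, s in emb.col_labels) + "\n")
        for label, row in zip(emb.row_labels, emb.matrix):
            fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_embedding(path: str | os.PathLike) -> FisherEmbedding:
    """Re-parse an exported embedding TSV (round-trips to 1e-9)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        col_labels = []
        for h in header:
            col, sym = h.split(":")
            col_labels.append((int(col), sym))
        row_labels, data = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_labels.append(parts[0])
            data.append([float(v) for v in parts[1:]])
    return FisherEmbedding(np.array(data), col_labels, row_labels)
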