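"""Supervised per-site analysis: LOOCV site classifiers and the covariation test.

``detect_sites`` trains one linear-kernel SVM per alignment column on one-hot
symbol features (gap is a category) and scores the column by leave-one-out
cross-validation error over the grouped sequences. Because the feature vector
of a sequence at a column is determined entirely by its symbol, LOOCV folds
whose left-out sequence shares (symbol, group) are identical; folds are
computed once per equivalence class, which makes the procedure exact and fast.

``binomial_covariation_test`` is the exact test behind "sequences carrying
residue X at site A avoid residue Y at site B": condition on a selection,
count carriers of the target symbol at the target column, and compare against
the symbol's frequency in a null population.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import binom

from .alignment import MSA, GroupAssignment, Selection
from .errors import GroupingError, InputError

_REL_TOL = 1 + 1e-7  # minlike two-sided tolerance, as in R / scipy


@dataclass
class SiteScoreTable:
    """Per-column LOOCV errors and the derived marker opacities."""

    columns: np.ndarray         # 1-based column indices
    loocv_error: np.ndarray
    baseline_error: float       # majority-class LOOCV error (column-free)
    marker_opacity: np.ndarray
    n_used: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "column": self.columns,
                "loocv_error": self.loocv_error,
                "baseline_error": self.baseline_error,
                "marker_opacity": self.marker_opacity,
                "n_used": self.n_used,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def best_column(self) -> int:
        """1-based column with the smallest LOOCV error (first on ties)."""
        return int(self.columns[int(np.argmin(self.loocv_error))])


def _one_hot(symbol_idx: int, n_categories: int) -> np.ndarray:
    v = np.zeros(n_categories)
    v[symbol_idx] = 1.0
    return v


def _fit_predict(
    X: np.ndarray, y: np.ndarray, x_test: np.ndarray, n_groups: int, C: float
) -> int:
    """Train linear SVC(s) on (X, y) and predict the group index of x_test.

    Two groups: a single binary machine. More: one-vs-rest with argmax of the
    decision values; ties resolve to the lowest group index (declaration order).
    """
    from sklearn.svm import SVC

    present = np.unique(y)
    if present.size == 1:
        return int(present[0])
    if n_groups == 2 or present.size == 2:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X, y)
        return int(clf.predict(x_test[None, :])[0])
    scores = np.full(n_groups, -np.inf)
    for g in present:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X, (y == g).astype(int))
        scores[g] = float(clf.decision_function(x_test[None, :])[0])
    return int(np.argmax(scores))


def _majority_loocv_error(group_counts: np.ndarray) -> float:
    """LOOCV error of always predicting the majority group of the training fold.

    Ties among remaining groups resolve by declaration order.
    """
    n = int(group_counts.sum())
    errors = 0
    for g, cnt in enumerate(group_counts):
        if cnt == 0:
            continue
        remaining = group_counts.copy()
        remaining[g] -= 1
        pred = int(np.argmax(remaining))  # first max = declaration order
        if pred != g:
            errors += cnt
    return errors / n


def detect_sites(msa: MSA, groups: GroupAssignment, C: float = 1.0) -> SiteScoreTable:
    """Score every column by how well it alone explains the grouping.

    Only grouped sequences participate; requires >= 2 groups, each with
    >= 2 members. Deterministic given inputs.
    """
    groups.validate(msa)
    group_names = list(groups.group_names)
    used = sorted(groups.membership)
    name_to_idx = {g: i for i, g in enumerate(group_names)}
    y_all = np.array([name_to_idx[groups.membership[i]] for i in used])
    counts = np.bincount(y_all, minlength=len(group_names))
    active = [g for g, c in zip(group_names, counts) if c > 0]
    if len(active) < 2:
        raise GroupingError("need at least 2 groups with members")
    for g, c in zip(group_names, counts):
        if 0 < c < 2:
            raise GroupingError(f"group {g!r} has fewer than 2 members")

    n_groups = len(group_names)
    gap = msa.alphabet.gap_symbol
    cat_index = {s: i for i, s in enumerate(msa.alphabet.symbols)}
    cat_index[gap] = len(cat_index)
    n_cat = len(cat_index)
    baseline = _majority_loocv_error(counts)

    loocv = np.zeros(msa.n_col)
    for col in range(1, msa.n_col + 1):
        symbols = np.array([cat_index[msa.rows[i - 1][col - 1]] for i in used])
        # (symbol, group) -> count of sequences in this equivalence class
        classes: dict[tuple[int, int], int] = {}
        for s, g in zip(symbols, y_all):
            classes[(int(s), int(g))] = classes.get((int(s), int(g)), 0) + 1
        errors = 0
        for (s, g), cnt in sorted(classes.items()):
            held = classes.copy()
            held[(s, g)] -= 1
            X, y = [], []
            for (s2, g2), c2 in sorted(held.items()):
                for _ in range(c2):
                    X.append(_one_hot(s2, n_cat))
                    y.append(g2)
            pred = _fit_predict(
                np.array(X), np.array(y), _one_hot(s, n_cat), n_groups, C
            )
            if pred != g:
                errors += cnt
        loocv[col - 1] = errors / len(used)

    if baseline > 0:
        opacity = np.clip((baseline - loocv) / baseline, 0.0, 1.0)
    else:
        opacity = np.zeros_like(loocv)
    return SiteScoreTable(
        columns=np.arange(1, msa.n_col + 1),
        loocv_error=loocv,
        baseline_error=baseline,
        marker_opacity=opacity,
        n_used=len(used),
    )


def marker_opacities(table: SiteScoreTable) -> np.ndarray:
    """Per-column marker opacity: clamp((baseline - loocv)/baseline, 0, 1).

    Opacity 1 means a perfectly explanatory site; 0 means no better than the
    majority-class baseline.
    """
    if table.baseline_error > 0:
        return np.clip(
            (table.baseline_error - table.loocv_error) / table.baseline_error,
            0.0, 1.0,
        )
    return np.zeros_like(table.loocv_error)


class NullPopulation(str, Enum):
    ALL_SEQUENCES = "all_sequences"
    COMPLEMENT = "complement"


@dataclass
class BinomialTestResult:
    n_trials: int
    n_success: int
    null_p: float
    p_value_one_sided_less: float
    p_value_one_sided_greater: float
    p_value_two_sided: float
    degenerate_null: bool = False


def _minlike_two_sided(k: int, n: int, p: float) -> float:
    """Exact two-sided p: sum of point probabilities <= P(X=k)·(1+1e-7)."""
    if p <= 0:
        return 1.0 if k == 0 else 0.0
    if p >= 1:
        return 1.0 if k == n else 0.0
    probs = binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, probs[probs <= probs[k] * _REL_TOL].sum()))


def _central_two_sided(less: float, greater: float) -> float:
    return float(min(1.0, 2 * min(less, greater)))


def binomial_covariation_test(
    msa: MSA,
    condition: Selection,
    target_col: int,
    target_symbol: str,
    null_from: NullPopulation | str = NullPopulation.ALL_SEQUENCES,
    two_sided: str = "minlike",
) -> BinomialTestResult:
    """Exact binomial test of symbol enrichment/avoidance under a condition.

    n_trials = |condition|; n_success = conditioned sequences carrying
    ``target_symbol`` at ``target_col``; null_p = that symbol's frequency at
    the column in the null population (all sequences, or the complement of
    the selection). Two-sided convention defaults to minlike (sum of outcomes
    no more likely than observed); ``two_sided="central"`` doubles the smaller
    tail instead.
    """
    null_from = NullPopulation(null_from)
    condition.validate(msa)
    msa.check_col(target_col)
    selected = sorted(condition.seq_indices)
    if not selected:
        raise InputError("condition selects no sequences")
    target_symbol = target_symbol.upper()

    column = msa.column(target_col)
    n = len(selected)
    k = sum(1 for i in selected if column[i - 1] == target_symbol)

    if null_from is NullPopulation.ALL_SEQUENCES:
        null_pop = list(range(1, msa.n_seq + 1))
    else:
        sel = set(selected)
        null_pop = [i for i in range(1, msa.n_seq + 1) if i not in sel]
        if not null_pop:
            raise InputError("complement null population is empty")
    null_hits = sum(1 for i in null_pop if column[i - 1] == target_symbol)
    p = null_hits / len(null_pop)

    degenerate = p in (0.0, 1.0) and not (p == 0.0 and k == 0) \
        and not (p == 1.0 and k == n)
    less = float(binom.cdf(k, n, p))
    greater = float(binom.sf(k - 1, n, p))
    if two_sided == "minlike":
        two = _minlike_two_sided(k, n, p)
    elif two_sided == "central":
        two = _central_two_sided(less, greater)
    else:
        raise InputError(f"unknown two-sided convention {two_sided!r}")
    return BinomialTestResult(
        n_trials=n,
        n_success=k,
        null_p=p,
        p_value_one_sided_less=less,
        p_value_one_sided_greater=greater,
        p_value_two_sided=two,
        degenerate_null=degenerate,
    )
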