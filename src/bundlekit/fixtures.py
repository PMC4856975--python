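"""Deterministic synthetic alignments for demonstration and testing.

``make_fig1a``/``make_fig1b`` build the two illustrative 1000 x 5 nucleotide
alignments whose per-column symbol frequencies are identical while their
row-level motifs differ — the canonical case where consensus-based logos are
blind and a non-aggregative bundle is not. ``make_planted_msa`` builds
protein-like grouped alignments with planted specificity-determining sites
and covariant site pairs, returning the ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import MSA, Alphabet, GroupAssignment, builtin_alphabets, default_palette
from .errors import FixtureSpecError


def _two_motif_msa(motif_a: str, motif_b: str) -> MSA:
    alpha = builtin_alphabets()["dna"]
    labels = [f"A{i:04d}" for i in range(1, 501)] + [f"T{i:04d}" for i in range(1, 501)]
    rows = [motif_a] * 500 + [motif_b] * 500
    return MSA(labels, rows, alpha)


def make_fig1a() -> MSA:
    """1000 x 5 alignment: 500 copies of AAAAA then 500 copies of TTTTT."""
    return _two_motif_msa("AAAAA", "TTTTT")


def make_fig1b() -> MSA:
    """1000 x 5 alignment: 500 copies of AATTT then 500 copies of TTAAA.

    Column-wise composition is identical to :func:`make_fig1a`; only the
    within-sequence motifs differ.
    """
    return _two_motif_msa("AATTT", "TTAAA")


def two_motif_groups(msa: MSA) -> GroupAssignment:
    """Group the two 500-row motif blocks of a figure fixture."""
    names = ["motifA", "motifB"]
    colors = dict(zip(names, default_palette(2)))
    membership = {i: ("motifA" if i <= 500 else "motifB") for i in range(1, msa.n_seq + 1)}
    return GroupAssignment(names, colors, membership)


@dataclass
class PlantedMSASpec:
    """Recipe for a grouped MSA with known informative sites.

    ``planted_sites`` maps a column to a per-group symbol; ``covariant_pairs``
    jointly writes two (column, symbol) pairs into a seeded random half of all
    rows. Background cells are drawn i.i.d. from ``background`` (uniform over
    the alphabet by default).
    """

    group_sizes: dict[str, int]
    n_col: int
    alphabet: Alphabet | None = None
    planted_sites: list[tuple[int, dict[str, str]]] = field(default_factory=list)
    covariant_pairs: list[tuple[tuple[int, str], tuple[int, str]]] = field(
        default_factory=list
    )
    background: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.alphabet is None:
            self.alphabet = builtin_alphabets()["protein"]
        planted_cols = [c for c, _ in self.planted_sites]
        if len(set(planted_cols)) != len(planted_cols):
            raise FixtureSpecError("planted site columns must be disjoint")
        covariant_cols = [c for pair in self.covariant_pairs for c, _ in pair]
        if set(planted_cols) & set(covariant_cols):
            raise FixtureSpecError(
                "covariant pair columns conflict with planted site columns"
            )
        all_cols = planted_cols + covariant_cols
        for c in all_cols:
            if not 1 <= c <= self.n_col:
                raise FixtureSpecError(f"column {c} out of range [1, {self.n_col}]")
        for name, size in self.group_sizes.items():
            if size < 2:
                raise FixtureSpecError(f"group {name!r} must have >= 2 members")
        for col, by_group in self.planted_sites:
            for g in by_group:
                if g not in self.group_sizes:
                    raise FixtureSpecError(
                        f"planted site {col} references unknown group {g!r}"
                    )


def make_planted_msa(
    spec: PlantedMSASpec,
) -> tuple[MSA, GroupAssignment, list[int]]:
    """Generate a grouped MSA per the spec; returns ground-truth site list.

    Deterministic given ``spec.seed``; labels encode the group for readable
    test failures.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = spec.alphabet
    symbols = list(alpha.symbols)
    if spec.background is None:
        probs = np.full(len(symbols), 1.0 / len(symbols))
    else:
        probs = np.array([spec.background.get(s, 0.0) for s in symbols])
        probs = probs / probs.sum()

    group_names = list(spec.group_sizes)
    labels, groups_of_row = [], []
    for g in group_names:
        for i in range(1, spec.group_sizes[g] + 1):
            labels.append(f"{g}_{i:03d}")
            groups_of_row.append(g)
    n_seq = len(labels)

    grid = rng.choice(len(symbols), size=(n_seq, spec.n_col), p=probs)
    rows_chars = [[symbols[grid[i, j]] for j in range(spec.n_col)] for i in range(n_seq)]

    for col, by_group in spec.planted_sites:
        for i, g in enumerate(groups_of_row):
            if g in by_group:
                rows_chars[i][col - 1] = by_group[g]

    for (col_a, sym_a), (col_b, sym_b) in spec.covariant_pairs:
        chosen = rng.permutation(n_seq)[: n_seq // 2]
        for i in chosen:
            rows_chars[i][col_a - 1] = sym_a
            rows_chars[i][col_b - 1] = sym_b

    msa = MSA(labels, ["".join(r) for r in rows_chars], alpha)
    colors = dict(zip(group_names, default_palette(len(group_names))))
    membership = {i + 1: groups_of_row[i] for i in range(n_seq)}
    ground_truth = sorted(c for c, _ in spec.planted_sites)
    return msa, GroupAssignment(group_names, colors, membership), ground_truth


_NAMED_FIXTURES = {
    "fig1a": make_fig1a,
    "fig1b": make_fig1b,
}


def named_fixture(name: str) -> MSA:
    """Look up a named deterministic fixture (``fig1a`` or ``fig1b``)."""
    if name not in _NAMED_FIXTURES:
        raise FixtureSpecError(
            f"unknown fixture {name!r} (available: {sorted(_NAMED_FIXTURES)})"
        )
    return _NAMED_FIXTURES[name]()
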