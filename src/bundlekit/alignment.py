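"""Core MSA data model: alphabets, alignments, groups, selections, FASTA/Stockholm I/O.

All column and sequence indices exposed by this package are 1-based; internal
numpy/list storage is 0-based. Symbols are upper-cased on read and the
Stockholm gap convention ``.`` is normalized to ``-``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    BoundsError,
    GroupingError,
    IdentityError,
)

GAP = "-"

# Kyte-Doolittle hydropathy index (J Mol Biol 157:105-132 values).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "D": -3.5, "E": -3.5, "N": -3.5, "Q": -3.5, "K": -3.9,
    "R": -4.5,
}

# Chemical classes used for the grouped y-axis ordering:
# hydrophobic, aromatic, polar, positively charged, negatively charged.
_CHEMICAL_CLASS_ORDER = "AVLIMCGP" + "FWY" + "STNQ" + "HKR" + "DE"


@dataclass(frozen=True)
class Alphabet:
    """An ordered symbol set with named orderings for the bundle y-axis.

    ``orderings`` maps an ordering name (e.g. ``"hydrophobicity"``) to a
    permutation of ``symbols``; the permutation is the top-to-bottom order of
    symbol rows in a Sequence Bundle.
    """

    name: str
    symbols: tuple[str, ...]
    gap_symbol: str = GAP
    orderings: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise AlphabetError(f"alphabet {self.name!r} has duplicate symbols")
        for s in self.symbols:
            if len(s) != 1:
                raise AlphabetError(f"alphabet symbol {s!r} is not a single character")
        if self.gap_symbol in self.symbols:
            raise AlphabetError(
                f"gap symbol {self.gap_symbol!r} must not be an alphabet symbol"
            )
        for oname, perm in self.orderings.items():
            if sorted(perm) != sorted(self.symbols):
                raise AlphabetError(
                    f"ordering {oname!r} is not a permutation of alphabet {self.name!r}"
                )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise AlphabetError(
                f"symbol {symbol!r} not in alphabet {self.name!r}"
            ) from None

    def ordering(self, name: str | None) -> tuple[str, ...]:
        """Resolve an ordering name; ``None`` means the alphabet's native order."""
        if name is None:
            return self.symbols
        if name not in self.orderings:
            from .errors import ConfigurationError

            raise ConfigurationError(
                f"alphabet {self.name!r} has no ordering {name!r} "
                f"(available: {sorted(self.orderings)})"
            )
        return tuple(self.orderings[name])


def builtin_alphabets() -> dict[str, Alphabet]:
    """The built-in DNA, RNA and protein alphabets with biochemical orderings."""
    hydro = tuple(
        sorted(KYTE_DOOLITTLE, key=lambda a: (-KYTE_DOOLITTLE[a], a))
    )
    protein_syms = tuple("ACDEFGHIKLMNPQRSTVWY")
    return {
        "dna": Alphabet(
            "dna",
            tuple("ACGT"),
            orderings={"alphabetical": tuple("ACGT"),
                       "purine-pyrimidine": tuple("AGCT")},
        ),
        "rna": Alphabet(
            "rna",
            tuple("ACGU"),
            orderings={"alphabetical": tuple("ACGU"),
                       "purine-pyrimidine": tuple("AGCU")},
        ),
        "protein": Alphabet(
            "protein",
            protein_syms,
            orderings={
                "alphabetical": protein_syms,
                "hydrophobicity": hydro,
                "chemical-class": tuple(_CHEMICAL_CLASS_ORDER),
            },
        ),
    }


def guess_alphabet(rows: Iterable[str]) -> Alphabet:
    """Pick the smallest built-in alphabet covering the observed symbols."""
    seen = set()
    for r in rows:
        seen.update(r.upper())
    seen.discard(GAP)
    seen.discard(".")
    for name in ("dna", "rna", "protein"):
        alpha = builtin_alphabets()[name]
        if seen <= set(alpha.symbols):
            return alpha
    raise AlphabetError(
        f"symbols {sorted(seen)} fit no built-in alphabet; supply a custom one"
    )


class MSA:
    """A rectangular multiple sequence alignment over an :class:`Alphabet`.

    Invariants are enforced at construction: equal row lengths, unique labels,
    every character in the alphabet or equal to the gap symbol.
    """

    def __init__(
        self,
        labels: list[str],
        rows: list[str],
        alphabet: Alphabet,
        descriptions: dict[str, str] | None = None,
    ):
        if len(labels) != len(rows):
            raise IdentityError(
                f"{len(labels)} labels but {len(rows)} rows"
            )
        if not rows:
            raise AlignmentShapeError("alignment has no sequences")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise IdentityError(f"duplicate sequence labels: {dupes}")
        n_col = len(rows[0])
        valid = set(alphabet.symbols) | {alphabet.gap_symbol}
        for label, row in zip(labels, rows):
            if len(row) != n_col:
                raise AlignmentShapeError(
                    f"record {label!r} has length {len(row)}, expected {n_col}"
                )
            for j, ch in enumerate(row):
                if ch not in valid:
                    raise AlphabetError(
                        f"symbol {ch!r} in record {label!r}, column {j + 1} "
                        f"is not in alphabet {alphabet.name!r}"
                    )
        self.labels = list(labels)
        self.rows = list(rows)
        self.alphabet = alphabet
        self.descriptions = dict(descriptions or {})
        self.n_seq = len(rows)
        self.n_col = n_col
        self._label_index = {l: i for i, l in enumerate(self.labels)}

    def __repr__(self):
        return f"<MSA {self.n_seq} x {self.n_col} over {self.alphabet.name!r}>"

    def __eq__(self, other):
        return (
            isinstance(other, MSA)
            and self.labels == other.labels
            and self.rows == other.rows
            and self.alphabet.symbols == other.alphabet.symbols
        )

    def row_of(self, label: str) -> str:
        if label not in self._label_index:
            raise IdentityError(f"no sequence labelled {label!r}")
        return self.rows[self._label_index[label]]

    def index_of(self, label: str) -> int:
        """1-based row index of a label."""
        if label not in self._label_index:
            raise IdentityError(f"no sequence labelled {label!r}")
        return self._label_index[label] + 1

    def check_col(self, col: int) -> None:
        if not 1 <= col <= self.n_col:
            raise BoundsError(f"column {col} out of range [1, {self.n_col}]")

    def column(self, col: int) -> str:
        """The symbols of 1-based column ``col``, one per sequence."""
        self.check_col(col)
        return "".join(row[col - 1] for row in self.rows)


def column_stats(msa: MSA, col: int) -> dict[str, int]:
    """Symbol counts (gap included) of a 1-based column; values sum to n_seq."""
    counts: dict[str, int] = {}
    for ch in msa.column(col):
        counts[ch] = counts.get(ch, 0) + 1
    return counts


@dataclass(frozen=True)
class Selection:
    """A set of selected sequences and sites, both 1-based."""

    seq_indices: frozenset[int] = frozenset()
    site_indices: frozenset[int] = frozenset()

    def validate(self, msa: MSA) -> None:
        for i in self.seq_indices:
            if not 1 <= i <= msa.n_seq:
                raise BoundsError(f"sequence index {i} out of range [1, {msa.n_seq}]")
        for j in self.site_indices:
            msa.check_col(j)


@dataclass
class GroupAssignment:
    """A partial assignment of sequences (1-based indices) to named groups."""

    group_names: list[str]
    colors: dict[str, str]
    membership: dict[int, str]

    def __post_init__(self):
        declared = set(self.group_names)
        for idx, g in self.membership.items():
            if g not in declared:
                raise GroupingError(f"sequence {idx} assigned to undeclared group {g!r}")
            if idx < 1:
                raise BoundsError(f"sequence index {idx} must be >= 1")

    def validate(self, msa: MSA) -> None:
        for idx in self.membership:
            if idx > msa.n_seq:
                raise BoundsError(
                    f"group member index {idx} out of range [1, {msa.n_seq}]"
                )

    def members(self, group: str) -> list[int]:
        return sorted(i for i, g in self.membership.items() if g == group)

    def group_of(self, seq_index: int) -> str | None:
        return self.membership.get(seq_index)


# ---------------------------------------------------------------------------
# I/O


def _normalize_row(raw: str) -> str:
    return raw.upper().replace(".", GAP)


def read_fasta(path: str | os.PathLike, alphabet: Alphabet) -> MSA:
    """Read an aligned FASTA file (wrapped or unwrapped) into an MSA.

    Labels are the first whitespace-delimited token of each header; the rest
    of the header is retained in ``MSA.descriptions``.
    """
    from Bio import SeqIO

    labels, rows, descriptions = [], [], {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        label = rec.id
        labels.append(label)
        rows.append(_normalize_row(str(rec.seq)))
        desc = rec.description[len(rec.id):].strip()
        if desc:
            descriptions[label] = desc
    if not labels:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return MSA(labels, rows, alphabet, descriptions)


def read_stockholm(path: str | os.PathLike, alphabet: Alphabet) -> MSA:
    """Read a Stockholm 1.0 alignment (sequence lines only; ``#=`` lines ignored)."""
    from Bio import AlignIO

    aln = AlignIO.read(os.fspath(path), "stockholm")
    labels = [rec.id for rec in aln]
    rows = [_normalize_row(str(rec.seq)) for rec in aln]
    return MSA(labels, rows, alphabet)


def write_fasta(msa: MSA, path: str | os.PathLike, width: int = 60) -> None:
    """Write an MSA to FASTA; guarantees exact round-trip through read_fasta."""
    if msa.n_col == 0:
        raise AlignmentShapeError("refusing to write a zero-column alignment")
    buf = io.StringIO()
    for label, row in zip(msa.labels, msa.rows):
        desc = msa.descriptions.get(label)
        header = f">{label} {desc}" if desc else f">{label}"
        buf.write(header + "\n")
        for start in range(0, len(row), width):
            buf.write(row[start:start + width] + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


_DEFAULT_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


def default_palette(n: int) -> list[str]:
    """n colours from the default categorical palette (cycled beyond 10)."""
    return [_DEFAULT_PALETTE[i % len(_DEFAULT_PALETTE)] for i in range(n)]


def read_groups_tsv(path: str | os.PathLike, msa: MSA) -> GroupAssignment:
    """Read a label/group/color TSV into a GroupAssignment for ``msa``.

    The color column may be empty; missing colours are filled from the
    default palette in group declaration order.
    """
    group_names: list[str] = []
    colors: dict[str, str] = {}
    membership: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "label" and lineno == 1:
                continue  # header
            if len(parts) < 2:
                raise GroupingError(
                    f"{path}:{lineno}: expected at least label<TAB>group"
                )
            label, group = parts[0], parts[1]
            color = parts[2] if len(parts) > 2 and parts[2] else None
            if group not in group_names:
                group_names.append(group)
            if color:
                colors[group] = color
            membership[msa.index_of(label)] = group
    for i, g in enumerate(group_names):
        colors.setdefault(g, default_palette(len(group_names))[i])
    return GroupAssignment(group_names, colors, membership)


def write_groups_tsv(groups: GroupAssignment, msa: MSA, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("label\tgroup\tcolor\n")
        for idx in sorted(groups.membership):
            g = groups.membership[idx]
            fh.write(f"{msa.labels[idx - 1]}\t{g}\t{groups.colors.get(g, '')}\n")
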