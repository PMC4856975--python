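"""Boolean-regex selection query language over labels, rows and sites.

Grammar (keywords case-insensitive, AND binds tighter than OR)::

    expr   := term ('OR' term)*
    term   := factor ('AND' factor)*
    factor := 'NOT' factor | '(' expr ')' | atom
    atom   := 'label' '~' /regex/
            | 'seq'   '~' [degap:]/regex/
            | 'site' '(' INT ')' '=' SYMBOL

Regexes are unanchored searches against the full aligned row string (gaps
included); the ``degap:`` prefix matches against the row with gaps removed.
``site(i) = X`` tests exact symbol equality at 1-based column ``i``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .alignment import MSA, Selection
from .errors import BoundsError, QuerySyntaxError

# --- AST ---------------------------------------------------------------


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]

    def __post_init__(self):
        assert len(self.children) >= 2


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]

    def __post_init__(self):
        assert len(self.children) >= 2


@dataclass(frozen=True)
class Not:
    child: "Node"


@dataclass(frozen=True)
class LabelMatch:
    pattern: str


@dataclass(frozen=True)
class SeqMatch:
    pattern: str
    degap: bool = False


@dataclass(frozen=True)
class SiteEq:
    col: int
    symbol: str


Node = And | Or | Not | LabelMatch | SeqMatch | SiteEq


# --- Tokenizer ---------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<KW>(?i:\bAND\b|\bOR\b|\bNOT\b|\blabel\b|\bseq\b|\bsite\b|\bdegap\b))
  | (?P<LP>\()
  | (?P<RP>\))
  | (?P<TILDE>~)
  | (?P<EQ>=)
  | (?P<COLON>:)
  | (?P<INT>\d+)
  | (?P<REGEX>/(?:\\.|[^/\\])*/)
  | (?P<SYM>\S)
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class _Tok:
    kind: str
    text: str
    pos: int


def _tokenize(text: str) -> list[_Tok]:
    toks, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise QuerySyntaxError(f"unrecognized character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind == "REGEX" and not m.group().endswith("/"):
            raise QuerySyntaxError("unterminated regex literal", pos)
        if kind != "WS":
            tok_text = m.group()
            if kind == "KW":
                toks.append(_Tok(tok_text.upper(), tok_text, pos))
            else:
                toks.append(_Tok(kind, tok_text, pos))
        pos = m.end()
    toks.append(_Tok("EOF", "", len(text)))
    return toks


# --- Parser ------------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0

    @property
    def cur(self) -> _Tok:
        return self.toks[self.i]

    def _advance(self) -> _Tok:
        tok = self.cur
        self.i += 1
        return tok

    def _expect(self, kind: str, what: str) -> _Tok:
        if self.cur.kind != kind:
            raise QuerySyntaxError(f"expected {what}", self.cur.pos)
        return self._advance()

    def parse(self) -> Node:
        node = self.expr()
        if self.cur.kind != "EOF":
            raise QuerySyntaxError(
                f"unexpected trailing input {self.cur.text!r}", self.cur.pos
            )
        return node

    def expr(self) -> Node:
        terms = [self.term()]
        while self.cur.kind == "OR":
            self._advance()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self) -> Node:
        factors = [self.factor()]
        while self.cur.kind == "AND":
            self._advance()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self) -> Node:
        if self.cur.kind == "NOT":
            self._advance()
            return Not(self.factor())
        if self.cur.kind == "LP":
            open_pos = self._advance().pos
            try:
                node = self.expr()
            except QuerySyntaxError as exc:
                if exc.position >= len(self.text):
                    # input ran out inside the group: blame the open paren
                    raise QuerySyntaxError(
                        "unclosed parenthesis", open_pos
                    ) from None
                raise
            if self.cur.kind != "RP":
                raise QuerySyntaxError("unclosed parenthesis", open_pos)
            self._advance()
            return node
        return self.atom()

    def _regex_literal(self) -> str:
        tok = self._expect("REGEX", "a /regex/ literal")
        pattern = tok.text[1:-1].replace(r"\/", "/")
        try:
            re.compile(pattern)
        except re.error as exc:
            raise QuerySyntaxError(f"invalid regex: {exc}", tok.pos) from exc
        return pattern

    def atom(self) -> Node:
        tok = self.cur
        if tok.kind == "LABEL":
            self._advance()
            self._expect("TILDE", "'~' after 'label'")
            return LabelMatch(self._regex_literal())
        if tok.kind == "SEQ":
            self._advance()
            self._expect("TILDE", "'~' after 'seq'")
            degap = False
            if self.cur.kind == "DEGAP":
                self._advance()
                self._expect("COLON", "':' after 'degap'")
                degap = True
            return SeqMatch(self._regex_literal(), degap=degap)
        if tok.kind == "SITE":
            self._advance()
            self._expect("LP", "'(' after 'site'")
            col_tok = self._expect("INT", "an integer column index")
            self._expect("RP", "')' after the column index")
            self._expect("EQ", "'=' after 'site(i)'")
            sym_tok = self._advance()
            if sym_tok.kind == "EOF" or len(sym_tok.text) != 1:
                raise QuerySyntaxError("expected a single symbol", sym_tok.pos)
            return SiteEq(int(col_tok.text), sym_tok.text.upper())
        raise QuerySyntaxError(
            f"expected an atom, got {tok.text!r}" if tok.kind != "EOF"
            else "unexpected end of query",
            tok.pos,
        )


def parse_query(text: str) -> Node:
    """Parse query text into an AST; raises QuerySyntaxError with a position."""
    if not text or not text.strip():
        raise QuerySyntaxError("empty query", 0)
    return _Parser(text).parse()


# --- Evaluation --------------------------------------------------------


def _eval_row(node: Node, label: str, row: str) -> bool:
    if isinstance(node, And):
        return all(_eval_row(c, label, row) for c in node.children)
    if isinstance(node, Or):
        return any(_eval_row(c, label, row) for c in node.children)
    if isinstance(node, Not):
        return not _eval_row(node.child, label, row)
    if isinstance(node, LabelMatch):
        return re.search(node.pattern, label) is not None
    if isinstance(node, SeqMatch):
        target = row.replace("-", "") if node.degap else row
        return re.search(node.pattern, target) is not None
    if isinstance(node, SiteEq):
        return row[node.col - 1] == node.symbol
    raise TypeError(f"unknown AST node {node!r}")


def _check_bounds(node: Node, msa: MSA) -> None:
    if isinstance(node, (And, Or)):
        for c in node.children:
            _check_bounds(c, msa)
    elif isinstance(node, Not):
        _check_bounds(node.child, msa)
    elif isinstance(node, SiteEq):
        if not 1 <= node.col <= msa.n_col:
            raise BoundsError(
                f"site({node.col}) out of range [1, {msa.n_col}]"
            )


def evaluate_query(ast: Node, msa: MSA) -> Selection:
    """Evaluate a query AST; returns the selected sequence indices (1-based).

    Queries select sequences only; ``site_indices`` of the result is empty.
    """
    _check_bounds(ast, msa)
    hits = frozenset(
        i + 1
        for i, (label, row) in enumerate(zip(msa.labels, msa.rows))
        if _eval_row(ast, label, row)
    )
    return Selection(seq_indices=hits)


def select(msa: MSA, text: str) -> Selection:
    """Parse and evaluate a query in one call."""
    return evaluate_query(parse_query(text), msa)
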