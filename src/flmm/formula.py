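"""Mixed-model formula sublanguage and design-matrix construction.

The grammar is a deliberate subset of the lme4 syntax: fixed terms joined
by ``+`` (``:`` interactions allowed), and random-effect blocks
``(terms | group)`` where ``group`` is a single factor or a nested pair
``a/b``. A nested pair expands to two random groups, ``(terms | a)`` and
``(terms | a:b)``. Each block carries an implicit intercept unless
suppressed with a ``0 +`` term.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np
import pandas as pd

from .data import RESERVED_ID_COLUMNS

__all__ = [
    "FormulaError",
    "DesignError",
    "RandomGroup",
    "ModelFormula",
    "parse_formula",
    "DesignMatrices",
    "RandomBlock",
    "build_design",
]


class FormulaError(ValueError):
    """Parse error; carries the character position in the formula string."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class DesignError(ValueError):
    """Raised when a parsed formula cannot be realised on a trial table."""


@dataclasses.dataclass(frozen=True)
class RandomGroup:
    """Random-effect terms sharing one grouping factor.

    ``grouping`` is either a bare factor name (``"id"``) or a nested
    interaction produced by ``a/b`` expansion (``"id:session"``).
    """

    terms: tuple[str, ...]  # includes "1" unless intercept suppressed
    grouping: str

    def __str__(self) -> str:
        terms = self.terms if "1" in self.terms else ("0",) + self.terms
        return f"({' + '.join(terms)} | {self.grouping})"


@dataclasses.dataclass(frozen=True)
class ModelFormula:
    response: str
    fixed_terms: tuple[str, ...]
    random_groups: tuple[RandomGroup, ...]

    def __str__(self) -> str:
        parts = list(self.fixed_terms)
        if "1" not in self.fixed_terms:
            parts = ["0"] + parts
        parts += [str(g) for g in self.random_groups]
        return f"{self.response} ~ {' + '.join(parts)}"


_TOKEN_RE = re.compile(r"\s*(~|\+|\(|\)|\||/|:|[A-Za-z_.][A-Za-z0-9_.]*|[01])")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start(1) != pos and not text[pos : m.start(1)].isspace():
            raise FormulaError(f"unexpected character {text[pos]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_formula(text: str) -> ModelFormula:
    """Parse ``response ~ fixed + (terms | group)`` into a :class:`ModelFormula`.

    Deterministic; nested groups ``a/b`` are expanded; the fixed and random
    parts carry an implicit intercept ``1`` unless a ``0`` term is present.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise FormulaError("empty formula", 0)
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def take(expected=None):
        nonlocal idx
        if idx >= len(tokens):
            raise FormulaError(f"unexpected end of formula, expected {expected}", len(text))
        tok, pos = tokens[idx]
        if expected is not None and tok != expected:
            raise FormulaError(f"expected {expected!r}, found {tok!r}", pos)
        idx += 1
        return tok, pos

    resp, pos = take()
    if not re.fullmatch(r"[A-Za-z_.][A-Za-z0-9_.]*", resp):
        raise FormulaError("response must be a column name", pos)
    take("~")

    fixed: list[str] = []
    random: list[RandomGroup] = []
    suppress_fixed_intercept = False

    def parse_name():
        tok, pos = take()
        if not re.fullmatch(r"[A-Za-z_.][A-Za-z0-9_.]*", tok):
            raise FormulaError(f"expected a name, found {tok!r}", pos)
        return tok

    def parse_fixed_term():
        nonlocal suppress_fixed_intercept
        tok, pos = take()
        if tok == "0":
            suppress_fixed_intercept = True
            return None
        if tok == "1":
            return "1"
        if not re.fullmatch(r"[A-Za-z_.][A-Za-z0-9_.]*", tok):
            raise FormulaError(f"unexpected token {tok!r} in fixed terms", pos)
        parts = [tok]
        while peek() == ":":
            take(":")
            parts.append(parse_name())
        return ":".join(parts)

    def parse_random_block():
        take("(")
        terms: list[str] = []
        suppress = False
        while True:
            tok, pos = take()
            if tok == "0":
                suppress = True
            elif tok == "1":
                terms.append("1")
            elif re.fullmatch(r"[A-Za-z_.][A-Za-z0-9_.]*", tok):
                if peek() == ":":
                    raise FormulaError("interactions are not allowed in random terms", tokens[idx][1])
                terms.append(tok)
            else:
                raise FormulaError(f"unexpected token {tok!r} in random terms", pos)
            nxt = peek()
            if nxt == "+":
                take("+")
                continue
            if nxt == "|":
                break
            raise FormulaError("random term must be followed by '|' group", tokens[idx][1] if idx < len(tokens) else len(text))
        take("|")
        g1 = parse_name()
        nested = None
        if peek() == "/":
            take("/")
            nested = parse_name()
        elif peek() == ":":
            # already-expanded nested grouping, e.g. "id:session"
            take(":")
            g1 = f"{g1}:{parse_name()}"
        take(")")
        if not suppress and "1" not in terms:
            terms = ["1"] + terms
        if not terms:
            raise FormulaError("random block has no terms", None)
        terms_t = tuple(dict.fromkeys(terms))
        random.append(RandomGroup(terms=terms_t, grouping=g1))
        if nested is not None:
            random.append(RandomGroup(terms=terms_t, grouping=f"{g1}:{nested}"))

    while True:
        if peek() == "(":
            parse_random_block()
        else:
            term = parse_fixed_term()
            if term is not None and term not in fixed:
                fixed.append(term)
        if peek() == "+":
            take("+")
            continue
        if peek() is None:
            break
        raise FormulaError(f"unexpected token {peek()!r}", tokens[idx][1])

    if not suppress_fixed_intercept and "1" not in fixed:
        fixed = ["1"] + fixed
    if not fixed and not random:
        raise FormulaError("formula has no terms", len(text))
    return ModelFormula(response=resp, fixed_terms=tuple(fixed), random_groups=tuple(random))


# ---------------------------------------------------------------------------
# Design construction


@dataclasses.dataclass
class RandomBlock:
    """Dense per-group random-effect design.

    ``Z`` has one column block of width ``q`` per grouping level, so its
    shape is (n_rows, q * n_levels); ``level_index`` maps each row to its
    level's position in ``levels``.
    """

    grouping: str
    levels: list
    q: int
    term_names: list[str]
    Z: np.ndarray
    level_index: np.ndarray

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_block(self, j: int) -> np.ndarray:
        return self.Z[:, j * self.q : (j + 1) * self.q]


@dataclasses.dataclass
class DesignMatrices:
    X: np.ndarray
    fixed_names: list[str]
    random_blocks: list[RandomBlock]
    centering: dict[str, float]  # covariate -> subtracted mean (only if centered)
    reference_levels: dict[str, object]
    formula: ModelFormula

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _is_indicator(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return np.all(np.isin(u, (0.0, 1.0)))


def _column_sets(
    name: str,
    trials: pd.DataFrame,
    center,
    centering: dict,
    reference_levels: dict,
):
    """Columns (matrix + names) for one covariate, with coding and centering applied."""
    if name not in trials.columns:
        raise DesignError(f"formula references unknown column '{name}'")
    col = trials[name]
    if pd.api.types.is_numeric_dtype(col):
        vals = col.to_numpy(dtype=float)
        do_center = center.get(name, center.get("__numeric__", True)) if isinstance(center, dict) else bool(center)
        if do_center and _is_indicator(vals) and not (isinstance(center, dict) and center.get(name) is True):
            do_center = False  # keep 0/1 condition indicators interpretable
        if do_center:
            mu = float(np.mean(vals))
            centering[name] = mu
            vals = vals - mu
        return vals[:, None], [name]
    # categorical: dummy coding against a reference level (sorted-unique order,
    # so the design is invariant to trial row order)
    if isinstance(col.dtype, pd.CategoricalDtype):
        levels = [l for l in col.cat.categories if (col == l).any()]
    else:
        levels = sorted(pd.unique(col.dropna()))
    if len(levels) < 2:
        raise DesignError(f"categorical covariate '{name}' has fewer than 2 observed levels")
    ref = levels[0]
    reference_levels[name] = ref
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((col == lev).to_numpy(dtype=float)[:, None])
        names.append(f"{name}[{lev}]")
    return np.hstack(cols), names


def _term_columns(term: str, trials, center, centering, reference_levels, n):
    if term == "1":
        return np.ones((n, 1)), ["(Intercept)"]
    mats, names = [], []
    for part in term.split(":"):
        m, nm = _column_sets(part, trials, center, centering, reference_levels)
        mats.append(m)
        names.append(nm)
    out_m, out_n = mats[0], names[0]
    for m, nm in zip(mats[1:], names[1:]):
        cols, labels = [], []
        for i in range(out_m.shape[1]):
            for j in range(m.shape[1]):
                cols.append((out_m[:, i] * m[:, j])[:, None])
                labels.append(f"{out_n[i]}:{nm[j]}")
        out_m, out_n = np.hstack(cols), labels
    return out_m, out_n


def build_design(
    formula: ModelFormula, trials: pd.DataFrame, center="default"
) -> DesignMatrices:
    """Build fixed design X and per-group random blocks Z from a trial table.

    ``center`` may be ``"default"`` (mean-center numeric covariates, never
    0/1 indicators), a bool applied to all numeric covariates, or a dict of
    per-covariate flags. The same centering is applied wherever a covariate
    appears (fixed or random terms). Subtracted means are recorded so the
    intercept keeps its "signal at average covariates" interpretation.
    """
    n = len(trials)
    if center == "default":
        center = {"__numeric__": True}
    elif isinstance(center, bool):
        center = {"__numeric__": center}
    centering: dict[str, float] = {}
    reference_levels: dict[str, object] = {}

    X_parts, names = [], []
    for term in formula.fixed_terms:
        m, nm = _term_columns(term, trials, center, centering, reference_levels, n)
        X_parts.append(m)
        names.extend(nm)
    if not X_parts:
        raise DesignError("model has no fixed-effect columns")
    X = np.hstack(X_parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            "fixed design matrix is rank deficient (aliased columns); "
            f"columns: {names}"
        )

    blocks: list[RandomBlock] = []
    for group in formula.random_groups:
        factors = []
        for f in group.grouping.split(":"):
            if f not in trials.columns:
                # lme4-style formulas conventionally call the subject factor "id"
                if f == "id" and "subject" in trials.columns:
                    f = "subject"
                elif f not in RESERVED_ID_COLUMNS:
                    raise DesignError(f"grouping factor '{f}' not in trial table")
            factors.append(f)
        key = trials[factors[0]].astype(str)
        for f in factors[1:]:
            key = key + ":" + trials[f].astype(str)
        levels = sorted(pd.unique(key))
        if len(levels) < 2:
            raise DesignError(
                f"grouping factor '{group.grouping}' has a single level"
            )
        level_index = np.asarray([levels.index(k) for k in key])
        Zt_parts, term_names = [], []
        for term in group.terms:
            m, nm = _term_columns(term, trials, center, centering, reference_levels, n)
            Zt_parts.append(m)
            term_names.extend(nm)
        Zsmall = np.hstack(Zt_parts)  # n x q
        q = Zsmall.shape[1]
        Z = np.zeros((n, q * len(levels)))
        for j in range(len(levels)):
            rows = level_index == j
            Z[np.ix_(rows, np.arange(j * q, (j + 1) * q))] = Zsmall[rows]
        blocks.append(
            RandomBlock(
                grouping=group.grouping,
                levels=levels,
                q=q,
                term_names=term_names,
                Z=Z,
                level_index=level_index,
            )
        )

    return DesignMatrices(
        X=X,
        fixed_names=names,
        random_blocks=blocks,
        centering=centering,
        reference_levels=reference_levels,
        formula=formula,
    )
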