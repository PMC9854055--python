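"""Molecular formula parsing restricted to the ten-element organic alphabet.

A formula string such as ``"C6H4(OH)2"`` is parsed into a mapping from element
symbol to a positive atom count.  Only the ten elements used by the MF-LOGP
feature space -- C, H, N, O, S, P, F, Cl, Br, I -- are accepted; anything else
(metals, deuterium, charge tokens, isotope brackets, hydrate dots) is rejected
rather than silently dropped, because the model space is defined by exactly
these ten columns.
"""

from __future__ import annotations

from typing import Dict, Mapping

#: Canonical element order; also the column order of the base feature matrix.
ELEMENTS = ("C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I")

_ELEMENT_SET = frozenset(ELEMENTS)

#: Halogen subset used by the double-bond-equivalent formula.
HALOGENS = ("F", "Cl", "Br", "I")

AtomCounts = Dict[str, int]


class FormulaError(ValueError):
    """Malformed or unsupported molecular formula string.

    Carries the character ``position`` at which parsing failed, when known.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


class UnsupportedElementError(FormulaError):
    """An element symbol outside the supported ten-element set."""

    def __init__(self, symbol: str, position: int | None = None):
        self.symbol = symbol
        super().__init__(f"unsupported element: {symbol}", position)


def parse_formula(formula: str) -> AtomCounts:
    """Parse a molecular formula string into atom counts.

    Supports integer multiplicities and arbitrarily nested parenthesized
    groups with integer multipliers, e.g. ``"C6H4(OH)2"`` -> ``{C:6, H:6,
    O:2}``.  Parsing is case-sensitive (``Cl`` is chlorine; ``CL`` is carbon
    followed by an invalid token).  Zero multiplicities are rejected: a
    formula asserts presence.

    Raises
    ------
    FormulaError
        On empty input, malformed syntax (unbalanced parentheses, dangling
        digits, zero multiplicity) -- with the offending position.
    UnsupportedElementError
        On any element symbol outside {C, H, N, O, S, P, F, Cl, Br, I}.
    """
    if not isinstance(formula, str):
        raise FormulaError("formula must be a string")
    s = formula.strip()
    if not s:
        raise FormulaError("empty formula string", 0)
    counts, pos = _parse_group(s, 0, depth=0)
    if pos != len(s):
        # only reachable on a stray closing parenthesis
        raise FormulaError(f"unbalanced ')' in {formula!r}", pos)
    if not counts:
        raise FormulaError("formula contains no atoms", 0)
    return counts


def _parse_int(s: str, i: int) -> tuple[int | None, int]:
    """Read an optional decimal integer at position *i*; None when absent."""
    j = i
    while j < len(s) and s[j].isdigit():
        j += 1
    if j == i:
        return None, i
    value = int(s[i:j])
    if value == 0:
        raise FormulaError("zero multiplicity is not allowed", i)
    return value, j


def _parse_group(s: str, i: int, depth: int) -> tuple[AtomCounts, int]:
    counts: AtomCounts = {}
    while i < len(s):
        ch = s[i]
        if ch == "(":
            inner, j = _parse_group(s, i + 1, depth + 1)
            if j >= len(s) or s[j] != ")":
                raise FormulaError("unbalanced '('", i)
            mult, j = _parse_int(s, j + 1)
            mult = 1 if mult is None else mult
            if not inner:
                raise FormulaError("empty parenthesized group", i)
            for sym, n in inner.items():
                counts[sym] = counts.get(sym, 0) + n * mult
            i = j
        elif ch == ")":
            if depth == 0:
                return counts, i
            return counts, i
        elif ch.isdigit():
            raise FormulaError("dangling digit without a preceding symbol", i)
        elif ch.isupper():
            j = i + 1
            while j < len(s) and s[j].islower():
                j += 1
            symbol = s[i:j]
            if symbol not in _ELEMENT_SET:
                raise UnsupportedElementError(symbol, i)
            mult, j = _parse_int(s, j)
            mult = 1 if mult is None else mult
            counts[symbol] = counts.get(symbol, 0) + mult
            i = j
        else:
            raise FormulaError(f"unexpected character {ch!r}", i)
    if depth > 0:
        raise FormulaError("unbalanced '('", i)
    return counts, i


def validate_counts(counts: Mapping[str, int]) -> AtomCounts:
    """Validate an atom-count mapping and return a plain dict copy.

    All keys must be supported element symbols, all values non-negative
    integers, and at least one value must be positive.
    """
    out: AtomCounts = {}
    for sym, n in counts.items():
        if sym not in _ELEMENT_SET:
            raise UnsupportedElementError(str(sym))
        if not isinstance(n, (int,)) or isinstance(n, bool) or n < 0:
            raise FormulaError(f"count for {sym} must be a non-negative integer, got {n!r}")
        if n:
            out[sym] = int(n)
    if not out:
        raise FormulaError("at least one atom count must be positive")
    return out


def is_organic(counts: Mapping[str, int]) -> bool:
    """True when the compound contains at least one carbon atom."""
    return counts.get("C", 0) >= 1


def hill_formula(counts: Mapping[str, int]) -> str:
    """Canonical Hill-notation string: C, then H, then the rest alphabetically.

    Carbon-free species are ordered fully alphabetically.  Unit multiplicities
    are omitted.  Used as the canonical key for duplicate detection and
    isomer grouping.
    """
    counts = validate_counts(counts)
    if is_organic(counts):
        order = ["C", "H"] + sorted(sym for sym in counts if sym not in ("C", "H"))
    else:
        order = sorted(counts)
    parts = []
    for sym in order:
        n = counts.get(sym, 0)
        if n == 0:
            continue
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)
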