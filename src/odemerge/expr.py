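"""Kinetic-law expression handling.

Laws are stored as strings using ``^`` or ``**`` for powers and plain
identifiers for species/parameters/compartments.  Parsing goes through sympy
with an explicit symbol table so that reserved sympy names (``E``, ``I``,
``S``, ``lambda`` ...) used as model identifiers never collapse into
constants or keywords.
"""

from __future__ import annotations

import re
from functools import lru_cache

import sympy

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")

#: function names allowed inside kinetic laws
_FUNCTIONS = {
    "exp": sympy.exp,
    "log": sympy.log,
    "ln": sympy.log,
    "log10": lambda x: sympy.log(x, 10),
    "sqrt": sympy.sqrt,
    "abs": sympy.Abs,
    "pow": sympy.Pow,
    "sin": sympy.sin,
    "cos": sympy.cos,
    "tan": sympy.tan,
    "tanh": sympy.tanh,
    "floor": sympy.floor,
    "ceil": sympy.ceiling,
    "ceiling": sympy.ceiling,
}

#: constructs we refuse to simulate
_UNSUPPORTED_TOKENS = ("piecewise", "delay", "time")


class ExpressionError(ValueError):
    pass


def identifiers(expr: str) -> list:
    """All identifiers in textual order (with duplicates)."""
    return _IDENT.findall(expr)


def expr_symbols(expr: str) -> set:
    """Set of non-function identifiers appearing in an expression string."""
    return {t for t in identifiers(expr) if t not in _FUNCTIONS}


@lru_cache(maxsize=4096)
def parse_expr(expr: str) -> sympy.Expr:
    """Parse a kinetic-law string into a sympy expression."""
    for tok in _UNSUPPORTED_TOKENS:
        if re.search(rf"\b{tok}\b", expr, flags=re.IGNORECASE):
            raise ExpressionError(f"unsupported construct {tok!r} in expression {expr!r}")
    local = {t: sympy.Symbol(t) for t in expr_symbols(expr)}
    local.update(_FUNCTIONS)
    try:
        parsed = sympy.parse_expr(
            expr.replace("^", "**"), local_dict=local, evaluate=True
        )
    except ExpressionError:
        raise
    except Exception as exc:  # sympy's parser raises a zoo of error types
        raise ExpressionError(f"cannot parse expression {expr!r}: {exc}") from exc
    return parsed


def to_string(expr: sympy.Expr) -> str:
    return sympy.sstr(expr)


def rename_symbols(expr: str, mapping: dict) -> str:
    """Rename identifiers in an expression string (textual, exact-word)."""
    if not mapping:
        return expr

    def repl(m):
        return mapping.get(m.group(0), m.group(0))

    return _IDENT.sub(repl, expr)


def equivalent_structure(expr_a: str, expr_b: str, param_map: dict) -> bool:
    """Whether two laws share the same symbolic structure.

    ``param_map`` maps identifiers of B's expression onto A's.  Equivalence
    is symbolic: expressions are compared after renaming and canonical
    expansion, so commutative reorderings are ignored but genuinely
    different rate laws are not.
    """
    try:
        ea = parse_expr(expr_a)
        eb = parse_expr(rename_symbols(expr_b, param_map))
    except ExpressionError:
        return False
    return sympy.expand(ea - eb) == 0
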