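"""Substructure pattern matching on linear-code glycan strings.

Patterns are fragments of the canonical linear code extended with wildcards:

========  =====================================================================
symbol    matches
========  =====================================================================
``-``     any string with parentheses matched, not ending in ``)`` (a single
          unbranched ligand chain; may be empty)
``…``     any string with parentheses matched (may be empty); ``...`` accepted
``_``     continuation toward the root: any string in which every ``(`` is
          closed by a following ``)`` (unmatched ``)`` allowed; may be empty)
``|``     a possible branch point: empty, ``(…)``, ``)`` or ``)(…)``
``*``     the reaction site anchor (zero width); only meaningful when the
          expression is evaluated against a known site
``Gnbis``  macro for the bisecting-GlcNAc motif ``Ma3(GNb4)(…Ma6)Mb4``
========  =====================================================================

A pattern-initial ``(`` matches either a literal ``(`` or the start of the
string, so it doubles as a non-reducing-terminus marker: a residue is terminal
exactly when it is preceded by ``(`` or starts the string.

Boolean expressions over patterns use ``&``, ``or`` and ``~`` (the ``|``
character is never boolean), residue-count comparisons such as ``#M = 9`` or
``#NN>1``, and ``Count <pattern>`` which yields the number of distinct match
positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

from .glycans import GlycanStructure

__all__ = [
    "PatternError",
    "CompiledPattern",
    "compile_pattern",
    "match_sites",
    "MatchSite",
    "PatternExpr",
    "parse_expr",
    "evaluate_expr",
    "count_matches",
]

GNBIS = "Ma3(GNb4)(…Ma6)Mb4"

_WILDCARDS = {"-": "chain", "…": "any", "_": "root", "|": "branch", "*": "site"}


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class MatchSite:
    """One match of a substrate pattern: start/end offsets and wildcard bindings.

    ``site`` is the reaction-site offset (first difference between the matched
    substrate text and the product replacement); it is filled in by the rule
    engine and is ``None`` for plain pattern matches.
    """

    start: int
    end: int
    bindings: tuple
    site: int | None = None


def _tokenize(pattern: str):
    """Split a pattern into ('lit', s) / wildcard / ('term',) elements."""
    pattern = pattern.replace("...", "…").replace("Gnbis", GNBIS)
    elems = []
    i = 0
    if pattern.startswith("("):
        elems.append(("term",))
        i = 1
    buf = []
    while i < len(pattern):
        ch = pattern[i]
        if ch in _WILDCARDS:
            if buf:
                elems.append(("lit", "".join(buf)))
                buf = []
            elems.append((_WILDCARDS[ch],))
        elif ch in "()ab2346" or ch.isalpha():
            buf.append(ch)
        else:
            raise PatternError(f"bad character {ch!r} in pattern {pattern!r}")
        i += 1
    if buf:
        elems.append(("lit", "".join(buf)))
    return tuple(elems)


@dataclass(frozen=True)
class CompiledPattern:
    source: str
    elems: tuple

    @property
    def site_anchored(self) -> bool:
        return any(e[0] in ("site", "root") for e in self.elems)

    def wildcard_kinds(self):
        return tuple(e[0] for e in self.elems if e[0] != "lit")


@lru_cache(maxsize=4096)
def compile_pattern(pattern: str) -> CompiledPattern:
    if not pattern:
        raise PatternError("empty pattern")
    return CompiledPattern(pattern, _tokenize(pattern))


def _balanced_ends(s: str, i: int):
    """Offsets j >= i with s[i:j] paren-balanced (depth never negative, ends 0)."""
    out = [i]
    depth = 0
    for j in range(i, len(s)):
        if s[j] == "(":
            depth += 1
        elif s[j] == ")":
            depth -= 1
            if depth < 0:
                break
        if depth == 0:
            out.append(j + 1)
    return out


def _rootward_ends(s: str, i: int):
    """Offsets j >= i with every '(' in s[i:j] closed within it."""
    out = [i]
    open_ = 0
    for j in range(i, len(s)):
        if s[j] == "(":
            open_ += 1
        elif s[j] == ")" and open_ > 0:
            open_ -= 1
        if open_ == 0:
            out.append(j + 1)
    return out


def _match_from(s: str, i: int, elems: tuple, k: int, bindings: list, site: list):
    """Yield (end, bindings, site_offset) for matches of elems[k:] at s[i:]."""
    if k == len(elems):
        yield i, tuple(bindings), site[0]
        return
    kind = elems[k]
    tag = kind[0]
    if tag == "lit":
        lit = kind[1]
        if s.startswith(lit, i):
            yield from _match_from(s, i + len(lit), elems, k + 1, bindings, site)
    elif tag == "term":
        if i < len(s) and s[i] == "(":
            bindings.append("(")
            yield from _match_from(s, i + 1, elems, k + 1, bindings, site)
            bindings.pop()
        elif i == 0:
            bindings.append("")
            yield from _match_from(s, i, elems, k + 1, bindings, site)
            bindings.pop()
    elif tag == "site":
        prev = site[0]
        site[0] = i
        bindings.append("")
        yield from _match_from(s, i, elems, k + 1, bindings, site)
        bindings.pop()
        site[0] = prev
    elif tag == "chain":
        for j in _balanced_ends(s, i):
            if j > i and s[j - 1] == ")":
                continue
            bindings.append(s[i:j])
            yield from _match_from(s, j, elems, k + 1, bindings, site)
            bindings.pop()
    elif tag == "any":
        for j in _balanced_ends(s, i):
            bindings.append(s[i:j])
            yield from _match_from(s, j, elems, k + 1, bindings, site)
            bindings.pop()
    elif tag == "root":
        for j in _rootward_ends(s, i):
            bindings.append(s[i:j])
            yield from _match_from(s, j, elems, k + 1, bindings, site)
            bindings.pop()
    elif tag == "branch":
        # alternatives: "", "(…)", ")", ")(…)"
        bindings.append("")
        yield from _match_from(s, i, elems, k + 1, bindings, site)
        bindings.pop()
        if i < len(s) and s[i] == "(":
            for j in _balanced_ends(s, i + 1):
                if j < len(s) and s[j] == ")":
                    bindings.append(s[i : j + 1])
                    yield from _match_from(s, j + 1, elems, k + 1, bindings, site)
                    bindings.pop()
        if i < len(s) and s[i] == ")":
            bindings.append(")")
            yield from _match_from(s, i + 1, elems, k + 1, bindings, site)
            bindings.pop()
            if i + 1 < len(s) and s[i + 1] == "(":
                for j in _balanced_ends(s, i + 2):
                    if j < len(s) and s[j] == ")":
                        bindings.append(s[i : j + 1])
                        yield from _match_from(s, j + 1, elems, k + 1, bindings, site)
                        bindings.pop()
    else:  # pragma: no cover
        raise PatternError(f"unknown element {kind!r}")


def iter_matches(pattern: str | CompiledPattern, s: str, at: int | None = None):
    """Yield MatchSite for every match; ``at`` restricts to one start offset."""
    cp = pattern if isinstance(pattern, CompiledPattern) else compile_pattern(pattern)
    starts = range(len(s) + 1) if at is None else [at]
    for i in starts:
        for end, bindings, site in _match_from(s, i, cp.elems, 0, [], [None]):
            yield MatchSite(start=i, end=end, bindings=bindings, site=site)


def match_sites(pattern: str | CompiledPattern, g: GlycanStructure | str) -> list[MatchSite]:
    """All distinct matches of ``pattern`` in canonical-string order."""
    s = g.text if isinstance(g, GlycanStructure) else g
    seen = set()
    out = []
    for m in iter_matches(pattern, s):
        key = (m.start, m.bindings)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def count_matches(pattern: str | CompiledPattern, g: GlycanStructure | str) -> int:
    """Number of distinct start offsets at which the pattern matches."""
    s = g.text if isinstance(g, GlycanStructure) else g
    cp = pattern if isinstance(pattern, CompiledPattern) else compile_pattern(pattern)
    n = 0
    for i in range(len(s) + 1):
        for _ in _match_from(s, i, cp.elems, 0, [], [None]):
            n += 1
            break
    return n


def _matches_at_site(cp: CompiledPattern, s: str, site: int) -> bool:
    """Match a '*'-anchored pattern so that its site anchor lands on ``site``."""
    for m in iter_matches(cp, s):
        if m.site == site:
            return True
    return False


# ---------------------------------------------------------------------------
# Boolean / count expressions
# ---------------------------------------------------------------------------

_CMP_RE = re.compile(r"^#\s*(GN|NN|M|A|F|G)\s*(=|>|<|>=|<=)\s*(\d+)$")


class PatternExpr:
    """Parsed boolean/count expression over patterns and residue counts."""

    def __init__(self, node, source: str):
        self._node = node
        self.source = source

    def __repr__(self):
        return f"PatternExpr({self.source!r})"

    @property
    def site_anchored(self) -> bool:
        def walk(n):
            tag = n[0]
            if tag in ("or", "and"):
                return any(walk(c) for c in n[1])
            if tag == "not":
                return walk(n[1])
            if tag in ("atom", "count"):
                return n[1].site_anchored
            return False

        return walk(self._node)

    def evaluate(self, g: GlycanStructure, site: int | None = None):
        return _eval_node(self._node, g, site)


def _eval_node(node, g: GlycanStructure, site):
    tag = node[0]
    if tag == "or":
        return any(_eval_node(c, g, site) for c in node[1])
    if tag == "and":
        return all(_eval_node(c, g, site) for c in node[1])
    if tag == "not":
        return not _eval_node(node[1], g, site)
    if tag == "cmp":
        code, op, val = node[1], node[2], node[3]
        n = g.composition[code]
        return {"=": n == val, ">": n > val, "<": n < val,
                ">=": n >= val, "<=": n <= val}[op]
    if tag == "count":
        return count_matches(node[1], g)
    if tag == "atom":
        cp = node[1]
        if any(e[0] == "site" for e in cp.elems):
            if site is None:
                raise PatternError(
                    f"site-anchored pattern {cp.source!r} evaluated without a site")
            return _matches_at_site(cp, g.text, site)
        for _ in iter_matches(cp, g.text):
            return True
        return False
    raise PatternError(f"bad node {node!r}")  # pragma: no cover


def _parse_atom(text: str):
    text = text.strip()
    neg = False
    while text.startswith("~"):
        neg = not neg
        text = text[1:].strip()
    m = _CMP_RE.match(text)
    if m:
        node = ("cmp", m.group(1), m.group(2), int(m.group(3)))
    elif text.startswith("Count "):
        node = ("count", compile_pattern(text[6:].strip()))
    else:
        node = ("atom", compile_pattern(text))
    return ("not", node) if neg else node


@lru_cache(maxsize=4096)
def parse_expr(text: str) -> PatternExpr:
    """Parse a constraint/feature expression.

    Grammar: ``expr := term (' or ' term)*``; ``term := atom (' & ' atom)*``;
    ``atom := '~'* (count-comparison | 'Count ' pattern | pattern)``.
    """
    src = text.strip()
    if not src:
        raise PatternError("empty expression")
    or_parts = re.split(r"\s+or\s+", src)
    or_nodes = []
    for part in or_parts:
        and_parts = re.split(r"\s*&\s*", part)
        and_nodes = [_parse_atom(p) for p in and_parts]
        or_nodes.append(("and", and_nodes) if len(and_nodes) > 1 else and_nodes[0])
    node = ("or", or_nodes) if len(or_nodes) > 1 else or_nodes[0]
    return PatternExpr(node, src)


def evaluate_expr(expr: PatternExpr | str, g: GlycanStructure,
                  site: int | None = None):
    """Evaluate a constraint (boolean) or ``Count`` (integer) expression."""
    if isinstance(expr, str):
        expr = parse_expr(expr)
    return expr.evaluate(g, site)
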