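"""Independent brute-force oracles used to cross-check the implementation.

These deliberately favour exhaustive enumeration over cleverness: every
wildcard binding is tried as an explicit substring and validated by a
stand-alone predicate, so agreement with the production matcher is a real
two-route check.
"""

from __future__ import annotations

GNBIS = "Ma3(GNb4)(…Ma6)Mb4"


def _is_balanced(s: str) -> bool:
    depth = 0
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return False
    return depth == 0


def _is_chain(s: str) -> bool:
    return _is_balanced(s) and not s.endswith(")")


def _is_rootward(s: str) -> bool:
    open_ = 0
    for ch in s:
        if ch == "(":
            open_ += 1
        elif ch == ")" and open_ > 0:
            open_ -= 1
    return open_ == 0


def _is_branch(s: str) -> bool:
    if s in ("", ")"):
        return True
    if s.startswith("(") and s.endswith(")") and _is_balanced(s[1:-1]):
        return True
    if s.startswith(")(") and s.endswith(")") and _is_balanced(s[2:-1]):
        return True
    return False


def _tokenize(pattern: str):
    pattern = pattern.replace("...", "…").replace("Gnbis", GNBIS)
    elems = []
    i = 0
    if pattern.startswith("("):
        elems.append("term")
        i = 1
    buf = ""
    for ch in pattern[i:]:
        if ch in "-…_|*":
            if buf:
                elems.append(("lit", buf))
                buf = ""
            elems.append({"-": "chain", "…": "any", "_": "root",
                          "|": "branch", "*": "site"}[ch])
        else:
            buf += ch
    if buf:
        elems.append(("lit", buf))
    return elems


def brute_force_matches(pattern: str, s: str):
    """All (start, bindings, site) triples by exhaustive substring enumeration."""
    elems = _tokenize(pattern)
    out = []

    def rec(i, k, bindings, site):
        if k == len(elems):
            out.append((start, tuple(bindings), site))
            return
        e = elems[k]
        if isinstance(e, tuple):  # literal
            if s.startswith(e[1], i):
                rec(i + len(e[1]), k + 1, bindings, site)
            return
        if e == "term":
            if i < len(s) and s[i] == "(":
                rec(i + 1, k + 1, bindings + ["("], site)
            elif i == 0:
                rec(i, k + 1, bindings + [""], site)
            return
        if e == "site":
            rec(i, k + 1, bindings + [""], i)
            return
        pred = {"chain": _is_chain, "any": _is_balanced,
                "root": _is_rootward, "branch": _is_branch}[e]
        for j in range(i, len(s) + 1):
            if pred(s[i:j]):
                rec(j, k + 1, bindings + [s[i:j]], site)

    for start in range(len(s) + 1):
        rec(start, 0, [], None)
    return out


def brute_force_sites(pattern: str, s: str):
    """Distinct (start, bindings) pairs, for comparison with match_sites."""
    seen = set()
    out = []
    for start, bindings, _ in brute_force_matches(pattern, s):
        key = (start, bindings)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out
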