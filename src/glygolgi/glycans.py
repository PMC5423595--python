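"""Glycan data model: condensed linear-code parser, canonicalizer and masses.

Glycan structures are written in a condensed IUPAC linear code, e.g. the
Man9GlcNAc2 precursor::

    Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN;Asn

Each residue token is ``<code><anomer><locant>`` (the locant is the carbon on
the *parent* residue), written leaf-to-root; the root residue carries no
linkage.  At a branch point the lowest-locant branch is written in-line and
every higher-locant branch is parenthesized, in ascending locant order, which
makes the string unique for each structure.  The optional ``;Asn`` suffix
marks the reducing-end attachment and is kept only as a flag.

Sugar codes: ``M`` mannose, ``GN`` N-acetylglucosamine, ``A`` galactose,
``F`` fucose, ``NN`` N-acetylneuraminic acid, ``G`` glucose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

__all__ = [
    "GlycanParseError",
    "Residue",
    "GlycanStructure",
    "parse_glycan",
    "canonicalize",
    "composition",
    "elemental_formula",
    "permethylated_mass",
    "read_structure_list",
    "MAN9",
    "GLC1MAN9",
]

RESIDUE_CODES = ("M", "GN", "A", "F", "NN", "G")
ANOMERS = ("a", "b")
LOCANTS = (2, 3, 4, 6)

#: Monoisotopic atomic masses (u), CODATA/AME values.
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
}

# Elemental increments of glycosidically linked, fully methylated residues.
# A permethylated hexose residue inside a chain is C9H16O5; HexNAc C11H19NO5;
# deoxyhexose C8H14O4; NeuAc C16H27NO8.  Glucose and galactose are hexoses.
_PERMETHYL_RESIDUE = {
    "M": {"C": 9, "H": 16, "O": 5},
    "A": {"C": 9, "H": 16, "O": 5},
    "G": {"C": 9, "H": 16, "O": 5},
    "GN": {"C": 11, "H": 19, "N": 1, "O": 5},
    "NN": {"C": 16, "H": 27, "N": 1, "O": 8},
    "F": {"C": 8, "H": 14, "O": 4},
}

# Free reducing end closure of the permethylated chain: the residue sum above
# is short one water plus the two extra methyls (as 2 x CH2) that cap the
# reducing-end and non-reducing-end oxygens, i.e. C2H6O in total.
_REDUCING_END_CLOSURE = {"C": 2, "H": 6, "O": 1}


class GlycanParseError(ValueError):
    """Raised for malformed linear-code strings; carries the offending offset."""

    def __init__(self, message: str, text: str, offset: int):
        super().__init__(f"{message} at offset {offset} in {text!r}")
        self.text = text
        self.offset = offset


@dataclass
class Residue:
    code: str
    anomer: str | None  # None only for the root residue
    locant: int | None  # carbon on the parent; None only for the root
    children: list["Residue"] = field(default_factory=list)

    def token(self) -> str:
        if self.anomer is None:
            return self.code
        return f"{self.code}{self.anomer}{self.locant}"


def _serialize(res: Residue) -> str:
    kids = sorted(res.children, key=lambda r: r.locant)
    parts = []
    if kids:
        parts.append(_serialize(kids[0]))
        for k in kids[1:]:
            parts.append("(" + _serialize(k) + ")")
    parts.append(res.token())
    return "".join(parts)


def _read_token(text: str, lo: int, hi: int, is_root: bool):
    """Read the residue token ending at ``hi``; return (code, anomer, locant, start)."""
    if is_root and text[hi - 1] in "2346":
        # subtree fragment: the outermost residue keeps its linkage token
        is_root = False
    if is_root:
        end = hi
    else:
        if hi - lo < 3:
            raise GlycanParseError("truncated residue token", text, lo)
        loc, ano = text[hi - 1], text[hi - 2]
        if loc not in "2346":
            raise GlycanParseError("missing linkage locant", text, hi - 1)
        if ano not in "ab":
            raise GlycanParseError("missing anomer", text, hi - 2)
        end = hi - 2
    # Codes ending in 'N' are always the two-letter codes GN / NN.
    if end - lo >= 2 and text[end - 1] == "N":
        code, start = text[end - 2 : end], end - 2
    else:
        code, start = text[end - 1 : end], end - 1
    if code not in RESIDUE_CODES:
        raise GlycanParseError(f"unknown residue code {code!r}", text, start)
    if is_root:
        return code, None, None, start
    return code, text[hi - 2], int(text[hi - 1]), start


def _parse_span(text: str, lo: int, hi: int, is_root: bool) -> Residue:
    if hi <= lo:
        raise GlycanParseError("empty residue", text, lo)
    code, anomer, locant, pos = _read_token(text, lo, hi, is_root)
    node = Residue(code, anomer, locant)
    branches = []
    while pos > lo and text[pos - 1] == ")":
        depth, j = 0, pos - 1
        while j >= lo:
            if text[j] == ")":
                depth += 1
            elif text[j] == "(":
                depth -= 1
                if depth == 0:
                    break
            j -= 1
        if j < lo or depth != 0:
            raise GlycanParseError("unbalanced parentheses", text, pos - 1)
        if pos - 1 == j + 1:
            raise GlycanParseError("empty branch", text, j)
        branches.append(_parse_span(text, j + 1, pos - 1, False))
        pos = j
    if pos > lo:
        branches.append(_parse_span(text, lo, pos, False))
    # collected right-to-left; canonical order is ascending locant
    branches.reverse()
    locs = [b.locant for b in branches]
    if len(set(locs)) != len(locs):
        raise GlycanParseError("duplicate branch locant", text, lo)
    node.children = sorted(branches, key=lambda r: r.locant)
    return node


@dataclass(frozen=True)
class GlycanStructure:
    """A canonical glycan: string form, tree, composition and permethylated mass."""

    text: str
    tree: Residue = field(compare=False, repr=False)
    asn: bool = field(default=False, compare=False)

    def __hash__(self):
        return hash(self.text)

    @property
    def composition(self) -> dict:
        return composition(self)

    @property
    def permethylated_mass(self) -> float:
        return permethylated_mass(self.composition)

    def sodiated_mass(self) -> float:
        return permethylated_mass(self.composition, adduct="Na")

    def n_residues(self) -> int:
        return sum(self.composition.values())

    def __str__(self):
        return self.text


@lru_cache(maxsize=200_000)
def _parse_cached(body: str) -> Residue:
    depth = 0
    for i, ch in enumerate(body):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise GlycanParseError("unbalanced parentheses", body, i)
    if depth != 0:
        raise GlycanParseError("unbalanced parentheses", body, len(body) - 1)
    return _parse_span(body, 0, len(body), True)


def parse_glycan(text: str) -> GlycanStructure:
    """Parse a linear-code string; non-canonical sibling order is re-sorted."""
    if not text:
        raise GlycanParseError("empty glycan string", text, 0)
    body, asn = text, False
    if body.endswith(";Asn"):
        body, asn = body[:-4], True
    tree = _parse_cached(body)
    return GlycanStructure(text=_serialize(tree), tree=tree, asn=asn)


def canonicalize(text: str) -> str:
    """Canonical string form of ``text`` (sibling branches sorted by locant)."""
    return parse_glycan(text).text


def _count(res: Residue, counts: dict) -> None:
    counts[res.code] = counts.get(res.code, 0) + 1
    for c in res.children:
        _count(c, counts)


def composition(g: GlycanStructure) -> dict:
    """Residue counts per sugar code (keys M, GN, A, F, NN, G, all present)."""
    counts = {c: 0 for c in RESIDUE_CODES}
    _count(g.tree, counts)
    return counts


def elemental_formula(counts: Mapping[str, int]) -> dict:
    """Elemental formula of the neutral, fully permethylated free glycan."""
    if sum(counts.values()) <= 0:
        raise ValueError("at least one residue required")
    formula: dict = dict(_REDUCING_END_CLOSURE)
    for code, n in counts.items():
        if n == 0:
            continue
        if n < 0:
            raise ValueError(f"negative residue count for {code}")
        for el, k in _PERMETHYL_RESIDUE[code].items():
            formula[el] = formula.get(el, 0) + k * n
    return formula


def permethylated_mass(counts: Mapping[str, int], adduct: str | None = None) -> float:
    """Monoisotopic mass (Da) of the permethylated glycan; ``adduct='Na'`` for [M+Na]+."""
    formula = elemental_formula(counts)
    mass = sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    if adduct is None:
        return mass
    if adduct == "Na":
        return mass + ATOMIC_MASS["Na"]
    raise ValueError(f"unsupported adduct {adduct!r}")


def read_structure_list(lines: Iterable[str]) -> list[GlycanStructure]:
    """Read one canonical string per line; '#' comments and a header row tolerated."""
    out = []
    for i, line in enumerate(lines):
        s = line.split("#", 1)[0].strip().rstrip(",")
        if not s:
            continue
        if "," in s:  # CSV row: structure string in the first column
            s = s.split(",", 1)[0].strip()
        try:
            out.append(parse_glycan(s))
        except GlycanParseError:
            if i == 0:  # header row
                continue
            raise
    return out


MAN9 = "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN"
#: Glucosylated Man9 (Glc alpha-1,3 cap); inert to the mannosidase rules.
GLC1MAN9 = "Ga3Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN"
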