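import random

import pytest
from hypothesis import given, settings, strategies as st

from glygolgi.glycans import (ATOMIC_MASS, GlycanParseError, MAN9,
                              canonicalize, composition, elemental_formula,
                              parse_glycan, permethylated_mass,
                              read_structure_list)

HEXOSE_INCREMENT = 204.09976  # permethylated hexose residue, C9H16O5


def test_man9_parses_to_nine_mannose_tree():
    g = parse_glycan(MAN9 + ";Asn")
    assert g.asn is True
    assert g.text == MAN9  # suffix stripped from the canonical text
    assert g.composition["M"] == 9
    assert g.composition["GN"] == 2
    assert g.n_residues() == 11


def test_branch_point_orders_ascending_by_locant():
    g = parse_glycan("Ma3(GNb4)(Ma6)Mb4")
    assert g.text == "Ma3(GNb4)(Ma6)Mb4"
    # scrambled sibling order re-canonicalizes to the same string
    assert canonicalize("Ma6(GNb4)(Ma3)Mb4") == "Ma3(GNb4)(Ma6)Mb4"


@pytest.mark.parametrize("bad", [
    "Ma3(Ma2Ma6",          # unbalanced
    "Ma3(Ma2Ma6))Mb4",     # unbalanced the other way
    "Xa3Mb4GN",            # unknown residue code
    "M3Mb4GN",             # missing anomer
    "",                    # empty
    "Ma3()Mb4",            # empty branch
])
def test_malformed_strings_raise_parse_error(bad):
    with pytest.raises(GlycanParseError):
        parse_glycan(bad)


def test_parse_error_carries_offset():
    with pytest.raises(GlycanParseError) as err:
        parse_glycan("Ma3(Ma2Ma6")
    assert "offset" in str(err.value)


@pytest.mark.parametrize("text,expected", [
    (MAN9, {"M": 9, "GN": 2}),
    ("GN", {"GN": 1}),
    ("GNb2Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN", {"M": 5, "GN": 3}),
])
def test_composition_counts(text, expected):
    counts = composition(parse_glycan(text))
    for code, n in expected.items():
        assert counts[code] == n
    assert sum(counts.values()) == sum(expected.values())


def _independent_mass(counts, adduct=None):
    # hand-summed elemental oracle: residue formulas + C2H6O closure
    per = {"M": (9, 16, 0, 5), "A": (9, 16, 0, 5), "G": (9, 16, 0, 5),
           "GN": (11, 19, 1, 5), "NN": (16, 27, 1, 8), "F": (8, 14, 0, 4)}
    c, h, n, o = 2, 6, 0, 1
    for code, k in counts.items():
        dc, dh, dn, do = per[code]
        c, h, n, o = c + dc * k, h + dh * k, n + dn * k, o + do * k
    mass = (c * ATOMIC_MASS["C"] + h * ATOMIC_MASS["H"]
            + n * ATOMIC_MASS["N"] + o * ATOMIC_MASS["O"])
    if adduct == "Na":
        mass += ATOMIC_MASS["Na"]
    return mass


@pytest.mark.parametrize("counts,printed", [
    ({"M": 5, "GN": 2}, 1579.78),   # permethylated sodiated Man5GlcNAc2
    ({"M": 9, "GN": 2}, 2396.18),   # permethylated sodiated Man9GlcNAc2
])
def test_sodiated_masses_match_elemental_oracle(counts, printed):
    value = permethylated_mass(counts, adduct="Na")
    assert value == pytest.approx(_independent_mass(counts, "Na"), abs=1e-9)
    assert value == pytest.approx(printed, abs=0.01)


def test_mass_additivity_per_hexose():
    base = permethylated_mass({"M": 5, "GN": 2})
    assert permethylated_mass({"M": 6, "GN": 2}) - base == \
        pytest.approx(HEXOSE_INCREMENT, abs=1e-4)
    # any hexose adds the same increment
    assert permethylated_mass({"M": 5, "GN": 2, "A": 1}) - base == \
        pytest.approx(HEXOSE_INCREMENT, abs=1e-4)


def test_mass_is_linear_in_composition():
    rng = random.Random(17)
    codes = ("M", "GN", "A", "F", "NN", "G")
    for _ in range(100):
        a = {c: rng.randint(0, 4) for c in codes}
        b = {c: rng.randint(0, 4) for c in codes}
        if sum(a.values()) == 0 or sum(b.values()) == 0:
            continue
        both = {c: a[c] + b[c] for c in codes}
        lhs = permethylated_mass(both)
        rhs = permethylated_mass(a) + permethylated_mass(b) \
            - _independent_mass({})  # one closure is double counted
        assert lhs == pytest.approx(rhs, abs=1e-9)


def test_glucose_counts_as_hexose_for_mass():
    assert elemental_formula({"G": 1}) == elemental_formula({"M": 1})


# --- random-tree round trip -------------------------------------------------

_CODES = ("M", "GN", "A", "F", "NN", "G")


def _random_tree(rng, depth=0):
    code = rng.choice(_CODES)
    n_children = 0 if depth >= 3 else rng.choices([0, 1, 2, 3],
                                                  [5, 3, 2, 1])[0]
    locants = rng.sample([2, 3, 4, 6], k=n_children)
    parts = []
    for loc in sorted(locants):
        sub = _random_tree(rng, depth + 1)
        parts.append((loc, sub))
    out = ""
    for i, (loc, sub) in enumerate(parts):
        token = sub + rng.choice("ab") + str(loc)
        out += token if i == 0 else "(" + token + ")"
    return out + code


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_parse_serialize_round_trip_on_random_trees(seed):
    rng = random.Random(seed)
    text = _random_tree(rng)
    g = parse_glycan(text)
    assert parse_glycan(g.text).text == g.text          # parse . serialize id
    assert canonicalize(canonicalize(text)) == canonicalize(text)  # idempotent
    assert sum(g.composition.values()) == g.n_residues()


def test_structure_list_reader_tolerates_headers_and_comments():
    lines = ["structure,abundance",       # header row
             "# a comment",
             f"{MAN9},0.5",
             "Ma3(Ma6)Mb4GNb4GN"]
    out = read_structure_list(lines)
    assert [g.text for g in out] == [MAN9, "Ma3(Ma6)Mb4GNb4GN"]
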