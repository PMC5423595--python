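"""Enzyme reaction rules: substrate matching, product construction, kinetics.

Each rule consists of a substrate pattern, a product pattern that differs from
it in exactly one region (the reaction site), an optional boolean constraint,
and the cosubstrate/coproduct chemistry.  Base kinetic parameters are assigned
per rule and modified by structure-dependent adjustment rules whose multipliers
combine multiplicatively when several conditions hold at once (a first-match
mode is available for sensitivity studies).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources

from .glycans import GlycanStructure, parse_glycan
from .patterns import (CompiledPattern, MatchSite, PatternError, PatternExpr,
                       compile_pattern, iter_matches, parse_expr)

__all__ = [
    "KineticParameters",
    "ReactionRule",
    "AdjustmentRule",
    "RuleSet",
    "apply_rule",
    "effective_params",
    "load_rules",
    "load_base_params",
    "load_adjustments",
    "load_default_ruleset",
    "ENZYMES",
]

#: The thirteen model enzymes, in the conventional reporting order.
ENZYMES = ("ManI", "ManII", "a6FucT", "GnTI", "GnTII", "GnTIII", "GnTIV",
           "GnTV", "iGnT", "b4GalT", "a3SiaT", "a3FucT", "a3GalT")


@dataclass(frozen=True)
class KineticParameters:
    kf: float   # 1/min
    Km: float   # uM (substrate)
    Kmd: float  # uM (donor); 0 means donor-saturated

    def scaled(self, kf_mult: float, km_mult: float, kmd_mult: float):
        return KineticParameters(self.kf * kf_mult, self.Km * km_mult,
                                 self.Kmd * kmd_mult)


@dataclass(frozen=True)
class ReactionRule:
    index: int
    enzyme: str
    cosubstrate: str
    coproduct: str
    substrate: CompiledPattern
    product: CompiledPattern
    constraint: PatternExpr | None

    def __post_init__(self):
        sub_kinds = self.substrate.wildcard_kinds()
        prod_kinds = self.product.wildcard_kinds()
        if sub_kinds != prod_kinds:
            raise PatternError(
                f"rule {self.index}: substrate/product wildcards differ "
                f"({sub_kinds} vs {prod_kinds})")


@dataclass(frozen=True)
class AdjustmentRule:
    rule_index: int
    condition: PatternExpr
    kf_mult: float
    km_mult: float
    kmd_mult: float


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[ReactionRule, ...]
    base_params: dict  # rule index -> KineticParameters
    adjustments: tuple[AdjustmentRule, ...]
    combine: str = "first"  # first satisfied row in table order; or "multiplicative"

    def rule(self, index: int) -> ReactionRule:
        for r in self.rules:
            if r.index == index:
                return r
        raise KeyError(index)

    def enzymes(self):
        seen = []
        for r in self.rules:
            if r.enzyme not in seen:
                seen.append(r.enzyme)
        return tuple(seen)

    def reference_params(self, enzyme: str) -> KineticParameters:
        """Base kf/Km of the enzyme's lowest-index rule (the reporting scale)."""
        idx = min(r.index for r in self.rules if r.enzyme == enzyme)
        return self.base_params[idx]

    def subset(self, indices) -> "RuleSet":
        keep = set(indices)
        return replace(
            self,
            rules=tuple(r for r in self.rules if r.index in keep),
            adjustments=tuple(a for a in self.adjustments if a.rule_index in keep),
        )


def _product_text(rule: ReactionRule, m: MatchSite) -> str:
    """Instantiate the product pattern with the substrate match's bindings."""
    out = []
    it = iter(m.bindings)
    for elem in rule.product.elems:
        if elem[0] == "lit":
            out.append(elem[1])
        else:
            out.append(next(it))
    return "".join(out)


def _site_offset(matched: str, replacement: str, start: int) -> int:
    """Reaction site: position of the first difference substrate vs product."""
    n = min(len(matched), len(replacement))
    for k in range(n):
        if matched[k] != replacement[k]:
            return start + k
    return start + n


def apply_rule(rule: ReactionRule, g: GlycanStructure,
               ) -> list[tuple[GlycanStructure, MatchSite]]:
    """All products of ``rule`` acting on ``g``, one per constraint-passing site.

    Products are re-canonicalized; sites whose products coincide as canonical
    strings are collapsed to the first occurrence.
    """
    s = g.text
    out: list[tuple[GlycanStructure, MatchSite]] = []
    seen_products = set()
    seen_sites = set()
    for m in iter_matches(rule.substrate, s):
        key = (m.start, m.bindings)
        if key in seen_sites:
            continue
        seen_sites.add(key)
        matched = s[m.start:m.end]
        replacement = _product_text(rule, m)
        site = _site_offset(matched, replacement, m.start)
        m = MatchSite(m.start, m.end, m.bindings, site)
        if rule.constraint is not None and not rule.constraint.evaluate(g, site):
            continue
        new_text = s[:m.start] + replacement + s[m.end:]
        try:
            product = parse_glycan(new_text)
        except Exception as exc:  # transcription bug in a rule table
            raise PatternError(
                f"rule {rule.index} produced invalid glycan {new_text!r} "
                f"from {s!r}: {exc}") from exc
        if product.text not in seen_products:
            seen_products.add(product.text)
            out.append((product, m))
    return out


def effective_params(rule: ReactionRule, base: KineticParameters,
                     adjustments, g: GlycanStructure, site: int | None,
                     combine: str = "multiplicative") -> KineticParameters:
    """Base parameters times every satisfied adjustment for this rule.

    ``combine='multiplicative'`` stacks all satisfied rows; ``'first'`` applies
    only the first satisfied row in table order.
    """
    kf_m = km_m = kmd_m = 1.0
    for adj in adjustments:
        if adj.rule_index != rule.index:
            continue
        if adj.condition.evaluate(g, site):
            kf_m *= adj.kf_mult
            km_m *= adj.km_mult
            kmd_m *= adj.kmd_mult
            if combine == "first":
                break
    return base.scaled(kf_m, km_m, kmd_m)


# ---------------------------------------------------------------------------
# Table loading
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("glygolgi.data").joinpath(name).read_text()


def _read_tsv(text: str):
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


def load_rules(text: str | None = None) -> tuple[ReactionRule, ...]:
    rows = _read_tsv(text if text is not None else _data_text("reaction_rules.tsv"))
    rules = []
    for row in rows:
        constraint = (row.get("constraint") or "").strip()
        rules.append(ReactionRule(
            index=int(row["index"]),
            enzyme=row["enzyme"].strip(),
            cosubstrate=row["cosubstrate"].strip(),
            coproduct=row["coproduct"].strip(),
            substrate=compile_pattern(row["substrate"].strip()),
            product=compile_pattern(row["product"].strip()),
            constraint=parse_expr(constraint) if constraint else None,
        ))
    return tuple(rules)


def load_base_params(text: str | None = None) -> dict:
    rows = _read_tsv(text if text is not None else _data_text("kinetic_parameters.tsv"))
    return {int(r["index"]): KineticParameters(float(r["kf"]), float(r["Km"]),
                                               float(r["Kmd"]))
            for r in rows}


def load_adjustments(text: str | None = None) -> tuple[AdjustmentRule, ...]:
    rows = _read_tsv(text if text is not None else _data_text("adjustment_rules.tsv"))
    return tuple(AdjustmentRule(
        rule_index=int(r["rule_index"]),
        condition=parse_expr(r["condition"].strip()),
        kf_mult=float(r["kf_mult"]),
        km_mult=float(r["km_mult"]),
        kmd_mult=float(r["kmd_mult"]),
    ) for r in rows)


def load_default_ruleset(combine: str = "first") -> RuleSet:
    """The packaged CHO rule set (reaction rules, base kinetics, adjustments)."""
    return RuleSet(rules=load_rules(), base_params=load_base_params(),
                   adjustments=load_adjustments(), combine=combine)
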