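"""Glycan structural-feature and lectin-substructure quantification.

A feature is a pattern expression evaluated per structure: boolean features
(e.g. high mannose, ``#GN = 2``) report the percentage of glycans carrying the
motif; ``Count`` features (e.g. lactosamine groups, ``Count Ab4GN``) report
occurrences per 100 glycans and may exceed 100.  Feature tables are the
abundance-weighted sums over a solved distribution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .glycans import GlycanStructure
from .golgi import AbundanceDistribution
from .patterns import PatternExpr, parse_expr

__all__ = ["FeatureDefinition", "feature_value", "feature_vector",
           "feature_table", "load_structural_features", "load_lectin_features"]


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    expression: PatternExpr

    @classmethod
    def from_text(cls, name: str, expression: str) -> "FeatureDefinition":
        return cls(name, parse_expr(expression))


def feature_value(g: GlycanStructure, f: FeatureDefinition) -> float:
    """0/1 for boolean features; the site count for ``Count`` features."""
    v = f.expression.evaluate(g)
    return float(v) if not isinstance(v, bool) else float(v)


def feature_vector(structures, f: FeatureDefinition) -> np.ndarray:
    return np.array([feature_value(g, f) for g in structures])


def feature_table(ab: AbundanceDistribution, features, structures=None) -> dict:
    """Per-feature abundance-weighted values, per 100 glycans.

    ``structures`` supplies parsed GlycanStructure objects matching
    ``ab.structures``; if omitted they are re-parsed from the canonical text.
    """
    from .glycans import parse_glycan

    if structures is None:
        structures = [parse_glycan(t) for t in ab.structures]
    weights = np.asarray(ab.outlet_percent)
    out = {}
    for f in features:
        vals = feature_vector(structures, f)
        out[f.name] = float(np.dot(weights, vals))
    return out


def _load_features(name: str):
    text = resources.files("glygolgi.data").joinpath(name).read_text()
    rows = csv.DictReader(text.splitlines(), delimiter="\t")
    return [FeatureDefinition.from_text(r["name"], r["expression"]) for r in rows]


def load_structural_features() -> list:
    """The 17 packaged structural features (high mannose ... VIM-2)."""
    return _load_features("features_structural.tsv")


def load_lectin_features() -> list:
    """The packaged lectin-binding substructure codes (L-PHA ... E-PHA)."""
    return _load_features("features_lectin.tsv")
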