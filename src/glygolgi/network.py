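"""Reaction-network generation: iterate the rule set to closure with pruning.

Starting from the seed structures (by default Man9 and its inert Glc-capped
variant) every rule is applied to every structure; new products below the
permethylated mass cutoff are added and the process repeats until no new
reaction appears.  Because mannosidases only remove mannose and transferases
only add their cosubstrate residue, the reaction graph is acyclic.

An optional pruning heuristic estimates glycan abundances by a single
competition-free forward pass (pseudo-first-order rates over the total Golgi
residence time, nominal wild-type activities) and drops structures whose
estimate falls below a relative threshold, together with dependent reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .glycans import GLC1MAN9, MAN9, GlycanStructure, parse_glycan
from .rules import KineticParameters, RuleSet, apply_rule, effective_params

__all__ = ["Reaction", "ReactionNetwork", "PruneConfig", "generate_network",
           "prune_network", "DEFAULT_SEEDS", "write_network", "read_network"]

DEFAULT_SEEDS = (MAN9, GLC1MAN9)

#: Nominal wild-type (Pro-5) activities used only by the pruning pre-estimate.
HEURISTIC_ACTIVITIES = {
    "ManI": 5.032, "ManII": 8.130, "a6FucT": 4.161, "GnTI": 1.049,
    "GnTII": 6.582, "GnTIII": 0.105, "GnTIV": 0.467, "GnTV": 2.183,
    "iGnT": 0.523, "b4GalT": 6.282, "a3SiaT": 0.081, "a3FucT": 0.006,
    "a3GalT": 0.028,
}

_TOTAL_RESIDENCE_MIN = 4 * 5.556


@dataclass(frozen=True)
class Reaction:
    rule_index: int
    enzyme: str
    substrate: int
    product: int
    params: KineticParameters      # effective (adjusted) parameters
    cosubstrate: str
    coproduct: str
    base: KineticParameters | None = None  # rule's unadjusted parameters


@dataclass
class ReactionNetwork:
    structures: list[GlycanStructure]
    reactions: list[Reaction]
    seeds: list[int]
    index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.index:
            self.index = {g.text: i for i, g in enumerate(self.structures)}

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


@dataclass
class PruneConfig:
    enabled: bool = True
    threshold: float = 3e-6
    heuristic_activities: dict = field(
        default_factory=lambda: dict(HEURISTIC_ACTIVITIES))

    def __post_init__(self):
        if not (0.0 <= self.threshold < 1.0):
            raise ValueError("prune threshold must be in [0, 1)")


class NetworkGenerationError(RuntimeError):
    pass


def _reaction_rate_constant(ruleset: RuleSet, rule, params: KineticParameters,
                            activities: dict) -> float:
    """Pseudo-first-order 1/min rate at nominal activity, ignoring competition.

    Uses the per-rule activity convention: the reported activity is the
    donor-saturated first-order coefficient of each of the enzyme's rules at
    base parameters, so only the adjustment multipliers scale it.
    """
    base = ruleset.base_params[rule.index]
    a = activities.get(rule.enzyme, 0.0)
    return a * (params.kf / base.kf) * (base.Km / params.Km)


def generate_network(ruleset: RuleSet,
                     seeds=DEFAULT_SEEDS,
                     mass_cutoff: float = 5000.0,
                     prune: PruneConfig | None = None,
                     inlet=None,
                     max_structures: int = 2_000_000) -> ReactionNetwork:
    """Apply the rule set to closure from ``seeds`` under the mass cutoff.

    ``mass_cutoff`` is on the neutral permethylated mass.  With pruning
    enabled, a product is only admitted while its running forward-flux
    abundance estimate stays above ``threshold`` (seeds are never dropped);
    the estimate uses the heuristic activities and the total residence time.
    """
    seed_structures = [s if isinstance(s, GlycanStructure) else parse_glycan(s)
                       for s in seeds]
    for s in seed_structures:
        if s.permethylated_mass > mass_cutoff:
            # degenerate cutoff: network is the seeds only
            return ReactionNetwork(structures=list(dict.fromkeys(seed_structures)),
                                   reactions=[], seeds=list(range(len(seed_structures))))

    structures: list[GlycanStructure] = []
    index: dict[str, int] = {}
    reactions: list[Reaction] = []
    est: list[float] = []  # heuristic abundance estimate per structure

    if inlet is None:
        inlet = {seed_structures[0].text: 1.0}

    def add_structure(g: GlycanStructure, estimate: float) -> int:
        i = index.get(g.text)
        if i is None:
            i = len(structures)
            index[g.text] = i
            structures.append(g)
            est.append(estimate)
        else:
            est[i] += estimate
        return i

    for s in seed_structures:
        add_structure(s, inlet.get(s.text, 1.0))

    seen_reactions = set()
    pruning = prune is not None and prune.enabled
    head = 0
    while head < len(structures):
        if len(structures) > max_structures:
            raise NetworkGenerationError(
                f"structure count exceeded {max_structures}; runaway expansion")
        g = structures[head]
        candidates = []
        for rule in ruleset.rules:
            for product, m in apply_rule(rule, g):
                if product.permethylated_mass > mass_cutoff:
                    continue
                params = effective_params(rule, ruleset.base_params[rule.index],
                                          ruleset.adjustments, g, m.site,
                                          combine=ruleset.combine)
                candidates.append((rule, product, params))
        if pruning:
            # split this structure's estimated abundance over its competing
            # reactions like a single merged CSTR pass (competition ignored)
            tks = [_TOTAL_RESIDENCE_MIN * _reaction_rate_constant(
                       ruleset, rule, params, prune.heuristic_activities)
                   for rule, _, params in candidates]
            denom = 1.0 + sum(tks)
        for idx, (rule, product, params) in enumerate(candidates):
            if pruning:
                contrib = est[head] * tks[idx] / denom
                if contrib < prune.threshold and product.text not in index:
                    continue
            else:
                contrib = est[head]
            j = add_structure(product, contrib)
            key = (rule.index, head, j)
            if key not in seen_reactions:
                seen_reactions.add(key)
                reactions.append(Reaction(rule.index, rule.enzyme, head, j,
                                          params, rule.cosubstrate,
                                          rule.coproduct,
                                          base=ruleset.base_params[rule.index]))
        head += 1

    return ReactionNetwork(structures=structures, reactions=reactions,
                           seeds=list(range(len(seed_structures))))


def _forward_estimates(net: ReactionNetwork, ruleset: RuleSet,
                       inlet: dict, activities: dict) -> list[float]:
    """Competition-free CSTR-like forward pass in generation (topological) order."""
    est = [0.0] * net.n_structures
    for i in net.seeds:
        est[i] = inlet.get(net.structures[i].text, 0.0)
    out_k: list[float] = [0.0] * net.n_structures
    per_rx_k = []
    for rx in net.reactions:
        k = _reaction_rate_constant(ruleset, ruleset.rule(rx.rule_index),
                                    rx.params, activities)
        per_rx_k.append(k)
        out_k[rx.substrate] += k
    retained = [0.0] * net.n_structures
    rx_by_sub: dict[int, list[int]] = {}
    for r_i, rx in enumerate(net.reactions):
        rx_by_sub.setdefault(rx.substrate, []).append(r_i)
    for i in _topological_order(net):
        denom = 1.0 + _TOTAL_RESIDENCE_MIN * out_k[i]
        retained[i] = est[i] / denom
        for r_i in rx_by_sub.get(i, ()):
            rx = net.reactions[r_i]
            est[rx.product] += retained[i] * _TOTAL_RESIDENCE_MIN * per_rx_k[r_i]
    return retained


def _topological_order(net: ReactionNetwork) -> list[int]:
    """Kahn ordering of the (acyclic) reaction graph, ties by structure index."""
    import heapq
    from heapq import heappop, heappush

    indeg = [0] * net.n_structures
    succ: dict[int, list[int]] = {}
    for rx in net.reactions:
        indeg[rx.product] += 1
        succ.setdefault(rx.substrate, []).append(rx.product)
    heap = [i for i in range(net.n_structures) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heappop(heap)
        order.append(i)
        for j in succ.get(i, ()):
            indeg[j] -= 1
            if indeg[j] == 0:
                heappush(heap, j)
    if len(order) != net.n_structures:
        raise NetworkGenerationError("reaction graph contains a cycle")
    return order


def prune_network(net: ReactionNetwork, ruleset: RuleSet,
                  prune: PruneConfig, inlet=None) -> ReactionNetwork:
    """Drop structures whose forward-pass abundance estimate is below threshold."""
    if not (0.0 <= prune.threshold < 1.0):
        raise ValueError("prune threshold must be in [0, 1)")
    if inlet is None:
        inlet = {net.structures[net.seeds[0]].text: 1.0}
    retained_est = _forward_estimates(net, ruleset, inlet,
                                      prune.heuristic_activities)
    total = sum(retained_est) or 1.0
    keep = [i for i in range(net.n_structures)
            if i in net.seeds or retained_est[i] / total >= prune.threshold]
    keep_set = set(keep)
    remap = {old: new for new, old in enumerate(keep)}
    structures = [net.structures[i] for i in keep]
    reactions = [Reaction(rx.rule_index, rx.enzyme, remap[rx.substrate],
                          remap[rx.product], rx.params, rx.cosubstrate,
                          rx.coproduct, base=rx.base)
                 for rx in net.reactions
                 if rx.substrate in keep_set and rx.product in keep_set]
    return ReactionNetwork(structures=structures, reactions=reactions,
                           seeds=[remap[i] for i in net.seeds])


# ---------------------------------------------------------------------------
# TSV export / import
# ---------------------------------------------------------------------------

def write_network(net: ReactionNetwork, structures_path, reactions_path) -> None:
    with open(structures_path, "w") as fh:
        fh.write("index\tstructure\tpermethylated_mass\tseed\n")
        for i, g in enumerate(net.structures):
            fh.write(f"{i}\t{g.text}\t{g.permethylated_mass:.4f}"
                     f"\t{int(i in net.seeds)}\n")
    with open(reactions_path, "w") as fh:
        fh.write("rule\tenzyme\tsubstrate\tproduct\tkf\tKm\tKmd"
                 "\tkf_base\tKm_base\tKmd_base\tcosubstrate\tcoproduct\n")
        for rx in net.reactions:
            base = rx.base or rx.params
            fh.write(f"{rx.rule_index}\t{rx.enzyme}\t{rx.substrate}"
                     f"\t{rx.product}\t{rx.params.kf!r}\t{rx.params.Km!r}"
                     f"\t{rx.params.Kmd!r}\t{base.kf!r}\t{base.Km!r}"
                     f"\t{base.Kmd!r}\t{rx.cosubstrate}\t{rx.coproduct}\n")


def read_network(structures_path, reactions_path) -> ReactionNetwork:
    structures, seeds = [], []
    with open(structures_path) as fh:
        next(fh)
        for line in fh:
            idx, text, _mass, seed = line.rstrip("\n").split("\t")
            structures.append(parse_glycan(text))
            if int(seed):
                seeds.append(int(idx))
    reactions = []
    with open(reactions_path) as fh:
        next(fh)
        for line in fh:
            (rule, enzyme, sub, prod, kf, km, kmd,
             kf_b, km_b, kmd_b, cos, cop) = line.rstrip("\n").split("\t")
            reactions.append(Reaction(
                int(rule), enzyme, int(sub), int(prod),
                KineticParameters(float(kf), float(km), float(kmd)), cos, cop,
                base=KineticParameters(float(kf_b), float(km_b), float(kmd_b))))
    return ReactionNetwork(structures=structures, reactions=reactions,
                           seeds=seeds)
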