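"""Four-compartment Golgi kinetics with competitive Michaelis-Menten rates.

The Golgi stack is idealized as four equal well-mixed reactors (CSTRs) in
series.  Glycoprotein substrates flow through with a fixed residence time per
compartment while each enzyme stays put, distributed over the compartments
according to a beta distribution on (0, 1): the fraction of enzyme in
compartment k is the beta probability mass of the k-th quartile.  The mean of
each beta distribution locates the enzyme along the cis-to-trans axis; the
shape-parameter sum (alpha + beta = 6 throughout) sets how sharply it peaks.

Each reaction i -> i+1 catalysed by enzyme E with donor D proceeds at

    r = kf [Et] ([D] / (Kmd + [D])) [Pi] / ( Km_i (1 + sum_j [Pj]/Km_j) )

where the sum runs over every substrate competing for the enzyme (Kmd = 0
denotes donor saturation, making the donor factor exactly 1).  Transferase
reactions are treated as irreversible; donor concentrations are held constant.

The steady-state balance per compartment, c_out = c_in + tau * S r(c_out), is
solved by freezing the competition denominators, solving the then-linear
sparse balance exactly, and iterating the denominators to a fixed point.
Because every reaction converts one glycan into one glycan, total glycan
concentration is conserved through every compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import betainc

from .network import ReactionNetwork
from .rules import ENZYMES, RuleSet

__all__ = ["EnzymeProfile", "GolgiConfig", "AbundanceDistribution",
           "beta_compartment_fractions", "reaction_rate", "GolgiSolver",
           "solve_golgi", "load_default_config", "load_cell_line_profiles"]


def beta_compartment_fractions(mean: float, alpha_plus_beta: float,
                               n_compartments: int = 4) -> np.ndarray:
    """Beta(mu*(a+b), (1-mu)*(a+b)) probability mass of the n equal subintervals."""
    if not (0.0 < mean < 1.0):
        raise ValueError("beta mean must lie strictly inside (0, 1)")
    if alpha_plus_beta <= 0:
        raise ValueError("alpha+beta must be positive")
    a = mean * alpha_plus_beta
    b = (1.0 - mean) * alpha_plus_beta
    edges = np.linspace(0.0, 1.0, n_compartments + 1)
    cdf = betainc(a, b, edges)
    return np.diff(cdf)


def reaction_rate(kf: float, Km: float, Kmd: float, enzyme_conc: float,
                  substrate_conc: float, donor_conc: float,
                  competition_sum: float) -> float:
    """Single-reaction competitive MM rate (uM/min); donor factor 1 when Kmd=0."""
    if Kmd == 0.0:
        donor_factor = 1.0
    elif donor_conc == 0.0:
        return 0.0
    else:
        donor_factor = donor_conc / (Kmd + donor_conc)
    return (kf * enzyme_conc * donor_factor * substrate_conc
            / (Km * (1.0 + competition_sum)))


@dataclass
class EnzymeProfile:
    """Total enzyme activities a = kf*c_enz/Km (1/min), the reporting convention."""

    activities: dict

    def __post_init__(self):
        for e, a in self.activities.items():
            if a < 0:
                raise ValueError(f"negative activity for {e}")

    def concentration(self, enzyme: str, ruleset: RuleSet) -> float:
        """Convert activity to enzyme concentration (uM) via the reference rule."""
        ref = ruleset.reference_params(enzyme)
        return self.activities.get(enzyme, 0.0) * ref.Km / ref.kf


@dataclass
class GolgiConfig:
    n_compartments: int = 4
    residence_times: tuple = (5.556, 5.556, 5.556, 5.556)  # min
    enzyme_fractions: dict = field(default_factory=dict)   # enzyme -> array(n)
    donor_concentrations: dict = field(default_factory=dict)  # compound -> array(n), uM
    total_glycan_concentration: float = 500.0  # uM
    inlet_composition: dict = field(default_factory=dict)  # structure text -> fraction
    competition: str = "substrates"  # or "substrates+products"
    # "per-rule": the reported activity a = kf*c/Km is the donor-saturated
    # first-order coefficient of every rule of the enzyme at base parameters
    # (the base kf/Km absorbed; adjustments still scale it).  "reference-rule":
    # a single enzyme concentration derived from the lowest-index rule.
    activity_convention: str = "per-rule"

    def validate(self):
        if any(t <= 0 for t in self.residence_times):
            raise ValueError("residence times must be positive")
        for e, f in self.enzyme_fractions.items():
            if abs(float(np.sum(f)) - 1.0) > 1e-9:
                raise ValueError(f"enzyme fractions for {e} do not sum to 1")
        if self.inlet_composition:
            if abs(sum(self.inlet_composition.values()) - 1.0) > 1e-9:
                raise ValueError("inlet fractions do not sum to 1")
        return self


@dataclass
class AbundanceDistribution:
    structures: list            # canonical strings
    concentrations: np.ndarray  # (n_compartments, n_structures), uM
    outlet_percent: np.ndarray  # % of total at the final outlet

    def as_mapping(self) -> dict:
        return dict(zip(self.structures, self.outlet_percent))


class SolverError(RuntimeError):
    pass


class GolgiSolver:
    """Pre-assembled solver for one network + config (profiles swappable)."""

    def __init__(self, net: ReactionNetwork, ruleset: RuleSet,
                 config: GolgiConfig):
        config.validate()
        self.net = net
        self.ruleset = ruleset
        self.config = config
        n_rx = len(net.reactions)
        self.enzyme_names = list(dict.fromkeys(
            [rx.enzyme for rx in net.reactions])) or list(ENZYMES)
        enz_index = {e: i for i, e in enumerate(self.enzyme_names)}

        self.rx_sub = np.array([rx.substrate for rx in net.reactions], dtype=np.int64)
        self.rx_prod = np.array([rx.product for rx in net.reactions], dtype=np.int64)
        self.rx_enz = np.array([enz_index[rx.enzyme] for rx in net.reactions],
                               dtype=np.int64)
        self.rx_kf = np.array([rx.params.kf for rx in net.reactions])
        self.rx_km = np.array([rx.params.Km for rx in net.reactions])
        self.rx_kmd = np.array([rx.params.Kmd for rx in net.reactions])
        self.rx_base_kf = np.array([(rx.base or rx.params).kf
                                    for rx in net.reactions])
        self.rx_base_km = np.array([(rx.base or rx.params).Km
                                    for rx in net.reactions])
        self.rx_donor = [rx.cosubstrate for rx in net.reactions]
        if config.activity_convention == "per-rule":
            # first-order scale per unit activity: adjustment multipliers only
            self.rx_unit_rate = (self.rx_kf / self.rx_base_kf) \
                * (self.rx_base_km / self.rx_km)
        elif config.activity_convention == "reference-rule":
            # first-order scale per unit enzyme concentration
            self.rx_unit_rate = self.rx_kf / self.rx_km
        else:
            raise ValueError("activity_convention must be 'per-rule' or "
                             "'reference-rule'")

        # competition membership: per enzyme, each binding structure at its
        # smallest effective Km over that enzyme's reactions
        n = net.n_structures
        ne = len(self.enzyme_names)
        inv_km: dict = {}
        for r in range(n_rx):
            key = (self.rx_enz[r], self.rx_sub[r])
            inv_km[key] = max(inv_km.get(key, 0.0), 1.0 / self.rx_km[r])
        if config.competition == "substrates+products":
            for r in range(n_rx):
                key = (self.rx_enz[r], self.rx_prod[r])
                inv_km[key] = max(inv_km.get(key, 0.0), 1.0 / self.rx_km[r])
        elif config.competition == "pool":
            # every glycan occupies the enzyme's substrate site: non-substrate
            # structures bind at the enzyme's reference (base) Km
            for e_name in self.enzyme_names:
                e = enz_index[e_name]
                km_ref = ruleset.reference_params(e_name).Km
                for j in range(n):
                    key = (e, j)
                    inv_km.setdefault(key, 1.0 / km_ref)
        elif config.competition != "substrates":
            raise ValueError("competition must be 'substrates', "
                             "'substrates+products' or 'pool'")
        rows = np.array([k[0] for k in inv_km], dtype=np.int64)
        cols = np.array([k[1] for k in inv_km], dtype=np.int64)
        vals = np.array(list(inv_km.values()))
        self.comp_matrix = sparse.csr_matrix((vals, (rows, cols)), shape=(ne, n))

        self._donor_factor = np.empty((config.n_compartments, n_rx))
        for k in range(config.n_compartments):
            for r in range(n_rx):
                kmd = self.rx_kmd[r]
                if kmd == 0.0:
                    self._donor_factor[k, r] = 1.0
                else:
                    d = float(config.donor_concentrations[self.rx_donor[r]][k])
                    self._donor_factor[k, r] = d / (kmd + d) if d > 0 else 0.0

    def inlet_vector(self) -> np.ndarray:
        c = np.zeros(self.net.n_structures)
        comp = self.config.inlet_composition or \
            {self.net.structures[self.net.seeds[0]].text: 1.0}
        index = self.net.index
        for text, frac in comp.items():
            c[index[text]] = frac * self.config.total_glycan_concentration
        return c

    def solve_compartment(self, c_in: np.ndarray, enzyme_conc: dict, k: int,
                          tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
        """Steady-state outlet of compartment k for inlet ``c_in``."""
        tau = self.config.residence_times[k]
        n = self.net.n_structures
        et = np.array([enzyme_conc.get(e, 0.0) for e in self.enzyme_names])
        if len(self.rx_sub) == 0 or not np.any(et):
            return c_in.copy()
        pref = self.rx_unit_rate * et[self.rx_enz] * self._donor_factor[k]
        c = c_in.copy()
        comp = self.comp_matrix @ c
        last_residual = np.inf
        for _ in range(max_iter):
            kappa = pref / (1.0 + comp[self.rx_enz])
            out_sum = np.zeros(n)
            np.add.at(out_sum, self.rx_sub, kappa)
            m = sparse.csc_matrix(
                (np.concatenate([1.0 + tau * out_sum, -tau * kappa]),
                 (np.concatenate([np.arange(n), self.rx_prod]),
                  np.concatenate([np.arange(n), self.rx_sub]))),
                shape=(n, n))
            c = splu(m).solve(c_in)
            new_comp = self.comp_matrix @ c
            delta = float(np.max(np.abs(new_comp - comp) / (1.0 + np.abs(new_comp))))
            comp = new_comp
            if delta < tol:
                break
        else:
            raise SolverError(f"compartment {k}: competition iteration did not "
                              f"converge (last delta {delta:.2e})")
        # verify the nonlinear residual
        kappa = pref / (1.0 + comp[self.rx_enz])
        rate = kappa * c[self.rx_sub]
        net_prod = np.zeros(n)
        np.add.at(net_prod, self.rx_prod, rate)
        np.add.at(net_prod, self.rx_sub, -rate)
        residual = np.max(np.abs(c - c_in - tau * net_prod)) / max(c_in.max(), 1.0)
        if residual > 1e-8:
            raise SolverError(f"compartment {k}: residual {residual:.2e}")
        return c

    def solve(self, profile: EnzymeProfile) -> AbundanceDistribution:
        cfg = self.config
        if cfg.activity_convention == "per-rule":
            totals = {e: profile.activities.get(e, 0.0)
                      for e in self.enzyme_names}
        else:
            totals = {e: profile.concentration(e, self.ruleset)
                      for e in self.enzyme_names}
        c = self.inlet_vector()
        rows = []
        for k in range(cfg.n_compartments):
            conc_k = {}
            for e in self.enzyme_names:
                frac = cfg.enzyme_fractions.get(e)
                if frac is None:
                    raise SolverError(f"no compartment fractions for enzyme {e}")
                conc_k[e] = totals[e] * float(frac[k])
            c = self.solve_compartment(c, conc_k, k)
            rows.append(c)
        conc = np.vstack(rows)
        outlet = conc[-1]
        pct = 100.0 * outlet / outlet.sum()
        return AbundanceDistribution(
            structures=[g.text for g in self.net.structures],
            concentrations=conc, outlet_percent=pct)


def solve_golgi(net: ReactionNetwork, ruleset: RuleSet, profile: EnzymeProfile,
                config: GolgiConfig) -> AbundanceDistribution:
    return GolgiSolver(net, ruleset, config).solve(profile)


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------

def _data_rows(name: str):
    import csv
    from importlib import resources
    text = resources.files("glygolgi.data").joinpath(name).read_text()
    return list(csv.reader(text.splitlines(), delimiter="\t"))


def load_default_config(inlet: dict | None = None,
                        competition: str = "substrates") -> GolgiConfig:
    """Compartment, donor and enzyme-localization defaults for the CHO model."""
    rows = _data_rows("compartments.tsv")
    header, body = rows[0], rows[1:]
    table = {r[0]: np.array([float(x) for x in r[1:]]) for r in body}
    residence = tuple(table.pop("residence_time_min"))
    dist_rows = _data_rows("enzyme_distributions.tsv")[1:]
    fractions = {r[0]: beta_compartment_fractions(float(r[1]), float(r[2]),
                                                  len(residence))
                 for r in dist_rows}
    return GolgiConfig(
        n_compartments=len(residence),
        residence_times=residence,
        enzyme_fractions=fractions,
        donor_concentrations=table,
        inlet_composition=inlet or {},
        competition=competition,
    )


def load_cell_line_profiles() -> dict:
    """The ten fitted CHO activity profiles, keyed by cell-line name."""
    rows = _data_rows("cell_line_activities.tsv")
    header, body = rows[0], rows[1:]
    lines = header[1:]
    profiles = {name: {} for name in lines}
    for r in body:
        for name, val in zip(lines, r[1:]):
            profiles[name][r[0]] = float(val)
    return {name: EnzymeProfile(acts) for name, acts in profiles.items()}
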