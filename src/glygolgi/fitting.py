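"""Enzyme-activity inference: least-squares fit of synthetic to measured spectra.

Activities are fitted in log space (positivity, comparable scales) by
Levenberg-Marquardt-style nonlinear least squares on the individual
isotopologue peak intensities of the model's mass grid, both spectra
normalized to a 100% total.  Shared parameters (e.g. the beta-localization
means) can be fitted jointly across several cases while each case keeps its
own activity vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .golgi import EnzymeProfile, GolgiSolver, beta_compartment_fractions
from .rules import ENZYMES
from .spectra import theoretical_spectrum

__all__ = ["FitSpec", "FitResult", "ModelSpectrum", "fit_single", "fit_shared",
           "sensitivity_profile"]

LOG_ACTIVITY_FLOOR = np.log(1e-6)
LOG_ACTIVITY_CEIL = np.log(1e4)


class ModelSpectrum:
    """Evaluates the model's isotopologue peak vector on a fixed mass grid."""

    def __init__(self, solver: GolgiSolver, mass_range=(1400.0, 5000.0),
                 n_peaks: int = 6):
        self.solver = solver
        self.mass_range = mass_range
        self.n_peaks = n_peaks
        self.compositions = [g.composition for g in solver.net.structures]
        # fixed m/z grid: every isotopologue of every composition in range
        ref = theoretical_spectrum(np.ones(len(self.compositions)),
                                   self.compositions, mass_range,
                                   n_peaks=n_peaks)
        self.grid = ref.mz

    def peak_vector(self, profile: EnzymeProfile) -> np.ndarray:
        ab = self.solver.solve(profile)
        spec = theoretical_spectrum(ab.outlet_percent, self.compositions,
                                    self.mass_range, n_peaks=self.n_peaks)
        return self.project(spec.mz, spec.intensity)

    def project(self, mz, intensity, tolerance: float = 0.2) -> np.ndarray:
        """Bin arbitrary (mz, intensity) onto the model grid; off-grid dropped."""
        out = np.zeros(self.grid.size)
        idx = np.searchsorted(self.grid, mz)
        for m, i, j in zip(np.asarray(mz), np.asarray(intensity), idx):
            best, dist = None, tolerance
            for jj in (j - 1, j):
                if 0 <= jj < self.grid.size and abs(self.grid[jj] - m) <= dist:
                    best, dist = jj, abs(self.grid[jj] - m)
            if best is not None:
                out[best] += i
        return out

    def target_from_peaklist(self, pl) -> np.ndarray:
        mz = [p.mz for p in pl.peaks]
        areas = [p.area for p in pl.peaks]
        vec = self.project(mz, areas)
        total = vec.sum()
        if total <= 0:
            raise ValueError("no target peaks fall on the model mass grid")
        return 100.0 * vec / total


@dataclass
class FitSpec:
    free: tuple = ENZYMES           # enzymes whose activities are fitted
    initial: EnzymeProfile | None = None
    bounds: tuple = (LOG_ACTIVITY_FLOOR, LOG_ACTIVITY_CEIL)
    weights: np.ndarray | None = None
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    diff_step: float = 1e-5
    max_nfev: int | None = None


@dataclass
class FitResult:
    profile: EnzymeProfile
    cost: float
    residuals: np.ndarray
    n_evaluations: int
    converged: bool
    message: str = ""
    shared: dict = field(default_factory=dict)


def _pack(profile: EnzymeProfile, free) -> np.ndarray:
    return np.log([max(profile.activities.get(e, 0.0), 1e-12) for e in free])


def _unpack(x, base: EnzymeProfile, free) -> EnzymeProfile:
    acts = dict(base.activities)
    for e, v in zip(free, x):
        acts[e] = float(np.exp(v))
    return EnzymeProfile(acts)


def fit_single(model: ModelSpectrum, target, spec: FitSpec) -> FitResult:
    """Fit one case's activities to one target peak vector/peak list."""
    if spec.initial is None:
        raise ValueError("FitSpec.initial profile is required")
    target_vec = target if isinstance(target, np.ndarray) \
        else model.target_from_peaklist(target)
    w = np.ones_like(target_vec) if spec.weights is None else spec.weights

    def residual(x):
        prof = _unpack(x, spec.initial, spec.free)
        return w * (model.peak_vector(prof) - target_vec)

    x0 = np.clip(_pack(spec.initial, spec.free), *spec.bounds)
    res = least_squares(residual, x0, bounds=spec.bounds, method="trf",
                        diff_step=spec.diff_step, xtol=spec.xtol,
                        ftol=spec.ftol, gtol=spec.gtol,
                        max_nfev=spec.max_nfev)
    return FitResult(profile=_unpack(res.x, spec.initial, spec.free),
                     cost=float(res.cost), residuals=res.fun,
                     n_evaluations=int(res.nfev),
                     converged=bool(res.success), message=res.message)


def fit_shared(models, targets, specs, shared_group: str,
               shared_enzymes, alpha_plus_beta: float = 6.0,
               shared_bounds=(0.05, 0.95), shared_init: float = 0.5):
    """Joint fit: one beta-localization mean shared across >= 2 cases.

    ``shared_enzymes`` lists the enzymes whose compartment fractions follow the
    shared beta mean.  Each case keeps its own free activities.
    """
    if len(models) < 2:
        raise ValueError("fit_shared needs at least two cases; use fit_single")
    if not (len(models) == len(targets) == len(specs)):
        raise ValueError("models, targets and specs must align")
    target_vecs = [t if isinstance(t, np.ndarray)
                   else m.target_from_peaklist(t)
                   for m, t in zip(models, targets)]
    sizes = [len(s.free) for s in specs]
    offsets = np.cumsum([1] + sizes)[:-1]

    def apply_shared(mu):
        frac = beta_compartment_fractions(mu, alpha_plus_beta,
                                          models[0].solver.config.n_compartments)
        for m in models:
            for e in shared_enzymes:
                m.solver.config.enzyme_fractions[e] = frac

    def residual(x):
        mu = float(np.clip(x[0], *shared_bounds))
        apply_shared(mu)
        parts = []
        for m, t, s, off, nsz in zip(models, target_vecs, specs, offsets, sizes):
            prof = _unpack(x[off:off + nsz], s.initial, s.free)
            parts.append(m.peak_vector(prof) - t)
        return np.concatenate(parts)

    x0 = np.concatenate([[shared_init]] +
                        [np.clip(_pack(s.initial, s.free), *s.bounds)
                         for s in specs])
    lo = np.concatenate([[shared_bounds[0]]] +
                        [np.full(n, s.bounds[0]) for n, s in zip(sizes, specs)])
    hi = np.concatenate([[shared_bounds[1]]] +
                        [np.full(n, s.bounds[1]) for n, s in zip(sizes, specs)])
    res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                        diff_step=specs[0].diff_step, xtol=specs[0].xtol,
                        ftol=specs[0].ftol, gtol=specs[0].gtol,
                        max_nfev=specs[0].max_nfev)
    mu = float(res.x[0])
    apply_shared(mu)
    results = []
    for m, t, s, off, nsz in zip(models, target_vecs, specs, offsets, sizes):
        prof = _unpack(res.x[off:off + nsz], s.initial, s.free)
        r = m.peak_vector(prof) - t
        results.append(FitResult(profile=prof, cost=0.5 * float(r @ r),
                                 residuals=r, n_evaluations=int(res.nfev),
                                 converged=bool(res.success),
                                 message=res.message,
                                 shared={shared_group: mu}))
    return results, {shared_group: mu}


def sensitivity_profile(model: ModelSpectrum, profile: EnzymeProfile,
                        step: float = 0.1, enzymes=None) -> dict:
    """||spectrum change|| per unit log-activity change, per enzyme."""
    enzymes = enzymes or list(profile.activities)
    base = model.peak_vector(profile)
    out = {}
    for e in enzymes:
        acts = dict(profile.activities)
        acts[e] = max(acts[e], 1e-12) * float(np.exp(step))
        delta = model.peak_vector(EnzymeProfile(acts)) - base
        out[e] = float(np.linalg.norm(delta)) / step
    return out
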