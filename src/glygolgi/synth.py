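"""Synthetic-data generator: ground-truth profiles and noisy MALDI fixtures.

Emulates the permethylated [M+Na]+ N-glycan spectra the model is fitted to:
continuous m/z profiles over 1400-5000 Da with Gaussian peak shapes, slow
baseline drift, seeded multiplicative intensity noise, and contaminant peaks
at non-model masses (mimicking the sample-processing artifacts real spectra
carry).  Every stochastic call takes an explicit seed; identical seeds give
bit-identical fixtures.  Ground truth (per-group intensities and the
generating activity profile) is returned alongside each fixture so the
preprocessing, projection and fitting stages can be scored end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .golgi import EnzymeProfile, GolgiSolver, load_cell_line_profiles
from .spectra import (ISOTOPE_SPACING, MassSpectrum, Peak, PeakList,
                      theoretical_spectrum, write_msd)

__all__ = ["NoiseModel", "make_profile", "synthesize_spectrum",
           "write_fixture"]


@dataclass
class NoiseModel:
    seed: int
    peak_noise_sd: float = 0.05       # multiplicative, per peak
    baseline_amplitude: float = 0.0   # in units of the max peak height
    baseline_wavelength: float = 800.0  # Da
    n_contaminants: int = 0
    contaminant_scale: float = 0.3    # fraction of the median peak height
    peak_sigma: float = 0.08          # Da, Gaussian peak width
    grid_step: float = 0.02           # Da

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("peak_noise_sd", "baseline_amplitude", "n_contaminants",
                     "contaminant_scale", "peak_sigma", "grid_step"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_profile(base: str, log_perturbation_sd: float = 0.0,
                 seed: int | None = None) -> EnzymeProfile:
    """A cell-line profile with seeded lognormal perturbation of activities."""
    profiles = load_cell_line_profiles()
    if base not in profiles:
        raise KeyError(f"unknown cell line {base!r}; choose from "
                       f"{sorted(profiles)}")
    acts = dict(profiles[base].activities)
    if log_perturbation_sd > 0:
        if seed is None:
            raise ValueError("a seed is required when perturbing")
        rng = np.random.default_rng(seed)
        for e in acts:
            acts[e] = acts[e] * float(np.exp(rng.normal(0.0, log_perturbation_sd)))
    return EnzymeProfile(acts)


def synthesize_spectrum(profile: EnzymeProfile, solver: GolgiSolver,
                        noise: NoiseModel, mass_range=(1400.0, 5000.0),
                        n_peaks: int = 6):
    """Raw profile-mode spectrum + ground-truth stick peak list.

    Returns ``(raw, truth, meta)``: the noisy continuous spectrum, the
    noise-free stick PeakList (grouped by isotope envelope), and a metadata
    dict with the generating activities and contaminant masses.
    """
    compositions = [g.composition for g in solver.net.structures]
    ab = solver.solve(profile)
    sticks = theoretical_spectrum(ab.outlet_percent, compositions, mass_range,
                                  n_peaks=n_peaks)
    rng = np.random.default_rng(noise.seed)
    lo, hi = mass_range
    grid = np.arange(lo - 5.0, hi + 5.0, noise.grid_step)
    y = np.zeros_like(grid)

    heights = sticks.intensity.copy()
    if noise.peak_noise_sd > 0:
        heights = heights * np.exp(rng.normal(0.0, noise.peak_noise_sd,
                                              heights.size))
    # contaminants at masses kept >= 3 Da away from any model peak
    contaminants = []
    if noise.n_contaminants > 0:
        median_h = float(np.median(sticks.intensity[sticks.intensity > 0]))
        attempts = 0
        while len(contaminants) < noise.n_contaminants and attempts < 10000:
            attempts += 1
            m = float(rng.uniform(lo + 10, hi - 10))
            if np.min(np.abs(sticks.mz - m)) < 3.0:
                continue
            contaminants.append((m, float(rng.uniform(0.2, 1.0))
                                 * noise.contaminant_scale * median_h))
    # contaminants carry small isotopic satellite groups of their own, like
    # the real serum/processing artifacts they emulate
    cont_mz, cont_h = [], []
    for m, h in contaminants:
        for i, frac in enumerate((1.0, 0.6, 0.25)):
            cont_mz.append(m + i * ISOTOPE_SPACING)
            cont_h.append(h * frac)
    all_mz = np.concatenate([sticks.mz, cont_mz])
    all_h = np.concatenate([heights, cont_h])
    sig = noise.peak_sigma
    for m, h in zip(all_mz, all_h):
        sel = np.abs(grid - m) < 6 * sig
        y[sel] += h * np.exp(-0.5 * ((grid[sel] - m) / sig) ** 2)
    if noise.baseline_amplitude > 0:
        amp = noise.baseline_amplitude * float(all_h.max())
        y += amp * (1.1 + np.sin(2 * np.pi * grid / noise.baseline_wavelength
                                 + rng.uniform(0, 2 * np.pi)))
    raw = MassSpectrum(grid, y)

    truth_peaks = []
    gid = -1
    last = None
    for m, a in zip(sticks.mz, sticks.intensity):
        if last is None or abs((m - last) - ISOTOPE_SPACING) > 0.02:
            gid += 1
        truth_peaks.append(Peak(float(m), float(a), gid))
        last = m
    truth = PeakList(peaks=truth_peaks, mass_range=mass_range)
    meta = {"activities": dict(profile.activities),
            "seed": noise.seed,
            "contaminant_mz": [m for m, _ in contaminants]}
    return raw, truth, meta


def write_fixture(raw: MassSpectrum, truth: PeakList, meta: dict, stem) -> None:
    """Write a fixture as ``<stem>.msd`` plus a ``<stem>.json`` truth sidecar."""
    write_msd(raw, f"{stem}.msd")
    payload = dict(meta)
    payload["truth"] = [[p.mz, p.area, p.group] for p in truth.peaks]
    with open(f"{stem}.json", "w") as fh:
        json.dump(payload, fh, indent=1)
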