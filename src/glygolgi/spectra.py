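"""Synthetic MALDI-TOF spectra of permethylated N-glycans, and peak-list tools.

Model spectra are computed for permethylated, sodiated, singly charged ions
([M+Na]+, the standard MALDI glycomics ion form).  Each glycan composition
contributes its isotopic envelope — the aggregated-isotopologue distribution
of its permethylated, sodiated elemental formula — scaled by abundance;
isobaric structures (same composition) pool.  Spectra are normalized so peak
intensities sum to 100%.

Experimental peak processing follows the usual pipeline: baseline subtraction
(rolling minimum), Savitzky-Golay smoothing, peak detection and integration,
grouping of isotopic satellites (~1.00336 Da spacing) and removal of isolated
peaks, then non-negative projection of the surviving group intensities onto
the model's masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import grey_erosion
from scipy.optimize import nnls
from scipy.signal import find_peaks, savgol_filter

from .glycans import ATOMIC_MASS, elemental_formula

__all__ = ["MassSpectrum", "Peak", "PeakList", "IsotopeEnvelope",
           "isotope_envelope", "theoretical_spectrum", "preprocess_spectrum",
           "project_onto_model", "read_msd", "write_msd", "PreprocessParams"]

#: Isotopic masses (u) and abundances per element (NIST), lightest first.
ISOTOPES = {
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "H": [(1.00782503207, 0.999885), (2.01410177812, 0.000115)],
    "N": [(14.0030740048, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317565, 0.00038),
          (17.9991596129, 0.00205)],
    "Na": [(22.9897692809, 1.0)],
}

#: Mean mass spacing of adjacent isotopologue peaks (Da).
ISOTOPE_SPACING = 1.00336


@dataclass
class MassSpectrum:
    mz: np.ndarray
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")

    def normalize(self) -> "MassSpectrum":
        total = self.intensity.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return MassSpectrum(self.mz, 100.0 * self.intensity / total,
                            normalized=True)


@dataclass(frozen=True)
class Peak:
    mz: float
    area: float
    group: int  # isotope-group id; -1 flags an isolated peak


@dataclass
class PeakList:
    peaks: list
    mass_range: tuple | None = None

    def group_intensities(self) -> dict:
        out: dict = {}
        for p in self.peaks:
            if p.group >= 0:
                out[p.group] = out.get(p.group, 0.0) + p.area
        return out

    def total(self) -> float:
        return sum(p.area for p in self.peaks)


@dataclass(frozen=True)
class IsotopeEnvelope:
    masses: tuple    # isotopologue masses, monoisotopic first
    intensities: tuple  # sum to 1


def _convolve_aggregated(dist_a, dist_b, threshold):
    """Convolve two (abundance, mean-mass) aggregated distributions."""
    size = len(dist_a) + len(dist_b) - 1
    ab = np.zeros(size)
    wm = np.zeros(size)
    for i, (pa, ma) in enumerate(dist_a):
        if pa == 0:
            continue
        for j, (pb, mb) in enumerate(dist_b):
            if pb == 0:
                continue
            p = pa * pb
            ab[i + j] += p
            wm[i + j] += p * (ma + mb)
    out = []
    for k in range(size):
        if ab[k] > threshold:
            out.append((ab[k], wm[k] / ab[k]))
        else:
            out.append((0.0, 0.0))
    while out and out[-1][0] == 0.0:
        out.pop()
    return out


def _element_distribution(element, count, threshold):
    base = [(p, m) for m, p in ISOTOPES[element]]
    # nucleon-indexed: offset of each isotope relative to the lightest
    lightest = ISOTOPES[element][0][0]
    slots = max(round(m - lightest) for m, _ in ISOTOPES[element]) + 1
    dist = [(0.0, 0.0)] * slots
    agg = {}
    for m, p in ISOTOPES[element]:
        agg[round(m - lightest)] = (p, m)
    dist = [agg.get(k, (0.0, 0.0)) for k in range(slots)]
    # exponentiate by squaring
    result = [(1.0, 0.0)]
    power = dist
    n = count
    while n:
        if n & 1:
            result = _convolve_aggregated(result, power, threshold)
        n >>= 1
        if n:
            power = _convolve_aggregated(power, power, threshold)
    return result


def isotope_envelope(formula: dict, n_peaks: int = 10,
                     threshold: float = 1e-10) -> IsotopeEnvelope:
    """Aggregated isotopologue envelope of an elemental formula."""
    dist = [(1.0, 0.0)]
    for el, count in formula.items():
        if count:
            dist = _convolve_aggregated(dist, _element_distribution(
                el, count, threshold), threshold)
    dist = dist[:n_peaks]
    total = sum(p for p, _ in dist)
    masses, intensities = [], []
    for p, m in dist:
        if p > 0:
            masses.append(m)
            intensities.append(p / total)
    return IsotopeEnvelope(tuple(masses), tuple(intensities))


def envelope_for_composition(counts, adduct: str = "Na",
                             n_peaks: int = 10) -> IsotopeEnvelope:
    formula = dict(elemental_formula(counts))
    if adduct == "Na":
        formula["Na"] = formula.get("Na", 0) + 1
    elif adduct is not None:
        raise ValueError(f"unsupported adduct {adduct!r}")
    return isotope_envelope(formula, n_peaks=n_peaks)


def theoretical_spectrum(abundances, compositions, mass_range=(1400.0, 5000.0),
                         adduct: str = "Na", n_peaks: int = 10) -> MassSpectrum:
    """Stick spectrum from per-structure abundances and compositions.

    ``abundances`` and ``compositions`` are parallel sequences; structures with
    equal composition are isobaric and pool into one envelope.  The spectrum is
    clipped to ``mass_range`` (on m/z) and normalized to 100%.
    """
    lo, hi = mass_range
    if not (hi > lo):
        raise ValueError("empty mass range")
    pooled: dict = {}
    for ab, comp in zip(abundances, compositions):
        if ab <= 0:
            continue
        key = tuple(sorted((k, v) for k, v in comp.items() if v))
        pooled[key] = pooled.get(key, 0.0) + ab
    sticks: dict = {}
    for key, ab in pooled.items():
        env = envelope_for_composition(dict(key), adduct=adduct, n_peaks=n_peaks)
        for m, p in zip(env.masses, env.intensities):
            if lo <= m <= hi:
                sticks[round(m, 6)] = sticks.get(round(m, 6), 0.0) + ab * p
    if not sticks:
        raise ValueError("no model peaks inside the mass range")
    mz = np.array(sorted(sticks))
    intensity = np.array([sticks[m] for m in mz])
    return MassSpectrum(mz, intensity).normalize()


# ---------------------------------------------------------------------------
# Experimental spectrum preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessParams:
    baseline_window: int = 501     # points, rolling-minimum footprint
    smooth_window: int = 5         # points, odd
    smooth_order: int = 2
    min_height: float = 0.0        # absolute, after baseline removal; 0 = auto
    group_tolerance: float = 0.01  # Da around the 1.00336 spacing
    integration_halfwidth: float = 0.35  # Da


def preprocess_spectrum(raw: MassSpectrum,
                        params: PreprocessParams | None = None) -> PeakList:
    """Baseline -> smoothing -> peak pick/integrate -> isotope grouping."""
    params = params or PreprocessParams()
    if len(raw.mz) < 2:
        raise ValueError("need at least two spectrum points")
    y = raw.intensity.astype(float)
    w = min(params.baseline_window, len(y) if len(y) % 2 else len(y) - 1)
    baseline = grey_erosion(y, size=max(w, 3))
    y = np.clip(y - baseline, 0.0, None)
    sw = min(params.smooth_window, len(y) - (1 - len(y) % 2))
    if sw >= 3:
        y_s = savgol_filter(y, sw, min(params.smooth_order, sw - 1))
        y_s = np.clip(y_s, 0.0, None)
    else:
        y_s = y
    height = params.min_height
    if height <= 0:
        height = max(float(y_s.max()) * 1e-4, 1e-12)
    idx, _ = find_peaks(y_s, height=height, prominence=height)
    mz = raw.mz
    peaks = []
    if idx.size:
        # watershed-style integration: every sample within the halfwidth of
        # some peak contributes to its nearest peak, so overlapping peaks
        # split the shared signal instead of double counting it
        centers = mz[idx]
        nearest = np.searchsorted(centers, mz)
        nearest = np.clip(nearest, 0, centers.size - 1)
        left_ok = nearest > 0
        pick_left = left_ok & (np.abs(mz - centers[np.maximum(nearest - 1, 0)])
                               < np.abs(mz - centers[nearest]))
        nearest[pick_left] -= 1
        dist = np.abs(mz - centers[nearest])
        step = np.median(np.diff(mz)) if mz.size > 1 else 1.0
        areas = np.zeros(centers.size)
        inside = dist <= params.integration_halfwidth
        np.add.at(areas, nearest[inside], y[inside] * step)
        peaks = [[float(c), float(a)] for c, a in zip(centers, areas) if a > 0]
    # group peaks spaced by ~one isotopologue unit
    groups = []
    gid = -1
    last_mz = None
    assigned = []
    for mz_i, area in peaks:
        if last_mz is not None and abs((mz_i - last_mz) - ISOTOPE_SPACING) \
                <= params.group_tolerance:
            assigned.append(Peak(mz_i, area, gid if gid >= 0 else 0))
            if gid < 0:
                gid = 0
        else:
            gid = gid + 1 if gid >= 0 else 0
            assigned.append(Peak(mz_i, area, gid))
        last_mz = mz_i
    # renumber: mark singleton groups isolated
    from collections import Counter
    sizes = Counter(p.group for p in assigned)
    out = []
    for p in assigned:
        if sizes[p.group] >= 2:
            out.append(p)
        else:
            out.append(Peak(p.mz, p.area, -1))
    kept = [p for p in out if p.group >= 0]
    return PeakList(peaks=kept,
                    mass_range=(float(mz[0]), float(mz[-1])))


def stick_peaklist(spec: MassSpectrum, group_tolerance: float = 0.02) -> PeakList:
    """Interpret an already-centroided stick spectrum as a peak list."""
    peaks = []
    gid = -1
    last = None
    for m, a in zip(spec.mz, spec.intensity):
        if a <= 0:
            continue
        if last is None or abs((m - last) - ISOTOPE_SPACING) > group_tolerance:
            gid += 1
        peaks.append(Peak(float(m), float(a), gid))
        last = m
    return PeakList(peaks=peaks, mass_range=(float(spec.mz[0]), float(spec.mz[-1])))


def project_onto_model(pl: PeakList, model_envelopes,
                       tolerance: float = 0.3) -> tuple[PeakList, np.ndarray, float]:
    """Non-negative projection of observed peaks onto model envelopes.

    ``model_envelopes`` is a sequence of IsotopeEnvelope (one per model
    composition).  Returns (projected peak list at model masses, coefficient
    vector, residual norm).  Observed intensity at non-model masses is
    discarded; the projected list is renormalized to a 100% total.
    """
    if not model_envelopes:
        raise ValueError("model_envelopes must be non-empty")
    obs_mz = np.array([p.mz for p in pl.peaks])
    obs_int = np.array([p.area for p in pl.peaks])
    if obs_mz.size == 0:
        return PeakList(peaks=[]), np.zeros(len(model_envelopes)), 0.0
    a = np.zeros((obs_mz.size, len(model_envelopes)))
    for j, env in enumerate(model_envelopes):
        for m, p in zip(env.masses, env.intensities):
            d = np.abs(obs_mz - m)
            i = int(np.argmin(d))
            if d[i] <= tolerance:
                a[i, j] += p
    coef, resid = nnls(a, obs_int)
    sticks: dict = {}
    for j, env in enumerate(model_envelopes):
        if coef[j] <= 0:
            continue
        for m, p in zip(env.masses, env.intensities):
            sticks[round(m, 6)] = sticks.get(round(m, 6), 0.0) + coef[j] * p
    total = sum(sticks.values())
    peaks = []
    if total > 0:
        gid = -1
        last = None
        for m in sorted(sticks):
            if last is None or abs((m - last) - ISOTOPE_SPACING) > 0.02:
                gid += 1
            peaks.append(Peak(m, 100.0 * sticks[m] / total, gid))
            last = m
    return PeakList(peaks=peaks, mass_range=pl.mass_range), coef, float(resid)


# ---------------------------------------------------------------------------
# CFG .msd dialect I/O (two-column text)
# ---------------------------------------------------------------------------

def read_msd(path_or_lines) -> MassSpectrum:
    """Read a two-column (m/z, intensity) text file; headers tolerated."""
    if isinstance(path_or_lines, (str, bytes)) or hasattr(path_or_lines, "__fspath__"):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    mz, inten = [], []
    for line in lines:
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            continue
        try:
            m, i = float(parts[0]), float(parts[1])
        except ValueError:
            continue
        mz.append(m)
        inten.append(i)
    if not mz:
        raise ValueError("no data rows found")
    order = np.argsort(mz)
    return MassSpectrum(np.array(mz)[order], np.array(inten)[order])


def write_msd(spec: MassSpectrum, path) -> None:
    with open(path, "w") as fh:
        for m, i in zip(spec.mz, spec.intensity):
            fh.write(f"{m:.5f}\t{i:.8g}\n")
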