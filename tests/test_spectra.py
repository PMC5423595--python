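import numpy as np
import pytest

from glygolgi.glycans import elemental_formula
from glygolgi.spectra import (ISOTOPES, MassSpectrum, PeakList, Peak,
                              envelope_for_composition, isotope_envelope,
                              preprocess_spectrum, project_onto_model,
                              read_msd, stick_peaklist, theoretical_spectrum,
                              write_msd, PreprocessParams)

MAN5 = {"M": 5, "GN": 2}
MAN9 = {"M": 9, "GN": 2}


def test_envelope_normalized_and_monoisotopic_first():
    env = envelope_for_composition(MAN5)
    assert sum(env.intensities) == pytest.approx(1.0)
    assert env.masses[0] == min(env.masses)
    assert env.masses[0] == pytest.approx(1579.78, abs=0.01)
    spacing = np.diff(env.masses)
    assert np.allclose(spacing, 1.00336, atol=5e-3)


def test_second_isotopologue_matches_first_order_theory():
    # P1/P0 ~= sum over elements of n_el * (p_heavy1 / p_light)
    formula = elemental_formula(MAN5)
    formula["Na"] = 1
    expected = 0.0
    for el, n in formula.items():
        iso = ISOTOPES[el]
        if len(iso) > 1 and round(iso[1][0] - iso[0][0]) == 1:
            expected += n * iso[1][1] / iso[0][1]
    env = isotope_envelope(formula)
    assert env.intensities[1] / env.intensities[0] == \
        pytest.approx(expected, rel=1e-3)


def test_theoretical_spectrum_single_structure_is_its_envelope():
    spec = theoretical_spectrum([1.0], [MAN5], mass_range=(1400, 5000))
    env = envelope_for_composition(MAN5)
    assert spec.intensity.sum() == pytest.approx(100.0)
    assert np.allclose(spec.mz[:4], env.masses[:4])
    assert np.allclose(spec.intensity[:4] / 100.0, env.intensities[:4],
                       atol=1e-9)


def test_isomers_pool_into_one_envelope():
    one = theoretical_spectrum([2.0], [MAN5], (1400, 5000))
    two = theoretical_spectrum([1.0, 1.0], [dict(MAN5), dict(MAN5)],
                               (1400, 5000))
    assert np.allclose(one.mz, two.mz)
    assert np.allclose(one.intensity, two.intensity)


def test_spectrum_is_linear_in_abundances():
    a = theoretical_spectrum([3.0, 1.0], [MAN5, MAN9], (1400, 5000))
    b = theoretical_spectrum([1.0, 3.0], [MAN5, MAN9], (1400, 5000))
    mix = theoretical_spectrum([2.0, 2.0], [MAN5, MAN9], (1400, 5000))
    assert np.allclose(mix.intensity, (a.intensity + b.intensity) / 2,
                       atol=1e-9)


def test_mass_range_is_enforced():
    spec = theoretical_spectrum([1.0, 1.0], [MAN5, MAN9], (2000, 5000))
    assert spec.mz.min() > 2000
    with pytest.raises(ValueError):
        theoretical_spectrum([1.0], [MAN5], (5000, 1400))


def test_mass_spectrum_invariants():
    with pytest.raises(ValueError):
        MassSpectrum([1.0, 1.0], [2.0, 3.0])      # non-increasing mz
    with pytest.raises(ValueError):
        MassSpectrum([1.0, 2.0], [-1.0, 3.0])     # negative intensity
    s = MassSpectrum([1.0, 2.0], [1.0, 3.0]).normalize()
    assert s.intensity.sum() == pytest.approx(100.0, abs=1e-6)


def _gaussian_profile(centers, heights, sigma=0.06, lo=1500.0, hi=1700.0,
                      baseline=0.0):
    grid = np.arange(lo, hi, 0.02)
    y = np.full_like(grid, baseline)
    for m, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((grid - m) / sigma) ** 2)
    return MassSpectrum(grid, y)


def test_preprocess_recovers_envelopes_and_drops_isolated_spike():
    env_starts = [1520.0, 1580.0, 1650.0]
    centers, heights = [], []
    for m0 in env_starts:
        for i, frac in enumerate([1.0, 0.8, 0.4]):
            centers.append(m0 + i * 1.00336)
            heights.append(100.0 * frac)
    centers.append(1610.0)   # isolated noise spike, no satellites
    heights.append(80.0)
    raw = _gaussian_profile(centers, heights, baseline=2.0)
    pl = preprocess_spectrum(raw)
    groups = {}
    for p in pl.peaks:
        groups.setdefault(p.group, []).append(p.mz)
    assert len(groups) == 3
    found_starts = sorted(min(v) for v in groups.values())
    assert np.allclose(found_starts, env_starts, atol=0.05)
    assert all(abs(p.mz - 1610.0) > 0.2 for p in pl.peaks)


def test_preprocess_constant_spectrum_gives_empty_peaklist():
    grid = np.arange(1500.0, 1600.0, 0.05)
    pl = preprocess_spectrum(MassSpectrum(grid, np.full_like(grid, 5.0)))
    assert pl.peaks == []


def test_stick_peaklist_identity_on_clean_sticks():
    spec = theoretical_spectrum([1.0, 2.0], [MAN5, MAN9], (1400, 5000))
    pl = stick_peaklist(spec)
    assert len(pl.peaks) == spec.mz.size
    assert {p.group for p in pl.peaks} == {0, 1}


def test_projection_reproduces_model_only_peaklist():
    spec = theoretical_spectrum([3.0, 1.0], [MAN5, MAN9], (1400, 5000))
    pl = stick_peaklist(spec)
    envs = [envelope_for_composition(MAN5), envelope_for_composition(MAN9)]
    proj, coef, resid = project_onto_model(pl, envs)
    assert resid == pytest.approx(0.0, abs=1e-9)
    assert coef[0] / coef[1] == pytest.approx(3.0, rel=1e-9)


def test_projection_discards_extraneous_mass():
    spec = theoretical_spectrum([3.0, 1.0], [MAN5, MAN9], (1400, 5000))
    peaks = [Peak(float(m), float(i), g.group) for m, i, g in
             zip(spec.mz, spec.intensity, stick_peaklist(spec).peaks)]
    peaks.append(Peak(3000.0, 25.0, 99))  # non-model contaminant
    pl = PeakList(peaks=sorted(peaks, key=lambda p: p.mz))
    envs = [envelope_for_composition(MAN5), envelope_for_composition(MAN9)]
    proj, coef, resid = project_onto_model(pl, envs)
    assert coef[0] / coef[1] == pytest.approx(3.0, rel=1e-6)
    total = sum(p.area for p in proj.peaks)
    assert total == pytest.approx(100.0, rel=1e-9)
    assert all(abs(p.mz - 3000.0) > 1.0 for p in proj.peaks)


def test_projection_matches_grid_search_on_overlapping_pair():
    # two adjacent compositions whose envelopes interleave ~1 Da apart
    man5f = {"M": 5, "GN": 2, "F": 1}
    envs = [envelope_for_composition(MAN5), envelope_for_composition(man5f)]
    truth = np.array([2.0, 1.0])
    sticks = {}
    for c, env in zip(truth, envs):
        for m, p in zip(env.masses, env.intensities):
            sticks[round(m, 6)] = sticks.get(round(m, 6), 0.0) + c * p
    mz = sorted(sticks)
    pl = PeakList(peaks=[Peak(m, sticks[m], 0) for m in mz])
    _, coef, _ = project_onto_model(pl, envs)

    def objective(x):
        a = np.zeros(len(mz))
        for c, env in zip(x, envs):
            for m, p in zip(env.masses, env.intensities):
                i = int(np.argmin(np.abs(np.array(mz) - m)))
                a[i] += c * p
        return np.sum((a - np.array([sticks[m] for m in mz])) ** 2)

    grid = np.linspace(0.5, 3.5, 61)
    best = min(((objective([x, y]), x, y) for x in grid for y in grid))
    assert coef[0] == pytest.approx(best[1], abs=0.05)
    assert coef[1] == pytest.approx(best[2], abs=0.05)
    assert objective(coef) <= best[0] + 1e-12


def test_nested_model_residual_is_non_increasing():
    spec = theoretical_spectrum([3.0, 1.0], [MAN5, MAN9], (1400, 5000))
    pl = stick_peaklist(spec)
    envs = [envelope_for_composition(MAN5), envelope_for_composition(MAN9)]
    _, _, r1 = project_onto_model(pl, envs[:1])
    _, _, r2 = project_onto_model(pl, envs)
    assert r2 <= r1 + 1e-12


def test_msd_round_trip(tmp_path):
    spec = theoretical_spectrum([1.0], [MAN5], (1400, 5000))
    path = tmp_path / "x.msd"
    write_msd(spec, path)
    back = read_msd(path)
    assert np.allclose(back.mz, spec.mz, atol=1e-5)
    assert np.allclose(back.intensity, spec.intensity, rtol=1e-6)


def test_msd_reader_tolerates_headers_and_commas():
    lines = ["m/z intensity", "# comment", "1500.5, 10.0", "1501.5\t20.0"]
    spec = read_msd(lines)
    assert spec.mz.tolist() == [1500.5, 1501.5]
    assert spec.intensity.tolist() == [10.0, 20.0]
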