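"""Source emission, interaction sampling, and the transport engine."""

import math

import numpy as np
import pytest
from scipy import stats

import mammomc as mm
from mammomc.geometry import GeometryConfig, PhantomAssembly, Region, Box
from mammomc.materials import Material, FormFactorTable, XsecLibrary
from mammomc.oracles import (
    SlabSpec, absorber_deposition, beer_lambert_transmission,
    compton_scattered_energy, kn_pdf_numeric, thomson_pdf,
)
from mammomc.transport import (
    PhotonState, SimulationConfig, emit_photon, emit_photons,
    sample_free_path, sample_compton, sample_rayleigh, transport_history,
    run_simulation,
)


# -- emission --------------------------------------------------------------

def test_all_emitted_photons_cross_the_entrance_field(default_assembly, rng):
    pos, dirs, e = emit_photons(default_assembly, 30.0, 100_000, rng)
    assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
    src = np.asarray(default_assembly.source_position)
    t = (default_assembly.field_z - src[2]) / dirs[:, 2]
    hx = src[0] + t * dirs[:, 0]
    hy = src[1] + t * dirs[:, 1]
    xlo, xhi, ylo, yhi = default_assembly.field
    assert np.all((hx >= xlo) & (hx <= xhi) & (hy >= ylo) & (hy <= yhi))
    assert np.all(e == 30.0)


def test_degenerate_tiny_field_collapses_the_cone(rng):
    asm = PhantomAssembly([], source_position=(0.0, 0.5, 10.0),
                          field=(-1e-4, 1e-4, 0.5 - 1e-4, 0.5 + 1e-4),
                          field_z=0.0)
    _, dirs, _ = emit_photons(asm, 30.0, 1000, rng)
    target = np.array([0.0, 0.0, -1.0])
    assert np.allclose(dirs, target, atol=1e-4)


def test_entrance_hit_density_matches_rejection_sampler_oracle(default_assembly):
    """Chi-square comparison of the cone sampler vs brute-force rejection."""
    n = 60_000
    rng1 = np.random.default_rng(77)
    _, dirs, _ = emit_photons(default_assembly, 30.0, n, rng1)
    src = np.asarray(default_assembly.source_position)
    xlo, xhi, ylo, yhi = default_assembly.field

    def hits(d):
        t = (default_assembly.field_z - src[2]) / d[:, 2]
        return src[0] + t * d[:, 0], src[1] + t * d[:, 1]

    # oracle: isotropic downward hemisphere directions, keep those in field
    rng2 = np.random.default_rng(88)
    kept = []
    while sum(len(k) for k in kept) < n:
        c = -rng2.random(200_000)          # cos(theta) uniform: isotropic
        phi = 2 * np.pi * rng2.random(200_000)
        s = np.sqrt(1 - c * c)
        d = np.column_stack([s * np.cos(phi), s * np.sin(phi), c])
        hx, hy = hits(d)
        ok = (hx >= xlo) & (hx <= xhi) & (hy >= ylo) & (hy <= yhi)
        kept.append(d[ok])
    d_oracle = np.concatenate(kept)[:n]

    bins = 10
    hx1, hy1 = hits(dirs)
    hx2, hy2 = hits(d_oracle)
    h1, _, _ = np.histogram2d(hx1, hy1, bins=bins,
                              range=[[xlo, xhi], [ylo, yhi]])
    h2, _, _ = np.histogram2d(hx2, hy2, bins=bins,
                              range=[[xlo, xhi], [ylo, yhi]])
    # two-sample chi-square over the 10x10 grid
    chi2 = ((h1 - h2) ** 2 / (h1 + h2)).sum()
    dof = bins * bins - 1
    assert chi2 < stats.chi2.ppf(0.999, dof)


def test_emit_photon_returns_valid_state(default_assembly, rng):
    st_ = emit_photon(default_assembly, 26.0, rng)
    assert st_.weight == 1.0 and st_.alive
    assert st_.energy == 26.0


# -- free path -------------------------------------------------------------

def test_free_path_mean_and_survival_match_exponential(rng):
    d = sample_free_path(np.ones(1_000_000), rng)
    assert d.mean() == pytest.approx(1.0, abs=3e-3)           # 3/sqrt(1e6)
    assert (d > 1.0).mean() == pytest.approx(math.exp(-1), abs=2e-3)


def test_free_path_scales_inversely_with_mu():
    r1 = sample_free_path(np.full(200_000, 1.0), np.random.default_rng(5))
    r2 = sample_free_path(np.full(200_000, 2.0), np.random.default_rng(5))
    assert r2.mean() == pytest.approx(r1.mean() / 2.0, rel=1e-12)


def test_free_path_requires_positive_mu(rng):
    with pytest.raises(ValueError):
        sample_free_path(np.array([0.0]), rng)


# -- Compton ---------------------------------------------------------------

def test_compton_relation_limits():
    assert compton_scattered_energy(30.0, 1.0) == pytest.approx(30.0)
    # backscatter at 36 keV: 36 / (1 + 2*36/511)
    assert compton_scattered_energy(36.0, -1.0) == pytest.approx(31.554, abs=1e-3)


def test_compton_sampler_energies_follow_kinematics(rng):
    e, mu = sample_compton(np.full(10_000, 30.0), rng)
    assert np.allclose(e, compton_scattered_energy(30.0, mu), rtol=1e-12)
    assert np.all((e > 0) & (e <= 30.0))
    assert np.all((mu >= -1) & (mu <= 1))


def _ks_against_pdf(samples, grid, pdf):
    cdf_grid = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf_grid /= cdf_grid[-1]
    return stats.kstest(samples, lambda x: np.interp(x, grid, cdf_grid))


def test_klein_nishina_sampler_matches_quadrature_pdf(rng):
    _, mu = sample_compton(np.full(1_000_000, 30.0), rng)
    grid, pdf = kn_pdf_numeric(30.0)
    res = _ks_against_pdf(mu, grid, pdf)
    assert res.pvalue > 0.01


# -- Rayleigh --------------------------------------------------------------

def test_rayleigh_with_flat_form_factor_is_thomson(library, rng):
    # replace form factors by constants: the angle must follow pure Thomson
    flat = {
        s: FormFactorTable(s, t.Z, np.linspace(0, 10, 11), np.full(11, float(t.Z)))
        for s, t in library.form_factors.items()
    }
    lib = XsecLibrary(tables=library.tables, form_factors=flat)
    m = Material("pureO", {"O": 1.0}, 1.0)
    mu = sample_rayleigh(np.full(200_000, 30.0), m, rng, lib)
    grid = np.linspace(-1, 1, 2001)
    res = _ks_against_pdf(mu, grid, thomson_pdf(grid))
    assert res.pvalue > 0.01


def test_rayleigh_is_forward_peaked_in_tissue(materials, rng):
    mu = sample_rayleigh(np.full(100_000, 30.0), materials["GF50"], rng)
    assert mu.mean() > 0.25


# -- single-history transport ----------------------------------------------

def test_history_ledger_conserves_energy(default_assembly):
    cfg = SimulationConfig(assembly=default_assembly, source_energy_keV=30.0,
                           nps=10, seed=42)
    rng = np.random.default_rng(9)
    for k in range(40):
        state = emit_photon(default_assembly, 30.0, rng)
        cfg.seed = 100 + k
        ledger = transport_history(cfg, state)
        assert ledger.total_keV == pytest.approx(30.0, rel=1e-9)
        assert np.all(ledger.deposits_keV >= 0)


def test_vacuum_world_deposits_nothing():
    asm = PhantomAssembly([], source_position=(0.0, 0.0, 10.0),
                          field=(-1.0, 1.0, -1.0, 1.0), field_z=0.0)
    cfg = SimulationConfig(assembly=asm, source_energy_keV=30.0,
                           nps=1000, seed=7, batches=2)
    res = run_simulation(cfg)
    assert res.total_deposited_MeV_per_photon == 0.0
    assert res.escape_fraction == 1.0
    assert res.escaped_MeV_per_photon == pytest.approx(0.030, rel=1e-12)


# -- full runs -------------------------------------------------------------

def test_identical_seed_gives_bit_identical_results(default_assembly):
    cfg = SimulationConfig(assembly=default_assembly, source_energy_keV=28.0,
                           nps=20_000, seed=31)
    r1 = run_simulation(cfg)
    r2 = run_simulation(cfg)
    assert np.array_equal(r1.deposited_MeV_per_photon,
                          r2.deposited_MeV_per_photon)
    assert np.array_equal(r1.relative_error, r2.relative_error)
    assert r1.escaped_MeV_per_photon == r2.escaped_MeV_per_photon


def test_global_energy_conservation(default_assembly):
    cfg = SimulationConfig(assembly=default_assembly, source_energy_keV=26.0,
                           nps=50_000, seed=13)
    res = run_simulation(cfg)
    balance = res.total_deposited_MeV_per_photon + res.escaped_MeV_per_photon
    assert balance == pytest.approx(0.026, rel=1e-9)


def test_relative_errors_shrink_as_one_over_sqrt_n(default_assembly):
    small = run_simulation(SimulationConfig(
        assembly=default_assembly, source_energy_keV=30.0, nps=20_000, seed=21))
    large = run_simulation(SimulationConfig(
        assembly=default_assembly, source_energy_keV=30.0, nps=80_000, seed=22))
    roles = ["layer1", "layer2", "layer3"]
    ratio = np.mean([small.rel_err(r) / large.rel_err(r) for r in roles])
    assert ratio == pytest.approx(2.0, rel=0.3)


def test_top_layer_absorbs_most_per_gram_at_26_keV(default_assembly):
    res = run_simulation(SimulationConfig(
        assembly=default_assembly, source_energy_keV=26.0, nps=60_000, seed=17))
    assert res.per_g("layer1") > res.per_g("layer2") > res.per_g("layer3")


def test_uncollided_transmission_matches_beer_lambert(slab_assembly, materials):
    res = run_simulation(SimulationConfig(
        assembly=slab_assembly, source_energy_keV=26.0, nps=150_000, seed=19,
        beam="pencil"))
    slab = SlabSpec([(materials["GF25"], 1.5), (materials["GF50"], 1.5),
                     (materials["GF75"], 1.5)], 26.0)
    expected = beer_lambert_transmission(slab)
    sigma = math.sqrt(expected * (1 - expected) / res.nps)
    assert res.uncollided_escape_fraction == pytest.approx(
        expected, abs=3 * sigma)


def test_absorber_mode_matches_layered_absorber_oracle(slab_assembly, materials):
    res = run_simulation(SimulationConfig(
        assembly=slab_assembly, source_energy_keV=26.0, nps=150_000, seed=23,
        beam="pencil", mode="absorber"))
    slab = SlabSpec([(materials["GF25"], 1.5), (materials["GF50"], 1.5),
                     (materials["GF75"], 1.5)], 26.0)
    oracle, transmitted = absorber_deposition(slab)
    for role, expected in zip(("layer1", "layer2", "layer3"), oracle):
        got = res.per_photon(role) / 0.026
        sigma = math.sqrt(expected * (1 - expected) / res.nps)
        assert got == pytest.approx(expected, abs=3 * sigma)
    assert res.escaped_MeV_per_photon / 0.026 == pytest.approx(
        transmitted, abs=3 * math.sqrt(transmitted * (1 - transmitted) / res.nps))


def test_disabling_coherent_channel_changes_tallies_only_modestly(
        default_assembly):
    base = run_simulation(SimulationConfig(
        assembly=default_assembly, source_energy_keV=30.0, nps=80_000, seed=29))
    noco = run_simulation(SimulationConfig(
        assembly=default_assembly, source_energy_keV=30.0, nps=80_000, seed=29,
        coherent_enabled=False))
    for role in ("layer1", "layer2", "layer3"):
        rel = abs(noco.per_g(role) - base.per_g(role)) / base.per_g(role)
        assert rel < 0.05


def test_config_validation():
    asm = mm.build_assembly()
    with pytest.raises(ValueError, match="cutoff"):
        SimulationConfig(assembly=asm, source_energy_keV=26.0, nps=100,
                         seed=1, cutoff_keV=30.0)
    with pytest.raises(ValueError, match="batches"):
        SimulationConfig(assembly=asm, source_energy_keV=26.0, nps=5, seed=1)
    with pytest.raises(ValueError, match="direction"):
        PhotonState(np.zeros(3), np.array([0.0, 0.0, -2.0]), 30.0)
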