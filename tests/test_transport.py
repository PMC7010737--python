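"""Monte Carlo kernel: interaction physics, tallies and statistics."""

import numpy as np
import pytest
from scipy.stats import chisquare

from mammomc.constants import MEC2_KEV, RE2_CM2
from mammomc.geometry import (Box, GeometryModel, PhantomConfig,
                              SourceConfig, build_thep)
from mammomc.materials import PMMA, breast_tissue, coefficient_table
from mammomc.spectrum import monoenergetic
from mammomc.transport import (PhysicsOptions, TallyResult, _CoherentSampler,
                               estimate_cv, run_histories, sample_compton,
                               sample_coherent, sample_interaction)


def _slab_model(material, thickness, world_material=None):
    """A single horizontal slab under a narrow vertical beam."""
    slab = Box([-8.0, 0.0, 2.0], [8.0, 10.0, 2.0 + thickness])
    source = SourceConfig(position=(0.0, 0.2, 65.0), field=(0.4, 0.4))
    world = Box([-10.0, -1.0, 0.0], [10.0, 11.0, 66.0])
    return GeometryModel([("slab", material, slab)], world, world_material,
                         ("slab",), source)


def _mk_tally(edep_batches):
    """Minimal TallyResult around given per-batch slab deposits."""
    arr = np.asarray(edep_batches, dtype=float)[:, None]
    k = arr.shape[0]
    return TallyResult(("slab",), arr, arr * 0.0, np.zeros(k), arr[:, 0],
                       np.zeros(k), np.ones(k, dtype=int))


# ------------------------------------------------------------ trivial limits

def test_vacuum_world_deposits_nothing():
    model = GeometryModel([], Box([-10, -1, 0], [10, 11, 66]), None,
                          (), SourceConfig(position=(0, 0, 65)))
    r = run_histories(model, monoenergetic(16.8), 2000, seed=1, batches=4)
    assert r.edep.sum() == 0
    assert r.escaped.sum() == pytest.approx(r.emitted.sum())


def test_beer_lambert_absorption_only_slab():
    """Transmission of a pe-only slab matches exp(-mu*t) at 3 sigma."""
    t = 1.0
    model = _slab_model(PMMA, t)
    phys = PhysicsOptions(disable_incoherent=True, disable_coherent=True)
    n = 200_000
    r = run_histories(model, monoenergetic(16.8), n, seed=2, physics=phys)
    mu_pe = coefficient_table().mixture(PMMA, 16.8, "pe") * PMMA.density
    expect = np.exp(-mu_pe * t)
    transmitted = r.escaped.sum() / r.emitted.sum()
    sigma = np.sqrt(expect * (1 - expect) / n)
    assert abs(transmitted - expect) < 3 * sigma


def test_energy_conservation_audit():
    model = build_thep(PhantomConfig(thickness=4.0))
    r = run_histories(model, monoenergetic(16.8), 5000, seed=3, batches=5)
    total = r.edep.sum() + r.escaped.sum()
    assert total == pytest.approx(r.emitted.sum(), rel=1e-9)


def test_determinism_same_seed():
    model = build_thep(PhantomConfig(thickness=4.0))
    r1 = run_histories(model, monoenergetic(18.0), 20_000, seed=9)
    r2 = run_histories(model, monoenergetic(18.0), 20_000, seed=9)
    np.testing.assert_array_equal(r1.edep, r2.edep)
    np.testing.assert_array_equal(r1.edep_g, r2.edep_g)
    r3 = run_histories(model, monoenergetic(18.0), 20_000, seed=10)
    assert not np.array_equal(r1.edep, r3.edep)


# ------------------------------------------------------------ interactions

def test_interaction_branching_frequencies(rng):
    mat = breast_tissue(0.5)
    tab = coefficient_table()
    e = 16.8
    kinds = sample_interaction(mat, e, rng, size=200_000)
    total = tab.mixture(mat, e, "mu_rho")
    for name, col in (("photoelectric", "pe"), ("incoherent", "incoh"),
                      ("coherent", "coh")):
        p = tab.mixture(mat, e, col) / total
        k = (kinds == name).mean()
        sigma = np.sqrt(p * (1 - p) / kinds.size)
        assert abs(k - p) < 3.5 * sigma


def test_photoelectric_dominates_at_5_kev_in_soft_tissue():
    tab = coefficient_table()
    mat = breast_tissue(0.5)
    assert tab.mixture(mat, 5.0, "pe") > tab.mixture(mat, 5.0, "incoh")


def test_disabled_channels_force_photoelectric(rng):
    phys = PhysicsOptions(disable_incoherent=True, disable_coherent=True)
    kinds = sample_interaction(breast_tissue(0.5), 20.0, rng, size=500,
                               physics=phys)
    assert set(kinds) == {"photoelectric"}


def test_compton_kinematics_formula(rng):
    e = 16.8
    ep, mu = sample_compton(e, rng, size=20_000)
    k = e / MEC2_KEV
    # exact Compton relation between E' and scattering angle
    np.testing.assert_allclose(ep, e / (1 + k * (1 - mu)), rtol=1e-12)
    # forward limit: no energy transfer; backscatter bound
    assert ep.max() <= e + 1e-12
    assert ep.min() >= e / (1 + 2 * k) - 1e-12
    backscatter = e / (1 + 2 * k)
    assert backscatter == pytest.approx(15.76, abs=0.01)


def test_compton_angle_matches_klein_nishina(rng):
    e = 20.0
    _, mu = sample_compton(e, rng, size=400_000)
    k = e / MEC2_KEV
    grid = np.linspace(-1, 1, 2001)
    r = 1.0 / (1.0 + k * (1.0 - grid))
    pdf = 0.5 * RE2_CM2 * r * r * (r + 1.0 / r - 1.0 + grid * grid)
    edges = np.linspace(-1, 1, 41)
    counts, _ = np.histogram(mu, bins=edges)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2
                                           * np.diff(grid))])
    probs = np.diff(np.interp(edges, grid, cdf))
    probs /= probs.sum()
    stat, p = chisquare(counts, probs * counts.sum())
    assert p > 0.01


def test_coherent_sampler_thomson_limit(rng):
    # with a flat F^2 the accepted angles must follow (1+cos^2)/2
    sampler = _CoherentSampler(breast_tissue(0.5))
    sampler.x2 = np.linspace(0.0, 64.0, 200)
    sampler.cum = sampler.x2.copy()  # constant F^2
    mu = sampler.sample(np.full(300_000, 12.0), rng)
    counts, edges = np.histogram(mu, bins=20, range=(-1, 1))
    c = (edges[:-1] + edges[1:]) / 2
    probs = (1 + c ** 2)
    probs /= probs.sum()
    stat, p = chisquare(counts, probs * counts.sum())
    assert p > 0.01


def test_coherent_mean_angle_decreases_with_energy(rng):
    mat = breast_tissue(0.5)
    mu10 = sample_coherent(10.0, mat, rng, size=50_000)
    mu30 = sample_coherent(30.0, mat, rng, size=50_000)
    # more forward-peaked (larger mean cosine) at higher energy
    assert mu30.mean() > mu10.mean() + 0.05


def test_cutoff_terminates_first_interaction():
    """With the cutoff above every possible Compton remnant, each
    interacting photon deposits its full energy: regional deposits are
    integer multiples of the photon energy."""
    e = 16.8
    model = _slab_model(breast_tissue(0.5), 4.0)
    phys = PhysicsOptions(cutoff_kev=17.0)
    r = run_histories(model, monoenergetic(e), 20_000, seed=4, physics=phys)
    dep = r.edep.sum(axis=0)
    frac = dep / e - np.round(dep / e)
    assert np.max(np.abs(frac)) < 1e-9


def test_g_weighted_never_exceeds_deposited():
    model = build_thep(PhantomConfig(thickness=4.0, gfs=(0.25, 0.5, 0.75)))
    r = run_histories(model, monoenergetic(18.0), 30_000, seed=5)
    assert np.all(r.edep_g <= r.edep + 1e-12)
    # breast layers actually accumulate G-weighted energy
    assert r.total("layer1", weighted=True) > 0


def test_depth_dose_monotone_in_homogeneous_phantom():
    model = build_thep(PhantomConfig(thickness=6.0, gfs=(0.5, 0.5, 0.5)))
    r = run_histories(model, monoenergetic(20.0), 150_000, seed=6)
    assert r.total("layer1") > r.total("layer2") > r.total("layer3")


# ------------------------------------------------------------ statistics

def test_cv_zero_for_identical_batches():
    assert estimate_cv(_mk_tally([2.0, 2.0, 2.0]), "slab") == 0.0


def test_cv_hand_value_two_batches():
    # means {1, 3}: population sd 1, k=2 -> CV = 1/sqrt(2)/2
    assert estimate_cv(_mk_tally([1.0, 3.0]), "slab") == pytest.approx(
        np.sqrt(2) / 4)


def test_cv_requires_two_batches():
    with pytest.raises(ValueError):
        estimate_cv(_mk_tally([1.0]), "slab")


def test_cv_scales_with_history_count():
    model = build_thep(PhantomConfig(thickness=4.0))
    spec = monoenergetic(18.0)
    cv1 = estimate_cv(run_histories(model, spec, 20_000, seed=8), "layer1")
    cv4 = estimate_cv(run_histories(model, spec, 80_000, seed=8), "layer1")
    assert 1.3 < cv1 / cv4 < 3.1  # ~ sqrt(4) = 2
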