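"""Phantom construction, point location, ray tracing and GF-triplet labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammomc.constants import PHANTOM_LIFT_CM
from mammomc.geometry import (DISTRIBUTION_GRID, PhantomConfig,
                              build_kerma_setup, build_tg195_case3,
                              build_thep, classify_distribution,
                              mean_glandular_fraction)
from mammomc.materials import breast_tissue


@pytest.fixture(scope="module")
def thep():
    return build_thep(PhantomConfig(thickness=4.0, gfs=(0.25, 0.5, 0.75)))


def test_layer_slab_thickness():
    cfg = PhantomConfig(thickness=4.0)
    assert cfg.layer_height == pytest.approx((4.0 - 0.8) / 3)


def test_layer_volumes_equal(thep):
    vols = [thep.solids[thep.region_index(f"layer{i}")].volume
            for i in (1, 2, 3)]
    assert vols[0] == pytest.approx(vols[1]) == pytest.approx(vols[2])


def test_total_volume_decomposition():
    # skin shell volume + 3 equal layers = full outer semicylinder
    cfg = PhantomConfig(thickness=4.0)
    m = build_thep(cfg)
    outer = m.solids[m.region_index("skin")].volume
    layers = sum(m.solids[m.region_index(f"layer{i}")].volume
                 for i in (1, 2, 3))
    interior = 0.5 * np.pi * cfg.radius ** 2 * (cfg.thickness - 2 * cfg.skin)
    assert layers == pytest.approx(interior, rel=1e-12)
    skin_vol = outer - interior
    assert skin_vol > 0
    assert outer == pytest.approx(
        0.5 * np.pi * (cfg.radius + cfg.skin) ** 2 * cfg.thickness, rel=1e-12)


def test_homogeneous_phantom_layers_share_material():
    m = build_thep(PhantomConfig(thickness=5.0, gfs=(0.5, 0.5, 0.5)))
    mats = [m.materials[m.region_index(f"layer{i}")] for i in (1, 2, 3)]
    assert mats[0] == mats[1] == mats[2]


def test_layer1_is_source_side(thep):
    # layer 1 must sit above layer 3 (source shines from +z)
    z1 = thep.solids[thep.region_index("layer1")].z0
    z3 = thep.solids[thep.region_index("layer3")].z0
    assert z1 > z3
    assert thep.materials[thep.region_index("layer1")].glandular_fraction \
        == 0.25


def test_phantom_config_validation():
    with pytest.raises(ValueError):
        PhantomConfig(thickness=0.7, skin=0.4)   # skin layers meet
    with pytest.raises(ValueError):
        PhantomConfig(thickness=4.0, gfs=(0.5, 1.2, 0.5))


# ------------------------------------------------------------ reference case

def test_tg195_interior_material_is_20pct_mixture():
    m = build_tg195_case3()
    mat = m.materials[m.region_index("interior")]
    assert mat == breast_tissue(0.20)
    assert mat.density == pytest.approx(0.9498, abs=2e-4)


def test_tg195_source_to_paddle_distance():
    m = build_tg195_case3()
    paddle = m.solids[m.region_index("paddle_top")]
    assert m.source.position[2] - paddle.hi[2] == pytest.approx(59.3)


def test_tg195_paddle_volume():
    m = build_tg195_case3()
    assert m.solids[m.region_index("paddle_top")].volume == pytest.approx(
        26 * 14 * 0.2)


# ------------------------------------------------------------ kerma setup

def test_kerma_chamber_volume_and_emptiness():
    m = build_kerma_setup(phantom=PhantomConfig(thickness=4.0))
    chamber = m.meta["chamber"]
    assert chamber.volume == pytest.approx(np.pi * 1.45 ** 2 * 0.2)
    assert all(n in ("chamber", "world") for n in m.names)


def test_kerma_chamber_entrance_placement_height():
    for t in (3.0, 6.0, 9.0):
        m = build_kerma_setup(phantom=PhantomConfig(thickness=t),
                              placement="entrance")
        assert m.meta["chamber"].z1 == pytest.approx(PHANTOM_LIFT_CM + t)


def test_kerma_chamber_centre_placement_height():
    m = build_kerma_setup(phantom=PhantomConfig(thickness=4.0))
    ch = m.meta["chamber"]
    assert (ch.z0 + ch.z1) / 2 == pytest.approx(PHANTOM_LIFT_CM + 2.0)


# ------------------------------------------------------------ locate / rays

def test_locate_examples(thep):
    assert thep.names[thep.locate(np.array([0.0, 4.0, 3.2]))] == "layer2"
    assert thep.locate(np.array([0.0, 0.0, 1000.0])) == -1
    assert thep.names[thep.locate(np.array([0.0, -5.0, 3.0]))] == "torso"
    assert thep.names[thep.locate(np.array([0.0, 4.0, 30.0]))] == "world"


def test_locate_region_volumes_by_monte_carlo(thep):
    rng = np.random.default_rng(7)
    n = 150_000
    lo, hi = np.array([-10, -1.0, 0.0]), np.array([10, 10.0, 6.0])
    pts = rng.uniform(lo, hi, size=(n, 3))
    box_vol = np.prod(hi - lo)
    reg = thep.locate(pts)
    for name in ("layer1", "layer2", "layer3"):
        i = thep.region_index(name)
        p_hat = (reg == i).mean()
        vol = thep.solids[i].volume
        sigma = np.sqrt(p_hat * (1 - p_hat) / n) * box_vol
        assert abs(p_hat * box_vol - vol) < 3 * sigma


def test_axial_ray_through_slab(thep):
    # vertical ray entering the phantom top travels skin -> layers -> skin
    d, nxt = thep.distance_to_boundary([0.0, 4.0, 30.0], [0.0, 0.0, -1.0])
    assert d == pytest.approx(30.0 - 5.2, abs=1e-9)
    assert thep.names[nxt] == "skin"


def test_chord_through_centre_equals_radius(thep):
    # from the chest-wall face through the semicircle centre
    d, nxt = thep.distance_to_boundary([0.0, 1e-9, 3.2], [0.0, 1.0, 0.0])
    assert d == pytest.approx(8.5, abs=1e-6)
    assert thep.names[nxt] == "skin"


def test_ray_telescoping_and_locate_consistency(thep):
    rng = np.random.default_rng(11)
    for _ in range(25):
        p = np.array([rng.uniform(-6, 6), rng.uniform(0.5, 6.0), 30.0])
        d = np.array([rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3), -1.0])
        d /= np.linalg.norm(d)
        # world chord along this ray
        t0, t1 = thep.world.interval(p[None, :], d[None, :])
        chord = float(t1[0])
        total = 0.0
        pos = p.copy()
        for _ in range(60):
            step, nxt = thep.distance_to_boundary(pos, d)
            if not np.isfinite(step):
                break
            # stepping past the boundary lands in the reported region
            landed = thep.locate(pos + (step + 1e-6) * d)
            assert landed == nxt
            total += step
            pos = pos + step * d
            if nxt == -1:
                break
        assert total == pytest.approx(chord, abs=1e-7)


# ------------------------------------------------------------ GF triplets

@pytest.mark.parametrize("triplet,label", [
    ((0.75, 0.50, 0.25), "superior"),
    ((0.25, 0.50, 0.75), "inferior"),
    ((0.50, 0.50, 0.50), "uniform"),
    ((0.50, 0.75, 0.25), "concentrated-upper"),
    ((0.25, 0.75, 0.50), "concentrated-lower"),
    ((0.75, 0.25, 0.50), "other"),
])
def test_classify_distribution(triplet, label):
    assert classify_distribution(*triplet) == label


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.sampled_from(DISTRIBUTION_GRID), st.floats(0.5, 1.3))
def test_classification_depends_only_on_rank_order(triplet, scale):
    scaled = tuple(min(g * scale, 1.0) for g in triplet)
    if len(set(np.sign(np.diff(triplet)))) == \
            len(set(np.sign(np.diff(scaled)))) and scale * max(triplet) <= 1:
        assert classify_distribution(*triplet) == \
            classify_distribution(*scaled)


def test_mean_glandular_fraction_examples():
    assert mean_glandular_fraction(0.25, 0.50, 0.75) == pytest.approx(0.50)
    assert mean_glandular_fraction(0.25, 0.25, 0.25) == pytest.approx(0.25)


def test_triplet_grid_combinatorics():
    assert len(DISTRIBUTION_GRID) == 27
    mgf_half = [t for t in DISTRIBUTION_GRID
                if mean_glandular_fraction(*t) == pytest.approx(0.5)]
    assert len(mgf_half) == 7
    for mgf in (0.25, 0.50, 0.75):
        uniform = [t for t in DISTRIBUTION_GRID
                   if classify_distribution(*t) == "uniform"
                   and mean_glandular_fraction(*t) == pytest.approx(mgf)]
        assert len(uniform) == 1
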