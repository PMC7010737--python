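"""Mean glandular dose, air kerma and the DgN coefficient.

MGD divides the G-weighted energy deposited in the three phantom layers by
the total glandular mass of those layers:

    MGD = sum_i Gi(E) * Ei / sum_i (V * rho_i * fg_i)

with G applied per deposition event at the photon energy at the moment of
interaction (accumulated during transport).  Skin glandularity is excluded
(fg_skin = 0).  Air kerma is estimated free-in-air with a track-length
estimator in a pancake chamber whose upper face lies in the phantom entrance
plane, and cross-checked against a deterministic bin-sum.  Both MGD and K
are "per photon emitted into the collimated field", so DgN = MGD/K is a
scale-free mGy/mGy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KEV_PER_G_TO_MGY
from .geometry import (GeometryModel, PhantomConfig, SourceConfig,
                       build_kerma_setup, build_thep)
from .materials import air_muen, breast_tissue, mass_attenuation, DRY_AIR
from .spectrum import Spectrum
from .transport import PhysicsOptions, TallyResult, run_histories

__all__ = [
    "DoseResult", "compute_mgd", "simulate_air_kerma", "analytic_air_kerma",
    "compute_dgn", "relative_difference", "glandular_mass", "simulate_mgd",
    "dgn_for_condition",
]

_LAYERS = ("layer1", "layer2", "layer3")


@dataclass(frozen=True)
class DoseResult:
    """One simulated condition: MGD, air kerma and their ratio DgN.

    MGD and kerma are mGy per photon emitted into the field; DgN is the
    dimensionless mGy/mGy ratio; CVs are batch-statistics fractions.
    """

    mgd: float
    kerma: float
    dgn: float
    cv_mgd: float
    cv_kerma: float

    @property
    def cv_dgn(self) -> float:
        return float(np.hypot(self.cv_mgd, self.cv_kerma))


def glandular_mass(phantom: PhantomConfig) -> float:
    """Total glandular mass (g) of the three layers."""
    v = 0.5 * np.pi * phantom.radius ** 2 * phantom.layer_height
    return float(sum(v * breast_tissue(g).density * g for g in phantom.gfs))


def compute_mgd(tally: TallyResult, phantom: PhantomConfig
                ) -> tuple[float, float]:
    """MGD (mGy per emitted photon) and its CV from a phantom tally."""
    mass = glandular_mass(phantom)
    if mass <= 0:
        raise ZeroDivisionError(
            "phantom has no glandular mass (all layer fractions zero)")
    num_kev = sum(tally.total(l, weighted=True) for l in _LAYERS)
    mgd = num_kev / tally.histories / mass * KEV_PER_G_TO_MGY
    sums = sum(tally.batch_means(l, weighted=True) for l in _LAYERS)
    cv = float(sums.std(ddof=0) / np.sqrt(tally.batches) / sums.mean()) \
        if sums.mean() > 0 else np.nan
    return mgd, cv


def simulate_mgd(phantom: PhantomConfig, spectrum: Spectrum, n: int,
                 seed: int, source: SourceConfig | None = None,
                 physics: PhysicsOptions | None = None,
                 **kw) -> tuple[float, float, TallyResult]:
    """Build the phantom arrangement, run ``n`` histories, return
    (MGD, CV, tally)."""
    model = build_thep(phantom, source=source)
    tally = run_histories(model, spectrum, n, seed, physics=physics, **kw)
    mgd, cv = compute_mgd(tally, phantom)
    return mgd, cv, tally


def simulate_air_kerma(model: GeometryModel, spectrum: Spectrum, n: int,
                       seed: int, physics: PhysicsOptions | None = None,
                       **kw) -> tuple[float, float, TallyResult]:
    """Track-length air kerma in the chamber region of a kerma arrangement.

    Returns (kerma mGy per emitted photon, CV, tally).
    """
    chamber = model.meta.get("chamber")
    if chamber is None:
        raise ValueError("model has no chamber (use build_kerma_setup)")
    tally = run_histories(model, spectrum, n, seed, physics=physics,
                          kerma_region="chamber", **kw)
    if tally.kerma_sum.sum() == 0:
        raise RuntimeError("no photon tracks crossed the chamber")
    k = tally.kerma_per_photon(chamber.volume) * KEV_PER_G_TO_MGY
    return k, tally.kerma_cv(), tally


def analytic_air_kerma(spectrum: Spectrum, distance: float,
                       solid_angle: float | None = None,
                       air_path: bool = False) -> float:
    """Deterministic air kerma at ``distance`` from the point source.

    Per-photon fluence is ``1/(solid_angle * distance^2)`` (or ``1/d^2``
    for a unit-fluence-at-1-cm convention when no solid angle is given);
    ``air_path`` additionally attenuates the primary beam by the air column.
    Returns mGy per emitted photon.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    p = spectrum.normalized()
    e = spectrum.energies
    w = p * e * air_muen(e)
    if air_path:
        mu_air = mass_attenuation(DRY_AIR, e) * DRY_AIR.density
        w = w * np.exp(-mu_air * distance)
    omega = solid_angle if solid_angle is not None else 1.0
    return float(w.sum() / (omega * distance ** 2) * KEV_PER_G_TO_MGY)


def compute_dgn(mgd: float, kerma: float, cv_mgd: float = 0.0,
                cv_kerma: float = 0.0) -> DoseResult:
    """DgN = MGD / K with propagated CV."""
    if kerma <= 0:
        raise ZeroDivisionError("air kerma must be positive")
    return DoseResult(mgd, kerma, mgd / kerma, cv_mgd, cv_kerma)


def relative_difference(dgn: float, dgn_uniform: float) -> float:
    """Percent difference of a DgN against the uniform-distribution DgN."""
    if dgn_uniform <= 0:
        raise ZeroDivisionError("reference DgN must be positive")
    return 100.0 * (dgn - dgn_uniform) / dgn_uniform


def dgn_for_condition(phantom: PhantomConfig, spectrum: Spectrum,
                      n_mgd: int, n_kerma: int, seed: int,
                      kerma_result: tuple[float, float] | None = None,
                      source: SourceConfig | None = None,
                      **kw) -> DoseResult:
    """Full pipeline for one condition; ``kerma_result`` may be passed to
    share one kerma run across GF triplets of the same beam/thickness."""
    mgd, cv_m, _ = simulate_mgd(phantom, spectrum, n_mgd, seed,
                                source=source, **kw)
    if kerma_result is None:
        kmodel = build_kerma_setup(source=source, phantom=phantom)
        k, cv_k, _ = simulate_air_kerma(kmodel, spectrum, n_kerma, seed + 1,
                                        **kw)
    else:
        k, cv_k = kerma_result
    return compute_dgn(mgd, k, cv_m, cv_k)
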