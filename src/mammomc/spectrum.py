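"""X-ray spectra: providers, filtration, half-value layer and HVL calibration.

Beams in this package are specified by (kVp, filter material, target HVL in
mm Al), the quantities a mammography physicist actually measures.  The
tungsten-anode provider is a semi-empirical Kramers-type model with W
L-fluorescence lines and a fixed inherent Al-equivalent filtration; because
every simulated beam is re-anchored to its published HVL by solving for the
filter thickness, residual provider-shape differences are second order.

The HVL uses the mammography-QC convention: the Al thickness that halves the
air kerma of the narrow beam, with kerma weighting by the NIST dry-air
muen/rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .constants import (CUTOFF_KEV, INHERENT_AL_UM, W_L_LINES,
                        WSPEC_ENDPOINT_EXP, WSPEC_LINE_STRENGTH,
                        WSPEC_SOFTENING_EXP)
from .materials import Material, air_muen, filter_material, mass_attenuation

__all__ = [
    "Spectrum", "BeamQuality", "generate_spectrum", "monoenergetic",
    "tungsten_spectrum", "read_spectrum", "write_spectrum", "apply_filter",
    "compute_hvl", "calibrate_filter_to_hvl", "sample_energy",
    "spectrum_for_beam",
]

BIN_WIDTH_KEV = 0.25


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon spectrum: bin-centre energies and relative fluence."""

    energies: np.ndarray = field(hash=False)
    fluence: np.ndarray = field(hash=False)
    kvp: float | None = None
    anode: str | None = None
    filters: tuple = ()

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        if e.ndim != 1 or e.shape != f.shape or e.size == 0:
            raise ValueError("energies and fluence must be equal 1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin energies must be strictly increasing")
        if np.any(f < 0) or not np.any(f > 0):
            raise ValueError("fluence must be >= 0 with at least one "
                             "populated bin")
        if self.kvp is not None and np.any(e[f > 0] > self.kvp + 1e-9):
            raise ValueError("populated bins above the tube voltage")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)

    @property
    def mean_energy(self) -> float:
        return float(np.average(self.energies, weights=self.fluence))

    def normalized(self) -> np.ndarray:
        return self.fluence / self.fluence.sum()


@dataclass(frozen=True)
class BeamQuality:
    """A clinical beam: tube voltage, target-filter label and HVL."""

    kvp: float
    target_filter: str       # e.g. "W/Al"
    filter_um: float
    hvl_mm_al: float

    def __post_init__(self):
        if self.hvl_mm_al <= 0:
            raise ValueError("HVL must be positive")
        if not 22.0 <= self.kvp <= 36.0:
            raise ValueError("tube voltage outside the mammography range "
                             "22-36 kVp")


# --------------------------------------------------------------------------
# providers
# --------------------------------------------------------------------------

def monoenergetic(energy: float) -> Spectrum:
    """Single-line spectrum at ``energy`` keV."""
    return Spectrum(np.array([energy]), np.array([1.0]), kvp=energy,
                    anode="mono")


def tungsten_spectrum(kvp: float, bin_width: float = BIN_WIDTH_KEV,
                      inherent_al_um: float = INHERENT_AL_UM) -> Spectrum:
    """Semi-empirical tungsten tube spectrum.

    Generalized-Kramers bremsstrahlung ``(kVp/E - 1)^c * E^-a`` on a uniform
    grid from the 5 keV transport cutoff to kVp, plus the W L-fluorescence
    lines.  The two shape exponents were fitted once to a published
    mammography filter-thickness vs HVL grid, so the shape already absorbs
    inherent filtration and target self-absorption.
    """
    if not 22.0 <= kvp <= 36.0:
        raise ValueError("tube voltage outside the mammography range")
    edges = np.arange(CUTOFF_KEV, kvp + bin_width / 2, bin_width)
    centres = (edges[:-1] + edges[1:]) / 2 if edges.size > 1 else edges
    fl = (np.clip(kvp / centres - 1.0, 0.0, None) ** WSPEC_ENDPOINT_EXP
          * centres ** -WSPEC_SOFTENING_EXP)
    # L lines: fixed strength relative to the local bremsstrahlung level
    brems_at_10 = np.interp(10.0, centres, fl)
    for e_line, strength in W_L_LINES:
        i = int(np.argmin(np.abs(centres - e_line)))
        fl[i] += WSPEC_LINE_STRENGTH * strength * brems_at_10
    spec = Spectrum(centres, fl, kvp=kvp, anode="W")
    if inherent_al_um > 0:
        spec = apply_filter(spec, filter_material("Al"), inherent_al_um)
        spec = replace(spec, filters=())
    return spec


_PROVIDERS = {"tungsten": tungsten_spectrum, "kramers": tungsten_spectrum}


def generate_spectrum(kvp: float, anode: str = "W",
                      model: str = "tungsten") -> Spectrum:
    """Unfiltered anode spectrum from a named provider (deterministic)."""
    if anode != "W":
        raise ValueError(f"unsupported anode {anode!r}; only W is modelled")
    try:
        provider = _PROVIDERS[model]
    except KeyError:
        raise ValueError(f"unknown spectrum provider {model!r}") from None
    return provider(kvp)


def read_spectrum(path) -> Spectrum:
    """Two-column whitespace text (energy_keV, relative_fluence); '#' comments."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 2:
        raise ValueError("spectrum file must have two columns")
    order = np.argsort(data[:, 0])
    e, f = data[order, 0], data[order, 1]
    return Spectrum(e, f, kvp=float(e.max()))


def write_spectrum(spectrum: Spectrum, path) -> None:
    header = (f"energy_keV relative_fluence\n"
              f"kVp={spectrum.kvp} anode={spectrum.anode} "
              f"filters={list(spectrum.filters)}")
    np.savetxt(path, np.column_stack([spectrum.energies, spectrum.fluence]),
               header=header, fmt="%.6g")


# --------------------------------------------------------------------------
# filtration and beam quality
# --------------------------------------------------------------------------

def apply_filter(spectrum: Spectrum, material: Material,
                 thickness_um: float) -> Spectrum:
    """Attenuate by ``exp(-mu/rho * rho * t)`` and record the filter."""
    if thickness_um < 0:
        raise ValueError("filter thickness must be >= 0")
    if thickness_um == 0:
        return spectrum
    t_cm = thickness_um * 1e-4
    mu = mass_attenuation(material, spectrum.energies) * material.density
    return replace(spectrum, fluence=spectrum.fluence * np.exp(-mu * t_cm),
                   filters=spectrum.filters
                   + ((material.name, thickness_um),))


def _kerma_vs_al(spectrum: Spectrum, t_mm: float) -> float:
    e = spectrum.energies
    mu_al = mass_attenuation(_AL, e) * _AL.density
    w = spectrum.fluence * e * air_muen(e)
    return float(np.sum(w * np.exp(-mu_al * t_mm / 10.0)))


_AL = filter_material("Al")


def compute_hvl(spectrum: Spectrum) -> float:
    """First half-value layer in mm Al (air-kerma weighted, narrow beam)."""
    k0 = _kerma_vs_al(spectrum, 0.0)
    if k0 <= 0:
        raise ValueError("spectrum carries no air kerma")
    f = lambda t: _kerma_vs_al(spectrum, t) / k0 - 0.5
    if f(5.0) > 0:
        raise RuntimeError("HVL exceeds 5 mm Al; no bracket")
    return float(brentq(f, 0.0, 5.0, xtol=1e-7))


def calibrate_filter_to_hvl(spectrum: Spectrum, material: Material,
                            target_hvl_mm: float,
                            max_um: float = 2000.0) -> float:
    """Filter thickness (micron) giving the target HVL, by root finding."""
    lo = compute_hvl(spectrum)
    hi = compute_hvl(apply_filter(spectrum, material, max_um))
    if not lo - 1e-3 <= target_hvl_mm <= hi + 1e-3:
        raise ValueError(
            f"target HVL {target_hvl_mm} mm Al unreachable with "
            f"{material.name}: achievable range [{lo:.3f}, {hi:.3f}] mm")
    if target_hvl_mm <= lo:
        return 0.0
    f = lambda t: compute_hvl(apply_filter(spectrum, material, t)) \
        - target_hvl_mm
    return float(brentq(f, 0.0, max_um, xtol=1e-2))


def spectrum_for_beam(kvp: float, filter_symbol: str, target_hvl_mm: float
                      ) -> tuple[Spectrum, BeamQuality]:
    """HVL-anchored clinical beam: provider spectrum + solved filtration."""
    base = tungsten_spectrum(kvp)
    mat = filter_material(filter_symbol)
    t_um = calibrate_filter_to_hvl(base, mat, target_hvl_mm)
    spec = apply_filter(base, mat, t_um)
    return spec, BeamQuality(kvp, f"W/{filter_symbol}", t_um, target_hvl_mm)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def sample_energy(spectrum: Spectrum, rng: np.random.Generator,
                  size: int | None = None):
    """Inverse-CDF sampling over bins, uniform within each bin."""
    n = 1 if size is None else int(size)
    p = spectrum.normalized()
    idx = rng.choice(p.size, size=n, p=p)
    e = spectrum.energies
    if e.size > 1:
        width = np.empty_like(e)
        width[:-1] = np.diff(e)
        width[-1] = width[-2]
        out = e[idx] + (rng.random(n) - 0.5) * width[idx]
    else:
        out = np.full(n, e[0])
    return float(out[0]) if size is None else out
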