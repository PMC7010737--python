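"""Materials, photon coefficient tables and the glandular dose G factor.

Breast tissue is modelled as a two-component glandular/adipose mixture in the
Hammerstein tradition: a glandular mass fraction ``gf`` mixes the two endpoint
tissues element-wise by mass, and densities combine reciprocally
(``1/rho = gf/rho_g + (1-gf)/rho_a``).  The endpoint compositions are recovered
by linear unmixing of the printed 25% and 75% mixture rows, which keeps the
package self-consistent with its reference composition table.

Photon interaction coefficients come from the bundled element tables
(``data/xcom_photon.csv``): total mass attenuation, mass energy-absorption and
the photoelectric / incoherent / coherent partition, log-log interpolated.
Mixtures use the standard mass-weighted mixture rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (DATA_DIR, ELEMENTS, ENERGY_MAX_KEV, ENERGY_MIN_KEV,
                        DRY_AIR_DEF, ICRU44_SOFT_TISSUE_DEF, PMMA_DEF,
                        SKIN_DEF, TABLE_BREAST, FILTER_DENSITY)

__all__ = [
    "Material", "CoefficientTable", "coefficient_table",
    "mix_breast_tissue", "derive_endpoints",
    "mass_attenuation", "mass_energy_absorption", "g_factor",
    "GLANDULAR", "ADIPOSE", "SKIN", "DRY_AIR", "ICRU44_SOFT_TISSUE", "PMMA",
    "breast_tissue", "filter_material", "save_registry", "load_registry",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

def _validate_composition(composition: Mapping[str, float]) -> dict:
    comp = {el: float(w) for el, w in composition.items()}
    for el, w in comp.items():
        if el not in ELEMENTS:
            raise ValueError(f"unknown element {el!r}")
        if w < 0:
            raise ValueError(f"negative mass fraction for {el}: {w}")
    total = sum(comp.values())
    # the reference skin row sums to 0.993 as printed (trace elements are
    # omitted from the source table), so allow a 1% shortfall
    if not 0.99 <= total <= 1.005:
        raise ValueError(f"mass fractions sum to {total:.4f}, not ~1")
    return comp


@dataclass(frozen=True)
class Material:
    """A named elemental mixture with a density.

    ``composition`` maps element symbols to mass fractions (sum ~ 1; printed
    reference values are rounded to 0.1% so a 0.5% slack is allowed).
    ``glandular_fraction`` marks breast mixtures so dose tallies know the
    glandular mass share of the material.
    """

    name: str
    density: float
    composition: Mapping[str, float] = field(hash=False)
    glandular_fraction: float | None = None

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        object.__setattr__(self, "composition",
                           _validate_composition(self.composition))

    def to_dict(self) -> dict:
        d = {"name": self.name, "density_g_cm3": self.density,
             "composition": dict(self.composition)}
        if self.glandular_fraction is not None:
            d["glandular_fraction"] = self.glandular_fraction
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Material":
        return cls(d["name"], d["density_g_cm3"], d["composition"],
                   d.get("glandular_fraction"))


class CoefficientTable:
    """Per-element photon coefficients over 1-50 keV, log-log interpolated.

    Columns: total mass attenuation ``mu_rho``, mass energy-absorption
    ``muen_rho`` and the partial cross sections ``pe``/``incoh``/``coh``
    (all cm^2/g).
    """

    COLUMNS = ("mu_rho", "muen_rho", "pe", "incoh", "coh")

    def __init__(self, frame: pd.DataFrame):
        self._log: dict[str, dict[str, np.ndarray]] = {}
        for el, grp in frame.groupby("element"):
            grp = grp.sort_values("energy_keV")
            e = grp["energy_keV"].to_numpy(float)
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"energies not strictly increasing for {el}")
            entry = {"loge": np.log(e)}
            for col in self.COLUMNS:
                v = grp[col].to_numpy(float)
                if np.any(v <= 0):
                    raise ValueError(f"non-positive {col} for {el}")
                entry[col] = np.log(v)
            self._log[el] = entry

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._log)

    def lookup(self, element: str, energy, column: str = "mu_rho"):
        """Coefficient (cm^2/g) for one element; scalar or array energy."""
        e = np.asarray(energy, dtype=float)
        if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
            raise ValueError(
                f"energy outside tabulated range "
                f"[{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
        entry = self._log[element]
        out = np.exp(np.interp(np.log(e), entry["loge"], entry[column]))
        return float(out) if np.isscalar(energy) else out

    def mixture(self, material: Material, energy, column: str = "mu_rho"):
        """Mass-weighted mixture rule over the material's elements.

        Compositions are renormalized to unit sum so that rows printed
        without their trace elements still yield physical coefficients.
        """
        e = np.asarray(energy, dtype=float)
        out = np.zeros_like(e)
        total = sum(material.composition.values())
        for el, w in material.composition.items():
            out = out + (w / total) * self.lookup(el, e, column)
        return float(out) if np.isscalar(energy) else out

    def save_csv(self, path) -> None:
        rows = []
        for el, entry in self._log.items():
            e = np.exp(entry["loge"])
            cols = {c: np.exp(entry[c]) for c in self.COLUMNS}
            for i, ev in enumerate(e):
                rows.append([el, ev] + [cols[c][i] for c in self.COLUMNS])
        pd.DataFrame(rows, columns=["element", "energy_keV", *self.COLUMNS]
                     ).to_csv(path, index=False, float_format="%.6g")


@lru_cache(maxsize=1)
def coefficient_table() -> CoefficientTable:
    """The bundled coefficient table (cached)."""
    return CoefficientTable(pd.read_csv(DATA_DIR / "xcom_photon.csv"))


@lru_cache(maxsize=1)
def air_muen_table() -> tuple[np.ndarray, np.ndarray]:
    """Directly tabulated NIST dry-air muen/rho (log energy, log value)."""
    t = pd.read_csv(DATA_DIR / "air_muen.csv").sort_values("energy_keV")
    return (np.log(t["energy_keV"].to_numpy(float)),
            np.log(t["muen_rho"].to_numpy(float)))


def air_muen(energy):
    """NIST dry-air mass energy-absorption coefficient, cm^2/g.

    Carried as a direct table (rather than the element mixture rule) because
    air kerma weighting is first-order for both the half-value layer and DgN.
    """
    loge, logv = air_muen_table()
    e = np.asarray(energy, dtype=float)
    out = np.exp(np.interp(np.log(e), loge, logv))
    return float(out) if np.isscalar(energy) else out


# --------------------------------------------------------------------------
# breast-tissue mixing
# --------------------------------------------------------------------------

def mix_breast_tissue(gf: float, glandular: "Material | None" = None,
                      adipose: "Material | None" = None) -> Material:
    """Breast tissue with glandular mass fraction ``gf``.

    Compositions mix element-wise by mass; densities combine reciprocally:
    ``1/rho = gf/rho_g + (1-gf)/rho_a``.
    """
    if not 0.0 <= gf <= 1.0:
        raise ValueError(f"glandular fraction must be in [0, 1], got {gf}")
    g = GLANDULAR if glandular is None else glandular
    a = ADIPOSE if adipose is None else adipose
    els = sorted(set(g.composition) | set(a.composition))
    comp = {el: gf * g.composition.get(el, 0.0)
            + (1 - gf) * a.composition.get(el, 0.0) for el in els}
    density = 1.0 / (gf / g.density + (1 - gf) / a.density)
    return Material(f"breast {100 * gf:g}% glandular", density, comp,
                    glandular_fraction=gf)


def derive_endpoints(row25: Material, row75: Material
                     ) -> tuple[Material, Material]:
    """Recover the pure glandular/adipose endpoints from the 25%/75% rows.

    Solves the 2x2 linear mixing system: glandular = (3*row75 - row25)/2 and
    adipose = (3*row25 - row75)/2, element-wise on compositions and on
    reciprocal densities.
    """
    els = sorted(set(row25.composition) | set(row75.composition))
    comp_g, comp_a = {}, {}
    for el in els:
        w25 = row25.composition.get(el, 0.0)
        w75 = row75.composition.get(el, 0.0)
        comp_g[el] = (3 * w75 - w25) / 2
        comp_a[el] = (3 * w25 - w75) / 2
        if comp_g[el] < -1e-9 or comp_a[el] < -1e-9:
            raise ValueError(
                f"inconsistent mixture rows: negative {el} fraction")
    inv_g = (3 / row75.density - 1 / row25.density) / 2
    inv_a = (3 / row25.density - 1 / row75.density) / 2
    if inv_g <= 0 or inv_a <= 0:
        raise ValueError("inconsistent mixture rows: negative density")
    gland = Material("glandular tissue", 1 / inv_g, comp_g,
                     glandular_fraction=1.0)
    adip = Material("adipose tissue", 1 / inv_a, comp_a,
                    glandular_fraction=0.0)
    return gland, adip


# --------------------------------------------------------------------------
# coefficient lookups
# --------------------------------------------------------------------------

def mass_attenuation(material: Material, energy):
    """Total mass attenuation coefficient mu/rho of a mixture, cm^2/g."""
    return coefficient_table().mixture(material, energy, "mu_rho")


def mass_energy_absorption(material: Material, energy):
    """Mass energy-absorption coefficient muen/rho of a mixture, cm^2/g."""
    return coefficient_table().mixture(material, energy, "muen_rho")


def g_factor(fg: float, energy):
    """Glandular energy-absorption share G(E) of a breast mixture.

    ``G = fg*(muen/rho)_g / [fg*(muen/rho)_g + (1-fg)*(muen/rho)_a]``
    with the coefficients of the pure glandular and adipose endpoints.
    """
    if not 0.0 <= fg <= 1.0:
        raise ValueError(f"glandular fraction must be in [0, 1], got {fg}")
    mg = mass_energy_absorption(GLANDULAR, energy)
    ma = mass_energy_absorption(ADIPOSE, energy)
    num = fg * np.asarray(mg, dtype=float)
    out = num / (num + (1 - fg) * np.asarray(ma, dtype=float))
    return float(out) if np.isscalar(energy) else out


# --------------------------------------------------------------------------
# reference materials
# --------------------------------------------------------------------------

def _table_material(gf: float) -> Material:
    row = TABLE_BREAST[gf]
    return Material(f"breast {100 * gf:g}% glandular (reference)",
                    row["density"], row["composition"],
                    glandular_fraction=gf)


BREAST_25 = _table_material(0.25)
BREAST_50 = _table_material(0.50)
BREAST_75 = _table_material(0.75)
GLANDULAR, ADIPOSE = derive_endpoints(BREAST_25, BREAST_75)
SKIN = Material("skin", SKIN_DEF["density"], SKIN_DEF["composition"])
DRY_AIR = Material("dry air", DRY_AIR_DEF["density"],
                   DRY_AIR_DEF["composition"])
ICRU44_SOFT_TISSUE = Material("ICRU-44 soft tissue",
                              ICRU44_SOFT_TISSUE_DEF["density"],
                              ICRU44_SOFT_TISSUE_DEF["composition"])
PMMA = Material("PMMA", PMMA_DEF["density"], PMMA_DEF["composition"])


def breast_tissue(gf: float) -> Material:
    """Breast mixture at glandular mass fraction ``gf`` (endpoint-mixed)."""
    return mix_breast_tissue(gf)


def filter_material(symbol: str) -> Material:
    """Elemental beam-filter material (Al, Rh or Ag)."""
    if symbol not in FILTER_DENSITY:
        raise ValueError(f"unsupported filter material {symbol!r}")
    return Material(symbol, FILTER_DENSITY[symbol], {symbol: 1.0})


def save_registry(materials, path) -> None:
    """Write a list of materials to a JSON registry file."""
    Path(path).write_text(json.dumps([m.to_dict() for m in materials],
                                     indent=2))


def load_registry(path) -> list[Material]:
    return [Material.from_dict(d) for d in json.loads(Path(path).read_text())]
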