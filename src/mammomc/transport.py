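"""Analog Monte Carlo photon transport.

Histories are traced in vectorized batches: each photon samples its energy
from the beam spectrum and its direction isotropically within the collimated
solid angle (rejection from the bounding cone, so every accepted history is
"one photon emitted into the field" — the normalization of all per-photon
results).  Free flight uses exponential path lengths against the local linear
attenuation; boundaries are exact ray-surface intersections.  Interactions:

* photoelectric — the photon energy deposits locally (K fluorescence of the
  tissue elements is sub-cutoff) and the history ends;
* incoherent — Klein-Nishina via Kahn's rejection method; the electron
  energy deposits locally; an optional incoherent-scattering-function
  correction S(x) can be enabled (off by default: the free-electron variant
  is the reference-case convention);
* coherent — Thomson angular law modulated by the material's
  independent-atom form factor, no energy transfer.

Photons falling below the 5 keV cutoff deposit their remaining energy on the
spot.  Tallies per region record deposited energy and G-weighted deposited
energy (G evaluated at the photon energy at the moment of interaction), in
equal batches for coefficient-of-variation estimates.  A track-length
estimator can accumulate air kerma in a designated region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .constants import (CUTOFF_KEV, DATA_DIR, DEFAULT_BATCHES, ELEMENTS,
                        ENERGY_MAX_KEV, ENERGY_MIN_KEV, HC_KEV_ANGSTROM,
                        MEC2_KEV, SURFACE_EPS)
from .geometry import GeometryModel
from .materials import Material, air_muen, coefficient_table, g_factor
from .spectrum import Spectrum, sample_energy

__all__ = [
    "PhysicsOptions", "TallyResult", "run_histories", "estimate_cv",
    "sample_interaction", "sample_compton", "sample_coherent",
    "INTERACTIONS",
]

INTERACTIONS = ("photoelectric", "incoherent", "coherent")

_EGRID = np.linspace(ENERGY_MIN_KEV, ENERGY_MAX_KEV, 2451)
_EGRID_STEP = float(_EGRID[1] - _EGRID[0])


@dataclass(frozen=True)
class PhysicsOptions:
    """Transport physics switches.

    ``incoherent_binding`` enables the S(x) incoherent-scattering-function
    rejection on Compton angles (off by default; introduces a small forward
    suppression).  The disable flags zero entire interaction channels, which
    is useful for narrow-beam/Beer-Lambert verification.
    """

    cutoff_kev: float = CUTOFF_KEV
    incoherent_binding: bool = False
    disable_incoherent: bool = False
    disable_coherent: bool = False


# --------------------------------------------------------------------------
# tallies
# --------------------------------------------------------------------------

@dataclass
class TallyResult:
    """Per-region deposited and G-weighted energy sums in equal batches."""

    region_names: tuple
    edep: np.ndarray            # (batches, nregions) keV
    edep_g: np.ndarray          # (batches, nregions) keV
    escaped: np.ndarray         # (batches,) keV
    emitted: np.ndarray         # (batches,) keV
    kerma_sum: np.ndarray       # (batches,) keV*cm^3/g (track-length)
    histories_per_batch: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def histories(self) -> int:
        return int(self.histories_per_batch.sum())

    @property
    def batches(self) -> int:
        return len(self.histories_per_batch)

    def index(self, region: str) -> int:
        return self.region_names.index(region)

    def total(self, region: str, weighted: bool = False) -> float:
        arr = self.edep_g if weighted else self.edep
        return float(arr[:, self.index(region)].sum())

    def per_photon(self, region: str, weighted: bool = False) -> float:
        """Mean deposited energy (keV) per photon emitted into the field."""
        return self.total(region, weighted) / self.histories

    def batch_means(self, region: str, weighted: bool = False) -> np.ndarray:
        arr = self.edep_g if weighted else self.edep
        return arr[:, self.index(region)] / self.histories_per_batch

    def kerma_per_photon(self, chamber_volume_cm3: float) -> float:
        """Track-length air kerma per emitted photon, keV/g."""
        return float(self.kerma_sum.sum()
                     / (chamber_volume_cm3 * self.histories))

    def kerma_cv(self) -> float:
        m = self.kerma_sum / self.histories_per_batch
        if m.mean() == 0:
            return np.nan
        return float(m.std(ddof=0) / np.sqrt(len(m)) / m.mean())


def estimate_cv(tally: TallyResult, region: str,
                weighted: bool = False) -> float:
    """Batch standard error over batch mean for a region's deposited energy."""
    if tally.batches < 2:
        raise ValueError("CV undefined with fewer than 2 batches")
    m = tally.batch_means(region, weighted)
    mean = m.mean()
    if mean == 0:
        raise ValueError(f"no energy deposited in region {region!r}")
    return float(m.std(ddof=0) / np.sqrt(tally.batches) / mean)


# --------------------------------------------------------------------------
# physics sampling
# --------------------------------------------------------------------------

def sample_compton(energy, rng: np.random.Generator, size: int | None = None):
    """Sample Klein-Nishina scattering: returns (E', cos theta).

    Kahn's composition-rejection method on x = E/E'.
    """
    E = np.full(size or 1, energy, dtype=float) if np.isscalar(energy) \
        else np.asarray(energy, dtype=float)
    k = E / MEC2_KEV
    x = np.empty_like(E)
    todo = np.arange(E.size)
    while todo.size:
        kk = k[todo]
        r1, r2, r3 = rng.random((3, todo.size))
        case1 = r1 <= (1 + 2 * kk) / (9 + 2 * kk)
        xx = np.where(case1, 1 + 2 * kk * r2, (1 + 2 * kk) / (1 + 2 * kk * r2))
        mu = 1 - (xx - 1) / kk
        acc = np.where(case1, r3 <= 4 * (1 / xx - 1 / xx ** 2),
                       r3 <= 0.5 * (mu * mu + 1 / xx))
        x[todo[acc]] = xx[acc]
        todo = todo[~acc]
    eprime = E / x
    costh = 1 - (x - 1) / k
    if np.isscalar(energy) and size is None:
        return float(eprime[0]), float(costh[0])
    return eprime, costh


@lru_cache(maxsize=1)
def _form_factor_frame() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "form_factors.csv")


class _CoherentSampler:
    """Inverse-CDF sampling of x^2 from the material's F^2, with the
    (1+cos^2)/2 Thomson rejection."""

    def __init__(self, material: Material):
        frame = _form_factor_frame()
        xs = np.sort(frame["x_A_inv"].unique())
        f2 = np.zeros_like(xs)
        s = np.zeros_like(xs)
        total_w = sum(material.composition.values())
        for el, w in material.composition.items():
            sub = frame[frame["element"] == el].sort_values("x_A_inv")
            fe = np.interp(xs, sub["x_A_inv"], sub["F"])
            se = np.interp(xs, sub["x_A_inv"], sub["S"])
            f2 += (w / total_w) / ELEMENTS[el][1] * fe ** 2
            s += (w / total_w) / ELEMENTS[el][1] * se
        self.x2 = xs ** 2
        self.cum = np.concatenate(
            [[0.0], np.cumsum(np.diff(self.x2) * (f2[1:] + f2[:-1]) / 2)])
        self._s_x = xs
        self._s = s

    def sample(self, energy: np.ndarray, rng: np.random.Generator
               ) -> np.ndarray:
        lam2 = (HC_KEV_ANGSTROM / energy) ** 2
        amax = np.interp(1.0 / lam2, self.x2, self.cum)
        mu = np.empty_like(energy)
        todo = np.arange(energy.size)
        while todo.size:
            u = rng.random(todo.size) * amax[todo]
            x2 = np.interp(u, self.cum, self.x2)
            m = 1.0 - 2.0 * x2 * lam2[todo]
            acc = rng.random(todo.size) <= 0.5 * (1 + m * m)
            mu[todo[acc]] = m[acc]
            todo = todo[~acc]
        return mu

    def s_of_x(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self._s_x, self._s)


def sample_coherent(energy, material: Material, rng: np.random.Generator,
                    size: int | None = None):
    """Sample a coherent-scattering polar angle cosine (elastic)."""
    E = np.full(size or 1, energy, dtype=float) if np.isscalar(energy) \
        else np.asarray(energy, dtype=float)
    mu = _CoherentSampler(material).sample(E, rng)
    if np.isscalar(energy) and size is None:
        return float(mu[0])
    return mu


def sample_interaction(material: Material, energy, rng: np.random.Generator,
                       size: int | None = None,
                       physics: PhysicsOptions = PhysicsOptions()):
    """Draw interaction types with probabilities from the partial cross
    sections at this energy."""
    tab = coefficient_table()
    pe = tab.mixture(material, energy, "pe")
    inc = 0.0 if physics.disable_incoherent else \
        tab.mixture(material, energy, "incoh")
    coh = 0.0 if physics.disable_coherent else \
        tab.mixture(material, energy, "coh")
    p = np.array([pe, inc, coh]) / (pe + inc + coh)
    idx = rng.choice(3, size=size, p=p)
    if size is None:
        return INTERACTIONS[int(idx)]
    return np.array(INTERACTIONS)[idx]


def _rotate(d: np.ndarray, costh: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle about themselves, azimuth phi."""
    sinth = np.sqrt(np.clip(1.0 - costh ** 2, 0.0, None))
    # orthonormal frame avoiding the polar singularity
    use_x = np.abs(d[:, 2]) > 0.9
    helper = np.where(use_x[:, None],
                      np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (costh[:, None] * d
           + sinth[:, None] * (np.cos(phi)[:, None] * u
                               + np.sin(phi)[:, None] * v))
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


# --------------------------------------------------------------------------
# per-model lookup tables
# --------------------------------------------------------------------------

class _RegionTables:
    """Fine-grid linear attenuation, branch fractions and G factors per
    region of a geometry model."""

    def __init__(self, model: GeometryModel, physics: PhysicsOptions):
        tab = coefficient_table()
        nreg = len(model.regions)
        ne = _EGRID.size
        self.mu = np.zeros((nreg, ne))
        self.cum_pe = np.ones((nreg, ne))
        self.cum_inc = np.ones((nreg, ne))
        self.g = np.zeros((nreg, ne))
        self.sampler_idx = np.full(nreg, -1, dtype=np.int64)
        self.samplers: list[_CoherentSampler] = []
        cache: dict[str, int] = {}
        for i, mat in enumerate(model.materials):
            if mat is None:
                continue  # vacuum
            pe = tab.mixture(mat, _EGRID, "pe")
            inc = np.zeros(ne) if physics.disable_incoherent else \
                tab.mixture(mat, _EGRID, "incoh")
            coh = np.zeros(ne) if physics.disable_coherent else \
                tab.mixture(mat, _EGRID, "coh")
            tot = pe + inc + coh
            self.mu[i] = tot * mat.density
            self.cum_pe[i] = pe / tot
            self.cum_inc[i] = (pe + inc) / tot
            fg = mat.glandular_fraction
            if fg:
                self.g[i] = g_factor(fg, _EGRID)
            if mat.name not in cache:
                cache[mat.name] = len(self.samplers)
                self.samplers.append(_CoherentSampler(mat))
            self.sampler_idx[i] = cache[mat.name]
        self.muen_air = air_muen(np.clip(_EGRID, 5.0, None))

    @staticmethod
    def _locate_e(E: np.ndarray):
        f = (E - ENERGY_MIN_KEV) / _EGRID_STEP
        i = np.clip(f.astype(np.int64), 0, _EGRID.size - 2)
        return i, f - i

    def lookup(self, arr2d: np.ndarray, reg: np.ndarray, E: np.ndarray):
        i, w = self._locate_e(E)
        a = arr2d[reg, i]
        b = arr2d[reg, i + 1]
        return a * (1 - w) + b * w

    def muen_air_at(self, E: np.ndarray) -> np.ndarray:
        i, w = self._locate_e(E)
        return self.muen_air[i] * (1 - w) + self.muen_air[i + 1] * w


# --------------------------------------------------------------------------
# source emission
# --------------------------------------------------------------------------

def _emit_directions(model: GeometryModel, rng: np.random.Generator,
                     n: int) -> np.ndarray:
    """Isotropic directions restricted to the collimated field (rejection
    from the bounding cone; accepted count defines 'emitted into field')."""
    src = model.source
    sp = np.asarray(src.position, dtype=float)
    x0, x1, y0, y1 = src.field_rect
    zf = src.field_z
    centre = np.array([(x0 + x1) / 2, (y0 + y1) / 2, zf])
    axis = centre - sp
    axis /= np.linalg.norm(axis)
    corners = np.array([[x0, y0, zf], [x0, y1, zf], [x1, y0, zf],
                        [x1, y1, zf]])
    cd = corners - sp
    cd /= np.linalg.norm(cd, axis=1, keepdims=True)
    cosmax = float(np.min(cd @ axis))
    # frame around the axis
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[2]) > 0.9 \
        else np.array([0.0, 0.0, 1.0])
    u = np.cross(helper, axis)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = int((n - got) * 2.5) + 64
        mu = 1.0 - rng.random(m) * (1.0 - cosmax)
        phi = rng.random(m) * 2 * np.pi
        st = np.sqrt(1.0 - mu ** 2)
        d = (mu[:, None] * axis
             + st[:, None] * (np.cos(phi)[:, None] * u
                              + np.sin(phi)[:, None] * v))
        dz = d[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (zf - sp[2]) / dz
        px = sp[0] + t * d[:, 0]
        py = sp[1] + t * d[:, 1]
        ok = ((dz < 0) & (t > 0) & (px >= x0) & (px <= x1)
              & (py >= y0) & (py <= y1))
        take = min(int(ok.sum()), n - got)
        out[got:got + take] = d[ok][:take]
        got += take
    return out


# --------------------------------------------------------------------------
# the kernel
# --------------------------------------------------------------------------

def run_histories(model: GeometryModel, spectrum: Spectrum, n: int,
                  seed: int, physics: PhysicsOptions | None = None,
                  batches: int = DEFAULT_BATCHES, chunk: int = 200_000,
                  kerma_region: str | None = None,
                  max_steps: int = 100_000) -> TallyResult:
    """Trace ``n`` photon histories through ``model``; reproducible for a
    given ``seed``."""
    if n < 1:
        raise ValueError("need at least one history")
    physics = physics or PhysicsOptions()
    tables = _RegionTables(model, physics)
    nreg = len(model.regions)
    batches = min(batches, n)
    nb = np.full(batches, n // batches)
    nb[:n % batches] += 1
    edep = np.zeros((batches, nreg))
    edep_g = np.zeros((batches, nreg))
    escaped = np.zeros(batches)
    emitted = np.zeros(batches)
    kerma = np.zeros(batches)
    k_idx = model.region_index(kerma_region) if kerma_region else -1

    for b in range(batches):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        left = int(nb[b])
        while left > 0:
            m = min(chunk, left)
            left -= m
            res = _simulate_chunk(model, tables, spectrum, rng, m, physics,
                                  k_idx, max_steps)
            edep[b] += res[0]
            edep_g[b] += res[1]
            escaped[b] += res[2]
            emitted[b] += res[3]
            kerma[b] += res[4]

    return TallyResult(model.names, edep, edep_g, escaped, emitted, kerma,
                       nb, meta={"seed": seed, "physics": physics,
                                 "kerma_region": kerma_region})


def _simulate_chunk(model, tables, spectrum, rng, m, physics, k_idx,
                    max_steps):
    nreg = len(model.regions)
    edep = np.zeros(nreg)
    edep_g = np.zeros(nreg)
    escaped = 0.0
    kerma = 0.0

    pos = np.tile(np.asarray(model.source.position, dtype=float), (m, 1))
    dirs = _emit_directions(model, rng, m)
    E = np.asarray(sample_energy(spectrum, rng, size=m), dtype=float)
    emitted = float(E.sum())
    reg = model.locate(pos)
    cutoff = physics.cutoff_kev

    def deposit(regions, amounts, energies):
        np.add.at(edep, regions, amounts)
        g = tables.lookup(tables.g, regions, energies)
        np.add.at(edep_g, regions, g * amounts)

    for _ in range(max_steps):
        if E.size == 0:
            break
        mu = tables.lookup(tables.mu, reg, E)
        tb = model.min_crossing(pos, dirs)
        with np.errstate(divide="ignore"):
            s = -np.log(rng.random(E.size)) / mu
        cross = s >= tb
        # kerma track-length tally (path in the chamber up to the event)
        if k_idx >= 0:
            inch = reg == k_idx
            if inch.any():
                seg = np.where(cross, tb, s)[inch]
                kerma += float(np.sum(E[inch] * seg
                                      * tables.muen_air_at(E[inch])))
        step = np.where(cross, tb + SURFACE_EPS, s)
        pos += dirs * step[:, None]

        # boundary crossings: relocate, drop escapes
        if cross.any():
            new_reg = model.locate(pos[cross])
            reg[cross] = new_reg
            gone = cross.copy()
            gone[cross] = new_reg == -1
            if gone.any():
                escaped += float(E[gone].sum())
        else:
            gone = np.zeros(E.size, dtype=bool)

        # interactions
        inter = ~cross
        if inter.any():
            ii = np.flatnonzero(inter)
            u = rng.random(ii.size)
            p_pe = tables.lookup(tables.cum_pe, reg[ii], E[ii])
            p_inc = tables.lookup(tables.cum_inc, reg[ii], E[ii])
            pe_m = u <= p_pe
            inc_m = (~pe_m) & (u <= p_inc)
            coh_m = ~(pe_m | inc_m)

            if pe_m.any():
                sel = ii[pe_m]
                deposit(reg[sel], E[sel], E[sel])
                gone[sel] = True

            if inc_m.any():
                sel = ii[inc_m]
                eprime, costh = sample_compton(E[sel], rng)
                if physics.incoherent_binding:
                    # S(x) rejection: resample rejected angles
                    samp_of = tables.sampler_idx[reg[sel]]
                    todo = np.arange(sel.size)
                    while todo.size:
                        lam = HC_KEV_ANGSTROM / E[sel[todo]]
                        x = np.sqrt((1 - costh[todo]) / 2) / lam
                        sv = np.empty(todo.size)
                        sm = np.empty(todo.size)
                        for si in np.unique(samp_of[todo]):
                            msk = samp_of[todo] == si
                            sv[msk] = tables.samplers[si].s_of_x(x[msk])
                            sm[msk] = tables.samplers[si].s_of_x(
                                1.0 / lam[msk])
                        rej = rng.random(todo.size) > sv / sm
                        if rej.any():
                            ep2, ct2 = sample_compton(E[sel[todo[rej]]], rng)
                            eprime[todo[rej]] = ep2
                            costh[todo[rej]] = ct2
                        todo = todo[rej]
                deposit(reg[sel], E[sel] - eprime, E[sel])
                dirs[sel] = _rotate(dirs[sel], costh,
                                    rng.random(sel.size) * 2 * np.pi)
                E[sel] = eprime
                low = sel[eprime < cutoff]
                if low.size:
                    deposit(reg[low], E[low], E[low])
                    gone[low] = True

            if coh_m.any():
                sel = ii[coh_m]
                sidx = tables.sampler_idx[reg[sel]]
                costh = np.empty(sel.size)
                for si in np.unique(sidx):
                    msk = sidx == si
                    costh[msk] = tables.samplers[si].sample(E[sel][msk], rng)
                dirs[sel] = _rotate(dirs[sel], costh,
                                    rng.random(sel.size) * 2 * np.pi)

        keep = ~gone
        if not keep.all():
            pos, dirs, E, reg = pos[keep], dirs[keep], E[keep], reg[keep]
    else:
        # safety: terminate stragglers as escapes
        escaped += float(E.sum())

    return edep, edep_g, escaped, emitted, kerma
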