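"""Condition grids and DgN result tables.

A run grid is the cross product (kVp x beam x thickness x GF triplet); one
air-kerma run is shared by all triplets of a (beam, thickness) cell.  Results
aggregate into a DgN table that round-trips losslessly through CSV or JSON
with a provenance block (code version, master seed, history budgets, solved
filter thicknesses).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .dosimetry import (DoseResult, compute_dgn, relative_difference,
                        simulate_air_kerma, simulate_mgd)
from .geometry import (PhantomConfig, build_kerma_setup,
                       classify_distribution, mean_glandular_fraction)
from .spectrum import spectrum_for_beam

__all__ = ["RunGrid", "DgNRecord", "DgNTable", "run_grid",
           "summarize_vs_uniform", "write_table", "read_table"]

_COLUMNS = ["kvp", "target_filter", "hvl_mm_al", "thickness_cm",
            "g1", "g2", "g3", "distribution", "mgf",
            "mgd", "kerma", "dgn", "cv_mgd", "cv_kerma", "cv_dgn"]


@dataclass(frozen=True)
class RunGrid:
    """Simulation grid: beams are (kVp, filter symbol, target HVL mm Al)."""

    beams: tuple                 # ((kvp, "Al", 0.423), ...)
    thicknesses: tuple           # cm
    triplets: tuple              # ((g1, g2, g3), ...)
    histories: int = 2_000_000
    kerma_histories: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if not (self.beams and self.thicknesses and self.triplets):
            raise ValueError("grid dimensions must be non-empty")


@dataclass(frozen=True)
class DgNRecord:
    kvp: float
    target_filter: str
    hvl_mm_al: float
    thickness_cm: float
    triplet: tuple[float, float, float]
    distribution: str
    mgf: float
    dose: DoseResult

    def as_row(self) -> dict:
        g1, g2, g3 = self.triplet
        return {"kvp": float(self.kvp), "target_filter": self.target_filter,
                "hvl_mm_al": float(self.hvl_mm_al),
                "thickness_cm": float(self.thickness_cm),
                "g1": float(g1), "g2": float(g2), "g3": float(g3),
                "distribution": self.distribution, "mgf": self.mgf,
                "mgd": self.dose.mgd, "kerma": self.dose.kerma,
                "dgn": self.dose.dgn, "cv_mgd": self.dose.cv_mgd,
                "cv_kerma": self.dose.cv_kerma, "cv_dgn": self.dose.cv_dgn}


@dataclass
class DgNTable:
    records: list[DgNRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.records],
                            columns=_COLUMNS)

    def __len__(self) -> int:
        return len(self.records)

    def find(self, **keys) -> list[DgNRecord]:
        out = []
        for r in self.records:
            row = r.as_row()
            if all(np.isclose(row[k], v) if isinstance(v, float)
                   else row[k] == v for k, v in keys.items()):
                out.append(r)
        return out


def run_grid(grid: RunGrid, progress=None) -> DgNTable:
    """Simulate every cell; one kerma run per (beam, thickness)."""
    table = DgNTable(provenance={
        "code_version": _version, "seed": grid.seed,
        "histories": grid.histories,
        "kerma_histories": grid.kerma_histories,
        "solved_filters_um": {},
    })
    n_cells = len(grid.beams) * len(grid.thicknesses)
    seeds = np.random.SeedSequence(grid.seed).generate_state(
        n_cells * (len(grid.triplets) + 1)).astype(np.int64) % (2 ** 31)
    s = 0
    for kvp, fsym, hvl in grid.beams:
        spec, quality = spectrum_for_beam(kvp, fsym, hvl)
        table.provenance["solved_filters_um"][
            f"{kvp:g}W/{fsym}@{hvl:g}"] = round(quality.filter_um, 1)
        for t in grid.thicknesses:
            phantom0 = PhantomConfig(thickness=t)
            kmodel = build_kerma_setup(phantom=phantom0)
            try:
                kerma, cv_k, _ = simulate_air_kerma(
                    kmodel, spec, grid.kerma_histories, int(seeds[s]))
            except Exception as exc:  # failed cell: record and continue
                table.failures.append({"beam": quality.target_filter,
                                       "thickness": t, "error": str(exc)})
                s += 1 + len(grid.triplets)
                continue
            s += 1
            for trip in grid.triplets:
                try:
                    phantom = PhantomConfig(thickness=t, gfs=tuple(trip))
                    mgd, cv_m, _ = simulate_mgd(
                        phantom, spec, grid.histories, int(seeds[s]))
                    dose = compute_dgn(mgd, kerma, cv_m, cv_k)
                    table.records.append(DgNRecord(
                        kvp, quality.target_filter, hvl, t, tuple(trip),
                        classify_distribution(*trip),
                        mean_glandular_fraction(*trip), dose))
                except Exception as exc:
                    table.failures.append({"beam": quality.target_filter,
                                           "thickness": t,
                                           "triplet": tuple(trip),
                                           "error": str(exc)})
                s += 1
                if progress is not None:
                    progress(table)
    return table


def summarize_vs_uniform(table: DgNTable) -> pd.DataFrame:
    """Relative difference of every record against the uniform record of
    the same (beam, thickness, MGF), plus the min/max DgN of that group."""
    rows = []
    frame = table.to_frame()
    for (kvp, tf, hvl, t, mgf), grp in frame.groupby(
            ["kvp", "target_filter", "hvl_mm_al", "thickness_cm", "mgf"]):
        uni = grp[grp.distribution == "uniform"]
        if uni.empty:
            raise ValueError(
                f"no uniform reference for {tf} {t} cm MGF {mgf}")
        ref = float(uni.dgn.iloc[0])
        for _, row in grp.iterrows():
            rows.append({
                "kvp": kvp, "target_filter": tf, "hvl_mm_al": hvl,
                "thickness_cm": t, "mgf": mgf,
                "distribution": row.distribution,
                "g1": row.g1, "g2": row.g2, "g3": row.g3,
                "dgn": row.dgn,
                "diff_vs_uniform_pct": relative_difference(row.dgn, ref),
                "group_min_dgn": float(grp.dgn.min()),
                "group_max_dgn": float(grp.dgn.max()),
            })
    return pd.DataFrame(rows)


def write_table(table: DgNTable, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "csv")
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write("# mammomc DgN table v1 "
                     + json.dumps(table.provenance, sort_keys=True) + "\n")
            table.to_frame().to_csv(fh, index=False)
    elif fmt == "json":
        payload = {"provenance": table.provenance,
                   "records": [r.as_row() for r in table.records]}
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _record_from_row(row: dict, line_no: int | None = None) -> DgNRecord:
    try:
        dose = DoseResult(float(row["mgd"]), float(row["kerma"]),
                          float(row["dgn"]), float(row["cv_mgd"]),
                          float(row["cv_kerma"]))
        return DgNRecord(float(row["kvp"]), str(row["target_filter"]),
                         float(row["hvl_mm_al"]), float(row["thickness_cm"]),
                         (float(row["g1"]), float(row["g2"]),
                          float(row["g3"])),
                         str(row["distribution"]), float(row["mgf"]), dose)
    except (KeyError, ValueError, TypeError) as exc:
        where = f" (line {line_no})" if line_no else ""
        raise ValueError(f"malformed DgN table row{where}: {exc}") from exc


def read_table(path) -> DgNTable:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return DgNTable([_record_from_row(r) for r in payload["records"]],
                        payload.get("provenance", {}))
    with open(path) as fh:
        first = fh.readline()
        provenance = {}
        if first.startswith("# mammomc DgN table"):
            provenance = json.loads(first.split("v1", 1)[1])
            header_line = 1
        else:
            fh.seek(0)
            header_line = 0
        frame = pd.read_csv(fh, dtype=str)
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"DgN table missing columns: {sorted(missing)}")
    records = [_record_from_row(row, line_no=header_line + 2 + i)
               for i, row in frame.iterrows()]
    return DgNTable(records, provenance)
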