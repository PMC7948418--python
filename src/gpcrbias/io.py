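"""File formats and study configuration.

All tables are long-format ("tidy") CSV, UTF-8, decimal point:

* kinetic plate table: ``time_min, well, channel, signal``
* endpoint plate table: ``well, signal``
* plate map: ``well, receptor, ligand, conc_M, condition, block``
* response table: ``ligand, pathway, concentration_M, block, response``
* intensity table: ``well, receptor, ligand, mesna, intensity, block``

Emitted files begin with a ``#`` comment line embedding the package version,
the seed, and the configuration hash, so every output is traceable to the
run that produced it; readers skip ``#`` lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assaysim import PlateDesign, Well
from .traces import KineticTrace

log = logging.getLogger("gpcrbias")

__all__ = [
    "StudyConfig",
    "read_plate_table",
    "read_plate_map",
    "read_response_table",
    "read_intensity_table",
    "annotate_traces",
    "write_plate_table",
    "write_plate_map",
    "write_table",
]


@dataclass
class StudyConfig:
    """Configuration of one pipeline run (JSON on disk)."""

    assay_type: str  # nanobit | bret | deret | fret_pka | htrf_endpoint | intensity_table | simulate_bias
    plate_table: str | None = None
    plate_map: str | None = None
    response_table: str | None = None
    intensity_table: str | None = None
    reference_ligand: str | None = None
    reference_pathway: str = "cAMP"
    comparator_pathway: str | None = None
    reference_receptor: str | None = None
    n_params: int = 4
    n_hill: float | None = None  # fix the operational transducer slope, or None
    baseline_end: float = 5.0
    seed: int = 0
    output_dir: str = "results"

    VALID = ("nanobit", "bret", "deret", "fret_pka", "htrf_endpoint",
             "intensity_table", "simulate_bias")

    def __post_init__(self):
        if self.assay_type not in self.VALID:
            raise ValueError(f"unknown assay_type {self.assay_type!r}")

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha(self) -> str:
        """Hash of the analytic configuration (the output location is not
        part of what was computed, so it is excluded)."""
        d = self.to_dict()
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def meta_line(self) -> str:
        return f"# gpcrbias v{__version__} seed={self.seed} config_sha={self.sha()}"


def _read_csv(path, required: set[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name} {path}: missing columns {sorted(missing)}")
    return df


def read_plate_table(path, baseline_end: float = 0.0):
    """Read a plate table; kinetic files yield traces, endpoint files a frame.

    Kinetic CSVs (``time_min, well, channel, signal``) are validated for
    strictly increasing per-well time, duplicate (well, time, channel) rows
    (rejected with the offending row number), numeric signals, and a channel
    set consistent across wells; they return a list of KineticTrace.
    Endpoint CSVs (``well, signal``) return a DataFrame.
    """
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if {"time_min", "well", "channel", "signal"} <= cols:
        bad = df[pd.to_numeric(df["signal"], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric signal at row {bad.index[0] + 2}")
        df["signal"] = df["signal"].astype(float)
        dup = df.duplicated(["well", "time_min", "channel"])
        if dup.any():
            raise ValueError(
                f"{path}: duplicate (well, time, channel) at row {df.index[dup][0] + 2}"
            )
        channel_sets = df.groupby("well")["channel"].agg(lambda s: tuple(sorted(set(s))))
        if channel_sets.nunique() != 1:
            raise ValueError(f"{path}: channel set differs across wells")
        traces = []
        for well, grp in df.groupby("well", sort=False):
            times = np.sort(grp["time_min"].unique())
            channels = {}
            for ch, cgrp in grp.groupby("channel", sort=False):
                cgrp = cgrp.sort_values("time_min")
                if len(cgrp) != len(times):
                    raise ValueError(f"{path}: well {well!r} channel {ch!r} "
                                     "has missing time points")
                channels[str(ch)] = cgrp["signal"].to_numpy(float)
            traces.append(KineticTrace(well_id=str(well), times=times,
                                       channels=channels, baseline_end=baseline_end))
        return traces
    if {"well", "signal"} <= cols:
        return df
    raise ValueError(f"{path}: unrecognized plate-table header {sorted(cols)}")


def read_plate_map(path) -> PlateDesign:
    """Read a plate map CSV into a PlateDesign; conc 0 marks vehicle wells."""
    df = _read_csv(path, {"well", "receptor", "ligand", "conc_M", "condition", "block"},
                   "plate map")
    if (df["conc_M"].astype(float) < 0).any():
        raise ValueError(f"{path}: negative concentration")
    wells = []
    for _, r in df.iterrows():
        conc = float(r["conc_M"])
        ligand = "vehicle" if conc == 0 else str(r["ligand"])
        cond = "" if pd.isna(r["condition"]) else str(r["condition"])
        wells.append(Well(str(r["well"]), str(r["receptor"]), ligand, conc,
                          cond, str(r["block"])))
    return PlateDesign(tuple(wells))


def read_response_table(path) -> pd.DataFrame:
    return _read_csv(path, {"ligand", "pathway", "concentration_M", "block", "response"},
                     "response table")


def read_intensity_table(path) -> pd.DataFrame:
    df = _read_csv(path, {"well", "receptor", "ligand", "mesna", "intensity", "block"},
                   "intensity table")
    if df["mesna"].dtype != bool:
        df["mesna"] = df["mesna"].astype(str).str.lower().isin(("true", "1", "yes"))
    return df


def annotate_traces(traces: list[KineticTrace], design: PlateDesign) -> list[KineticTrace]:
    """Attach plate-map annotations; unmapped wells are excluded with a warning."""
    by_id = {w.well_id: w for w in design.wells}
    out = []
    for tr in traces:
        w = by_id.get(tr.well_id)
        if w is None:
            log.warning("well %r not in plate map: excluded", tr.well_id)
            continue
        tr.receptor = w.receptor
        tr.ligand = w.ligand
        tr.concentration = w.concentration
        tr.is_vehicle = w.is_vehicle
        tr.block_id = w.block_id
        out.append(tr)
    return out


def _write_with_meta(df: pd.DataFrame, path, meta: str | None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta:
            fh.write(meta + "\n")
        df.to_csv(fh, index=False)


def write_table(df: pd.DataFrame, path, meta: str | None = None):
    """Write a tidy CSV with an optional leading ``#`` metadata line."""
    _write_with_meta(df, path, meta)


def write_plate_table(traces: list[KineticTrace], path, meta: str | None = None):
    rows = []
    for tr in traces:
        for ch, sig in tr.channels.items():
            for t, s in zip(tr.times, sig):
                rows.append((float(t), tr.well_id, ch, float(s)))
    df = pd.DataFrame(rows, columns=["time_min", "well", "channel", "signal"])
    _write_with_meta(df, path, meta)


def write_plate_map(design: PlateDesign, path, meta: str | None = None):
    _write_with_meta(design.to_frame(), path, meta)
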