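"""Receptor surface-expression and internalization quantification.

Consumes per-well (or per-imaged-region) mean fluorescence intensities from
a cleavable-probe (Mesna) assay: surface receptors are labeled with a
cleavable SNAP probe, agonist drives internalization, and Mesna strips the
label from receptors still at the surface. Protected (internalized) receptor
is therefore the Mesna-resistant signal above the nonspecific floor measured
in Mesna-treated vehicle wells.

The fraction internalized is computed per replicate block as

    (S_mesna,ligand - S_mesna,vehicle) / (S_no-mesna - S_mesna,vehicle)

so a ligand that triggers no internalization scores exactly 0 and complete
protection scores exactly 1. (A raw-denominator mode, without background
subtraction of the denominator, is available via ``subtract_background=False``.)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("gpcrbias")

__all__ = [
    "quantify_internalization",
    "surface_expression",
    "receptor_response_heatmap",
]

_REQUIRED = {"well", "receptor", "ligand", "mesna", "intensity", "block"}


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    if (table["intensity"] < 0).any():
        raise ValueError("intensities must be >= 0")
    return table


def quantify_internalization(
    table: pd.DataFrame,
    subtract_background: bool = True,
) -> pd.DataFrame:
    """Per-receptor, per-ligand internalized fraction with block summaries.

    Returns a tidy frame with one row per (receptor, ligand) and columns
    ``fraction_mean``, ``fraction_sem``, ``n_blocks`` plus the per-block
    values in ``per_block`` (a list column). Blocks whose denominator is
    <= 0 are flagged and excluded with a log entry; a stratum without
    Mesna+vehicle wells is rejected.
    """
    _check_table(table)
    rows = []
    for (rec, block), grp in table.groupby(["receptor", "block"], sort=False):
        no_mesna = grp.loc[~grp["mesna"], "intensity"]
        mes_veh = grp.loc[grp["mesna"] & (grp["ligand"] == "vehicle"), "intensity"]
        if no_mesna.empty:
            raise ValueError(f"{rec}/{block}: no-Mesna wells missing")
        if mes_veh.empty:
            raise ValueError(f"{rec}/{block}: Mesna+vehicle wells missing")
        background = float(mes_veh.mean())
        for lig, lgrp in grp[grp["mesna"] & (grp["ligand"] != "vehicle")].groupby(
            "ligand", sort=False
        ):
            matched = grp.loc[~grp["mesna"] & (grp["ligand"] == lig), "intensity"]
            total = float(matched.mean()) if not matched.empty else float(no_mesna.mean())
            denom = (total - background) if subtract_background else total
            if denom <= 0:
                log.warning("%s/%s/%s: denominator %.3g <= 0, block excluded",
                            rec, block, lig, denom)
                continue
            frac = (float(lgrp["intensity"].mean()) - background) / denom
            rows.append((rec, lig, block, frac))
    if not rows:
        raise ValueError("no usable strata in intensity table")
    per_block = pd.DataFrame(rows, columns=["receptor", "ligand", "block", "fraction"])
    out = []
    for (rec, lig), grp in per_block.groupby(["receptor", "ligand"], sort=False):
        vals = grp["fraction"].to_numpy(float)
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        out.append((rec, lig, float(np.mean(vals)), sem, len(vals), list(vals)))
    return pd.DataFrame(out, columns=[
        "receptor", "ligand", "fraction_mean", "fraction_sem", "n_blocks", "per_block",
    ])


def surface_expression(
    table: pd.DataFrame,
    reference_receptor: str,
) -> pd.DataFrame:
    """Background-subtracted surface signal per receptor, relative to a reference.

    Surface signal is the mean no-Mesna intensity minus the nonspecific floor
    (Mesna+vehicle mean), computed within each block and expressed relative
    to the reference receptor in the same block.
    """
    _check_table(table)
    if reference_receptor not in set(table["receptor"]):
        raise ValueError(f"reference receptor {reference_receptor!r} absent")
    surf = {}
    for (rec, block), grp in table.groupby(["receptor", "block"], sort=False):
        no_mesna = grp.loc[~grp["mesna"] & (grp["ligand"] == "vehicle"), "intensity"]
        if no_mesna.empty:  # fall back to any no-Mesna well
            no_mesna = grp.loc[~grp["mesna"], "intensity"]
        mes_veh = grp.loc[grp["mesna"] & (grp["ligand"] == "vehicle"), "intensity"]
        if no_mesna.empty or mes_veh.empty:
            raise ValueError(f"{rec}/{block}: control wells missing")
        surf[(rec, block)] = float(no_mesna.mean()) - float(mes_veh.mean())
    rows = []
    for (rec, block), s in surf.items():
        ref = surf.get((reference_receptor, block))
        if ref is None or ref <= 0:
            log.warning("block %r: unusable reference surface signal, excluded", block)
            continue
        rows.append((rec, block, s / ref))
    per_block = pd.DataFrame(rows, columns=["receptor", "block", "relative_surface"])
    out = []
    for rec, grp in per_block.groupby("receptor", sort=False):
        vals = grp["relative_surface"].to_numpy(float)
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        out.append((rec, float(np.mean(vals)), sem, len(vals)))
    return pd.DataFrame(out, columns=["receptor", "surface_mean", "surface_sem", "n_blocks"])


def receptor_response_heatmap(
    responses: pd.DataFrame,
    reference_receptor: str,
    value_col: str = "value",
) -> pd.DataFrame:
    """log2 fold-change of per-receptor summary responses vs a reference.

    ``responses`` has columns receptor, readout, ``value_col``. Non-positive
    or missing responses cannot be expressed on a log scale and are flagged
    ``below_range`` (the heat-map 'X' convention) instead of producing a
    number. A non-positive reference value is an error.
    """
    need = {"receptor", "readout", value_col}
    if need - set(responses.columns):
        raise ValueError(f"responses table needs columns {sorted(need)}")
    rows = []
    for readout, grp in responses.groupby("readout", sort=False):
        ref = grp.loc[grp["receptor"] == reference_receptor, value_col]
        if ref.empty or not float(ref.iloc[0]) > 0:
            raise ValueError(f"readout {readout!r}: reference value missing or <= 0")
        refval = float(ref.iloc[0])
        for _, r in grp.iterrows():
            v = r[value_col]
            below = not (pd.notna(v) and v > 0)
            rows.append((
                r["receptor"], readout,
                float(np.log2(v / refval)) if not below else float("nan"),
                below,
            ))
    return pd.DataFrame(rows, columns=["receptor", "readout", "log2_fold", "below_range"])
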