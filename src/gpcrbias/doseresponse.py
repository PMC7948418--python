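"""Concentration-response construction and 3/4-parameter logistic fitting.

Fits are performed in log10-concentration space:

    E(A) = basal + (e_max - basal) / (1 + 10^(hill * (logEC50 - log10 A)))

The 3-parameter variant fixes the Hill slope at 1. When replicate blocks are
present each block is fitted separately and parameters are summarized as
mean +/- SEM across blocks (the convention used for plate-reader assays run
as randomized blocks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .traces import KineticTrace, trace_auc

log = logging.getLogger("gpcrbias")

__all__ = [
    "ConcentrationResponse",
    "LogisticFit",
    "logistic_curve",
    "fit_logistic",
    "summarize_fits",
    "auc_concentration_response",
]

HILL_BOUNDS = (0.1, 5.0)  # guards against pathological slopes on weak partials


@dataclass
class ConcentrationResponse:
    """(concentration, response) records for one ligand/pathway/assay."""

    ligand_id: str
    pathway_id: str
    data: pd.DataFrame  # columns: concentration_M, response, block

    def __post_init__(self):
        need = {"concentration_M", "response", "block"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.data["concentration_M"] < 0).any():
            raise ValueError("concentrations must be >= 0 (0 reserved for vehicle)")

    def nonzero(self) -> pd.DataFrame:
        return self.data[self.data["concentration_M"] > 0]

    @classmethod
    def from_study(cls, study: pd.DataFrame, ligand: str, pathway: str,
                   blocks=None) -> "ConcentrationResponse":
        sel = study[(study["ligand"] == ligand) & (study["pathway"] == pathway)]
        if blocks is not None:
            sel = sel[sel["block"].isin(blocks)]
        return cls(ligand, pathway,
                   sel[["concentration_M", "response", "block"]].reset_index(drop=True))


@dataclass
class LogisticFit:
    ligand_id: str
    pathway_id: str
    n_params: int
    basal: float
    e_max: float
    log_ec50: float
    hill: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    per_block: pd.DataFrame | None = None  # block, basal, e_max, log_ec50, hill
    summary: pd.DataFrame | None = None  # parameter, mean, sem, n_blocks

    def predict(self, conc):
        return logistic_curve(np.log10(np.asarray(conc, float)),
                              self.basal, self.e_max, self.log_ec50, self.hill)


def logistic_curve(log_conc, basal, e_max, log_ec50, hill):
    log_conc = np.asarray(log_conc, dtype=float)
    return basal + (e_max - basal) / (1.0 + 10.0 ** (hill * (log_ec50 - log_conc)))


def _logistic_jac(log_conc, basal, e_max, log_ec50, hill, with_hill):
    z = 10.0 ** (hill * (log_ec50 - log_conc))
    s = 1.0 / (1.0 + z)
    ds_dz = -(s ** 2)
    common = (e_max - basal) * ds_dz * z * np.log(10.0)
    cols = [1.0 - s, s, common * hill]
    if with_hill:
        cols.append(common * (log_ec50 - log_conc))
    return np.column_stack(cols)


def _fit_single(log_conc, y, n_params, basal_anchor=None):
    """Least-squares logistic fit on one set of points. Returns (params, flags)."""
    span = float(np.max(y) - np.min(y))
    scale = max(abs(float(np.max(y))), abs(float(np.min(y))), 1.0)
    flags = []
    if span <= 1e-8 * scale:
        # monotone-flat data: e_max unidentifiable
        p = dict(basal=float(np.mean(y)), e_max=float(np.mean(y)),
                 log_ec50=float(np.median(log_conc)), hill=1.0)
        return p, ["unidentifiable: flat response"], False

    b0 = float(np.min(y)) if basal_anchor is None else float(basal_anchor)
    e0 = float(np.max(y))
    # mid-range half-maximal crossing as logEC50 start
    half = (b0 + e0) / 2.0
    order = np.argsort(log_conc)
    lx, ly = log_conc[order], y[order]
    above = ly >= half
    x0 = float(lx[np.argmax(above)]) if above.any() else float(np.median(lx))

    lo_x, hi_x = float(np.min(log_conc)) - 3.0, float(np.max(log_conc)) + 3.0
    pad = 2.0 * span + 1e-9 * scale

    if n_params == 3:
        def resid(p):
            return logistic_curve(log_conc, p[0], p[1], p[2], 1.0) - y

        def jac(p):
            return _logistic_jac(log_conc, p[0], p[1], p[2], 1.0, with_hill=False)
        p0 = [b0, e0, x0]
        lb = [b0 - pad, b0 - pad, lo_x]
        ub = [e0 + pad, e0 + pad, hi_x]
    else:
        def resid(p):
            return logistic_curve(log_conc, p[0], p[1], p[2], p[3]) - y

        def jac(p):
            return _logistic_jac(log_conc, p[0], p[1], p[2], p[3], with_hill=True)
        p0 = [b0, e0, x0, 1.0]
        lb = [b0 - pad, b0 - pad, lo_x, HILL_BOUNDS[0]]
        ub = [e0 + pad, e0 + pad, hi_x, HILL_BOUNDS[1]]

    # one start from the data heuristics; multi-start only on failure
    best = None
    for x_start in (x0, float(np.median(log_conc)), float(np.min(log_conc)) + 1.0):
        p0[2] = min(max(x_start, lo_x), hi_x)
        try:
            res = optimize.least_squares(
                resid, p0, jac=jac, bounds=(lb, ub),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - scipy failure path
            flags.append(f"fit error: {exc}")
            continue
        if best is None or res.cost < best.cost:
            best = res
        # accept an interior converged optimum without further starts
        if res.status > 0 and lo_x + 0.5 < res.x[2] < hi_x - 0.5:
            break
    if best is None:
        p = dict(basal=b0, e_max=e0, log_ec50=x0, hill=1.0)
        return p, flags + ["non-convergence"], False

    p = best.x
    out = dict(basal=float(p[0]), e_max=float(p[1]), log_ec50=float(p[2]),
               hill=1.0 if n_params == 3 else float(p[3]))
    if abs(out["e_max"] - out["basal"]) <= 1e-6 * scale:
        flags.append("unidentifiable: e_max ~ basal")
    return out, flags, True


def fit_logistic(cr: ConcentrationResponse, n_params: int = 4) -> LogisticFit:
    """Fit the 3- or 4-parameter logistic to one concentration-response set.

    Vehicle rows (concentration 0) are excluded from the fit but, for the
    3-parameter model, anchor the basal initialization. Per-block fits and a
    mean +/- SEM summary are produced whenever more than one block is present.
    """
    if n_params not in (3, 4):
        raise ValueError("n_params must be 3 or 4")
    pts = cr.nonzero()
    n_distinct = pts["concentration_M"].nunique()
    if n_distinct < (4 if n_params == 3 else 5):
        raise ValueError(
            f"need >= {4 if n_params == 3 else 5} distinct concentrations, "
            f"got {n_distinct}"
        )
    if not np.isfinite(pts["response"]).all():
        raise ValueError("responses must be finite")

    vehicle = cr.data[cr.data["concentration_M"] == 0]
    anchor = float(vehicle["response"].mean()) if (n_params == 3 and len(vehicle)) else None

    log_conc = np.log10(pts["concentration_M"].to_numpy(float))
    y = pts["response"].to_numpy(float)
    pooled, flags, ok = _fit_single(log_conc, y, n_params, anchor)

    fit = LogisticFit(cr.ligand_id, cr.pathway_id, n_params, converged=ok,
                      flags=flags, **pooled)
    blocks = pts["block"].unique()
    if len(blocks) > 1:
        rows = []
        for b in blocks:
            sel = pts[pts["block"] == b]
            lc = np.log10(sel["concentration_M"].to_numpy(float))
            yy = sel["response"].to_numpy(float)
            pb, fl, okb = _fit_single(lc, yy, n_params, anchor)
            if not okb or any("unidentifiable" in f for f in fl):
                log.warning("block %r: %s", b, "; ".join(fl) or "fit failed")
            rows.append(dict(block=b, **pb))
        fit.per_block = pd.DataFrame(rows)
        fit.summary = summarize_fits(fit.per_block)
    return fit


def summarize_fits(per_block: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of each logistic parameter across replicate blocks."""
    params = [c for c in ("basal", "e_max", "log_ec50", "hill") if c in per_block]
    n = len(per_block)
    rows = []
    for p in params:
        vals = per_block[p].to_numpy(float)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append((p, float(np.mean(vals)), sem, n))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sem", "n_blocks"])


def auc_concentration_response(
    traces: list[KineticTrace],
    ligand_id: str,
    pathway_id: str,
) -> ConcentrationResponse:
    """Build a concentration-response set from kinetic traces via AUC.

    Each well's trace is normalized to its own baseline mean, integrated over
    the post-agonist window, and expressed as a fold of the mean vehicle AUC
    within its block (so vehicle wells map to ~1.0). Blocks lacking a vehicle
    trace are excluded with a log entry. The result feeds fit_logistic.
    """
    by_block: dict[str, list[KineticTrace]] = {}
    for tr in traces:
        by_block.setdefault(tr.block_id or "B1", []).append(tr)
    rows = []
    for block, trs in by_block.items():
        aucs = {}
        for tr in trs:
            b = tr.baseline_mean()
            if b <= 0:
                log.warning("well %r: baseline <= 0, skipped", tr.well_id)
                continue
            normed = KineticTrace(
                well_id=tr.well_id, times=tr.times,
                channels={"n": tr.single_channel() / b},
                concentration=tr.concentration, is_vehicle=tr.is_vehicle,
                block_id=tr.block_id, baseline_end=tr.baseline_end,
            )
            aucs[tr.well_id] = (tr, trace_auc(normed))
        veh = [a for tr, a in aucs.values() if tr.is_vehicle]
        if not veh:
            log.warning("block %r excluded: no vehicle trace", block)
            continue
        vmean = float(np.mean(veh))
        for tr, a in aucs.values():
            rows.append((tr.concentration, a / vmean, block))
    if not rows:
        raise ValueError("no usable blocks (vehicle traces missing?)")
    return ConcentrationResponse(
        ligand_id, pathway_id,
        pd.DataFrame(rows, columns=["concentration_M", "response", "block"]),
    )
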