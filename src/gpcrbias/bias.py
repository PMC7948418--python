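"""Operational-model fitting and DeltaDeltalog(tau/K_A) bias statistics.

Biased agonism between two pathways (here conventionally cAMP vs
beta-arrestin-2 recruitment) is quantified from transduction coefficients
tau/K_A estimated by globally fitting the Black-Leff operational model to all
ligands of one assay, with the system parameters (Em, transducer slope,
basal) shared across ligands. On a per-assay (block) basis each ligand's
log10(tau/K_A) is normalized to the reference endogenous ligand
(Deltalog(tau/K_A)) and then to the reference pathway
(DeltaDeltalog(tau/K_A)); positive values mean bias toward the reference
pathway. Significance is assessed from the 95% t-interval of the per-block
DeltaDelta values: bias is significant when the interval excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .doseresponse import ConcentrationResponse, _fit_single

log = logging.getLogger("gpcrbias")

__all__ = [
    "OperationalFit",
    "BiasResult",
    "fit_operational",
    "delta_log_r",
    "delta_delta_log_r",
    "bias_interval",
    "transduction_bias",
]

LOG_TAU_BOUNDS = (-5.0, 5.0)
LOG_KA_BOUNDS = (-14.0, -2.0)
N_HILL_BOUNDS = (0.3, 3.0)
WEAK_SPAN_FRACTION = 0.1  # fitted span below this fraction of Em-basal => weak partial


@dataclass
class OperationalFit:
    """Global operational-model fit for one pathway in one assay block."""

    pathway_id: str
    block_id: str
    Em: float
    n_hill: float
    basal: float
    ligands: pd.DataFrame  # ligand, log_tau, log_KA, log_R, se_log_R, weak_partial
    converged: bool
    cost: float
    message: str = ""

    def log_R(self, ligand: str) -> float:
        row = self.ligands.loc[self.ligands["ligand"] == ligand]
        if row.empty:
            raise KeyError(f"ligand {ligand!r} not in fit")
        return float(row["log_R"].iloc[0])


@dataclass
class BiasResult:
    """Per-ligand bias summary across blocks for one pathway pair."""

    ligand_id: str
    pathway_pair: tuple[str, str]  # (reference pathway, comparator)
    per_block: pd.DataFrame  # block, delta_delta
    mean: float
    sem: float
    ci95: tuple[float, float] | None
    bias_factor: float
    significant: bool | None
    is_reference: bool = False


def _op_eval_and_grads(logA, Em, basal, nh, lt, lk):
    """Operational-model value and partials for one ligand's points.

    Returns (E, dEm, dbasal, dlog_tau, dlog_KA, dn) for A = 10**logA > 0.
    """
    A = 10.0 ** logA
    tau = 10.0 ** lt
    KA = 10.0 ** lk
    u = (tau * A) ** nh
    v = (A + KA) ** nh
    w = u + v
    f = u / w
    span = Em - basal
    uv_w2 = u * v / (w * w)
    ln10 = np.log(10.0)
    dlt = span * nh * ln10 * uv_w2
    dlk = -span * nh * ln10 * uv_w2 * KA / (A + KA)
    dn = span * uv_w2 * np.log((tau * A) / (A + KA))
    return basal + span * f, f, 1.0 - f, dlt, dlk, dn


def _pack(theta, n_lig, fix_hill):
    """Unpack [Em, basal, (n_hill), (log_R, log_tau) per ligand].

    The fit is parameterized directly in log_R = log10(tau/K_A) (with
    log_KA = log_tau - log_R derived): for full agonists tau and K_A are
    individually near-degenerate while their ratio stays well identified, so
    fitting log_R keeps both the optimizer and the covariance of the
    quantity of interest well conditioned.
    """
    if fix_hill is None:
        Em, basal, n_hill = theta[0], theta[1], theta[2]
        per = theta[3:]
    else:
        Em, basal, n_hill = theta[0], theta[1], fix_hill
        per = theta[2:]
    lr = per[0::2][:n_lig]
    lt = per[1::2][:n_lig]
    return Em, basal, n_hill, lr, lt


def fit_operational(
    cr_by_ligand: list[ConcentrationResponse],
    block_id: str = "B1",
    n_hill: float | None = None,
    reference_ligand: str | None = None,
) -> OperationalFit:
    """Globally fit the operational model to all ligands of one assay.

    ``Em``, ``basal`` and the transducer slope are shared across ligands;
    each ligand contributes (log_R, log_tau), with log_KA = log_tau - log_R
    derived, and the standard error of log_R read from the local covariance
    of the fit.
    Pass ``n_hill`` to fix the transducer slope (e.g. 1.0); by default it is
    estimated within (0.3, 3). Ligands whose fitted span is below 10% of
    Em - basal are flagged as weak partial agonists: their log_R carries a
    very large standard error and bias estimates built on it are unreliable.
    """
    if not cr_by_ligand:
        raise ValueError("no concentration-response data supplied")
    pathway = cr_by_ligand[0].pathway_id
    for cr in cr_by_ligand:
        if cr.pathway_id != pathway:
            raise ValueError("all ligands must share one pathway per fit")
        if cr.nonzero()["concentration_M"].nunique() < 5:
            raise ValueError(
                f"ligand {cr.ligand_id!r}: >= 5 distinct concentrations required"
            )
    if reference_ligand is not None:
        if all(cr.ligand_id != reference_ligand for cr in cr_by_ligand):
            raise ValueError(f"reference ligand {reference_ligand!r} missing")

    ligs = [cr.ligand_id for cr in cr_by_ligand]
    xs = [np.log10(cr.nonzero()["concentration_M"].to_numpy(float)) for cr in cr_by_ligand]
    ys = [cr.nonzero()["response"].to_numpy(float) for cr in cr_by_ligand]
    y_all = np.concatenate(ys)
    ymin, ymax = float(np.min(y_all)), float(np.max(y_all))
    span = max(ymax - ymin, 1e-12)
    scale = max(abs(ymax), abs(ymin), 1.0)

    # seed from per-ligand logistic fits; the largest-span ligand anchors Em
    seeds = []
    for lx, ly in zip(xs, ys):
        p, _, _ = _fit_single(lx, ly, 4)
        seeds.append(p)
    ref_idx = int(np.argmax([s["e_max"] - s["basal"] for s in seeds]))

    fix_hill = float(n_hill) if n_hill is not None else None
    n_lig = len(ligs)

    n_pts = [len(x) for x in xs]
    off = 2 if fix_hill is not None else 3
    n_theta = off + 2 * n_lig

    def residuals(theta):
        Em, basal, nh, lr, lt = _pack(theta, n_lig, fix_hill)
        out = []
        for i in range(n_lig):
            E, *_ = _op_eval_and_grads(xs[i], Em, basal, nh, lt[i], lt[i] - lr[i])
            out.append(E - ys[i])
        return np.concatenate(out)

    def jacobian(theta):
        Em, basal, nh, lr, lt = _pack(theta, n_lig, fix_hill)
        J = np.zeros((sum(n_pts), n_theta))
        r0 = 0
        for i in range(n_lig):
            _, dEm, dbasal, dlt, dlk, dn = _op_eval_and_grads(
                xs[i], Em, basal, nh, lt[i], lt[i] - lr[i])
            rows = slice(r0, r0 + n_pts[i])
            J[rows, 0] = dEm
            J[rows, 1] = dbasal
            if fix_hill is None:
                J[rows, 2] = dn
            # chain rule for the (log_R, log_tau) parameterization:
            # log_KA = log_tau - log_R
            J[rows, off + 2 * i] = -dlk
            J[rows, off + 2 * i + 1] = dlt + dlk
            r0 += n_pts[i]
        return J

    def start(tau0):
        b0 = seeds[ref_idx]["basal"]
        e_ref = seeds[ref_idx]["e_max"]
        Em0 = b0 + (e_ref - b0) * (1.0 + tau0) / tau0
        theta = [Em0, b0] if fix_hill is not None else [Em0, b0, 1.0]
        for s in seeds:
            frac = np.clip((s["e_max"] - b0) / max(Em0 - b0, 1e-12), 1e-4, 0.999)
            tau_i = np.clip(frac / (1.0 - frac), 1e-3, 1e4)
            ka_i = np.clip(s["log_ec50"] + np.log10(1.0 + tau_i), *LOG_KA_BOUNDS)
            lt_i = float(np.clip(np.log10(tau_i), *LOG_TAU_BOUNDS))
            theta += [lt_i - float(ka_i), lt_i]
        return np.asarray(theta, float)

    LOG_R_BOUNDS = (LOG_TAU_BOUNDS[0] - LOG_KA_BOUNDS[1],
                    LOG_TAU_BOUNDS[1] - LOG_KA_BOUNDS[0])
    # Em capped at 3x the observed span: with a (near-)full reference agonist
    # present, solutions with a far larger system maximum and uniformly tiny
    # tau sit on a likelihood ridge that leaves every log_R unidentified
    lb = [ymin + 0.2 * span, ymin - span] + ([] if fix_hill is not None else [N_HILL_BOUNDS[0]])
    ub = [ymin + 3.0 * span, ymin + 0.5 * span] + ([] if fix_hill is not None else [N_HILL_BOUNDS[1]])
    lb += [LOG_R_BOUNDS[0], LOG_TAU_BOUNDS[0]] * n_lig
    ub += [LOG_R_BOUNDS[1], LOG_TAU_BOUNDS[1]] * n_lig
    lb, ub = np.asarray(lb, float), np.asarray(ub, float)

    def _interior(x):
        # shared Em/basal and transduction parameters away from the box edges
        pad = 0.05 * (ub - lb)
        return bool(np.all(x > lb + pad) and np.all(x < ub - pad))

    # start from the logistic seeds; multi-start over the assumed reference
    # efficacy only when a start fails to converge to an interior optimum
    best = None
    prev_cost = None
    for tau0 in (10.0, 1.0, 100.0):
        x0 = np.clip(start(tau0), lb + 1e-12, ub - 1e-12)
        try:
            res = optimize.least_squares(
                residuals, x0, jac=jacobian, bounds=(lb, ub), x_scale="jac",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover
            log.warning("operational fit start tau0=%g failed: %s", tau0, exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost <= 1e-18 * scale ** 2 * len(y_all):
            break
        if res.status > 0 and _interior(res.x):
            break
        if prev_cost is not None and res.status > 0 and \
                abs(res.cost - prev_cost) <= 1e-6 * max(best.cost, 1e-300):
            break
        prev_cost = res.cost
    if best is None:
        raise RuntimeError("operational model fit failed from every start")

    Em, basal, nh, lr, lt = _pack(best.x, n_lig, fix_hill)
    m, p = len(y_all), len(best.x)
    sigma2 = 2.0 * best.cost / max(m - p, 1)
    cov = sigma2 * np.linalg.pinv(best.jac.T @ best.jac)

    rows = []
    for i, lig in enumerate(ligs):
        ir = off + 2 * i
        se_r = float(np.sqrt(max(cov[ir, ir], 0.0)))
        tau_n = (10.0 ** lt[i]) ** nh
        fit_span = (Em - basal) * tau_n / (1.0 + tau_n)  # high-dose asymptote
        weak = fit_span < WEAK_SPAN_FRACTION * (Em - basal)
        if weak:
            log.info(
                "%s block %s: ligand %r flagged weak partial agonist "
                "(bias estimates will carry large error)",
                pathway, block_id, lig,
            )
        rows.append((lig, float(lt[i]), float(lt[i] - lr[i]), float(lr[i]), se_r, weak))

    converged = bool(best.status > 0)
    return OperationalFit(
        pathway_id=pathway,
        block_id=block_id,
        Em=float(Em),
        n_hill=float(nh),
        basal=float(basal),
        ligands=pd.DataFrame(
            rows,
            columns=["ligand", "log_tau", "log_KA", "log_R", "se_log_R", "weak_partial"],
        ),
        converged=converged,
        cost=float(best.cost),
        message=best.message,
    )


def delta_log_r(fit: OperationalFit, reference_ligand: str) -> pd.DataFrame:
    """Per-ligand Deltalog(tau/K_A) vs the reference ligand, within one block.

    The reference ligand's own Delta is exactly 0 by construction.
    """
    ref = fit.log_R(reference_ligand)
    out = fit.ligands[["ligand"]].copy()
    out["block"] = fit.block_id
    out["delta_log_R"] = [
        0.0 if lig == reference_ligand else float(r - ref)
        for lig, r in zip(fit.ligands["ligand"], fit.ligands["log_R"])
    ]
    return out


def delta_delta_log_r(
    delta_reference_pathway: pd.DataFrame,
    delta_comparator_pathway: pd.DataFrame,
) -> pd.DataFrame:
    """Per-block DeltaDeltalog(tau/K_A) = Delta(ref pathway) - Delta(comparator).

    Inputs are per-block Delta tables (columns ligand, block, delta_log_R);
    only blocks present in both pathways are used, with a log entry when
    block sets differ. Positive values indicate bias toward the reference
    pathway (cAMP in the study's convention).
    """
    a = delta_reference_pathway.rename(columns={"delta_log_R": "d_ref"})
    b = delta_comparator_pathway.rename(columns={"delta_log_R": "d_cmp"})
    blocks_a, blocks_b = set(a["block"]), set(b["block"])
    if blocks_a != blocks_b:
        log.warning(
            "unmatched block sets (%s vs %s): using intersection",
            sorted(blocks_a), sorted(blocks_b),
        )
    merged = a.merge(b, on=["ligand", "block"], how="inner")
    merged["delta_delta"] = merged["d_ref"] - merged["d_cmp"]
    return merged[["ligand", "block", "delta_delta"]]


def bias_interval(
    per_block_dd,
    ligand_id: str = "",
    pathway_pair: tuple[str, str] = ("cAMP", "barr2"),
    is_reference: bool = False,
) -> BiasResult:
    """Summarize per-block DeltaDelta values into mean, 95% t-CI and bias factor.

    The interval is mean +/- t_{0.975, n-1} * SEM over blocks; bias is flagged
    significant when the interval excludes zero. With a single block the
    interval and the significance call are undefined.
    """
    if isinstance(per_block_dd, pd.DataFrame):
        df = per_block_dd[["block", "delta_delta"]].copy()
    else:
        vals = np.asarray(list(per_block_dd), float)
        df = pd.DataFrame({"block": [f"B{i+1}" for i in range(len(vals))],
                           "delta_delta": vals})
    vals = df["delta_delta"].to_numpy(float)
    n = len(vals)
    if n == 0:
        raise ValueError("no DeltaDelta values")
    mean = float(np.mean(vals))
    if n >= 2:
        sem = float(np.std(vals, ddof=1) / np.sqrt(n))
        tcrit = float(stats.t.ppf(0.975, n - 1))
        ci = (mean - tcrit * sem, mean + tcrit * sem)
        significant = bool(ci[0] > 0 or ci[1] < 0)
    else:
        sem, ci, significant = float("nan"), None, None
    return BiasResult(
        ligand_id=ligand_id,
        pathway_pair=pathway_pair,
        per_block=df,
        mean=mean,
        sem=sem,
        ci95=ci,
        bias_factor=float(10.0 ** mean),
        significant=significant,
        is_reference=is_reference,
    )


def transduction_bias(
    study: pd.DataFrame,
    reference_ligand: str,
    reference_pathway: str = "cAMP",
    comparator_pathway: str | None = None,
    n_hill: float | None = None,
) -> tuple[list[BiasResult], pd.DataFrame]:
    """End-to-end bias analysis of a matched two-pathway study table.

    ``study`` has columns ligand, pathway, concentration_M, block, response
    (the long format emitted by the simulator and the plate readers). For
    every block and pathway the operational model is fitted globally across
    ligands; Delta and DeltaDelta log(tau/K_A) are formed per block, then
    summarized with 95% t-intervals. Returns the per-ligand BiasResults and
    a tidy summary table.
    """
    pathways = list(dict.fromkeys(study["pathway"]))
    if reference_pathway not in pathways:
        raise ValueError(f"reference pathway {reference_pathway!r} absent")
    if comparator_pathway is None:
        others = [p for p in pathways if p != reference_pathway]
        if len(others) != 1:
            raise ValueError("specify comparator_pathway explicitly")
        comparator_pathway = others[0]
    ligands = list(dict.fromkeys(study["ligand"]))
    if reference_ligand not in ligands:
        raise ValueError(f"reference ligand {reference_ligand!r} absent")

    deltas: dict[str, list[pd.DataFrame]] = {reference_pathway: [], comparator_pathway: []}
    fits: list[OperationalFit] = []
    for pw in (reference_pathway, comparator_pathway):
        sub = study[study["pathway"] == pw]
        for block in sorted(sub["block"].unique()):
            crs = [
                ConcentrationResponse.from_study(sub, lig, pw, blocks=[block])
                for lig in ligands
                if not sub[(sub["ligand"] == lig) & (sub["block"] == block)].empty
            ]
            fit = fit_operational(crs, block_id=block, n_hill=n_hill,
                                  reference_ligand=reference_ligand)
            fits.append(fit)
            deltas[pw].append(delta_log_r(fit, reference_ligand))

    d_ref = pd.concat(deltas[reference_pathway], ignore_index=True)
    d_cmp = pd.concat(deltas[comparator_pathway], ignore_index=True)
    dd = delta_delta_log_r(d_ref, d_cmp)

    results = []
    rows = []
    for lig in ligands:
        sub = dd[dd["ligand"] == lig]
        res = bias_interval(
            sub, ligand_id=lig,
            pathway_pair=(reference_pathway, comparator_pathway),
            is_reference=lig == reference_ligand,
        )
        results.append(res)
        lo, hi = res.ci95 if res.ci95 else (float("nan"), float("nan"))
        rows.append((
            lig, reference_pathway, comparator_pathway, len(sub), res.mean,
            res.sem, lo, hi, res.bias_factor,
            res.significant if res.significant is not None else False,
            res.is_reference,
        ))
    table = pd.DataFrame(rows, columns=[
        "ligand", "reference_pathway", "comparator_pathway", "n_blocks",
        "delta_delta_log_R", "sem", "ci95_low", "ci95_high", "bias_factor",
        "significant", "is_reference",
    ])
    return results, table
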