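"""Black–Leff operational model of agonism.

The operational model links agonist concentration ``A`` to response through
two ligand-specific parameters — the operational efficacy ``tau`` and the
functional affinity ``K_A`` — and three system parameters shared by all
ligands acting on one receptor/pathway in one assay: the maximal system
response ``Em``, the transducer slope ``n``, and the basal response:

    E(A) = basal + (Em - basal) * tau^n A^n / ((A + K_A)^n + tau^n A^n)

The ratio ``tau/K_A`` (the transduction coefficient) is the pathway-activity
scale on which biased agonism is quantified; its log10 is written ``log_R``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "operational_response",
    "observed_emax",
    "observed_ec50",
]


def operational_response(
    conc,
    Em: float,
    log_tau: float,
    log_KA: float,
    n_hill: float = 1.0,
    basal: float = 0.0,
):
    """Evaluate the operational model at concentration(s) ``conc`` (molar).

    Vectorized over ``conc``; ``conc == 0`` returns ``basal`` exactly.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    tau = 10.0 ** log_tau
    KA = 10.0 ** log_KA
    ta = tau * conc
    num = ta ** n_hill
    den = (conc + KA) ** n_hill + num
    with np.errstate(invalid="ignore"):
        frac = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out = basal + (Em - basal) * frac
    return out if out.ndim else float(out)


def observed_emax(Em: float, log_tau: float, basal: float = 0.0) -> float:
    """Asymptotic response for n = 1: basal + (Em - basal) * tau / (1 + tau)."""
    tau = 10.0 ** log_tau
    return basal + (Em - basal) * tau / (1.0 + tau)


def observed_ec50(log_tau: float, log_KA: float) -> float:
    """Half-maximal concentration for n = 1: K_A / (1 + tau), in molar."""
    return 10.0 ** log_KA / (1.0 + 10.0 ** log_tau)
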