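"""Synthetic plate-experiment generator.

Stands in for the study's raw plate-reader exports (not deposited), emulating
the statistical structure the analysis assumes: sustained mini-G vs transient
beta-arrestin recruitment kinetics, single- and dual-channel detection,
matched-incubation concentration-response designs with randomized replicate
blocks, and Mesna-cleavage internalization plates.

Noise is multiplicative Gaussian (coefficient of variation) plus an additive
Gaussian floor; between-assay scatter is a block-level offset on the
log10(tau/K_A) scale shared by all ligands measured in that assay, which the
per-assay Delta normalization of the bias pipeline is designed to cancel.
Identical inputs and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .operational import operational_response
from .traces import KineticTrace

__all__ = [
    "LigandPathwayParams",
    "KineticScenario",
    "NoiseModel",
    "Well",
    "PlateDesign",
    "DEFAULT_CONC_GRID",
    "simulate_kinetic_trace",
    "simulate_concentration_response_study",
    "simulate_internalization_plate",
    "internalization_design",
    "example_bias_study",
]

# 9 concentrations spanning 1 pM - 1 uM, mirroring typical figure axes
DEFAULT_CONC_GRID = tuple(np.logspace(-12.0, -6.0, 9))


@dataclass(frozen=True)
class LigandPathwayParams:
    """Ground-truth operational parameters for one ligand at one pathway."""

    ligand_id: str
    pathway_id: str
    Em: float
    log_tau: float
    log_KA: float
    n_hill: float = 1.0
    basal: float = 0.0

    def __post_init__(self):
        if not self.Em > self.basal:
            raise ValueError("Em must exceed basal")
        if not self.n_hill > 0:
            raise ValueError("n_hill must be positive")
        if not np.isfinite(self.log_KA):
            raise ValueError("log_KA must be finite")

    @property
    def log_R(self) -> float:
        """log10 transduction coefficient, log10(tau/K_A)."""
        return self.log_tau - self.log_KA

    def response(self, conc):
        return operational_response(
            conc, self.Em, self.log_tau, self.log_KA, self.n_hill, self.basal
        )


@dataclass(frozen=True)
class KineticScenario:
    """Shape and read schedule of one kinetic assay.

    The time course after agonist addition is a difference of exponentials
    normalized to unit peak, f(t) proportional to e^{-decay t} - e^{-onset t}
    (equivalently (1 - e^{-(onset-decay) t}) e^{-decay t}); ``decay_rate = 0``
    gives the sustained association 1 - e^{-onset t}.  ``plateau`` scales the
    peak amplitude, as a fraction of the baseline signal, reached by a
    maximal-response agonist.
    """

    onset_rate: float
    decay_rate: float = 0.0
    plateau: float = 1.0
    channel_model: str = "single"  # "single" | "ratiometric"
    baseline_duration: float = 5.0
    read_interval: float = 0.5
    total_duration: float = 30.0
    baseline_level: float = 1000.0
    num_wavelength: str = "620"
    den_wavelength: str = "520"
    num_gain: float = 0.6  # fractional rise of the numerator channel at peak
    den_gain: float = -0.4  # fractional change of the denominator channel

    def __post_init__(self):
        if self.onset_rate < 0 or self.decay_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.decay_rate > 0 and self.onset_rate <= self.decay_rate:
            raise ValueError("transient scenarios require onset_rate > decay_rate")
        if not self.read_interval > 0:
            raise ValueError("read_interval must be positive")
        if self.channel_model not in ("single", "ratiometric"):
            raise ValueError(f"unknown channel_model {self.channel_model!r}")

    def shape(self, t_post: np.ndarray) -> np.ndarray:
        """Unit-peak response shape vs time from agonist addition (min)."""
        t = np.maximum(np.asarray(t_post, dtype=float), 0.0)
        if self.decay_rate == 0.0:
            return 1.0 - np.exp(-self.onset_rate * t)
        f = np.exp(-self.decay_rate * t) - np.exp(-self.onset_rate * t)
        t_peak = self.peak_time()
        f_peak = np.exp(-self.decay_rate * t_peak) - np.exp(-self.onset_rate * t_peak)
        return f / f_peak

    def peak_time(self) -> float:
        """Time of maximal response; ln(onset/decay)/(onset - decay) if transient."""
        if self.decay_rate == 0.0:
            return float("inf")
        return float(
            np.log(self.onset_rate / self.decay_rate)
            / (self.onset_rate - self.decay_rate)
        )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement + between-assay noise; all scatter parameters >= 0."""

    cv_multiplicative: float = 0.0
    sd_additive: float = 0.0
    block_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.cv_multiplicative, self.sd_additive, self.block_sd) < 0:
            raise ValueError("scatter parameters must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, mean, rng: np.random.Generator):
        mean = np.asarray(mean, dtype=float)
        out = mean * (1.0 + rng.normal(0.0, self.cv_multiplicative, mean.shape))
        return out + rng.normal(0.0, self.sd_additive, mean.shape)


NONE_NOISE = NoiseModel()


@dataclass(frozen=True)
class Well:
    well_id: str
    receptor: str
    ligand: str  # "vehicle" for agonist-free wells
    concentration: float = 0.0
    condition: str = ""  # e.g. "mesna", "no-mesna", "forskolin"
    block_id: str = "B1"

    @property
    def is_vehicle(self) -> bool:
        return self.ligand == "vehicle"


@dataclass(frozen=True)
class PlateDesign:
    wells: tuple[Well, ...]

    def __post_init__(self):
        object.__setattr__(self, "wells", tuple(self.wells))
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well_ids must be unique")
        blocks = {}
        for w in self.wells:
            if not w.is_vehicle and not w.concentration > 0:
                raise ValueError(f"well {w.well_id!r}: non-vehicle well needs conc > 0")
            blocks.setdefault(w.block_id, []).append(w)
        for b, ws in blocks.items():
            if not any(w.is_vehicle for w in ws):
                raise ValueError(f"block {b!r} has no vehicle well")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (w.well_id, w.receptor, w.ligand, w.concentration, w.condition, w.block_id)
                for w in self.wells
            ],
            columns=["well", "receptor", "ligand", "conc_M", "condition", "block"],
        )


def simulate_kinetic_trace(
    params: LigandPathwayParams,
    scenario: KineticScenario,
    concentration: float,
    noise: NoiseModel = NONE_NOISE,
    well_id: str = "W01",
    block_id: str = "B1",
) -> KineticTrace:
    """One well's kinetic trace for the given agonist concentration (molar).

    The baseline segment sits at the basal signal level; after agonist
    addition the scenario's unit-peak shape is scaled by the operational-model
    fractional response at this concentration. A noise-free vehicle trace
    (concentration 0) is flat.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    n_reads = int(round((scenario.baseline_duration + scenario.total_duration)
                        / scenario.read_interval)) + 1
    times = np.arange(n_reads) * scenario.read_interval
    t_post = times - scenario.baseline_duration
    frac = (params.response(concentration) - params.basal) / (params.Em - params.basal)
    amp = scenario.plateau * frac
    g = np.where(t_post >= 0, scenario.shape(t_post), 0.0)
    rng = noise.rng()
    B = scenario.baseline_level
    if scenario.channel_model == "single":
        channels = {"signal": noise.apply(B * (1.0 + amp * g), rng)}
    else:
        channels = {
            scenario.num_wavelength: noise.apply(B * (1.0 + scenario.num_gain * amp * g), rng),
            scenario.den_wavelength: noise.apply(B * (1.0 + scenario.den_gain * amp * g), rng),
        }
    return KineticTrace(
        well_id=well_id,
        times=times,
        channels=channels,
        ligand=params.ligand_id if concentration > 0 else "vehicle",
        concentration=concentration,
        is_vehicle=concentration == 0,
        block_id=block_id,
        baseline_end=scenario.baseline_duration,
    )


def simulate_concentration_response_study(
    params_by_ligand: list[LigandPathwayParams],
    conc_grid=DEFAULT_CONC_GRID,
    n_blocks: int = 5,
    noise: NoiseModel = NONE_NOISE,
) -> pd.DataFrame:
    """Matched-incubation concentration-response study over replicate blocks.

    Returns one row per (ligand, pathway, concentration, block) with columns
    ``ligand, pathway, concentration_M, block, response``. Within each block
    every pathway (assay) receives one shared random offset on log10(tau/K_A),
    drawn with SD ``noise.block_sd``; noise-free output equals the
    operational-model mean exactly.
    """
    conc = np.asarray(list(conc_grid), dtype=float)
    if conc.size == 0:
        raise ValueError("conc_grid must be non-empty")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("conc_grid must be strictly increasing")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = noise.rng()
    pathways = list(dict.fromkeys(p.pathway_id for p in params_by_ligand))
    rows = []
    for b in range(1, n_blocks + 1):
        offsets = {pw: rng.normal(0.0, noise.block_sd) for pw in pathways}
        for p in params_by_ligand:
            mean = operational_response(
                conc, p.Em, p.log_tau + offsets[p.pathway_id], p.log_KA,
                p.n_hill, p.basal,
            )
            resp = noise.apply(mean, rng)
            for c, r in zip(conc, resp):
                rows.append((p.ligand_id, p.pathway_id, c, f"B{b}", r))
    return pd.DataFrame(
        rows, columns=["ligand", "pathway", "concentration_M", "block", "response"]
    )


def internalization_design(
    receptors=("GLP-1R", "GIPR", "GCGR"),
    ligands=("GLP-1",),
    n_blocks: int = 5,
) -> PlateDesign:
    """Mesna-cleavage plate: (no-Mesna, Mesna+vehicle, Mesna+agonist) wells
    per receptor and block, agonist at 100 nM."""
    wells, i = [], 0
    for b in range(1, n_blocks + 1):
        for rec in receptors:
            for ligand, mesna in [("vehicle", "no-mesna"), ("vehicle", "mesna")] + [
                (lg, m) for lg in ligands for m in ("no-mesna", "mesna")
            ]:
                i += 1
                wells.append(
                    Well(
                        well_id=f"W{i:03d}",
                        receptor=rec,
                        ligand=ligand,
                        concentration=0.0 if ligand == "vehicle" else 1e-7,
                        condition=mesna,
                        block_id=f"B{b}",
                    )
                )
    return PlateDesign(tuple(wells))


def simulate_internalization_plate(
    surface_signal: float,
    internalized_fraction: dict[str, float],
    nonspecific_signal: float,
    noise: NoiseModel,
    design: PlateDesign,
) -> pd.DataFrame:
    """Well intensity table for a Mesna-cleavage internalization plate.

    ``internalized_fraction`` maps ligand -> protected fraction of the
    cleavable surface pool; may be keyed by ligand or (receptor, ligand).
    no-Mesna wells read the full surface signal; Mesna+vehicle wells the
    nonspecific floor; Mesna+agonist wells the floor plus the protected
    fraction of the specific signal.
    """
    if not nonspecific_signal < surface_signal:
        raise ValueError("nonspecific_signal must be below surface_signal")

    def frac_for(w: Well) -> float:
        f = internalized_fraction.get((w.receptor, w.ligand))
        if f is None:
            f = internalized_fraction.get(w.ligand, 0.0)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"internalized fraction {f} outside [0, 1]")
        return f

    rng = noise.rng()
    rows = []
    for w in design.wells:
        if w.condition == "no-mesna":
            mean = surface_signal
        elif w.is_vehicle:
            mean = nonspecific_signal
        else:
            mean = nonspecific_signal + frac_for(w) * (surface_signal - nonspecific_signal)
        val = float(noise.apply(mean, rng))
        rows.append((w.well_id, w.receptor, w.ligand, w.condition == "mesna", val, w.block_id))
    return pd.DataFrame(
        rows, columns=["well", "receptor", "ligand", "mesna", "intensity", "block"]
    )


def example_bias_study(
    dd_true: float = 0.5,
    reference: str = "GIP",
    analog: str = "GIP-Gly2",
) -> list[LigandPathwayParams]:
    """Two-ligand, two-pathway study with a known true bias.

    The analog loses 1.0 log unit of transduction in cAMP and
    (1.0 + dd_true) log units in beta-arrestin-2 recruitment, so its true
    DeltaDeltalog(tau/K_A) toward cAMP is exactly ``dd_true``. The analog is
    a weak partial agonist for arrestin recruitment, as in the study's
    N-terminally substituted peptides.
    """
    return [
        LigandPathwayParams(reference, "cAMP", Em=100.0, log_tau=1.0, log_KA=-8.0),
        LigandPathwayParams(analog, "cAMP", Em=100.0, log_tau=0.4, log_KA=-7.6),
        LigandPathwayParams(reference, "barr2", Em=60.0, log_tau=0.7, log_KA=-7.5),
        LigandPathwayParams(analog, "barr2", Em=60.0, log_tau=0.3 - dd_true, log_KA=-6.9),
    ]
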