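"""Synthetic study generators with known ground truth.

Every downstream stage (plate normalization, hit calling, dose-response
fitting, uptake quantification, survival risk modelling) gets a generator
that emulates the corresponding experiment and returns the truth used to
build it, so parameter-recovery tests need no external data.

The screen generator reproduces the structure of a 96-well YFP-iodide
screen: multiplicative log-normal plate and well-position artefacts on raw
fluorescence (exactly the artefact class that ratio normalization removes),
a common baseline quench from the NaI injection in every injected well, a
mostly-null drug population with a minority of true quenchers, and a subset
of cytotoxic drugs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .screen_model import KineticWell, Role, WellAddress, ROWS, N_COLUMNS

logger = logging.getLogger("iodoscreen")


@dataclass
class ScreenSimSpec:
    """Design of a simulated primary screen.

    Defaults mirror a 15-plate, 96-well screen: 1,200 drug wells at a single
    dose, 120 DMSO vehicle wells, and NaI/PBS control columns on every
    plate.  ``active_quench_range`` is the total fractional cycle-4 quench
    of a true active (it exceeds ``baseline_quench``, the quench every
    NaI-injected well shows); PBS wells receive no iodide and do not quench.
    """

    n_plates: int = 15
    wells_per_plate: int = 96
    n_dmso_total: int = 120
    baseline_fluor: float = 50000.0
    plate_effect_sd: float = 0.10
    wellpos_effect_sd: float = 0.05
    noise_cv: float = 0.02
    baseline_quench: float = 0.25
    active_fraction: float = 0.08
    active_quench_range: tuple[float, float] = (0.30, 0.80)
    control_quench: float = 0.80
    toxic_fraction: float = 0.05
    toxic_viability_range: tuple[float, float] = (0.10, 0.60)
    viability_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("active_fraction", "toxic_fraction", "baseline_quench",
                     "control_quench"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.active_quench_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("active_quench_range must be within [0, 1]")


@dataclass
class FourPLParams:
    """Four-parameter logistic dose-response curve.

    response(d) = bottom + (top - bottom) / (1 + (ec50 / d) ** hill)
    """

    bottom: float
    top: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")

    def response(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        if np.any(d <= 0):
            raise ValueError("doses must be > 0")
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / d) ** self.hill)


@dataclass
class CohortSimSpec:
    """Design of a simulated recurrence cohort.

    Event times are exponential with per-patient hazard
    baseline_hazard * exp(lp_i - mean(lp)), where the linear predictor lp
    sums causal-gene log-hazard coefficients times log2(FPKM+1) expression
    (plus optional covariate effects); centering fixes the marginal event
    rate without changing the coefficients a Cox fit estimates.  Censoring
    is independent exponential tuned to the requested censoring fraction.
    """

    n_patients: int = 600
    n_genes: int = 13
    causal_genes: Mapping[str, float] = field(
        default_factory=lambda: {"GENE_01": 0.7, "GENE_02": 0.5, "GENE_03": -0.6})
    baseline_hazard: float = 0.08
    censoring_rate: float = 0.30
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    expr_sigma: float = 0.7
    seed: int = 0

    @property
    def genes(self) -> list[str]:
        return [f"GENE_{i + 1:02d}" for i in range(self.n_genes)]

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        unknown = set(self.causal_genes) - set(self.genes)
        if unknown:
            raise ValueError(f"causal_genes not in gene panel: {sorted(unknown)}")


def _default_layout(spec: ScreenSimSpec) -> dict[str, list[tuple[WellAddress, Role]]]:
    """Column 1 holds controls (rows A-D NaI, E-H PBS); DMSO wells fill
    columns 12 then 11 top-down; everything else is a drug well."""
    if spec.wells_per_plate != 96:
        raise ValueError("default layout requires 96-well plates")
    per_plate = [spec.n_dmso_total // spec.n_plates] * spec.n_plates
    for i in range(spec.n_dmso_total % spec.n_plates):
        per_plate[i] += 1
    if max(per_plate) > 16:
        raise ValueError(
            f"n_dmso_total={spec.n_dmso_total} exceeds DMSO capacity "
            f"(16 wells/plate over {spec.n_plates} plates)")
    if min(per_plate) < 1:
        raise ValueError("every plate needs at least one DMSO well")
    layout: dict[str, list[tuple[WellAddress, Role]]] = {}
    for p in range(spec.n_plates):
        plate_id = f"P{p + 1:02d}"
        plan: list[tuple[WellAddress, Role]] = []
        dmso_slots = [(r, c) for c in (12, 11) for r in ROWS][: per_plate[p]]
        for row in ROWS:
            for col in range(1, N_COLUMNS + 1):
                addr = WellAddress(plate_id, row, col)
                if col == 1:
                    role = Role.NAI_POSITIVE if row in "ABCD" else Role.PBS_NEGATIVE
                elif (row, col) in dmso_slots:
                    role = Role.DMSO_CONTROL
                else:
                    role = Role.DRUG
                plan.append((addr, role))
        layout[plate_id] = plan
    return layout


def simulate_screen(
    spec: Optional[ScreenSimSpec] = None,
) -> tuple[list[KineticWell], pd.DataFrame]:
    """Generate one primary screen plus a per-drug ground-truth table.

    Returns (wells, truth) where truth has columns drug_id, true_quench,
    viability, is_active, is_toxic.  Deterministic for a fixed spec/seed.
    """
    spec = spec or ScreenSimSpec()
    rng = np.random.default_rng(spec.seed)
    layout = _default_layout(spec)

    plate_ids = sorted(layout)
    plate_eff = {p: math.exp(rng.normal(0, spec.plate_effect_sd)) for p in plate_ids}
    pos_eff = {(r, c): math.exp(rng.normal(0, spec.wellpos_effect_sd))
               for r in ROWS for c in range(1, N_COLUMNS + 1)}

    drug_slots = [(addr, role) for p in plate_ids for addr, role in layout[p]
                  if role is Role.DRUG]
    n_drugs = len(drug_slots)
    drug_ids = [f"DRUG_{i + 1:04d}" for i in range(n_drugs)]
    is_active = rng.random(n_drugs) < spec.active_fraction
    lo, hi = spec.active_quench_range
    quench = np.where(is_active, rng.uniform(lo, hi, n_drugs), spec.baseline_quench)
    is_toxic = rng.random(n_drugs) < spec.toxic_fraction
    tlo, thi = spec.toxic_viability_range
    viability = np.where(is_toxic, rng.uniform(tlo, thi, n_drugs),
                         np.clip(rng.normal(1.0, spec.viability_noise_sd, n_drugs),
                                 0.0, None))
    truth = pd.DataFrame({
        "drug_id": drug_ids,
        "true_quench": quench,
        "viability": viability,
        "is_active": is_active,
        "is_toxic": is_toxic,
    })
    by_slot = dict(zip((a for a, _ in drug_slots), range(n_drugs)))

    wells: list[KineticWell] = []
    for p in plate_ids:
        for addr, role in layout[p]:
            if role is Role.DRUG:
                i = by_slot[addr]
                q, drug_id, viab = float(quench[i]), drug_ids[i], float(viability[i])
                dose = 10.0
            elif role is Role.DMSO_CONTROL:
                q, drug_id, viab, dose = spec.baseline_quench, None, 1.0, None
            elif role is Role.NAI_POSITIVE:
                q, drug_id, viab, dose = spec.control_quench, None, 1.0, None
            else:  # PBS negative: no iodide injected, no quench
                q, drug_id, viab, dose = 0.0, None, 1.0, None
            yfp0 = (spec.baseline_fluor * plate_eff[p] * pos_eff[addr.position]
                    * (1.0 + rng.normal(0, spec.noise_cv)))
            cycles = []
            for k in (1, 2, 3):
                cycles.append(yfp0 * (1.0 - q * k / 4.0)
                              * (1.0 + rng.normal(0, spec.noise_cv)))
            cycles.append(yfp0 * (1.0 - q) * (1.0 + rng.normal(0, spec.noise_cv)))
            wells.append(KineticWell(
                address=addr, role=role, drug_id=drug_id, dose=dose,
                yfp0=yfp0, yfp_cycles=tuple(cycles), viability=viab,
            ))
    logger.info("simulate_screen: %d plates, %d wells, %d drugs "
                "(%d active, %d toxic), seed=%d",
                len(plate_ids), len(wells), n_drugs,
                int(is_active.sum()), int(is_toxic.sum()), spec.seed)
    return wells, truth


def simulate_dose_response(
    params: FourPLParams,
    doses: Sequence[float],
    noise_cv: float = 0.05,
    seed: int = 0,
    drug_id: str = "DRUG",
    with_control: bool = True,
) -> pd.DataFrame:
    """Simulate a secondary multi-dose series for one drug.

    Returns a tidy frame (drug_id, cell_line, dose_uM, response) with
    multiplicative noise on the 4PL response in the NIS-expressing reporter
    line; ``with_control`` adds a flat (top == bottom) YFP-only control
    series modelling a non-NIS-specific readout.
    """
    d = np.asarray(doses, dtype=float)
    if np.any(d <= 0):
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    frames = []
    resp = params.response(d) * (1.0 + rng.normal(0, noise_cv, d.size))
    frames.append(pd.DataFrame({
        "drug_id": drug_id, "cell_line": "NIS_YFP", "dose_uM": d, "response": resp}))
    if with_control:
        flat = FourPLParams(params.bottom, params.bottom, params.ec50, params.hill)
        resp_c = flat.response(d) * (1.0 + rng.normal(0, noise_cv, d.size))
        frames.append(pd.DataFrame({
            "drug_id": drug_id, "cell_line": "YFP_ONLY",
            "dose_uM": d, "response": resp_c}))
    return pd.concat(frames, ignore_index=True)


# counts = PMOL_TO_COUNTS * pmol/ug * protein_ug inverts the gamma-counter
# calibration pmol/ug = 5000 * (counts / protein) / 12000.
PMOL_TO_COUNTS = 12000.0 / 5000.0


def simulate_uptake(
    n_replicates: int = 3,
    true_fold: float = 2.0,
    vehicle_pmol: float = 1.0,
    protein_range: tuple[float, float] = (2000.0, 6000.0),
    seed: int = 0,
    noise_cv: float = 0.05,
    perchlorate_background: float = 0.05,
    with_perchlorate: bool = True,
) -> pd.DataFrame:
    """Simulate a radioiodide (125-I) uptake experiment.

    Returns replicate rows (sample_id, condition, counts, total_protein_ug,
    perchlorate_treated) for a vehicle arm, a treated arm at
    ``true_fold`` x vehicle uptake, and — when requested — a treated +
    perchlorate arm at background, modelling competitive NIS inhibition.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    rng = np.random.default_rng(seed)
    rows = []

    def arm(condition: str, pmol: float, perchlorate: bool) -> None:
        tag = f"{condition}_perchlorate" if perchlorate else condition
        for i in range(n_replicates):
            protein = rng.uniform(*protein_range)
            counts = PMOL_TO_COUNTS * pmol * protein * (1.0 + rng.normal(0, noise_cv))
            rows.append({
                "sample_id": f"{tag}_{i + 1}",
                "condition": condition,
                "counts": max(counts, 0.0),
                "total_protein_ug": protein,
                "perchlorate_treated": perchlorate,
            })

    arm("vehicle", vehicle_pmol, False)
    arm("treated", vehicle_pmol * true_fold, False)
    if with_perchlorate:
        arm("treated", vehicle_pmol * true_fold * perchlorate_background, True)
    return pd.DataFrame(rows)


_STAGES = ["I", "II", "III", "IV"]
_TSTAGES = ["T1", "T2", "T3", "T4"]


def simulate_cohort(
    spec: Optional[CohortSimSpec] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an expression + recurrence cohort.

    Returns (cohort, true_beta): a frame with patient_id, one FPKM column
    per gene, time, event, and clinical covariates; and the per-gene true
    log-hazard coefficients (zero for non-causal genes).  Retries (max 5,
    logged) if a draw has no events at all.
    """
    spec = spec or CohortSimSpec()
    genes = spec.genes
    beta = pd.Series({g: float(spec.causal_genes.get(g, 0.0)) for g in genes})

    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        n = spec.n_patients
        gene_mu = rng.uniform(0.5, 3.0, spec.n_genes)
        fpkm = np.exp(rng.normal(gene_mu, spec.expr_sigma, size=(n, spec.n_genes)))
        x = np.log2(fpkm + 1.0)

        age = rng.normal(48.0, 12.0, n).clip(18, 90)
        gender = rng.choice(["F", "M"], n, p=[0.75, 0.25])
        disease_stage = rng.choice(_STAGES, n, p=[0.55, 0.1, 0.2, 0.15])
        tumor_stage = rng.choice(_TSTAGES, n, p=[0.3, 0.35, 0.25, 0.1])
        node_status = rng.choice(["N0", "N1"], n, p=[0.55, 0.45])

        lp = x @ beta.to_numpy()
        for cov, b in spec.covariate_effects.items():
            if cov == "age":
                lp = lp + b * age
            else:
                raise ValueError(f"unsupported covariate effect: {cov}")
        lp = lp - lp.mean()
        hazard = spec.baseline_hazard * np.exp(lp)
        t_event = rng.exponential(1.0 / hazard)
        if spec.censoring_rate > 0:
            rate_c = spec.baseline_hazard * spec.censoring_rate / (1 - spec.censoring_rate)
            t_cens = rng.exponential(1.0 / rate_c, n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
        if event.any():
            break
        logger.warning("simulate_cohort: all-censored draw, retry %d", attempt + 1)
    else:
        raise RuntimeError("simulate_cohort: 5 all-censored draws in a row")

    cohort = pd.DataFrame(fpkm, columns=genes)
    cohort.insert(0, "patient_id", [f"PT_{i + 1:04d}" for i in range(n)])
    cohort["time"] = time
    cohort["event"] = event
    cohort["age"] = age
    cohort["gender"] = gender
    cohort["disease_stage"] = disease_stage
    cohort["tumor_stage"] = tumor_stage
    cohort["node_status"] = node_status
    cohort["rai_treated"] = True
    cohort["braf_like"] = True
    logger.info("simulate_cohort: n=%d, %d events (%.0f%% censored), seed=%d",
                n, int(event.sum()), 100 * (1 - event.mean()), spec.seed)
    return cohort, beta
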