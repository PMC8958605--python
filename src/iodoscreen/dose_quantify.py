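"""Secondary-screen analytics: dose-response AUC / dAUC / EC50, radioiodide
uptake quantification, and qPCR relative expression.

Drugs surviving the single-dose screen are retested over a dose ladder in
both the NIS-expressing reporter line and a NIS-free YFP-only control line.
The per-drug dose series is summarized by area under the response curve on
a log10-dose axis (negative responses clipped at zero: only positive peaks
— genuine quench — count), the NIS-specific effect is the AUC difference
between the two lines, and potency is the EC50 of a four-parameter logistic
fit.  Uptake experiments convert gamma-counter counts to picomoles of
125-I per microgram protein and report fold change over vehicle.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic_data import FourPLParams

logger = logging.getLogger("iodoscreen")


class CellLine(enum.Enum):
    NIS_YFP = "NIS_YFP"
    YFP_ONLY = "YFP_ONLY"
    OTHER = "OTHER"


@dataclass
class DoseResponseCurve:
    """One drug's dose series in one cell line, with fitted summaries."""

    drug_id: str
    cell_line: CellLine
    doses: np.ndarray
    responses: np.ndarray
    auc: float = float("nan")
    ec50: Optional[float] = None
    fit: Optional[FourPLParams] = None
    fit_ok: bool = False

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.size != self.responses.size or self.doses.size < 2:
            raise ValueError("need matching dose/response arrays of length >= 2")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be > 0")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")


@dataclass
class UptakeMeasurement:
    """One gamma-counter replicate with its protein normalization."""

    sample_id: str
    condition: str
    counts: float
    total_protein: float
    perchlorate_treated: bool = False

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise ValueError("counts must be >= 0")
        if self.total_protein <= 0:
            raise ValueError("total_protein must be > 0")

    @property
    def picomoles_per_ug(self) -> float:
        return picomoles_per_ug(self.counts, self.total_protein)


def auc_positive_log_dose(doses: Sequence[float], responses: Sequence[float]) -> float:
    """Area under the response curve on a log10-dose axis, positive peaks only.

    Responses are clipped at zero from below before trapezoidal integration,
    so inhibitory (negative) excursions contribute nothing; an all-negative
    curve scores 0.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.size < 2 or d.size != r.size:
        raise ValueError("need >= 2 matched dose/response points")
    if np.any(d <= 0):
        raise ValueError("doses must be > 0")
    order = np.argsort(d)
    d, r = d[order], r[order]
    return float(np.trapezoid(np.clip(r, 0.0, None), np.log10(d)))


def delta_auc(nis_curve: DoseResponseCurve, control_curve: DoseResponseCurve) -> float:
    """AUC in the NIS-expressing line minus the YFP-only control line;
    negative values flag non-NIS-specific fluorescence loss."""
    if nis_curve.drug_id != control_curve.drug_id:
        raise ValueError(
            f"drug_id mismatch: {nis_curve.drug_id!r} vs {control_curve.drug_id!r}")
    a_nis = auc_positive_log_dose(nis_curve.doses, nis_curve.responses)
    a_ctl = auc_positive_log_dose(control_curve.doses, control_curve.responses)
    return a_nis - a_ctl


def _fourpl_logd(logd: np.ndarray, bottom: float, top: float,
                 log_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logd) * hill))


def fit_ec50(
    doses: Sequence[float],
    responses: Sequence[float],
    three_param: bool = False,
) -> tuple[Optional[FourPLParams], Optional[float], bool]:
    """Least-squares four-parameter logistic fit on log10 dose.

    Returns (params, ec50, fit_ok).  The EC50 is reported only when the fit
    converged with an EC50 inside [min dose / 10, max dose * 10] and a
    non-degenerate response span; otherwise fit_ok is False and no exception
    is raised.  ``three_param`` pins bottom = 0.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.any(d <= 0):
        raise ValueError("doses must be > 0")
    if d.size < 4:
        raise ValueError("need >= 4 dose points for a 4PL fit")
    logd = np.log10(d)
    span = r.max() - r.min()
    if span <= 0 or not np.all(np.isfinite(r)):
        return None, None, False

    p0 = [r.min(), r.max(), float(np.median(logd)), 1.0]
    lo = [-np.inf, -np.inf, logd.min() - 1.0, 0.05]
    hi = [np.inf, np.inf, logd.max() + 1.0, 20.0]
    if three_param:
        model = lambda x, top, le, h: _fourpl_logd(x, 0.0, top, le, h)  # noqa: E731
        p0, lo, hi = p0[1:], lo[1:], hi[1:]
    else:
        model = _fourpl_logd
    try:
        popt, _ = curve_fit(model, logd, r, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        return None, None, False
    if three_param:
        bottom, (top, log_ec50, hill) = 0.0, popt
    else:
        bottom, top, log_ec50, hill = popt
    ec50 = 10.0 ** log_ec50
    # an EC50 at (or essentially on) the optimizer bounds is unidentified,
    # not estimated — the curve's midpoint lies outside the tested range
    if not (d.min() / 10.0 * 1.001 <= ec50 <= d.max() * 10.0 / 1.001):
        return None, None, False
    if abs(top - bottom) < 1e-3 * max(span, 1e-12):
        return None, None, False
    if top < bottom:  # falling curve: swap into canonical top >= bottom form
        bottom, top = top, bottom
    params = FourPLParams(bottom=float(bottom), top=float(top),
                          ec50=float(ec50), hill=float(hill))
    return params, float(ec50), True


def summarize_curve(drug_id: str, cell_line: CellLine, doses, responses) -> DoseResponseCurve:
    """Build a DoseResponseCurve with AUC and (when identifiable) EC50."""
    curve = DoseResponseCurve(drug_id=drug_id, cell_line=cell_line,
                              doses=doses, responses=responses)
    curve.auc = auc_positive_log_dose(curve.doses, curve.responses)
    if curve.doses.size >= 4:
        curve.fit, curve.ec50, curve.fit_ok = fit_ec50(curve.doses, curve.responses)
    return curve


def summarize_dose_table(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a tidy curve table (drug_id, cell_line, dose_uM, response).

    Returns one row per drug with AUC per cell line, dAUC (NIS minus
    YFP-only control, NaN when the control series is absent), EC50 and
    fit_ok from the NIS line, sorted by dAUC (fallback AUC) descending.
    """
    rows = []
    for drug_id, g in table.groupby("drug_id"):
        curves: dict[str, DoseResponseCurve] = {}
        for cl, gg in g.groupby("cell_line"):
            gg = gg.sort_values("dose_uM")
            curves[cl] = summarize_curve(
                drug_id, CellLine(cl), gg["dose_uM"].to_numpy(),
                gg["response"].to_numpy())
        nis = curves.get("NIS_YFP")
        ctl = curves.get("YFP_ONLY")
        if nis is None:
            logger.warning("summarize_dose_table: %s has no NIS_YFP series", drug_id)
            continue
        rows.append({
            "drug_id": drug_id,
            "auc_nis": nis.auc,
            "auc_control": ctl.auc if ctl is not None else math.nan,
            "delta_auc": delta_auc(nis, ctl) if ctl is not None else math.nan,
            "ec50_uM": nis.ec50 if nis.fit_ok else math.nan,
            "fit_ok": nis.fit_ok,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        key = out["delta_auc"].fillna(out["auc_nis"])
        out = out.loc[key.sort_values(ascending=False).index].reset_index(drop=True)
    return out


def picomoles_per_ug(counts: float, total_protein: float) -> float:
    """Convert gamma counts and protein mass to picomoles 125-I per ug
    protein using the counter's specific-activity calibration:
    pmol/ug = 5000 * (counts / total_protein) / 12000."""
    if total_protein <= 0:
        raise ValueError("total_protein must be > 0")
    if counts < 0:
        raise ValueError("counts must be >= 0")
    return 5000.0 * (counts / total_protein) / 12000.0


def fold_uptake(
    treated: Sequence[UptakeMeasurement],
    vehicle: Sequence[UptakeMeasurement],
) -> tuple[float, float]:
    """Mean fold increase in uptake over vehicle, with SEM by first-order
    ratio (delta-method) propagation of the two arms' replicate SEMs."""
    t = np.array([m.picomoles_per_ug for m in treated], dtype=float)
    v = np.array([m.picomoles_per_ug for m in vehicle], dtype=float)
    if t.size < 1 or v.size < 1:
        raise ValueError("need >= 1 replicate per arm")
    mt, mv = float(t.mean()), float(v.mean())
    if mv <= 0:
        raise ValueError("vehicle mean uptake must be > 0")
    fold = mt / mv
    sem_t = float(t.std(ddof=1) / np.sqrt(t.size)) if t.size > 1 else 0.0
    sem_v = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    rel_t = (sem_t / mt) ** 2 if mt > 0 else 0.0
    rel_v = (sem_v / mv) ** 2
    sem = fold * math.sqrt(rel_t + rel_v)
    return fold, sem


def nis_specificity_check(
    plus_perchlorate: Sequence[UptakeMeasurement],
    minus_perchlorate: Sequence[UptakeMeasurement],
    cutoff: float = 0.2,
) -> tuple[bool, float]:
    """Perchlorate competition control: uptake is called NIS-mediated when
    the +perchlorate / -perchlorate mean ratio falls below ``cutoff``."""
    plus = np.array([m.picomoles_per_ug for m in plus_perchlorate], dtype=float)
    minus = np.array([m.picomoles_per_ug for m in minus_perchlorate], dtype=float)
    if plus.size < 1 or minus.size < 1:
        raise ValueError("need both perchlorate arms")
    if minus.mean() <= 0:
        raise ValueError("-perchlorate arm mean must be > 0")
    ratio = float(plus.mean() / minus.mean())
    return ratio < cutoff, ratio


def uptake_fold_table(table: pd.DataFrame, vehicle_condition: str = "vehicle") -> pd.DataFrame:
    """Fold-uptake summary from a replicate table (sample_id, condition,
    counts, total_protein_ug, perchlorate_treated)."""
    def to_measurements(g: pd.DataFrame) -> list[UptakeMeasurement]:
        return [UptakeMeasurement(r.sample_id, r.condition, r.counts,
                                  r.total_protein_ug, bool(r.perchlorate_treated))
                for r in g.itertuples()]

    veh = table[(table["condition"] == vehicle_condition)
                & ~table["perchlorate_treated"]]
    if veh.empty:
        raise ValueError(f"no vehicle condition {vehicle_condition!r} in table")
    vehicle = to_measurements(veh)
    rows = []
    for cond, g in table.groupby("condition"):
        if cond == vehicle_condition:
            continue
        arm = to_measurements(g[~g["perchlorate_treated"]])
        if not arm:
            continue
        fold, sem = fold_uptake(arm, vehicle)
        perc = to_measurements(g[g["perchlorate_treated"]])
        if perc:
            specific, ratio = nis_specificity_check(perc, arm)
        else:
            specific, ratio = None, math.nan
        rows.append({"condition": cond, "fold_uptake": fold, "sem": sem,
                     "nis_specific": specific, "perchlorate_ratio": ratio})
    return pd.DataFrame(rows).sort_values("fold_uptake", ascending=False,
                                          ignore_index=True)


def ddct_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method (target vs reference gene,
    treated vs control condition)."""
    vals = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)
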