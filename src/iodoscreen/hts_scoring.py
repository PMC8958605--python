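"""Primary-screen statistics: the interquartile-mean well-based normalization
chain, Z'-factor assay QC, viability-gated hit calling and ranking.

The hit statistic for a drug well is

    %YFP   = (YFP_0 - YFP_4) / YFP_0 * 100          (fractional quench)
    S_IQM  = %YFP / mu_IQ(plate)                     (per-plate ratio norm)
    S_IQMW = S_IQM / mu_IQW(well position)           (per-position ratio norm)
    dYFP   = (S_IQMW(drug) - mean S_IQMW(plate DMSO)) / SD(S_IQMW, all DMSO)

where mu_IQ and mu_IQW are interquartile (trimmed) means.  Because the two
normalizations are ratios, any multiplicative plate-wide or position-wide
artefact cancels exactly.  Positive dYFP means more fluorescence quench than
vehicle, i.e. increased intracellular iodide.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .screen_model import (
    AssayQuality,
    KineticWell,
    NormalizedWell,
    Role,
    ScreenConfig,
    ScreenStats,
    ScreenValidationError,
)

logger = logging.getLogger("iodoscreen")


def percent_yfp(yfp0: float, yfp4: float) -> float:
    """Percentage fluorescence quench between the pre-injection reading and
    the final cycle; positive when fluorescence dropped."""
    if not yfp0 > 0:
        raise ValueError(f"yfp0 must be > 0, got {yfp0}")
    return (yfp0 - yfp4) / yfp0 * 100.0


def interquartile_mean(values: Sequence[float], trim_proportion: float = 0.5) -> float:
    """Trimmed mean with spreadsheet TRIMMEAN semantics.

    Excludes floor(n * trim_proportion / 2) points from each tail of the
    sorted values and returns the mean of the rest; trim_proportion=0.5 gives
    the interquartile mean.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("interquartile_mean of empty input")
    if not 0 <= trim_proportion < 1:
        raise ValueError("trim_proportion must be in [0, 1)")
    # scipy trims floor(n * proportiontocut) per side == TRIMMEAN's
    # floor(n * percent / 2) per side.
    return float(stats.trim_mean(arr, proportiontocut=trim_proportion / 2.0))


def normalize_per_plate(
    pct_by_well: dict, trim_proportion: float = 0.5
) -> tuple[dict, dict[str, float]]:
    """Divide each well's %YFP by its plate's interquartile mean (mu_IQ).

    ``pct_by_well`` maps WellAddress -> %YFP.  Returns (S_IQM per address,
    mu_IQ per plate).  Plates whose mu_IQ is 0 are flagged and their wells
    excluded.
    """
    by_plate: dict[str, list[float]] = {}
    for addr, pct in pct_by_well.items():
        by_plate.setdefault(addr.plate_id, []).append(pct)
    mu_iq: dict[str, float] = {}
    for plate, vals in by_plate.items():
        mu_iq[plate] = interquartile_mean(vals, trim_proportion)
    s_iqm = {}
    dropped = []
    for addr, pct in pct_by_well.items():
        mu = mu_iq[addr.plate_id]
        if mu == 0:
            dropped.append(addr)
            continue
        s_iqm[addr] = pct / mu
    if dropped:
        bad_plates = sorted({a.plate_id for a in dropped})
        logger.warning("normalize_per_plate: mu_IQ == 0 on plates %s; "
                       "%d wells excluded", bad_plates, len(dropped))
    return s_iqm, mu_iq


def normalize_per_wellposition(
    s_iqm_by_well: dict, trim_proportion: float = 0.5
) -> tuple[dict, dict[tuple[str, int], float]]:
    """Divide each well's S_IQM by the interquartile mean of its well
    position across the whole screen (mu_IQW), removing positional artefacts
    such as edge effects."""
    by_pos: dict[tuple[str, int], list[float]] = {}
    for addr, v in s_iqm_by_well.items():
        by_pos.setdefault(addr.position, []).append(v)
    mu_iqw = {pos: interquartile_mean(vals, trim_proportion)
              for pos, vals in by_pos.items()}
    s_iqmw = {}
    dropped = []
    for addr, v in s_iqm_by_well.items():
        mu = mu_iqw[addr.position]
        if mu == 0:
            dropped.append(addr)
            continue
        s_iqmw[addr] = v / mu
    if dropped:
        bad = sorted({a.position for a in dropped})
        logger.warning("normalize_per_wellposition: mu_IQW == 0 at positions "
                       "%s; %d wells excluded", bad, len(dropped))
    return s_iqmw, mu_iqw


def delta_yfp(
    drug_s_iqmw: float,
    plate_matched_dmso_s_iqmw: float,
    dmso_sd_screenwide: float,
) -> float:
    """Drug effect in units of the screen-wide DMSO standard deviation,
    relative to the same plate's mean DMSO value."""
    if not (math.isfinite(dmso_sd_screenwide) and dmso_sd_screenwide > 0):
        raise ScreenValidationError(
            "screen-wide DMSO SD must be > 0; check that the screen has "
            "enough DMSO control wells with variation")
    return (drug_s_iqmw - plate_matched_dmso_s_iqmw) / dmso_sd_screenwide


def z_factor(pos_values: Sequence[float], neg_values: Sequence[float]) -> AssayQuality:
    """Z'-factor: 1 - 3 (SD_pos + SD_neg) / |mean_pos - mean_neg|.

    Values > 0.5 indicate an assay window wide enough for full-scale
    high-throughput screening.  SDs are sample standard deviations.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("z_factor needs >= 2 values per control arm")
    mean_p, mean_n = float(pos.mean()), float(neg.mean())
    if mean_p == mean_n:
        raise ValueError("z_factor undefined: control means are equal")
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mean_p - mean_n)
    return AssayQuality(mean_pos=mean_p, sd_pos=sd_p, mean_neg=mean_n,
                        sd_neg=sd_n, z_factor=z)


def score_screen(
    wells: Sequence[KineticWell],
    config: Optional[ScreenConfig] = None,
) -> tuple[list[NormalizedWell], ScreenStats]:
    """Run the full normalization chain over a screen.

    Non-analyzable wells (yfp0 <= 0 or missing trace) are excluded from all
    statistics and omitted from the output.  Replicate drug wells are kept
    as individual wells; call_hits averages replicates at the S_IQMW level.
    """
    config = config or ScreenConfig()
    usable = [w for w in wells if w.analyzable]
    excluded = len(wells) - len(usable)
    logger.info("score_screen: %d wells in, %d excluded as non-analyzable",
                len(wells), excluded)
    if not usable:
        raise ScreenValidationError("no analyzable wells in screen")

    cycle = min(config.cycles_used, min(len(w.yfp_cycles) for w in usable))
    pct = {w.address: percent_yfp(w.yfp0, w.yfp_at(cycle)) for w in usable}
    s_iqm, mu_iq = normalize_per_plate(pct, config.trim_proportion)
    s_iqmw, mu_iqw = normalize_per_wellposition(s_iqm, config.trim_proportion)

    dmso_by_plate: dict[str, list[float]] = {}
    all_dmso: list[float] = []
    for w in usable:
        if w.role is Role.DMSO_CONTROL and w.address in s_iqmw:
            dmso_by_plate.setdefault(w.address.plate_id, []).append(s_iqmw[w.address])
            all_dmso.append(s_iqmw[w.address])
    if len(all_dmso) < 2:
        raise ScreenValidationError(
            f"need >= 2 analyzable DMSO wells screen-wide, got {len(all_dmso)}")
    dmso_sd = float(np.std(all_dmso, ddof=1))
    stats_out = ScreenStats(
        mu_iq_per_plate=mu_iq,
        mu_iqw_per_position=mu_iqw,
        dmso_sd=dmso_sd,
        n_dmso=len(all_dmso),
    )

    dmso_mean_by_plate = {p: float(np.mean(v)) for p, v in dmso_by_plate.items()}
    out: list[NormalizedWell] = []
    for w in usable:
        if w.address not in s_iqmw:
            continue
        plate = w.address.plate_id
        if plate not in dmso_mean_by_plate:
            raise ScreenValidationError(
                f"plate {plate} has no analyzable DMSO wells; "
                "delta-YFP needs a plate-matched DMSO reference")
        d = delta_yfp(s_iqmw[w.address], dmso_mean_by_plate[plate], dmso_sd)
        out.append(NormalizedWell(
            address=w.address, drug_id=w.drug_id, role=w.role,
            pct_yfp=pct[w.address], s_iqm=s_iqm[w.address],
            s_iqmw=s_iqmw[w.address], delta_yfp=d, viability=w.viability,
        ))
    logger.info("score_screen: %d wells scored, DMSO SD=%.4g over %d wells",
                len(out), dmso_sd, len(all_dmso))
    return out, stats_out


def call_hits(
    wells: Iterable[NormalizedWell],
    config: Optional[ScreenConfig] = None,
) -> list[NormalizedWell]:
    """Flag hits and return drug wells ranked by dYFP (descending).

    A drug is a hit when dYFP exceeds the threshold (strict > by default)
    AND viability is at or above the floor — drugs with negligible viability
    are not counted however strong the quench.  Replicate wells of one drug
    are averaged (dYFP and viability) into a single ranked entry.  Ties
    break lexicographically by drug id.
    """
    config = config or ScreenConfig()
    drug_wells = [w for w in wells if w.role is Role.DRUG and w.drug_id]
    by_drug: dict[str, list[NormalizedWell]] = {}
    for w in drug_wells:
        by_drug.setdefault(w.drug_id, []).append(w)

    ranked: list[NormalizedWell] = []
    for drug_id, group in by_drug.items():
        d = float(np.mean([w.delta_yfp for w in group]))
        v = float(np.mean([w.viability for w in group]))
        rep = group[0]
        passes = (d > config.hit_threshold if config.strict_hit_inequality
                  else d >= config.hit_threshold)
        ranked.append(NormalizedWell(
            address=rep.address, drug_id=drug_id, role=Role.DRUG,
            pct_yfp=float(np.mean([w.pct_yfp for w in group])),
            s_iqm=float(np.mean([w.s_iqm for w in group])),
            s_iqmw=float(np.mean([w.s_iqmw for w in group])),
            delta_yfp=d, viability=v,
            hit=bool(passes and v >= config.viability_floor),
        ))
    ranked.sort(key=lambda w: (-w.delta_yfp, w.drug_id))
    n_hits = sum(w.hit for w in ranked)
    logger.info("call_hits: %d drugs, %d hits (threshold %.3g, viability floor %.2f)",
                len(ranked), n_hits, config.hit_threshold, config.viability_floor)
    return ranked


def plate_z_factors(wells: Sequence[KineticWell], cycle: int = 4) -> dict[str, AssayQuality]:
    """Per-plate Z' from whatever wells are labeled NaI-positive vs
    PBS-negative, computed on %YFP."""
    by_plate: dict[str, dict[Role, list[float]]] = {}
    for w in wells:
        if not w.analyzable:
            continue
        c = min(cycle, len(w.yfp_cycles))
        if w.role in (Role.NAI_POSITIVE, Role.PBS_NEGATIVE):
            by_plate.setdefault(w.address.plate_id, {}).setdefault(
                w.role, []).append(percent_yfp(w.yfp0, w.yfp_at(c)))
    out = {}
    for plate, arms in sorted(by_plate.items()):
        pos = arms.get(Role.NAI_POSITIVE, [])
        neg = arms.get(Role.PBS_NEGATIVE, [])
        if len(pos) >= 2 and len(neg) >= 2:
            out[plate] = z_factor(pos, neg)
    return out
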