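"""Domain types and I/O for YFP-iodide screening data.

The screen measures intracellular iodide influx through the sodium iodide
symporter (NIS) with a halide-sensitive YFP biosensor: iodide entering the
cell quenches YFP fluorescence, so the fractional fluorescence drop after
NaI injection reports iodide uptake.  This module holds the well-level data
model (kinetic traces, roles, plate coordinates), the long-format CSV/TSV
readers and writers used by every stage, plate-layout validation, and the
run configuration.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

logger = logging.getLogger("iodoscreen")

ROWS = "ABCDEFGH"
N_COLUMNS = 12


class ScreenFormatError(ValueError):
    """Malformed screen file (missing columns, unparseable rows)."""


class ScreenValidationError(ValueError):
    """Structurally valid file that violates screen invariants."""


class Role(enum.Enum):
    """What a well contains."""

    DRUG = "DRUG"
    DMSO_CONTROL = "DMSO_CONTROL"
    NAI_POSITIVE = "NAI_POSITIVE"
    PBS_NEGATIVE = "PBS_NEGATIVE"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well on a 96-well plate: plate label, row letter A-H, column 1-12."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ScreenValidationError(f"row {self.row!r} not in A-H")
        if not 1 <= self.column <= N_COLUMNS:
            raise ScreenValidationError(f"column {self.column} not in 1-12")

    @property
    def well(self) -> str:
        return f"{self.row}{self.column:02d}"

    @property
    def position(self) -> tuple[str, int]:
        """(row, column) — the plate-independent well position."""
        return (self.row, self.column)

    @classmethod
    def parse(cls, plate_id: str, well: str) -> "WellAddress":
        well = well.strip().upper()
        if len(well) < 2 or not well[1:].isdigit():
            raise ScreenValidationError(f"cannot parse well label {well!r}")
        return cls(plate_id=plate_id, row=well[0], column=int(well[1:]))


@dataclass
class KineticWell:
    """One well's identity and fluorescence trace around iodide injection.

    ``yfp0`` is the raw fluorescence before NaI injection; ``yfp_cycles``
    holds the post-injection readings (cycles 1..4, 3-minute spacing).
    ``viability`` is relative to vehicle (1.0 = vehicle-like).
    """

    address: WellAddress
    role: Role
    drug_id: Optional[str] = None
    dose: Optional[float] = None
    yfp0: float = float("nan")
    yfp_cycles: Sequence[float] = ()
    viability: float = 1.0

    @property
    def analyzable(self) -> bool:
        """Usable in normalization statistics: positive pre-read, a trace."""
        return (
            math.isfinite(self.yfp0)
            and self.yfp0 > 0
            and len(self.yfp_cycles) >= 1
            and all(math.isfinite(v) for v in self.yfp_cycles)
        )

    def yfp_at(self, cycle: int) -> float:
        """Reading at a 1-based post-injection cycle."""
        if not 1 <= cycle <= len(self.yfp_cycles):
            raise IndexError(f"cycle {cycle} outside 1..{len(self.yfp_cycles)}")
        return self.yfp_cycles[cycle - 1]


@dataclass
class NormalizedWell:
    """The %YFP -> S_IQM -> S_IQMW -> dYFP chain for one drug/control well."""

    address: WellAddress
    drug_id: Optional[str]
    role: Role
    pct_yfp: float
    s_iqm: float = float("nan")
    s_iqmw: float = float("nan")
    delta_yfp: float = float("nan")
    viability: float = 1.0
    hit: bool = False


@dataclass
class ScreenStats:
    """Screen-level normalization statistics.

    ``mu_iq_per_plate`` maps plate -> interquartile mean of %YFP (mu_IQ);
    ``mu_iqw_per_position`` maps (row, col) -> interquartile mean of S_IQM
    across the screen (mu_IQW); ``dmso_sd`` is the screen-wide SD of S_IQMW
    over DMSO wells — the denominator of the dYFP statistic.
    """

    mu_iq_per_plate: dict[str, float] = field(default_factory=dict)
    mu_iqw_per_position: dict[tuple[str, int], float] = field(default_factory=dict)
    dmso_sd: float = float("nan")
    n_dmso: int = 0


@dataclass
class AssayQuality:
    """Z'-factor assay window summary for one positive/negative control pair."""

    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    z_factor: float

    @property
    def suitable(self) -> bool:
        """Screen-ready window by the conventional Z' > 0.5 rule."""
        return self.z_factor > 0.5


@dataclass
class ScreenConfig:
    """Tunable analysis parameters.

    hit_threshold: dYFP cutoff (strict >) for hit calling.
    viability_floor: minimum viability fraction for a hit to be counted.
    trim_proportion: total fraction trimmed by the interquartile mean.
    cycles_used: which post-injection cycle is treated as YFP_4.
    """

    hit_threshold: float = 1.5
    viability_floor: float = 0.70
    trim_proportion: float = 0.5
    cycles_used: int = 4
    strict_hit_inequality: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.trim_proportion < 1:
            raise ScreenValidationError("trim_proportion must be in (0, 1)")
        if self.hit_threshold <= 0:
            raise ScreenValidationError("hit_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


SCREEN_COLUMNS = [
    "plate_id", "well", "role", "drug_id", "dose_uM",
    "yfp0", "yfp_c1", "yfp_c2", "yfp_c3", "yfp_c4", "viability",
]

RESULT_COLUMNS = [
    "plate", "well", "drug_id", "pct_yfp", "s_iqm", "s_iqmw",
    "delta_yfp", "viability", "hit",
]


def read_screen(path: Union[str, Path]) -> list[KineticWell]:
    """Read a long-format plate CSV (one row per well) into KineticWells.

    Wells with yfp0 <= 0 are kept but flagged non-analyzable (they are
    reported and excluded from normalization statistics downstream, never
    imputed).  Duplicate (plate, well) rows raise a validation error.
    """
    path = Path(path)
    wells: list[KineticWell] = []
    seen: set[WellAddress] = set()
    problems: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ScreenFormatError(f"{path}: empty file")
        missing = [c for c in SCREEN_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ScreenFormatError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                addr = WellAddress.parse(row["plate_id"].strip(), row["well"])
                role = Role(row["role"].strip())
                drug_id = row["drug_id"].strip() or None
                dose = float(row["dose_uM"]) if row["dose_uM"].strip() else None
                yfp0 = float(row["yfp0"])
                cycles = tuple(
                    float(row[f"yfp_c{i}"]) for i in range(1, 5)
                    if row[f"yfp_c{i}"].strip()
                )
                viability = float(row["viability"]) if row["viability"].strip() else 1.0
            except (ValueError, KeyError) as exc:
                raise ScreenFormatError(f"{path}:{lineno}: {exc}") from exc
            if addr in seen:
                raise ScreenValidationError(
                    f"{path}:{lineno}: duplicate well {addr.plate_id}/{addr.well}"
                )
            seen.add(addr)
            well = KineticWell(
                address=addr, role=role, drug_id=drug_id, dose=dose,
                yfp0=yfp0, yfp_cycles=cycles, viability=viability,
            )
            if not well.analyzable:
                problems.append(f"{path}:{lineno}: {addr.plate_id}/{addr.well} "
                                f"not analyzable (yfp0={yfp0})")
            wells.append(well)
    logger.info("read_screen: %d wells from %s (%d flagged non-analyzable)",
                len(wells), path, len(problems))
    for p in problems:
        logger.info("read_screen: %s", p)
    return wells


def write_screen(wells: Iterable[KineticWell], path: Union[str, Path]) -> None:
    """Write KineticWells back to the long CSV dialect read_screen accepts."""
    path = Path(path)
    rows = sorted(wells, key=lambda w: w.address)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCREEN_COLUMNS)
        for w in rows:
            cyc = list(w.yfp_cycles) + [""] * (4 - len(w.yfp_cycles))
            writer.writerow([
                w.address.plate_id, w.address.well, w.role.value,
                w.drug_id or "",
                "" if w.dose is None else repr(float(w.dose)),
                repr(float(w.yfp0)),
                *(("" if c == "" else repr(float(c))) for c in cyc),
                repr(float(w.viability)),
            ])
    logger.info("write_screen: %d wells -> %s", len(rows), path)


def write_results(wells: Iterable[NormalizedWell], path: Union[str, Path]) -> None:
    """Write normalized wells as a deterministic TSV sorted by plate/row/col."""
    path = Path(path)
    rows = sorted(wells, key=lambda w: w.address)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(RESULT_COLUMNS)
        for w in rows:
            writer.writerow([
                w.address.plate_id, w.address.well, w.drug_id or "",
                f"{w.pct_yfp:.6f}", f"{w.s_iqm:.6f}", f"{w.s_iqmw:.6f}",
                f"{w.delta_yfp:.6f}", f"{w.viability:.6f}",
                "1" if w.hit else "0",
            ])
    logger.info("write_results: %d wells -> %s", len(rows), path)


def read_results(path: Union[str, Path]) -> list[dict]:
    """Read a results TSV back into plain dicts (typed columns)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append({
                "plate": row["plate"], "well": row["well"],
                "drug_id": row["drug_id"] or None,
                "pct_yfp": float(row["pct_yfp"]),
                "s_iqm": float(row["s_iqm"]),
                "s_iqmw": float(row["s_iqmw"]),
                "delta_yfp": float(row["delta_yfp"]),
                "viability": float(row["viability"]),
                "hit": row["hit"] == "1",
            })
    return out


@dataclass
class LayoutFinding:
    level: str  # "warning" | "error"
    plate_id: Optional[str]
    message: str


def validate_layout(wells: Sequence[KineticWell]) -> list[LayoutFinding]:
    """Report-only layout check.

    Flags plates lacking NaI-positive or PBS-negative control wells, a
    screen with no DMSO wells (which makes the dYFP denominator
    uncomputable), and occupancy gaps relative to the fullest plate.
    """
    findings: list[LayoutFinding] = []
    plates: dict[str, list[KineticWell]] = {}
    for w in wells:
        plates.setdefault(w.address.plate_id, []).append(w)
    for plate_id, pw in sorted(plates.items()):
        roles = {w.role for w in pw}
        if Role.NAI_POSITIVE not in roles:
            findings.append(LayoutFinding(
                "warning", plate_id, f"plate {plate_id} has no NAI_POSITIVE wells"))
        if Role.PBS_NEGATIVE not in roles:
            findings.append(LayoutFinding(
                "warning", plate_id, f"plate {plate_id} has no PBS_NEGATIVE wells"))
    n_dmso = sum(1 for w in wells if w.role is Role.DMSO_CONTROL)
    if wells and n_dmso == 0:
        findings.append(LayoutFinding(
            "error", None,
            "screen has no DMSO_CONTROL wells: delta-YFP is uncomputable "
            "(its denominator is the screen-wide SD over DMSO wells)"))
    occupancy = {p: {w.address.position for w in pw} for p, pw in plates.items()}
    if occupancy:
        fullest = max(len(pos) for pos in occupancy.values())
        for plate_id, pos in sorted(occupancy.items()):
            if len(pos) < fullest:
                findings.append(LayoutFinding(
                    "warning", plate_id,
                    f"plate {plate_id} occupies {len(pos)} positions "
                    f"vs {fullest} on the fullest plate"))
    logger.info("validate_layout: %d plates, %d findings", len(plates), len(findings))
    return findings
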