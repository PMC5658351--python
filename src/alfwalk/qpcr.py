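"""Enrichment-evaluation arithmetic: relative Cq, dilution correction,
fold-change estimation, and genome copy numbers.

The enrichment achieved by linear enrichment (LE) and the subsequent
semi-nested PCR (snPCR) is quantified by qPCR before and after each step.
The relative Cq of a target is the Cq of the starting material minus the Cq
after the step; with an assumed amplification efficiency E (default 2, a
perfect doubling per cycle), a difference of dCq cycles corresponds to a
fold change of E**dCq.  Material diluted d-fold before measurement has its
Cq corrected downward by log_E(d) cycles.

Rounding follows the reporting chain of the published protocol: logs to two
decimals, dCq to one decimal before exponentiation, fold changes to three
significant figures.  A target diluted beyond the detection limit is an
explicit BEYOND_DETECTION state that poisons any arithmetic touching it —
never a number.

Copy numbers convert a DNA mass to haploid genome equivalents via the 1C
value (haploid genome mass in pg: 2.725 for maize, 2.33 for cotton) and a
zygosity factor (0.5 for hetero-/hemizygous material, where the insert sits
on one homolog only).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Optional, Union

import pandas as pd


class _BeyondDetection(enum.Enum):
    """Singleton sentinel for a qPCR signal beyond the detection limit."""

    BEYOND_DETECTION = "beyond_detection"

    def __repr__(self) -> str:
        return "BEYOND_DETECTION"


BEYOND_DETECTION = _BeyondDetection.BEYOND_DETECTION

Cycles = Union[float, _BeyondDetection]


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class CqRecord:
    """qPCR measurements for one target at a known distance from the LE start."""

    target_name: str
    distance_nt: int
    cq_sm: Cycles
    cq_le: Cycles
    cq_snpcr: Cycles
    dilution_le: float = 1.0
    dilution_snpcr: float = 1.0

    def __post_init__(self) -> None:
        for label, value in (("cq_sm", self.cq_sm), ("cq_le", self.cq_le),
                             ("cq_snpcr", self.cq_snpcr)):
            if isinstance(value, _BeyondDetection):
                continue
            if not value > 0:
                raise QpcrError(f"{self.target_name}: {label} must be > 0 when detected")


@dataclass(frozen=True)
class EnrichmentEstimate:
    target_name: str
    delta_cq: Cycles
    fold_change: Cycles


@dataclass(frozen=True)
class MixtureComponent:
    """One GMO in the mixture: mass fraction, genome size, zygosity."""

    name: str
    mass_fraction: float
    c1_pg: float
    zygosity_factor: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.mass_fraction <= 1.0):
            raise QpcrError(f"{self.name}: mass_fraction outside [0, 1]")
        if not self.c1_pg > 0:
            raise QpcrError(f"{self.name}: 1C value must be positive")
        if not (0.0 < self.zygosity_factor <= 1.0):
            raise QpcrError(f"{self.name}: zygosity_factor outside (0, 1]")


# ---------------------------------------------------------------------------
# Cq arithmetic
# ---------------------------------------------------------------------------

def relative_cq(cq_sm: Cycles, cq_step: Cycles) -> Cycles:
    """Cq of the starting material minus the Cq after an enrichment step.

    Zero for the starting material itself; BEYOND_DETECTION propagates.
    """
    if isinstance(cq_sm, _BeyondDetection) or isinstance(cq_step, _BeyondDetection):
        return BEYOND_DETECTION
    return cq_sm - cq_step


def dilution_correct(cq: Cycles, dilution_factor: float, efficiency: float = 2.0) -> Cycles:
    """Correct a measured Cq for a pre-measurement dilution.

    A d-fold dilution delays detection by log_E(d) cycles (rounded to two
    decimals, e.g. 6.64 for a 100-fold dilution at E=2); that many cycles are
    subtracted from the measured value.
    """
    if dilution_factor < 1:
        raise QpcrError(f"dilution_factor must be >= 1, got {dilution_factor}")
    if efficiency <= 1:
        raise QpcrError(f"efficiency must be > 1, got {efficiency}")
    if isinstance(cq, _BeyondDetection):
        return BEYOND_DETECTION
    shift = round(math.log(dilution_factor, efficiency), 2)
    return cq - shift


def fold_change(
    cq_sm: Cycles,
    cq_obs: Cycles,
    dilution_factor: float = 1.0,
    efficiency: float = 2.0,
) -> Cycles:
    """Estimated enrichment of a target from its Cq shift.

    dCq = Cq(starting material) - dilution-corrected Cq(after step), rounded
    to one decimal; the fold change is efficiency**dCq.
    """
    corrected = dilution_correct(cq_obs, dilution_factor, efficiency)
    delta = relative_cq(cq_sm, corrected)
    if isinstance(delta, _BeyondDetection):
        return BEYOND_DETECTION
    return efficiency ** round(delta, 1)


def delta_cq(
    cq_sm: Cycles,
    cq_obs: Cycles,
    dilution_factor: float = 1.0,
    efficiency: float = 2.0,
) -> Cycles:
    """The rounded dCq underlying :func:`fold_change`."""
    corrected = dilution_correct(cq_obs, dilution_factor, efficiency)
    delta = relative_cq(cq_sm, corrected)
    if isinstance(delta, _BeyondDetection):
        return BEYOND_DETECTION
    return round(delta, 1)


def round_sig(x: float, figures: int = 3) -> float:
    """Round to a number of significant figures (reporting helper)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, figures - 1 - exponent)


# ---------------------------------------------------------------------------
# Copy numbers
# ---------------------------------------------------------------------------

def copy_number(
    total_mass_ng: float,
    mass_fraction: float,
    c1_pg: float,
    zygosity_factor: float = 0.5,
) -> int:
    """Haploid GM genome copies in a DNA mass.

    copies = total_mass_ng * 1000 * mass_fraction / c1_pg * zygosity_factor,
    rounded to the nearest integer.  200 ng of a 97% maize component at
    1C = 2.725 pg and zygosity 0.5 gives 35596 copies.
    """
    if not c1_pg > 0:
        raise QpcrError(f"1C value must be positive, got {c1_pg}")
    if total_mass_ng <= 0:
        raise QpcrError(f"total mass must be positive, got {total_mass_ng}")
    if mass_fraction < 0:
        raise QpcrError(f"mass_fraction must be >= 0, got {mass_fraction}")
    if not (0.0 < zygosity_factor <= 1.0):
        raise QpcrError(f"zygosity_factor outside (0, 1]: {zygosity_factor}")
    return round(total_mass_ng * 1000.0 * mass_fraction / c1_pg * zygosity_factor)


def mixture_copy_numbers(
    total_mass_ng: float, components: list[MixtureComponent]
) -> dict[str, int]:
    total_fraction = sum(c.mass_fraction for c in components)
    if not math.isclose(total_fraction, 1.0, abs_tol=1e-6):
        raise QpcrError(f"mass fractions sum to {total_fraction}, expected 1")
    return {
        c.name: copy_number(total_mass_ng, c.mass_fraction, c.c1_pg, c.zygosity_factor)
        for c in components
    }


# ---------------------------------------------------------------------------
# Table input/output
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "target", "distance_nt", "cq_sm", "cq_le", "cq_snpcr",
    "dilution_le", "dilution_snpcr",
]

_ND_STRINGS = {"nd", "na", "beyond_detection", "-", ""}


def _parse_cq(value) -> Cycles:
    if isinstance(value, str) and value.strip().lower() in _ND_STRINGS:
        return BEYOND_DETECTION
    if pd.isna(value):
        return BEYOND_DETECTION
    return float(value)


def read_cq_table(path: Union[str, Path, StringIO]) -> list[CqRecord]:
    """Read a TSV of qPCR measurements (see _TABLE_COLUMNS for the layout)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise QpcrError(f"cq table is missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            CqRecord(
                target_name=row["target"],
                distance_nt=int(row["distance_nt"]),
                cq_sm=_parse_cq(row["cq_sm"]),
                cq_le=_parse_cq(row["cq_le"]),
                cq_snpcr=_parse_cq(row["cq_snpcr"]),
                dilution_le=float(row["dilution_le"]),
                dilution_snpcr=float(row["dilution_snpcr"]),
            )
        )
    return records


def evaluate_cq_table(records: list[CqRecord], efficiency: float = 2.0) -> pd.DataFrame:
    """Relative Cq and fold change per target for both enrichment steps.

    BEYOND_DETECTION states are rendered as the string ``beyond_detection``.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "target": rec.target_name,
            "distance_nt": rec.distance_nt,
        }
        for step, cq_obs, dilution in (
            ("le", rec.cq_le, rec.dilution_le),
            ("snpcr", rec.cq_snpcr, rec.dilution_snpcr),
        ):
            d = delta_cq(rec.cq_sm, cq_obs, dilution, efficiency)
            f = fold_change(rec.cq_sm, cq_obs, dilution, efficiency)
            if isinstance(d, _BeyondDetection):
                row[f"relative_cq_{step}"] = "beyond_detection"
                row[f"fold_change_{step}"] = "beyond_detection"
            else:
                row[f"relative_cq_{step}"] = d
                row[f"fold_change_{step}"] = round_sig(f, 3)
        rows.append(row)
    return pd.DataFrame(rows)
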