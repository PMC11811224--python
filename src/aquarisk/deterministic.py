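"""Point-estimate risk engine: EDI, HQ and HI for every brand and age group.

The chronic ingestion model is the standard screening-level chain

    EDI = C * IR * EF * ED / (BW * AT)        [mg/kg/day]
    HQ  = EDI / RfD                           [dimensionless]
    HI  = sum of HQ over co-occurring contaminants

where C is the concentration in water (mg/L), IR the ingestion rate (L/day),
EF the exposure frequency (days/year), ED the exposure duration (years), BW
body weight (kg), AT the averaging time (days), and RfD the contaminant's
chronic oral reference dose (mg/kg/day).  When AT = ED * EF — true for every
default profile — the duration terms cancel and EDI reduces to C * IR / BW.

HQ > 1 signals potential non-carcinogenic concern for the receptor group;
the hazard index applies the same threshold to the summed quotients.
Hazard indices are always summed *within* a brand, pairing panel records by
brand identifier, never by row position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import BrandPanel, ExposureProfile, round_half_up
from .errors import ConfigurationError, EmptyInputError, ValidationError

__all__ = [
    "RiskCell",
    "HiCell",
    "RiskTable",
    "GroupSummary",
    "edi",
    "hazard_quotient",
    "hazard_index",
    "risk_table",
    "group_summary",
]

#: Exceedance threshold for both HQ and HI ("greater than 1", strict).
HAZARD_THRESHOLD = 1.0


def _edi_expr(c, ir, ef, ed, bw, at):
    # Shared between the deterministic and Monte Carlo engines so that a
    # point-distribution simulation collapses onto this value bit-for-bit.
    return c * ir * ef * ed / (bw * at)


def edi(c: float, profile: ExposureProfile) -> float:
    """Estimated daily intake, mg per kg body weight per day.

    ``c`` is the concentration in water, mg/L.  Accepts numpy arrays for ``c``
    and broadcasts.
    """
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValidationError(f"concentration must be >= 0, got {c!r}")
    result = _edi_expr(arr, profile.ir, profile.ef, profile.ed, profile.bw, profile.at)
    return float(result) if np.isscalar(c) or arr.ndim == 0 else result


def hazard_quotient(edi_value: float, rfd: float) -> float:
    """Ratio of intake to reference dose; values above 1 flag potential concern."""
    if not (rfd > 0):
        raise ConfigurationError(f"rfd must be > 0, got {rfd!r}")
    arr = np.asarray(edi_value, dtype=float) / rfd
    return float(arr) if arr.ndim == 0 else arr


def hazard_index(hqs: Iterable[float]) -> float:
    """Arithmetic sum of hazard quotients for one receptor."""
    values = list(hqs)
    if not values:
        raise EmptyInputError("hazard_index requires at least one hazard quotient")
    return float(sum(values))


@dataclass(frozen=True)
class RiskCell:
    """EDI and HQ for one brand, one receptor group, one contaminant."""

    brand: str
    group: str
    contaminant: str
    edi: float
    hq: float


@dataclass(frozen=True)
class HiCell:
    """Hazard index (sum of same-brand HQs) for one brand and group."""

    brand: str
    group: str
    hi: float


@dataclass(frozen=True)
class RiskTable:
    """Full deterministic output: one cell per brand x group x contaminant.

    ``cells`` and ``hi_cells`` preserve panel row order within each group;
    groups appear in the order the profiles were given.
    """

    cells: tuple[RiskCell, ...]
    hi_cells: tuple[HiCell, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "brand": [c.brand for c in self.cells],
                "group": [c.group for c in self.cells],
                "contaminant": [c.contaminant for c in self.cells],
                "edi": [c.edi for c in self.cells],
                "hq": [c.hq for c in self.cells],
            }
        )

    def hi_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "brand": [c.brand for c in self.hi_cells],
                "group": [c.group for c in self.hi_cells],
                "hi": [c.hi for c in self.hi_cells],
            }
        )

    def cell(self, brand: str, group: str, contaminant: str) -> RiskCell:
        for c in self.cells:
            if c.brand == brand and c.group == group and c.contaminant == contaminant:
                return c
        raise KeyError((brand, group, contaminant))

    def hi_cell(self, brand: str, group: str) -> HiCell:
        for c in self.hi_cells:
            if c.brand == brand and c.group == group:
                return c
        raise KeyError((brand, group))

    def hq_exceedances(self, group: str, contaminant: str, threshold: float = HAZARD_THRESHOLD) -> tuple[str, ...]:
        """Brands whose HQ is strictly greater than ``threshold`` for the group."""
        return tuple(
            c.brand
            for c in self.cells
            if c.group == group and c.contaminant == contaminant and c.hq > threshold
        )

    def hi_exceedances(self, group: str, threshold: float = HAZARD_THRESHOLD) -> tuple[str, ...]:
        """Brands whose hazard index is strictly greater than ``threshold``."""
        return tuple(c.brand for c in self.hi_cells if c.group == group and c.hi > threshold)


def risk_table(
    panels: Sequence[BrandPanel],
    profiles: Sequence[ExposureProfile],
) -> RiskTable:
    """Compute every per-brand EDI/HQ cell plus same-brand hazard indices.

    All panels must cover the same brand set; mismatches raise a
    :class:`ValidationError` listing the symmetric difference.  HI pairing is
    by brand identifier, so panel row order never affects the index.
    """
    if not panels:
        raise EmptyInputError("risk_table requires at least one panel")
    if not profiles:
        raise EmptyInputError("risk_table requires at least one exposure profile")
    names = [p.contaminant.name for p in panels]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate contaminants in panels: {names}")

    reference = set(panels[0].brands)
    for p in panels[1:]:
        diff = reference.symmetric_difference(p.brands)
        if diff:
            raise ValidationError(
                f"panels for {panels[0].contaminant.name!r} and {p.contaminant.name!r} "
                f"cover different brands; symmetric difference: {sorted(diff)}"
            )

    cells: list[RiskCell] = []
    hi_cells: list[HiCell] = []
    brand_order = panels[0].brands
    for profile in profiles:
        hq_by_brand: dict[str, float] = {b: 0.0 for b in brand_order}
        for panel in panels:
            rfd = panel.contaminant.rfd
            for record in panel:
                e = edi(record.measured, profile)
                hq = hazard_quotient(e, rfd)
                cells.append(
                    RiskCell(
                        brand=record.brand,
                        group=profile.group,
                        contaminant=panel.contaminant.name,
                        edi=e,
                        hq=hq,
                    )
                )
                hq_by_brand[record.brand] += hq
        for brand in brand_order:
            hi_cells.append(HiCell(brand=brand, group=profile.group, hi=hq_by_brand[brand]))
    return RiskTable(cells=tuple(cells), hi_cells=tuple(hi_cells))


@dataclass(frozen=True)
class GroupSummary:
    """Per-group aggregates of a :class:`RiskTable`.

    ``risk`` has one row per (group, contaminant) with mean/min/max of EDI and
    HQ and the count of brands with HQ > 1; ``hi`` has one row per group with
    mean/min/max of the hazard index and the count of brands with HI > 1.
    Means are arithmetic over brands; group order follows the input table.
    """

    risk: pd.DataFrame
    hi: pd.DataFrame

    def rounded(self, ndigits: int = 2) -> "GroupSummary":
        risk = self.risk.copy()
        hi = self.hi.copy()
        for col in ("edi_mean", "edi_min", "edi_max", "hq_mean", "hq_min", "hq_max"):
            risk[col] = risk[col].map(lambda x: round_half_up(x, ndigits))
        for col in ("hi_mean", "hi_min", "hi_max"):
            hi[col] = hi[col].map(lambda x: round_half_up(x, ndigits))
        return GroupSummary(risk=risk, hi=hi)


def group_summary(table: RiskTable, threshold: float = HAZARD_THRESHOLD) -> GroupSummary:
    """Aggregate a risk table to group-level statistics and exceedance counts."""
    if not table.cells:
        raise EmptyInputError("cannot summarise an empty risk table")

    frame = table.to_frame()
    group_order = list(dict.fromkeys(frame["group"]))
    cont_order = list(dict.fromkeys(frame["contaminant"]))

    rows = []
    for group in group_order:
        for cont in cont_order:
            sub = frame[(frame["group"] == group) & (frame["contaminant"] == cont)]
            rows.append(
                {
                    "group": group,
                    "contaminant": cont,
                    "n_brands": len(sub),
                    "edi_mean": sub["edi"].mean(),
                    "edi_min": sub["edi"].min(),
                    "edi_max": sub["edi"].max(),
                    "hq_mean": sub["hq"].mean(),
                    "hq_min": sub["hq"].min(),
                    "hq_max": sub["hq"].max(),
                    "hq_above_threshold": int((sub["hq"] > threshold).sum()),
                }
            )
    hi_frame = table.hi_frame()
    hi_rows = []
    for group in group_order:
        sub = hi_frame[hi_frame["group"] == group]
        hi_rows.append(
            {
                "group": group,
                "n_brands": len(sub),
                "hi_mean": sub["hi"].mean(),
                "hi_min": sub["hi"].min(),
                "hi_max": sub["hi"].max(),
                "hi_above_threshold": int((sub["hi"] > threshold).sum()),
            }
        )
    return GroupSummary(risk=pd.DataFrame(rows), hi=pd.DataFrame(hi_rows))
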