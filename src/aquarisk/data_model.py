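"""Domain types and delimited-file I/O for brand concentration panels.

A *panel* is the concentration table for one contaminant across a set of
bottled-water brands: for each brand, the declared (label) value when one is
printed on the bottle, the mean of replicate measurements, and the replicate
standard deviation, all in mg/L.  Panels feed the deterministic risk engine
and the Monte Carlo engine.

File dialect: comma-delimited UTF-8 with a single header row naming the
columns ``brand, water_type, labeled, measured, sd``.  A label cell of ``NL``
(any case) or an empty cell means the bottle carries no declared value.  A
label printed as a bound (e.g. ``< 2``) is stored as an *absent* numeric
label with the raw string preserved in a note field; bound labels are never
compared numerically.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    EmptyInputError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "WaterType",
    "ContaminantSpec",
    "ExposureProfile",
    "BrandRecord",
    "BrandPanel",
    "PanelSummary",
    "RangeFlag",
    "GuidelineScreen",
    "FLUORIDE",
    "NITRATE",
    "load_panel",
    "write_panel",
    "panel_summary",
    "guideline_screen",
    "round_half_up",
    "read_exposure_config",
]

_REQUIRED_COLUMNS = ("brand", "water_type", "labeled", "measured", "sd")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention used for report display.

    Internal computation is always carried at full precision; this helper is
    applied only when a number is printed.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


class WaterType(str, Enum):
    """Bottled-water category: treated drinking water or mineral (spring) water."""

    DW = "DW"
    MW = "MW"


@dataclass(frozen=True)
class ContaminantSpec:
    """Identity and toxicological constants of one contaminant.

    Parameters
    ----------
    name
        Identifier, e.g. ``"fluoride"``.
    rfd
        Chronic oral reference dose, mg per kg body weight per day. Must be
        positive; exposure at or below the RfD is assumed to carry no
        appreciable non-carcinogenic risk over a lifetime.
    guideline_low, guideline_high
        Optional drinking-water guideline bounds, mg/L. Fluoride has both
        (the WHO range 0.5-1.5 mg/L); nitrate has only an upper bound.
    """

    name: str
    rfd: float
    guideline_low: float | None = None
    guideline_high: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("contaminant name must be non-empty")
        if not (self.rfd > 0):
            raise ConfigurationError(f"rfd must be > 0, got {self.rfd!r}")
        if (
            self.guideline_low is not None
            and self.guideline_high is not None
            and not (self.guideline_low <= self.guideline_high)
        ):
            raise ConfigurationError(
                f"guideline_low ({self.guideline_low}) must not exceed "
                f"guideline_high ({self.guideline_high})"
            )

    @property
    def has_guideline(self) -> bool:
        return self.guideline_low is not None or self.guideline_high is not None


#: Default contaminant constants: RfD 0.06 mg/kg/day and the WHO 0.5-1.5 mg/L
#: range for fluoride; RfD 1.6 mg/kg/day and the WHO 45 mg/L ceiling for nitrate.
FLUORIDE = ContaminantSpec("fluoride", rfd=0.06, guideline_low=0.5, guideline_high=1.5)
NITRATE = ContaminantSpec("nitrate", rfd=1.6, guideline_high=45.0)


@dataclass(frozen=True)
class ExposureProfile:
    """One receptor group's chronic ingestion parameters.

    ``ir`` is daily water intake (L/day), ``ef`` exposure frequency
    (days/year), ``ed`` exposure duration (years), ``bw`` body weight (kg) and
    ``at`` averaging time (days).  All must be strictly positive.

    ``at_consistent`` records whether ``at == ed * ef``; when it holds, the
    intake equation collapses to C*IR/BW and the duration terms cancel.  It
    holds for all four default profiles.
    """

    group: str
    ir: float
    ef: float
    ed: float
    bw: float
    at: float

    def __post_init__(self) -> None:
        if not self.group:
            raise ConfigurationError("group name must be non-empty")
        for name in ("ir", "ef", "ed", "bw", "at"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ConfigurationError(
                    f"profile {self.group!r}: {name} must be strictly positive, got {value!r}"
                )

    @property
    def at_consistent(self) -> bool:
        return math.isclose(self.at, self.ed * self.ef, rel_tol=1e-9)


@dataclass(frozen=True)
class BrandRecord:
    """One brand's measured and declared concentration for one contaminant.

    ``labeled`` is the numeric declared value when the bottle prints one;
    ``label_note`` preserves non-numeric label text (e.g. ``"< 2"``).  A
    record is *unlabeled* when it has neither.
    """

    brand: str
    water_type: WaterType
    measured: float
    sd: float | None = None
    labeled: float | None = None
    label_note: str | None = None

    def __post_init__(self) -> None:
        if not self.brand:
            raise ValidationError("brand identifier must be non-empty")
        if self.measured < 0 or not math.isfinite(self.measured):
            raise ValidationError(
                f"brand {self.brand!r}: measured concentration must be >= 0, got {self.measured!r}"
            )
        if self.sd is not None and (self.sd < 0 or not math.isfinite(self.sd)):
            raise ValidationError(f"brand {self.brand!r}: sd must be >= 0, got {self.sd!r}")
        if self.labeled is not None and self.labeled < 0:
            raise ValidationError(
                f"brand {self.brand!r}: labeled concentration must be >= 0, got {self.labeled!r}"
            )

    @property
    def unlabeled(self) -> bool:
        return self.labeled is None and self.label_note is None


@dataclass(frozen=True)
class BrandPanel:
    """An ordered collection of :class:`BrandRecord` for one contaminant."""

    contaminant: ContaminantSpec
    records: tuple[BrandRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        brands = [r.brand for r in self.records]
        dupes = {b for b in brands if brands.count(b) > 1}
        if dupes:
            raise ValidationError(f"duplicate brand identifiers in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BrandRecord]:
        return iter(self.records)

    @property
    def brands(self) -> tuple[str, ...]:
        return tuple(r.brand for r in self.records)

    @property
    def measured(self) -> np.ndarray:
        """Measured concentrations as a float array, in input order."""
        return np.array([r.measured for r in self.records], dtype=float)

    def record(self, brand: str) -> BrandRecord:
        for r in self.records:
            if r.brand == brand:
                return r
        raise KeyError(brand)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "brand": [r.brand for r in self.records],
                "water_type": [r.water_type.value for r in self.records],
                "labeled": [r.labeled for r in self.records],
                "label_note": [r.label_note for r in self.records],
                "measured": [r.measured for r in self.records],
                "sd": [r.sd for r in self.records],
            }
        )


def _parse_label_cell(raw: object) -> tuple[float | None, str | None]:
    """Return ``(labeled, label_note)`` for one raw label cell."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None, None
    text = str(raw).strip()
    if text == "" or text.upper() == "NL":
        return None, None
    try:
        return float(text), None
    except ValueError:
        return None, text


def load_panel(path: str | Path, contaminant: ContaminantSpec) -> BrandPanel:
    """Read a brand panel from a comma-delimited file.

    Row order is preserved.  ``NL`` or empty label cells become absent labels;
    non-numeric label text (detection bounds such as ``< 2``) is kept verbatim
    in ``label_note``.  Raises :class:`SchemaError` naming any missing column
    and :class:`ValidationError` naming the offending row for negative
    concentrations.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[BrandRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # data starts on line 2
        brand = str(row.brand).strip()
        try:
            water_type = WaterType(str(row.water_type).strip().upper())
        except ValueError as exc:
            raise DataError(
                f"{path}, line {i} (brand {brand!r}): unknown water type {row.water_type!r}"
            ) from exc
        try:
            measured = float(row.measured)
            sd = float(row.sd) if str(row.sd).strip() != "" else None
        except ValueError as exc:
            raise DataError(f"{path}, line {i} (brand {brand!r}): unparseable number") from exc
        labeled, note = _parse_label_cell(row.labeled)
        try:
            records.append(
                BrandRecord(
                    brand=brand,
                    water_type=water_type,
                    measured=measured,
                    sd=sd,
                    labeled=labeled,
                    label_note=note,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
    return BrandPanel(contaminant=contaminant, records=tuple(records))


def write_panel(panel: BrandPanel, path: str | Path) -> None:
    """Write a panel back to the delimited dialect read by :func:`load_panel`.

    Numeric values round-trip at full precision (``repr`` formatting); absent
    labels are written as ``NL`` and bound labels as their preserved note text.
    """
    lines = [",".join(_REQUIRED_COLUMNS)]
    for r in panel:
        if r.labeled is not None:
            label = repr(r.labeled)
        elif r.label_note is not None:
            label = r.label_note
        else:
            label = "NL"
        sd = "" if r.sd is None else repr(r.sd)
        lines.append(f"{r.brand},{r.water_type.value},{label},{repr(r.measured)},{sd}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class PanelSummary:
    """Descriptive statistics of a panel's measured concentrations, mg/L.

    ``sd`` is the sample standard deviation (n-1 denominator) and is reported
    as ``None`` for a single-record panel, where it is undefined.
    """

    contaminant: str
    n: int
    mean: float
    sd: float | None
    min: float
    max: float

    def rounded(self, ndigits: int = 2) -> dict[str, float | int | None]:
        return {
            "contaminant": self.contaminant,
            "n": self.n,
            "mean": round_half_up(self.mean, ndigits),
            "sd": None if self.sd is None else round_half_up(self.sd, ndigits),
            "min": round_half_up(self.min, ndigits),
            "max": round_half_up(self.max, ndigits),
        }


def panel_summary(panel: BrandPanel) -> PanelSummary:
    """Mean, sample SD, min and max of the measured concentrations."""
    if len(panel) == 0:
        raise EmptyInputError("cannot summarise an empty panel")
    values = panel.measured
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return PanelSummary(
        contaminant=panel.contaminant.name,
        n=len(values),
        mean=float(np.mean(values)),
        sd=sd,
        min=float(np.min(values)),
        max=float(np.max(values)),
    )


class RangeFlag(str, Enum):
    """Position of a measured value relative to the guideline bounds."""

    BELOW_LOW = "below_low"
    WITHIN = "within"
    ABOVE_HIGH = "above_high"


@dataclass(frozen=True)
class GuidelineScreen:
    """Per-brand guideline flags plus an independent unlabeled flag.

    Every record gets exactly one :class:`RangeFlag` (bounds inclusive), so
    the three counts partition the panel.  ``unlabeled_brands`` lists brands
    whose bottle declares no value at all for the contaminant; brands whose
    label is a detection bound are *not* counted as unlabeled.
    """

    contaminant: str
    flags: Mapping[str, RangeFlag]
    unlabeled_brands: tuple[str, ...]

    def count(self, flag: RangeFlag) -> int:
        return sum(1 for f in self.flags.values() if f is flag)

    @property
    def counts(self) -> dict[str, int]:
        return {
            RangeFlag.BELOW_LOW.value: self.count(RangeFlag.BELOW_LOW),
            RangeFlag.WITHIN.value: self.count(RangeFlag.WITHIN),
            RangeFlag.ABOVE_HIGH.value: self.count(RangeFlag.ABOVE_HIGH),
            "unlabeled": len(self.unlabeled_brands),
        }

    def brands_with(self, flag: RangeFlag) -> tuple[str, ...]:
        return tuple(b for b, f in self.flags.items() if f is flag)


def guideline_screen(panel: BrandPanel) -> GuidelineScreen:
    """Screen a panel against its contaminant's guideline bounds."""
    spec = panel.contaminant
    if not spec.has_guideline:
        raise ConfigurationError(
            f"contaminant {spec.name!r} has no guideline bounds to screen against"
        )
    flags: dict[str, RangeFlag] = {}
    for r in panel:
        if spec.guideline_low is not None and r.measured < spec.guideline_low:
            flags[r.brand] = RangeFlag.BELOW_LOW
        elif spec.guideline_high is not None and r.measured > spec.guideline_high:
            flags[r.brand] = RangeFlag.ABOVE_HIGH
        else:
            flags[r.brand] = RangeFlag.WITHIN
    unlabeled = tuple(r.brand for r in panel if r.unlabeled)
    return GuidelineScreen(contaminant=spec.name, flags=flags, unlabeled_brands=unlabeled)


def _profile_from_mapping(group: str, fields: Mapping[str, object]) -> ExposureProfile:
    try:
        return ExposureProfile(
            group=group,
            ir=float(fields["ir"]),  # type: ignore[arg-type]
            ef=float(fields["ef"]),  # type: ignore[arg-type]
            ed=float(fields["ed"]),  # type: ignore[arg-type]
            bw=float(fields["bw"]),  # type: ignore[arg-type]
            at=float(fields["at"]),  # type: ignore[arg-type]
        )
    except KeyError as exc:
        raise ConfigurationError(f"profile {group!r}: missing field {exc.args[0]!r}") from exc


def read_exposure_config(document: Mapping[str, Mapping[str, object]]) -> tuple[ExposureProfile, ...]:
    """Build exposure profiles from a plain mapping (parsed JSON/YAML).

    The document maps group names to ``{ir, ef, ed, bw, at}`` field mappings.
    """
    if not document:
        raise ConfigurationError("exposure configuration is empty")
    return tuple(_profile_from_mapping(g, f) for g, f in document.items())
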