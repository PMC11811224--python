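"""Synthetic concentration panels with known ground truth, plus built-in fixtures.

The generator emulates the salient features of a real bottled-water survey
panel: right-skewed (lognormal) concentrations, occasional values pinned at a
detection floor, replicate measurement noise, and a fraction of brands whose
bottles declare no value.  Because the generating parameters are known,
every downstream stage (fitting, simulation, sensitivity) can be tested for
parameter recovery rather than merely for plausibility.

The built-in fixtures are the 22-brand fluoride and nitrate survey panels and
the four-group exposure-parameter table that the package's worked examples
and acceptance checks run on; they ship as packaged CSV resources.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .data_model import (
    FLUORIDE,
    NITRATE,
    BrandPanel,
    BrandRecord,
    ContaminantSpec,
    ExposureProfile,
    WaterType,
    load_panel,
)
from .errors import ConfigurationError, FixtureLookupError

__all__ = ["GroundTruth", "generate_panel", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("fluoride_table2", "nitrate_table2", "exposure_table1")

#: Fraction of mineral-water brands in the reference survey (8 of 22).
_MW_RATE = 8.0 / 22.0


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for a synthetic panel.

    ``p1``/``p2`` are the log-mean and log-SD of the concentration lognormal
    (mg/L scale); ``floor`` is the detection floor applied after drawing;
    ``label_missing_rate`` is the probability that a brand ships unlabeled.
    """

    p1: float
    p2: float
    n_brands: int = 22
    floor: float = 0.005
    label_missing_rate: float = 8.0 / 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p2 < 0:
            raise ConfigurationError(f"p2 must be >= 0, got {self.p2!r}")
        if not (0.0 <= self.label_missing_rate <= 1.0):
            raise ConfigurationError(
                f"label_missing_rate must lie in [0, 1], got {self.label_missing_rate!r}"
            )
        if self.n_brands < 1:
            raise ConfigurationError(f"n_brands must be >= 1, got {self.n_brands!r}")
        if not (self.floor > 0):
            raise ConfigurationError(f"floor must be > 0, got {self.floor!r}")


def generate_panel(
    truth: GroundTruth, contaminant: ContaminantSpec
) -> tuple[BrandPanel, GroundTruth]:
    """Draw a reproducible synthetic panel from known ground truth.

    Measured means are lognormal(p1, p2) draws floored at the detection
    floor; replicate SDs are |N(0, 0.05 * measured)| (5% relative replicate
    noise); labels are present with probability 1 - label_missing_rate and
    drawn as measured * lognormal(0, 0.2) to emulate label/measurement
    discrepancy.  Brands are named ``B1..Bn``.  The ground truth is returned
    alongside the panel as its sidecar.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_brands
    measured = np.maximum(rng.lognormal(truth.p1, truth.p2, size=n), truth.floor)
    sds = np.abs(rng.normal(0.0, 0.05 * measured))
    labeled_mask = rng.random(n) >= truth.label_missing_rate
    label_factor = rng.lognormal(0.0, 0.2, size=n)
    water = np.where(rng.random(n) < _MW_RATE, WaterType.MW.value, WaterType.DW.value)

    records = tuple(
        BrandRecord(
            brand=f"B{i + 1}",
            water_type=WaterType(water[i]),
            measured=float(measured[i]),
            sd=float(sds[i]),
            labeled=float(measured[i] * label_factor[i]) if labeled_mask[i] else None,
        )
        for i in range(n)
    )
    return BrandPanel(contaminant=contaminant, records=records), truth


def _resource(name: str) -> Path:
    return Path(str(resources.files("aquarisk").joinpath("data", f"{name}.csv")))


def _load_exposure_fixture() -> tuple[ExposureProfile, ...]:
    import csv

    with open(_resource("exposure_table1"), newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return tuple(
        ExposureProfile(
            group=row["group"],
            ir=float(row["ir"]),
            ef=float(row["ef"]),
            ed=float(row["ed"]),
            bw=float(row["bw"]),
            at=float(row["at"]),
        )
        for row in rows
    )


def load_fixture(name: str) -> BrandPanel | tuple[ExposureProfile, ...]:
    """Load a built-in fixture by name.

    ``fluoride_table2`` and ``nitrate_table2`` return the 22-brand survey
    panels (with default contaminant constants attached); ``exposure_table1``
    returns the four default exposure profiles (infants, children, teenagers,
    adults).  Unknown names raise :class:`FixtureLookupError`.
    """
    if name == "fluoride_table2":
        return load_panel(_resource("fluoride_table2"), FLUORIDE)
    if name == "nitrate_table2":
        return load_panel(_resource("nitrate_table2"), NITRATE)
    if name == "exposure_table1":
        return _load_exposure_fixture()
    raise FixtureLookupError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
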