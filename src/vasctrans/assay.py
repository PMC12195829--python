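"""Ellman-assay potency arithmetic.

Inhibition is ``(E - S) / E * 100`` with ``E`` the enzyme activity without
and ``S`` with the inhibitor.  For carrier-immobilized compounds the apparent
IC50 (expressed on total hybrid-material mass) is corrected to the active
complex by multiplying with the loaded mass fraction; potency versus a
reference inhibitor is the ratio of IC50s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InhibitionRecord",
    "CarrierInfo",
    "PotencyResult",
    "inhibition_percent",
    "estimate_ic50",
    "correct_ic50",
    "fold_potency",
    "read_assay_csv",
    "potency_report",
    "BUILTIN_CARRIERS",
    "BUILTIN_IC50_UM",
]


def inhibition_percent(activity_without: float, activity_with: float) -> float:
    """Inhibition percentage (E - S)/E * 100.

    Values outside [0, 100] (activation, S > E) are reported, not clamped.
    """
    if activity_without <= 0:
        raise ValueError("enzyme activity without inhibitor (E) must be > 0")
    if activity_with < 0:
        raise ValueError("enzyme activity with inhibitor (S) must be >= 0")
    return (activity_without - activity_with) / activity_without * 100.0


@dataclass(frozen=True)
class InhibitionRecord:
    """One dose-response point."""

    concentration: float  # ug/mL or uM, consistent within a series
    activity_without: float  # E
    activity_with: float  # S

    @property
    def inhibition_pct(self) -> float:
        return inhibition_percent(self.activity_without, self.activity_with)


@dataclass(frozen=True)
class CarrierInfo:
    """Mass fraction of the active complex loaded on the carrier."""

    mass_fraction: float
    basis: str = "complex_weight"

    def __post_init__(self) -> None:
        if not 0.0 < self.mass_fraction < 1.0:
            raise ValueError(f"mass fraction must lie in (0, 1), got {self.mass_fraction}")


@dataclass(frozen=True)
class PotencyResult:
    apparent_ic50: float
    corrected_ic50: float | None
    fold_vs_reference: float | None


class EstimationError(ValueError):
    pass


def estimate_ic50(series: list[InhibitionRecord] | pd.DataFrame) -> float:
    """IC50 by log-linear interpolation between the pair bracketing 50 %.

    The series is sorted by concentration; the first adjacent pair whose
    inhibition values bracket 50 % (in either direction) defines the
    interpolation interval.  A point exactly at 50 % wins outright.
    """
    if isinstance(series, pd.DataFrame):
        series = [
            InhibitionRecord(r["concentration"], r["activity_without"], r["activity_with"])
            for _, r in series.iterrows()
        ]
    if len(series) < 2:
        raise EstimationError("need at least two concentrations to estimate an IC50")
    pts = sorted(((r.concentration, r.inhibition_pct) for r in series), key=lambda p: p[0])
    for conc, inh in pts:
        if inh == 50.0:
            return float(conc)
    for (c0, i0), (c1, i1) in zip(pts, pts[1:]):
        if (i0 - 50.0) * (i1 - 50.0) < 0:
            if c0 <= 0:
                raise EstimationError("non-positive concentration in the bracketing pair")
            f = (50.0 - i0) / (i1 - i0)
            return float(10 ** (math.log10(c0) + f * (math.log10(c1) - math.log10(c0))))
    raise EstimationError(
        "no adjacent concentration pair brackets 50% inhibition; widen the dose range"
    )


def correct_ic50(apparent: float, carrier: CarrierInfo) -> float:
    """Carrier-corrected IC50: apparent value times the complex mass fraction."""
    if apparent <= 0:
        raise ValueError("apparent IC50 must be > 0")
    return apparent * carrier.mass_fraction


def fold_potency(reference_ic50: float, test_ic50: float) -> float:
    """Potency gain of the test compound over the reference: ref / test."""
    if reference_ic50 <= 0 or test_ic50 <= 0:
        raise ValueError("IC50 values must be > 0")
    return reference_ic50 / test_ic50


#: Loaded-complex mass fractions of the two hybrid materials (complex weight
#: per total hybrid weight).
BUILTIN_CARRIERS = {
    "SBA-15~Cl|Ph3SnL1": CarrierInfo(0.0435),
    "SBA-15~Cl|Ph3SnL2": CarrierInfo(0.0446),
}

#: Measured apparent IC50 values (uM) against AChE.
BUILTIN_IC50_UM = {
    "SBA-15~Cl|Ph3SnL1": 23.93,
    "SBA-15~Cl|Ph3SnL2": 13.44,
    "Ph3SnL1": 105.81,
    "Ph3SnL2": 88.00,
    "Galantamine": 15.00,
}


def read_assay_csv(path: str | Path) -> pd.DataFrame:
    """Read an assay table (columns: compound, concentration, E, S[, replicate])."""
    df = pd.read_csv(path)
    required = {"compound", "concentration", "E", "S"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV {path} lacks column(s) {sorted(missing)}")
    bad = df.index[df["E"] <= 0].tolist()
    if bad:
        raise ValueError(f"assay CSV {path}: non-positive E in row(s) {bad}")
    return df


def potency_report(
    apparent_um: dict[str, float] | None = None,
    carriers: dict[str, CarrierInfo] | None = None,
    reference: str = "Galantamine",
) -> pd.DataFrame:
    """Apparent / corrected / fold-vs-reference table for a set of compounds.

    Defaults to the built-in measured IC50s and carrier loadings.  The fold
    column compares the reference's IC50 against each compound's effective
    (corrected when available, else apparent) IC50.
    """
    apparent_um = apparent_um if apparent_um is not None else dict(BUILTIN_IC50_UM)
    carriers = carriers if carriers is not None else BUILTIN_CARRIERS
    rows = []
    ref_ic50 = apparent_um.get(reference)
    for name, app in apparent_um.items():
        corrected = correct_ic50(app, carriers[name]) if name in carriers else None
        effective = corrected if corrected is not None else app
        fold = fold_potency(ref_ic50, effective) if ref_ic50 else None
        rows.append(
            {
                "compound": name,
                "apparent_ic50_uM": app,
                "corrected_ic50_uM": corrected,
                "fold_vs_reference": fold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["compound", "apparent_ic50_uM", "corrected_ic50_uM", "fold_vs_reference"],
    )
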