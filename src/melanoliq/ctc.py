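"""Circulating tumor cell enumeration bookkeeping and DLA recovery.

Diagnostic leukapheresis (DLA) processes liters of blood into a small
mononuclear-cell product.  The expected number of CTCs in that product is
extrapolated from the peripheral-blood (PB) CellSearch count per 7.5 mL and
the processed blood volume; the measured total is extrapolated from the
concentration in the analyzed product aliquot.  Recovery is their ratio as
a percentage (it can exceed 100% through counting noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import DomainError, MelanoliqError

PB_VOLUME_ML = 7.5

PLATFORMS = ("PB_CellSearch", "DLA_CellSearch", "DLA_FCM")


@dataclass
class CTCMeasurement:
    """One platform's CTC count for one patient."""

    sample_id: str
    platform: str
    count: int
    volume_analyzed_mL: float
    product_total_volume_mL: float | None = None  # DLA only
    processed_blood_volume_L: float | None = None  # DLA only

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if self.volume_analyzed_mL <= 0:
            raise ValueError("volume_analyzed_mL must be positive")


@dataclass
class RecoveryResult:
    """Measured vs theoretically expected cell yield of the DLA product."""

    expected_total_in_product: float
    measured_total_in_product: float
    recovery_pct: float


def concentration(count: int, volume_mL: float) -> float:
    """Cells per mL."""
    if volume_mL <= 0:
        raise DomainError("volume must be positive")
    return count / volume_mL


def expected_ctc_in_dla(pb_count_per_7_5mL: int, processed_blood_L: float) -> float:
    """CTCs theoretically expected in the whole DLA product: the PB
    concentration (count / 7.5 mL) times the processed blood volume."""
    if pb_count_per_7_5mL < 0 or processed_blood_L < 0:
        raise DomainError("inputs must be nonnegative")
    return (pb_count_per_7_5mL / PB_VOLUME_ML) * processed_blood_L * 1000.0


def recovery(
    measured_concentration_per_mL: float,
    product_volume_mL: float,
    expected_total: float,
) -> RecoveryResult:
    """Recovery percentage: measured product total / expected total x 100.

    Undefined (raises) when no CTCs are expected; such patients are excluded
    from recovery statistics rather than recorded as 0%.
    """
    if expected_total <= 0:
        raise DomainError("recovery undefined when expected total is 0 (not evaluable)")
    measured_total = measured_concentration_per_mL * product_volume_mL
    return RecoveryResult(
        expected_total_in_product=expected_total,
        measured_total_in_product=measured_total,
        recovery_pct=100.0 * measured_total / expected_total,
    )


def recovery_from_measurements(pb: CTCMeasurement, dla: CTCMeasurement) -> RecoveryResult:
    """Recovery from a paired PB CellSearch and DLA measurement."""
    expected = expected_ctc_in_dla(pb.count, dla.processed_blood_volume_L)
    conc = concentration(dla.count, dla.volume_analyzed_mL)
    return recovery(conc, dla.product_total_volume_mL, expected)


def detection_summary(
    measurements: list[CTCMeasurement] | pd.DataFrame,
    positivity_threshold: int = 1,
) -> pd.DataFrame:
    """Per-platform detection rates: n_positive, n_total, rate.

    A patient is positive on a platform iff count >= threshold.  Duplicate
    patient/platform rows are rejected.
    """
    if isinstance(measurements, list):
        df = pd.DataFrame(
            [{"sample_id": m.sample_id, "platform": m.platform, "count": m.count} for m in measurements]
        )
    else:
        df = measurements[["sample_id", "platform", "count"]].copy()
    if df.duplicated(["sample_id", "platform"]).any():
        raise MelanoliqError("duplicate patient/platform measurement")
    df["positive"] = df["count"] >= positivity_threshold
    out = df.groupby("platform")["positive"].agg(n_positive="sum", n_total="count")
    out["rate"] = out["n_positive"] / out["n_total"]
    return out.reset_index()
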