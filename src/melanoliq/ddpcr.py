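"""Poisson-corrected digital droplet PCR concentration and VAF estimation.

Each droplet is an independent partition; a channel's positive-droplet
fraction p maps to the mean number of target copies per droplet via
``lambda = -ln(1 - p)``.  The variant allele frequency is the ratio of
mutant to total corrected concentrations.  A sample is called "detected"
when at least ``min_droplets`` mutant-positive droplets are observed (the
field-standard limit-of-detection convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import SaturationError

DEFAULT_MIN_DROPLETS = 3


@dataclass
class DropletAssay:
    """Droplet counts for one uniplex mutation assay on one sample."""

    sample_id: str
    assay_name: str
    mutant_positive: int
    wildtype_positive: int
    total_droplets: int
    droplet_volume_nl: float = 0.85  # metadata only

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be positive")
        for name in ("mutant_positive", "wildtype_positive"):
            v = getattr(self, name)
            if not 0 <= v <= self.total_droplets:
                raise ValueError(f"{name}={v} outside [0, total_droplets]")


@dataclass
class VAFEstimate:
    """Poisson-corrected per-channel concentrations and the derived VAF."""

    sample_id: str
    assay_name: str
    lambda_mut: float
    lambda_wt: float
    vaf: float
    detected: bool
    n_mutant_positive: int


def lambda_from_droplets(positive: int, total: int) -> float:
    """Mean copies per droplet from the positive fraction: -ln(1 - k/n)."""
    if not 0 <= positive <= total:
        raise ValueError("positive must be in [0, total]")
    if positive == total:
        raise SaturationError(
            "all droplets positive: concentration not estimable, dilute the sample"
        )
    return -math.log1p(-positive / total)


def estimate_vaf(assay: DropletAssay, min_droplets: int = DEFAULT_MIN_DROPLETS) -> VAFEstimate:
    """VAF = lambda_mut / (lambda_mut + lambda_wt); 0 when both channels empty."""
    lam_m = lambda_from_droplets(assay.mutant_positive, assay.total_droplets)
    lam_w = lambda_from_droplets(assay.wildtype_positive, assay.total_droplets)
    vaf = lam_m / (lam_m + lam_w) if (lam_m + lam_w) > 0 else 0.0
    return VAFEstimate(
        sample_id=assay.sample_id,
        assay_name=assay.assay_name,
        lambda_mut=lam_m,
        lambda_wt=lam_w,
        vaf=vaf,
        detected=assay.mutant_positive >= min_droplets,
        n_mutant_positive=assay.mutant_positive,
    )


def merge_wells(assays: list[DropletAssay]) -> DropletAssay:
    """Pool replicate wells of one assay by summing positives and totals
    before Poisson correction (maximum-likelihood pooling)."""
    if not assays:
        raise ValueError("no wells to merge")
    first = assays[0]
    if any(a.sample_id != first.sample_id or a.assay_name != first.assay_name for a in assays):
        raise ValueError("wells to merge must share sample and assay")
    return DropletAssay(
        sample_id=first.sample_id,
        assay_name=first.assay_name,
        mutant_positive=sum(a.mutant_positive for a in assays),
        wildtype_positive=sum(a.wildtype_positive for a in assays),
        total_droplets=sum(a.total_droplets for a in assays),
        droplet_volume_nl=first.droplet_volume_nl,
    )


def dominant_vaf(estimates: list[VAFEstimate]) -> VAFEstimate:
    """The detected assay with the highest VAF; an undetected zero-VAF
    placeholder when no assay is detected (dominant-mutation convention)."""
    if not estimates:
        raise ValueError("no assays for sample")
    detected = [e for e in estimates if e.detected]
    if detected:
        return max(detected, key=lambda e: e.vaf)
    best = max(estimates, key=lambda e: e.vaf)
    return VAFEstimate(
        sample_id=best.sample_id,
        assay_name=best.assay_name,
        lambda_mut=best.lambda_mut,
        lambda_wt=best.lambda_wt,
        vaf=0.0,
        detected=False,
        n_mutant_positive=best.n_mutant_positive,
    )
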