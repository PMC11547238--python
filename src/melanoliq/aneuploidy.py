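"""Chromosome-arm aneuploidy scoring of cfDNA against a healthy-donor panel.

The assay counts reads per chromosome arm (LINE-1 amplicon sequencing).  A
sample's arm read *fractions* are standardized against a reference panel of
healthy blood donors (HBDs): per arm, ``z_a = (f_a - mu_a) / sigma_a`` with
the panel mean and sample SD.  The squared z-scores are summed over arms to
a genome-wide statistic; because a raw sum of ~39 squared z-scores has null
expectation close to the number of arms, the reported *aneuploidy score*
re-standardizes the raw sum against the leave-one-out raw sums of the panel
members themselves, so that healthy samples score around 0 with unit spread
and the conventional positivity cutoff of 3 applies.

`AneuploidyScorer` follows the scikit-learn estimator protocol: ``fit`` on
the HBD panel (samples x arms count matrix), ``transform`` to arm z-scores,
``score_samples`` to per-sample summary scores.  Samples whose id matches a
panel member are automatically scored leave-one-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .arms import AUTOSOMAL_ARMS
from .exceptions import (
    EmptyProfileError,
    InsufficientPanelError,
    UnreliableScoreError,
)

DEFAULT_SCORE_THRESHOLD = 3.0
DEFAULT_MIN_MAPPED_READS = 90_000


@dataclass
class ArmCountProfile:
    """Per-arm read counts for one sample.

    ``total_mapped_reads`` may exceed the sum of arm counts (reads mapping
    outside the configured arm set still count towards the QC depth).
    """

    sample_id: str
    counts: dict[str, int]
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"negative arm count in sample {self.sample_id!r}")
        if sum(self.counts.values()) > self.total_mapped_reads:
            raise ValueError(
                f"sample {self.sample_id!r}: arm counts exceed total_mapped_reads"
            )


@dataclass
class AneuploidyResult:
    """Genome-wide aneuploidy call for one sample."""

    sample_id: str
    arm_z: dict[str, float]
    raw_sum: float
    score: float
    positive: bool
    qc_pass: bool
    n_arms_used: int
    excluded_arms: tuple[str, ...] = field(default_factory=tuple)


def qc_mapped_reads(profile: ArmCountProfile, threshold: int = DEFAULT_MIN_MAPPED_READS) -> bool:
    """True iff the sample reached the minimum sequencing depth (default 90,000 mapped reads)."""
    return profile.total_mapped_reads >= threshold


def arm_fractions(profile: ArmCountProfile) -> dict[str, float]:
    """Normalized read counts: fraction of on-target reads per arm."""
    total = sum(profile.counts.values())
    if total == 0:
        raise EmptyProfileError(f"sample {profile.sample_id!r} has no arm reads")
    return {arm: c / total for arm, c in profile.counts.items()}


def profiles_to_frame(profiles: list[ArmCountProfile], arms: tuple[str, ...] = AUTOSOMAL_ARMS) -> pd.DataFrame:
    """Stack profiles into a samples x arms count matrix (missing arms become 0)."""
    rows = {p.sample_id: [p.counts.get(a, 0) for a in arms] for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(arms))


class AneuploidyScorer(TransformerMixin, BaseEstimator):
    """Score cfDNA aneuploidy against an HBD reference panel.

    Parameters
    ----------
    threshold:
        Positivity cutoff on the normalized score (positive iff score >= threshold).
    min_mapped_reads:
        QC depth below which a sample is not evaluable.
    min_arms:
        Minimum number of usable (non-degenerate) arms required to report a score.

    Attributes
    ----------
    arms_ : list of arm identifiers seen at fit.
    member_ids_ : panel sample ids.
    member_fractions_ : panel arm-fraction matrix (members x arms).
    mean_, sd_ : per-arm panel mean and sample SD (ddof=1) of arm fractions.
    usable_arms_ : boolean mask of arms with sd_ > 0.
    loo_raw_sums_ : leave-one-out raw squared-z sums of the panel members.
    loo_sum_mean_, loo_sum_sd_ : normalization constants for the reported score.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_SCORE_THRESHOLD,
        min_mapped_reads: int = DEFAULT_MIN_MAPPED_READS,
        min_arms: int = 5,
    ):
        self.threshold = threshold
        self.min_mapped_reads = min_mapped_reads
        self.min_arms = min_arms

    # -- fitting ---------------------------------------------------------

    def fit(self, X: pd.DataFrame | list[ArmCountProfile], y=None) -> "AneuploidyScorer":
        """Fit the panel statistics on HBD arm counts (samples x arms)."""
        X = self._as_frame(X)
        if len(X) < 3:
            raise InsufficientPanelError(
                f"reference panel needs >= 3 members, got {len(X)}"
            )
        totals = X.to_numpy(float).sum(axis=1)
        if np.any(totals == 0):
            raise EmptyProfileError("panel member with zero arm reads")
        frac = X.to_numpy(float) / totals[:, None]

        self.arms_ = list(X.columns)
        self.member_ids_ = list(X.index)
        self.member_fractions_ = frac
        self.mean_ = frac.mean(axis=0)
        self.sd_ = frac.std(axis=0, ddof=1)
        self.usable_arms_ = self.sd_ > 0
        if self.usable_arms_.sum() < self.min_arms:
            raise InsufficientPanelError(
                f"only {int(self.usable_arms_.sum())} arms with non-zero panel SD"
            )

        self.loo_raw_sums_ = np.array(
            [self._loo_raw_sum(i) for i in range(len(frac))]
        )
        self.loo_sum_mean_ = float(self.loo_raw_sums_.mean())
        self.loo_sum_sd_ = float(self.loo_raw_sums_.std(ddof=1))
        if self.loo_sum_sd_ == 0:
            raise InsufficientPanelError("degenerate panel: identical members")
        return self

    def _loo_raw_sum(self, i: int) -> float:
        """Raw squared-z sum of member i against the panel without it."""
        others = np.delete(self.member_fractions_, i, axis=0)
        mu = others.mean(axis=0)
        sd = others.std(axis=0, ddof=1)
        use = sd > 0
        z = (self.member_fractions_[i, use] - mu[use]) / sd[use]
        return float((z**2).sum())

    # -- scoring ---------------------------------------------------------

    def transform(self, X: pd.DataFrame | list[ArmCountProfile]) -> pd.DataFrame:
        """Arm z-scores (samples x usable arms); panel members use leave-one-out stats."""
        X = self._as_frame(X)
        rows = [self._sample_z(X.loc[sid].to_numpy(float), sid) for sid in X.index]
        arms = [a for a, u in zip(self.arms_, self.usable_arms_) if u]
        return pd.DataFrame([r[0] for r in rows], index=X.index, columns=arms)

    def _sample_z(self, counts: np.ndarray, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        """z over globally usable arms, plus mask of arms usable for this sample."""
        total = counts.sum()
        if total == 0:
            raise EmptyProfileError(f"sample {sample_id!r} has no arm reads")
        frac = counts / total
        if sample_id in self.member_ids_:
            i = self.member_ids_.index(sample_id)
            others = np.delete(self.member_fractions_, i, axis=0)
            mu, sd = others.mean(axis=0), others.std(axis=0, ddof=1)
        else:
            mu, sd = self.mean_, self.sd_
        use = self.usable_arms_ & (sd > 0)
        z_full = np.full(len(self.arms_), np.nan)
        z_full[use] = (frac[use] - mu[use]) / sd[use]
        return z_full[self.usable_arms_], use

    def score_samples(
        self,
        X: pd.DataFrame | list[ArmCountProfile],
        total_mapped_reads: dict[str, int] | None = None,
    ) -> pd.DataFrame:
        """Per-sample qc_pass, raw_sum, score, positive and n_arms_used.

        ``total_mapped_reads`` supplies QC depths when ``X`` is a plain count
        matrix; with `ArmCountProfile` inputs the profiles carry their own.
        """
        profiles = X if isinstance(X, list) else None
        X = self._as_frame(X)
        if total_mapped_reads is None:
            if profiles is not None:
                total_mapped_reads = {p.sample_id: p.total_mapped_reads for p in profiles}
            else:
                total_mapped_reads = {
                    sid: int(X.loc[sid].sum()) for sid in X.index
                }
        out = []
        for sid in X.index:
            out.append(self._score_one(X.loc[sid].to_numpy(float), sid, total_mapped_reads[sid]))
        return pd.DataFrame(out, index=X.index)

    def _score_one(self, counts: np.ndarray, sample_id: str, depth: int) -> dict:
        qc = depth >= self.min_mapped_reads
        z, use = self._sample_z(counts, sample_id)
        n_used = int(np.isfinite(z).sum())
        if n_used < self.min_arms:
            raise UnreliableScoreError(
                f"sample {sample_id!r}: only {n_used} usable arms"
            )
        raw = float(np.nansum(z**2))
        score = (raw - self.loo_sum_mean_) / self.loo_sum_sd_
        return {
            "qc_pass": qc,
            "raw_sum": raw,
            "score": score,
            "positive": bool(qc and score >= self.threshold),
            "n_arms_used": n_used,
        }

    def score_profile(self, profile: ArmCountProfile) -> AneuploidyResult:
        """Full result object for a single profile."""
        frame = profiles_to_frame([profile], tuple(self.arms_))
        z, use = self._sample_z(frame.iloc[0].to_numpy(float), profile.sample_id)
        row = self._score_one(
            frame.iloc[0].to_numpy(float), profile.sample_id, profile.total_mapped_reads
        )
        arms = [a for a, u in zip(self.arms_, self.usable_arms_) if u]
        arm_z = {a: float(v) for a, v in zip(arms, z) if np.isfinite(v)}
        excluded = tuple(a for a, u in zip(self.arms_, use) if not u)
        return AneuploidyResult(
            sample_id=profile.sample_id,
            arm_z=arm_z,
            raw_sum=row["raw_sum"],
            score=row["score"],
            positive=row["positive"],
            qc_pass=row["qc_pass"],
            n_arms_used=row["n_arms_used"],
            excluded_arms=excluded,
        )

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, list):
            if hasattr(self, "arms_"):
                arms = tuple(self.arms_)
            else:  # pre-fit: take the arm universe from the profiles
                seen: list[str] = []
                for p in X:
                    seen.extend(a for a in p.counts if a not in seen)
                arms = tuple(seen)
            return profiles_to_frame(X, arms)
        return X


# -- thin functional wrappers -------------------------------------------


def build_panel(profiles: list[ArmCountProfile], **kwargs) -> AneuploidyScorer:
    """Fit an `AneuploidyScorer` on QC-passing HBD profiles."""
    failing = [p.sample_id for p in profiles if not qc_mapped_reads(p)]
    if failing:
        warnings.warn(f"panel members failing read-depth QC: {failing}")
    return AneuploidyScorer(**kwargs).fit(profiles)


def arm_zscores(profile: ArmCountProfile, panel: AneuploidyScorer) -> dict[str, float]:
    """Per-arm z-scores of one sample against the panel (leave-one-out for members)."""
    return panel.score_profile(profile).arm_z


def aneuploidy_score(profile: ArmCountProfile, panel: AneuploidyScorer) -> tuple[float, float]:
    """(raw squared-z sum, panel-normalized genome-wide aneuploidy score)."""
    res = panel.score_profile(profile)
    return res.raw_sum, res.score


def call_aneuploid(result: AneuploidyResult, threshold: float = DEFAULT_SCORE_THRESHOLD) -> bool:
    """Positivity call: score >= threshold, only evaluable under QC pass."""
    if not result.qc_pass:
        raise UnreliableScoreError(
            f"sample {result.sample_id!r} failed QC; call not evaluable"
        )
    return result.score >= threshold
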