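"""Genome-wide cfDNA methylation scoring against a healthy-donor panel.

Methylation-dependent restriction-enzyme sequencing yields read counts over
genomic regions.  The analysis chain implemented here:

1. region filtering — keep regions with data (non-zero reads) in at least
   75% of all samples and in every HBD control;
2. normalization — counts-per-million over the retained regions, log2(x+1);
3. per-region z-scores against the nine-HBD panel (leave-one-out when the
   scored sample is itself a panel member);
4. squared z-scores summed into a genome-wide score, and, restricted to the
   differentially methylated regions (DMRs) separating HBDs from
   high-ctDNA patients, into a melanoma-specific methylation score;
5. DMR discovery by a two-group moderated t-statistic with empirical-Bayes
   variance shrinkage and Benjamini-Hochberg FDR control;
6. an "altered methylation" call when the melanoma score exceeds the upper
   limit of the 95% CI of the leave-one-out HBD scores.

`MethylationScorer` and `DMRFinder` follow the scikit-learn estimator
protocol with a samples x regions orientation; the tabular container
`RegionCountMatrix` keeps the field's regions x samples layout for I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientPanelError, MelanoliqError

HBD = "HBD"
PATIENT = "patient"


@dataclass
class RegionCountMatrix:
    """Methylation read counts over regions x samples, with region metadata.

    ``regions``: DataFrame with columns region_id, chrom (1-22), start, end
    (0-based half-open), indexed by region_id in the same order as
    ``counts``.  ``groups``: sample_id -> "HBD" | "patient".
    """

    regions: pd.DataFrame
    counts: pd.DataFrame  # regions x samples
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if not (self.regions.index == self.counts.index).all():
            raise ValueError("regions and counts must share the same region index")
        bad = self.regions[self.regions["start"] >= self.regions["end"]]
        if len(bad):
            raise ValueError(f"invalid region coordinates: {list(bad.index[:5])}")
        chroms = pd.to_numeric(self.regions["chrom"], errors="coerce")
        if chroms.isna().any() or not chroms.isin(range(1, 23)).all():
            raise ValueError("regions must lie on autosomes 1-22")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)[:5]}")

    @property
    def hbd_ids(self) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == HBD]

    @property
    def patient_ids(self) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] != HBD]


def lpnpi_qc(
    reads_passing_filter: int,
    reads_inspected: int = 2_000_000,
    min_fraction: float = 0.20,
) -> bool:
    """Digestion QC: fraction of reads passing the LpnPI filter in the first
    ``reads_inspected`` reads must be at least ``min_fraction``."""
    if reads_inspected <= 0:
        raise ValueError("reads_inspected must be positive")
    return reads_passing_filter / reads_inspected >= min_fraction


def filter_regions(
    matrix: RegionCountMatrix,
    completeness: float = 0.75,
    require_all_hbds: bool = True,
) -> RegionCountMatrix:
    """Keep regions with non-zero data in >= ``completeness`` of all samples
    and (optionally) in every HBD control.  Region order is preserved."""
    has_data = matrix.counts > 0
    keep = has_data.mean(axis=1) >= completeness
    if require_all_hbds:
        hbds = matrix.hbd_ids
        if not hbds:
            raise InsufficientPanelError("no HBD samples in matrix")
        keep &= has_data[hbds].all(axis=1)
    if not keep.any():
        raise MelanoliqError("no regions survive the completeness filter")
    return replace(
        matrix,
        regions=matrix.regions.loc[keep],
        counts=matrix.counts.loc[keep],
    )


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) over the retained regions (regions x samples).

    Library size is the per-sample total over the retained regions, so the
    transform is invariant to proportional scaling of a sample's counts.
    """
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("sample with zero library size")
    cpm = counts.div(libsize, axis=1) * 1e6
    return np.log2(cpm + 1.0)


class MethylationScorer(TransformerMixin, BaseEstimator):
    """Per-region z-scores and squared-z summary scores vs an HBD panel.

    Fit on the HBD panel's *normalized* values (samples x regions, e.g. the
    transpose of :func:`normalize_counts` output restricted to HBD columns).
    Panel members (matched by sample id) are scored leave-one-out.
    """

    def __init__(self, min_panel: int = 3):
        self.min_panel = min_panel

    def fit(self, X: pd.DataFrame, y=None) -> "MethylationScorer":
        if len(X) < self.min_panel:
            raise InsufficientPanelError(
                f"HBD panel needs >= {self.min_panel} members, got {len(X)}"
            )
        self.regions_ = list(X.columns)
        self.member_ids_ = list(X.index)
        self.member_values_ = X.to_numpy(float)
        self.mean_ = self.member_values_.mean(axis=0)
        self.sd_ = self.member_values_.std(axis=0, ddof=1)
        self.usable_ = self.sd_ > 0
        if not self.usable_.any():
            raise InsufficientPanelError("all regions have zero panel SD")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Region z-scores (samples x usable regions)."""
        rows = [self._zscores(X.loc[sid].to_numpy(float), sid) for sid in X.index]
        cols = [r for r, u in zip(self.regions_, self.usable_) if u]
        return pd.DataFrame(rows, index=X.index, columns=cols)

    def _zscores(self, values: np.ndarray, sample_id: str) -> np.ndarray:
        if sample_id in self.member_ids_:
            i = self.member_ids_.index(sample_id)
            others = np.delete(self.member_values_, i, axis=0)
            mu, sd = others.mean(axis=0), others.std(axis=0, ddof=1)
        else:
            mu, sd = self.mean_, self.sd_
        use = self.usable_ & (sd > 0)
        z = np.full(len(self.regions_), np.nan)
        z[use] = (values[use] - mu[use]) / sd[use]
        return z[self.usable_]

    def score_samples(
        self, X: pd.DataFrame, dmr_regions: list[str] | None = None
    ) -> pd.DataFrame:
        """genome_wide_z_sum (all usable regions) and, if a DMR set is given,
        dmr_score (squared z summed over the DMRs present in the panel)."""
        z = self.transform(X)
        out = pd.DataFrame(index=X.index)
        out["genome_wide_z_sum"] = np.nansum(z.to_numpy() ** 2, axis=1)
        if dmr_regions is not None:
            present = [r for r in dmr_regions if r in z.columns]
            if len(present) < len(dmr_regions):
                warnings.warn(
                    f"{len(dmr_regions) - len(present)} DMR regions missing "
                    "from the scored matrix; excluded"
                )
            out["dmr_score"] = np.nansum(z[present].to_numpy() ** 2, axis=1)
            out["n_dmr_used"] = len(present)
        return out


def region_zscores(sample_values: pd.Series, scorer: MethylationScorer) -> pd.Series:
    """z-scores of one sample's normalized values against the fitted panel."""
    frame = sample_values.to_frame().T
    frame.index = [sample_values.name]
    return scorer.transform(frame).iloc[0]


def genome_wide_score(z: pd.Series | np.ndarray) -> float:
    """Sum of squared region z-scores."""
    return float(np.nansum(np.asarray(z, float) ** 2))


def melanoma_score(sample_z: pd.Series, dmr_regions: list[str]) -> float:
    """Sum of squared z-scores restricted to the melanoma DMR set."""
    present = [r for r in dmr_regions if r in sample_z.index]
    if len(present) < len(dmr_regions):
        warnings.warn(
            f"{len(dmr_regions) - len(present)} DMR regions missing; excluded"
        )
    return float(np.nansum(sample_z[present].to_numpy(float) ** 2))


def select_high_ctdna(
    aneuploidy_scores: pd.Series | dict[str, float], min_score: float = 3.0
) -> list[str]:
    """Patients usable for DMR discovery: aneuploidy score >= min_score."""
    scores = pd.Series(aneuploidy_scores)
    selected = list(scores.index[scores >= min_score])
    if not selected:
        raise MelanoliqError(
            "no patient reaches the aneuploidy threshold; DMR discovery refused"
        )
    return selected


# -- moderated t / empirical Bayes --------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    return brentq(lambda x: special.polygamma(1, x) - y, 1e-6, 1e8, xtol=1e-12)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log sample variances to the theoretical
    moments of a scaled F distribution, yielding the prior degrees of freedom
    d0 and prior variance s0^2.  d0 = inf means complete shrinkage.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise MelanoliqError("degenerate variance ensemble")
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    target = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if target <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def moderated_ttest(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Two-group moderated t per column of ``a`` (group A) and ``b`` (group B).

    Returns (log-fold-change B-A, moderated t, p, prior df, prior variance).
    Falls back to the ordinary pooled t (with a warning) when the ensemble of
    region variances cannot support a prior fit.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n_a, n_b = a.shape[0], b.shape[0]
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    df = n_a + n_b - 2
    lfc = b.mean(axis=0) - a.mean(axis=0)
    s2 = ((n_a - 1) * a.var(axis=0, ddof=1) + (n_b - 1) * b.var(axis=0, ddof=1)) / df
    se_factor = np.sqrt(1 / n_a + 1 / n_b)
    try:
        d0, s0_sq = _fit_variance_prior(s2, df)
    except MelanoliqError:
        warnings.warn("variance ensemble degenerate; using ordinary t")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / (np.sqrt(s2) * se_factor)
        p = 2 * stats.t.sf(np.abs(t), df)
        return lfc, t, p, 0.0, float("nan")
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    t = lfc / (np.sqrt(s2_post) * se_factor)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return lfc, t, p, d0, s0_sq


class DMRFinder(BaseEstimator):
    """Differentially methylated region discovery (HBDs vs high-ctDNA patients).

    ``fit(X, y)`` takes normalized values (samples x regions) and group
    labels ("HBD" as reference).  Fitted attributes: ``stats_`` with
    per-region log-fold-change, moderated t, p and BH q; ``dmrs_`` with the
    regions at q < ``fdr``; ``prior_df_`` and ``prior_var_``.
    """

    def __init__(self, fdr: float = 0.10, reference_label: str = HBD):
        self.fdr = fdr
        self.reference_label = reference_label

    def fit(self, X: pd.DataFrame, y) -> "DMRFinder":
        y = np.asarray(y)
        ref = y == self.reference_label
        if ref.sum() < 3 or (~ref).sum() < 3:
            raise InsufficientPanelError("both groups need >= 3 samples")
        a = X.to_numpy(float)[ref]
        b = X.to_numpy(float)[~ref]
        lfc, t, p, d0, s0 = moderated_ttest(a, b)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        self.stats_ = pd.DataFrame(
            {"lfc": lfc, "t": t, "p": p, "q": q}, index=X.columns
        )
        self.dmrs_ = list(self.stats_.index[self.stats_["q"] < self.fdr])
        self.prior_df_ = d0
        self.prior_var_ = s0
        return self


def find_dmrs(
    normalized: pd.DataFrame,
    hbd_ids: list[str],
    patient_ids: list[str],
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Functional wrapper over `DMRFinder` on a regions x samples matrix.

    Returns the per-region statistics restricted to DMRs (q < fdr)."""
    X = normalized[list(hbd_ids) + list(patient_ids)].T
    y = [HBD] * len(hbd_ids) + [PATIENT] * len(patient_ids)
    finder = DMRFinder(fdr=fdr).fit(X, y)
    return finder.stats_.loc[finder.dmrs_]


# -- cutoff and PCA ------------------------------------------------------


def hbd_cutoff(
    hbd_scores, level: float = 0.95, mode: str = "ci_mean"
) -> float:
    """Upper limit of the ``level`` confidence interval of the HBD scores.

    ``ci_mean`` (default): mean + t * SD/sqrt(n), the CI of the mean score.
    ``prediction``: mean + t * SD*sqrt(1 + 1/n), a prediction interval for a
    new healthy sample (more conservative).
    """
    x = np.asarray(list(hbd_scores), float)
    n = len(x)
    if n < 3:
        raise InsufficientPanelError("cutoff needs >= 3 HBD scores")
    tcrit = stats.t.ppf((1 + level) / 2, n - 1)
    sd = x.std(ddof=1)
    if mode == "ci_mean":
        return float(x.mean() + tcrit * sd / np.sqrt(n))
    if mode == "prediction":
        return float(x.mean() + tcrit * sd * np.sqrt(1 + 1 / n))
    raise ValueError(f"unknown cutoff mode {mode!r}")


def call_altered(dmr_score: float, cutoff: float) -> bool:
    """Altered methylation iff the score is strictly above the HBD cutoff."""
    return dmr_score > cutoff


def pca_top_variable(
    normalized: pd.DataFrame,
    fraction: float = 0.50,
    n_components: int = 3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the most variable regions.

    ``normalized`` is regions x samples.  Regions are ranked by variance
    across all samples, the top ``fraction`` kept, values centered per
    region, and coordinates obtained by SVD.  Returns (samples x PCs
    coordinates, explained-variance ratios).
    """
    var = normalized.var(axis=1, ddof=1)
    if not (var > 0).any():
        raise MelanoliqError("constant matrix: PCA undefined")
    n_keep = max(1, int(np.ceil(fraction * len(var))))
    top = var.sort_values(ascending=False, kind="stable").index[:n_keep]
    X = normalized.loc[top].T.to_numpy(float)  # samples x regions
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=normalized.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
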