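"""Cohort statistics: rank correlations, exact tests, and the Simon
two-stage phase-II design search.

The hypothesis tests mirror a small-cohort biomarker analysis: tie-corrected
Spearman correlation (exact permutation p for very small n), two-sided
Mann-Whitney U (exact enumeration when feasible), and the Fisher exact test
with the probability-mass two-sided convention.  The Simon two-stage design
is found by exhaustive search with exact binomial operating characteristics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError, MelanoliqError

# -- rank statistics -----------------------------------------------------


def spearman(x, y, exact_n: int = 9) -> tuple[float, float]:
    """Tie-corrected Spearman rho with two-sided p.

    Missing pairs are removed pairwise (logged).  rho is the Pearson
    correlation of average ranks.  For n <= ``exact_n`` the p-value comes
    from full permutation enumeration; otherwise from the t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < len(x):
        warnings.warn(f"spearman: dropped {int(len(x) - keep.sum())} incomplete pairs")
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise DomainError("spearman needs >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("spearman undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_n:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(min(1.0, 2 * sps.t.sf(abs(t), n - 2)))
    return rho, p


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p: share of y-rank permutations with |rho| >= |rho_obs|."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # n! x n
    cx = rx - rx.mean()
    cy = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((cx**2).sum()) * np.sqrt((cy**2).sum(axis=1))
    rhos = (cy @ cx) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for two independent samples.

    Exact enumeration when n_x * n_y <= 400 and there are no ties; otherwise
    the normal approximation with tie correction.  Returns (U of x, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise DomainError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) * len(y) <= 400 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired measurements
    (e.g. CTC concentration in peripheral blood vs DLA product)."""
    res = sps.wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test, probability-mass convention.

    Returns (sample odds ratio, p).  A zero margin yields p = 1 by
    convention (with a warning).
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise DomainError("table entries must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("fisher_exact_2x2: zero margin, p = 1 by convention")
        odds = np.nan if b * c == 0 else a * d / (b * c)
        return float(odds), 1.0
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def sqrt_display(values) -> np.ndarray:
    """Square-root transform for plotting skewed nonnegative quantities.
    Display only: rank statistics are invariant to it."""
    v = np.asarray(values, float)
    if (v < 0).any():
        raise DomainError("sqrt_display requires nonnegative values")
    return np.sqrt(v)


# -- Simon two-stage design ----------------------------------------------


@dataclass
class SimonDesign:
    """A two-stage single-arm design: stop after stage 1 (n1 patients) if
    responses <= r1; declare the treatment promising iff total responses
    over n patients exceed r."""

    r1: int
    n1: int
    r: int
    n: int
    attained_alpha: float
    attained_power: float
    expected_n_p0: float
    pet_p0: float
    criterion: str


def two_stage_reject_prob(r1: int, n1: int, r: int, n: int, p: float) -> float:
    """Exact P(declare promising | response probability p) for the design:
    sum over stage-1 outcomes x > r1 of P(X1 = x) * P(X2 > r - x)."""
    n2 = n - n1
    xs = np.arange(r1 + 1, n1 + 1)
    if len(xs) == 0:
        return 0.0
    return float(np.sum(sps.binom.pmf(xs, n1, p) * sps.binom.sf(r - xs, n2, p)))


def simon_two_stage(
    p0: float,
    p1: float,
    alpha: float = 0.05,
    beta: float = 0.20,
    n_max: int = 60,
) -> dict[str, SimonDesign]:
    """Exhaustive search for the optimal and minimax Simon two-stage designs.

    Feasible designs attain type-I error <= ``alpha`` under p0 and power
    >= 1 - ``beta`` under p1, computed by the exact two-stage binomial
    convolution.  "optimal" minimizes the expected sample size under p0,
    E[N|p0] = n1 + (1 - PET(p0)) (n - n1); "minimax" minimizes n first.
    Ties are broken by smaller E[N|p0] / n, then smaller n1, then smaller r.
    """
    if not (0 < p0 < p1 < 1):
        raise DomainError("need 0 < p0 < p1 < 1")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise DomainError("alpha and beta must be in (0, 1)")

    feasible: list[tuple] = []
    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            n2 = n - n1
            xs = np.arange(n1 + 1)
            pmf0 = sps.binom.pmf(xs, n1, p0)
            pmf1 = sps.binom.pmf(xs, n1, p1)
            rs = np.arange(n + 1)
            # sf_mat[x, r] = P(X2 > r - x)
            diff = rs[None, :] - xs[:, None]
            sf0 = sps.binom.sf(diff, n2, p0)
            sf1 = sps.binom.sf(diff, n2, p1)
            t0 = pmf0[:, None] * sf0
            t1 = pmf1[:, None] * sf1
            # A[r1, r] = sum_{x = r1+1}^{n1} t[x, r]
            rej0 = np.flip(np.cumsum(np.flip(t0, axis=0), axis=0), axis=0)
            rej1 = np.flip(np.cumsum(np.flip(t1, axis=0), axis=0), axis=0)
            cdf0 = np.cumsum(pmf0)  # PET(p0) for r1 = 0..n1
            for r1 in range(0, n1):
                alpha_att = rej0[r1 + 1]
                power_att = rej1[r1 + 1]
                ok = (alpha_att <= alpha) & (power_att >= 1 - beta)
                ok[: r1 + 1] = False  # require r > r1
                if not ok.any():
                    continue
                r = int(np.argmax(ok))  # smallest feasible r (maximal power)
                pet0 = float(cdf0[r1])
                en0 = n1 + (1 - pet0) * n2
                feasible.append(
                    (en0, n, n1, r1, r, float(alpha_att[r]), float(power_att[r]), pet0)
                )
    if not feasible:
        raise MelanoliqError(f"no feasible two-stage design with n <= {n_max}")

    def make(rec, criterion):
        en0, n, n1, r1, r, a, pw, pet = rec
        return SimonDesign(
            r1=r1, n1=n1, r=r, n=n,
            attained_alpha=a, attained_power=pw,
            expected_n_p0=en0, pet_p0=pet, criterion=criterion,
        )

    optimal = min(feasible, key=lambda t: (t[0], t[1], t[2], t[4]))
    minimax = min(feasible, key=lambda t: (t[1], t[0], t[2], t[4]))
    return {"optimal": make(optimal, "optimal"), "minimax": make(minimax, "minimax")}


# -- integrated cohort report --------------------------------------------

_SCORE_COLS = ("vaf", "aneuploidy_score", "dmr_score")
_CLINICAL_COLS = ("ldh", "tumor_volume_cm3", "lesion_count")
_CTC_COLS = ("ctc_pb_cellsearch", "ctc_dla_cellsearch", "ctc_dla_fcm")


def cohort_report(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Integrated per-patient call matrix and the pairwise cohort tests.

    ``table`` has one row per patient with the blood-based scores (vaf,
    aneuploidy_score, dmr_score), per-platform CTC counts, clinical
    covariates (ldh, tumor_volume_cm3, lesion_count) and boolean call
    columns where available (mutation_detected, aneuploidy_positive,
    methylation_altered).  Tests that cannot run (too few patients, constant
    values, empty groups) are reported as not evaluable, never dropped
    silently.  No multiple-testing correction is applied; raw p-values are
    reported with that caveat.
    """
    if table["patient_id"].duplicated().any():
        raise MelanoliqError("duplicate patient ids in cohort table")
    rows = []

    def record(kind, var_a, var_b, fn):
        try:
            if len(table) < 3:
                raise MelanoliqError("fewer than 3 patients: test not evaluable")
            stat, p = fn()
            rows.append(
                {"test": kind, "a": var_a, "b": var_b, "statistic": stat,
                 "p": p, "significant": p < alpha, "evaluable": True}
            )
        except (MelanoliqError, ValueError) as exc:
            rows.append(
                {"test": kind, "a": var_a, "b": var_b, "statistic": np.nan,
                 "p": np.nan, "significant": False, "evaluable": False,
                 "note": str(exc)}
            )

    for score in _SCORE_COLS:
        for clin in _CLINICAL_COLS:
            if score in table and clin in table:
                record("spearman", score, clin,
                       lambda s=score, c=clin: spearman(table[s], table[c]))

    for ctc in _CTC_COLS:
        if ctc not in table:
            continue
        pos = table[ctc] >= 1
        for clin in _CLINICAL_COLS:
            if clin not in table:
                continue

            def mw(c=clin, m=pos):
                g1 = table.loc[m, c].dropna()
                g0 = table.loc[~m, c].dropna()
                return mann_whitney(g1, g0)

            record("mann_whitney", f"{clin} by {ctc}>=1", ctc, mw)

    present_ctc = [c for c in _CTC_COLS if c in table]
    for c1, c2 in itertools.combinations(present_ctc, 2):
        pos1 = (table[c1] >= 1).sum()
        pos2 = (table[c2] >= 1).sum()
        n = len(table)
        record(
            "fisher", c1, c2,
            lambda a=pos1, b=pos2, n=n: fisher_exact_2x2(a, n - a, b, n - b),
        )

    calls = table.set_index("patient_id")[
        [c for c in ("mutation_detected", "aneuploidy_positive", "methylation_altered") if c in table]
    ].copy()
    for ctc in present_ctc:
        calls[f"{ctc}_positive"] = (table.set_index("patient_id")[ctc] >= 1)
    return {"calls": calls, "tests": pd.DataFrame(rows)}
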