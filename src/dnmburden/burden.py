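"""Per-genome de novo mutation burden and the four burden inference routes.

A newborn's *burden* is its count of autosomal de novo mutations.  Because
burden is strongly scaled by paternal age, a naive case/control comparison
is confounded; this module implements the full battery used to separate the
preterm signal from parental-age effects:

1. direct two-group Wilcoxon rank-sum comparison of counts,
2. logistic regression of preterm status on z-scored paternal age,
   maternal age and burden,
3. residualization of burden on (paternal or maternal) age via OLS,
   followed by the rank-sum comparison of residuals,
4. replication-timing context (base-weighted mean over a 1 kb window
   centered at each mutation) compared between groups.

The Wilcoxon rank-sum implementation uses midranks, a tie-corrected normal
approximation (continuity correction off by default) and an exact
enumeration path when both groups have <= 12 observations, which makes the
exact path directly checkable against brute-force label permutation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AUTOSOMES, DeNovoMutation, ReplicationTimingTrack, TestResult, TrioRecord

#: Largest per-group size for which the exact enumeration path is used.
EXACT_MAX_GROUP = 12


# ---------------------------------------------------------------------------
# Burden counting


def count_burden(
    mutations: Iterable[DeNovoMutation], trios: Sequence[TrioRecord]
) -> pd.Series:
    """Autosomal de novo mutation count per subject.

    Only chromosomes 1-22 are counted.  Every mutation's ``subject_id`` must
    belong to a trio; subjects with no mutations get count 0.
    """
    counts = {t.family_id: 0 for t in trios}
    orphans = set()
    for m in mutations:
        if m.subject_id not in counts:
            orphans.add(m.subject_id)
        elif m.chrom in AUTOSOMES:
            counts[m.subject_id] += 1
    if orphans:
        raise ValueError(
            f"mutations reference {len(orphans)} subject(s) absent from the trio "
            f"table: {', '.join(sorted(orphans)[:10])}"
        )
    return pd.Series(counts, name="burden")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _tie_corrected_sd(pooled_ranks_source: np.ndarray, m: int, n: int) -> float:
    N = m + n
    _, t = np.unique(pooled_ranks_source, return_counts=True)
    tie_term = float(np.sum(t**3 - t))
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    return math.sqrt(max(var, 0.0))


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    *,
    alternative: str = "two-sided",
    method: str = "auto",
    continuity: bool = False,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    The reported statistic is U for the first sample: the number of (x, y)
    pairs with x > y, counting ties as 1/2 (so U ranges over [0, m*n] and
    complete separation with all x below all y gives U = 0).

    ``method`` is ``"exact"`` (full enumeration of rank assignments, valid
    with ties), ``"normal"`` (tie-corrected normal approximation) or
    ``"auto"`` (exact when both groups have <= 12 observations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:m].sum())
    u = w - m * (m + 1) / 2.0
    mu_w = m * (m + n + 1) / 2.0
    if method == "auto":
        method = "exact" if max(m, n) <= EXACT_MAX_GROUP else "normal"
    if method == "exact":
        p = _exact_rank_sum_p(ranks, m, w, mu_w, alternative)
        label = "wilcoxon-rank-sum-exact"
    elif method == "normal":
        sd = _tie_corrected_sd(pooled, m, n)
        if sd == 0.0:
            p = 1.0
            z = 0.0
        else:
            dev = w - mu_w
            if continuity:
                dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev) if dev else 0.0
            z = dev / sd
            if alternative == "two-sided":
                p = 2.0 * stats.norm.sf(abs(z))
            elif alternative == "greater":
                p = stats.norm.sf(z)
            else:
                p = stats.norm.cdf(z)
        label = "wilcoxon-rank-sum-normal"
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        method=label,
        statistic=u,
        p_value=min(float(p), 1.0),
        n_group1=m,
        n_group2=n,
    )


def _exact_rank_sum_p(
    ranks: np.ndarray, m: int, w_obs: float, mu_w: float, alternative: str
) -> float:
    """Exact p by enumerating all C(N, m) assignments of pooled midranks."""
    N = len(ranks)
    eps = 1e-9
    dev_obs = abs(w_obs - mu_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(N), m):
        w = ranks[list(combo)].sum()
        total += 1
        if alternative == "two-sided":
            if abs(w - mu_w) >= dev_obs - eps:
                count += 1
        elif alternative == "greater":
            if w >= w_obs - eps:
                count += 1
        else:
            if w <= w_obs + eps:
                count += 1
    return count / total


def compare_groups(
    values: Mapping[str, float] | Sequence[float],
    labels: Mapping[str, object] | Sequence[object],
    *,
    alternative: str = "two-sided",
    method: str = "auto",
) -> TestResult:
    """Two-group comparison of per-subject values given group labels.

    Labels must take exactly two distinct values; groups are ordered by
    sorted label (so with boolean labels, group 1 is ``False`` = term and
    group 2 is ``True`` = preterm).  The test is label-symmetric for the
    two-sided alternative.
    """
    if isinstance(values, Mapping):
        keys = list(values)
        vals = np.asarray([values[k] for k in keys], dtype=float)
        labs = np.asarray([labels[k] for k in keys])
    else:
        vals = np.asarray(values, dtype=float)
        labs = np.asarray(labels)
        if len(vals) != len(labs):
            raise ValueError("values and labels must have equal length")
    uniq = sorted(set(labs.tolist()), key=repr)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {len(uniq)}")
    g1 = vals[labs == uniq[0]]
    g2 = vals[labs == uniq[1]]
    result = rank_sum_test(g1, g2, alternative=alternative, method=method)
    result.extra["groups"] = [repr(u) for u in uniq]
    return result


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass
class BurdenRegressionResult:
    """Logistic model of preterm status: three z-scored predictors + intercept."""

    coef: dict[str, float]
    p_values: dict[str, float]
    standardization: dict[str, tuple[float, float]]  # predictor -> (mean, sd)
    n: int
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "coef": {k: float(v) for k, v in self.coef.items()},
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "standardization": {
                k: [float(a), float(b)] for k, (a, b) in self.standardization.items()
            },
            "n": int(self.n),
            "converged": bool(self.converged),
        }


def fit_preterm_logistic(
    trios: Sequence[TrioRecord], burden: Mapping[str, float]
) -> BurdenRegressionResult:
    """Fit preterm ~ z(paternal_age) + z(maternal_age) + z(burden).

    Maximum-likelihood logistic fit with per-term Wald p-values.  Predictors
    are z-score normalized (population mean/SD recorded).  Requires at least
    10 subjects per outcome class; non-convergence or separation raises.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.array([float(t.preterm) for t in trios])
    if min((y == 0).sum(), (y == 1).sum()) < 10:
        raise ValueError("need >= 10 subjects in each outcome class")
    predictors = {
        "paternal_age": np.array([t.paternal_age for t in trios], dtype=float),
        "maternal_age": np.array([t.maternal_age for t in trios], dtype=float),
        "burden": np.array([float(burden[t.family_id]) for t in trios]),
    }
    standardization = {}
    cols = []
    for name, v in predictors.items():
        mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
        standardization[name] = (mu, sd)
        cols.append((v - mu) / sd)
    X = sm.add_constant(np.column_stack(cols))
    names = ["intercept", *predictors]
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"logistic fit failed ({exc})") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge (possible separation)")
    if np.max(np.abs(fit.params)) > 50:
        raise ValueError("diverging coefficients: outcome is separable")
    return BurdenRegressionResult(
        coef=dict(zip(names, (float(b) for b in fit.params))),
        p_values=dict(zip(names, (float(p) for p in fit.pvalues))),
        standardization=standardization,
        n=len(y),
    )


# ---------------------------------------------------------------------------
# Residualization and extreme load


def residualize_burden(
    burden: Sequence[float], ages: Sequence[float]
) -> np.ndarray:
    """Residuals of an OLS simple linear fit of burden on age.

    Removes the (paternal- or maternal-) age effect from the counts; the
    residuals sum to zero.
    """
    burden = np.asarray(burden, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(burden) != len(ages):
        raise ValueError("burden and ages must have equal length")
    if len(burden) < 3:
        raise ValueError("need >= 3 subjects for residualization")
    if np.var(ages) == 0:
        raise ValueError("age variance is zero; cannot residualize")
    fit = stats.linregress(ages, burden)
    return burden - (fit.intercept + fit.slope * ages)


def extreme_load_subset(
    burden: Mapping[str, float], fraction: float = 0.05
) -> set[str]:
    """Subjects in the top ``fraction`` of the burden distribution.

    The threshold is the k-th largest burden with k = ceil(fraction * n);
    all subjects tied at the threshold are included, so the set has at least
    k members.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    items = list(burden.items())
    if not items:
        return set()
    values = sorted((v for _, v in items), reverse=True)
    k = math.ceil(fraction * len(items))
    threshold = values[k - 1]
    return {s for s, v in items if v >= threshold}


def age_burden_correlation(
    trios: Sequence[TrioRecord], burden: Mapping[str, float], which: str = "paternal"
) -> tuple[float, float]:
    """Pearson correlation (and r^2) between parental age and burden.

    Computed on raw, unstandardized values; r^2 is reported as the fraction
    of burden variability explained by age.
    """
    ages = np.array(
        [t.paternal_age if which == "paternal" else t.maternal_age for t in trios]
    )
    counts = np.array([float(burden[t.family_id]) for t in trios])
    r = float(stats.pearsonr(ages, counts).statistic)
    return r, r * r


# ---------------------------------------------------------------------------
# Replication-timing context


def timing_context(
    mutations: Sequence[DeNovoMutation],
    track: ReplicationTimingTrack,
    window: int = 1000,
) -> np.ndarray:
    """Base-weighted mean replication timing around each mutation.

    The window spans ``window`` bp centered at the mutation locus, i.e.
    ``[pos0 - window/2, pos0 + window/2)`` in 0-based coordinates where
    ``pos0 = pos - 1``.  Mutations whose window has zero covered bases yield
    NaN (and are excluded from any downstream group comparison).
    """
    if window <= 0 or window % 2:
        raise ValueError(f"window must be a positive even integer, got {window}")
    half = window // 2
    out = np.empty(len(mutations))
    for i, m in enumerate(mutations):
        pos0 = m.pos - 1
        out[i] = track.mean_over(m.chrom, pos0 - half, pos0 + half)[0]
    return out


# ---------------------------------------------------------------------------
# Gestational-age stratification


@dataclass
class StratumResult:
    """Burden comparison for one gestational-age bin against the term group."""

    bin: tuple[float, float]
    n_bin: int
    result: TestResult | None
    underpowered: bool

    def to_dict(self) -> dict:
        return {
            "bin": [float(self.bin[0]), float(self.bin[1])],
            "n_bin": int(self.n_bin),
            "result": None if self.result is None else self.result.to_dict(),
            "underpowered": bool(self.underpowered),
        }


def stratified_burden(
    trios: Sequence[TrioRecord],
    burden: Mapping[str, float],
    bins: Sequence[tuple[float, float]],
    *,
    term_cutoff: float = 37.0,
    min_subjects: int = 5,
) -> list[StratumResult]:
    """Burden comparison per gestational-age bin vs the term group (GA >= 37).

    Bins are half-open ``[lo, hi)``, must be pairwise disjoint and lie
    entirely below the term cutoff.  Bins with fewer than ``min_subjects``
    members are flagged underpowered but still reported; empty bins carry no
    test result.
    """
    for lo, hi in bins:
        if not lo < hi:
            raise ValueError(f"bad bin [{lo}, {hi})")
        if hi > term_cutoff:
            raise ValueError(f"bin [{lo}, {hi}) overlaps the term range (>= {term_cutoff})")
    for (a1, b1), (a2, b2) in itertools.combinations(bins, 2):
        if max(a1, a2) < min(b1, b2):
            raise ValueError(f"overlapping bins [{a1}, {b1}) and [{a2}, {b2})")
    term = [float(burden[t.family_id]) for t in trios if t.gestational_age >= term_cutoff]
    out = []
    for lo, hi in bins:
        members = [
            float(burden[t.family_id])
            for t in trios
            if lo <= t.gestational_age < hi
        ]
        result = None
        if members:
            result = rank_sum_test(members, term)
        out.append(
            StratumResult(
                bin=(lo, hi),
                n_bin=len(members),
                result=result,
                underpowered=len(members) < min_subjects,
            )
        )
    return out
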