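"""Strain-level population statistics for binary behavioral endpoints.

Aggregates per-worm outcomes into the analyses used to compare strains:
habituation curves with binomial confidence intervals, the day-level
quality-control gate on wild-type initial responsiveness, binomial logistic
regression across strains with Tukey-type (single-step multivariate-normal)
adjusted pairwise contrasts, proportion endpoints (swimming at 10 min,
responding to a stimulus), and the basal slowing index.

The model unit is the individual worm: proportions are "worms reversing over
worms tracked", so untracked worms never enter a denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from ._rng import stream
from .errors import ParameterError, QCError

__all__ = [
    "ProportionCI",
    "StrainComparison",
    "QCResult",
    "binomial_ci",
    "habituation_curve",
    "qc_day",
    "compare_habituated_level",
    "proportion_endpoint",
    "basal_slowing_summary",
]

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}

#: Fixed internal seed for the randomized multivariate-normal CDF used by the
#: single-step adjustment; pinned so identical inputs give identical p-values.
_MVN_SEED = 20190227


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its confidence interval."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    method: str
    level: float


@dataclass
class StrainComparison:
    """Fitted strain-level logistic model with pairwise adjusted p-values.

    ``coefficients`` has one row per strain (k, n, log-odds, SE);
    ``contrasts`` one row per unordered strain pair with the log-odds
    difference, Wald SE and z, raw and adjusted p-values.  ``penalized``
    flags the Jeffreys-penalized fit used under complete separation.
    """

    endpoint: str
    coefficients: pd.DataFrame
    contrasts: pd.DataFrame
    adjustment: str
    penalized: bool = False
    factor_coding: str = "treatment (first strain alphabetically is reference)"


@dataclass(frozen=True)
class QCResult:
    passed: bool
    proportion: float
    numerator: int
    denominator: int
    reference_strain: str
    min_initial_response: float


def binomial_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> ProportionCI:
    """Binomial proportion CI (Wilson score by default, Clopper–Pearson by flag)."""
    if n < 1:
        raise ParameterError("undefined proportion: n must be >= 1")
    if not 0 <= k <= n:
        raise ParameterError("require 0 <= k <= n")
    if method not in _CI_METHODS:
        raise ParameterError(f"method must be one of {sorted(_CI_METHODS)}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=_CI_METHODS[method])
    # boundary cases are analytically exact; snap away float residue
    lo = 0.0 if k == 0 else max(0.0, float(lo))
    hi = 1.0 if k == n else min(1.0, float(hi))
    return ProportionCI(
        numerator=int(k),
        denominator=int(n),
        proportion=k / n,
        ci_low=float(lo),
        ci_high=float(hi),
        method=method,
        level=level,
    )


def _tracked(events: pd.DataFrame) -> pd.DataFrame:
    return events[events["tracked"].astype(bool)]


def habituation_curve(
    events: pd.DataFrame,
    strain: Optional[str] = None,
    level: float = 0.95,
    method: str = "wilson",
) -> pd.DataFrame:
    """Per-tap proportion of tracked worms reversing, with binomial CIs.

    Untracked worms are excluded from numerator and denominator alike.  Taps
    with zero tracked worms are kept as flagged gap rows (NaN proportion),
    never interpolated.
    """
    df = events if strain is None else events[events["strain"] == strain]
    if df.empty:
        raise ParameterError(f"no events for strain {strain!r}")
    rows = []
    for tap, grp in df.groupby("tap_index", sort=True):
        tracked = _tracked(grp)
        n = len(tracked)
        if n == 0:
            rows.append(
                dict(tap_index=tap, numerator=0, denominator=0, proportion=np.nan,
                     ci_low=np.nan, ci_high=np.nan, method=method, level=level, gap=True)
            )
            continue
        k = int(tracked["reversed"].astype(bool).sum())
        ci = binomial_ci(k, n, level=level, method=method)
        rows.append(
            dict(tap_index=tap, numerator=k, denominator=n, proportion=ci.proportion,
                 ci_low=ci.ci_low, ci_high=ci.ci_high, method=method, level=level, gap=False)
        )
    return pd.DataFrame(rows)


def qc_day(
    events: pd.DataFrame,
    reference_strain: str = "N2",
    min_initial_response: float = 0.80,
) -> QCResult:
    """Day-level inclusion gate on the reference strain's initial response.

    A day fails when fewer than ``min_initial_response`` (default "at least
    80%", boundary inclusive) of tracked reference-strain worms reversed to
    the first tap.
    """
    ref = events[(events["strain"] == reference_strain) & (events["tap_index"] == 1)]
    ref = _tracked(ref)
    if ref.empty:
        raise QCError(f"reference strain {reference_strain!r} absent at tap 1")
    k = int(ref["reversed"].astype(bool).sum())
    n = len(ref)
    prop = k / n
    return QCResult(
        passed=prop >= min_initial_response,
        proportion=prop,
        numerator=k,
        denominator=n,
        reference_strain=reference_strain,
        min_initial_response=min_initial_response,
    )


# ---------------------------------------------------------------------------
# logistic strain comparison


def _strain_counts(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate worm-level binary outcomes to per-strain (k, n)."""
    grp = outcomes.groupby("strain", sort=True)["outcome"]
    return pd.DataFrame({"k": grp.sum().astype(int), "n": grp.count().astype(int)})


def _fit_strain_logodds(counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-strain log-odds and their variances.

    Without separation, a binomial logistic GLM of outcome on the strain
    factor (treatment coding) is fitted and per-strain log-odds recovered
    from the coefficients.  Under complete separation (a strain at 0% or
    100%) the fit switches to the Jeffreys-penalized closed form — for a
    saturated one-way layout Firth's correction reduces exactly to adding
    1/2 to each success and failure cell.
    """
    k = counts["k"].to_numpy(float)
    n = counts["n"].to_numpy(float)
    separated = bool(np.any((k == 0) | (k == n)))
    if separated:
        logodds = np.log((k + 0.5) / (n - k + 0.5))
        var = 1.0 / (k + 0.5) + 1.0 / (n - k + 0.5)
        return logodds, var, True
    s = len(counts)
    # worm-level Bernoulli rows with a treatment-coded strain factor
    # (intercept = first strain alphabetically, one dummy per other strain)
    n_tot = int(n.sum())
    y = np.zeros(n_tot)
    X = np.zeros((n_tot, s))
    X[:, 0] = 1.0
    pos = 0
    for i in range(s):
        ni, ki = int(n[i]), int(k[i])
        y[pos : pos + ki] = 1.0
        if i > 0:
            X[pos : pos + ni, i] = 1.0
        pos += ni
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    # per-strain log-odds: L maps coefficients back onto the strain cells
    L = np.zeros((s, s))
    L[:, 0] = 1.0
    L[np.arange(1, s), np.arange(1, s)] = 1.0
    logodds = L @ res.params
    var = np.einsum("ij,jk,ik->i", L, res.cov_params(), L)
    return logodds, var, False


#: Monte-Carlo sample size for the single-step max-|z| reference distribution.
_MVN_DRAWS = 200_000


def _mvn_adjust(
    z: np.ndarray, pairs: list[tuple[int, int]], var: np.ndarray, se: np.ndarray
) -> tuple[np.ndarray, str]:
    """Single-step max-|z| (Tukey-type) adjustment of pairwise contrasts.

    The joint null of the contrast z-statistics is multivariate normal with
    the correlation induced by the shared per-strain estimates (singular for
    three or more strains, since pairwise contrasts are linearly dependent).
    Adjusted p-values p_i = P(max_j |Z_j| >= |z_i|) are evaluated by seeded
    Monte Carlo on that exact joint distribution: the independent per-strain
    Gaussian estimates are sampled and propagated through the contrasts.
    Falls back to Bonferroni if the reference cannot be evaluated.
    """
    m = len(z)
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    if m == 1:
        return p_raw, "none (single contrast)"
    try:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(_MVN_SEED)))
        draws = rng.normal(0.0, np.sqrt(var), size=(_MVN_DRAWS, len(var)))
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        max_abs = np.max(np.abs(draws[:, a] - draws[:, b]) / se[None, :], axis=1)
        if not np.all(np.isfinite(max_abs)):
            raise FloatingPointError("non-finite contrast draws")
        max_abs.sort()
        # P(max >= |z_i|) with a midpoint continuity convention
        p_adj = 1.0 - np.searchsorted(max_abs, np.abs(z), side="left") / _MVN_DRAWS
        label = "single-step max-|z| over the joint normal (Tukey-type)"
    except FloatingPointError:
        p_adj = np.minimum(1.0, m * p_raw)
        label = "bonferroni (fallback)"
    p_adj = np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)
    return p_adj, label


def _compare_counts(counts: pd.DataFrame, endpoint: str) -> StrainComparison:
    strains = list(counts.index)
    if len(strains) < 2:
        raise ParameterError("need at least two strains to compare")
    logodds, var, penalized = _fit_strain_logodds(counts)
    coef = counts.copy()
    coef["log_odds"] = logodds
    coef["se"] = np.sqrt(var)

    pairs = list(itertools.combinations(range(len(strains)), 2))
    est = np.array([logodds[a] - logodds[b] for a, b in pairs])
    # per-strain estimates are independent (one parameter per cell), so the
    # contrast covariance is var_a + var_b with cov(ab, ac) = var_a etc.
    cov = np.empty((len(pairs), len(pairs)))
    for i, (a, b) in enumerate(pairs):
        for j, (c, d) in enumerate(pairs):
            cov[i, j] = (
                var[a] * ((a == c) - (a == d))
                + var[b] * ((b == d) - (b == c))
            )
    se = np.sqrt(np.diag(cov))
    z = est / se
    p_adj, adj_label = _mvn_adjust(z, pairs, var, se)
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    contrasts = pd.DataFrame(
        {
            "strain_a": [strains[a] for a, _ in pairs],
            "strain_b": [strains[b] for _, b in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    return StrainComparison(
        endpoint=endpoint,
        coefficients=coef.reset_index(),
        contrasts=contrasts,
        adjustment=adj_label,
        penalized=penalized,
    )


def compare_habituated_level(
    events: pd.DataFrame, endpoint_tap: int = 30, min_worms: int = 5
) -> StrainComparison:
    """Compare the habituated level (proportion reversing at the final tap).

    Fits a binomial logistic regression of reversal at ``endpoint_tap`` on
    strain and reports all pairwise log-odds contrasts with single-step
    multivariate-normal (Tukey-type) adjusted p-values.
    """
    at_tap = _tracked(events[events["tap_index"] == endpoint_tap])
    if at_tap.empty:
        raise ParameterError(f"no tracked worms at tap {endpoint_tap}")
    outcomes = pd.DataFrame(
        {"strain": at_tap["strain"], "outcome": at_tap["reversed"].astype(bool)}
    )
    counts = _strain_counts(outcomes)
    if len(counts) < 2:
        raise ParameterError("need at least two strains")
    if (counts["n"] < min_worms).any():
        thin = counts.index[counts["n"] < min_worms].tolist()
        raise ParameterError(
            f"fewer than {min_worms} tracked worms at tap {endpoint_tap} for {thin}"
        )
    return _compare_counts(counts, endpoint=f"reversal-at-tap-{endpoint_tap}")


def proportion_endpoint(
    outcomes: pd.DataFrame,
    endpoint: str = "endpoint",
    level: float = 0.95,
    method: str = "wilson",
) -> tuple[dict[str, ProportionCI], StrainComparison]:
    """Per-strain proportions with CIs plus the pairwise strain comparison.

    ``outcomes`` holds one row per worm with columns ``strain`` and a boolean
    ``outcome`` (e.g. swimming at 10 min, or responding to a stimulus).
    """
    if not {"strain", "outcome"} <= set(outcomes.columns):
        raise ParameterError("outcomes must have 'strain' and 'outcome' columns")
    counts = _strain_counts(outcomes)
    cis = {
        s: binomial_ci(int(r["k"]), int(r["n"]), level=level, method=method)
        for s, r in counts.iterrows()
    }
    comparison = _compare_counts(counts, endpoint=endpoint)
    return cis, comparison


# ---------------------------------------------------------------------------
# basal slowing


def basal_slowing_summary(
    bends: pd.DataFrame,
    seed: int = 0,
    n_boot: int = 1000,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slowing index per strain with bootstrap intervals, and pairwise differences.

    ``bends`` has one row per worm: columns ``strain``, ``condition``
    ("on_food" / "off_food") and ``bends`` (body-bend count over the scoring
    interval).  The slowing index is 1 - mean(on food) / mean(off food);
    wild-type dopamine signaling makes it positive.  Worm-level bootstrap
    (seeded) supplies the intervals.
    """
    required = {"strain", "condition", "bends"}
    if not required <= set(bends.columns):
        raise ParameterError(f"bends table must have columns {sorted(required)}")
    alpha = 1.0 - level
    strains = sorted(bends["strain"].unique())
    per_strain = {}
    boot_idx = {}
    rows = []
    for s in strains:
        on = bends.query("strain == @s and condition == 'on_food'")["bends"].to_numpy(float)
        off = bends.query("strain == @s and condition == 'off_food'")["bends"].to_numpy(float)
        if on.size == 0 or off.size == 0:
            raise ParameterError(f"strain {s!r} is missing a condition")
        if off.mean() == 0:
            raise ParameterError(f"strain {s!r} has zero mean off-food bends: index undefined")
        index = 1.0 - on.mean() / off.mean()
        rng = stream(seed, f"slowing/{s}")
        boot = np.empty(n_boot)
        for b in range(n_boot):
            on_b = rng.choice(on, on.size, replace=True)
            off_b = rng.choice(off, off.size, replace=True)
            m_off = off_b.mean()
            boot[b] = 1.0 - on_b.mean() / m_off if m_off > 0 else np.nan
        boot_idx[s] = boot
        per_strain[s] = index
        lo, hi = np.nanquantile(boot, [alpha / 2, 1 - alpha / 2])
        rows.append(
            dict(strain=s, n_on=on.size, n_off=off.size,
                 mean_on=on.mean(), sd_on=on.std(ddof=1) if on.size > 1 else 0.0,
                 mean_off=off.mean(), sd_off=off.std(ddof=1) if off.size > 1 else 0.0,
                 slowing_index=index, ci_low=float(lo), ci_high=float(hi))
        )
    summary = pd.DataFrame(rows)

    pair_rows = []
    for a, b in itertools.combinations(strains, 2):
        diff = per_strain[a] - per_strain[b]
        boot_diff = boot_idx[a] - boot_idx[b]
        lo, hi = np.nanquantile(boot_diff, [alpha / 2, 1 - alpha / 2])
        pair_rows.append(
            dict(strain_a=a, strain_b=b, index_diff=diff,
                 ci_low=float(lo), ci_high=float(hi),
                 significant=bool(lo > 0 or hi < 0))
        )
    return summary, pd.DataFrame(pair_rows)
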