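"""Screen-level statistics: percent inhibition, autophagy flux, and the
comparison scheme used throughout (Shapiro-Wilk normality gate, unpaired
two-tailed Student t-test for two groups, one-way ANOVA followed by Dunnett's
many-to-one comparison for more).

The replicate unit for every test is the independent experiment mean (one
field/run summary), never the single cell, to avoid pseudo-replication.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA = 0.05
HIT_THRESHOLD_PCT = 50.0


@dataclass(frozen=True)
class StatResult:
    test: str
    comparison: str
    statistic: float
    p_value: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class HitCall:
    compound: str
    percent_inhibition: float
    adjusted_p: float
    is_hit: bool
    threshold: float
    capped: bool  # True when inhibition exceeded 100% (below-baseline)


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    replicate_means: tuple[float, ...]

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_means)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_means))

    @property
    def sem(self) -> float:
        if self.n_replicates < 2:
            return float("nan")
        return float(np.std(self.replicate_means, ddof=1) / np.sqrt(self.n_replicates))


class NoInductionError(ValueError):
    """Percent inhibition is undefined when the inducer did not raise the readout."""


def percent_inhibition(control_mean: float, inducer_mean: float, treated_mean: float) -> tuple[float, bool]:
    """Inhibition of the induced response, in percent of the induction window.

    100 * (inducer - treated) / (inducer - control). Values above 100
    (below-baseline suppression) are retained and flagged via the second
    return value. Raises :class:`NoInductionError` when inducer <= control.
    """
    window = inducer_mean - control_mean
    if window <= 0:
        raise NoInductionError(
            f"inducer mean {inducer_mean} does not exceed control mean {control_mean}"
        )
    pct = 100.0 * (inducer_mean - treated_mean) / window
    return pct, pct > 100.0


def autophagy_flux(lc3ii_plus_inhibitor: float, lc3ii_minus_inhibitor: float) -> float:
    """LC3-II ratio with/without lysosomal inhibitor; >= 1 under functional flux."""
    if lc3ii_minus_inhibitor <= 0 or lc3ii_plus_inhibitor <= 0:
        raise ValueError("LC3-II intensities must be positive")
    flux = lc3ii_plus_inhibitor / lc3ii_minus_inhibitor
    if flux < 1.0:
        log.warning("flux ratio %.3f < 1: no measurable flux", flux)
    return flux


def flux_table(df: pd.DataFrame, plus_col: str = "lc3ii_plus", minus_col: str = "lc3ii_minus") -> pd.DataFrame:
    """Per-row flux ratio (primary) and LC3-II difference (secondary column)."""
    out = df.copy()
    out["flux_ratio"] = [
        autophagy_flux(p, m) for p, m in zip(df[plus_col], df[minus_col])
    ]
    out["lc3ii_difference"] = df[plus_col] - df[minus_col]
    return out


def normality_gate(groups: dict[str, Sequence[float]], alpha: float = ALPHA) -> pd.DataFrame:
    """Shapiro-Wilk normality check per group; reported, not branching.

    Groups with n < 3 are skipped with a warning; degenerate (constant)
    groups are flagged. Columns: group, n, statistic, p_value, normal, note.
    """
    rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            log.warning("group %r has n=%d < 3; normality gate skipped", name, v.size)
            rows.append(dict(group=name, n=v.size, statistic=np.nan, p_value=np.nan,
                             normal=None, note="skipped: n < 3"))
            continue
        if np.ptp(v) == 0:
            rows.append(dict(group=name, n=v.size, statistic=np.nan, p_value=np.nan,
                             normal=None, note="degenerate: constant sample"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = sps.shapiro(v)
        rows.append(dict(group=name, n=v.size, statistic=float(w), p_value=float(p),
                         normal=bool(p >= alpha), note=""))
    return pd.DataFrame(rows)


def t_test_two_group(a: Sequence[float], b: Sequence[float], welch: bool = False) -> StatResult:
    """Unpaired two-tailed t-test (Student by default; Welch via flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if float(a.mean()) == float(b.mean()):
            # identical constant groups: no evidence of difference
            return StatResult("t_test", "a vs b", 0.0, 1.0)
        raise ValueError("zero variance in both groups; t statistic undefined")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return StatResult("welch_t_test" if welch else "t_test", "a vs b", float(t), float(p))


def _dunnett_correlation(n_treat: Sequence[int], n_control: int) -> np.ndarray:
    lam = np.sqrt(np.asarray(n_treat, float) / (np.asarray(n_treat, float) + n_control))
    return np.eye(len(lam)) + np.outer(lam, lam) * (1 - np.eye(len(lam)))


def dunnett_critical_value(
    k: int,
    n_treat: int,
    n_control: Optional[int] = None,
    alpha: float = ALPHA,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided equicoordinate critical value of Dunnett's max-|t| statistic.

    Solves P(max_i |T_i| <= c) = 1 - alpha for the central multivariate t
    with the many-to-one correlation structure; the rectangle probability is
    evaluated by quasi-Monte Carlo integration (seeded for reproducibility).
    """
    if n_control is None:
        n_control = n_treat
    if rng is None:
        rng = np.random.default_rng(0)
    corr = _dunnett_correlation([n_treat] * k, n_control)
    df = k * n_treat + n_control - (k + 1)  # pooled within-group dof
    seed = int(rng.integers(2**31 - 1))

    def coverage(c: float) -> float:
        return float(
            sps.multivariate_t.cdf(
                np.full(k, c),
                loc=np.zeros(k),
                shape=corr,
                df=df,
                lower_limit=np.full(k, -c),
                random_state=np.random.default_rng(seed),
            )
        )

    return float(optimize.brentq(lambda c: coverage(c) - (1 - alpha), 1.0, 8.0, xtol=1e-4))


#: comparison count above which the adjustment switches to direct Monte Carlo
#: sampling of the max-|t| null (the high-dimensional QMC integral is slow)
_DUNNETT_MC_KMIN = 9
_DUNNETT_MC_DRAWS = 200_000


def _dunnett_pvalues_mc(
    t_stats: np.ndarray,
    lam: np.ndarray,
    df: int,
    rng: np.random.Generator,
    draws: int = _DUNNETT_MC_DRAWS,
) -> np.ndarray:
    """Adjusted p-values by Monte Carlo sampling of Dunnett's max-|t| null.

    The many-to-one statistics share one factor: T_j = (lam_j Z0 +
    sqrt(1-lam_j^2) E_j) / sqrt(W/df) with Z0, E_j standard normal and W a
    chi-square, which reproduces the corr(T_i, T_j) = lam_i lam_j structure
    exactly; p_i = P(max_j |T_j| >= |t_i|).
    """
    k = lam.size
    z0 = rng.standard_normal(draws)
    e = rng.standard_normal((draws, k))
    z = lam * z0[:, None] + np.sqrt(1.0 - lam**2) * e
    w = rng.chisquare(df, draws)
    max_t = np.abs(z / np.sqrt(w / df)[:, None]).max(axis=1)
    return np.array([(max_t >= abs(t)).mean() for t in t_stats])


def anova_dunnett(
    groups: dict[str, Sequence[float]],
    reference: str,
    rng: Optional[np.random.Generator] = None,
) -> tuple[StatResult, list[StatResult]]:
    """One-way ANOVA omnibus plus Dunnett-adjusted treatment-vs-reference tests.

    The Dunnett adjustment integrates the many-to-one multivariate t (seeded
    quasi-Monte Carlo); with a single comparison it reduces to the unpaired
    two-sided t-test, and with many comparisons the null of the max-|t|
    statistic is sampled directly (seeded, 2e5 draws).
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} absent from groups")
    treat = {k: np.asarray(v, float) for k, v in groups.items() if k != reference}
    if not treat:
        raise ValueError("need at least one non-reference group")
    ref = np.asarray(groups[reference], float)
    if any(v.size < 2 for v in treat.values()) or ref.size < 2:
        raise ValueError("each group needs n >= 2")
    if rng is None:
        rng = np.random.default_rng(0)

    f, p = sps.f_oneway(ref, *treat.values())
    omnibus = StatResult("anova", "omnibus", float(f), float(p))

    if len(treat) >= _DUNNETT_MC_KMIN:
        samples = list(treat.values())
        n_i = np.array([v.size for v in samples])
        n0 = ref.size
        df = int(n_i.sum() + n0 - (len(samples) + 1))
        sp2 = (
            sum(((v - v.mean()) ** 2).sum() for v in samples)
            + ((ref - ref.mean()) ** 2).sum()
        ) / df
        t_stats = np.array(
            [(v.mean() - ref.mean()) / np.sqrt(sp2 * (1 / v.size + 1 / n0)) for v in samples]
        )
        lam = np.sqrt(n_i / (n_i + n0))
        pvals_arr = _dunnett_pvalues_mc(
            t_stats, lam, df, np.random.default_rng(int(rng.integers(2**31 - 1)))
        )
        comparisons = [
            StatResult("dunnett", f"{name} vs {reference}", float(t), float(pv))
            for name, t, pv in zip(treat, t_stats, pvals_arr)
        ]
        return omnibus, comparisons

    res = sps.dunnett(
        *treat.values(),
        control=ref,
        alternative="two-sided",
        rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
    )
    if len(treat) == 1:
        # single comparison: the adjustment vanishes and the p-value is the
        # exact two-sided Student tail, not a QMC estimate
        t_stat = float(res.statistic[0])
        df = sum(v.size for v in treat.values()) + ref.size - 2
        pvals = [2.0 * float(sps.t.sf(abs(t_stat), df))]
    else:
        pvals = [float(pv) for pv in res.pvalue]
    comparisons = [
        StatResult("dunnett", f"{name} vs {reference}", float(t), pv)
        for name, t, pv in zip(treat, res.statistic, pvals)
    ]
    return omnibus, comparisons


def screen_report(
    summaries: list[ConditionSummary],
    control_label: str,
    inducer_label: str,
    threshold: float = HIT_THRESHOLD_PCT,
    alpha: float = ALPHA,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Rank compounds by percent inhibition of the induced mitophagy response.

    A compound is a hit when its inhibition reaches `threshold` AND its
    Dunnett-adjusted p against the inducer condition is significant. Columns:
    compound, percent_inhibition, capped, adjusted_p, is_hit, threshold.
    """
    by_label = {s.condition: s for s in summaries}
    if control_label not in by_label or inducer_label not in by_label:
        raise ValueError("control and inducer conditions are both required")
    control = by_label[control_label]
    inducer = by_label[inducer_label]
    compounds = [s for s in summaries if s.condition not in (control_label, inducer_label)]
    if not compounds:
        return pd.DataFrame(
            columns=["compound", "percent_inhibition", "capped", "adjusted_p", "is_hit", "threshold"]
        )
    groups = {s.condition: s.replicate_means for s in compounds}
    groups[inducer_label] = inducer.replicate_means
    _, comparisons = anova_dunnett(groups, reference=inducer_label, rng=rng)
    adj = {c.comparison.split(" vs ")[0]: c.p_value for c in comparisons}

    rows = []
    for s in compounds:
        pct, capped = percent_inhibition(control.mean, inducer.mean, s.mean)
        p_adj = adj[s.condition]
        rows.append(
            dict(
                compound=s.condition,
                percent_inhibition=pct,
                capped=capped,
                adjusted_p=p_adj,
                is_hit=bool(pct >= threshold and p_adj < alpha and s.mean < inducer.mean),
                threshold=threshold,
            )
        )
    return (
        pd.DataFrame(rows)
        .sort_values("percent_inhibition", ascending=False, ignore_index=True)
    )
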