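"""Nonparametric inference layer: rank tests, trend tests and the mixed model.

All group comparisons are rank-based (Mann-Whitney, Kruskal-Wallis, Friedman)
to avoid normality assumptions on power values; Dunn's test provides the post
hoc pairwise comparisons, Mann-Kendall the monotone-trend tests, and a linear
mixed model (random intercept and slope per animal) relates daily circadian
power to same-day fecal estradiol.

Mann-Kendall and Dunn's test are implemented here directly (with tie
corrections) and are validated against brute-force oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "TrendResult",
    "MixedModelResult",
    "downsample_for_stats",
    "rank_test_two",
    "omnibus_with_dunn",
    "mann_kendall",
    "mixed_cr_fe2",
]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    group_ns: tuple
    pairwise: pd.DataFrame | None = None


@dataclass
class TrendResult:
    S: int
    tau: float
    p_value: float
    z: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.S))


@dataclass
class MixedModelResult:
    intercept: float
    slope: float
    slope_se: float
    re_var_intercept: float
    re_var_slope: float
    resid_var: float
    r2_marginal: float
    aic: float
    random_slope: bool
    converged: bool


def downsample_for_stats(age_min: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Thin a minute-resolution series to one value per hour or per day.

    Spans shorter than 3 days keep one (mean) value per hour; spans of 3 days
    or longer keep one per day.  Returns (bin_age_days, bin_means); NaN-only
    bins are dropped.
    """
    age_min = np.asarray(age_min)
    values = np.asarray(values, dtype=float)
    if age_min.size == 0:
        raise ValueError("empty span")
    span_days = (age_min[-1] - age_min[0] + 1) / 1440.0
    width = 60 if span_days < 3 else 1440
    bins = age_min // width
    df = pd.DataFrame({"bin": bins, "v": values}).groupby("bin")["v"].mean().dropna()
    return df.index.to_numpy() * (width / 1440.0), df.to_numpy()


def rank_test_two(a, b, alternative: str = "two-sided") -> ComparisonResult:
    """Mann-Whitney U rank-sum test between two independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("all values tied across both groups; U test undefined")
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return ComparisonResult("mann-whitney", float(res.statistic), float(res.pvalue),
                            (a.size, b.size))


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def _dunn_independent(groups, labels) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks after a Kruskal-Wallis omnibus."""
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append((labels[i], labels[j], z, 2 * sps.norm.sf(abs(z))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])


def _dunn_repeated(table: np.ndarray, labels) -> pd.DataFrame:
    """Dunn's z-tests on within-block rank sums after a Friedman omnibus."""
    n_blocks, k = table.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, table)
    rank_sums = ranks.sum(axis=0)
    se = np.sqrt(n_blocks * k * (k + 1) / 6.0)
    rows = []
    for i, j in combinations(range(k), 2):
        z = (rank_sums[i] - rank_sums[j]) / se
        rows.append((labels[i], labels[j], z, 2 * sps.norm.sf(abs(z))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])


def omnibus_with_dunn(
    groups,
    design: str = "independent",
    labels=None,
    alpha: float = 0.05,
    p_adjust: str = "holm",
    always_pairwise: bool = False,
) -> ComparisonResult:
    """Kruskal-Wallis (independent) or Friedman (repeated) omnibus + Dunn post hoc.

    ``groups``: for the independent design, a sequence of >= 3 samples; for the
    repeated design, a blocks x conditions array (each row one block, e.g. one
    estrous cycle of one animal).  Pairwise Dunn z-statistics (with Holm or
    Bonferroni adjustment) are attached when the omnibus is significant at
    ``alpha`` (or unconditionally with ``always_pairwise``).
    """
    if design == "independent":
        groups = [np.asarray(g, dtype=float) for g in groups]
        if len(groups) < 3:
            raise ValueError("need >= 3 groups for Kruskal-Wallis")
        labels = list(labels) if labels is not None else list(range(len(groups)))
        stat, p = sps.kruskal(*groups)
        ns = tuple(len(g) for g in groups)
        pair_fn = lambda: _dunn_independent(groups, labels)
        name = "kruskal-wallis"
    elif design == "repeated":
        table = np.asarray(groups, dtype=float)
        if table.ndim != 2:
            raise ValueError("repeated design needs a blocks x conditions table")
        n_blocks, k = table.shape
        if k < 3 or n_blocks < 2:
            raise ValueError("Friedman needs >= 3 conditions and >= 2 complete blocks")
        if np.isnan(table).any():
            raise ValueError("incomplete blocks must be dropped before the Friedman test")
        labels = list(labels) if labels is not None else list(range(1, k + 1))
        if np.all(table.max(axis=1) == table.min(axis=1)):
            # every block fully tied: no evidence of condition differences
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.friedmanchisquare(*table.T)
        ns = (n_blocks,) * k
        pair_fn = lambda: _dunn_repeated(table, labels)
        name = "friedman"
    else:
        raise ValueError(f"unknown design {design!r}")

    pairwise = None
    if p < alpha or always_pairwise:
        pairwise = pair_fn()
        if p_adjust == "holm":
            pairwise["p_adj"] = _holm(pairwise["p_raw"].to_numpy())
        elif p_adjust == "bonferroni":
            pairwise["p_adj"] = np.minimum(1.0, pairwise["p_raw"] * len(pairwise))
        elif p_adjust == "none":
            pairwise["p_adj"] = pairwise["p_raw"]
        else:
            raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return ComparisonResult(name, float(stat), float(p), ns, pairwise)


def mann_kendall(values) -> TrendResult:
    """Mann-Kendall monotone trend test.

    S = sum_{i<j} sign(x_j - x_i); the normal approximation uses the
    tie-corrected variance and a continuity correction.  tau is Kendall's
    tau-b (equal to S / (n(n-1)/2) when there are no ties).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Mann-Kendall needs >= 4 values")
    if np.isnan(x).any():
        raise ValueError("missing values in trend input")
    diffs = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diffs, k=1).sum())

    _, counts = np.unique(x, return_counts=True)
    tie_var = (counts * (counts - 1) * (2 * counts + 5)).sum()
    var_s = (n * (n - 1) * (2 * n + 5) - tie_var) / 18.0

    n0 = n * (n - 1) / 2.0
    t_ties = (counts * (counts - 1) / 2.0).sum()
    denom = np.sqrt((n0 - t_ties) * n0)
    tau = S / denom if denom > 0 else 0.0

    if S > 0:
        z = (S - 1) / np.sqrt(var_s)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2 * sps.norm.sf(abs(z)) if var_s > 0 else 1.0
    return TrendResult(S, float(tau), float(p), float(z))


def mixed_cr_fe2(df: pd.DataFrame, response: str = "cr_power",
                 predictor: str = "fe2", group: str = "animal_id") -> MixedModelResult:
    """Mixed-effects regression of daily circadian power on same-day fE2.

    Fits ``response ~ 1 + predictor`` with correlated random intercept and
    slope per animal, by maximum likelihood (so AICs are comparable across
    fixed-effect structures).  Falls back to a random-intercept-only model when
    the random-slope fit is singular or fails to converge.  The reported R^2 is
    marginal: variance of the fixed-effect predictions over total (fixed +
    random + residual) variance.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    data = df[[group, response, predictor]].dropna()
    n_per = data.groupby(group).size()
    if (n_per >= 3).sum() < 2:
        raise ValueError("need >= 2 animals with >= 3 paired days each")

    endog = data[response].to_numpy(dtype=float)
    exog = sm.add_constant(data[predictor].to_numpy(dtype=float))
    groups = data[group].to_numpy()

    def _fit(re_formula_slope: bool):
        exog_re = exog if re_formula_slope else exog[:, :1]
        model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            return model.fit(reml=False, method="lbfgs", maxiter=200)

    random_slope = True
    try:
        res = _fit(True)
        singular = not np.all(np.isfinite(res.bse_fe)) or not res.converged
    except Exception:
        singular = True
    if singular:
        random_slope = False
        res = _fit(False)

    fe_pred = exog @ res.fe_params
    var_f = float(np.var(fe_pred))
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    var_re = float(np.trace(cov_re @ (exog[:, : cov_re.shape[0]].T
                                      @ exog[:, : cov_re.shape[0]]) / exog.shape[0]))
    var_e = float(res.scale)
    r2m = var_f / (var_f + var_re + var_e)

    re_var_slope = float(cov_re[1, 1]) if random_slope and cov_re.shape[0] > 1 else 0.0
    return MixedModelResult(
        intercept=float(res.fe_params[0]),
        slope=float(res.fe_params[1]),
        slope_se=float(res.bse_fe[1]),
        re_var_intercept=float(cov_re[0, 0]),
        re_var_slope=re_var_slope,
        resid_var=var_e,
        r2_marginal=float(r2m),
        aic=float(res.aic),
        random_slope=random_slope,
        converged=bool(res.converged),
    )
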