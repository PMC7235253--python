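"""Group-level statistics for electrode cohorts.

Covers prevalence of significant effects against a binomial chance model,
two-proportion comparisons, the logistic model of oscillator class on A-P
position, anatomical frequency-gradient correlations, hemisphere and
subregion comparisons, the two-way (region x band) ANOVA of subject-level
speed-frequency prevalence, the harmonic permutation test on dual-oscillator
band frequencies, and the low/high co-occurrence test.

Conventions: the binomial prevalence test and the two-proportion z-test are
one-sided (upper tail); the permutation p-value uses the add-one rule; the
unbalanced two-way ANOVA uses Type II sums of squares.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "binomial_prevalence_test",
    "proportion_z_test",
    "oscillator_logistic",
    "gradient_correlation",
    "hemisphere_tests",
    "speedfreq_anova",
    "harmonic_permutation_test",
    "cooccurrence_test",
    "subject_cell_table",
]


def binomial_prevalence_test(k_significant: int, n: int, alpha: float = 0.05) -> float:
    """Exact one-sided binomial tail P(X >= k) with X ~ Binomial(n, alpha).

    Used to ask whether ``k`` of ``n`` electrodes reaching per-electrode
    significance at level ``alpha`` exceeds chance.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k_significant <= n:
        raise ValueError("k must be in [0, n]")
    return float(
        sum(
            math.comb(n, i) * alpha**i * (1 - alpha) ** (n - i)
            for i in range(k_significant, n + 1)
        )
    )


def proportion_z_test(k1: int, n1: int, k2: int, n2: int,
                      one_sided: bool = True) -> dict:
    """Pooled two-proportion z-test (group 1 vs group 2).

    One-sided tests H1: p1 > p2.  A pooled proportion of exactly 0 or 1 makes
    the statistic undefined and is flagged.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    out = {"z": np.nan, "p": np.nan, "flag": None}
    if pooled in (0.0, 1.0):
        out["flag"] = "degenerate_pooled_proportion"
        return out
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = stats.norm.sf(z) if one_sided else 2 * stats.norm.sf(abs(z))
    out["z"], out["p"] = float(z), float(p)
    return out


def oscillator_logistic(ap_fractions: np.ndarray, classes: np.ndarray) -> dict:
    """Logistic regression of single (1) vs dual (0) on A-P fraction.

    Returns the ML intercept and slope with the Wald p-value for the slope.
    Perfect separation is flagged and no p-value is reported.
    """
    import statsmodels.api as sm

    ap = np.asarray(ap_fractions, dtype=float)
    y = np.asarray(
        [1 if c in (1, "single", True) else 0 for c in np.asarray(classes).ravel()]
    )
    if ap.size < 10:
        raise ValueError("need at least 10 electrodes")
    if y.min() == y.max():
        raise ValueError("both oscillator classes must be present")
    X = sm.add_constant(ap)
    out = {"beta0": np.nan, "beta1": np.nan, "p": np.nan, "flag": None}
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e4):
            raise sm.tools.sm_exceptions.PerfectSeparationError
        out["beta0"], out["beta1"] = float(fit.params[0]), float(fit.params[1])
        out["p"] = float(fit.pvalues[1])
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        out["flag"] = "perfect_separation"
    return out


def gradient_correlation(table: pd.DataFrame, by: str = "all",
                         min_n: int = 3) -> dict:
    """Pearson correlation of band peak frequency with A-P position.

    ``table`` needs columns ``peak_hz``, ``ap_fraction`` and (for stratified
    runs) ``hemisphere``; ``by`` is ``all``, ``L`` or ``R``.  Strata with
    fewer than ``min_n`` electrodes are skipped with a flag.
    """
    sub = table if by == "all" else table[table["hemisphere"] == by]
    out = {"stratum": by, "r": np.nan, "p": np.nan, "n": int(len(sub)), "flag": None}
    if len(sub) < min_n:
        out["flag"] = "insufficient_n"
        return out
    r, p = stats.pearsonr(sub["ap_fraction"], sub["peak_hz"])
    out["r"], out["p"] = float(r), float(p)
    return out


def hemisphere_tests(table: pd.DataFrame) -> dict:
    """Hemisphere and subregion comparisons on a per-band cohort table.

    Runs (a) an unpaired t-test of high-theta single-oscillator peak
    frequencies L vs R, (b) a Wilcoxon rank-sum test of electrode A-P
    positions L vs R (positioning balance), and (c) a one-way ANOVA of single
    oscillator peak frequency across subregions.
    """
    out: dict = {}
    hs = table[(table["oscillator_class"] == "single") & (table["label"] == "high")]
    left = hs[hs["hemisphere"] == "L"]["peak_hz"]
    right = hs[hs["hemisphere"] == "R"]["peak_hz"]
    if len(left) < 2 or len(right) < 2:
        raise ValueError("both hemispheres must be represented")
    t, p = stats.ttest_ind(right, left, equal_var=True)
    out["freq_t"] = {"t": float(t), "df": int(len(left) + len(right) - 2),
                     "p": float(p), "mean_L": float(left.mean()),
                     "mean_R": float(right.mean())}
    pos = table.drop_duplicates("electrode_id")
    zstat, zp = stats.ranksums(
        pos[pos["hemisphere"] == "L"]["ap_fraction"],
        pos[pos["hemisphere"] == "R"]["ap_fraction"],
    )
    out["position_ranksum"] = {"z": float(zstat), "p": float(zp)}
    single = table[table["oscillator_class"] == "single"]
    groups = [g["peak_hz"].to_numpy() for _, g in single.groupby("subregion")
              if len(g) >= 2]
    if len(groups) >= 2:
        F, ap = stats.f_oneway(*groups)
        out["subregion_anova"] = {"F": float(F), "p": float(ap),
                                  "k_groups": len(groups)}
    else:
        out["subregion_anova"] = {"F": np.nan, "p": np.nan, "k_groups": len(groups)}
    return out


def subject_cell_table(corr_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Subject-level prevalence of significant positive speed-frequency effects.

    For each subject x region (anterior/posterior) x band (low/high) cell, the
    value is the fraction of that subject's electrodes in the cell with r > 0
    and p < alpha.  Needs columns subject_id, region, label, r, p.
    """
    df = corr_table.dropna(subset=["r", "p"]).copy()
    df["significant_pos"] = (df["r"] > 0) & (df["p"] < alpha)
    cells = (
        df.groupby(["subject_id", "region", "label"])["significant_pos"]
        .mean()
        .rename("value")
        .reset_index()
    )
    return cells


def speedfreq_anova(subject_cells: pd.DataFrame) -> dict:
    """Two-way factorial ANOVA (region x band, with interaction).

    Operates on subject-level cell values (one value per subject x region x
    band); uses Type II sums of squares, appropriate for unbalanced tables.
    Returns F and p for the region and band main effects and the interaction.
    An all-identical value column is degenerate and flagged.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = subject_cells.rename(columns={"label": "band"}).copy()
    if df["value"].nunique() <= 1:
        return {"flag": "degenerate"}
    if df["region"].nunique() < 2 or df["band"].nunique() < 2:
        raise ValueError("need both regions and both bands")
    import warnings as _warnings

    model = ols("value ~ C(region) * C(band)", data=df).fit()
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        with np.errstate(all="ignore"):
            table = sm.stats.anova_lm(model, typ=2)
    if not np.isfinite(table["F"].iloc[:3]).all():
        return {"flag": "insufficient_cells"}
    def _row(name: str) -> dict:
        return {"F": float(table.loc[name, "F"]), "p": float(table.loc[name, "PR(>F)"]),
                "df": float(table.loc[name, "df"])}
    return {
        "region": _row("C(region)"),
        "band": _row("C(band)"),
        "interaction": _row("C(region):C(band)"),
        "flag": None,
    }


def harmonic_permutation_test(f_low: np.ndarray, f_high: np.ndarray,
                              n_perm: int = 10_000,
                              rng: np.random.Generator | int | None = None) -> dict:
    """Permutation test of the low/high frequency correlation at dual sites.

    A strong positive correlation would indicate the high band is a harmonic
    of the low one.  The null is built by shuffling the high-frequency
    assignment across electrodes; the two-sided p-value uses the add-one rule
    ``(1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``.
    """
    f_low = np.asarray(f_low, dtype=float)
    f_high = np.asarray(f_high, dtype=float)
    if f_low.size != f_high.size or f_low.size < 5:
        raise ValueError("need >= 5 matched (low, high) frequency pairs")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r_obs = float(stats.pearsonr(f_low, f_high)[0])
    count = 0
    for _ in range(n_perm):
        r_perm = stats.pearsonr(f_low, rng.permutation(f_high))[0]
        if abs(r_perm) >= abs(r_obs):
            count += 1
    return {"r": r_obs, "p": (1 + count) / (n_perm + 1), "n_perm": n_perm}


def cooccurrence_test(mask_pairs: list[tuple[np.ndarray, np.ndarray]]) -> dict:
    """Do the two bands of dual oscillators tend to occur simultaneously?

    Per electrode the statistic is ``P(both present) - P(low) * P(high)``
    (excess joint presence over independence); electrodes with zero presence
    in either band are excluded.  The group-level test is a two-sided Wilcoxon
    signed-rank of the statistics against 0.
    """
    statistics = []
    n_excluded = 0
    for low, high in mask_pairs:
        low = np.asarray(low, dtype=bool)
        high = np.asarray(high, dtype=bool)
        if low.size != high.size:
            raise ValueError("band masks must be equally long")
        p_lo, p_hi = low.mean(), high.mean()
        if p_lo == 0 or p_hi == 0:
            import warnings

            warnings.warn("electrode with zero presence in one band excluded",
                          stacklevel=2)
            n_excluded += 1
            continue
        statistics.append(float((low & high).mean() - p_lo * p_hi))
    out = {"statistics": statistics, "n_excluded": n_excluded,
           "p": np.nan, "flag": None}
    if len(statistics) < 5:
        out["flag"] = "too_few_electrodes"
        return out
    if np.allclose(statistics, 0):
        out["flag"] = "all_zero"
        out["p"] = 1.0
        return out
    _, p = stats.wilcoxon(statistics, alternative="two-sided")
    out["p"] = float(p)
    return out
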