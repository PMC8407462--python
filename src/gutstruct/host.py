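"""Host-factor analyses: hypergeometric prevalence screening by
demographic group, IQR-winsorized age-conditioned linear association of
ASV abundance with host factors, diet-pattern PCA and age-diversity
correlation.

The linear association predicts the host factor from the log-transformed
relative abundance of one ASV.  When that abundance is more strongly
associated with age than with the factor (smaller p in the univariate
age model), age enters the model as a covariate and the abundance term
is tested by a partial F-test.  Zeros are handled by a per-ASV
pseudocount of half the smallest nonzero relative abundance
(``zero_policy="pseudocount"``), or excluded (``"nonzero"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import relative_abundance
from .conetwork import bh_fdr

logger = logging.getLogger("gutstruct")


# ---------------------------------------------------------------------------
# prevalence screening


def hypergeom_tails(N: int, K: int, n: int, k: int):
    """Upper and lower tail probabilities of Hypergeometric(N, K, n) at k.

    ``p_enriched`` = P(X >= k), ``p_depleted`` = P(X <= k); both include
    the observed value, so each lies in (0, 1].
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError("inconsistent hypergeometric parameters")
    p_enriched = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_depleted = float(stats.hypergeom.cdf(k, N, K, n))
    return p_enriched, p_depleted


def prevalence_enrichment(presence: pd.DataFrame, groups: pd.Series,
                          alpha: float = 0.1) -> pd.DataFrame:
    """Screen every ASV x demographic group for prevalence differences.

    ``presence`` is a samples x ASVs boolean table; ``groups`` assigns
    each sample to one demographic group.  For each (ASV, group) the
    carrier count k in the group is compared against drawing n group
    samples from the full cohort of N samples with K carriers.  The
    reported two-sided p doubles the smaller tail (capped at 1); BH runs
    across all ASV x group tests at FDR ``alpha``.  ``direction`` is "+"
    for enrichment, "-" for depletion, "" for no call.
    """
    groups = groups.reindex(presence.index)
    if groups.isna().any():
        raise ValueError("groups must cover all samples")
    N = len(presence)
    rows = []
    for g, idx in presence.groupby(groups).groups.items():
        n = len(idx)
        if n == 0:
            raise ValueError(f"empty group {g!r}")
        sub = presence.loc[idx]
        for asv in presence.columns:
            K = int(presence[asv].sum())
            k = int(sub[asv].sum())
            p_enr, p_dep = hypergeom_tails(N, K, n, k)
            p_two = min(1.0, 2 * min(p_enr, p_dep))
            rows.append((asv, g, N, K, n, k, p_enr, p_dep, p_two))
    out = pd.DataFrame(rows, columns=["asv", "group", "N", "K", "n", "k",
                                      "p_enriched", "p_depleted", "p"])
    out["q"], reject = bh_fdr(out["p"].to_numpy(), alpha)
    out["direction"] = np.where(~reject, "",
                                np.where(out["p_enriched"] < out["p_depleted"], "+", "-"))
    return out


def direction_matrix(screen: pd.DataFrame) -> pd.DataFrame:
    """Pivot a prevalence screen into the ASV x group +/- display table."""
    return screen.pivot(index="asv", columns="group", values="direction").fillna("")


# ---------------------------------------------------------------------------
# winsorization and association


def winsorize_iqr(values, factor: float = 1.5) -> np.ndarray:
    """Clip values beyond quartile +/- ``factor`` x IQR to the cutoffs.

    Quartiles use linear interpolation (numpy's default, R type 7).
    Idempotent: applying twice changes nothing.
    """
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("need at least 4 values to estimate quartiles")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return np.clip(x, q1 - factor * iqr, q3 + factor * iqr)


def log_abundance(counts: pd.DataFrame, zero_policy: str = "pseudocount") -> pd.DataFrame:
    """Natural-log relative abundance for association analyses.

    "pseudocount": zeros replaced by half the ASV's smallest nonzero
    relative abundance before the log (every sample retained).
    "nonzero": zeros become NaN and drop out of downstream fits.
    """
    rel = relative_abundance(counts)
    if zero_policy == "pseudocount":
        half_min = rel.where(rel > 0).min(axis=0) / 2
        filled = rel.where(rel > 0, half_min, axis=1)
        # ASVs absent everywhere have no nonzero minimum; leave them NaN
        return np.log(filled)
    if zero_policy == "nonzero":
        with np.errstate(divide="ignore"):
            return np.log(rel.where(rel > 0))
    raise ValueError(f"unknown zero_policy {zero_policy!r}")


def _ols_slope_test(y: np.ndarray, X: np.ndarray):
    """OLS of y on columns of X (intercept added); returns (betas, p_last,
    F_last) where the last column's coefficient is tested by partial F
    (equals the squared t of that slope)."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X])
    k = Z.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    rss = float(resid @ resid)
    df = n - k
    if df <= 0 or rank < k:
        return beta[1:], np.nan, np.nan
    # reduced model without the last column
    Zr = Z[:, :-1]
    br, _, _, _ = np.linalg.lstsq(Zr, y, rcond=None)
    rss_r = float((y - Zr @ br) @ (y - Zr @ br))
    if rss <= 0:
        return beta[1:], 0.0, np.inf
    F = (rss_r - rss) / (rss / df)
    p = float(stats.f.sf(F, 1, df))
    return beta[1:], p, float(F)


@dataclass
class AssociationResult:
    table: pd.DataFrame      # asv, factor, beta, F, p, q, age_adjusted, n_used
    fdr: float


def associate(counts: pd.DataFrame, factors: pd.DataFrame,
              age: pd.Series | None = None, fdr: float = 0.2,
              zero_policy: str = "pseudocount", min_samples: int = 10,
              winsorize: bool = True) -> AssociationResult:
    """Linear association of every host factor with every ASV abundance.

    For each (ASV, factor): fit ``factor ~ log_abundance``; if age is
    supplied and the ASV's abundance is more strongly associated with
    age than with the factor, refit ``factor ~ log_abundance + age`` and
    test the abundance term by partial F.  Factors are IQR-winsorized
    (unless ``winsorize=False``); BH runs across all pairs at FDR
    ``fdr``.  Zero-variance inputs and pairs with fewer than
    ``min_samples`` usable samples are excluded and logged.
    """
    logab = log_abundance(counts, zero_policy)
    factors = factors.loc[counts.index]
    if age is not None:
        age = age.loc[counts.index].astype(float)
    rows, n_skipped = [], 0
    for factor in factors.columns:
        raw = factors[factor].astype(float)
        fac_all = pd.Series(winsorize_iqr(raw.dropna()), index=raw.dropna().index) \
            if winsorize and raw.dropna().size >= 4 else raw.dropna()
        for asv in counts.columns:
            x_all = logab[asv]
            mask = x_all.notna() & fac_all.reindex(x_all.index).notna()
            if age is not None:
                mask &= age.notna()
            n_used = int(mask.sum())
            if n_used < min_samples:
                n_skipped += 1
                continue
            x = x_all[mask].to_numpy()
            y = fac_all.reindex(x_all.index)[mask].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                n_skipped += 1
                continue
            age_adjusted = False
            bp, p_plain, F_plain = _ols_slope_test(y, x[:, None])
            beta_hat, p_use, F_use = bp[0], p_plain, F_plain
            if age is not None:
                a = age[mask].to_numpy()
                if np.ptp(a) > 0:
                    _, p_age, _ = _ols_slope_test(a, x[:, None])
                    if np.isfinite(p_age) and p_age < p_plain:
                        b2, p2, F2 = _ols_slope_test(y, np.column_stack([a, x]))
                        beta_hat, p_use, F_use = b2[1], p2, F2
                        age_adjusted = True
            rows.append((asv, factor, beta_hat, F_use, p_use, age_adjusted, n_used))
    if n_skipped:
        logger.info("associate: skipped %d ASV x factor pairs (too few samples "
                    "or zero variance)", n_skipped)
    table = pd.DataFrame(rows, columns=["asv", "factor", "beta", "F", "p",
                                        "age_adjusted", "n_used"])
    if len(table):
        table["q"], _ = bh_fdr(table["p"].to_numpy(), fdr)
    else:
        table["q"] = []
    table = table[["asv", "factor", "beta", "F", "p", "q", "age_adjusted", "n_used"]]
    return AssociationResult(table=table, fdr=fdr)


# ---------------------------------------------------------------------------
# diet PCA


@dataclass
class DietPCA:
    loadings: pd.DataFrame             # food groups x axes
    scores: pd.DataFrame               # samples x axes
    variance_explained: np.ndarray


def diet_pca(food_groups: pd.DataFrame, n_axes: int | None = None) -> DietPCA:
    """PCA of standardized food-group intakes.

    Columns are z-scored, constant columns dropped with a warning.  Each
    axis is oriented so its largest-magnitude loading is positive.
    """
    X = food_groups.astype(float)
    sd = X.std(ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        logger.warning("diet_pca: dropping constant columns %s", list(constant))
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (X - X.mean()) / sd
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = s ** 2 / (len(Z) - 1)
    var_explained = var / var.sum()
    k = Vt.shape[0] if n_axes is None else min(n_axes, Vt.shape[0])
    loadings = Vt[:k].T.copy()
    scores = (U[:, :k] * s[:k]).copy()
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    axes = [f"PC{i+1}" for i in range(k)]
    return DietPCA(
        loadings=pd.DataFrame(loadings, index=X.columns, columns=axes),
        scores=pd.DataFrame(scores, index=X.index, columns=axes),
        variance_explained=var_explained[:k],
    )


# ---------------------------------------------------------------------------
# age correlations


def age_diversity_correlation(richness: pd.Series, age: pd.Series,
                              sex: pd.Series, min_stratum: int = 10) -> pd.DataFrame:
    """Spearman correlation of alpha diversity with age within each sex
    stratum, plus the pooled estimate."""
    rows = []
    strata = [("all", richness.index)]
    strata += [(s, sex.index[sex == s]) for s in sorted(sex.dropna().unique())]
    for name, idx in strata:
        idx = richness.index.intersection(idx)
        if len(idx) < min_stratum:
            continue
        r = richness.loc[idx].astype(float)
        a = age.loc[idx].astype(float)
        if r.nunique() < 2 or a.nunique() < 2:
            raise ValueError(f"constant input in stratum {name!r}")
        rho, p = stats.spearmanr(a, r)
        rows.append((name, len(idx), float(rho), float(p)))
    return pd.DataFrame(rows, columns=["stratum", "n", "rho", "p"])


def age_abundance_correlation(counts: pd.DataFrame, age: pd.Series,
                              fdr: float = 0.2,
                              zero_policy: str = "pseudocount") -> pd.DataFrame:
    """Per-ASV Spearman correlation of log abundance with age, BH at
    ``fdr``.  Returns every tested ASV with rho, p, q and a reject flag."""
    logab = log_abundance(counts, zero_policy)
    age = age.loc[counts.index].astype(float)
    rows = []
    for asv in counts.columns:
        x = logab[asv]
        mask = x.notna() & age.notna()
        if mask.sum() < 10 or x[mask].nunique() < 2:
            continue
        rho, p = stats.spearmanr(age[mask], x[mask])
        rows.append((asv, int(mask.sum()), float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["asv", "n", "rho", "p"])
    if len(out):
        out["q"], out["significant"] = bh_fdr(out["p"].to_numpy(), fdr)
    else:
        out["q"], out["significant"] = [], []
    return out
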