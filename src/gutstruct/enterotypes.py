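"""Enterotype detection and cross-cohort comparison.

Enterotypes are fit by embedding the weighted-UniFrac distance matrix
with PCoA and clustering the leading coordinates with a Gaussian mixture
model; each cluster is labeled by the genus with the highest mean
relative abundance among its samples (e.g. "Bacteroides" / "Prevotella").
External cohorts are labeled by nearest-neighbor transfer on cross
UniFrac distances.  Cohorts are compared three ways: a Yates-corrected
2x2 chi-squared test on enterotype ratios, PERMANOVA on the pooled
distance matrix, and a Mann-Whitney test on average within-enterotype
distances to the reference cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .community import Ordination, pcoa, relative_abundance

logger = logging.getLogger("gutstruct")


@dataclass
class EnterotypeModel:
    ordination: Ordination
    labels: pd.Series                # per reference sample, 0..K-1
    genus_labels: dict               # cluster index -> dominant genus name
    K: int
    mixture: GaussianMixture
    bic_by_k: dict | None = None


def fit_enterotypes(d: pd.DataFrame, counts: pd.DataFrame, tax: pd.DataFrame,
                    K: int = 2, n_axes: int = 3, seed: int = 0,
                    scan_k: bool = False) -> EnterotypeModel:
    """Cluster samples into K enterotypes on the PCoA embedding of ``d``.

    The mixture is fit on the leading ``n_axes`` principal coordinates
    (default 3: with full covariances, adding many low-inertia axes lets
    a component chase noise directions and degrades the clustering).
    A singular fit is retried with a stronger covariance regularizer.
    With ``scan_k`` a BIC profile over K in 2..6 is recorded for
    inspection; labeling always uses ``K``.
    """
    if K > d.shape[0]:
        raise ValueError("K exceeds the number of samples")
    ord_ = pcoa(d)
    n_axes = min(n_axes, ord_.coordinates.shape[1])
    x = ord_.coordinates.iloc[:, :n_axes].to_numpy()
    try:
        gmm = GaussianMixture(n_components=K, covariance_type="full",
                              n_init=5, random_state=seed).fit(x)
    except ValueError:
        logger.warning("fit_enterotypes: singular component, refitting with reg_covar=1e-4")
        gmm = GaussianMixture(n_components=K, covariance_type="full",
                              n_init=5, reg_covar=1e-4, random_state=seed).fit(x)
    labels = pd.Series(gmm.predict(x), index=d.index, name="enterotype")

    genus_ab = relative_abundance(counts, tax, level="genus")
    genus_labels: dict[int, str] = {}
    for k in range(K):
        members = labels.index[labels == k]
        mean_ab = genus_ab.loc[members].mean(axis=0).drop("Unassigned", errors="ignore")
        # distinct labels per cluster: take the top genus not already used
        for genus in mean_ab.sort_values(ascending=False).index:
            if genus not in genus_labels.values():
                genus_labels[k] = genus
                break
    bic = None
    if scan_k:
        bic = {k: GaussianMixture(n_components=k, covariance_type="full",
                                  n_init=3, random_state=seed).fit(x).bic(x)
               for k in range(2, 7)}
    return EnterotypeModel(ordination=ord_, labels=labels,
                           genus_labels=genus_labels, K=K, mixture=gmm,
                           bic_by_k=bic)


def assign_enterotype_nn(ref_labels: pd.Series, d_cross: pd.DataFrame) -> pd.Series:
    """Label each query sample with the enterotype of its nearest
    reference sample (rows of ``d_cross`` are queries, columns reference
    samples).  Ties go to the smallest reference column index."""
    if d_cross.isna().any().any():
        raise ValueError("d_cross contains missing distances")
    ref_labels = ref_labels.reindex(d_cross.columns)
    if ref_labels.isna().any():
        raise KeyError("reference labels missing for some d_cross columns")
    nearest = d_cross.to_numpy().argmin(axis=1)  # argmin takes first minimum
    return pd.Series(ref_labels.to_numpy()[nearest], index=d_cross.index,
                     name="enterotype")


def compare_et_proportions(ref_counts: tuple, other_counts: tuple):
    """Yates-corrected chi-squared test on a 2x2 enterotype table.

    ``ref_counts`` and ``other_counts`` are (n_first_ET, n_second_ET)
    pairs.  Returns (statistic, p).  A zero margin leaves the test
    undefined and raises.
    """
    table = np.array([ref_counts, other_counts], float)
    if table.min() < 0 or table.sum(axis=1).min() == 0:
        raise ValueError("both cohorts must be nonempty with nonnegative counts")
    if table.sum(axis=0).min() == 0:
        raise ValueError("a zero enterotype margin leaves the test undefined")
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# PERMANOVA


def _pseudo_f(d2: np.ndarray, groups: np.ndarray, group_ids: np.ndarray) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    g = len(group_ids)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for k in group_ids:
        idx = np.flatnonzero(groups == k)
        n_k = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(n_k, 1)].sum() / n_k
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(d: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0):
    """Permutational MANOVA on a distance matrix.

    Returns (pseudo-F, p) with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm),
    so p is never 0.  Requires at least two nonempty groups and nonzero
    within-group variation.
    """
    arr = d.to_numpy(float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    groups = np.asarray(pd.Categorical(np.asarray(groups)).codes)
    ids = np.unique(groups)
    if len(ids) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if not arr[np.triu_indices(arr.shape[0], 1)].any():
        raise ValueError("all distances are zero; pseudo-F undefined")
    d2 = arr ** 2
    f_obs = _pseudo_f(d2, groups, ids)
    rng = np.random.default_rng(seed)
    count = 0
    perm = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _pseudo_f(d2, perm, ids) >= f_obs:
            count += 1
    return float(f_obs), (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# average-distance comparison


def avg_distance_test(d_cross: pd.DataFrame, d_ref: pd.DataFrame,
                      ref_labels: pd.Series, query_labels: pd.Series,
                      target_et):
    """Compare foreign vs reference average within-enterotype distances.

    For each foreign sample of ``target_et``: its mean distance to all
    reference samples of that enterotype.  For each reference sample of
    ``target_et``: its mean distance to the *other* reference samples of
    the enterotype (self excluded).  The two sets of averages are
    compared with a two-sided Mann-Whitney U test (exact for <= 20 per
    side, normal approximation with tie correction otherwise).

    Returns (U, p, foreign_averages, reference_averages).
    """
    ref_members = ref_labels.index[ref_labels == target_et]
    query_members = query_labels.index[query_labels == target_et]
    if len(ref_members) < 2 or len(query_members) < 1:
        raise ValueError("need >=2 reference and >=1 query samples in the target enterotype")
    foreign_avg = d_cross.loc[query_members, ref_members].mean(axis=1)
    sub = d_ref.loc[ref_members, ref_members].to_numpy(float)
    m = len(ref_members)
    ref_avg = pd.Series(sub.sum(axis=1) / (m - 1), index=ref_members)
    if len(foreign_avg) < 2 or len(ref_avg) < 2:
        raise ValueError("need >=2 averages on each side")
    method = "exact" if max(len(foreign_avg), len(ref_avg)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(foreign_avg, ref_avg, alternative="two-sided",
                             method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # every pooled value identical: no evidence of a shift
        p = 1.0
    return float(res.statistic), p, foreign_avg, ref_avg
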