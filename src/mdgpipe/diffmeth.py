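"""Per-CpG differential methylation, bootstrap DM counting, sample clustering.

A CpG is differentially methylated between two phenotypes when the absolute
group mean beta difference reaches ``mean_diff_threshold`` (default 0.15)
and the two-sided Wilcoxon rank-sum p-value is below ``p_threshold``
(default 0.05, uncorrected).  With the beta band on (default), the call
additionally requires the tumor-group mean beta of the CpG to leave the
0.4-0.6 band: above 0.6 for hypermethylated, below 0.4 for hypomethylated
calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 8  # exact Wilcoxon when both groups are at most this size


def _group_columns(samples: pd.DataFrame, matrix: pd.DataFrame, phenotype: str) -> list[str]:
    ids = samples.loc[samples["phenotype"] == phenotype, "sample_id"]
    return [s for s in ids if s in matrix.columns]


def rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Wilcoxon rank-sum p-values for matrices x, y.

    Exact null distribution (via scipy) when both group sizes are <= 8;
    otherwise a normal approximation with tie and continuity correction,
    vectorized across rows.
    """
    n1, n2 = x.shape[1], y.shape[1]
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        out = np.empty(x.shape[0])
        for i in range(x.shape[0]):
            if np.ptp(np.concatenate([x[i], y[i]])) == 0:
                out[i] = 1.0
                continue
            out[i] = stats.mannwhitneyu(x[i], y[i], alternative="two-sided",
                                        method="exact").pvalue
        return out

    combined = np.concatenate([x, y], axis=1)
    n = n1 + n2
    ranks = stats.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per row
    sorted_rows = np.sort(combined, axis=1)
    new_val = np.ones_like(sorted_rows, dtype=bool)
    new_val[:, 1:] = sorted_rows[:, 1:] != sorted_rows[:, :-1]
    tie_term = np.zeros(combined.shape[0])
    for i in range(combined.shape[0]):
        counts = np.diff(np.append(np.flatnonzero(new_val[i]), n))
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    constant = sigma_sq <= 0
    sigma = np.sqrt(np.where(constant, 1.0, sigma_sq))
    z = (np.abs(u1 - mu) - 0.5) / sigma  # continuity correction
    p = 2.0 * stats.norm.sf(np.maximum(z, 0.0))
    return np.where(constant, 1.0, np.minimum(p, 1.0))


def dm_test(beta: pd.DataFrame, samples: pd.DataFrame, baseline: str, target: str,
            mean_diff_threshold: float = 0.15, p_threshold: float = 0.05,
            apply_band: bool = True, beta_low: float = 0.4, beta_high: float = 0.6,
            adjust: bool = False) -> pd.DataFrame:
    """Per-CpG differential methylation of ``target`` vs ``baseline``.

    Returns ``cpg_id, mean_diff, pvalue, tumor_mean_beta, status`` where
    ``mean_diff`` is target mean beta minus baseline mean beta and
    ``tumor_mean_beta`` the target-group mean.  ``adjust=True`` applies BH
    to the p-values before thresholding (off by default: the thresholds act
    on raw p-values).
    """
    base_cols = _group_columns(samples, beta, baseline)
    targ_cols = _group_columns(samples, beta, target)
    if len(base_cols) < 2 or len(targ_cols) < 2:
        raise ValueError("need >=2 samples per group")
    xb = beta[base_cols].to_numpy(dtype=float)
    xt = beta[targ_cols].to_numpy(dtype=float)
    if np.isnan(xb).any() or np.isnan(xt).any():
        raise ValueError("beta matrix contains missing values; run clean_cpgs first")

    mean_diff = xt.mean(axis=1) - xb.mean(axis=1)
    tumor_mean = xt.mean(axis=1)
    pvalue = rank_sum_pvalues(xt, xb)
    p_eff = multipletests(pvalue, method="fdr_bh")[1] if adjust else pvalue

    sig = (np.abs(mean_diff) >= mean_diff_threshold) & (p_eff < p_threshold)
    hyper = sig & (mean_diff > 0)
    hypo = sig & (mean_diff < 0)
    if apply_band:
        hyper &= tumor_mean > beta_high
        hypo &= tumor_mean < beta_low
    status = np.full(beta.shape[0], "none", dtype=object)
    status[hyper] = "hyper"
    status[hypo] = "hypo"

    return pd.DataFrame({
        "cpg_id": beta.index,
        "mean_diff": mean_diff,
        "pvalue": pvalue,
        "tumor_mean_beta": tumor_mean,
        "status": status,
    }).reset_index(drop=True)


def bootstrap_dm_counts(beta: pd.DataFrame, samples: pd.DataFrame,
                        contrasts: list[tuple[str, str]], n_boot: int = 1000,
                        group_size: int | None = None, seed: int = 0,
                        interval: tuple[float, float] = (2.5, 97.5),
                        **dm_kwargs) -> pd.DataFrame:
    """Bootstrap hyper/hypo DM-CpG counts with balanced resampled groups.

    Each replicate draws ``group_size`` samples per phenotype (default: the
    smallest group size across all phenotypes used, mirroring down-scaling
    to the smallest group), without replacement when the group is larger
    than ``group_size`` and with replacement otherwise, then counts
    hyper/hypo calls from :func:`dm_test` per contrast.  Returns one row per
    contrast and class with the mean and percentile interval across
    replicates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    phenos = sorted({p for pair in contrasts for p in pair})
    cols = {p: _group_columns(samples, beta, p) for p in phenos}
    for p in phenos:
        if not cols[p]:
            raise ValueError(f"no samples for phenotype {p}")
    if group_size is None:
        group_size = min(len(c) for c in cols.values())

    records: dict[tuple[str, str, str], list[int]] = {}
    for _ in range(n_boot):
        chosen = {}
        for p in phenos:
            pool = cols[p]
            replace = len(pool) < group_size
            idx = rng.choice(len(pool), size=group_size, replace=replace)
            chosen[p] = [pool[i] for i in idx]
        for baseline, target in contrasts:
            sub_ids = chosen[baseline] + chosen[target]
            sub_samples = pd.DataFrame({
                "sample_id": [f"b{i}" for i in range(len(sub_ids))],
                "phenotype": [baseline] * group_size + [target] * group_size,
            })
            sub_beta = beta[sub_ids].copy()
            sub_beta.columns = sub_samples["sample_id"]
            res = dm_test(sub_beta, sub_samples, baseline, target, **dm_kwargs)
            for cls in ("hyper", "hypo"):
                records.setdefault((baseline, target, cls), []).append(
                    int((res["status"] == cls).sum()))

    rows = []
    for (baseline, target, cls), vals in records.items():
        arr = np.asarray(vals)
        rows.append({
            "baseline": baseline, "target": target, "status": cls,
            "mean_count": arr.mean(),
            "lo": np.percentile(arr, interval[0]),
            "hi": np.percentile(arr, interval[1]),
            "n_boot": n_boot,
        })
    return pd.DataFrame(rows)


def cluster_samples(beta: pd.DataFrame, samples: pd.DataFrame, n_clusters: int = 2,
                    reference: str = "NT"):
    """Hierarchical clustering of samples on their beta profiles.

    Euclidean distance on beta columns, average linkage, cut into
    ``n_clusters`` flat clusters.  Returns ``(labels, purity)`` where purity
    is the fraction of reference (NT) samples falling in the cluster that
    holds the majority of them.
    """
    cols = [s for s in samples["sample_id"] if s in beta.columns]
    if len(cols) < n_clusters:
        raise ValueError("fewer samples than clusters requested")
    data = beta[cols].to_numpy(dtype=float).T
    Z = linkage(data, method="average", metric="euclidean")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = pd.Series(flat, index=cols, name="cluster")
    pheno = samples.set_index("sample_id").loc[cols, "phenotype"]
    ref_mask = pheno == reference
    if not ref_mask.any():
        return labels, np.nan
    ref_clusters = labels[ref_mask.to_numpy()]
    majority = ref_clusters.value_counts().idxmax()
    purity = float((ref_clusters == majority).mean())
    return labels, purity
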