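"""Two-group negative-binomial differential expression.

Normalization uses median-of-ratios size factors; testing is a Wald test on
the difference of group log-means with a method-of-moments negative-binomial
dispersion, followed by Benjamini-Hochberg correction.  A gene is called
``up`` when LogFC > lfc_threshold and FDR < fdr_threshold (strict
inequalities), ``down`` for the mirrored rule, ``none`` otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median of count / geometric-mean-across-samples.  A single-sample
    matrix gets factor 1.
    """
    vals = counts.to_numpy(dtype=float)
    if vals.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    all_nonzero = (vals > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene with nonzero counts in all samples")
    sub = vals[all_nonzero]
    log_geo_mean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def de_test(counts: pd.DataFrame, samples: pd.DataFrame, baseline: str, target: str,
            lfc_threshold: float = 2.0, fdr_threshold: float = 0.05,
            pseudocount: float = 0.5) -> pd.DataFrame:
    """Differential expression of ``target`` phenotype over ``baseline``.

    Returns one row per gene: ``gene_id, log2fc, pvalue, fdr, status``.
    Genes with all-zero counts in both groups are excluded from testing and
    reported with status ``none`` and missing statistics.
    """
    groups = samples.set_index("sample_id")["phenotype"]
    base_ids = groups.index[groups == baseline]
    targ_ids = groups.index[groups == target]
    base_ids = [s for s in base_ids if s in counts.columns]
    targ_ids = [s for s in targ_ids if s in counts.columns]
    if len(base_ids) < 2 or len(targ_ids) < 2:
        raise ValueError("need >=2 samples per group")

    sub = counts[[*base_ids, *targ_ids]]
    factors = size_factors(sub)
    norm = (sub / factors).to_numpy(dtype=float)
    nb = len(base_ids)
    xb, xt = norm[:, :nb], norm[:, nb:]
    nt = xt.shape[1]

    mb = xb.mean(axis=1)
    mt = xt.mean(axis=1)
    log2fc = np.log2((mt + pseudocount) / (mb + pseudocount))

    # method-of-moments NB dispersion pooled across the two groups
    vb = xb.var(axis=1, ddof=1)
    vt = xt.var(axis=1, ddof=1)
    pooled_var = ((nb - 1) * vb + (nt - 1) * vt) / (nb + nt - 2)
    pooled_mean = (nb * mb + nt * mt) / (nb + nt)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mean) / pooled_mean**2
    disp = np.where(np.isfinite(disp), disp, DISPERSION_FLOOR)
    disp = np.maximum(disp, DISPERSION_FLOOR)

    # Wald test on log2(mean_t) - log2(mean_b) by the delta method:
    # Var(log2 m) ~= (m + a m^2) / (n m^2 ln(2)^2), mean shifted by pseudocount
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = (mb + disp * mb**2) / (nb * (mb + pseudocount) ** 2 * ln2sq)
        var_t = (mt + disp * mt**2) / (nt * (mt + pseudocount) ** 2 * ln2sq)
        se = np.sqrt(var_b + var_t)
        z = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    testable = (xb.sum(axis=1) + xt.sum(axis=1)) > 0
    pvalue = np.where(testable, pvalue, np.nan)
    fdr = np.full_like(pvalue, np.nan)
    if testable.any():
        fdr[testable] = multipletests(pvalue[testable], method="fdr_bh")[1]

    status = np.full(counts.shape[0], "none", dtype=object)
    with np.errstate(invalid="ignore"):
        up = testable & (log2fc > lfc_threshold) & (fdr < fdr_threshold)
        down = testable & (log2fc < -lfc_threshold) & (fdr < fdr_threshold)
    status[up] = "up"
    status[down] = "down"

    return pd.DataFrame({
        "gene_id": counts.index,
        "log2fc": np.where(testable, log2fc, np.nan),
        "pvalue": pvalue,
        "fdr": fdr,
        "status": status,
    }).reset_index(drop=True)
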