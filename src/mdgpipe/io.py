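"""Tabular I/O and cohort preprocessing.

All matrices travel as :class:`pandas.DataFrame` with feature ids (genes or
CpGs) on the index and sample ids on the columns.  Files are plain
tab-separated text with a header row; the CpG map is a BED-like TSV with
0-based positions; gene sets use the standard GMT layout.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PHENOTYPES = ("NT", "I", "II", "III", "IV")
TUMOR_STAGES = ("I", "II", "III", "IV")

# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate feature ids in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = read_matrix(path)
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    return counts.astype(np.int64)


def read_beta(path: str | Path) -> pd.DataFrame:
    beta = read_matrix(path).astype(float)
    vals = beta.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError("beta values outside [0, 1]")
    return beta


def read_cpg_map(path: str | Path) -> pd.DataFrame:
    """BED-like CpG->gene map: cpg_id, chrom, pos (0-based), gene_id, region.

    Each CpG keeps only its first occurrence (first-occurrence rule).
    """
    cmap = pd.read_csv(path, sep="\t")
    required = {"cpg_id", "chrom", "pos", "gene_id", "region"}
    missing = required - set(cmap.columns)
    if missing:
        raise ValueError(f"cpg map missing columns: {sorted(missing)}")
    return cmap.drop_duplicates(subset="cpg_id", keep="first").reset_index(drop=True)


def write_cpg_map(cmap: pd.DataFrame, path: str | Path) -> None:
    cmap.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    if "sample_id" not in samples.columns or "phenotype" not in samples.columns:
        raise ValueError("sample table needs sample_id and phenotype columns")
    bad = set(samples["phenotype"].dropna()) - set(PHENOTYPES)
    if bad:
        raise ValueError(f"unknown phenotypes: {sorted(bad)}")
    return samples


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene role catalog TSV: gene_id, role in {oncogene, tumor_suppressor, both, none}."""
    ann = pd.read_csv(path, sep="\t")
    if "gene_id" not in ann.columns:
        raise ValueError("annotation needs a gene_id column")
    if "role" not in ann.columns:
        ann["role"] = "none"
    ann["role"] = ann["role"].fillna("none")
    return ann


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line, name TAB description TAB members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# preprocessing


def beta_from_intensities(M, U):
    """Methylation level beta = M / (M + U) from methylated/unmethylated intensities.

    Works element-wise on arrays; positions with M + U == 0 are returned as NaN
    (undefined, to be treated as missing).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("intensities must be nonnegative")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / np.where(total > 0, total, 1.0), np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def filter_genes(counts: pd.DataFrame, annotation: pd.DataFrame | None = None,
                 max_zero_fraction: float = 0.5, min_mean: float = 10.0) -> pd.DataFrame:
    """Apply the three gene filters, in order.

    1. drop genes absent from the annotation (if an annotation is given);
    2. drop genes with zeros in more than ``max_zero_fraction`` of samples
       (strictly more);
    3. drop genes with mean count strictly below ``min_mean`` (a mean of
       exactly ``min_mean`` is retained).

    Gene order of survivors is preserved.  Idempotent.
    """
    out = counts
    if annotation is not None:
        annotated = set(annotation["gene_id"])
        out = out.loc[[g in annotated for g in out.index]]
    vals = out.to_numpy()
    if vals.size:
        zero_frac = (vals == 0).mean(axis=1)
        out = out.loc[zero_frac <= max_zero_fraction]
        vals = out.to_numpy()
    if vals.size:
        out = out.loc[vals.mean(axis=1) >= min_mean]
    if out.shape[0] == 0:
        warnings.warn("no genes survived filtering", stacklevel=2)
    return out


def clean_cpgs(beta: pd.DataFrame) -> pd.DataFrame:
    """Drop every CpG row with at least one missing beta value (no imputation)."""
    out = beta.dropna(axis=0, how="any")
    if out.shape[0] == 0 and beta.shape[0] > 0:
        warnings.warn("all CpG rows contained missing values", stacklevel=2)
    return out


def within_bin_quantile_normalize(counts: pd.DataFrame, covariate: pd.Series,
                                  n_bins: int = 10) -> pd.DataFrame:
    """Full-quantile normalization of counts within equal-frequency covariate bins.

    Genes are split into ``n_bins`` equal-frequency bins of the per-gene
    covariate (e.g. GC content or gene length).  Within each sample, the
    counts of each bin are quantile-mapped onto the pooled across-bin
    reference distribution of that sample, removing any systematic
    count-covariate trend.  Output is rounded half-even back to integers.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cov = covariate.reindex(counts.index)
    if cov.isna().any():
        raise ValueError("covariate missing for some genes")
    n_genes = counts.shape[0]
    # equal-frequency binning on covariate values; ties share a bin, so a
    # constant covariate collapses to one bin and the map is the identity
    if cov.nunique() == 1:
        bins = np.zeros(n_genes, dtype=np.int64)
    else:
        bins = pd.qcut(cov.to_numpy(), q=n_bins, labels=False, duplicates="drop")
        bins = np.asarray(bins, dtype=np.int64)
    # merge undersized bins into a neighbor
    ids, sizes = np.unique(bins, return_counts=True)
    if (sizes < 2).any() and len(ids) > 1:
        warnings.warn("merging covariate bins with <2 genes", stacklevel=2)
        while True:
            ids, sizes = np.unique(bins, return_counts=True)
            small = ids[sizes < 2]
            if small.size == 0 or len(ids) == 1:
                break
            b = small[0]
            neighbor = ids[ids < b].max() if (ids < b).any() else ids[ids > b].min()
            bins[bins == b] = neighbor

    from scipy.stats import rankdata

    out = counts.to_numpy().astype(float).copy()
    for s in range(out.shape[1]):
        col = out[:, s]
        pooled = np.sort(col)  # across-bin reference for this sample
        new = col.copy()
        for b in np.unique(bins):
            idx = np.flatnonzero(bins == b)
            sub = col[idx]
            m = len(sub)
            if m == 1:
                q = np.array([0.5])
            else:
                q = (rankdata(sub, method="average") - 1.0) / (m - 1.0)
            new[idx] = np.quantile(pooled, q)
        out[:, s] = new
    rounded = np.rint(out).astype(np.int64)  # round-half-even keeps counts integral
    return pd.DataFrame(rounded, index=counts.index, columns=counts.columns)
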