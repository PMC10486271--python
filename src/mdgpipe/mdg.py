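"""Methylation-driven gene (MDG) calling and stage intersection.

A gene is an MDG candidate for a contrast when at least one of its promoter
CpGs is differentially methylated *and* the gene itself is differentially
expressed in the same contrast.  Candidates are then classified by the
anticorrelation rule on the tumor-group median of all promoter CpG beta
values:

* ``hypo``  — median < 0.4 and expression status ``up``;
* ``hyper`` — median > 0.6 and expression status ``down``;

candidates failing both class rules are dropped.  Strict inequalities: a
median exactly at a threshold is never classified.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

BETA_LOW = 0.4
BETA_HIGH = 0.6


def promoter_cpgs(cpg_map: pd.DataFrame, gene: str | None = None) -> pd.DataFrame:
    prom = cpg_map[cpg_map["region"] == "promoter"]
    if gene is not None:
        prom = prom[prom["gene_id"] == gene]
    return prom


def promoter_median(beta: pd.DataFrame, cpg_map: pd.DataFrame, gene: str,
                    sample_ids) -> float:
    """Median beta over all (promoter CpG, sample) cells of one gene."""
    cpgs = promoter_cpgs(cpg_map, gene)["cpg_id"]
    cpgs = [c for c in cpgs if c in beta.index]
    if not cpgs:
        raise KeyError(f"gene {gene!r} has no promoter CpGs in the beta matrix")
    cols = [s for s in sample_ids if s in beta.columns]
    return float(np.median(beta.loc[cpgs, cols].to_numpy(dtype=float)))


def call_mdgs(dm: pd.DataFrame, de: pd.DataFrame, beta: pd.DataFrame,
              cpg_map: pd.DataFrame, samples: pd.DataFrame,
              baseline: str, target: str,
              beta_low: float = BETA_LOW, beta_high: float = BETA_HIGH,
              require_anticorrelation: bool = True) -> pd.DataFrame:
    """Call MDGs for one contrast from its DM and DE tables.

    ``require_anticorrelation=False`` keeps every candidate (debug mode);
    candidates that fail both class rules then carry ``methyl_class='none'``.
    Returns one row per called gene with tumor- and NT-side medians, CpG
    counts, expression status, class and contrast label.
    """
    prom = promoter_cpgs(cpg_map)
    prom = prom[prom["cpg_id"].isin(beta.index)]
    dm_status = dm.set_index("cpg_id")["status"]
    de_idx = de.set_index("gene_id")

    base_cols = [s for s in samples.loc[samples["phenotype"] == baseline, "sample_id"]
                 if s in beta.columns]
    targ_cols = [s for s in samples.loc[samples["phenotype"] == target, "sample_id"]
                 if s in beta.columns]

    targ_beta = beta[targ_cols]
    base_beta = beta[base_cols]

    rows = []
    for gene, grp in prom.groupby("gene_id", sort=True):
        if gene not in de_idx.index:
            continue
        cpgs = grp["cpg_id"].tolist()
        statuses = dm_status.reindex(cpgs).fillna("none")
        n_dm = int((statuses != "none").sum())
        expr_status = de_idx.at[gene, "status"]
        if n_dm < 1 or expr_status == "none":
            continue
        med_t = float(np.median(targ_beta.loc[cpgs].to_numpy(dtype=float)))
        med_b = float(np.median(base_beta.loc[cpgs].to_numpy(dtype=float)))
        if med_t < beta_low and expr_status == "up":
            methyl_class = "hypo"
        elif med_t > beta_high and expr_status == "down":
            methyl_class = "hyper"
        else:
            if require_anticorrelation:
                continue
            methyl_class = "none"
        rows.append({
            "gene_id": gene,
            "contrast": f"{baseline}:{target}",
            "median_beta_tumor": med_t,
            "median_beta_nt": med_b,
            "n_promoter_cpgs": len(cpgs),
            "n_dm_cpgs": n_dm,
            "expr_status": expr_status,
            "methyl_class": methyl_class,
        })
    cols = ["gene_id", "contrast", "median_beta_tumor", "median_beta_nt",
            "n_promoter_cpgs", "n_dm_cpgs", "expr_status", "methyl_class"]
    return pd.DataFrame(rows, columns=cols)


def stage_sets(mdg_tables: dict[str, pd.DataFrame]) -> dict:
    """Shared and exclusive MDG id sets per methylation class across contrasts.

    ``mdg_tables`` maps contrast label -> MDG table.  Returns, per class,
    the intersection across all contrasts (``shared``), each contrast's
    exclusive set, and per-contrast sets for Venn cells.
    """
    if len(mdg_tables) < 2:
        raise ValueError("need >=2 contrasts for stage sets")
    out: dict[str, dict] = {}
    for cls in ("hypo", "hyper"):
        per_contrast = {
            label: set(tab.loc[tab["methyl_class"] == cls, "gene_id"])
            for label, tab in mdg_tables.items()
        }
        shared = set.intersection(*per_contrast.values()) if per_contrast else set()
        exclusive = {}
        for label, genes in per_contrast.items():
            others = set.union(*(g for lb, g in per_contrast.items() if lb != label)) \
                if len(per_contrast) > 1 else set()
            exclusive[label] = genes - others
        out[cls] = {"per_contrast": per_contrast, "shared": shared,
                    "exclusive": exclusive}
    return out


def venn_cells(per_contrast: dict[str, set]) -> dict[frozenset, set]:
    """All 2^k - 1 Venn cells of k contrast sets (exact membership patterns)."""
    labels = list(per_contrast)
    cells: dict[frozenset, set] = {}
    for r in range(1, len(labels) + 1):
        for inside in combinations(labels, r):
            inside_s = set(inside)
            cell = set.intersection(*(per_contrast[lb] for lb in inside))
            for lb in labels:
                if lb not in inside_s:
                    cell = cell - per_contrast[lb]
            cells[frozenset(inside)] = cell
    return cells


def build_role_catalog(oncogenes, tumor_suppressors) -> pd.DataFrame:
    """Merge oncogene and tumor-suppressor lists; genes in both get role 'both'."""
    og, tsg = set(oncogenes), set(tumor_suppressors)
    rows = [{"gene_id": g,
             "role": "both" if g in og and g in tsg
             else "oncogene" if g in og else "tumor_suppressor"}
            for g in sorted(og | tsg)]
    return pd.DataFrame(rows, columns=["gene_id", "role"])


def annotate_roles(genes, catalog: pd.DataFrame) -> pd.DataFrame:
    """Label genes with oncogene / tumor_suppressor / both / none roles."""
    roles = catalog.set_index("gene_id")["role"] if "role" in catalog.columns \
        else pd.Series(dtype=object)
    rows = [{"gene_id": g, "role": roles.get(g, "none")} for g in sorted(genes)]
    return pd.DataFrame(rows, columns=["gene_id", "role"])


def role_bearing(annotated: pd.DataFrame) -> pd.DataFrame:
    return annotated[annotated["role"] != "none"].reset_index(drop=True)
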