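"""Mutual-information co-expression networks over MDG-gene pairs.

MI is estimated by rank-based equal-frequency discretization of each
expression profile into ``B = max(2, floor(n^(1/3)))`` bins followed by the
plug-in estimate sum p(a,b) ln[p(a,b) / (p(a) p(b))] with a Miller-Madow
bias correction, clamped at zero.  The rank-based binning makes the
estimate invariant under strictly monotone transforms of either input
(e.g. log-scaling normalized counts changes nothing).

Networks are undirected edge lists ``(gene_a, gene_b, mi)`` with
``gene_a < gene_b`` lexicographically, no self-edges and no duplicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

EDGE_COLUMNS = ["gene_a", "gene_b", "mi"]


def n_bins(n: int) -> int:
    return max(2, int(np.floor(n ** (1.0 / 3.0))))


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin labels from average ranks; constant input -> one bin."""
    n = len(x)
    r = rankdata(x, method="average") - 1.0
    return np.minimum((r * bins / n).astype(np.int64), bins - 1)


def mutual_information(x, y, bins: int | None = None) -> float:
    """Bias-corrected plug-in MI (nats) between two samples of equal length."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 8:
        raise ValueError("need n >= 8 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    B = bins or n_bins(n)
    bx = _discretize(x, B)
    by = _discretize(y, B)
    joint = np.bincount(bx * B + by, minlength=B * B).astype(float) / n
    px = np.bincount(bx, minlength=B).astype(float) / n
    py = np.bincount(by, minlength=B).astype(float) / n
    nz = joint > 0
    outer = (px[:, None] * py[None, :]).ravel()
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    # Miller-Madow: MI_mm = MI + [(m_x - 1) + (m_y - 1) - (m_xy - 1)] / (2n)
    mx = int(np.count_nonzero(px))
    my = int(np.count_nonzero(py))
    mxy = int(np.count_nonzero(joint))
    mi += ((mx - 1) + (my - 1) - (mxy - 1)) / (2.0 * n)
    return max(mi, 0.0)


def pair_count(n_mdg: int, n_all: int, n_overlap: int) -> int:
    """Number of MDG x gene pairs excluding self-pairs."""
    return n_mdg * n_all - n_overlap


def infer_network(expr: pd.DataFrame, mdg_set, all_genes=None,
                  phenotype: str | None = None, samples: pd.DataFrame | None = None,
                  bins: int | None = None) -> pd.DataFrame:
    """MI edge list for every (MDG, gene) pair within one phenotype.

    ``expr`` is a normalized gene x sample expression matrix; if ``samples``
    and ``phenotype`` are given, only that phenotype's samples are used.
    ``all_genes`` defaults to every gene in ``expr`` (set it to ``mdg_set``
    for an MDG-only network).  Returns a canonical edge list
    (``gene_a < gene_b``, deduplicated, no self-edges).
    """
    mdg_list = sorted(set(mdg_set) & set(expr.index))
    if not mdg_list:
        raise ValueError("empty MDG set (or none present in the matrix)")
    partners = sorted(set(all_genes) & set(expr.index)) if all_genes is not None \
        else list(expr.index)
    genes = sorted(set(partners) | set(mdg_list))
    if samples is not None and phenotype is not None:
        cols = [s for s in samples.loc[samples["phenotype"] == phenotype, "sample_id"]
                if s in expr.columns]
    else:
        cols = list(expr.columns)
    n = len(cols)
    if n < 8:
        raise ValueError("phenotype needs >= 8 samples for MI estimation")
    B = bins or n_bins(n)

    mat = expr.loc[genes, cols].to_numpy(dtype=float)
    labels = np.empty((len(genes), n), dtype=np.int64)
    constant = np.zeros(len(genes), dtype=bool)
    for i in range(len(genes)):
        if np.ptp(mat[i]) == 0:
            constant[i] = True
            labels[i] = 0
        else:
            labels[i] = _discretize(mat[i], B)
    onehot = np.zeros((len(genes), n, B))
    onehot[np.arange(len(genes))[:, None], np.arange(n)[None, :], labels] = 1.0
    marg = onehot.sum(axis=1) / n                    # genes x B
    m_bins = np.count_nonzero(marg, axis=1)          # occupied bins per gene

    gene_pos = {g: i for i, g in enumerate(genes)}
    seen: set[tuple[str, str]] = set()
    rows_a, rows_b, vals = [], [], []
    for mg in mdg_list:
        i = gene_pos[mg]
        # joint bin counts of this MDG against every gene: genes x B x B
        joint = np.einsum("sb,gsc->gbc", onehot[i], onehot) / n
        outer = marg[i][None, :, None] * marg[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(joint > 0, joint * np.log(joint / outer), 0.0)
        mi = term.sum(axis=(1, 2))
        mxy = np.count_nonzero(joint > 0, axis=(1, 2))
        mi += ((m_bins[i] - 1) + (m_bins - 1) - (mxy - 1)) / (2.0 * n)
        mi = np.maximum(mi, 0.0)
        mi[constant] = 0.0
        if constant[i]:
            mi[:] = 0.0
        for g in partners:
            j = gene_pos[g]
            if g == mg:
                continue
            a, b = (mg, g) if mg < g else (g, mg)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            rows_a.append(a)
            rows_b.append(b)
            vals.append(float(mi[j]))
    edges = pd.DataFrame({"gene_a": rows_a, "gene_b": rows_b, "mi": vals})
    if phenotype is not None:
        edges.insert(0, "phenotype", phenotype)
    return edges.sort_values(["gene_a", "gene_b"], ignore_index=True)


def top_k_edges(network: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k largest-MI edges; boundary ties break by lexicographic pair order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = network.sort_values(["mi", "gene_a", "gene_b"],
                                  ascending=[False, True, True], kind="mergesort")
    return ordered.head(k).reset_index(drop=True)


def first_neighbors(network: pd.DataFrame, seed_gene: str) -> pd.DataFrame:
    """Edges incident to ``seed_gene`` (empty edge list if the gene is absent)."""
    mask = (network["gene_a"] == seed_gene) | (network["gene_b"] == seed_gene)
    return network[mask].reset_index(drop=True)


def subnetwork_nodes(subnetwork: pd.DataFrame) -> set[str]:
    return set(subnetwork["gene_a"]) | set(subnetwork["gene_b"])


def neighbor_concordance(subnetwork: pd.DataFrame, de: pd.DataFrame,
                         seed_gene: str) -> float:
    """Fraction of first neighbors sharing the seed gene's DE status.

    Neighbors without a DE status (missing or 'none') are excluded from the
    denominator; with no scorable neighbor the result is NaN.
    """
    de_status = de.set_index("gene_id")["status"]
    if seed_gene not in de_status.index:
        raise KeyError(f"no DE status for seed gene {seed_gene!r}")
    seed_status = de_status[seed_gene]
    neighbors = subnetwork_nodes(subnetwork) - {seed_gene}
    scored = [g for g in neighbors
              if g in de_status.index and de_status[g] in ("up", "down")]
    if not scored:
        return float("nan")
    return float(np.mean([de_status[g] == seed_status for g in scored]))


def dpi_prune(network: pd.DataFrame, tolerance: float = 0.15) -> pd.DataFrame:
    """Data-processing-inequality pruning: drop the weakest edge of each
    triangle when it falls below ``(1 - tolerance)`` times the smaller of the
    other two.  Off by default in the pipeline."""
    mi_map = {(r.gene_a, r.gene_b): r.mi for r in network.itertuples()}
    adjacency: dict[str, set[str]] = {}
    for a, b in mi_map:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    def get(a, b):
        return mi_map.get((a, b) if a < b else (b, a))

    drop = set()
    for (a, b), w in mi_map.items():
        for c in adjacency[a] & adjacency[b]:
            w_ac, w_bc = get(a, c), get(b, c)
            if w < (1 - tolerance) * min(w_ac, w_bc):
                drop.add((a, b))
                break
    keep = [(a, b) not in drop for a, b in zip(network["gene_a"], network["gene_b"])]
    return network[keep].reset_index(drop=True)


def to_networkx(network: pd.DataFrame):
    """Edge list as a networkx Graph with MI edge weights."""
    import networkx as nx

    g = nx.Graph()
    for r in network.itertuples():
        g.add_edge(r.gene_a, r.gene_b, mi=r.mi)
    return g


def write_sif(network: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in network.itertuples():
            fh.write(f"{r.gene_a}\tmi\t{r.gene_b}\n")
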