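"""Seeded synthetic paired methylation/expression cohorts.

The generator emulates the structure of a staged tumor cohort: five
phenotype groups (normal tissue NT plus tumor stages I-IV) with unbalanced
sizes, a CpG x sample beta matrix with the bimodal hypo/hyper shape typical
of array methylation data, a gene x sample negative-binomial count matrix,
and right-censored survival.  A configurable number of *planted*
methylation-driven genes shift their promoter methylation and expression in
opposite directions between NT and tumor groups, giving every downstream
stage a known ground truth:

* planted **hypo** genes: promoter beta high in NT, low in tumor, expression
  up in tumor (hypomethylation releases repression);
* planted **hyper** genes: the mirror image (promoter gain of methylation,
  expression down).

Beta values are drawn from Beta distributions parameterized by mean and a
precision knob; counts from a negative binomial with log-normally
distributed gene means.  The seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio

DEFAULT_GROUP_SIZES: dict[str, int] = {"NT": 24, "I": 158, "II": 31, "III": 72, "IV": 57}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    ``beta_shift`` is the promoter beta displacement of planted genes between
    NT and tumor (0.45 by default, so planted tumor medians cross the 0.4/0.6
    classification thresholds); ``expr_log2fc`` is the planted expression
    log2 fold change (applied with sign + for hypo-planted, - for
    hyper-planted genes).
    """

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_genes: int = 1000
    cpgs_per_gene: int = 5
    n_hypo_planted: int = 50
    n_hyper_planted: int = 50
    beta_shift: float = 0.45
    expr_log2fc: float = 3.0
    nb_dispersion: float = 0.1
    baseline_beta_low: float = 0.2
    baseline_beta_high: float = 0.8
    beta_precision: float = 50.0
    mean_log_expression: float = 6.0
    sd_log_expression: float = 1.0
    planted_stages: Sequence[str] | None = None  # None = all tumor stages
    missing_rate: float = 0.0
    survival_link_gene: str | None = None
    survival_hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes is empty")
        for g, n in self.group_sizes.items():
            if g not in mio.PHENOTYPES:
                raise ValueError(f"unknown phenotype {g!r}")
            if n < 2:
                raise ValueError(f"group {g} has <2 samples; downstream tests undefined")
        for name in ("n_genes", "cpgs_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_hypo_planted + self.n_hyper_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        for mu in (self.baseline_beta_low, self.baseline_beta_high):
            if not 0 < mu < 1:
                raise ValueError("beta means must lie in (0,1)")
        if not 0 < self.baseline_beta_high - self.beta_shift < 1:
            raise ValueError("baseline_beta_high - beta_shift outside (0,1)")
        if not 0 < self.baseline_beta_low + self.beta_shift < 1:
            raise ValueError("baseline_beta_low + beta_shift outside (0,1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0,1)")


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, precision: float) -> np.ndarray:
    a = mean * precision
    b = (1.0 - mean) * precision
    return rng.beta(a, b)


def simulate_cohort(config: SimulationConfig):
    """Generate one cohort.

    Returns ``(beta, counts, cpg_map, samples, truth)``: the CpG x sample
    beta matrix, gene x sample integer count matrix, BED-like CpG->gene map
    (all CpGs labeled promoter), sample table with phenotype and survival
    columns, and the planted-gene truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids: list[str] = []
    phenotypes: list[str] = []
    for g in mio.PHENOTYPES:
        n = config.group_sizes.get(g, 0)
        for i in range(n):
            sample_ids.append(f"{g}_{i:03d}")
            phenotypes.append(g)
    n_samples = len(sample_ids)
    is_tumor = np.array([p != "NT" for p in phenotypes])
    planted_stages = set(config.planted_stages) if config.planted_stages is not None \
        else set(mio.TUMOR_STAGES)
    affected = np.array([p in planted_stages for p in phenotypes])

    # --- truth assignment
    planted_idx = rng.choice(config.n_genes,
                             size=config.n_hypo_planted + config.n_hyper_planted,
                             replace=False)
    hypo_idx = set(planted_idx[: config.n_hypo_planted].tolist())
    hyper_idx = set(planted_idx[config.n_hypo_planted:].tolist())
    planted_class = np.array(
        ["hypo" if i in hypo_idx else "hyper" if i in hyper_idx else "null"
         for i in range(config.n_genes)])
    direction = np.where(planted_class == "hypo", "up",
                         np.where(planted_class == "hyper", "down", "none"))
    truth = pd.DataFrame({"gene_id": genes, "planted_class": planted_class,
                          "planted_direction": direction})

    # --- methylation: per-CpG bimodal baseline mean, planted genes overridden
    n_cpgs = config.n_genes * config.cpgs_per_gene
    low_mode = rng.random(n_cpgs) < 0.5
    cpg_mean_nt = np.where(low_mode, config.baseline_beta_low, config.baseline_beta_high)
    cpg_gene = np.repeat(np.arange(config.n_genes), config.cpgs_per_gene)
    for i in range(config.n_genes):
        rows = slice(i * config.cpgs_per_gene, (i + 1) * config.cpgs_per_gene)
        if planted_class[i] == "hypo":
            cpg_mean_nt[rows] = config.baseline_beta_high
        elif planted_class[i] == "hyper":
            cpg_mean_nt[rows] = config.baseline_beta_low
    shift = np.zeros(n_cpgs)
    shift[np.isin(cpg_gene, list(hypo_idx))] = -config.beta_shift
    shift[np.isin(cpg_gene, list(hyper_idx))] = config.beta_shift

    mean_matrix = np.tile(cpg_mean_nt[:, None], (1, n_samples))
    mean_matrix[:, affected] = (cpg_mean_nt + shift)[:, None]
    beta_vals = _beta_draw(rng, mean_matrix, config.beta_precision)
    if config.missing_rate > 0:
        mask = rng.random(beta_vals.shape) < config.missing_rate
        beta_vals = np.where(mask, np.nan, beta_vals)

    cpg_ids = [f"cg{i:07d}" for i in range(n_cpgs)]
    beta = pd.DataFrame(beta_vals, index=pd.Index(cpg_ids, name="cpg_id"),
                        columns=sample_ids)
    cpg_map = pd.DataFrame({
        "cpg_id": cpg_ids,
        "chrom": ["chr1"] * n_cpgs,
        "pos": np.arange(n_cpgs) * 500,
        "gene_id": [genes[g] for g in cpg_gene],
        "region": ["promoter"] * n_cpgs,
    })

    # --- expression: NB counts, log-normal gene means, planted fold changes
    base_mean = np.exp(rng.normal(config.mean_log_expression,
                                  config.sd_log_expression, size=config.n_genes))
    fc = np.where(planted_class == "hypo", 2.0 ** config.expr_log2fc,
                  np.where(planted_class == "hyper", 2.0 ** -config.expr_log2fc, 1.0))
    mean_expr = np.tile(base_mean[:, None], (1, n_samples))
    mean_expr[:, affected] = (base_mean * fc)[:, None]
    r = 1.0 / config.nb_dispersion
    counts_vals = rng.negative_binomial(r, r / (r + mean_expr))
    counts = pd.DataFrame(counts_vals.astype(np.int64),
                          index=pd.Index(genes, name="gene_id"), columns=sample_ids)

    samples = pd.DataFrame({"sample_id": sample_ids, "phenotype": phenotypes})
    samples = simulate_survival(
        samples, counts,
        link_gene=config.survival_link_gene,
        hazard_ratio=config.survival_hazard_ratio,
        censor_rate=config.censor_rate,
        seed=int(rng.integers(2**31 - 1)),
        baseline_hazard=config.baseline_hazard,
    )
    return beta, counts, cpg_map, samples, truth


def simulate_survival(sample_table: pd.DataFrame, expr: pd.DataFrame,
                      link_gene: str | None, hazard_ratio: float,
                      censor_rate: float, seed: int,
                      baseline_hazard: float = 1.0 / 1000.0) -> pd.DataFrame:
    """Attach exponential event times with optional expression-linked hazard.

    Samples whose expression of ``link_gene`` is strictly above its median
    have their hazard multiplied by ``hazard_ratio``.  Each sample is then
    independently censored with probability ``censor_rate``; a censored
    sample's observation time is uniform on (0, event time).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    out = sample_table.copy()
    n = len(out)
    hazard = np.full(n, baseline_hazard)
    if link_gene is not None:
        if link_gene not in expr.index:
            raise KeyError(f"link gene {link_gene!r} not in expression matrix")
        vals = expr.loc[link_gene, out["sample_id"]].to_numpy(dtype=float)
        hazard = np.where(vals > np.median(vals), baseline_hazard * hazard_ratio,
                          baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censor_rate
    time = np.where(censored, rng.uniform(0, event_time), event_time)
    out["vital_status"] = np.where(censored, "alive", "dead")
    out["time"] = time
    out["event"] = (~censored).astype(int)
    return out


def write_fixtures(beta: pd.DataFrame, counts: pd.DataFrame, cpg_map: pd.DataFrame,
                   samples: pd.DataFrame, truth: pd.DataFrame,
                   directory: str | Path) -> dict[str, Path]:
    """Write the cohort as plain TSV/GMT files that round-trip through ``io``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": d / "beta.tsv",
        "counts": d / "counts.tsv",
        "cpg_map": d / "cpg_map.tsv",
        "samples": d / "samples.tsv",
        "truth": d / "truth.tsv",
        "sets": d / "sets.gmt",
    }
    mio.write_matrix(beta, paths["beta"])
    mio.write_matrix(counts, paths["counts"])
    mio.write_cpg_map(cpg_map, paths["cpg_map"])
    mio.write_samples(samples, paths["samples"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    planted = {
        "planted_hypo": truth.loc[truth["planted_class"] == "hypo", "gene_id"].tolist(),
        "planted_hyper": truth.loc[truth["planted_class"] == "hyper", "gene_id"].tolist(),
    }
    planted = {k: v for k, v in planted.items() if v}
    mio.write_gmt(planted, paths["sets"],
                  descriptions={k: "synthetic planted set" for k in planted})
    return paths


def simulate_block_cohort(n_block: int = 10, n_null: int = 200,
                          group_sizes: Mapping[str, int] | None = None,
                          block_sd: float = 1.0, log2fc: float = 3.0,
                          nb_dispersion: float = 0.05,
                          mean_log_expression: float = 6.0, seed: int = 0):
    """Counts with one co-expressed gene block (shared latent factor).

    Block genes share a per-sample latent log-scale factor ``z ~ N(0,
    block_sd)``, making them mutually correlated within every phenotype, and
    are additionally shifted by ``log2fc`` in tumor groups.  Null genes vary
    only through negative-binomial noise.  Returns ``(counts, samples,
    block_gene_ids)``; with a single phenotype group the sample table still
    round-trips through the io module.
    """
    group_sizes = dict(group_sizes or {"NT": 25, "I": 25})
    rng = np.random.default_rng(seed)
    sample_ids, phenotypes = [], []
    for g, n in group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{g}_{i:03d}")
            phenotypes.append(g)
    n_samples = len(sample_ids)
    is_tumor = np.array([p != "NT" for p in phenotypes])

    genes = [f"B{i:03d}" for i in range(n_block)] + [f"N{i:04d}" for i in range(n_null)]
    base = np.exp(rng.normal(mean_log_expression, 0.5, size=len(genes)))
    z = rng.normal(0.0, block_sd, size=n_samples)
    log_mean = np.tile(np.log(base)[:, None], (1, n_samples))
    log_mean[:n_block] += z[None, :]
    log_mean[:n_block, is_tumor] += np.log(2.0) * log2fc
    mean = np.exp(log_mean)
    r = 1.0 / nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    counts = pd.DataFrame(counts.astype(np.int64),
                          index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "phenotype": phenotypes})
    return counts, samples, genes[:n_block]


def config_from_dict(d: Mapping) -> SimulationConfig:
    return SimulationConfig(**dict(d))


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


__all__ = ["SimulationConfig", "simulate_cohort", "simulate_survival",
           "write_fixtures", "config_from_dict", "config_to_dict", "replace",
           "DEFAULT_GROUP_SIZES"]
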