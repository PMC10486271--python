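"""Configuration-driven orchestration of the full MDG analysis.

Stages, in order: preprocessing (gene/CpG filters, size-factor
normalization) -> per-contrast differential expression and methylation ->
MDG calling -> stage intersection sets -> role annotation -> per-phenotype
MI networks and first-neighbor concordance -> survival for role-bearing
MDGs -> over-representation analysis of the shared sets.  Every
intermediate table is written as TSV; a JSON manifest records the config,
seed, package version and a checksum per output so a rerun can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as mio
from . import diffexpr, diffmeth, enrichment, mdg, network, survival

log = logging.getLogger("mdgpipe")

DEFAULT_CONTRASTS = [("NT", s) for s in mio.TUMOR_STAGES]


@dataclass
class PipelineConfig:
    counts: str = "counts.tsv"
    beta: str = "beta.tsv"
    cpg_map: str = "cpg_map.tsv"
    samples: str = "samples.tsv"
    annotation: str | None = None      # gene role catalog TSV (optional)
    gmt: str | None = None             # gene sets for enrichment (optional)
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_CONTRASTS))
    sequential_contrasts: bool = False  # stage-vs-previous-stage scheme instead
    lfc: float = 2.0
    fdr: float = 0.05
    mean_diff: float = 0.15
    dm_p: float = 0.05
    beta_low: float = 0.4
    beta_high: float = 0.6
    enrich_alpha: float = 0.01
    top_k: list[int] = field(default_factory=lambda: [1000, 10000, 100000])
    bootstrap_n: int = 0               # 0 disables the bootstrap stage
    bootstrap_group_size: int | None = None
    dpi_tolerance: float | None = None  # None disables DPI pruning
    require_anticorrelation: bool = True
    survival_genes: list[str] = field(default_factory=list)  # extra KM genes
    seed: int = 0

    def validate(self) -> None:
        if not self.contrasts:
            raise ValueError("contrast list is empty")
        for th, lo, hi in (("fdr", 0, 1), ("dm_p", 0, 1), ("enrich_alpha", 0, 1),
                           ("beta_low", 0, 1), ("beta_high", 0, 1)):
            v = getattr(self, th)
            if not lo < v < hi:
                raise ValueError(f"{th}={v} outside ({lo},{hi})")
        if self.beta_low >= self.beta_high:
            raise ValueError("beta_low must be below beta_high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contrasts" in raw:
            raw["contrasts"] = [tuple(c.split(":")) if isinstance(c, str) else tuple(c)
                                for c in raw["contrasts"]]
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and return the result directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc_type is not None:
                    log.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, timings[name])
        return _Timer()

    try:
        with stage("load"):
            counts = mio.read_counts(config.counts)
            beta = mio.read_beta(config.beta)
            cpg_map = mio.read_cpg_map(config.cpg_map)
            samples = mio.read_samples(config.samples)
            samples = samples[samples["phenotype"].notna()].reset_index(drop=True)
            shared = [s for s in samples["sample_id"]
                      if s in counts.columns and s in beta.columns]
            if not shared:
                raise ValueError("no sample ids shared between counts and beta")
            samples = samples[samples["sample_id"].isin(shared)].reset_index(drop=True)
            counts = counts[shared]
            beta = beta[shared]
            catalog = mio.read_gene_annotation(config.annotation) \
                if config.annotation else None

        with stage("preprocess"):
            counts = mio.filter_genes(counts, annotation=catalog)
            beta = mio.clean_cpgs(beta)
            factors = diffexpr.size_factors(counts)
            norm = counts / factors
            _write(counts, out / "counts_filtered.tsv", index=True)
            _write(beta, out / "beta_clean.tsv", index=True)
            outputs["counts_filtered"] = out / "counts_filtered.tsv"
            outputs["beta_clean"] = out / "beta_clean.tsv"

        contrasts = list(config.contrasts)
        if config.sequential_contrasts:
            phenos = [p for p in mio.PHENOTYPES
                      if p in set(samples["phenotype"])]
            contrasts = list(zip(phenos[:-1], phenos[1:]))

        de_tables: dict[str, pd.DataFrame] = {}
        dm_tables: dict[str, pd.DataFrame] = {}
        mdg_tables: dict[str, pd.DataFrame] = {}
        for baseline, target in contrasts:
            label = f"{baseline}:{target}"
            tag = f"{baseline}_vs_{target}"
            with stage(f"de[{label}]"):
                de = diffexpr.de_test(counts, samples, baseline, target,
                                      lfc_threshold=config.lfc,
                                      fdr_threshold=config.fdr)
                de_tables[label] = de
                _write(de, out / f"de_{tag}.tsv")
                outputs[f"de_{tag}"] = out / f"de_{tag}.tsv"
            with stage(f"dm[{label}]"):
                dm = diffmeth.dm_test(beta, samples, baseline, target,
                                      mean_diff_threshold=config.mean_diff,
                                      p_threshold=config.dm_p,
                                      beta_low=config.beta_low,
                                      beta_high=config.beta_high)
                dm_tables[label] = dm
                _write(dm, out / f"dm_{tag}.tsv")
                outputs[f"dm_{tag}"] = out / f"dm_{tag}.tsv"
            with stage(f"mdg[{label}]"):
                table = mdg.call_mdgs(dm, de, beta, cpg_map, samples,
                                      baseline, target,
                                      beta_low=config.beta_low,
                                      beta_high=config.beta_high,
                                      require_anticorrelation=config.require_anticorrelation)
                mdg_tables[label] = table
                _write(table, out / f"mdg_{tag}.tsv")
                outputs[f"mdg_{tag}"] = out / f"mdg_{tag}.tsv"

        if config.bootstrap_n > 0:
            with stage("dm_bootstrap"):
                boot = diffmeth.bootstrap_dm_counts(
                    beta, samples, contrasts, n_boot=config.bootstrap_n,
                    group_size=config.bootstrap_group_size, seed=config.seed,
                    mean_diff_threshold=config.mean_diff,
                    p_threshold=config.dm_p,
                    beta_low=config.beta_low, beta_high=config.beta_high)
                _write(boot, out / "dm_bootstrap.tsv")
                outputs["dm_bootstrap"] = out / "dm_bootstrap.tsv"

        with stage("cluster"):
            labels, purity = diffmeth.cluster_samples(beta, samples)
            cl = labels.rename_axis("sample_id").reset_index()
            cl["nt_purity"] = purity
            _write(cl, out / "clusters.tsv")
            outputs["clusters"] = out / "clusters.tsv"

        shared_sets: dict[str, set] = {"hypo": set(), "hyper": set()}
        if len(mdg_tables) >= 2:
            with stage("stage_sets"):
                sets = mdg.stage_sets(mdg_tables)
                rows = []
                for cls in ("hypo", "hyper"):
                    shared_sets[cls] = sets[cls]["shared"]
                    for g in sorted(sets[cls]["shared"]):
                        rows.append({"methyl_class": cls, "set": "shared", "gene_id": g})
                    for label, excl in sets[cls]["exclusive"].items():
                        for g in sorted(excl):
                            rows.append({"methyl_class": cls,
                                         "set": f"exclusive[{label}]", "gene_id": g})
                _write(pd.DataFrame(rows, columns=["methyl_class", "set", "gene_id"]),
                       out / "stage_sets.tsv")
                outputs["stage_sets"] = out / "stage_sets.tsv"
        else:
            only = next(iter(mdg_tables.values()))
            for cls in ("hypo", "hyper"):
                shared_sets[cls] = set(only.loc[only["methyl_class"] == cls, "gene_id"])

        all_mdgs = sorted(set().union(*(set(t["gene_id"]) for t in mdg_tables.values())))
        with stage("roles"):
            if catalog is not None:
                annotated = mdg.annotate_roles(all_mdgs, catalog)
            else:
                annotated = pd.DataFrame({"gene_id": all_mdgs,
                                          "role": ["none"] * len(all_mdgs)})
            _write(annotated, out / "mdg_roles.tsv")
            outputs["mdg_roles"] = out / "mdg_roles.tsv"
        role_genes = annotated.loc[annotated["role"] != "none", "gene_id"].tolist()

        with stage("networks"):
            k = config.top_k[0] if config.top_k else None
            concord_rows = []
            for baseline, target in contrasts:
                label = f"{baseline}:{target}"
                tag = f"{baseline}_vs_{target}"
                mdg_genes = set(mdg_tables[label]["gene_id"])
                n_pheno = int((samples["phenotype"] == target).sum())
                if not mdg_genes or n_pheno < 8:
                    log.info("network[%s]: skipped (%d MDGs, %d samples)",
                             label, len(mdg_genes), n_pheno)
                    continue
                net = network.infer_network(norm, mdg_genes, phenotype=target,
                                            samples=samples)
                if config.dpi_tolerance is not None:
                    net = network.dpi_prune(net, tolerance=config.dpi_tolerance)
                if k:
                    net = network.top_k_edges(net, k)
                _write(net, out / f"network_{tag}.tsv")
                outputs[f"network_{tag}"] = out / f"network_{tag}.tsv"
                de = de_tables[label]
                for g in role_genes:
                    sub = network.first_neighbors(net, g)
                    if len(sub) == 0:
                        continue
                    concord_rows.append({
                        "contrast": label, "gene_id": g, "n_neighbors": len(sub),
                        "concordance": network.neighbor_concordance(sub, de, g)})
            _write(pd.DataFrame(concord_rows,
                                columns=["contrast", "gene_id", "n_neighbors",
                                         "concordance"]),
                   out / "neighbor_concordance.tsv")
            outputs["neighbor_concordance"] = out / "neighbor_concordance.tsv"

        with stage("survival"):
            rows = []
            curves = []
            has_surv = {"time", "event"} <= set(samples.columns)
            for g in sorted(set(role_genes) | set(config.survival_genes)):
                if not has_surv or g not in counts.index:
                    continue
                res = survival.survival_by_expression(norm, samples, g)
                rows.append({"gene_id": g, "statistic": res["statistic"],
                             "pvalue": res["pvalue"]})
                for grp, fit in res["fits"].items():
                    for t, s in zip(fit.event_times, fit.survival):
                        curves.append({"gene_id": g, "group": grp,
                                       "time": t, "survival": s})
            _write(pd.DataFrame(rows, columns=["gene_id", "statistic", "pvalue"]),
                   out / "survival_summary.tsv")
            _write(pd.DataFrame(curves, columns=["gene_id", "group", "time",
                                                 "survival"]),
                   out / "survival_curves.tsv")
            outputs["survival_summary"] = out / "survival_summary.tsv"
            outputs["survival_curves"] = out / "survival_curves.tsv"

        with stage("enrichment"):
            if config.gmt:
                collection = mio.read_gmt(config.gmt)
                universe = set(counts.index)
                tables = []
                for cls in ("hypo", "hyper"):
                    if not shared_sets[cls]:
                        continue
                    tab = enrichment.enrich(shared_sets[cls], collection, universe,
                                            alpha=config.enrich_alpha)
                    tab.insert(0, "methyl_class", cls)
                    tables.append(tab)
                res = pd.concat(tables, ignore_index=True) if tables else \
                    pd.DataFrame(columns=["methyl_class", "set", "overlap",
                                          "set_size", "p", "fdr"])
                _write(res, out / "enrichment.tsv")
                outputs["enrichment"] = out / "enrichment.tsv"

        with stage("manifest"):
            manifest = {
                "config": asdict(config),
                "seed": config.seed,
                "version": __version__,
                "outputs": {name: {"path": p.name, "sha256": _sha256(p)}
                            for name, p in sorted(outputs.items())},
            }
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
            with open(out / "timings.json", "w") as fh:
                json.dump(timings, fh, indent=2)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
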