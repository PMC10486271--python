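"""Kaplan-Meier estimation and log-rank comparison of median-split groups.

The estimator and test are delegated to lifelines; this module adds the
median-split labeling rule (strictly above the median -> ``high``, at or
below -> ``low``) and a compact fitted-curve container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank


@dataclass
class SurvivalFit:
    """Product-limit fit: one entry per distinct event time."""

    event_times: np.ndarray   # ordered distinct times with >=1 event
    at_risk: np.ndarray       # subjects at risk just before each event time
    n_events: np.ndarray      # events at each time
    survival: np.ndarray      # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def median_split(values) -> pd.Series:
    """Label samples ``high`` (strictly above the median) or ``low``."""
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need >=2 samples to split")
    med = float(np.median(values.to_numpy()))
    labels = pd.Series(np.where(values.to_numpy() > med, "high", "low"),
                       index=values.index, name="group")
    if (labels == "low").all():
        warnings.warn("constant (or tie-dominated) expression: all samples 'low'",
                      stacklevel=2)
    return labels


def km_estimate(times, events) -> SurvivalFit:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    event_times = observed.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(observed.index).to_numpy()
    return SurvivalFit(
        event_times=event_times,
        at_risk=observed["at_risk"].to_numpy(dtype=int),
        n_events=observed["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_test(times, events, labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("labels must define exactly two nonempty groups")
    g0 = labels == groups[0]
    res = _lifelines_logrank(times[g0], times[~g0], events[g0], events[~g0])
    return float(res.test_statistic), float(res.p_value)


def survival_by_expression(expr: pd.DataFrame, samples: pd.DataFrame, gene: str,
                           stages=None) -> dict:
    """Median-split KM + log-rank for one gene over the tumor samples.

    ``stages`` restricts which phenotypes are pooled (default: all tumor
    stages).  Returns the per-group fits, group labels and the log-rank
    statistic and p-value.
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    use = samples[samples["phenotype"] != "NT"] if stages is None else \
        samples[samples["phenotype"].isin(stages)]
    use = use[use["sample_id"].isin(expr.columns)].reset_index(drop=True)
    vals = expr.loc[gene, use["sample_id"]].astype(float)
    labels = median_split(vals)
    times = use["time"].to_numpy(dtype=float)
    events = use["event"].to_numpy(dtype=int)
    lab = labels.to_numpy()
    fits = {}
    for grp in ("high", "low"):
        mask = lab == grp
        if mask.any():
            fits[grp] = km_estimate(times[mask], events[mask])
    if len(fits) == 2:
        stat, p = logrank_test(times, events, lab)
    else:
        stat, p = float("nan"), float("nan")
    return {"gene": gene, "labels": labels, "fits": fits,
            "statistic": stat, "pvalue": p}
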