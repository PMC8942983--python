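"""Kaplan-Meier / log-rank prognostic screening of network genes.

Each candidate gene dichotomises the cohort at its median expression
(ties go to "low"), and the two arms are compared with the two-group
log-rank test; a gene is flagged prognostic when p < alpha (strict,
uncorrected — the per-gene screen is reported as such). Estimation and
testing are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .types import ExpressionMatrix, ValidationError, validate_clinical


@dataclass
class KMCurve:
    """Product-limit survival curve: S(t) as a right-continuous step function."""

    event_times: np.ndarray  # ascending distinct event times
    at_risk: np.ndarray      # n at risk just before each event time
    survival: np.ndarray     # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    pvalue: float
    n_high: int
    n_low: int


def median_split(values: pd.Series) -> pd.Series:
    """Label samples "high" (> median) or "low" (<= median).

    A degenerate split (all samples on one side, e.g. constant expression)
    is an error because it leaves an empty arm.
    """
    med = values.median()
    labels = pd.Series(np.where(values > med, "high", "low"), index=values.index)
    if labels.nunique() < 2:
        raise ValidationError("degenerate median split: all samples in one group")
    return labels


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod(1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    event_times = tab.index.to_numpy(dtype=float)
    at_risk = tab["at_risk"].to_numpy(dtype=int)
    survival = np.asarray(
        [kmf.predict(t) for t in event_times], dtype=float
    )
    return KMCurve(event_times=event_times, at_risk=at_risk, survival=survival)


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test; p-value from chi-square with 1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 non-empty groups, got {len(labels)}")
    a, b = groups == labels[0], groups == labels[1]
    res = _lifelines_logrank(times[a], times[b], events[a], events[b])
    return LogRankResult(
        chi_square=float(res.test_statistic),
        pvalue=float(res.p_value),
        n_high=int(b.sum()), n_low=int(a.sum()),
    )


def screen_prognostic(matrix: ExpressionMatrix, clinical: pd.DataFrame,
                      gene_ids, alpha: float = 0.05) -> pd.DataFrame:
    """Median-split log-rank screen of ``gene_ids``.

    Returns (gene, chi_square, pvalue, flagged) per gene; only samples
    present in both the expression matrix and the clinical table are used.
    Genes whose median split is degenerate get pvalue NaN, not flagged.
    """
    validate_clinical(clinical)
    clin = clinical.set_index("sample")
    common = [s for s in matrix.sample_ids if s in clin.index]
    if len(common) < 4:
        raise ValidationError("need >= 4 samples shared between expression and clinical data")
    times = clin.loc[common, "time"].to_numpy(dtype=float)
    events = clin.loc[common, "event"].to_numpy(dtype=int)
    rows = []
    for gene in gene_ids:
        if gene not in matrix.gene_ids:
            raise ValidationError(f"unknown gene: {gene!r}")
        expr = matrix.counts.loc[gene, common]
        try:
            arms = median_split(expr)
        except ValidationError:
            rows.append({"gene": gene, "chi_square": np.nan, "pvalue": np.nan,
                         "flagged": False})
            continue
        res = logrank_test(times, events, arms.to_numpy())
        rows.append({"gene": gene, "chi_square": res.chi_square,
                     "pvalue": res.pvalue, "flagged": res.pvalue < alpha})
    return pd.DataFrame(rows, columns=["gene", "chi_square", "pvalue", "flagged"])


def plot_km(times, events, groups, path, title: str = "") -> None:
    """Save a two-arm KM plot (used for flagged genes)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label in np.unique(groups):
        mask = groups == label
        kmf = KaplanMeierFitter(label=str(label))
        kmf.fit(times[mask], event_observed=events[mask])
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
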