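"""Differential expression on log-CPM with empirical-Bayes moderated t-tests.

Each stress condition is compared against its same-timepoint neutral
control.  Per gene, the log2 fold change is the difference of group
means of log2(CPM + pseudocount); the residual variance is pooled
within groups and shrunk toward a common prior estimated by matching
the moments of the log residual variances to a scaled inverse-chi-square
(the classical moderated-t construction: the posterior variance is
(d0*s0^2 + d*s^2)/(d0 + d) and the moderated t has d0 + d degrees of
freedom).  P-values are adjusted by Benjamini-Hochberg, and genes are
called differentially expressed when |log2FC| > 1 and FDR < 0.05
(strict inequalities), the thresholds used throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import CountMatrix, DETable, SampleDesign

__all__ = [
    "Contrast",
    "DEGCall",
    "cpm",
    "fit_contrast",
    "bh_adjust",
    "call_degs",
    "calls_as_series",
    "fold_from_log2fc",
    "zero_count_genes",
]


@dataclass(frozen=True)
class Contrast:
    """A stress-vs-control comparison at one regime and timepoint."""

    regime: str
    timepoint_h: float
    stress_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.stress_samples or not self.control_samples:
            raise ValueError("both sample sets must be nonempty")
        if set(self.stress_samples) & set(self.control_samples):
            raise ValueError("stress and control sample sets overlap")

    @classmethod
    def from_design(
        cls, design: SampleDesign, regime: str, timepoint_h: float
    ) -> "Contrast":
        stress = design.samples_for(regime, "stress", timepoint_h)
        control = design.samples_for(regime, "control", timepoint_h)
        return cls(regime, float(timepoint_h), stress, control)

    @property
    def samples(self) -> tuple[str, ...]:
        return self.stress_samples + self.control_samples


@dataclass(frozen=True)
class DEGCall:
    """Direction call for one gene: up, down, or ns (not significant)."""

    gene_id: str
    direction: str  # 'up' | 'down' | 'ns'


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million, per sample (columns each sum to 1e6)."""
    totals = counts.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = [s for s, t in zip(counts.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-library samples: {bad}")
    values = counts.counts / totals * 1e6
    return pd.DataFrame(values, index=list(counts.gene_ids), columns=list(counts.sample_ids))


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_adj(i) = min over ranks j >= rank(i) of (m / j) * p(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = max(x + step, 1e-8)
        if abs(step) < tol * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of a scaled inverse-chi-square variance prior.

    If s^2 ~ s0^2 * d0/chi^2_{d0} scaled by a chi^2_d sampling step,
    log s^2 has mean log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)
    and variance psi'(d/2) + psi'(d0/2).  A non-positive excess variance
    means no gene-to-gene spread beyond sampling noise -> d0 = inf
    (full shrinkage to s0^2).
    """
    positive = s2[s2 > 0]
    e = np.log(positive)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = var_e - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        d0 = np.inf
        log_s0 = mean_e - float(special.polygamma(0, d / 2.0)) + np.log(d / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            mean_e
            - float(special.polygamma(0, d / 2.0))
            + np.log(d / 2.0)
            + float(special.polygamma(0, d0 / 2.0))
            - np.log(d0 / 2.0)
        )
    return d0, float(np.exp(log_s0))


def zero_count_genes(counts: CountMatrix, contrast: Contrast) -> tuple[str, ...]:
    """Genes with zero counts in every sample of the contrast."""
    sub = counts.subset_samples(list(contrast.samples))
    mask = sub.counts.sum(axis=1) == 0
    return tuple(g for g, z in zip(sub.gene_ids, mask) if z)


def fit_contrast(
    counts: CountMatrix,
    design: SampleDesign,
    contrast: Contrast,
    pseudocount: float = 0.5,
) -> DETable:
    """Moderated-t differential expression for one stress-vs-control contrast.

    Genes with zero counts in all samples of the contrast are dropped
    from testing (retrieve them with :func:`zero_count_genes`).  When
    every gene has zero residual variance the test falls back to an
    unmoderated t with a warning.
    """
    n1, n2 = len(contrast.stress_samples), len(contrast.control_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group")
    design.validate_against(counts)
    sub = counts.subset_samples(list(contrast.samples))
    nonzero = sub.counts.sum(axis=1) > 0
    if not nonzero.any():
        raise ValueError("no gene has nonzero counts in this contrast")
    gene_ids = [g for g, keep in zip(sub.gene_ids, nonzero) if keep]
    sub = CountMatrix(tuple(gene_ids), sub.sample_ids, sub.counts[nonzero])

    cpm_mat = cpm(sub)
    mean_cpm = cpm_mat.mean(axis=1).to_numpy()
    log_cpm = np.log2(cpm_mat.to_numpy() + pseudocount)
    x1 = log_cpm[:, :n1]
    x2 = log_cpm[:, n1:]
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)

    d = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)
    if np.all(s2 == 0):
        warnings.warn(
            "all genes have zero residual variance; using unmoderated t",
            stacklevel=2,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(log2fc == 0, 0.0, np.sign(log2fc) * np.inf)
        p = np.where(log2fc == 0, 1.0, 0.0)
    else:
        d0, s02 = _fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
        else:
            s2_post = (d0 * s02 + d * s2) / (d0 + d)
            df_total = d0 + d
        t = log2fc / (np.sqrt(s2_post) * se_factor)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    p_adj = bh_adjust(p)
    return DETable(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2fc": log2fc,
                "p": p,
                "p_adj": p_adj,
                "mean_cpm": mean_cpm,
            }
        )
    )


def call_degs(
    table: DETable, lfc_threshold: float = 1.0, fdr_threshold: float = 0.05
) -> list[DEGCall]:
    """Direction calls with strict thresholds: |log2FC| > 1 and FDR < 0.05."""
    calls = []
    for row in table.table.itertuples(index=False):
        if row.p_adj < fdr_threshold and row.log2fc > lfc_threshold:
            direction = "up"
        elif row.p_adj < fdr_threshold and row.log2fc < -lfc_threshold:
            direction = "down"
        else:
            direction = "ns"
        calls.append(DEGCall(row.gene_id, direction))
    return calls


def calls_as_series(calls: Sequence[DEGCall]) -> pd.Series:
    """gene_id -> direction as a pandas Series (convenience for set algebra)."""
    return pd.Series({c.gene_id: c.direction for c in calls})


def fold_from_log2fc(log2fc: float) -> tuple[float, str]:
    """Linear fold-change magnitude with direction ('up', 'down', 'none')."""
    fold = float(2.0 ** abs(log2fc))
    if log2fc > 0:
        return fold, "up"
    if log2fc < 0:
        return fold, "down"
    return 1.0, "none"
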