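"""Synthetic data with known ground truth for the two-regime stress design.

Generates negative-binomial count matrices over an acute (stress pH 4.0
vs control pH 7.0 at 1 and 4 h) and a sustained (stress pH 5.5 vs
control at 1, 8, 18 h) regime, regulatory networks with planted-active
and decoy transcription factors, and exponential / logistic growth
curves — so every downstream stage can be benchmarked against a
TruthTable instead of the study's deposited raw reads.

The negative binomial is parameterised by mean ``m`` and dispersion
``phi`` with variance ``m + phi * m**2`` (the standard RNA-seq
convention); ``phi = 0`` degenerates to Poisson.  Per-sample library
sizes are drawn once, uniformly in the configured range, and the
per-gene expected counts are renormalised within each sample so that
expected column sums equal the drawn library size (fold-changes
reallocate sequencing depth rather than add reads, as in a real
sequencing run of fixed depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GrowthCurve, NetworkEdgeList, SampleDesign

__all__ = [
    "SimConfig",
    "TruthTable",
    "contrast_key",
    "simulate_counts",
    "simulate_network",
    "simulate_growth",
]

#: regime -> stress timepoints (hours) of the emulated study design
DEFAULT_REGIMES: dict[str, tuple[float, ...]] = {
    "acute": (1.0, 4.0),
    "sustained": (1.0, 8.0, 18.0),
}


def contrast_key(regime: str, timepoint_h: float) -> str:
    """Canonical name of a stress-vs-control contrast, e.g. ``acute_t1h``."""
    tp = int(timepoint_h) if float(timepoint_h).is_integer() else timepoint_h
    return f"{regime}_t{tp}h"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic count generator.

    Defaults emulate the study design at desk scale: ~3,000 genes,
    triplicate libraries, library sizes 1–2 million (a rescaling of the
    study's 11.4–17.3 million read pairs per sample), 10% of genes
    differentially expressed per contrast with |log2FC| uniform in
    [1.5, 4], and gamma-distributed dispersions with mean 0.1.
    """

    n_genes: int = 3000
    replicates: int = 3
    regimes: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGIMES)
    )
    baseline_log_mean: float = 4.0  # lognormal location of relative expression
    baseline_log_sd: float = 1.5  # lognormal scale
    dispersion_mean: float = 0.1  # gamma mean; 0 -> Poisson
    dispersion_shape: float = 2.0  # gamma shape
    library_size_range: tuple[float, float] = (1e6, 2e6)
    de_fraction: float = 0.1
    lfc_range: tuple[float, float] = (1.5, 4.0)
    n_planted_tfs: int = 1
    n_decoy_tfs: int = 20
    regulon_size: int = 10
    responsive_fraction: float = 0.8
    decoy_pool: Literal["non_de", "all"] = "non_de"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.replicates < 2:
            raise ValueError(
                "replicates must be >= 2 (differential expression needs "
                "residual degrees of freedom)"
            )
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion_mean < 0 or self.dispersion_shape <= 0:
            raise ValueError("dispersion parameters must be nonnegative/positive")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must be positive and ordered")
        lo, hi = self.lfc_range
        if not 0 < lo <= hi:
            raise ValueError("lfc_range must be positive and ordered")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must lie in [0, 1]")

    @property
    def contrasts(self) -> tuple[str, ...]:
        return tuple(
            contrast_key(regime, tp)
            for regime, tps in self.regimes.items()
            for tp in tps
        )


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth: per-gene true log2FC per contrast, per-TF status.

    ``lfc`` is a genes x contrasts frame; nonzero entries are planted
    differential expression.  ``tf_truth`` is filled by
    :func:`simulate_network` (planted flag and intended direction).
    """

    lfc: pd.DataFrame
    tf_truth: pd.DataFrame | None = None

    def de_genes(self, contrast: str) -> tuple[str, ...]:
        col = self.lfc[contrast]
        return tuple(col.index[col != 0.0])

    def non_de_genes(self, contrast: str) -> tuple[str, ...]:
        col = self.lfc[contrast]
        return tuple(col.index[col == 0.0])

    def with_tf_truth(self, tf_truth: pd.DataFrame) -> "TruthTable":
        return TruthTable(self.lfc, tf_truth)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean m, dispersion phi): variance m + phi m^2; phi=0 -> Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = phi <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / phi[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def _balanced_signs(
    props: np.ndarray, magnitudes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Assign DE signs so up/down mass changes roughly cancel.

    Genes are visited in random order; each takes the sign that moves
    the running mass imbalance sum(p * (2**(s*l) - 1)) closer to zero.
    """
    n = len(props)
    signs = np.empty(n)
    order = rng.permutation(n)
    imbalance = 0.0
    for i in order:
        d_up = props[i] * (2.0 ** magnitudes[i] - 1.0)
        d_down = props[i] * (2.0 ** -magnitudes[i] - 1.0)
        if abs(imbalance + d_up) < abs(imbalance + d_down):
            signs[i] = 1.0
            imbalance += d_up
        elif abs(imbalance + d_up) > abs(imbalance + d_down):
            signs[i] = -1.0
            imbalance += d_down
        else:
            signs[i] = rng.choice([-1.0, 1.0])
            imbalance += d_up if signs[i] > 0 else d_down
    return signs


def simulate_counts(
    config: SimConfig, return_means: bool = False
) -> tuple[CountMatrix, SampleDesign, TruthTable] | tuple[
    CountMatrix, SampleDesign, TruthTable, pd.DataFrame
]:
    """Draw a count matrix, its design table, and the planted truth.

    Per-contrast DE gene sets are drawn independently (exactly
    ``round(de_fraction * n_genes)`` genes each, signs mass-balanced);
    effects apply to stress samples only, against the shared
    same-timepoint control baseline.  With ``return_means`` the
    gene x sample matrix of expected counts is returned as well.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = tuple(f"gene{g:04d}" for g in range(config.n_genes))

    # relative baseline expression, shared by all samples
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    props = base / base.sum()

    if config.dispersion_mean > 0:
        phi = rng.gamma(
            config.dispersion_shape,
            config.dispersion_mean / config.dispersion_shape,
            config.n_genes,
        )
    else:
        phi = np.zeros(config.n_genes)

    # planted truth per contrast; signs are assigned to approximately
    # balance up- and down-regulated transcript mass so that the fixed
    # sequencing depth does not impose a compositional fold-change shift
    # on unaffected genes
    n_de = int(round(config.de_fraction * config.n_genes))
    lo, hi = config.lfc_range
    lfc = pd.DataFrame(
        0.0, index=list(gene_ids), columns=list(config.contrasts)
    )
    for ck in config.contrasts:
        idx = rng.choice(config.n_genes, size=n_de, replace=False)
        magnitudes = rng.uniform(lo, hi, n_de)
        signs = _balanced_signs(props[idx], magnitudes, rng)
        lfc.iloc[idx, lfc.columns.get_loc(ck)] = signs * magnitudes

    sample_ids: list[str] = []
    design_rows: list[dict] = []
    columns: list[np.ndarray] = []
    mean_cols: list[np.ndarray] = []
    lib_lo, lib_hi = config.library_size_range
    for regime, tps in config.regimes.items():
        for tp in tps:
            ck = contrast_key(regime, tp)
            fold = np.power(2.0, lfc[ck].to_numpy())
            for condition in ("control", "stress"):
                rel = props * fold if condition == "stress" else props
                rel = rel / rel.sum()
                for rep in range(1, config.replicates + 1):
                    lib = rng.uniform(lib_lo, lib_hi)
                    mean = lib * rel
                    mean_cols.append(mean)
                    columns.append(_nb_draw(rng, mean, phi))
                    sid = f"{ck}_{condition}_r{rep}"
                    sample_ids.append(sid)
                    design_rows.append(
                        {
                            "sample_id": sid,
                            "regime": regime,
                            "condition": condition,
                            "timepoint_h": float(tp),
                            "replicate": rep,
                        }
                    )

    counts = CountMatrix(gene_ids, tuple(sample_ids), np.column_stack(columns))
    design = SampleDesign(pd.DataFrame(design_rows).set_index("sample_id"))
    truth = TruthTable(lfc)
    if return_means:
        means = pd.DataFrame(
            np.column_stack(mean_cols), index=list(gene_ids), columns=sample_ids
        )
        return counts, design, truth, means
    return counts, design, truth


def simulate_network(
    config: SimConfig, truth: TruthTable, reference_contrast: str | None = None
) -> tuple[NetworkEdgeList, TruthTable]:
    """Wire planted-active and decoy TF regulons onto the simulated genes.

    Planted TFs draw ``responsive_fraction`` of their targets from the
    reference contrast's planted-DE genes (edge effect matching the
    target's true direction: activation for up, repression for down)
    and the remainder from non-DE genes.  Decoy regulons are sampled
    from non-DE genes (``decoy_pool="non_de"``, the default) or from
    all genes.  Returns the edge list and a TruthTable annotated with
    per-TF planted flags.
    """
    if config.regulon_size > config.n_genes:
        raise ValueError("regulon size exceeds number of genes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E7]))
    if reference_contrast is None:
        reference_contrast = config.contrasts[0]
    de = list(truth.de_genes(reference_contrast))
    non_de = list(truth.non_de_genes(reference_contrast))
    all_genes = list(truth.lfc.index)

    edges: list[tuple[str, str, str]] = []
    tf_rows: list[dict] = []
    n_responsive = int(round(config.responsive_fraction * config.regulon_size))
    for i in range(config.n_planted_tfs):
        tf = f"TF_planted_{i + 1}"
        if n_responsive > len(de):
            raise ValueError(
                f"planted regulon needs {n_responsive} DE targets but only "
                f"{len(de)} DE genes exist in {reference_contrast}"
            )
        responsive = rng.choice(len(de), size=n_responsive, replace=False)
        chosen = [de[j] for j in responsive]
        de = [g for j, g in enumerate(de) if j not in set(responsive)]
        n_rest = config.regulon_size - n_responsive
        rest_idx = rng.choice(len(non_de), size=n_rest, replace=False)
        rest = [non_de[j] for j in rest_idx]
        for g in chosen:
            effect = (
                "activation"
                if truth.lfc.loc[g, reference_contrast] > 0
                else "repression"
            )
            edges.append((tf, g, effect))
        for g in rest:
            edges.append((tf, g, str(rng.choice(["activation", "repression"]))))
        tf_rows.append({"tf_id": tf, "planted": True, "direction": "up"})

    decoy_pool = non_de if config.decoy_pool == "non_de" else all_genes
    for i in range(config.n_decoy_tfs):
        tf = f"TF_decoy_{i + 1}"
        idx = rng.choice(len(decoy_pool), size=config.regulon_size, replace=False)
        for j in idx:
            edges.append(
                (tf, decoy_pool[j], str(rng.choice(["activation", "repression"])))
            )
        tf_rows.append({"tf_id": tf, "planted": False, "direction": "none"})

    tf_truth = pd.DataFrame(tf_rows).set_index("tf_id")
    return NetworkEdgeList(tuple(edges)), truth.with_tf_truth(tf_truth)


def simulate_growth(
    model: Literal["exponential", "logistic"] = "logistic",
    od0: float = 0.1,
    mu: float = 0.4,
    carrying_capacity: float = 30.0,
    lag_h: float = 2.0,
    noise_sd: float = 0.0,
    dt_h: float = 0.25,
    duration_h: float = 24.0,
    seed: int = 0,
    with_ph: bool = False,
    ph0: float = 4.0,
    ph_max: float = 7.1,
    ph_peak_h: float = 8.0,
    ph_end: float = 5.5,
    with_cfu: bool = False,
    cfu_per_od: float = 4.1e9,
) -> GrowthCurve:
    """Generate a growth curve from a closed-form model plus noise.

    ``logistic`` uses OD(t) = K / (1 + ((K - OD0)/OD0) * exp(-mu*(t-lag)+))
    (no growth before the lag); ``exponential`` is OD0 * exp(mu*t).
    Noise is multiplicative lognormal with the given log-scale sd.  The
    optional pH trace rises linearly from ``ph0`` to ``ph_max`` at
    ``ph_peak_h`` then declines to ``ph_end`` — mimicking the broth
    alkalinisation followed by re-acidification seen after acid shock.
    """
    if od0 <= 0 or mu <= 0 or dt_h <= 0 or duration_h <= 0:
        raise ValueError("od0, mu, dt_h and duration_h must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    t = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    if model == "exponential":
        od = od0 * np.exp(mu * t)
    elif model == "logistic":
        K = carrying_capacity
        if K <= od0:
            raise ValueError("carrying capacity must exceed od0")
        shifted = np.maximum(t - lag_h, 0.0)
        od = K / (1.0 + ((K - od0) / od0) * np.exp(-mu * shifted))
    else:
        raise ValueError(f"unknown growth model {model!r}")
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, od.shape))

    ph = None
    if with_ph:
        ph = np.where(
            t <= ph_peak_h,
            ph0 + (ph_max - ph0) * t / ph_peak_h,
            ph_max + (ph_end - ph_max) * (t - ph_peak_h) / max(duration_h - ph_peak_h, dt_h),
        )
    cfu = None
    if with_cfu:
        cfu = cfu_per_od * od
        if noise_sd > 0:
            cfu = cfu * np.exp(rng.normal(0.0, noise_sd, od.shape))
    return GrowthCurve(time_h=t, od=od, ph=ph, cfu_per_ml=cfu)
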