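"""Reporter transcription-factor analysis on a regulatory network.

Scores each TF by the collective differential-expression significance
of its regulon: with gene significance s = -log10(adjusted p), the
reporter score is Z = (mu_target - mu_bg) / sigma_bg, where mu_target
is the mean s over the TF's surviving targets and mu_bg / sigma_bg are
the mean and population standard deviation of s over the background
(all abundance-filtered, tested genes, including each TF's own
targets).  As printed, the statistic carries no sqrt(k) size
correction; size-aware significance comes from a sampling null that
draws random same-size gene sets from the background, followed by
Benjamini-Hochberg adjustment across TFs.  Per-TF direction profiles
(fractions of up / down / ns targets) summarise how each regulon moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .de_stats import DEGCall, bh_adjust, cpm
from .io_formats import CountMatrix, DETable, NetworkEdgeList

__all__ = [
    "RegulatoryNetwork",
    "ReporterResult",
    "clean_network",
    "abundance_filter",
    "gene_significance",
    "reporter_z",
    "sampling_null",
    "direction_profile",
    "reporter_analysis",
]

#: adjusted p-values are clamped here before -log10, keeping s finite
P_ADJ_FLOOR = 1e-300


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Cleaned TF -> target edges with a per-TF target index."""

    edges: tuple[tuple[str, str, str], ...]
    n_redundant_removed: int = 0
    n_ambiguous_removed: int = 0

    def targets_of(self, tf_id: str) -> tuple[str, ...]:
        return tuple(t for tf, t, _ in self.edges if tf == tf_id)

    @property
    def tf_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for tf, _, _ in self.edges:
            seen.setdefault(tf)
        return tuple(seen)


@dataclass(frozen=True)
class ReporterResult:
    """Per-TF reporter score with its background moments and null p."""

    tf_id: str
    n_targets_used: int
    mu_target: float | None
    mu_bg: float
    sigma_bg: float
    z: float | None
    p_sampling: float | None = None
    p_adj: float | None = None
    up_frac: float | None = None
    down_frac: float | None = None
    ns_frac: float | None = None
    skipped_reason: str | None = None


def clean_network(edges: NetworkEdgeList) -> RegulatoryNetwork:
    """Collapse redundant edges and drop ambiguous (TF, target) pairs.

    Exact duplicate rows collapse to one.  A pair carrying both an
    activation and a repression row is removed entirely as ambiguous —
    unless one of its rows is already labelled dual, in which case the
    dual row wins.  Self-loops are retained.
    """
    by_pair: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    n_redundant = 0
    for tf, target, effect in edges:
        key = (tf, target)
        if key not in by_pair:
            by_pair[key] = [effect]
            order.append(key)
        elif effect in by_pair[key]:
            n_redundant += 1
        else:
            by_pair[key].append(effect)

    cleaned = []
    n_ambiguous = 0
    for key in order:
        effects = by_pair[key]
        if len(effects) == 1:
            cleaned.append((key[0], key[1], effects[0]))
        elif "dual" in effects:
            cleaned.append((key[0], key[1], "dual"))
        else:  # activation + repression with no dual row
            n_ambiguous += 1
    return RegulatoryNetwork(tuple(cleaned), n_redundant, n_ambiguous)


def abundance_filter(
    counts: CountMatrix,
    de_table: DETable | None = None,
    threshold_cpm: float = 1.0,
) -> tuple[str, ...]:
    """Background gene set: mean CPM >= threshold, and tested if a DE table is given.

    Genes with mean CPM (across the supplied samples) strictly below
    the threshold are excluded; a gene at exactly the threshold is
    retained.
    """
    mean_cpm = cpm(counts).mean(axis=1)
    kept = set(mean_cpm.index[mean_cpm >= threshold_cpm])
    if de_table is not None:
        kept &= set(de_table.gene_ids)
    return tuple(g for g in counts.gene_ids if g in kept)


def gene_significance(de_table: DETable) -> dict[str, float]:
    """s = -log10(adjusted p) per gene, with p_adj clamped to >= 1e-300."""
    t = de_table.table
    p = np.maximum(t["p_adj"].to_numpy(dtype=float), P_ADJ_FLOOR)
    return dict(zip(t["gene_id"], -np.log10(p)))


def _background_moments(
    significance: Mapping[str, float], background: Sequence[str], ddof: int = 0
) -> tuple[float, float, np.ndarray]:
    if not background:
        raise ValueError("empty background gene set")
    s = np.array([significance[g] for g in background], dtype=float)
    mu = float(s.mean())
    sigma = float(s.std(ddof=ddof))
    if sigma == 0.0:
        raise ValueError("degenerate background: all significances identical")
    return mu, sigma, s


def reporter_z(
    network: RegulatoryNetwork,
    significance: Mapping[str, float],
    background: Sequence[str],
    min_targets: int = 3,
    sigma_ddof: int = 0,
    leave_out_background: bool = False,
) -> list[ReporterResult]:
    """Reporter Z for every TF with enough surviving targets.

    Targets outside the background (filtered out or untested) are
    dropped; TFs with fewer than ``min_targets`` survivors are reported
    unscored with a reason rather than silently omitted.  The
    background includes each TF's own targets unless
    ``leave_out_background`` is set.
    """
    bg_set = set(background)
    mu_bg, sigma_bg, _ = _background_moments(significance, background, sigma_ddof)
    results = []
    for tf in network.tf_ids:
        targets = [t for t in network.targets_of(tf) if t in bg_set]
        if len(targets) < min_targets:
            results.append(
                ReporterResult(
                    tf_id=tf,
                    n_targets_used=len(targets),
                    mu_target=None,
                    mu_bg=mu_bg,
                    sigma_bg=sigma_bg,
                    z=None,
                    skipped_reason=(
                        f"only {len(targets)} surviving targets "
                        f"(min_targets={min_targets})"
                    ),
                )
            )
            continue
        if leave_out_background:
            rest = [g for g in background if g not in set(targets)]
            mu, sigma, _ = _background_moments(significance, rest, sigma_ddof)
        else:
            mu, sigma = mu_bg, sigma_bg
        mu_t = float(np.mean([significance[t] for t in targets]))
        results.append(
            ReporterResult(
                tf_id=tf,
                n_targets_used=len(targets),
                mu_target=mu_t,
                mu_bg=mu,
                sigma_bg=sigma,
                z=(mu_t - mu) / sigma,
            )
        )
    return results


def _null_means(
    k: int, s: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_draws`` random size-k subsets of s, without replacement."""
    # random-key trick: the k smallest of iid uniform keys per row form a
    # uniform without-replacement sample of the indices
    keys = rng.random((n_draws, s.size))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return s[idx].mean(axis=1)


def sampling_null(
    k: int,
    mu_target: float,
    significance: Mapping[str, float],
    background: Sequence[str],
    n_draws: int = 10000,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided (enrichment) sampling p-value for a target-set mean.

    Draws ``n_draws`` random size-k gene sets from the background
    without replacement; p = (1 + #{mean s >= mu_target}) / (n_draws + 1).
    """
    if k > len(background):
        raise ValueError(f"k={k} exceeds background size {len(background)}")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    s = np.array([significance[g] for g in background], dtype=float)
    means = _null_means(k, s, n_draws, rng)
    exceed = int(np.count_nonzero(means >= mu_target - 1e-12))
    return (1 + exceed) / (n_draws + 1)


def direction_profile(
    tf_id: str,
    network: RegulatoryNetwork,
    calls: Sequence[DEGCall],
    background: Sequence[str] | None = None,
) -> tuple[float, float, float] | None:
    """Fractions of the TF's surviving targets called up / down / ns.

    Dual-effect targets are counted by their observed direction like
    any other; returns None for a TF with no surviving targets.
    """
    call_map = {c.gene_id: c.direction for c in calls}
    targets = [t for t in network.targets_of(tf_id) if t in call_map]
    if background is not None:
        bg = set(background)
        targets = [t for t in targets if t in bg]
    if not targets:
        return None
    n = len(targets)
    up = sum(call_map[t] == "up" for t in targets)
    down = sum(call_map[t] == "down" for t in targets)
    return up / n, down / n, (n - up - down) / n


def reporter_analysis(
    edges: NetworkEdgeList,
    de_table: DETable,
    counts: CountMatrix,
    calls: Sequence[DEGCall] | None = None,
    threshold_cpm: float = 1.0,
    min_targets: int = 3,
    n_draws: int = 10000,
    seed: int = 0,
    leave_out_background: bool = False,
) -> list[ReporterResult]:
    """End-to-end reporter scoring for one contrast.

    Cleans the network, builds the abundance-filtered background,
    computes Z per TF, attaches sampling p-values (BH-adjusted across
    scored TFs) and direction profiles.
    """
    from .de_stats import call_degs

    network = clean_network(edges)
    background = abundance_filter(counts, de_table, threshold_cpm)
    significance = gene_significance(de_table)
    if calls is None:
        calls = call_degs(de_table)
    results = reporter_z(
        network,
        significance,
        background,
        min_targets=min_targets,
        leave_out_background=leave_out_background,
    )
    rng = np.random.default_rng(seed)
    scored_idx = [i for i, r in enumerate(results) if r.z is not None]
    s_bg = np.array([significance[g] for g in background], dtype=float)
    # same-size regulons share one set of null draws
    null_cache: dict[int, np.ndarray] = {}
    p_raw = []
    for i in scored_idx:
        r = results[i]
        k = r.n_targets_used
        if k not in null_cache:
            null_cache[k] = _null_means(k, s_bg, n_draws, rng)
        means = null_cache[k]
        exceed = int(np.count_nonzero(means >= r.mu_target - 1e-12))
        p_raw.append((1 + exceed) / (n_draws + 1))
    p_adj = bh_adjust(np.array(p_raw)) if p_raw else np.array([])

    out = []
    j = 0
    for i, r in enumerate(results):
        profile = direction_profile(r.tf_id, network, calls, background)
        up = down = ns = None
        if profile is not None:
            up, down, ns = profile
        if i in scored_idx:
            out.append(
                ReporterResult(
                    tf_id=r.tf_id,
                    n_targets_used=r.n_targets_used,
                    mu_target=r.mu_target,
                    mu_bg=r.mu_bg,
                    sigma_bg=r.sigma_bg,
                    z=r.z,
                    p_sampling=p_raw[j],
                    p_adj=float(p_adj[j]),
                    up_frac=up,
                    down_frac=down,
                    ns_frac=ns,
                )
            )
            j += 1
        else:
            out.append(
                ReporterResult(
                    tf_id=r.tf_id,
                    n_targets_used=r.n_targets_used,
                    mu_target=r.mu_target,
                    mu_bg=r.mu_bg,
                    sigma_bg=r.sigma_bg,
                    z=r.z,
                    up_frac=up,
                    down_frac=down,
                    ns_frac=ns,
                    skipped_reason=r.skipped_reason,
                )
            )
    return out
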