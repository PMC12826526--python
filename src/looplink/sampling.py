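"""Replicate saturation, subsample similarity and leave-one-out analyses.

A single MS run detects only a small fraction of the theoretically
possible cross-links, so unique-link coverage is assessed by
accumulation curves over randomly permuted technical replicates and
compared against a uniform random-sampling null (a fixed pool of P
possible pairs, a fixed number of distinct links drawn per simulated
replicate).  The number of observations needed to resolve two protein
states is probed by bootstrapped subsample-similarity curves, and the
structural weight of individual cross-links by a leave-one-out scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ecs import ECSConfig, ECSResult, ecs_compare
from .exceptions import ContractError
from .loopclust import LoopClustering, extract_loops
from .netbuild import NetworkConfig, StructuralNetwork, build_network
from .xl_io import CrossLinkSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateSeries:
    """Ordered per-replicate CrossLinkSets for one protein/condition."""

    protein_id: str
    replicates: tuple[tuple[str, CrossLinkSet], ...]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.replicates]
        if len(set(ids)) != len(ids):
            raise ValueError("replicate ids must be unique")
        for _, xls in self.replicates:
            if xls.protein_id != self.protein_id:
                raise ValueError("all replicates must share the series protein_id")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def union_pairs(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for _, xls in self.replicates:
            out.update(xls.pairs)
        return out


@dataclass(frozen=True)
class AccumulationCurve:
    """Unique cross-links vs pooled replicates, averaged over cycles."""

    x: tuple[int, ...]
    mean_unique: tuple[float, ...]
    per_cycle: np.ndarray  # shape (n_cycles, len(x))

    @property
    def n_cycles(self) -> int:
        return self.per_cycle.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        sd = self.per_cycle.std(axis=0) if self.n_cycles else np.zeros(len(self.x))
        pd.DataFrame({"replicate": self.x, "mean": self.mean_unique, "sd": sd}
                     ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class NullModelConfig:
    """Uniform random-sampling null for cross-link accumulation."""

    pool_size: int
    links_per_cycle: int = 100
    n_cycles: int = 199

    def __post_init__(self) -> None:
        if not 0 < self.links_per_cycle <= self.pool_size:
            raise ContractError("need 0 < links_per_cycle <= pool_size")


@dataclass(frozen=True)
class SimilarityCurve:
    """Mean ECS (+/- spread) as a function of cross-link sample size."""

    sizes: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    n_boot: int
    per_draw: np.ndarray = field(compare=False, default=None)  # (n_boot, n_sizes)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"size": self.sizes, "mean": self.mean, "sd": self.sd,
                      "ci_low": self.ci_low, "ci_high": self.ci_high}
                     ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LOOLink:
    """Leave-one-out record for one condition-specific cross-link."""

    pair: tuple[int, int]
    ecs_vs_self: float
    ecs_vs_other: float
    deviation: float      # 1 - ecs_vs_self
    shift: float          # ecs_vs_other - baseline ECS(a, b)


@dataclass(frozen=True)
class LOOResult:
    """Per-link influence of condition-specific cross-links."""

    per_link: tuple[LOOLink, ...]
    baseline_ecs: float
    mean_deviation: float
    mean_shift: float

    @property
    def mean_deviation_pct(self) -> float:
        return 100.0 * self.mean_deviation

    @property
    def mean_shift_pct(self) -> float:
        return 100.0 * self.mean_shift

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"site_a": l.pair[0], "site_b": l.pair[1],
                 "ecs_vs_self": l.ecs_vs_self, "ecs_vs_other": l.ecs_vs_other,
                 "deviation": l.deviation, "shift": l.shift}
                for l in self.per_link
            ]
        ).to_csv(path, sep="\t", index=False)


def empirical_accumulation(
    series: ReplicateSeries,
    n_cycles: int,
    rng: np.random.Generator,
) -> AccumulationCurve:
    """Accumulation of unique pairs over randomly permuted replicates.

    Each cycle draws a fresh uniform permutation of the replicate order
    and records the cumulative count of distinct site pairs after each
    replicate; the curve is the mean over cycles.
    """
    R = series.n_replicates
    if R < 1:
        raise ContractError("need at least one replicate")
    pair_sets = [set(xls.pairs) for _, xls in series.replicates]
    per_cycle = np.zeros((n_cycles, R), dtype=float)
    for c in range(n_cycles):
        order = rng.permutation(R)
        seen: set[tuple[int, int]] = set()
        for k, idx in enumerate(order):
            seen.update(pair_sets[idx])
            per_cycle[c, k] = len(seen)
    return AccumulationCurve(
        x=tuple(range(1, R + 1)),
        mean_unique=tuple(per_cycle.mean(axis=0)),
        per_cycle=per_cycle,
    )


def null_accumulation(
    config: NullModelConfig,
    n_replicates: int,
    rng: np.random.Generator,
) -> AccumulationCurve:
    """Expected accumulation under uniform sampling from a fixed pool.

    Each simulated replicate draws ``links_per_cycle`` *distinct* pairs
    uniformly from the pool of ``pool_size`` (a replicate's unique-link
    list has no duplicates); cumulative distinct counts are averaged over
    ``n_cycles`` simulations.  The closed-form expectation is
    E[U_k] = P * (1 - (1 - m/P)^k).
    """
    if n_replicates == 0:
        return AccumulationCurve(x=(), mean_unique=(),
                                 per_cycle=np.zeros((config.n_cycles, 0)))
    P, m = config.pool_size, config.links_per_cycle
    per_cycle = np.zeros((config.n_cycles, n_replicates), dtype=float)
    for c in range(config.n_cycles):
        seen = np.zeros(P, dtype=bool)
        for k in range(n_replicates):
            draw = rng.choice(P, size=m, replace=False)
            seen[draw] = True
            per_cycle[c, k] = int(seen.sum())
    return AccumulationCurve(
        x=tuple(range(1, n_replicates + 1)),
        mean_unique=tuple(per_cycle.mean(axis=0)),
        per_cycle=per_cycle,
    )


def expected_null_accumulation(pool_size: int, links_per_cycle: int,
                               n_replicates: int) -> np.ndarray:
    """Closed-form E[U_k] = P(1 - (1 - m/P)^k) for k = 1..n_replicates."""
    k = np.arange(1, n_replicates + 1)
    frac = links_per_cycle / pool_size
    return pool_size * (1.0 - (1.0 - frac) ** k)


def _loops_from_observations(
    observations: list[tuple[int, int]],
    protein_id: str,
    L: int,
    net_config: NetworkConfig,
) -> LoopClustering:
    pairs: dict[tuple[int, int], int] = {}
    for p in observations:
        pairs[p] = pairs.get(p, 0) + 1
    xls = CrossLinkSet(
        protein_id=protein_id,
        pairs=pairs,
        provenance={p: ("subsample",) * mult for p, mult in pairs.items()},
    )
    return extract_loops(build_network(L, xls, net_config))


def subsample_similarity(
    ref: CrossLinkSet,
    other: CrossLinkSet,
    L: int,
    sizes: list[int],
    n_boot: int = 10,
    ecs_config: ECSConfig = ECSConfig(),
    net_config: NetworkConfig = NetworkConfig(),
    rng: np.random.Generator | None = None,
    with_replacement: bool = False,
) -> SimilarityCurve:
    """ECS between networks built from random cross-link subsamples.

    For each sample size m and bootstrap draw, m observations (duplicates
    counted as separate observations) are drawn without replacement from
    each set's observation multiset, collapsed to unique pairs, and the
    two resulting loop clusterings are compared.  ``with_replacement``
    switches to a conventional bootstrap for sensitivity analysis.
    """
    if rng is None:
        rng = np.random.default_rng()
    obs_ref = ref.observations()
    obs_other = other.observations()
    for m in sizes:
        if m > len(obs_ref) or m > len(obs_other):
            raise ContractError(
                f"sample size {m} exceeds total observations "
                f"({len(obs_ref)} ref, {len(obs_other)} other)"
            )
    per_draw = np.zeros((n_boot, len(sizes)), dtype=float)
    for b in range(n_boot):
        for s, m in enumerate(sizes):
            idx_r = (rng.choice(len(obs_ref), size=m, replace=True)
                     if with_replacement
                     else rng.choice(len(obs_ref), size=m, replace=False))
            idx_o = (rng.choice(len(obs_other), size=m, replace=True)
                     if with_replacement
                     else rng.choice(len(obs_other), size=m, replace=False))
            loops_r = _loops_from_observations(
                [obs_ref[i] for i in idx_r], ref.protein_id, L, net_config)
            loops_o = _loops_from_observations(
                [obs_other[i] for i in idx_o], other.protein_id, L, net_config)
            per_draw[b, s] = ecs_compare(loops_r, loops_o, ecs_config).mean_score
    mean = per_draw.mean(axis=0)
    sd = per_draw.std(axis=0)
    half = 1.96 * sd / np.sqrt(n_boot)
    return SimilarityCurve(
        sizes=tuple(sizes),
        mean=tuple(mean), sd=tuple(sd),
        ci_low=tuple(mean - half), ci_high=tuple(mean + half),
        n_boot=n_boot, per_draw=per_draw,
    )


def detect_divergence_threshold(
    intra: SimilarityCurve,
    inter: SimilarityCurve,
) -> int | None:
    """Smallest sample size from which the curves stay CI-separated.

    Returns the smallest grid size m such that at m and every larger grid
    size the inter-state 95% CI upper bound lies strictly below the
    intra-state 95% CI lower bound; None if separation is never sustained.
    """
    if intra.sizes != inter.sizes:
        raise ContractError("similarity curves must share the same sizes grid")
    separated = [hi < lo for hi, lo in zip(inter.ci_high, intra.ci_low)]
    threshold = None
    for m, sep in zip(reversed(intra.sizes), reversed(separated)):
        if sep:
            threshold = m
        else:
            break
    return threshold


def loo_analysis(
    a: CrossLinkSet,
    b: CrossLinkSet,
    L: int,
    ecs_config: ECSConfig = ECSConfig(),
    net_config: NetworkConfig = NetworkConfig(),
) -> LOOResult:
    """Leave-one-out influence of the cross-links specific to condition a.

    For each unique pair present in a but not in b, the pair is removed
    from a's network, the loop clustering re-extracted and compared to
    both the unmodified a (deviation = 1 - similarity) and to b (shift =
    similarity - baseline ECS(a, b)); positive shift means the perturbed
    network moved closer to the other condition.
    """
    from .ecs import element_affinities, scores_from_affinities

    net_a = build_network(L, a, net_config)
    net_b = build_network(L, b, net_config)
    loops_a = extract_loops(net_a)
    loops_b = extract_loops(net_b)
    # reference affinities are solved once and reused for every removal
    P_a = element_affinities(loops_a, ecs_config)
    P_b = element_affinities(loops_b, ecs_config)
    baseline = scores_from_affinities(P_a, P_b, ecs_config).mean_score
    specific = sorted(set(net_a.crosslink_edges) - set(net_b.crosslink_edges))
    if not specific:
        logger.warning("loo_analysis: no condition-specific cross-links")
        return LOOResult(per_link=(), baseline_ecs=baseline,
                         mean_deviation=0.0, mean_shift=0.0)
    links: list[LOOLink] = []
    for pair in specific:
        loops_mod = extract_loops(net_a.without_crosslink(pair))
        P_mod = element_affinities(loops_mod, ecs_config)
        vs_self = scores_from_affinities(P_mod, P_a, ecs_config).mean_score
        vs_other = scores_from_affinities(P_mod, P_b, ecs_config).mean_score
        links.append(LOOLink(pair=pair, ecs_vs_self=vs_self, ecs_vs_other=vs_other,
                             deviation=1.0 - vs_self, shift=vs_other - baseline))
    return LOOResult(
        per_link=tuple(links),
        baseline_ecs=baseline,
        mean_deviation=float(np.mean([l.deviation for l in links])),
        mean_shift=float(np.mean([l.shift for l in links])),
    )


def plot_accumulation(
    empirical: AccumulationCurve,
    null: AccumulationCurve,
    path: str | Path,
    title: str = "",
) -> None:
    """Red empirical vs black null accumulation scatterlines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(empirical.x, empirical.mean_unique, "r.-", label="measured")
    ax.plot(null.x, null.mean_unique, "k.-", label="random-sampling null")
    ax.set_xlabel("technical replicates")
    ax.set_ylabel("unique cross-links")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_similarity_curves(
    curves: dict[str, SimilarityCurve],
    path: str | Path,
    title: str = "",
) -> None:
    """Mean similarity vs sample size with +/- sd shading per curve."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        mean = np.asarray(curve.mean)
        sd = np.asarray(curve.sd)
        ax.plot(curve.sizes, mean, ".-", label=label)
        ax.fill_between(curve.sizes, mean - sd, mean + sd, alpha=0.25)
    ax.set_xlabel("cross-link observations sampled")
    ax.set_ylabel("mean element-centric similarity")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
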