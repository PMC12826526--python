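"""Synthetic cross-link studies with known ground truth.

Real XL-MS measurements sample residue contacts of an unknown conformer
through a distance-dependent detection process.  This module builds the
whole chain of that process synthetically: a ground-truth conformer (a
confinement-restricted random walk with fixed 3.8 A Calpha bonds), a
detection model that turns site-pair Calpha distances into observation
probabilities (certain detection up to the linker span, exponential
decay beyond, plus a uniform false-positive floor), and per-replicate
observation tables written in the same dialect the parser reads.  A
second protein state is produced by re-growing a chosen sequence
segment, which rewires the contact map inside the segment while leaving
the remainder untouched — the synthetic analogue of a local
conformational transition.

Only the contact topology matters to the pipeline under test, so the
conformers are geometric random walks, not physical simulations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContractError, GenerationError
from .netbuild import BACKBONE_SPACING
from .sampling import ReplicateSeries
from .xl_io import (
    LINKABLE_RESIDUES,
    CrossLinkSet,
    ProteinSequence,
    SiteSet,
    enumerate_sites,
)

logger = logging.getLogger(__name__)

_NONSITE_RESIDUES = "ACDEFGHILMNPQVW"  # standard residues DSBU does not target


@dataclass(frozen=True)
class SyntheticConformer:
    """A fixed-bond chain of Calpha positions inside a confinement sphere."""

    coords: np.ndarray  # (L, 3), Angstrom
    bond_length: float = BACKBONE_SPACING
    confinement_radius: float = 30.0

    @property
    def L(self) -> int:
        return self.coords.shape[0]

    def site_distance(self, i: int, j: int) -> float:
        """Calpha distance between residues i and j (1-based)."""
        return float(np.linalg.norm(self.coords[i - 1] - self.coords[j - 1]))

    def contact_pairs(self, sites: SiteSet, cutoff: float = 30.0) -> set[tuple[int, int]]:
        """Site pairs within ``cutoff`` A (|i-j| >= 2): the contact map."""
        out: set[tuple[int, int]] = set()
        s = sites.sites
        for a in range(len(s)):
            for b in range(a + 1, len(s)):
                i, j = s[a], s[b]
                if j - i >= 2 and self.site_distance(i, j) <= cutoff:
                    out.add((i, j))
        return out


@dataclass(frozen=True)
class DetectionModel:
    """Distance-dependent cross-link observation probabilities.

    Detection probability is ``p_max`` for Calpha distances up to the
    linker span (default 30 A, the maximum span of DSBU) and decays as
    ``p_max * exp(-(d - span) / decay_scale)`` beyond it.  ``fp_rate``
    is the fraction of observations replaced by uniformly random site
    pairs (search-engine false positives).
    """

    span: float = 30.0
    p_max: float = 0.9
    decay_scale: float = 5.0
    fp_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")

    def probability(self, distance: float) -> float:
        if distance <= self.span:
            return self.p_max
        if self.decay_scale <= 0.0:
            return 0.0
        return self.p_max * float(np.exp(-(distance - self.span) / self.decay_scale))


def _uniform_in_ball(radius: float, rng: np.random.Generator) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            return p


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def generate_chain(
    L: int,
    confinement_radius: float,
    rng: np.random.Generator,
    bond_length: float = BACKBONE_SPACING,
    max_retries: int = 500,
) -> SyntheticConformer:
    """Fixed-bond random walk confined to a sphere around the origin.

    Step directions are uniform on the sphere; steps leaving the
    confinement sphere are rejection-resampled.  Deterministic under a
    seeded generator.
    """
    if confinement_radius < bond_length:
        raise ContractError("confinement_radius must be >= bond_length")
    coords = np.zeros((L, 3))
    coords[0] = _uniform_in_ball(confinement_radius, rng)
    for k in range(1, L):
        for attempt in range(max_retries):
            step = coords[k - 1] + bond_length * _random_unit(rng)
            if np.linalg.norm(step) <= confinement_radius:
                coords[k] = step
                break
        else:
            raise GenerationError(
                f"could not place residue {k + 1} inside the confinement sphere "
                f"after {max_retries} attempts"
            )
    return SyntheticConformer(coords=coords, bond_length=bond_length,
                              confinement_radius=confinement_radius)


def _closing_point(prev: np.ndarray, target: np.ndarray, b: float,
                   rng: np.random.Generator) -> np.ndarray:
    """A point at distance b from both prev and target (two-sphere circle)."""
    v = target - prev
    d = float(np.linalg.norm(v))
    if d < 1e-12:
        return prev + b * _random_unit(rng)
    if d >= 2.0 * b:
        return 0.5 * (prev + target)  # degenerate: stretched straight
    n_hat = v / d
    centre = 0.5 * (prev + target)
    rc = float(np.sqrt(max(b * b - 0.25 * d * d, 0.0)))
    # orthonormal basis of the circle plane
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n_hat[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n_hat, helper)
    u /= np.linalg.norm(u)
    w = np.cross(n_hat, u)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return centre + rc * (np.cos(theta) * u + np.sin(theta) * w)


def _grow_bridge(start: np.ndarray, target: np.ndarray, n_points: int,
                 b: float, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Fixed-bond walk of n_points from start that ends one bond from target.

    Each placement keeps the remaining distance reachable with the
    remaining bonds (|p - target| <= r*b); the final point is sampled on
    the exact two-sphere intersection circle.  Confinement is honoured
    where feasible and relaxed otherwise (the caller widens the recorded
    radius if needed).
    """
    points = np.zeros((n_points, 3))
    prev = start
    for k in range(n_points):
        remaining = n_points - k  # bonds left after this placement
        if remaining == 1:
            points[k] = _closing_point(prev, target, b, rng)
            prev = points[k]
            continue
        placed = None
        for attempt in range(200):
            cand = prev + b * _random_unit(rng)
            if np.linalg.norm(cand - target) <= remaining * b and (
                np.linalg.norm(cand) <= radius or attempt >= 100
            ):
                placed = cand
                break
        if placed is None:
            # deterministic fallback: step straight toward the target
            v = target - prev
            dist = np.linalg.norm(v)
            placed = prev + (b * v / dist if dist >= b
                             else b * _random_unit(rng))
        points[k] = placed
        prev = placed
    return points


def perturb_segment(
    conf: SyntheticConformer,
    segment: tuple[int, int],
    rng: np.random.Generator,
) -> SyntheticConformer:
    """Re-grow one sequence segment, leaving the rest of the chain fixed.

    The segment is replaced by a fresh fixed-bond random walk anchored at
    its boundary residues (a random bridge when both anchors exist), so
    contacts inside and into the segment rewire while residues outside
    keep their coordinates — a synthetic local conformational change.
    An empty segment (lo > hi) returns the conformer unchanged.
    """
    lo, hi = segment
    L = conf.L
    if lo > hi:
        return conf
    if not (1 <= lo and hi <= L):
        raise ContractError(f"segment {segment} outside residues 1..{L}")
    b = conf.bond_length
    radius = conf.confinement_radius
    if lo == 1 and hi == L:
        return generate_chain(L, radius, rng, bond_length=b)
    coords = conf.coords.copy()
    if lo == 1:
        # free backward growth from the right anchor
        anchor = coords[hi]
        walk = np.zeros((hi, 3))
        prev = anchor
        for k in range(hi):
            nxt = None
            for attempt in range(200):
                cand = prev + b * _random_unit(rng)
                if np.linalg.norm(cand) <= radius or attempt >= 100:
                    nxt = cand
                    break
            walk[k] = nxt
            prev = nxt
        coords[lo - 1:hi] = walk[::-1]
    elif hi == L:
        prev = coords[lo - 2]
        for k in range(lo - 1, L):
            nxt = None
            for attempt in range(200):
                cand = prev + b * _random_unit(rng)
                if np.linalg.norm(cand) <= radius or attempt >= 100:
                    nxt = cand
                    break
            coords[k] = nxt
            prev = nxt
    else:
        start = coords[lo - 2]
        target = coords[hi]
        n_points = hi - lo + 1
        coords[lo - 1:hi] = _grow_bridge(start, target, n_points, b, radius, rng)
    max_norm = float(np.linalg.norm(coords, axis=1).max())
    new_radius = max(radius, max_norm)
    if new_radius > radius:
        logger.debug("perturb_segment: confinement radius widened to %.2f A",
                     new_radius)
    return SyntheticConformer(coords=coords, bond_length=b,
                              confinement_radius=new_radius)


def observable_pairs(
    conf: SyntheticConformer,
    sites: SiteSet,
    model: DetectionModel = DetectionModel(),
) -> dict[tuple[int, int], float]:
    """Detection probability of every site pair with |i-j| >= 2."""
    if sites.sites and sites.sites[-1] > conf.L:
        raise ContractError("sites extend beyond the chain")
    probs: dict[tuple[int, int], float] = {}
    s = sites.sites
    for a in range(len(s)):
        for bdx in range(a + 1, len(s)):
            i, j = s[a], s[bdx]
            if j - i < 2:
                continue
            probs[(i, j)] = model.probability(conf.site_distance(i, j))
    return probs


def sample_replicates(
    probmap: dict[tuple[int, int], float],
    n_reps: int,
    draws_per_rep: int,
    model: DetectionModel,
    rng: np.random.Generator,
    sites: SiteSet,
    protein_id: str = "synthetic",
    replicate_prefix: str = "rep",
) -> ReplicateSeries:
    """Draw per-replicate observation tables from a probability map.

    Each replicate draws ``draws_per_rep`` observations with replacement,
    weighted by detection probability (so duplicates occur, as in real
    data); a fraction ``fp_rate`` of draws is replaced by uniformly
    random site pairs.
    """
    if not probmap:
        raise ContractError("probmap must be non-empty")
    pairs = sorted(probmap)
    weights = np.array([probmap[p] for p in pairs], dtype=float)
    if weights.sum() <= 0:
        raise ContractError("all detection probabilities are zero")
    weights = weights / weights.sum()
    all_site_pairs = sorted(
        (sites.sites[a], sites.sites[b])
        for a in range(len(sites.sites))
        for b in range(a + 1, len(sites.sites))
        if sites.sites[b] - sites.sites[a] >= 2
    )
    replicates: list[tuple[str, CrossLinkSet]] = []
    for r in range(n_reps):
        rep_id = f"{replicate_prefix}{r + 1:03d}"
        idx = rng.choice(len(pairs), size=draws_per_rep, replace=True, p=weights)
        observed = [pairs[i] for i in idx]
        if model.fp_rate > 0:
            flips = rng.random(draws_per_rep) < model.fp_rate
            fp_idx = rng.integers(0, len(all_site_pairs), size=draws_per_rep)
            observed = [
                all_site_pairs[fp_idx[k]] if flips[k] else observed[k]
                for k in range(draws_per_rep)
            ]
        counts: dict[tuple[int, int], int] = {}
        for p in observed:
            counts[p] = counts.get(p, 0) + 1
        replicates.append((rep_id, CrossLinkSet(
            protein_id=protein_id,
            pairs={p: counts[p] for p in sorted(counts)},
            provenance={p: (rep_id,) * counts[p] for p in sorted(counts)},
        )))
    return ReplicateSeries(protein_id=protein_id, replicates=tuple(replicates))


def write_tables(series: ReplicateSeries, out_dir: str | Path) -> list[Path]:
    """Write one CSV per replicate in the default parser dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for rep_id, xls in series.replicates:
        rows = []
        for (i, j), mult in sorted(xls.pairs.items()):
            for _ in range(mult):
                rows.append({
                    "protein_a": series.protein_id, "protein_b": series.protein_id,
                    "site_a": i, "site_b": j,
                    "is_decoy": "target", "score": 100.0, "replicate": rep_id,
                })
        path = out_dir / f"{rep_id}.csv"
        pd.DataFrame(rows, columns=["protein_a", "protein_b", "site_a", "site_b",
                                    "is_decoy", "score", "replicate"]
                     ).to_csv(path, index=False)
        paths.append(path)
    return paths


def synthetic_sequence(
    L: int,
    n_sites: int,
    rng: np.random.Generator,
    protein_id: str = "synthetic",
) -> ProteinSequence:
    """A random sequence of length L with exactly n_sites K/S/T/Y residues."""
    if n_sites > L:
        raise ContractError("n_sites cannot exceed L")
    site_positions = set(rng.choice(L, size=n_sites, replace=False).tolist())
    letters_site = sorted(LINKABLE_RESIDUES)
    residues = "".join(
        letters_site[rng.integers(0, len(letters_site))]
        if k in site_positions
        else _NONSITE_RESIDUES[rng.integers(0, len(_NONSITE_RESIDUES))]
        for k in range(L)
    )
    return ProteinSequence(id=protein_id, residues=residues)


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete two-condition synthetic cross-link study."""

    sequence: ProteinSequence
    sites: SiteSet
    conformers: dict[str, SyntheticConformer] = field(compare=False)
    probmaps: dict[str, dict[tuple[int, int], float]] = field(compare=False)
    series: dict[str, ReplicateSeries] = field(compare=False)
    detection: DetectionModel = DetectionModel()

    def pooled(self, condition: str) -> CrossLinkSet:
        from .xl_io import merge_crosslink_sets

        return merge_crosslink_sets(
            xls for _, xls in self.series[condition].replicates
        )

    def write(self, out_dir: str | Path) -> None:
        """Dump tables, FASTA and a JSON ground-truth file."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{self.sequence.id}.fasta").write_text(
            f">{self.sequence.id}\n{self.sequence.residues}\n"
        )
        for condition, series in self.series.items():
            write_tables(series, out_dir / condition)
        truth = {
            "sites": list(self.sites.sites),
            "detection": {"span": self.detection.span, "p_max": self.detection.p_max,
                          "decay_scale": self.detection.decay_scale,
                          "fp_rate": self.detection.fp_rate},
            "conformers": {
                c: conf.coords.tolist() for c, conf in self.conformers.items()
            },
            "probmaps": {
                c: {f"{i}-{j}": p for (i, j), p in sorted(pm.items())}
                for c, pm in self.probmaps.items()
            },
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(truth))


def generate_two_state_study(
    rng: np.random.Generator,
    L: int = 441,
    n_sites: int = 129,
    n_reps: int = 30,
    draws_per_rep: int = 75,
    segment: tuple[int, int] = (150, 350),
    confinement_radius: float = 30.0,
    detection: DetectionModel = DetectionModel(),
    protein_id: str = "synthetic",
) -> SyntheticStudy:
    """Generate the reference two-state study.

    Defaults emulate the measured study conditions: a Tau-sized chain
    (441 residues, 129 linkable sites), 30 technical replicates of 75
    observations each per state, and a large internal segment re-grown
    in the second state.
    """
    sequence = synthetic_sequence(L, n_sites, rng, protein_id=protein_id)
    sites = enumerate_sites(sequence)
    conf_a = generate_chain(L, confinement_radius, rng)
    conf_b = perturb_segment(conf_a, segment, rng)
    prob_a = observable_pairs(conf_a, sites, detection)
    prob_b = observable_pairs(conf_b, sites, detection)
    series_a = sample_replicates(prob_a, n_reps, draws_per_rep, detection, rng,
                                 sites, protein_id=protein_id,
                                 replicate_prefix="a")
    series_b = sample_replicates(prob_b, n_reps, draws_per_rep, detection, rng,
                                 sites, protein_id=protein_id,
                                 replicate_prefix="b")
    return SyntheticStudy(
        sequence=sequence,
        sites=sites,
        conformers={"state_a": conf_a, "state_b": conf_b},
        probmaps={"state_a": prob_a, "state_b": prob_b},
        series={"state_a": series_a, "state_b": series_b},
        detection=detection,
    )
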