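"""Sphere-exclusion diversity (SEDiv), internal diversity and clustering.

SEDiv is the fraction of a molecule set picked as sphere-exclusion
(leader-algorithm) centroids at a Tanimoto distance radius of 0.65 on
Morgan fingerprints.  Because a 0.65 distance threshold broadly corresponds
to molecules sharing a bioactivity class, SEDiv reads as the minimum
fraction of the set needed to explain its bioactivity-relevant chemical
diversity — an interpretation internal diversity (one minus mean pairwise
similarity) lacks, and one that is robust to the heavy-atom-count confound
that depresses mean pairwise similarity for larger molecules.

Conventions fixed here and asserted in the test suite:

* the leader scan visits fingerprints in input order; a molecule becomes a
  centroid iff its distance to every earlier centroid is strictly greater
  than the radius;
* when a subsample size k is configured (the "@1k" convention, k = 1000),
  a seeded random subset is evaluated whenever the input exceeds k;
* internal diversity averages the full pairwise similarity matrix
  including the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from denovoeval.fingerprints import (
    DEFAULT_FP_CONFIG,
    FingerprintConfig,
    _as_matrix,
    fingerprint_matrix,
    tanimoto_matrix,
)

__all__ = [
    "SphereConfig",
    "SCAFFOLD_RADIUS",
    "SedivResult",
    "ClusterAssignment",
    "ScaffoldMetrics",
    "sphere_exclusion_pick",
    "sediv",
    "internal_diversity",
    "cluster_assign",
    "scaffold_metrics",
]

#: Sphere radius (Tanimoto distance) used when clustering Bemis-Murcko
#: scaffolds instead of whole molecules.
SCAFFOLD_RADIUS = 0.2


@dataclass(frozen=True)
class SphereConfig:
    """Sphere-exclusion parameters.

    ``radius`` is a Tanimoto *distance* threshold (0.65 for molecules, 0.2
    for scaffolds); centroids must be strictly more than ``radius`` apart.
    ``subsample_k`` enables the @1k convention: evaluate a seeded random
    subset of that size when the input is larger.
    """

    radius: float = 0.65
    subsample_k: int | None = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.radius < 1.0):
            raise ValueError("radius must be in (0, 1)")
        if self.subsample_k is not None and self.subsample_k <= 0:
            raise ValueError("subsample_k must be positive")


def sphere_exclusion_pick(
    fps: np.ndarray | Sequence[np.ndarray], radius: float
) -> list[int]:
    """Leader-algorithm centroid picking in input order.

    A fingerprint is picked iff its Tanimoto distance to every previously
    picked centroid is strictly greater than ``radius``.  Deterministic for
    a fixed input order.
    """
    F = _as_matrix(fps)
    n = F.shape[0]
    if n == 0:
        raise ValueError("empty fingerprint set")
    # distance > radius  <=>  similarity < 1 - radius; the small epsilon
    # makes boundary equality (distance == radius) exclude a pick robustly
    # under floating point, matching the strict-inequality convention.
    sim_cut = 1.0 - radius - 1e-9
    picked: list[int] = [0]
    centroids = F[[0]].astype(np.int32)
    pops = centroids.sum(axis=1)
    Fi = F.astype(np.int32)
    fpops = Fi.sum(axis=1)
    for i in range(1, n):
        inter = centroids @ Fi[i]
        union = pops + fpops[i] - inter
        sims = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
        if np.all(sims < sim_cut):
            picked.append(i)
            centroids = np.vstack([centroids, Fi[i]])
            pops = np.append(pops, fpops[i])
    return picked


@dataclass(frozen=True)
class SedivResult:
    """SEDiv value plus the provenance of the evaluated set."""

    value: float
    n_input: int
    n_evaluated: int
    n_picked: int
    subsampled: bool
    seed: int | None


def sediv(
    fps: np.ndarray | Sequence[np.ndarray], config: SphereConfig | None = None
) -> SedivResult:
    """Sphere-exclusion diversity: picked centroids / evaluated set size.

    The input should be the valid-and-unique subset of a sample (duplicate
    molecules are a property of the sample, not of the metric; passing raw
    duplicates is allowed and simply lowers the value).  With
    ``subsample_k`` set and more input than k, a seeded random subset of
    size k is evaluated.
    """
    config = config or SphereConfig()
    F = _as_matrix(fps)
    n_input = F.shape[0]
    if n_input == 0:
        raise ValueError("empty fingerprint set")
    subsampled = False
    seed = None
    if config.subsample_k is not None and n_input > config.subsample_k:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(n_input, size=config.subsample_k, replace=False)
        F = F[idx]
        subsampled = True
        seed = config.seed
    picked = sphere_exclusion_pick(F, config.radius)
    n_eval = F.shape[0]
    return SedivResult(
        value=len(picked) / n_eval,
        n_input=n_input,
        n_evaluated=n_eval,
        n_picked=len(picked),
        subsampled=subsampled,
        seed=seed,
    )


def internal_diversity(fps: np.ndarray | Sequence[np.ndarray]) -> float:
    """One minus the mean of the full pairwise similarity matrix.

    The diagonal is included in the mean, so an all-identical set scores
    exactly 0.  Note the known confound: larger molecules set more bits and
    systematically lower pairwise Tanimoto similarity, inflating this
    metric independently of any real diversity difference.
    """
    F = _as_matrix(fps)
    if F.shape[0] == 0:
        raise ValueError("empty fingerprint set")
    return float(1.0 - tanimoto_matrix(F, F).mean())


@dataclass(frozen=True)
class ClusterAssignment:
    """Sphere-exclusion centroids plus nearest-centroid membership.

    ``centroid_indices`` are indices into the input set in pick order;
    ``membership[i]`` is the position (in pick order) of the centroid
    nearest to molecule i, ties broken by earliest-picked centroid;
    ``cluster_sizes`` counts members per centroid and sums to the input
    size.
    """

    centroid_indices: tuple[int, ...]
    membership: np.ndarray
    cluster_sizes: np.ndarray


def cluster_assign(
    fps: np.ndarray | Sequence[np.ndarray], config: SphereConfig | None = None
) -> ClusterAssignment:
    """Pick sphere-exclusion centroids, then assign every molecule to the
    nearest centroid by Tanimoto distance."""
    config = config or SphereConfig(subsample_k=None)
    F = _as_matrix(fps)
    if F.shape[0] == 0:
        raise ValueError("empty fingerprint set")
    picked = sphere_exclusion_pick(F, config.radius)
    sims = tanimoto_matrix(F, F[picked])
    membership = sims.argmax(axis=1)  # argmax returns the first (earliest-picked) tie
    sizes = np.bincount(membership, minlength=len(picked))
    return ClusterAssignment(
        centroid_indices=tuple(picked),
        membership=membership,
        cluster_sizes=sizes,
    )


@dataclass(frozen=True)
class ScaffoldMetrics:
    """Scaffold uniqueness and sphere-exclusion scaffold diversity."""

    uniqueness: float
    diversity: float
    n_records: int
    n_unique_scaffolds: int


def scaffold_metrics(
    scaffold_smiles: Sequence[str],
    config: SphereConfig | None = None,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
) -> ScaffoldMetrics:
    """Scaffold uniqueness and diversity for a set of molecules.

    ``scaffold_smiles`` holds one Bemis-Murcko scaffold string per molecule
    (empty string for acyclic molecules).  Uniqueness is the fraction of
    distinct scaffold strings; diversity is SEDiv over fingerprints of the
    unique scaffolds at the scaffold radius (0.2 distance).  The acyclic
    pseudo-scaffold fingerprints to the all-zero vector, which behaves as a
    single identical-to-itself scaffold.
    """
    if len(scaffold_smiles) == 0:
        raise ValueError("empty scaffold list")
    config = config or SphereConfig(radius=SCAFFOLD_RADIUS)
    unique = list(dict.fromkeys(scaffold_smiles))
    F = fingerprint_matrix(unique, fp_config)
    result = sediv(F, config)
    return ScaffoldMetrics(
        uniqueness=len(unique) / len(scaffold_smiles),
        diversity=result.value,
        n_records=len(scaffold_smiles),
        n_unique_scaffolds=len(unique),
    )
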