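"""Seeded synthetic-data generators for the evaluation toolkit.

Everything the other modules consume can be generated here without any
external download: scaffold-series chemical libraries of controllable
diversity, per-class Gaussian docking-score tables, Bernoulli-sampled SIFt
bit matrices, and generator batch streams whose uniqueness and diversity
either stay stable or collapse over training steps (the overfitting
signature of a reward-hacking agent that resamples known high-reward
molecules).

The scaffold library is built from a curated pool of template cores, each
with one substituent slot, crossed with a pool of small aliphatic
substituents.  The pools were curated so that, under Morgan(2, 1024)
Tanimoto similarity, every pair of molecules sharing a core is closer than
the 0.65-distance sphere radius while molecules from different cores are
farther apart.  A library of k cores therefore has a sphere-exclusion
diversity of exactly k / n by construction — the design value the
diversity tests recover.

Default docking-score moments are realistic values for a dopamine-receptor
docking campaign (actives around -7.45 +/- 1.01, an unoptimized generator
around -6.17 +/- 1.02, a docking-optimized generator around -8.05 +/-
0.95); they parameterize the Gaussian score generator and are not
normative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from denovoeval.sift import SIFT_BITS, SiftMatrix
from denovoeval.standardize import canonicalize

__all__ = [
    "SCAFFOLD_POOL",
    "DECORATION_POOL",
    "LibrarySpec",
    "generate_scaffold_library",
    "ScoreSpec",
    "ClassSpec",
    "generate_labelled_scores",
    "generate_sift_matrix",
    "generate_run_stream",
    "ACTIVE_SCORE_MOMENTS",
    "PRIOR_SCORE_MOMENTS",
    "OPTIMIZED_SCORE_MOMENTS",
]

#: Template cores; "({R})" marks the substituent slot (removed for the
#: unsubstituted parent).  Curated so distinct cores stay beyond Tanimoto
#: distance 0.65 for every decoration in DECORATION_POOL, while molecules
#: sharing a core stay within it.
SCAFFOLD_POOL: tuple[str, ...] = (
    "CCn1nc(C2CCC(C)CC2)cc1COc1ccnc({R})c1",
    "CN1CCC(Oc2ccccc2C(=O)Nc2ccc({R})cn2)CC1",
    "O=S(=O)(c1ccc2c(c1)CCN2C({R}))N1CCOCC1",
    "c1ccc(-c2nc(N3CCN(CC({R}))CC3)c3ccccc3n2)cc1",
    "O=C1N(Cc2ccc({R})cc2)CCN1c1cccc(C(F)(F)F)c1",
    "CC(=O)Nc1nnc(SCC(=O)Nc2ccc({R})c(C)c2)s1",
    "CSc1ncccc1-c1csc(C2CC(CC({R}))CO2)n1",
    "Clc1ccc2nc(N3CCC(CN({R})C)CC3)ccc2c1",
)

_DECO_HEADS = (
    "", "C", "CC", "CCC", "C(C)", "CC(C)", "O", "OC", "OCC", "N", "NC",
    "N(C)", "CN", "CO", "CCN", "CCO", "OCC(C)", "COC",
)
_DECO_TAILS = ("[H]", "C", "F", "Cl", "O", "N", "C#N", "C(F)(F)F", "CC", "CO")


def _build_decoration_pool() -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for head in _DECO_HEADS:
        for tail in _DECO_TAILS:
            deco = (head + ("" if tail == "[H]" else tail)) or "[H]"
            seen.setdefault(deco)
    return tuple(seen)


#: Small substituents ("[H]" = unsubstituted parent) attached at the slot.
DECORATION_POOL: tuple[str, ...] = _build_decoration_pool()

# Realistic docking-score moments (mean, sd) for the Gaussian generator.
ACTIVE_SCORE_MOMENTS = (-7.45, 1.01)
PRIOR_SCORE_MOMENTS = (-6.17, 1.02)
OPTIMIZED_SCORE_MOMENTS = (-8.05, 0.95)


def _attach(template: str, decoration: str) -> str:
    if decoration == "[H]":
        return template.replace("({R})", "")
    return template.replace("{R}", decoration)


@dataclass(frozen=True)
class LibrarySpec:
    """Scaffold-series library: n_scaffolds cores x n_decorations analogues.

    The first ``n_scaffolds`` templates of the pool are used (keeping the
    curated mutual-distance guarantee); decorations are drawn per scaffold
    with a seeded shuffle of the decoration pool, deduplicated on canonical
    SMILES.  Same spec + seed reproduces the library byte for byte.
    """

    n_scaffolds: int = 5
    n_decorations_per_scaffold: int = 100
    scaffold_pool: tuple[str, ...] = SCAFFOLD_POOL
    decoration_pool: tuple[str, ...] = DECORATION_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scaffold_pool or not self.decoration_pool:
            raise ValueError("pools must be non-empty")
        if self.n_scaffolds < 1 or self.n_decorations_per_scaffold < 1:
            raise ValueError("counts must be >= 1")
        if self.n_scaffolds > len(self.scaffold_pool):
            raise ValueError("n_scaffolds exceeds the scaffold pool")
        for template in self.scaffold_pool:
            if "({R})" not in template:
                raise ValueError(f"template without substituent slot: {template!r}")


def generate_scaffold_library(spec: LibrarySpec) -> list[tuple[str, str]]:
    """Enumerate (id, SMILES) records for a scaffold-series library.

    Every emitted SMILES parses; within one scaffold the records are
    deduplicated on canonical SMILES.  Raises if the decoration pool
    cannot supply the requested number of unique, valid analogues.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    for s_idx in range(spec.n_scaffolds):
        template = spec.scaffold_pool[s_idx]
        order = rng.permutation(len(spec.decoration_pool))
        seen: set[str] = set()
        emitted = 0
        for d_idx in order:
            if emitted >= spec.n_decorations_per_scaffold:
                break
            smiles = _attach(template, spec.decoration_pool[d_idx])
            canon = canonicalize(smiles)
            if canon is None or canon in seen:
                continue
            seen.add(canon)
            records.append((f"S{s_idx}_D{d_idx}", smiles))
            emitted += 1
        if emitted < spec.n_decorations_per_scaffold:
            raise ValueError(
                f"decoration pool yields only {emitted} unique analogues for "
                f"scaffold {s_idx} (requested {spec.n_decorations_per_scaffold})"
            )
    return records


@dataclass(frozen=True)
class ClassSpec:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class ScoreSpec:
    """Per-class Gaussian docking-score table specification."""

    classes: tuple[ClassSpec, ...] = (
        ClassSpec("active", 2000, *ACTIVE_SCORE_MOMENTS),
        ClassSpec("inactive", 2000, *PRIOR_SCORE_MOMENTS),
    )
    seed: int = 0


def generate_labelled_scores(spec: ScoreSpec) -> pd.DataFrame:
    """Labelled Gaussian score draws as a DataFrame (id, label, score)."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for cls in spec.classes:
        scores = rng.normal(cls.mean, cls.sd, size=cls.n)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{cls.label}_{i}" for i in range(cls.n)],
                    "label": cls.label,
                    "score": scores,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_sift_matrix(
    n_molecules: int,
    residues: Sequence[str],
    bit_probabilities: Sequence[float] | np.ndarray,
    seed: int = 0,
) -> SiftMatrix:
    """Independent Bernoulli SIFt bits of shape (n_molecules, residues, 9).

    ``bit_probabilities`` is either a length-9 vector (shared by all
    residues, in :data:`~denovoeval.sift.SIFT_BITS` order) or a
    (len(residues), 9) matrix of per-residue probabilities.
    """
    probs = np.asarray(bit_probabilities, dtype=float)
    if probs.ndim == 1:
        probs = np.tile(probs, (len(residues), 1))
    if probs.shape != (len(residues), 9):
        raise ValueError("bit_probabilities must be length 9 or (n_residues, 9)")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bits = rng.random((n_molecules, len(residues), 9)) < probs[None, :, :]
    ids = [f"mol_{i}" for i in range(n_molecules)]
    return SiftMatrix(molecule_ids=ids, residues=list(residues), bits=bits)


def generate_run_stream(
    n_steps: int,
    batch_size: int = 64,
    profile: str = "stable",
    seed: int = 0,
    library_spec: LibrarySpec | None = None,
    n_collapse_series: int = 2,
) -> Iterator[tuple[int, list[str]]]:
    """Ordered (step, SMILES batch) stream emulating a training generator.

    ``stable`` draws every batch uniformly from the whole scaffold library,
    so per-interval uniqueness and diversity stay flat up to sampling
    noise.  ``collapsing`` linearly shrinks the set of scaffold series the
    generator samples from — down to ``n_collapse_series`` by the final
    step — so the batches increasingly resample a narrow sub-library and
    uniqueness and sphere-exclusion diversity decline monotonically in
    expectation, the signature of an agent overfitting its scoring
    function.
    """
    if n_steps < 1 or batch_size < 1:
        raise ValueError("n_steps and batch_size must be >= 1")
    if profile not in ("stable", "collapsing"):
        raise ValueError(f"unknown profile: {profile!r}")
    spec = library_spec or LibrarySpec(
        n_scaffolds=len(SCAFFOLD_POOL), n_decorations_per_scaffold=100, seed=seed
    )
    records = generate_scaffold_library(spec)
    per_series = spec.n_decorations_per_scaffold
    n_series = spec.n_scaffolds
    n_collapse = min(n_collapse_series, n_series)
    smiles = [s for _, s in records]
    rng = np.random.default_rng(seed)
    for step in range(1, n_steps + 1):
        if profile == "stable" or n_steps == 1:
            avail = n_series
        else:
            frac = (step - 1) / (n_steps - 1)
            avail = int(round(n_series - frac * (n_series - n_collapse)))
            avail = max(n_collapse, avail)
        pool_size = avail * per_series
        idx = rng.integers(0, pool_size, size=batch_size)
        yield step, [smiles[i] for i in idx]
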