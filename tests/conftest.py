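"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from denovoeval.synthetic import LibrarySpec, generate_scaffold_library


def naive_tanimoto(a, b) -> float:
    """Plain-Python Tanimoto on boolean sequences (oracle)."""
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return 1.0 if union == 0 else inter / union


def naive_leader_pick(fps, radius) -> list[int]:
    """O(N^2) leader-algorithm scan in input order (oracle)."""
    picked: list[int] = []
    for i, fp in enumerate(fps):
        # strictly-greater-than-radius separation; epsilon resolves float
        # ties at the boundary the same way the implementation declares
        if all(1.0 - naive_tanimoto(fp, fps[j]) > radius + 1e-9 for j in picked):
            picked.append(i)
    return picked


def random_fp_set(rng: np.random.Generator, n: int, nbits: int = 64, density: float = 0.3):
    return rng.random((n, nbits)) < density


@pytest.fixture(scope="session")
def design_library():
    """5 mutually distant scaffold series x 100 near-duplicate analogues."""
    spec = LibrarySpec(n_scaffolds=5, n_decorations_per_scaffold=100, seed=7)
    return generate_scaffold_library(spec)


@pytest.fixture(scope="session")
def design_library_fps(design_library):
    from denovoeval.fingerprints import fingerprint_matrix

    return fingerprint_matrix([s for _, s in design_library])
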