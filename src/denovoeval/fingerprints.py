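"""Morgan fingerprints and Tanimoto similarity.

Fingerprints are binary Morgan (circular) fingerprints, radius 2 folded to
1024 bits by default — the configuration used for every similarity-based
metric in this package.  In memory a fingerprint is a boolean numpy vector;
a set of fingerprints is an (n, nbits) boolean matrix, which keeps the
pairwise-similarity math as integer matrix products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "FingerprintConfig",
    "morgan_fingerprint",
    "fingerprint_matrix",
    "popcount",
    "tanimoto",
    "tanimoto_matrix",
    "snn_profile",
    "SnnProfile",
    "save_fingerprints",
    "load_fingerprints",
]


@dataclass(frozen=True)
class FingerprintConfig:
    """Morgan fingerprint parameters: bond radius and folded length."""

    radius: int = 2
    nbits: int = 1024

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.nbits <= 0 or (self.nbits & (self.nbits - 1)) != 0:
            raise ValueError("nbits must be a positive power of two")


DEFAULT_FP_CONFIG = FingerprintConfig()

_generators: dict[FingerprintConfig, object] = {}


def _generator(config: FingerprintConfig):
    gen = _generators.get(config)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=config.radius, fpSize=config.nbits
        )
        _generators[config] = gen
    return gen


def morgan_fingerprint(
    molecule: str | Chem.Mol, config: FingerprintConfig = DEFAULT_FP_CONFIG
) -> np.ndarray:
    """Binary Morgan fingerprint as a boolean vector of length ``nbits``.

    Accepts an RDKit Mol or a SMILES string; stereochemistry is stripped so
    any spelling of the same molecule maps to the same bit vector.  An
    empty molecule ('' parses to zero atoms) yields the all-zero vector.
    Raises ValueError on unparseable input.
    """
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"invalid molecule: {molecule!r}")
    else:
        mol = Chem.Mol(molecule)
    Chem.RemoveStereochemistry(mol)
    fp = _generator(config).GetFingerprint(mol)
    return np.array(fp, dtype=bool)


def fingerprint_matrix(
    molecules: Iterable[str | Chem.Mol], config: FingerprintConfig = DEFAULT_FP_CONFIG
) -> np.ndarray:
    """Stack fingerprints of many molecules into an (n, nbits) bool matrix."""
    fps = [morgan_fingerprint(m, config) for m in molecules]
    if not fps:
        return np.zeros((0, config.nbits), dtype=bool)
    return np.vstack(fps)


def popcount(fp: np.ndarray) -> int:
    return int(np.count_nonzero(fp))


def _as_matrix(fps: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    arr = np.asarray(fps, dtype=bool)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1].

    Two all-zero fingerprints are defined as identical (1.0): they encode
    the same (empty) feature set, and this avoids 0/0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(
    a: np.ndarray | Sequence[np.ndarray], b: np.ndarray | Sequence[np.ndarray]
) -> np.ndarray:
    """All-pairs Tanimoto similarity between two fingerprint sets.

    Returns an (len(a), len(b)) float matrix.  Pairs of all-zero
    fingerprints score 1.0, matching :func:`tanimoto`.
    """
    A = _as_matrix(a).astype(np.int32)
    B = _as_matrix(b).astype(np.int32)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    inter = A @ B.T
    pa = A.sum(axis=1)[:, None]
    pb = B.sum(axis=1)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return sim


@dataclass(frozen=True)
class SnnProfile:
    """Per-query maximum similarity to a reference set, plus the mean."""

    per_query: np.ndarray
    mean: float


def snn_profile(
    query: np.ndarray | Sequence[np.ndarray], reference: np.ndarray | Sequence[np.ndarray]
) -> SnnProfile:
    """Single-nearest-neighbour similarity of each query to a reference set."""
    R = _as_matrix(reference)
    if R.shape[0] == 0:
        raise ValueError("reference set must be non-empty")
    Q = _as_matrix(query)
    best = tanimoto_matrix(Q, R).max(axis=1)
    return SnnProfile(per_query=best, mean=float(best.mean()))


def save_fingerprints(
    path: str | Path,
    fps: np.ndarray,
    config: FingerprintConfig = DEFAULT_FP_CONFIG,
    ids: Sequence[str] | None = None,
) -> None:
    """Cache a fingerprint matrix (packed bits) with a JSON header sidecar."""
    path = Path(path)
    fps = _as_matrix(fps)
    np.save(path.with_suffix(".npy"), np.packbits(fps, axis=1))
    header = {
        "nbits": config.nbits,
        "radius": config.radius,
        "n": int(fps.shape[0]),
        "ids": list(ids) if ids is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(header))


def load_fingerprints(path: str | Path) -> tuple[np.ndarray, FingerprintConfig, list[str] | None]:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    packed = np.load(path.with_suffix(".npy"))
    fps = np.unpackbits(packed, axis=1)[:, : header["nbits"]].astype(bool)
    config = FingerprintConfig(radius=header["radius"], nbits=header["nbits"])
    return fps, config, header["ids"]
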