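"""Structural interaction fingerprint (SIFt) collapse and differential analysis.

A SIFt describes a docked ligand pose as one 9-bit vector per protein
residue, with non-exclusive interaction bits: any contact, backbone,
sidechain, polar, hydrophobic, hydrogen-bond acceptor, hydrogen-bond donor,
aromatic, charged.  For interpretable downstream analysis the nine raw
bits are collapsed to a single exclusive interaction type per residue by a
fixed precedence hierarchy: charged hydrogen-bond donor/acceptor, then
hydrogen-bond donor/acceptor, then charged, aromatic, hydrophobic, polar.
A vector with only the location bits (any contact / backbone / sidechain)
set collapses to ``contact_only``; the all-zero vector to ``none``.  When
both hydrogen-bond bits are set, donor outranks acceptor — a declared
convention for an ambiguity the hierarchy itself leaves open.

Frequencies of collapsed types per residue, compared between a dataset and
a baseline generator, highlight which residue interactions a scoring
function drives toward or away from; changes of at least 10 percentage
points (by default) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIFT_BITS",
    "EXCLUSIVE_TYPES",
    "collapse_sift",
    "SiftMatrix",
    "sift_frequencies",
    "sift_delta",
    "SiftDelta",
]

#: Fixed order of the nine raw interaction bits.
SIFT_BITS = (
    "any_contact",
    "backbone",
    "sidechain",
    "polar",
    "hydrophobic",
    "hb_acceptor",
    "hb_donor",
    "aromatic",
    "charged",
)

#: Exclusive interaction types, in precedence order (plus the two fallbacks).
EXCLUSIVE_TYPES = (
    "charged_hbd",
    "charged_hba",
    "hbd",
    "hba",
    "charged",
    "aromatic",
    "hydrophobic",
    "polar",
    "contact_only",
    "none",
)

_BIT_INDEX = {name: i for i, name in enumerate(SIFT_BITS)}


def collapse_sift(bits: Sequence[int] | Mapping[str, bool] | np.ndarray) -> str:
    """Collapse one raw 9-bit vector to its exclusive interaction type.

    Accepts a length-9 sequence in :data:`SIFT_BITS` order or a mapping
    from bit name to boolean.  Total over all 512 patterns: every pattern
    maps to exactly one type.
    """
    if isinstance(bits, Mapping):
        vec = np.array([bool(bits.get(name, False)) for name in SIFT_BITS])
    else:
        vec = np.asarray(bits).astype(bool)
        if vec.shape != (9,):
            raise ValueError("expected a 9-element bit vector")
    charged = vec[_BIT_INDEX["charged"]]
    hbd = vec[_BIT_INDEX["hb_donor"]]
    hba = vec[_BIT_INDEX["hb_acceptor"]]
    if charged and hbd:
        return "charged_hbd"
    if charged and hba:
        return "charged_hba"
    if hbd:
        return "hbd"
    if hba:
        return "hba"
    if charged:
        return "charged"
    if vec[_BIT_INDEX["aromatic"]]:
        return "aromatic"
    if vec[_BIT_INDEX["hydrophobic"]]:
        return "hydrophobic"
    if vec[_BIT_INDEX["polar"]]:
        return "polar"
    if vec.any():  # only location bits (any_contact/backbone/sidechain) set
        return "contact_only"
    return "none"


@dataclass
class SiftMatrix:
    """Molecules x residues x 9 raw interaction bits.

    ``bits`` has shape (n_molecules, n_residues, 9) in :data:`SIFT_BITS`
    order; residue labels are free strings (e.g. "D114").
    """

    molecule_ids: list[str]
    residues: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        expected = (len(self.molecule_ids), len(self.residues), 9)
        if self.bits.shape != expected:
            raise ValueError(f"bits shape {self.bits.shape} != {expected}")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def collapse(self) -> pd.DataFrame:
        """Exclusive type per (molecule, residue) as a string DataFrame."""
        types = np.empty((self.n_molecules, len(self.residues)), dtype=object)
        for i in range(self.n_molecules):
            for j in range(len(self.residues)):
                types[i, j] = collapse_sift(self.bits[i, j])
        return pd.DataFrame(types, index=self.molecule_ids, columns=self.residues)

    def to_tsv(self, path: str | Path) -> None:
        """One row per (molecule, residue), nine bit columns."""
        rows = []
        for i, mid in enumerate(self.molecule_ids):
            for j, res in enumerate(self.residues):
                rows.append([mid, res, *self.bits[i, j].astype(int)])
        df = pd.DataFrame(rows, columns=["molecule", "residue", *SIFT_BITS])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiftMatrix":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("molecule", "residue", *SIFT_BITS) if c not in df.columns]
        if missing:
            raise ValueError(f"SIFt TSV missing columns: {missing}")
        mol_ids = list(dict.fromkeys(df["molecule"].astype(str)))
        residues = list(dict.fromkeys(df["residue"].astype(str)))
        bits = np.zeros((len(mol_ids), len(residues), 9), dtype=bool)
        mi = {m: i for i, m in enumerate(mol_ids)}
        ri = {r: j for j, r in enumerate(residues)}
        for _, row in df.iterrows():
            bits[mi[str(row["molecule"])], ri[str(row["residue"])]] = [
                bool(row[b]) for b in SIFT_BITS
            ]
        return cls(molecule_ids=mol_ids, residues=residues, bits=bits)


def sift_frequencies(matrix: SiftMatrix) -> pd.DataFrame:
    """Per-residue frequency of each exclusive interaction type.

    Returns a DataFrame (residue x type); each row sums to 1 over the
    types, ``none`` included.
    """
    if matrix.n_molecules == 0:
        raise ValueError("empty SIFt matrix")
    collapsed = matrix.collapse()
    freq = pd.DataFrame(0.0, index=matrix.residues, columns=list(EXCLUSIVE_TYPES))
    for res in matrix.residues:
        counts = collapsed[res].value_counts()
        for t, c in counts.items():
            freq.loc[res, t] = c / matrix.n_molecules
    return freq


@dataclass
class SiftDelta:
    """Frequency differences against a baseline with change flags.

    ``delta`` holds f - baseline per (residue, type) cell in frequency
    units (percentage points / 100).  ``flags`` marks 'increase' where
    delta >= +threshold and 'decrease' where delta <= -threshold ('' else).
    With ``relative=True`` the delta is instead the ratio change
    (f - baseline) / baseline where the baseline frequency is non-zero.
    """

    delta: pd.DataFrame
    flags: pd.DataFrame
    threshold: float
    relative: bool


def sift_delta(
    frequencies: pd.DataFrame,
    baseline: pd.DataFrame,
    flag_threshold: float = 0.10,
    relative: bool = False,
) -> SiftDelta:
    """Baseline-relative frequency change per residue and interaction type."""
    if not frequencies.index.equals(baseline.index) or not frequencies.columns.equals(
        baseline.columns
    ):
        raise ValueError("frequency tables must share residue/type axes")
    if relative:
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (frequencies - baseline) / baseline
        delta = delta.where(baseline != 0, np.nan)
    else:
        delta = frequencies - baseline
    # inclusive threshold; tiny tolerance so 0.50 - 0.40 still counts as 0.10
    tol = 1e-12
    flags = pd.DataFrame("", index=delta.index, columns=delta.columns)
    flags = flags.mask(delta >= flag_threshold - tol, "increase")
    flags = flags.mask(delta <= -(flag_threshold - tol), "decrease")
    return SiftDelta(delta=delta, flags=flags, threshold=flag_threshold, relative=relative)


def delta_heatmap(delta: SiftDelta, path: str | Path) -> None:
    """Write a simple residue-by-type heatmap of frequency deltas."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = delta.delta.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * values.shape[1]), max(3, 0.3 * values.shape[0]))
    )
    vmax = np.nanmax(np.abs(values)) or 1.0
    im = ax.imshow(values, cmap="RdYlGn", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(values.shape[1]), delta.delta.columns, rotation=90)
    ax.set_yticks(range(values.shape[0]), delta.delta.index)
    fig.colorbar(im, ax=ax, label="frequency delta")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
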