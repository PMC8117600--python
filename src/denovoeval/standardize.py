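"""SMILES parsing, canonicalization, neutralization and library curation.

The pipeline mirrors the common curation applied to drug-like training sets
for SMILES-based generative models: keep the largest fragment, neutralize
protonatable/deprotonatable atoms instead of discarding charged molecules,
strip stereochemistry, canonicalize, and apply drug-likeness filters
(molecular weight, rotatable bonds, logP, element whitelist, ring size,
medicinal-chemistry and PAINS substructure alerts).  A blocklist step
removes molecules whose canonical SMILES matches a reference set of known
actives, so that generators trained on the curated set cannot trivially
reproduce them.

One canonical dialect is used everywhere: RDKit canonical SMILES with
stereochemistry removed.  Every cross-set string comparison in this package
(novelty, recovery, blocklist matching) relies on that single dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

# Charged atoms with an (attachable) proton that are not counter-charged
# internally: +1 centres carrying at least one H, or -1 centres not adjacent
# to a positive atom (keeps zwitterion-internal ylides etc. untouched).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)

# Small default medicinal-chemistry alert list: reactive or unstable groups
# commonly excluded from screening libraries.  Configurable via FilterConfig.
DEFAULT_MCF_SMARTS: tuple[str, ...] = (
    "[N;!$(N-C=O)]=[N;!$(N-C=O)]",  # azo
    "C(=O)Cl",                      # acyl chloride
    "[S;D2](-[#6])-[S;D2]-[#6]",    # disulfide
    "[C;!R]=[C;!R]-[C;!R]=[C;!R]",  # acyclic conjugated diene
    "[N+](=O)[O-]",                 # nitro
    "C1OC1",                        # epoxide
    "C1NC1",                        # aziridine
    "[CX3](=O)[OX2][CX3](=O)",      # anhydride
    "[#6]S(=O)(=O)[F,Cl,Br,I]",     # sulfonyl halide
    "[CX3](=[OX1])[F,Cl,Br,I]",     # acyl halide (generic)
    "N=C=O",                        # isocyanate
    "N=C=S",                        # isothiocyanate
)

DEFAULT_ALLOWED_ELEMENTS: frozenset[str] = frozenset(
    {"C", "N", "S", "O", "F", "Cl", "Br", "H"}
)

FILTER_RULES = (
    "molecular_weight",
    "rotatable_bonds",
    "logp",
    "elements",
    "ring_size",
    "mcf",
    "pains",
)

_pains_catalog: FilterCatalog | None = None


def _get_pains_catalog() -> FilterCatalog:
    global _pains_catalog
    if _pains_catalog is None:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        _pains_catalog = FilterCatalog(params)
    return _pains_catalog


@dataclass(frozen=True)
class FilterConfig:
    """Property and substructure filters for drug-like library curation.

    Defaults select small drug-like molecules: molecular weight 250-350 Da,
    at most 8 rotatable bonds, Crippen logP at most 3.5, organic elements
    only, no rings larger than 8 atoms, plus medicinal-chemistry and PAINS
    substructure alerts.
    """

    mw_min: float = 250.0
    mw_max: float = 350.0
    max_rot_bonds: int = 8
    max_logp: float = 3.5
    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS
    max_ring_size: int = 8
    apply_mcf: bool = True
    apply_pains: bool = True
    mcf_smarts: tuple[str, ...] = DEFAULT_MCF_SMARTS

    def __post_init__(self) -> None:
        if self.mw_min > self.mw_max:
            raise ValueError("mw_min must not exceed mw_max")
        if self.max_rot_bonds < 0 or self.max_ring_size < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_rules: tuple[str, ...] = ()


@dataclass
class MoleculeRecord:
    """One input molecule after standardization.

    ``canonical_smiles`` is None exactly when the raw SMILES failed to
    parse; ``scaffold_smiles`` is the Bemis-Murcko framework (empty string
    for acyclic molecules, None for invalid input).
    """

    id: str
    raw_smiles: str
    canonical_smiles: str | None = None
    valid: bool = False
    scaffold_smiles: str | None = None
    filter_verdict: FilterVerdict | None = None


def _mol_from_input(molecule: str | Chem.Mol) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"invalid molecule: {molecule!r}")
    return mol


def canonicalize(smiles: str) -> str | None:
    """Return the canonical, stereochemistry-free SMILES, or None.

    Unparseable input yields None rather than raising: invalid strings are
    an expected outcome when scoring generator output.  The result is
    idempotent under re-canonicalization.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with the most heavy atoms (salt stripping)."""
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def neutralize(molecule: str | Chem.Mol) -> Chem.Mol:
    """Zero formal charges by adding/removing protons where possible.

    Quaternary nitrogens and other centres without an attachable/removable
    proton are left unchanged, as are internally compensated zwitterionic
    pairs.  The heavy-atom skeleton is never modified.  Raises ValueError
    on invalid input (caller bug by contract).
    """
    mol = Chem.Mol(_mol_from_input(molecule))
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        # -1 centre gains a proton; +1 centre loses one.
        atom.SetNumExplicitHs(max(0, h_count - charge))
        atom.SetNoImplicit(True)
        atom.UpdatePropertyCache()
    if matches:
        Chem.SanitizeMol(mol)
    return mol


def _ring_sizes(mol: Chem.Mol) -> list[int]:
    return [len(ring) for ring in mol.GetRingInfo().AtomRings()]


def apply_filters(molecule: str | Chem.Mol, config: FilterConfig | None = None) -> FilterVerdict:
    """Evaluate all curation rules; the verdict names every failed rule."""
    config = config or FilterConfig()
    mol = _mol_from_input(molecule)
    failed: list[str] = []

    mw = Descriptors.MolWt(mol)
    if not (config.mw_min <= mw <= config.mw_max):
        failed.append("molecular_weight")
    if rdMolDescriptors.CalcNumRotatableBonds(mol) > config.max_rot_bonds:
        failed.append("rotatable_bonds")
    if Crippen.MolLogP(mol) > config.max_logp:
        failed.append("logp")
    if any(a.GetSymbol() not in config.allowed_elements for a in mol.GetAtoms()):
        failed.append("elements")
    if any(size > config.max_ring_size for size in _ring_sizes(mol)):
        failed.append("ring_size")
    if config.apply_mcf:
        for smarts in config.mcf_smarts:
            patt = Chem.MolFromSmarts(smarts)
            if patt is not None and mol.HasSubstructMatch(patt):
                failed.append("mcf")
                break
    if config.apply_pains and _get_pains_catalog().HasMatch(mol):
        failed.append("pains")

    return FilterVerdict(passed=not failed, failed_rules=tuple(failed))


def bemis_murcko_scaffold(molecule: str | Chem.Mol) -> str:
    """Canonical SMILES of the Bemis-Murcko framework ('' if acyclic)."""
    mol = _mol_from_input(molecule)
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    Chem.RemoveStereochemistry(scaffold)
    return Chem.MolToSmiles(scaffold)


def remove_blocklist(
    records: Sequence[MoleculeRecord], blocklist_smiles: Iterable[str]
) -> list[MoleculeRecord]:
    """Drop records whose canonical SMILES matches the canonicalized blocklist.

    Blocklist entries are re-canonicalized here, so any SMILES spelling of a
    blocked molecule matches.  Input order is preserved.
    """
    blocked = {c for c in (canonicalize(s) for s in blocklist_smiles) if c is not None}
    return [r for r in records if r.canonical_smiles not in blocked]


def standardize_record(
    mol_id: str,
    raw_smiles: str,
    config: FilterConfig | None = None,
) -> MoleculeRecord:
    """Run the full pipeline for one molecule.

    Parse -> largest fragment -> neutralize -> strip stereo + canonicalize
    -> scaffold -> filters.  Invalid input yields a record with
    ``valid=False`` and no verdict.
    """
    record = MoleculeRecord(id=mol_id, raw_smiles=raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles) if isinstance(raw_smiles, str) else None
    if mol is None:
        return record
    mol = largest_fragment(mol)
    try:
        mol = neutralize(mol)
    except Exception:
        return record
    Chem.RemoveStereochemistry(mol)
    record.canonical_smiles = Chem.MolToSmiles(mol)
    record.valid = True
    record.scaffold_smiles = bemis_murcko_scaffold(mol)
    record.filter_verdict = apply_filters(mol, config)
    return record


def standardize_library(
    records: Iterable[tuple[str, str] | str],
    config: FilterConfig | None = None,
    blocklist_smiles: Iterable[str] | None = None,
) -> list[MoleculeRecord]:
    """Standardize a library of (id, smiles) pairs or bare SMILES strings."""
    out: list[MoleculeRecord] = []
    for i, entry in enumerate(records):
        if isinstance(entry, str):
            mol_id, smiles = f"mol{i}", entry
        else:
            mol_id, smiles = entry
        out.append(standardize_record(mol_id, smiles, config))
    if blocklist_smiles is not None:
        out = remove_blocklist(out, blocklist_smiles)
    return out


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read 'SMILES[\\tID]' lines; '#' comment lines ignored."""
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            out.append((mol_id, smiles))
    return out


def write_smiles_file(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.valid:
                fh.write(f"{r.canonical_smiles}\t{r.id}\n")


def write_audit_csv(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "raw", "canonical", "valid", "failed_rules"])
        for r in records:
            failed = ";".join(r.filter_verdict.failed_rules) if r.filter_verdict else ""
            writer.writerow([r.id, r.raw_smiles, r.canonical_smiles or "", r.valid, failed])
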