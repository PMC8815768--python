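"""SMILES chemistry layer: canonicalization, validity, molecular properties.

All chemistry goes through RDKit. A string is *valid* iff RDKit can parse and
sanitize it; molecular identity (for uniqueness/novelty counting) is canonical
SMILES equality. Four properties are exposed: logP (Crippen octanol-water
partition coefficient), SAS (synthetic accessibility, 1 easy .. 10 hard),
TPSA (topological polar surface area, A^2) and QED (drug-likeness in [0, 1]).
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Iterable

from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import Crippen, QED, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

# synthetic-accessibility scorer ships in RDKit's contrib tree
sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402

PROPERTY_NAMES = ("logP", "SAS", "TPSA", "QED")


@dataclass
class MoleculeRecord:
    """A molecule as seen by the pipeline.

    ``is_valid`` is true iff ``canonical`` is present; ``properties`` holds any
    of logP / SAS / TPSA / QED that have been computed for the molecule.
    """

    smiles: str
    canonical: str | None = None
    is_valid: bool = False
    properties: dict[str, float] = field(default_factory=dict)


def canonicalize(smiles: str) -> MoleculeRecord:
    """Parse ``smiles`` and return a record with RDKit's canonical form.

    Never raises on chemically invalid input: the record simply comes back
    with ``is_valid=False`` and no canonical SMILES.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return MoleculeRecord(smiles=smiles if isinstance(smiles, str) else "")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return MoleculeRecord(smiles=smiles)
    return MoleculeRecord(smiles=smiles, canonical=Chem.MolToSmiles(mol), is_valid=True)


def _mol(record: MoleculeRecord) -> Chem.Mol:
    if not record.is_valid or record.canonical is None:
        raise ValueError(f"cannot compute properties of invalid SMILES {record.smiles!r}")
    mol = Chem.MolFromSmiles(record.canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always reparse
        raise ValueError(f"canonical SMILES failed to reparse: {record.canonical!r}")
    return mol


_PROPERTY_FN = {
    "logP": Crippen.MolLogP,
    "SAS": sascorer.calculateScore,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "QED": QED.qed,
}


def compute_property(record: MoleculeRecord, which: str) -> float:
    """Compute one of logP / SAS / TPSA / QED and cache it on the record."""
    if which not in _PROPERTY_FN:
        raise KeyError(f"unknown property {which!r}; expected one of {PROPERTY_NAMES}")
    value = float(_PROPERTY_FN[which](_mol(record)))
    record.properties[which] = value
    return value


def binarize_property(values: Iterable[float], threshold: float | str = "median") -> list[int]:
    """Threshold property values into {0, 1} labels; label 1 iff value > threshold.

    ``threshold="median"`` resolves to the sample median, so an all-equal list
    maps to all zeros (nothing strictly exceeds its own median).
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("binarize_property requires a non-empty list")
    if threshold == "median":
        import statistics

        cut = statistics.median(vals)
    else:
        cut = float(threshold)
    return [1 if v > cut else 0 for v in vals]


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    return mol.GetNumHeavyAtoms()


def read_smiles_file(path: str | os.PathLike) -> list[str]:
    """Read one-SMILES-per-line text; '#' comments and blank lines are skipped.

    Only the first whitespace/tab-separated column is used, so files carrying
    extra property columns load unchanged.
    """
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split()[0])
    return out


def write_smiles_file(path: str | os.PathLike, smiles: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
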