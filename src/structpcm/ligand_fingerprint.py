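"""Circular (ECFP6) fingerprints for ligands.

Small molecules are encoded as 2048-bit binary Morgan fingerprints of bond
radius 3 — the ECFP6 convention — via RDKit.  The binary folded form is
used as-is as model input; no standardization or salt stripping is applied,
though multi-fragment SMILES are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

ECFP6_N_BITS = 2048
ECFP6_RADIUS = 3

_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=ECFP6_RADIUS, fpSize=ECFP6_N_BITS
)


@dataclass(frozen=True)
class MoleculeRecord:
    molecule_id: str
    smiles: str


@dataclass(frozen=True)
class MoleculeFingerprint:
    molecule_id: str
    on_bits: frozenset[int]
    n_bits: int = ECFP6_N_BITS

    def __post_init__(self) -> None:
        if self.on_bits and not all(0 <= b < self.n_bits for b in self.on_bits):
            raise ValueError("on-bit index out of range")

    @property
    def popcount(self) -> int:
        return len(self.on_bits)


def ecfp6(record: MoleculeRecord) -> MoleculeFingerprint:
    """2048-bit radius-3 Morgan fingerprint of a SMILES string.

    Deterministic and invariant to the SMILES spelling of the molecule.
    Unparseable SMILES raise with the molecule id in the message.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(
            f"molecule {record.molecule_id!r}: unparseable SMILES {record.smiles!r}"
        )
    if "." in record.smiles:
        logger.warning(
            "molecule %s: multi-fragment SMILES fingerprinted as given",
            record.molecule_id,
        )
    fp = _generator.GetFingerprint(mol)
    return MoleculeFingerprint(
        molecule_id=record.molecule_id,
        on_bits=frozenset(fp.GetOnBits()),
    )


def fingerprint_table(table: pd.DataFrame) -> dict[str, MoleculeFingerprint]:
    """ECFP6 fingerprints for a table with molecule_id and smiles columns."""
    required = {"molecule_id", "smiles"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    return {
        row.molecule_id: ecfp6(MoleculeRecord(row.molecule_id, row.smiles))
        for row in table.itertuples(index=False)
    }
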