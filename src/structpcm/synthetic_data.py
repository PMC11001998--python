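"""Synthetic study generator: toy structures, molecules and activities.

Everything downstream of the raw inputs — fingerprinting, curation,
projection, modeling — is exercised in tests and examples on data built
here, with a *planted* structure–activity signal whose recovery is the
benchmark for the modeling regimes.

The generator emulates three kinds of input:

* **Structures** — Cα-trace random walks with 3.8 Å steps confined to a
  sphere whose radius scales as n^(1/3), giving globularly packed chains
  with genuine sequence-nonlocal 3D contacts at the 5 Å fingerprint
  radius.  Targets grouped into *motif families* additionally carry an
  identical pendant residue cluster (the motif), so family members share
  fingerprint bits and are mutually similar by Jaccard — the hook for
  semi-blind validation.
* **Molecules** — sparse random 2048-bit fingerprints (a small bundled
  SMILES set covers the real ECFP6 path separately).
* **Activities** — ChEMBL-like raw Ki tables derived from a planted
  linear model: the true spKi of (molecule, target) couples the
  molecule's signal bits to the target's motif family.  Records are
  emitted with unit variety, censored relations, duplicated measurements
  and occasional wrong units so that curation has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .activity_curation import spki_to_ki
from .ligand_fingerprint import ECFP6_N_BITS, MoleculeFingerprint
from .structure_io import (
    AMINO_ALPHABET,
    AtomRecord,
    ProteinStructure,
    StructureSource,
)

CA_STEP_ANGSTROM = 3.8   # consecutive Cα-Cα distance in a protein chain
_PACKING_COEFF = 3.2     # sphere radius ≈ 3.2 · n^(1/3) Å, protein-like density


@dataclass(frozen=True)
class Motif:
    """A fixed local residue arrangement shared by a target family."""

    codes: str
    offsets: np.ndarray  # (len(codes), 3) Å, relative coordinates

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.offsets):
            raise ValueError("codes and offsets length mismatch")


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth linear structure–activity model.

    ``interaction_terms`` maps (molecule bit, motif family id) to a weight:
    a molecule carrying that bit gains that much spKi against every target
    of that family.  ``family_intercepts`` give each family its own
    baseline potency level — as in real panels, where different targets
    have visibly different label means — on top of which the bit-level
    structure–activity signal acts.  True scores are clamped to [0, 1].
    """

    interaction_terms: dict[tuple[int, int], float]
    intercept: float = 0.1
    family_intercepts: dict[int, float] = field(default_factory=dict)

    def true_spki(self, mol_bits: frozenset[int], family: int) -> float:
        base = self.family_intercepts.get(family, self.intercept)
        total = base + sum(
            w for (bit, fam), w in self.interaction_terms.items()
            if fam == family and bit in mol_bits
        )
        return float(np.clip(total, 0.0, 1.0))

    def family_bits(self, family: int) -> list[int]:
        return sorted(
            bit for (bit, fam) in self.interaction_terms if fam == family
        )


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a desk-scale study: 20 targets in 10 motif families
    of two, 60-residue globules, 400 molecules, 200 activities per target.
    ``effect_size`` is the spKi gain per planted signal bit (4 bits per
    family, each carried by ~40% of molecules), ``noise_sd`` the
    measurement noise on the spKi scale.
    """

    n_targets: int = 20
    residues_per_target: int = 60
    n_molecules: int = 400
    activities_per_target: int = 200
    packing_radius_scale: float = 1.0
    motif_families: Union[int, Sequence[Sequence[int]]] = 10
    motif_length: int = 12
    effect_size: float = 0.2
    noise_sd: float = 0.05
    censor_fraction: float = 0.05
    duplicate_fraction: float = 0.10
    wrong_unit_fraction: float = 0.02
    unit_mix_fraction: float = 0.2   # fraction of '=' records reported in µM
    signal_bits_per_family: int = 4
    signal_bit_prob: float = 0.4     # carrier frequency of signal bits
    molecule_density: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("censor_fraction", "duplicate_fraction",
                     "wrong_unit_fraction", "unit_mix_fraction",
                     "signal_bit_prob", "molecule_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_targets", "residues_per_target", "n_molecules",
                     "activities_per_target", "motif_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def family_assignment(self) -> dict[int, int]:
        """target index → family id (round-robin for an integer count)."""
        if isinstance(self.motif_families, int):
            n_fam = max(1, self.motif_families)
            return {i: i % n_fam for i in range(self.n_targets)}
        assignment: dict[int, int] = {}
        for fam, members in enumerate(self.motif_families):
            for t in members:
                if t in assignment:
                    raise ValueError(f"target {t} in two families")
                assignment[t] = fam
        missing = set(range(self.n_targets)) - set(assignment)
        if missing:
            raise ValueError(f"targets without a family: {sorted(missing)}")
        return assignment


def make_motif(length: int, seed: int) -> Motif:
    """A linear residue cluster with fixed codes, spaced at the Cα step."""
    rng = np.random.default_rng(seed)
    codes = "".join(rng.choice(list(AMINO_ALPHABET), size=length))
    offsets = np.zeros((length, 3))
    offsets[:, 0] = CA_STEP_ANGSTROM * np.arange(length)
    return Motif(codes=codes, offsets=offsets)


def make_structure(
    n_res: int,
    packing_radius_scale: float = 1.0,
    seed: int = 0,
    motif: Optional[Motif] = None,
    structure_id: str = "synthetic",
) -> ProteinStructure:
    """Cα-trace random walk confined to a protein-density sphere.

    Consecutive Cα atoms are exactly 3.8 Å apart; confinement to a sphere
    of radius ``3.2 · n_res^(1/3) · packing_radius_scale`` Å forces the
    chain back on itself, producing sequence-nonlocal contacts within the
    5 Å fingerprint radius, as in a folded globule.  If a ``motif`` is
    given, its residues are appended as a rigid pendant cluster placed
    10 Å outside the sphere, so the motif's neighborhood patterns are
    identical in every structure carrying it.
    """
    rng = np.random.default_rng(seed)
    radius = _PACKING_COEFF * n_res ** (1 / 3) * packing_radius_scale
    coords = [np.zeros(3)]
    for _ in range(n_res - 1):
        pos = coords[-1]
        for _try in range(100):
            step = rng.normal(size=3)
            step *= CA_STEP_ANGSTROM / np.linalg.norm(step)
            cand = pos + step
            if np.linalg.norm(cand) <= radius:
                break
        else:  # fully cornered: step straight back toward the center
            cand = pos - CA_STEP_ANGSTROM * pos / np.linalg.norm(pos)
        coords.append(cand)
    codes = rng.choice(list(AMINO_ALPHABET), size=n_res)

    atoms = [
        AtomRecord(
            serial=i + 1, atom_name="CA", residue_code=codes[i],
            residue_number=i + 1, chain_id="A",
            x=float(c[0]), y=float(c[1]), z=float(c[2]),
        )
        for i, c in enumerate(coords)
    ]
    if motif is not None:
        anchor = np.array([radius + 10.0, 0.0, 0.0])
        for j, (code, offset) in enumerate(zip(motif.codes, motif.offsets)):
            p = anchor + offset
            atoms.append(
                AtomRecord(
                    serial=n_res + j + 1, atom_name="CA", residue_code=code,
                    residue_number=n_res + j + 1, chain_id="A",
                    x=float(p[0]), y=float(p[1]), z=float(p[2]),
                )
            )
    return ProteinStructure(
        structure_id=structure_id,
        source=StructureSource.SYNTHETIC,
        chain_id="A",
        atoms=atoms,
    )


def make_molecules(
    n: int, density: float = 0.03, seed: int = 0
) -> dict[str, MoleculeFingerprint]:
    """Random sparse 2048-bit molecule fingerprints keyed by molecule id."""
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out: dict[str, MoleculeFingerprint] = {}
    for i in range(n):
        bits = frozenset(np.flatnonzero(rng.random(ECFP6_N_BITS) < density))
        mol_id = f"M{i:05d}"
        out[mol_id] = MoleculeFingerprint(molecule_id=mol_id, on_bits=bits)
    return out


#: A handful of real drug-like SMILES to exercise the RDKit ECFP6 path.
EXAMPLE_SMILES: dict[str, str] = {
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
    "haloperidol": "OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1",
    "serotonin": "NCCc1c[nH]c2ccc(O)cc12",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
}


def default_planted_model(config: SyntheticConfig, seed: int) -> PlantedModel:
    """Pick ``signal_bits_per_family`` distinct bits per family at
    ``effect_size`` weight each."""
    rng = np.random.default_rng(seed)
    families = sorted(set(config.family_assignment().values()))
    terms: dict[tuple[int, int], float] = {}
    intercepts: dict[int, float] = {}
    for fam in families:
        bits = rng.choice(ECFP6_N_BITS, size=config.signal_bits_per_family,
                          replace=False)
        for b in bits:
            terms[(int(b), fam)] = config.effect_size
        intercepts[fam] = float(rng.uniform(0.15, 0.45))
    return PlantedModel(interaction_terms=terms, family_intercepts=intercepts)


def plant_activities(
    structures: Mapping[str, ProteinStructure],
    molecules: Mapping[str, MoleculeFingerprint],
    planted: PlantedModel,
    config: SyntheticConfig,
    family_of: Mapping[str, int],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a raw ChEMBL-like activity table plus its ground truth.

    Each sampled (molecule, target) pair gets a true spKi from the planted
    model plus Gaussian noise (clamped to [0, 1]), converted to Ki through
    the inverse spKi transform; clamped scores map to the representative
    boundary values 20,000 nM (inactive) and 0.5 nM (very active).  A
    configurable share of records is censored ('<' at the true Ki, or '>'
    at 10,000 nM for inactives), duplicated with a perturbed value and a
    different year, reported in µM, or given junk units.
    """
    for bit, _fam in planted.interaction_terms:
        if not 0 <= bit < ECFP6_N_BITS:
            raise ValueError(f"planted term references bit {bit} out of range")
    rng = np.random.default_rng(seed)
    mol_ids = np.array(sorted(molecules))
    raw_rows: list[dict] = []
    truth_rows: list[dict] = []
    for tgt in sorted(structures):
        fam = family_of[tgt]
        chosen = rng.choice(
            mol_ids, size=min(config.activities_per_target, len(mol_ids)),
            replace=False,
        )
        for mol in chosen:
            signal = planted.true_spki(molecules[mol].on_bits, fam)
            observed = float(
                np.clip(signal + rng.normal(0.0, config.noise_sd), 0.0, 1.0)
            )
            if observed <= 0.0:
                ki = 20_000.0
            elif observed >= 1.0:
                ki = 0.5
            else:
                ki = spki_to_ki(observed)
            year = int(rng.integers(1995, 2024))
            truth_rows.append(
                dict(molecule_id=mol, target_id=tgt, family=fam,
                     spki_signal=signal, spki_true=observed)
            )
            u = rng.random()
            if u < config.wrong_unit_fraction:
                raw_rows.append(
                    dict(molecule_id=mol, target_id=tgt, activity_type="Ki",
                         relation="=", value=ki, units="ug.mL-1",
                         comment=None, year=year)
                )
                continue
            if u < config.wrong_unit_fraction + config.censor_fraction:
                if observed <= 0.0:
                    raw_rows.append(
                        dict(molecule_id=mol, target_id=tgt,
                             activity_type="Ki", relation=">", value=10_000.0,
                             units="nM", comment=None, year=year)
                    )
                else:
                    raw_rows.append(
                        dict(molecule_id=mol, target_id=tgt,
                             activity_type="Ki", relation="<", value=ki,
                             units="nM", comment=None, year=year)
                    )
                continue
            if rng.random() < config.unit_mix_fraction:
                value, units = ki / 1e3, "uM"
            else:
                value, units = ki, "nM"
            raw_rows.append(
                dict(molecule_id=mol, target_id=tgt, activity_type="Ki",
                     relation="=", value=value, units=units,
                     comment=None, year=year)
            )
            if rng.random() < config.duplicate_fraction:
                # second assay within one order of magnitude, other year
                factor = 10.0 ** rng.uniform(-0.45, 0.45)
                raw_rows.append(
                    dict(molecule_id=mol, target_id=tgt, activity_type="Ki",
                         relation="=", value=ki * factor, units="nM",
                         comment=None, year=year + 1)
                )
    raw = pd.DataFrame(
        raw_rows,
        columns=["molecule_id", "target_id", "activity_type", "relation",
                 "value", "units", "comment", "year"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["molecule_id", "target_id", "family",
                 "spki_signal", "spki_true"],
    )
    return raw, truth


@dataclass
class SyntheticStudy:
    """A complete generated study: inputs plus ground truth."""

    config: SyntheticConfig
    structures: dict[str, ProteinStructure]
    family_of: dict[str, int]
    molecules: dict[str, MoleculeFingerprint]
    planted: PlantedModel
    raw_activities: pd.DataFrame
    truth: pd.DataFrame

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.structures)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full study deterministically from ``config.seed``."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=6)

    assignment = config.family_assignment()
    families = sorted(set(assignment.values()))
    motifs = {
        fam: make_motif(config.motif_length, seed=int(seeds[0]) + fam)
        for fam in families
    }
    structures: dict[str, ProteinStructure] = {}
    family_of: dict[str, int] = {}
    for i in range(config.n_targets):
        tid = f"T{i:03d}"
        fam = assignment[i]
        structures[tid] = make_structure(
            config.residues_per_target,
            packing_radius_scale=config.packing_radius_scale,
            seed=int(seeds[1]) + i,
            motif=motifs[fam],
            structure_id=tid,
        )
        family_of[tid] = fam

    molecules = make_molecules(
        config.n_molecules, density=config.molecule_density, seed=int(seeds[2])
    )
    planted = default_planted_model(config, seed=int(seeds[3]))
    # signal bits get a realistic carrier frequency across the library
    carrier = np.random.default_rng(int(seeds[4]))
    signal_bits = sorted({b for b, _f in planted.interaction_terms})
    boosted: dict[str, MoleculeFingerprint] = {}
    for mol_id, fp in molecules.items():
        bits = set(fp.on_bits)
        for b in signal_bits:
            bits.discard(b)
            if carrier.random() < config.signal_bit_prob:
                bits.add(b)
        boosted[mol_id] = MoleculeFingerprint(
            molecule_id=mol_id, on_bits=frozenset(bits)
        )
    raw, truth = plant_activities(
        structures, boosted, planted, config, family_of, seed=int(seeds[5])
    )
    return SyntheticStudy(
        config=config,
        structures=structures,
        family_of=family_of,
        molecules=boosted,
        planted=planted,
        raw_activities=raw,
        truth=truth,
    )
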