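import numpy as np
import pytest

from structpcm import (
    AtomRecord,
    ProteinStructure,
    StructureSource,
    SyntheticConfig,
    build_features,
    generate_study,
)


def line_structure(codes: str, spacing: float = 3.8,
                   structure_id: str = "line",
                   start_number: int = 1) -> ProteinStructure:
    """Residues on a straight line, one CA atom each, fixed spacing (Å)."""
    atoms = [
        AtomRecord(
            serial=i + 1, atom_name="CA", residue_code=c,
            residue_number=start_number + i, chain_id="A",
            x=i * spacing, y=0.0, z=0.0,
        )
        for i, c in enumerate(codes)
    ]
    return ProteinStructure(
        structure_id=structure_id, source=StructureSource.SYNTHETIC,
        chain_id="A", atoms=atoms,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def small_study():
    """A fast six-target study: three motif families of two targets."""
    config = SyntheticConfig(
        n_targets=6, residues_per_target=40, n_molecules=150,
        activities_per_target=60, motif_families=3, seed=11,
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def small_features(small_study):
    return build_features(
        small_study.structures,
        small_study.molecules,
        small_study.raw_activities,
        min_activities=30,
    )
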