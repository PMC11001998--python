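"""PCA reduction of protein fingerprints and feature-row assembly.

A protein fingerprint is 16,381 bits wide but a study contains only on the
order of a hundred targets, and every activity row of a target repeats the
same fingerprint, so the raw bits are hugely redundant as model input.
They are therefore projected with centered PCA fitted on the target ×
n_bits fingerprint matrix — an unsupervised step that uses no activity
labels, so it may legitimately include targets whose activities are held
out of training.  Molecule fingerprints (2048 bits) are passed through
untransformed.  A feature row is the concatenation of the 2048 molecule
bits and the k protein components, labeled with the pair's spKi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .ligand_fingerprint import ECFP6_N_BITS, MoleculeFingerprint
from .protein_fingerprint import ProteinFingerprint


class ProjectionPolicy(str, Enum):
    #: one component per target (truncated to matrix rank)
    N_TARGETS = "n_targets"
    #: smallest k explaining at least 99% of fingerprint variance
    VARIANCE_99 = "variance_99"


@dataclass
class ProjectionModel:
    """Fitted centered-PCA projection of protein fingerprints."""

    component_loadings: np.ndarray   # (k, n_bits), rows orthonormal
    column_means: np.ndarray         # (n_bits,)
    variance_explained: np.ndarray   # (k,) fractions
    fitted_on: list[str]
    policy: ProjectionPolicy

    @property
    def n_components(self) -> int:
        return self.component_loadings.shape[0]

    @property
    def n_bits(self) -> int:
        return self.component_loadings.shape[1]


def _fingerprint_matrix(fps: Sequence[ProteinFingerprint]) -> np.ndarray:
    n_bits = {fp.n_bits for fp in fps}
    if len(n_bits) != 1:
        raise ValueError("fingerprints have mixed lengths")
    mat = np.zeros((len(fps), n_bits.pop()), dtype=float)
    for i, fp in enumerate(fps):
        if fp.on_bits:
            mat[i, sorted(fp.on_bits)] = 1.0
    return mat


def fit_projection(
    protein_fps: Sequence[ProteinFingerprint],
    policy: ProjectionPolicy | str = ProjectionPolicy.N_TARGETS,
) -> ProjectionModel:
    """Fit centered PCA on a set of protein fingerprints.

    Under ``n_targets`` the number of components matches the number of
    targets (truncated to the matrix rank, with a warning, when the
    fingerprints are linearly dependent).  Under ``variance_99`` the
    smallest k whose cumulative explained variance reaches 99% is kept.
    The sign of each component is fixed by making its largest-magnitude
    loading positive, so fits are deterministic for a given row order.
    """
    import warnings

    policy = ProjectionPolicy(policy)
    if len(protein_fps) < 2:
        raise ValueError("need at least two fingerprints to fit a projection")
    mat = _fingerprint_matrix(protein_fps)
    if np.allclose(mat.var(axis=0), 0.0):
        raise ValueError(
            "degenerate input: all fingerprints identical, PCA undefined"
        )
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(mat)
    ratios = pca.explained_variance_ratio_
    # rank = number of components with non-negligible variance
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if policy is ProjectionPolicy.N_TARGETS:
        k = min(len(protein_fps), mat.shape[1])
        if rank < k:
            warnings.warn(
                f"fingerprint matrix rank {rank} < requested {k} components; "
                "truncating", stacklevel=2,
            )
            k = rank
    else:
        cumulative = np.cumsum(ratios)
        k = int(np.searchsorted(cumulative, 0.99) + 1)
        k = min(k, rank if rank > 0 else 1)
    loadings = pca.components_[:k].copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for row in loadings:
        pivot = np.argmax(np.abs(row))
        if row[pivot] < 0:
            row *= -1.0
    return ProjectionModel(
        component_loadings=loadings,
        column_means=pca.mean_.copy(),
        variance_explained=ratios[:k].copy(),
        fitted_on=[fp.structure_id for fp in protein_fps],
        policy=policy,
    )


def project(model: ProjectionModel, fp: ProteinFingerprint) -> np.ndarray:
    """Project a fingerprint (seen or unseen) onto the fitted components."""
    if fp.n_bits != model.n_bits:
        raise ValueError(
            f"fingerprint has {fp.n_bits} bits, projection expects {model.n_bits}"
        )
    x = np.zeros(model.n_bits, dtype=float)
    if fp.on_bits:
        x[sorted(fp.on_bits)] = 1.0
    return (x - model.column_means) @ model.component_loadings.T


@dataclass
class AssembledDataset:
    """Feature rows (2048 molecule bits ⊕ k protein components) + labels."""

    X: np.ndarray                 # (n_rows, n_mol_bits + k) float
    y: np.ndarray                 # (n_rows,) spKi labels
    molecule_ids: list[str]
    target_ids: list[str]
    n_mol_bits: int = ECFP6_N_BITS
    n_protein_components: int = 0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = self.n_mol_bits + self.n_protein_components
        if self.X.shape[1] != expected:
            raise ValueError(
                f"feature width {self.X.shape[1]} != {expected} "
                "(n_mol_bits + n_protein_components)"
            )
        if not (len(self.y) == len(self.molecule_ids)
                == len(self.target_ids) == self.X.shape[0]):
            raise ValueError("row count mismatch across fields")
        pairs = list(zip(self.molecule_ids, self.target_ids))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (molecule, target) pair in dataset")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def target_index(self) -> dict[str, np.ndarray]:
        idx: dict[str, list[int]] = {}
        for i, t in enumerate(self.target_ids):
            idx.setdefault(t, []).append(i)
        return {t: np.array(rows) for t, rows in idx.items()}

    def molecule_block(self) -> np.ndarray:
        """Ligand-only feature view (baseline QSAR models use this)."""
        return self.X[:, : self.n_mol_bits]

    def subset(self, rows: np.ndarray) -> "AssembledDataset":
        rows = np.asarray(rows)
        return AssembledDataset(
            X=self.X[rows],
            y=self.y[rows],
            molecule_ids=[self.molecule_ids[i] for i in rows],
            target_ids=[self.target_ids[i] for i in rows],
            n_mol_bits=self.n_mol_bits,
            n_protein_components=self.n_protein_components,
            provenance=[self.provenance[i] for i in rows] if self.provenance else [],
        )


def assemble(
    curated: pd.DataFrame,
    mol_fps: Mapping[str, MoleculeFingerprint],
    protein_projections: Mapping[str, np.ndarray],
) -> tuple[AssembledDataset, pd.DataFrame]:
    """Join curated activities with molecule bits and protein components.

    Returns the assembled dataset and a missing-key report listing every
    curated row whose molecule fingerprint or target projection is absent
    (reported, never silently dropped).
    """
    k_set = {len(np.asarray(v)) for v in protein_projections.values()}
    if len(k_set) > 1:
        raise ValueError("protein projections have mixed lengths")
    k = k_set.pop() if k_set else 0

    rows, labels, mols, tgts, provs, missing = [], [], [], [], [], []
    for rec in curated.itertuples(index=False):
        fp = mol_fps.get(rec.molecule_id)
        proj = protein_projections.get(rec.target_id)
        if fp is None or proj is None:
            missing.append(
                dict(
                    molecule_id=rec.molecule_id,
                    target_id=rec.target_id,
                    missing=("molecule fingerprint" if fp is None
                             else "target projection"),
                )
            )
            continue
        mol_vec = np.zeros(fp.n_bits, dtype=float)
        if fp.on_bits:
            mol_vec[sorted(fp.on_bits)] = 1.0
        rows.append(np.concatenate([mol_vec, np.asarray(proj, dtype=float)]))
        labels.append(float(rec.spki))
        mols.append(rec.molecule_id)
        tgts.append(rec.target_id)
        provs.append(getattr(rec, "provenance", ""))

    n_mol_bits = next(iter(mol_fps.values())).n_bits if mol_fps else ECFP6_N_BITS
    X = (np.array(rows) if rows
         else np.empty((0, n_mol_bits + k)))
    dataset = AssembledDataset(
        X=X,
        y=np.array(labels, dtype=float),
        molecule_ids=mols,
        target_ids=tgts,
        n_mol_bits=n_mol_bits,
        n_protein_components=k,
        provenance=provs,
    )
    report = pd.DataFrame(
        missing, columns=["molecule_id", "target_id", "missing"]
    )
    return dataset, report
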