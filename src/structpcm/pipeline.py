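"""End-to-end convenience pipeline: structures + activities → feature rows.

Glues the individual stages together the way the examples, the CLI and the
benchmark runs use them: fingerprint every structure, curate the raw
activity table, filter thin targets, fit the PCA projection on all target
fingerprints (an unsupervised, label-free step) and assemble feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .activity_curation import CurationResult, curate_activities, filter_targets
from .feature_assembly import (
    AssembledDataset,
    ProjectionModel,
    ProjectionPolicy,
    assemble,
    fit_projection,
    project,
)
from .ligand_fingerprint import MoleculeFingerprint
from .protein_fingerprint import (
    DEFAULT_N_BITS,
    DEFAULT_RADIUS_ANGSTROM,
    ProteinFingerprint,
    fingerprint,
)
from .structure_io import ProteinStructure


@dataclass
class FeaturePipelineResult:
    dataset: AssembledDataset
    projection: ProjectionModel
    protein_fps: dict[str, ProteinFingerprint]
    curation: CurationResult
    filtered: pd.DataFrame
    dropped_targets: pd.DataFrame
    missing_keys: pd.DataFrame


def build_features(
    structures: Mapping[str, ProteinStructure],
    molecules: Mapping[str, MoleculeFingerprint],
    raw_activities: pd.DataFrame,
    radius: float = DEFAULT_RADIUS_ANGSTROM,
    n_bits: int = DEFAULT_N_BITS,
    policy: ProjectionPolicy | str = ProjectionPolicy.N_TARGETS,
    min_activities: int = 40,
    min_label_spread: float = 0.01,
) -> FeaturePipelineResult:
    """Run fingerprinting, curation, projection and assembly in one call."""
    curation = curate_activities(raw_activities)
    filtered, dropped = filter_targets(
        curation.curated,
        min_activities=min_activities,
        min_label_spread=min_label_spread,
    )
    kept_targets = sorted(set(filtered["target_id"]))
    fps = {
        tid: fingerprint(structures[tid], radius=radius, n_bits=n_bits)
        for tid in kept_targets
        if tid in structures
    }
    projection = fit_projection([fps[t] for t in sorted(fps)], policy=policy)
    projections = {t: project(projection, fps[t]) for t in fps}
    dataset, missing = assemble(filtered, molecules, projections)
    return FeaturePipelineResult(
        dataset=dataset,
        projection=projection,
        protein_fps=fps,
        curation=curation,
        filtered=filtered,
        dropped_targets=dropped,
        missing_keys=missing,
    )
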