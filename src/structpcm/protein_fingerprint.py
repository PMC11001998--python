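"""Hashed 3D residue-neighborhood fingerprints for protein structures.

The encoding sweeps every atom of a structure and records which residues
have at least one atom within a radius *r* (default 5.0 Å) of it — the
atom's *neighborhood*.  A residue joins the neighborhood if **any** of its
atoms is within the radius, and the central atom's own residue is always a
member.  Neighborhoods that contain exactly the same residues are collapsed
to a single pattern.  Each pattern is then encoded as the sorted string of
its one-letter residue codes (duplicated letters kept: two phenylalanines
at different positions contribute "FF") and hashed to a bit index of a
fixed-length binary array, by default 16,381 bits — the largest prime below
2^14, a prime length spreading hash collisions.

Two structures can then be compared by the Jaccard similarity of their
on-bit sets, which is how structurally similar targets are identified for
semi-blind validation.

The hash is a seedless byte-stable digest (SHA-1 of the ASCII key reduced
modulo the array length), so fingerprints are identical across runs,
processes and platforms.  Collisions — distinct keys sharing a bit — are an
accepted property of the scheme.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, ProteinStructure

DEFAULT_RADIUS_ANGSTROM = 5.0


def largest_prime_below(n: int) -> int:
    """Largest prime strictly below ``n`` (trial division; n is small)."""
    if n <= 2:
        raise ValueError("no prime below 2")
    for cand in range(n - 1, 1, -1):
        if cand < 4 or all(cand % d for d in range(2, int(cand**0.5) + 1)):
            return cand
    raise AssertionError("unreachable")


#: Default fingerprint length: the largest prime below 2**14.
DEFAULT_N_BITS = largest_prime_below(2**14)


@dataclass(frozen=True)
class NeighborhoodPattern:
    """The set of (residue_code, residue_number) pairs around one atom."""

    members: frozenset[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("neighborhood pattern must be non-empty")


@dataclass(frozen=True)
class ProteinFingerprint:
    """Binary fingerprint of a protein structure's residue neighborhoods."""

    structure_id: str
    on_bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS
    radius_angstrom: float = DEFAULT_RADIUS_ANGSTROM

    def __post_init__(self) -> None:
        if self.on_bits and not all(0 <= b < self.n_bits for b in self.on_bits):
            raise ValueError("on-bit index out of range")

    @property
    def popcount(self) -> int:
        return len(self.on_bits)

    def to_dense(self) -> np.ndarray:
        """Dense 0/1 vector of length n_bits."""
        v = np.zeros(self.n_bits, dtype=np.uint8)
        if self.on_bits:
            v[sorted(self.on_bits)] = 1
        return v


def atom_neighborhood(
    structure: ProteinStructure, atom: AtomRecord, radius: float
) -> NeighborhoodPattern:
    """Residues of ``structure`` with any atom within ``radius`` Å of ``atom``.

    The cutoff is inclusive (distance ≤ radius) and the central atom's own
    residue is always a member (it is at distance 0 from itself).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if atom not in structure.atoms:
        raise ValueError("atom does not belong to the structure")
    coords = structure.coordinates()
    center = atom.position()
    d2 = np.sum((coords - center) ** 2, axis=1)
    mask = d2 <= radius * radius
    members = frozenset(
        (a.residue_code, a.residue_number)
        for a, hit in zip(structure.atoms, mask)
        if hit
    )
    return NeighborhoodPattern(members)


def unique_patterns(
    structure: ProteinStructure, radius: float = DEFAULT_RADIUS_ANGSTROM
) -> set[NeighborhoodPattern]:
    """Deduplicated neighborhoods over all atoms of the structure.

    Atoms in the same local environment often see identical residue sets;
    those duplicates are removed.  Deduplication happens on the
    position-annotated member sets, before letter-sorting.  The neighbor
    scan uses a k-d tree; the result is an exact set, identical to a
    brute-force all-pairs distance scan, and independent of atom order.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = structure.coordinates()
    res_ids = [(a.residue_code, a.residue_number) for a in structure.atoms]
    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r=radius)
    patterns: set[NeighborhoodPattern] = set()
    for i, neighbors in enumerate(neighbor_lists):
        members = frozenset(res_ids[j] for j in neighbors)
        # query_ball_point always includes the center itself (distance 0)
        patterns.add(NeighborhoodPattern(members))
    return patterns


def encode_pattern(pattern: NeighborhoodPattern) -> str:
    """Sorted one-letter key of a neighborhood, multiplicity preserved.

    {R23, F24, G25, F27} → ``"FFGR"``.
    """
    return "".join(sorted(code for code, _num in pattern.members))


def hash_key(key: str, n_bits: int = DEFAULT_N_BITS) -> int:
    """Deterministic bit index for a pattern key in ``[0, n_bits)``.

    SHA-1 of the ASCII key reduced modulo ``n_bits``: stable across runs,
    processes and platforms (never Python's per-process randomized hash).
    """
    if not key:
        raise ValueError("empty pattern key")
    if n_bits < 2:
        raise ValueError("n_bits must be at least 2")
    digest = hashlib.sha1(key.encode("ascii")).digest()
    return int.from_bytes(digest, "big") % n_bits


def fingerprint(
    structure: ProteinStructure,
    radius: float = DEFAULT_RADIUS_ANGSTROM,
    n_bits: int = DEFAULT_N_BITS,
) -> ProteinFingerprint:
    """Fingerprint of all residue-neighborhood patterns of a structure."""
    bits = frozenset(
        hash_key(encode_pattern(p), n_bits)
        for p in unique_patterns(structure, radius)
    )
    return ProteinFingerprint(
        structure_id=structure.structure_id,
        on_bits=bits,
        n_bits=n_bits,
        radius_angstrom=radius,
    )


def pattern_keys(
    structure: ProteinStructure, radius: float = DEFAULT_RADIUS_ANGSTROM
) -> frozenset[str]:
    """Pre-hash pattern-key set, for collision-free similarity if wanted."""
    return frozenset(
        encode_pattern(p) for p in unique_patterns(structure, radius)
    )


def jaccard(a: ProteinFingerprint, b: ProteinFingerprint) -> float:
    """Jaccard similarity |A∩B| / |A∪B| of two fingerprints' on-bit sets."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}")
    union = a.on_bits | b.on_bits
    if not union:
        raise ValueError("Jaccard similarity undefined for two empty fingerprints")
    return len(a.on_bits & b.on_bits) / len(union)


def jaccard_sets(a: Iterable, b: Iterable) -> float:
    """Jaccard similarity of two arbitrary sets (e.g. pre-hash pattern keys)."""
    a, b = set(a), set(b)
    if not (a | b):
        raise ValueError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(a | b)


def similarity_matrix(
    fps: Sequence[ProteinFingerprint],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Jaccard matrix and a ranked closest-pair report.

    Returns ``(matrix, pairs)``: a symmetric DataFrame indexed by structure
    id with unit diagonal, and a DataFrame of all unordered pairs sorted by
    descending similarity (columns: target, partner, similarity).
    """
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    n_bits = {fp.n_bits for fp in fps}
    if len(n_bits) != 1:
        raise ValueError("fingerprints have mixed lengths")
    ids = [fp.structure_id for fp in fps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate structure ids")
    n = len(fps)
    mat = np.eye(n)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            s = jaccard(fps[i], fps[j])
            mat[i, j] = mat[j, i] = s
            rows.append((ids[i], ids[j], s))
    matrix = pd.DataFrame(mat, index=ids, columns=ids)
    pairs = (
        pd.DataFrame(rows, columns=["target", "partner", "similarity"])
        .sort_values(["similarity", "target", "partner"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    return matrix, pairs
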