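"""Generalized Procrustes analysis (GPA) and form-space construction.

Configurations are superimposed by removing translation (centering), size
(scaling to unit centroid size, optional) and orientation (least-squares
proper rotation onto an iteratively re-estimated consensus). Shape space is
turned into form space by appending ln(centroid size) to the flattened
Procrustes coordinates.

Conventions
-----------
* Reflections are excluded by default (proper rotations, det = +1), the
  standard geometric-morphometrics choice; ``allow_reflection=True`` gives
  the full orthogonal fit.
* The consensus is initialized from the first configuration and re-scaled to
  unit centroid size every iteration; convergence is declared when its RMS
  change drops below ``tol`` (default 1e-10).
* The whole procedure is deterministic: identical inputs give bit-identical
  outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkConfiguration

__all__ = [
    "centroid_size",
    "optimal_rotation",
    "gpa_align",
    "AlignedDataset",
    "FormSpaceData",
    "procrustes_distance",
    "pairwise_procrustes_distance",
    "to_form_space",
]


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the
    configuration centroid. Accepts a LandmarkConfiguration or a k x d array.
    """
    coords = config.coordinates if hasattr(config, "coordinates") else np.asarray(config, float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("centroid_size requires at least 2 landmarks")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum()))


def optimal_rotation(source: np.ndarray, target: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimizing ||source @ R - target||_F (Kabsch).

    Returns a proper rotation (det +1) unless ``allow_reflection``.
    """
    m = source.T @ target
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


@dataclass
class AlignedDataset:
    """Procrustes-superimposed sample.

    ``shape_coordinates`` are n x k x 3 (dimensionless when scaled);
    ``centroid_sizes`` are the original sizes in mm. The per-specimen
    similarity transform raw -> aligned is retained (``centroids``,
    ``rotations``) so results of downstream operations (e.g. semilandmark
    sliding) can be mapped back to the raw frame.
    """

    shape_coordinates: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    iterations_used: int
    converged: bool
    scaled: bool = True
    centroids: np.ndarray = field(default=None, repr=False)
    rotations: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.shape_coordinates.shape[0]

    @property
    def k(self) -> int:
        return self.shape_coordinates.shape[1]

    @property
    def lncs(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    def as_matrix(self) -> np.ndarray:
        """Flattened n x 3k shape-coordinate matrix."""
        return self.shape_coordinates.reshape(self.n, -1)

    def save_npz(self, path) -> None:
        np.savez(
            path,
            shape_coordinates=self.shape_coordinates,
            consensus=self.consensus,
            centroid_sizes=self.centroid_sizes,
            specimen_ids=np.array(self.specimen_ids),
            iterations_used=self.iterations_used,
            converged=self.converged,
            scaled=self.scaled,
            centroids=self.centroids,
            rotations=self.rotations,
        )

    @classmethod
    def load_npz(cls, path) -> "AlignedDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                shape_coordinates=z["shape_coordinates"],
                consensus=z["consensus"],
                centroid_sizes=z["centroid_sizes"],
                specimen_ids=[str(s) for s in z["specimen_ids"]],
                iterations_used=int(z["iterations_used"]),
                converged=bool(z["converged"]),
                scaled=bool(z["scaled"]),
                centroids=z["centroids"],
                rotations=z["rotations"],
            )


@dataclass
class FormSpaceData:
    """Flattened shape coordinates with lnCS appended as the last column."""

    augmented_coordinates: np.ndarray
    specimen_ids: list[str]


def gpa_align(
    configs: list[LandmarkConfiguration],
    scale: bool = True,
    allow_reflection: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> AlignedDataset:
    """Generalized Procrustes superimposition of a homogeneous sample."""
    if not configs:
        raise ValueError("gpa_align: empty configuration list")
    k = configs[0].k
    for c in configs:
        if c.k != k:
            raise ValueError(
                f"gpa_align: heterogeneous landmark counts ({c.k} vs {k})"
            )
    raw = np.stack([c.coordinates for c in configs]).astype(float)
    n = raw.shape[0]
    centroids = raw.mean(axis=1)
    x = raw - centroids[:, None, :]
    cs = np.sqrt((x ** 2).sum(axis=(1, 2)))
    if np.any(cs < 1e-12):
        bad = [configs[i].specimen_id for i in np.nonzero(cs < 1e-12)[0]]
        raise ValueError(f"gpa_align: degenerate (all-coincident) configuration(s): {bad}")
    if scale:
        x = x / cs[:, None, None]

    rotations = np.tile(np.eye(3), (n, 1, 1))
    # Initial consensus: normalized mean of the centered (and scaled) inputs
    # as digitized. This makes an already-superimposed sample an exact fixed
    # point (identity rotations, zero consensus change on iteration 1); if
    # arbitrary orientations make the mean degenerate, fall back to the first
    # configuration.
    consensus = x.mean(axis=0)
    norm0 = np.sqrt((consensus ** 2).sum())
    if norm0 < 1e-6:
        consensus = x[0].copy()
        norm0 = np.sqrt((consensus ** 2).sum())
    consensus = consensus / norm0
    iterations = 0
    converged = False
    aligned = x.copy()
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            r = optimal_rotation(x[i], consensus, allow_reflection)
            rotations[i] = r
            aligned[i] = x[i] @ r
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus ** 2).sum())
        if norm < 1e-12:
            raise ValueError("gpa_align: consensus collapsed to a point")
        new_consensus /= norm
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    return AlignedDataset(
        shape_coordinates=aligned,
        consensus=consensus,
        centroid_sizes=cs,
        specimen_ids=[c.specimen_id for c in configs],
        iterations_used=iterations,
        converged=converged,
        scaled=scale,
        centroids=centroids,
        rotations=rotations,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two already-superimposed configurations
    (the metric of the group-difference permutation tests)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"procrustes_distance: shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def pairwise_procrustes_distance(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = False
) -> float:
    """Full ordinary Procrustes distance: center, scale and rotate ``b`` onto
    ``a`` before measuring. Used for oracle checks; ``procrustes_distance``
    (common GPA frame) is what the analyses use."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"pairwise_procrustes_distance: shape mismatch {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ac = ac / np.sqrt((ac ** 2).sum())
    bc = bc / np.sqrt((bc ** 2).sum())
    r = optimal_rotation(bc, ac, allow_reflection)
    return float(np.sqrt(((bc @ r - ac) ** 2).sum()))


def to_form_space(aligned: AlignedDataset) -> FormSpaceData:
    """Append lnCS (unweighted) to the flattened shape coordinates.

    Centering happens inside PCA, not here.
    """
    if not aligned.scaled:
        raise ValueError("to_form_space requires a scaled (unit-size) alignment")
    if np.any(aligned.centroid_sizes <= 0):
        raise ValueError("to_form_space: nonpositive centroid size")
    mat = aligned.as_matrix()
    aug = np.column_stack([mat, aligned.lncs])
    return FormSpaceData(aug, list(aligned.specimen_ids))
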