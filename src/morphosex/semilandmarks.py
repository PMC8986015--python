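"""Thin-plate-spline machinery: bending energy, semilandmark sliding, warps.

The thin-plate spline (TPS) interpolates a deformation of a reference
configuration with the fundamental-solution kernels U(r) = r^2 log r^2 in 2D
and U(r) = r in 3D. Its bending energy — a quadratic form that is zero
exactly on affine deformations — quantifies the non-affine part of a
deformation and is the criterion minimized when curve semilandmarks slide
along their local tangents to remove arbitrary spacing along digitized
curves.

Sliding protocol: GPA-align the sample, build the bending-energy model from
the current reference (sample consensus by default), slide each specimen's
semilandmarks jointly (one constrained linear solve per specimen), map the
displacements back to the raw coordinate frame, and repeat for a small
number of outer iterations with a re-estimated reference. Fixed landmarks
never move; semilandmarks move along straight tangent lines (no surface
re-projection — no meshes are assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkConfiguration, TemplateDefinition
from .superimposition import AlignedDataset, gpa_align

__all__ = [
    "BendingEnergyModel",
    "SlidingResult",
    "bending_energy",
    "curve_tangents",
    "slide_semilandmarks",
    "tps_warp",
    "mean_difference_field",
]


def _tps_kernel(r: np.ndarray, dimension: int) -> np.ndarray:
    # 3D: U(r) = -r. The biharmonic fundamental solution is -r/(8pi); the
    # negative sign is what makes the bending-energy quadratic form positive
    # semidefinite (|r| alone is conditionally *negative* definite).
    if dimension == 3:
        return -r
    # 2D: U(r) = r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz] ** 2)
    return out


@dataclass
class BendingEnergyModel:
    """TPS kernel system and bending-energy quadratic form for a reference.

    ``bending_energy_matrix`` (L_k) is the upper-left k x k block of the
    inverse of the bordered kernel system; it is symmetric, positive
    semidefinite, and annihilates displacement fields that are affine
    functions of the reference.
    """

    reference: np.ndarray
    kernel_matrix: np.ndarray
    bending_energy_matrix: np.ndarray
    dimension: int
    affine_columns: tuple[int, ...] = (0, 1, 2, 3)

    @classmethod
    def from_reference(cls, reference: np.ndarray) -> "BendingEnergyModel":
        ref = np.asarray(reference, dtype=float)
        if ref.ndim != 2 or ref.shape[1] not in (2, 3):
            raise ValueError("reference must be k x 2 or k x 3")
        k, dim = ref.shape
        d = np.sqrt(((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(k, 1)
        if k < 3 or (d[iu] < 1e-9).any():
            raise ValueError(
                "singular TPS kernel system (coincident or too few "
                "reference landmarks)"
            )
        kmat = _tps_kernel(d, dim)
        # drop affine columns that are degenerate for this reference (e.g.
        # the z column of a coplanar reference): pivoted QR column selection
        q_full = np.column_stack([np.ones(k), ref])
        from scipy.linalg import qr as _qr

        _, r, piv = _qr(q_full, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        keep = sorted(piv[i] for i in range(len(diag))
                      if diag[i] > 1e-9 * diag.max())
        q = q_full[:, keep]
        m = q.shape[1]
        l = np.zeros((k + m, k + m))
        l[:k, :k] = kmat
        l[:k, k:] = q
        l[k:, :k] = q.T
        cond = np.linalg.cond(l)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                "singular TPS kernel system (degenerate reference landmarks)"
            )
        linv = np.linalg.inv(l)
        lk = linv[:k, :k]
        lk = 0.5 * (lk + lk.T)
        return cls(reference=ref, kernel_matrix=kmat,
                   bending_energy_matrix=lk, dimension=dim,
                   affine_columns=tuple(keep))

    @property
    def k(self) -> int:
        return self.reference.shape[0]


def bending_energy(model: BendingEnergyModel, target: np.ndarray) -> float:
    """TPS bending energy of the deformation reference -> target, summed
    over coordinate axes. Zero (to rounding) iff the deformation is affine."""
    target = np.asarray(target, dtype=float)
    if target.shape != model.reference.shape:
        raise ValueError(
            f"target shape {target.shape} does not match reference "
            f"{model.reference.shape}"
        )
    disp = target - model.reference
    return float(np.einsum("ia,ij,ja->", disp, model.bending_energy_matrix, disp))


def curve_tangents(
    coords: np.ndarray, template: TemplateDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangent directions for every semilandmark of a configuration.

    Tangents are central differences of the neighboring points of the curve
    chain (anchors included); one-sided differences at chain ends. Returns
    ``(indices, tangents)`` with indices into the landmark list.

    Raises if a curve has fewer than 3 chain points (tangent undefined).
    """
    idx: list[int] = []
    tans: list[np.ndarray] = []
    for c in template.curves:
        chain = c.chain
        if len(chain) < 3:
            raise ValueError(
                f"curve {c.curve_id!r} has {len(chain)} points (< 3, incl. "
                "anchors): tangents undefined"
            )
        pts = coords[list(chain)]
        semi_set = set(c.semilandmarks)
        for pos, lm in enumerate(chain):
            if lm not in semi_set:
                continue
            if pos == 0:
                t = pts[1] - pts[0]
            elif pos == len(chain) - 1:
                t = pts[-1] - pts[-2]
            else:
                t = pts[pos + 1] - pts[pos - 1]
            norm = np.linalg.norm(t)
            if norm < 1e-12:
                raise ValueError(
                    f"degenerate tangent at landmark {lm} on curve "
                    f"{c.curve_id!r}"
                )
            idx.append(lm)
            tans.append(t / norm)
    order = np.argsort(idx)
    return np.array(idx, dtype=int)[order], np.array(tans)[order]


@dataclass
class SlidingResult:
    """Outcome of bending-energy sliding.

    ``configs`` hold the slid coordinates in each specimen's original (raw,
    mm) frame — fixed landmarks bit-identical to the input. Energies refer
    to the final outer pass (reference = final consensus); ``energy_history``
    stores (before, after) arrays per pass.
    """

    configs: list[LandmarkConfiguration]
    bending_energy_before: np.ndarray
    bending_energy_after: np.ndarray
    outer_iterations: int
    energy_history: list[tuple[np.ndarray, np.ndarray]]

    @property
    def slid_coordinates(self) -> np.ndarray:
        return np.stack([c.coordinates for c in self.configs])


def _slide_one(
    aligned_coords: np.ndarray,
    template: TemplateDefinition,
    model: BendingEnergyModel,
) -> tuple[np.ndarray, float, float]:
    """One exact joint sliding solve for one specimen in the aligned frame.

    Minimizes the bending energy of (reference -> slid specimen) over the
    sliding offsets s (one scalar per semilandmark along its unit tangent):
    the quadratic has Hessian A[j,l] = (t_j . t_l) * Lk[i_j, i_l] and
    gradient b = rows of Lk @ D0 projected on the tangents.
    """
    idx, tans = curve_tangents(aligned_coords, template)
    lk = model.bending_energy_matrix
    d0 = aligned_coords - model.reference
    e_before = float(np.einsum("ia,ij,ja->", d0, lk, d0))
    if idx.size == 0:
        return aligned_coords.copy(), e_before, e_before
    a = lk[np.ix_(idx, idx)] * (tans @ tans.T)
    b = np.einsum("ja,ja->j", (lk @ d0)[idx], tans)
    try:
        s = np.linalg.solve(a, -b)
    except np.linalg.LinAlgError:
        s, *_ = np.linalg.lstsq(a, -b, rcond=None)
    slid = aligned_coords.copy()
    slid[idx] += s[:, None] * tans
    d1 = slid - model.reference
    e_after = float(np.einsum("ia,ij,ja->", d1, lk, d1))
    return slid, e_before, e_after


def slide_semilandmarks(
    configs: list[LandmarkConfiguration],
    template: TemplateDefinition,
    reference_mode: str = "consensus",
    outer_iterations: int = 3,
) -> SlidingResult:
    """Slide curve semilandmarks by bending-energy minimization.

    Parameters
    ----------
    reference_mode : "consensus" (sample Procrustes consensus, re-estimated
        each outer pass) or "first" (first specimen's aligned shape).
    outer_iterations : GPA -> slide -> GPA cycles (conventional default 3).

    Returns configurations in the raw frame; fixed landmarks are unchanged
    to machine precision and per-pass bending energy never increases.
    """
    if not template.curves:
        raise ValueError("template declares no semilandmark curves")
    if reference_mode not in ("consensus", "first"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if outer_iterations < 1:
        raise ValueError("outer_iterations must be >= 1")
    for c in template.curves:
        if len(c.chain) < 3:
            raise ValueError(
                f"curve {c.curve_id!r} has {len(c.chain)} points (< 3, incl. "
                "anchors): tangents undefined"
            )

    current = [c.copy() for c in configs]
    history: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(outer_iterations):
        aligned = gpa_align(current, scale=True)
        ref = (
            aligned.consensus
            if reference_mode == "consensus"
            else aligned.shape_coordinates[0]
        )
        model = BendingEnergyModel.from_reference(ref)
        before = np.empty(aligned.n)
        after = np.empty(aligned.n)
        for i in range(aligned.n):
            slid, e0, e1 = _slide_one(
                aligned.shape_coordinates[i], template, model
            )
            before[i] = e0
            after[i] = e1  # exact solve: e1 <= e0 up to rounding
            # map aligned-frame displacement back to the raw frame:
            # raw = aligned @ R^T * CS + centroid
            delta = slid - aligned.shape_coordinates[i]
            raw_delta = (
                delta @ aligned.rotations[i].T * aligned.centroid_sizes[i]
            )
            current[i].coordinates = current[i].coordinates + raw_delta
        history.append((before, after))
    return SlidingResult(
        configs=current,
        bending_energy_before=history[-1][0],
        bending_energy_after=history[-1][1],
        outer_iterations=outer_iterations,
        energy_history=history,
    )


def tps_warp(
    model: BendingEnergyModel, target: np.ndarray, query_points: np.ndarray
) -> np.ndarray:
    """Evaluate the TPS interpolant mapping reference -> target at query
    points. Exactly interpolates the landmarks; identity when target equals
    the reference; equals the affine map when the target is affine."""
    target = np.asarray(target, dtype=float)
    query = np.asarray(query_points, dtype=float)
    if target.shape != model.reference.shape:
        raise ValueError("target does not match the model reference")
    if query.ndim != 2 or query.shape[1] != model.dimension:
        raise ValueError(f"query points must be m x {model.dimension}")
    k, dim = model.reference.shape
    cols = list(model.affine_columns)
    q = np.column_stack([np.ones(k), model.reference])[:, cols]
    m = q.shape[1]
    l = np.zeros((k + m, k + m))
    l[:k, :k] = model.kernel_matrix
    l[:k, k:] = q
    l[k:, :k] = q.T
    rhs = np.zeros((k + m, dim))
    rhs[:k] = target
    coeffs = np.linalg.solve(l, rhs)
    w, a = coeffs[:k], coeffs[k:]
    r = np.sqrt(((query[:, None, :] - model.reference[None, :, :]) ** 2).sum(-1))
    u = _tps_kernel(r, dim)
    return u @ w + np.column_stack([np.ones(len(query)), query])[:, cols] @ a


def mean_difference_field(
    aligned: AlignedDataset,
    labels,
    group_a,
    group_b,
    exaggeration: float = 1.0,
    ts: tuple[float, ...] | None = None,
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Displacement field between two group mean shapes plus warped means.

    Returns ``(field, warps)`` where ``field = exaggeration * (mean_b -
    mean_a)`` per landmark, and ``warps[t] = mean_a + t * (mean_b - mean_a)``
    for each t in ``ts`` (default: -exaggeration, 0, 0.5, 1, 1+exaggeration —
    the exaggerated-A, mean-A, grand-mean, mean-B, exaggerated-B sequence).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != aligned.n:
        raise ValueError("labels length does not match sample size")
    mask_a = labels == group_a
    mask_b = labels == group_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"empty group: {group_a!r} n={mask_a.sum()}, "
                         f"{group_b!r} n={mask_b.sum()}")
    mean_a = aligned.shape_coordinates[mask_a].mean(axis=0)
    mean_b = aligned.shape_coordinates[mask_b].mean(axis=0)
    diff = mean_b - mean_a
    if ts is None:
        ts = (-exaggeration, 0.0, 0.5, 1.0, 1.0 + exaggeration)
    warps = {float(t): mean_a + t * diff for t in ts}
    return exaggeration * diff, warps
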