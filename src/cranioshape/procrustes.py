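"""Ordinary and Generalized Procrustes superimposition.

Shape is what remains of a landmark configuration after location, scale and
orientation are removed.  Size is measured by centroid size (the square root
of the summed squared distances of the landmarks to their centroid) and is
removed by scaling every configuration to centroid size one.  Orientation is
removed by proper rotations only (determinant +1): anatomical landmark sets
are chirally meaningful, so reflections are never absorbed.

Generalized Procrustes Analysis (GPA) iterates rotation of all configurations
to their running consensus until the consensus stabilizes, leaving pure shape
coordinates in which downstream statistics (PCA, group distances, PLS) are
computed directly, without an explicit tangent projection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkConfiguration, SampleSet

__all__ = [
    "AlignedSampleSet",
    "PairAlignment",
    "centroid_size",
    "align_pair",
    "gpa",
    "procrustes_distance",
]

logger = logging.getLogger(__name__)

_DEGENERATE_EPS = 1e-12


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark deviations from the centroid.

    Scales linearly with the configuration and is invariant to translation
    and rotation.  Raises on a degenerate (all-coincident) configuration.
    """
    coords = config.coordinates if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size <= _DEGENERATE_EPS:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return size


def _optimal_rotation(target: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Proper rotation R (d x d) minimizing ||target - source @ R||_F.

    Solved by SVD of the cross-product matrix with a determinant correction:
    if the best orthogonal map is a reflection, the axis of the smallest
    singular value is flipped.
    """
    H = source.T @ target
    U, _s, Vt = np.linalg.svd(H)
    D = np.eye(H.shape[0])
    D[-1, -1] = np.sign(np.linalg.det(U @ Vt))
    return U @ D @ Vt


@dataclass
class PairAlignment:
    """Result of ordinary (two-configuration) Procrustes superimposition."""

    rotation: np.ndarray  # d x d proper rotation applied to the moving shape
    scale: float  # least-squares optimal scale applied to the moving shape
    aligned: np.ndarray  # moving shape superimposed on the reference (k x d)
    residual: float  # minimized sum of squared landmark distances


def align_pair(
    reference: LandmarkConfiguration | np.ndarray,
    moving: LandmarkConfiguration | np.ndarray,
) -> PairAlignment:
    """Superimpose ``moving`` on ``reference`` by translation, rotation, scale.

    The moving configuration is centered, rotated by the optimal proper
    rotation, and scaled by the least-squares optimal factor; the returned
    ``aligned`` copy is translated onto the reference centroid.  The residual
    is the minimized sum of squares; a reflected copy keeps a strictly
    positive residual because reflections are not absorbed.
    """
    A = reference.coordinates if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    B = moving.coordinates if isinstance(moving, LandmarkConfiguration) else np.asarray(moving, float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    centroid_A = A.mean(axis=0)
    Ac = A - centroid_A
    Bc = B - B.mean(axis=0)
    if np.sum(Ac**2) <= _DEGENERATE_EPS or np.sum(Bc**2) <= _DEGENERATE_EPS:
        raise ValueError("degenerate configuration: all landmarks coincide")
    R = _optimal_rotation(Ac, Bc)
    rotated = Bc @ R
    # least-squares optimal scale for min ||Ac - s * rotated||^2
    scale = float(np.sum(Ac * rotated) / np.sum(rotated**2))
    fitted = scale * rotated
    residual = float(np.sum((Ac - fitted) ** 2))
    return PairAlignment(rotation=R, scale=scale, aligned=fitted + centroid_A, residual=residual)


@dataclass
class AlignedSampleSet:
    """Procrustes-superimposed sample: unit-centroid-size, centered coordinates.

    ``aligned`` holds n specimens of k x d dimensionless shape coordinates;
    ``centroid_sizes`` keeps the original physical sizes (mm); ``consensus``
    is the mean shape rescaled to unit centroid size and rotated to its
    principal axes (a deterministic canonical orientation, so the consensus
    does not depend on specimen input order).
    """

    aligned: np.ndarray  # (n, k, d)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, d)
    specimen_ids: list[str]
    groups: dict[str, str]
    structure: str = "custom"
    stage: str = ""
    iterations: int = 0
    converged: bool = True
    tolerance: float = 1e-10
    residual_history: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def d(self) -> int:
        return self.aligned.shape[2]

    def flattened(self) -> np.ndarray:
        """(n, k*d) view of the aligned coordinates."""
        return self.aligned.reshape(self.n, -1)

    def group_indices(self, label: str) -> np.ndarray:
        return np.array(
            [i for i, sid in enumerate(self.specimen_ids) if self.groups.get(sid) == label],
            dtype=int,
        )

    def subset(self, specimen_ids: list[str]) -> "AlignedSampleSet":
        """Row-subset in the given id order, keeping the common frame."""
        index = {sid: i for i, sid in enumerate(self.specimen_ids)}
        rows = [index[s] for s in specimen_ids]
        return AlignedSampleSet(
            aligned=self.aligned[rows],
            centroid_sizes=self.centroid_sizes[rows],
            consensus=self.consensus,
            specimen_ids=list(specimen_ids),
            groups={s: self.groups[s] for s in specimen_ids},
            structure=self.structure,
            stage=self.stage,
            iterations=self.iterations,
            converged=self.converged,
            tolerance=self.tolerance,
        )


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus to its principal axes.

    Column signs are fixed so the largest-magnitude loading of each of the
    first d-1 axes is positive (sign flips applied in pairs to keep the
    rotation proper), making the orientation deterministic.
    """
    d = consensus.shape[1]
    _U, _s, Vt = np.linalg.svd(consensus, full_matrices=False)
    R = Vt.T
    if np.linalg.det(R) < 0:
        R[:, -1] *= -1
    rotated = consensus @ R
    for j in range(d - 1):
        col = rotated[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            R[:, j] *= -1
            R[:, -1] *= -1
            rotated = consensus @ R
    return R


def gpa(
    sample: SampleSet,
    tolerance: float = 1e-10,
    max_iterations: int = 500,
) -> AlignedSampleSet:
    """Generalized Procrustes Analysis of a homogeneous sample.

    All configurations are centered and scaled to unit centroid size, rotated
    to the first specimen as initial reference, then repeatedly rotated to the
    running consensus (the mean shape rescaled to unit centroid size) until
    the consensus moves less than ``tolerance`` between iterations.  The
    summed squared residual about the mean is non-increasing across
    iterations.  Non-convergence returns a result flagged
    ``converged=False`` with a logged warning.
    """
    if sample.n < 2:
        raise ValueError("GPA requires at least 2 configurations")
    X = sample.coordinates_array().astype(float)
    n = X.shape[0]

    sizes = np.empty(n)
    for i in range(n):
        X[i] = X[i] - X[i].mean(axis=0)
        sizes[i] = np.sqrt(np.sum(X[i] ** 2))
        if sizes[i] <= _DEGENERATE_EPS:
            raise ValueError(
                f"degenerate configuration {sample.configurations[i].specimen_id!r}"
            )
        X[i] /= sizes[i]

    # initial alignment to the first specimen
    for i in range(1, n):
        X[i] = X[i] @ _optimal_rotation(X[0], X[i])
    mean = X.mean(axis=0)
    consensus = mean / np.sqrt(np.sum(mean**2))

    residuals: list[float] = [float(np.sum((X - mean) ** 2))]
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(consensus, X[i])
        mean = X.mean(axis=0)
        residuals.append(float(np.sum((X - mean) ** 2)))
        new_consensus = mean / np.sqrt(np.sum(mean**2))
        delta = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iterations} iterations "
            f"(structure={sample.structure!r}, stage={sample.stage!r})",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("GPA non-convergence after %d iterations", max_iterations)

    # canonical orientation: principal axes of the consensus
    R = _canonical_orientation(consensus)
    consensus = consensus @ R
    X = X @ R

    return AlignedSampleSet(
        aligned=X,
        centroid_sizes=sizes,
        consensus=consensus,
        specimen_ids=sample.specimen_ids,
        groups=sample.group_labels,
        structure=sample.structure,
        stage=sample.stage,
        iterations=iterations,
        converged=converged,
        tolerance=tolerance,
        residual_history=residuals,
    )


def procrustes_distance(
    shape1: np.ndarray,
    shape2: np.ndarray,
    mode: str = "fixed",
) -> float:
    """Procrustes distance between two k x d shapes.

    ``mode='fixed'``: the square root of the summed squared landmark-wise
    differences, for shapes already expressed in a common superimposition
    frame (the metric used for group mean comparisons and deviance scores).

    ``mode='optimal'``: both shapes are first centered and scaled to unit
    centroid size, the moving shape is optimally rotated (proper rotations
    only) and rescaled; the minimized root-sum-of-squares is returned.  Zero
    iff the shapes are identical up to a similarity transform.
    """
    A = np.asarray(shape1, float)
    B = np.asarray(shape2, float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if mode == "fixed":
        return float(np.sqrt(np.sum((A - B) ** 2)))
    if mode == "optimal":
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        na, nb = np.sqrt(np.sum(Ac**2)), np.sqrt(np.sum(Bc**2))
        if na <= _DEGENERATE_EPS or nb <= _DEGENERATE_EPS:
            raise ValueError("degenerate configuration")
        Ac /= na
        Bc /= nb
        R = _optimal_rotation(Ac, Bc)
        # optimal scale for unit-norm preshapes is the alignment trace itself
        trace = float(np.sum(Ac * (Bc @ R)))
        return float(np.sqrt(max(0.0, 1.0 - trace**2)))
    raise ValueError(f"unknown mode {mode!r}")
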