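"""Morphospace construction: PCA of shape coordinates and derived measures.

After superimposition the aligned coordinates live in a high-dimensional
shape space; principal component analysis of their covariance matrix yields
uncorrelated axes ordered by the amount of shape variation they carry.  The
first two components span the morphospace in which groups are compared
visually.  Shapes along an axis ("morphings") are reconstructed as
``mean + score * axis``.

Linear measures (e.g. the cephalic index, a width-to-length ratio used as a
proxy for brachycephaly) are computed from raw physical coordinates, with
per-stage landmark-index overrides for stages digitized with a different
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkConfiguration
from .procrustes import AlignedSampleSet

__all__ = [
    "PCAResult",
    "MeasureDefinition",
    "pca",
    "shape_at_score",
    "score_of_shape",
    "derived_measures",
    "default_brain_measures",
]

_NULL_EIGENVALUE_RATIO = 1e-12


@dataclass
class PCAResult:
    """Eigen-decomposition of the covariance of flattened shape coordinates.

    ``axes`` are unit-norm component vectors in the flattened k*d space with
    each axis' sign fixed so its largest-magnitude loading is positive.
    Components in the similarity null space left by superimposition
    (eigenvalue <= 1e-12 x leading) are dropped; ``zero_variance`` flags a
    totally degenerate sample.
    """

    mean_shape: np.ndarray  # (k, d)
    eigenvalues: np.ndarray  # non-increasing, length n_components
    percent_variance: np.ndarray  # share of total variance, sums to ~100
    scores: np.ndarray  # (n, n_components), zero column means
    axes: np.ndarray  # (n_components, k*d), unit norm rows
    k: int
    d: int
    total_variance: float
    zero_variance: bool = False

    @property
    def n_components(self) -> int:
        return self.axes.shape[0]


def pca(aligned: AlignedSampleSet) -> PCAResult:
    """PCA of Procrustes coordinates (covariance matrix, divisor n-1)."""
    if aligned.n < 3:
        raise ValueError(f"PCA requires n >= 3 specimens, got {aligned.n}")
    X = aligned.flattened()
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    total_variance = float(np.sum(Xc**2) / (n - 1))
    k, d = aligned.k, aligned.d

    if total_variance <= _NULL_EIGENVALUE_RATIO:
        return PCAResult(
            mean_shape=mean.reshape(k, d),
            eigenvalues=np.zeros(0),
            percent_variance=np.zeros(0),
            scores=np.zeros((n, 0)),
            axes=np.zeros((0, p)),
            k=k,
            d=d,
            total_variance=0.0,
            zero_variance=True,
        )

    _U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > _NULL_EIGENVALUE_RATIO * eigenvalues[0]
    eigenvalues = eigenvalues[keep]
    axes = Vt[keep]

    # deterministic sign: largest-magnitude loading positive
    for j in range(axes.shape[0]):
        if axes[j, np.argmax(np.abs(axes[j]))] < 0:
            axes[j] = -axes[j]

    scores = Xc @ axes.T
    percent = 100.0 * eigenvalues / total_variance
    return PCAResult(
        mean_shape=mean.reshape(k, d),
        eigenvalues=eigenvalues,
        percent_variance=percent,
        scores=scores,
        axes=axes,
        k=k,
        d=d,
        total_variance=total_variance,
    )


def shape_at_score(result: PCAResult, axis: int, score: float) -> np.ndarray:
    """Reconstruct the k x d shape at a given score along one component."""
    if not 0 <= axis < result.n_components:
        raise ValueError(f"axis {axis} out of range (have {result.n_components})")
    flat = result.mean_shape.reshape(-1) + score * result.axes[axis]
    return flat.reshape(result.k, result.d)


def score_of_shape(result: PCAResult, shape: np.ndarray, axis: int) -> float:
    """Project a shape onto one component axis (inverse of shape_at_score)."""
    if not 0 <= axis < result.n_components:
        raise ValueError(f"axis {axis} out of range (have {result.n_components})")
    return float((np.asarray(shape).reshape(-1) - result.mean_shape.reshape(-1)) @ result.axes[axis])


# ---------------------------------------------------------------------------
# Derived linear measures
# ---------------------------------------------------------------------------

IndexPair = tuple[int, int]


@dataclass
class MeasureDefinition:
    """A named distance or ratio defined on 1-based landmark indices.

    ``indices`` holds one pair for a distance, or (numerator pair,
    denominator pair) for a ratio.  ``stage_overrides`` maps a stage label to
    alternative indices of the same form, for stages whose landmark scheme
    differs.
    """

    name: str
    kind: str  # "distance" | "ratio"
    indices: IndexPair | tuple[IndexPair, IndexPair]
    stage_overrides: dict[str, IndexPair | tuple[IndexPair, IndexPair]] = field(
        default_factory=dict
    )

    def resolve(self, stage: str) -> IndexPair | tuple[IndexPair, IndexPair]:
        return self.stage_overrides.get(stage, self.indices)


def _point(config: LandmarkConfiguration, index_1based: int, measure: str) -> np.ndarray:
    if not 1 <= index_1based <= config.k:
        raise ValueError(
            f"measure {measure!r} (stage {config.stage!r}): landmark index "
            f"{index_1based} out of range 1..{config.k}"
        )
    return config.coordinates[index_1based - 1]


def _distance(config: LandmarkConfiguration, pair: IndexPair, measure: str) -> float:
    a = _point(config, pair[0], measure)
    b = _point(config, pair[1], measure)
    return float(np.linalg.norm(a - b))


def derived_measures(
    config: LandmarkConfiguration,
    definitions: list[MeasureDefinition],
) -> dict[str, float]:
    """Evaluate distance/ratio measures on one configuration's raw coordinates.

    Distances are in the configuration's physical units (mm); ratios are
    dimensionless.  Stage overrides are resolved against ``config.stage``
    before indexing; an out-of-range index raises naming the measure and
    stage.
    """
    out: dict[str, float] = {}
    for md in definitions:
        idx = md.resolve(config.stage)
        if md.kind == "distance":
            out[md.name] = _distance(config, idx, md.name)  # type: ignore[arg-type]
        elif md.kind == "ratio":
            num, den = idx  # type: ignore[misc]
            denominator = _distance(config, den, md.name)
            if denominator == 0.0:
                raise ValueError(f"measure {md.name!r}: zero denominator distance")
            out[md.name] = _distance(config, num, md.name) / denominator
        else:
            raise ValueError(f"measure {md.name!r}: unknown kind {md.kind!r}")
    return out


def default_brain_measures() -> list[MeasureDefinition]:
    """Standard brain measures: cephalic index (width 4-5 over length 1-3,
    with the length pair 1-11 at PD3), olfactory-bulb length (1-2) and
    cerebellum length (10-3)."""
    return [
        MeasureDefinition(
            name="cephalic_index",
            kind="ratio",
            indices=((4, 5), (1, 3)),
            stage_overrides={"PD3": ((4, 5), (1, 11))},
        ),
        MeasureDefinition(name="olfactory_bulb_length", kind="distance", indices=(1, 2)),
        MeasureDefinition(name="cerebellum_length", kind="distance", indices=(10, 3)),
    ]
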