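"""Two-block partial least squares analysis of morphological integration.

Integration between two anatomical structures (here brain and skull) is the
tendency of their shapes to covary across individuals.  Each block is
superimposed by its own separate GPA (the structures come from different
imaging modalities), the flattened coordinates are column-centered, and the
singular value decomposition of the inter-block covariance matrix yields
paired axes ordered by the amount of covariation they carry.  The Pearson
correlation of paired axis scores summarizes each axis pair; the RV
coefficient — a trace-based multivariate analogue of the squared correlation
— summarizes the overall magnitude of integration.

Significance is assessed by permutation under the null of complete
independence between blocks: rows of the second block are randomly re-paired
against the first and the statistic (first singular value, or RV) is
recomputed per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .group_inference import PermutationTestResult
from .procrustes import AlignedSampleSet

__all__ = [
    "PLSResult",
    "two_block_pls",
    "rv_coefficient",
    "pls_permutation_test",
    "pls_axis_shapes",
    "pls_group_slopes",
]

_RANK_EPS = 1e-12


@dataclass
class PLSResult:
    """Paired singular axes of the inter-block covariance matrix.

    ``blockX_axes`` are unit-norm vectors in each block's flattened landmark
    space; ``blockX_scores`` are the centered data projected on them.  The
    sign of the first block-2 axis is flipped if needed so the first axis
    correlation is non-negative.  ``percent_covariance`` is each axis pair's
    share of the total squared covariance (sums to 100).
    """

    singular_values: np.ndarray
    percent_covariance: np.ndarray
    block1_axes: np.ndarray  # (n_axes, p1)
    block2_axes: np.ndarray  # (n_axes, p2)
    block1_scores: np.ndarray  # (n, n_axes)
    block2_scores: np.ndarray  # (n, n_axes)
    axis_correlations: np.ndarray
    rv: float
    specimen_ids: list[str]
    groups: dict[str, str]
    block1_mean: np.ndarray  # (k1, d1)
    block2_mean: np.ndarray  # (k2, d2)
    rv_p_value: float | None = None
    axis1_p_value: float | None = None
    seed: int | None = None
    n_permutations: int = 0
    # centered data kept for permutation tests and slope summaries
    block1_centered: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    block2_centered: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return self.block1_scores.shape[0]

    @property
    def n_axes(self) -> int:
        return self.singular_values.size


def rv_coefficient(block1: np.ndarray, block2: np.ndarray) -> float:
    """RV coefficient between two variable blocks (rows = specimens).

    RV = trace(S12 S21) / sqrt(trace(S11^2) trace(S22^2)), with S the
    empirical (co)variance blocks of the column-centered data.  Lies in
    [0, 1]; equals the squared Pearson correlation for single-column blocks
    and is invariant to orthogonal transformations within a block.
    """
    X = np.asarray(block1, float)
    Y = np.asarray(block2, float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    n = X.shape[0]
    if n < 3:
        raise ValueError("RV requires n >= 3")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S11 = Xc.T @ Xc / (n - 1)
    S22 = Yc.T @ Yc / (n - 1)
    S12 = Xc.T @ Yc / (n - 1)
    denom = np.sqrt(np.sum(S11**2) * np.sum(S22**2))
    if denom <= _RANK_EPS:
        raise ValueError("zero total variance in a block: RV undefined")
    # trace(S12 @ S21) equals the squared Frobenius norm of S12
    return float(np.sum(S12**2) / denom)


def two_block_pls(
    block1: AlignedSampleSet,
    block2: AlignedSampleSet,
    pairing: dict[str, str] | None = None,
    group: str | None = None,
) -> PLSResult:
    """Two-block PLS of paired aligned samples.

    Specimens are paired on shared ids (or via ``pairing``, mapping block-1
    ids to block-2 ids); specimens missing from either block are excluded
    pairwise.  ``group`` restricts the analysis to one group's pairs.
    Scores of distinct axes within a block are mutually orthogonal within
    the data rank, and the sum of squared singular values equals the squared
    Frobenius norm of the inter-block covariance matrix.
    """
    if pairing is None:
        ids2 = set(block2.specimen_ids)
        shared = [s for s in block1.specimen_ids if s in ids2]
        pairing_list = [(s, s) for s in shared]
    else:
        ids2 = set(block2.specimen_ids)
        pairing_list = [
            (a, b) for a, b in pairing.items() if a in set(block1.specimen_ids) and b in ids2
        ]
    if group is not None:
        pairing_list = [(a, b) for a, b in pairing_list if block1.groups.get(a) == group]
    if not pairing_list:
        raise ValueError("no overlapping specimens between blocks")
    if len(pairing_list) < 3:
        raise ValueError(f"PLS requires >= 3 paired specimens, got {len(pairing_list)}")

    sub1 = block1.subset([a for a, _ in pairing_list])
    sub2 = block2.subset([b for _, b in pairing_list])
    X = sub1.flattened()
    Y = sub2.flattened()
    n = X.shape[0]
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    C = Xc.T @ Yc / (n - 1)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    keep = s > _RANK_EPS * max(s[0], _RANK_EPS)
    s = s[keep]
    U = U[:, keep]
    Vt = Vt[keep]

    # deterministic block-1 axis signs (largest-magnitude loading positive),
    # block-2 axes follow through the SVD pairing
    for j in range(U.shape[1]):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] *= -1
            Vt[j] *= -1

    scores1 = Xc @ U
    scores2 = Yc @ Vt.T
    correlations = np.array(
        [
            stats.pearsonr(scores1[:, j], scores2[:, j])[0]
            if np.std(scores1[:, j]) > 0 and np.std(scores2[:, j]) > 0
            else np.nan
            for j in range(s.size)
        ]
    )
    # first-pair convention: flip the block-2 axis alone so corr_1 >= 0
    if s.size and np.isfinite(correlations[0]) and correlations[0] < 0:
        Vt[0] *= -1
        scores2[:, 0] *= -1
        correlations[0] = -correlations[0]

    total_sq = float(np.sum(s**2))
    percent = 100.0 * s**2 / total_sq if total_sq > 0 else np.zeros_like(s)

    return PLSResult(
        singular_values=s,
        percent_covariance=percent,
        block1_axes=U.T,
        block2_axes=Vt,
        block1_scores=scores1,
        block2_scores=scores2,
        axis_correlations=correlations,
        rv=rv_coefficient(Xc, Yc),
        specimen_ids=sub1.specimen_ids,
        groups={s_: sub1.groups[s_] for s_ in sub1.specimen_ids},
        block1_mean=x_mean.reshape(sub1.k, sub1.d),
        block2_mean=y_mean.reshape(sub2.k, sub2.d),
        block1_centered=Xc,
        block2_centered=Yc,
    )


def pls_permutation_test(
    result: PLSResult,
    n_permutations: int = 999,
    seed: int | None = 0,
    statistic: str = "axis1_singular_value",
) -> PermutationTestResult:
    """Permutation test under the null of complete block independence.

    Rows of block 2 are randomly re-paired against block 1 and the statistic
    (``'axis1_singular_value'``, ``'rv'`` or ``'axis1_correlation'``)
    recomputed per draw; p = (count >= observed + 1) / (N + 1),
    deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Xc = result.block1_centered
    Yc = result.block2_centered
    n = Xc.shape[0]
    rng = np.random.default_rng(seed)

    if statistic == "rv":
        observed = result.rv
        S11 = Xc.T @ Xc
        S22 = Yc.T @ Yc
        denom = np.sqrt(np.sum(S11**2) * np.sum(S22**2))

        def stat(Yp: np.ndarray) -> float:
            S12 = Xc.T @ Yp
            return float(np.sum(S12**2) / denom)

    elif statistic == "axis1_singular_value":
        observed = float(result.singular_values[0])

        def stat(Yp: np.ndarray) -> float:
            C = Xc.T @ Yp / (n - 1)
            return float(np.linalg.svd(C, compute_uv=False)[0])

    elif statistic == "axis1_correlation":
        observed = float(abs(result.axis_correlations[0]))
        u = result.block1_axes[0]
        v = result.block2_axes[0]
        x_scores = Xc @ u

        def stat(Yp: np.ndarray) -> float:
            y_scores = Yp @ v
            if np.std(y_scores) == 0:
                return 0.0
            return float(abs(stats.pearsonr(x_scores, y_scores)[0]))

    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    b = 0
    for _ in range(n_permutations):
        Yp = Yc[rng.permutation(n)]
        if stat(Yp) >= observed:
            b += 1
    return PermutationTestResult(
        observed_statistic=observed,
        n_permutations=n_permutations,
        n_as_extreme=b,
        p_value=(b + 1) / (n_permutations + 1),
        seed=seed,
        statistic_name=f"pls_{statistic}",
        exhaustive=False,
    )


def pls_axis_shapes(
    result: PLSResult, axis: int, score: float
) -> tuple[np.ndarray, np.ndarray]:
    """Paired block shapes at a given score along one PLS axis pair.

    Each block's consensus is deformed by ``score`` times its axis vector —
    the paired "morphings" that express, e.g., how more brachycephalic
    skulls go with wider, shorter brains.
    """
    if not 0 <= axis < result.n_axes:
        raise ValueError(f"axis {axis} out of range (have {result.n_axes})")
    k1, d1 = result.block1_mean.shape
    k2, d2 = result.block2_mean.shape
    s1 = result.block1_mean.reshape(-1) + score * result.block1_axes[axis]
    s2 = result.block2_mean.reshape(-1) + score * result.block2_axes[axis]
    return s1.reshape(k1, d1), s2.reshape(k2, d2)


def pls_group_slopes(result: PLSResult, axis: int = 0) -> dict[str, float]:
    """Per-group standardized major-axis slope of block-2 vs block-1 scores.

    The SMA slope sign(r) * sd(y) / sd(x) summarizes how the two blocks
    covary within each group; parallel slopes across groups indicate a
    shared covariation pattern.  Exactly 1 when block 2 duplicates block 1.
    """
    if not 0 <= axis < result.n_axes:
        raise ValueError(f"axis {axis} out of range (have {result.n_axes})")
    x = result.block1_scores[:, axis]
    y = result.block2_scores[:, axis]
    labels = np.array([result.groups[s] for s in result.specimen_ids])
    slopes: dict[str, float] = {}
    for g in sorted(set(labels)):
        sel = labels == g
        if sel.sum() < 3 or np.std(x[sel]) == 0 or np.std(y[sel]) == 0:
            slopes[g] = float("nan")
            continue
        r = stats.pearsonr(x[sel], y[sel])[0]
        slopes[g] = float(np.sign(r) * np.std(y[sel]) / np.std(x[sel]))
    return slopes
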