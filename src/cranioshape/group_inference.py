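"""Group mean-shape comparison, permutation inference, and deviance scoring.

Group shape differences are quantified as the Procrustes distance between the
two group mean shapes inside the joint superimposition frame (the frame is
label-blind, so it is not recomputed per permutation).  Significance comes
from permuting group labels over the pooled specimens with group sizes
preserved, one-tailed on large distances, with the Monte-Carlo convention
p = (b + 1) / (N + 1).  When the number of distinct label partitions is small
the null is enumerated exhaustively instead.

Per-individual dysmorphology ("deviance") is a specimen's Procrustes distance
to the consensus of a designated reference group (here the untreated
wild types); correlating brain and skull deviances per group asks whether
more dysmorphic brains accompany more dysmorphic skulls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .procrustes import AlignedSampleSet

__all__ = [
    "PermutationTestResult",
    "mean_shape_distance",
    "permutation_test_distance",
    "deviance_scores",
    "deviance_correlation",
]

EXHAUSTIVE_PARTITION_LIMIT = 20_000


@dataclass
class PermutationTestResult:
    """Observed statistic, null summary and p-value of a permutation test.

    The convention p = (n_as_extreme + 1) / (n_permutations + 1) counts the
    observed statistic as one member of the null, guaranteeing validity and
    p >= 1 / (n_permutations + 1).
    """

    observed_statistic: float
    n_permutations: int
    n_as_extreme: int
    p_value: float
    seed: int | None
    statistic_name: str
    exhaustive: bool = False


def _group_rows(aligned: AlignedSampleSet, label: str, min_n: int = 1) -> np.ndarray:
    rows = aligned.group_indices(label)
    if rows.size == 0:
        raise ValueError(f"group {label!r} is empty or absent")
    if rows.size < min_n:
        raise ValueError(f"group {label!r} has n={rows.size} < {min_n}")
    return rows


def mean_shape_distance(aligned: AlignedSampleSet, group_a: str, group_b: str) -> float:
    """Procrustes distance (fixed frame) between two group mean shapes."""
    X = aligned.flattened()
    ra = _group_rows(aligned, group_a)
    rb = _group_rows(aligned, group_b)
    return float(np.linalg.norm(X[ra].mean(axis=0) - X[rb].mean(axis=0)))


def permutation_test_distance(
    aligned: AlignedSampleSet,
    group_a: str,
    group_b: str,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    exhaustive: str | bool = "auto",
) -> PermutationTestResult:
    """Permutation test of the mean-shape distance between two groups.

    Pooled specimens are randomly reassigned to the two groups (sizes
    preserved); the null is one-tailed on large distances.  When the number
    of distinct partitions C(n, n_a) does not exceed 20,000 (and
    ``exhaustive`` is ``'auto'`` or True) the null is enumerated completely;
    otherwise ``n_permutations`` Monte-Carlo draws are used, deterministic
    given ``seed``.  The result is invariant to swapping the two group
    labels.
    """
    ra = _group_rows(aligned, group_a, min_n=1)
    rb = _group_rows(aligned, group_b, min_n=1)
    if set(ra) & set(rb):
        raise ValueError("groups overlap")
    if ra.size + rb.size < 4:
        raise ValueError("need at least 4 specimens pooled for a meaningful null")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    # canonical internal order so the p-value is label-order invariant
    swap = group_b < group_a
    first, second = (rb, ra) if swap else (ra, rb)

    X = aligned.flattened()
    pooled = np.concatenate([first, second])
    Xp = X[pooled]
    na = first.size
    n = pooled.size
    observed = float(np.linalg.norm(Xp[:na].mean(axis=0) - Xp[na:].mean(axis=0)))

    n_partitions = comb(n, na)
    use_exhaustive = (
        exhaustive is True
        or (exhaustive == "auto" and n_partitions <= EXHAUSTIVE_PARTITION_LIMIT)
    )

    if use_exhaustive:
        count = 0
        rows = np.arange(n)
        for combo in itertools.combinations(rows, na):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            dist = float(np.linalg.norm(Xp[sel].mean(axis=0) - Xp[~sel].mean(axis=0)))
            if dist >= observed:
                count += 1
        return PermutationTestResult(
            observed_statistic=observed,
            n_permutations=n_partitions - 1,
            n_as_extreme=count - 1,
            p_value=count / n_partitions,
            seed=seed,
            statistic_name="mean_shape_procrustes_distance",
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    idx = np.tile(np.arange(n), (n_permutations, 1))
    idx = rng.permuted(idx, axis=1)
    A = Xp[idx[:, :na]].mean(axis=1)
    B = Xp[idx[:, na:]].mean(axis=1)
    null = np.linalg.norm(A - B, axis=1)
    b = int(np.sum(null >= observed))
    return PermutationTestResult(
        observed_statistic=observed,
        n_permutations=n_permutations,
        n_as_extreme=b,
        p_value=(b + 1) / (n_permutations + 1),
        seed=seed,
        statistic_name="mean_shape_procrustes_distance",
        exhaustive=False,
    )


def deviance_scores(aligned: AlignedSampleSet, reference_group: str) -> pd.DataFrame:
    """Per-specimen Procrustes distance to the reference-group consensus.

    The reference consensus is the arithmetic mean of the reference group's
    aligned coordinates within the joint superimposition frame; reference
    specimens are scored too (their spread indexes normal intra-group
    variation).  Returns a tidy table with columns ``specimen_id, group,
    structure, stage, deviance``.
    """
    rows = _group_rows(aligned, reference_group, min_n=2)
    X = aligned.flattened()
    consensus = X[rows].mean(axis=0)
    deviances = np.linalg.norm(X - consensus, axis=1)
    return pd.DataFrame(
        {
            "specimen_id": aligned.specimen_ids,
            "group": [aligned.groups[s] for s in aligned.specimen_ids],
            "structure": aligned.structure,
            "stage": aligned.stage,
            "deviance": deviances,
        }
    )


def deviance_correlation(
    brain: pd.DataFrame,
    skull: pd.DataFrame,
    by_group: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of paired brain vs skull deviances.

    Tables are joined on ``specimen_id``; only specimens present in both are
    used.  With ``by_group`` the correlation is computed within each group
    (n >= 3 required); p-values come from the t-distribution with n-2 df.
    Zero variance in either variable makes the correlation undefined for
    that group (reported with ``computable=False``).
    """
    merged = brain.merge(skull, on="specimen_id", suffixes=("_brain", "_skull"))
    if merged.empty:
        raise ValueError("no shared specimens between the two deviance tables")
    merged["group"] = merged["group_brain"]
    groups = sorted(merged["group"].unique()) if by_group else ["all"]

    records = []
    for g in groups:
        sub = merged if g == "all" else merged[merged["group"] == g]
        x = sub["deviance_brain"].to_numpy()
        y = sub["deviance_skull"].to_numpy()
        n = len(sub)
        if n < 3:
            records.append({"group": g, "n": n, "r": np.nan, "p_value": np.nan, "computable": False})
            continue
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            records.append({"group": g, "n": n, "r": np.nan, "p_value": np.nan, "computable": False})
            continue
        r, p = stats.pearsonr(x, y)
        records.append({"group": g, "n": n, "r": float(r), "p_value": float(p), "computable": True})
    return pd.DataFrame.from_records(records)
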