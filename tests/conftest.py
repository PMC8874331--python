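import numpy as np
import pytest

from cranioshape.landmark_io import LandmarkConfiguration, SampleSet
from cranioshape.procrustes import AlignedSampleSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_configuration(rng, k=5, d=3, specimen_id="s", group="G", stage="PD3",
                         structure="custom", scale_range=(5.0, 15.0)):
    lo, hi = scale_range
    coords = rng.uniform(lo, hi, size=(k, d))
    return LandmarkConfiguration(
        specimen_id=specimen_id, coordinates=coords, structure=structure,
        stage=stage, group=group,
    )


def random_sample_set(rng, n=6, k=5, d=3, groups=("A", "B"), stage="PD3",
                      structure="custom"):
    configs = []
    for i in range(n):
        g = groups[i % len(groups)]
        configs.append(
            random_configuration(
                rng, k=k, d=d, specimen_id=f"{g}{i:02d}", group=g,
                stage=stage, structure=structure,
            )
        )
    return SampleSet(configurations=configs, structure=structure, stage=stage)


def make_aligned(X, groups, structure="custom", stage="PD3"):
    """Wrap an (n, k, d) array as an AlignedSampleSet for controlled tests.

    No superimposition is performed; the frame is taken as given.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    ids = [f"s{i:02d}" for i in range(n)]
    mean = X.mean(axis=0)
    size = np.sqrt(np.sum((mean - mean.mean(axis=0)) ** 2))
    consensus = (mean - mean.mean(axis=0)) / size if size > 0 else mean
    return AlignedSampleSet(
        aligned=X,
        centroid_sizes=np.ones(n),
        consensus=consensus,
        specimen_ids=ids,
        groups={sid: g for sid, g in zip(ids, groups)},
        structure=structure,
        stage=stage,
    )


def random_rotation(rng, d):
    """Haar-ish random proper rotation."""
    M = rng.standard_normal((d, d))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
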