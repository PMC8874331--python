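"""Synthetic developmental cohorts with known ground truth.

The generator emulates the statistical structure of a paired brain/skull
landmark study across postnatal stages: per-group mean-shape offsets,
stage-dependent isotropic growth, isotropic Gaussian landmark (digitizing)
noise, a shared per-specimen latent factor that induces brain-skull
covariation of tunable strength, group-shifted milestone-day distributions,
and volume-like scalar traits.  Every draw is deterministic given one global
seed, which is expanded into independent substreams (shapes, milestones,
traits) so adding one component never perturbs another's draws.

The latent-factor construction: a standard-normal scalar ``z`` per specimen
and stage enters every structure as
``rho * noise_sd * sqrt(k*d) * z * loading`` with a unit-norm loading
vector, so the integration strength ``rho`` is the per-coordinate RMS
displacement of the shared factor in units of the landmark-noise standard
deviation (at ``rho = 1`` the integration signal and the digitizing noise
move each coordinate equally hard).  Loadings are projected orthogonal to
the similarity directions (translation, scaling, rotation) at the template,
so superimposition does not absorb the integration signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .integration import rv_coefficient
from .landmark_io import LandmarkConfiguration, SampleSet
from .univariate import MilestoneRecord, milestone_frame

__all__ = [
    "StructureSpec",
    "MilestoneSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "GroundTruth",
    "brain_template",
    "skull_template",
    "ventricle_template",
    "project_out_similarity",
    "default_config",
    "simulate_shape_cohort",
    "simulate_milestones",
    "simulate_traits",
    "true_rv",
    "loading_in_aligned_frame",
    "with_strength",
]

DEFAULT_GROUPS = {"WT": 12, "TS": 8, "WT_T": 13, "TS_T": 9}
DEFAULT_STAGES = {"PD3": 1.0, "PD14": 1.4, "PD29": 1.6}


# ---------------------------------------------------------------------------
# Templates (mm, deterministic)
# ---------------------------------------------------------------------------

def brain_template() -> np.ndarray:
    """10 landmarks on an idealized pup brain (half-axes 8 x 6 x 5 mm).

    Landmark semantics used by the derived measures: 1/3 anterior and
    posterior poles (length), 4/5 lateral extremes (width), 2 olfactory-bulb
    boundary, 10 cerebellum boundary.
    """
    return np.array(
        [
            [8.0, 0.0, 0.0],   # 1 anterior pole (olfactory tip)
            [5.5, 0.0, 2.8],   # 2 olfactory-bulb / cortex boundary
            [-8.0, 0.0, 0.0],  # 3 posterior pole
            [0.0, 6.0, 0.0],   # 4 right lateral extreme
            [0.0, -6.0, 0.0],  # 5 left lateral extreme
            [0.0, 0.0, 5.0],   # 6 dorsal extreme
            [0.0, 0.0, -4.0],  # 7 ventral extreme
            [4.5, 4.0, 2.0],   # 8 right fronto-dorsal
            [4.5, -4.0, 2.0],  # 9 left fronto-dorsal
            [-5.0, 0.0, 3.0],  # 10 cerebellum boundary
        ]
    )


def skull_template() -> np.ndarray:
    """20 landmarks distributed over an idealized skull vault and base
    (half-axes 10 x 8 x 6 mm)."""
    pts = []
    for i in range(12):  # vault ring
        theta = 2 * np.pi * i / 12
        pts.append([10.0 * np.cos(theta), 8.0 * np.sin(theta), 2.5])
    for i in range(6):  # base ring
        theta = 2 * np.pi * (i + 0.5) / 6
        pts.append([7.0 * np.cos(theta), 5.5 * np.sin(theta), -3.0])
    pts.append([0.0, 0.0, 6.0])   # bregma-like apex
    pts.append([9.0, 0.0, -1.0])  # anterior nasal point
    return np.asarray(pts)


def ventricle_template() -> np.ndarray:
    """9 landmarks along an idealized midsagittal ventricular profile (2D)."""
    t = np.linspace(0.0, np.pi, 9)
    x = 6.0 * np.cos(t)
    y = 2.0 * np.sin(t) + 0.35 * x**2 / 6.0
    return np.column_stack([x, y])


def project_out_similarity(vector: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Project a flattened k*d deformation orthogonal to similarity directions.

    Removes the components along translations (per-axis constants), uniform
    scaling (the centered template direction), and infinitesimal rotations
    (template times antisymmetric generators), then renormalizes to unit
    length.  A deformation in this complement survives superimposition.
    """
    k, d = template.shape
    centered = template - template.mean(axis=0)
    basis: list[np.ndarray] = []
    for axis in range(d):  # translations
        e = np.zeros((k, d))
        e[:, axis] = 1.0
        basis.append(e.reshape(-1))
    basis.append(centered.reshape(-1))  # scaling
    if d == 2:
        gens = [np.array([[0.0, -1.0], [1.0, 0.0]])]
    else:
        gens = [
            np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
            np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]),
        ]
    for G in gens:  # rotations
        basis.append((centered @ G.T).reshape(-1))
    B = np.column_stack(basis)
    Q, _ = np.linalg.qr(B)
    v = np.asarray(vector, float).reshape(-1).copy()
    original_norm = np.linalg.norm(v)
    v -= Q @ (Q.T @ v)
    norm = np.linalg.norm(v)
    if norm <= 1e-9 * max(original_norm, 1e-300):
        raise ValueError("deformation lies entirely in the similarity space")
    return v / norm


def _brachycephaly_direction(template: np.ndarray) -> np.ndarray:
    """Unit deformation that shortens the antero-posterior axis and widens
    the medio-lateral axis, orthogonal to similarity directions."""
    raw = np.zeros_like(template)
    raw[:, 0] = -template[:, 0]
    raw[:, 1] = +template[:, 1]
    return project_out_similarity(raw.reshape(-1), template)


def _dorsoventral_direction(template: np.ndarray) -> np.ndarray:
    """Unit deformation flattening the dorso-ventral (last) axis while
    elongating the first axis; a treatment-like effect distinct from
    brachycephaly."""
    raw = np.zeros_like(template)
    raw[:, -1] = -template[:, -1]
    raw[:, 0] = +0.5 * template[:, 0]
    return project_out_similarity(raw.reshape(-1), template)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class StructureSpec:
    """Generating parameters for one structure."""

    template: np.ndarray  # (k, d), mm
    noise_sd: float  # isotropic landmark noise SD, mm
    group_offsets: dict[str, np.ndarray]  # flattened k*d offsets, mm
    integration_loading: np.ndarray | None = None  # unit-norm flattened k*d


@dataclass
class MilestoneSpec:
    """Baseline first-appearance day and additive per-group day shifts."""

    base_day: float
    sd: float = 1.2
    shifts: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    seed: int = 0
    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    stages: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGES))
    structures: dict[str, StructureSpec] = field(default_factory=dict)
    integration_strength: float = 1.0  # rho, in units of the noise SD
    milestones: dict[str, MilestoneSpec] = field(default_factory=dict)
    scalar_traits: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    missing_modality_rate: float = 0.0
    observed_through: int = 15

    def validate(self) -> None:
        if not self.groups or any(n < 1 for n in self.groups.values()):
            raise ValueError("each group needs n >= 1")
        for name, spec in self.structures.items():
            k, d = spec.template.shape
            if spec.noise_sd <= 0:
                raise ValueError(f"{name}: noise SD must be positive")
            for g, off in spec.group_offsets.items():
                if np.asarray(off).size != k * d:
                    raise ValueError(f"{name}/{g}: offset length != k*d")
            if spec.integration_loading is not None and spec.integration_loading.size != k * d:
                raise ValueError(f"{name}: loading length != k*d")
        if not 0 <= self.missing_modality_rate < 1:
            raise ValueError("missing_modality_rate must lie in [0, 1)")


def default_config(seed: int = 0, integration_strength: float = 1.0) -> SimulationConfig:
    """Study-condition defaults.

    Group sizes follow the earliest-stage imaging cohort (WT 12, TS 8,
    WT treated 13, TS treated 9); three stages with growth multipliers;
    trisomy produces a brachycephalic offset in brain and skull (stronger in
    the skull, which is dysmorphic from the earliest stage), treatment a
    distinct dorso-ventral offset; milestone delays concentrate on incisor
    eruption, eye opening and tactile orientation in the trisomic group.
    """
    brain = brain_template()
    skull = skull_template()
    vent = ventricle_template()

    brain_brachy = _brachycephaly_direction(brain)
    skull_brachy = _brachycephaly_direction(skull)
    vent_brachy = _brachycephaly_direction(vent)
    brain_treat = _dorsoventral_direction(brain)
    skull_treat = _dorsoventral_direction(skull)
    vent_treat = _dorsoventral_direction(vent)

    def offsets(brachy: np.ndarray, treat: np.ndarray, noise_sd: float, ts_gain: float):
        return {
            "WT": np.zeros_like(brachy),
            "TS": ts_gain * noise_sd * brachy,
            "WT_T": 1.5 * noise_sd * treat,
            "TS_T": ts_gain * noise_sd * brachy + 1.5 * noise_sd * treat,
        }

    structures = {
        "brain": StructureSpec(
            template=brain,
            noise_sd=0.10,
            group_offsets=offsets(brain_brachy, brain_treat, 0.10, ts_gain=2.0),
            integration_loading=brain_brachy,
        ),
        "skull": StructureSpec(
            template=skull,
            noise_sd=0.10,
            group_offsets=offsets(skull_brachy, skull_treat, 0.10, ts_gain=3.0),
            integration_loading=skull_brachy,
        ),
        "ventricles": StructureSpec(
            template=vent,
            noise_sd=0.05,
            group_offsets=offsets(vent_brachy, vent_treat, 0.05, ts_gain=2.0),
            integration_loading=None,
        ),
    }

    milestones = {
        "pinna_detachment": MilestoneSpec(4.0, shifts={"TS": 0.5}),
        "incisor_eruption": MilestoneSpec(9.5, shifts={"TS": 2.0, "WT_T": 1.5, "TS_T": 2.0}),
        "eye_opening": MilestoneSpec(13.0, shifts={"TS": 1.5, "TS_T": -1.0}),
        "tactile_orientation": MilestoneSpec(8.0, shifts={"TS": 2.0, "WT_T": 2.0, "TS_T": 2.0}),
        "vibrissae_placing": MilestoneSpec(11.0, shifts={"TS": 0.5}),
        "blast_response": MilestoneSpec(12.0, shifts={"TS": 0.5, "WT_T": -1.0, "TS_T": -1.0}),
    }

    scalar_traits = {
        "brain_volume": {
            "WT": (450.0, 25.0),
            "TS": (420.0, 25.0),
            "WT_T": (460.0, 25.0),
            "TS_T": (430.0, 25.0),
        },
        "lateral_ventricle_volume": {
            "WT": (6.0, 1.0),
            "TS": (6.8, 1.2),
            "WT_T": (5.2, 1.0),
            "TS_T": (5.6, 1.0),
        },
    }

    return SimulationConfig(
        seed=seed,
        structures=structures,
        integration_strength=integration_strength,
        milestones=milestones,
        scalar_traits=scalar_traits,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generating parameters plus derived true quantities."""

    config: SimulationConfig
    true_group_distances: dict[str, dict[tuple[str, str], float]]
    loadings: dict[str, np.ndarray]


@dataclass
class SyntheticCohort:
    """Paired per-structure, per-stage samples with milestone and trait data."""

    sample_sets: dict[tuple[str, str], SampleSet]  # (structure, stage) -> SampleSet
    milestones: pd.DataFrame
    traits: pd.DataFrame
    ground_truth: GroundTruth

    def sample_set(self, structure: str, stage: str) -> SampleSet:
        return self.sample_sets[(structure, stage)]

    @property
    def structures(self) -> list[str]:
        return sorted({s for s, _ in self.sample_sets})

    @property
    def stages(self) -> list[str]:
        return sorted({t for _, t in self.sample_sets})


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "shapes": np.random.default_rng(children[0]),
        "milestones": np.random.default_rng(children[1]),
        "traits": np.random.default_rng(children[2]),
    }


def _specimen_ids(groups: dict[str, int]) -> list[tuple[str, str]]:
    out = []
    for g, n in groups.items():
        for i in range(1, n + 1):
            out.append((f"{g}_{i:02d}", g))
    return out


def simulate_shape_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort under the latent-factor shape model.

    Each specimen's configuration at a stage is
    ``stage_scale * template + group_offset + rho * noise_sd * z * loading
    + noise`` with the scalar latent factor ``z`` shared across structures
    (within a specimen and stage) and everything else independent.
    Bitwise-deterministic given the seed.
    """
    config.validate()
    rngs = _substreams(config.seed)
    rng = rngs["shapes"]
    ids = _specimen_ids(config.groups)

    sample_sets: dict[tuple[str, str], SampleSet] = {}
    for stage, stage_scale in config.stages.items():
        z = rng.standard_normal(len(ids))  # shared latent factor per specimen
        drop: dict[str, str] = {}
        if config.missing_modality_rate > 0:
            loses = rng.random(len(ids)) < config.missing_modality_rate
            modality = rng.random(len(ids)) < 0.5
            structure_names = sorted(config.structures)
            for (sid, _g), lost, which in zip(ids, loses, modality):
                if lost and len(structure_names) >= 2:
                    drop[sid] = structure_names[0] if which else structure_names[1]
        for structure, spec in config.structures.items():
            k, d = spec.template.shape
            configs = []
            for j, (sid, g) in enumerate(ids):
                offset = np.asarray(spec.group_offsets.get(g, np.zeros(k * d))).reshape(k, d)
                shape = stage_scale * spec.template + offset
                if spec.integration_loading is not None:
                    shape = shape + (
                        config.integration_strength
                        * spec.noise_sd
                        * np.sqrt(k * d)
                        * z[j]
                        * spec.integration_loading.reshape(k, d)
                    )
                shape = shape + rng.normal(0.0, spec.noise_sd, size=(k, d))
                if drop.get(sid) == structure:
                    continue
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=sid,
                        coordinates=shape,
                        structure=structure if structure in ("brain", "skull", "ventricles") else "custom",
                        stage=stage,
                        group=g,
                    )
                )
            sample_sets[(structure, stage)] = SampleSet(
                configurations=configs,
                structure=structure if structure in ("brain", "skull", "ventricles") else "custom",
                stage=stage,
            )

    true_distances: dict[str, dict[tuple[str, str], float]] = {}
    for structure, spec in config.structures.items():
        pairs: dict[tuple[str, str], float] = {}
        labels = sorted(config.groups)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                oa = np.asarray(spec.group_offsets.get(a, 0.0)).reshape(-1)
                ob = np.asarray(spec.group_offsets.get(b, 0.0)).reshape(-1)
                pairs[(a, b)] = float(np.linalg.norm(oa - ob))
        true_distances[structure] = pairs

    ground_truth = GroundTruth(
        config=config,
        true_group_distances=true_distances,
        loadings={
            s: spec.integration_loading
            for s, spec in config.structures.items()
            if spec.integration_loading is not None
        },
    )
    return SyntheticCohort(
        sample_sets=sample_sets,
        milestones=simulate_milestones(config),
        traits=simulate_traits(config),
        ground_truth=ground_truth,
    )


def simulate_milestones(config: SimulationConfig) -> pd.DataFrame:
    """Per-specimen milestone first-appearance days.

    Days are integer-rounded normal draws around the group-shifted baseline,
    clipped below at day 1; draws past the last test day are censored there
    (event recorded as missing).  Deterministic given the seed; warns when a
    shift pushes all mass beyond the observation window.
    """
    rng = _substreams(config.seed)["milestones"]
    ids = _specimen_ids(config.groups)
    records: list[MilestoneRecord] = []
    for milestone, spec in config.milestones.items():
        n_censored = 0
        for sid, g in ids:
            mean_day = spec.base_day + spec.shifts.get(g, 0.0)
            day = int(round(rng.normal(mean_day, spec.sd)))
            day = max(1, day)
            if day > config.observed_through:
                records.append(
                    MilestoneRecord(sid, g, milestone, None, config.observed_through)
                )
                n_censored += 1
            else:
                records.append(
                    MilestoneRecord(sid, g, milestone, day, config.observed_through)
                )
        if n_censored == len(ids):
            import warnings

            warnings.warn(
                f"milestone {milestone!r}: all animals censored "
                f"(shift beyond day {config.observed_through})",
                RuntimeWarning,
                stacklevel=2,
            )
    return milestone_frame(records)


def simulate_traits(config: SimulationConfig) -> pd.DataFrame:
    """Volume-like scalar traits per specimen and stage (normal draws whose
    group mean scales with the stage growth multiplier)."""
    rng = _substreams(config.seed)["traits"]
    ids = _specimen_ids(config.groups)
    rows = []
    for trait, per_group in config.scalar_traits.items():
        for stage, stage_scale in config.stages.items():
            for sid, g in ids:
                mean, sd = per_group.get(g, (0.0, 1.0))
                rows.append(
                    {
                        "specimen_id": sid,
                        "group": g,
                        "stage": stage,
                        "trait": trait,
                        "value": float(rng.normal(mean * stage_scale, sd)),
                    }
                )
    return pd.DataFrame(rows)


def true_rv(
    config: SimulationConfig,
    n_mc: int = 20_000,
    n_bootstrap: int = 50,
    block_size: int = 200,
    structures: tuple[str, str] = ("brain", "skull"),
) -> tuple[float, float]:
    """Monte-Carlo pseudo-population RV at the configured integration strength.

    Generates one large single-group sample (first configured group, first
    stage) of the two structures on raw coordinates and computes the RV
    coefficient, with a block-bootstrap standard error.  This is the
    ground-truth integration magnitude the estimators should recover.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10000 for a pseudo-population value")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    name1, name2 = structures
    s1 = config.structures[name1]
    s2 = config.structures[name2]
    k1, d1 = s1.template.shape
    k2, d2 = s2.template.shape
    z = rng.standard_normal(n_mc)

    def block(spec: StructureSpec, k: int, d: int) -> np.ndarray:
        X = np.tile(spec.template.reshape(-1), (n_mc, 1))
        if spec.integration_loading is not None:
            X = X + (
                config.integration_strength
                * spec.noise_sd
                * np.sqrt(k * d)
                * np.outer(z, spec.integration_loading)
            )
        return X + rng.normal(0.0, spec.noise_sd, size=(n_mc, k * d))

    X1 = block(s1, k1, d1)
    X2 = block(s2, k2, d2)
    rv = rv_coefficient(X1, X2)

    n_blocks = n_mc // block_size
    starts = np.arange(n_blocks) * block_size
    estimates = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        rows = np.concatenate([np.arange(s, s + block_size) for s in starts[chosen]])
        estimates[b] = rv_coefficient(X1[rows], X2[rows])
    return float(rv), float(np.std(estimates, ddof=1))


def loading_in_aligned_frame(
    config: SimulationConfig,
    structure: str,
    aligned_consensus: np.ndarray,
) -> np.ndarray:
    """Ground-truth loading expressed in a GPA-aligned frame.

    GPA reports shapes in a canonically oriented, unit-size frame, so the
    generating loading (defined in template coordinates) must be rotated by
    the template-to-consensus rotation before it can be compared with an
    estimated axis.  Returns a unit-norm flattened vector.
    """
    from .procrustes import _optimal_rotation  # local import avoids cycle at module load

    spec = config.structures[structure]
    if spec.integration_loading is None:
        raise ValueError(f"structure {structure!r} has no integration loading")
    tpl = spec.template - spec.template.mean(axis=0)
    tpl = tpl / np.sqrt(np.sum(tpl**2))
    R = _optimal_rotation(aligned_consensus, tpl)
    k, d = spec.template.shape
    rotated = spec.integration_loading.reshape(k, d) @ R
    flat = rotated.reshape(-1)
    return flat / np.linalg.norm(flat)


def with_strength(config: SimulationConfig, rho: float, seed: int | None = None) -> SimulationConfig:
    """Copy of a config at a different integration strength (and seed)."""
    return replace(
        config,
        integration_strength=rho,
        seed=config.seed if seed is None else seed,
    )
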