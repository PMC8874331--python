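"""Config-driven orchestration of the full per-stage, per-structure analysis.

``run_integration_analysis`` executes, for each stage and structure: GPA,
PCA, all pairwise group mean-shape permutation tests, deviance scoring
against the reference group, derived linear measures; per stage it adds the
brain-skull deviance correlation and the two-block PLS with RV and
permutation p-values (overall and per group); plus Mann-Whitney/BH screening
of scalar traits and logrank milestone tests.  All tables are written as
tidy CSV together with a run manifest (config hash, seed, version), and a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_inference import (
    deviance_correlation,
    deviance_scores,
    mean_shape_distance,
    permutation_test_distance,
)
from .integration import pls_group_slopes, pls_permutation_test, two_block_pls
from .landmark_io import read_landmark_table, validate_sample_set
from .morphospace import MeasureDefinition, derived_measures, pca
from .procrustes import gpa
from .simulate import SimulationConfig, SyntheticCohort, default_config, simulate_shape_cohort
from .univariate import bh_discoveries, cumulative_incidence, logrank_test, mann_whitney

__all__ = ["AnalysisConfig", "ReportBundle", "run_integration_analysis", "dose_rate"]

logger = logging.getLogger(__name__)

DEFAULT_GROUP_PAIRS = [
    ("WT", "TS"),
    ("WT", "WT_T"),
    ("WT", "TS_T"),
    ("TS", "WT_T"),
    ("TS", "TS_T"),
    ("TS_T", "WT_T"),
]


@dataclass
class AnalysisConfig:
    """End-to-end analysis configuration.

    Either ``simulate`` provides a synthetic-cohort configuration, or
    ``input_tables`` maps (structure, stage) to long-format landmark CSV
    paths.  Every random operation derives its seed from ``seed`` and the
    cell identity, so the manifest suffices to reproduce every number.
    """

    seed: int = 0
    simulate: SimulationConfig | None = None
    input_tables: dict[tuple[str, str], str] = field(default_factory=dict)
    reference_group: str = "WT"
    group_pairs: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_GROUP_PAIRS))
    n_permutations: int = 10_000
    bh_q: float = 0.05
    measures: dict[str, list[MeasureDefinition]] = field(default_factory=dict)
    pls_pair: tuple[str, str] = ("brain", "skull")
    outdir: str = "cranioshape_report"


@dataclass
class ReportBundle:
    """In-memory result tables plus the manifest; ``write`` exports CSVs."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    errors: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in sorted(self.tables):
            self.tables[name].to_csv(
                outdir / f"{name}.csv", index=False, float_format="%.10g"
            )
        (outdir / "manifest.yaml").write_text(
            yaml.safe_dump(self.manifest, sort_keys=True), encoding="utf-8"
        )
        if self.errors:
            (outdir / "errors.log").write_text("\n".join(self.errors) + "\n", encoding="utf-8")
        return outdir

    def content_hash(self) -> str:
        """SHA-256 over all tables and the manifest (path-independent)."""
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=False, float_format="%.10g").encode())
        h.update(yaml.safe_dump(self.manifest, sort_keys=True).encode())
        return h.hexdigest()


def _cell_seed(seed: int, *parts: str) -> int:
    """Stable per-cell sub-seed below 2^31."""
    return zlib.crc32(f"{seed}:{':'.join(parts)}".encode()) & 0x7FFFFFFF


def _config_manifest(cfg: AnalysisConfig) -> dict:
    sim = None
    if cfg.simulate is not None:
        sim = {
            "seed": cfg.simulate.seed,
            "groups": dict(cfg.simulate.groups),
            "stages": {k: float(v) for k, v in cfg.simulate.stages.items()},
            "integration_strength": float(cfg.simulate.integration_strength),
            "missing_modality_rate": float(cfg.simulate.missing_modality_rate),
            "structures": {
                name: {
                    "k": int(spec.template.shape[0]),
                    "d": int(spec.template.shape[1]),
                    "noise_sd": float(spec.noise_sd),
                }
                for name, spec in cfg.simulate.structures.items()
            },
        }
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "reference_group": cfg.reference_group,
        "group_pairs": [list(p) for p in cfg.group_pairs],
        "n_permutations": cfg.n_permutations,
        "bh_q": cfg.bh_q,
        "pls_pair": list(cfg.pls_pair),
        "simulate": sim,
        "input_tables": {f"{s}/{t}": p for (s, t), p in sorted(cfg.input_tables.items())},
    }
    manifest["config_hash"] = hashlib.sha256(
        yaml.safe_dump(manifest, sort_keys=True).encode()
    ).hexdigest()
    return manifest


def _load_cohort(cfg: AnalysisConfig) -> SyntheticCohort | dict:
    if cfg.simulate is not None:
        return simulate_shape_cohort(cfg.simulate)
    if not cfg.input_tables:
        raise ValueError("config must provide either a simulation or input tables")
    sample_sets = {key: read_landmark_table(path) for key, path in cfg.input_tables.items()}
    return {"sample_sets": sample_sets}


def run_integration_analysis(cfg: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis plan; cell-level failures are isolated."""
    manifest = _config_manifest(cfg)
    cohort = _load_cohort(cfg)
    if isinstance(cohort, SyntheticCohort):
        sample_sets = cohort.sample_sets
        milestones = cohort.milestones
        traits = cohort.traits
    else:
        sample_sets = cohort["sample_sets"]
        milestones = None
        traits = None

    tables: dict[str, pd.DataFrame] = {}
    errors: list[str] = []

    gpa_rows, pca_eigen_rows, pca_score_rows = [], [], []
    distance_rows, deviance_frames, measure_rows = [], [], []
    aligned_cache: dict[tuple[str, str], object] = {}

    for (structure, stage), sample in sorted(sample_sets.items()):
        cell = f"{structure}/{stage}"
        if sample.n < 3:
            errors.append(f"{cell}: skipped (n={sample.n} < 3)")
            continue
        try:
            report = validate_sample_set(sample)
            if not report.passed:
                errors.append(f"{cell}: validation failed: {report.violations[:3]}")
                continue
            aligned = gpa(sample)
            aligned_cache[(structure, stage)] = aligned
            gpa_rows.append(
                {
                    "structure": structure,
                    "stage": stage,
                    "n": aligned.n,
                    "k": aligned.k,
                    "d": aligned.d,
                    "iterations": aligned.iterations,
                    "converged": aligned.converged,
                    "mean_centroid_size": float(np.mean(aligned.centroid_sizes)),
                }
            )

            result = pca(aligned)
            for i in range(min(result.n_components, 10)):
                pca_eigen_rows.append(
                    {
                        "structure": structure,
                        "stage": stage,
                        "component": i + 1,
                        "eigenvalue": float(result.eigenvalues[i]),
                        "percent_variance": float(result.percent_variance[i]),
                    }
                )
            for row, sid in enumerate(aligned.specimen_ids):
                pca_score_rows.append(
                    {
                        "structure": structure,
                        "stage": stage,
                        "specimen_id": sid,
                        "group": aligned.groups[sid],
                        "pc1": float(result.scores[row, 0]) if result.n_components > 0 else np.nan,
                        "pc2": float(result.scores[row, 1]) if result.n_components > 1 else np.nan,
                    }
                )

            present = {aligned.groups[s] for s in aligned.specimen_ids}
            for ga, gb in cfg.group_pairs:
                if ga not in present or gb not in present:
                    continue
                try:
                    seed = _cell_seed(cfg.seed, "compare", structure, stage, ga, gb)
                    test = permutation_test_distance(
                        aligned, ga, gb, n_permutations=cfg.n_permutations, seed=seed
                    )
                    distance_rows.append(
                        {
                            "structure": structure,
                            "stage": stage,
                            "group_a": ga,
                            "group_b": gb,
                            "distance": test.observed_statistic,
                            "p_value": test.p_value,
                            "n_permutations": test.n_permutations,
                            "exhaustive": test.exhaustive,
                            "seed": seed,
                        }
                    )
                except ValueError as exc:
                    errors.append(f"{cell} {ga}-{gb}: {exc}")

            if cfg.reference_group in present:
                deviance_frames.append(deviance_scores(aligned, cfg.reference_group))

            for md in cfg.measures.get(structure, []):
                for config in sample.configurations:
                    try:
                        values = derived_measures(config, [md])
                    except ValueError as exc:
                        errors.append(f"{cell} measure {md.name!r}: {exc}")
                        break
                    measure_rows.append(
                        {
                            "structure": structure,
                            "stage": stage,
                            "specimen_id": config.specimen_id,
                            "group": config.group,
                            "measure": md.name,
                            "value": values[md.name],
                        }
                    )
        except Exception as exc:  # cell isolation: report, keep going
            errors.append(f"{cell}: {type(exc).__name__}: {exc}")
            logger.exception("cell %s failed", cell)

    if gpa_rows:
        tables["gpa_summary"] = pd.DataFrame(gpa_rows)
    if pca_eigen_rows:
        tables["pca_eigenvalues"] = pd.DataFrame(pca_eigen_rows)
    if pca_score_rows:
        tables["pca_scores"] = pd.DataFrame(pca_score_rows)
    if distance_rows:
        tables["group_distances"] = pd.DataFrame(distance_rows)
    if deviance_frames:
        tables["deviance"] = pd.concat(deviance_frames, ignore_index=True)
    if measure_rows:
        tables["derived_measures"] = pd.DataFrame(measure_rows)

    # ---- cross-structure analyses per stage -------------------------------
    s1, s2 = cfg.pls_pair
    stages = sorted({t for (_s, t) in sample_sets})
    corr_rows, pls_rows, pls_score_rows = [], [], []
    for stage in stages:
        b = aligned_cache.get((s1, stage))
        k = aligned_cache.get((s2, stage))
        if b is None or k is None:
            continue
        try:
            dev_b = deviance_scores(b, cfg.reference_group)
            dev_k = deviance_scores(k, cfg.reference_group)
            corr = deviance_correlation(dev_b, dev_k, by_group=True)
            corr.insert(0, "stage", stage)
            corr_rows.append(corr)
        except ValueError as exc:
            errors.append(f"deviance correlation {stage}: {exc}")
        try:
            pls = two_block_pls(b, k)
            seed_sv = _cell_seed(cfg.seed, "pls_sv", stage)
            seed_rv = _cell_seed(cfg.seed, "pls_rv", stage)
            sv_test = pls_permutation_test(
                pls, n_permutations=cfg.n_permutations, seed=seed_sv,
                statistic="axis1_singular_value",
            )
            rv_test = pls_permutation_test(
                pls, n_permutations=cfg.n_permutations, seed=seed_rv, statistic="rv"
            )
            slopes = pls_group_slopes(pls)
            pls_rows.append(
                {
                    "stage": stage,
                    "group": "all",
                    "n": pls.n,
                    "axis1_singular_value": float(pls.singular_values[0]),
                    "percent_covariance_axis1": float(pls.percent_covariance[0]),
                    "axis1_correlation": float(pls.axis_correlations[0]),
                    "rv": pls.rv,
                    "axis1_p_value": sv_test.p_value,
                    "rv_p_value": rv_test.p_value,
                    "sma_slope": np.nan,
                    "seed": seed_sv,
                }
            )
            for row, sid in enumerate(pls.specimen_ids):
                pls_score_rows.append(
                    {
                        "stage": stage,
                        "specimen_id": sid,
                        "group": pls.groups[sid],
                        "block1_axis1_score": float(pls.block1_scores[row, 0]),
                        "block2_axis1_score": float(pls.block2_scores[row, 0]),
                    }
                )
            for g in sorted({pls.groups[s] for s in pls.specimen_ids}):
                try:
                    gp = two_block_pls(b, k, group=g)
                    seed_g = _cell_seed(cfg.seed, "pls_group", stage, g)
                    corr_test = pls_permutation_test(
                        gp,
                        n_permutations=min(cfg.n_permutations, 9999),
                        seed=seed_g,
                        statistic="axis1_correlation",
                    )
                    pls_rows.append(
                        {
                            "stage": stage,
                            "group": g,
                            "n": gp.n,
                            "axis1_singular_value": float(gp.singular_values[0]),
                            "percent_covariance_axis1": float(gp.percent_covariance[0]),
                            "axis1_correlation": float(gp.axis_correlations[0]),
                            "rv": gp.rv,
                            "axis1_p_value": corr_test.p_value,
                            "rv_p_value": np.nan,
                            "sma_slope": slopes.get(g, np.nan),
                            "seed": seed_g,
                        }
                    )
                except ValueError as exc:
                    errors.append(f"pls {stage} group {g}: {exc}")
        except ValueError as exc:
            errors.append(f"pls {stage}: {exc}")

    if corr_rows:
        tables["deviance_correlations"] = pd.concat(corr_rows, ignore_index=True)
    if pls_rows:
        tables["pls_summary"] = pd.DataFrame(pls_rows)
    if pls_score_rows:
        tables["pls_scores"] = pd.DataFrame(pls_score_rows)

    # ---- scalar traits: Mann-Whitney per stage + BH family ----------------
    if traits is not None and not traits.empty:
        mw_rows = []
        for (trait, stage), sub in traits.groupby(["trait", "stage"], sort=True):
            for ga, gb in cfg.group_pairs:
                x = sub.loc[sub["group"] == ga, "value"].to_numpy()
                y = sub.loc[sub["group"] == gb, "value"].to_numpy()
                if x.size == 0 or y.size == 0:
                    continue
                res = mann_whitney(x, y)
                mw_rows.append(
                    {
                        "trait": trait,
                        "stage": stage,
                        "group_a": ga,
                        "group_b": gb,
                        "U": res.statistic,
                        "p_value": res.p_value,
                        "method": res.method,
                    }
                )
        if mw_rows:
            mw = pd.DataFrame(mw_rows)
            mw["bh_discovery"] = bh_discoveries(mw["p_value"].to_numpy(), cfg.bh_q)
            tables["trait_tests"] = mw

    # ---- milestones -------------------------------------------------------
    if milestones is not None and not milestones.empty:
        lr_rows, ci_frames = [], []
        for milestone in sorted(milestones["milestone"].unique()):
            for ga, gb in cfg.group_pairs:
                try:
                    res = logrank_test(milestones, ga, gb, milestone=milestone)
                except ValueError as exc:
                    errors.append(f"logrank {milestone} {ga}-{gb}: {exc}")
                    continue
                lr_rows.append(
                    {
                        "milestone": milestone,
                        "group_a": ga,
                        "group_b": gb,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                    }
                )
            for g in sorted(milestones["group"].unique()):
                try:
                    ci = cumulative_incidence(milestones, g, milestone=milestone)
                except ValueError:
                    continue
                ci.insert(0, "group", g)
                ci.insert(0, "milestone", milestone)
                ci_frames.append(ci)
        if lr_rows:
            tables["milestone_tests"] = pd.DataFrame(lr_rows)
        if ci_frames:
            tables["cumulative_incidence"] = pd.concat(ci_frames, ignore_index=True)

    return ReportBundle(tables=tables, manifest=manifest, errors=errors)


def dose_rate(
    concentration_mg_per_ml: float,
    intake_ml_per_day: float,
    body_mass_g: float,
) -> tuple[float, int]:
    """Daily dose in mg/kg/day from drinking-water exposure.

    concentration x intake / body mass; e.g. 0.33 mg/mL in water, 6 mL/day
    drunk by a 20 g mouse gives 99 mg/kg/day, ~100 when rounded to the
    nearest 10 for summary reporting.  Returns (raw, rounded-to-10).
    """
    if concentration_mg_per_ml <= 0 or intake_ml_per_day <= 0 or body_mass_g <= 0:
        raise ValueError("all dose inputs must be positive")
    raw = concentration_mg_per_ml * intake_ml_per_day / (body_mass_g / 1000.0)
    return float(raw), int(round(raw / 10.0) * 10)
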