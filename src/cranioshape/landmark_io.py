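"""Reading, validating and writing landmark datasets.

A landmark configuration is an ordered set of anatomically homologous points
digitized on one specimen: index ``i`` refers to the same anatomical locus on
every specimen of the same structure and stage.  Two interchange formats are
supported:

* TPS files (``LM=``/``LM3=`` count lines, coordinate rows, optional ``ID=``
  and ``SCALE=`` keys), the lingua franca of landmark digitizing tools;
* a long-format delimited table with columns ``specimen_id, group, stage,
  structure, landmark_index, x, y[, z]``.

Missing landmarks are not supported: superimposition requires complete
point-to-point correspondence, so incomplete configurations are rejected
rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "SampleSet",
    "ValidationReport",
    "LandmarkFormatError",
    "read_tps",
    "write_tps",
    "read_landmark_table",
    "write_landmark_table",
    "validate_sample_set",
]

KNOWN_STRUCTURES = ("brain", "skull", "ventricles", "custom")


class LandmarkFormatError(ValueError):
    """Raised for malformed TPS or tabular landmark files."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered k x d landmark coordinates plus metadata.

    Coordinates are in physical units (mm); ``scale``, when given, records
    the physical-units-per-coordinate-unit factor that was already applied
    by the reader.
    """

    specimen_id: str
    coordinates: np.ndarray
    structure: str = "custom"
    stage: str = ""
    group: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2:
            raise ValueError(
                f"{self.specimen_id}: coordinates must be a k x d array, "
                f"got shape {coords.shape}"
            )
        k, d = coords.shape
        if d not in (2, 3):
            raise ValueError(f"{self.specimen_id}: dimension must be 2 or 3, got {d}")
        if k < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 landmarks, got {k}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinate")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"{self.specimen_id}: scale must be positive")
        self.coordinates = coords

    @property
    def k(self) -> int:
        return self.coordinates.shape[0]

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class SampleSet:
    """A homogeneous sample of configurations (same structure, stage, k, d).

    The container itself is permissive so that malformed sets can still be
    inspected; :func:`validate_sample_set` reports invariant violations.
    """

    configurations: list[LandmarkConfiguration]
    structure: str = "custom"
    stage: str = ""

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        ks = {c.k for c in self.configurations}
        if len(ks) != 1:
            raise ValueError(f"ragged landmark counts across specimens: {sorted(ks)}")
        return ks.pop()

    @property
    def d(self) -> int:
        ds = {c.d for c in self.configurations}
        if len(ds) != 1:
            raise ValueError(f"mixed dimensions across specimens: {sorted(ds)}")
        return ds.pop()

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def group_labels(self) -> dict[str, str]:
        return {c.specimen_id: c.group for c in self.configurations}

    def coordinates_array(self) -> np.ndarray:
        """Stack all configurations into an (n, k, d) array."""
        _ = self.k, self.d  # raises on ragged sets
        return np.stack([c.coordinates for c in self.configurations])

    def subset(self, specimen_ids: Iterable[str]) -> "SampleSet":
        wanted = set(specimen_ids)
        return SampleSet(
            configurations=[c for c in self.configurations if c.specimen_id in wanted],
            structure=self.structure,
            stage=self.stage,
        )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    group_counts: dict[str, int] = field(default_factory=dict)
    n_configurations: int = 0

    @property
    def passed(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_TPS_IGNORED_KEYS = ("IMAGE=", "COMMENT=", "CURVES=", "POINTS=")


def read_tps(
    path: str | Path,
    *,
    structure: str = "custom",
    stage: str = "",
    group: str = "",
) -> list[LandmarkConfiguration]:
    """Parse a TPS file into a list of configurations.

    ``LM=`` records are 2D, ``LM3=`` records 3D; ``SCALE=`` multiplies all
    coordinates of its record; ``IMAGE=``/``COMMENT=`` keys are ignored.
    A record whose declared landmark count does not match the number of
    coordinate rows raises :class:`LandmarkFormatError` naming the record.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]

    configs: list[LandmarkConfiguration] = []
    file_d: int | None = None
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            d = 3 if upper.startswith("LM3=") else 2
            if file_d is not None and d != file_d:
                raise LandmarkFormatError(
                    f"{path.name}: record {record_index} is {d}D but earlier "
                    f"records are {file_d}D (mixed dimensions)"
                )
            file_d = d
            try:
                declared = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise LandmarkFormatError(
                    f"{path.name}: record {record_index}: bad count line {line!r}"
                ) from exc
            i += 1
            rows: list[list[float]] = []
            specimen_id: str | None = None
            scale: float | None = None
            while i < len(lines):
                ln = lines[i]
                if not ln:
                    i += 1
                    continue
                u = ln.upper()
                if u.startswith("LM3=") or u.startswith("LM="):
                    break
                if u.startswith("ID="):
                    specimen_id = ln.split("=", 1)[1].strip()
                    i += 1
                    continue
                if u.startswith("SCALE="):
                    scale = float(ln.split("=", 1)[1])
                    i += 1
                    continue
                if any(u.startswith(key) for key in _TPS_IGNORED_KEYS):
                    i += 1
                    continue
                parts = ln.replace(",", " ").split()
                try:
                    values = [float(p) for p in parts]
                except ValueError as exc:
                    raise LandmarkFormatError(
                        f"{path.name}: record {record_index}: "
                        f"unparseable coordinate line {ln!r}"
                    ) from exc
                if len(values) != d:
                    raise LandmarkFormatError(
                        f"{path.name}: record {record_index}: coordinate line has "
                        f"{len(values)} values, expected {d}"
                    )
                rows.append(values)
                i += 1
            if len(rows) != declared:
                raise LandmarkFormatError(
                    f"{path.name}: record {record_index} declares {declared} "
                    f"landmarks but {len(rows)} coordinate lines were parsed"
                )
            coords = np.asarray(rows, dtype=float)
            if scale is not None:
                coords = coords * scale
            configs.append(
                LandmarkConfiguration(
                    specimen_id=specimen_id or f"record_{record_index}",
                    coordinates=coords,
                    structure=structure,
                    stage=stage,
                    group=group,
                    scale=scale,
                )
            )
            record_index += 1
        else:
            raise LandmarkFormatError(
                f"{path.name}: unexpected line outside a record: {line!r}"
            )
    return configs


def write_tps(configurations: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations to a TPS file (6-decimal coordinates).

    If a configuration records a ``scale``, raw (unscaled) coordinates are
    written alongside a ``SCALE=`` key so a read/write round trip is the
    identity on physical coordinates.
    """
    path = Path(path)
    out: list[str] = []
    for cfg in configurations:
        key = "LM3" if cfg.d == 3 else "LM"
        out.append(f"{key}={cfg.k}")
        coords = cfg.coordinates if cfg.scale is None else cfg.coordinates / cfg.scale
        for row in coords:
            out.append(" ".join(f"{v:.6f}" for v in row))
        out.append(f"ID={cfg.specimen_id}")
        if cfg.scale is not None:
            out.append(f"SCALE={cfg.scale:.6f}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Long-format tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("specimen_id", "group", "stage", "structure", "landmark_index", "x", "y")


def read_landmark_table(path: str | Path, *, sep: str = ",") -> SampleSet:
    """Read a long-format landmark table into a :class:`SampleSet`.

    Landmark indices are 1-based in the file; rows are assembled in index
    order per specimen.  Duplicate ``(specimen, landmark_index)`` rows, a
    missing index for any specimen, or ragged landmark counts across
    specimens are format errors.
    """
    df = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LandmarkFormatError(f"missing columns: {missing_cols}")
    has_z = "z" in df.columns and df["z"].notna().any()
    if "z" in df.columns and has_z and df["z"].isna().any():
        raise LandmarkFormatError("z column present but partially missing")
    coord_cols = ["x", "y", "z"] if has_z else ["x", "y"]

    structures = df["structure"].unique()
    stages = df["stage"].unique()
    if len(structures) != 1 or len(stages) != 1:
        raise LandmarkFormatError(
            f"a sample set must be homogeneous: structures={list(structures)}, "
            f"stages={list(stages)}"
        )

    dup = df.duplicated(subset=["specimen_id", "landmark_index"])
    if dup.any():
        bad = df.loc[dup, ["specimen_id", "landmark_index"]].iloc[0]
        raise LandmarkFormatError(
            f"duplicate landmark {int(bad['landmark_index'])} for specimen "
            f"{bad['specimen_id']!r}"
        )

    k_global = df["landmark_index"].max()
    expected = set(range(1, int(k_global) + 1))
    configs: list[LandmarkConfiguration] = []
    for spec_id, sub in df.groupby("specimen_id", sort=True):
        got = set(int(v) for v in sub["landmark_index"])
        if got != expected:
            missing_idx = sorted(expected - got)
            raise LandmarkFormatError(
                f"specimen {spec_id!r}: missing landmark index(es) {missing_idx}"
            )
        sub = sub.sort_values("landmark_index")
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise LandmarkFormatError(f"specimen {spec_id!r}: conflicting group labels")
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(spec_id),
                coordinates=sub[coord_cols].to_numpy(dtype=float),
                structure=str(structures[0]),
                stage=str(stages[0]),
                group=str(groups[0]),
            )
        )
    return SampleSet(configurations=configs, structure=str(structures[0]), stage=str(stages[0]))


def write_landmark_table(sample: SampleSet, path: str | Path, *, sep: str = ",") -> None:
    """Write a sample set as a long-format table (1-based landmark indices)."""
    rows = []
    for cfg in sample.configurations:
        for idx, point in enumerate(cfg.coordinates, start=1):
            row = {
                "specimen_id": cfg.specimen_id,
                "group": cfg.group,
                "stage": cfg.stage,
                "structure": cfg.structure,
                "landmark_index": idx,
                "x": point[0],
                "y": point[1],
            }
            if cfg.d == 3:
                row["z"] = point[2]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_sample_set(sample: SampleSet) -> ValidationReport:
    """Report violations of sample-set invariants (report-only, never raises).

    Checks: shared structure/stage/k/d across members, unique specimen ids,
    finite coordinates.  Also tallies per-group sample sizes.
    """
    report = ValidationReport(n_configurations=sample.n)
    seen: set[str] = set()
    ks: set[int] = set()
    ds: set[int] = set()
    for cfg in sample.configurations:
        if cfg.specimen_id in seen:
            report.violations.append(f"duplicated specimen_id {cfg.specimen_id!r}")
        seen.add(cfg.specimen_id)
        ks.add(cfg.k)
        ds.add(cfg.d)
        if cfg.structure != sample.structure:
            report.violations.append(
                f"{cfg.specimen_id!r}: structure {cfg.structure!r} != {sample.structure!r}"
            )
        if cfg.stage != sample.stage:
            report.violations.append(
                f"{cfg.specimen_id!r}: stage {cfg.stage!r} != {sample.stage!r}"
            )
        bad = ~np.isfinite(cfg.coordinates)
        if bad.any():
            for lm, _axis in zip(*np.nonzero(bad)):
                report.violations.append(
                    f"{cfg.specimen_id!r}: non-finite coordinate at landmark {lm + 1}"
                )
                break  # one violation per specimen is enough to fail
        report.group_counts[cfg.group] = report.group_counts.get(cfg.group, 0) + 1
    if len(ks) > 1:
        report.violations.append(f"ragged landmark counts: {sorted(ks)}")
    if len(ds) > 1:
        report.violations.append(f"mixed dimensions: {sorted(ds)}")
    return report
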