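"""Per-block datasets: domain types, delimited-text IO, covariate preprocessing, splits.

A *block* is one line of therapy (LoT): time restarts at the block's first day,
every patient contributes at most one observed time with an event code
(0 censored, 1 death, 2 transition to the next LoT), and each biomarker forms an
irregular longitudinal series on the block clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerSeries",
    "SurvivalOutcome",
    "CovariateTable",
    "PreprocessSpec",
    "BlockDataset",
    "SchemaError",
    "IntegrityError",
    "read_block",
    "write_block",
    "preprocess_covariates",
    "split_train_test",
]

LONGITUDINAL_COLUMNS = ["patient_id", "biomarker_id", "time", "value"]
SURVIVAL_COLUMNS = ["patient_id", "time", "event"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class IntegrityError(ValueError):
    """Rows are inconsistent with the block invariants."""


@dataclass(frozen=True)
class BiomarkerSeries:
    """One patient's measurements of one biomarker on the block clock.

    ``times`` are days since block start, strictly increasing; ``values`` are
    concentrations in g/L. Empty series are legal (patients with no recorded
    measurements still contribute to the survival likelihood).
    """

    patient_id: object
    biomarker_id: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise IntegrityError("times and values must be aligned 1-d arrays")
        if times.size:
            if np.any(times < 0):
                raise IntegrityError("negative measurement time")
            if np.any(np.diff(times) <= 0):
                raise IntegrityError(
                    f"times not strictly increasing for patient {self.patient_id!r}"
                )
            if not np.all(np.isfinite(values)):
                raise IntegrityError("non-finite biomarker value")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SurvivalOutcome:
    """Observed time (days, > 0) and event code for one patient.

    ``event`` is 0 (censored), 1 (death) or 2 (next line of therapy); code 2 is
    illegal in a single-event block.
    """

    patient_id: object
    time: float
    event: int

    def __post_init__(self):
        if not self.time > 0:
            raise IntegrityError(f"observed time must be positive, got {self.time}")
        if self.event not in (0, 1, 2):
            raise IntegrityError(f"event code must be 0, 1 or 2, got {self.event}")


@dataclass(frozen=True)
class CovariateTable:
    """Per-patient baseline covariates.

    ``frame`` is indexed by patient id. ``continuous`` and ``categorical`` name the
    raw columns; after :func:`preprocess_covariates` the categorical columns are
    replaced by 0/1 indicator columns (first level is the reference) and
    ``design_columns`` lists the columns of the design vector in order.
    """

    frame: pd.DataFrame
    continuous: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    design_columns: tuple[str, ...] = ()

    @property
    def patient_ids(self) -> pd.Index:
        return self.frame.index

    def design_matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Return the (n, p) design array; requires a preprocessed table."""
        if not self.design_columns:
            raise ValueError("covariates are not preprocessed; no design columns")
        cols = list(columns) if columns is not None else list(self.design_columns)
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"design columns not present: {missing}")
        return self.frame[cols].to_numpy(dtype=float)


@dataclass(frozen=True)
class PreprocessSpec:
    """Learned covariate transformations, reusable verbatim on held-out data.

    For each continuous column: an optional log transform, the training mean/SD of
    the (transformed) column, and mean imputation — after standardization a missing
    entry becomes 0, the standardized training mean. Categorical columns store the
    training level set (first level = reference) and the training mode for
    imputation.
    """

    continuous: Mapping[str, tuple[bool, float, float]] = field(default_factory=dict)
    categorical: Mapping[str, tuple[tuple, object]] = field(default_factory=dict)

    @property
    def design_columns(self) -> tuple[str, ...]:
        cols = list(self.continuous)
        for col, (levels, _mode) in self.categorical.items():
            cols.extend(f"{col}_{lev}" for lev in levels[1:])
        return tuple(cols)


@dataclass(frozen=True)
class BlockDataset:
    """All observed data for one line-of-therapy block."""

    block_id: int
    series: tuple[BiomarkerSeries, ...]
    outcomes: tuple[SurvivalOutcome, ...]
    covariates: CovariateTable
    n_events: int

    def __post_init__(self):
        if self.n_events not in (1, 2):
            raise ValueError("n_events must be 1 or 2")
        out_ids = {o.patient_id for o in self.outcomes}
        if len(out_ids) != len(self.outcomes):
            raise IntegrityError("duplicate patient in survival outcomes")
        if self.n_events == 1 and any(o.event == 2 for o in self.outcomes):
            raise IntegrityError("event code 2 in a single-event block")
        cov_ids = set(self.covariates.patient_ids)
        if not out_ids <= cov_ids:
            raise IntegrityError("outcome patient missing from covariate table")
        times = {o.patient_id: o.time for o in self.outcomes}
        seen = set()
        for s in self.series:
            key = (s.patient_id, s.biomarker_id)
            if key in seen:
                raise IntegrityError(f"duplicate series for {key}")
            seen.add(key)
            if s.patient_id not in times:
                raise IntegrityError(
                    f"series patient {s.patient_id!r} missing from survival table"
                )
            if len(s) and s.times[-1] > times[s.patient_id]:
                raise IntegrityError(
                    f"measurement at t={s.times[-1]:g} after observed time "
                    f"{times[s.patient_id]:g} for patient {s.patient_id!r}"
                )

    @property
    def patient_ids(self) -> list:
        return [o.patient_id for o in self.outcomes]

    @property
    def n_patients(self) -> int:
        return len(self.outcomes)

    @property
    def biomarker_ids(self) -> list[int]:
        return sorted({s.biomarker_id for s in self.series})

    def get_series(self, patient_id, biomarker_id: int) -> BiomarkerSeries:
        for s in self.series:
            if s.patient_id == patient_id and s.biomarker_id == biomarker_id:
                return s
        return BiomarkerSeries(patient_id, biomarker_id, np.empty(0), np.empty(0))

    def longitudinal_frame(self) -> pd.DataFrame:
        rows = [
            (s.patient_id, s.biomarker_id, t, v)
            for s in self.series
            for t, v in zip(s.times, s.values)
        ]
        return pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS)

    def survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(o.patient_id, o.time, o.event) for o in self.outcomes],
            columns=SURVIVAL_COLUMNS,
        )

    def subset(self, patient_ids: Iterable) -> "BlockDataset":
        keep = set(patient_ids)
        return BlockDataset(
            block_id=self.block_id,
            series=tuple(s for s in self.series if s.patient_id in keep),
            outcomes=tuple(o for o in self.outcomes if o.patient_id in keep),
            covariates=replace(
                self.covariates,
                frame=self.covariates.frame.loc[
                    [p for p in self.covariates.patient_ids if p in keep]
                ],
            ),
            n_events=self.n_events,
        )


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def _series_from_frame(frame: pd.DataFrame) -> list[BiomarkerSeries]:
    dup = frame.duplicated(subset=["patient_id", "biomarker_id", "time"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise IntegrityError(
            "duplicate (patient, biomarker, time) row: "
            f"({row['patient_id']!r}, {row['biomarker_id']!r}, {row['time']!r})"
        )
    out = []
    for (pid, k), grp in frame.groupby(["patient_id", "biomarker_id"], sort=True):
        grp = grp.sort_values("time")
        out.append(
            BiomarkerSeries(pid, int(k), grp["time"].to_numpy(), grp["value"].to_numpy())
        )
    return out


def build_block(
    longitudinal: pd.DataFrame,
    survival: pd.DataFrame,
    covariates: pd.DataFrame,
    n_events: int,
    block_id: int = 1,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> BlockDataset:
    """Assemble a :class:`BlockDataset` from in-memory tables."""
    _require_columns(longitudinal, LONGITUDINAL_COLUMNS, "longitudinal")
    _require_columns(survival, SURVIVAL_COLUMNS, "survival")
    _require_columns(covariates, ["patient_id"], "covariate")
    outcomes = tuple(
        SurvivalOutcome(r.patient_id, float(r.time), int(r.event))
        for r in survival.itertuples()
    )
    cov_frame = covariates.set_index("patient_id")
    cols = [c for c in cov_frame.columns]
    cont = tuple(continuous) if continuous else tuple(
        c for c in cols if pd.api.types.is_numeric_dtype(cov_frame[c])
    )
    cat = tuple(categorical) if categorical else tuple(c for c in cols if c not in cont)
    return BlockDataset(
        block_id=block_id,
        series=tuple(_series_from_frame(longitudinal)),
        outcomes=outcomes,
        covariates=CovariateTable(cov_frame, continuous=cont, categorical=cat),
        n_events=n_events,
    )


def read_block(
    longitudinal_table: str | Path,
    survival_table: str | Path,
    covariate_table: str | Path,
    n_events: int,
    block_id: int = 1,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> BlockDataset:
    """Read one block from three comma-separated UTF-8 tables with header rows."""
    if n_events not in (1, 2):
        raise ValueError("n_events must be 1 or 2")
    longitudinal = pd.read_csv(longitudinal_table)
    survival = pd.read_csv(survival_table)
    covariates = pd.read_csv(covariate_table)
    return build_block(
        longitudinal, survival, covariates, n_events, block_id,
        continuous=continuous, categorical=categorical,
    )


def write_block(dataset: BlockDataset, directory: str | Path, prefix: str = "block") -> dict:
    """Write the three tables of a block; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "longitudinal": directory / f"{prefix}_longitudinal.csv",
        "survival": directory / f"{prefix}_survival.csv",
        "covariates": directory / f"{prefix}_covariates.csv",
    }
    dataset.longitudinal_frame().to_csv(paths["longitudinal"], index=False)
    dataset.survival_frame().to_csv(paths["survival"], index=False)
    dataset.covariates.frame.reset_index(names="patient_id").to_csv(
        paths["covariates"], index=False
    )
    return paths


def preprocess_covariates(
    raw: CovariateTable,
    spec: PreprocessSpec | None = None,
    log_columns: Sequence[str] = (),
) -> tuple[CovariateTable, PreprocessSpec]:
    """Log-transform, standardize and mean-impute continuous covariates; one-hot
    encode categoricals with the first level as reference.

    With ``spec=None`` the transformations are learned from ``raw`` (the training
    path) and returned; with a spec given it is applied verbatim (the test path):
    missing continuous entries become 0, the standardized training mean.
    """
    frame = raw.frame.copy()
    if spec is None:
        cont_spec: dict[str, tuple[bool, float, float]] = {}
        for col in raw.continuous:
            x = frame[col].astype(float)
            use_log = col in log_columns
            if use_log:
                if (x.dropna() <= 0).any():
                    raise ValueError(f"nonpositive value in log-flagged column {col!r}")
                x = np.log(x)
            mean = float(x.mean())
            sd = float(x.std(ddof=0))
            if not sd > 0:
                raise ValueError(f"zero training SD in column {col!r}")
            cont_spec[col] = (use_log, mean, sd)
        cat_spec: dict[str, tuple[tuple, object]] = {}
        for col in raw.categorical:
            observed = frame[col].dropna()
            levels = tuple(sorted(observed.unique(), key=str))
            if not levels:
                raise ValueError(f"categorical column {col!r} has no observed level")
            mode = observed.mode().iloc[0]
            cat_spec[col] = (levels, mode)
        spec = PreprocessSpec(continuous=cont_spec, categorical=cat_spec)
    else:
        expected = set(spec.continuous) | set(spec.categorical)
        present = set(raw.continuous) | set(raw.categorical)
        if expected != present:
            raise SchemaError(
                f"spec columns {sorted(expected)} do not match table columns {sorted(present)}"
            )

    out = pd.DataFrame(index=frame.index)
    for col, (use_log, mean, sd) in spec.continuous.items():
        x = frame[col].astype(float)
        if use_log:
            if (x.dropna() <= 0).any():
                raise ValueError(f"nonpositive value in log-flagged column {col!r}")
            x = np.log(x)
        z = (x - mean) / sd
        out[col] = z.fillna(0.0)
    for col, (levels, mode) in spec.categorical.items():
        filled = frame[col].where(frame[col].notna(), mode)
        for lev in levels[1:]:
            out[f"{col}_{lev}"] = (filled == lev).astype(float)
    table = CovariateTable(
        out,
        continuous=tuple(spec.continuous),
        categorical=tuple(spec.categorical),
        design_columns=spec.design_columns,
    )
    return table, spec


def split_train_test(
    dataset: BlockDataset, fraction: float, seed: int
) -> tuple[BlockDataset, BlockDataset]:
    """Patient-level split: ceil(fraction * n) training patients, rest test.

    The same seed always reproduces the same partition.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    ids = np.asarray(dataset.patient_ids, dtype=object)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.ceil(fraction * len(ids)))
    train_ids = ids[perm[:n_train]]
    test_ids = ids[perm[n_train:]]
    return dataset.subset(train_ids), dataset.subset(test_ids)
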