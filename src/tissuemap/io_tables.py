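"""Typed cell tables, run configuration, and CSV interchange.

Every downstream analysis consumes the structures defined here.  A
:class:`CellTable` holds one record per segmented cell (or landmark object):
its sample of origin, a pre-assigned phenotype label, a position in
micrometers, per-channel mean fluorescence intensities (columns prefixed
``ch_``), and optional morphology columns.  Phenotype gating happens
upstream (histo-cytometry); this package never touches pixels.

CSV is the canonical interchange dialect: UTF-8, comma delimiter, ``.``
decimal, mandatory header row.  2D sections are encoded with a constant
``z_um`` column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "CellTable",
    "RunConfig",
    "read_cell_table",
    "write_cell_table",
    "write_outputs",
    "read_neighborhoods",
    "read_assignments",
    "read_correlations",
]

REQUIRED_COLUMNS = ("sample_id", "phenotype", "x_um", "y_um", "z_um")
CHANNEL_PREFIX = "ch_"
MORPHOLOGY_COLUMNS = ("volume_um3", "sphericity")


class SchemaError(ValueError):
    """A table is missing a required column or violates an invariant."""


@dataclass
class CellTable:
    """One record per segmented cell/landmark object.

    Parameters
    ----------
    data
        DataFrame with columns ``sample_id``, ``phenotype``, ``x_um``,
        ``y_um``, ``z_um``, zero or more ``ch_*`` channel columns and
        optional morphology columns (``volume_um3``, ``sphericity``).
    vocabulary
        The fixed phenotype vocabulary for the run.  Defaults to the
        phenotypes observed in ``data`` (sorted).
    """

    data: pd.DataFrame
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"required column {col!r} is missing")
        for col in ("x_um", "y_um", "z_um"):
            values = pd.to_numeric(self.data[col], errors="coerce")
            bad = ~np.isfinite(values.to_numpy(dtype=float))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise SchemaError(
                    f"non-numeric or non-finite position in column {col!r} at row {row}"
                )
            self.data[col] = values.astype(float)
        self.data = self.data.reset_index(drop=True)
        if not self.vocabulary:
            self.vocabulary = tuple(sorted(self.data["phenotype"].astype(str).unique()))
        else:
            self.vocabulary = tuple(self.vocabulary)
            unknown = set(self.data["phenotype"].astype(str)) - set(self.vocabulary)
            if unknown:
                raise SchemaError(f"phenotypes outside run vocabulary: {sorted(unknown)}")

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of x, y, z in micrometers."""
        return self.data[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c.startswith(CHANNEL_PREFIX))

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["sample_id"].astype(str)))

    def for_sample(self, sample_id: str) -> "CellTable":
        mask = self.data["sample_id"].astype(str) == str(sample_id)
        return CellTable(self.data.loc[mask].copy(), vocabulary=self.vocabulary)

    def subset(self, mask) -> "CellTable":
        """Row subset (boolean mask or index array); vocabulary is kept."""
        sub = self.data.loc[np.asarray(mask)] if not isinstance(mask, pd.Series) else self.data.loc[mask]
        return CellTable(sub.copy(), vocabulary=self.vocabulary)

    def of_phenotype(self, phenotype: str) -> "CellTable":
        return self.subset((self.data["phenotype"].astype(str) == phenotype).to_numpy())

    def z_extent(self, sample_id: str | None = None) -> float:
        z = self.data["z_um"] if sample_id is None else self.for_sample(sample_id).data["z_um"]
        return float(z.max() - z.min()) if len(z) else 0.0


@dataclass
class RunConfig:
    """Run-level parameters shared by the CLI subcommands.

    Defaults follow the workflow's published choices: a 30 µm neighborhood
    radius, a region-count sweep capped at 50 clusters, and a region-network
    edge threshold of 0.005% of neighborhoods.
    """

    radius_um: float = 30.0
    feature_mode: str = "composition"  # raw | composition | standardized
    sweep_min: int = 2
    sweep_max: int = 10
    seed: int = 0
    smoothing_window: int = 50
    edge_threshold_pct: float = 0.005
    alpha_um: float | None = None  # None -> 2 x grid spacing (= radius)

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.feature_mode not in ("raw", "composition", "standardized"):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        if not (2 <= self.sweep_min <= self.sweep_max <= 50):
            raise ValueError("sweep range must satisfy 2 <= min <= max <= 50")
        if self.edge_threshold_pct < 0:
            raise ValueError("edge_threshold_pct must be >= 0")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# -- cell-table I/O --------------------------------------------------------


def read_cell_table(path: str | Path, vocabulary: Sequence[str] = ()) -> CellTable:
    """Read a cell table from the canonical CSV dialect.

    Unknown numeric columns are preserved; channel columns must carry the
    ``ch_`` prefix.  Raises :class:`SchemaError` naming the first missing
    required column or the row index of the first non-numeric position.
    """
    df = pd.read_csv(path)
    return CellTable(df, vocabulary=tuple(vocabulary))


def write_cell_table(table: CellTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# -- analysis-output I/O ---------------------------------------------------

_COUNT_PREFIX = "n_"


def write_outputs(obj, path: str | Path) -> None:
    """Write a NeighborhoodSet, RegionAssignment, or CorrelationResult to CSV.

    Numeric fields round-trip at full precision (pandas writes shortest
    exact ``repr`` floats).  Dispatch is by object type.
    """
    from .neighborhoods import NeighborhoodSet
    from .regions import RegionAssignment
    from .spatial_stats import CorrelationResult

    if isinstance(obj, NeighborhoodSet):
        _write_neighborhoods(obj, path)
    elif isinstance(obj, RegionAssignment):
        _write_assignments(obj, path)
    elif isinstance(obj, CorrelationResult):
        _write_correlations(obj, path)
    else:  # pragma: no cover - programming error
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def _write_neighborhoods(nbhd, path) -> None:
    df = nbhd.centers.copy()
    df.insert(0, "neighborhood_id", np.arange(len(df)))
    df["geometry"] = [nbhd.geometry[s] for s in df["sample_id"].astype(str)]
    df["radius_um"] = nbhd.radius
    for col in nbhd.counts.columns:
        df[_COUNT_PREFIX + str(col)] = nbhd.counts[col].to_numpy()
    for col in nbhd.mfi_sums.columns:
        df[str(col)] = nbhd.mfi_sums[col].to_numpy()
    df.to_csv(path, index=False)


def read_neighborhoods(path: str | Path):
    from .neighborhoods import NeighborhoodSet

    df = pd.read_csv(path)
    fixed = {"neighborhood_id", "sample_id", "x_um", "y_um", "z_um", "geometry", "radius_um"}
    count_cols = [c for c in df.columns if c.startswith(_COUNT_PREFIX) and c not in fixed]
    chan_cols = [c for c in df.columns if c.startswith(CHANNEL_PREFIX)]
    if df.empty:
        return NeighborhoodSet(
            centers=pd.DataFrame(columns=["sample_id", "x_um", "y_um", "z_um"]),
            radius=float("nan"),
            geometry={},
            counts=pd.DataFrame(columns=[c[len(_COUNT_PREFIX):] for c in count_cols]),
            mfi_sums=pd.DataFrame(columns=chan_cols),
        )
    geometry = dict(
        df.groupby(df["sample_id"].astype(str))["geometry"].first().astype(str)
    )
    counts = df[count_cols].rename(columns=lambda c: c[len(_COUNT_PREFIX):]).astype(int)
    return NeighborhoodSet(
        centers=df[["sample_id", "x_um", "y_um", "z_um"]].copy(),
        radius=float(df["radius_um"].iloc[0]),
        geometry=geometry,
        counts=counts,
        mfi_sums=df[chan_cols].astype(float).copy(),
    )


def _write_assignments(assignment, path) -> None:
    ids = (
        assignment.neighborhood_ids
        if assignment.neighborhood_ids is not None
        else np.arange(len(assignment.region))
    )
    df = pd.DataFrame(
        {
            "neighborhood_id": ids,
            "region": assignment.region,
            "annotated_region": [
                assignment.annotations.get(int(r), "") for r in assignment.region
            ],
        }
    )
    df.to_csv(path, index=False)


def read_assignments(path: str | Path):
    from .regions import RegionAssignment

    df = pd.read_csv(path, keep_default_na=False)
    region = df["region"].to_numpy(dtype=int)
    annotations: dict[int, str] = {}
    for r, a in zip(region, df["annotated_region"].astype(str)):
        if a:
            annotations[int(r)] = a
    ids = df["neighborhood_id"].to_numpy(dtype=int)
    if np.array_equal(ids, np.arange(len(region))):
        ids = None
    return RegionAssignment(region=region, annotations=annotations, neighborhood_ids=ids)


def _write_correlations(result, path) -> None:
    rows = []
    for sample, r in result.r_per_sample.items():
        p = result.p_per_sample[sample]
        for a in r.index:
            for b in r.columns:
                rows.append((sample, a, b, r.loc[a, b], p.loc[a, b]))
    for a in result.r_mean.index:
        for b in result.r_mean.columns:
            rows.append(("__cohort_mean__", a, b, result.r_mean.loc[a, b], np.nan))
    pd.DataFrame(rows, columns=["sample_id", "phenotype_a", "phenotype_b", "r", "p"]).to_csv(
        path, index=False
    )


def read_correlations(path: str | Path):
    from .spatial_stats import CorrelationResult

    df = pd.read_csv(path)
    r_per_sample: dict[str, pd.DataFrame] = {}
    p_per_sample: dict[str, pd.DataFrame] = {}
    r_mean = None
    for sample, grp in df.groupby("sample_id", sort=False):
        r = grp.pivot(index="phenotype_a", columns="phenotype_b", values="r")
        p = grp.pivot(index="phenotype_a", columns="phenotype_b", values="p")
        order = list(pd.unique(grp["phenotype_a"]))
        r, p = r.loc[order, order], p.loc[order, order]
        r.index.name = r.columns.name = None
        p.index.name = p.columns.name = None
        if sample == "__cohort_mean__":
            r_mean = r
        else:
            r_per_sample[str(sample)] = r
            p_per_sample[str(sample)] = p
    return CorrelationResult(
        r_per_sample=r_per_sample, p_per_sample=p_per_sample, r_mean=r_mean, scope="all"
    )
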