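"""Raster-scanned and object-centered local neighborhoods.

A neighborhood is the set of cells within a fixed radius of a center: a
cylindrical window (distance in x-y only) when the sample is effectively 2D,
or a spherical window in 3D.  A sample is treated as effectively 2D whenever
its z thickness (max z - min z) is smaller than the neighborhood radius.

Raster centers form an axis-aligned grid with spacing radius/2 per gridded
axis, anchored at the per-sample coordinate minima and spanning through the
maxima.  For each neighborhood we record the number of cells of each
phenotype and, per channel, the MFI summed over all member cells.
Membership uses a closed ball: cells at distance exactly r are members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_tables import CellTable

__all__ = [
    "NeighborhoodSet",
    "raster_scan_neighborhoods",
    "cell_centered_neighborhoods",
]

CYLINDER_2D = "cylinder2D"
SPHERE_3D = "sphere3D"

@dataclass
class NeighborhoodSet:
    """Neighborhood centers plus per-phenotype counts and per-channel MFI sums.

    Attributes
    ----------
    centers : DataFrame with ``sample_id, x_um, y_um, z_um``, one row per
        neighborhood.
    radius : window radius in µm.
    geometry : per-sample window geometry, ``cylinder2D`` or ``sphere3D``.
    counts : [neighborhood x phenotype] nonnegative integers.
    mfi_sums : [neighborhood x channel] nonnegative reals.
    """

    centers: pd.DataFrame
    radius: float
    geometry: dict[str, str]
    counts: pd.DataFrame
    mfi_sums: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.centers)
        if len(self.counts) != n or len(self.mfi_sums) != n:
            raise ValueError("counts/mfi_sums rows must match number of centers")
        self.centers = self.centers.reset_index(drop=True)
        self.counts = self.counts.reset_index(drop=True)
        self.mfi_sums = self.mfi_sums.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.centers)

    @property
    def phenotypes(self) -> tuple[str, ...]:
        return tuple(map(str, self.counts.columns))

    @property
    def sample_ids(self) -> np.ndarray:
        return self.centers["sample_id"].astype(str).to_numpy()

    def center_positions(self) -> np.ndarray:
        return self.centers[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    def grid_spacing(self) -> float:
        """Raster grid spacing (radius / 2)."""
        return self.radius / 2.0

    def nonempty(self) -> "NeighborhoodSet":
        """Subset of neighborhoods containing at least one cell.

        Composition features of empty neighborhoods are all-zero and carry
        no compositional information; region clustering on composition
        features operates on this subset.
        """
        return self.for_mask(self.counts.sum(axis=1).to_numpy() > 0)

    def for_mask(self, mask: np.ndarray) -> "NeighborhoodSet":
        mask = np.asarray(mask)
        return NeighborhoodSet(
            centers=self.centers.loc[mask].copy(),
            radius=self.radius,
            geometry=dict(self.geometry),
            counts=self.counts.loc[mask].copy(),
            mfi_sums=self.mfi_sums.loc[mask].copy(),
        )


def _sample_geometry(cells: CellTable, sample_id: str, radius: float) -> str:
    return CYLINDER_2D if cells.z_extent(sample_id) < radius else SPHERE_3D


def _grid_axis(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Grid anchored at lo, stepping by spacing, spanning through hi."""
    n_steps = int(np.ceil(max(hi - lo, 0.0) / spacing - 1e-12))
    return lo + spacing * np.arange(n_steps + 1)


def _accumulate(
    cells: CellTable,
    sample: str,
    centers_xyz: np.ndarray,
    radius: float,
    geometry: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and MFI sums for one sample's centers via a KD-tree query."""
    sub = cells.for_sample(sample)
    pos = sub.positions
    ndim = 2 if geometry == CYLINDER_2D else 3
    tree = cKDTree(pos[:, :ndim])
    # query_ball_point is inclusive: cells at distance exactly r are members
    members = tree.query_ball_point(centers_xyz[:, :ndim], r=radius)

    phenos = list(cells.vocabulary)
    pheno_idx = {p: i for i, p in enumerate(phenos)}
    cell_pheno = sub.data["phenotype"].astype(str).map(pheno_idx).to_numpy()
    chan_names = list(sub.channel_names)
    chan = sub.data[chan_names].to_numpy(dtype=float) if chan_names else np.zeros((len(pos), 0))

    counts = np.zeros((len(centers_xyz), len(phenos)), dtype=int)
    mfi = np.zeros((len(centers_xyz), len(chan_names)))
    for i, idx in enumerate(members):
        if not idx:
            continue
        idx = np.asarray(idx)
        np.add.at(counts[i], cell_pheno[idx], 1)
        if chan_names:
            mfi[i] = chan[idx].sum(axis=0)
    return (
        pd.DataFrame(counts, columns=phenos),
        pd.DataFrame(mfi, columns=chan_names),
    )


def raster_scan_neighborhoods(cells: CellTable, radius: float) -> NeighborhoodSet:
    """Raster scan a circular/spherical window over each sample.

    Centers form a grid with spacing ``radius/2`` anchored at the per-sample
    minima of the gridded axes and spanning through the maxima.  Samples
    whose z thickness is below ``radius`` use a cylindrical window (z
    ignored for membership; center z set to the sample's z midpoint);
    otherwise z is gridded too and the window is spherical.  Empty
    neighborhoods are retained.
    """
    if cells.n == 0:
        raise ValueError("cell table is empty")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    spacing = radius / 2.0

    all_centers, all_counts, all_mfi = [], [], []
    geometry: dict[str, str] = {}
    for sample in cells.samples:
        sub = cells.for_sample(sample)
        geom = _sample_geometry(cells, sample, radius)
        geometry[sample] = geom
        pos = sub.positions
        gx = _grid_axis(pos[:, 0].min(), pos[:, 0].max(), spacing)
        gy = _grid_axis(pos[:, 1].min(), pos[:, 1].max(), spacing)
        if geom == SPHERE_3D:
            gz = _grid_axis(pos[:, 2].min(), pos[:, 2].max(), spacing)
        else:
            gz = np.array([(pos[:, 2].min() + pos[:, 2].max()) / 2.0])
        xx, yy, zz = np.meshgrid(gx, gy, gz, indexing="ij")
        centers_xyz = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        counts, mfi = _accumulate(cells, sample, centers_xyz, radius, geom)
        all_centers.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "x_um": centers_xyz[:, 0],
                    "y_um": centers_xyz[:, 1],
                    "z_um": centers_xyz[:, 2],
                }
            )
        )
        all_counts.append(counts)
        all_mfi.append(mfi)

    return NeighborhoodSet(
        centers=pd.concat(all_centers, ignore_index=True),
        radius=float(radius),
        geometry=geometry,
        counts=pd.concat(all_counts, ignore_index=True),
        mfi_sums=pd.concat(all_mfi, ignore_index=True),
    )


def cell_centered_neighborhoods(
    cells: CellTable,
    centers: CellTable,
    radius: float,
    include_center: bool = True,
) -> NeighborhoodSet:
    """One neighborhood per center object, centered on its position.

    Membership and the cylinder/sphere rule are identical to the raster
    scan (geometry decided from the *cells* table's per-sample z thickness).

    The center object itself counts as a member by default.  When the
    centers are rows of ``cells`` (the usual case: centering on one
    phenotype of the same table) they lie at distance 0 and are counted
    automatically; ``include_center=False`` then removes one
    exactly-coincident cell of the center's phenotype per neighborhood.
    When centers are disjoint from ``cells``, ``include_center=True`` adds
    the center's own phenotype (if in the vocabulary) and channel values.
    """
    if cells.n == 0:
        raise ValueError("cell table is empty")
    if centers.n == 0:
        raise ValueError("centers table is empty")
    if radius <= 0:
        raise ValueError("radius must be > 0")

    cell_keys = set(
        zip(
            cells.data["sample_id"].astype(str),
            cells.data["phenotype"].astype(str),
            cells.data["x_um"],
            cells.data["y_um"],
            cells.data["z_um"],
        )
    )

    all_centers, all_counts, all_mfi = [], [], []
    geometry: dict[str, str] = {}
    phenos = list(cells.vocabulary)
    chan_names = list(cells.channel_names)
    for sample in centers.samples:
        if sample not in cells.samples:
            raise ValueError(f"center sample {sample!r} absent from cell table")
        geom = _sample_geometry(cells, sample, radius)
        geometry[sample] = geom
        csub = centers.for_sample(sample)
        centers_xyz = csub.positions
        counts, mfi = _accumulate(cells, sample, centers_xyz, radius, geom)
        for i, (_, row) in enumerate(csub.data.iterrows()):
            key = (
                str(row["sample_id"]),
                str(row["phenotype"]),
                row["x_um"],
                row["y_um"],
                row["z_um"],
            )
            in_cells = key in cell_keys
            pheno = str(row["phenotype"])
            if include_center and not in_cells and pheno in phenos:
                counts.loc[i, pheno] += 1
                for c in chan_names:
                    if c in csub.data.columns:
                        mfi.loc[i, c] += float(row[c])
            elif not include_center and in_cells and pheno in phenos:
                counts.loc[i, pheno] -= 1
                for c in chan_names:
                    mfi.loc[i, c] -= float(row[c])
        all_centers.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "x_um": centers_xyz[:, 0],
                    "y_um": centers_xyz[:, 1],
                    "z_um": centers_xyz[:, 2],
                }
            )
        )
        all_counts.append(counts)
        all_mfi.append(mfi)

    return NeighborhoodSet(
        centers=pd.concat(all_centers, ignore_index=True),
        radius=float(radius),
        geometry=geometry,
        counts=pd.concat(all_counts, ignore_index=True),
        mfi_sums=pd.concat(all_mfi, ignore_index=True),
    )
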