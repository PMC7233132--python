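"""Shared fixtures: random cell tables and brute-force neighborhood oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tissuemap import CellTable


def random_cell_table(
    rng: np.random.Generator,
    n: int,
    phenotypes=("A", "B", "C"),
    channels=("ch_one", "ch_two"),
    box=((0.0, 0.0, 0.0), (100.0, 100.0, 0.0)),
    sample_id: str = "s1",
) -> CellTable:
    lo, hi = np.asarray(box[0]), np.asarray(box[1])
    pos = np.column_stack(
        [
            rng.uniform(lo[a], hi[a], size=n) if hi[a] > lo[a] else np.full(n, lo[a])
            for a in range(3)
        ]
    )
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "phenotype": rng.choice(phenotypes, size=n),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
        }
    )
    for c in channels:
        df[c] = rng.gamma(2.0, 50.0, size=n)
    return CellTable(df, vocabulary=tuple(sorted(phenotypes)))


def brute_force_neighborhood(cells: CellTable, centers_xyz: np.ndarray, radius: float, ndim: int):
    """All-pairs membership oracle: counts and summed MFI per neighborhood.

    Membership: Euclidean distance <= radius over the first ``ndim`` axes.
    """
    pos = cells.positions[:, :ndim]
    centers = np.atleast_2d(centers_xyz)[:, :ndim]
    d = np.linalg.norm(centers[:, None, :] - pos[None, :, :], axis=2)
    member = d <= radius
    phenos = list(cells.vocabulary)
    onehot = np.stack(
        [(cells.data["phenotype"].astype(str) == p).to_numpy() for p in phenos], axis=1
    )
    counts = member.astype(int) @ onehot.astype(int)
    chans = list(cells.channel_names)
    mfi = member.astype(float) @ cells.data[chans].to_numpy(dtype=float) if chans else np.zeros((len(centers), 0))
    return (
        pd.DataFrame(counts, columns=phenos),
        pd.DataFrame(mfi, columns=chans),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
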