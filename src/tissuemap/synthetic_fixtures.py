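"""Synthetic compartmentalized tissues with ground-truth labels.

Real multiplexed-imaging datasets are large and proprietary; the generator
here produces download-free, seedable point patterns that emulate the
compartmental organization of a lymph node: B-cell follicles at the
periphery, a central T-cell zone, and a macrophage/DC-rich medullary ring.
Each compartment draws an independent homogeneous Poisson point process per
phenotype (spatial interaction between cells is deliberately not modeled),
with later compartments taking precedence where geometries overlap.
Channel intensities are lognormal, bright for the phenotype's hallmark
channel and dim elsewhere.

Ground truth is exposed two ways: a per-cell compartment label, and a
position -> label oracle (``TissueSpec.label_at``) so that neighborhood
*centers* — not only cells — can be truth-labeled when scoring region
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import CellTable

__all__ = [
    "Disk",
    "Annulus",
    "Box",
    "Compartment",
    "TissueSpec",
    "SimulatedTissue",
    "simulate_tissue",
    "ln_preset",
]

MAX_EXPECTED_CELLS = 10_000_000

OUTSIDE_LABEL = "outside"


# -- geometry primitives (exact area/containment; z = 0 unless 3D box) -----


@dataclass(frozen=True)
class Disk:
    cx: float
    cy: float
    r: float

    @property
    def measure(self) -> float:
        return math.pi * self.r**2

    @property
    def bbox(self):
        return (self.cx - self.r, self.cy - self.r, 0.0), (self.cx + self.r, self.cy + self.r, 0.0)

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        return (xyz[:, 0] - self.cx) ** 2 + (xyz[:, 1] - self.cy) ** 2 <= self.r**2


@dataclass(frozen=True)
class Annulus:
    cx: float
    cy: float
    r_inner: float
    r_outer: float

    def __post_init__(self):
        if not 0 <= self.r_inner < self.r_outer:
            raise ValueError("need 0 <= r_inner < r_outer")

    @property
    def measure(self) -> float:
        return math.pi * (self.r_outer**2 - self.r_inner**2)

    @property
    def bbox(self):
        return (
            (self.cx - self.r_outer, self.cy - self.r_outer, 0.0),
            (self.cx + self.r_outer, self.cy + self.r_outer, 0.0),
        )

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        d2 = (xyz[:, 0] - self.cx) ** 2 + (xyz[:, 1] - self.cy) ** 2
        return (d2 >= self.r_inner**2) & (d2 <= self.r_outer**2)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box; zero z extent makes it 2D (rate per µm²)."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    @property
    def measure(self) -> float:
        dx, dy, dz = (h - l for l, h in zip(self.lo, self.hi))
        return dx * dy * (dz if dz > 0 else 1.0)

    @property
    def bbox(self):
        return tuple(self.lo), tuple(self.hi)

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((xyz >= lo) & (xyz <= hi), axis=1)


@dataclass(frozen=True)
class Compartment:
    """A named geometry with per-phenotype Poisson intensities (cells/µm²
    in 2D, cells/µm³ in 3D) and per-phenotype channel brightness."""

    name: str
    shape: Disk | Annulus | Box
    rates: dict[str, float]
    # phenotype -> channel -> (lognormal mean of log, sigma of log)
    channels: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self):
        if any(lam < 0 for lam in self.rates.values()):
            raise ValueError("rates must be >= 0")


@dataclass
class TissueSpec:
    """Overall tissue plus compartments; later compartments win overlaps."""

    compartments: list[Compartment]
    sample_id: str = "synthetic"

    def __post_init__(self):
        expected = sum(
            lam * c.shape.measure for c in self.compartments for lam in c.rates.values()
        )
        if not math.isfinite(expected):
            raise ValueError("expected cell count must be finite")
        if expected > MAX_EXPECTED_CELLS:
            raise ValueError(f"expected cell count {expected:.3g} exceeds the desk-scale guard")

    @property
    def phenotypes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.compartments:
            for p in c.rates:
                if p not in seen:
                    seen.append(p)
        return tuple(seen)

    @property
    def channel_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.compartments:
            for chans in c.channels.values():
                for ch in chans:
                    if ch not in seen:
                        seen.append(ch)
        return tuple(seen)

    def label_at(self, xyz: np.ndarray) -> np.ndarray:
        """Ground-truth compartment label per position (later-wins)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        if xyz.shape[1] == 2:
            xyz = np.column_stack([xyz, np.zeros(len(xyz))])
        labels = np.full(len(xyz), OUTSIDE_LABEL, dtype=object)
        for comp in self.compartments:  # later compartments overwrite
            labels[comp.shape.contains(xyz)] = comp.name
        return labels.astype(str)


@dataclass
class SimulatedTissue:
    cells: CellTable
    truth: pd.Series  # per-cell compartment label, aligned with cells.data
    spec: TissueSpec


def _sample_in_shape(shape, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a primitive via bounding-box rejection."""
    (lo, hi) = shape.bbox
    lo, hi = np.asarray(lo), np.asarray(hi)
    out = np.empty((0, 3))
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        cand = np.column_stack(
            [
                rng.uniform(lo[a], hi[a], size=m) if hi[a] > lo[a] else np.full(m, lo[a])
                for a in range(3)
            ]
        )
        out = np.vstack([out, cand[shape.contains(cand)]])
    return out[:n]


def simulate_tissue(spec: TissueSpec, seed: int) -> SimulatedTissue:
    """Draw one tissue realization: a CellTable plus ground-truth labels.

    Each (compartment, phenotype) pair draws N ~ Poisson(rate x measure)
    uniform points in the compartment geometry; points falling where a
    *later* compartment overlaps are discarded (precedence thinning), which
    keeps every compartment's interior homogeneous at its own rate.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    labels: list[np.ndarray] = []
    chan_names = list(spec.channel_names)
    for comp in spec.compartments:
        for pheno, lam in comp.rates.items():
            n = rng.poisson(lam * comp.shape.measure)
            if n == 0:
                continue
            xyz = _sample_in_shape(comp.shape, n, rng)
            keep = spec.label_at(xyz) == comp.name
            xyz = xyz[keep]
            if len(xyz) == 0:
                continue
            df = pd.DataFrame(
                {
                    "sample_id": spec.sample_id,
                    "phenotype": pheno,
                    "x_um": xyz[:, 0],
                    "y_um": xyz[:, 1],
                    "z_um": xyz[:, 2],
                }
            )
            params = comp.channels.get(pheno, {})
            for ch in chan_names:
                if ch in params:
                    mu, sigma = params[ch]
                    df[ch] = rng.lognormal(mu, sigma, size=len(df))
                else:
                    df[ch] = 0.0
            rows.append(df)
            labels.append(np.full(len(df), comp.name, dtype=object))

    if rows:
        data = pd.concat(rows, ignore_index=True)
        truth = pd.Series(np.concatenate(labels).astype(str), name="compartment")
    else:
        data = pd.DataFrame(
            {
                "sample_id": pd.Series(dtype=str),
                "phenotype": pd.Series(dtype=str),
                "x_um": pd.Series(dtype=float),
                "y_um": pd.Series(dtype=float),
                "z_um": pd.Series(dtype=float),
            }
        )
        for ch in chan_names:
            data[ch] = pd.Series(dtype=float)
        truth = pd.Series(dtype=str, name="compartment")
    cells = CellTable(data, vocabulary=spec.phenotypes)
    return SimulatedTissue(cells=cells, truth=truth, spec=spec)


# -- lymph-node preset -----------------------------------------------------

# Poisson intensities in cells/µm², chosen once as a desk-scale caricature
# of lymph-node organization: follicles dominated by B cells (B:T = 10),
# a T-cell zone with moderate DCs, and a macrophage/DC-rich medullary ring.
_LN_RATES = {
    "tzone": {"T": 3e-3, "DC": 1e-3, "B": 2e-4},
    "medulla": {"Mac": 2e-3, "DC": 1.5e-3, "T": 3e-4},
    "follicle": {"B": 4e-3, "T": 4e-4, "DC": 2e-4},
}

_LN_CHANNELS = {
    "B": {"ch_B220": (4.0, 0.3), "ch_CD3": (1.0, 0.3), "ch_CD11c": (1.0, 0.3), "ch_CD64": (1.0, 0.3)},
    "T": {"ch_B220": (1.0, 0.3), "ch_CD3": (4.0, 0.3), "ch_CD11c": (1.0, 0.3), "ch_CD64": (1.0, 0.3)},
    "DC": {"ch_B220": (1.0, 0.3), "ch_CD3": (1.0, 0.3), "ch_CD11c": (4.0, 0.3), "ch_CD64": (1.5, 0.3)},
    "Mac": {"ch_B220": (1.0, 0.3), "ch_CD3": (1.0, 0.3), "ch_CD11c": (1.5, 0.3), "ch_CD64": (4.0, 0.3)},
}

LN_DISK_RADIUS_UM = 500.0
LN_FOLLICLE_RADIUS_UM = 120.0
LN_FOLLICLE_RING_UM = 340.0
LN_N_FOLLICLES = 6
LN_MEDULLA_INNER_UM = 400.0


def ln_preset(sample_id: str = "LN_synthetic") -> TissueSpec:
    """Lymph-node-like tissue: a 1,000 µm disk with six peripheral B-cell
    follicles (120 µm radius), a central T zone, and a 100 µm medullary
    ring.  Compartment order encodes precedence: follicles override the T
    zone and the medullary ring where they overlap."""
    comps = [
        Compartment(
            "tzone",
            Disk(0.0, 0.0, LN_MEDULLA_INNER_UM),
            _LN_RATES["tzone"],
            _LN_CHANNELS,
        ),
        Compartment(
            "medulla",
            Annulus(0.0, 0.0, LN_MEDULLA_INNER_UM, LN_DISK_RADIUS_UM),
            _LN_RATES["medulla"],
            _LN_CHANNELS,
        ),
    ]
    for i in range(LN_N_FOLLICLES):
        angle = 2 * math.pi * i / LN_N_FOLLICLES
        comps.append(
            Compartment(
                "follicle",
                Disk(
                    LN_FOLLICLE_RING_UM * math.cos(angle),
                    LN_FOLLICLE_RING_UM * math.sin(angle),
                    LN_FOLLICLE_RADIUS_UM,
                ),
                _LN_RATES["follicle"],
                _LN_CHANNELS,
            )
        )
    return TissueSpec(compartments=comps, sample_id=sample_id)
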