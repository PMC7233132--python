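"""Neighborhood-level spatial statistics.

Cell-cell correlation: the Pearson correlation of per-phenotype cell counts
across neighborhoods reveals which populations co-occur locally and which
avoid one another.  It is computed per sample (whole tissue or restricted to
one annotated region) and averaged, unweighted, across the sample cohort.
Significance uses the classic t transform of the correlation coefficient,
t = r*sqrt(n-2)/sqrt(1-r^2), two-sided against Student's t with n-2 df.

Pseudo-space: neighborhoods are sorted on a weighted combination of their
per-phenotype features (negative weights sort a phenotype to the left,
positive to the right), collapsing the tissue onto a 1-D axis; each
phenotype's profile along that axis is boxcar-smoothed and normalized to
its own maximum so different cell types can be compared on one plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .neighborhoods import NeighborhoodSet
from .regions import FeatureMatrix, RegionAssignment

__all__ = [
    "CorrelationResult",
    "PseudoSpaceResult",
    "correlate",
    "correlation_pvalue",
    "pseudo_space",
]


@dataclass
class CorrelationResult:
    """Per-sample Pearson matrices, matching p-values, and the cohort mean.

    Entries for zero-variance phenotypes are missing (NaN), never 0; the
    cohort mean excludes missing entries pairwise.
    """

    r_per_sample: dict[str, pd.DataFrame]
    p_per_sample: dict[str, pd.DataFrame]
    r_mean: pd.DataFrame
    scope: str = "all"


@dataclass
class PseudoSpaceResult:
    """A 1-D ordering of neighborhoods and the smoothed phenotype curves.

    ``order`` is a permutation: position k of the pseudo-space axis shows
    neighborhood ``order[k]``.  ``curves`` has one max-normalized column per
    feature, indexed by axis rank.
    """

    order: np.ndarray
    curves: pd.DataFrame
    weights: dict[str, float]
    window: int


def correlation_pvalue(r, n: int):
    """Two-sided p-value for a Pearson correlation via the t transform.

    ``t = r*sqrt(n-2)/sqrt(1-r^2)`` referred to Student's t with ``n-2``
    degrees of freedom; ``|r| = 1`` maps to ``p = 0`` by convention.
    Accepts scalars or arrays; NaN correlations give NaN p-values.
    """
    if n < 3:
        raise ValueError("need n >= 3 neighborhoods for a correlation p-value")
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, np.nan)
    finite = np.isfinite(r)
    exact = finite & (np.abs(r) >= 1.0)
    out[exact] = 0.0
    ok = finite & ~exact
    t = r[ok] * np.sqrt(n - 2) / np.sqrt(1.0 - r[ok] ** 2)
    out[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return out if out.ndim else float(out)


def _pearson_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pearson matrix with NaN for zero-variance columns (incl. diagonal)."""
    r = counts.astype(float).corr(method="pearson")
    constant = counts.std(ddof=0) == 0
    r.loc[constant, :] = np.nan
    r.loc[:, constant] = np.nan
    return r


def correlate(
    nbhd: NeighborhoodSet,
    scope: str = "all",
    assignment: RegionAssignment | None = None,
    pooled: bool = False,
) -> CorrelationResult:
    """Pairwise Pearson correlation of phenotype counts over neighborhoods.

    ``scope="all"`` uses every neighborhood; any other value names a region
    (an integer index or a composite annotation label) and requires an
    ``assignment`` aligned with ``nbhd``.  By default correlations are
    computed per sample and the cohort matrix is their unweighted mean;
    ``pooled=True`` instead concatenates all samples' neighborhoods first.
    """
    counts = nbhd.counts.astype(float)
    samples = nbhd.sample_ids
    if scope != "all":
        if assignment is None:
            raise ValueError("region-scoped correlation requires an assignment")
        if len(assignment.region) != nbhd.n:
            raise ValueError("assignment length does not match the neighborhood set")
        in_scope = assignment.labels() == scope
        if scope.isdigit():
            in_scope |= assignment.region == int(scope)
        counts = counts.loc[in_scope]
        samples = samples[np.asarray(in_scope)]
    if len(counts) < 3:
        raise ValueError("need >= 3 neighborhoods in scope")

    r_per_sample: dict[str, pd.DataFrame] = {}
    p_per_sample: dict[str, pd.DataFrame] = {}
    if pooled:
        groups = {"__pooled__": counts}
    else:
        groups = {s: counts.loc[samples == s] for s in pd.unique(samples)}
    for sample, sub in groups.items():
        if len(sub) < 3:
            raise ValueError(f"sample {sample!r} has < 3 neighborhoods in scope")
        r = _pearson_matrix(sub)
        p = pd.DataFrame(
            correlation_pvalue(r.to_numpy(), n=len(sub)), index=r.index, columns=r.columns
        )
        r_per_sample[str(sample)] = r
        p_per_sample[str(sample)] = p

    stacked = np.stack([m.to_numpy() for m in r_per_sample.values()])
    with warnings.catch_warnings():
        # entries missing in every sample stay missing in the cohort mean
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
    first = next(iter(r_per_sample.values()))
    r_mean = pd.DataFrame(mean, index=first.index, columns=first.columns)
    return CorrelationResult(
        r_per_sample=r_per_sample, p_per_sample=p_per_sample, r_mean=r_mean, scope=scope
    )


def pseudo_space(
    features: FeatureMatrix,
    weights: dict[str, float],
    window: int = 50,
) -> PseudoSpaceResult:
    """Sort neighborhoods onto a 1-D pseudo-space axis and smooth the curves.

    The sort key of a neighborhood is the weighted sum of its feature values
    (negative weight: that phenotype drives the neighborhood to the left;
    positive: to the right); the sort is ascending and stable, with the
    neighborhood index as the final tie-break.  Each feature's curve along
    the axis is a boxcar moving average (``window`` neighborhoods,
    edge-truncated) divided by its own maximum; all-zero curves stay zero.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    w = np.zeros(len(features.feature_names))
    known = set(features.feature_names)
    unknown = set(weights) - known
    if unknown:
        raise ValueError(f"weights for unknown features: {sorted(unknown)}")
    for i, name in enumerate(features.feature_names):
        w[i] = weights.get(name, 0.0)
    if not np.any(w):
        raise ValueError("at least one weight must be nonzero")

    key = features.values @ w
    order = np.argsort(key, kind="stable")
    sorted_values = features.values[order]
    smoothed = (
        pd.DataFrame(sorted_values, columns=list(features.feature_names))
        .rolling(window=window, center=True, min_periods=1)
        .mean()
    )
    maxima = smoothed.max(axis=0)
    for col in smoothed.columns:
        if maxima[col] > 0:
            smoothed[col] = smoothed[col] / maxima[col]
    smoothed.index.name = "rank"
    return PseudoSpaceResult(order=order, curves=smoothed, weights=dict(weights), window=int(window))
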