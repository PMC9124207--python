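"""Self-organizing map on a circular district canvas.

The map is a two-dimensional layout of districts arranged in concentric
rings. Batch Kohonen training alternates best-matching-district assignment
with neighborhood-kernel-weighted prototype updates; the Gaussian kernel
width shrinks linearly from radius/2 down to the ``smoothness`` floor, so a
larger smoothness yields a smoother, more conservative fit. Distances
tolerate missing inputs by rescaling the observed squared deviations by
D/d_observed, which keeps sparse rows comparable to complete rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "MapTopology",
    "SomModel",
    "MapAssignment",
    "Coloring",
    "create_map_topology",
    "create_grid_topology",
    "train_som",
    "map_participants",
    "district_coloring",
    "qc_map",
]


@dataclass
class MapTopology:
    districts: np.ndarray       # ordered integer ids
    coords: np.ndarray          # (n_districts, 2) positions
    neighbor_dist: np.ndarray   # Euclidean distances between positions

    @property
    def n_districts(self) -> int:
        return len(self.districts)


@dataclass
class SomModel:
    topology: MapTopology
    prototypes: np.ndarray      # (districts, inputs), column order = training matrix
    columns: list[str]
    smoothness: float
    epochs: int
    seed: int
    training_log: list[float] = field(default_factory=list)  # per-epoch quantization error
    radius: int | None = None


@dataclass
class MapAssignment:
    district_of: pd.Series      # participant id -> district id
    residual: pd.Series         # missing-adjusted distance to own prototype (SD units)
    coverage: pd.Series         # fraction of non-missing inputs
    excluded: list = field(default_factory=list)  # ids with zero observed inputs


@dataclass
class Coloring:
    variable: str
    district_value: np.ndarray  # smoothed mean per district
    amplitude: float            # SD of district values (color-intensity scale)


def create_map_topology(radius: int) -> MapTopology:
    """Concentric-ring layout: ring 0 is one district at the origin, ring k
    holds 6k districts equally spaced on a circle of radius k; total
    1 + 3*radius*(radius-1) districts."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    pts = [(0.0, 0.0)]
    for k in range(1, radius):
        for j in range(6 * k):
            theta = 2.0 * np.pi * j / (6 * k)
            pts.append((k * np.cos(theta), k * np.sin(theta)))
    coords = np.array(pts)
    return MapTopology(
        districts=np.arange(len(pts)),
        coords=coords,
        neighbor_dist=cdist(coords, coords),
    )


def create_grid_topology(n_rows: int, n_cols: int) -> MapTopology:
    """Rectangular-grid alternative to the ring layout."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    coords = np.array([(float(c), float(r)) for r in range(n_rows) for c in range(n_cols)])
    return MapTopology(
        districts=np.arange(n_rows * n_cols),
        coords=coords,
        neighbor_dist=cdist(coords, coords),
    )


def _as_matrix(Z) -> tuple[np.ndarray, list[str], pd.Index]:
    if hasattr(Z, "Z"):  # TrainingMatrix
        df = Z.Z
    elif isinstance(Z, pd.DataFrame):
        df = Z
    else:
        arr = np.asarray(Z, dtype=float)
        return arr, [f"x{i}" for i in range(arr.shape[1])], pd.RangeIndex(arr.shape[0])
    return df.to_numpy(dtype=float), list(df.columns), df.index


def _scaled_sq_distances(Z0: np.ndarray, M: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Missing-adjusted squared distances (D/d_obs)*sum_obs (z - p)^2 between
    every row (NaN encoded as 0 in Z0, mask M) and every prototype."""
    d_obs = M.sum(axis=1).astype(float)
    sq = (Z0**2).sum(axis=1)[:, None] - 2.0 * Z0 @ P.T + M.astype(float) @ (P**2).T
    np.maximum(sq, 0.0, out=sq)
    D = Z0.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return sq * (D / d_obs)[:, None]


def train_som(
    Z,
    topology: MapTopology,
    smoothness: float = 2.0,
    epochs: int = 50,
    seed: int = 0,
    radius: int | None = None,
) -> SomModel:
    """Batch Kohonen training.

    Each epoch assigns every row to its best-matching district and then
    replaces each prototype with the Gaussian-neighborhood-weighted mean of
    the rows (per input, over observed entries). Prototypes are initialized
    from a seeded sample of distinct data rows. Identical seed and inputs
    give identical models.
    """
    X, columns, _ = _as_matrix(Z)
    if X.size == 0:
        raise ValueError("empty training matrix")
    if np.isinf(X).any():
        r, c = np.argwhere(np.isinf(X))[0]
        raise ValueError(f"non-finite input at row {r}, column {columns[c]}")
    M = ~np.isnan(X)
    if not M.any(axis=1).any():
        raise ValueError("no row has any observed input")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    P_n = topology.n_districts
    n = X.shape[0]
    Z0 = np.where(M, X, 0.0)
    if n >= P_n:
        init_idx = rng.choice(n, size=P_n, replace=False)
    else:
        init_idx = rng.choice(n, size=P_n, replace=True)
    prototypes = Z0[init_idx].copy()
    if n < P_n:  # break exact duplicates so districts can differentiate
        prototypes += rng.normal(0, 1e-6, prototypes.shape)

    if radius is None:
        radius = int(np.ceil(topology.neighbor_dist.max() / 2.0)) + 1
    sigma_start = max(radius / 2.0, smoothness)
    log: list[float] = []
    for e in range(epochs):
        sq = _scaled_sq_distances(Z0, M, prototypes)
        bmu = np.argmin(sq, axis=1)
        log.append(float(np.sqrt(np.take_along_axis(sq, bmu[:, None], 1)).mean()))
        frac = e / (epochs - 1) if epochs > 1 else 1.0
        sigma = max(smoothness, sigma_start + (smoothness - sigma_start) * frac)
        K = np.exp(-(topology.neighbor_dist**2) / (2.0 * sigma**2))
        W = K[:, bmu]                      # (districts, rows)
        num = W @ Z0                       # (districts, inputs)
        den = W @ M.astype(float)
        updated = den > 0
        prototypes = np.where(updated, num / np.where(updated, den, 1.0), prototypes)
    return SomModel(
        topology=topology,
        prototypes=prototypes,
        columns=columns,
        smoothness=smoothness,
        epochs=epochs,
        seed=seed,
        training_log=log,
        radius=radius,
    )


def map_participants(model: SomModel, Z) -> MapAssignment:
    """Assign rows to best-matching districts.

    The distance is sqrt((D/d_obs) * sum_observed (z - prototype)^2); ties
    break to the lowest district id. Rows with zero observed inputs are
    excluded and reported in ``excluded``.
    """
    X, columns, index = _as_matrix(Z)
    if columns != model.columns:
        raise ValueError("column order does not match the trained model")
    M = ~np.isnan(X)
    ok = M.any(axis=1)
    excluded = list(index[~ok])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} row(s) with no observed inputs")
    Xv, Mv = X[ok], M[ok]
    Z0 = np.where(Mv, Xv, 0.0)
    sq = _scaled_sq_distances(Z0, Mv, model.prototypes)
    bmu = np.argmin(sq, axis=1)  # argmin -> first (lowest district id) on ties
    resid = np.sqrt(np.take_along_axis(sq, bmu[:, None], 1).ravel())
    cov = Mv.sum(axis=1) / Xv.shape[1]
    idx = index[ok]
    return MapAssignment(
        district_of=pd.Series(model.topology.districts[bmu], index=idx, name="district"),
        residual=pd.Series(resid, index=idx, name="residual"),
        coverage=pd.Series(cov, index=idx, name="coverage"),
        excluded=excluded,
    )


def district_coloring(
    assignment: MapAssignment,
    values: pd.Series,
    topology: MapTopology,
    smoothness: float,
    name: str | None = None,
) -> Coloring:
    """Smoothed district mean of a per-participant value.

    District value = Gaussian-kernel-weighted mean over participants with
    weight exp(-dist(district, BMU_i)^2 / (2*smoothness^2)); smoothness -> 0
    degenerates to the raw within-district mean. The amplitude is the SD of
    the district values across the map.
    """
    common = assignment.district_of.index.intersection(values.dropna().index)
    if len(common) == 0:
        raise ValueError("no assigned participant has an observed value")
    v = values.loc[common].to_numpy(dtype=float)
    d_of = assignment.district_of.loc[common].to_numpy()
    pos = np.searchsorted(topology.districts, d_of)
    n_d = topology.n_districts
    counts = np.bincount(pos, minlength=n_d).astype(float)
    sums = np.bincount(pos, weights=v, minlength=n_d)
    if smoothness <= 0:
        with np.errstate(invalid="ignore"):
            dv = sums / counts
    else:
        K = np.exp(-(topology.neighbor_dist**2) / (2.0 * smoothness**2))
        wnum = K @ sums
        wden = K @ counts
        with np.errstate(invalid="ignore"):
            dv = wnum / wden
    finite = np.isfinite(dv)
    amp = float(np.std(dv[finite])) if finite.any() else float("nan")
    return Coloring(
        variable=name or (values.name or "value"), district_value=dv, amplitude=amp
    )


def qc_map(model: SomModel, assignment: MapAssignment) -> pd.DataFrame:
    """Per-district quality control: sample density (counts summing to the
    number of assigned participants), mean residual in SD units (flagged
    above 3), mean data coverage, and an empty-district flag."""
    if len(assignment.district_of) == 0:
        raise ValueError("empty assignment")
    n_d = model.topology.n_districts
    pos = np.searchsorted(model.topology.districts, assignment.district_of.to_numpy())
    counts = np.bincount(pos, minlength=n_d).astype(int)
    with np.errstate(invalid="ignore"):
        mean_resid = np.bincount(pos, weights=assignment.residual.to_numpy(), minlength=n_d) / counts
        mean_cov = np.bincount(pos, weights=assignment.coverage.to_numpy(), minlength=n_d) / counts
    return pd.DataFrame(
        {
            "district": model.topology.districts,
            "count": counts,
            "mean_residual": mean_resid,
            "mean_coverage": mean_cov,
            "empty": counts == 0,
            "high_residual": np.nan_to_num(mean_resid) > 3.0,
        }
    )
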