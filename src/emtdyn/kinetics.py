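"""Grid-based Markov estimation of E<->M state-transition probabilities.

The estimator mirrors how transition rates are measured from live-cell
imaging when individual cells cannot be tracked reliably: the plate is
partitioned into square grids, per-grid class proportions of E and M
cells are compared between consecutive frames, and the per-interval 2x2
row-stochastic transition matrix P is recovered by constrained least
squares over grids,

    minimize sum_g || p_g(t) P - p_g(t+1) ||^2,   P row-stochastic,

where p_g = (fraction M, fraction E) in grid g.  With two states P has
two free entries a = P(M->E), b = P(E->M) and the problem is a bounded
linear least squares.  Estimates from every consecutive frame pair and
several grid sizes are aggregated into mean +- SD per ordered pair
(M-M, M-E, E-M, E-E).

Because the synthetic generator retains cell identity, a track-based
maximum-likelihood mode (count label flips along tracks) is also
provided as an oracle for validation; real imaging data generally does
not support it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .errors import ConfigError, UnderdeterminedError

PAIRS = ("M-M", "M-E", "E-M", "E-E")


def grid_partition(
    tracks: pd.DataFrame,
    grid_size: float,
    plate: tuple[float, float] | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Count E and M cells per square grid cell per frame.

    Binning is half-open ([lo, hi) per axis) anchored at ``origin`` (the
    plate's lower corner), so a point exactly on an interior boundary
    belongs to the higher-index cell; a point on the far plate edge is
    kept in the last cell; a grid size larger than the plate yields a
    single cell.  Translating positions and origin together leaves the
    partition unchanged.  Only live observations are counted.
    """
    if grid_size <= 0:
        raise ConfigError("grid size must be positive")
    if plate is None:
        plate = tracks.attrs.get("plate", (1000.0, 1000.0))
    live = tracks[tracks["alive"]]
    col = np.minimum(
        np.floor((live["x"].to_numpy() - origin[0]) / grid_size).astype(int),
        max(int(np.ceil(plate[0] / grid_size)) - 1, 0),
    )
    row = np.minimum(
        np.floor((live["y"].to_numpy() - origin[1]) / grid_size).astype(int),
        max(int(np.ceil(plate[1] / grid_size)) - 1, 0),
    )
    df = pd.DataFrame(
        {
            "frame": live["frame"].to_numpy(),
            "row": row,
            "col": col,
            "is_m": (live["label"] == "M").to_numpy().astype(int),
        }
    )
    counts = (
        df.groupby(["frame", "row", "col"])
        .agg(n_m=("is_m", "sum"), n=("is_m", "size"))
        .reset_index()
    )
    counts["n_e"] = counts["n"] - counts["n_m"]
    counts["grid_size"] = grid_size
    return counts[["frame", "row", "col", "grid_size", "n_m", "n_e"]]


def estimate_transition_matrix(
    counts: pd.DataFrame,
    frame_from: int,
    frame_to: int,
    n_min: int = 5,
) -> tuple[np.ndarray, int]:
    """One per-interval transition-matrix estimate from grid proportions.

    Uses every grid cell populated with at least ``n_min`` cells at both
    frames.  Returns (P, number of grids used) with P the constrained
    least-squares row-stochastic matrix in (M, E) order.  Raises
    :class:`UnderdeterminedError` when fewer than two usable grids exist
    or the design is rank-deficient (e.g. every grid is pure
    single-class at the earlier frame, which leaves one of the two
    transition probabilities unidentified).
    """
    a = counts[counts["frame"] == frame_from].set_index(["row", "col"])
    b = counts[counts["frame"] == frame_to].set_index(["row", "col"])
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    usable = (a["n_m"] + a["n_e"] >= n_min) & (b["n_m"] + b["n_e"] >= n_min)
    a, b = a[usable], b[usable]
    if len(a) < 2:
        raise UnderdeterminedError(
            f"only {len(a)} usable grids between frames {frame_from} and {frame_to}"
        )
    m0 = (a["n_m"] / (a["n_m"] + a["n_e"])).to_numpy()
    m1 = (b["n_m"] / (b["n_m"] + b["n_e"])).to_numpy()
    e0 = 1.0 - m0
    # residual per grid: m0*(1-a) + e0*b - m1, linear in (a, b); grids are
    # weighted by sqrt(occupancy) since the binomial noise variance of a
    # proportion scales as 1/n
    w = np.sqrt((b["n_m"] + b["n_e"]).to_numpy(dtype=float))
    design = np.column_stack([-m0, e0])
    rhs = m1 - m0
    if np.linalg.matrix_rank(design, tol=1e-8) < 2:
        raise UnderdeterminedError(
            "grid proportions do not identify both transition probabilities "
            f"between frames {frame_from} and {frame_to} (rank-deficient design)"
        )
    sol = lsq_linear(design * w[:, None], rhs * w, bounds=(0.0, 1.0))
    p_me, p_em = sol.x
    P = np.array([[1.0 - p_me, p_me], [p_em, 1.0 - p_em]])
    return P, int(len(a))


def estimate_transition_matrix_unconstrained(
    counts: pd.DataFrame,
    frame_from: int,
    frame_to: int,
    n_min: int = 5,
) -> tuple[np.ndarray, int]:
    """Per-pair regression without the row-sum constraint.

    Regresses each class's proportion at t+1 on both proportions at t
    independently, so rows of the returned matrix need not sum to one.
    Provided for comparison with rate tables reported without the
    simplex constraint; the constrained estimator is the default.
    """
    a = counts[counts["frame"] == frame_from].set_index(["row", "col"])
    b = counts[counts["frame"] == frame_to].set_index(["row", "col"])
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    usable = (a["n_m"] + a["n_e"] >= n_min) & (b["n_m"] + b["n_e"] >= n_min)
    a, b = a[usable], b[usable]
    if len(a) < 2:
        raise UnderdeterminedError(
            f"only {len(a)} usable grids between frames {frame_from} and {frame_to}"
        )
    m0 = (a["n_m"] / (a["n_m"] + a["n_e"])).to_numpy()
    e0 = 1.0 - m0
    design = np.column_stack([m0, e0])
    if np.linalg.matrix_rank(design, tol=1e-8) < 2:
        raise UnderdeterminedError("rank-deficient design")
    m1 = (b["n_m"] / (b["n_m"] + b["n_e"])).to_numpy()
    e1 = 1.0 - m1
    col_m, *_ = np.linalg.lstsq(design, m1, rcond=None)
    col_e, *_ = np.linalg.lstsq(design, e1, rcond=None)
    P = np.array([[col_m[0], col_e[0]], [col_m[1], col_e[1]]])
    return P, int(len(a))


def estimate_transitions_pooled(
    tracks: pd.DataFrame,
    grid_sizes: tuple[float, ...] | None = None,
    n_min: int = 5,
    plate: tuple[float, float] | None = None,
) -> np.ndarray:
    """One constrained estimate pooling all intervals and grid sizes.

    Stacks the per-grid regression rows of every consecutive frame pair
    (and every grid size) into a single bounded least-squares problem.
    Unlike the per-interval estimator — in which all grids of one
    interval share the same expected composition, so both transition
    probabilities are identified only through finite-population
    fluctuations — the pooled design mixes intervals at different
    compositions and is therefore consistent as the cell count grows.
    Returns the row-stochastic 2x2 matrix in (M, E) order.
    """
    if plate is None:
        plate = tracks.attrs.get("plate", (1000.0, 1000.0))
    if grid_sizes is None:
        grid_sizes = (plate[0] / 8, plate[0] / 4, plate[0] / 2)
    designs, rhss = [], []
    frames = np.sort(tracks["frame"].unique())
    for gs in grid_sizes:
        counts = grid_partition(tracks, gs, plate)
        for f0, f1 in zip(frames[:-1], frames[1:]):
            a = counts[counts["frame"] == f0].set_index(["row", "col"])
            b = counts[counts["frame"] == f1].set_index(["row", "col"])
            shared = a.index.intersection(b.index)
            a, b = a.loc[shared], b.loc[shared]
            ok = (a["n_m"] + a["n_e"] >= n_min) & (b["n_m"] + b["n_e"] >= n_min)
            a, b = a[ok], b[ok]
            if len(a) == 0:
                continue
            m0 = (a["n_m"] / (a["n_m"] + a["n_e"])).to_numpy()
            m1 = (b["n_m"] / (b["n_m"] + b["n_e"])).to_numpy()
            w = np.sqrt((b["n_m"] + b["n_e"]).to_numpy(dtype=float))
            designs.append(np.column_stack([-m0, 1.0 - m0]) * w[:, None])
            rhss.append((m1 - m0) * w)
    if not designs:
        raise UnderdeterminedError("no usable grids in any interval")
    design = np.vstack(designs)
    rhs = np.concatenate(rhss)
    if np.linalg.matrix_rank(design, tol=1e-8) < 2:
        raise UnderdeterminedError("pooled design is rank-deficient")
    p_me, p_em = lsq_linear(design, rhs, bounds=(0.0, 1.0)).x
    return np.array([[1.0 - p_me, p_me], [p_em, 1.0 - p_em]])


def estimate_transitions_tracked(tracks: pd.DataFrame) -> np.ndarray:
    """Track-based maximum-likelihood estimate (oracle mode).

    Counts label flips between consecutive observations of the same
    cell; division and death intervals contribute the surviving
    observations only.  Needs cell identity, so it applies to synthetic
    or fully tracked data.
    """
    live = tracks[tracks["alive"]].sort_values(["cell_id", "frame"])
    same_cell = live["cell_id"].to_numpy()[1:] == live["cell_id"].to_numpy()[:-1]
    consecutive = np.diff(live["frame"].to_numpy()) == 1
    ok = same_cell & consecutive
    s0 = (live["label"].to_numpy()[:-1] == "E").astype(int)[ok]
    s1 = (live["label"].to_numpy()[1:] == "E").astype(int)[ok]
    C = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            C[i, j] = np.sum((s0 == i) & (s1 == j))
    rows = C.sum(axis=1, keepdims=True)
    if np.any(rows == 0):
        raise UnderdeterminedError("a state is never observed at interval starts")
    return C / rows


@dataclass
class TransitionRateEstimate:
    """Aggregated per-interval transition probabilities.

    ``table`` holds mean, population SD and count per ordered pair,
    stratified by grid size plus an "all" stratum pooling every
    per-interval estimate.
    """

    table: pd.DataFrame
    estimates: pd.DataFrame  # one row per (grid_size, frame interval)

    def mean(self, pair: str, grid_size: str | float = "all") -> float:
        sel = self.table[
            (self.table["pair"] == pair)
            & (self.table["grid_size"].astype(str) == str(grid_size))
        ]
        return float(sel["mean"].iloc[0])


def aggregate_rates(estimates: pd.DataFrame) -> TransitionRateEstimate:
    """Mean +- SD per ordered pair, overall and per grid size.

    ``estimates`` needs columns grid_size and the four pair columns.
    When an ``n_grids`` column is present each per-interval estimate is
    weighted by the number of grids that informed it (coarse partitions
    contribute few, weakly identified estimates); otherwise estimates
    are weighted equally.  The SD is the sample (n-1 denominator)
    dispersion of the per-interval estimates, generalized to weights by
    the n/(n-1) correction on the weighted variance; it is 0 for a
    single estimate.
    """
    if estimates.empty:
        raise ConfigError("no per-interval estimates to aggregate")
    rows = []
    strata = [("all", estimates)] + [
        (gs, df) for gs, df in estimates.groupby("grid_size")
    ]
    for name, df in strata:
        w = (
            df["n_grids"].to_numpy(dtype=float)
            if "n_grids" in df.columns
            else np.ones(len(df))
        )
        for pair in PAIRS:
            vals = df[pair].to_numpy(dtype=float)
            mean = float(np.average(vals, weights=w))
            n_est = len(vals)
            var = np.average((vals - mean) ** 2, weights=w)
            sd = float(np.sqrt(var * n_est / (n_est - 1))) if n_est > 1 else 0.0
            rows.append(
                {
                    "grid_size": name,
                    "pair": pair,
                    "mean": mean,
                    "sd": sd,
                    "n": int(len(vals)),
                }
            )
    return TransitionRateEstimate(table=pd.DataFrame(rows), estimates=estimates)


def estimate_rates(
    tracks: pd.DataFrame,
    grid_sizes: tuple[float, ...] | None = None,
    n_min: int = 5,
    mode: str = "constrained",
    plate: tuple[float, float] | None = None,
) -> TransitionRateEstimate:
    """Full pipeline: partition, per-interval estimation, aggregation.

    ``grid_sizes`` defaults to 1/8, 1/4 and 1/2 of the plate side.
    Intervals whose grid design is underdetermined (for instance the
    first interval of a single-class seeding) are skipped; at least one
    interval must be estimable.
    """
    if plate is None:
        plate = tracks.attrs.get("plate", (1000.0, 1000.0))
    if grid_sizes is None:
        grid_sizes = (plate[0] / 8, plate[0] / 4, plate[0] / 2)
    if mode not in ("constrained", "unconstrained"):
        raise ConfigError(f"unknown estimation mode {mode!r}")
    est_fn = (
        estimate_transition_matrix
        if mode == "constrained"
        else estimate_transition_matrix_unconstrained
    )
    frames = np.sort(tracks["frame"].unique())
    rows = []
    for gs in grid_sizes:
        counts = grid_partition(tracks, gs, plate)
        for f0, f1 in zip(frames[:-1], frames[1:]):
            try:
                P, n_grids = est_fn(counts, f0, f1, n_min)
            except UnderdeterminedError:
                continue
            rows.append(
                {
                    "grid_size": gs,
                    "frame_from": int(f0),
                    "frame_to": int(f1),
                    "n_grids": n_grids,
                    "M-M": P[0, 0],
                    "M-E": P[0, 1],
                    "E-M": P[1, 0],
                    "E-E": P[1, 1],
                }
            )
    if not rows:
        raise UnderdeterminedError("no frame interval yielded an identifiable estimate")
    return aggregate_rates(pd.DataFrame(rows))
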