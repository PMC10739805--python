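"""Synthetic live-imaging data: cell tracks, morphology, scratch wounds.

An agent-based generator standing in for time-lapse microscopy of cancer
cell colonies.  Cells live on a rectangular plate, are imaged on a fixed
frame grid (default every 2 h), and carry one of two phenotype labels —
E (epithelial-like) or M (mesenchymal-like).  Per imaging interval each
cell may die, divide (daughters inherit the mother's label), switch
label according to a 2x2 per-interval Markov matrix, and take a random
motility step.  Class-conditional morphology features and a scratch-
wound scenario (cells migrating into a denuded band) are layered on top.

All outputs are synthetic; distributions are chosen to be qualitatively
realistic (M cells small/compact, E cells large/flat/irregular), not to
match any particular instrument's units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

LABELS = ("M", "E")  # state 0 = M, state 1 = E

DEFAULT_PLATE = (1000.0, 1000.0)
DEFAULT_FRAME_HOURS = 2.0


@dataclass
class SwitchModel:
    """Per-interval stochastic rules for one imaging interval.

    ``p_me`` / ``p_em`` are the M->E and E->M switch probabilities per
    interval; the implied transition matrix has rows (M, E).  Division
    and death probabilities and the motility step scale (plate units per
    interval, isotropic Gaussian) are class-specific.
    """

    p_me: float = 0.05
    p_em: float = 0.05
    division_m: float = 0.0
    division_e: float = 0.0
    death_m: float = 0.0
    death_e: float = 0.0
    # ~2 plate units per 2-h interval: cells covering 20-40 um in 2 h on a
    # well whose 15 mm width maps to 1000 units
    step_m: float = 2.0
    step_e: float = 2.0

    def __post_init__(self) -> None:
        for name in ("p_me", "p_em", "division_m", "division_e", "death_m", "death_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.step_m < 0 or self.step_e < 0:
            raise ConfigError("motility step scales must be non-negative")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic per-interval matrix [[M-M, M-E], [E-M, E-E]]."""
        return np.array(
            [[1.0 - self.p_me, self.p_me], [self.p_em, 1.0 - self.p_em]]
        )

    def per_class(self, attr: str) -> np.ndarray:
        return np.array([getattr(self, f"{attr}_m"), getattr(self, f"{attr}_e")])


TRACK_COLUMNS = [
    "cell_id", "parent_id", "frame", "time_h", "x", "y", "label", "alive",
]


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect positions into [lo, hi] (single bounce is enough here)."""
    pos = np.where(pos < lo, 2 * lo - pos, pos)
    pos = np.where(pos > hi, 2 * hi - pos, pos)
    return np.clip(pos, lo, hi)


def simulate_colony(
    n0: dict[str, int] | tuple[int, int],
    switch: SwitchModel,
    n_frames: int,
    plate: tuple[float, float] = DEFAULT_PLATE,
    frame_hours: float = DEFAULT_FRAME_HOURS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate phenotype-labelled cell tracks on a plate.

    ``n0`` gives initial cell counts per class (dict with keys "M"/"E"
    or an (n_M, n_E) pair); initial positions are uniform over the
    plate.  ``n_frames`` counts imaging intervals after frame 0.  Per
    interval and per live cell, in order: death, division (daughter
    inherits the label and appears next to the mother), label switching
    (applied to mothers and daughters alike), motility step reflected at
    the plate boundary.  Returns a tidy frame with one row per cell per
    frame while alive; the frame a cell dies it appears once more with
    ``alive=False`` and has no later rows.
    """
    if isinstance(n0, dict):
        n_m, n_e = int(n0.get("M", 0)), int(n0.get("E", 0))
    else:
        n_m, n_e = int(n0[0]), int(n0[1])
    if n_m < 0 or n_e < 0 or n_m + n_e < 1:
        raise ConfigError("need at least one initial cell")
    if n_frames < 0:
        raise ConfigError("n_frames must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n = n_m + n_e
    ids = np.arange(1, n + 1)
    parents = np.zeros(n, dtype=np.int64)  # 0 = root
    state = np.concatenate([np.zeros(n_m, np.int64), np.ones(n_e, np.int64)])
    x = rng.uniform(0, plate[0], n)
    y = rng.uniform(0, plate[1], n)
    next_id = n + 1

    death = switch.per_class("death")
    division = switch.per_class("division")
    step = switch.per_class("step")
    p_switch = np.array([switch.p_me, switch.p_em])

    chunks: list[pd.DataFrame] = []

    def record(frame: int, ids_, parents_, state_, x_, y_, alive_) -> None:
        chunks.append(
            pd.DataFrame(
                {
                    "cell_id": ids_,
                    "parent_id": parents_,
                    "frame": frame,
                    "time_h": frame * frame_hours,
                    "x": x_,
                    "y": y_,
                    "label": np.array(LABELS)[state_],
                    "alive": alive_,
                }
            )
        )

    record(0, ids, parents, state, x, y, np.ones(n, bool))
    for frame in range(1, n_frames + 1):
        if ids.size == 0:
            break
        dies = rng.random(ids.size) < death[state]
        if dies.any():
            record(frame, ids[dies], parents[dies], state[dies],
                   x[dies], y[dies], np.zeros(int(dies.sum()), bool))
        keep = ~dies
        ids, parents, state, x, y = ids[keep], parents[keep], state[keep], x[keep], y[keep]

        divides = rng.random(ids.size) < division[state]
        nd = int(divides.sum())
        if nd:
            d_ids = np.arange(next_id, next_id + nd)
            next_id += nd
            jitter = rng.normal(0, 2.0, (nd, 2))
            mothers, m_state = ids[divides], state[divides]
            mx, my = x[divides], y[divides]
            ids = np.concatenate([ids, d_ids])
            parents = np.concatenate([parents, mothers])
            state = np.concatenate([state, m_state])
            x = np.concatenate([x, mx + jitter[:, 0]])
            y = np.concatenate([y, my + jitter[:, 1]])

        flips = rng.random(ids.size) < p_switch[state]
        state = np.where(flips, 1 - state, state)

        x = _reflect(x + rng.normal(0, 1, ids.size) * step[state], 0, plate[0])
        y = _reflect(y + rng.normal(0, 1, ids.size) * step[state], 0, plate[1])
        record(frame, ids, parents, state, x, y, np.ones(ids.size, bool))

    tracks = pd.concat(chunks, ignore_index=True)
    tracks.attrs["plate"] = plate
    tracks.attrs["frame_hours"] = frame_hours
    return tracks


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

FEATURES = [
    "radius", "area", "perimeter", "solidity", "formfactor",
    "eccentricity", "compactness",
]

# latent (pre-transform) base mean, SD, and the sign of the E-minus-M gap:
# E cells are larger (radius/area/perimeter), more eccentric; M cells are
# more solid, rounder (formfactor) and more compact.
_FEATURE_LATENTS = {
    "radius": (2.5, 0.20, +1, "exp"),
    "area": (5.0, 0.40, +1, "exp"),
    "perimeter": (4.4, 0.25, +1, "exp"),
    "solidity": (1.2, 0.60, -1, "logistic"),
    "formfactor": (0.8, 0.60, -1, "logistic"),
    "eccentricity": (0.0, 0.80, +1, "logistic"),
    "compactness": (0.2, 0.30, -1, "exp"),
}


def attach_morphology(
    tracks: pd.DataFrame,
    separation: float = 3.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw class-conditional shape features for every live observation.

    Each feature arises from a Gaussian latent (independent across
    features) pushed through a monotone link: exp for sizes, logistic
    for the [0, 1]-bounded descriptors.  The two class means differ by
    ``separation`` latent standard deviations along every feature (with
    class-appropriate signs), so ``separation=0`` makes E and M
    identically distributed and larger values make the classes linearly
    separable.  The true label is retained for evaluation.
    """
    if separation < 0:
        raise ConfigError("separation must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    obs = tracks[tracks["alive"]].reset_index(drop=True)
    s = (obs["label"] == "E").to_numpy().astype(float)  # 0 = M, 1 = E
    out = obs[["cell_id", "frame", "time_h", "label"]].copy()
    for name, (mu, sd, gap_sign, link) in _FEATURE_LATENTS.items():
        shift = gap_sign * separation * sd * (s - 0.5)
        z = rng.normal(mu, sd, len(obs)) + shift
        out[name] = np.exp(z) if link == "exp" else 1.0 / (1.0 + np.exp(-z))
    return out


# ---------------------------------------------------------------------------
# scratch wound
# ---------------------------------------------------------------------------

@dataclass
class WoundAssayResult:
    """Per-frame wound occupancy and in-wound cell counts."""

    series: pd.DataFrame  # frame, time_h, occupancy_pct, n_m_in_wound, n_e_in_wound
    band: tuple[float, float]
    footprint_radius: float


def _band_occupancy(
    x: np.ndarray, y: np.ndarray, band: tuple[float, float],
    plate: tuple[float, float], r: float, pixel: float,
) -> float:
    """Fraction (%) of band area within radius r of an in-band cell centre.

    Only cells that have migrated into the band contribute footprints, so
    an intact monolayer hugging the scratch edge leaves occupancy at 0.
    """
    nx = max(1, int(np.ceil((band[1] - band[0]) / pixel)))
    ny = max(1, int(np.ceil(plate[1] / pixel)))
    covered = np.zeros((nx, ny), bool)
    inside = (x >= band[0]) & (x <= band[1])
    px = (np.arange(nx) + 0.5) * pixel + band[0]
    py = (np.arange(ny) + 0.5) * pixel
    for cx, cy in zip(x[inside], y[inside]):
        dx2 = (px - cx) ** 2
        dy2 = (py - cy) ** 2
        covered |= dx2[:, None] + dy2[None, :] <= r * r
    return 100.0 * covered.mean()


def simulate_wound(
    tracks: pd.DataFrame,
    band: tuple[float, float],
    n_frames: int,
    rng: np.random.Generator | int | None = None,
    bias_m: float = 6.0,
    bias_e: float = 3.0,
    step_m: float = 4.0,
    step_e: float = 4.0,
    footprint_radius: float = 10.0,
    plate: tuple[float, float] = DEFAULT_PLATE,
    frame_hours: float = DEFAULT_FRAME_HOURS,
    pixel: float = 4.0,
) -> WoundAssayResult:
    """Scratch-wound assay on an existing monolayer.

    The last frame of ``tracks`` is taken as the confluent monolayer;
    cells inside the vertical ``band`` are removed at t = 0 (the
    scratch).  Remaining cells then migrate with a class-specific drift
    (``bias_m`` / ``bias_e`` plate units per interval toward the band
    centre, zero once inside) plus Gaussian noise; no division, death or
    switching.  Per frame the result reports the percentage of the band
    area within ``footprint_radius`` of a cell centre (the occupied
    denuded area) and the per-class counts of cells inside the band.
    """
    if not (0 <= band[0] < band[1] <= plate[0]):
        raise ConfigError(f"band {band} not inside plate x-range (0, {plate[0]})")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    last = tracks[tracks["alive"] & (tracks["frame"] == tracks["frame"].max())]
    if last.empty:
        raise ConfigError("empty monolayer: no live cells in the final frame")
    x = last["x"].to_numpy(copy=True)
    y = last["y"].to_numpy(copy=True)
    state = (last["label"] == "E").to_numpy().astype(int)
    outside = (x < band[0]) | (x > band[1])
    x, y, state = x[outside], y[outside], state[outside]
    if x.size == 0:
        raise ConfigError("scratch removed every cell; no monolayer left")

    bias = np.array([bias_m, bias_e])
    step = np.array([step_m, step_e])
    centre = 0.5 * (band[0] + band[1])
    rows = []

    def snapshot(frame: int) -> None:
        occ = _band_occupancy(x, y, band, plate, footprint_radius, pixel)
        inside = (x >= band[0]) & (x <= band[1])
        rows.append(
            {
                "frame": frame,
                "time_h": frame * frame_hours,
                "occupancy_pct": occ,
                "n_m_in_wound": int(((state == 0) & inside).sum()),
                "n_e_in_wound": int(((state == 1) & inside).sum()),
            }
        )

    snapshot(0)
    for frame in range(1, n_frames + 1):
        inside = (x >= band[0]) & (x <= band[1])
        drift = np.sign(centre - x) * bias[state] * (~inside)
        x = _reflect(x + drift + rng.normal(0, 1, x.size) * step[state], 0, plate[0])
        y = _reflect(y + rng.normal(0, 1, y.size) * step[state], 0, plate[1])
        snapshot(frame)

    return WoundAssayResult(
        series=pd.DataFrame(rows), band=band, footprint_radius=footprint_radius
    )
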