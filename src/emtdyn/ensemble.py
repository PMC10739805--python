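"""Random-parameter ensemble simulation of a gene circuit.

The circuit topology is evaluated under thousands of kinetic models whose
parameters are drawn from biologically plausible ranges (production 1-100,
degradation 0.1-1, fold change 1-100, integer Hill coefficients 1-6,
thresholds by the half-functional rule).  Each model is integrated by
Euler's method from many random initial conditions; converged endpoints
are deduplicated into the model's stable steady states.  Pooled states
are z-scored per node on the log2 scale, classified into the four
PPARG/SMAD3 quadrants (E, M, double-negative, double-positive), and the
same machinery supports in-silico over/under-expression by scaling a
node's production rate and re-classifying in the control z-coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numba import njit

from .circuit import GeneCircuit, KineticParameters
from .errors import (
    ConfigError,
    DegenerateEnsembleError,
    EmptyEnsembleError,
    InvalidParameterError,
)

STATE_CLASSES = ("E", "M", "DN", "DP")


@dataclass
class EnsembleConfig:
    """Sampling ranges, integrator settings and bookkeeping for one run.

    ``n_models`` defaults to the full-scale ensemble size; reduced
    ensembles (>= 2000 models) give fractions within sampling error of
    the full run and are used throughout the test-bench.
    """

    n_models: int = 50_000
    n_initial_conditions: int = 100
    g_min: float = 1.0
    g_max: float = 100.0
    k_min: float = 0.1
    k_max: float = 1.0
    fold_min: float = 1.0
    fold_max: float = 100.0
    hill_min: int = 1
    hill_max: int = 6
    # threshold range as multiples of the source node's median unregulated level
    b0_rel_min: float = 0.02
    b0_rel_max: float = 1.98
    dt: float = 0.05
    t_max: float = 200.0
    eps_conv: float = 1e-6
    eps_dedup: float = 0.01
    max_states_per_model: int = 10
    log_offset: float = 1e-9
    seed: int = 0

    def validate(self) -> None:
        pairs = [
            ("g", self.g_min, self.g_max),
            ("k", self.k_min, self.k_max),
            ("fold", self.fold_min, self.fold_max),
            ("hill", self.hill_min, self.hill_max),
            ("b0_rel", self.b0_rel_min, self.b0_rel_max),
        ]
        for name, lo, hi in pairs:
            if lo > hi:
                raise ConfigError(f"degenerate {name} range: min {lo} > max {hi}")
        if self.g_min <= 0 or self.k_min <= 0 or self.fold_min < 1:
            raise ConfigError("g, k must be positive and fold_min >= 1")
        if self.n_models < 1 or self.n_initial_conditions < 1:
            raise ConfigError("n_models and n_initial_conditions must be >= 1")
        if self.dt <= 0 or self.t_max <= 0:
            raise ConfigError("dt and t_max must be positive")
        if self.eps_conv <= 0 or self.eps_dedup <= 0:
            raise ConfigError("tolerances must be positive")
        if self.hill_min < 1:
            raise ConfigError("hill_min must be >= 1")

    @property
    def ic_low(self) -> float:
        """Lower bound of the log-uniform initial-condition range."""
        return 0.01

    @property
    def ic_high(self) -> float:
        """Upper bound: 100x the largest unregulated level g_max/k_min."""
        return 100.0 * self.g_max / self.k_min


_MEDIAN_SEED = 987_654_321  # internal seed: threshold medians must not vary with run seed


def median_unregulated_level(
    config: EnsembleConfig, n_draws: int = 200_000
) -> float:
    """Median of g/k under the sampling ranges (Monte Carlo, fixed seed).

    The baseline level scale entering the half-functional threshold rule.
    A dedicated internal seed keeps the constant independent of the run
    seed.
    """
    rng = np.random.default_rng(_MEDIAN_SEED)
    g = rng.uniform(config.g_min, config.g_max, n_draws)
    k = rng.uniform(config.k_min, config.k_max, n_draws)
    return float(np.median(g / k))


_node_median_cache: dict[tuple, tuple[float, np.ndarray]] = {}


def node_median_levels(
    circuit: GeneCircuit, config: EnsembleConfig, n_draws: int = 200_000
) -> tuple[float, np.ndarray]:
    """Per-node median levels for the half-functional threshold rule.

    Each node's level distribution is estimated by one Monte-Carlo step:
    the unregulated level g/k is multiplied by the shifted Hill term of
    every incoming link, with the regulator level drawn from its own
    unregulated distribution and the inner threshold centred on the
    unregulated median.  Thresholds of outgoing links are then sampled
    around these medians, which keeps each regulation dynamically
    relevant in a substantial part of the ensemble even for nodes whose
    levels are inflated (activator fold changes) or depressed
    (inhibitors) by their regulation.

    Returns ``(median_unregulated, medians_per_node)``; results are
    cached per (topology, ranges).
    """
    key = (
        tuple(circuit.nodes),
        tuple((e.source, e.target, e.sign) for e in circuit.edges),
        config.g_min, config.g_max, config.k_min, config.k_max,
        config.fold_min, config.fold_max, config.hill_min, config.hill_max,
        config.b0_rel_min, config.b0_rel_max, n_draws,
    )
    if key in _node_median_cache:
        return _node_median_cache[key]
    rng = np.random.default_rng(_MEDIAN_SEED)
    mu = median_unregulated_level(config, n_draws)
    src, tgt, sign = circuit.edge_arrays()
    med = np.empty(circuit.n_nodes)
    for i in range(circuit.n_nodes):
        lvl = rng.uniform(config.g_min, config.g_max, n_draws) / rng.uniform(
            config.k_min, config.k_max, n_draws
        )
        for e in range(circuit.n_edges):
            if tgt[e] != i:
                continue
            lam_raw = rng.uniform(config.fold_min, config.fold_max, n_draws)
            lam = lam_raw if sign[e] > 0 else 1.0 / lam_raw
            n = rng.integers(config.hill_min, config.hill_max + 1, n_draws)
            b0 = rng.uniform(config.b0_rel_min, config.b0_rel_max, n_draws) * mu
            b = rng.uniform(config.g_min, config.g_max, n_draws) / rng.uniform(
                config.k_min, config.k_max, n_draws
            )
            lvl = lvl * (lam + (1.0 - lam) / (1.0 + (b / b0) ** n))
        med[i] = np.median(lvl)
    _node_median_cache[key] = (mu, med)
    return mu, med


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def _sample_ensemble_parameters(
    circuit: GeneCircuit, config: EnsembleConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorized draw of kinetic parameters for all models at once."""
    config.validate()
    nm, nn, ne = config.n_models, circuit.n_nodes, circuit.n_edges
    src, _, sign = circuit.edge_arrays()
    _, med = node_median_levels(circuit, config)
    g = rng.uniform(config.g_min, config.g_max, (nm, nn))
    k = rng.uniform(config.k_min, config.k_max, (nm, nn))
    lam_raw = rng.uniform(config.fold_min, config.fold_max, (nm, ne))
    hill_n = rng.integers(config.hill_min, config.hill_max + 1, (nm, ne))
    b0 = rng.uniform(
        config.b0_rel_min * med[src], config.b0_rel_max * med[src], (nm, ne)
    )
    lam_eff = np.where(sign[None, :] > 0, lam_raw, 1.0 / lam_raw)
    return {
        "g": g,
        "k": k,
        "lam_raw": lam_raw,
        "lam_eff": lam_eff,
        "hill_n": hill_n,
        "b0": b0,
    }


def sample_parameters(
    circuit: GeneCircuit, config: EnsembleConfig, rng: np.random.Generator
) -> KineticParameters:
    """Draw one random kinetic model for the circuit."""
    one = replace(config, n_models=1)
    p = _sample_ensemble_parameters(circuit, one, rng)
    return KineticParameters(
        circuit=circuit,
        g=p["g"][0],
        k=p["k"][0],
        lam_raw=p["lam_raw"][0],
        hill_n=p["hill_n"][0].astype(float),
        b0=p["b0"][0],
    )


# ---------------------------------------------------------------------------
# Euler integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _euler_kernel(x, g, k, src, tgt, lam, nh, b0, h, n_steps, min_steps, eps):
    """Integrate each trajectory until the residual criterion or n_steps.

    x : (n_traj, n_nodes) initial conditions, overwritten with endpoints.
    Per-trajectory parameters: g, k (n_traj, n_nodes); lam, nh, b0
    (n_traj, n_edges).  Returns a boolean convergence flag per
    trajectory (residual inf-norm <= eps * max(1, level inf-norm)).
    """
    n_traj, n_nodes = x.shape
    n_edges = src.size
    conv = np.zeros(n_traj, np.bool_)
    mult = np.empty(n_nodes)
    dx = np.empty(n_nodes)
    for i in range(n_traj):
        xi = x[i]
        for s in range(n_steps):
            for j in range(n_nodes):
                mult[j] = 1.0
            for e in range(n_edges):
                r = xi[src[e]] / b0[i, e]
                p = 1.0
                for _ in range(nh[i, e]):
                    p *= r
                le = lam[i, e]
                mult[tgt[e]] *= le + (1.0 - le) / (1.0 + p)
            res = 0.0
            big = 1.0
            for j in range(n_nodes):
                dx[j] = g[i, j] * mult[j] - k[i, j] * xi[j]
                a = abs(dx[j])
                if a > res:
                    res = a
                if xi[j] > big:
                    big = xi[j]
            if res <= eps * big and s >= min_steps:
                conv[i] = True
                break
            for j in range(n_nodes):
                xi[j] += h * dx[j]
    return conv


def _integrate_models(
    circuit: GeneCircuit,
    config: EnsembleConfig,
    params: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Run all models x initial conditions; return endpoints and flags."""
    nm, nic, nn = config.n_models, config.n_initial_conditions, circuit.n_nodes
    src, tgt, _ = circuit.edge_arrays()
    n_traj = nm * nic
    lo, hi = np.log10(config.ic_low), np.log10(config.ic_high)
    x0 = 10.0 ** rng.uniform(lo, hi, (n_traj, nn))
    rep = np.repeat  # each model's parameters tiled across its ICs
    conv = _euler_kernel(
        x0,
        rep(params["g"], nic, axis=0),
        rep(params["k"], nic, axis=0),
        src,
        tgt,
        rep(params["lam_eff"], nic, axis=0),
        rep(params["hill_n"].astype(np.int64), nic, axis=0),
        rep(params["b0"], nic, axis=0),
        config.dt,
        int(round(config.t_max / config.dt)),
        min(400, int(round(config.t_max / config.dt))),
        config.eps_conv,
    )
    return x0, conv


def _dedup_states(
    endpoints: np.ndarray, eps: float, max_states: int
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy dedup at relative inf-norm tolerance; returns reps, counts."""
    reps: list[np.ndarray] = []
    counts: list[int] = []
    for x in endpoints:
        for idx, r in enumerate(reps):
            if np.max(np.abs(x - r)) <= eps * max(1.0, np.max(np.abs(r))):
                counts[idx] += 1
                break
        else:
            reps.append(x)
            counts.append(1)
    if len(reps) > max_states:
        order = np.argsort(-np.asarray(counts), kind="stable")[:max_states]
        order = np.sort(order)
        reps = [reps[i] for i in order]
        counts = [counts[i] for i in order]
    return np.asarray(reps), np.asarray(counts)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SteadyState:
    """One stable steady state of one kinetic model."""

    model_id: int
    levels: np.ndarray
    multiplicity: int


@dataclass
class SteadyStateEnsemble:
    """All stable steady states pooled across models.

    ``solutions`` has one row per distinct stable state with columns
    ``model_id``, ``multiplicity``, one level column per node and (after
    :func:`z_normalize`) one ``z_<node>`` column per node.  ``ref_mean``
    and ``ref_std`` are the per-node mean/SD of log2 levels used for the
    z-scores (population-SD convention).
    """

    circuit: GeneCircuit
    config: EnsembleConfig
    solutions: pd.DataFrame
    n_non_converged: int = 0
    ref_mean: pd.Series | None = None
    ref_std: pd.Series | None = None

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    def log2_levels(self) -> pd.DataFrame:
        lv = self.solutions[list(self.circuit.nodes)]
        return np.log2(lv + self.config.log_offset)


@dataclass
class StateFractionTable:
    """Fractions of the four PPARG/SMAD3 quadrant classes."""

    fractions: dict[str, float]
    counts: dict[str, int]
    total: int
    counting_basis: str = "solutions"

    def as_series(self) -> pd.Series:
        return pd.Series({c: self.fractions[c] for c in STATE_CLASSES})


@dataclass
class PerturbationResult:
    """Outcome of an in-silico over/under-expression experiment."""

    node: str
    direction: str  # "OE" or "DE"
    fold: float
    fractions: StateFractionTable
    control_fractions: StateFractionTable
    ensemble: SteadyStateEnsemble


# ---------------------------------------------------------------------------
# ensemble runs
# ---------------------------------------------------------------------------

def find_steady_states(
    circuit: GeneCircuit,
    params: KineticParameters,
    config: EnsembleConfig,
    rng: np.random.Generator,
) -> list[SteadyState]:
    """Stable steady states of a single kinetic model.

    Integrates from ``n_initial_conditions`` log-uniform random starts,
    keeps converged endpoints, deduplicates them at the relative
    tolerance and records how many starts reached each state.
    """
    one = replace(config, n_models=1)
    p = {
        "g": params.g[None, :],
        "k": params.k[None, :],
        "lam_eff": params.lam_eff[None, :],
        "hill_n": params.hill_n[None, :],
        "b0": params.b0[None, :],
    }
    endpoints, conv = _integrate_models(circuit, one, p, rng)
    good = endpoints[conv]
    if good.size == 0:
        return []
    reps, counts = _dedup_states(
        good, config.eps_dedup, config.max_states_per_model
    )
    return [
        SteadyState(model_id=0, levels=r, multiplicity=int(c))
        for r, c in zip(reps, counts)
    ]


def _run_raw(
    circuit: GeneCircuit,
    config: EnsembleConfig,
    g_scale: np.ndarray | None = None,
) -> SteadyStateEnsemble:
    """Sample, integrate and dedup the whole ensemble.

    ``g_scale`` (n_nodes,) multiplies every model's production rates and
    implements over/under-expression; sampling uses the config seed so a
    perturbed run reuses exactly the control parameter draws.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = _sample_ensemble_parameters(circuit, config, rng)
    if g_scale is not None:
        params = dict(params)
        params["g"] = params["g"] * np.asarray(g_scale, dtype=float)
    endpoints, conv = _integrate_models(circuit, config, params, rng)
    nic = config.n_initial_conditions
    rows: list[np.ndarray] = []
    model_ids: list[int] = []
    mults: list[int] = []
    n_nc = int(np.count_nonzero(~conv))
    for m in range(config.n_models):
        block = slice(m * nic, (m + 1) * nic)
        good = endpoints[block][conv[block]]
        if good.size == 0:
            continue
        reps, counts = _dedup_states(
            good, config.eps_dedup, config.max_states_per_model
        )
        for r, c in zip(reps, counts):
            rows.append(r)
            model_ids.append(m + 1)
            mults.append(int(c))
    if not rows:
        raise EmptyEnsembleError("no initial condition converged in any model")
    df = pd.DataFrame(np.asarray(rows), columns=list(circuit.nodes))
    df.insert(0, "multiplicity", mults)
    df.insert(0, "model_id", model_ids)
    return SteadyStateEnsemble(
        circuit=circuit, config=config, solutions=df, n_non_converged=n_nc
    )


def z_normalize(
    ensemble: SteadyStateEnsemble,
    reference: tuple[pd.Series, pd.Series] | None = None,
) -> SteadyStateEnsemble:
    """Z-score each node's levels across all steady-state solutions.

    Levels are log2-transformed (small offset guards exact zeros) before
    standardization; the population (n-denominator) SD is used.  When
    ``reference`` provides a control (mean, SD) pair the z-scores are
    computed in those coordinates instead, which is how perturbed
    ensembles are compared with the control.
    """
    if ensemble.n_solutions < 2 and reference is None:
        raise DegenerateEnsembleError("need >= 2 solutions to z-normalize")
    logs = ensemble.log2_levels()
    if reference is None:
        mean = logs.mean()
        std = logs.std(ddof=0)
        zero = std[std <= 0]
        if len(zero):
            raise DegenerateEnsembleError(
                f"zero dispersion on node(s): {', '.join(zero.index)}"
            )
    else:
        mean, std = reference
    z = (logs - mean) / std
    sol = ensemble.solutions.copy()
    for node in ensemble.circuit.nodes:
        sol[f"z_{node}"] = z[node]
    return SteadyStateEnsemble(
        circuit=ensemble.circuit,
        config=ensemble.config,
        solutions=sol,
        n_non_converged=ensemble.n_non_converged,
        ref_mean=mean,
        ref_std=std,
    )


def run_ensemble(circuit: GeneCircuit, config: EnsembleConfig) -> SteadyStateEnsemble:
    """Full control run: sample models, collect states, z-normalize."""
    return z_normalize(_run_raw(circuit, config))


def classify_states(
    ensemble: SteadyStateEnsemble,
    e_marker: str = "PPARG",
    m_marker: str = "SMAD3",
    weighted: bool = True,
) -> StateFractionTable:
    """Quadrant classification of z-scored solutions.

    E = (z_e > 0, z_m <= 0), M = (z_e <= 0, z_m > 0), DN = both <= 0,
    DP = both > 0.  By default each state is weighted by its basin
    multiplicity (how many random initial conditions reached it), which
    is equivalent to pooling the endpoint of every initial condition
    across the ensemble; ``weighted=False`` counts each distinct stable
    state once instead.
    """
    for marker in (e_marker, m_marker):
        if f"z_{marker}" not in ensemble.solutions.columns:
            raise KeyError(f"no z-scores for node {marker!r} in ensemble")
    ze = ensemble.solutions[f"z_{e_marker}"].to_numpy()
    zm = ensemble.solutions[f"z_{m_marker}"].to_numpy()
    w = (
        ensemble.solutions["multiplicity"].to_numpy().astype(float)
        if weighted
        else np.ones_like(ze)
    )
    masks = {
        "E": (ze > 0) & (zm <= 0),
        "M": (ze <= 0) & (zm > 0),
        "DN": (ze <= 0) & (zm <= 0),
        "DP": (ze > 0) & (zm > 0),
    }
    total = float(w.sum())
    fractions = {c: float(w[m].sum() / total) for c, m in masks.items()}
    counts = {c: int(np.count_nonzero(m)) for c, m in masks.items()}
    return StateFractionTable(
        fractions=fractions,
        counts=counts,
        total=int(len(ze)),
        counting_basis="multiplicity" if weighted else "solutions",
    )


def perturb_ensemble(
    circuit: GeneCircuit,
    config: EnsembleConfig,
    node: str,
    direction: str,
    fold: float = 20.0,
    control: SteadyStateEnsemble | None = None,
    e_marker: str = "PPARG",
    m_marker: str = "SMAD3",
) -> PerturbationResult:
    """In-silico over- (OE) or down-expression (DE) of one node.

    The ensemble is re-run with the node's sampled production rate
    multiplied (OE) or divided (DE) by ``fold``; perturbed solutions are
    z-scored with the control mean/SD and classified in those control
    coordinates, so fractions are directly comparable to the control.
    """
    direction = direction.upper()
    if direction not in ("OE", "DE"):
        raise ConfigError(f"direction must be 'OE' or 'DE', got {direction!r}")
    if fold <= 1:
        raise ConfigError("fold must be > 1")
    idx = circuit.node_index(node)  # KeyError for unknown node
    if control is None:
        control = run_ensemble(circuit, config)
    elif control.ref_mean is None:
        control = z_normalize(control)
    scale = np.ones(circuit.n_nodes)
    scale[idx] = fold if direction == "OE" else 1.0 / fold
    raw = _run_raw(circuit, config, g_scale=scale)
    pert = z_normalize(raw, reference=(control.ref_mean, control.ref_std))
    return PerturbationResult(
        node=node,
        direction=direction,
        fold=fold,
        fractions=classify_states(pert, e_marker, m_marker),
        control_fractions=classify_states(control, e_marker, m_marker),
        ensemble=pert,
    )
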