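"""Signed gene circuits and shifted-Hill regulatory kinetics.

A circuit is a signed directed graph of transcription factors.  The
dynamics of node levels follow

    dX_i/dt = g_i * prod_j H(X_j; B0_ji, n_ji, lam_ji) - k_i * X_i

where the product runs over regulators j of node i (self-loops included)
and H is the shifted Hill function.  The packaged default circuit is the
three-node SMAD3-KLF4-PPARG network: each node self-activates, SMAD3 and
KLF4 activate each other, PPARG activates KLF4, and SMAD3 and PPARG
mutually inhibit (a toggle switch).  In this circuit the epithelial-like
state is PPARG-high/SMAD3-low and the mesenchymal-like state is
PPARG-low/SMAD3-high.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CircuitParseError, InvalidParameterError

ACTIVATION = "activation"
INHIBITION = "inhibition"

_SIGN_TOKENS = {"->": ACTIVATION, "-|": INHIBITION}


@dataclass(frozen=True)
class Edge:
    """One signed regulatory interaction."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise CircuitParseError(f"unknown edge sign {self.sign!r}")


@dataclass
class GeneCircuit:
    """A validated signed gene-regulatory network."""

    nodes: list[str]
    edges: list[Edge]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise CircuitParseError("circuit has an empty node list")
        if len(set(self.nodes)) != len(self.nodes):
            raise CircuitParseError("duplicated node name")
        seen: set[tuple[str, str]] = set()
        declared = set(self.nodes)
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in declared:
                    raise CircuitParseError(
                        f"edge {e.source}->{e.target} references undeclared node "
                        f"{endpoint!r}"
                    )
            key = (e.source, e.target)
            if key in seen:
                raise CircuitParseError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)

    # -- convenience accessors -------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise KeyError(f"node {name!r} not in circuit") from None

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(source index, target index, +1/-1 sign) arrays, one entry per edge."""
        src = np.array([self.node_index(e.source) for e in self.edges], dtype=np.int64)
        tgt = np.array([self.node_index(e.target) for e in self.edges], dtype=np.int64)
        sign = np.array(
            [1 if e.sign == ACTIVATION else -1 for e in self.edges], dtype=np.int64
        )
        return src, tgt, sign

    @classmethod
    def default(cls) -> "GeneCircuit":
        """The packaged SMAD3-KLF4-PPARG circuit (3 nodes, 8 edges)."""
        ref = importlib.resources.files("emtdyn.data") / "smad3_klf4_pparg.topo"
        with importlib.resources.as_file(ref) as path:
            return load_circuit(path)


@dataclass
class KineticParameters:
    """One random kinetic model for a circuit.

    Per node: production rate ``g`` (level/time) and degradation rate ``k``
    (1/time).  Per edge: raw fold change ``lam_raw`` >= 1, integer Hill
    coefficient ``hill_n`` and threshold ``b0`` > 0.  The effective fold
    change is ``lam_raw`` for activations and ``1/lam_raw`` for
    inhibitions.
    """

    circuit: GeneCircuit
    g: np.ndarray
    k: np.ndarray
    lam_raw: np.ndarray
    hill_n: np.ndarray
    b0: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.circuit.n_nodes, self.circuit.n_edges
        for name, arr, size in (
            ("g", self.g, n),
            ("k", self.k, n),
            ("lam_raw", self.lam_raw, m),
            ("hill_n", self.hill_n, m),
            ("b0", self.b0, m),
        ):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (size,):
                raise InvalidParameterError(f"{name} must have shape ({size},)")
            setattr(self, name, arr)
        if np.any(self.g <= 0) or np.any(self.k <= 0):
            raise InvalidParameterError("g and k must be positive")
        if np.any(self.lam_raw < 1):
            raise InvalidParameterError("lam_raw must be >= 1")
        if np.any(self.hill_n < 1) or np.any(self.hill_n != np.round(self.hill_n)):
            raise InvalidParameterError("hill_n must be positive integers")
        if np.any(self.b0 <= 0):
            raise InvalidParameterError("b0 must be positive")

    @property
    def lam_eff(self) -> np.ndarray:
        """Effective fold change per edge (inverted on inhibitory edges)."""
        _, _, sign = self.circuit.edge_arrays()
        return np.where(sign > 0, self.lam_raw, 1.0 / self.lam_raw)


def shifted_hill(
    b: float | np.ndarray,
    b0: float | np.ndarray,
    n: int | np.ndarray,
    lam_eff: float | np.ndarray,
) -> float | np.ndarray:
    """Shifted Hill regulation term H = lam + (1 - lam) / (1 + (B/B0)^n).

    H interpolates between 1 (no regulator, B = 0) and the effective fold
    change ``lam_eff`` at saturation, so lam_eff > 1 is activation and
    lam_eff < 1 inhibition.
    """
    b = np.asarray(b, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    lam_eff = np.asarray(lam_eff, dtype=float)
    if np.any(b < 0):
        raise InvalidParameterError("regulator level B must be non-negative")
    if np.any(b0 <= 0):
        raise InvalidParameterError("threshold B0 must be positive")
    if np.any(lam_eff <= 0):
        raise InvalidParameterError("effective fold change must be positive")
    if np.any(np.asarray(n) < 1):
        raise InvalidParameterError("Hill coefficient must be >= 1")
    ratio = (b / b0) ** np.asarray(n, dtype=float)
    out = lam_eff + (1.0 - lam_eff) / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def circuit_rhs(
    x: Sequence[float] | np.ndarray,
    circuit: GeneCircuit,
    params: KineticParameters,
) -> np.ndarray:
    """Time derivative of node levels for one kinetic model.

    Accepts a single state vector (n_nodes,) or a batch (m, n_nodes);
    regulators acting on the same target combine multiplicatively.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    xs = np.atleast_2d(x)
    if xs.shape[1] != circuit.n_nodes:
        raise InvalidParameterError(
            f"state has {xs.shape[1]} components, circuit has {circuit.n_nodes} nodes"
        )
    src, tgt, _ = circuit.edge_arrays()
    lam = params.lam_eff
    mult = np.ones_like(xs)
    for e in range(circuit.n_edges):
        h = shifted_hill(xs[:, src[e]], params.b0[e], params.hill_n[e], lam[e])
        mult[:, tgt[e]] *= h
    dx = params.g * mult - params.k * xs
    return dx[0] if squeeze else dx


def _parse_edge_line(line: str, lineno: int, nodes: list[str]) -> Edge:
    for token, sign in _SIGN_TOKENS.items():
        if f" {token} " in line:
            left, right = line.split(f" {token} ", 1)
            source, target = left.strip(), right.strip()
            if not source or not target or " " in source or " " in target:
                raise CircuitParseError(f"line {lineno}: malformed edge {line!r}")
            return Edge(source, target, sign)
    raise CircuitParseError(
        f"line {lineno}: no sign token ('->' or '-|') in edge {line!r}"
    )


def load_circuit(path: str | Path) -> GeneCircuit:
    """Read a circuit topology file.

    Format: a ``[nodes]`` block with one gene per line, then an
    ``[edges]`` block with lines ``SOURCE -> TARGET`` (activation) or
    ``SOURCE -| TARGET`` (inhibition).  '#' starts a comment.
    """
    path = Path(path)
    nodes: list[str] = []
    edges: list[Edge] = []
    section: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() in ("[nodes]", "[edges]"):
            section = line.lower().strip("[]")
            continue
        if section == "nodes":
            if " " in line:
                raise CircuitParseError(f"line {lineno}: node name {line!r} has spaces")
            nodes.append(line)
        elif section == "edges":
            edges.append(_parse_edge_line(line, lineno, nodes))
        else:
            raise CircuitParseError(
                f"line {lineno}: content before a [nodes]/[edges] header"
            )
    try:
        return GeneCircuit(nodes=nodes, edges=edges)
    except CircuitParseError as exc:
        raise CircuitParseError(f"{path.name}: {exc}") from None
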