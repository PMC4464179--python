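"""Random regulatory-network ensembles (Erdős–Rényi and scale-free).

Both generators produce validated :class:`RegulatoryNetwork` objects with
signed directed edges and randomly assigned update rules:

* **ER** — every ordered pair of distinct nodes receives a directed edge
  with equal probability, calibrated so the expected density
  (connections per node) matches the target.
* **SF** — undirected Barabási–Albert preferential attachment (degree
  exponent near 3), after which every edge is oriented uniformly at random.
  Fractional attachment counts are realised by randomising between the two
  neighbouring integers, so non-integer target densities are hit in
  expectation.

Activating self-loops are added per node with ``loop_probability``; each
edge is activating with ``sign_probability``.  Rules default to SQDS with
unit weights; for the cube interpolations random *sign-monotone* truth
tables are drawn as linear threshold functions, so activators never act as
repressors and vice versa.

One ensemble seed is expanded into per-network substreams, making ensembles
reproducible regardless of how many networks are drawn from them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .network import (
    ACTIVATING,
    INHIBITING,
    Connection,
    NodeSpec,
    RegulatoryNetwork,
    TruthTable,
    build_network,
)


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a random-network ensemble."""

    model: str = "SF"  # "ER" or "SF"
    n_nodes: int = 15
    density: float = 2.5
    loop_probability: float = 0.5
    sign_probability: float = 0.5
    n_networks: int = 100
    seed: int = 0
    interpolation: str = "sqds"

    def __post_init__(self) -> None:
        if self.model not in ("ER", "SF"):
            raise ValueError("model must be 'ER' or 'SF'")
        if self.density <= 0:
            raise ValueError("density must be positive")
        for p in (self.loop_probability, self.sign_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if self.n_networks < 1 or self.n_nodes < 2:
            raise ValueError("need n_networks >= 1 and n_nodes >= 2")

    def with_(self, **kw) -> "EnsembleSpec":
        return replace(self, **kw)


def _node_names(n: int) -> list[str]:
    return [f"n{i:02d}" for i in range(n)]


def _finalize(
    edges: list[tuple[int, int]],
    spec: EnsembleSpec,
    rng: np.random.Generator,
    name: str,
) -> RegulatoryNetwork:
    names = _node_names(spec.n_nodes)
    conns = []
    for i, j in edges:
        sign = ACTIVATING if rng.random() < spec.sign_probability else INHIBITING
        conns.append(Connection(names[i], names[j], sign))
    for i in range(spec.n_nodes):
        if spec.loop_probability and rng.random() < spec.loop_probability:
            if not any(c.source == names[i] and c.target == names[i] for c in conns):
                conns.append(Connection(names[i], names[i], ACTIVATING))
    net = build_network(names, conns, interpolation="sqds", name=name)
    return assign_random_functions(net, rng, interpolation=spec.interpolation)


def generate_er(
    spec: EnsembleSpec, rng: np.random.Generator | int | None = None
) -> RegulatoryNetwork:
    """One Erdős–Rényi network at the requested target density."""
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    n = spec.n_nodes
    p = spec.density / (n - 1)
    if p > 1:
        raise ValueError(
            f"density {spec.density} infeasible for {n} nodes (needs p <= 1)"
        )
    edges = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return _finalize(edges, spec, rng, name="er")


def generate_sf(
    spec: EnsembleSpec, rng: np.random.Generator | int | None = None
) -> RegulatoryNetwork:
    """One scale-free network by preferential attachment, randomly oriented."""
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    n = spec.n_nodes
    if n < 4:
        raise ValueError("scale-free generation needs at least 4 nodes")
    target_edges = spec.density * n
    # smallest complete seed graph whose attachment count m stays feasible
    m = m0 = None
    for m0_try in range(3, n):
        seed_count = m0_try * (m0_try - 1) // 2
        m_try = (target_edges - seed_count) / (n - m0_try)
        if 0 < m_try <= m0_try:
            m0, m = m0_try, m_try
            break
    if m0 is None:
        raise ValueError(
            f"density {spec.density} infeasible for preferential attachment "
            f"with {n} nodes"
        )
    seed_edges = [(i, j) for i in range(m0) for j in range(i + 1, m0)]
    undirected = list(seed_edges)
    degree = np.zeros(n)
    for a, b in seed_edges:
        degree[a] += 1
        degree[b] += 1
    for new in range(m0, n):
        mi = int(np.floor(m)) + (1 if rng.random() < m - np.floor(m) else 0)
        mi = max(1, min(mi, new))
        probs = degree[:new] / degree[:new].sum()
        targets = rng.choice(new, size=mi, replace=False, p=probs)
        for t in targets:
            undirected.append((new, int(t)))
            degree[new] += 1
            degree[t] += 1
    edges = []
    for a, b in undirected:
        edges.append((a, b) if rng.random() < 0.5 else (b, a))
    return _finalize(edges, spec, rng, name="sf")


def _random_monotone_table(
    activators: tuple[str, ...],
    inhibitors: tuple[str, ...],
    rng: np.random.Generator,
) -> TruthTable:
    """Random sign-monotone Boolean rule as a linear threshold function.

    Weights are positive for activators, negative for inhibitors; the
    threshold is drawn so neither tautology nor contradiction is guaranteed.
    The resulting table is non-decreasing in every activator and
    non-increasing in every inhibitor by construction.
    """
    inputs = activators + inhibitors
    k = len(inputs)
    w = rng.uniform(0.2, 1.0, size=k)
    w[len(activators):] *= -1.0
    lo, hi = np.minimum(w, 0).sum(), np.maximum(w, 0).sum()
    theta = rng.uniform(lo, hi)
    out = []
    for idx in range(2**k):
        bits = np.array([(idx >> i) & 1 for i in range(k)], dtype=float)
        out.append(int(float(w @ bits) >= theta))
    return TruthTable(inputs, tuple(out))


def assign_random_functions(
    topology: RegulatoryNetwork,
    rng: np.random.Generator | int | None = None,
    interpolation: str = "sqds",
) -> RegulatoryNetwork:
    """Equip a signed topology with update rules for the chosen interpolation.

    SQDS networks need no explicit rules (unit weights with edge signs are
    the rule); cube interpolations get random sign-monotone truth tables.
    """
    rng = np.random.default_rng(rng)
    if interpolation == "sqds":
        if topology.interpolation == "sqds":
            return topology
        return RegulatoryNetwork(
            tuple(replace(n, rule=None) for n in topology.nodes),
            topology.connections,
            "sqds",
            topology.name,
        )
    from dataclasses import replace as _replace

    nodes = []
    for n in topology.nodes:
        incoming = topology.incoming(n.name)
        if incoming:
            acts = tuple(c.source for c in incoming if c.activating)
            inhs = tuple(c.source for c in incoming if not c.activating)
            nodes.append(_replace(n, rule=_random_monotone_table(acts, inhs, rng)))
        else:
            nodes.append(_replace(n, rule=None))
    return RegulatoryNetwork(
        tuple(nodes), topology.connections, interpolation, topology.name
    )


def generate_ensemble(spec: EnsembleSpec) -> Iterator[RegulatoryNetwork]:
    """Yield ``spec.n_networks`` reproducible networks from per-network substreams."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_networks)
    gen = generate_er if spec.model == "ER" else generate_sf
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        net = gen(spec, rng)
        yield replace_name(net, f"{spec.model.lower()}_{i:03d}")


def replace_name(net: RegulatoryNetwork, name: str) -> RegulatoryNetwork:
    return RegulatoryNetwork(net.nodes, net.connections, net.interpolation, name)


__all__ = [
    "EnsembleSpec",
    "assign_random_functions",
    "generate_ensemble",
    "generate_er",
    "generate_sf",
    "replace_name",
]
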