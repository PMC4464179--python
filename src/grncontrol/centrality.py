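"""Convergence-based control centralities.

The convergence difference of two networks sharing their nodes is

    D(N1, N2) = Integral over v0 in [0,1]^n of
                mu(conv_N1(v0), conv_N2(v0)) dv0,

where ``conv_N(v0)`` is the steady state reached from the initial vector
``v0`` and ``mu`` is the mean squared difference over the shared nodes.
All integrals are Monte-Carlo estimates with *common random numbers*: the
same initial vectors are fed to both networks, so ``D(N, N) == 0`` exactly
and tiny differences (the < 1e-10 regime that separates inert from active
nodes) are measured without Monte-Carlo noise floors.

Three centralities are derived from D:

* **Total centrality** (TC) — D between the network and the network with a
  connection (or all connections leaving a node) deleted: the impact of a
  null mutation.
* **Value centrality** (VC) — the expected squared divergence of the steady
  states when only one node's initial value differs (two independent uniform
  redraws of that coordinate): the leverage of the node's *value*.
* **Dynamic centrality** (DC) — the residual D after the node's outputs are
  rerouted through a constant surrogate whose value is chosen optimally
  (min over the surrogate value c in [0,1]): the *relay* component of
  influence that no constant can imitate.

Aggregates: controllability = mean node VC, vulnerability V = mean node TC,
robustness = 1 - V, relative controllability = controllability / V, plus the
Gini coefficient of each centrality distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import CompiledNetwork, SimulationSettings
from .network import (
    RegulatoryNetwork,
    delete_connection,
    delete_outgoing,
    split_connection_input,
    split_node_outputs,
)

CentralityKind = Literal["TC", "VC", "DC"]


# ---------------------------------------------------------------------------
# distribution statistics
# ---------------------------------------------------------------------------

def gini(values: Sequence[float]) -> float:
    """Population Gini coefficient of a non-negative distribution.

    ``sum_ij |c_i - c_j| / (2 n^2 mean)``; 0 for a uniform distribution,
    ``(n-1)/n`` when all mass sits on one of n entries.  All-zero input
    returns 0 by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("gini of empty input")
    if np.any(v < 0):
        raise ValueError("gini requires non-negative values")
    total = v.sum()
    if total == 0:
        return 0.0
    v = np.sort(v)
    n = v.size
    # identity: sum_ij |v_i - v_j| = 2 * sum_i (2i - n + 1) v_(i)
    diff_sum = 2.0 * np.sum((2.0 * np.arange(n) - n + 1.0) * v)
    return float(diff_sum / (2.0 * n * total))


def cumulative_share(values: Sequence[float], k: int) -> float:
    """Fraction of the total held by the k largest entries."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cumulative_share of empty input")
    if not 0 <= k <= v.size:
        raise ValueError(f"k={k} out of range for {v.size} values")
    total = v.sum()
    if total == 0:
        return 0.0 if k < v.size else 1.0
    return float(np.sort(v)[::-1][:k].sum() / total)


def min_nodes_for_share(values: Sequence[float], threshold: float = 0.5) -> int:
    """Smallest k whose k largest entries exceed ``threshold`` of the total."""
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    total = v.sum()
    if total == 0:
        return v.size
    cum = np.cumsum(v) / total
    return int(np.argmax(cum > threshold) + 1)


# ---------------------------------------------------------------------------
# Monte-Carlo workspace
# ---------------------------------------------------------------------------

def _name_stream(seed: int, name: str, tag: int) -> np.random.Generator:
    """Independent, order-insensitive uniform stream for one node name."""
    key = [seed & 0x7FFFFFFF, tag] + list(name.encode("utf8"))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(key)))


@dataclass
class Estimate:
    """Monte-Carlo point estimate with its standard error."""

    value: float
    stderr: float

    def __float__(self) -> float:
        return self.value


class Workspace:
    """Shared sample set and cached steady states for one base network.

    All centralities of a network are integrals over the same initial-vector
    sample; holding them in one workspace guarantees common random numbers
    across every comparison and lets the base network's steady states be
    converged once and reused.
    """

    def __init__(self, network: RegulatoryNetwork, settings: SimulationSettings):
        self.network = network
        self.settings = settings
        self.names = network.node_names
        self._columns: dict[tuple[str, int], np.ndarray] = {}
        self._base: np.ndarray | None = None
        self._base_conv_flags: np.ndarray | None = None
        self._compiled: dict[int, CompiledNetwork] = {}

    # -- sampling -----------------------------------------------------------
    def column(self, name: str, tag: int = 0) -> np.ndarray:
        key = (name, tag)
        if key not in self._columns:
            rng = _name_stream(self.settings.seed, name, tag)
            self._columns[key] = rng.uniform(size=self.settings.mc_samples)
        return self._columns[key]

    def initial_matrix(self, net: RegulatoryNetwork, overrides: dict | None = None) -> np.ndarray:
        overrides = overrides or {}
        cols = []
        for name in net.node_names:
            if name in overrides:
                v = np.asarray(overrides[name], dtype=float)
                cols.append(np.broadcast_to(v, (self.settings.mc_samples,)))
            else:
                cols.append(self.column(name))
        return np.column_stack(cols)

    # -- convergence --------------------------------------------------------
    def _compile(self, net: RegulatoryNetwork) -> CompiledNetwork:
        key = id(net)
        comp = self._compiled.get(key)
        if comp is None or comp.network is not net:
            comp = CompiledNetwork(net, self.settings.input_behavior)
            self._compiled[key] = comp
        return comp

    def converged(self, net: RegulatoryNetwork, overrides: dict | None = None) -> np.ndarray:
        x0 = self.initial_matrix(net, overrides)
        final, _, _ = self._compile(net).integrate(x0, self.settings)
        return final

    def base_states(self) -> np.ndarray:
        if self._base is None:
            x0 = self.initial_matrix(self.network)
            final, conv, _ = self._compile(self.network).integrate(x0, self.settings)
            self._base = final
            self._base_conv_flags = conv
        return self._base

    # -- comparisons --------------------------------------------------------
    def mu_samples(
        self,
        states_a: np.ndarray,
        names_a: Sequence[str],
        states_b: np.ndarray,
        names_b: Sequence[str],
        over: Sequence[str],
    ) -> np.ndarray:
        ia = [list(names_a).index(n) for n in over]
        ib = [list(names_b).index(n) for n in over]
        diff = states_a[:, ia] - states_b[:, ib]
        return np.mean(diff * diff, axis=1)

    @staticmethod
    def estimate(mu: np.ndarray) -> Estimate:
        return Estimate(float(np.mean(mu)), float(np.std(mu) / np.sqrt(mu.size)))


def _as_estimate(x: Estimate | float) -> Estimate:
    return x if isinstance(x, Estimate) else Estimate(float(x), 0.0)


# ---------------------------------------------------------------------------
# convergence difference
# ---------------------------------------------------------------------------

def convergence_difference(
    n1: RegulatoryNetwork,
    n2: RegulatoryNetwork,
    settings: SimulationSettings = SimulationSettings(),
    shared_nodes: Sequence[str] | None = None,
    return_stderr: bool = False,
):
    """Monte-Carlo convergence difference D(N1, N2) over the shared nodes.

    The same uniform initial draws are used for both networks (matched by
    node name); nodes present in only one network get their own independent
    draws unless the caller overrides them.
    """
    if shared_nodes is None:
        shared_nodes = [n for n in n1.node_names if n2.has_node(n)]
    shared_nodes = list(shared_nodes)
    if not shared_nodes:
        raise ValueError("networks share no nodes")
    ws = Workspace(n1, settings)
    s1, _, _ = ws._compile(n1).integrate(ws.initial_matrix(n1), settings)
    s2, _, _ = ws._compile(n2).integrate(ws.initial_matrix(n2), settings)
    mu = ws.mu_samples(s1, n1.node_names, s2, n2.node_names, shared_nodes)
    est = ws.estimate(mu)
    return est if return_stderr else est.value


# ---------------------------------------------------------------------------
# centralities (workspace-level implementations)
# ---------------------------------------------------------------------------

def _tc(ws: Workspace, mutant: RegulatoryNetwork, over: Sequence[str]) -> Estimate:
    base = ws.base_states()
    s2, _, _ = ws._compile(mutant).integrate(ws.initial_matrix(mutant), ws.settings)
    mu = ws.mu_samples(base, ws.names, s2, mutant.node_names, over)
    return ws.estimate(mu)


def _vc(ws: Workspace, net: RegulatoryNetwork, node: str, over: Sequence[str]) -> Estimate:
    """E[mu(conv(v, x=a), conv(v, x=b))] with a, b independent uniforms.

    For the workspace's own network the first draw a is the node's base
    column, so the cached base steady states serve as the a-side; the b-side
    is an independent redraw.  Both sides share every other coordinate
    (common random numbers), so a node without influence scores exactly 0.
    """
    b = ws.column(node, tag=2)
    if net is ws.network:
        sa = ws.base_states()
    else:
        a = ws.column(node, tag=1)
        sa, _, _ = ws._compile(net).integrate(
            ws.initial_matrix(net, {node: a}), ws.settings
        )
    sb, _, _ = ws._compile(net).integrate(ws.initial_matrix(net, {node: b}), ws.settings)
    mu = ws.mu_samples(sa, net.node_names, sb, net.node_names, over)
    return ws.estimate(mu)


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _dc(
    ws: Workspace, split_net: RegulatoryNetwork, split_name: str, over: Sequence[str]
) -> Estimate:
    """Minimise D(base, split at constant c) over the surrogate value c.

    A coarse grid (``dc_grid`` points on [0,1]) is evaluated in a single
    batched convergence run — the guard against a non-unimodal D(c) — and
    the bracket around the best grid point is then narrowed by golden-section
    search until its width falls below ``dc_tol``.  All samples and all
    candidate values share the base network's initial draws.
    """
    settings = ws.settings
    base = ws.base_states()
    comp = ws._compile(split_net)
    x0_one = ws.initial_matrix(split_net, {split_name: 0.0})
    split_col = list(split_net.node_names).index(split_name)
    over_b = [list(split_net.node_names).index(n) for n in over]
    over_a = [list(ws.names).index(n) for n in over]
    base_sel = base[:, over_a]
    s = settings.mc_samples

    def eval_grid(cs: np.ndarray) -> np.ndarray:
        big = np.tile(x0_one, (cs.size, 1))
        big[:, split_col] = np.repeat(cs, s)
        final, _, _ = comp.integrate(big, settings)
        mus = np.empty((cs.size, s))
        for j in range(cs.size):
            diff = final[j * s : (j + 1) * s, over_b] - base_sel
            mus[j] = np.mean(diff * diff, axis=1)
        return mus

    cs = np.linspace(0.0, 1.0, settings.dc_grid)
    mus = eval_grid(cs)
    ds = mus.mean(axis=1)
    j = int(np.argmin(ds))
    best_d = float(ds[j])
    best_mu = mus[j]
    lo = cs[max(j - 1, 0)]
    hi = cs[min(j + 1, settings.dc_grid - 1)]

    def eval_one(c: float):
        mu = eval_grid(np.array([c]))[0]
        return float(np.mean(mu)), mu

    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1, mu1 = eval_one(x1)
    f2, mu2 = eval_one(x2)
    while hi - lo > settings.dc_tol:
        if f1 <= f2:
            hi, x2, f2, mu2 = x2, x1, f1, mu1
            x1 = hi - _GOLDEN * (hi - lo)
            f1, mu1 = eval_one(x1)
        else:
            lo, x1, f1, mu1 = x1, x2, f2, mu2
            x2 = lo + _GOLDEN * (hi - lo)
            f2, mu2 = eval_one(x2)
        if f1 < best_d:
            best_d, best_mu = f1, mu1
        if f2 < best_d:
            best_d, best_mu = f2, mu2
    return ws.estimate(best_mu)


# ---------------------------------------------------------------------------
# public centrality operations
# ---------------------------------------------------------------------------

def total_centrality_connection(
    network: RegulatoryNetwork,
    source: str,
    target: str,
    settings: SimulationSettings = SimulationSettings(),
    return_stderr: bool = False,
):
    """Impact of the null mutation of one connection."""
    ws = Workspace(network, settings)
    est = _tc(ws, delete_connection(network, source, target), list(ws.names))
    return est if return_stderr else est.value


def total_centrality_node(
    network: RegulatoryNetwork,
    node: str,
    settings: SimulationSettings = SimulationSettings(),
    return_stderr: bool = False,
):
    """Impact of deleting all connections originating in a node."""
    ws = Workspace(network, settings)
    est = _tc(ws, delete_outgoing(network, node), list(ws.names))
    return est if return_stderr else est.value


def value_centrality_node(
    network: RegulatoryNetwork,
    node: str,
    settings: SimulationSettings = SimulationSettings(),
    return_stderr: bool = False,
):
    """Influence of a node's initial value on network convergence."""
    network.node(node)
    ws = Workspace(network, settings)
    est = _vc(ws, network, node, list(ws.names))
    return est if return_stderr else est.value


def value_centrality_connection(
    network: RegulatoryNetwork,
    source: str,
    target: str,
    settings: SimulationSettings = SimulationSettings(),
    return_stderr: bool = False,
):
    """Value centrality of one connection, via the node-split construction."""
    ws = Workspace(network, settings)
    split_net, split_name = split_connection_input(network, source, target)
    est = _vc(ws, split_net, split_name, list(ws.names))
    return est if return_stderr else est.value


def dynamic_centrality_connection(
    network: RegulatoryNetwork,
    source: str,
    target: str,
    settings: SimulationSettings = SimulationSettings(),
    return_stderr: bool = False,
):
    """Relay influence of a connection: D after optimally neutralising its input."""
    ws = Workspace(network, settings)
    split_net, split_name = split_connection_input(network, source, target)
    est = _dc(ws, split_net, split_name, list(ws.names))
    return est if return_stderr else est.value


def dynamic_centrality_node(
    network: RegulatoryNetwork,
    node: str,
    settings: SimulationSettings = SimulationSettings(),
    return_stderr: bool = False,
):
    """Relay influence of a node (0 for sinks by construction)."""
    network.node(node)
    if not network.outgoing(node):
        est = Estimate(0.0, 0.0)
        return est if return_stderr else 0.0
    ws = Workspace(network, settings)
    split_net, split_name = split_node_outputs(network, node)
    est = _dc(ws, split_net, split_name, list(ws.names))
    return est if return_stderr else est.value


def pairwise_influence(
    network: RegulatoryNetwork,
    source: str | tuple[str, str],
    target_node: str,
    kind: CentralityKind,
    settings: SimulationSettings = SimulationSettings(),
) -> float:
    """Influence of a node or connection on a single target node.

    The corresponding centrality with the mean squared difference restricted
    to the target node's converged value only.
    """
    network.node(target_node)
    over = [target_node]
    ws = Workspace(network, settings)
    is_conn = not isinstance(source, str)
    if kind == "TC":
        mutant = (
            delete_connection(network, *source)
            if is_conn
            else delete_outgoing(network, source)
        )
        return _tc(ws, mutant, over).value
    if kind == "VC":
        if is_conn:
            split_net, split_name = split_connection_input(network, *source)
            return _vc(ws, split_net, split_name, over).value
        return _vc(ws, network, source, over).value
    if kind == "DC":
        if is_conn:
            split_net, split_name = split_connection_input(network, *source)
        else:
            if not network.outgoing(source):
                return 0.0
            split_net, split_name = split_node_outputs(network, source)
        return _dc(ws, split_net, split_name, over).value
    raise ValueError(f"unknown centrality kind {kind!r}")


def sensitivity(
    network: RegulatoryNetwork,
    target_node: str,
    kind: CentralityKind,
    settings: SimulationSettings = SimulationSettings(),
) -> float:
    """Total influence received by a node: sum of all pairwise node influences."""
    return float(
        sum(
            pairwise_influence(network, src, target_node, kind, settings)
            for src in network.node_names
        )
    )


def influence_matrix(
    network: RegulatoryNetwork,
    kind: CentralityKind,
    settings: SimulationSettings = SimulationSettings(),
    sources: Iterable[str | tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise influence I(source, target) for all targets; last row = sensitivity.

    Rows are sources (nodes by default), columns are target nodes.
    """
    if sources is None:
        sources = list(network.node_names)
    sources = list(sources)
    targets = list(network.node_names)
    data = np.zeros((len(sources), len(targets)))
    for i, src in enumerate(sources):
        for j, tgt in enumerate(targets):
            data[i, j] = pairwise_influence(network, src, tgt, kind, settings)
    index = [s if isinstance(s, str) else f"{s[0]}->{s[1]}" for s in sources]
    df = pd.DataFrame(data, index=index, columns=targets)
    df.loc["__sensitivity__"] = df.sum(axis=0)
    return df


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class CentralityReport:
    """All centralities of one network plus network-level aggregates."""

    network_name: str
    nodes: pd.DataFrame  # index: node; columns TC, VC, DC (+ _stderr)
    connections: pd.DataFrame | None
    controllability: float
    vulnerability: float
    robustness: float
    relative_controllability: float  # NaN when vulnerability == 0
    rc_defined: bool
    gini_tc: float
    gini_vc: float
    gini_dc: float
    settings: SimulationSettings = field(repr=False, default=SimulationSettings())

    STRONG = 1e-6
    WEAK = 1e-10

    def magnitude_band(self, value: float) -> str:
        """Annotation bands: strong > 1e-6 > intermediate > 1e-10 > weak."""
        if value > self.STRONG:
            return "strong"
        if value >= self.WEAK:
            return "intermediate"
        return "weak"

    def to_tsv(self) -> str:
        frames = [self.nodes.assign(kind="node")]
        if self.connections is not None:
            frames.append(self.connections.assign(kind="connection"))
        table = pd.concat(frames)
        table = table.reset_index().rename(columns={"index": "name"})
        cols = ["kind", "name"] + [c for c in table.columns if c not in ("kind", "name")]
        return table[cols].to_csv(sep="\t", index=False, lineterminator="\n")


def node_centralities(
    network: RegulatoryNetwork,
    settings: SimulationSettings = SimulationSettings(),
    kinds: Sequence[CentralityKind] = ("TC", "VC", "DC"),
    workspace: Workspace | None = None,
) -> pd.DataFrame:
    """Per-node TC/VC/DC with Monte-Carlo standard errors, sharing one sample set."""
    ws = workspace or Workspace(network, settings)
    over = list(ws.names)
    rows: dict[str, dict[str, float]] = {n: {} for n in over}
    for name in over:
        if "TC" in kinds:
            est = _tc(ws, delete_outgoing(network, name), over)
            rows[name]["TC"], rows[name]["TC_stderr"] = est.value, est.stderr
        if "VC" in kinds:
            est = _vc(ws, network, name, over)
            rows[name]["VC"], rows[name]["VC_stderr"] = est.value, est.stderr
        if "DC" in kinds:
            if network.outgoing(name):
                split_net, split_name = split_node_outputs(network, name)
                est = _dc(ws, split_net, split_name, over)
            else:
                est = Estimate(0.0, 0.0)
            rows[name]["DC"], rows[name]["DC_stderr"] = est.value, est.stderr
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(over)]


def connection_centralities(
    network: RegulatoryNetwork,
    settings: SimulationSettings = SimulationSettings(),
    kinds: Sequence[CentralityKind] = ("TC", "VC", "DC"),
    workspace: Workspace | None = None,
) -> pd.DataFrame:
    ws = workspace or Workspace(network, settings)
    over = list(ws.names)
    rows = {}
    for c in network.connections:
        key = f"{c.source}->{c.target}"
        row: dict[str, float] = {}
        if "TC" in kinds:
            est = _tc(ws, delete_connection(network, c.source, c.target), over)
            row["TC"], row["TC_stderr"] = est.value, est.stderr
        if "VC" in kinds or "DC" in kinds:
            split_net, split_name = split_connection_input(network, c.source, c.target)
            if "VC" in kinds:
                est = _vc(ws, split_net, split_name, over)
                row["VC"], row["VC_stderr"] = est.value, est.stderr
            if "DC" in kinds:
                est = _dc(ws, split_net, split_name, over)
                row["DC"], row["DC_stderr"] = est.value, est.stderr
        rows[key] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_report(
    network: RegulatoryNetwork,
    settings: SimulationSettings = SimulationSettings(),
    include_connections: bool = True,
) -> CentralityReport:
    """Full centrality survey of one network.

    Deterministic given the settings seed, and invariant under node
    reordering (sample streams are keyed by node name).
    """
    ws = Workspace(network, settings)
    nodes = node_centralities(network, settings, workspace=ws)
    conns = (
        connection_centralities(network, settings, workspace=ws)
        if include_connections and network.connections
        else None
    )
    vulnerability = float(nodes["TC"].mean())
    controllability = float(nodes["VC"].mean())
    rc_defined = vulnerability > 0
    rc = controllability / vulnerability if rc_defined else float("nan")
    return CentralityReport(
        network_name=network.name,
        nodes=nodes,
        connections=conns,
        controllability=controllability,
        vulnerability=vulnerability,
        robustness=1.0 - vulnerability,
        relative_controllability=rc,
        rc_defined=rc_defined,
        gini_tc=gini(nodes["TC"]),
        gini_vc=gini(nodes["VC"]),
        gini_dc=gini(nodes["DC"]),
        settings=settings,
    )


__all__ = [
    "CentralityKind",
    "CentralityReport",
    "Estimate",
    "Workspace",
    "aggregate_report",
    "connection_centralities",
    "convergence_difference",
    "cumulative_share",
    "dynamic_centrality_connection",
    "dynamic_centrality_node",
    "gini",
    "influence_matrix",
    "min_nodes_for_share",
    "node_centralities",
    "pairwise_influence",
    "sensitivity",
    "total_centrality_connection",
    "total_centrality_node",
    "value_centrality_connection",
    "value_centrality_node",
]
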