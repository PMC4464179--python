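"""In-memory representation and structural editing of regulatory networks.

A :class:`RegulatoryNetwork` is a signed directed graph whose nodes carry
Boolean update rules together with the kinetic parameters needed to embed
those rules in continuous dynamics (multilinear BooleCube interpolation,
its sigmoidal HillCube variant, or the exponential standardised qualitative
dynamical system, SQDS).

Networks are value objects: every structural edit (deleting a connection,
splitting a node, adding input loops) returns a new network and leaves its
argument untouched.  Node splitting replaces the source of one or all
outgoing connections by a fresh *constant* input node — the structural
primitive behind dynamic control centrality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

ACTIVATING = "+"
INHIBITING = "-"

_SIGN_ALIASES = {
    "+": ACTIVATING,
    "-": INHIBITING,
    "activating": ACTIVATING,
    "inhibiting": INHIBITING,
    "activation": ACTIVATING,
    "inhibition": INHIBITING,
}

INTERPOLATIONS = ("boolecube", "hillcube", "sqds")


class NetworkValidationError(ValueError):
    """Raised when a network fails structural validation."""


def _normalise_sign(sign: str) -> str:
    try:
        return _SIGN_ALIASES[sign.lower() if isinstance(sign, str) else sign]
    except (KeyError, AttributeError):
        raise NetworkValidationError(f"unknown connection sign {sign!r}") from None


@dataclass(frozen=True)
class Connection:
    """A signed, weighted directed edge.  Self-loops are allowed."""

    source: str
    target: str
    sign: str = ACTIVATING
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sign", _normalise_sign(self.sign))
        if self.weight <= 0:
            raise NetworkValidationError(
                f"connection {self.source}->{self.target}: weight must be > 0"
            )

    @property
    def activating(self) -> bool:
        return self.sign == ACTIVATING


@dataclass(frozen=True)
class TruthTable:
    """Boolean update rule as an explicit truth table.

    ``inputs`` is the ordered tuple of regulator names; ``outputs`` holds the
    rule value for every input combination, indexed by
    ``sum(v_i << i)`` where ``v_i`` is the Boolean value of ``inputs[i]``
    (first input = least significant bit).
    """

    inputs: tuple[str, ...]
    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.outputs) != 2 ** len(self.inputs):
            raise NetworkValidationError(
                f"truth table over {self.inputs} needs "
                f"{2 ** len(self.inputs)} rows, got {len(self.outputs)}"
            )
        if any(v not in (0, 1) for v in self.outputs):
            raise NetworkValidationError("truth table entries must be 0 or 1")
        if len(set(self.inputs)) != len(self.inputs):
            raise NetworkValidationError("duplicate truth table inputs")

    def __call__(self, values: Mapping[str, int] | Sequence[int]) -> int:
        if isinstance(values, Mapping):
            bits = [int(bool(values[name])) for name in self.inputs]
        else:
            bits = [int(bool(v)) for v in values]
        idx = sum(b << i for i, b in enumerate(bits))
        return self.outputs[idx]

    def rename_input(self, old: str, new: str) -> "TruthTable":
        if old not in self.inputs:
            raise NetworkValidationError(f"{old!r} is not an input of this rule")
        return TruthTable(
            tuple(new if n == old else n for n in self.inputs), self.outputs
        )

    def fix_input(self, name: str, value: int) -> "TruthTable":
        """Marginalise the table by pinning one input to a Boolean value."""
        if name not in self.inputs:
            raise NetworkValidationError(f"{name!r} is not an input of this rule")
        pos = self.inputs.index(name)
        rest = tuple(n for n in self.inputs if n != name)
        out = []
        for combo in itertools.product((0, 1), repeat=len(rest)):
            bits = list(combo[:pos]) + [value] + list(combo[pos:])
            idx = sum(b << i for i, b in enumerate(bits))
            out.append(self.outputs[idx])
        return TruthTable(rest, tuple(out))

    def monotonicity(self, name: str) -> int:
        """+1 if non-decreasing in ``name``, -1 if non-increasing, 0 if mixed.

        A constant dependence reports +1 (vacuously non-decreasing).
        """
        pos = self.inputs.index(name)
        inc = dec = False
        for combo in itertools.product((0, 1), repeat=len(self.inputs) - 1):
            bits0 = list(combo[:pos]) + [0] + list(combo[pos:])
            bits1 = list(combo[:pos]) + [1] + list(combo[pos:])
            lo = self.outputs[sum(b << i for i, b in enumerate(bits0))]
            hi = self.outputs[sum(b << i for i, b in enumerate(bits1))]
            if hi > lo:
                inc = True
            elif hi < lo:
                dec = True
        if inc and dec:
            return 0
        return -1 if dec else 1


def default_table(activators: Sequence[str], inhibitors: Sequence[str]) -> TruthTable:
    """Canonical rule for a signed edge list: (OR of activators) AND NOT (OR of inhibitors).

    A node with inhibitors only is active when none of them is.
    """
    inputs = tuple(activators) + tuple(inhibitors)
    n_act = len(activators)
    out = []
    for idx in range(2 ** len(inputs)):
        bits = [(idx >> i) & 1 for i in range(len(inputs))]
        act = any(bits[:n_act]) if n_act else True
        inh = any(bits[n_act:])
        out.append(int(act and not inh))
    return TruthTable(inputs, tuple(out))


@dataclass(frozen=True)
class NodeSpec:
    """A network node: name, Boolean rule and continuous-dynamics parameters.

    Parameters
    ----------
    rule:
        Truth table for BooleCube/HillCube interpolation; may be ``None`` for
        SQDS networks (where the rule is carried by the signed connection
        weights) and for input nodes.
    h:
        SQDS sigmoid gain (dimensionless).
    gamma:
        SQDS first-order decay rate (1/time).
    hill_n, hill_k:
        Hill exponent and threshold for HillCube inputs.
    tau:
        Time constant of the BooleCube/HillCube relaxation.
    constant:
        Clamped nodes never change value (zero derivative regardless of the
        input-node convention).  Node splits create such surrogates.
    """

    name: str
    rule: TruthTable | None = None
    h: float = 10.0
    gamma: float = 1.0
    hill_n: float = 3.0
    hill_k: float = 0.5
    tau: float = 1.0
    constant: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkValidationError("node name must be non-empty")
        if self.h <= 0 or self.gamma <= 0 or self.tau <= 0:
            raise NetworkValidationError(f"node {self.name}: h, gamma, tau must be > 0")
        if self.hill_n < 1 or not (0 < self.hill_k < 1):
            raise NetworkValidationError(
                f"node {self.name}: need hill_n >= 1 and 0 < hill_k < 1"
            )


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A validated regulatory network.

    Use :func:`build_network` to construct one; the constructor itself
    performs full validation so invalid networks cannot circulate.
    """

    nodes: tuple[NodeSpec, ...]
    connections: tuple[Connection, ...]
    interpolation: str = "sqds"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "connections", tuple(self.connections))
        _validate(self)

    # -- structural queries -------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def node(self, name: str) -> NodeSpec:
        try:
            return next(n for n in self.nodes if n.name == name)
        except StopIteration:
            raise NetworkValidationError(f"unknown node {name!r}") from None

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def incoming(self, name: str) -> tuple[Connection, ...]:
        return tuple(c for c in self.connections if c.target == name)

    def outgoing(self, name: str) -> tuple[Connection, ...]:
        return tuple(c for c in self.connections if c.source == name)

    def connection(self, source: str, target: str) -> Connection:
        for c in self.connections:
            if c.source == source and c.target == target:
                return c
        raise NetworkValidationError(f"no connection {source}->{target}")

    def in_degree(self, name: str) -> int:
        return len(self.incoming(name))

    def out_degree(self, name: str) -> int:
        return len(self.outgoing(name))

    def is_input(self, name: str) -> bool:
        """Input nodes have no incoming connections; they hold their value."""
        return self.in_degree(name) == 0

    @property
    def density(self) -> float:
        return len(self.connections) / len(self.nodes)

    # -- derived views ------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(name=self.name, interpolation=self.interpolation)
        for n in self.nodes:
            g.add_node(n.name)
        for c in self.connections:
            g.add_edge(c.source, c.target, sign=c.sign, weight=c.weight)
        return g


def _validate(net: RegulatoryNetwork) -> None:
    if net.interpolation not in INTERPOLATIONS:
        raise NetworkValidationError(
            f"interpolation must be one of {INTERPOLATIONS}, got {net.interpolation!r}"
        )
    names = [n.name for n in net.nodes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise NetworkValidationError(f"duplicate node names: {dupes}")
    name_set = set(names)
    seen_pairs: set[tuple[str, str]] = set()
    for c in net.connections:
        if c.source not in name_set:
            raise NetworkValidationError(f"connection source {c.source!r} not a node")
        if c.target not in name_set:
            raise NetworkValidationError(f"connection target {c.target!r} not a node")
        pair = (c.source, c.target)
        if pair in seen_pairs:
            raise NetworkValidationError(f"duplicate connection {c.source}->{c.target}")
        seen_pairs.add(pair)
    if net.interpolation in ("boolecube", "hillcube"):
        for n in net.nodes:
            sources = {c.source for c in net.incoming(n.name)}
            if not sources:
                if n.rule is not None and n.rule.inputs:
                    raise NetworkValidationError(
                        f"node {n.name}: rule lists inputs {n.rule.inputs} but "
                        "has no incoming connections"
                    )
                continue  # input node (or 0-ary constant rule)
            if n.rule is None:
                raise NetworkValidationError(
                    f"node {n.name}: {net.interpolation} networks need a truth "
                    "table for every regulated node"
                )
            if set(n.rule.inputs) != sources:
                raise NetworkValidationError(
                    f"node {n.name}: rule inputs {sorted(n.rule.inputs)} do not "
                    f"match incoming connections {sorted(sources)}"
                )


def build_network(
    node_specs: Iterable[NodeSpec | str],
    connections: Iterable[Connection | tuple],
    interpolation: str = "sqds",
    name: str = "",
) -> RegulatoryNetwork:
    """Assemble and validate a regulatory network.

    ``node_specs`` may mix :class:`NodeSpec` objects and bare names (which get
    default parameters).  ``connections`` may mix :class:`Connection` objects
    and ``(source, target, sign[, weight])`` tuples.  For BooleCube/HillCube
    networks, regulated nodes without an explicit rule receive the default
    "(OR of activators) AND NOT (OR of inhibitors)" table.
    """
    specs = [n if isinstance(n, NodeSpec) else NodeSpec(str(n)) for n in node_specs]
    conns = [c if isinstance(c, Connection) else Connection(*c) for c in connections]
    if interpolation in ("boolecube", "hillcube"):
        filled = []
        for n in specs:
            incoming = [c for c in conns if c.target == n.name]
            if incoming and n.rule is None:
                acts = [c.source for c in incoming if c.activating]
                inhs = [c.source for c in incoming if not c.activating]
                n = replace(n, rule=default_table(acts, inhs))
            filled.append(n)
        specs = filled
    return RegulatoryNetwork(tuple(specs), tuple(conns), interpolation, name)


def _unique_name(base: str, taken: Iterable[str]) -> str:
    taken = set(taken)
    if base not in taken:
        return base
    i = 2
    while f"{base}{i}" in taken:
        i += 1
    return f"{base}{i}"


def delete_connection(
    net: RegulatoryNetwork, source: str, target: str
) -> RegulatoryNetwork:
    """Null-mutate one interaction.

    Truth-table rules are marginalised with the lost input pinned at Boolean 0
    (the signal never arrives); SQDS rules simply lose the weight.  A node
    whose last incoming connection is deleted becomes an input node and holds
    its value.
    """
    net.connection(source, target)  # raises if missing
    conns = tuple(
        c for c in net.connections if not (c.source == source and c.target == target)
    )
    nodes = []
    for n in net.nodes:
        if n.name == target and n.rule is not None and source in n.rule.inputs:
            n = replace(n, rule=n.rule.fix_input(source, 0))
        nodes.append(n)
    return RegulatoryNetwork(tuple(nodes), conns, net.interpolation, net.name)


def delete_outgoing(net: RegulatoryNetwork, node: str) -> RegulatoryNetwork:
    """Delete every connection originating in ``node`` (self-loop included)."""
    net.node(node)
    out = net.outgoing(node)
    for c in out:
        net = delete_connection(net, c.source, c.target)
    return net


def split_connection_input(
    net: RegulatoryNetwork, source: str, target: str
) -> tuple[RegulatoryNetwork, str]:
    """Segregate the input of one connection into a new constant node.

    The new node has no incoming connections (zero derivative — it holds
    whatever value it is initialised with) and becomes the source of the
    chosen connection with the original sign and weight.  The original source
    keeps its dynamics and all its other outgoing connections.  Node count
    rises by one; connection count is unchanged.
    """
    old = net.connection(source, target)
    split_name = _unique_name(f"{source}__split", net.node_names)
    src_spec = net.node(source)
    split_spec = NodeSpec(
        split_name,
        rule=None,
        h=src_spec.h,
        gamma=src_spec.gamma,
        hill_n=src_spec.hill_n,
        hill_k=src_spec.hill_k,
        tau=src_spec.tau,
        constant=True,
    )
    conns = tuple(
        replace(c, source=split_name)
        if (c.source == source and c.target == target)
        else c
        for c in net.connections
    )
    nodes = []
    for n in net.nodes:
        if n.name == target and n.rule is not None and source in n.rule.inputs:
            # the rule now listens to the split node in place of the source
            n = replace(n, rule=n.rule.rename_input(source, split_name))
        nodes.append(n)
    nodes.append(split_spec)
    new = RegulatoryNetwork(tuple(nodes), conns, net.interpolation, net.name)
    del old
    return new, split_name


def split_node_outputs(
    net: RegulatoryNetwork, node: str, include_self_loop: bool = True
) -> tuple[RegulatoryNetwork, str]:
    """Replace ``node`` as the source of ALL its outgoing connections by one
    shared constant node.

    The self-loop, if any, is rerouted through the surrogate as well — the
    exact structural analogue of ``delete_outgoing``, so the dynamic
    centrality of a node is commensurable with its total centrality.  With
    ``include_self_loop=False`` the self-loop stays attached to the node,
    isolating the node's relay role from its state-holding role.
    """
    net.node(node)
    out = [
        c
        for c in net.outgoing(node)
        if include_self_loop or c.target != node
    ]
    if not net.outgoing(node):
        raise NetworkValidationError(f"node {node!r} has no outgoing connections")
    split_name = _unique_name(f"{node}__split", net.node_names)
    spec = net.node(node)
    split_spec = NodeSpec(
        split_name,
        rule=None,
        h=spec.h,
        gamma=spec.gamma,
        hill_n=spec.hill_n,
        hill_k=spec.hill_k,
        tau=spec.tau,
        constant=True,
    )
    rerouted = {(c.source, c.target) for c in out}
    conns = tuple(
        replace(c, source=split_name)
        if (c.source, c.target) in rerouted
        else c
        for c in net.connections
    )
    targets = {c.target for c in out}
    nodes = []
    for n in net.nodes:
        if n.name in targets and n.rule is not None and node in n.rule.inputs:
            n = replace(n, rule=n.rule.rename_input(node, split_name))
        nodes.append(n)
    nodes.append(split_spec)
    return RegulatoryNetwork(tuple(nodes), conns, net.interpolation, net.name), split_name


def add_input_loops(net: RegulatoryNetwork, weight: float = 1.0) -> RegulatoryNetwork:
    """Give every input node an activating self-loop so it can hold a state
    dynamically rather than by fiat.  Regulated nodes are untouched."""
    inputs = [n.name for n in net.nodes if net.is_input(n.name)]
    if not inputs:
        return net
    conns = list(net.connections)
    nodes = []
    for n in net.nodes:
        if n.name in inputs:
            conns.append(Connection(n.name, n.name, ACTIVATING, weight))
            if net.interpolation in ("boolecube", "hillcube"):
                n = replace(n, rule=TruthTable((n.name,), (0, 1)))  # identity
        nodes.append(n)
    return RegulatoryNetwork(tuple(nodes), tuple(conns), net.interpolation, net.name)


def structural_hash(net: RegulatoryNetwork) -> int:
    """Order-insensitive hash of the full network content (for no-mutation checks)."""
    node_part = frozenset(
        (n.name, n.rule.inputs if n.rule else None, n.rule.outputs if n.rule else None,
         n.h, n.gamma, n.hill_n, n.hill_k, n.tau, n.constant)
        for n in net.nodes
    )
    conn_part = frozenset(
        (c.source, c.target, c.sign, c.weight) for c in net.connections
    )
    return hash((node_part, conn_part, net.interpolation))


__all__ = [
    "ACTIVATING",
    "INHIBITING",
    "Connection",
    "TruthTable",
    "NodeSpec",
    "RegulatoryNetwork",
    "NetworkValidationError",
    "build_network",
    "default_table",
    "delete_connection",
    "delete_outgoing",
    "split_connection_input",
    "split_node_outputs",
    "add_input_loops",
    "structural_hash",
]
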