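"""Readers and writers for regulatory-network files.

Two on-disk formats are supported:

* A BoolNet-style text dialect (``targets, factors`` header, one Boolean
  expression per node with ``&``, ``|``, ``!`` and parentheses).  Per-node
  dynamics parameters, edge signs/weights, the interpolation tag and input
  nodes are carried in structured ``#!`` comment lines, so standard BoolNet
  consumers can still read the files while a round-trip through this module
  preserves the full network.
* GraphML (via networkx), with signed edges (``sign`` attribute, "+" or
  "-") and node/graph attributes for the dynamics parameters.

Readers validate rather than repair: structural errors raise
:class:`ParseError`; only a missing edge sign is defaulted (to activating,
with a warning).
"""

from __future__ import annotations

import ast
import io
import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .network import (
    ACTIVATING,
    INHIBITING,
    Connection,
    NodeSpec,
    RegulatoryNetwork,
    TruthTable,
    build_network,
)

_PARAM_DEFAULTS = {"h": 10.0, "gamma": 1.0, "hill_n": 3.0, "hill_k": 0.5, "tau": 1.0}


class ParseError(ValueError):
    """Raised on malformed network documents (includes a line number)."""


@dataclass
class NetworkDocument:
    """A parsed document: the network plus provenance and warnings."""

    network: RegulatoryNetwork
    format: str
    source: str = "<string>"
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Boolean expression handling
# ---------------------------------------------------------------------------

def _expression_to_python(expr: str) -> str:
    return expr.replace("!", " not ").replace("&", " and ").replace("|", " or ").strip()


_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.Name,
    ast.Load,
    ast.Constant,
)


def _parse_expression(expr: str, lineno: int) -> tuple[ast.Expression, tuple[str, ...]]:
    try:
        tree = ast.parse(_expression_to_python(expr), mode="eval")
    except SyntaxError as exc:
        raise ParseError(f"line {lineno}: cannot parse rule {expr!r}: {exc}") from None
    names: list[str] = []
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ParseError(
                f"line {lineno}: non-Boolean construct {type(node).__name__} in {expr!r}"
            )
        if isinstance(node, ast.Constant) and node.value not in (0, 1, True, False):
            raise ParseError(f"line {lineno}: constant {node.value!r} is not Boolean")
        if isinstance(node, ast.Name) and node.id not in names:
            names.append(node.id)
    return tree, tuple(names)


def _compile_table(expr: str, lineno: int) -> TruthTable:
    tree, names = _parse_expression(expr, lineno)
    code = compile(tree, "<rule>", "eval")
    out = []
    for combo in itertools.product((0, 1), repeat=len(names)):
        env = dict(zip(names, combo))
        out.append(int(bool(eval(code, {"__builtins__": {}}, env))))
    # table index convention: first input = least significant bit
    table = [0] * len(out)
    for idx, combo in enumerate(itertools.product((0, 1), repeat=len(names))):
        pos = sum(b << i for i, b in enumerate(combo))
        table[pos] = out[idx]
    return TruthTable(names, tuple(table))


def _table_to_expression(rule: TruthTable) -> str:
    """Full disjunctive normal form of a truth table (deterministic output)."""
    if not rule.inputs:
        return str(rule.outputs[0])
    terms = []
    for idx, val in enumerate(rule.outputs):
        if not val:
            continue
        bits = [(idx >> i) & 1 for i in range(len(rule.inputs))]
        lits = [
            name if bit else f"!{name}"
            for name, bit in zip(rule.inputs, bits)
        ]
        terms.append("(" + " & ".join(lits) + ")")
    if not terms:
        return "0"
    return " | ".join(terms)


# ---------------------------------------------------------------------------
# BoolNet-style dialect
# ---------------------------------------------------------------------------

def read_bnet(text: str, source: str = "<string>") -> RegulatoryNetwork:
    """Parse a BoolNet-style document into a validated network."""
    return read_bnet_document(text, source).network


def read_bnet_document(text: str, source: str = "<string>") -> NetworkDocument:
    interpolation = "boolecube"
    name = ""
    inputs_declared: set[str] = set()
    node_params: dict[str, dict[str, float]] = {}
    edge_meta: dict[tuple[str, str], dict] = {}
    rules: dict[str, tuple[str, int]] = {}
    order: list[str] = []
    warns: list[str] = []
    header_seen = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            _parse_directive(
                line[2:].strip(), lineno, node_params, edge_meta, inputs_declared
            )
            directive = line[2:].strip()
            if directive.startswith("interpolation:"):
                interpolation = directive.split(":", 1)[1].strip()
            elif directive.startswith("name:"):
                name = directive.split(":", 1)[1].strip()
            continue
        if line.startswith("#"):
            continue
        if not header_seen and line.lower().replace(" ", "") in (
            "targets,factors",
            "targets,functions",
        ):
            header_seen = True
            continue
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'target, factors'")
        target, expr = (part.strip() for part in line.split(",", 1))
        if not target.isidentifier():
            raise ParseError(f"line {lineno}: invalid node name {target!r}")
        if target in rules:
            raise ParseError(f"line {lineno}: duplicate rule for {target!r}")
        rules[target] = (expr, lineno)
        order.append(target)

    if not rules:
        raise ParseError("document contains no rules")

    tables: dict[str, TruthTable | None] = {}
    regulators: dict[str, tuple[str, ...]] = {}
    for target in order:
        expr, lineno = rules[target]
        is_input = target in inputs_declared or (
            expr == target and (target, target) not in edge_meta
        )
        if is_input:
            # a node listed as its own sole factor is an input node,
            # unless an edge directive marks a genuine self-loop
            if expr not in (target, "0"):
                raise ParseError(
                    f"line {lineno}: input node {target!r} cannot have factors"
                )
            tables[target] = None
            regulators[target] = ()
            continue
        table = _compile_table(expr, lineno)
        tables[target] = table
        regulators[target] = table.inputs

    known = set(order)
    for target, regs in regulators.items():
        for reg in regs:
            if reg not in known:
                raise ParseError(f"rule for {target!r} references unknown node {reg!r}")

    connections = []
    for target in order:
        for reg in regulators[target]:
            meta = edge_meta.get((reg, target), {})
            sign = meta.get("sign")
            if sign is None:
                mono = tables[target].monotonicity(reg)
                if mono == 0:
                    warns.append(
                        f"rule for {target!r} is non-monotone in {reg!r}; "
                        "edge recorded as activating"
                    )
                    sign = ACTIVATING
                else:
                    sign = ACTIVATING if mono > 0 else INHIBITING
            connections.append(
                Connection(reg, target, sign, float(meta.get("weight", 1.0)))
            )

    specs = []
    for node in order:
        params = {**_PARAM_DEFAULTS, **node_params.get(node, {})}
        specs.append(
            NodeSpec(
                node,
                rule=None if interpolation == "sqds" else tables[node],
                h=params["h"],
                gamma=params["gamma"],
                hill_n=params["hill_n"],
                hill_k=params["hill_k"],
                tau=params["tau"],
            )
        )
    net = build_network(specs, connections, interpolation=interpolation, name=name)
    for w in warns:
        warnings.warn(w, stacklevel=3)
    return NetworkDocument(net, "bnet", source, warns)


def _parse_directive(directive, lineno, node_params, edge_meta, inputs_declared):
    if directive.startswith("node "):
        body = directive[5:]
        if ":" not in body:
            raise ParseError(f"line {lineno}: malformed node directive")
        node, rest = (s.strip() for s in body.split(":", 1))
        params = {}
        for item in rest.split():
            if "=" not in item:
                raise ParseError(f"line {lineno}: malformed parameter {item!r}")
            key, val = item.split("=", 1)
            if key not in _PARAM_DEFAULTS:
                raise ParseError(f"line {lineno}: unknown parameter {key!r}")
            params[key] = float(val)
        node_params[node] = params
    elif directive.startswith("edge "):
        body = directive[5:]
        if ":" not in body or "->" not in body:
            raise ParseError(f"line {lineno}: malformed edge directive")
        pair, rest = (s.strip() for s in body.split(":", 1))
        src, dst = (s.strip() for s in pair.split("->", 1))
        meta = {}
        for item in rest.split():
            key, val = item.split("=", 1)
            if key == "sign":
                meta["sign"] = ACTIVATING if val == "+" else INHIBITING
            elif key == "weight":
                meta["weight"] = float(val)
            else:
                raise ParseError(f"line {lineno}: unknown edge attribute {key!r}")
        edge_meta[(src, dst)] = meta
    elif directive.startswith("inputs:"):
        for node in directive.split(":", 1)[1].replace(",", " ").split():
            inputs_declared.add(node)


def write_bnet(net: RegulatoryNetwork) -> str:
    """Serialise a network to the BoolNet-style dialect (nodes alphabetical)."""
    out = io.StringIO()
    out.write(f"#! interpolation: {net.interpolation}\n")
    if net.name:
        out.write(f"#! name: {net.name}\n")
    input_nodes = sorted(
        n.name for n in net.nodes if net.is_input(n.name) and n.rule is None
    )
    if input_nodes:
        out.write(f"#! inputs: {', '.join(input_nodes)}\n")
    for spec in sorted(net.nodes, key=lambda s: s.name):
        tweaks = {
            key: getattr(spec, key)
            for key, default in _PARAM_DEFAULTS.items()
            if getattr(spec, key) != default
        }
        if tweaks:
            body = " ".join(f"{k}={v:g}" for k, v in sorted(tweaks.items()))
            out.write(f"#! node {spec.name}: {body}\n")
    for conn in sorted(net.connections, key=lambda c: (c.source, c.target)):
        out.write(
            f"#! edge {conn.source}->{conn.target}: sign={conn.sign} "
            f"weight={conn.weight:g}\n"
        )
    out.write("targets, factors\n")
    for spec in sorted(net.nodes, key=lambda s: s.name):
        incoming = net.incoming(spec.name)
        if not incoming and spec.rule is None:
            out.write(f"{spec.name}, {spec.name}\n")
        elif spec.rule is not None:
            out.write(f"{spec.name}, {_table_to_expression(spec.rule)}\n")
        else:
            # SQDS node: canonical table from signs, for BoolNet consumers
            acts = sorted(c.source for c in incoming if c.activating)
            inhs = sorted(c.source for c in incoming if not c.activating)
            parts = []
            if acts:
                parts.append("(" + " | ".join(acts) + ")")
            if inhs:
                parts.append("!(" + " | ".join(inhs) + ")")
            out.write(f"{spec.name}, {' & '.join(parts)}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def read_graphml(text: str, source: str = "<string>") -> RegulatoryNetwork:
    """Parse GraphML with signed edges into a validated network.

    Edges without a ``sign`` attribute default to activating (warning).
    """
    try:
        g = nx.read_graphml(io.StringIO(text))
    except Exception as exc:
        raise ParseError(f"malformed GraphML: {exc}") from None
    if not g.is_directed():
        raise ParseError("GraphML graph must be directed")
    interpolation = g.graph.get("interpolation", "sqds")
    specs = []
    for node, data in g.nodes(data=True):
        rule = None
        if data.get("rule"):
            rule = _compile_table(data["rule"], 0)
        specs.append(
            NodeSpec(
                str(node),
                rule=rule,
                h=float(data.get("h", _PARAM_DEFAULTS["h"])),
                gamma=float(data.get("gamma", _PARAM_DEFAULTS["gamma"])),
                hill_n=float(data.get("hill_n", _PARAM_DEFAULTS["hill_n"])),
                hill_k=float(data.get("hill_k", _PARAM_DEFAULTS["hill_k"])),
                tau=float(data.get("tau", _PARAM_DEFAULTS["tau"])),
            )
        )
    conns = []
    for src, dst, data in g.edges(data=True):
        sign = data.get("sign")
        if sign is None:
            warnings.warn(
                f"edge {src}->{dst} has no sign attribute; assuming activating",
                stacklevel=2,
            )
            sign = ACTIVATING
        conns.append(
            Connection(str(src), str(dst), sign, float(data.get("weight", 1.0)))
        )
    return build_network(
        specs, conns, interpolation=interpolation, name=g.graph.get("name", "")
    )


def write_graphml(net: RegulatoryNetwork) -> str:
    """Serialise to GraphML, preserving signs, weights, rules and parameters."""
    g = nx.DiGraph(interpolation=net.interpolation)
    if net.name:
        g.graph["name"] = net.name
    for spec in net.nodes:
        attrs = {
            key: getattr(spec, key)
            for key, default in _PARAM_DEFAULTS.items()
            if getattr(spec, key) != default
        }
        if spec.rule is not None:
            attrs["rule"] = _table_to_expression(spec.rule)
        g.add_node(spec.name, **attrs)
    for c in net.connections:
        g.add_edge(c.source, c.target, sign=c.sign, weight=c.weight)
    return "\n".join(nx.generate_graphml(g)) + "\n"


__all__ = [
    "NetworkDocument",
    "ParseError",
    "read_bnet",
    "read_bnet_document",
    "read_graphml",
    "write_bnet",
    "write_graphml",
]
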