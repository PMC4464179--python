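"""Small didactic networks used throughout the docs and tests.

``mutual_inhibition`` is the classic bistable two-node toggle switch;
``toy_network`` is a six-node SQDS motif combining an upstream input, a
self-amplifying relay with a three-node feedback cycle, and a linear output
pathway — the standard showcase for separating total, value and dynamic
control centrality.
"""

from __future__ import annotations

from .network import (
    ACTIVATING,
    INHIBITING,
    Connection,
    NodeSpec,
    RegulatoryNetwork,
    build_network,
)


def mutual_inhibition(
    interpolation: str = "hillcube",
    w_ab: float = 1.0,
    w_ba: float = 1.0,
) -> RegulatoryNetwork:
    """Two mutually inhibiting nodes A and B (a bistable toggle switch).

    Defaults to the switch-like HillCube interpolation: the plain multilinear
    toggle is degenerate (every state with A + B = 1 is a fixed point), while
    the sigmoidal variants resolve it into the two corner attractors.
    ``w_ba`` scales the strength of the B -| A inhibition (meaningful under
    SQDS); doubling it enlarges the basin of the (A=0, B=1) attractor.
    """
    return build_network(
        ["A", "B"],
        [
            Connection("A", "B", INHIBITING, w_ab),
            Connection("B", "A", INHIBITING, w_ba),
        ],
        interpolation=interpolation,
        name="toggle",
    )


def toy_network(
    interpolation: str = "sqds",
    with_input_loop: bool = False,
) -> RegulatoryNetwork:
    """Six-node control-centrality showcase (SQDS, unit weights).

    Topology: input A activates the relay hub B; B amplifies itself, feeds
    the cycle B -> C -| D -> B and drives the output pathway B -> E -> F.
    C inhibits D, so the cycle is a positive (double-relay) feedback loop
    through which B sustains its own activity; E merely relays B to the
    sink F.  With ``with_input_loop`` the input A additionally receives an
    activating self-loop, letting it hold a state instead of being a silent
    input.
    """
    conns = [
        Connection("A", "B", ACTIVATING),
        Connection("B", "B", ACTIVATING),
        Connection("B", "C", ACTIVATING),
        Connection("C", "D", INHIBITING),
        Connection("D", "B", ACTIVATING),
        Connection("B", "E", ACTIVATING),
        Connection("E", "F", ACTIVATING),
    ]
    if with_input_loop:
        conns.append(Connection("A", "A", ACTIVATING))
    return build_network(
        list("ABCDEF"), conns, interpolation=interpolation, name="toy6"
    )


__all__ = ["mutual_inhibition", "toy_network"]
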