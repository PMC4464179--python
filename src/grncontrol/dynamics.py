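"""Continuous dynamics of Boolean regulatory networks and convergence.

Three interpolation families embed a Boolean network in the unit hypercube:

* **BooleCube** — the multilinear interpolation
  ``B~(x) = sum_v B(v) * prod_i [x_i v_i + (1-x_i)(1-v_i)]`` over the Boolean
  vertices ``v``; dynamics ``dx/dt = (B~(x) - x) / tau``.
* **HillCube** — BooleCube applied to Hill-transformed inputs
  ``x^n / (x^n + k^n)``; the *normalised* variant rescales each Hill term by
  its value at ``x = 1`` so the Boolean vertices remain fixed points of the
  interpolation.
* **SQDS** — the standardised qualitative dynamical system: a steep
  exponential sigmoid of a standardised weighted activator/inhibitor
  combination ``omega`` with first-order decay,
  ``dx/dt = f_h(omega) - gamma * x``, where
  ``f_h(w) = (-exp(h/2) + exp(-h(w - 1/2))) / ((1 - exp(h/2)) (1 + exp(-h(w - 1/2))))``.
  ``f_h(1/2) = 1/2`` for every gain ``h`` and ``f_h`` maps [0,1] into [0,1].

Nodes without incoming connections are *input nodes*.  Three conventions
for them are supported via ``SimulationSettings.input_behavior``:

* ``"zero"`` (default) — a bare input node delivers no signal: its value is
  pinned at 0 throughout.  The network's *intrinsic* behaviour, free of
  external stimuli, is what is simulated; an activating self-loop is what
  turns an input into a node that can receive and hold a state.
* ``"decay"`` — an input node receives no production drive (``omega = 0``
  under SQDS, an empty rule under the cube interpolations), so its initial
  value acts as a transient stimulus that relaxes to zero.
* ``"hold"`` — an input node has derivative zero and keeps its initial
  value forever (a clamped external condition).

Constant surrogate nodes created by node splits have zero derivative under
either convention.

Integration is fixed-step classical Runge-Kutta with clamping to [0,1]
after every step, applied to whole batches of initial states at once; a
state counts as converged when the derivative max-norm stays below
``conv_eps`` for ``conv_window`` consecutive steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import _fastpath
from .network import NodeSpec, RegulatoryNetwork, TruthTable


@dataclass(frozen=True)
class SimulationSettings:
    """Integrator, convergence and Monte-Carlo settings.

    dt:
        Runge-Kutta step (time units).
    t_max:
        Hard cap on simulated time.
    conv_eps:
        Convergence threshold on the derivative max-norm.
    conv_window:
        Number of consecutive sub-threshold steps required.
    mc_samples:
        Initial vectors per Monte-Carlo state-space integral.
    seed:
        Seed for all random draws.
    dc_grid:
        Points in the coarse neutral-value grid for dynamic centrality.
    dc_tol:
        Bracket width at which the neutral-value search stops.
    input_behavior:
        ``"zero"`` (input nodes are pinned at 0: no external stimulus),
        ``"decay"`` (initial values are transient stimuli that relax away)
        or ``"hold"`` (input nodes keep their initial value).
    relax_dt, relax_after:
        Optional step-size ramp: after ``relax_after`` time units the
        integrator switches from ``dt`` to the coarser ``relax_dt``.  The
        early transient (where basins of attraction are decided) keeps the
        fine step; the asymptotic relaxation and limit-cycle averaging use
        the coarse one.  Disabled when ``relax_dt`` is None.
    """

    dt: float = 0.1
    t_max: float = 1000.0
    conv_eps: float = 1e-6
    conv_window: int = 10
    mc_samples: int = 1000
    seed: int = 0
    dc_grid: int = 11
    dc_tol: float = 1e-4
    input_behavior: str = "zero"
    relax_dt: float | None = None
    relax_after: float = 30.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= 0 or self.conv_eps <= 0:
            raise ValueError("dt, t_max and conv_eps must be positive")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.dc_grid < 3:
            raise ValueError("dc_grid must be >= 3")
        if self.input_behavior not in ("zero", "decay", "hold"):
            raise ValueError("input_behavior must be 'zero', 'decay' or 'hold'")
        if self.relax_dt is not None and self.relax_dt <= 0:
            raise ValueError("relax_dt must be positive when set")

    def phases(self) -> tuple[tuple[float, int], tuple[float, int]]:
        """Step plan ((dt1, n1), (dt2, n2)); n2 = 0 when the ramp is off."""
        if self.relax_dt is None or self.relax_after >= self.t_max:
            return (self.dt, int(np.ceil(self.t_max / self.dt))), (self.dt, 0)
        n1 = int(np.ceil(self.relax_after / self.dt))
        n2 = int(np.ceil((self.t_max - self.relax_after) / self.relax_dt))
        return (self.dt, n1), (self.relax_dt, n2)

    def with_(self, **kw) -> "SimulationSettings":
        return replace(self, **kw)


@dataclass(frozen=True)
class Trajectory:
    """Recorded integration run: times, states, and convergence status."""

    times: np.ndarray  # (T,)
    states: np.ndarray  # (T, n)
    converged: bool
    node_names: tuple[str, ...]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


# ---------------------------------------------------------------------------
# interpolation primitives (scalar / single-state forms)
# ---------------------------------------------------------------------------

def boolecube(rule: TruthTable, input_values: Sequence[float]) -> float:
    """Multilinear interpolation of a truth table at a point of [0,1]^k."""
    x = np.asarray(input_values, dtype=float)
    if x.shape != (len(rule.inputs),):
        raise ValueError(
            f"rule over {len(rule.inputs)} inputs evaluated with {x.shape} values"
        )
    out = np.asarray(rule.outputs, dtype=float)
    acc = np.zeros(())
    for idx in range(out.size):
        bits = (idx >> np.arange(x.size)) & 1
        acc = acc + out[idx] * np.prod(np.where(bits, x, 1.0 - x))
    return float(acc)


def hill(x: np.ndarray, n: float, k: float, normalised: bool = True) -> np.ndarray:
    """Hill function ``x^n / (x^n + k^n)``, optionally rescaled to hit 1 at x=1."""
    x = np.asarray(x, dtype=float)
    val = x**n / (x**n + k**n)
    if normalised:
        val = val * (1.0 + k**n)
    return val


def hillcube(
    rule: TruthTable,
    input_values: Sequence[float],
    hill_n: float = 3.0,
    hill_k: float = 0.5,
    normalised: bool = True,
) -> float:
    """BooleCube composed with Hill-transformed inputs (switch-like response)."""
    x = hill(np.asarray(input_values, dtype=float), hill_n, hill_k, normalised)
    return boolecube(rule, np.clip(x, 0.0, 1.0))


def sqds_sigmoid(omega: np.ndarray, h: float) -> np.ndarray:
    """The SQDS activation ``f_h``; fixes 1/2 at omega = 1/2, monotone on [0,1]."""
    e = np.exp(-h * (np.asarray(omega, dtype=float) - 0.5))
    return (-np.exp(0.5 * h) + e) / ((1.0 - np.exp(0.5 * h)) * (1.0 + e))


def sqds_omega(
    act_sum: np.ndarray,
    act_total: float,
    inh_sum: np.ndarray,
    inh_total: float,
) -> np.ndarray:
    """Standardised activator/inhibitor combination in [0,1].

    ``act_sum`` is the weighted sum of current activator values, ``act_total``
    the corresponding sum of weights (similarly for inhibitors).  The
    standardisation makes omega hit 1 (0) exactly when all activators
    (inhibitors) are fully on and the opposite side fully off.
    """
    if act_total > 0:
        wa = ((1.0 + act_total) / act_total) * (act_sum / (1.0 + act_sum))
    else:
        wa = None
    if inh_total > 0:
        wb = ((1.0 + inh_total) / inh_total) * (inh_sum / (1.0 + inh_sum))
    else:
        wb = None
    if wa is None and wb is None:
        raise ValueError("sqds_omega needs at least one regulator")
    if wb is None:
        return wa
    if wa is None:
        return 1.0 - wb
    return wa * (1.0 - wb)


def sqds_derivative(
    node: NodeSpec,
    incoming: Sequence[tuple[float, float, str]],
    x_current: float,
) -> float:
    """SQDS derivative of one node.

    ``incoming`` lists ``(value, weight, sign)`` triples for the node's
    regulators; an empty list marks an input node (derivative 0).
    """
    if not incoming:
        return 0.0
    act = [(v, w) for v, w, s in incoming if s == "+"]
    inh = [(v, w) for v, w, s in incoming if s != "+"]
    act_sum = sum(v * w for v, w in act)
    inh_sum = sum(v * w for v, w in inh)
    omega = sqds_omega(
        act_sum, sum(w for _, w in act), inh_sum, sum(w for _, w in inh)
    )
    return float(sqds_sigmoid(omega, node.h) - node.gamma * x_current)


# ---------------------------------------------------------------------------
# compiled batch evaluator
# ---------------------------------------------------------------------------

class CompiledNetwork:
    """Array-form of a network for fast batched derivative evaluation.

    States are (S, n) matrices (S samples, n nodes, column order =
    ``network.node_names``).  Input-node columns always have derivative 0.
    """

    def __init__(self, net: RegulatoryNetwork, input_behavior: str = "zero"):
        if input_behavior not in ("zero", "decay", "hold"):
            raise ValueError("input_behavior must be 'zero', 'decay' or 'hold'")
        self.network = net
        self.input_behavior = input_behavior
        names = net.node_names
        self.names = names
        self.index = {name: i for i, name in enumerate(names)}
        n = len(names)
        self.n = n
        in_deg = np.array([net.in_degree(name) for name in names])
        self.const_mask = np.array([sp.constant for sp in net.nodes])
        # pure input nodes: no regulators, no residual rule, not clamped
        self.input_mask = (in_deg == 0) & ~self.const_mask & np.array(
            [sp.rule is None for sp in net.nodes]
        )
        # zero-derivative columns: clamped constants, plus inputs unless
        # they decay ("zero" pins them at 0, "hold" at their initial value)
        if input_behavior in ("hold", "zero"):
            self.frozen_mask = self.const_mask | self.input_mask
        else:
            self.frozen_mask = self.const_mask.copy()
        self.kind = net.interpolation

        if net.interpolation == "sqds":
            wa = np.zeros((n, n))
            wb = np.zeros((n, n))
            for c in net.connections:
                j, i = self.index[c.source], self.index[c.target]
                if c.activating:
                    wa[j, i] += c.weight
                else:
                    wb[j, i] += c.weight
            self.wa, self.wb = wa, wb
            self.ta = wa.sum(axis=0)  # total activator weight per node
            self.tb = wb.sum(axis=0)
            self.h = np.array([sp.h for sp in net.nodes])
            self.gamma = np.array([sp.gamma for sp in net.nodes])
            self.eh = np.exp(0.5 * self.h)
            self.has_act = self.ta > 0
            self.has_inh = self.tb > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                self.ca = np.where(self.has_act, (1.0 + self.ta) / np.where(self.ta > 0, self.ta, 1.0), 0.0)
                self.cb = np.where(self.has_inh, (1.0 + self.tb) / np.where(self.tb > 0, self.tb, 1.0), 0.0)
            case = np.full(n, 4, dtype=np.int64)
            case[self.has_act & self.has_inh] = 1
            case[self.has_act & ~self.has_inh] = 2
            case[~self.has_act & self.has_inh] = 3
            case[self.frozen_mask] = 0
            self.case = case
            # CSR-style regulator lists for the compiled per-row kernel
            aptr, aidx, aval = [0], [], []
            bptr, bidx, bval = [0], [], []
            for i in range(n):
                src = np.nonzero(wa[:, i])[0]
                aidx.extend(src)
                aval.extend(wa[src, i])
                aptr.append(len(aidx))
                src = np.nonzero(wb[:, i])[0]
                bidx.extend(src)
                bval.extend(wb[src, i])
                bptr.append(len(bidx))
            self.aptr = np.asarray(aptr, dtype=np.int64)
            self.aidx = np.asarray(aidx, dtype=np.int64)
            self.aval = np.asarray(aval, dtype=float)
            self.bptr = np.asarray(bptr, dtype=np.int64)
            self.bidx = np.asarray(bidx, dtype=np.int64)
            self.bval = np.asarray(bval, dtype=float)
        else:
            # per ruled node: input index array and float table (0-ary = constant drive)
            self.tables: list[tuple[int, np.ndarray, np.ndarray]] = []
            for i, sp in enumerate(net.nodes):
                if sp.rule is None or self.const_mask[i]:
                    continue
                idx = np.array([self.index[s] for s in sp.rule.inputs], dtype=int)
                self.tables.append((i, idx, np.asarray(sp.rule.outputs, dtype=float)))
            self.tau = np.array([sp.tau for sp in net.nodes])
            self.hill_n = np.array([sp.hill_n for sp in net.nodes])
            self.hill_k = np.array([sp.hill_k for sp in net.nodes])

    # -- derivative ---------------------------------------------------------
    def derivative(self, x: np.ndarray) -> np.ndarray:
        """Batched derivative field; ``x`` is (S, n), result is (S, n)."""
        if self.kind == "sqds":
            return self._derivative_sqds(x)
        return self._derivative_cube(x)

    def _derivative_sqds(self, x: np.ndarray) -> np.ndarray:
        sa = x @ self.wa
        sb = x @ self.wb
        wa = self.ca * sa / (1.0 + sa)
        wb = self.cb * sb / (1.0 + sb)
        # regulator-free nodes: omega = 0 (no production signal) => f = 0
        omega = np.where(
            self.has_act & self.has_inh,
            wa * (1.0 - wb),
            np.where(self.has_act, wa, np.where(self.has_inh, 1.0 - wb, 0.0)),
        )
        e = np.exp(-self.h * (omega - 0.5))
        f = (-self.eh + e) / ((1.0 - self.eh) * (1.0 + e))
        d = f - self.gamma * x
        d[:, self.frozen_mask] = 0.0
        return d

    def _derivative_cube(self, x: np.ndarray) -> np.ndarray:
        if self.input_behavior == "decay":
            # input nodes relax to zero; ruled nodes overwritten below
            d = -x / self.tau
            d[:, self.frozen_mask] = 0.0
        else:
            d = np.zeros_like(x)  # inputs frozen (at 0 or held)
        hillmode = self.kind == "hillcube"
        for entry in self.tables:
            i, idx, table = entry
            xi = x[:, idx]
            if hillmode:
                n, k = self.hill_n[i], self.hill_k[i]
                xi = np.clip(xi**n / (xi**n + k**n) * (1.0 + k**n), 0.0, 1.0)
            b = np.zeros(x.shape[0])
            for v in range(table.size):
                if table[v] == 0.0:
                    continue
                bits = (v >> np.arange(idx.size)) & 1
                b += np.prod(np.where(bits, xi, 1.0 - xi), axis=1)
            d[:, i] = (b - x[:, i]) / self.tau[i]
        return d

    # -- integration --------------------------------------------------------
    def integrate(
        self,
        x0: np.ndarray,
        settings: SimulationSettings,
        record: bool = False,
    ):
        """Integrate a batch of initial states to steady state.

        Returns ``(final, converged, trajectory)`` where ``final`` is (S, n),
        ``converged`` a boolean (S,) array, and ``trajectory`` the recorded
        (T, S, n) array when ``record`` is set (else ``None``).

        Samples that fail to converge by ``t_max`` are continued for a further
        10% of ``t_max`` and report the time-average over that tail — the
        natural steady descriptor of a limit cycle.
        """
        x = np.array(x0, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        if x.shape[1] != self.n:
            raise ValueError(f"state has {x.shape[1]} entries, network has {self.n}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite initial state")
        np.clip(x, 0.0, 1.0, out=x)
        if self.input_behavior == "zero":
            x[:, self.input_mask] = 0.0

        (dt1, n1), (dt2, n2) = settings.phases()
        tail_steps = max(1, int(np.ceil(0.1 * settings.t_max / dt2)))
        if self.kind == "sqds" and not record and _fastpath.HAVE_NUMBA:
            x = np.ascontiguousarray(x)
            conv = _fastpath.integrate_sqds(
                x,
                self.aptr,
                self.aidx,
                self.aval,
                self.bptr,
                self.bidx,
                self.bval,
                self.ca,
                self.cb,
                self.case,
                self.h,
                self.eh,
                self.gamma,
                dt1,
                n1,
                dt2,
                n2,
                settings.conv_eps,
                settings.conv_window,
                tail_steps,
            )
            if not np.all(np.isfinite(x)):
                raise FloatingPointError("non-finite state during integration")
            if squeeze:
                return x[0], bool(conv[0]), None
            return x, conv, None

        s = x.shape[0]
        frozen = np.zeros(s, dtype=bool)
        streak = np.zeros(s, dtype=int)
        traj = [x.copy()] if record else None
        times = [0.0] if record else None

        active_idx = np.arange(s)
        t_now = 0.0
        for dt, n_steps in ((dt1, n1), (dt2, n2)):
            for _step in range(n_steps):
                if active_idx.size == 0:
                    break
                xa = x[active_idx]
                k1 = self.derivative(xa)
                # convergence bookkeeping on the pre-step derivative
                small = np.max(np.abs(k1), axis=1) < settings.conv_eps
                streak[active_idx] = np.where(small, streak[active_idx] + 1, 0)
                newly = streak[active_idx] >= settings.conv_window
                if np.any(newly):
                    frozen[active_idx[newly]] = True
                    keep = ~newly
                    active_idx = active_idx[keep]
                    if active_idx.size == 0:
                        break
                    xa = xa[keep]
                    k1 = k1[keep]
                k2 = self.derivative(xa + 0.5 * dt * k1)
                k3 = self.derivative(xa + 0.5 * dt * k2)
                k4 = self.derivative(xa + dt * k3)
                xa = xa + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                np.clip(xa, 0.0, 1.0, out=xa)
                if not np.all(np.isfinite(xa)):
                    raise FloatingPointError(
                        f"non-finite state during integration at t={t_now:.3f}"
                    )
                x[active_idx] = xa
                t_now += dt
                if record:
                    times.append(t_now)
                    traj.append(x.copy())

        if active_idx.size:
            # limit cycle / slow mode: average over a 10% tail
            acc = np.zeros((active_idx.size, self.n))
            xa = x[active_idx]
            for _ in range(tail_steps):
                k1 = self.derivative(xa)
                k2 = self.derivative(xa + 0.5 * dt2 * k1)
                k3 = self.derivative(xa + 0.5 * dt2 * k2)
                k4 = self.derivative(xa + dt2 * k3)
                xa = xa + (dt2 / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                np.clip(xa, 0.0, 1.0, out=xa)
                acc += xa
            x[active_idx] = acc / tail_steps

        converged = frozen if not squeeze else bool(frozen[0])
        trajectory = None
        if record:
            trajectory = (np.array(times), np.stack(traj))
        return (x[0] if squeeze else x), converged, trajectory


def compile_network(
    net: RegulatoryNetwork, input_behavior: str = "zero"
) -> CompiledNetwork:
    return CompiledNetwork(net, input_behavior)


def derivative_field(
    net: RegulatoryNetwork | CompiledNetwork,
    state: Sequence[float] | Mapping[str, float],
    input_behavior: str = "zero",
) -> np.ndarray:
    """Derivative of every node at one state (vector ordered as the nodes)."""
    comp = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net, input_behavior)
    if isinstance(state, Mapping):
        x = np.array([state[name] for name in comp.names], dtype=float)
    else:
        x = np.asarray(state, dtype=float)
    return comp.derivative(x[None, :])[0]


def simulate(
    net: RegulatoryNetwork | CompiledNetwork,
    v0: Sequence[float] | Mapping[str, float],
    settings: SimulationSettings = SimulationSettings(),
) -> Trajectory:
    """Integrate one initial state, recording the whole trajectory."""
    comp = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net, settings.input_behavior)
    if isinstance(v0, Mapping):
        v0 = [v0[name] for name in comp.names]
    x0 = np.asarray(v0, dtype=float)
    final, conv, (times, states) = comp.integrate(x0, settings, record=True)
    states = states[:, 0, :]
    if not conv:
        states = np.vstack([states, final[None, :]])
        times = np.append(times, times[-1] + settings.dt)
    return Trajectory(times, states, bool(conv), comp.names)


def converge(
    net: RegulatoryNetwork | CompiledNetwork,
    v0,
    settings: SimulationSettings = SimulationSettings(),
) -> np.ndarray:
    """Steady state reached from ``v0`` (tail-average if a limit cycle)."""
    comp = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net, settings.input_behavior)
    if isinstance(v0, Mapping):
        v0 = [v0[name] for name in comp.names]
    x0 = np.asarray(v0, dtype=float)
    final, _conv, _ = comp.integrate(x0, settings, record=False)
    return final


def converge_batch(
    net: RegulatoryNetwork | CompiledNetwork,
    v0: np.ndarray,
    settings: SimulationSettings = SimulationSettings(),
) -> tuple[np.ndarray, np.ndarray]:
    """Steady states for a whole (S, n) batch of initial vectors."""
    comp = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net, settings.input_behavior)
    final, conv, _ = comp.integrate(np.asarray(v0, dtype=float), settings, record=False)
    return final, conv


__all__ = [
    "SimulationSettings",
    "Trajectory",
    "CompiledNetwork",
    "compile_network",
    "boolecube",
    "hill",
    "hillcube",
    "sqds_sigmoid",
    "sqds_omega",
    "sqds_derivative",
    "derivative_field",
    "simulate",
    "converge",
    "converge_batch",
]
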