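"""Scripted quantitative experiments: toy-network centralities, random-network
surveys, concentration and decomposition analyses.

Every experiment is a pure function of its parameters and seed: rerunning
with the same arguments reproduces the tables bit for bit.  Ensemble means
are reported with standard errors; statistical tests (Pearson p-values,
t-tests) are included for completeness but are descriptive only.

The default ensemble simulation settings are scaled for desk-size runs:
200 Monte-Carlo initial vectors per centrality, a 60-time-unit horizon
with a step-size ramp (dt 0.1 for the first 10 time units, 0.5 after), a
7-point neutral-value grid and a search tolerance of 0.02.  The methods notes discuss what
these sizes do and do not resolve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import gini, min_nodes_for_share, node_centralities
from .dynamics import SimulationSettings
from .examples import toy_network
from .network import RegulatoryNetwork, Connection
from .random_networks import EnsembleSpec, generate_ensemble


def ensemble_settings(seed: int = 0, mc_samples: int = 200) -> SimulationSettings:
    """Scaled-down simulation settings used for random-network surveys."""
    return SimulationSettings(
        mc_samples=mc_samples,
        seed=seed,
        t_max=60.0,
        relax_dt=0.5,
        relax_after=10.0,
        dc_grid=7,
        dc_tol=2e-2,
    )


@dataclass
class ExperimentResult:
    """Named experiment output: parameters, tidy tables and summary scalars."""

    name: str
    parameters: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "parameters": self.parameters,
            "summary": self.summary,
            "tables": {k: json.loads(v.to_json(orient="split")) for k, v in self.tables.items()},
        }
        return json.dumps(payload, indent=2, default=float)

    def write(self, prefix: str) -> None:
        with open(f"{prefix}.json", "w") as fh:
            fh.write(self.to_json())
        for key, table in self.tables.items():
            table.to_csv(f"{prefix}_{key}.tsv", sep="\t")


# ---------------------------------------------------------------------------
# ensemble survey core
# ---------------------------------------------------------------------------

def survey_ensemble(
    spec: EnsembleSpec,
    settings: SimulationSettings | None = None,
    kinds: Sequence[str] = ("TC", "VC", "DC"),
    progress: bool = False,
) -> pd.DataFrame:
    """Per-node centralities and degrees for every network of an ensemble.

    Returns a tidy frame with one row per (network, node): centralities,
    in/out-degree, self-loop flag and the network id.
    """
    settings = settings or ensemble_settings(seed=spec.seed)
    rows = []
    for i, net in enumerate(generate_ensemble(spec)):
        per_net = settings.with_(seed=(settings.seed * 100003 + i) % 2**31)
        table = node_centralities(net, per_net, kinds=kinds)
        table = table.assign(
            network=net.name,
            out_degree=[net.out_degree(n) for n in table.index],
            in_degree=[net.in_degree(n) for n in table.index],
            has_loop=[
                any(c.source == n and c.target == n for c in net.connections)
                for n in table.index
            ],
            density=net.density,
        )
        rows.append(table)
        if progress:
            print(f"  network {i + 1}/{spec.n_networks} done", flush=True)
    frame = pd.concat(rows)
    frame.index.name = "node"
    return frame.reset_index()


def network_aggregates(node_table: pd.DataFrame) -> pd.DataFrame:
    """Per-network controllability, vulnerability, RC, Ginis and min-k."""
    def agg(group: pd.DataFrame) -> pd.Series:
        out = {}
        if "VC" in group:
            out["controllability"] = group["VC"].mean()
            out["gini_vc"] = gini(group["VC"])
            out["min_k_half_vc"] = min_nodes_for_share(group["VC"], 0.5)
        if "TC" in group:
            out["vulnerability"] = group["TC"].mean()
            out["gini_tc"] = gini(group["TC"])
        if "DC" in group:
            out["gini_dc"] = gini(group["DC"])
        if "TC" in group and "VC" in group:
            v = out["vulnerability"]
            out["relative_controllability"] = (
                out["controllability"] / v if v > 0 else np.nan
            )
        return pd.Series(out)

    return node_table.groupby("network", sort=True).apply(agg, include_groups=False)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def reproduce_toy(
    settings: SimulationSettings | None = None,
) -> ExperimentResult:
    """All node centralities of the six-node showcase network.

    The hub B carries by far the highest total centrality; the relay E a
    modest one; the sink F exactly zero.  The silent input A has zero value
    and dynamic centrality: every influence it could exert would need an
    external stimulus.
    """
    settings = settings or SimulationSettings(
        mc_samples=1000, seed=1, t_max=150.0, relax_dt=0.5, relax_after=30.0
    )
    net = toy_network()
    table = node_centralities(net, settings)
    return ExperimentResult(
        name="toy_centralities",
        parameters={"network": net.name, "mc_samples": settings.mc_samples,
                    "seed": settings.seed},
        tables={"nodes": table},
        summary={
            "TC_B": table.loc["B", "TC"],
            "TC_E": table.loc["E", "TC"],
            "TC_F": table.loc["F", "TC"],
            "VC_B": table.loc["B", "VC"],
            "VC_E": table.loc["E", "VC"],
            "DC_A": table.loc["A", "DC"],
            "DC_B": table.loc["B", "DC"],
        },
    )


def density_sweep(
    spec: EnsembleSpec,
    densities: Iterable[float] = (1.0, 1.5, 2.5, 3.5, 5.0),
    settings: SimulationSettings | None = None,
) -> ExperimentResult:
    """Mean relative controllability as a function of network density.

    Sparse networks (density 2-3) are the easiest to steer per unit of
    mutational vulnerability; the sweep reports the argmax density.
    """
    densities = list(densities)
    if len(densities) < 1:
        raise ValueError("need at least one density")
    rows = []
    for d in densities:
        sub = spec.with_(density=d, seed=spec.seed + int(round(d * 1000)))
        table = survey_ensemble(sub, settings, kinds=("TC", "VC"))
        aggs = network_aggregates(table)
        rc = aggs["relative_controllability"].dropna()
        rows.append(
            {
                "density": d,
                "mean_rc": rc.mean(),
                "se_rc": rc.std(ddof=1) / np.sqrt(len(rc)) if len(rc) > 1 else np.nan,
                "n_networks": len(rc),
            }
        )
    table = pd.DataFrame(rows).set_index("density")
    argmax = float(table["mean_rc"].idxmax())
    return ExperimentResult(
        name="density_sweep",
        parameters={"model": spec.model, "n_nodes": spec.n_nodes,
                    "n_networks": spec.n_networks, "seed": spec.seed,
                    "densities": densities},
        tables={"per_density": table},
        summary={"argmax_density": argmax,
                 "max_mean_rc": float(table["mean_rc"].max())},
    )


def loop_effect(
    spec: EnsembleSpec,
    loop_probability: float = 0.5,
    settings: SimulationSettings | None = None,
) -> ExperimentResult:
    """Effect of self-amplifying loops on controllability and centralities.

    Compares an ensemble without self-loops against one where each node
    receives an activating self-loop with the given probability, both at
    the network level (relative controllability) and node level (TC/VC/DC
    of looped vs loop-free nodes).
    """
    base = survey_ensemble(spec.with_(loop_probability=0.0), settings)
    looped = survey_ensemble(
        spec.with_(loop_probability=loop_probability, seed=spec.seed + 1), settings
    )
    agg_base = network_aggregates(base)
    agg_loop = network_aggregates(looped)
    rc0 = agg_base["relative_controllability"].dropna()
    rc1 = agg_loop["relative_controllability"].dropna()
    node_level = looped
    with_loop = node_level[node_level["has_loop"]]
    without = node_level[~node_level["has_loop"]]
    summary = {
        "mean_rc_no_loops": rc0.mean(),
        "mean_rc_with_loops": rc1.mean(),
        "se_rc_no_loops": rc0.std(ddof=1) / np.sqrt(len(rc0)),
        "se_rc_with_loops": rc1.std(ddof=1) / np.sqrt(len(rc1)),
    }
    for kind in ("TC", "VC", "DC"):
        if kind in node_level:
            a, b = with_loop[kind], without[kind]
            t, p = stats.ttest_ind(a, b, equal_var=False)
            summary[f"mean_{kind}_looped"] = a.mean()
            summary[f"mean_{kind}_loopfree"] = b.mean()
            summary[f"ttest_p_{kind}"] = p
    return ExperimentResult(
        name="loop_effect",
        parameters={"model": spec.model, "n_nodes": spec.n_nodes,
                    "n_networks": spec.n_networks,
                    "loop_probability": loop_probability, "seed": spec.seed},
        tables={"aggregates_no_loops": agg_base, "aggregates_with_loops": agg_loop},
        summary=summary,
    )


def degree_effect(
    node_table: pd.DataFrame,
) -> ExperimentResult:
    """Correlation of in-/out-degree with value and dynamic centrality.

    Outgoing connections raise both VC and DC (a node's reach); incoming
    connections feed its relay role (DC) but not the leverage of its own
    value (VC).
    """
    summary = {}
    for deg in ("out_degree", "in_degree"):
        if node_table[deg].nunique() < 2:
            summary[f"corr_{deg}_VC"] = np.nan
            summary[f"corr_{deg}_DC"] = np.nan
            summary["degenerate"] = True
            continue
        for kind in ("VC", "DC"):
            if kind in node_table:
                r, p = stats.pearsonr(node_table[deg], node_table[kind])
                summary[f"corr_{deg}_{kind}"] = r
                summary[f"p_{deg}_{kind}"] = p
    return ExperimentResult(
        name="degree_effect",
        parameters={"n_nodes_total": len(node_table)},
        tables={},
        summary=summary,
    )


def concentration_analysis(
    node_table: pd.DataFrame,
) -> ExperimentResult:
    """Gini coefficients and cumulative-share statistics of the centralities.

    Control concentrates in few driver nodes: the per-network Gini of the
    total and value centralities and the minimal number of nodes holding
    more than half of the total value centrality quantify this.
    """
    aggs = network_aggregates(node_table)
    summary = {
        "mean_gini_tc": aggs["gini_tc"].mean(),
        "se_gini_tc": aggs["gini_tc"].std(ddof=1) / np.sqrt(len(aggs)),
        "mean_gini_vc": aggs["gini_vc"].mean(),
        "se_gini_vc": aggs["gini_vc"].std(ddof=1) / np.sqrt(len(aggs)),
        "mean_min_k_half_vc": aggs["min_k_half_vc"].mean(),
        "n_networks": len(aggs),
    }
    return ExperimentResult(
        name="concentration",
        parameters={"n_networks": len(aggs)},
        tables={"aggregates": aggs},
        summary=summary,
    )


def decomposition_regression(
    node_table: pd.DataFrame,
) -> ExperimentResult:
    """Node-level regressions TC ~ DC + VC and VC ~ DC.

    The joint regression shows that dynamic and value centrality together
    account for nearly all variance in total centrality; the pairwise one
    shows how weakly the two components are associated with each other.
    """
    import statsmodels.api as sm

    data = node_table.dropna(subset=["TC", "VC", "DC"])
    x = sm.add_constant(data[["DC", "VC"]])
    fit_joint = sm.OLS(data["TC"], x).fit()
    x2 = sm.add_constant(data[["DC"]])
    fit_pair = sm.OLS(data["VC"], x2).fit()
    r, p = stats.pearsonr(data["DC"], data["VC"])
    return ExperimentResult(
        name="decomposition_regression",
        parameters={"n_nodes_total": len(data)},
        tables={},
        summary={
            "r2_tc_on_dc_vc": fit_joint.rsquared,
            "r2_vc_on_dc": fit_pair.rsquared,
            "pearson_r_vc_dc": r,
            "pearson_p_vc_dc": p,
            "coef_dc": fit_joint.params["DC"],
            "coef_vc": fit_joint.params["VC"],
        },
    )


def parameter_robustness(
    network: RegulatoryNetwork,
    perturbation_scale: float = 0.2,
    n_replicates: int = 10,
    settings: SimulationSettings | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Stability of the centrality ranking under random weight jitter.

    SQDS connection weights are multiplied by (1 + U(-scale, scale)); the
    Spearman rank correlation of node total centralities between the
    original and jittered networks measures how much of the control
    structure is encoded in topology rather than in parameters.
    """
    settings = settings or SimulationSettings(
        mc_samples=300, seed=seed, t_max=150.0, relax_dt=0.5, relax_after=30.0,
        dc_tol=1e-2,
    )
    base = node_centralities(network, settings, kinds=("TC",))["TC"]
    rng = np.random.default_rng(seed)
    rows = []
    top_node = base.idxmax()
    top_preserved = 0
    for rep in range(n_replicates):
        if perturbation_scale > 0:
            factors = {
                (c.source, c.target): 1.0 + rng.uniform(
                    -perturbation_scale, perturbation_scale
                )
                for c in network.connections
            }
            jittered = RegulatoryNetwork(
                network.nodes,
                tuple(
                    Connection(
                        c.source, c.target, c.sign,
                        c.weight * factors[(c.source, c.target)],
                    )
                    for c in network.connections
                ),
                network.interpolation,
                network.name,
            )
        else:
            jittered = network
        jit = node_centralities(jittered, settings, kinds=("TC",))["TC"]
        rho = stats.spearmanr(base, jit).statistic if base.nunique() > 1 else 1.0
        if perturbation_scale == 0:
            rho = 1.0 if np.allclose(base, jit) else rho
        rows.append({"replicate": rep, "spearman_tc": rho})
        if jit.idxmax() == top_node:
            top_preserved += 1
    table = pd.DataFrame(rows).set_index("replicate")
    return ExperimentResult(
        name="parameter_robustness",
        parameters={"scale": perturbation_scale, "n_replicates": n_replicates,
                    "seed": seed},
        tables={"replicates": table},
        summary={
            "mean_spearman_tc": float(table["spearman_tc"].mean()),
            "top_node_preserved_fraction": top_preserved / n_replicates,
        },
    )


__all__ = [
    "EnsembleSpec",
    "ExperimentResult",
    "concentration_analysis",
    "decomposition_regression",
    "degree_effect",
    "density_sweep",
    "ensemble_settings",
    "loop_effect",
    "network_aggregates",
    "parameter_robustness",
    "reproduce_toy",
    "survey_ensemble",
]
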