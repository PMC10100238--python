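"""Synthetic trees and trait tables with known ground truth.

The generator mirrors the statistical structure the analysis assumes:

* an ultrametric pure-birth (Yule) tree, depth-normalised to 1 so that
  evolutionary rates are comparable across tip counts;
* log10 body mass evolving by Brownian motion on the tree;
* log10 brain volume built as group-specific allometric intercepts and
  slopes on log10 mass, plus additive categorical/continuous effects,
  plus lambda-structured phylogenetic noise
  ``eps ~ MVN(0, sigma_true * V_lambda)``;
* categorical predictors evolving under symmetric k-state Mk models on
  the same tree, and a continuous developmental-mode score evolving by
  Brownian motion.

Every generator is a pure function of its parameters and seed, so a
scenario regenerates byte-identically. The truth record carries every
generating parameter for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import traits as traits_mod
from .pgls import lambda_transform
from .treeio import Phylogeny, PhyloCov, vcv

__all__ = [
    "SyntheticScenario",
    "simulate_tree",
    "simulate_bm",
    "simulate_mk",
    "generate_scenario",
]

#: Level sets used for the simulated categorical predictors.
DEFAULT_MK_TERMS: dict[str, tuple[str, ...]] = {
    "cooperative": traits_mod.COOPERATIVE_LEVELS,
    "social_bond": traits_mod.SOCIAL_BOND_LEVELS,
    "territoriality": traits_mod.TERRITORIALITY_LEVELS,
    "migration": traits_mod.MIGRATION_LEVELS,
    "diet6": traits_mod.DIET6_LEVELS,
    "foraging6": traits_mod.FORAGING6_LEVELS,
}


@dataclass
class SyntheticScenario:
    """Generating parameters for one synthetic dataset.

    Defaults describe a two-group allometric shift (intercept gap 0.4,
    slopes 0.55 and 0.75) with lambda-structured residual noise of SD 0.1
    on log10 brain volume and a developmental-mode coefficient of -0.02
    per score unit; categorical effects default to zero.
    """

    seed: int = 0
    n_species: int = 300
    birth_rate: float = 1.0
    group_sizes: tuple[int, ...] = (150, 150)
    intercepts: tuple[float, ...] = (-0.6, -0.2)
    slopes: tuple[float, ...] = (0.55, 0.75)
    lambda_true: float = 0.8
    sigma_true: float = 0.01  # residual variance at unit depth (log10 units^2)
    mass_mean: float = 2.0  # log10 grams, ~100 g
    mass_rate: float = 0.5
    dev_mode_rate: float = 1.0
    dev_mode_coef: float = -0.02
    mk_terms: dict = field(default_factory=lambda: dict(DEFAULT_MK_TERMS))
    mk_rates: dict = field(default_factory=dict)  # per-term; default 0.5
    effects: dict = field(default_factory=dict)  # term -> {level: offset}
    group_prefix: str = "g"

    def __post_init__(self):
        if sum(self.group_sizes) != self.n_species:
            raise ValueError("group sizes must sum to n_species")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.sigma_true < 0 or self.mass_rate < 0 or self.birth_rate <= 0:
            raise ValueError("rates must be positive")
        if not (len(self.group_sizes) == len(self.intercepts) == len(self.slopes)):
            raise ValueError("groups, intercepts and slopes must align")

    @property
    def group_names(self) -> list[str]:
        return [f"{self.group_prefix}{i + 1}" for i in range(len(self.group_sizes))]

    def mk_rate(self, term: str) -> float:
        return float(self.mk_rates.get(term, 0.5))


def simulate_tree(n: int, birth: float = 1.0, seed=None) -> Phylogeny:
    """A pure-birth ultrametric tree with ``n`` tips, depth normalised to 1.

    Lineages split at exponential waiting times with total rate
    ``k * birth`` while ``k`` lineages are extant; after the (n-1)th split
    one further waiting time stretches every pending branch to the
    present.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # active lineages as (parent_record, birth_time); records become newick
    children: list = []  # record: [child_records] or tip index
    t = 0.0
    # record = dict(start=..., end=None, kids=[])
    root = {"start": 0.0, "kids": []}
    active = []
    for _ in range(2):
        node = {"start": 0.0, "kids": []}
        root["kids"].append(node)
        active.append(node)
    k = 2
    while k < n:
        t += rng.exponential(1.0 / (k * birth))
        i = rng.integers(k)
        parent = active.pop(i)
        parent["end"] = t
        for _ in range(2):
            node = {"start": t, "kids": []}
            parent["kids"].append(node)
            active.append(node)
        k += 1
    t += rng.exponential(1.0 / (k * birth))
    depth = t
    labels = iter(f"t{i + 1}" for i in range(n))
    for node in active:
        node["end"] = depth
        node["label"] = next(labels)

    def to_newick(node) -> str:
        length = (node["end"] - node["start"]) / depth
        if node["kids"]:
            inner = ",".join(to_newick(c) for c in node["kids"])
            return f"({inner}):{length:.17g}"
        return f"{node['label']}:{length:.17g}"

    newick = "(" + ",".join(to_newick(c) for c in root["kids"]) + ");"
    return Phylogeny.from_newick(newick)


def simulate_bm(cov, rate: float, lam: float = 1.0, seed=None) -> pd.Series:
    """Draw one trait from ``MVN(0, rate * V_lambda)`` on a tree.

    ``cov`` may be a Phylogeny or a precomputed PhyloCov (reused across
    replicate draws).
    """
    if isinstance(cov, Phylogeny):
        cov = vcv(cov)
    rng = np.random.default_rng(seed)
    n = len(cov.taxa)
    if rate == 0:
        return pd.Series(np.zeros(n), index=list(cov.taxa))
    C = rate * lambda_transform(cov.V, lam)
    # tiny jitter guards exact ties in degenerate trees
    L = np.linalg.cholesky(C + 1e-12 * rate * np.eye(n))
    x = L @ rng.standard_normal(n)
    return pd.Series(x, index=list(cov.taxa))


def simulate_mk(phy: Phylogeny, levels, rate: float, seed=None) -> pd.Series:
    """Evolve a discrete character under a symmetric Mk process.

    The root state is uniform; along a branch of length ``t`` change
    events arrive at rate ``rate * (k - 1) / k`` (off-diagonal rates
    ``rate / k``), each moving to a uniformly chosen different state.
    """
    if isinstance(levels, int):
        levels = [f"s{i + 1}" for i in range(levels)]
    levels = list(levels)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 states")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    leave_rate = rate * (k - 1) / k
    states: dict = {}
    out: dict[str, str] = {}
    for node in phy.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            state = int(rng.integers(k))
            e = node.edge.length or 0.0
        else:
            state = states[parent]
            e = node.edge.length or 0.0
        n_events = rng.poisson(leave_rate * e)
        for _ in range(n_events):
            step = int(rng.integers(k - 1))
            state = (state + 1 + step) % k
        states[node] = state
        if node.is_leaf():
            out[node.taxon.label] = levels[state]
    return pd.Series([out[t] for t in phy.tips], index=list(phy.tips))


def generate_scenario(scenario: SyntheticScenario):
    """Generate ``(tree, TraitTable, truth)`` for a scenario.

    Groups are assigned as contiguous blocks of the tree's tip-traversal
    order, which makes them approximately clade-structured. The truth
    record holds the scenario parameters, the group assignment, and the
    per-species residual noise.
    """
    ss = np.random.SeedSequence(scenario.seed)
    streams = ss.spawn(4 + len(scenario.mk_terms))
    tree = simulate_tree(scenario.n_species, scenario.birth_rate, seed=streams[0])
    cov = vcv(tree)
    taxa = list(tree.tips)

    log_mass = scenario.mass_mean + simulate_bm(
        cov, scenario.mass_rate, 1.0, seed=streams[1]
    )
    dev_mode = simulate_bm(cov, scenario.dev_mode_rate, 1.0, seed=streams[2])
    eps = simulate_bm(cov, scenario.sigma_true, scenario.lambda_true, seed=streams[3])

    categories: dict[str, pd.Series] = {}
    for stream, (term, levels) in zip(streams[4:], scenario.mk_terms.items()):
        categories[term] = simulate_mk(tree, levels, scenario.mk_rate(term), seed=stream)

    groups = pd.Series(
        np.repeat(scenario.group_names, scenario.group_sizes), index=taxa
    )
    a = pd.Series(
        np.repeat(scenario.intercepts, scenario.group_sizes), index=taxa, dtype=float
    )
    b = pd.Series(
        np.repeat(scenario.slopes, scenario.group_sizes), index=taxa, dtype=float
    )

    log_brain = a + b * log_mass + scenario.dev_mode_coef * dev_mode + eps
    for term, offsets in scenario.effects.items():
        if term == "dev_mode":
            continue  # handled by dev_mode_coef
        series = categories[term]
        log_brain = log_brain + series.map(lambda lev: offsets.get(lev, 0.0)).astype(
            float
        )

    df = pd.DataFrame(
        {
            "species": taxa,
            "group": groups.values,
            "brain_volume": np.power(10.0, log_brain.values),
            "body_mass": np.power(10.0, log_mass.values),
            "dev_mode": dev_mode.values,
        }
    )
    for term, series in categories.items():
        df[term] = series.values

    truth = {
        "scenario": _scenario_dict(scenario),
        "groups": dict(zip(taxa, groups.values)),
        "log_mass": dict(zip(taxa, log_mass.values)),
        "residual_eps": dict(zip(taxa, eps.values)),
    }
    return tree, traits_mod.TraitTable(df=df), truth


def _scenario_dict(scenario: SyntheticScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["group_sizes"] = list(scenario.group_sizes)
    d["intercepts"] = list(scenario.intercepts)
    d["slopes"] = list(scenario.slopes)
    d["mk_terms"] = {k: list(v) for k, v in scenario.mk_terms.items()}
    return d


def write_scenario(scenario: SyntheticScenario, out_dir: str) -> dict[str, str]:
    """Materialise a scenario as Newick + CSV + truth JSON files."""
    import os

    from .treeio import write_newick

    os.makedirs(out_dir, exist_ok=True)
    tree, table, truth = generate_scenario(scenario)
    paths = {
        "tree": os.path.join(out_dir, "tree.nwk"),
        "traits": os.path.join(out_dir, "traits.csv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_newick(tree, paths["tree"], sig_digits=17)
    table.df.to_csv(paths["traits"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return paths
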