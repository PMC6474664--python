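"""Synthetic knowledge bases, expression sets and growth responses.

The generator emulates the statistical structure the analysis pipeline
assumes: a gene universe of ~1e4 log2-scale expression values with paired
treated/control replicates; nine angiogenic pathways whose upstream and
downstream member sets are planted with treatment-specific log2 effects; a
background fraction of off-pathway differentially expressed genes; a signed
regulator network and a partially-covering interaction graph over the same
universe; and growth rates generated as a linear map of the 18 percent-
activation features plus Gaussian noise.  Everything is a pure function of
the configuration (including its seed): identical configs give identical
data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .compendium import CompendiumProfile
from .knowledge import (
    REQUIRED_PATHWAYS,
    STRATA,
    PathwayCompendium,
    RegulatorNetwork,
    canonical_pathway,
)
from .preprocess import ExpressionSet

__all__ = [
    "DEFAULT_TREATMENTS",
    "SimulationConfig",
    "default_growth_coefficients",
    "generate_knowledge_base",
    "generate_expression_set",
    "generate_growth_response",
]

DEFAULT_TREATMENTS = (
    "PNF-1",
    "SC-3-141",
    "SC-3-143",
    "SC-3-263",
    "VEGF",
    "endostatin",
)

# Planted log2 effects per (treatment, pathway, stratum): each drug activates
# a small signature of pathway strata, echoing the study system where the
# phthalimides act through TNF-alpha/TGF-beta/NR3C1 signaling while the VEGF
# axis separates the positive and negative controls.
_DEFAULT_EFFECTS: dict[tuple[str, str, str], float] = {
    ("PNF-1", "TNF-alpha", "downstream"): 2.0,
    ("PNF-1", "TGF-beta", "downstream"): 1.8,
    ("PNF-1", "NR3C1", "downstream"): 1.5,
    ("SC-3-141", "VEGF", "downstream"): -2.0,
    ("SC-3-141", "NR3C1", "downstream"): 2.0,
    ("SC-3-141", "TNF-alpha", "downstream"): 1.8,
    ("SC-3-141", "PDGF", "downstream"): 1.2,
    ("SC-3-143", "TNF-alpha", "downstream"): 2.0,
    ("SC-3-143", "TGF-beta", "downstream"): 1.8,
    ("SC-3-143", "PDGF", "downstream"): 1.5,
    ("SC-3-263", "TNF-alpha", "downstream"): 2.2,
    ("SC-3-263", "TGF-beta", "downstream"): 1.8,
    ("SC-3-263", "NR3C1", "downstream"): 1.5,
    ("SC-3-263", "bFGF", "downstream"): 1.2,
    ("VEGF", "VEGF", "downstream"): 2.5,
    ("VEGF", "bFGF", "downstream"): 1.2,
    ("endostatin", "VEGF", "downstream"): -1.5,
}

# Growth-rate weights per unit percent activation of selected features.
_DEFAULT_GROWTH_WEIGHTS: dict[tuple[str, str], float] = {
    ("VEGF", "downstream"): 0.030,
    ("TGF-beta", "downstream"): 0.020,
    ("TNF-alpha", "downstream"): 0.020,
    ("NR3C1", "downstream"): 0.010,
}


def default_growth_coefficients(
    pathway_names: Sequence[str] = REQUIRED_PATHWAYS,
    weights: Mapping[tuple[str, str], float] = _DEFAULT_GROWTH_WEIGHTS,
) -> tuple[float, ...]:
    """Coefficient vector over the compendium feature order."""
    order = sorted(pathway_names, key=str.casefold)
    return tuple(
        float(weights.get((p, s), 0.0)) for p in order for s in STRATA
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study conditions as defaults.

    Effects and noise are on the log2 expression scale.  ``planted_effects``
    maps (treatment, pathway, stratum) to a signed log2 shift applied to
    every member gene of that stratum under that treatment.
    ``growth_coefficients`` follow the compendium feature order (pathway
    alphabetical x upstream-then-downstream).
    """

    n_genes: int = 10_000
    n_replicates: int = 12
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    pathway_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {p: (15, 30) for p in REQUIRED_PATHWAYS}
    )
    planted_effects: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    de_background_rate: float = 0.08
    noise_sd: float = 0.25
    baseline_range: tuple[float, float] = (4.0, 12.0)
    growth_coefficients: tuple[float, ...] = field(
        default_factory=default_growth_coefficients
    )
    growth_noise_sd: float = 0.05
    seed: int = 0

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1 or self.n_treatments < 1:
            raise ValueError("n_genes, n_replicates and treatments must be nonempty")
        if not 0 <= self.de_background_rate <= 1:
            raise ValueError("de_background_rate must lie in [0, 1]")
        if self.noise_sd < 0 or self.growth_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        total = sum(u + d for u, d in self.pathway_sizes.values())
        if total > self.n_genes:
            raise ValueError(
                f"pathway memberships require {total} genes but the universe "
                f"has only {self.n_genes}"
            )
        canon = {canonical_pathway(p) for p in self.pathway_sizes}
        for (treatment, pathway, stratum) in self.planted_effects:
            if treatment not in self.treatments:
                raise ValueError(f"planted effect for unknown treatment {treatment!r}")
            if canonical_pathway(pathway) not in canon:
                raise ValueError(f"planted effect for unknown pathway {pathway!r}")
            if stratum not in STRATA:
                raise ValueError(f"planted effect for unknown stratum {stratum!r}")
        n_features = 2 * len(self.pathway_sizes)
        if len(self.growth_coefficients) != n_features:
            raise ValueError(
                f"growth_coefficients has {len(self.growth_coefficients)} "
                f"entries; expected {n_features}"
            )

    @property
    def gene_universe(self) -> list[str]:
        width = max(5, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def _rng(seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible stream per (seed, purpose) pair."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_knowledge_base(
    config: SimulationConfig,
) -> tuple[PathwayCompendium, RegulatorNetwork, nx.Graph]:
    """Sample a compendium, signed regulator network, and interaction graph.

    Pathway member sets are drawn without replacement from the universe and
    are globally disjoint.  One activating regulator per pathway targets its
    downstream members (giving the regulator-inference stage a planted
    ground truth) alongside random-sign decoy regulators.  The interaction
    graph stars each pathway on its first upstream member and adds random
    background edges over ~80% of the universe, so most but not all DE genes
    are eligible focus genes.
    """
    config.validate()
    rng = _rng(config.seed, "kb")
    universe = config.gene_universe
    perm = rng.permutation(config.n_genes)

    pathways: dict[str, dict[str, set[str]]] = {}
    cursor = 0
    for name in sorted(config.pathway_sizes, key=str.casefold):
        n_up, n_down = config.pathway_sizes[name]
        upstream = {universe[i] for i in perm[cursor:cursor + n_up]}
        cursor += n_up
        downstream = {universe[i] for i in perm[cursor:cursor + n_down]}
        cursor += n_down
        pathways[name] = {"upstream": upstream, "downstream": downstream}
    compendium = PathwayCompendium.from_dict(pathways)

    edges: list[tuple[str, str, int]] = []
    for name in compendium.pathway_names:
        regulator = "UR_" + name.upper().replace("-", "")
        for target in sorted(compendium.pathways[name]["downstream"]):
            edges.append((regulator, target, 1))
    n_decoys = 15
    for i in range(n_decoys):
        regulator = f"UR_RND{i:02d}"
        targets = rng.choice(config.n_genes, size=min(20, config.n_genes), replace=False)
        signs = rng.choice([-1, 1], size=targets.size)
        for t, s in zip(targets, signs):
            edges.append((regulator, universe[t], int(s)))
    network = RegulatorNetwork.from_edges(edges)

    graph = nx.Graph()
    member_genes = sorted(compendium.all_genes)
    for name in compendium.pathway_names:
        strata = compendium.pathways[name]
        hub_pool = sorted(strata["upstream"]) or sorted(strata["downstream"])
        if not hub_pool:
            continue
        hub = hub_pool[0]
        for gene in sorted(strata["upstream"] | strata["downstream"]):
            if gene != hub:
                graph.add_edge(hub, gene)
    non_members = sorted(set(universe) - set(member_genes))
    n_background = max(0, int(round(0.8 * config.n_genes)) - len(member_genes))
    n_background = min(n_background, len(non_members))
    background = [
        non_members[i]
        for i in rng.choice(len(non_members), size=n_background, replace=False)
    ] if n_background else []
    node_pool = member_genes + sorted(background)
    n_random_edges = int(1.5 * len(node_pool))
    if len(node_pool) >= 2:
        pairs = rng.integers(0, len(node_pool), size=(n_random_edges, 2))
        for a, b in pairs:
            if a != b:
                graph.add_edge(node_pool[a], node_pool[b])
    graph.add_nodes_from(node_pool)
    return compendium, network, graph


def generate_expression_set(
    config: SimulationConfig, kb: PathwayCompendium, treatment: str
) -> ExpressionSet:
    """Simulate one treatment's paired log2 expression matrices.

    Controls are per-gene baselines plus Gaussian noise; treated replicates
    add the treatment's planted pathway effects and, for a
    ``de_background_rate`` fraction of non-member genes, an off-pathway
    effect of random sign with magnitude Uniform(1, 2) log2 units.
    """
    config.validate()
    if treatment not in config.treatments:
        raise KeyError(f"unknown treatment {treatment!r}")
    universe = config.gene_universe
    index = {g: i for i, g in enumerate(universe)}

    baseline = _rng(config.seed, "baseline").uniform(
        config.baseline_range[0], config.baseline_range[1], config.n_genes
    )
    rng = _rng(config.seed, "expr", treatment)
    shape = (config.n_genes, config.n_replicates)
    noise_control = rng.normal(0.0, config.noise_sd, shape)
    noise_treated = rng.normal(0.0, config.noise_sd, shape)

    effect = np.zeros(config.n_genes)
    for (t, pathway, stratum), value in sorted(config.planted_effects.items()):
        if t != treatment:
            continue
        for gene in kb.members(pathway, stratum):
            effect[index[gene]] += value

    member_idx = {index[g] for g in kb.all_genes}
    non_member = np.array(
        [i for i in range(config.n_genes) if i not in member_idx], dtype=int
    )
    n_bg = int(round(config.de_background_rate * non_member.size))
    if n_bg:
        chosen = non_member[rng.choice(non_member.size, size=n_bg, replace=False)]
        magnitudes = rng.uniform(1.0, 2.0, n_bg)
        signs = rng.choice([-1.0, 1.0], size=n_bg)
        effect[chosen] += magnitudes * signs

    control = baseline[:, None] + noise_control
    treated = baseline[:, None] + effect[:, None] + noise_treated
    return ExpressionSet(
        gene_ids=universe, control=control, treated=treated, treatment=treatment
    )


def generate_growth_response(
    config: SimulationConfig, profiles: Sequence[CompendiumProfile]
) -> pd.Series:
    """Growth rate per treatment: coefficients . percent-features + noise."""
    config.validate()
    coefficients = np.asarray(config.growth_coefficients, dtype=float)
    values = []
    for profile in profiles:
        percents = np.asarray(profile.percents, dtype=float)
        if percents.size != coefficients.size:
            raise ValueError(
                f"profile for {profile.treatment!r} has {percents.size} "
                f"features; growth model expects {coefficients.size}"
            )
        values.append(float(coefficients @ percents))
    noise = _rng(config.seed, "growth").normal(
        0.0, config.growth_noise_sd, len(profiles)
    )
    series = pd.Series(
        np.asarray(values) + noise,
        index=pd.Index([p.treatment for p in profiles], name="treatment"),
        name="growth_rate",
    )
    return series
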