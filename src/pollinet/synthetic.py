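"""Synthetic networks, phylogenies and study sets.

Everything the analysis consumes can be generated here with planted,
recoverable structure: heterogeneous degree distributions with tunable
nestedness, overdispersed quantitative weights on top of a rank-one
mass-action expectation, exotic labels planted on a subset of plants, and a
logistic attachment rule tying exotic links to pollinator degree and
nestedness contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nestedness import nestedness_contribution, rank_normalize
from .network_io import (
    BipartiteNetwork,
    PlantPhylogeny,
    drop_unconnected,
    phylogeny_from_string,
)

__all__ = [
    "SyntheticSpec",
    "generate_network",
    "plant_exotic_attachment",
    "generate_phylogeny",
    "generate_study_set",
]

_MAX_DRAWS = 1000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic network draw."""

    n_plants: int = 20
    n_pollinators: int = 30
    target_connectance: float = 0.15
    nestedness_strength: float = 1.0
    weight_dispersion: float = 1.0
    exotic_fraction: float = 0.0
    attachment_coeffs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    quantitative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 2 or self.n_pollinators < 2:
            raise ValueError("need at least 2 plants and 2 pollinators")
        if not 0.0 < self.target_connectance < 1.0:
            raise ValueError("target_connectance must lie in (0, 1)")
        if self.nestedness_strength < 0:
            raise ValueError("nestedness_strength must be >= 0")
        if self.weight_dispersion <= 0:
            raise ValueError("weight_dispersion must be > 0")
        if not 0.0 <= self.exotic_fraction < 1.0:
            raise ValueError("exotic_fraction must lie in [0, 1)")
        if self.target_connectance * min(self.n_plants, self.n_pollinators) < 0.5:
            raise ValueError(
                "target connectance too low for this size; expected degrees < 0.5"
            )


def _propensities(n: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Decreasing species propensities, mean 1; strength 0 = homogeneous."""
    base = ((np.arange(n) + 1.0) / n) ** (-strength)
    base = base * np.exp(rng.normal(0.0, 0.1 * strength, n))
    return base / base.mean()


def generate_network(spec: SyntheticSpec) -> BipartiteNetwork:
    """Draw a connected network under the averaged-fill cell model.

    Cell probability is the target connectance times the mean of the plant's
    and pollinator's propensity; propensity heterogeneity (hence degree
    heterogeneity and nestedness) grows with ``nestedness_strength``.  Draws
    with empty rows or columns are rejected and redrawn.  Quantitative
    weights are geometric counts (dispersion configurable) scaled by planted
    rank-one mass-action factors.
    """
    rng = np.random.default_rng(spec.seed)
    P, A = spec.n_plants, spec.n_pollinators
    for _ in range(_MAX_DRAWS):
        x = _propensities(P, spec.nestedness_strength, rng)
        y = _propensities(A, spec.nestedness_strength, rng)
        probs = np.clip(spec.target_connectance * 0.5 * (x[:, None] + y[None, :]), 0, 1)
        binary = (rng.random((P, A)) < probs).astype(float)
        if np.all(binary.sum(axis=1) > 0) and np.all(binary.sum(axis=0) > 0):
            break
    else:
        raise RuntimeError(
            "could not draw a connected network; connectance/size combination infeasible"
        )

    weights = binary
    if spec.quantitative:
        # rank-one mass-action factors; geometric counts supply overdispersion
        u = np.exp(rng.normal(0.0, 0.5, P))
        v = np.exp(rng.normal(0.0, 0.5, A))
        mean_extra = np.outer(u, v) * spec.weight_dispersion
        p_geom = 1.0 / (1.0 + mean_extra)
        weights = binary * rng.geometric(p_geom)
        weights[binary == 0] = 0.0

    plant_ids = tuple(f"plant_{i:03d}" for i in range(P))
    pollinator_ids = tuple(f"pollinator_{j:03d}" for j in range(A))
    network = BipartiteNetwork(
        plant_ids=plant_ids,
        pollinator_ids=pollinator_ids,
        weights=weights,
        quantitative=spec.quantitative,
        exotic=np.zeros(P, dtype=bool),
        network_id=f"synthetic-{spec.seed}",
    )
    if spec.exotic_fraction > 0.0:
        network = plant_exotic_attachment(
            network,
            spec.attachment_coeffs,
            spec.exotic_fraction,
            seed=int(rng.integers(2**32)),
        )
        network = drop_unconnected(network)
    return network


def plant_exotic_attachment(
    network: BipartiteNetwork,
    coeffs: tuple[float, float, float, float],
    exotic_fraction: float,
    seed: int = 0,
    contribution_reps: int = 25,
    pollinator_scores: np.ndarray | None = None,
) -> BipartiteNetwork:
    """Plant exotic labels and rewire exotic plants by the logistic rule.

    A fraction of plants is flagged exotic; each keeps its degree but its
    partners are re-sampled without replacement with selection weight
    ``logistic(alpha + beta*k_j + gamma*c_j + delta*k_j*c_j)`` over
    pollinators j, where ranked degree k and ranked nestedness contribution
    c are computed before any rewiring.  ``pollinator_scores`` can supply
    pre-computed c ranks to skip the contribution ensemble.
    """
    rng = np.random.default_rng(seed)
    n_exotic = int(round(exotic_fraction * network.n_plants))
    if n_exotic < 1:
        raise ValueError(
            f"exotic_fraction {exotic_fraction} selects no plant out of "
            f"{network.n_plants}"
        )
    alpha, beta, gamma, delta = coeffs

    k = rank_normalize(network.pollinator_degrees)
    if pollinator_scores is not None:
        c = np.asarray(pollinator_scores, dtype=float)
    elif gamma == 0.0 and delta == 0.0:
        c = np.zeros(network.n_pollinators)  # unused by the rule
    else:
        seeds = np.random.SeedSequence(seed).spawn(network.n_pollinators)
        z = [
            nestedness_contribution(
                network,
                label,
                n_reps=contribution_reps,
                rng_seed=int(child.generate_state(1)[0]),
                guild="pollinator",
            ).z
            or 0.0
            for label, child in zip(network.pollinator_ids, seeds)
        ]
        c = rank_normalize(z)

    attach = 1.0 / (1.0 + np.exp(-(alpha + beta * k + gamma * c + delta * k * c)))

    exotic_idx = rng.choice(network.n_plants, size=n_exotic, replace=False)
    exotic = np.zeros(network.n_plants, dtype=bool)
    exotic[exotic_idx] = True

    weights = network.weights.copy()
    for i in exotic_idx:
        degree = int((weights[i] > 0).sum())
        if degree > network.n_pollinators:
            raise ValueError("degree exceeds eligible pollinators")
        link_weights = weights[i][weights[i] > 0]
        partners = rng.choice(
            network.n_pollinators,
            size=degree,
            replace=False,
            p=attach / attach.sum(),
        )
        new_row = np.zeros(network.n_pollinators)
        new_row[partners] = rng.permutation(link_weights)
        weights[i] = new_row

    # rewiring may strand a pollinator; downstream metrics are defined on
    # the connected submatrix, so callers drop stranded columns themselves
    return replace(network, weights=weights, exotic=exotic)


def generate_phylogeny(
    n_taxa: int, seed: int = 0, depth: float = 100.0, labels=None
) -> PlantPhylogeny:
    """Ultrametric pure-birth (Yule) tree scaled to a fixed root-to-tip depth."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"plant_{i:03d}" for i in range(n_taxa)]
    labels = list(labels)
    if len(labels) != n_taxa:
        raise ValueError("label count must equal n_taxa")

    def new_node(start: float) -> dict:
        return {"start": start, "end": None, "children": []}

    roots = [new_node(0.0), new_node(0.0)]
    active = list(roots)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node["end"] = t
        node["children"] = [new_node(t), new_node(t)]
        active.extend(node["children"])
    total = t + rng.exponential(1.0 / len(active))
    for node in active:
        node["end"] = total
    scale = depth / total

    tips = iter(labels)

    def newick(node: dict) -> str:
        length = (node["end"] - node["start"]) * scale
        if node["children"]:
            inner = ",".join(newick(child) for child in node["children"])
            return f"({inner}):{length:.10f}"
        return f"{next(tips)}:{length:.10f}"

    text = f"({newick(roots[0])},{newick(roots[1])});"
    return phylogeny_from_string(text)


def generate_study_set(
    n_invaded: int,
    n_uninvaded: int,
    template: SyntheticSpec,
    richness_shift: float = 0.0,
    nestedness_shift: float = 0.0,
    exotic_fraction: float = 0.15,
    seed: int = 0,
) -> list[BipartiteNetwork]:
    """Generate an invaded + uninvaded collection of networks.

    Invaded networks receive exotic plants (rewired per the template's
    attachment coefficients) and optionally shifted richness (multiplicative
    ``1 + richness_shift``) and nestedness strength, so group comparisons
    have planted differences; uninvaded networks have zero exotic plants.
    Per-network sizes are jittered so richness varies within groups.
    """
    if n_invaded < 1 or n_uninvaded < 1:
        raise ValueError("need at least one network per group")
    rng = np.random.default_rng(seed)
    networks = []
    for idx in range(n_invaded + n_uninvaded):
        invaded = idx < n_invaded
        scale = (1.0 + richness_shift) if invaded else 1.0
        n_p = max(2, int(round(template.n_plants * scale * rng.uniform(0.7, 1.3))))
        n_a = max(2, int(round(template.n_pollinators * scale * rng.uniform(0.7, 1.3))))
        spec = replace(
            template,
            n_plants=n_p,
            n_pollinators=n_a,
            nestedness_strength=template.nestedness_strength
            + (nestedness_shift if invaded else 0.0),
            exotic_fraction=exotic_fraction if invaded else 0.0,
            seed=int(rng.integers(2**32)),
        )
        net = generate_network(spec)
        group = "invaded" if invaded else "uninvaded"
        networks.append(replace(net, network_id=f"{group}-{idx:03d}"))
    return networks
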