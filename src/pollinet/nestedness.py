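"""Network-level structure metrics.

Connectance family, NODF nestedness, relative nestedness against the
averaged-fill null, and per-species nestedness contribution z-scores.
Quantitative weights are binarized at weight > 0 throughout; NODF is a
binary-structure metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .network_io import BipartiteNetwork
from .null_models import build_ensemble

__all__ = [
    "NetworkMetrics",
    "NestednessContribution",
    "nodf",
    "relative_nestedness",
    "nestedness_contribution",
    "rank_normalize",
    "network_metrics",
]

DEFAULT_RELATIVE_REPS = 1000
DEFAULT_CONTRIBUTION_REPS = 100


@dataclass(frozen=True)
class NetworkMetrics:
    """One network's structural summary (connectance family + nestedness)."""

    network_id: str
    S: int
    P: int
    A: int
    R: float
    L: int
    C: float
    C_P: float
    C_A: float
    N: float
    N_star: float | None = None
    null_mean_N: float | None = None
    null_sd_N: float | None = None
    n_reps: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class NestednessContribution:
    """z-score of observed NODF against a focal-species rewiring ensemble."""

    species: str
    guild: str
    observed_N: float
    mu: float
    sigma: float
    z: float | None
    undefined: bool
    n_reps: int
    seed: int


def _nodf_matrix(binary: np.ndarray) -> float:
    """NODF of a binary matrix (no validation)."""
    b = np.asarray(binary) > 0
    n_rows, n_cols = b.shape

    def axis_sum(m: np.ndarray) -> float:
        # m: species x partners boolean; sum of paired overlap terms over
        # ordered pairs (u, v) with deg(u) > deg(v) > 0.
        deg = m.sum(axis=1)
        shared = (m.astype(int) @ m.astype(int).T).astype(float)
        decreasing = (deg[:, None] > deg[None, :]) & (deg[None, :] > 0)
        terms = 100.0 * shared / np.maximum(deg[None, :], 1)
        return float(terms[decreasing].sum())

    n_pairs = n_rows * (n_rows - 1) / 2 + n_cols * (n_cols - 1) / 2
    return (axis_sum(b) + axis_sum(b.T)) / n_pairs


def nodf(network: BipartiteNetwork | np.ndarray) -> float:
    """NODF nestedness in [0, 100].

    Overlap over decreasing-degree row pairs and column pairs: each ordered
    pair contributes 100 * |shared partners| / degree of the sparser species
    when degrees strictly decrease, 0 otherwise; the sum is divided by the
    number of row pairs plus column pairs.
    """
    binary = (
        network.binary if isinstance(network, BipartiteNetwork) else np.asarray(network)
    )
    if binary.shape[0] < 2 or binary.shape[1] < 2:
        raise ValueError("NODF requires at least 2 plants and 2 pollinators")
    return _nodf_matrix(binary)


def relative_nestedness(
    network: BipartiteNetwork,
    n_reps: int = DEFAULT_RELATIVE_REPS,
    rng_seed: int = 0,
) -> tuple[float | None, float, float]:
    """Relative nestedness ``N* = (N - mean_null N) / mean_null N``.

    The null is the averaged-fill cell model.  Returns ``(N_star, null_mean,
    null_sd)``; ``N_star`` is None when the null mean is zero.
    """
    if n_reps < 2:
        raise ValueError("relative nestedness needs n_reps >= 2")
    observed = nodf(network)
    ensemble = build_ensemble(network, "cell_model", n_reps, rng_seed)
    null_vals = np.array([_nodf_matrix(rep.binary) for rep in ensemble.replicates])
    null_mean = float(null_vals.mean())
    null_sd = float(null_vals.std(ddof=1))
    if null_mean == 0.0:
        return None, null_mean, null_sd
    return (observed - null_mean) / null_mean, null_mean, null_sd


def nestedness_contribution(
    network: BipartiteNetwork,
    species: str,
    n_reps: int = DEFAULT_CONTRIBUTION_REPS,
    rng_seed: int = 0,
    guild: str | None = None,
) -> NestednessContribution:
    """Contribution of one species to network nestedness.

    z = (observed N - mu) / sigma over an ensemble in which only the focal
    species' links are rewired under the cell model.  Positive z means the
    species' observed links raise nestedness above its random rewiring.
    """
    if n_reps < 2:
        raise ValueError("nestedness contribution needs n_reps >= 2")
    if guild is None:
        guild = "plant" if species in network.plant_ids else "pollinator"
    observed = nodf(network)
    ensemble = build_ensemble(
        network, "focal_species", n_reps, rng_seed, focal=species, focal_guild=guild
    )
    null_vals = np.array([_nodf_matrix(rep.binary) for rep in ensemble.replicates])
    mu = float(null_vals.mean())
    sigma = float(null_vals.std(ddof=1))
    undefined = sigma == 0.0
    z = None if undefined else (observed - mu) / sigma
    return NestednessContribution(
        species=species,
        guild=guild,
        observed_N=observed,
        mu=mu,
        sigma=sigma,
        z=z,
        undefined=undefined,
        n_reps=n_reps,
        seed=rng_seed if isinstance(rng_seed, int) else -1,
    )


def rank_normalize(values) -> np.ndarray:
    """Average-rank the values, then map affinely so min -> 0 and max -> 1.

    Ties share their average rank.  A constant (or single-element) vector
    maps to all 0.5 by convention.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    ranks = scipy.stats.rankdata(arr, method="average")
    lo, hi = ranks.min(), ranks.max()
    if hi == lo:
        return np.full(arr.shape, 0.5)
    return (ranks - lo) / (hi - lo)


def network_metrics(
    network: BipartiteNetwork,
    n_reps: int = DEFAULT_RELATIVE_REPS,
    rng_seed: int = 0,
    with_null: bool = True,
) -> NetworkMetrics:
    """Connectance family plus (optionally) relative nestedness."""
    P, A, L = network.n_plants, network.n_pollinators, network.n_links
    n_star = null_mean = null_sd = None
    if with_null:
        n_star, null_mean, null_sd = relative_nestedness(network, n_reps, rng_seed)
    return NetworkMetrics(
        network_id=network.network_id,
        S=P + A,
        P=P,
        A=A,
        R=A / P,
        L=L,
        C=L / (P * A),
        C_P=L / P,
        C_A=L / A,
        N=nodf(network),
        N_star=n_star,
        null_mean_N=null_mean,
        null_sd_N=null_sd,
        n_reps=n_reps if with_null else None,
        seed=rng_seed if with_null else None,
    )
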