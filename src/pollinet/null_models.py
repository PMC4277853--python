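"""Randomization schemes for bipartite networks.

Two null families are implemented:

* the probabilistic cell model, where each cell (i, j) is filled with
  probability ``p_ij = (k_i/A + k_j/P) / 2`` (row fill averaged with column
  fill) -- used for relative nestedness and nestedness contributions; and
* degree-preserving checkerboard swaps on the binary structure -- used for
  the pollinator-level contrast.

All samplers are pure functions of (input, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network_io import BipartiteNetwork, EmptyNetworkError

__all__ = [
    "CellProbabilityMatrix",
    "RandomEnsemble",
    "DegenerateNullError",
    "cell_probabilities",
    "sample_cell_model",
    "randomize_focal_species",
    "swap_randomize",
    "build_ensemble",
]

#: attempted swaps per link for burn-in and between thinned replicates
SWAP_ATTEMPTS_PER_LINK = 10

#: bounded retries when the cell model produces an empty row/column
CELL_MODEL_MAX_RETRIES = 1000


class DegenerateNullError(RuntimeError):
    """The null ensemble cannot produce a valid replicate."""


@dataclass(frozen=True)
class CellProbabilityMatrix:
    """Per-cell interaction probabilities of the averaged-fill null model."""

    probs: np.ndarray
    network_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must form a 2-D matrix within [0, 1]")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class RandomEnsemble:
    """A seeded collection of randomized replicates of one source network."""

    replicates: tuple[BipartiteNetwork, ...]
    method: str
    n_reps: int
    seed: int
    network_id: str = ""


def cell_probabilities(network: BipartiteNetwork) -> CellProbabilityMatrix:
    """Averaged-fill cell probabilities ``p_ij = (k_i/A + k_j/P) / 2``.

    The sum of all entries equals the link count L exactly.
    """
    if network.n_plants == 0 or network.n_pollinators == 0:
        raise EmptyNetworkError("cannot build cell probabilities for empty network")
    row_fill = network.plant_degrees / network.n_pollinators
    col_fill = network.pollinator_degrees / network.n_plants
    probs = 0.5 * (row_fill[:, None] + col_fill[None, :])
    return CellProbabilityMatrix(probs=probs, network_id=network.network_id)


def _binary_replicate(
    source: BipartiteNetwork, binary: np.ndarray, suffix: str
) -> BipartiteNetwork:
    return BipartiteNetwork(
        plant_ids=source.plant_ids,
        pollinator_ids=source.pollinator_ids,
        weights=binary.astype(float),
        quantitative=False,
        exotic=source.exotic,
        location=source.location,
        network_id=f"{source.network_id}{suffix}" if source.network_id else suffix,
    )


def sample_cell_model(
    probs: CellProbabilityMatrix,
    rng_seed: int | np.random.Generator,
    source: BipartiteNetwork | None = None,
    max_retries: int = CELL_MODEL_MAX_RETRIES,
) -> BipartiteNetwork | np.ndarray:
    """Draw one Bernoulli replicate of the cell model.

    Replicates with an empty row or column are rejected and redrawn, up to
    ``max_retries`` attempts.  When ``source`` is given the result is a
    :class:`BipartiteNetwork` carrying its labels; otherwise the raw binary
    matrix is returned.
    """
    rng = np.random.default_rng(rng_seed)
    p = probs.probs
    for _ in range(max_retries):
        draw = (rng.random(p.shape) < p).astype(int)
        if np.all(draw.sum(axis=1) > 0) and np.all(draw.sum(axis=0) > 0):
            if source is None:
                return draw
            return _binary_replicate(source, draw, ":cell")
    raise DegenerateNullError(
        f"cell model for network {probs.network_id!r} produced empty "
        f"rows/columns in {max_retries} consecutive draws"
    )


def _weighted_subset(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Sample k distinct indices, successively, with prob proportional to weight."""
    weights = np.asarray(weights, dtype=float)
    if k > np.count_nonzero(weights):
        # fall back: allow zero-probability partners rather than fail
        weights = np.where(weights > 0, weights, np.min(weights[weights > 0]) * 1e-9)
    chosen = rng.choice(
        len(weights), size=k, replace=False, p=weights / weights.sum()
    )
    return np.sort(chosen)


def randomize_focal_species(
    network: BipartiteNetwork,
    focal: str,
    rng_seed: int | np.random.Generator,
    guild: str | None = None,
) -> BipartiteNetwork:
    """Redraw only the focal species' links; everything else is untouched.

    The focal species keeps its degree k; its partners are re-sampled as k
    distinct species with selection probability proportional to the
    averaged-fill cell probability of the corresponding cells.

    ``guild`` may be ``"plant"`` or ``"pollinator"``; when omitted the label
    is resolved in both guilds (plants first).
    """
    rng = np.random.default_rng(rng_seed)
    probs = cell_probabilities(network).probs
    binary = network.binary.copy()

    if guild not in (None, "plant", "pollinator"):
        raise ValueError("guild must be 'plant' or 'pollinator'")
    as_plant = guild == "plant" or (guild is None and focal in network.plant_ids)
    if as_plant:
        i = network.plant_index(focal)
        k = int(binary[i].sum())
        new_row = np.zeros(network.n_pollinators, dtype=int)
        new_row[_weighted_subset(rng, probs[i], k)] = 1
        binary[i] = new_row
    else:
        j = network.pollinator_index(focal)
        k = int(binary[:, j].sum())
        new_col = np.zeros(network.n_plants, dtype=int)
        new_col[_weighted_subset(rng, probs[:, j], k)] = 1
        binary[:, j] = new_col
    return _binary_replicate(network, binary, ":focal")


def swap_checkerboards(
    binary: np.ndarray, rng: np.random.Generator, n_attempts: int
) -> int:
    """Attempt ``n_attempts`` checkerboard swaps in place; return accept count."""
    n_rows, n_cols = binary.shape
    accepted = 0
    batch = 4096
    done = 0
    while done < n_attempts:
        m = min(batch, n_attempts - done)
        rows = rng.integers(0, n_rows, size=(m, 2))
        cols = rng.integers(0, n_cols, size=(m, 2))
        for (r1, r2), (c1, c2) in zip(rows, cols):
            if r1 == r2 or c1 == c2:
                continue
            a, b = binary[r1, c1], binary[r1, c2]
            c, d = binary[r2, c1], binary[r2, c2]
            if a == d and b == c and a != b:
                binary[r1, c1] = b
                binary[r1, c2] = a
                binary[r2, c1] = d
                binary[r2, c2] = c
                accepted += 1
        done += m
    return accepted


def has_checkerboard(binary: np.ndarray) -> bool:
    """True when some 2x2 submatrix is a checkerboard (swap is possible)."""
    b = np.asarray(binary) > 0
    n_rows = b.shape[0]
    for r1 in range(n_rows):
        for r2 in range(r1 + 1, n_rows):
            only_r1 = b[r1] & ~b[r2]
            only_r2 = b[r2] & ~b[r1]
            if only_r1.any() and only_r2.any():
                return True
    return False


def swap_randomize(
    network: BipartiteNetwork,
    rng_seed: int | np.random.Generator,
    n_attempts: int | None = None,
) -> BipartiteNetwork:
    """One degree-preserving swap replicate of the binary structure.

    Performs ``n_attempts`` (default ``10 * L``) attempted 2x2 checkerboard
    swaps.  Row and column degree sequences are preserved exactly.  If the
    topology admits no checkerboard at all, the source structure is returned
    unchanged with a warning.
    """
    if network.n_plants < 2 or network.n_pollinators < 2:
        raise ValueError("swap randomization needs at least 2 rows and 2 columns")
    rng = np.random.default_rng(rng_seed)
    binary = network.binary.copy()
    if n_attempts is None:
        n_attempts = SWAP_ATTEMPTS_PER_LINK * max(network.n_links, 1)
    accepted = swap_checkerboards(binary, rng, n_attempts)
    if accepted == 0 and not has_checkerboard(binary):
        warnings.warn(
            f"network {network.network_id!r} admits no checkerboard swap; "
            "returning the source structure",
            stacklevel=2,
        )
    return _binary_replicate(network, binary, ":swap")


def build_ensemble(
    network: BipartiteNetwork,
    method: str,
    n_reps: int,
    rng_seed: int,
    focal: str | None = None,
    focal_guild: str | None = None,
    thinned_chain: bool = True,
) -> RandomEnsemble:
    """Generate ``n_reps`` replicates under one of the null schemes.

    ``method`` is one of ``cell_model``, ``focal_species`` or ``swap``.  Swap
    replicates come by default from a single thinned chain (burn-in of
    ``10 * L`` attempts, the same number between successive replicates);
    ``thinned_chain=False`` restarts an independent chain per replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = np.random.SeedSequence(rng_seed).spawn(n_reps)
    replicates: list[BipartiteNetwork] = []

    if method == "cell_model":
        probs = cell_probabilities(network)
        for child in seeds:
            replicates.append(
                sample_cell_model(probs, np.random.default_rng(child), source=network)
            )
    elif method == "focal_species":
        if focal is None:
            raise ValueError("focal_species ensemble requires a focal label")
        for child in seeds:
            replicates.append(
                randomize_focal_species(
                    network, focal, np.random.default_rng(child), guild=focal_guild
                )
            )
    elif method == "swap":
        if thinned_chain:
            if network.n_plants < 2 or network.n_pollinators < 2:
                raise ValueError(
                    "swap randomization needs at least 2 rows and 2 columns"
                )
            rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
            binary = network.binary.copy()
            step = SWAP_ATTEMPTS_PER_LINK * max(network.n_links, 1)
            if not has_checkerboard(binary):
                warnings.warn(
                    f"network {network.network_id!r} admits no checkerboard swap; "
                    "ensemble replicates equal the source structure",
                    stacklevel=2,
                )
            for _ in range(n_reps):
                swap_checkerboards(binary, rng, step)
                replicates.append(
                    _binary_replicate(network, binary.copy(), ":swap")
                )
        else:
            for child in seeds:
                replicates.append(
                    swap_randomize(network, np.random.default_rng(child))
                )
    else:
        raise ValueError(f"unknown null method: {method!r}")

    return RandomEnsemble(
        replicates=tuple(replicates),
        method=method,
        n_reps=n_reps,
        seed=rng_seed,
        network_id=network.network_id,
    )
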