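"""Quantitative interaction-level measures.

For every observed link (w > 0) in a quantitative network we compute the
mutual dependences (the share of each endpoint's total visitation carried by
the link) and the mass-action preference Gamma.  Gamma is estimated by a
least-squares additive decomposition of log weights over the observed cells,

    log w_ij = mu + a_i + b_j + log Gamma_ij,

with sum-to-zero constraints on the plant effects {a_i} and pollinator
effects {b_j}; Gamma_ij = exp(residual).  Structural zeros are excluded from
the fit, so no expectation is assigned to unobserved links, and the
geometric mean of Gamma over observed links is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_io import BipartiteNetwork

__all__ = ["InteractionRecord", "dependences", "preferences", "interaction_table"]


class QualitativeNetworkError(TypeError):
    """Interaction-level metrics require visit counts, not presence/absence."""


@dataclass
class InteractionRecord:
    """One observed plant-pollinator link with its interaction-level metrics."""

    network_id: str
    plant: str
    pollinator: str
    weight: float
    d_plant: float | None = None
    d_pollinator: float | None = None
    gamma: float | None = None
    gamma_reliable: bool = True
    plant_exotic: bool = False


def _require_quantitative(network: BipartiteNetwork, what: str) -> None:
    if not network.quantitative:
        raise QualitativeNetworkError(
            f"{what} requires a quantitative network; "
            f"{network.network_id!r} is qualitative"
        )


def dependences(network: BipartiteNetwork) -> list[InteractionRecord]:
    """Mutual dependences for every observed link.

    ``d_plant(i, j)`` is the fraction of plant i's total visits carried by
    pollinator j; ``d_pollinator(i, j)`` the fraction of pollinator j's
    visits going to plant i.  Per species, dependences sum to 1.
    """
    _require_quantitative(network, "dependence calculation")
    w = network.weights
    row_tot = w.sum(axis=1)
    col_tot = w.sum(axis=0)
    records = []
    for i, j in zip(*np.nonzero(w)):
        records.append(
            InteractionRecord(
                network_id=network.network_id,
                plant=network.plant_ids[i],
                pollinator=network.pollinator_ids[j],
                weight=float(w[i, j]),
                d_plant=float(w[i, j] / row_tot[i]),
                d_pollinator=float(w[i, j] / col_tot[j]),
                plant_exotic=bool(network.exotic[i]),
            )
        )
    return records


def _log_gamma_fit(network: BipartiteNetwork) -> np.ndarray:
    """Residuals of the constrained two-way fit on log weights (observed cells)."""
    w = network.weights
    rows, cols = np.nonzero(w)
    logw = np.log(w[rows, cols])
    n_obs = len(logw)
    P, A = w.shape
    # Sum-to-zero (Helmert-free) encoding: drop the last level, represent it
    # as -1 across the retained dummies.
    X = np.ones((n_obs, 1 + (P - 1) + (A - 1)))
    for r in range(P - 1):
        X[:, 1 + r] = (rows == r).astype(float) - (rows == P - 1).astype(float)
    for c in range(A - 1):
        X[:, P + c] = (cols == c).astype(float) - (cols == A - 1).astype(float)
    beta, *_ = np.linalg.lstsq(X, logw, rcond=None)
    return logw - X @ beta


def preferences(network: BipartiteNetwork) -> list[InteractionRecord]:
    """Mass-action preference Gamma for every observed link.

    Gamma > 1 marks an interaction occurring more often than the mass-action
    (random-encounter) expectation, Gamma < 1 less often.  Links whose plant
    or pollinator has a single observed partner are flagged unreliable: their
    residual is absorbed by the species effect.
    """
    _require_quantitative(network, "preference estimation")
    if network.n_plants < 2 or network.n_pollinators < 2:
        raise ValueError("preference estimation needs >= 2 plants and pollinators")
    w = network.weights
    resid = _log_gamma_fit(network)
    rows, cols = np.nonzero(w)
    row_deg = (w > 0).sum(axis=1)
    col_deg = (w > 0).sum(axis=0)
    records = []
    for idx, (i, j) in enumerate(zip(rows, cols)):
        records.append(
            InteractionRecord(
                network_id=network.network_id,
                plant=network.plant_ids[i],
                pollinator=network.pollinator_ids[j],
                weight=float(w[i, j]),
                gamma=float(np.exp(resid[idx])),
                gamma_reliable=bool(row_deg[i] > 1 and col_deg[j] > 1),
                plant_exotic=bool(network.exotic[i]),
            )
        )
    return records


def interaction_table(network: BipartiteNetwork) -> pd.DataFrame:
    """Dependences and preferences merged into one row per observed link."""
    dep = dependences(network)
    pref = {(r.plant, r.pollinator): r for r in preferences(network)}
    rows = []
    for r in dep:
        p = pref[(r.plant, r.pollinator)]
        rows.append(
            {
                "network_id": r.network_id,
                "plant": r.plant,
                "pollinator": r.pollinator,
                "weight": r.weight,
                "d_plant": r.d_plant,
                "d_pollinator": r.d_pollinator,
                "gamma": p.gamma,
                "gamma_reliable": p.gamma_reliable,
                "plant_exotic": r.plant_exotic,
            }
        )
    return pd.DataFrame(rows)
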