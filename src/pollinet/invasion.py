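"""Statistical surface of the invasion analysis.

Group comparisons across invaded/uninvaded networks, interaction-level
regressions, and the empirical-vs-randomized mixed-effects logistic contrast
linking a pollinator's probability of interacting with an exotic plant to its
ranked degree k and ranked nestedness contribution c:

    logit p = alpha + beta*k + gamma*c + delta*k*c (+ starred contrasts for
    randomized instances) + random intercept per network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .glmm import GLMMResult, fit_logistic_glmm
from .nestedness import nestedness_contribution, rank_normalize
from .network_io import BipartiteNetwork
from .null_models import RandomEnsemble

__all__ = [
    "GroupComparisonResult",
    "ExoticLinkModelResult",
    "kruskal_wallis",
    "exotic_prevalence_trends",
    "dependence_regression",
    "preference_regression",
    "exotic_link_indicator",
    "pollinator_species_table",
    "assemble_model_table",
    "fit_exotic_link_model",
    "relative_probability",
    "simulate_link_table",
]

MODEL_COLUMNS = ["y", "k", "c", "is_random", "network_id", "replicate"]
_COEF_NAMES = [
    "alpha",
    "beta",
    "gamma",
    "delta",
    "alpha_star",
    "beta_star",
    "gamma_star",
    "delta_star",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    property_name: str
    n_invaded: int
    n_uninvaded: int
    statistic: float
    pvalue: float


def kruskal_wallis(values, invaded_flags, property_name: str = "") -> GroupComparisonResult:
    """Kruskal-Wallis rank-sum comparison of a property across two groups."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(invaded_flags, dtype=bool)
    a, b = values[flags], values[~flags]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(values == values[0]):
        # all observations tied: no evidence of any difference
        return GroupComparisonResult(property_name, len(a), len(b), 0.0, 1.0)
    stat, p = scipy.stats.kruskal(a, b)
    return GroupComparisonResult(property_name, len(a), len(b), float(stat), float(p))


def exotic_prevalence_trends(frame: pd.DataFrame) -> pd.DataFrame:
    """Rank-correlation trends of exotic prevalence with community richness.

    ``frame`` needs columns S, P, A and n_exotic, one row per invaded
    network.  Tests (a) endemic plant richness vs the exotic count and
    (b) the exotic proportion (n_exotic / P) vs each of S, P, A; Spearman
    rho with its p-value per pair.
    """
    if len(frame) < 3:
        raise ValueError("need at least 3 invaded networks")
    out = []
    endemic = frame["P"] - frame["n_exotic"]
    proportion = frame["n_exotic"] / frame["P"]
    pairs = [("endemic_richness_vs_n_exotic", endemic, frame["n_exotic"])]
    pairs += [
        (f"exotic_proportion_vs_{col}", proportion, frame[col]) for col in ("S", "P", "A")
    ]
    for name, x, y in pairs:
        if np.all(x == x.iloc[0]) or np.all(y == y.iloc[0]):
            out.append({"pair": name, "rho": np.nan, "pvalue": np.nan, "undefined": True})
            continue
        rho, p = scipy.stats.spearmanr(x, y)
        out.append(
            {"pair": name, "rho": float(rho), "pvalue": float(p), "undefined": False}
        )
    return pd.DataFrame(out)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


def dependence_regression(records, side: str):
    """Binomial (logit) regression of dependence on the exotic indicator.

    ``side='plant'`` regresses each plant's dependence on its own exotic
    status; ``side='pollinator'`` regresses pollinator dependences on the
    partner plant's status.  Positive coefficient = higher dependence when
    the plant is exotic.  Returns (coefficient, z, p).
    """
    frame = _records_frame(records)
    col = {"plant": "d_plant", "pollinator": "d_pollinator"}[side]
    y = frame[col].to_numpy(dtype=float)
    x = frame["plant_exotic"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("both exotic and native links are required")
    if np.all(y == 1.0):
        raise ValueError("degenerate dependences: all equal to 1 (separation)")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer binomial proportions
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1])


def preference_regression(records):
    """OLS of log-preference on the exotic indicator; returns (slope, t, p)."""
    frame = _records_frame(records)
    frame = frame.dropna(subset=["gamma"])
    y = np.log(frame["gamma"].to_numpy(dtype=float))
    x = frame["plant_exotic"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("both exotic and native links are required")
    if np.allclose(y.var(), 0.0):
        return 0.0, np.nan, np.nan
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1])


def exotic_link_indicator(network: BipartiteNetwork) -> np.ndarray:
    """Per-pollinator flag: does it have >= 1 link to an exotic plant?"""
    if not network.exotic.any():
        raise ValueError(
            f"network {network.network_id!r} has no exotic plants; "
            "exclude it from the pollinator-level analysis"
        )
    return (network.weights[network.exotic, :] > 0).any(axis=0)


def pollinator_species_table(
    network: BipartiteNetwork,
    contribution_reps: int = 25,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-pollinator ranked degree k, ranked nestedness contribution c and
    the exotic-link indicator for one network instance."""
    indicator = exotic_link_indicator(network)
    k = rank_normalize(network.pollinator_degrees)
    seeds = np.random.SeedSequence(rng_seed).spawn(network.n_pollinators)
    zscores = []
    for label, child in zip(network.pollinator_ids, seeds):
        contrib = nestedness_contribution(
            network,
            label,
            n_reps=contribution_reps,
            rng_seed=int(child.generate_state(1)[0]),
            guild="pollinator",
        )
        zscores.append(contrib.z if contrib.z is not None else 0.0)
    c = rank_normalize(zscores)
    return pd.DataFrame(
        {
            "pollinator": list(network.pollinator_ids),
            "y": indicator.astype(int),
            "k": k,
            "c": c,
            "network_id": network.network_id,
        }
    )


def assemble_model_table(
    network: BipartiteNetwork,
    ensemble: RandomEnsemble,
    contribution_reps: int = 25,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Stack the empirical instance and each randomized replicate.

    One row per pollinator per instance with columns y, k, c, is_random,
    network_id and replicate (-1 for the empirical instance).  Degrees (and
    hence k) are constant across swap replicates; c is recomputed per
    replicate.
    """
    seeds = np.random.SeedSequence(rng_seed).spawn(len(ensemble.replicates) + 1)
    frames = []
    emp = pollinator_species_table(
        network, contribution_reps, int(seeds[0].generate_state(1)[0])
    )
    emp["is_random"] = 0
    emp["replicate"] = -1
    frames.append(emp)
    for r, (rep, child) in enumerate(zip(ensemble.replicates, seeds[1:])):
        rep_exotic = BipartiteNetwork(
            plant_ids=rep.plant_ids,
            pollinator_ids=rep.pollinator_ids,
            weights=rep.weights,
            quantitative=rep.quantitative,
            exotic=network.exotic,
            location=rep.location,
            network_id=network.network_id,
        )
        tab = pollinator_species_table(
            rep_exotic, contribution_reps, int(child.generate_state(1)[0])
        )
        tab["is_random"] = 1
        tab["replicate"] = r
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ExoticLinkModelResult:
    """Fitted empirical-vs-randomized exotic-attachment model."""

    estimates: dict[str, float]
    se: dict[str, float]
    zvalues: dict[str, float]
    pvalues: dict[str, float]
    sigma_network: float
    loglik: float
    converged: bool
    n_obs: int
    n_networks: int
    glmm: GLMMResult = field(repr=False)

    def coefficient_table(self) -> pd.DataFrame:
        """Summary with randomized-network rows shown as sums (a + a*, ...)."""
        est = self.estimates
        rows = []
        predictors = ["Intercept", "Degree", "Nestedness contribution", "Degree x Contribution"]
        for name, pred in zip(_COEF_NAMES[:4], predictors):
            rows.append(
                {
                    "network_type": "Empirical",
                    "predictor": pred,
                    "parameter": name,
                    "estimate": est[name],
                    "z": self.zvalues[name],
                    "p": self.pvalues[name],
                }
            )
        for base, star, pred in zip(_COEF_NAMES[:4], _COEF_NAMES[4:], predictors):
            rows.append(
                {
                    "network_type": "Random",
                    "predictor": pred,
                    "parameter": f"{base}+{star}",
                    "estimate": est[base] + est[star],
                    "z": self.zvalues[star],
                    "p": self.pvalues[star],
                }
            )
        return pd.DataFrame(rows)

    def predict_probability(self, k, c, randomized: bool = False) -> np.ndarray:
        """Predicted attachment probability at (k, c), random effect at 0."""
        k = np.asarray(k, dtype=float)
        c = np.asarray(c, dtype=float)
        e = self.estimates
        eta = e["alpha"] + e["beta"] * k + e["gamma"] * c + e["delta"] * k * c
        if randomized:
            eta = eta + (
                e["alpha_star"]
                + e["beta_star"] * k
                + e["gamma_star"] * c
                + e["delta_star"] * k * c
            )
        return 1.0 / (1.0 + np.exp(-eta))


def _model_design(table: pd.DataFrame) -> np.ndarray:
    k = table["k"].to_numpy(dtype=float)
    c = table["c"].to_numpy(dtype=float)
    r = table["is_random"].to_numpy(dtype=float)
    return np.column_stack(
        [np.ones(len(table)), k, c, k * c, r, r * k, r * c, r * k * c]
    )


def fit_exotic_link_model(table: pd.DataFrame, n_quad: int = 15) -> ExoticLinkModelResult:
    """Fit the mixed-effects logistic contrast on a stacked observation table.

    The table must hold both empirical and randomized instances from >= 2
    networks.  Complete separation is reported as a failure to converge.
    """
    missing = [col for col in MODEL_COLUMNS if col not in table.columns]
    if missing:
        raise ValueError(f"model table is missing columns: {missing}")
    if table[["k", "c"]].isna().any().any():
        raise ValueError("missing k or c for some pollinator")
    if table["is_random"].nunique() < 2:
        raise ValueError("both empirical and randomized instances are required")
    if table["network_id"].nunique() < 2:
        raise ValueError("random intercept needs >= 2 networks")
    X = _model_design(table)
    res = fit_logistic_glmm(
        X, table["y"].to_numpy(dtype=float), table["network_id"].to_numpy(), n_quad=n_quad
    )
    est = dict(zip(_COEF_NAMES, res.coef))
    return ExoticLinkModelResult(
        estimates=est,
        se=dict(zip(_COEF_NAMES, res.se)),
        zvalues=dict(zip(_COEF_NAMES, res.zvalues)),
        pvalues=dict(zip(_COEF_NAMES, res.pvalues)),
        sigma_network=res.sigma,
        loglik=res.loglik,
        converged=res.converged,
        n_obs=res.n_obs,
        n_networks=res.n_groups,
        glmm=res,
    )


def relative_probability(result: ExoticLinkModelResult, k, c) -> np.ndarray:
    """Ratio of predicted empirical to randomized attachment probability."""
    return result.predict_probability(k, c, randomized=False) / result.predict_probability(
        k, c, randomized=True
    )


def simulate_link_table(
    n_networks: int,
    n_pollinators: int,
    coeffs: tuple[float, float, float, float],
    contrasts: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    sigma_network: float = 0.5,
    n_random_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a stacked observation table directly from the logistic rule.

    Each network gets ``n_pollinators`` pollinators with k and c taken as
    rank-normalized uniform draws, a Gaussian random intercept, one
    empirical instance and ``n_random_reps`` randomized instances whose
    coefficients are shifted by ``contrasts``.
    """
    rng = np.random.default_rng(seed)
    a, b, g, d = coeffs
    rows = []
    for n in range(n_networks):
        k = rank_normalize(rng.random(n_pollinators))
        c = rank_normalize(rng.random(n_pollinators))
        intercept = rng.normal(0.0, sigma_network)
        eta_emp = a + b * k + g * c + d * k * c + intercept
        y = (rng.random(n_pollinators) < 1.0 / (1.0 + np.exp(-eta_emp))).astype(int)
        for j in range(n_pollinators):
            rows.append((y[j], k[j], c[j], 0, f"net{n}", -1))
        eta_rand = (
            (a + contrasts[0])
            + (b + contrasts[1]) * k
            + (g + contrasts[2]) * c
            + (d + contrasts[3]) * k * c
            + intercept
        )
        for rep in range(n_random_reps):
            y_r = (rng.random(n_pollinators) < 1.0 / (1.0 + np.exp(-eta_rand))).astype(int)
            for j in range(n_pollinators):
                rows.append((y_r[j], k[j], c[j], 1, f"net{n}", rep))
    return pd.DataFrame(rows, columns=MODEL_COLUMNS)
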