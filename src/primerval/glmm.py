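"""Logistic mixed-model comparison of two primer sets.

Per-sequence binary success (bound/unbound, or Working/Failed) is
modelled as

    logit P(success_ij) = intercept + effect * [improved_j] + u_species(i),
    u_s ~ Normal(0, random_sd^2),

a logistic regression with a species random intercept, so that the
primer-set effect is estimated within species rather than confounded
with uneven per-species sequence counts.  The marginal likelihood is
maximised with adaptive Gauss-Hermite quadrature (each species'
integral is centred at its Laplace mode and scaled by the local
curvature) and a quasi-Newton outer optimisation; Wald standard errors
come from the numerical Hessian at the optimum.  exp(effect) is the
odds ratio of success for the improved primer set versus the reference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .exceptions import PrimervalError, SeparationError

REFERENCE = "reference"
IMPROVED = "improved"

_P_FLOOR = 1e-16


@dataclass(frozen=True)
class GlmmFit:
    intercept: float
    effect: float
    effect_se: float
    wald_z: float
    p_value: float
    odds_ratio: float
    random_sd: float
    log_likelihood: float
    converged: bool
    n_obs: int
    n_species: int

    @property
    def p_value_text(self) -> str:
        return f"{self.p_value:.4g}" if self.p_value >= _P_FLOOR else f"< {_P_FLOOR:g}"

    def to_json(self) -> str:
        doc = asdict(self)
        doc["p_value_text"] = self.p_value_text
        return json.dumps(doc, indent=2)


def build_records(
    reference: pd.DataFrame,
    improved: pd.DataFrame,
    outcome: str = "binding",
) -> pd.DataFrame:
    """Join two per-sequence result frames into amplification records.

    ``outcome='binding'`` reads the ``pair_status`` column (success =
    bound); ``outcome='penalty'`` reads ``classification`` (success =
    Working).  Missing-class sequences are excluded.  Returns one row
    per sequence per primer set with columns sequence_id, species,
    primer_set, outcome.
    """
    if outcome == "binding":
        col, success, missing = "pair_status", "bound", "missing"
    elif outcome == "penalty":
        col, success, missing = "classification", "Working", "Missing"
    else:
        raise ValueError(f"unknown outcome source {outcome!r}")

    ids_ref = set(reference["sequence_id"])
    ids_imp = set(improved["sequence_id"])
    if not ids_ref & ids_imp:
        raise PrimervalError("primer sets were evaluated on disjoint sequence sets")

    frames = []
    for label, df in ((REFERENCE, reference), (IMPROVED, improved)):
        keep = df[df[col] != missing]
        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": keep["sequence_id"].to_numpy(),
                    "species": keep["species"].to_numpy(),
                    "primer_set": label,
                    "outcome": (keep[col] == success).astype(int).to_numpy(),
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    if records.duplicated(["sequence_id", "primer_set"]).any():
        raise PrimervalError("duplicate (sequence_id, primer_set) records")
    return records


def _check_records(records: pd.DataFrame) -> None:
    for col in ("species", "primer_set", "outcome"):
        if col not in records:
            raise PrimervalError(f"records lack column {col!r}")
    if records["species"].nunique() < 2:
        raise PrimervalError("need >= 2 species for a species random intercept")
    levels = set(records["primer_set"])
    if levels != {REFERENCE, IMPROVED}:
        raise PrimervalError(
            f"primer_set must have levels {{{REFERENCE!r}, {IMPROVED!r}}}, got {sorted(levels)}"
        )
    for level, sub in records.groupby("primer_set"):
        if sub["outcome"].nunique() < 2:
            raise SeparationError(
                f"all outcomes identical for primer_set {level!r}: the log-odds "
                "difference is unbounded (complete separation); consider an exact "
                "or penalised logistic method"
            )


def _nll_factory(y, x, cluster, n_clusters, nodes, weights):
    """Negative marginal log-likelihood via adaptive Gauss-Hermite."""
    log_w = np.log(weights) + nodes**2  # GH weights against e^{-z^2}
    sqrt2 = np.sqrt(2.0)

    def nll(theta: np.ndarray) -> float:
        b0, b1, log_sd = theta
        sd = np.exp(log_sd)
        var = sd * sd
        eta = b0 + b1 * x

        # Laplace mode per cluster (Newton on the concave integrand exponent)
        u = np.zeros(n_clusters)
        for _ in range(50):
            p = expit(eta + u[cluster])
            score = np.bincount(cluster, weights=y - p, minlength=n_clusters) - u / var
            info = np.bincount(cluster, weights=p * (1 - p), minlength=n_clusters) + 1.0 / var
            step = score / info
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        tau = 1.0 / np.sqrt(info)  # curvature scale at the mode

        # evaluate the exponent at shifted/scaled GH nodes
        # g_c(u) = sum_i loglik_i(u) - u^2/(2 var)
        points = u[:, None] + sqrt2 * tau[:, None] * nodes[None, :]  # (C, K)
        eta_k = eta[:, None] + points[cluster]  # (n_obs, K)
        ll_obs = y[:, None] * eta_k - np.logaddexp(0.0, eta_k)
        ll_clust = np.zeros((n_clusters, ll_obs.shape[1]))
        np.add.at(ll_clust, cluster, ll_obs)
        g = ll_clust - points**2 / (2.0 * var)
        # log integral per cluster: logsumexp over nodes + log(sqrt(2) tau)
        m = g.max(axis=1, keepdims=True)
        log_int = m[:, 0] + np.log(np.exp(g - m) @ np.exp(log_w)) + 0.5 * np.log(2.0) + np.log(tau)
        ll = np.sum(log_int) - n_clusters * (0.5 * np.log(2 * np.pi) + log_sd)
        return -ll

    return nll


def fit_glmm(
    records: pd.DataFrame,
    n_quadrature: int = 15,
    random_sd: float | None = None,
) -> GlmmFit:
    """Maximum-likelihood fit of the species random-intercept logistic model.

    ``random_sd`` fixes the random-effect standard deviation instead of
    estimating it (``random_sd=0`` reduces the model to ordinary
    logistic regression); by default it is profiled on the log scale.
    """
    _check_records(records)
    y = records["outcome"].to_numpy(dtype=float)
    x = (records["primer_set"] == IMPROVED).to_numpy(dtype=float)
    species, cluster = np.unique(records["species"].to_numpy(), return_inverse=True)
    n_clusters = species.size
    nodes, weights = np.polynomial.hermite.hermgauss(n_quadrature)

    nll = _nll_factory(y, x, cluster, n_clusters, nodes, weights)

    # crude logit start values from the 2x2 table
    def logit_rate(mask):
        r = (y[mask].mean() * len(y[mask]) + 0.5) / (len(y[mask]) + 1.0)
        return np.log(r / (1 - r))

    b0_0 = logit_rate(x == 0)
    b1_0 = logit_rate(x == 1) - b0_0

    if random_sd is not None:
        fixed_log_sd = np.log(max(random_sd, 1e-8))
        obj = lambda t: nll(np.array([t[0], t[1], fixed_log_sd]))
        res = minimize(obj, np.array([b0_0, b1_0]), method="L-BFGS-B")
        theta = np.array([res.x[0], res.x[1], fixed_log_sd])
    else:
        obj = nll
        res = minimize(
            obj,
            np.array([b0_0, b1_0, np.log(0.5)]),
            method="L-BFGS-B",
            bounds=[(-30, 30), (-30, 30), (-10, 5)],
        )
        theta = res.x

    hess = _numerical_hessian(obj, res.x)
    try:
        cov = np.linalg.inv(hess)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")

    effect = float(theta[1])
    z = effect / se if se > 0 else float("nan")
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return GlmmFit(
        intercept=float(theta[0]),
        effect=effect,
        effect_se=se,
        wald_z=float(z),
        p_value=p,
        odds_ratio=float(np.exp(effect)),
        random_sd=float(np.exp(theta[2])) if random_sd is None else float(random_sd),
        log_likelihood=float(-res.fun),
        converged=bool(res.success),
        n_obs=int(y.size),
        n_species=int(n_clusters),
    )


def _numerical_hessian(fun, x0: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; adequate for the 2-3 parameter fits here."""
    k = x0.size
    hess = np.empty((k, k))
    f0 = fun(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            if i == j:
                hess[i, i] = (fun(x0 + ei) - 2 * f0 + fun(x0 - ei)) / eps**2
            else:
                hess[i, j] = hess[j, i] = (
                    fun(x0 + ei + ej) - fun(x0 + ei - ej) - fun(x0 - ei + ej) + fun(x0 - ei - ej)
                ) / (4 * eps**2)
    return hess
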