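"""Bayesian model selection over mediation DAGs.

Candidate models are edge subsets of {a: X->M, b: M->Y, c: X->Y, b_rev: Y->M}
(``b`` and ``b_rev`` never coexist).  The named models are Causal = {a, b},
Independent = {a, c}, Reactive = {c, b_rev}, Complex = {a, b, c}; every other
subset is a non-mediation model.

For each model the marginal likelihood factorizes as (density of M given its
parents) x (density of Y given its parents).  Each factor is the closed-form
marginal likelihood of a Gaussian linear model on standardized variables
under a conjugate prior: per-edge effect prior N(0, phi^2 * sigma^2),
inverse-gamma(kappa/2, lambda/2) prior on sigma^2, and a flat prior on the
intercept and covariates (handled by residualizing them out, identically
across models, so Bayes factors compare edge structure only).  Posteriors use
a uniform prior over the enumerated model set.

Two option sets are supported.  ``three_choice`` enumerates exactly {Causal,
Independent, Reactive}; ``expanded`` enumerates all acyclic edge subsets
minus the Y->M models that are likelihood equivalent to an M->Y counterpart
({b_rev} alone, and the complete model {a, c, b_rev}).

For univariate X with no covariates, every marginal likelihood depends on the
data only through the sample correlations and N; :func:`select_from_correlations`
exploits this for vectorized scoring of many datasets at once.  A consequence
of the factorized form is the *weakest-correlation rule*: three-choice
selection always picks the model with no direct edge between the pair whose
estimated data correlation is weakest in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .correlation_model import CorrelationTriple, ValidationError
from .simulator import TripletDataset

__all__ = [
    "MediationModel",
    "Priors",
    "ModelPosterior",
    "enumerate_models",
    "log_marginal_likelihood",
    "select_model",
    "select_from_correlations",
    "weakest_correlation_rule",
    "DesignError",
]


class DesignError(ValueError):
    """The design matrix is rank deficient beyond the intercept redundancy."""


@dataclass(frozen=True)
class MediationModel:
    """A mediation DAG given as an edge subset."""

    edges: frozenset

    def __post_init__(self) -> None:
        bad = set(self.edges) - {"a", "b", "c", "b_rev"}
        if bad:
            raise ValidationError(f"unknown edges {bad}")
        if "b" in self.edges and "b_rev" in self.edges:
            raise ValidationError("edges b and b_rev cannot coexist (acyclicity)")

    @property
    def label(self) -> str:
        """Named model label, or 'other-nonmediation'."""
        e = self.edges
        if e == {"a", "b"}:
            return "Causal"
        if e == {"a", "c"}:
            return "Independent"
        if e == {"c", "b_rev"}:
            return "Reactive"
        if e == {"a", "b", "c"}:
            return "Complex"
        return "other-nonmediation"

    @property
    def name(self) -> str:
        """Unique short name (named label or explicit edge list)."""
        lab = self.label
        if lab != "other-nonmediation":
            return lab
        return "null" if not self.edges else "+".join(sorted(self.edges))

    @property
    def parents_m(self) -> tuple[str, ...]:
        p = []
        if "a" in self.edges:
            p.append("x")
        if "b_rev" in self.edges:
            p.append("y")
        return tuple(p)

    @property
    def parents_y(self) -> tuple[str, ...]:
        p = []
        if "c" in self.edges:
            p.append("x")
        if "b" in self.edges:
            p.append("m")
        return tuple(p)


def _mk(*edges: str) -> MediationModel:
    return MediationModel(frozenset(edges))


THREE_CHOICE = (_mk("a", "b"), _mk("a", "c"), _mk("c", "b_rev"))

# All acyclic edge subsets minus Y->M models likelihood equivalent to an
# M->Y counterpart: {b_rev} ~ {b} and {a, c, b_rev} ~ {a, b, c} (both
# complete DAGs are Markov equivalent).  {a, b_rev} (v-structure at M) and
# {c, b_rev} (Reactive) have no M->Y equivalent and are retained.
EXPANDED = (
    _mk(),
    _mk("a"),
    _mk("b"),
    _mk("c"),
    _mk("a", "b"),  # Causal
    _mk("a", "c"),  # Independent
    _mk("b", "c"),
    _mk("a", "b", "c"),  # Complex
    _mk("a", "b_rev"),
    _mk("c", "b_rev"),  # Reactive
)


def enumerate_models(option_set: str) -> tuple[MediationModel, ...]:
    """The model universe for an option set ('three_choice' or 'expanded')."""
    if option_set == "three_choice":
        return THREE_CHOICE
    if option_set == "expanded":
        return EXPANDED
    raise ValidationError("option_set must be 'three_choice' or 'expanded'")


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the conjugate effect-size and variance priors.

    ``phi_sq`` is the prior variance (relative to the residual variance) of
    each standardized edge effect; ``kappa`` and ``lam`` are the
    inverse-gamma shape/scale of the residual-variance prior.  The defaults
    are weakly informative; ``phi_sq`` is the main knob affecting
    expanded-option selection rates.
    """

    phi_sq: float = 1.0
    kappa: float = 0.001
    lam: float = 0.001

    def __post_init__(self) -> None:
        if self.phi_sq <= 0 or self.kappa <= 0 or self.lam <= 0:
            raise ValidationError("prior hyperparameters must be positive")


DEFAULT_PRIORS = Priors()


# ---------------------------------------------------------------------------
# closed-form marginal likelihoods


def _residualize(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
    return v - basis @ coef


def _standardize_columns(v: np.ndarray, label: str) -> np.ndarray:
    """Scale (already centered) columns to unit population variance."""
    v = np.atleast_2d(v.T).T if v.ndim == 1 else v
    sd = np.sqrt(np.mean(v**2, axis=0))
    if np.any(sd < 1e-12):
        raise DesignError(f"column of {label} is constant after removing intercept/covariates")
    return v / sd


def _prepare(data: TripletDataset) -> tuple[dict[str, np.ndarray], int]:
    """Residualize intercept/covariates, standardize, return blocks and dof.

    Returns ``(blocks, m_eff)`` where blocks maps 'x', 'm', 'y' to centered,
    unit-variance column blocks and ``m_eff = n - 1 - n_covariates`` is the
    effective sample size after projecting out the flat-prior columns.
    """
    n = data.n
    basis = np.ones((n, 1))
    n_cov = 0
    if data.covariates is not None:
        basis = np.column_stack([basis, data.covariates])
        n_cov = data.covariates.shape[1]
        if np.linalg.matrix_rank(basis) < basis.shape[1]:
            raise DesignError("covariate block is rank deficient")
    m_eff = n - 1 - n_cov
    if m_eff < 3:
        raise DesignError("too few samples after adjusting for covariates")
    x = data.x if data.multistate else data.x[:, None]
    if data.multistate:
        # dosage columns sum to 1 per row: exactly the intercept redundancy.
        # After centering the block has rank n_states - 1; the proper effect
        # prior keeps the marginal likelihood well defined without dropping a
        # column.
        pass
    blocks = {}
    for key, v in (("x", x), ("m", data.m[:, None]), ("y", data.y[:, None])):
        r = np.column_stack([_residualize(v[:, j], basis) for j in range(v.shape[1])])
        blocks[key] = _standardize_columns(r, key)
    return blocks, m_eff


def _lml_design(
    resp: np.ndarray, Z: np.ndarray | None, m_eff: int, priors: Priors
) -> float:
    """Marginal likelihood of one Gaussian linear factor from design matrices.

    ``resp`` is the centered, standardized response column; ``Z`` the
    predictor block (or None).  Integrates the effects and the residual
    variance analytically.
    """
    kap, lam, phi2 = priors.kappa, priors.lam, priors.phi_sq
    m = m_eff
    yty = float(resp @ resp)
    const = (
        -(m / 2.0) * np.log(2.0 * np.pi)
        + (kap / 2.0) * np.log(lam / 2.0)
        - gammaln(kap / 2.0)
        + gammaln((kap + m) / 2.0)
    )
    if Z is None or Z.shape[1] == 0:
        q = yty
        logdet = 0.0
    else:
        p = Z.shape[1]
        A = Z.T @ Z + np.eye(p) / phi2
        zy = Z.T @ resp
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            raise DesignError("predictor Gram matrix is not positive definite")
        logdet = p * np.log(phi2) + logdet_a  # log det(I + phi^2 Z'Z)
        q = yty - float(zy @ np.linalg.solve(A, zy))
    return float(const - 0.5 * logdet - ((kap + m) / 2.0) * np.log((lam + q) / 2.0))


def log_marginal_likelihood(
    data: TripletDataset, model: MediationModel, priors: Priors = DEFAULT_PRIORS
) -> float:
    """Log marginal likelihood of a mediation DAG for one triplet dataset.

    Factorizes as log p(M | parents of M) + log p(Y | parents of Y); the
    genotype block enters only as a predictor.  Deterministic.
    """
    blocks, m_eff = _prepare(data)

    def factor(resp_key: str, parents: tuple[str, ...]) -> float:
        Z = (
            np.column_stack([blocks[p] for p in parents])
            if parents
            else None
        )
        return _lml_design(blocks[resp_key][:, 0], Z, m_eff, priors)

    return factor("m", model.parents_m) + factor("y", model.parents_y)


@dataclass
class ModelPosterior:
    """Per-model log marginal likelihoods and normalized posteriors."""

    models: tuple[MediationModel, ...]
    log_ml: np.ndarray
    posterior: np.ndarray
    option_set: str
    tie: bool = False

    @property
    def selected(self) -> MediationModel:
        return self.models[int(np.argmax(self.posterior))]

    @property
    def classification(self) -> str:
        """Label of the selected model (named model or 'other-nonmediation')."""
        return self.selected.label

    def as_row(self) -> dict:
        row: dict = {"option_set": self.option_set}
        for mod, lml, post in zip(self.models, self.log_ml, self.posterior):
            row[f"lnML[{mod.name}]"] = lml
            row[f"P[{mod.name}]"] = post
        row["selected"] = self.selected.name
        row["classification"] = self.classification
        row["tie"] = self.tie
        return row


def _finalize(models, log_ml, option_set) -> ModelPosterior:
    log_ml = np.asarray(log_ml, dtype=float)
    post = np.exp(log_ml - logsumexp(log_ml))
    post /= post.sum()
    order = np.sort(post)[::-1]
    tie = bool(order[0] - order[1] < 1e-12)
    return ModelPosterior(tuple(models), log_ml, post, option_set, tie)


def select_model(
    data: TripletDataset,
    option_set: str = "expanded",
    priors: Priors = DEFAULT_PRIORS,
) -> ModelPosterior:
    """Posterior over the option set and the maximum-posterior model.

    A uniform prior is placed over the enumerated models.  Posterior ties
    (gap below 1e-12) are resolved by the fixed enumeration order and
    flagged.
    """
    models = enumerate_models(option_set)
    log_ml = [log_marginal_likelihood(data, mod, priors) for mod in models]
    return _finalize(models, log_ml, option_set)


# ---------------------------------------------------------------------------
# vectorized scoring from sample correlations (univariate X, no covariates)


def _lml0_corr(n, m, priors):
    kap, lam = priors.kappa, priors.lam
    const = (
        -(m / 2.0) * np.log(2.0 * np.pi)
        + (kap / 2.0) * np.log(lam / 2.0)
        - gammaln(kap / 2.0)
        + gammaln((kap + m) / 2.0)
    )
    return const - ((kap + m) / 2.0) * np.log((lam + n) / 2.0)


def _lml1_corr(r, n, m, priors):
    kap, lam, phi2 = priors.kappa, priors.lam, priors.phi_sq
    tau = 1.0 / phi2
    q = n - (n * r) ** 2 / (n + tau)
    return (
        _lml0_corr(n, m, priors)
        + ((kap + m) / 2.0) * np.log(lam + n)
        - 0.5 * np.log(1.0 + phi2 * n)
        - ((kap + m) / 2.0) * np.log(lam + q)
    )


def _lml2_corr(r1, r2, r12, n, m, priors):
    kap, lam, phi2 = priors.kappa, priors.lam, priors.phi_sq
    tau = 1.0 / phi2
    det_a = (n + tau) ** 2 - (n * r12) ** 2
    quad = n**2 * ((r1**2 + r2**2) * (n + tau) - 2.0 * r1 * r2 * n * r12) / det_a
    q = n - quad
    logdet = 2.0 * np.log(phi2) + np.log(det_a)
    return (
        _lml0_corr(n, m, priors)
        + ((kap + m) / 2.0) * np.log(lam + n)
        - 0.5 * logdet
        - ((kap + m) / 2.0) * np.log(lam + q)
    )


def log_ml_from_correlations(
    rho_xy, rho_xm, rho_ym, n: int, option_set: str = "expanded",
    priors: Priors = DEFAULT_PRIORS,
):
    """Log marginal likelihoods for every model, from sample correlations.

    Valid for univariate gaussian X with no covariates, where the sample
    correlation matrix and N are sufficient.  Inputs broadcast; returns an
    array of shape ``(..., n_models)`` aligned with ``enumerate_models``.
    """
    rxy, rxm, rym = np.broadcast_arrays(
        np.asarray(rho_xy, float), np.asarray(rho_xm, float), np.asarray(rho_ym, float)
    )
    m = n - 1
    models = enumerate_models(option_set)
    f0 = _lml0_corr(n, m, priors)
    f0 = np.broadcast_to(f0, rxy.shape)

    def f_m(mod):
        p = mod.parents_m
        if not p:
            return f0
        if p == ("x",):
            return _lml1_corr(rxm, n, m, priors)
        if p == ("y",):
            return _lml1_corr(rym, n, m, priors)
        return _lml2_corr(rxm, rym, rxy, n, m, priors)  # M on (x, y)

    def f_y(mod):
        p = mod.parents_y
        if not p:
            return f0
        if p == ("x",):
            return _lml1_corr(rxy, n, m, priors)
        if p == ("m",):
            return _lml1_corr(rym, n, m, priors)
        return _lml2_corr(rxy, rym, rxm, n, m, priors)  # Y on (x, m)

    return np.stack([f_m(mod) + f_y(mod) for mod in models], axis=-1)


def select_from_correlations(
    rho_xy, rho_xm, rho_ym, n: int, option_set: str = "expanded",
    priors: Priors = DEFAULT_PRIORS,
) -> np.ndarray:
    """Vectorized maximum-posterior classification from sample correlations.

    Returns an array of model labels ('Causal', 'Independent', 'Reactive',
    'Complex', or 'other-nonmediation') with the broadcast shape of the
    inputs.
    """
    log_ml = log_ml_from_correlations(rho_xy, rho_xm, rho_ym, n, option_set, priors)
    models = enumerate_models(option_set)
    labels = np.array([mod.label for mod in models])
    return labels[np.argmax(log_ml, axis=-1)]


# ---------------------------------------------------------------------------
# deterministic rule


_RULE = {"xy": "Causal", "ym": "Independent", "xm": "Reactive"}


def weakest_correlation_rule(data) -> str:
    """Three-choice label from the weakest estimated data correlation.

    Selects the model with no direct edge between the pair whose correlation
    is weakest in magnitude: |r_XY| weakest -> Causal, |r_YM| -> Independent,
    |r_XM| -> Reactive.  Exact ties return 'ambiguous'.  Only defined for
    univariate X, M, Y.
    """
    if isinstance(data, TripletDataset):
        if data.multistate:
            raise ValidationError(
                "rule not applicable: the weakest-correlation rule holds only "
                "for univariate X"
            )
        rxy = float(np.corrcoef(data.x, data.y)[0, 1])
        rxm = float(np.corrcoef(data.x, data.m)[0, 1])
        rym = float(np.corrcoef(data.y, data.m)[0, 1])
        triple = CorrelationTriple(rxy, rxm, rym, role="estimated")
    elif isinstance(data, CorrelationTriple):
        triple = data
    else:
        raise TypeError("expected a TripletDataset or CorrelationTriple")
    mags = {"xy": abs(triple.rho_xy), "xm": abs(triple.rho_xm), "ym": abs(triple.rho_ym)}
    order = sorted(mags, key=mags.get)
    if mags[order[0]] == mags[order[1]]:
        return "ambiguous"
    return _RULE[order[0]]


def classify_frame(
    data: TripletDataset, option_set: str, priors: Priors = DEFAULT_PRIORS
) -> pd.DataFrame:
    """One-row table of log MLs, posteriors and the selected label."""
    return pd.DataFrame([select_model(data, option_set, priors).as_row()])
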