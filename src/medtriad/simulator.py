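"""Synthetic triplet generation under the measurement-error model.

Configurations are drawn the way the simulation study defines them: for each
constrained structure, the two free causal correlations (the edges present in
the DAG) and the three error correlations are sampled iid from
``Beta(5, 1.25)`` -- a distribution with mean 0.8 and 95% highest-density
interval roughly (0.5, 1), favoring moderate-to-strong correlations while
allowing weak ones.  The third causal correlation is set by the product
constraint, which also guarantees a positive semidefinite causal matrix.

Datasets are standardized linear-Gaussian: the exogenous genotype ``X*`` is
standard normal (or a uniformly drawn 8-state haplotype in the multistate
variant), each downstream causal variable is ``rho * parent +
sqrt(1 - rho^2) * noise`` following the structure's topological order, and
each measured variable is generated from its causal counterpart the same way
using the error correlation.  All continuous variables have population mean 0
and variance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation_model import (
    CONSTRAINED_STRUCTURES,
    CausalStructure,
    CorrelationTriple,
    MeasurementErrorConfig,
    Role,
    ValidationError,
)

__all__ = [
    "SimulationDesign",
    "TripletDataset",
    "sample_configs",
    "simulate_dataset",
]

_C = CausalStructure

#: Beta shape parameters of the correlation prior used throughout the study
BETA_SHAPE_A = 5.0
BETA_SHAPE_B = 1.25


@dataclass(frozen=True)
class SimulationDesign:
    """Defines one arm of the simulation study."""

    structure: CausalStructure
    n_configs: int = 10_000
    sample_size: int = 200
    beta_shape_a: float = BETA_SHAPE_A
    beta_shape_b: float = BETA_SHAPE_B
    seed: int = 0
    x_kind: str = "gaussian"  # 'gaussian' or 'multistate'
    n_states: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", CausalStructure(self.structure))
        if self.sample_size < 10:
            raise ValidationError("sample_size must be >= 10")
        if self.n_configs < 1:
            raise ValidationError("n_configs must be >= 1")
        if self.beta_shape_a <= 0 or self.beta_shape_b <= 0:
            raise ValidationError("beta shapes must be positive")
        if self.x_kind not in ("gaussian", "multistate"):
            raise ValidationError("x_kind must be 'gaussian' or 'multistate'")


@dataclass
class TripletDataset:
    """N samples of (X, M, Y), optionally with covariates and generating truth.

    ``x`` is an (N,) vector for a gaussian genotype or an (N, n_states) block
    of dosage columns (rows nonnegative, summing to 1) for a multistate one.
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    covariates: np.ndarray | None = None
    truth: MeasurementErrorConfig | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.m)
        if len(self.y) != n or self.x.shape[0] != n:
            raise ValidationError("x, m, y must have the same number of rows")
        for arr in (self.x, self.m, self.y):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("triplet data must not contain missing values")
        if self.multistate:
            if np.any(self.x < 0) or not np.allclose(self.x.sum(axis=1), 1.0):
                raise ValidationError("multistate dosage rows must be nonnegative and sum to 1")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValidationError("covariates must have one row per sample")

    @property
    def n(self) -> int:
        return len(self.m)

    @property
    def multistate(self) -> bool:
        return self.x.ndim == 2

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with columns x (or x1..xk), m, y and covariate columns."""
        if self.multistate:
            cols = {f"x{i + 1}": self.x[:, i] for i in range(self.x.shape[1])}
        else:
            cols = {"x": self.x}
        cols.update({"m": self.m, "y": self.y})
        if self.covariates is not None:
            for i in range(self.covariates.shape[1]):
                cols[f"cov{i + 1}"] = self.covariates[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TripletDataset":
        xcols = [c for c in frame.columns if c == "x" or (c.startswith("x") and c[1:].isdigit())]
        covcols = [c for c in frame.columns if c.startswith("cov")]
        x = frame[xcols[0]].to_numpy() if xcols == ["x"] else frame[xcols].to_numpy()
        cov = frame[covcols].to_numpy() if covcols else None
        return cls(x=x, m=frame["m"].to_numpy(), y=frame["y"].to_numpy(), covariates=cov)

    @classmethod
    def read_csv(cls, path) -> "TripletDataset":
        return cls.from_frame(pd.read_csv(path))


def sample_configs(design: SimulationDesign) -> list[MeasurementErrorConfig]:
    """Draw measurement-error configurations for one study arm.

    The two causal correlations on the structure's edges and the three error
    correlations are iid Beta(a, b); the off-edge causal correlation is their
    product.  Deterministic given ``design.seed``.
    """
    if design.structure not in CONSTRAINED_STRUCTURES:
        raise ValidationError("configs are sampled for the three constrained structures")
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    draws = rng.beta(design.beta_shape_a, design.beta_shape_b, size=(design.n_configs, 5))
    configs = []
    for e1, e2, ex, em, ey in draws:
        if design.structure is _C.CAUSAL:  # edges X*->M* (rho_xm), M*->Y* (rho_ym)
            causal = CorrelationTriple(e1 * e2, e1, e2, role=Role.CAUSAL)
        elif design.structure is _C.INDEPENDENT:  # edges X*->M*, X*->Y*
            causal = CorrelationTriple(e2, e1, e1 * e2, role=Role.CAUSAL)
        else:  # Reactive: edges X*->Y* (rho_xy), Y*->M* (rho_ym)
            causal = CorrelationTriple(e1, e1 * e2, e2, role=Role.CAUSAL)
        configs.append(
            MeasurementErrorConfig(
                structure=design.structure, causal=causal, err_x=ex, err_m=em, err_y=ey
            )
        )
    return configs


def _noisy_copy(parent: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """rho * parent + sqrt(1 - rho^2) * independent standard normal."""
    return rho * parent + np.sqrt(1.0 - rho * rho) * rng.standard_normal(parent.shape)


def _state_effects(n_states: int, rng: np.random.Generator) -> np.ndarray:
    """Mean-centered state-effect vector with unit variance over uniform states."""
    gamma = rng.standard_normal(n_states)
    gamma -= gamma.mean()
    scale = np.sqrt(np.mean(gamma**2))
    if scale < 1e-12:  # pathologically flat draw; redraw deterministically
        return _state_effects(n_states, rng)
    return gamma / scale


def simulate_dataset(
    config: MeasurementErrorConfig,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    x_kind: str = "gaussian",
    n_states: int = 8,
) -> TripletDataset:
    """Simulate one finite-sample triplet dataset from a configuration.

    Gaussian path: ``X*`` is standard normal, downstream causal variables
    follow the structure's topological order, and measured variables are
    noisy copies of their causal counterparts at the error correlations.

    Multistate path: ``X*`` is a uniformly drawn state out of ``n_states``;
    a mean-centered, unit-variance state-effect vector (one draw per config)
    is scaled by the edge correlation, so the canonical correlation between
    the dosage block and the downstream child equals the causal correlation
    (effect size rho^2 on the variance scale).  Genotyping error relabels the
    measured state uniformly with probability ``1 - err_x``, which makes the
    canonical correlation between measured and causal genotype equal
    ``err_x``.  The measured genotype is reported as one-hot dosage rows.
    """
    if n < 10:
        raise ValidationError("n must be >= 10")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    c = config.causal
    s = config.structure

    if x_kind == "gaussian":
        x_star = rng.standard_normal(n)
        x_meas: np.ndarray = _noisy_copy(x_star, config.err_x, rng)
        x_drive = x_star  # what downstream children respond to
    elif x_kind == "multistate":
        states = rng.integers(0, n_states, size=n)
        gamma = _state_effects(n_states, rng)
        x_drive = gamma[states]
        u = rng.random(n)
        relabel = rng.integers(0, n_states, size=n)
        meas_states = np.where(u < config.err_x, states, relabel)
        x_meas = np.eye(n_states)[meas_states]
    else:
        raise ValidationError("x_kind must be 'gaussian' or 'multistate'")

    if s is _C.CAUSAL:  # X* -> M* -> Y*
        m_star = _noisy_copy(x_drive, c.rho_xm, rng)
        y_star = _noisy_copy(m_star, c.rho_ym, rng)
    elif s is _C.INDEPENDENT:  # M* <- X* -> Y*
        m_star = _noisy_copy(x_drive, c.rho_xm, rng)
        y_star = _noisy_copy(x_drive, c.rho_xy, rng)
    elif s is _C.REACTIVE:  # X* -> Y* -> M*
        y_star = _noisy_copy(x_drive, c.rho_xy, rng)
        m_star = _noisy_copy(y_star, c.rho_ym, rng)
    else:  # Complex: X* -> M*, then Y* responds to both X* and M*
        m_star = _noisy_copy(x_drive, c.rho_xm, rng)
        # coefficients of the linear Gaussian SEM reproducing (rho_xy, rho_ym)
        denom = 1.0 - c.rho_xm**2
        if denom < 1e-12:
            raise ValidationError("Complex config degenerate: |rho_xm| = 1")
        b_x = (c.rho_xy - c.rho_ym * c.rho_xm) / denom
        b_m = (c.rho_ym - c.rho_xy * c.rho_xm) / denom
        resid_var = 1.0 - (b_x**2 + b_m**2 + 2 * b_x * b_m * c.rho_xm)
        if resid_var < -1e-10:
            raise ValidationError("Complex causal triple is not positive semidefinite")
        y_star = (
            b_x * x_drive
            + b_m * m_star
            + np.sqrt(max(resid_var, 0.0)) * rng.standard_normal(n)
        )

    m_meas = _noisy_copy(m_star, config.err_m, rng)
    y_meas = _noisy_copy(y_star, config.err_y, rng)
    return TripletDataset(x=x_meas, m=m_meas, y=y_meas, truth=config)
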