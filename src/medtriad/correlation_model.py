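"""Measurement-error model for mediation triplets, parameterized by correlations.

A *triplet* is a set of three variables analyzed jointly in genetic mediation
analysis: the genotype at a QTL (``X``), a candidate mediator such as a
transcript or protein abundance (``M``), and a target trait (``Y``).  Each
measured variable is a noisy surrogate of an unobserved, error-free *causal
variable* (written X*, M*, Y*).  The model has two kinds of parameters, both
expressed as correlations:

* **causal correlations** -- the pairwise correlations among the causal
  variables (``rho_xm``, ``rho_xy``, ``rho_ym`` in causal role), which encode
  the causal structure; and
* **error correlations** -- the correlation between each causal variable and
  its measured surrogate (``err_x``, ``err_m``, ``err_y``).  An error
  correlation of 1 means the variable is measured without error; error
  correlations are inversely related to the more conventional error variance.

The *data correlations* -- the only quantities estimable from a triplet --
are products of causal and error correlations::

    rho_XY = err_x * rho_xy_causal * err_y
    rho_XM = err_x * rho_xm_causal * err_m
    rho_YM = err_y * rho_ym_causal * err_m

Four causal structures are distinguished.  Causal (complete mediation,
X->M->Y), Independent (X->M and X->Y, no M-Y effect), Reactive (X->Y->M), and
Complex (partial mediation, all three effects).  Each constrained structure
has a *middle variable* (M, X, and Y respectively) that separates the other
two; the causal correlation of the non-middle pair is then the product of the
other two causal correlations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CausalStructure",
    "Role",
    "CorrelationTriple",
    "MeasurementErrorConfig",
    "ValidationError",
    "implied_data_correlations",
    "check_structure_constraint",
    "complex_equivalent",
    "is_psd",
    "save_config",
    "load_config",
]

#: default tolerance for exact structural constraints
CONSTRAINT_TOL = 1e-8
#: default eigenvalue tolerance when testing positive semidefiniteness
EIG_TOL = 1e-10


class ValidationError(ValueError):
    """A configuration violates one of the model's structural constraints."""


class CausalStructure(str, enum.Enum):
    """The four mediation DAGs over (X, M, Y)."""

    CAUSAL = "Causal"
    INDEPENDENT = "Independent"
    REACTIVE = "Reactive"
    COMPLEX = "Complex"

    @property
    def middle(self) -> str | None:
        """The middle variable ('x', 'm' or 'y'); ``None`` for Complex."""
        return {_C.CAUSAL: "m", _C.INDEPENDENT: "x", _C.REACTIVE: "y", _C.COMPLEX: None}[self]


_C = CausalStructure

CONSTRAINED_STRUCTURES = (_C.CAUSAL, _C.INDEPENDENT, _C.REACTIVE)


class Role(str, enum.Enum):
    """What a correlation triple refers to.

    ``causal``    -- correlations among the error-free causal variables.
    ``data``      -- population correlations among the measured variables.
    ``estimated`` -- sample correlations computed from a finite dataset.
    """

    CAUSAL = "causal"
    DATA = "data"
    ESTIMATED = "estimated"


@dataclass(frozen=True)
class CorrelationTriple:
    """The three pairwise correlations among (X, M, Y) in a given role.

    Correlations are signed.  For ``causal`` and ``data`` roles the implied
    3x3 unit-diagonal matrix must be positive semidefinite; sample estimates
    (role ``estimated``) are stored as-is.
    """

    rho_xy: float
    rho_xm: float
    rho_ym: float
    role: Role = Role.DATA

    def __post_init__(self) -> None:
        for name in ("rho_xy", "rho_xm", "rho_ym"):
            v = getattr(self, name)
            if not np.isfinite(v) or abs(v) > 1.0 + 1e-12:
                raise ValidationError(f"{name}={v!r} is not a correlation in [-1, 1]")
        object.__setattr__(self, "role", Role(self.role))
        if self.role in (Role.CAUSAL, Role.DATA) and not is_psd(self):
            raise ValidationError(
                f"{self.role.value} correlation triple {self.values()} implies a "
                "correlation matrix that is not positive semidefinite"
            )

    def values(self) -> tuple[float, float, float]:
        """Return ``(rho_xy, rho_xm, rho_ym)``."""
        return (self.rho_xy, self.rho_xm, self.rho_ym)

    def matrix(self) -> np.ndarray:
        """The 3x3 correlation matrix in variable order (X, M, Y)."""
        return np.array(
            [
                [1.0, self.rho_xm, self.rho_xy],
                [self.rho_xm, 1.0, self.rho_ym],
                [self.rho_xy, self.rho_ym, 1.0],
            ]
        )


def is_psd(triple: CorrelationTriple, eig_tol: float = EIG_TOL) -> bool:
    """Whether the triple's 3x3 correlation matrix is positive semidefinite.

    Matrices whose smallest eigenvalue is within ``eig_tol`` of zero are
    accepted as boundary cases.
    """
    for v in triple.values():
        if abs(v) > 1.0 + 1e-12:
            raise ValidationError(f"correlation {v!r} outside [-1, 1]")
    eigmin = float(np.linalg.eigvalsh(triple.matrix())[0])
    return eigmin >= -eig_tol


def check_structure_constraint(
    triple: CorrelationTriple,
    structure: CausalStructure,
    tol: float = CONSTRAINT_TOL,
) -> tuple[bool, float]:
    """Test the product constraint a constrained structure puts on a triple.

    In a constrained structure the two non-middle variables share no edge, so
    their correlation must equal the product of the two correlations that
    involve the middle variable (equivalently, their partial correlation given
    the middle variable is zero).

    Returns ``(ok, residual)`` where ``residual`` is the signed difference
    between the non-middle-pair correlation and the product of the other two.
    """
    structure = CausalStructure(structure)
    if structure is _C.COMPLEX:
        raise ValidationError("Complex is an unconstrained structure: no product constraint")
    rxy, rxm, rym = triple.values()
    if structure is _C.CAUSAL:  # middle M: X-Y pair constrained
        residual = rxy - rxm * rym
    elif structure is _C.INDEPENDENT:  # middle X: Y-M pair constrained
        residual = rym - rxm * rxy
    else:  # Reactive, middle Y: X-M pair constrained
        residual = rxm - rxy * rym
    return (abs(residual) <= tol, residual)


@dataclass(frozen=True)
class MeasurementErrorConfig:
    """One point in the generative model: structure, causal and error correlations.

    ``err_x``, ``err_m``, ``err_y`` live in (0, 1]; a zero error correlation
    would make the measured variable pure noise (all its data correlations
    vanish) and is rejected.
    """

    structure: CausalStructure
    causal: CorrelationTriple
    err_x: float
    err_m: float
    err_y: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", CausalStructure(self.structure))
        if self.causal.role is not Role.CAUSAL:
            raise ValidationError("config.causal must carry role='causal'")
        for name in ("err_x", "err_m", "err_y"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(
                    f"error correlation {name}={v!r} must lie in (0, 1]; a zero "
                    "error correlation makes the measured variable pure noise"
                )
        if self.structure is not _C.COMPLEX:
            ok, residual = check_structure_constraint(self.causal, self.structure)
            if not ok:
                raise ValidationError(
                    f"{self.structure.value} structure requires the non-middle causal "
                    f"correlation to equal the product of the other two "
                    f"(residual {residual:+.3e})"
                )
        if not is_psd(self.causal):
            raise ValidationError("causal correlation matrix is not positive semidefinite")

    @property
    def errors(self) -> tuple[float, float, float]:
        """Return ``(err_x, err_m, err_y)``."""
        return (self.err_x, self.err_m, self.err_y)


def implied_data_correlations(config: MeasurementErrorConfig) -> CorrelationTriple:
    """Population correlations among the measured variables.

    Each data correlation is the causal correlation attenuated by the error
    correlations of the two variables it touches, so data correlations are
    never stronger in magnitude than their causal counterparts.
    """
    c = config.causal
    return CorrelationTriple(
        rho_xy=config.err_x * c.rho_xy * config.err_y,
        rho_xm=config.err_x * c.rho_xm * config.err_m,
        rho_ym=config.err_y * c.rho_ym * config.err_m,
        role=Role.DATA,
    )


def complex_equivalent(config: MeasurementErrorConfig) -> MeasurementErrorConfig:
    """The error-free Complex model that is likelihood equivalent to ``config``.

    Every measurement-error model is observationally indistinguishable from a
    Complex (partial mediation) model without measurement error whose causal
    correlations equal the original model's data correlations.  This is the
    crux of why standard mediation analysis drifts toward partial mediation
    under measurement error.
    """
    data = implied_data_correlations(config)
    return MeasurementErrorConfig(
        structure=_C.COMPLEX,
        causal=replace(data, role=Role.CAUSAL),
        err_x=1.0,
        err_m=1.0,
        err_y=1.0,
    )


# ---------------------------------------------------------------------------
# flat key-value serialization

_FIELDS = ("structure", "rho_xy", "rho_xm", "rho_ym", "err_x", "err_m", "err_y")


def config_to_mapping(config: MeasurementErrorConfig) -> dict[str, str]:
    c = config.causal
    return {
        "structure": config.structure.value,
        "rho_xy": repr(c.rho_xy),
        "rho_xm": repr(c.rho_xm),
        "rho_ym": repr(c.rho_ym),
        "err_x": repr(config.err_x),
        "err_m": repr(config.err_m),
        "err_y": repr(config.err_y),
    }


def config_from_mapping(mapping: dict[str, str]) -> MeasurementErrorConfig:
    missing = [k for k in _FIELDS if k not in mapping]
    if missing:
        raise ValidationError(f"config mapping missing keys: {missing}")
    causal = CorrelationTriple(
        rho_xy=float(mapping["rho_xy"]),
        rho_xm=float(mapping["rho_xm"]),
        rho_ym=float(mapping["rho_ym"]),
        role=Role.CAUSAL,
    )
    return MeasurementErrorConfig(
        structure=CausalStructure(mapping["structure"]),
        causal=causal,
        err_x=float(mapping["err_x"]),
        err_m=float(mapping["err_m"]),
        err_y=float(mapping["err_y"]),
    )


def save_config(config: MeasurementErrorConfig, path) -> None:
    """Write a config as flat ``key = value`` lines."""
    lines = [f"{k} = {v}" for k, v in config_to_mapping(config).items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path) -> MeasurementErrorConfig:
    """Read a config written by :func:`save_config`."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            mapping[key.strip()] = value.strip()
    return config_from_mapping(mapping)
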