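"""Single-latent-factor reparameterization of the measurement-error model.

The constrained measurement-error models (Causal, Independent, Reactive) have
five free parameters but only three observable data correlations.  Each is
equivalent to a one-factor model in which a single latent variable ``U``
drives all three measured variables, with *latent correlations*
``(rho_xu, rho_mu, rho_yu)`` such that every data correlation is a product of
the two latent correlations it touches::

    rho_XY = rho_xu * rho_yu
    rho_XM = rho_xu * rho_mu
    rho_YM = rho_yu * rho_mu

The latent correlations are identified combinations of causal and error
correlations (the middle variable's latent correlation is exactly its error
correlation), and -- unlike the causal and error correlations themselves --
they are estimable from data via the classical tetrad formulas.  Their
relative magnitudes determine whether three-choice model selection is
asymptotically consistent: the strongest latent correlation picks the model
whose middle variable it belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation_model import (
    CausalStructure,
    CorrelationTriple,
    MeasurementErrorConfig,
    Role,
    ValidationError,
)

__all__ = [
    "LatentTriple",
    "latent_from_config",
    "estimate_latent",
    "Diagnosis",
    "diagnose_consistency",
]

_C = CausalStructure

#: below this magnitude a data correlation makes the tetrad ratios meaningless
MIN_ABS = 1e-6


@dataclass(frozen=True)
class LatentTriple:
    """Correlations between each measured variable and the latent factor U.

    ``clipped`` flags a Heywood-type boundary case: a finite-sample estimate
    exceeded 1 in magnitude and was clipped.
    """

    rho_xu: float
    rho_mu: float
    rho_yu: float
    clipped: bool = False

    def values(self) -> tuple[float, float, float]:
        """Return ``(rho_xu, rho_mu, rho_yu)``."""
        return (self.rho_xu, self.rho_mu, self.rho_yu)

    def data_correlations(self, role: Role = Role.DATA) -> CorrelationTriple:
        """The data correlations implied by the one-factor model (pairwise products)."""
        return CorrelationTriple(
            rho_xy=self.rho_xu * self.rho_yu,
            rho_xm=self.rho_xu * self.rho_mu,
            rho_ym=self.rho_yu * self.rho_mu,
            role=role,
        )


def latent_from_config(config: MeasurementErrorConfig) -> LatentTriple:
    """Forward map from a constrained measurement-error config to latent correlations.

    The middle variable's latent correlation equals its error correlation;
    each non-middle variable's latent correlation is its error correlation
    times its causal correlation with the middle variable.
    """
    c, ex, em, ey = config.causal, config.err_x, config.err_m, config.err_y
    if config.structure is _C.CAUSAL:
        return LatentTriple(rho_xu=ex * c.rho_xm, rho_mu=em, rho_yu=ey * c.rho_ym)
    if config.structure is _C.INDEPENDENT:
        return LatentTriple(rho_xu=ex, rho_mu=em * c.rho_xm, rho_yu=ey * c.rho_xy)
    if config.structure is _C.REACTIVE:
        return LatentTriple(rho_xu=ex * c.rho_xy, rho_mu=em * c.rho_ym, rho_yu=ey)
    raise ValidationError("the Complex model has no single-latent-factor representation")


def estimate_latent(data: CorrelationTriple, min_abs: float = MIN_ABS) -> LatentTriple:
    """Closed-form (tetrad) estimator of the latent correlations.

    Inverts the pairwise-product equations: the magnitudes are

        |rho_xu| = sqrt(|rho_xy * rho_xm / rho_ym|)
        |rho_mu| = sqrt(|rho_xm * rho_ym / rho_xy|)
        |rho_yu| = sqrt(|rho_xy * rho_ym / rho_xm|)

    The factor's orientation is arbitrary, so signs are fixed by the
    convention ``rho_mu >= 0``; the signs of ``rho_xu`` and ``rho_yu`` then
    follow from the signs of ``rho_xm`` and ``rho_ym``.  A one-factor model
    requires the product of the three data correlations to be positive.
    Finite-sample estimates can exceed 1 in magnitude (Heywood cases); these
    are clipped to 1 and flagged rather than rejected.
    """
    rxy, rxm, rym = data.values()
    if min(abs(rxy), abs(rxm), abs(rym)) < min_abs:
        raise ValidationError(
            f"latent model unidentified: a data correlation is below min_abs={min_abs}"
        )
    if rxy * rxm * rym <= 0:
        raise ValidationError(
            "sign-inconsistent with single factor: the product of the three "
            "data correlations must be positive"
        )
    axu = np.sqrt(abs(rxy * rxm / rym))
    amu = np.sqrt(abs(rxm * rym / rxy))
    ayu = np.sqrt(abs(rxy * rym / rxm))
    clipped = bool(max(axu, amu, ayu) > 1.0)
    axu, amu, ayu = (min(a, 1.0) for a in (axu, amu, ayu))
    # rho_mu >= 0 by convention; rho_xm = rho_xu*rho_mu and rho_ym = rho_yu*rho_mu
    # then force the signs of rho_xu, rho_yu.
    return LatentTriple(
        rho_xu=float(np.sign(rxm) * axu),
        rho_mu=float(amu),
        rho_yu=float(np.sign(rym) * ayu),
        clipped=clipped,
    )


_SELECTED_BY_STRONGEST = {"x": _C.INDEPENDENT, "m": _C.CAUSAL, "y": _C.REACTIVE}


@dataclass(frozen=True)
class Diagnosis:
    """Outcome of the latent-correlation consistency diagnosis."""

    latent: LatentTriple
    assumed: CausalStructure
    strongest: str | None  # 'x', 'm', 'y', or None when ambiguous
    selected: CausalStructure | None  # asymptotically selected three-choice model
    verdict: str  # 'consistent', 'inconsistent', or 'ambiguous'
    margin: float

    @property
    def consistent(self) -> bool | None:
        if self.verdict == "ambiguous":
            return None
        return self.verdict == "consistent"

    def as_row(self) -> dict:
        """Flat-table representation (one row per diagnosis)."""
        return {
            "rho_xu": self.latent.rho_xu,
            "rho_mu": self.latent.rho_mu,
            "rho_yu": self.latent.rho_yu,
            "clipped": self.latent.clipped,
            "assumed": self.assumed.value,
            "strongest": self.strongest,
            "selected": None if self.selected is None else self.selected.value,
            "verdict": self.verdict,
            "margin": self.margin,
        }


def diagnose_consistency(
    latent: LatentTriple,
    assumed: CausalStructure,
    margin: float = 0.0,
) -> Diagnosis:
    """Which three-choice model large samples will drift toward, and whether
    that matches the assumed structure.

    The asymptotic rule: the strongest latent correlation in magnitude makes
    the data correlation between the *other two* variables the weakest, so
    three-choice selection tends to the model whose middle variable carries
    the strongest latent correlation (``rho_mu`` -> Causal, ``rho_xu`` ->
    Independent, ``rho_yu`` -> Reactive).  Ties within ``margin`` yield an
    'ambiguous' verdict.
    """
    assumed = CausalStructure(assumed)
    if assumed is _C.COMPLEX:
        raise ValidationError("diagnosis is defined for the three constrained structures")
    mags = {"x": abs(latent.rho_xu), "m": abs(latent.rho_mu), "y": abs(latent.rho_yu)}
    order = sorted(mags, key=mags.get, reverse=True)
    gap = mags[order[0]] - mags[order[1]]
    if gap <= margin:
        return Diagnosis(latent, assumed, None, None, "ambiguous", margin)
    strongest = order[0]
    selected = _SELECTED_BY_STRONGEST[strongest]
    verdict = "consistent" if selected is assumed else "inconsistent"
    return Diagnosis(latent, assumed, strongest, selected, verdict, margin)
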