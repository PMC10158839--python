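"""Bootstrap diagnostic: which model parameters could explain observed data?

The causal and error correlations of a triplet are not separately
identifiable, but their feasible ranges can be mapped out.  The procedure:

1. bootstrap the observed triplet (case resampling) and build an empirical
   region for the three data correlations;
2. filter a library of simulated measurement-error configurations -- each
   with the sample data correlations it realized at a comparable sample
   size -- to those whose correlations fall jointly inside the region;
3. summarize the surviving configurations' causal, error, latent and data
   correlations by median and 95% highest-density interval, per assumed
   causal structure.

A structure with no surviving configurations is inconsistent with the data
at the library's resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation_model import (
    CONSTRAINED_STRUCTURES,
    CausalStructure,
    CorrelationTriple,
    Role,
    ValidationError,
)
from .latent_model import latent_from_config
from .simulator import SimulationDesign, TripletDataset, sample_configs, simulate_dataset
from .util import multiple_correlation, pearson

__all__ = [
    "BootstrapResult",
    "FeasibleSet",
    "bootstrap_correlations",
    "build_config_library",
    "filter_configs",
    "hdi",
]


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval of an empirical distribution.

    Sorted-window method: the shortest contiguous interval of the sorted
    samples containing ``ceil(mass * n)`` of them.
    """
    samples = np.sort(np.asarray(samples, dtype=float))
    n = len(samples)
    if n < 20:
        raise ValidationError("hdi requires at least 20 samples")
    if not (0.0 < mass < 1.0):
        raise ValidationError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k >= n:
        return (float(samples[0]), float(samples[-1]))
    widths = samples[k:] - samples[: n - k]
    i = int(np.argmin(widths))
    return (float(samples[i]), float(samples[i + k]))


@dataclass
class BootstrapResult:
    """Empirical distribution of the estimated data correlations."""

    n_boot: int
    samples: np.ndarray  # (n_boot, 3) columns (r_xy, r_xm, r_ym)
    point_estimate: CorrelationTriple
    region: np.ndarray  # (3, 2) per-correlation interval bounds
    n_redraws: int = 0

    def covers(self, triple: CorrelationTriple) -> bool:
        v = np.array(triple.values())
        return bool(np.all((v >= self.region[:, 0]) & (v <= self.region[:, 1])))


def _triple_correlations(x, m, y) -> tuple[float, float, float]:
    """(r_xy, r_xm, r_ym); canonical correlation when x is a block."""
    if x.ndim == 2:
        return (multiple_correlation(x, y), multiple_correlation(x, m), pearson(y, m))
    return (pearson(x, y), pearson(x, m), pearson(y, m))


def _degenerate(x, m, y) -> bool:
    cols = [m, y] + ([x] if x.ndim == 1 else [x[:, j] for j in range(x.shape[1])])
    return any(np.ptp(col) == 0 for col in cols)


def bootstrap_correlations(
    data: TripletDataset,
    n_boot: int = 10_000,
    seed: int = 0,
    mass: float = 0.95,
    region: str = "central",
) -> BootstrapResult:
    """Case-resampling bootstrap of the three data correlations.

    Rows are resampled with replacement ``n_boot`` times; each resample's
    correlation triple is computed (first canonical correlation for a
    multistate genotype block, Pearson otherwise).  Covariates, if present,
    are residualized out of M and Y first.  The region is the central
    ``mass`` interval per correlation by default, or the full min/max range
    with ``region='minmax'`` (noisier, and it widens as n_boot grows).

    Degenerate resamples (a zero-variance column) are redrawn and counted;
    more than 1% redraws aborts.
    """
    if data.n < 30:
        raise ValidationError("bootstrap requires at least 30 samples")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if region not in ("central", "minmax"):
        raise ValidationError("region must be 'central' or 'minmax'")
    x, m, y = data.x, data.m, data.y
    if data.covariates is not None:
        basis = np.column_stack([np.ones(data.n), data.covariates])

        def resid(v):
            coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
            return v - basis @ coef

        m, y = resid(m), resid(y)
    rng = np.random.default_rng(seed)
    samples = np.empty((n_boot, 3))
    n_redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, data.n, size=data.n)
            xb = x[idx]
            if not _degenerate(xb, m[idx], y[idx]):
                break
            n_redraws += 1
            if n_redraws > 0.01 * n_boot:
                raise ValidationError("more than 1% of bootstrap resamples were degenerate")
        samples[b] = _triple_correlations(xb, m[idx], y[idx])
    point = CorrelationTriple(*_triple_correlations(x, m, y), role=Role.ESTIMATED)
    if region == "central":
        lo, hi = (1.0 - mass) / 2.0, 1.0 - (1.0 - mass) / 2.0
        bounds = np.quantile(samples, [lo, hi], axis=0).T
    else:
        bounds = np.column_stack([samples.min(axis=0), samples.max(axis=0)])
    return BootstrapResult(
        n_boot=n_boot,
        samples=samples,
        point_estimate=point,
        region=bounds,
        n_redraws=n_redraws,
    )


_PARAM_COLS = [
    "rho_xy_causal", "rho_xm_causal", "rho_ym_causal",
    "err_x", "err_m", "err_y",
    "rho_xu", "rho_mu", "rho_yu",
    "r_xy", "r_xm", "r_ym",
]


def build_config_library(
    n_configs: int = 10_000,
    sample_size: int = 200,
    seed: int = 0,
    structures=CONSTRAINED_STRUCTURES,
) -> pd.DataFrame:
    """Simulate a library of configurations with realized sample correlations.

    One dataset is simulated per configuration at ``sample_size`` (matching
    the observed data's N is recommended); the realized *estimated* data
    correlations (r_xy, r_xm, r_ym), not population values, are stored
    alongside the causal, error and latent parameters.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for structure, arm_seq in zip(structures, root.spawn(len(structures))):
        cfg_seq, sim_seq = arm_seq.spawn(2)
        design = SimulationDesign(
            structure=structure, n_configs=n_configs, sample_size=sample_size,
            seed=cfg_seq.generate_state(1)[0] % (2**31),
        )
        configs = sample_configs(design)
        for config, child in zip(configs, sim_seq.spawn(len(configs))):
            ds = simulate_dataset(config, sample_size, np.random.default_rng(child))
            rxy, rxm, rym = _triple_correlations(ds.x, ds.m, ds.y)
            latent = latent_from_config(config)
            rows.append(
                {
                    "structure": structure.value,
                    "rho_xy_causal": config.causal.rho_xy,
                    "rho_xm_causal": config.causal.rho_xm,
                    "rho_ym_causal": config.causal.rho_ym,
                    "err_x": config.err_x,
                    "err_m": config.err_m,
                    "err_y": config.err_y,
                    "rho_xu": latent.rho_xu,
                    "rho_mu": latent.rho_mu,
                    "rho_yu": latent.rho_yu,
                    "r_xy": rxy,
                    "r_xm": rxm,
                    "r_ym": rym,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FeasibleSet:
    """Configurations of one assumed structure consistent with the data."""

    structure: CausalStructure
    survivors: pd.DataFrame
    summary: pd.DataFrame  # one row per parameter: median, hdi_low, hdi_high
    n_library: int

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)

    @property
    def feasible(self) -> bool:
        """False means no library config reproduced the observed correlations."""
        return self.n_survivors > 0


def filter_configs(
    library: pd.DataFrame,
    boot: BootstrapResult,
    structure: CausalStructure,
    mass: float = 0.95,
) -> FeasibleSet:
    """Feasible parameter set for one assumed causal structure.

    Keeps library configurations of the assumed structure whose realized
    sample correlations fall inside all three bootstrap region intervals
    simultaneously, then summarizes every parameter by median and
    ``mass``-level HDI over the survivors.  An empty survivor set yields an
    explicit infeasible result with an empty summary.
    """
    structure = CausalStructure(structure)
    sub = library[library["structure"] == structure.value]
    (xy_lo, xy_hi), (xm_lo, xm_hi), (ym_lo, ym_hi) = boot.region
    mask = (
        sub["r_xy"].between(xy_lo, xy_hi)
        & sub["r_xm"].between(xm_lo, xm_hi)
        & sub["r_ym"].between(ym_lo, ym_hi)
    )
    survivors = sub[mask].reset_index(drop=True)
    if len(survivors) == 0:
        summary = pd.DataFrame(columns=["parameter", "median", "hdi_low", "hdi_high"])
        return FeasibleSet(structure, survivors, summary, len(sub))
    rows = []
    for col in _PARAM_COLS:
        vals = survivors[col].to_numpy()
        if len(vals) >= 20:
            lo, hi = hdi(vals, mass)
        else:  # too few survivors for a density interval: report the range
            lo, hi = float(vals.min()), float(vals.max())
        rows.append(
            {"parameter": col, "median": float(np.median(vals)), "hdi_low": lo, "hdi_high": hi}
        )
    return FeasibleSet(structure, survivors, pd.DataFrame(rows), len(sub))


def summarize_feasible_sets(sets) -> pd.DataFrame:
    """Long-format summary: one row per (structure, parameter)."""
    frames = []
    for fs in sets:
        frame = fs.summary.copy()
        frame.insert(0, "structure", fs.structure.value)
        frame["n_survivors"] = fs.n_survivors
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
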