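import numpy as np
import pytest

from medtriad import CausalStructure, CorrelationTriple, MeasurementErrorConfig
from medtriad.correlation_model import Role
from medtriad.simulator import SimulationDesign, sample_configs


@pytest.fixture
def causal_config():
    """Reference Causal config: causal (0.72, 0.9, 0.8), errors (0.9, 0.8, 0.9)."""
    return MeasurementErrorConfig(
        structure=CausalStructure.CAUSAL,
        causal=CorrelationTriple(0.72, 0.9, 0.8, role=Role.CAUSAL),
        err_x=0.9,
        err_m=0.8,
        err_y=0.9,
    )


@pytest.fixture
def errorfree_config():
    return MeasurementErrorConfig(
        structure=CausalStructure.CAUSAL,
        causal=CorrelationTriple(0.72, 0.9, 0.8, role=Role.CAUSAL),
        err_x=1.0,
        err_m=1.0,
        err_y=1.0,
    )


def random_configs(n, seed, structures=None):
    """Beta-sampled configs across the constrained structures."""
    structures = structures or list(CausalStructure)[:3]
    out = []
    per = max(1, n // len(structures))
    for i, s in enumerate(structures):
        out.extend(
            sample_configs(SimulationDesign(structure=s, n_configs=per, seed=seed + i))
        )
    return out
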