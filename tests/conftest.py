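"""Shared fixtures: small simulated panels reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from finescale import simdata

#: Posterior-median-like parameter point used for direction checks: a very
#: small U population and a very large B population.
MEDIAN_PARAMS = simdata.ParameterVector(
    Ne_GRUBP=27079.55, Ne_GR=1586.39, Ne_UPB=1248.50, Ne_G=840.17,
    Ne_R=1678.87, Ne_U=320.11, Ne_P=719.12, Ne_B=7766.21,
    t_GRUBP=2480.21, t_GR=1960.69, t_UPB=1698.16, m=0.0,
)


def structured_params(t_root: float = 14500.0, m: float = 0.0) -> simdata.ParameterVector:
    """Median-like sizes with a configurable (old by default) root split."""
    return simdata.ParameterVector(
        Ne_GRUBP=27000, Ne_GR=1600, Ne_UPB=1250, Ne_G=840, Ne_R=1680,
        Ne_U=320, Ne_P=720, Ne_B=7766, t_GRUBP=t_root,
        t_GR=min(2000.0, t_root), t_UPB=min(1700.0, t_root), m=m,
    )


def splits_gr_upb(labels: np.ndarray, regions: np.ndarray) -> bool:
    """True if a 2-group labelling separates {G,R} from {U,P,B} exactly."""
    labels = np.asarray(labels)
    gr = np.isin(regions, ["G", "R"])
    return (
        len(set(labels[gr])) == 1
        and len(set(labels[~gr])) == 1
        and labels[gr][0] != labels[~gr][0]
    )


@pytest.fixture(scope="session")
def small_panel() -> simdata.HaplotypePanel:
    """500 kb panel under an old, migration-free split (clear structure)."""
    return simdata.simulate_dataset(
        structured_params(), simdata.ModelConfig(sequence_length=5e5, seed=42)
    )


@pytest.fixture(scope="session")
def panmictic_panel() -> simdata.HaplotypePanel:
    """500 kb panel with no population structure."""
    return simdata.simulate_dataset(
        simdata.panmictic_params(5000.0),
        simdata.ModelConfig(sequence_length=5e5, seed=43),
    )
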