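"""Shared fixtures.

The expensive artifacts (neural-ODE fits and full framework runs on the
regime-switching benchmark) are session-scoped and shared across test
modules; everything else is generated on demand. All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from msid import case_parameters, make_fixture
from msid.node import NodeConfig, fit_node
from msid.pipeline import desk_profile, run_pipeline
from msid.simulate import NoiseSpec


@pytest.fixture(scope="session")
def case1_params():
    return case_parameters("case1")


@pytest.fixture(scope="session")
def case2_params():
    return case_parameters("case2")


@pytest.fixture(scope="session")
def case3_params():
    return case_parameters("case3")


@pytest.fixture(scope="session")
def case1_surrogate():
    """Neural-ODE surrogate fitted to the noiseless sQSSA-regime case."""
    traj = make_fixture("case1", "full")
    return traj, fit_node(traj, NodeConfig(epochs=500, seed=0))


@pytest.fixture(scope="session")
def case3_report():
    """Full framework run (NN Jacobian) on the deterministic benchmark."""
    return run_pipeline(desk_profile(case="case3", model="full",
                                     force_framework=True, seed=0))


@pytest.fixture(scope="session")
def case3_report_analytic():
    """Same flow with the analytic Jacobian injected."""
    return run_pipeline(desk_profile(case="case3", model="full",
                                     force_framework=True, seed=0,
                                     jacobian_source="analytic"))


@pytest.fixture(scope="session")
def case3_report_additive():
    return run_pipeline(desk_profile(case="case3", model="full",
                                     force_framework=True, seed=0,
                                     noise=NoiseSpec("additive", 0.02)))


@pytest.fixture(scope="session")
def case3_report_multiplicative():
    return run_pipeline(desk_profile(case="case3", model="full",
                                     force_framework=True, seed=0,
                                     noise=NoiseSpec("multiplicative", 0.01)))


@pytest.fixture(scope="session")
def case3_pea_report():
    """Natural decision flow on reduced-model data: direct fit fails, the
    framework path engages."""
    return run_pipeline(desk_profile(case="case3", model="PEA", seed=0))


def split_by_regime(report):
    """Map regime label -> SplitResult for a framework report."""
    return {sp.regime: sp for sp in report.splits}
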