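"""Shared fixtures: study-scale synthetic cohorts built once per session."""

import numpy as np
import pandas as pd
import pytest

from mirmod import (CoexpressionNetwork, ExpressionMatrix, generate_cohorts)
from mirmod.simulate import SyntheticDesign, default_design


@pytest.fixture(scope="session")
def study():
    """Study-scale cohorts (300 features, 10 modules, rho 0.7, 90/90/34
    samples, 3 modules disrupted in norm) plus the fitted reference
    network and its detected partition — the conditions the acceptance
    checks exercise, built once."""
    design = default_design(seed=1)
    ref, rep, norm, truth = generate_cohorts(design)
    net = CoexpressionNetwork.from_expression(ref)
    part = net.detect_modules(min_module_size=3)
    return {"design": design, "ref": ref, "rep": rep, "norm": norm,
            "truth": truth, "net": net, "partition": part}


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(
        n_features=60, module_sizes=[10, 8, 6], rho_within=0.7,
        n_ref=40, n_rep=40, n_norm=20, disrupted_in_norm={3},
        de_features={}, rep_noise_sd=0.3, seed=5)


@pytest.fixture(scope="session")
def small_cohorts(small_design):
    ref, rep, norm, truth = generate_cohorts(small_design)
    return {"ref": ref, "rep": rep, "norm": norm, "truth": truth}


@pytest.fixture()
def toy_expr():
    """5 features x 8 samples deterministic matrix."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(rng.standard_normal((5, 8)),
                        index=[f"f{i}" for i in range(5)],
                        columns=[f"s{j}" for j in range(8)])
    return ExpressionMatrix(data)
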