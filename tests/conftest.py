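"""Shared fixtures and the independent brute-force comparison oracle.

The oracle computes two-arm posterior comparison probabilities by direct
2-D quadrature of the joint beta density over the unit square.  It shares no
code path with the package's Monte-Carlo sampler or its adaptive 1-D
quadrature, so agreement between the three is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from screentrial import Arm, PopulationSpec, Subgroup, TrialConfig
from screentrial.bayes import BetaParams


def oracle_grid_2d(a: BetaParams, b: BetaParams, n: int = 1200):
    """Probability masses of the two posteriors on a shared uniform grid."""
    x = (np.arange(n) + 0.5) / n
    wa = beta_dist.pdf(x, a.alpha, a.beta)
    wb = beta_dist.pdf(x, b.alpha, b.beta)
    return x, wa / wa.sum(), wb / wb.sum()


def oracle_prob_best(a: BetaParams, b: BetaParams, n: int = 2000) -> float:
    """P(X_a > X_b) by brute-force summation over the discretised unit square.

    Same-cell mass (a discretisation artefact of the shared grid) is split
    evenly, the midpoint treatment of a continuous tie.
    """
    x, wa, wb = oracle_grid_2d(a, b, n)
    cum_a_gt = 1.0 - np.cumsum(wa)  # P(X > x_j) on the shared grid
    return float(np.sum(wb * (cum_a_gt + 0.5 * wa)))


def oracle_prob_within_margin(
    a: BetaParams, b: BetaParams, margin: float, n: int = 1200
) -> float:
    """P(|X_a - X_b| < margin) by brute-force 2-D summation."""
    x, wa, wb = oracle_grid_2d(a, b, n)
    inside = np.abs(x[:, None] - x[None, :]) < margin
    return float(wa @ inside @ wb)


@pytest.fixture
def two_arm_config():
    def make(seed: int = 0, **kwargs) -> TrialConfig:
        return TrialConfig(
            arms=[Arm("control", is_control=True), Arm("intervention")],
            master_seed=seed,
            **kwargs,
        )

    return make


@pytest.fixture
def uniform_population():
    def make(
        baseline: float = 0.50, effect: float = 0.0, seed: int = 0
    ) -> PopulationSpec:
        return PopulationSpec(
            subgroups=(Subgroup("all", 1.0, baseline),),
            arm_effects={"control": 0.0, "intervention": effect},
            seed=seed,
        )

    return make
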