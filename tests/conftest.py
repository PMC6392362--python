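"""Shared fixtures and independent brute-force oracles.

The oracles enumerate every latent configuration (detection class,
occupancy sequence, availability sequence) directly from the model's
generative description. They are deliberately written without reference
to the package's forward recursions so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from occdyn.histories import MISSING, DetectionHistory
from occdyn.likelihood import ParameterPoint


def enumerate_stop_prob(y_row, theta0, theta, theta_prime, p_row) -> float:
    """Pr(y_row | occupied, one class) by summing over all 2^S availability paths."""
    S = len(y_row)
    total = 0.0
    for mask in range(2**S):
        avail = [(mask >> s) & 1 for s in range(S)]
        pr = theta0 if avail[0] else 1.0 - theta0
        for s in range(1, S):
            trans = theta_prime if avail[s - 1] else theta
            pr *= trans if avail[s] else 1.0 - trans
        for s in range(S):
            if y_row[s] == MISSING:
                continue
            if avail[s]:
                pr *= p_row[s] if y_row[s] == 1 else 1.0 - p_row[s]
            elif y_row[s] == 1:
                pr = 0.0
                break
        total += pr
    return total


def enumerate_route_likelihood(obs: np.ndarray, pp: ParameterPoint) -> float:
    """Full enumeration over classes x occupancy sequences x availability."""
    T, _ = obs.shape
    total = 0.0
    for weight, p_mat in ((pp.pi_mix, pp.p1), (1.0 - pp.pi_mix, pp.p2)):
        for zmask in range(2**T):
            z = [(zmask >> t) & 1 for t in range(T)]
            pr = pp.psi if z[0] else 1.0 - pp.psi
            for t in range(T - 1):
                if z[t] == 1:
                    pr *= pp.epsilon[t] if z[t + 1] == 0 else 1.0 - pp.epsilon[t]
                else:
                    pr *= pp.gamma[t] if z[t + 1] == 1 else 1.0 - pp.gamma[t]
            for t in range(T):
                if z[t] == 1:
                    pr *= enumerate_stop_prob(
                        obs[t], pp.theta0, pp.theta, pp.theta_prime, p_mat[t]
                    )
                elif (obs[t] == 1).any():
                    pr = 0.0
                    break
            total += weight * pr
    return total


def random_parameter_point(rng: np.random.Generator, T: int, S: int) -> ParameterPoint:
    return ParameterPoint(
        psi=rng.uniform(),
        theta=rng.uniform(),
        theta_prime=rng.uniform(),
        theta0=rng.uniform(),
        p1=rng.uniform(size=(T, S)),
        p2=rng.uniform(size=(T, S)),
        pi_mix=rng.uniform(),
        gamma=rng.uniform(size=T - 1),
        epsilon=rng.uniform(size=T - 1),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_history():
    obs = np.array([[0, 1, 0], [0, 0, 0]], dtype=np.int8)
    return DetectionHistory("r0001", [2000, 2001], obs)
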