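"""Numerical kernels for the two-state annual occupancy hidden Markov model.

State z_t in {0, 1} is region occupancy; transitions are governed by
colonization (gamma_t) and extinction (eps_t) probabilities indexed by the
*arrival* year t, emissions by detection probability p_t with no false
positives.  Detection histories use -1 for unsurveyed (missing) years, which
contribute no emission term.  All kernels run over every region of one
species at once and use scaled forward/backward recursions.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def forward_nll(y, p, gamma, eps, psi1):
    """Negative log-likelihood summed over regions (scaled forward pass)."""
    R, T = y.shape
    total = 0.0
    for r in range(R):
        a1 = psi1
        a0 = 1.0 - psi1
        if y[r, 0] == 1:
            a1 *= p[r, 0]
            a0 *= 0.0
        elif y[r, 0] == 0:
            a1 *= 1.0 - p[r, 0]
        c = a0 + a1
        if c <= 0.0:
            return np.inf
        total -= np.log(c)
        a0 /= c
        a1 /= c
        for t in range(1, T):
            b1 = a0 * gamma[r, t] + a1 * (1.0 - eps[r, t])
            b0 = a0 * (1.0 - gamma[r, t]) + a1 * eps[r, t]
            if y[r, t] == 1:
                b1 *= p[r, t]
                b0 *= 0.0
            elif y[r, t] == 0:
                b1 *= 1.0 - p[r, t]
            c = b0 + b1
            if c <= 0.0:
                return np.inf
            total -= np.log(c)
            a0 = b0 / c
            a1 = b1 / c
    return total


@njit(cache=False)
def smoothed_occupancy(y, p, gamma, eps, psi1):
    """Posterior Pr(z_t = 1 | full detection history), per region and year."""
    R, T = y.shape
    out = np.empty((R, T))
    f0 = np.empty(T)
    f1 = np.empty(T)
    for r in range(R):
        a1 = psi1
        a0 = 1.0 - psi1
        if y[r, 0] == 1:
            a1 *= p[r, 0]
            a0 *= 0.0
        elif y[r, 0] == 0:
            a1 *= 1.0 - p[r, 0]
        c = a0 + a1
        a0 /= c
        a1 /= c
        f0[0] = a0
        f1[0] = a1
        for t in range(1, T):
            b1 = a0 * gamma[r, t] + a1 * (1.0 - eps[r, t])
            b0 = a0 * (1.0 - gamma[r, t]) + a1 * eps[r, t]
            if y[r, t] == 1:
                b1 *= p[r, t]
                b0 *= 0.0
            elif y[r, t] == 0:
                b1 *= 1.0 - p[r, t]
            c = b0 + b1
            a0 = b0 / c
            a1 = b1 / c
            f0[t] = a0
            f1[t] = a1
        # backward pass
        bb0 = 1.0
        bb1 = 1.0
        out[r, T - 1] = f1[T - 1]
        for t in range(T - 2, -1, -1):
            e0 = 1.0
            e1 = 1.0
            if y[r, t + 1] == 1:
                e1 = p[r, t + 1]
                e0 = 0.0
            elif y[r, t + 1] == 0:
                e1 = 1.0 - p[r, t + 1]
            n0 = (1.0 - gamma[r, t + 1]) * e0 * bb0 + gamma[r, t + 1] * e1 * bb1
            n1 = eps[r, t + 1] * e0 * bb0 + (1.0 - eps[r, t + 1]) * e1 * bb1
            c = n0 + n1
            bb0 = n0 / c
            bb1 = n1 / c
            num = f1[t] * bb1
            den = f0[t] * bb0 + f1[t] * bb1
            out[r, t] = num / den
    return out


def project_occupancy(psi1: float, gamma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Marginal (data-independent) occupancy recursion.

    psi_t = psi_{t-1} (1 - eps_t) + (1 - psi_{t-1}) gamma_t, psi_0 = psi1.
    """
    gamma = np.asarray(gamma, dtype=float)
    eps = np.asarray(eps, dtype=float)
    R, T = gamma.shape
    psi = np.empty((R, T))
    psi[:, 0] = psi1
    for t in range(1, T):
        psi[:, t] = psi[:, t - 1] * (1.0 - eps[:, t]) + (1.0 - psi[:, t - 1]) * gamma[
            :, t
        ]
    return psi


def simulate_states(rng, psi1, gamma, eps):
    """Draw latent occupancy chains z (R, T) from the Markov dynamics."""
    R, T = gamma.shape
    z = np.empty((R, T), dtype=np.int8)
    z[:, 0] = rng.random(R) < psi1
    u = rng.random((R, T))
    for t in range(1, T):
        stay = z[:, t - 1] == 1
        z[:, t] = np.where(stay, u[:, t] > eps[:, t], u[:, t] < gamma[:, t])
    return z


def simulate_detections(rng, z, p, surveyed):
    """Bernoulli detections given latent states; -1 outside the survey mask."""
    y = np.full(z.shape, -1, dtype=np.int8)
    det = (rng.random(z.shape) < p) & (z == 1)
    y[surveyed] = det[surveyed]
    return y
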