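"""Numba forward-algorithm kernel for the marginalized multistate likelihood.

Latent states are indexed 0-3 (the four living family-association states)
plus 4 = dead. The per-age transition matrix ``trans[a-1]`` combines
survival and state movement:

    trans[a-1][s, s2] = phi_s(a) * psi_{s->s2}(a)   (living s, s2)
    trans[a-1][s, 4]  = 1 - phi_s(a)
    trans[a-1][4, 4]  = 1

Emission given a living latent state s: the true state with probability
``p[s]``, code 0 otherwise; the dead state always emits 0. The forward pass
conditions on first capture (alive, state 1, observed) and rescales each
step, accumulating the log normalizer.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _forward(obs, length, trans, p, alpha, new):
    """Forward log-likelihood of one history using caller-owned buffers."""
    for s in range(5):
        alpha[s] = 0.0
    alpha[0] = 1.0
    ll = 0.0
    for j in range(1, length):
        a = j if j < 7 else 7
        T = trans[a - 1]
        for s2 in range(5):
            new[s2] = 0.0
        for s in range(5):
            av = alpha[s]
            if av > 0.0:
                for s2 in range(5):
                    new[s2] += av * T[s, s2]
        o = obs[j]
        if o > 0:
            norm = new[o - 1] * p[o - 1]
            if norm <= 0.0:
                return -np.inf
            for s in range(5):
                alpha[s] = 0.0
            alpha[o - 1] = 1.0
        else:
            norm = new[4]
            for s in range(4):
                alpha[s] = new[s] * (1.0 - p[s])
                norm += alpha[s]
            alpha[4] = new[4]
            if norm <= 0.0:
                return -np.inf
            for s in range(5):
                alpha[s] /= norm
        ll += np.log(norm)
    return ll


@njit(cache=True)
def forward_one(obs, length, trans, p):
    """Log-likelihood of one history (observations from marking onward)."""
    alpha = np.empty(5)
    new = np.empty(5)
    return _forward(obs, length, trans, p, alpha, new)


@njit(cache=True)
def total_loglik(patterns, lengths, counts, trans, p):
    """Weighted sum of forward log-likelihoods over deduplicated patterns."""
    alpha = np.empty(5)
    new = np.empty(5)
    total = 0.0
    for k in range(patterns.shape[0]):
        ll = _forward(patterns[k], lengths[k], trans, p, alpha, new)
        if ll == -np.inf:
            return -np.inf
        total += counts[k] * ll
    return total
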