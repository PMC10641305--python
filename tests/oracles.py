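"""Independent brute-force oracles used only by the test suite.

These deliberately use the data-augmented formulation (explicit latent
alive/dead chains) and naive enumeration so they share no code path with
the marginalized likelihood they check.
"""

import itertools

import numpy as np


def enumerate_cjs_loglik(history, phi, p) -> float:
    """Exhaustive latent-state CJS likelihood for one capture history.

    Sums, over every alive/dead sequence z with z[first]=1, the product of
    the Bernoulli state transitions z[t+1] ~ Bern(z[t] * phi[t]) and the
    Bernoulli observations y[t] ~ Bern(z[t] * p[t]) for t > first.
    """
    y = np.asarray(history, dtype=int)
    T = len(y)
    first = int(np.argmax(y == 1))
    tail = T - 1 - first
    total = 0.0
    for bits in itertools.product((0, 1), repeat=tail):
        z = np.zeros(T, dtype=int)
        z[first] = 1
        z[first + 1:] = bits
        prob = 1.0
        for t in range(first, T - 1):
            p_alive = z[t] * phi[t]
            prob *= p_alive if z[t + 1] == 1 else 1.0 - p_alive
        for t in range(first + 1, T):
            p_det = z[t] * p[t - 1]
            prob *= p_det if y[t] == 1 else 1.0 - p_det
        total += prob
    return float(np.log(total))


def all_history_probs(first, T, phi, p):
    """Probabilities of every possible post-first-capture history."""
    probs = []
    for bits in itertools.product((0, 1), repeat=T - 1 - first):
        y = np.zeros(T, dtype=int)
        y[first] = 1
        y[first + 1:] = bits
        probs.append(np.exp(enumerate_cjs_loglik(y, phi, p)))
    return np.array(probs)


def permutation_pvalue(u, v, n_perm=10000, seed=0) -> float:
    """Two-sided permutation p-value for a Pearson correlation."""
    rng = np.random.default_rng(seed)
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    r_obs = abs(np.corrcoef(u, v)[0, 1])
    count = 0
    for _ in range(n_perm):
        r = np.corrcoef(u, rng.permutation(v))[0, 1]
        if abs(r) >= r_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
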