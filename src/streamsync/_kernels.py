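"""Compiled kernels: m-array CJS log-likelihood and the MCMC chain runner.

The sampler is an adaptive random-walk Metropolis-within-Gibbs over the
marginalized CJS posterior: scalar proposals for intercepts, effect sizes,
random effects and detection probabilities (proposal scales adapted during
burn-in toward a 0.44 acceptance rate, then frozen), conjugate truncated
inverse-gamma Gibbs draws for the random-effect variances under the
Uniform(0, sd_upper) prior on each sd, and likelihood-invariant "ridge"
swap moves that transfer mass between confounded location parameters
(mu <-> e4, e1 <-> e2, e1 <-> e3, e2 <-> e4, e3 <-> e4, beta <-> e1)
accepted on the prior ratio alone.  Everything runs in one nopython
function so a full sweep costs microseconds regardless of sample size
(the likelihood depends on the m-array, not on individuals).
"""

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def group_loglik(m_g, never_g, phi_g, p_g):
    """CJS multinomial log-likelihood for one group's m-array rows.

    phi_g[t] is survival over interval t (occasion t -> t+1, 0-based) and
    p_g[t] is detection at occasion t+1.
    """
    Tm1 = m_g.shape[0]
    chi = np.empty(Tm1 + 1)
    chi[Tm1] = 1.0
    for t in range(Tm1 - 1, -1, -1):
        chi[t] = (1.0 - phi_g[t]) + phi_g[t] * (1.0 - p_g[t]) * chi[t + 1]
    ll = 0.0
    for t in range(Tm1):
        if never_g[t] > 0:
            ll += never_g[t] * np.log(chi[t])
        logprod = 0.0
        for c in range(t + 1, Tm1 + 1):
            if c == t + 1:
                logprod = np.log(phi_g[t])
            else:
                logprod += np.log(1.0 - p_g[c - 2]) + np.log(phi_g[c - 1])
            cnt = m_g[t, c - 1]
            if cnt > 0:
                ll += cnt * (logprod + np.log(p_g[c - 1]))
    return ll


@njit(cache=True)
def marray_loglik(m, never, phi, p):
    G = m.shape[0]
    total = 0.0
    for g in range(G):
        total += group_loglik(m[g], never[g], phi[g], p[g])
    return total


@njit(cache=True)
def _phi_scalar(eta, nd_exp):
    v = 1.0 / (1.0 + np.exp(-eta))
    v = v ** nd_exp
    if v < _EPS:
        v = _EPS
    elif v > 1.0 - _EPS:
        v = 1.0 - _EPS
    return v


@njit(cache=True)
def _gibbs_var(e, sd_upper, current):
    """Draw a variance from its truncated inverse-gamma full conditional
    (Uniform(0, sd_upper) prior on the sd)."""
    n = e.shape[0]
    ss = 0.0
    for i in range(n):
        ss += e[i] * e[i]
    if ss < 1e-12:
        ss = 1e-12
    a = (n - 1) / 2.0
    vmax = sd_upper * sd_upper
    for _ in range(100):
        gam = np.random.gamma(a, 1.0)
        if gam > 0.0:
            v = (ss / 2.0) / gam
            if v < vmax:
                return v
    return current


@njit(cache=True)
def run_chain(m, never, gj, gs, nd_exp, x, beta_mode, use_eps,
              mu_sd, beta_sd, sd_upper, p_init,
              n_iter, n_burn, thin, seed, init_jitter,
              out_mu, out_beta, out_eps1, out_eps2, out_eps3, out_eps4,
              out_s2t, out_s2j, out_s2s, out_s2js, out_p, out_dev):
    np.random.seed(seed)
    G, Tm1 = p_init.shape
    J = int(gj.max()) + 1
    S = int(gs.max()) + 1
    NB = out_beta.shape[1]

    # -- state ---------------------------------------------------------
    mu = init_jitter * np.random.randn(G)
    beta = np.zeros(NB)
    if beta_mode > 0:
        beta += init_jitter * np.random.randn(NB)
    eps1 = np.zeros(Tm1)
    eps2 = np.zeros((J, Tm1))
    eps3 = np.zeros((S, Tm1))
    eps4 = np.zeros((J, S, Tm1))
    if use_eps == 1:
        eps1 += 0.05 * np.random.randn(Tm1)
        eps2 += 0.05 * np.random.randn(J, Tm1)
        eps3 += 0.05 * np.random.randn(S, Tm1)
        eps4 += 0.05 * np.random.randn(J, S, Tm1)
    s2t = 0.25
    s2j = 0.25 * np.ones(J)
    s2s = 0.25 * np.ones(S)
    s2js = 0.25 * np.ones((J, S))
    p = np.empty((G, Tm1))
    for g in range(G):
        for t in range(Tm1):
            v = p_init[g, t] + 0.05 * np.random.randn()
            p[g, t] = min(max(v, 0.02), 0.98)

    eta = np.empty((G, Tm1))
    phi = np.empty((G, Tm1))
    for g in range(G):
        j = gj[g]
        s = gs[g]
        for t in range(Tm1):
            e = mu[g] + eps1[t] + eps2[j, t] + eps3[s, t] + eps4[j, s, t]
            if beta_mode == 1:
                e += beta[0] * x[t]
            elif beta_mode == 2:
                e += beta[j] * x[t]
            eta[g, t] = e
            phi[g, t] = _phi_scalar(e, nd_exp[t])

    ll_g = np.empty(G)
    for g in range(G):
        ll_g[g] = group_loglik(m[g], never[g], phi[g], p[g])

    # -- adaptive proposal scales and acceptance counters --------------
    sc_mu = 0.2 * np.ones(G)
    ac_mu = np.zeros(G)
    sc_beta = 0.2 * np.ones(NB)
    ac_beta = np.zeros(NB)
    sc_e1 = 0.2 * np.ones(Tm1)
    ac_e1 = np.zeros(Tm1)
    sc_e2 = 0.2 * np.ones((J, Tm1))
    ac_e2 = np.zeros((J, Tm1))
    sc_e3 = 0.2 * np.ones((S, Tm1))
    ac_e3 = np.zeros((S, Tm1))
    sc_e4 = 0.2 * np.ones((J, S, Tm1))
    ac_e4 = np.zeros((J, S, Tm1))
    sc_p = 0.1 * np.ones((G, Tm1))
    ac_p = np.zeros((G, Tm1))
    sc_swap = 0.3 * np.ones(6)
    ac_swap = np.zeros(6)
    n_swap = np.zeros(6)

    phibuf = np.empty(Tm1)
    pbuf = np.empty(Tm1)
    new_ll = np.empty(G)
    new_phi = np.empty(G)

    batch = 50
    target = 0.44
    store = 0

    for it in range(n_iter):
        # ---- mu -------------------------------------------------------
        for g in range(G):
            d = sc_mu[g] * np.random.randn()
            for t in range(Tm1):
                phibuf[t] = _phi_scalar(eta[g, t] + d, nd_exp[t])
            llnew = group_loglik(m[g], never[g], phibuf, p[g])
            dpost = (llnew - ll_g[g]) \
                - ((mu[g] + d) ** 2 - mu[g] ** 2) / (2.0 * mu_sd * mu_sd)
            if np.log(np.random.rand()) < dpost:
                mu[g] += d
                for t in range(Tm1):
                    eta[g, t] += d
                    phi[g, t] = phibuf[t]
                ll_g[g] = llnew
                ac_mu[g] += 1.0

        # ---- beta -----------------------------------------------------
        if beta_mode == 1:
            d = sc_beta[0] * np.random.randn()
            dll = 0.0
            for g in range(G):
                for t in range(Tm1):
                    phibuf[t] = _phi_scalar(eta[g, t] + d * x[t], nd_exp[t])
                new_ll[g] = group_loglik(m[g], never[g], phibuf, p[g])
                dll += new_ll[g] - ll_g[g]
            dpost = dll - ((beta[0] + d) ** 2 - beta[0] ** 2) / (2.0 * beta_sd * beta_sd)
            if np.log(np.random.rand()) < dpost:
                beta[0] += d
                for g in range(G):
                    for t in range(Tm1):
                        eta[g, t] += d * x[t]
                        phi[g, t] = _phi_scalar(eta[g, t], nd_exp[t])
                    ll_g[g] = new_ll[g]
                ac_beta[0] += 1.0
        elif beta_mode == 2:
            for j in range(J):
                d = sc_beta[j] * np.random.randn()
                dll = 0.0
                for g in range(G):
                    if gj[g] != j:
                        continue
                    for t in range(Tm1):
                        phibuf[t] = _phi_scalar(eta[g, t] + d * x[t], nd_exp[t])
                    new_ll[g] = group_loglik(m[g], never[g], phibuf, p[g])
                    dll += new_ll[g] - ll_g[g]
                dpost = dll - ((beta[j] + d) ** 2 - beta[j] ** 2) / (2.0 * beta_sd * beta_sd)
                if np.log(np.random.rand()) < dpost:
                    beta[j] += d
                    for g in range(G):
                        if gj[g] != j:
                            continue
                        for t in range(Tm1):
                            eta[g, t] += d * x[t]
                            phi[g, t] = _phi_scalar(eta[g, t], nd_exp[t])
                        ll_g[g] = new_ll[g]
                    ac_beta[j] += 1.0

        if use_eps == 1:
            # ---- eps1[t]: all groups ---------------------------------
            for t in range(Tm1):
                d = sc_e1[t] * np.random.randn()
                dll = 0.0
                for g in range(G):
                    for u in range(Tm1):
                        phibuf[u] = phi[g, u]
                    phibuf[t] = _phi_scalar(eta[g, t] + d, nd_exp[t])
                    new_phi[g] = phibuf[t]
                    new_ll[g] = group_loglik(m[g], never[g], phibuf, p[g])
                    dll += new_ll[g] - ll_g[g]
                dpost = dll - ((eps1[t] + d) ** 2 - eps1[t] ** 2) / (2.0 * s2t)
                if np.log(np.random.rand()) < dpost:
                    eps1[t] += d
                    for g in range(G):
                        eta[g, t] += d
                        phi[g, t] = new_phi[g]
                        ll_g[g] = new_ll[g]
                    ac_e1[t] += 1.0

            # ---- eps2[j,t]: groups of species j ----------------------
            for j in range(J):
                for t in range(Tm1):
                    d = sc_e2[j, t] * np.random.randn()
                    dll = 0.0
                    for g in range(G):
                        if gj[g] != j:
                            continue
                        for u in range(Tm1):
                            phibuf[u] = phi[g, u]
                        phibuf[t] = _phi_scalar(eta[g, t] + d, nd_exp[t])
                        new_phi[g] = phibuf[t]
                        new_ll[g] = group_loglik(m[g], never[g], phibuf, p[g])
                        dll += new_ll[g] - ll_g[g]
                    dpost = dll - ((eps2[j, t] + d) ** 2 - eps2[j, t] ** 2) / (2.0 * s2j[j])
                    if np.log(np.random.rand()) < dpost:
                        eps2[j, t] += d
                        for g in range(G):
                            if gj[g] != j:
                                continue
                            eta[g, t] += d
                            phi[g, t] = new_phi[g]
                            ll_g[g] = new_ll[g]
                        ac_e2[j, t] += 1.0

            # ---- eps3[s,t]: groups of stream s -----------------------
            for s in range(S):
                for t in range(Tm1):
                    d = sc_e3[s, t] * np.random.randn()
                    dll = 0.0
                    for g in range(G):
                        if gs[g] != s:
                            continue
                        for u in range(Tm1):
                            phibuf[u] = phi[g, u]
                        phibuf[t] = _phi_scalar(eta[g, t] + d, nd_exp[t])
                        new_phi[g] = phibuf[t]
                        new_ll[g] = group_loglik(m[g], never[g], phibuf, p[g])
                        dll += new_ll[g] - ll_g[g]
                    dpost = dll - ((eps3[s, t] + d) ** 2 - eps3[s, t] ** 2) / (2.0 * s2s[s])
                    if np.log(np.random.rand()) < dpost:
                        eps3[s, t] += d
                        for g in range(G):
                            if gs[g] != s:
                                continue
                            eta[g, t] += d
                            phi[g, t] = new_phi[g]
                            ll_g[g] = new_ll[g]
                        ac_e3[s, t] += 1.0

            # ---- eps4[j,s,t]: one group ------------------------------
            for g in range(G):
                j = gj[g]
                s = gs[g]
                for t in range(Tm1):
                    d = sc_e4[j, s, t] * np.random.randn()
                    for u in range(Tm1):
                        phibuf[u] = phi[g, u]
                    phibuf[t] = _phi_scalar(eta[g, t] + d, nd_exp[t])
                    llnew = group_loglik(m[g], never[g], phibuf, p[g])
                    dpost = (llnew - ll_g[g]) \
                        - ((eps4[j, s, t] + d) ** 2 - eps4[j, s, t] ** 2) / (2.0 * s2js[j, s])
                    if np.log(np.random.rand()) < dpost:
                        eps4[j, s, t] += d
                        eta[g, t] += d
                        phi[g, t] = phibuf[t]
                        ll_g[g] = llnew
                        ac_e4[j, s, t] += 1.0

            # ---- variance Gibbs --------------------------------------
            s2t = _gibbs_var(eps1, sd_upper, s2t)
            for j in range(J):
                s2j[j] = _gibbs_var(eps2[j], sd_upper, s2j[j])
            for s in range(S):
                s2s[s] = _gibbs_var(eps3[s], sd_upper, s2s[s])
            for j in range(J):
                for s in range(S):
                    s2js[j, s] = _gibbs_var(eps4[j, s], sd_upper, s2js[j, s])

            # ---- likelihood-invariant swap moves ---------------------
            # (0) e1[t] <-> e2[:,t]
            for t in range(Tm1):
                d = sc_swap[0] * np.random.randn()
                dpr = -((eps1[t] + d) ** 2 - eps1[t] ** 2) / (2.0 * s2t)
                for j in range(J):
                    dpr -= ((eps2[j, t] - d) ** 2 - eps2[j, t] ** 2) / (2.0 * s2j[j])
                n_swap[0] += 1.0
                if np.log(np.random.rand()) < dpr:
                    eps1[t] += d
                    for j in range(J):
                        eps2[j, t] -= d
                    ac_swap[0] += 1.0
            # (1) e1[t] <-> e3[:,t]
            for t in range(Tm1):
                d = sc_swap[1] * np.random.randn()
                dpr = -((eps1[t] + d) ** 2 - eps1[t] ** 2) / (2.0 * s2t)
                for s in range(S):
                    dpr -= ((eps3[s, t] - d) ** 2 - eps3[s, t] ** 2) / (2.0 * s2s[s])
                n_swap[1] += 1.0
                if np.log(np.random.rand()) < dpr:
                    eps1[t] += d
                    for s in range(S):
                        eps3[s, t] -= d
                    ac_swap[1] += 1.0
            # (2) e2[j,t] <-> e4[j,:,t]
            for j in range(J):
                for t in range(Tm1):
                    d = sc_swap[2] * np.random.randn()
                    dpr = -((eps2[j, t] + d) ** 2 - eps2[j, t] ** 2) / (2.0 * s2j[j])
                    for s in range(S):
                        dpr -= ((eps4[j, s, t] - d) ** 2 - eps4[j, s, t] ** 2) / (2.0 * s2js[j, s])
                    n_swap[2] += 1.0
                    if np.log(np.random.rand()) < dpr:
                        eps2[j, t] += d
                        for s in range(S):
                            eps4[j, s, t] -= d
                        ac_swap[2] += 1.0
            # (3) e3[s,t] <-> e4[:,s,t]
            for s in range(S):
                for t in range(Tm1):
                    d = sc_swap[3] * np.random.randn()
                    dpr = -((eps3[s, t] + d) ** 2 - eps3[s, t] ** 2) / (2.0 * s2s[s])
                    for j in range(J):
                        dpr -= ((eps4[j, s, t] - d) ** 2 - eps4[j, s, t] ** 2) / (2.0 * s2js[j, s])
                    n_swap[3] += 1.0
                    if np.log(np.random.rand()) < dpr:
                        eps3[s, t] += d
                        for j in range(J):
                            eps4[j, s, t] -= d
                        ac_swap[3] += 1.0
            # (4) mu[g] <-> e4[j,s,:]
            for g in range(G):
                j = gj[g]
                s = gs[g]
                d = sc_swap[4] * np.random.randn()
                dpr = -((mu[g] + d) ** 2 - mu[g] ** 2) / (2.0 * mu_sd * mu_sd)
                for t in range(Tm1):
                    dpr -= ((eps4[j, s, t] - d) ** 2 - eps4[j, s, t] ** 2) / (2.0 * s2js[j, s])
                n_swap[4] += 1.0
                if np.log(np.random.rand()) < dpr:
                    mu[g] += d
                    for t in range(Tm1):
                        eps4[j, s, t] -= d
                    ac_swap[4] += 1.0
            # (5) beta <-> e1 (shared-beta models only)
            if beta_mode == 1:
                d = sc_swap[5] * np.random.randn()
                dpr = -((beta[0] + d) ** 2 - beta[0] ** 2) / (2.0 * beta_sd * beta_sd)
                for t in range(Tm1):
                    dpr -= ((eps1[t] - d * x[t]) ** 2 - eps1[t] ** 2) / (2.0 * s2t)
                n_swap[5] += 1.0
                if np.log(np.random.rand()) < dpr:
                    beta[0] += d
                    for t in range(Tm1):
                        eps1[t] -= d * x[t]
                    ac_swap[5] += 1.0

        # ---- detection p ---------------------------------------------
        for g in range(G):
            for t in range(Tm1):
                d = sc_p[g, t] * np.random.randn()
                pn = p[g, t] + d
                if pn <= 0.001 or pn >= 0.999:
                    continue
                for u in range(Tm1):
                    pbuf[u] = p[g, u]
                pbuf[t] = pn
                llnew = group_loglik(m[g], never[g], phi[g], pbuf)
                if np.log(np.random.rand()) < llnew - ll_g[g]:
                    p[g, t] = pn
                    ll_g[g] = llnew
                    ac_p[g, t] += 1.0

        # ---- burn-in adaptation --------------------------------------
        if it < n_burn and (it + 1) % batch == 0:
            fac_up = np.exp(0.1)
            for g in range(G):
                sc_mu[g] *= fac_up if ac_mu[g] / batch > target else 1.0 / fac_up
                sc_mu[g] = min(max(sc_mu[g], 1e-3), 5.0)
                ac_mu[g] = 0.0
            for b in range(NB):
                sc_beta[b] *= fac_up if ac_beta[b] / batch > target else 1.0 / fac_up
                sc_beta[b] = min(max(sc_beta[b], 1e-3), 5.0)
                ac_beta[b] = 0.0
            if use_eps == 1:
                for t in range(Tm1):
                    sc_e1[t] *= fac_up if ac_e1[t] / batch > target else 1.0 / fac_up
                    sc_e1[t] = min(max(sc_e1[t], 1e-3), 5.0)
                    ac_e1[t] = 0.0
                for j in range(J):
                    for t in range(Tm1):
                        sc_e2[j, t] *= fac_up if ac_e2[j, t] / batch > target else 1.0 / fac_up
                        sc_e2[j, t] = min(max(sc_e2[j, t], 1e-3), 5.0)
                        ac_e2[j, t] = 0.0
                for s in range(S):
                    for t in range(Tm1):
                        sc_e3[s, t] *= fac_up if ac_e3[s, t] / batch > target else 1.0 / fac_up
                        sc_e3[s, t] = min(max(sc_e3[s, t], 1e-3), 5.0)
                        ac_e3[s, t] = 0.0
                for j in range(J):
                    for s in range(S):
                        for t in range(Tm1):
                            sc_e4[j, s, t] *= fac_up if ac_e4[j, s, t] / batch > target else 1.0 / fac_up
                            sc_e4[j, s, t] = min(max(sc_e4[j, s, t], 1e-3), 5.0)
                            ac_e4[j, s, t] = 0.0
                for k in range(6):
                    if n_swap[k] > 0:
                        sc_swap[k] *= fac_up if ac_swap[k] / n_swap[k] > target else 1.0 / fac_up
                        sc_swap[k] = min(max(sc_swap[k], 1e-3), 5.0)
                        ac_swap[k] = 0.0
                        n_swap[k] = 0.0
            for g in range(G):
                for t in range(Tm1):
                    sc_p[g, t] *= fac_up if ac_p[g, t] / batch > target else 1.0 / fac_up
                    sc_p[g, t] = min(max(sc_p[g, t], 1e-3), 5.0)
                    ac_p[g, t] = 0.0

        # ---- store ----------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            for g in range(G):
                out_mu[store, g] = mu[g]
            for b in range(NB):
                out_beta[store, b] = beta[b]
            for t in range(Tm1):
                out_eps1[store, t] = eps1[t]
            for j in range(J):
                for t in range(Tm1):
                    out_eps2[store, j, t] = eps2[j, t]
            for s in range(S):
                for t in range(Tm1):
                    out_eps3[store, s, t] = eps3[s, t]
            for j in range(J):
                for s in range(S):
                    for t in range(Tm1):
                        out_eps4[store, j, s, t] = eps4[j, s, t]
            out_s2t[store] = s2t
            for j in range(J):
                out_s2j[store, j] = s2j[j]
            for s in range(S):
                out_s2s[store, s] = s2s[s]
            for j in range(J):
                for s in range(S):
                    out_s2js[store, j, s] = s2js[j, s]
            for g in range(G):
                for t in range(Tm1):
                    out_p[store, g, t] = p[g, t]
            dev = 0.0
            for g in range(G):
                dev += ll_g[g]
            out_dev[store] = -2.0 * dev
            store += 1

    return store
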