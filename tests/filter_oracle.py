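"""Independent direct-enumeration reference for the discretized filter model.

Deliberately coded as a dense forward pass: the full (logvmu, mu, logSD)
state is flattened into one vector per (kmu, vSD) candidate, the one-step
transition is assembled as an explicit dense matrix from Gaussian
cell-integral kernels, and candidates are mixed by explicitly tracked
marginal evidences.  Slow but transparent; used only on tiny grids.
"""

import numpy as np
from scipy.stats import norm


def _centers_edges(lo, hi, n):
    centers = np.linspace(lo, hi, n)
    mids = (centers[1:] + centers[:-1]) / 2
    edges = np.concatenate(([-np.inf], mids, [np.inf]))
    return centers, edges


def _kernel(centers, edges, sigma):
    n = len(centers)
    K = np.zeros((n, n))
    for src in range(n):
        if sigma < 1e-12:
            K[src, src] = 1.0
            continue
        for dst in range(n):
            hi = norm.cdf(edges[dst + 1], loc=centers[src], scale=sigma)
            lo = norm.cdf(edges[dst], loc=centers[src], scale=sigma)
            K[dst, src] = hi - lo
    return K


def enumerate_filter(y, config):
    """Filtered marginal expectations by direct dense enumeration.

    ``y`` is the transformed series with NaN for missing days; ``config``
    is a circavol FilterConfig.  Returns a dict of per-time expectation
    arrays keyed like PosteriorState.expectations().
    """
    mu_c, mu_e = _centers_edges(*config.mu_bounds, config.n_mu)
    j_c, j_e = _centers_edges(*config.logvmu_bounds, config.n_logvmu)
    s_c, s_e = _centers_edges(*config.logsd_bounds, config.n_logsd)
    M, J, S = len(mu_c), len(j_c), len(s_c)
    dim = J * M * S  # flatten order: (j, m, s)

    # grids of each coordinate over the flattened state
    jj = np.repeat(j_c, M * S)
    mm = np.tile(np.repeat(mu_c, S), J)
    ss = np.tile(s_c, J * M)

    t_mu = {j: _kernel(mu_c, mu_e, float(np.exp(j_c[j]))) for j in range(J)}

    candidates = [(k, v) for k in config.kmu_candidates for v in config.vsd_candidates]
    transitions = []
    for kmu, vsd in candidates:
        t_j = _kernel(j_c, j_e, kmu)
        t_s = _kernel(s_c, s_e, vsd)
        T = np.zeros((dim, dim))
        for j2 in range(J):
            blk = np.kron(t_mu[j2], t_s)  # (M*S, M*S), mu step uses NEW logvmu
            for j1 in range(J):
                T[j2 * M * S:(j2 + 1) * M * S, j1 * M * S:(j1 + 1) * M * S] = t_j[j2, j1] * blk
        transitions.append(T)

    states = [np.full(dim, 1.0 / dim) for _ in candidates]
    log_evidence = [0.0 for _ in candidates]

    n = len(y)
    out = {k: np.zeros(n) for k in
           ("mu", "logvmu", "logsd", "spread_mu", "spread_logvmu", "spread_logsd")}
    for t in range(n):
        for c in range(len(candidates)):
            if t > 0:
                states[c] = transitions[c] @ states[c]
            if not np.isnan(y[t]):
                # likelihood mass of N(y, sd) inside each finite-width mu cell
                half = 0.5 * (mu_c[1] - mu_c[0])
                fin_e = np.concatenate(([mu_c[0] - half], mu_e[1:-1], [mu_c[-1] + half]))
                m_idx = (np.arange(dim) // S) % M
                hi = norm.cdf(fin_e[m_idx + 1], loc=y[t], scale=np.exp(ss))
                lo = norm.cdf(fin_e[m_idx], loc=y[t], scale=np.exp(ss))
                lik = hi - lo
                states[c] = states[c] * lik
                tot = states[c].sum()
                log_evidence[c] += np.log(tot)
                states[c] /= tot
        w = np.exp(np.array(log_evidence) - max(log_evidence))
        w /= w.sum()
        mix = sum(wi * si for wi, si in zip(w, states))
        for key, grid in (("mu", mm), ("logvmu", jj), ("logsd", ss)):
            m1 = float(mix @ grid)
            out[key][t] = m1
            out["spread_" + key][t] = float(np.sqrt(max(mix @ (grid - m1) ** 2, 0.0)))
    return out
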