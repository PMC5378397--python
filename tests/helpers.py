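"""Independent oracles shared across tests.

These deliberately avoid the package's own computational paths: the
likelihood oracle enumerates every latent state, the discriminant oracle
solves the normal equations directly, and the summary-test oracles apply
textbook formulas symbol by symbol.
"""

import numpy as np
from scipy.special import gammaln


def oracle_history_prob(hist, phi, p, beta):
    """Pr(one super-population bird shows this 0/1 history), by exhaustive
    enumeration of entry occasion and death interval."""
    T = len(p)
    total = 0.0
    for e in range(1, T + 1):
        for d in range(e, T + 1):  # alive through occasion d; dies after unless d==T
            pr = beta[e - 1]
            for k in range(e, d):
                pr *= phi[k - 1]
            if d < T:
                pr *= 1 - phi[d - 1]
            ok = True
            for occ in range(1, T + 1):
                if e <= occ <= d:
                    pr *= p[occ - 1] if hist[occ - 1] else 1 - p[occ - 1]
                elif hist[occ - 1]:
                    ok = False
                    break
            if ok:
                total += pr
    return total


def oracle_loglik(histories, phi, p, beta, N):
    """Log joint probability of an unordered observed history set."""
    n = len(histories)
    T = len(p)
    ll = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    if N > n:
        ll += (N - n) * np.log(oracle_history_prob((0,) * T, phi, p, beta))
    for h in histories:
        ll += np.log(oracle_history_prob(tuple(h), phi, p, beta))
    return float(ll)


def oracle_lda_coefficients(Xf, Xm):
    """Classic discriminant functions from the normal equations.

    Returns (coef_female, const_female, coef_male, const_male) computed
    directly as ``Sigma^-1 mu_k`` / ``-mu_k' Sigma^-1 mu_k / 2`` with the
    unbiased pooled within-group covariance.
    """
    Xf, Xm = np.asarray(Xf, float), np.asarray(Xm, float)
    mf, mm = Xf.mean(axis=0), Xm.mean(axis=0)
    Sf = (Xf - mf).T @ (Xf - mf)
    Sm = (Xm - mm).T @ (Xm - mm)
    pooled = (Sf + Sm) / (len(Xf) + len(Xm) - 2)
    prec = np.linalg.inv(pooled)
    return (prec @ mf, -0.5 * mf @ prec @ mf, prec @ mm, -0.5 * mm @ prec @ mm)


def oracle_pooled_t(a, b):
    """Textbook equal-variance two-sample t."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def oracle_icc_oneway(d):
    """One-way variance-components ICC computed from scratch."""
    d = np.asarray(d, float)
    n, k = d.shape
    grand = d.mean()
    ssb = k * ((d.mean(axis=1) - grand) ** 2).sum()
    ssw = ((d - d.mean(axis=1, keepdims=True)) ** 2).sum()
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)
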