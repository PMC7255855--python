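"""Independent brute-force references the fast implementations are checked
against.  Everything here is deliberately naive: scalar loops and a
derivative-free minimizer, no shared code with the package internals beyond
the public scoring contract."""

import numpy as np
from scipy.optimize import minimize


def scalar_score(dists, k, m, b):
    """Direct scalar evaluation of the neighbor scoring formula."""
    mu = sum(d / (i + 1) for i, d in enumerate(dists[:k])) / sum(
        1.0 / (i + 1) for i in range(k)
    )
    var = sum((d - mu) ** 2 / (i + 1) for i, d in enumerate(dists[:k])) / sum(
        1.0 / (i + 1) for i in range(k)
    )
    sigma = var**0.5
    ck = dists[k - 1]
    out = []
    for i in range(k):
        far = np.exp(b * (mu - dists[i]) / sigma) if sigma > 0 else 1.0
        out.append(far * (1.0 - np.exp((dists[i] - ck) / (m * ck))))
    return out


def minimize_projection_objective(x, model, params, scores, order):
    """Numerically minimize the weighted projection-error objective

        sum over pairs of  s * <<h>> * (d - <out - l_i, h> / <<h>>)^2

    over the output space with a derivative-free simplex search."""
    high, low = model.high, model.low
    k = params.k
    terms = []
    for ia in range(k - 2):
        for jb in range(ia + 1, k - 1):
            i, j = order[ia], order[jb]
            dL = high[j] - high[i]
            denom = float(dL @ dL)
            h = low[j] - low[i]
            hh = float(h @ h)
            if denom < 1e-12 or hh < 1e-12:
                continue
            d = float((x - high[i]) @ dL) / denom
            s = (1.0 + hh) ** (-params.a) * np.exp(-((d - 0.5) ** 2))
            s *= scores[ia] * scores[jb]
            terms.append((s * hh, d, low[i], h, hh))

    def objective(out):
        return sum(
            w * (d - float((out - li) @ h) / hh) ** 2 for (w, d, li, h, hh) in terms
        )

    best = None
    for x0 in (np.zeros(low.shape[1]), low.mean(axis=0)):
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-14, maxiter=20000, maxfev=20000),
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def lloyd_step(X, centers):
    """One k-means (Lloyd) update: assign to nearest center, move each
    center to the mean of its points; empty centers stay put."""
    out = centers.copy()
    d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    assign = d.argmin(axis=1)
    for j in range(centers.shape[0]):
        pts = X[assign == j]
        if pts.shape[0]:
            out[j] = pts.mean(axis=0)
    return out
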