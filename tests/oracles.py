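"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code path with the
package: ranks by explicit sorting and tie-group averaging, Pearson by the
textbook formula, and stepwise selection driven by lstsq-based t tests.
"""

import numpy as np
from scipy import stats as sps


def brute_average_ranks(values):
    values = np.asarray(values, dtype=float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # average of 1-based positions i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def brute_spearman(x, y):
    return brute_pearson(brute_average_ranks(x), brute_average_ranks(y))


def _ols_pvalues(y, X):
    """Coefficient p-values for y ~ 1 + X via lstsq (no statsmodels)."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = n - k - 1
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), dof)
    return beta, p


def brute_stepwise(y, pool, names, alpha_in=0.05, alpha_out=0.10):
    """Forward selection with backward elimination, identical criteria to
    the package but driven entirely by lstsq."""
    y = np.asarray(y, dtype=float)
    pool = np.asarray(pool, dtype=float)
    selected = []
    seen = set()
    while True:
        changed = False
        best = None
        for j in range(pool.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            _, p = _ols_pvalues(y, pool[:, cols])
            pj = p[-1]
            if best is None or pj < best[0]:
                best = (pj, j)
        if best is not None and best[0] < alpha_in:
            selected.append(best[1])
            changed = True
        while selected:
            _, p = _ols_pvalues(y, pool[:, selected])
            worst = int(np.argmax(p[1:]))
            if p[1 + worst] > alpha_out:
                selected.pop(worst)
                changed = True
            else:
                break
        key = frozenset(selected)
        if not changed or key in seen:
            break
        seen.add(key)
    if selected:
        beta, _ = _ols_pvalues(y, pool[:, selected])
        coeffs = {names[j]: beta[1 + i] for i, j in enumerate(selected)}
        coeffs["const"] = beta[0]
    else:
        coeffs = {"const": float(np.mean(y))}
    return {names[j] for j in selected}, coeffs
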