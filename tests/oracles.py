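"""Independent brute-force oracles used to cross-check the statistics.

These deliberately avoid the package's solvers: the constrained Poisson
null is maximised by an exhaustive log-grid search (with zoom stages so the
oracle itself resolves the statistic well below the comparison tolerance),
the BH step-up is evaluated straight from its definition, and the NB null
mean is maximised on a 1-D grid.
"""

import numpy as np
from scipy.special import xlogy


def grid_lrt_oracle(sa, sb, sd, la, lb, ld, t_ab, t_d,
                    n_grid=400, decades=4.0, zooms=2):
    """2*deltaLL for the AB-vs-D Poisson test via grid search over the null
    (e_A, e_B) plane with e_D = (e_A + e_B)/2."""
    ll_alt = (
        xlogy(sa, sa / (la * t_ab) if sa else 0)
        + xlogy(sb, sb / (lb * t_ab) if sb else 0)
        + xlogy(sd, sd / (ld * t_d) if sd else 0)
        - (sa + sb + sd)
    )
    ca = np.log10(max(sa, 0.5) / (la * t_ab))
    cb = np.log10(max(sb, 0.5) / (lb * t_ab))
    w = decades
    best = -np.inf
    for _ in range(zooms + 1):
        ga = np.logspace(ca - w, ca + w, n_grid)
        gb = np.logspace(cb - w, cb + w, n_grid)
        a, b = np.meshgrid(ga, gb, indexing="ij")
        d = 0.5 * (a + b)
        ll = (xlogy(sa, a) + xlogy(sb, b) + xlogy(sd, d)
              - a * la * t_ab - b * lb * t_ab - d * ld * t_d)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = ll[i, j]
        ca, cb = np.log10(ga[i]), np.log10(gb[j])
        w = 2 * w * decades / n_grid
    return max(0.0, 2.0 * (ll_alt - best))


def bh_stepup_bruteforce(p):
    """q_i = min_{j: p_(j) >= p_(i)} (n * p_(j) / rank_j), capped at 1 —
    the step-up definition evaluated literally."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    sorted_p = p[order]
    for i in range(n):
        q[order[i]] = min(
            1.0, min(n * sorted_p[j] / (j + 1) for j in range(i, n))
        )
    return q


def _nb_ll(x, s, q, phi):
    mu = q * s
    if phi == 0.0:
        return xlogy(x, mu).sum() - mu.sum()
    r = 1.0 / phi
    return xlogy(x, mu).sum() - ((x + r) * np.log1p(phi * mu)).sum()


def _grid_max_q(x, s, phi, n_grid=2000, decades=4.0, zooms=2):
    if x.sum() == 0:
        return 0.0, 0.0
    c = np.log10(x.sum() / s.sum())
    w = decades
    best_q, best = None, -np.inf
    for _ in range(zooms + 1):
        grid = np.logspace(c - w, c + w, n_grid)
        ll = np.array([_nb_ll(x, s, q, phi) for q in grid])
        k = int(np.argmax(ll))
        best_q, best = grid[k], ll[k]
        c = np.log10(best_q)
        w = 2 * w * decades / n_grid
    return best_q, best


def nb_lrt_oracle(x1, x2, s1, s2, phi):
    """2*deltaLL for the two-group NB test via 1-D grid maximisation of
    every mean parameter."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    s1, s2 = np.asarray(s1, float), np.asarray(s2, float)
    _, ll1 = _grid_max_q(x1, s1, phi)
    _, ll2 = _grid_max_q(x2, s2, phi)
    _, ll0 = _grid_max_q(np.concatenate([x1, x2]), np.concatenate([s1, s2]), phi)
    return max(0.0, 2.0 * (ll1 + ll2 - ll0))
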