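"""Independent oracles used by the tests.

These deliberately avoid the package's own likelihood/EM code paths: the
likelihood oracle enumerates every latent (Z, Y) configuration from the
generative story, and the MLE oracles maximise a directly-transcribed
likelihood numerically.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize


def enumeration_loglik(sites, f, r):
    """Exhaustive sum over all (Z_i, (Y_ij)) latent configurations.

    Each site contributes sum_z P(z) * sum_{y in {R,M}^N} prod_j
    P(y_j | z) P(x_j | y_j).  Exponential in N: tiny instances only.
    """
    total = 0.0
    for s in sites:
        site_lik = 0.0
        n = s.n_reads
        for z in (0, 1):
            pz = r if z else (1 - r)
            if pz == 0:
                continue
            p_mut = f / 2 if z else 0.0
            branch = 0.0
            for ys in itertools.product((0, 1), repeat=n):  # 1 = mutant
                term = 1.0
                for j, y in enumerate(ys):
                    term *= p_mut if y else (1 - p_mut)
                    if y:
                        term *= (1 - s.e_mr[j]) if s.is_alt[j] else s.e_mr[j]
                    else:
                        term *= s.e_rm[j] if s.is_alt[j] else (1 - s.e_rm[j])
                branch += term
            site_lik += pz * branch
        total += math.log(site_lik)
    return total


def direct_loglik(sites, f, r):
    """The printed two-branch mixture likelihood, transcribed literally."""
    total = 0.0
    for s in sites:
        l0 = 1.0
        l1 = 1.0
        for j in range(s.n_reads):
            if s.is_alt[j]:
                l0 *= s.e_rm[j]
                l1 *= s.e_rm[j] * (1 - f / 2) + (1 - s.e_mr[j]) * (f / 2)
            else:
                l0 *= 1 - s.e_rm[j]
                l1 *= (1 - s.e_rm[j]) * (1 - f / 2) + s.e_mr[j] * (f / 2)
        total += math.log((1 - r) * l0 + r * l1)
    return total


def numerical_mle(sites, fix_r=None, n_grid=21):
    """Grid-seeded bounded maximisation of the direct likelihood."""
    if fix_r is not None:
        def neg(x):
            return -direct_loglik(sites, x[0], fix_r)
        grid = [(f,) for f in np.linspace(1e-6, 1 - 1e-6, n_grid)]
        bounds = [(0.0, 1.0)]
    else:
        def neg(x):
            return -direct_loglik(sites, x[0], x[1])
        grid = [(f, r)
                for f in np.linspace(1e-6, 1 - 1e-6, n_grid)
                for r in np.linspace(1e-6, 1 - 1e-6, n_grid)]
        bounds = [(0.0, 1.0), (0.0, 1.0)]
    best = None
    x0 = min(grid, key=neg)
    res = optimize.minimize(neg, x0, bounds=bounds, method="L-BFGS-B")
    best = res.x if res.fun < neg(x0) else np.asarray(x0)
    if fix_r is not None:
        return float(best[0]), float(fix_r)
    return float(best[0]), float(best[1])


def grid_search_f(sites, r=1.0, n=200001):
    """Dense 1-d grid maximiser of the direct likelihood over f."""
    fs = np.linspace(0.0, 1.0, n)
    vals = [direct_loglik(sites, f, r) for f in fs[:: max(1, n // 2001)]]
    coarse = fs[:: max(1, n // 2001)]
    f0 = coarse[int(np.argmax(vals))]
    lo, hi = max(0.0, f0 - 0.001), min(1.0, f0 + 0.001)
    fine = np.linspace(lo, hi, 2001)
    vals = [direct_loglik(sites, f, r) for f in fine]
    return float(fine[int(np.argmax(vals))])


def reconstruct_md(read_seq: str, ref_seq: str) -> str:
    """Re-derive the MD string for a gapless alignment, independently."""
    parts = []
    run = 0
    for r, q in zip(ref_seq, read_seq):
        if r == q:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
    parts.append(str(run))
    return "".join(parts)
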