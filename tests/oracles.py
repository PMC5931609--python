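"""Independent reference implementations used only to cross-check the
package. These deliberately share no code with csom: the expansion oracle
is a naive fixed-point iteration with explicit wave bookkeeping over dicts,
and the t-distribution CDF is obtained by direct numerical quadrature of
the density.
"""

import math

import numpy as np
from scipy.integrate import quad


def brute_force_expand(occupied_dists, width, height):
    """Naive wavefront fill of a toroidal grid.

    ``occupied_dists`` maps (row, col) -> list of class-distribution vectors
    (the examples sitting in that cell). Returns (vectors, waves) as dicts
    keyed by (row, col).
    """
    vec = {}
    weight = {}
    wave = {}
    for cell, dists in occupied_dists.items():
        arr = np.asarray(dists, dtype=float)
        vec[cell] = arr.mean(axis=0)
        weight[cell] = float(len(dists))
        wave[cell] = 0
    k = 0
    while len(vec) < width * height:
        k += 1
        pending = {}
        for r in range(height):
            for c in range(width):
                if (r, c) in vec:
                    continue
                neighbors = set()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        nb = ((r + dr) % height, (c + dc) % width)
                        if nb != (r, c):
                            neighbors.add(nb)
                acc = None
                for nb in sorted(neighbors):
                    if nb in vec and wave[nb] < k:
                        term = weight[nb] * vec[nb]
                        acc = term if acc is None else acc + term
                if acc is not None:
                    pending[(r, c)] = acc / acc.sum()
        for cell, v in pending.items():
            vec[cell] = v
            weight[cell] = 1.0
            wave[cell] = k
    return vec, wave


def t_cdf_quadrature(x, df):
    """Student-t CDF via quadrature of the density written from scratch."""
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(u):
        return const * (1 + u * u / df) ** (-(df + 1) / 2)

    if x >= 0:
        tail, _ = quad(pdf, x, np.inf)
        return 1.0 - tail
    tail, _ = quad(pdf, -np.inf, x)
    return tail
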