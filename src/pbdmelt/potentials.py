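"""On-site Morse and nearest-neighbour stacking potentials of the PBD model.

The configurational energy of an N-pair chain is

    V(y_1..y_N) = sum_n D_n (exp(-a_n y_n) - 1)^2
                + sum_n (kappa/2)(y_n - y_{n-1})^2 [1 + rho exp(-b(y_n + y_{n-1}))]

The Morse term models the hydrogen bond of pair n (depth D_n, inverse
width a_n, both class-dependent and crowder-scaled); the stacking term
couples adjacent pairs with an anharmonicity that makes closed regions
stiffer than open ones, sharpening the melting transition.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams


def morse(y, D, a):
    """Morse potential ``D (exp(-a y) - 1)^2`` in eV.

    Vectorized over any broadcastable combination of displacement ``y``
    (angstrom), depth ``D`` (eV) and inverse width ``a`` (1/angstrom).
    Zero at y = 0, approaches D as y -> +inf, steep wall for y < 0.
    """
    return D * np.square(np.expm1(-a * np.asarray(y, dtype=float)))


def stacking(y_n, y_prev, params: ModelParams):
    """Anharmonic stacking energy between adjacent pairs, in eV.

    ``(kappa/2)(y_n - y_prev)^2 [1 + rho exp(-b (y_n + y_prev))]``;
    symmetric in its two arguments and zero when they coincide.
    """
    y_n = np.asarray(y_n, dtype=float)
    y_prev = np.asarray(y_prev, dtype=float)
    anharmonic = 1.0 + params.rho * np.exp(-params.b * (y_n + y_prev))
    return 0.5 * params.kappa * np.square(y_n - y_prev) * anharmonic


def chain_energy(y, depths, widths, params: ModelParams) -> float:
    """Total configurational energy of a chain configuration (eV).

    ``y``, ``depths`` and ``widths`` are length-N arrays; used by the
    Monte Carlo sampler and brute-force test oracles.
    """
    y = np.asarray(y, dtype=float)
    e = float(np.sum(morse(y, depths, widths)))
    if len(y) > 1:
        e += float(np.sum(stacking(y[1:], y[:-1], params)))
    return e
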