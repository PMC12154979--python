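"""Transfer-integral evaluation of the configurational partition function.

The N-dimensional Boltzmann integral of the chain factorizes over
nearest-neighbour links, so it can be contracted site by site on a fixed
quadrature grid: Z_c = sum over node indices i_1..i_N of

    prod_n w_{i_n} exp(-beta V_M,n(y_{i_n}))  *
    prod_n exp(-beta V_s(y_{i_n}, y_{i_{n+1}}))

with Gauss-Legendre nodes/weights on the truncated domain
[y_min, y_max].  Equivalently: a start vector carrying the first site's
Morse factor, N-1 multiplications by the stacking kernel
S(i, j) = exp(-beta V_s(y_i, y_j)) interleaved with per-site diagonal
Morse factors, and a final sum.  The half-splitting of on-site energies
between adjacent kernels telescopes so that every site carries exactly
one full Morse factor.  Each step is max-rescaled with an accumulated
log factor, so neither underflow at low T nor overflow up to 500 K
affects the result.

A forward/backward pass yields the exact per-site marginal densities of
the same measure at no extra asymptotic cost; restricting one site's
nodes to y >= y0 (or y < y0) gives the numerator of the opening
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .potentials import morse, stacking
from .sequences import Duplex


@dataclass(frozen=True)
class QuadratureGrid:
    """Gauss-Legendre nodes and weights mapped onto [y_min, y_max]."""

    nodes: np.ndarray
    weights: np.ndarray
    y_min: float
    y_max: float

    @property
    def n(self) -> int:
        return len(self.nodes)

    def integrate(self, values: np.ndarray) -> float:
        """Quadrature of a function sampled on the nodes."""
        return float(np.dot(self.weights, values))


def build_grid(params: ModelParams, n: int | None = None) -> QuadratureGrid:
    """Gauss-Legendre grid on [params.y_min, params.y_max].

    Exact for polynomials up to degree 2n-1; the weights sum to the
    interval length.  ``n`` overrides ``params.n_grid`` (used by
    convergence checks).
    """
    n = params.n_grid if n is None else n
    if n < 2:
        raise ValueError("need at least 2 quadrature nodes")
    if not params.y_min < params.y_max:
        raise ValueError("y_min must be below y_max")
    x, w = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (params.y_max - params.y_min)
    mid = 0.5 * (params.y_max + params.y_min)
    return QuadratureGrid(nodes=mid + half * x, weights=half * w,
                          y_min=params.y_min, y_max=params.y_max)


def stacking_kernel(grid: QuadratureGrid, params: ModelParams, T: float) -> np.ndarray:
    """Symmetric kernel ``S(i, j) = exp(-beta V_s(y_i, y_j))``.

    Weights are NOT absorbed here; the contraction applies them
    per site so that marginals come out as plain weighted densities.
    Entries where the stacking energy is huge underflow harmlessly to 0.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    beta = 1.0 / (params.k_B * T)
    y = grid.nodes
    with np.errstate(under="ignore"):
        return np.exp(-beta * stacking(y[:, None], y[None, :], params))


def site_log_boltzmann(
    depths: np.ndarray, widths: np.ndarray, grid: QuadratureGrid, params: ModelParams,
    T: float,
) -> np.ndarray:
    """Per-site log Boltzmann factors ``-beta V_M,n(y_i)``, shape (N, n)."""
    beta = 1.0 / (params.k_B * T)
    d = np.asarray(depths, dtype=float)[:, None]
    a = np.asarray(widths, dtype=float)[:, None]
    return -beta * morse(grid.nodes[None, :], d, a)


@dataclass(frozen=True)
class PartitionResult:
    """Configurational partition function and site-resolved marginals.

    ``site_masses[k, i]`` is the probability that site k+1 sits at grid
    node i (quadrature weight included), so each row sums to 1; the
    corresponding continuous density is ``site_masses / weights``.
    """

    log_Zc: float
    site_masses: np.ndarray
    temperature: float
    grid: QuadratureGrid

    @property
    def marginals(self) -> np.ndarray:
        """Per-site densities over displacement; weighted integral is 1."""
        return self.site_masses / self.grid.weights[None, :]


def _forward(site_boltz, log_consts, S, w, start=0, stop=None):
    """Left-to-right contraction with per-step max-rescaling.

    Returns the list of normalized forward vectors F_k and the
    cumulative log scale for each, for sites start..stop-1.
    ``site_boltz[k]`` must be exp(-beta V_k) rescaled so its max is 1,
    with the subtracted max in ``log_consts[k]``.
    """
    stop = len(site_boltz) if stop is None else stop
    vecs = np.empty((stop - start, len(w)))
    scales = np.empty(stop - start)
    v = w * site_boltz[start]
    total = log_consts[start]
    s = v.max()
    v = v / s
    vecs[0] = v
    scales[0] = total + np.log(s)
    for k in range(start + 1, stop):
        v = (S @ v) * w * site_boltz[k]
        s = v.max()
        if not np.isfinite(s) or s <= 0:
            raise FloatingPointError(
                f"transfer contraction degenerated at site {k + 1} "
                "(all-zero or non-finite vector)"
            )
        v = v / s
        vecs[k - start] = v
        scales[k - start] = scales[k - start - 1] + np.log(s) + log_consts[k]
    return vecs, scales


def _prepare_site_factors(logB):
    """Split (N, n) log factors into O(1)-scaled exponentials + constants."""
    consts = logB.max(axis=1)
    with np.errstate(under="ignore"):
        boltz = np.exp(logB - consts[:, None])
    return boltz, consts


def compute_partition(
    duplex: Duplex,
    depths: np.ndarray,
    params: ModelParams,
    T: float,
    widths: np.ndarray | None = None,
    grid: QuadratureGrid | None = None,
    kernel: np.ndarray | None = None,
) -> PartitionResult:
    """log Z_c and all site marginals for one duplex at one temperature.

    ``depths`` is the (possibly crowder-scaled) per-site Morse depth
    vector; ``widths`` defaults to the class widths of the duplex.
    ``grid`` and ``kernel`` may be supplied to share work across calls
    at the same temperature.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if len(depths) != duplex.N:
        raise ValueError("depth vector length does not match duplex")
    if grid is None:
        grid = build_grid(params)
    if kernel is None:
        kernel = stacking_kernel(grid, params, T)
    if widths is None:
        widths = np.array([params.width(p) for p in duplex.pairs])

    logB = site_log_boltzmann(depths, widths, grid, params, T)
    boltz, consts = _prepare_site_factors(logB)
    w = grid.weights
    N = duplex.N

    F, f_scales = _forward(boltz, consts, kernel, w)
    log_Zc = float(np.log(F[-1].sum()) + f_scales[-1])

    # Backward pass: B_k(i) = contraction of sites k+1..N conditioned on
    # node i at site k (no weight or Morse factor at site k itself).
    B = np.empty_like(F)
    B[-1] = 1.0
    b_scale = np.zeros(N)
    for k in range(N - 2, -1, -1):
        v = kernel @ (w * boltz[k + 1] * B[k + 1])
        s = v.max()
        v = v / s
        B[k] = v
        b_scale[k] = b_scale[k + 1] + np.log(s) + consts[k + 1]

    masses = F * B
    norms = masses.sum(axis=1, keepdims=True)
    masses = masses / norms
    return PartitionResult(log_Zc=log_Zc, site_masses=masses,
                           temperature=T, grid=grid)


def log_partition(
    duplex: Duplex,
    depths: np.ndarray,
    params: ModelParams,
    T: float,
    widths: np.ndarray | None = None,
    grid: QuadratureGrid | None = None,
    kernel: np.ndarray | None = None,
    site_mask: tuple[int, np.ndarray] | None = None,
) -> float:
    """Forward-only log Z_c; cheaper than :func:`compute_partition`.

    ``site_mask = (site, keep)`` zeroes the quadrature weights of nodes
    where boolean ``keep`` is False at the given 1-based site,
    restricting that site's integral to a sub-domain.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if grid is None:
        grid = build_grid(params)
    if kernel is None:
        kernel = stacking_kernel(grid, params, T)
    if widths is None:
        widths = np.array([params.width(p) for p in duplex.pairs])
    logB = site_log_boltzmann(depths, widths, grid, params, T)
    boltz, consts = _prepare_site_factors(logB)
    if site_mask is not None:
        site, keep = site_mask
        if not 1 <= site <= duplex.N:
            raise ValueError(f"site {site} out of range 1..{duplex.N}")
        boltz = boltz.copy()
        boltz[site - 1] = boltz[site - 1] * keep
    F, scales = _forward(boltz, consts, kernel, grid.weights)
    total = F[-1].sum()
    if total <= 0:
        raise FloatingPointError(f"restricted partition vanished at T={T} K")
    return float(np.log(total) + scales[-1])


def compute_restricted_partition(
    duplex: Duplex,
    depths: np.ndarray,
    params: ModelParams,
    T: float,
    site: int,
    region: str,
    **kwargs,
) -> float:
    """log Z_c with one site's integral restricted to open or closed states.

    ``region='open'`` keeps nodes with y >= y0, ``'closed'`` keeps
    y < y0.  The open and closed restricted partitions sum exactly to
    the unrestricted Z_c on the shared grid, and their ratio to Z_c is
    the opening (closing) probability of the site.
    """
    grid = kwargs.get("grid") or build_grid(params)
    kwargs["grid"] = grid
    if region == "open":
        keep = grid.nodes >= params.y0
    elif region == "closed":
        keep = grid.nodes < params.y0
    else:
        raise ValueError(f"region must be 'open' or 'closed', got {region!r}")
    return log_partition(duplex, depths, params, T, site_mask=(site, keep), **kwargs)


def batch_log_partition(
    site_logB: np.ndarray, kernel: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """log Z_c for C chains sharing one grid/kernel; input shape (C, N, n).

    Used by temperature scans over many crowder configurations: the
    stacking kernel depends only on T, so all configurations at one
    temperature contract together as a single matrix-matrix product per
    site.
    """
    C, N, n = site_logB.shape
    consts = site_logB.max(axis=2)  # (C, N)
    with np.errstate(under="ignore"):
        boltz = np.exp(site_logB - consts[:, :, None])
    V = (weights[None, :] * boltz[:, 0, :]).T  # (n, C)
    scales = consts[:, 0].copy()
    for k in range(1, N):
        V = (kernel @ V) * (weights[:, None] * boltz[:, k, :].T)
        s = V.max(axis=0)
        V = V / s[None, :]
        scales += np.log(s) + consts[:, k]
    return np.log(V.sum(axis=0)) + scales
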