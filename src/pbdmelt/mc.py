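"""Metropolis Monte Carlo sampler of the chain's configurational measure.

An independent route to the same Boltzmann distribution the transfer
integral computes: single-site Metropolis updates of the stretching
coordinates, restricted to the truncated domain [y_min, y_max] so both
methods target the identical measure.  Used by the test suite to
cross-validate opening probabilities and mean separations; standard
errors come from block averaging, which absorbs the autocorrelation of
the chain.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .params import ModelParams
from .potentials import morse, stacking
from .sequences import Duplex


@dataclass(frozen=True)
class MCResult:
    """Summary statistics of one Metropolis run."""

    n_samples: int
    mean_y: np.ndarray
    se_y: np.ndarray
    open_freq: np.ndarray
    se_open: np.ndarray
    acceptance_rate: float
    seed: int


def metropolis_sample(
    duplex: Duplex,
    depths: np.ndarray,
    params: ModelParams,
    T: float,
    n_sweeps: int = 20000,
    step_size: float = 0.5,
    seed: int = 0,
    n_blocks: int = 25,
) -> MCResult:
    """Sample the configurational Boltzmann distribution at temperature T.

    One sweep is one attempted move per site plus one collective move.
    The proposal kernel is a mixture of symmetric moves, so detailed
    balance holds with respect to the truncated measure (proposals
    leaving [y_min, y_max] are rejected):

    * local: y_i -> y_i + U(-step, step) (90% of single-site proposals);
    * redraw: y_i -> U(y_min, y_max) (10%), which nucleates and removes
      openings without waiting for diffusion;
    * translation: all sites shifted by one U(-5, 5) draw, once per
      sweep.  The stacking energy is invariant under translation, so
      this mixes the chain's collective coordinate through the melted
      (flat-Morse) region, where single-site moves alone diffuse it
      O(N (L/step)^2) sweeps slowly.

    The first 20% of sweeps are burn-in, during which the local step
    size adapts toward ~40% acceptance; it is frozen afterwards.
    Deterministic for a fixed seed.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if T <= 0:
        raise ValueError("temperature must be positive")
    N = duplex.N
    depths = np.asarray(depths, dtype=float)
    widths = np.array([params.width(p) for p in duplex.pairs])
    beta = 1.0 / (params.k_B * T)
    rng = np.random.default_rng(seed)

    y = np.zeros(N)  # start at the Morse minimum
    n_burn = max(1, n_sweeps // 5)
    step = step_size

    def local_energy(i: int, yi: float) -> float:
        e = float(morse(yi, depths[i], widths[i]))
        if i > 0:
            e += float(stacking(yi, y[i - 1], params))
        if i < N - 1:
            e += float(stacking(y[i + 1], yi, params))
        return e

    n_keep = n_sweeps - n_burn
    traj = np.empty((n_keep, N))
    accepted = 0
    attempted = 0
    adapt_acc = 0
    adapt_att = 0
    redraw_frac = 0.1
    shift_width = 5.0
    lo, hi = params.y_min, params.y_max
    for sweep in range(n_sweeps):
        moves = rng.uniform(-step, step, size=N)
        redraws = rng.random(N) < redraw_frac
        redraw_vals = rng.uniform(lo, hi, size=N)
        us = rng.random(N)
        for i in range(N):
            if redraws[i]:
                y_new = redraw_vals[i]
            else:
                y_new = y[i] + moves[i]
            if not lo <= y_new <= hi:
                if sweep < n_burn:
                    adapt_att += 1
                else:
                    attempted += 1
                continue
            dE = local_energy(i, y_new) - local_energy(i, y[i])
            accept = dE <= 0 or us[i] < np.exp(-beta * dE)
            if not redraws[i]:  # only local moves drive step adaptation
                if sweep < n_burn:
                    adapt_att += 1
                    adapt_acc += accept
                else:
                    attempted += 1
                    accepted += accept
            if accept:
                y[i] = y_new
        # collective translation: stacking-invariant, symmetric proposal
        shift = rng.uniform(-shift_width, shift_width)
        u_shift = rng.random()
        y_shifted = y + shift
        if y_shifted.min() >= lo and y_shifted.max() <= hi:
            dE = float(np.sum(morse(y_shifted, depths, widths))
                       - np.sum(morse(y, depths, widths)))
            if dE <= 0 or u_shift < np.exp(-beta * dE):
                y = y_shifted
        if sweep < n_burn:
            # crude Robbins-Monro style retune every 100 sweeps
            if (sweep + 1) % 100 == 0 and adapt_att > 0:
                rate = adapt_acc / adapt_att
                if rate < 0.3:
                    step *= 0.8
                elif rate > 0.5:
                    step *= 1.25
                adapt_acc = adapt_att = 0
        else:
            traj[sweep - n_burn] = y

    acc_rate = accepted / max(attempted, 1)
    if not 0.1 <= acc_rate <= 0.9:
        warnings.warn(
            f"Metropolis acceptance rate {acc_rate:.2f} outside [0.1, 0.9]; "
            "consider retuning step_size",
            RuntimeWarning,
        )

    open_traj = (traj >= params.y0).astype(float)

    def block_stats(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nb = min(n_blocks, len(series))
        usable = (len(series) // nb) * nb
        blocks = series[:usable].reshape(nb, -1, N).mean(axis=1)
        mean = blocks.mean(axis=0)
        se = blocks.std(axis=0, ddof=1) / np.sqrt(nb)
        return mean, se

    mean_y, se_y = block_stats(traj)
    open_freq, se_open = block_stats(open_traj)
    return MCResult(
        n_samples=n_keep,
        mean_y=mean_y,
        se_y=se_y,
        open_freq=open_freq,
        se_open=se_open,
        acceptance_rate=acc_rate,
        seed=seed,
    )
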