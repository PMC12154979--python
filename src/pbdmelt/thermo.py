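"""Free energy, specific heat and melting temperature from Z_c.

The Helmholtz free energy per base pair is

    f(T) = -(k_B T / 2) ln(2 pi m k_B T) - (k_B T / N) ln Z_c

where the first (momentum) term is analytic — the kinetic sector of the
Hamiltonian factors out as (2 pi m k_B T)^{N/2} — and contributes a
constant k_B/2 to the specific heat.  The specific heat is
C_v = -T d^2f/dT^2, evaluated by central second differences on a fine
temperature grid, and the melting temperature T_m is the location of the
C_v peak, refined by three-point parabolic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crowders import CrowderConfig, effective_depths, site_widths
from .params import ModelParams
from .sequences import Duplex
from .transfer import (
    QuadratureGrid,
    batch_log_partition,
    build_grid,
    compute_partition,
    log_partition,
    site_log_boltzmann,
    stacking_kernel,
)


def free_energy(
    duplex: Duplex,
    depths: np.ndarray,
    params: ModelParams,
    T: float,
    grid: QuadratureGrid | None = None,
    kernel=None,
) -> float:
    """Helmholtz free energy per base pair (eV) at temperature T."""
    log_Zc = log_partition(duplex, depths, params, T, grid=grid, kernel=kernel)
    return momentum_free_energy(params, T) - params.k_B * T * log_Zc / duplex.N


def momentum_free_energy(params: ModelParams, T: float) -> float:
    """Analytic kinetic contribution -(k_B T/2) ln(2 pi m k_B T) per pair."""
    return -0.5 * params.k_B * T * np.log(2.0 * np.pi * params.m * params.k_B * T)


def free_energy_curve(
    duplex: Duplex,
    depths: np.ndarray,
    params: ModelParams,
    temperatures: np.ndarray,
    grid: QuadratureGrid | None = None,
) -> np.ndarray:
    """f(T) over a temperature grid, sharing the quadrature grid."""
    if grid is None:
        grid = build_grid(params)
    widths = site_widths(duplex, params)
    return np.array([
        free_energy(duplex, depths, params, float(T), grid=grid)
        for T in temperatures
    ])


def specific_heat(temperatures: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """C_v = -T f''(T) by central second differences on a uniform grid.

    Returns the interior temperatures and C_v there (eV/K per base
    pair).  Warns (via ValueError guidance in callers) if the step
    exceeds 1 K, where discretization error becomes visible at the peak.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(temperatures) < 3:
        raise ValueError("need at least 3 temperatures for a second difference")
    dT = np.diff(temperatures)
    if not np.allclose(dT, dT[0], rtol=1e-8):
        raise ValueError("specific_heat requires a uniform temperature grid")
    h = float(dT[0])
    d2f = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / h**2
    return temperatures[1:-1], -temperatures[1:-1] * d2f


def melting_temperature(temperatures: np.ndarray, Cv: np.ndarray) -> float:
    """Location of the global C_v maximum, parabolically refined.

    The three points around the discrete argmax define a parabola whose
    vertex is returned; ties in the discrete maximum break toward lower
    temperature.  A maximum at a scan boundary raises, telling the
    caller to widen the range.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    Cv = np.asarray(Cv, dtype=float)
    i = int(np.argmax(Cv))  # argmax returns the first (lowest-T) maximizer
    if i == 0 or i == len(Cv) - 1:
        raise ValueError(
            f"specific-heat maximum at scan boundary (T={temperatures[i]:.1f} K); "
            "widen the temperature range"
        )
    y0, y1, y2 = Cv[i - 1], Cv[i], Cv[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(temperatures[i])
    h = temperatures[i + 1] - temperatures[i]
    return float(temperatures[i] + 0.5 * h * (y0 - y2) / denom)


@dataclass
class MeltingProfile:
    """A full melting scan: f(T), C_v(T), open fraction and T_m.

    ``specific_heat`` is stored in eV/K per base pair; the ``Cv_kB``
    property rescales to units of k_B for readability.
    """

    temperatures: np.ndarray
    free_energy: np.ndarray
    specific_heat: np.ndarray
    open_fraction: np.ndarray
    Tm: float
    metadata: dict = field(default_factory=dict)

    @property
    def Cv_kB(self) -> np.ndarray:
        from .params import KB
        return self.specific_heat / KB


def melting_scan(
    duplex: Duplex,
    crowders: CrowderConfig,
    params: ModelParams,
    T_range: tuple[float, float] = (200.0, 400.0),
    coarse_step: float = 1.0,
    fine_step: float = 0.1,
    fine_window: float = 10.0,
    compute_phi: bool = True,
) -> MeltingProfile:
    """Assemble a complete melting profile for one duplex + crowder set.

    A coarse scan brackets the C_v peak; a fine scan (default 0.1 K in a
    +-10 K window) pins T_m.  Deterministic for fixed inputs.
    """
    from .observables import fraction_open  # local import avoids a cycle

    lo, hi = T_range
    if not (0 < lo < hi):
        raise ValueError(f"bad temperature range {T_range}")
    depths = effective_depths(duplex, crowders, params)
    grid = build_grid(params)

    coarse_T = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    f_coarse = np.empty_like(coarse_T)
    phi = np.empty_like(coarse_T)
    for j, T in enumerate(coarse_T):
        kernel = stacking_kernel(grid, params, float(T))
        if compute_phi:
            result = compute_partition(duplex, depths, params, float(T),
                                       grid=grid, kernel=kernel)
            phi[j] = fraction_open(result, params)
            log_Zc = result.log_Zc
        else:
            phi[j] = np.nan
            log_Zc = log_partition(duplex, depths, params, float(T),
                                   grid=grid, kernel=kernel)
        f_coarse[j] = momentum_free_energy(params, float(T)) \
            - params.k_B * T * log_Zc / duplex.N

    Tc, Cv_coarse = specific_heat(coarse_T, f_coarse)
    T_peak = melting_temperature(Tc, Cv_coarse)

    fine_lo = max(lo, T_peak - fine_window)
    fine_hi = min(hi, T_peak + fine_window)
    fine_T = np.arange(fine_lo, fine_hi + 0.5 * fine_step, fine_step)
    f_fine = np.array([
        free_energy(duplex, depths, params, float(T), grid=grid)
        for T in fine_T
    ])
    Tf, Cv_fine = specific_heat(fine_T, f_fine)
    Tm = melting_temperature(Tf, Cv_fine)

    meta = {
        "duplex": duplex.label or None,
        "crowders": crowders.describe(),
        "params_hash": params.config_hash(),
        "T_range": [lo, hi],
        "coarse_step": coarse_step,
        "fine_step": fine_step,
    }
    return MeltingProfile(
        temperatures=Tc,
        free_energy=f_coarse[1:-1],
        specific_heat=Cv_coarse,
        open_fraction=phi[1:-1],
        Tm=Tm,
        metadata=meta,
    )


def crowder_tm_scan(
    duplex: Duplex,
    configs: list[CrowderConfig],
    params: ModelParams,
    T_range: tuple[float, float] = (250.0, 350.0),
    coarse_step: float = 1.0,
    fine_step: float = 0.1,
    fine_window: float = 3.0,
) -> np.ndarray:
    """T_m for many crowder configurations of one duplex, batched.

    The stacking kernel depends only on temperature, so at each T every
    configuration is contracted in one BLAS call; this is what makes the
    56-configuration scan of an 8-mer take seconds rather than minutes.
    Returns T_m in the order of ``configs``.
    """
    lo, hi = T_range
    grid = build_grid(params)
    widths = site_widths(duplex, params)
    all_depths = np.stack([effective_depths(duplex, c, params) for c in configs])
    C = len(configs)

    def f_at(temps: np.ndarray) -> np.ndarray:
        """(C, nT) free energies, kernel shared across configurations."""
        out = np.empty((C, len(temps)))
        for j, T in enumerate(temps):
            kernel = stacking_kernel(grid, params, float(T))
            logB = np.stack([
                site_log_boltzmann(all_depths[c], widths, grid, params, float(T))
                for c in range(C)
            ])
            log_Zc = batch_log_partition(logB, kernel, grid.weights)
            out[:, j] = momentum_free_energy(params, float(T)) \
                - params.k_B * float(T) * log_Zc / duplex.N
        return out

    coarse_T = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    f_coarse = f_at(coarse_T)
    peaks = np.empty(C)
    for c in range(C):
        Tc, Cv = specific_heat(coarse_T, f_coarse[c])
        peaks[c] = melting_temperature(Tc, Cv)

    # Windows snap to one global fine lattice anchored at the scan start,
    # so every configuration's window is uniform and kernels are still
    # built once per shared temperature.
    lattice_index: set[int] = set()
    windows = []
    for c in range(C):
        j0 = int(np.ceil((max(lo, peaks[c] - fine_window) - lo) / fine_step - 1e-9))
        j1 = int(np.floor((min(hi, peaks[c] + fine_window) - lo) / fine_step + 1e-9))
        windows.append((j0, j1))
        lattice_index.update(range(j0, j1 + 1))
    idx = np.array(sorted(lattice_index))
    fine_T = lo + idx * fine_step
    f_fine = f_at(fine_T)
    pos = {j: p for p, j in enumerate(idx)}

    tms = np.empty(C)
    for c in range(C):
        j0, j1 = windows[c]
        sel = [pos[j] for j in range(j0, j1 + 1)]
        Tf, Cv = specific_heat(fine_T[sel], f_fine[c][sel])
        tms[c] = melting_temperature(Tf, Cv)
    return tms
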