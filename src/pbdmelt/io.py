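"""Tabular input/output: melting profiles, opening maps, experimental curves.

All CSV output embeds the full parameter set and a config hash in
``#``-prefixed header comments so a run can be reproduced exactly from
its own output.  Experimental melting curves (two columns: temperature,
open fraction) are read for overlay/scoring only — the package never
computes them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observables import OpeningMap
from .thermo import MeltingProfile


def _header_lines(metadata: dict) -> str:
    return "".join(f"# {k}: {json.dumps(v)}\n" for k, v in sorted(metadata.items()))


def write_profile(profile: MeltingProfile, path: str | Path) -> None:
    """Write a melting profile as commented CSV (T_K, f_eV, Cv_kB, phi)."""
    df = pd.DataFrame({
        "T_K": profile.temperatures,
        "f_eV": profile.free_energy,
        "Cv_kB": profile.Cv_kB,
        "phi": profile.open_fraction,
    })
    path = Path(path)
    meta = dict(profile.metadata)
    meta["Tm_K"] = round(profile.Tm, 6)
    with path.open("w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False, float_format="%.10g")


def read_profile(path: str | Path) -> pd.DataFrame:
    """Read back a profile CSV written by :func:`write_profile`."""
    return pd.read_csv(path, comment="#")


def write_profile_summary(profile: MeltingProfile, path: str | Path) -> None:
    """JSON summary: T_m plus the run metadata."""
    payload = {"Tm_K": profile.Tm, **profile.metadata}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_opening_map(omap: OpeningMap, path: str | Path, metadata: dict | None = None) -> None:
    """Opening map in long format: one row per (site, T) with P."""
    sites = np.repeat(omap.sites, len(omap.temperatures))
    temps = np.tile(omap.temperatures, len(omap.sites))
    df = pd.DataFrame({"site": sites, "T_K": temps, "P_open": omap.P.ravel()})
    path = Path(path)
    meta = dict(metadata or {})
    meta["y0_A"] = omap.y0_used
    with path.open("w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False, float_format="%.10g")


def read_experimental_curve(path: str | Path, celsius: bool = False) -> pd.DataFrame:
    """Read an experimental melting curve CSV with columns T, phi.

    ``celsius=True`` converts the temperature column via
    T_K = T_C + 273.15.  Open fractions must lie in [0, 1].
    """
    df = pd.read_csv(path, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    if "t" not in cols or "phi" not in cols:
        raise ValueError(f"{path}: expected columns 'T' and 'phi', got {list(df.columns)}")
    out = pd.DataFrame({"T_K": df[cols["t"]].astype(float),
                        "phi": df[cols["phi"]].astype(float)})
    if celsius:
        out["T_K"] = out["T_K"] + 273.15
    bad = out.index[(out["phi"] < 0) | (out["phi"] > 1)]
    if len(bad):
        # +2 converts the 0-based frame index to the 1-based data line
        # number (after the header row).
        raise ValueError(
            f"{path}: phi outside [0, 1] at data line {int(bad[0]) + 2}"
        )
    return out.sort_values("T_K").reset_index(drop=True)


def rms_phi_difference(profile: MeltingProfile, experiment: pd.DataFrame) -> float:
    """RMS difference between model and experimental phi.

    The model curve is interpolated onto the experimental temperatures
    that fall inside the scanned range.
    """
    T = experiment["T_K"].to_numpy()
    inside = (T >= profile.temperatures[0]) & (T <= profile.temperatures[-1])
    if not inside.any():
        raise ValueError("no experimental points inside the scanned temperature range")
    model = np.interp(T[inside], profile.temperatures, profile.open_fraction)
    return float(np.sqrt(np.mean((model - experiment["phi"].to_numpy()[inside]) ** 2)))
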