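# pbdmelt

DNA melting thermodynamics in crowded solution, computed from the
Peyrard–Bishop–Dauxois (PBD) model with molecular crowders represented
as local stabilization of base-pair hydrogen bonds.

The cellular interior is dense with inert macromolecules (PEG is the
usual in-vitro mimic).  A crowder sitting next to a base pair restricts
its stretching fluctuation and makes the hydrogen bond effectively
harder to break.  `pbdmelt` is for biophysicists who want to ask, for a
given duplex sequence and a given placement of crowders: at what
temperature does the duplex melt, which base pairs open first, and how
does the melting curve change as crowders move or strengthen?

## The model

Each base pair *n* of an *N*-pair duplex carries one stretching
coordinate *y<sub>n</sub>* (Å).  The configurational energy is

```
V = Σₙ Dₙ (e^(−aₙ yₙ) − 1)²                          (Morse, H-bond)
  + Σₙ (κ/2)(yₙ − yₙ₋₁)² [1 + ρ e^(−b(yₙ + yₙ₋₁))]   (anharmonic stacking)
```

with class-dependent Morse parameters (AT: D = 0.0395 eV, a = 4.2 Å⁻¹;
GC: D = 0.059 eV, a = 6.3 Å⁻¹) and one stacking set
(κ = 0.03 eV/Å², ρ = 2.0, b = 0.35 Å⁻¹) for all steps.  A crowder at
site *i* scales the Morse depth there, D<sub>i</sub> = α·D₀ with
α > 1 (α = 1.5 for the weak PEG-like crowder; α = 5–9 for strong,
graded crowders on long chains).

The configurational partition function Z<sub>c</sub> is the
N-dimensional Boltzmann integral on the truncated domain
[−5, 200] Å, evaluated exactly (per grid) by transfer-integral
contraction on a 900-node Gauss–Legendre grid.  From it:

* Helmholtz free energy per pair
  f(T) = −(k_B T/2) ln(2π m k_B T) − (k_B T/N) ln Z_c,
* specific heat C_v = −T ∂²f/∂T², whose peak defines the melting
  temperature T_m,
* per-site opening probabilities P_i(T) = P(y_i ≥ y₀) with
  y₀ = 2.0 Å, and the open fraction ϕ(T) = mean_i P_i(T) — the model
  counterpart of a UV melting curve.

An independent Metropolis Monte Carlo sampler of the same truncated
measure cross-validates the transfer-integral observables in the test
suite.

## Worked example

Sequences use a two-letter shorthand: `G` is a GC pair, `A` is an AT
pair.  The 8-bp duplex GGGAGAAG with weak crowders (α = 1.5) at sites
2, 7 and 8:

```bash
$ pbdmelt melt --seq GGGAGAAG --crowders 2:1.5,7:1.5,8:1.5 \
      --t-min 200 --t-max 350 --out chainA
INFO Tm = 261.95 K (cli-sequence, crowders: 2:1.5,7:1.5,8:1.5)
261.95
```

The printed number is the melting temperature in kelvin: the location
of the specific-heat peak, refined to 0.1 K.  `chainA.csv` holds the
full profile (temperature, free energy per pair in eV, C_v in units of
k_B per pair, open fraction ϕ), with the parameter hash and crowder
configuration echoed in the header:

```
# Tm_K: 261.946498
# crowders: "2:1.5,7:1.5,8:1.5"
# params_hash: "042d03e96515"
T_K,f_eV,Cv_kB,phi
201,-0.003478300571,1.865903105,0.00195586049
...
```

For comparison, the crowder-free duplex melts at 224.0 K: the three
crowders shift T_m up by ~38 K, the local-stabilization signature of
crowding.  `pbdmelt scan-crowders --seq GGGAGAAG --k 3 --alpha 1.5`
ranks all 56 distinct three-crowder placements by T_m;
`pbdmelt openmap` writes the site-by-temperature opening-probability
map that reveals where denaturation bubbles nucleate; `pbdmelt
fixtures` writes the shipped 50/100/300-bp graded-crowder scenarios.

## Layout

* `pbdmelt.sequences` / `pbdmelt.crowders` — duplex parsing (shorthand
  or literal FASTA alphabet), crowder enumeration, depth scaling
* `pbdmelt.potentials` / `pbdmelt.transfer` — PBD energies and the
  transfer-integral engine (partition function, marginals, restricted
  partitions)
* `pbdmelt.thermo` / `pbdmelt.observables` — free energy, C_v, T_m,
  opening maps, melting curves
* `pbdmelt.mc` — Metropolis cross-check sampler
* `pbdmelt.scenarios` — reference chains and long-chain crowding
  scenarios
* `pbdmelt.cli` — `pbdmelt` command (melt, scan-crowders, openmap, mc,
  fixtures)

See `docs/methods.md` for the modelling and numerical choices.
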