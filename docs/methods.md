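# Methods

## Model

The duplex is a quasi-one-dimensional lattice: base pair *n* has a
single stretching coordinate *y_n* (Å) measuring the separation of the
two bases from their equilibrium position, with configurational energy

    V(y_1..y_N) = Σ_n V_M(y_n) + Σ_{n=2..N} V_s(y_n, y_{n-1})

* **Morse on-site term** `V_M(y) = D (e^{-a y} - 1)^2` models the
  hydrogen bond: depth *D* (eV) sets bond strength, inverse width *a*
  (Å⁻¹) sets the well's stiffness and the entropy of the bound state.
  GC pairs (three H-bonds) are deeper and narrower than AT pairs (two).
* **Anharmonic stacking**
  `V_s = (κ/2)(y_n - y_{n-1})² [1 + ρ e^{-b(y_n + y_{n-1})}]` couples
  neighbours.  When both pairs are closed (small *y*) the bracket is
  ≈ 1+ρ and the chain is stiff; when either opens, the coupling
  softens toward κ/2 Δy².  This entropy release is what sharpens the
  denaturation transition.
* **Crowders** are inert, static, and local: a crowder at site *i*
  multiplies that site's Morse depth, D_i = α·D0_i (α > 1 stabilizes;
  α = 1 is a no-op).  No excluded-volume geometry or residence-time
  dynamics is modelled.  Several crowders on one site combine
  multiplicatively by default (`multiplicity_rule="product"`), which
  realizes the observed extra stabilization of doubly-crowded sites; a
  collapse-to-one-α rule is available since the combination law is
  phenomenological.

The kinetic sector (momenta with reduced mass m) factors out of the
canonical partition function analytically as Z_p = (2π m k_B T)^{N/2},
so all sequence dependence lives in the configurational part Z_c.

### Default parameters

| symbol | value | units | role |
|---|---|---|---|
| D_AT / D_GC | 0.0395 / 0.059 | eV | Morse depths |
| a_AT / a_GC | 4.2 / 6.3 | Å⁻¹ | Morse inverse widths |
| κ | 0.03 | eV/Å² | stacking stiffness |
| ρ / b | 2.0 / 0.35 | – / Å⁻¹ | stacking anharmonicity amplitude / range |
| m | 300 | amu | reduced pair mass (momentum factor only) |
| k_B | 8.617333×10⁻⁵ | eV/K | fixed unit system: eV, Å, K |
| y_min / y_max | −5 / 200 | Å | integration cutoffs |
| n_grid | 900 | – | Gauss–Legendre nodes |
| y0 | 2.0 | Å | open/closed threshold |

Any parameter can be overridden from a YAML/JSON file; outputs echo a
hash of the full set so runs are reproducible from their own headers.

## Transfer-integral numerics

Z_c on an unbounded domain diverges (the Morse plateau is integrable in
e^{-βV} only on a finite box), so the integral is truncated to
[−5, 200] Å and evaluated on a single-interval Gauss–Legendre grid.
The N-dimensional integral factorizes into a left-to-right contraction:
a start vector carrying site 1's Boltzmann factor and quadrature
weights, one multiplication by the stacking kernel
S(i,j) = e^{-β V_s(y_i, y_j)} per step interleaved with the next site's
diagonal Morse factor, and a final sum.  The textbook half-splitting of
on-site energies between adjacent kernels telescopes so each site
carries exactly one full Morse factor; the code applies the factors
per site directly, which is algebraically identical and keeps per-site
marginals simple.  Numerical safeguards:

* every site's log Boltzmann factors are max-shifted before
  exponentiation, and each contraction step is max-rescaled with an
  accumulated log factor — no overflow/underflow of the running vector
  from 1 K to well above 500 K (deep-well entries that underflow to 0
  contribute nothing and are harmless);
* a forward/backward pass gives every site's marginal mass vector at
  O(N n²) total cost; opening probabilities are read off the marginals
  and are exactly equal to the masked-contraction (restricted
  partition) ratio — the test suite asserts both routes agree to 1e−10;
* the Planck-constant prefactor of the kinetic sector is set to 1
  (reduced units): it adds a T-independent constant to f and cancels in
  C_v, ϕ and P_i.

**Grid resolution caveat.**  The GC Morse well has width
1/a_GC ≈ 0.16 Å while 900 Gauss–Legendre nodes on [−5, 200] Å space
≈ 0.11 Å apart near y = 0, so the well is only marginally resolved.
The partition function itself is accurate (validated against
brute-force tensor quadrature on the same grid to 1e−10 and against
Monte Carlo on the continuum measure), but quantities sensitive to the
well shape drift with the node count: for the 8-bp reference duplex,
doubling 450 → 900 nodes moves T_m by ≈ 3.5 K, and 900 → 4000 by a
further ≈ 1.7 K.  The package keeps 900 nodes as the canonical default
grid for comparability and exposes `n_grid` for convergence studies;
very low node counts (≲ 300) produce qualitatively wrong short-chain
melting temperatures and are suitable only for structural smoke tests
(e.g. row counts), not for physics.

## Thermodynamics

* f(T) = −(k_B T/2) ln(2π m k_B T) − (k_B T/N) ln Z_c per base pair.
  The momentum term is analytic and contributes exactly k_B/2 to C_v
  (asserted in tests); only the Z_c term carries sequence and crowder
  dependence, so conventions in the momentum term cannot move the peak.
* C_v = −T ∂²f/∂T² by central second differences on a uniform grid.
  f is smooth at machine precision, so a 0.1 K step puts the
  differencing noise ~6 orders below the signal.
* T_m is the C_v-curve's global maximum: discrete argmax (ties break
  toward lower T, the numpy convention) refined by a three-point
  parabolic fit.  A maximum on the scan boundary raises an error
  instructing the user to widen the range rather than silently
  reporting a clipped value.
* A melting scan brackets the peak with a 1 K coarse pass
  (default range 200–400 K) and refines in a ±10 K window at 0.1 K.
  Multi-configuration scans (e.g. all 56 three-crowder placements on an
  8-mer) share the temperature-only stacking kernel across
  configurations and contract all of them in one BLAS product per
  site, which makes the 56-configuration scan a ~25 s computation.
* C_v is reported in units of k_B per base pair for readability; the
  raw eV/K array is the stored quantity.

## Observables

A pair is open when y ≥ y0 with y0 = 2.0 Å, inside the 1.5–2.2 Å range
used in the melting literature and matching where the mean separation
⟨y⟩(T) rises steeply through the transition.  The open fraction is the
threshold estimator ϕ(T) = 1 − θ(T) = mean_i P(y_i ≥ y0): by
construction ϕ equals the column mean of the opening map, so the
melting curve and the per-site picture can never disagree.  The
threshold is a parameter (`y0`), not a constant, so the
bound-state-projector alternative can be emulated by threshold
sensitivity studies.  Experimental melting curves are only read
(CSV: T, ϕ), interpolated onto the model grid, and scored by RMS
difference — never computed.

## Monte Carlo cross-check

The Metropolis sampler targets the *same* truncated measure as the
quadrature (proposals outside [y_min, y_max] are rejected), which is
essential for agreement and easy to get wrong silently.  The proposal
kernel is a symmetric mixture: local uniform steps (adaptive during the
20% burn-in only, frozen afterwards so production sampling satisfies
detailed balance), 10% full-domain redraws of single sites, and one
whole-chain translation per sweep.  The translation leaves the stacking
energy invariant and is what lets the collective coordinate traverse
the flat melted region in O((L/Δ)²) sweeps instead of
O(N (L/step)²).  Standard errors come from ≥ 20-block averaging, which
absorbs the residual autocorrelation; the suite requires 3-SE agreement
with the transfer integral for opening probabilities and mean
separations across the transition of an N = 4 chain.

## Synthetic sequences and scenarios

The long-chain scenarios (50/100/300 bp, five crowders of graded
strength α = 5, 6, 7, 8, 9 at fixed positions, crowded-site fractions
10%, 5%, ~1.7%) model heterogeneous cell-like crowding.  The underlying
heteropolymer sequences are generated, not measured: 50% GC content
with an exact GC count placed uniformly at random from a fixed
package-level seed (1234), so the shipped fixtures are identical
everywhere.  The generator reproduces composition and randomness of
arrangement only — no dinucleotide correlation, no CpG structure, no
relation to any genomic sequence — so scenario results demonstrate the
model's qualitative behaviour (interior bubble formation between
crowders, pinned crowded sites, multiple specific-heat maxima when
crowder strengths are graded), not predictions for a specific real
sequence.

## Known limitations

* **Absolute temperature scale.**  With the default parameter set the
  computed short-duplex melting temperatures fall in the 190–270 K
  range (e.g. 224.0 K for the crowder-free 8-bp reference duplex,
  261.7 K mean over its 56 three-crowder configurations) — low compared
  with experimental melting temperatures of comparable PEG-crowded
  8-mers (~303 K).  T_m in this model scales roughly with √(D κ)/a, so
  modestly deeper Morse wells (e.g. the widely used
  D_AT = 0.05 / D_GC = 0.075 eV set) shift the scale up by ~40–50 K
  without changing any ordering.  All comparative statements the
  package makes (crowders stabilize; T_m monotone in α; GC-richer and
  terminal-GC duplexes melt higher; position dependence of crowders)
  are insensitive to this scale.
* Crowders are static depth multipliers; no diffusion, residence
  times, or excluded volume.
* One stacking parameter set for all steps; sequence enters only
  through the Morse term.
* No strand-dissociation (bimolecular) entropy: the two strands remain
  lattice-paired even when fully open, as in the standard PBD
  treatment, which compresses short-chain melting temperatures.
* Single-interval Gauss–Legendre quadrature: see the resolution caveat
  above.
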