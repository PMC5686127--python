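# Methods

## Conformational equilibrium from labeling kinetics

The tail is modeled as two-state: surface-bound (chemically unreactive)
or unbound (reactive), interconverting fast relative to the labeling
reaction. With probe in pseudo-first-order excess, progress curves are
single exponentials `A(t) = A0(1 − e^(−kt))` and the observed NCP rate is
`k_ncp = k_free · K_conf/(1 + K_conf)`.

Two estimators convert a rate pair into K_conf:

* `ratio` (default): `K_conf = k_ncp/k_free`. This is the literal
  rate-ratio procedure; it equals the exact value only in the small-K
  limit.
* `two_state`: `K_conf = r/(1 − r)`, the exact inversion of the
  pre-equilibrium relation. Rejected (domain error) when `r ≥ 1`.

The two agree within ~1% for K ≤ 0.01 and differ by ~10% at K = 0.1
(r = 1/11 ⇒ ratio estimate 0.0909 for a true 0.1). Both are exposed
because published rate-ratio values are ambiguous at the 10% level near
physiological salt; synthetic round trips use `two_state`, which is
self-consistent with the generator. `fraction_unbound` returns
`K/(1+K)`, the reader-accessible fraction.

Rate fitting: per-trace nonlinear least squares in `(log k, log A0)`
(positivity by construction), initialized from the half-rise time
(`t_1/2 = ln 2/k`), with ×0.1/×10 restarts; a global mode shares one
`(k, A0)` across replicates. Default time grids: the six benchtop gel
lanes (10, 20, 30, 60, 120, 300 s) for NCP and a faster quenched-flow
grid (0.5–60 s) for the free tetramer, both configurable.

## Binding models

* Quadratic ligand-depletion: exact two-component equilibrium, required
  when receptor concentration (0.5–1 μM in the tryptophan-fluorescence
  setup) is comparable to Kd. Evaluated in the conjugate form
  `bound = 2L/(s + √(s² − 4PL))`, `s = L+P+Kd`, which is exact algebra
  but avoids catastrophic cancellation when the bound fraction is small;
  this is what makes the dilute-receptor limit agree with the hyperbolic
  model to 1e-6 relative.
* Hyperbolic: `ΔImax·L/(Kd+L)` for dilute receptor.
* Isotherm: the same saturation form applied to a trace labeled receptor
  (5 nM fluorescent nucleosome) titrated with protein, with anisotropy as
  the signal. Kept as a separate tag; no anisotropy-specific intensity
  correction is applied.

Fitting is per replicate in `log Kd` (positivity without bounds),
initialized at the concentration of half-maximal signal with five
multiplicative restarts (×0.01…×100) before a fit is flagged
non-converged; never silent. SSE is unweighted. Replicates are fit
independently and reported as mean ± SD, mirroring averaging over three
or four experiments; a model choice is always explicit (no guessing from
the protein concentration, which is unreliable near the
depletion/dilute boundary).

## Accessibility → apparent affinity

Minimal competition model: the reader binds only the unbound tail state,
K_conf acting as a fast pre-equilibrium; no ternary reader·tail·DNA
species. Then `Kd_app = Kd_peptide·(1+K)/K`. Both the exact factor
`(1+K)/K` and the small-K approximation `1/K` are reported side by side
(they differ by exactly 1); a quoted "~10-fold at K ≈ 0.1" corresponds to
the approximate form, 11 to the exact one.

## FRET

**(ratio)A.** The donor-only spectrum is scaled to the donor/acceptor
spectrum over a donor-dominated, acceptor-dark window (default
530–545 nm) and subtracted; the remaining acceptor emission under donor
excitation is integrated over the acceptor band (default 650–720 nm) and
ratioed to the directly excited acceptor integral. Efficiency:
`E = ((ratio)A − εA(λD)/εA(λA)) · (εA(λA)/εD(λD)) / d+`, with `d+` the
donor labeling fraction. The extinction-coefficient ratios are
configuration inputs (`RatioAParams`), not hard-coded constants; the
shipped defaults (0.05, 2.0, d+ = 1) are placeholders representative of
a Cy3/Cy5 pair, and the synthetic spectra are generated consistently
with whatever params are supplied, so round trips hold for any valid
values. E outside [0, 1] is clamped with a flag; a negative sensitized
integral floors E at 0 with a flag.

**Site exposure.** `E(C) = E0 + (Ef − E0)/(1 + S_1/2/C)`, Hill
coefficient fixed at 1, `E(0) = E0` by limit. Three-parameter least
squares in `(E0, Ef, log S_1/2)`; a series whose efficiency span is
below `flat_tol` (default 0.01) is flagged degenerate rather than
force-fit — the expected outcome for titrants that do not shift the
unwrapping equilibrium.

## NMR titration profiling

CSP: `√(ΔδH² + (α·ΔδN)²)` with α = 0.14 (community standard; the
normalization constant is configurable since conventions vary).
Disappeared peaks contribute I/I0 = 0 to the intensity metric but a
missing CSP — never infinity. Interface calls threshold each metric
against its own regional mean + k·SD (defaults k = 1 for PHD1, 2 for
PHD2), computed excluding missing residues; region boundaries default to
the tandem-construct definitions 361–417 / 418–442 / 443–503 and are
configurable. Fast-exchange Kd fits reuse the quadratic bound fraction
per residue; the pooled estimate is the median over residues whose
fitted CSP amplitude exceeds a floor (default 0.02 ppm), which keeps
unresponsive residues from dragging the pool.

## Synthetic data

Generators emit exactly the CSV schemas the analysis stages read and are
deterministic: one seed per call, replicate r drawn from the stream
`(seed, r)` so any replicate regenerates alone and replicate i does not
depend on how many replicates are requested.

Noise families: gel-band intensities get multiplicative log-normal noise
(band volumes are positive and scale-dependent) parameterized mean-one,
`exp(σz − σ²/2)` with `σ² = ln(1+CV²)`, default CV 5%; titration signals
and FRET efficiencies get additive Gaussian noise (defaults 2% of ΔImax
and σE = 0.01); NMR peaks get Gaussian position noise (¹⁵N scaled ×5
relative to ¹H) and multiplicative intensity noise. Peaks below 1% of
the reference intensity are dropped as undetectable. The NMR generator
produces pure fast-exchange behavior with per-residue attenuation
`I = I0((1−f) + fγ)`; `γ ≈ 0` reproduces complete disappearance of one
domain's amides at saturation.

What the generators do **not** emulate: baseline drift and photobleaching
in fluorescence, partial labeling and gel-loading covariance, slow or
intermediate NMR exchange (peak tracking is by residue index, assignments
assumed transferred), spectral overlap, and LexA–DNA sequence context.
Passing round-trip tests therefore demonstrate estimator correctness and
freedom from algorithmic bias under the assumed noise families, not
robustness to every artifact of real data.

## Problem sizes and numerical choices

Acceptance-scale recoveries use 200 replicates for titrations and 100
replicate pairs for kinetics and unwrapping fits — enough that the mean
recovered parameter isolates estimator bias (Monte-Carlo SEM well under
the 10% band) while the whole battery runs in seconds. All optimizer
starts are data-driven; ties in restarts resolve to the lowest SSE.
Degenerate inputs (all-zero signal, flat titrations, zero reference
intensity, both P and Kd zero) raise typed errors or return flagged
fits rather than numbers without provenance.

Known limitations: no weighted fitting beyond an optional per-point σ;
no cooperative (Hill) binding or multi-phase kinetics; the ratio-method
K_conf understates the true equilibrium by `1/(1+K)` (documented above);
(ratio)A accuracy is bounded by band overlap between donor emission and
the acceptor integration window (~1e-7 relative for the default
Gaussian shapes, larger for real dye spectra with long red tails).
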