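# tailaccess

Quantitative analysis of histone H3 tail accessibility in the nucleosome
and its consequences for tail-binding reader domains.

The N-terminal tail of histone H3 protrudes from the nucleosome core
particle (NCP) between the DNA gyres, but it is not freely available:
electrostatic contacts with nucleosomal DNA hold most tails against the
particle surface. `tailaccess` implements the quantitative chain that
turns experimental readouts of this equilibrium into numbers:

1. **Labeling kinetics → K_conf.** A cysteine engineered into the tail
   reacts with fluorescein-5-maleimide only while the tail is off the DNA.
   Progress curves follow `A(t) = A0(1 − e^(−kt))`; the ratio of the NCP
   rate to the free-tetramer rate gives the conformational equilibrium
   constant, either directly (`K_conf = k_ncp/k_free`) or through the
   two-state inversion `K_conf = r/(1 − r)` with `r = k_ncp/k_free`.
   At low salt `K_conf ≈ 0.004–0.01`, i.e. under 1% of tails are in the
   reader-accessible state (`K/(1+K)`); near physiological ionic strength
   `K_conf ≈ 0.1`.
2. **Accessibility → apparent reader affinity.** If a reader binds only
   the unbound tail state, its apparent dissociation constant against the
   nucleosome is `Kd_app = Kd_peptide · (1+K_conf)/K_conf` — roughly a
   ten-fold penalty at `K_conf = 0.1` (small-K limit `1/K_conf`).
3. **Equilibrium binding fits.** Quadratic ligand-depletion
   (`ΔI = ΔImax·((L+P+Kd) − √((L+P+Kd)² − 4PL))/(2P)`), hyperbolic
   (`ΔImax·L/(Kd+L)`), and trace-receptor isotherm models, fit per
   replicate by nonlinear least squares with mean ± SD aggregation.
4. **FRET site exposure.** Efficiency from donor/acceptor emission
   spectra by the (ratio)A method, and unwrapping titrations fit to
   `E = E0 + (Ef − E0)/(1 + S_1/2/C)`.
5. **NMR titration profiling.** Per-residue chemical shift perturbations
   `√(ΔδH² + (0.14·ΔδN)²)`, intensity fractions I/I0, region-wise
   mean + k·SD interface calls, and fast-exchange Kd fits.

A seeded synthetic-data module generates every input type at realistic
conditions, so the full pipeline is testable without external data.

Intended users: biophysicists and structural biologists analyzing
nucleosome accessibility, reader binding, or analogous
labeling-kinetics / titration / FRET / CSP datasets.

## Worked example

What does a tail held at `K_conf = 0.1` cost a reader whose free-peptide
affinity is 0.11 μM?

```bash
$ tailaccess suppress --kconf 0.1 --kd-peptide 0.11
{
  "factor_approx": 10.0,
  "factor_exact": 11.0,
  "k_conf": 0.1,
  "kd_apparent_predicted_uM": 1.21,
  "kd_peptide_uM": 0.11
}
```

Reader binding is suppressed ~10-fold (exactly `(1+K)/K = 11`); a
0.11 μM peptide interaction would appear as ~1.2 μM against the
nucleosome if accessibility were the only penalty.

The full synthetic pipeline (simulate → fit → summarize) in one command:

```bash
$ tailaccess report --seed 1
```

prints a JSON report whose stages include (abridged):

```
"kconf":          k_free = 0.499 s⁻¹, k_ncp = 0.00558 s⁻¹ → K_conf = 0.0113
                  (generated at 0.01; 1.1% of tails accessible)
"binding":        Kd = 0.109 ± 0.005 μM from quadratic fits
                  (generated at 0.11 μM, P = 0.5 μM)
"site_exposure":  S_1/2 = 1.41 ± 0.25 μM from unwrapping isotherm fits
                  (generated at 1.4 μM)
```

Each block reports the fitted value next to the generating one, so a
glance shows the recovery quality at the default three replicates.

The same operations are available as library calls
(`tailaccess.fit_binding_titration`, `tailaccess.kconf_from_rates`, …)
and as per-stage subcommands: `simulate`, `fit-binding`, `fit-kinetics`,
`kconf`, `suppress`, `fret ratioa`, `fit-unwrap`, `nmr-csp`, `report`.

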