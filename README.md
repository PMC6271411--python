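# duplextherm

Thermodynamic analysis of DNA duplex UV melting, for nucleic-acid
biophysicists and assay designers who need duplex stabilities
(ΔH°, ΔS°, ΔG°₃₇, Tm), their salt dependence, and matched-vs-mismatched
discrimination energies from absorbance melting curves.

## What it computes

A short non-self-complementary duplex melts in two states: full duplex AB
or free strands A + B, each strand at Ct/2 where **Ct is the total strand
concentration** (the convention that makes K(Tm) = 4/Ct; passing per-strand
concentrations is the classic factor-of-two bug). The 260 nm absorbance is
a population-weighted mix of two linear baselines,

    A(T) = f(T)·(b_ds + m_ds·T) + (1 − f(T))·(b_ss + m_ss·T),

with the duplex fraction f(T) solved from mass action at
K(T) = exp(−ΔG°(T)/RT), ΔG°(T) = ΔH° − T·ΔS°. The package recovers
parameters two independent ways and cross-checks them, as melting studies
do:

1. **curve fitting** — nonlinear least squares of each curve for
   (ΔH°, Tm) plus four baseline coefficients;
2. **the van't Hoff concentration plot** — OLS of Tm⁻¹ on log₁₀(Ct/4),
   whose slope is 2.303·R/ΔH°.

Agreement of the two ΔH° values (within 15% by default) is the standard
evidence of a genuine two-state transition.

Around that core:

- **Salt dependence / counterion uptake** — the slope of −ΔG°₃₇ against
  log₁₀[M] converts to the net number of cations taken up per duplex
  formed, Δn = slope/(2.303·α·R·T), with nonideality factors α = 0.9
  (NaCl) and 0.88 (MgCl₂); an equivalent Tm⁻¹-based estimator
  (δ(Tm⁻¹)/δlog[M] = 2.303·α·R·Δn/ΔH°) is provided as a cross-check.
- **Nearest-neighbor prediction** — the unified Watson-Crick DNA
  parameter set plus the internal G·T wobble set, with a
  trinucleotide-core decomposition that attributes a measured whole-duplex
  value to a central base pair and its two flanking stacks. Inosine (I)
  and 2,6-diaminopurine (D) pairs are recognized in sequences but have no
  published parameters and are rejected by prediction rather than guessed.
- **Discrimination** — ΔΔG°₃₇ and ΔTm between matched and mismatched
  duplexes under one solution condition.
- **A synthetic-data generator** — the two-state model run forward with
  Gaussian photometric noise, strand-concentration series, and salt series
  (−ΔG°₃₇ linear in log₁₀[M], ΔH° salt-independent), so the whole chain is
  testable without raw spectrophotometer data.

## Worked example

The built-in study simulates the six-variant 13-mer system
5'-TTTGTATCXCAAT-3'/5'-ATTGYGATACAAA-3' (X·Y one of G·C, D·T, I·C, A·T,
G·T, I·T) across four Na⁺ concentrations and four strand concentrations,
then runs the full analysis:

```python
from duplextherm.pipeline import RunConfig, run_synthetic_study

report = run_synthetic_study(RunConfig(seed=7))
gc = report["duplexes"]["G·C"]
print(gc["conditions"]["0.1"]["consolidated"])  # 120 mM-like condition
print(gc["salt"])
```

prints (abridged):

```
curve-fit ΔH° −105.2, van't Hoff ΔH° −104.6 kcal/mol  (0.6% apart → two_state_flag True)
consolidated: ΔH° −104.9 kcal/mol, ΔS° −310.5 cal/mol/K, ΔG°37 −8.6 kcal/mol
salt: slope 3.93 ± 0.01 kcal/mol per decade, 1 M intercept 12.52, Δn 3.08 → reported 3.1
```

meaning: at ~0.1 M Na⁺ the G·C duplex forms with −105 kcal/mol of
enthalpy and is worth −8.6 kcal/mol at 37 °C; across the salt series its
stability gains 3.93 kcal/mol per tenfold Na⁺ increase, i.e. about 3.1
sodium ions are taken up per duplex formed. The discrimination table in
the same report shows the G·C/G·T gap growing from 1.36 kcal/mol (ΔTm
5.2 K) at 30 mM to 3.35 kcal/mol (ΔTm 9.8 K) at 1 M — high, physiological
salt sharpens mismatch discrimination.

The same stages are available as a CLI
(`duplextherm simulate|fit|vanthoff|salt|nn|pipeline`); see `--help`.

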