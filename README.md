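# subsite

Protease substrate-specificity profiling and enzyme-kinetic
characterization, built around the workflow used to characterize
trypsin-like serine proteases such as kallikrein-related peptidase 8
(KLK8/neuropsin).

## What it does

A protease's extended substrate specificity is described in
Schechter–Berger nomenclature: residues P6…P1 sit N-terminal of the
scissile bond (binding subsites S6…S1), P1′…P6′ C-terminal; cleavage
occurs between P1 and P1′.  `subsite` implements both experimental routes
to that profile and the kinetics used to quantify activity and its
regulation:

- **PSSCL reduction** (`subsite.psscl`): positional-scanning synthetic
  combinatorial libraries — four tetrapeptide sub-libraries fixing one of
  P4…P1 to each of 19 canonical residues + norleucine — are reduced from
  per-well fluorogenic rates to a P4…P1 specificity matrix, with
  replicate QC and blank handling.
- **PICS** (`subsite.pics`): proteomic identification of cleavage sites.
  A reference proteome is digested in silico with a library protease
  (GluC: cleavage after Glu, blocked by P1′-Pro), quantified peptides are
  filtered at a strict >8-fold enrichment, matched back to the proteome,
  and *semi-specific* peptides (exactly one terminus not explained by the
  library digestion) yield P6…P6′ cleavage windows.  Heat maps are
  emitted raw and corrected for the proteome's amino-acid abundance:
  `corrected(a, p) ∝ f_obs(a, p) / f_bg(a)`, column-rescaled.
- **Profile analytics** (`subsite.profile`): per-subsite Shannon entropy
  and information content `log2(20) − H`; background-aware log-odds
  models `w(a, p) = log2 f̂(a, p) / f_bg(a)` (pseudocounted); scoring and
  ranked scanning of candidate cleavage sites in protein substrates; a
  bootstrap reliability assessment that flags profiles built from fewer
  than 30 cleavage events.
- **Kinetics** (`subsite.kinetics`):
  - Michaelis–Menten fits `v = kcat·E_active·[S]/(KM + [S])` with
    Hanes–Woolf initialization and the catalytic efficiency kcat/KM
    (M⁻¹s⁻¹) with propagated standard errors;
  - NPGB burst titration `A(t) = π(1 − e^{−kt}) + mt + A₀`, converting
    the burst amplitude π to the molar concentration of active enzyme
    through Beer–Lambert;
  - four-parameter log-logistic IC₅₀/EC₅₀ dose–response fits;
  - inhibition-mechanism classification (competitive / noncompetitive /
    uncompetitive / mixed) by global fitting across inhibitor levels with
    AICc model selection and Eadie–Hofstee diagnostics;
  - hyperbolic activation fits (e.g. Ca²⁺ stimulation)
    `v([A]) = v₀(1 + (F−1)[A]/(K_act+[A]))`, optionally attenuated at
    high activator.
- **Synthetic data** (`subsite.simulate`): seeded generators for every
  input — E. coli-like proteomes, PICS quantification tables with planted
  cleavage sites, PSSCL plates, and kinetic datasets — each shipping a
  `TruthRecord` of the planted parameters for recovery testing.

## Worked example

```python
from subsite.simulate import (CompositionSpec, generate_proteome,
                              simulate_pics_experiment, simulate_mm_rates)
from subsite.pics import run_pics
from subsite.kinetics import fit_michaelis_menten
from subsite.profile import position_entropy

# PICS on a synthetic proteome with 73 planted cleavages and 200 decoys
proteome, _ = generate_proteome(CompositionSpec(n_proteins=500), seed=7)
planted, quant, truth = simulate_pics_experiment(proteome, n_true=73,
                                                 n_decoy=200, seed=7)
result = run_pics(planted, quant)
print(f"accepted cleavage events: {len(result.events)}")
print(f"rejections: {result.report['rejections']}")
h, info = position_entropy(result.raw_matrix, "P1")
print(f"P1 entropy: {h:.2f} bits (information {info:.2f} bits)")
top = result.corrected_matrix.values["P1"].nlargest(3)
print("top corrected P1 residues:",
      ", ".join(f"{a} {v:.1f}%" for a, v in top.items()))

# Michaelis-Menten fit on a noisy synthetic titration
series, _ = simulate_mm_rates(48.0, 15.3, [2, 5, 10, 20, 50, 100],
                              enzyme_total_nM=60, active_fraction=0.62,
                              noise_cv=0.05, replicates=2, seed=1)
fit = fit_michaelis_menten(series)
print(f"kcat = {fit.kcat:.1f} /s, KM = {fit.km:.1f} uM, "
      f"kcat/KM = {fit.efficiency:.3g} /M/s")
```

prints

```
accepted cleavage events: 73
rejections: {'fully_specific': 100}
P1 entropy: 1.34 bits (information 2.98 bits)
top corrected P1 residues: R 72.7%, K 17.7%, A 3.2%
kcat = 48.8 /s, KM = 15.5 uM, kcat/KM = 3.15e+06 /M/s
```

All 273 quantified peptides are processed; the 100 fully specific GluC
fragments are rejected as ordinary digestion products, the 100
below-threshold peptides never pass the >8-fold filter, and the 73
planted semi-specific peptides are reconstructed as cleavage events.
The corrected P1 column shows the tryptic-like preference (Arg ≫ Lys);
1.34 bits of entropy at P1 against the 4.32-bit maximum reflects that
strong primary specificity.  The kinetic fit recovers the generating
constants (kcat 48 s⁻¹, KM 15.3 µM) within the 5% noise level.

A `subsite` command-line tool wraps the same functionality:
`subsite simulate proteome|pics|psscl|kinetics`, `subsite psscl reduce`,
`subsite pics run`, `subsite profile entropy|scan`, and
`subsite kinetics mm|ic50|mode|burst|activation`.

## Documentation

See `docs/methods.md` for the models, their assumptions, the synthetic
data generators' design, and numerical choices.
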