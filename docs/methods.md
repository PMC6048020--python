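# Methods

This note documents the models implemented in `subsite`, their
assumptions, the synthetic-data generators, and the numerical choices
made where the design was genuinely open.

## Subsite conventions and specificity matrices

Substrate residues are indexed in Schechter–Berger nomenclature, P6…P1
N-terminal and P1′…P6′ C-terminal of the scissile bond (internally
P1 = −1, P1′ = +1).  A `SpecificityMatrix` holds nonnegative weights for
20 amino-acid rows (one-letter codes, alphabetical: ACDEFGHIKLMNPQRSTVWY)
by subsite-position columns.  PSSCL matrices use 19 canonical residues
plus norleucine (written `n`, in Cys's alphabetical slot), because the
library substitutes the oxidation-prone cysteine.  Matrix modes:

- `counts` — cleavage-event tallies (PICS); per-column `n_events` counts
  only events for which that position is defined, since windows at
  protein termini leave outer positions undefined (gap `-`).
- `rate` — fluorogenic cleavage rates (PSSCL).
- `pct_sum` / `pct_max` — column-normalized (sum 100 / max 100).

Per-position specificity is quantified by Shannon entropy H (bits) of the
column distribution and information content log₂20 − H.  Profiles built
from fewer than 30 cleavage events are flagged `low_confidence`, the
commonly cited lower bound for a reliable entropy-based specificity
determination; a seeded multinomial bootstrap (B = 1000 by default)
provides percentile intervals for the per-position entropy.

## Log-odds scoring and substrate scanning

Cleavage-site propensity is scored with a background-aware log-odds
model.  With column counts c(a, p), column totals n_p, background
frequencies f_bg(a) and pseudocount κ (default 1.0):

    f̂(a, p) = (c(a, p) + κ·f_bg(a)) / (n_p + κ)
    w(a, p)  = log2( f̂(a, p) / f_bg(a) )     [bits]

The background-scaled pseudocount pulls unobserved residues toward the
background rather than toward uniform, so observed ≡ background gives
exactly zero weights.  A window's score is the sum of w over its non-gap
positions (positions absent from the model contribute 0, making the
score additive over any position split).  `scan_sequence` scores every
eligible bond (optionally restricting P1 to e.g. {R, K} for a
trypsin-like protease), gap-padding windows at the sequence ends, and
ranks by descending score with ties broken by ascending position, so
output is deterministic.

The packaged "KLK8-like" profile is an *emulation* constructed from the
protease's published qualitative preferences — P1 Arg ≫ Lys (Lys set at
20% of Arg), P2 aliphatic (Leu/Val/Ile), P3 basic (Arg/Lys, the unusual
feature of this enzyme), P4 mildly Thr/Trp, P1′ Ser/Met, P2′
Ile/Ala/Val/Trp, P5′ His, P6′ Tyr, other positions at background — with
the exact numbers chosen once as a realistic strength scale.  It is not
measured data and is used for simulation and for worked examples such as
ranking the neuroserpin Arg38 site above the EphB2 Arg518 site.

## PSSCL reduction

Each well of the positional-scanning library fixes one position of an
acetyl-P4-P3-P2-P1-ACC tetrapeptide to one residue while the other three
positions are equimolar mixtures.  Reduction takes the replicate mean of
blank-subtracted rates per (sub-library, fixed residue), clips negative
means at zero (fluorogenic rates are physically nonnegative; clipping is
logged), and optionally normalizes per column.  Replicate QC flags
groups with coefficient of variation (sample SD / mean) above a
threshold or fewer than two replicates.  Blank subtraction is optional;
with no blank column, blanks are zero, so both raw-rate and
blank-subtracted workflows are supported.  A converter maps PSSCL
matrices onto the 20-canonical alphabet for comparison with PICS
profiles: the norleucine row is dropped (it carries no information about
a natural residue) and Cys is imputed at its background frequency, with
columns re-expressed as pct_sum.

Default assay metadata (enzyme 60 nM, 31.25 nM per compound, 250 µM
total, 25 °C) mirrors the reference screen and is used by the simulator
only, never by the reduction arithmetic.

## PICS pipeline

1. **Digestion.**  The reference proteome is digested in silico with the
   library protease.  Default rule: GluC cleaving after Glu with Pro
   blocking in P1′; Asp cleavage (phosphate-buffer behavior) is
   available via configuration.  With the length filter off and no
   missed cleavages the fragments tile each protein exactly.  A peptide
   length filter of 6–30 residues (MS observability) is applied by
   default and is configurable.
2. **Fold-change filter.**  A peptide is accepted as a cleavage-product
   candidate iff treated/control > 8 — strictly, so 8.0 exactly is
   rejected.  Zero control intensities are floored at a configurable
   fraction (default 10⁻⁶) of the median control intensity, so "appeared
   from nothing" peptides become large finite ratios and pass.
3. **Semi-specific matching.**  Each accepted peptide is located in the
   proteome by exact substring search.  Peptides matching no location
   are rejected (`not_in_proteome`); peptides matching multiple
   locations are rejected by default (`ambiguous_location`; a
   count-all-locations mode exists behind a flag).  A terminus is
   *conforming* if it coincides with a protein terminus or a library cut
   site.  Both termini conforming ⇒ ordinary digestion product
   (rejected); neither ⇒ ambiguous double cleavage (rejected); exactly
   one neo terminus ⇒ a cleavage event at that terminus.  All rejection
   reasons are counted and reported.
4. **Windows and heat maps.**  The P6…P6′ window is read from the
   reference protein around the scissile bond; positions beyond the
   protein termini are gaps and are excluded from per-column counts
   (not imputed).  The raw heat map is the pct_sum-normalized count
   matrix.  The corrected map divides observed frequencies by the
   proteome's residue abundance before renormalizing —
   `corrected(a, p) ∝ f_obs(a, p)/f_bg(a)` — the standard
   fold-enrichment convention; both maps are exported since heat-map
   conventions differ between tools.

## Kinetics

**Initial rates.**  Least-squares slope over an initial window covering
at most 10% substrate depletion (when the substrate concentration is
known), but never fewer than 10% of the points or 4 points; the slope is
converted to µM/s through the signal calibration.

**Michaelis–Menten.**  v = kcat·E_active·[S]/(KM+[S]) by
Levenberg–Marquardt, initialized from a Hanes–Woolf ([S]/v vs [S])
linearization.  E_active is the enzyme concentration times the active
fraction from a burst titration, so kcat refers to active enzyme.
kcat/KM is reported in M⁻¹s⁻¹ with a standard error propagated through
the fit covariance.  Fits that fail to converge or return KM outside
0.01–100× the design range are flagged.  Residuals are unweighted by
default; `weighting="relative"` divides by the model value and is the
appropriate choice when noise is multiplicative (it is used for the
coverage validation, whose simulated noise is multiplicative).

**Burst titration.**  A(t) = π(1 − e^{−kt}) + mt + A₀.  The burst
amplitude π equals ε·l·[E_active] (one chromophore released per active
site), giving active molarity and active fraction.  Default extinction
coefficients — not part of the fit, only of the conversion — are
ε(p-nitrophenol, 410 nm, pH 8.0) = 16,600 M⁻¹cm⁻¹ and
ε(p-nitroaniline, 405 nm) = 9,920 M⁻¹cm⁻¹, both overridable.  If the
burst is complete before the second sample (k·Δt > 3) the rate constant
is unresolvable: the fit is flagged and the amplitude is recovered from
the intercept of the steady-state line.

**Dose–response.**  v = bottom + (top − bottom)/(1 + ([I]/IC₅₀)^h), with
the Hill coefficient free (init 1.0) and the bottom optionally fixed at
0 for complete inhibition.  IC₅₀ is the fitted curve midpoint.  Flat
responses (range < 5% of the signal) raise a no-transition error rather
than returning an unconstrained IC₅₀.

**Inhibition mechanism.**  Global fits across all inhibitor levels with
shared parameters:

- competitive: v = Vmax·S/(KM(1+I/Ki) + S)
- noncompetitive: v = (Vmax/(1+I/Ki))·S/(KM + S)
- uncompetitive: v = Vmax·S/(KM + S(1+I/Ki))
- mixed: v = Vmax·S/(KM(1+I/Ki) + S(1+I/(αKi))), α ∈ [0.1, 10]

Models are ranked by small-sample AICc (k counts the residual variance
as a parameter, the standard least-squares form) and Akaike weights.
Because the mixed model nests the pure mechanisms, an α̂ within
[2/3, 3/2] means Ki and Ki′ agree within 50% — operationally
noncompetitive — so such a mixed fit is excluded from the weight
calculation (weight 0; its parameters and AICc are still reported).
Without this collapse, noise alone makes the one-extra-parameter model
win a nontrivial fraction of AICc comparisons on small panels, which is
a statement about nested-model selection, not about the data.  α outside
[0.1, 10] is operationally competitive or uncompetitive, hence the
bounds.  Eadie–Hofstee coordinates (v vs v/[S]) are emitted per
inhibitor level: parallel lines (equal slopes −KM) diagnose
noncompetitive inhibition, a common intercept (Vmax) competitive.

**Activation.**  v([A]) = v₀(1 + (F−1)[A]/(K_act+[A])), with F the
maximal fold-stimulation and K_act the half-maximal activator
concentration; an optional attenuation factor 1/(1 + [A]/K_att) captures
loss of stimulation at high activator, and the pure vs attenuated model
is chosen by AICc.  Monotone-decreasing data raise a not-an-activator
error.

All fits are deterministic given the data (no random restarts).

## Synthetic-data generators

Every generator is a pure function of its parameters and a seed
(`numpy.random.default_rng`), and ships a `TruthRecord` with the planted
parameters.

**Proteomes.**  I.i.d. residues at a stated composition; the embedded
default is an E. coli K-12-like average composition (the organism whose
digested proteome forms the PICS peptide library).  Protein lengths are
normal (mean 300, SD 80, floor 30).  I.i.d. sequence has no domain
structure, homology or low-complexity regions, so multi-location
peptides are much rarer than in a real proteome; the ambiguity-handling
code paths are exercised by dedicated unit fixtures instead.

**PICS experiments.**  Cleavage-site selection proportional to a
truth-profile likelihood over a background proteome induces, at each
subsite position, the residue law q(a, p) ∝ f_bg(a)·truth(a, p).  The
generator realizes that law constructively: for each planted site it
splices a cassette into a copy of the proteome — a planted GluC boundary
(Glu, with a non-Pro successor), a background spacer, the P6…P1 residues
drawn from q (Glu excluded on the non-prime side so no library cut is
recreated), and P1′…P6′ drawn from q — and emits the semi-specific
peptide between the planted boundary and the planted bond (8–20
residues).  Direct selection-by-weighting over a fixed desk-scale
proteome was rejected: the product-form weights are so heavy-tailed that
a 500-protein pool has an effective sample size of only tens of sites,
and drawing hundreds of distinct sites visibly distorts the per-position
marginals.  The constructive form samples the identical generative law
with exact marginals, so the abundance-corrected heat map converges on
the truth profile (Pearson r ≈ 0.96 at 300 events against a ≥ 0.9
requirement).  Planted peptides get log-normal fold changes (σ = 0.3 in
log₂ space around 2⁵, resampled to stay above the acceptance threshold);
decoys are fully specific library fragments above threshold (rejected as
digestion products) and semi-specific peptides at or below threshold
(one pinned exactly at the threshold to exercise the strict inequality),
so exactly `n_true` events survive the full pipeline by construction.
Uniqueness of every planted peptide is verified against the final
proteome.

**PSSCL plates.**  Well rate = truth rate × (1 + N(0, cv)), clipped at
0, for a configurable replicate count (default 3, cv 5%).  The default
truth matrix is the KLK8-like profile's P4…P1 columns scaled to a
100 FU/s maximum on the Nle alphabet.

**Kinetics.**  Rates come from the closed-form model plus multiplicative
Gaussian noise; progress curves integrate substrate depletion
dP/dt = kcat·E·(S₀−P)/(KM+S₀−P) with fixed-step RK4 at 1 s (desk scale,
deterministic), then sample and add noise.  The default inhibition
scenario uses the wild-type Zn²⁺ IC₅₀ (3.6 µM) as true Ki; the default
burst scenario uses 120 nM total enzyme at 62% activity; the default
activation scenario uses 2-fold stimulation with K_act = 60 µM.

What passing recovery tests on these generators shows: the estimators
are consistent and well-calibrated under their own noise model
(multiplicative Gaussian, i.i.d. residues, exact peptide identification).
What they do not show: robustness to MS identification errors, inner-
filter effects, substrate depletion during "initial" rates, enzyme
instability, or real-proteome sequence redundancy — all outside the
generators by design.

## Problem sizes and validation choices

The test suite and the acceptance script run at desk scale, chosen as
the smallest sizes at which the statistical requirements are
comfortably met: 500-protein proteomes (~150k residues), 73–300 planted
cleavage events, 20 seeded repetitions for dose–response and activation
recoveries (3 replicates per concentration), 10 for burst titrations,
and 50 panels per mechanism for selection-accuracy checks (5 substrate ×
3 inhibitor levels, 2% noise).  Grid-search oracles (200×200 for
Michaelis–Menten, 1000-point IC₅₀ grid with profiled plateau) verify
that the analytic fits sit at the global least-squares optimum to
better than 1%.

## Known limitations

- The exact normalization convention of published PICS heat maps varies
  between tools; both raw and corrected matrices are exported rather
  than asserting one convention.
- Scoring is purely sequence-based and additive; it cannot capture
  substrates recognized through three-dimensional context (e.g. basic
  residues on a neighboring strand substituting for P3), which is
  exactly where natural substrates deviate from profile predictions.
- No tight-binding (Morrison) correction: inhibitor depletion at
  enzyme ≈ Ki is not modeled.
- The burst model assumes a single exponential acylation phase; slow
  secondary phases or substrate depletion during the burst are not
  modeled.
- Ca²⁺ activation data with different substrates can show a maximum at
  different activator concentrations; the attenuated model accommodates
  a decline after the optimum but no single parameter set is asserted
  across substrates.
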