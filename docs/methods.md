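# Methods

## Mass model

All masses are monoisotopic, built from CODATA/NIST atomic masses
(C = 12 exact, H = 1.00782503207, N = 14.0030740048, O = 15.9949146196,
S = 31.97207100, P = 30.97376163) with the proton at 1.007276466 Da.
Electron mass is neglected everywhere, including radical species; radicals
carry a flag that affects only labels.  Published modification masses
computed with other constant sets differ from ours by ≲2×10⁻⁶ Da, so all
registry comparisons in the tests use a 5×10⁻⁵ Da tolerance rather than
exact printed digits.  Average masses, isotope fine structure and non-proton
adducts are out of scope.

Peptide neutral mass is the residue-mass sum + H2O + modification deltas;
an independent test path assembles the full elemental composition and the
two must agree to 1×10⁻⁹ Da.  Residue numbering is 1-based, matching the
convention used for protein sites ("Cys14").  Ambiguity/rare codes
(B, Z, X, U) are rejected rather than approximated.

The modification registry (TSV bundled with the package; user registries
accepted in the same dialect) carries a **lability class** per entry:
`thioester_acyl` (myristoyl C14H26O, palmitoyl C16H30O, stearoyl C18H34O),
`thioether_prenyl` (farnesyl C15H24, geranylgeranyl C20H32), or `stable`
(NEM, carbamidomethyl, acetyl, Met oxidation).  The class, not the name,
decides which neutral-loss channels apply.

## Fragmentation model

Backbone ions follow the standard relations: y = C-terminal residues + H2O
+ protons, b = y-complement, c = b + NH3 (17.026549), z˙ = y − NH2
(16.018724; the radical z+1 species is the only z type emitted).  Default
fragment charges run 1..min(2, precursor charge).

Loss channels per activation:

| activation | backbone | thioester (acyl) | thioether (prenyl) |
|-----------|----------|------------------|--------------------|
| CID   | b, y       | ketene loss on y, p; d\* | intact loss on b, y, p |
| HCD   | b, y       | ketene loss on b, y, p; d\* | intact loss on b, y, p |
| ETD   | c, z˙      | S–C radical losses (formula + S, + S + H) on p, z˙ | — |
| EThcD | b, y, c, z˙ | both of the above | intact loss on b, y, p |

Loss variants are emitted only for ions whose residue span contains a
modification of the channel's class; for multiply modified spans the loss
multiplicity is capped at 2 by default (di-acylated peptides make a double
loss physically possible, but single losses dominate observed spectra).
Whether b\* ions occur under CID is not settled; the default emits b\* under
HCD only, and the rule set is a plain dataclass the user can replace.

Precursor species: p at charges 1..z (for ETD, charge-reduced species that
retain all protons at reduced charge), p±H2O at the precursor charge, and
one p\* per loss channel.  Geranylgeranyl precursors additionally lose a
partial C10H16 fragment; its formula-derived mass is 136.1252 Da (a printed
value of 136.14 circulates, which C10H16 cannot produce — we emit the
formula-derived value).  The diagnostic d\* is modeled as the acylium-type
ion, acyl delta + proton (239.2369 for palmitoyl); the model is an
assumption — it reproduces the observed mass, but the ion's formula has not
been assigned independently.  The S–C radical-loss formulas are
demonstrated for palmitoyl only; homologous channels for other chain
lengths are generated the same way and flagged "(extrapolated)" in their
species labels.

## Annotation and localization

Peak matching assigns each theoretical ion the observed peak minimizing
|ppm error| within the tolerance (default 20 ppm); a peak satisfying
several ions is retained for each and flagged shared.  **Ion coverage** is
defined over backbone cleavage sites, not ion counts: site i (1..n−1) is
covered when any matched b/c ion of index i or y/z˙ ion of index n−i
exists.  Neutral-loss variants count by default because they still carry
sequence information; a strict flag excludes them.  Precursor and
diagnostic matches never count — they carry no backbone position.  This
definition is ours; published ion-coverage percentages computed with other
tools need not be numerically comparable.

Localization enumerates every distinct assignment of the modification
multiset to the candidate sites and scores each as (number of matched
site-determining ions) + 0.01 × matched-intensity fraction, where an ion is
site-determining when its m/z (rounded to 10⁻⁴) occurs in no competing
assignment's theoretical spectrum.  The intensity term only breaks ties; a
gap below one ion with zero site-determining matches on both top forms is
reported as delta = 0 (ambiguous).  Probabilistic site scoring
(Ascore-style) is deliberately out of scope — the score is transparent and
its failure mode (no site-determining ion present) is explicit.

## Database search

The search space is strict-trypsin digestion (cleave after K/R except
before P), two missed cleavages, peptide length 7–50, protein N-terminal
Met clipping emitting both clipped and unclipped forms, and variable
modifications capped at 3 per peptide by default (the cap is a choice, not
a published value).  At the bare-peptide level a protein-N-term rule
behaves like peptide-N-term.  Decoys are per-protein reversals with the
C-terminal residue fixed, preserving tryptic C-termini; target and decoy
peptidoforms are indexed by neutral mass for window queries.

Scoring is matched-ion counting (backbone + loss + diagnostic ions, the
lipid-specific evidence) plus 0.01 × matched-intensity fraction — the
package's claim is the lipid-aware search space, not parity with a
production engine; a flag disables loss-ion credit for ablation.  PSMs with
fewer than 4 matched ions are not reported (a standard reporting floor;
without it, zero-evidence target/decoy ties can leak through the FDR
estimate).  q-values are classical target-decoy: sort by score, running
FDR = decoys/targets, monotone minimum from the bottom.  Unknown precursor
charge is handled by trying 2–4 and flagging the assumption.
Open/mass-offset search, protein inference and rescoring are out of scope.

## Stability quantification

XIC extraction sums, per MS1 scan, the intensity within ±tol ppm of the
target m/z (zero when absent).  Peak boundaries are the widest contiguous
region around the apex with intensity above 5% of the apex, extended one
point to include the crossing; area is the trapezoidal integral
(intensity × seconds).  The 5% rule is configurable — commercial tools use
unstated boundary models, so absolute areas are comparable only within one
rule.

Replicate areas are divided by the control-group mean (the control
therefore has mean exactly 1 by construction; when a design pools control
replicates across conditions, normalization uses the pooled mean).  Two
groups: unpaired two-sided t-test, equal-variance by default ("Student's"
read literally) with Welch as a flag.  Three or more: one-way ANOVA, then
Tukey HSD adjusted pairwise p-values via the studentized-range distribution
on the pooled residual variance (scipy implementation).  Significance
labels: * ≤0.05, ** ≤0.01, *** ≤0.001.

## Synthetic data

Spectrum simulation takes the full theoretical ion list, keeps each ion
with probability `ion_sampling_fraction`, draws intensities from a
log-normal (σ=0.3) scaled by activation-specific series weights (HCD:
y ≥ b, loss ions at 0.8× their parent by default; CID at 3+: p\* dominant;
ETD: c/z˙ with prominent precursor losses), jitters m/z with Gaussian ppm
noise (≤10 ppm), and appends uniform noise peaks.  One RNG stream per
simulation, consumed in a fixed documented order (mask, intensities,
jitter, noise), so any step is independently recomputable; everything is
bit-reproducible under a fixed seed.

The quantification simulator emits Gaussian elution peaks (σ = 5 s, scans
1 s apart) whose areas are the condition mean times unit-mean log-normal
scatter at the requested CV.  The fixture bundle is a 20-protein Cys-rich
toy proteome (synthetic sequences; a slot exists to substitute real ones),
100 planted HCD spectra (90% ion sampling, 3 ppm jitter, 20 noise peaks)
and 100 noise spectra whose precursors reuse planted masses — so they pass
the precursor filter and genuinely exercise decoy competition — plus a
quant dataset and a manifest with seeds and ground truth.

What the simulators do **not** model: isotope envelopes, realistic peak
shapes and tailing, co-isolation/chimeric spectra, intensity prediction,
retention-time drift between runs.  Passing the recovery tests therefore
shows the inference machinery is correct under its own generative
assumptions, not that real spectra of lipidated peptides will identify at
these rates.

## Problem sizes and calibration

The bundled benchmarks use 200 localization spectra, a 100+100
planted/noise search against the 20-protein proteome, 1000 ANOVA null
repetitions and 200 quantification seeds — sizes chosen so the whole
battery runs in about a minute on one CPU while keeping binomial
uncertainty on the reported rates near or below one percentage point.

One calibration note: with 3 treated and 3 control replicates at 10% CV,
the normalized treated mean is a ratio of two 3-replicate means and has
standard deviation ≈ 0.5·√(0.01/3 + 0.01/3) ≈ 0.041.  Its probability of
landing within ±0.05 of the truth is therefore ≈78–80% — an intrinsic
property of that design, not an estimator defect (the across-seed mean is
unbiased at 0.50).  Tightening the interval requires more replicates or a
larger pooled control, not a different algorithm.
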