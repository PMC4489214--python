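# Methods

## Problem setting

Highly diversified receptor families generate many near-identical
protein isoforms from one genomic locus: alternative promoters produce
long (*alpha*) and short (*beta*) variants in which the beta sequence is
a C-terminal suffix of alpha preceded by a short beta-unique N-terminus,
and binary exon insertions at named alternatively spliced segments
(AS3/AS4/AS6 in the neurexin-style architecture) multiply the variant
count. Isoform-level questions — which variants exist as protein, at
what absolute abundance, with what regional distribution and binding
selectivity — require peptide-level measurements that discriminate
sequences differing by a handful of residues. `srmiso` implements the
assay-design and data-analysis layers of such an SRM workflow; raw
signal processing (chromatographic peak integration, MS/MS database
search) is out of scope and its outputs (peak areas, spectral counts)
are the package's inputs.

## Digestion, membership, classification

Tryptic digestion uses the standard rule: cleavage C-terminal to K or R
unless the next residue is proline, with 0–2 missed cleavages for
identification contexts. A peptide's *membership* is the exact set of
isoforms whose digest contains it — substring matching restricted to
tryptic boundaries, because SRM observes digest products, not arbitrary
subsequences. Isoleucine and leucine are isobaric and indistinguishable
by SRM, so membership folds I and L together by default (`il_equivalent`
flag); without this, sequence-unique but mass-degenerate peptides would
be called proteotypic incorrectly.

Detection groups form a three-level taxonomy per gene: *pan* (all
isoforms), *promoter* (all alpha or all beta), and *splice-insertion*
(all carriers of one segment). Classification demands exact member-set
equality; when member sets coincide (e.g. a single-promoter gene where
pan = alpha) the most specific level wins, with a lexicographic label
tie-break for determinism. Memberships that span genes, or match no
group exactly, are `non_proteotypic`; empty membership is `absent`.

## Candidate filtering and panel assembly

Defaults: length 7–25 residues, fully cleaved peptides only for
quantification (missed-cleavage products are digest-variable and bias
isotope-dilution ratios), and exclusion of any peptide containing the
start of an N-X-[S/T] (X ≠ P) glycosylation sequon, evaluated in full
parent context because a sequon can extend past the peptide's
C-terminus. Methionine and tryptophan are oxidation-prone, so
M/W-containing peptides are *penalized in ranking*, not forbidden;
cysteine is acceptable because it is quantitatively carbamidomethylated.
Ranking is (no penalized residues, shorter, lexicographic), and panel
assembly takes up to `max_ptps` candidates per group, flagging groups
below `min_ptps`. The exact amino-acid-composition criteria of
practical PTP selection vary between laboratories; ours are explicit
and configurable rather than implicit.

## Masses and transitions

Monoisotopic residue masses come from pyteomics; water 18.010565 Da,
proton 1.007276 Da, carbamidomethyl +57.021464 Da on every C, heavy
labels +8.014199 Da per K and +10.008269 Da per R (13C/15N). Fragment
m/z follows the y/b conventions (y_i = last *i* residues + water +
z·proton over z, b_i analogous without water). Transition selection
implements the triple-quadrupole rule for tryptic peptides: singly
charged y-ions whose m/z exceeds the precursor m/z, highest indices
first, with a flagged fallback to b-ions when fewer than two y-ions
qualify. Because tryptic y-ions always contain the C-terminal K/R,
light and heavy species select identical fragment index sets. Collision
energy is the vendor-style linear function CE = slope(z)·m/z +
intercept(z) (defaults 0.034/3.314 for z = 2, 0.044/3.314 for z = 3);
per-peptide empirical optimization is instrument-bound and out of
scope, so the parameters are configuration.

## Quantification model

Transition areas are summed per peptide and label over the transition
set shared by both labels before ratioing — robust to single-transition
dropouts, and preferable to averaging per-transition ratios, which is
dominated by weak transitions. Species estimates are means ± sample SD
over peptides × replicates (median available by option).

Absolute quantification uses the two-step PSAQ chain: with a known
light anchor (GFP) spike *G*, anchor peptides give the heavy fusion
standard amount *H = G · mean(heavy/light)*, and target peptides give
the endogenous amount *E = H · mean(light/heavy) / m* for sample
protein mass *m* (fmol/µg). Ratios are averaged per step (averaging
after the product is an alternative reading; per-step averaging is the
package's choice and is recorded in the estimate provenance). The chain
is invariant to any global rescaling of areas within a run. Where a
variant lacks enough unique sequence for a direct standard, beta = pan −
alpha with SDs propagated in quadrature (independence assumption);
negative differences are flagged (`negative_subtraction`), never
clamped, since clamping biases low-abundance estimates. The titration
rule flags estimates whose standard/endogenous ratio leaves the closed
interval [0.5, 2]. Copies per synapse scale a target amount by an
anchor protein of known copy number measured in the same units.

Splice-insertion amounts are normalized to the parent pool that can
carry them: AS3 and AS6 exist only in alpha variants, hence are divided
by the alpha amount; AS4 occurs in both promoter classes, hence by pan.
Regional profiles are normalized to a reference region (ratio 1 there).

## Calibration limits

LoB = mean(blank) + 1.645·SD(blank); LoD = LoB + 1.645·SD(low-conc);
one-sided 95% multipliers, sample (n−1) SDs. The blank/low-concentration
method names no LoQ criterion, so LoQ is operationalized as the lowest
calibration level with replicate CV ≤ 20% (configurable) and mean area
≥ LoD, with an explicit not-determined sentinel otherwise. Standard
curves are ordinary least squares of area on concentration with a
back-calculation inverse; weighted/robust variants are a deliberate
non-goal (hook reserved).

## Profiling

NSAF_i = ((SpC_i + pseudo)/L_i) / Σ_j ((SpC_j + pseudo)/L_j) per sample;
columns sum to one, and a +1 pseudo-count keeps zero-count rows
log-representable. Clustering is agglomerative with Ward's objective on
either Euclidean distances or the correlation distance, defined as
1 − Pearson r between row profiles (1 − |r| rejected as nonstandard);
rows are pre-sorted by label so results are invariant to input order.
Spearman correlation uses midranks for ties; for profiles of length
≤ 8 the two-sided p-value is exact by full enumeration of the n!
permutations (8! = 40320, trivially feasible — and 8 matches a typical
brain-region panel), larger n uses the t approximation. Binding
specificity between two baits is log10 of parent-normalized recovery
ratios with the same parent rules as splice normalization; the
adhesion readout is (mean bound − background)/(mean input − background).

## Simulator

The family generator assembles sequences from unique random tryptic
blocks (7–16 residues ending K/R). Interior residues exclude K/R
(would create extra cleavage sites), P (would suppress the terminal
cleavage), I (keeps I/L-folded uniqueness equal to raw uniqueness), and
N (keeps backbones sequon-free so composition filters never empty a
detection group). Each gene has an alpha-specific block region hosting
the alpha-only insertion slots, a shared region hosting shared-segment
slots, and a beta-unique prefix; segment inserts are themselves single
tryptic blocks placed at block boundaries. Consequently every
detection group is covered by whole-block proteotypic peptides by
construction, which the generator verifies before returning. All 2^k
insertion combinations are emitted per promoter class (alpha: all
segments; beta: shared segments only), giving 26 isoforms and 17
detection groups for the default 3-gene configuration.

SRM simulation draws one log-normal base response per peptide ×
transition, shared between light and heavy — the co-elution /
co-fragmentation assumption that underlies isotope dilution — and
scales it by endogenous amount × protein mass (light) or standard spike
(heavy), with multiplicative log-normal noise of specified CV (mean 1)
applied independently per transition × replicate × label. PSAQ mode
adds anchor-peptide rows per standard chain. Shotgun counts are
multinomial with probabilities ∝ amount × length.

Default study conditions: promoter-variant amounts on the whole-brain
scale (alpha 2.19–4.18 fmol/µg, beta 0.87–1.97 fmol/µg; pan = alpha +
beta), insertion pools as fixed fractions of their parent (AS3 0.5 of
alpha, AS6 0.25 of alpha, AS4 0.4 of pan — chosen once as plausible
mid-range usage since absolute insertion amounts are not established),
5 µg digested protein, heavy spikes titrated to the endogenous level
(ratio 1), transition CV 10%, 4 replicates.

What the simulator does *not* emulate: chromatographic interference and
integration error, retention-time drift, digestion variability
(missed-cleavage kinetics), matrix-dependent ionization suppression,
label impurity, and between-animal biological variance. Passing
recovery tests therefore demonstrates the correctness of the
quantification arithmetic and its noise propagation, not the field
accuracy of SRM on tissue.

## Numerical choices and problem sizes

Sample SD (ddof = 1) everywhere dispersion is reported; single values
report SD 0. Ratio denominators of zero raise identified errors rather
than propagate NaN. Exports print m/z to 5 decimals and CE to 2, with a
fixed row order so re-exports are byte-identical. Tests and the
acceptance script use a 26-isoform default family, 50 two-gene families
for transition-rule checks, 100 families for membership-oracle checks,
20 seeds for exact zero-noise recovery and 100 seeds for stochastic
recovery — sizes chosen to keep the full suite under a minute while
exercising every code path; all are parameters, not limits.

## Known limitations

- Only trypsin is modeled; alternative proteases would widen isoform
  coverage but are not implemented.
- No detectability prediction: candidate ranking is compositional, not
  learned from spectral libraries.
- No retention-time scheduling; transition lists are unscheduled.
- The correlation-distance Ward tree uses the Lance–Williams update on
  a precomputed dissimilarity, the standard practice when the metric is
  non-Euclidean; its "variance" interpretation is then heuristic.
- Group classification requires exact member-set equality; partially
  overlapping memberships (e.g. a peptide shared by an arbitrary subset
  of isoforms) are conservatively non-proteotypic.
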