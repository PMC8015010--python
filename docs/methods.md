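# Methods

## Model and procedure

`oxiprot` treats a TMT 10-plex oxidation experiment at the peptide
level: the unit of inference is one peptide *form* (a sequence together
with its modification annotations), carrying ten reporter-channel
intensities from five control and five treated biological replicates.
The pipeline assumes reporter intensities are positive, roughly
log-normal, and that unequal channel totals reflect loading differences
rather than biology — hence normalization rescales every channel to the
mean of the original channel totals. The normalization target is
cosmetic: fold changes and t statistics are invariant to any common
rescaling (tested), so only the equal-totals property matters.

Differential abundance per peptide is mean(treated)/mean(control) of
normalized intensities with a two-tailed two-sample t-test. The default
is the pooled-variance Student form (df = 8 for 5+5), matching the
spreadsheet convention for balanced designs; Welch is available via
`QuantConfig(equal_var=False)` for unequal-variance data. Degenerate
rows where both groups have zero variance take p = 1 (equal means) or
p = 0 (unequal) by convention. Benjamini–Hochberg runs across all
quantified peptides as a single family — no stratification by
modification class — and significance means adjusted p < alpha
(default 0.05). Categories at significance are fold > 1 and fold < 1,
with fold > 2 and fold < 0.5 as nested subsets; the no-change,
increase->1 and decrease-<1 columns therefore partition the quantified
set exactly, an identity asserted on every synthetic run.

A peptide is *quantified* only when all ten channels are present;
rows with any missing channel are carried as *detected-only* so that
detection totals can exceed quantification totals, as they do in real
exports. The co-isolation filter (keep ≤ 30%, inclusive) runs before
everything else; rows lacking a co-isolation value pass.

## Modification chemistry

The registry stores six modifications: carbamidomethyl (+57.02146, C),
oxidation/hydroxylation (+15.99491, CDEFHILMNPQRSTVWY), carbonylation
(+13.97926, AEILQRSV), dioxidation (+31.98983, CEFILMPRVWY),
trioxidation (+47.98474, CFWY) and the TMT label (+229.16293, static on
K and N-termini). Delta masses are stored at full precision and derived
from elemental compositions over hard-coded monoisotopic element masses
(consistency enforced at 5e-4 Da); displays round to 3 decimals. The
residue lists are taken as the accepted search conventions for these
adducts; their chemical rationale is not re-derived here. The
+31.99 Da class is labelled dioxidation throughout although the same
shift can arise from peroxidation — the two are indistinguishable by
mass. Oxidative classification is presence-based per class; the inert
adducts (carbamidomethyl, TMT) never set flags, and ambiguously
localized sites (candidate sets like "H/P") still count toward their
class because classification never needs the residue. In the residue ×
class site matrix, by contrast, only uniquely localized sites
contribute; ambiguous sites are excluded outright rather than
fractionally attributed, and cells for never-searched residue/class
pairs are marked unavailable. N-terminal sites use a dedicated `nterm`
token; all residue positions are 1-based.

## Digestion

The combined trypsin + Lys-C rule cleaves after every K (Lys-C cuts
K-P) and after R except before P. Peptides with 0..max_missed missed
cleavages are enumerated with protein coordinates and flanking
residues. Initiator methionine is not removed. Synthetic proteotypic
peptides are restricted to 6–50 residues (typical search-engine
bounds); mapping back to proteins requires equality with a digest
peptide, not mere substring occurrence.

## Channel-permutation null

The null shuffles the ten reporter values uniformly within each
peptide, using one seeded generator consumed over rows sorted by
(peptide, accession, mods) so results do not depend on input order, and
re-runs the entire pipeline (normalization included) on the shuffled
table. Shuffling raw rather than exported-normalized values is the
default; for near-balanced totals the two differ negligibly because a
within-row permutation barely moves column totals. Shuffling destroys
group structure, so discoveries on shuffled data estimate the
pipeline's false-positive behaviour. Two subtleties bound what "zero
discoveries" can mean here. First, under a global null BH still allows
any-discovery in about alpha of runs, so across many shuffles a few
percent of runs with one borderline discovery is expected behaviour,
not a defect. Second, a permuted peptide whose values are strongly
bimodal (a true fold change well above ~2 relative to the noise) keeps
its bimodal value multiset: with probability 2/252 a random 5/5 split
reconstitutes perfect separation and yields an extreme p-value. With
purely technical reporter noise (CV 0.10) these "atoms" occasionally
clear the BH threshold on 10^4-peptide tables; real biological
replicate variance, which the generator deliberately omits, suppresses
them. The discovery count on shuffled tables is therefore reported as a
distribution over seeds rather than asserted to be identically zero.

## Synthetic data

The generator emulates the 5+5 design with: log-normal baselines
(ln-mean 11.5, ln-sd 1.0 — reporter-scale intensities around 1e5);
per-channel multiplicative loading factors (log-normal, sigma 0.1,
removed exactly by normalization — verified by regenerating with
different factors under the same seed); multiplicative log-normal
reporter noise at CV 0.10 per cell; background modification
probabilities per class (hydroxylation 0.125, dioxidation 0.021,
trioxidation 0.003, carbonylation 0.006 — the background fractions seen
in unstressed bacterial proteomes), each emitted as a separate row from
the unmodified form, with residue-eligibility enforced; a 0.12 fraction
of rows with true effects, log2 fold ~ Normal(0, 0.35) truncated at
|log2| ≥ 0.1 so effects are real but predominantly sub-2-fold; and
explicit planted effects, by default the GAPDH-like active-site peptide
YAGQDIVSNASCTTNCLAPLAK with trioxidation on its catalytic Cys (C12) at
a true fold of 20.12. Co-isolation draws put 5% of rows above the 30%
threshold to exercise the filter; 2% of non-planted rows lose one
random channel. The generated proteome always contains exactly one
canonical SCTTNC motif (in the GAPDH-like record) and, when configured,
one SCTTNS Deinococcus-type variant; catalog molecular weights are the
monoisotopic protein mass in kDa and copy numbers are log-normal with
log10 mean 2.4, sd 1.0, placing the whole-catalog RAM distribution
around 3.9–4.

Noise magnitude is the one parameter real experiments do not pin down;
CV 0.10 represents technical reporter noise only. Because biological
replicate variability, within-protein peptide correlation,
intensity-dependent noise and channel cross-talk are all absent,
passing tests demonstrate the correctness and calibration of the
inference machinery — not that real data would reach the same power.
On small tables (a few hundred rows) a planted 20-fold peptide slightly
compresses its own estimate (median ~5% low) because it inflates the
treated-channel totals used for normalization; the effect vanishes at
realistic table sizes.

## Numerical choices and problem sizes

Percentages in summary tables use decimal half-up rounding to one
decimal place (the convention that reproduces published table cells
exactly); zero-denominator columns render N/A. Volcano export caps
-log10(adjusted p) at 16. BH validation rejects p outside [0, 1].
Normalization refuses zero-total channels by name. Validation exercises
use: 10,000-peptide tables for the permutation null (20 shuffle seeds)
and for FDR control (re-drawn abundances over a fixed peptide set);
100 seeded replicates of 300-peptide tables for planted-fold recovery
(median relative error < 10%, top-rank in every replicate); brute-force
oracles for BH (n ≤ 20), digestion (500 random sequences ≤ 60 aa) and
motif scanning (1000 random sequences).

## Known limitations

Peptide-level only: no PSM aggregation, no protein roll-up beyond
unique-protein counting, no localization scoring (ambiguity is carried,
never resolved), no isotope-envelope or fragment-spectrum modelling.
The RAM convention (base-10 log, kDa, absolute copies) is one of
several defensible choices; comparisons within a catalog are invariant
to the convention up to an additive constant.
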