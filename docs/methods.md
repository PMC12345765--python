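# Methods

## The deconvolution model

sfdkit operates on presence/absence only. A proteome is a finite set of
canonical identifiers in a single namespace (UniProt accession or gene
symbol); a cascade is an ordered list of two step kinds applied to a disease
set: subtraction of a reference (healthy-EV scaffold, serum contaminants)
and intersection with a function-specific reference (metastasis-associated
genes, surfaceome, immunosuppression, and iterated sub-functions). Because
set difference and intersection commute, the *final* candidate set is
invariant under step reordering; only the intermediate funnel counts depend
on order. Step order is therefore configuration: the three shipped presets
fix conventional orders so funnel reports are comparable across runs, and
the order-invariance property is enforced by test rather than assumed.

The underlying assumption is binary detection: a protein is either observed
in a sample type or it is not. The model has no notion of abundance, so a
protein present at trace level in any healthy source is removed exactly as
if it were abundant there. This is deliberate (it is what makes the
subtraction safe for therapeutic-target nomination) and is also the
method's sharpest limitation — see below.

## Identifier handling

Gene symbols are upper-cased; accessions are upper-cased and stripped of
isoform suffixes (`-<digits>`), since detection is not isoform-resolved.
Accession→symbol translation uses only a user-supplied two-column table: no
remote lookups, no synonym expansion. Unmapped accessions are retained in a
side list and excluded from set algebra by default — silently dropping them
would corrupt funnel accounting. Many-to-one collapses keep one set member
and log the collapse count, because downstream set semantics are by gene
identity (the survival screen is gene-level).

## The healthy compendium

The scaffold reference is built from per-source presence lists. The default
is the union (`min_sources = 1`): a protein seen in *any* healthy source
counts as scaffold. This is the conservative reading — it maximizes
background removal and minimizes the chance of nominating a constitutive
vesicle protein — but a presence threshold is exposed (`min_sources = k`)
for users who consider a single-source sighting insufficient evidence.
The reference is monotone nonincreasing in `min_sources`. A multi-donor
reference for a matched healthy cell type is built the same way (union over
donors by default).

## Classification

Each candidate is assigned exactly one of four categories —
metabolic/acidification, immune modulation, oncogenic driver, and the
metastasis-associated/unknown fallback — by matching its annotation terms
(GO/KEGG/functional-description keywords, supplied as a table) against
per-category trigger-term lists. A trigger matches as a case-insensitive
substring of an annotation term. When several categories match, the lowest
precedence number wins; the shipped default order is immune (1) < metabolic
(2) < oncogenic (3), with the fallback absorbing everything unmatched.
Exactly-one-category assignment with explicit precedence is a design choice:
real curation of such lists is subjective, so the rule file makes the
criteria explicit and auditable rather than pretending to NLP over
free-text records. Category counts always partition the candidate set, and
assignment is independent of input iteration order.

## Survival screening

Per gene, expression is transformed log2(x+1) and z-scored, then fit as a
continuous covariate in a univariate Cox proportional-hazards model (Efron
tie handling; lifelines `CoxPHFitter`). Hazard ratios are therefore per SD
of log expression and comparable across genes. Wald 95% CIs and p-values
are reported, with Benjamini–Hochberg q-values across the screened set —
reported alongside, not instead of, raw p, since univariate screens are
conventionally read both ways. Proportionality is checked by the
correlation test of scaled Schoenfeld residuals against event-time rank
(lifelines `proportional_hazard_test`, rank transform); p < 0.05 sets a
violation flag.

Degenerate inputs never raise mid-screen: a constant covariate (including
near-constant columns whose post-transform SD is within 1e-12 of zero,
which are zeroed to avoid float-noise pseudo-variance) or fewer than two
events yields a flagged result with beta = 0 and undefined CI/p, and the
Schoenfeld check is skipped with the reason recorded. Records missing an
endpoint's time/event are dropped pairwise per endpoint. OS is time to
any-cause death; DFS is time to recurrence or death; both in months.

The Kaplan–Meier median is the smallest observed time at which the survival
curve drops strictly below 0.5; a curve that only touches 0.5 exactly is
reported as "not reached". This strict-inequality tie convention is the
package's choice for the knife-edge case (it errs toward "not reached");
away from exact ties it coincides with the usual `inf{t : S(t) ≤ 0.5}`.

## Synthetic worlds

The generator emulates the structure of a disease-EV study: a scaffold core
shared with healthy sources, per-source healthy-specific cargo,
disease-unique cargo (a fraction of it function-annotated, plus a disjoint
decoy fraction of scaffold ids in the function reference so that the
function filter alone cannot recover truth), and independent per-source
detection dropout — each scaffold protein appears in each healthy source
with probability 1 − dropout. Defaults (1000 scaffold proteins, 24 healthy
sample types, 150 disease-unique, 40% function-annotated, dropout 0) are a
desk-scale rendering of a melanoma-style EV proteome against a multi-source
healthy compendium. Disease-side dropout defaults to 0 so presence/absence
truth is exact and the cascade's set logic is tested in isolation; turning
it on reproduces the false-negative regime in which genuine disease markers
are lost to the subtraction.

Under a two-source union compendium with dropout d, a scaffold protein
survives subtraction iff it is missed in both sources, so leakage is
Binomial(n_scaffold, d²); the generator's calibration is tested against
this closed form (mean over 200 seeds within 3 binomial SD of n·d²).

Survival cohorts plant a hazard gene: a standard-normal latent z per
patient drives exponential event times with hazard h0·exp(β·z),
h0 = 0.05/month (median ≈ 14 months at z = 0). Expression is stored as
2^(z+8) − 1, so the screen's log2(x+1) transform recovers the latent
exactly up to the affine shift that z-scoring removes. Censoring times are
uniform on [0, m] with m calibrated by bisection (80 iterations) against
the realized event times so the achieved censoring fraction matches the
request; null genes are independent of survival. One seeded NumPy
generator drives everything: identical config + seed gives byte-identical
worlds.

What the generator does *not* emulate: MS intensities, peptide-level
identification and FDR, correlated detection across related sample types,
and annotation noise. Passing tests therefore demonstrate the correctness
of the set logic, calibration of the dropout model, and the statistical
behavior of the screen — not robustness to real MS artifacts.

## Verification scale and numerical choices

The test suite checks cascade results against brute-force per-element
evaluation on 1000 random instances (universe ≤ 50, ≤ 5 steps); Cox fits
against an independent grid-search maximizer of the Efron partial
likelihood over [−5, 5] at step 1e-4 on fixtures with n ≤ 8 (agreement to
|Δβ| ≤ 1e-3); effect-size recovery at β = 0.7 over 100 cohorts of 500
patients with 30% censoring (mean within 2 Monte-Carlo SE); null p-value
uniformity over 200 replicates (KS at α = 0.01); and Schoenfeld flag rates
under proportional and crossing-hazards data. These sizes were chosen so
the whole suite runs in about a minute while keeping the Monte-Carlo
checks well-powered.

## Known limitations

- Presence/absence blindness: proteins enriched in disease but detectable
  in any healthy source are removed; the per-step `removed_members` record
  exists precisely so such exclusions can be audited and rescued manually.
- Single-namespace set algebra; no isoform or proteoform resolution.
- Classification quality is bounded by the supplied annotation table and
  trigger terms; the default rule file is a starting point, not a curated
  ontology.
- The Cox screen is univariate by design — no adjustment for stage, age or
  other covariates — and the Schoenfeld check at nominal 5% will flag ~5%
  of truly proportional genes.
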