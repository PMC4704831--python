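# Methods

## The analysis model

The pipeline formalises a two-stage biomarker discovery design for blood DNA
methylation in Alzheimer's disease (AD) and amnesic MCI (aMCI).

**Stage one (discovery).** Beta values (methylation fractions in [0,1]) for a
small, age-matched subset — by default the 4 youngest subjects per group —
pass through a nested candidate funnel. Each locus is tested with unpaired
Student t-tests for the three group pairs; a locus survives stage 1 iff its
two-sided p < α in *all three* comparisons (α = 0.05, unadjusted; an optional
per-pair Benjamini–Hochberg correction is off by default because the design
deliberately trades specificity for a shortlist that later validation must
confirm). Stage 2 keeps loci whose group means are strictly monotone along
disease progression NC → aMCI → AD in either direction; exact ties fail
(conservative, and measure-zero under the noise model). Stages 3–5 are
annotation predicates on a 450K-style manifest: at least one transcript
accession; at least one RefGene group among TSS1500, TSS200, 5'UTR and
1stExon under **any-transcript semantics** (a probe annotated
`Body;1stExon` is promoter-proximal — membership in any transcript
suffices); and CpG-island location. The funnel is nested by construction:
stage5 ⊆ stage4 ⊆ stage3 ⊆ stage2 ⊆ stage1 ⊆ CpG loci.

**Candidate ranking.** Survivors are correlated (Spearman) with MMSE and FAB
over the scored patients. NC subjects carry no scores by design; missing
scores are dropped pairwise, so the FAB n may be smaller than the MMSE n. The
selection rule is: among loci with p < α on *both* scores, maximise
min(|ρ_MMSE|, |ρ_FAB|); ties break by smaller max(p), then lexicographic
locus id; if nothing passes both, fall back to the strongest |ρ_MMSE| with a
warning. Ranking uses magnitudes, not signs — the direction of association is
reported, not enforced.

**Stage two (validation).** The candidate is re-measured in the full cohort
on a pyrosequencing-style percent scale, per CpG of the assay. Per CpG the
module fits the one-covariate ANCOVA *y* = μ + group + β·age + ε by least
squares; the group effect is the extra-sum-of-squares F against the age-only
model, adjusted means are predictions at the grand mean age, and pairwise
contrasts are t-tests on differences of adjusted means with the full model's
residual variance (unadjusted for multiplicity, with significance stars at
0.05 / 0.01 / 0.0001). The report adds Spearman correlations with MMSE, FAB
(patients), age (everyone), disease duration and onset age (patients), a
sex t-test, per-CpG Pearson correlation against the array betas for subjects
measured on both platforms, and an APOE ε4 carrier (≥ 1 ε4 allele) vs
non-carrier t-test.

## Statistics

All tests are implemented from their textbook definitions, with scipy used
only for the t, F and χ² reference distributions; scipy's own test functions
and statsmodels OLS serve as independent oracles in the test suite. Details
worth noting:

* The unpaired t-test is the Student pooled-variance form by default (Welch
  by flag).
* One-way ANOVA on all-constant input returns F = 0, p = 1 by documented
  convention instead of erroring, so pipelines survive degenerate loci.
* Spearman's ρ is the Pearson correlation of mid-ranks; p-values use the
  t approximation t = ρ√((n−2)/(1−ρ²)) by default, with an exact permutation
  p (all n! permutations) available for n ≤ 9 — the regime of the discovery
  stage (n = 8 MMSE, n = 6 FAB).
* χ² independence uses no continuity correction by default (configurable).
* ANCOVA requires ≥ 3 subjects per group and a complete age column; singular
  designs raise an error naming the collinear term.

## The synthetic-data generator

The generator emulates the study conditions so every stage is testable
without any download.

**Cohort.** Group sizes default to 30/28/30. Clinical marginals are fixed
module constants on the published mean ± SEM scale: age 70.5 ± 1.0 /
72.0 ± 0.9 / 71.8 ± 0.9 years (subject-level sd = SEM·√n, truncated by
redraw to 55–90); female fractions 0.600/0.536/0.533; MMSE 27.2 ± 0.4 (aMCI)
and 18.5 ± 1.0 (AD), FAB 14.8 ± 0.4 and 12.0 ± 0.7, integer-rounded and
clipped to their scales; disease duration 26.5 ± 4.4 / 28.2 ± 3.5 months.
Onset age is derived as age − duration/12, which reproduces the published
onset means (≈ 69.8/69.4) while guaranteeing onset < age per subject. FAB is
missing for 7/30 of AD subjects (only 23 of 30 were scored). APOE alleles
are drawn i.i.d. per group from the published allele counts (e.g. ε4
frequency 25/60 in AD vs 11/60 in NC). Scores exist only for patients.

**Manifest.** Locus annotations are drawn independently per category:
CpG fraction 482421/485777 (the 450K array's CpG share); accession presence
0.75; RefGene-group and island-relation frequencies chosen to resemble the
450K's composition at reduced scale (Body 0.43, promoter groups ≈ 0.49
combined; Island 0.31, shores/shelves 0.32, open sea 0.37). The first
`n_planted` loci are forced to satisfy all four funnel annotation predicates,
matching the contract with the beta generator, which plants its effects at
those loci.

**Beta values.** Noise is Gaussian on the logit scale, mapped back by the
inverse logit: values stay strictly inside (0,1) and variance shrinks near
the boundaries, as in real beta distributions. Null loci draw a baseline
β ∈ (0.05, 0.95) per locus with no group effect; the default logit sd of 0.2
gives a beta-scale sd ≈ 0.05 near β = 0.5. Planted loci follow a per-group
mean profile, default (0.8, 0.6, 0.4) for NC/aMCI/AD — strictly decreasing,
i.e. hypomethylation with disease. Under this null the pairwise Student
t-tests are empirically calibrated (rejection rate within ±0.001 of α at
n = 4/group), because with equal group sizes the difference of means is
symmetric even though the per-group distributions are skewed.

**Score linkage.** Optionally, patient MMSE/FAB are re-drawn as the group
centre plus a slope times the subject's percent-scale deviation from the
group mean at the first planted locus, plus noise: cognition and methylation
fall together with disease, between- and within-group components aligned, so
the linked locus carries the strongest score correlation by magnitude —
the structure the selection rule keys on. Slopes default to 0.8 (MMSE) and
0.7 (FAB) points per percent with noise sd 0.5/0.4: the noise sits below the
integer rounding granularity of the score scales, so the link's rank
ordering survives discretisation at the discovery-stage sample sizes. Note a
structural property of bounded scales: with the aMCI MMSE centre at 27.2 on
a 0–30 scale, strong *negative* within-group links saturate at the ceiling,
which is why the generator links scores positively to the decreasing
methylation profile rather than reproducing the observed negative
correlation signs; the selection rule is sign-blind either way.

**Validation measurement.** The pyrosequencing replicate maps a latent
per-subject beta to percent per CpG: clamp(100·(o + s·β) + N(0, σ), 0, 100)
with (o, s) = (0, +1), or (1, −1) when the assay reads the inverted scale
(σ = 3 percent points by default). The full-cohort latent beta shares each
subject's logit-scale deviation with the array measurement (the same blood
sample underlies both platforms) while its group means follow a separate
validation-shaped profile, default (0.60, 0.40, 0.45) — NC highest, aMCI
lowest — emulating a validation stage whose group ordering departs from the
discovery ordering. Shared deviations make the cross-platform Pearson r
reliably positive on the same scale and negative under inversion.

**What the generator does not model.** Probe-type chemistry differences,
batch effects, cell-composition confounding, partial bisulfite conversion,
and PCR amplification bias between methylated and unmethylated templates.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted structure under idealised noise —
not performance on real blood methylomes.

## Assay utilities

Bisulfite conversion is modelled as complete: every cytosine not in the
methylation map becomes thymine; methylated CpG cytosines are retained.
Coordinates are 0-based on the top strand. Primer compatibility requires the
forward and sequencing primers as exact substrings of the converted top
strand and the reverse primer via its reverse complement; a primer that is
absent but whose C→T image is present is reported as a composition
violation (a C at a non-CpG position can never match a converted template),
and primer footprints covering CpG positions draw a warning
(conversion-state ambiguity under the primer). CpG enumeration returns
reference CpG positions strictly downstream of the sequencing primer's 3'
end within the amplicon.

## Numerical and design choices

* Deterministic seeding: every generator draws from a dedicated
  `numpy` SeedSequence stream spawned from the config seed, so regenerating
  one artifact never perturbs another; identical config + seed yields
  byte-identical output files (fixed float formatting, sorted JSON keys, no
  timestamps).
* Discovery subset: the k youngest per group (k = 4), a deterministic
  age-matched choice nested inside the validation cohort.
* Missing data: empty cells on disk, NaN/None in memory; readers reject
  out-of-range values naming the row and field rather than coercing.
* Problem sizes in the test suite (10,000 loci × 100 seeds for null
  calibration, 2,000 × 100 for funnel sensitivity, 400-locus studies for
  two-stage recovery) were chosen to give tight Monte-Carlo bounds while
  keeping the suite quick on one CPU.

## Known limitations

* The funnel's α is per-test and unadjusted, mirroring the original design;
  at genome scale the stage-1 intersection is expected to contain false
  positives (≈ n_loci × Pr(three joint rejections) under the null), which is
  why validation on an independent measurement is part of the design.
* ANCOVA assumes a common age slope across groups (no interaction term).
* The exact Spearman permutation p is limited to n ≤ 9 (factorial growth).
* The assay module checks primer/template composition, not thermodynamics;
  dispensation order and pyrogram simulation are out of scope.
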