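# Methods

This note documents the statistical model behind `proxidiff`, the
decisions taken where the analysis conventions leave choices open,
what the synthetic-data generator does and does not emulate, and the
pipeline's measured operating characteristics and known limitations.

## Experimental design assumed

Twelve biological samples — 3 replicates for each cell of a 2×2 design
(genotype ∈ {WT, GS} × construct ∈ {EZR bait, CYT control}) — plus 3
injections of a study pool QC (SPQC) made by combining equal volumes of
every sample. Biological groups are the genotype × construct cells; SPQC
injections are technical replicates of a fixed pool and are excluded from
every biological group. Statistics require ≥ 2 replicates per group;
single-replicate groups are accepted at read time but flagged, and any
contrast touching them raises an error.

## Peptide-level processing

The stage order is fixed: **filter → total-intensity normalization →
imputation → trimmed-mean normalization**. All processing happens on the
linear intensity scale; log2 is applied only inside the statistics.

**Filter.** A peptide is kept iff it was observed at least twice across
all runs (SPQC included) *and* in at least 50% of the replicates of at
least one biological group. The rule is idempotent and order-preserving.

**Total-intensity normalization.** Each sample is rescaled so its
observed total equals the across-sample mean total. Column sums agree to
1e-9 relative tolerance afterwards, and reapplication is the identity.

**Imputation.** For each (peptide, biological group) with missing
entries, one of three branches applies:

1. *binned-normal* — fewer than half the group missing. All observed
   values in the matrix are binned into 20 equal-width bins over the
   log10 range of observed intensities; each missing entry is drawn from
   a normal distribution with the mean and standard deviation of the
   (linear) observed values in the bin containing the peptide-group's
   observed mean. Draws are truncated positive by rejection. Bins with
   fewer than 2 members fall back to the global mean/sd (logged, never an
   exception). Bins are log-spaced because intensities span several
   decades — linear bins would put nearly all mass in one bin.
2. *misaligned-zero* — at least half the group missing and the observed
   mean above 5×10⁶ (compared on the post-total-normalization scale; the
   group's observed mean is the single summary a per-peptide-group rule
   needs). The feature is treated as a cross-run alignment artifact and
   the entire peptide-group — observed entries included — is set to 0,
   since the "measured" values are the artifact being discarded.
3. *low-value* — everything else, including fully-missing groups (which
   have no observed mean for rule 2 to test). Missing entries are set to
   the 2nd-percentile point of all detected intensities. The quantile
   point is used rather than a random draw from the bottom 2% for
   determinism; the left-censoring (MNAR) reading of low-intensity
   missingness motivates a floor value.

SPQC columns form their own group and only ever receive branch 3: they
are technical replicates of one pool, so a "biological group" normal fit
or misalignment verdict has no meaning for them.

Every imputed (peptide, group) is recorded in an audit table (branch,
bin, number of entries filled). Observed values outside branch 2 are
never altered. Imputation is a deterministic function of the
configuration seed.

Zeros created by branch 2 are retained through the roll-up sums. Wherever
a log2 transform is later required, non-positive values are floored at
**half the branch-3 quantile** (`zero_floor`), since log2(0) is
undefined and any floor below the detection regime preserves the "absent"
ranking without producing infinities.

**Trimmed-mean normalization.** Per sample, the positive intensities are
ranked, `floor(0.10 · n)` values are discarded from each tail, and the
mean of the remainder is equalized across samples by rescaling. Zeros are
excluded from the trimming statistics but scaled like everything else
(they stay zero).

## Protein inference and roll-up

Shared peptides are resolved by razor rules: each peptide is exclusively
assigned to the candidate protein with the larger number of identified
peptides, counted over the filter-surviving peptides (the peptides
actually in the final dataset). Proteins left with identical assigned
peptide sets merge into one group; the master accession is the member
with the highest % coverage (sum of unique assigned-peptide lengths over
protein length) when lengths are available, else the highest peptide
count. All ties break to the lexicographically smaller accession, making
inference a pure, row-order-independent function of its inputs. Protein
intensity is the plain sum of assigned peptide intensities, so per-sample
totals are conserved exactly through roll-up.

## Differential statistics

For a contrast A vs B the log2 fold-change is the difference of group
means of log2 intensities (not the log2 of a ratio of means), matching
the choice to test on log2-transformed data. Significance is Welch's
two-tailed heteroscedastic t-test with Satterthwaite degrees of freedom;
rows with zero variance in both groups resolve to p = 1 on equal means
(imputation floors can create exact ties) rather than erroring.
Benjamini–Hochberg adjusted p-values are always reported alongside raw
p-values, but screening uses the unadjusted p, favoring discovery.

Fold-changes are reported in the signed convention: ratio r becomes +r
when r ≥ 1 and −1/r otherwise, so |signed FC| ≥ 1 always and symmetric
thresholds read "> 1.5 or < −1.5". *Up* requires signed FC > 1.5 and
p < 0.05; *Down* requires signed FC < −1.5 and p < 0.05 (the only
self-consistent reading of the threshold pair).

## Two-stage interactor calling

Stage 1 (bait enrichment): within each genotype, EZR vs CYT; enriched
means signed FC > 1.5 at unadjusted p < 0.05. Stage 2 (genotype
contrast): GS-EZR vs WT-EZR. **Gained** = GS-enriched proteins with
contrast signed FC > 1.5 (and, by default, contrast p < 0.05); **lost** =
WT-enriched proteins with contrast signed FC < −1.5 (same p rule). The
gained list draws on the GS enrichment set and the lost list on the WT
set because gaining proximity in the mutant presupposes presence near
the bait in the mutant, and symmetrically for loss. Requiring p on the
contrast stage is configurable (`require_contrast_p`) but on by default,
consistent with the volcano-style labeling. Gained and lost are disjoint
by construction; shrinking the fold threshold grows both sets
monotonically.

## QC

%CV = 100 · sd/mean per protein on linear intensities with the sample
(n−1) standard deviation — the standard choice at n = 3. Proteins with
any non-positive value in the evaluated sample set are excluded (logged).
PCA operates on log2, per-protein-centered intensities; samples are
projected on the top two components with a deterministic sign convention
(the largest-magnitude loading of each component is made positive).

## The synthetic-data generator

The generator emulates the data-generating process the pipeline assumes:

- protein base abundances log-normal (log10 mean 6.5, sd 0.5); peptide
  ionizabilities log-normal; ~7.5 peptides per protein (range 3–12),
  mirroring the ~30k peptides / ~4k proteins scale of a real experiment
  at default `n_proteins = 2000`;
- 8% of proteins bait-proximal (enriched `bait_enrichment_fold`, default
  4, in every EZR column); 15% of those genotype-modulated, split evenly
  between gained (×`genotype_fold`, default 3, in GS-EZR) and lost
  (÷`genotype_fold` in GS-EZR);
- biological noise (CV 16.5%) and technical noise (CV 11%) both
  multiplicative log-normal at the **protein × sample** level, shared by
  a protein's peptides within an injection, so the %CV of a rolled-up
  protein reflects the generating CVs (combined ≈ 20% within groups,
  ≈ 11% across SPQC injections);
- SPQC columns are the noiseless pool mean of the 12 biological columns
  plus technical noise only, matching an equal-volume pool and making
  SPQC %CV a clean estimate of technical precision;
- shared (razor) peptides (15%) carry the *sum* of both host proteins'
  contributions — one sequence present in two proteins contributes ion
  current from both;
- dropout is logistic in log10 intensity (midpoint 10⁶, steepness 3 per
  decade), i.e. left-censoring-like MNAR, giving ~28% missingness
  overall — a realistic label-free DDA scale;
- misaligned features: with probability 1% a peptide whose entries all
  dropped out in some biological group receives one spurious high
  intensity (~3×10⁷) in that group — the cross-run aligner "finding" a
  feature that was never genuinely detected there. This is exactly the
  artifact class branch 2 of the imputation zeroes.

Everything is a deterministic function of the parameter set including
its seed. Fold parameters validate as ≥ 1 — fold = 1 is the explicit
null (no effect) condition.

**What the generator does not emulate:** peptide-level residual noise
(peptides of a protein move together within an injection up to their
fixed ionizability), retention-time/charge structure, homology-driven
correlation between shared-peptide partners (partners are chosen
uniformly), interference/co-isolation, batch drift across the run order,
and contaminant or spiked-standard proteins. Passing recovery tests on
this generator therefore demonstrates correctness of the analysis chain
under its own assumptions, not robustness to every real-data pathology.

## Measured operating characteristics

The numbers below are recomputed by `scripts/acceptance.py` and the test
suite at the stated sizes; none is hard-coded.

- **Recovery** (20 simulations, 2000 proteins, bait fold 4, genotype
  fold 3, ~20% CV, n = 3): mean sensitivity ≈ 0.97, mean false-discovery
  proportion ≈ 0.24 for the gained/lost caller. The dominant
  false-positive source is razor bleed-through: a shared peptide carrying
  a modulated protein's signal that razor rules assign to its partner.
  This is inherent to razor roll-up, not a defect of the implementation.
  The second source is misaligned-feature zeroing, which removes a
  peptide's contribution from one group only and can tip a borderline
  protein past the thresholds.
- **SPQC %CV** ≈ 13.7% at a generating technical CV of 11%: the excess
  over 11% comes from imputation of dropout in the SPQC columns. On fully
  observed data the estimate is unbiased (checked separately).
- **Null calibration.** On pure-noise lognormal protein matrices (CV
  20%, n = 3 vs 3, 2000 proteins) the Welch p < 0.05 fraction is ≈ 0.035
  — slightly conservative, as expected for Welch at n = 3. The two-stage
  caller, however, is **not** null-clean: because the bait-enrichment
  stage (GS-EZR vs GS-CYT) and the genotype contrast (GS-EZR vs WT-EZR)
  share the same three GS-EZR replicates, their false positives are
  strongly correlated — the joint per-protein null rate is ≈ 1.7×10⁻⁴,
  about 21× what independent stages would give, i.e. ≈ 0.7 expected calls
  per 2000-protein null dataset. Treating the two stages as independent
  filters overstates the specificity of this calling scheme; analysts
  using unadjusted p-values in both stages should expect a handful of
  correlated-noise calls per few thousand proteins.
- **Full-pipeline null with missingness** is further inflated (contrast
  p < 0.05 fraction ≈ 0.08): binned-normal imputation draws are
  quantized by bin and anchored on MNAR-biased observed means, a known
  anti-conservatism of this imputation family.

## Known limitations

- The imputation scheme imputes single values without propagating
  imputation uncertainty into the test statistics; variance can be
  understated when many entries in a group are imputed.
- Razor assignment transfers whole peptides; no signal splitting between
  shared-peptide partners is attempted (the standard razor convention).
- % coverage-based master selection needs protein lengths, which
  peptide-level inputs usually lack; the count/lexicographic fallback is
  then used.
- The two-stage caller's stages are statistically dependent (see above);
  its false-discovery behavior should be judged by the measured
  recovery surface, not by multiplying per-stage error rates.
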