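# Methods

`libscreen` models one experiment shape end to end: a partly randomized
coding library built on a stable template is screened for catalytic
activity by fluorescence-activated droplet sorting (FADS), the variable
region is sequenced before and after sorting, frameshifts and premature
stop codons are called against the template, their positional enrichment
is quantified, and hit enzymology is characterised by nonlinear kinetic
fits. This note records the models, the parameters that matter, and the
choices made where the design was genuinely open.

## Library model

A `LibraryDesign` is a template coding sequence plus a set of randomized
codon positions, each carrying a 3-letter IUPAC degenerate codon. The
schemes used throughout (NDT, VRC, RRC) encode 12, 6 and 4 amino acids
respectively and none of their codons is a stop, so every designed member
is full length by construction; premature stops can only enter through
indels (or sequencing errors). Theoretical diversity is the product of the
per-site codon (or amino-acid) set sizes; for NDT/VRC/RRC these coincide
because each codon encodes a distinct amino acid. Sampling draws each site
codon uniformly from its expansion.

Coordinates are 1-based: residues in full-protein numbering, nucleotides
on the coding strand. The sequenced window defaults to residues 19–83, so
a merged read starts at a codon boundary and truncation positions read in
full-protein numbering.

**The packaged template is synthetic.** The deposited gene of the
published library is not bundled; `libscreen.fixtures` ships a synthetic
102-codon template (plus 8 sites mixing the three schemes) constructed so
that single-nucleotide deletions inside the window frameshift into
premature stops with strong hotspots at residues 40 and 60 — the
positional signature the analysis is designed to detect. Roughly 32% of
in-window deletions stop at 40, 31% at 60, and 68% of indels produce some
in-window stop. Nothing in the pipeline is specific to this fixture; any
design file replaces it.

## Screening simulator

The simulator is the package's synthetic-data generator; its defaults are
the study conditions the analysis is built around.

- **Population.** `n_library` members (default 5,000) are sampled from the
  design; a fraction `indel_rate` receives one single-nucleotide indel
  (80% deletions / 20% insertions) uniformly inside the sequenced window,
  since only that region is observed. The default `indel_rate = 0.25` is a
  one-time calibration: with the packaged template an indel yields an
  in-window stop with probability ≈ 0.68, so 0.17/0.68 ≈ 0.25 reproduces
  the 17% input truncation load the published input library carries.
- **Activity.** Variants truncated at the designated hit residues (40, 60)
  get 50× background activity; everything else (including full-length
  members, mirroring an inactive parent) gets background 1. The published
  work gives no quantitative activity landscape, so these are simulator
  inputs, not claims.
- **Encapsulation.** Cells per droplet ~ Poisson(λ); occupants drawn
  multinomially from the population. Droplet fluorescence is the *sum* of
  occupant activities (co-encapsulation lets inactive hitchhikers ride
  through the gate — the reason a permissive λ = 0.43 first sort is
  followed by a stringent λ = 0.1 second sort), scaled by `incubation_scale`
  and multiplied by lognormal noise with CV 0.3 (multiplicative, strictly
  positive). The top `gate_fraction` of droplets is pooled.
- **Campaign defaults** mirror the published geometry at desk scale:
  sort 1 at λ = 0.43 gating the top 0.5%, sort 2 at λ = 0.1 gating the top
  0.2%, with 200,000 droplets per round instead of millions (a scale
  choice; the Poisson/gating arithmetic is scale-free and the closed-form
  module handles the published absolute numbers).
- **Reads.** Paired 150-nt reads cover the window from both ends (2×150
  over a ~195-nt amplicon gives a ~105-nt overlap); reads longer than the
  amplicon run into adapter. Substitution and deletion errors are drawn
  per base; qualities follow a linearly decaying profile with Gaussian
  jitter. Read IDs carry the variant id and ground-truth class so that
  recovery can be scored exactly. The default error model (0.3%
  substitutions) is short-read-realistic; the recovery analyses use a
  low-error model (10⁻⁴ substitutions, 10⁻⁵ deletions) because their
  purpose is to verify the pipeline's bookkeeping against ground truth,
  not to measure error robustness — at 0.3% substitutions roughly 2% of
  reads acquire a spurious in-frame stop, a real phenomenon that would
  confound a bias test of the caller itself.

What the generator does *not* emulate: PCR amplification bias, chimeras,
quality-dependent substitution spectra, droplet physics, lysis kinetics or
sorter false positives. Passing recovery tests therefore show that the
calling and enrichment arithmetic is unbiased under clean sampling, not
that the pipeline is robust to every artefact of real NGS data.

## Read processing

A deliberately small reimplementation of the standard amplicon-counting
path (published analyses of this kind delegate it to pipelines such as
DiMSum; this module targets fidelity in the zero/low-error regime, not
bit-compatibility):

- adapter trimming by exact match, keeping the longest adapter-free
  fragment, rejecting inserts < 10 nt;
- pair merging by best ungapped overlap (score = matches − mismatches,
  ties to the largest overlap), requiring ≥ 20 nt overlap and ≤ 10%
  mismatches — the merge thresholds are our documented stand-ins where
  the published parameter list is silent; consensus takes the
  higher-quality base, with quality max(Q) at agreements and
  |Q_f − Q_r| (floored at 2) at disagreements;
- a minimum-base-quality filter at Q20;
- exact-sequence dereplication into a round × variant count table.

Every input pair is accounted for exactly once (trimmed / merge-rejected /
quality-rejected / ambiguous-N / passed), and the zero-error round trip
reproduces the simulator's multiset of window sequences exactly.

## Truncation calling

Each unique observed sequence is globally aligned (unit costs) to the
template window in which degenerate sites are written as IUPAC letters, so
any codon of a site's scheme scores as a match. Alignment uses edlib; the
resulting operations are post-processed to left-align every indel run, so
reported indel positions are reproducible and leftmost. Reads below 70%
identity are unalignable; reads with more than 3 indel events are binned
as unalignable-complex and excluded from spectra (both counted).

Because the window starts on a codon boundary, the frame implied by the
global alignment at the read's first base is frame 0; the read is
translated codon-by-codon and the first stop encountered is reported in
full-protein residue numbering. The signed nucleotide offset
(insertions − deletions) tracked through the alignment classifies the
rest: non-multiple-of-3 offsets without a visible stop are frameshifts
whose stop lies outside the window; multiple-of-3 offsets (including 0)
are full length. A gained-Cys flag marks reads whose translation shows
cysteine at a position where neither the template residue nor the site's
scheme can encode it — the frameshift byproduct signal.

Spectra are count-weighted fractions of reads truncated at each residue
(read-weighting is the default; unique-variant weighting is available
because published counts of this kind do not always state which was used).
Enrichment rows report frequency in the input round, frequency in the
compared round, their ratio, and a confidence interval: Wilson score
intervals on each proportion, propagated to the ratio by dividing opposite
bounds. Positions absent from the input are flagged undefined rather than
infinite.

## Kinetics

Models: Michaelis–Menten v/E₀ = k_cat·S/(K_M + S); global competitive
inhibition v/E₀ = k_cat·S/(K_M(1 + I/K_i) + S) with k_cat and K_M shared
across inhibitor levels; single-ionization pH-rate
k₂(pH) = k_lim/(1 + 10^(pKa − pH)). All quantities SI. Initial rates are
the least-squares slope of progress-curve points below 10% conversion
(≥ 3 points required); note that this slope is analytically biased low by
−ln(1−c)/2 (≈ 2.6% at c = 0.05) relative to the true t→0 derivative — an
inherent property of the truncated-window fit, asserted exactly in the
tests. HPLC quantitation follows n = AUC·F/(d·ε).

Fits are nonlinear least squares (scipy) on v/E₀, unweighted by default
(matching the plain-nls convention of the published fits), with a
relative-error weighting flag. Start values: k_cat⁰ = max(v)/E₀,
K_M⁰ = median(S); K_i⁰ from apparent-K_M algebra at the highest inhibitor
level. Standard errors come from the fit curvature and confidence
intervals use Student's t with n − p degrees of freedom. The
calibration study in the tests (200 seeds, 5% multiplicative noise) uses
the relative-error weighting because it is the estimator matched to that
noise model; with it, 95% intervals cover the generating parameters at
93.5–95.5%, within binomial tolerance, whereas unweighted fits undercover
k_cat (≈ 87%) exactly as heteroscedasticity predicts. A Lineweaver–Burk
summary (per-level double-reciprocal slopes/intercepts, plus a K_i from
the slope-on-I regression) is emitted as a diagnostic because the
published K_i's provenance (global fit vs double-reciprocal) is not
stated; on competitive data both agree.

Derived constants: efficiency k_cat/K_M, rate enhancement k_cat/k_uncat,
catalytic proficiency (k_cat/K_M)/k_uncat, with a registry of uncatalysed
reference rates (phosphonate 1.7×10⁻¹¹ s⁻¹; dialkyl phosphate 7×10⁻¹⁶ s⁻¹;
cyclic phosphate 3×10⁻¹⁵ s⁻¹ — measured at different temperatures, carried
as metadata, not corrected). A printed derived cell is "consistent" when
recomputation from the printed k_cat/K_M (or, for proficiencies, from the
printed efficiency cell) agrees to the printed precision (within half a
unit of the last printed digit); three cells in the published table carry
rounding residue from unrounded internal values and are reported as
flagged, never forced to match.

## Screening arithmetic

Clones screened = n_droplets × λ (total cells), the convention that
reproduces the published bookkeeping; occupied droplets
n(1 − e^−λ) is also exposed. Oversampling = clones/library size; coverage
= 1 − e^−fold under Poisson sampling. The sequence-space helper returns
the exact exponent L·log₁₀(alphabet) and the integer exponent of the
scientific-notation form (its floor): 102 residues → 10¹³²; 59 residues →
10⁷⁶·⁸, whose published rendering as 10⁷⁸ is reported as a discrepancy,
not reconciled.

## Reproducibility and limitations

Every stochastic operation takes an explicit seed or Generator; the CLI
pipeline is byte-deterministic under a fixed seed and each subcommand
writes a JSON provenance record (version, parameters, input checksums).
Problem sizes in the analysis scripts and checks (200k droplets/round,
5,000-member library, 10⁵ read pairs/round, 200 fit replicates) are desk
scale by design; all statistics used on them are scale-aware (binomial
standard errors, Wilson intervals).

Known limitations: merging is ungapped (an indel sequencing error inside
the overlap rejects the pair rather than resolving it); the caller's
complex-indel bin hides reads with > 3 indel events from spectra; the
gained-Cys scan maps residues frame-naively, which is exactly the regime
where gained cysteines occur but can mislabel edge cases in heavily
substituted reads; and the simulator's enrichment strength depends
entirely on the assumed activity landscape — only recovery of whatever
was planted, not the published enrichment magnitudes, is testable without
the archived sequencing data.
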