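# libscreen

Simulation and analysis of a droplet-sorting enrichment experiment on a
degenerate-codon protein library, plus the enzymology of its hits.

The scientific setting: a stable designed protein scaffold is partly
randomized with degenerate codons (NDT/VRC/RRC) and screened for
phosphoesterase activity by fluorescence-activated droplet sorting.
Sequencing the library's variable window before and after sorting shows
that selection enriched single-nucleotide deletions — frameshifts whose
premature stop codons truncate the protein, with hotspots at specific
residues — and the best hit is a truncated, dimerizing mini-enzyme whose
cAMP hydrolysis is characterised by Michaelis–Menten, competitive
inhibition and pH-rate analysis. This package makes every computational
step of that story reproducible on synthetic or printed data:

- `libscreen.library` — degenerate-codon expansion, library diversity,
  variant sampling, indels, translation;
- `libscreen.screen_sim` — stochastic forward simulator of the droplet
  campaign (Poisson encapsulation, summed-occupant fluorescence, gating,
  multi-round enrichment) and FASTQ read emission with errors;
- `libscreen.reads` — adapter trimming, pair merging, quality filtering,
  dereplication into a round × variant count table;
- `libscreen.calling` — template alignment (degenerate-aware, leftmost
  indels), frameshift/premature-stop calling, positional truncation
  spectra, fold-enrichment with Wilson intervals;
- `libscreen.kinetics` — initial rates, HPLC quantitation
  (n = AUC·F/(d·ε)), Michaelis–Menten v/E₀ = k_cat·S/(K_M+S), global
  competitive inhibition (shared k_cat, K_M; K_i scaling the apparent
  K_M), pH-rate k₂ = k_lim/(1+10^(pKa−pH)), and the derived-constant
  calculus k_cat/K_M, k_cat/k_uncat, (k_cat/K_M)/k_uncat;
- `libscreen.screen_stats` — closed-form campaign arithmetic (clones
  screened = N·λ, Poisson occupancy, gate fractions, oversampling and
  coverage, sequence-space exponents).

The numbered scripts under `analysis/` walk the full story:
library design → campaign simulation → read processing → truncation
enrichment → kinetics → screening arithmetic, writing their tables under
`results/` (bulky intermediates go to `scratch/`).

## Worked example

Simulate a two-sort campaign on the packaged synthetic design, process the
reads and quantify truncation enrichment (also available as the `libscreen`
CLI: `simulate`, `process`, `call`, `enrich`, `kinetics`, `dropstats`):

```sh
python analysis/02_simulate_screen.py
python analysis/03_process_reads.py
python analysis/04_call_truncations.py
```

which prints, for the default seed:

```
round  cells  truncated_fraction  truncated_at_40  truncated_at_60
input   5000            0.160600         0.060000         0.062000
sort1   1589            0.766520         0.364380         0.390812
sort2    679            0.986745         0.487482         0.499264
...
most truncation-enriched positions (vs input):
position  freq_input  freq_round  fold_change   ci_low  ci_high  defined
      60    0.062769    0.499258     7.953894 7.429195 8.515653     True
      40    0.062718    0.485647     7.743372 7.229587 8.293672     True
```

Reading it: the simulated input library carries a 16% truncation load
(the calibrated study condition is 17%); because truncations at residues
40 and 60 carry 50× activity in the simulator, two rounds of gating drive
the truncated fraction to ~99%, and the read-level pipeline — which sees
only FASTQ — recovers the positional spectrum peaking at exactly those two
residues, with Wilson-interval fold-enrichments. The ground-truth table
from the simulator (`results/screen_truth_summary.csv`) and the
pipeline's estimates agree within binomial sampling error.

The kinetics side runs from printed constants alone:

```sh
python analysis/05_fit_kinetics.py
```

recomputes the derived-constant table — e.g. for cAMP, k_cat = 22×10⁻⁶ s⁻¹
and K_M = 10 µM give an efficiency of 2.2 M⁻¹s⁻¹, a rate enhancement of
7×10⁹ over the uncatalysed reaction (k_uncat = 3×10⁻¹⁵ s⁻¹) and a
catalytic proficiency of 7×10¹⁴ M⁻¹ — flags the three printed cells that
are not arithmetically reachable from their printed inputs, and
demonstrates exact recovery (k_cat 22.0, K_M 10.0 µM, K_i 70.0 µM,
pKa 7.80) when fitting noiseless synthetic data generated at those values.

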