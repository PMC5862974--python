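# Methods

This note records the models and procedures `cisphase` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## 1. Non-diploid phasing

### Model

A phase block is a set of heterozygous SNV positions connected by
molecule co-observation. Each barcoded molecule derives from exactly one
chromosome copy, observes the haplotype base at every candidate position
it covers, and may be corrupted by sequencing/base-calling error.
Ploidy is unknown and may vary along the genome, so the number of
haplotypes per block is an output, not an input.

### Procedure

1. **Index** (`build_snv_molecule_index`): observations at non-candidate
   positions are dropped; molecules with read score ≤ 20, and individual
   base calls with score ≤ 20, are excluded (strict inequalities).
   Indels are biallelic markers keyed by their left-aligned anchor
   position; the "base" is the full allele string, observed
   all-or-nothing.
2. **Exhaustive merge** (`merge_molecules`): two molecules are
   compatible when they share ≥ 1 position and conflict nowhere. Every
   maximal conflict-free, overlap-connected molecule group defines a
   preliminary haplotype (the union of its members' observations); a
   molecule may belong to several groups. Joint consistency equals
   pairwise consistency (a conflict always involves two molecules at one
   position), which the enumeration exploits: rather than enumerating
   molecule *subsets* (a Bron–Kerbosch-style search that degenerates on
   the dense agreement cliques formed by same-haplotype molecules), it
   enumerates the distinct partial-haplotype *maps* by memoised
   breadth-first growth — a map is extended by every compatible
   overlapping molecule that contributes a new position, and a map no
   molecule can extend is the union of a maximal group. Both views
   produce identical deduplicated allele maps; the map walk is ~60×
   faster at realistic coverage. A state cap (200 000 maps) guards
   against pathologically ambiguous input.
3. **Blocks** (`define_phase_blocks`): connected components of the
   position graph with edges between positions co-observed by ≥ 1
   molecule; singleton components are unreportable and dropped.
4. **Greedy completion** (`greedy_complete_haplotypes`): preliminary
   haplotypes are processed in ascending number of missing block
   positions (ties: leftmost start, then lexicographic allele string).
   Each is repeatedly extended by the most similar conflict-free
   preliminary haplotype covering ≥ 1 missing position, where similarity
   is #agreements − #disagreements over shared positions and 0 for
   disjoint pairs; similarity ties prefer the candidate with more filled
   positions, then canonical order. Zero-similarity (disjoint) fills are
   allowed; fills that conflict at any overlap position are not.
   Haplotypes that cannot be completed are reported with their gaps and
   excluded from final counts. Completed haplotypes are deduplicated.
5. **Parsimonious reporting** (`select_parsimonious_haplotypes`): the
   exhaustive merge deliberately over-generates. Wherever two true
   haplotypes agree over a run of sites, molecules ending inside the run
   can splice into chimeric, conflict-free groups whose completions are
   plausible but wrong. Reporting therefore keeps a **minimum** subset of
   completed haplotypes such that every molecule touching the block is
   consistent with at least one kept haplotype (error-bearing molecules
   consistent with none are set aside). Among minimum covers, the one
   whose members jointly explain the most molecules wins; remaining ties
   break canonically, so output is independent of input order. Exact
   search is used up to ~10 cover members / 500k combinations, then a
   greedy cover. `phase(..., parsimony=False)` disables the step.

On noiseless data with every adjacent site pair co-covered per haplotype,
this recovers the exact truth set in 149/150 blocks over 50 seeds ×
ploidy {2, 3, 4}; the single failure is a genuinely ambiguous tie between
two minimum covers at ploidy 4. At ploidy 2 recovery is exact by
construction (haplotypes differ at every het site, so chimeras cannot
form).

### Statistics

Block span = max − min position + 1. N50 is the span at which the
cumulative sorted-descending span total reaches half the grand total.
Fraction phased = phased het SNVs / eligible het SNVs.

## 2. Long-read validation

Reads with mapping quality ≤ 10 are ignored; in 1D mode base calls with
quality ≤ 15 are also dropped (2D mode applies no base filter — the two
modes mirror nanopore chemistry generations). A read covering ≤ 1
remaining block position is uninformative. A covered block is *supported*
iff supportive > 2 × unsupportive **and** supportive ≥ 1; the explicit
≥ 1 clause prevents a 0-vs-0 block from counting as vacuously supported.
Partial matches (a read agreeing with one haplotype on part of its span
and another on the rest) are unsupportive — such a read contradicts every
single haplotype, which is what the tally asks.

Read-length regimes matter: a 90%-identity read covering 12 sites
carries ≥ 1 error with probability ≈ 0.72 and can only count against a
block, so validation experiments use nanopore-realistic ~8 kb spans
(2–3 het sites per read) — also the generator default — while
switch-error experiments use block-spanning reads, since only reads
crossing the switch junction can detect it.

## 3. Allelic imbalance

Anchoring to WGS separates regulatory signal from genomic copy-number
skew. With per-million normalisation n(x) = 10⁶·x/library_total and
pseudocount ε = 0.5:

R = [(n(alt)+ε)/(n(ref)+ε)]_assay ÷ [(n(alt)+ε)/(n(ref)+ε)]_WGS,
fold = max(R, 1/R), favored allele = alt iff R > 1.

*Biased* requires fold > 5 and a two-sided exact binomial p < 0.01 for
the assay's alt count against the WGS alt fraction. Choices worth
flagging:

- The statistic behind "p < 0.01" was an open design point; the exact
  binomial against the WGS fraction is implemented in one private
  function (`_binomial_p`) so it can be swapped.
- ε = 0.5 keeps the ratio finite at zero counts; at depth ≥ 50 it
  perturbs fold by < 1%.
- A degenerate WGS fraction (0 or 1, possible after miscalled genotypes)
  is stabilised with the same pseudocount.
- Indel calls carry a warning flag rather than a manual re-check of
  mapping errors, which is not reproducible in code.
- The log₁₀(x+1) transform is exposed separately and used for plotting
  only.
- Site validity: ref+alt tags > 4, strict, in both the WGS anchor and
  the assay.

**Imprinting filter**: a transcript is imprinting-like when the number of
samples with ≥ 1 biased RNA call in it strictly exceeds n_samples/3; all
its calls are removed. The pattern is undefined for a single sample, so
the filter is a no-op at n_samples < 2. A configurable known-imprinted
gene list flags but never removes. chrX calls are flagged (possible X
inactivation) and excluded from candidate calling by default.

## 4. Regulatory map

TSS tags cluster greedily left-to-right into fixed 500-bp windows per
chromosome and strand; a tag beyond the current window opens a new one;
the representative TSS is the modal tag position (ties → smallest).
Cross-sample merging unions overlapping same-strand windows and
recomputes the representative from pooled tags. Peak→TSS distance is 0
inside the peak, else the gap from the nearer peak edge, unsigned
(upstream and downstream are not distinguished); peaks assign to the
closest representative TSS within 150 kb, ties to the smaller position.
An SNV inside several assigned peaks yields one regulatory SNV per peak,
by design. TADs must be non-overlapping per chromosome (overlap is a
hard error); concordance means one TAD contains both the SNV and the
TSS, and an SNV in no TAD returns "unassigned" rather than False. CpG
overlap tests the reference dinucleotides (pos−1,pos) and (pos,pos+1)
for "CG".

## 5. Candidate integration

A linkage joins a regulatory SNV and a transcript SNV lying in the same
phase block where the transcript is the peak's assigned target; the
per-haplotype allele pairing is read off the completed haplotypes only.
A candidate requires ≥ 1 biased ChIP call at the regulatory SNV and ≥ 1
biased RNA call at a linked transcript SNV (imprinting-filtered first).
Direction concordance — the chromatin-favored regulatory allele maps to
the expression-favored transcript allele on some haplotype — is
*reported*, and only required when `require_concordance` is set, since
the selection logic is defensible either way; both modes are exposed.
Substitution spectra collapse onto the pyrimidine reference base (G>A
counts as C>T); fractions are over unique regulatory SNVs.

## 6. Motif annotation

PWM counts (TRANSFAC-like flat files, parsed with Biopython) get a 0.01
pseudocount per cell before row normalisation. Per-position information
I(i) = Σ_b f(i,b)·ln(4f(i,b)) with 0·ln0 = 0; MSS = (Current − Min) /
(Max − Min) where Current = Σ I(i)·f(i, base_i) and Max/Min use the
per-position extrema of I(i)·f(i,·). The consensus scores exactly 1 and
the anti-consensus exactly 0; a fully degenerate matrix (Max = Min)
scores 1 by convention. Both strands of the ±10 bp context are scanned;
windows containing non-ACGT are skipped; hits need MSS strictly above
0.95. Gain/loss compares (matrix, strand) hit *sets* between reference
and variant contexts — deliberately not offsets, so an indel shifting
downstream coordinates does not fabricate a paired gain+loss. A
core-similarity pre-filter (most-conserved-pentamer short cut used by
some Match implementations) is not applied; only the MSS threshold is.
The bundled `data/toy_pwms.dat` contains two synthetic matrices (an ETS
GGAA-core and an AP-4-style E-box with a degenerate first position) used
by tests and examples; they are not TRANSFAC data.

## 7. Synthetic data: what it emulates and what it does not

Defaults describe one regulatory locus in an aneuploid cell line:
ploidy 3 (the average haplotype count per block in the system emulated),
60 kb region, 12 het sites (≥ 2 bp apart; 10% indels, observed
all-or-nothing), molecules of exponential span (mean 30 kb, capped at
5× mean, ~20 per haplotype), long reads of mean 8 kb at identity 0.9,
WGS depth 60 and assay depth 100, libraries of 10⁶ tags. Layout: an
H3K27ac peak at 10% of the region, a Pol II peak at 20%, target
transcript TX1 spanning 40–70% (TSS at 40%), transcript TX2 at 72–95%,
one TAD covering the region. A cis-effect divides the chosen haplotype's
tag contribution by `effect_fold` inside the peak (ChIP) and TX1 (RNA);
cohorts silence haplotype 0 of TX2 in 40% of samples to exercise the
imprinting filter. Errors substitute uniformly among the three non-truth
bases (indels flip to the other allele); a configurable fraction of
read/base scores falls below the 20 threshold, and `ensure_adjacent_
coverage` appends a pair-spanning molecule per haplotype wherever random
sampling left an adjacent site pair uncovered. Everything is
deterministic under `seed`.

Not emulated: GC/mappability bias, PCR duplicates, copy-number change
along the region, partially observed indel alleles, barcode collisions,
reference bias. Passing tests therefore demonstrate correctness of the
algorithms under the stated sampling model, not robustness to alignment
artifacts in real data.

## 8. Problem sizes used in tests and the acceptance script

Phasing recovery: 50 seeds × ploidy {2,3,4} (150 blocks, 12 sites each).
Oracle equivalence: 200 random instances of ≤ 12 molecules against a
full-subset enumeration, and 200 against union-find. Imbalance power:
200 sites at depth 100. End-to-end: 30 effect samples + 30 null samples,
one locus each. Long-read validation: 50 blocks at identity 0.9 (40
reads/haplotype) and 100 switch-errored blocks with block-spanning
reads. These sizes keep a full run in the tens of seconds on one CPU
while leaving binomial noise well inside the asserted margins.

## 9. Known limitations

- Minimum-cover reporting can tie when two haplotype subsets explain the
  molecules equally well (observed once in 150 ploidy-4 blocks); the
  canonical tie-break is deterministic but not guaranteed to pick truth.
- The merge's map enumeration is exponential in the worst case (hence
  the state cap); real linked-read coverage is nowhere near it.
- Heterozygosity falls back to a VAF window (0.2–0.8) when the VCF
  genotype is absent — a proxy, and logged as such.
- The imbalance test treats tags as independent draws; fragment-level
  correlation in real libraries would make p-values anti-conservative.
- Phasing quality is bounded by the candidate SNV list; miscalled
  genotypes surface as unexplained molecules, which the parsimony step
  sets aside rather than modelling.
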