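# Methods

## Specificity model

Each PDZ domain is modeled by a 7 × 20 position weight matrix (PWM)
over the standard amino-acid alphabet, indexed by offset from the
C-terminal residue (offset 0 = last residue, offset 6 =
seventh-from-last). The matrix is estimated from a set of interacting
peptides aligned at their C-terminus: per-offset residue counts are
normalized to frequencies, and offsets beyond the longest peptide carry
the uniform row (probability 1/20, zero information).

**Pseudocount.** Counts are smoothed by adding κ·w(IC_n)/20 to every
cell of column *n*, where IC_n = log₂20 − H_n is the column's
information content in bits (computed from the raw frequencies) and the
weight function is configurable: `proportional` (w = IC_n, default),
`inverse` (w = log₂20 − IC_n) or `flat` (w = 1). The default direction
adds more random mass to specific (high-information) columns, which
compensates under-sampling of rare-but-tolerated residues at otherwise
conserved positions; the inverse direction is the more common
convention in motif work and is retained as an option because the
evidence for either choice is weak. κ = 1 by default; κ = 0 yields raw
frequencies, in which unobserved residues are genuinely forbidden
(score −∞). All synthetic end-to-end runs in this package use κ = 0 so
that the rebuilt matrices preserve the generator's planted forbidden
residues exactly.

**Score.** A C-terminus *j* scores against domain *i* as the summed
log₁₀ probability of its residues at their offsets,
S_ij = Σ_n log₁₀ p_i[n][j(n)]. Base 10 is the package contract: the
working thresholds S_min = −8.3 and S_max = −6.4 bracket the
uniform-background score 7·log₁₀(1/20) ≈ −9.11 only on that scale (a
natural-log scale would put the background near −21, far below both
thresholds). Sequences shorter than seven residues score over their
available offsets only, keeping the sum total and C-terminally
anchored. Scores are ≤ 0, with equality only when every visited entry
equals 1.

## C-termini, isoforms, compartments

The motif window is the last seven residues of each protein isoform
(shorter proteins use their full length). Isoforms are first-class:
every splice variant contributes its own window, windows are not
deduplicated, and a variant counts as C-terminal if it falls in the
window of *any* isoform that carries it (same position, same reference
residue). Coordinates in all I/O are 1-based inclusive protein
positions; offsets from the C-terminus are used internally.

The compartment filter removes proteins annotated with
extracellular-matrix (GO:0031012) or extracellular-space (GO:0005615)
terms unless they also carry plasma-membrane-part (GO:0044459), and
removes mitochondrial-part (GO:0044429) proteins unconditionally.
Membership is by the literal term sets supplied — no GO-graph ancestor
propagation — and unannotated proteins are retained. The filter is
idempotent.

## Variant classification

For a missense variant inside a window, the mutant window substitutes
one residue; for a stop-gain at position *p*, the truncated protein is
residues 1..p−1 and its trailing window is scored instead. Domain *i*
supports **disrupts** iff S_i(wt) > S_max and S_i(mut) < S_min, both
strict; **creates** is the mirror. Scores inside the confidence band
never support a call: the band enforces that wild type and mutant are
far enough apart for the call to be meaningful. Verdicts roll up across
isoforms and domains with precedence disrupts > creates > neutral; both
domain lists are retained in the output, since a variant can in
principle disrupt binding of one domain while creating a site for
another. Antisymmetry (swap wild type and mutant, swap the verdict)
holds exactly at the per-domain level; at the verdict level it can be
broken only by that precedence rule.

Stop-gain bookkeeping counts *suppressed predicted interactions*:
unique (domain, protein) pairs where a stop-gain's wild-type score
exceeds S_max and its truncated score falls below S_min. Several stops
can hit one pair; the pair counts once.

## Statistics

**C-terminal enrichment.** Exact binomial test with one trial per
region position and the proteome-wide nsSNP rate (total nsSNPs /
total residues) as success probability, two-sided by default. A
binomial rather than a hypergeometric model is used because several
nsSNPs can affect the same residue. The expected count is
region_aa × rate. No normal approximation is used anywhere. The test
refuses inputs implying a per-position rate above 1, where this
position-trial model is undefined.

**Threshold sweep.** For each threshold *t* on a descending grid
(default −12 to −4, step 0.1), a C-terminus contains a motif when its
best score over all domains exceeds *t*; the sweep reports the number
of qualifying C-termini, the nsSNPs falling in them, their residue
total, the density ratio, and the one-sided (less) exact binomial
p-value against the global C-terminal nsSNP density — the
under-representation question. Thresholds above the global maximum
yield zero motifs and missing ratio/p-value.

**Gold-standard overlap.** One-sided (greater) Fisher exact tests,
computed as the hypergeometric upper tail of the 2×2 table. For a
curated interaction set, the universe is every (domain, protein) pair
over the domains present in both the score matrix and the gold
standard, a protein scoring by its best isoform; hits are pairs above
S_min. For stop-gains, the sample is the set of suppressed predicted
interactions and hits are those present in the curated network.

**Randomization null.** The observed curve is the fraction of
C-terminal missense variants classified disrupts as S_max varies with
S_min fixed. Each of n_reps (default 1000) randomizations replaces
every variant's alternate residue with a uniform draw from the 19
non-identical residues at the same position — "excluding synonymous"
is implemented at the amino-acid level, as no codon information exists
in protein-level variant tables — and reclassifies. The summary
reports per-threshold null mean and population standard deviation
(ddof = 0, matching error bars defined as the standard deviation over
randomizations). Internally the null exploits the decomposition that a
variant disrupts at threshold *t* iff m(alt) > *t*, where m(alt) is the
largest wild-type score among domains whose mutant score falls below
S_min; the 19 m-values per variant are enumerated once and the
randomization reduces to resampling them, making 1000 replicates
effectively free. The computation is bitwise reproducible for a fixed
seed.

## Synthetic data generator

The generator emulates the five external inputs (per-domain peptide
sets, a proteome with splice isoforms, GO compartment annotations, a
protein-level variant table, curated interaction pairs) with known
ground truth, so that the full pipeline can be exercised and verdict
recovery measured without any download.

Ground-truth PWMs are *designed*: every column has a peak residue
(p = 0.9), a secondary residue (p = 0.095) and a poison residue
(p = 10⁻⁹), the remaining 17 residues sharing the leftover 0.005.
The construction is deliberate: a single substitution must be able to
jump the whole confidence band plus margins, which requires a
per-position log₁₀ probability ratio of at least
(S_max − S_min) + 2·margin = 3.9 decades at the default margin 1.0;
peak → poison provides ≈ 8.95 decades. Real phage-display matrices are
softer, so planted variants here are *easier* than typical real ones —
recovery results on synthetic data certify the machinery (windowing,
scoring, thresholds, roll-up), not expected sensitivity on real
proteomes.

Planted sequence classes: **motif** proteins end in a domain's
consensus with 1–2 positions degraded to the secondary residue
(scores ≈ −1.3 to −2.3, above S_max + margin for the matched domain and
at most S_max for every other); **near-motif** proteins additionally
carry one poison residue (score < S_min − margin), so reverting it
creates a motif; **background** C-termini are uniform-random 7-mers,
redrawn until every domain scores them below S_min − margin. A uniform
background composition keeps the uniform-score baseline exact for
tests; an empirical composition can be supplied via custom PWMs.

Planted variants: disrupts = consensus residue → poison on a motif
protein; creates = poison → peak on a near-motif protein; neutral =
random substitutions on background C-termini (half) and outside any
window (half); stop-gains truncate motif-bearing and plain proteins in
a configurable proportion (default half and half), the stop placed 9–17
residues from the end so the new window is interior background
sequence. Every planted variant is re-scored against all ground-truth
PWMs at generation time and its intended verdict verified (with the
threshold margins for the matched domain) before it is accepted;
infeasible requests fail with an error naming the shortfall. All
generators are pure functions of (parameters, seed).

Defaults — 100 proteins of 50–300 residues, 5 domains, motif fraction
0.25, near-motif fraction 0.15, isoform rate 0.1, 2000 peptides per
domain, 20/10/50/10 disrupt/create/neutral/stop-gain variants, GO terms
on 10 % of background proteins — are chosen so that every pipeline
stage (filter, isoform logic, each verdict class, both Fisher tests)
has non-trivial work at a size that runs in seconds.

## Numerical choices and edge cases

* Ties: consensus argmax breaks ties alphabetically; classification
  inequalities are strict, so scores exactly at a threshold never
  support a call.
* −∞ scores (κ = 0 only) are legal throughout: a −∞ wild type can
  never disrupt (it cannot exceed S_max); −∞ − (−∞) score swings are
  treated as zero when selecting the best supporting domain for
  reporting.
* Degenerate inputs: empty variant tables and empty proteomes produce
  empty outputs, not errors; per-variant failures (reference mismatch,
  out-of-range positions) are logged and marked `skipped`, never fatal;
  empty peptide alignments, malformed GO identifiers and inconsistent
  contingency counts are hard errors.
* PWM rows always sum to 1 within 1e-9; information content is clipped
  to [0, log₂20] by construction.
* Byte-identical reruns: all randomness flows from explicit seeds
  through `numpy.random.default_rng`; the manifest contains no
  timestamps.

## Known limitations

* Binding is modeled positionally and independently: no residue
  covariation, no affinity/energy model, no structure, and no
  non-canonical or internal PDZ binding modes.
* The compartment filter is a coarse proxy for co-localization; real
  interaction feasibility also depends on expression and competition.
* The amino-acid-level randomization null ignores codon structure, so
  its "excluding synonymous" exclusion is necessarily approximate.
* Verdict recovery on synthetic data does not predict sensitivity on
  real proteomes (see the generator's design notes above).
* Stop-loss (read-through) variants, indels and multi-nucleotide
  variants are out of scope; variant tables arrive protein-mapped.
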