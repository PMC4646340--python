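# Methods

## Presence/absence model

The unit of analysis is the binary incidence matrix **X** ∈ {0,1}^(G×C):
genome *g* carries cluster *c* (≥ 1 member, paralogs collapsed) or it does
not. Binarization deliberately discards copy number — carriage, not
abundance, is the signal of interest, and collapsing paralogs makes the
matrix robust to how an upstream ortholog-clustering pipeline splits gene
families. Cleaning removes only discrimination-neutral content: clusters
present in every genome or absent from every genome can never separate two
groups, and genomes without a group label cannot contribute to the
contrast. Nothing else is touched; in particular no frequency-based
pre-filtering is applied, because a marker for a small target group is by
definition rare overall.

Paralog cells in wide cluster tables may join names with spaces, commas or
semicolons; all three are accepted as separators since the count never
survives binarization anyway. Genome-id matching between matrix and labels
is exact string comparison — fuzzy matching would silently paper over
upstream bookkeeping errors.

## Marker statistics

For each cluster the carriage fractions f_T = k_T/n_T and f_B = k_B/n_B are
exact rationals evaluated in double precision. The dual-threshold filter
(enriched: f_T ≥ α and f_B ≤ β; depleted: the same predicate on the
complemented fractions, one code path for both views) is the primary
selection device. The ranking score is s = f_T − f_B with |s| descending
and lexicographic tie-break on cluster id: the simplest monotone statistic
consistent with the threshold semantics, and easy for a user to substitute.
A one-sided hypergeometric tail probability is emitted alongside as a
reference column but never used for filtering: the genome collection is
treated as a census, not a sample, so no significance testing or
multiple-testing correction is performed, and any phylogenetic
non-independence of genomes is addressed by the explicit stratified
confound check rather than by a tree-aware model.

The stratified check counts marker carriage inside one named background
taxon stratum. If a marker's carriage inside the stratum that is
over-represented in the target group looks like its target-group carriage,
the marker tracks the clade; if it looks like background carriage, it
tracks the phenotype.

## Boolean signatures

A signature (P, A) classifies a genome as target iff it carries every
cluster in P and none in A. The empty signature is the vacuous conjunction
and classifies everything as target; this convention makes the monotonicity
law exact (adding any constraint can only lose true positives and gain true
negatives). Search enumerates all disjoint (P, A) with |P| ≤ p_max,
|A| ≤ a_max over a candidate pool, ranking by accuracy, then specificity,
then smaller signature, then lexicographic order — a deterministic total
order independent of pool ordering. Unweighted accuracy is the objective
because the use case reports raw correct counts; a `min_sensitivity` floor
lets the user demand perfect recall instead. Exhaustive enumeration is
guarded at a 40-cluster pool (≈ 10^4 signatures at p_max = 2, a_max = 1);
beyond that a greedy forward selection adds the single best constraint
until accuracy stops improving.

## Indel regions in alignments

Group-specific inserts are found on gap structure alone: column *j* is
discriminating when the non-gap fraction among target sequences is
≥ `min_target_occupancy` (default 0.9) and among background sequences is
≤ `max_background_occupancy` (default 0.1); maximal runs of at least
`min_len` (default 30) discriminating columns are reported. The defaults
tolerate a couple of ragged sequences per group while still resolving a
~60-residue insert; `min_len` = 30 is half that scale, so a detector miss
means the insert genuinely is not group-specific, not that the window was
too strict. Residue content is ignored during detection — substitutions do
not move gaps — which is what makes recovery of a planted insert exact at
any realistic substitution rate.

Each region is summarized on the target-group majority-consensus residue
per column (gaps excluded from the vote, ties broken alphabetically):
Kyte–Doolittle mean and *population* standard deviation (divide by n — the
region is the whole object of interest, not a sample), and
Henderson–Hasselbalch net charge at pH 7 by default. The pKa set is frozen
as constants (side chains D 3.65, E 4.25, C 8.30, Y 10.07, K 10.53,
R 12.48, H 6.00; termini 9.0/2.0 — a standard biochemistry textbook set);
published per-protein values computed with an unknown pKa set can therefore
differ in the second decimal. Termini are excluded by default because an
insert is an internal region of a larger chain. Coordinates are 0-based
half-open in all machine output, 1-based inclusive only in log lines.

## In-silico PCR

Primer–template matching follows the IUPAC subset rule (code matches base
iff base ∈ code's set); template `N` matches nothing, so unknown sequence
can never be claimed as a binding site. Mismatches are per-position
Hamming counts; indels inside a 16–23-mer binding site are out of scope.
The reverse primer is specified 5'→3' as synthesized and binds where the
plus strand contains its reverse complement. Both template orientations
are scanned with the primer roles swapped, making the hit set invariant
(up to coordinate mirroring and reverse complement) under
reverse-complementing any template. Product length is primer-inclusive, as
a gel reports it. 3'-end stability weighting is deliberately not modelled:
there is nothing to calibrate it against, and unweighted Hamming matching
is the transparent conservative choice.

Degeneracy of a primer is the product of per-position code cardinalities;
explicit enumeration is produced only below a 4096-variant guard and is
checked against the count by de-duplication.

## Simulators and what they do and do not show

All generators are pure functions of (parameters, seed) through one
`numpy.random.Generator`; no global RNG state.

* **Pangenome**: each cell is an independent Bernoulli draw; unplanted
  clusters share one carriage probability in both groups, planted clusters
  get per-group probabilities. Defaults (15 target / 200 background
  genomes, 50 clusters, 10% background carriage, one planted marker with
  p_target = 1.0, p_background = 0.1) represent a small but realistic
  contrast: a rare phenotype against a couple-hundred-genome background
  with a marker that is perfectly sensitive but imperfectly specific.
  Independence across cells means no linkage or phylogenetic correlation —
  passing recovery tests shows the statistics are computed correctly, not
  that the method is immune to clade confounding (that is what the
  stratified check is for).
* **Contingency fixture**: seed-free, realizes exact per-pattern genome
  counts. The shipped predator-typing fixture pins the published marginals
  (14/14 and 302, 434, 1221 of 2272) and the published 17 signature-
  matching background genomes; the unpublished remainder of the joint
  distribution is completed in a fixed documented pattern order
  (50 × (1,1,1), 135 × (1,0,1), 100 × (1,0,0), 267 × (0,1,1),
  100 × (0,1,0), 769 × (0,0,1), 834 × (0,0,0)) chosen so that every
  partial rule has strictly more false positives than the full three-gene
  rule, as in any real census where partial carriage patterns all occur.
  Quantities that depend only on the pinned counts (fractions, sensitivity,
  specificity, stratified counts) are completion-independent; the strict
  ranking of the full rule above its sub-rules is a property of this
  completion.
* **MSA**: one random ancestral sequence, independent substitutions at
  `sub_rate` per site, insert columns blanked to gaps in background
  sequences. Substitutions never create or move gaps, so detector recovery
  is exact by construction; real alignments add alignment error and ragged
  insert edges the simulator does not model.
* **Templates**: positives embed one random expansion of the forward
  primer and the reverse complement of one random expansion of the reverse
  primer at a fixed spacing inside random flanks (defaults 3 positives /
  5 negatives, 141 bp gap → 180 bp product, mirroring a small wet-lab
  panel); negatives are uniform random DNA, where a spurious degenerate
  16-mer site has probability ≪ 10⁻³ per panel.

## Numerical and interface choices

Fractions are reported at full double precision internally and formatted to
one decimal percent in reports. All ranking keys are explicit total orders
(documented tie-breaks) so every output is byte-reproducible. CLI outputs
are plain TSV/JSON written atomically (temp file + rename) and embed the
exact parameter set used. Problem sizes in the test-suite and the
acceptance script (200-replicate oracle sweeps at ≤ 30 × 15, 100-replicate
recovery runs at 15/200 genomes and 5/20 sequences) were chosen as the
smallest sizes at which the binomial/coverage claims are sharp; all
complete in seconds.

## Known limitations

* Two groups only; multi-class contrasts are out of scope.
* No phylogenetically-aware association testing; the stratified count is a
  diagnostic, not a correction.
* No sequence-level typing: signatures use carriage only.
* The in-silico PCR has no thermodynamic model (Tm, ΔG, 3' stability), so
  a predicted product is a necessary, not sufficient, condition for
  amplification.
* Upstream ortholog clustering and multiple alignment are consumed, never
  produced; the quality of both bounds the quality of everything here.
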