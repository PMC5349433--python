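# Methods

## Problem and model

Crystallographic models of protein–peptide complexes are validated here by
combining independent per-chain evidence streams into one ranking.  The
underlying reasoning is Bayesian in spirit: a peptide bound in a specific
pose is a strong claim, so it needs strong evidence (good real-space fit)
*and* reasonable prior plausibility (unstrained stereochemistry).  Chains
weak on both fronts are flagged for human inspection; the score is a
prioritization device, not a classifier.

### Chain detection

A chain qualifies as a peptide-ligand chain when it is a protein chain
(majority of residue names in the amino-acid vocabulary) with strictly
fewer than 50 residues and a length strictly below 1/5 of the longest
protein chain, in an entry with ≥ 2 protein chains and no nucleic-acid
chains.  Chain length is the canonical (SEQRES) length when a canonical
sequence exists, else the modelled residue count; both are retained on the
chain model for audit.  Each entry-level condition is independently
switchable through `PeptideLigandCriteria` so the rules can be tested in
isolation.

### Residue selection by local alignment

Scored residues are the intersection of "in the canonical sequence" and
"present in coordinates", obtained by a Smith–Waterman local alignment of
the SEQRES token sequence against the coordinate-derived residue-name
token sequence.  Tokens are opaque strings, so the aligner works over
arbitrary alphabets and modified residues (MSE, SEP, …) are distinct
symbols that align through context.  Scoring defaults are match +2,
mismatch −1, linear gap −2: identity-heavy by design, because the two
sequences are near-identical in practice and the job of the alignment is
to trim unmodelled termini and trailing heterogens, not to detect remote
homology.  Ties are resolved deterministically (smallest ending position
in the coordinate sequence, diagonal-preferring traceback).  A chain with
no aligned pair at all is flagged alignment-failed and excluded from
scoring.  Chains without SEQRES fall back to an amino-acid-vocabulary
filter (logged).

### Geometry and RSRZ columns

Bond-length and bond-angle outliers (> 5σ) are counted per *instance*;
Ramachandran and rotamer outliers per *residue* — this mirrors how the
validation reports express them.  Each count is divided by the number of
scored residues.  The RSRZ column counts residues with RSRZ strictly > 2
and divides by the number of residues that carry an RSRZ at all (the
report states RSRZ only for standard amino acids); residues without an
RSRZ contribute to neither side.  Absent XML attributes are parsed as
missing, never as zero.

### B-factor environment contrast

For the chain and for its environment — every non-hydrogen atom of *other*
chains within 6.0 Å (inclusive) of any non-hydrogen chain atom — the
occupancy-weighted mean B factor Σ occ·B / Σ occ is computed, and the
difference (chain − environment) taken.  Waters and heterogens belong to
the environment.  Zero-occupancy atoms are excluded from both means.  The
difference is converted to a midrank percentile over all scored chains:
100·(#below + ½·#equal)/N.  The neighbourhood is found with a k-d tree and
is exactly equal (set equality, tested) to the brute-force all-pairs
check.  Distances use the deposited asymmetric unit only; crystallographic
symmetry mates are not generated, a known limitation for peptides packed
against symmetry-related copies.

### RSCC sum probability

The per-residue RSCC values of all scored chains are pooled into an
empirical density f₁ on the fixed support [−1, 1] with bin width 0.01
(values attributed to bin centres; boundary values go to the upper
half-open bin).  Assuming per-residue RSCC values independent of chain
position, a chain of length n is n i.i.d. draws from f₁, and the density
of the sum is the n-fold discrete self-convolution, computed by iterated
direct convolution (mass conserved to ≲ 1e-15 per order; asserted < 1e-6
up to the supported cap n = 60, comfortably above the < 50-residue chain
bound).  Cohort scoring caches convolution orders incrementally, so a
whole cohort costs one pass up to the longest chain.  The reported value
is P(Sₙ ≤ sₙ) with the CDF interpolated linearly inside the containing bin
(each bin's mass spread uniformly across its width), which bounds the
step-vs-interpolated ambiguity by one bin mass.  Residues lacking an RSCC
are dropped and n reduced; the dropped count is recorded.  Single-residue
chains are scored by the f₁ CDF directly rather than dropped.  The
independence assumption ignores serial correlation of density fit along
the chain, so the probability is a screening statistic, not a calibrated
p-value.

### Combination and ranking

Missing column entries are imputed by the column median, which provably
leaves the median unchanged (asserted on every run).  Each column is
ranked with the most suspicious value at rank 1 — high fractions bad, high
B-difference percentile bad, low RSCC probability bad — with ties given
average ranks.  The combined score is Σ_c w_c · ln(rank_c/N) with default
weights 1; the log base only rescales scores, so the ordering is
base-invariant (tested), and natural log is fixed for comparability.
Because ranking a percentile column is identical to ranking its underlying
raw column, the intermediate percentiles are reported for audit while the
combination ranks the raw values.  Final ranks sort ascending by combined
score with exact ties broken by (entry id, chain id).

## Synthetic data: what it emulates, what it does not

The generator produces entries with one target chain (persistent random
walk, consecutive Cα ≈ 3.8 Å, four backbone atoms per residue) and 1–4
peptide chains started within ~4.5 Å of a random target residue, so the
6 Å neighbourhood is never empty.  Matched validation facts are generated
alongside: per-residue RSCC from a two-component truncated-normal mixture
(0.9·N(0.93, 0.04²) + 0.1·N(0.55, 0.15²), truncated to [−1, 1] — a sharp
well-fit mode plus a poor-fit tail), RSRZ from N(0, 1) baseline, and
Bernoulli-planted Ramachandran/rotamer/bond/RSRZ outliers.  Pathologies
are planted per chain with exact ground truth: additive B inflation,
downward RSCC shift, outlier rates and unmodelled N-terminal residues.
Default baseline B is 40 Å² with σ = 3 Å², occupancies 1.0.

Deliberately *not* emulated: real stereochemistry (torsion outliers are
planted in the validation facts, never derived from coordinates — the
pipeline itself never computes torsions), crystal packing and symmetry,
partial occupancies, correlated RSCC along the chain, and the archive's
actual RSCC distribution.  Passing the planted-recovery tests therefore
demonstrates that the pipeline's plumbing and statistics respond correctly
to the signals it is designed to measure; it does not certify performance
on the real archive, where signal strengths and correlations differ.

The "severe pathology" profile used in the end-to-end recovery check —
B inflation +30 Å², RSCC shift −0.3, Ramachandran/rotamer rate 0.4,
bond-outlier rate 0.2, RSRZ-outlier rate 0.3, on peptides of 8–30 residues
— represents a chain modelled with essentially no supporting density:
strongly heated atoms, clearly degraded fit, near-zeroth-percentile
stereochemistry.  It was chosen as a realistic worst-class offender, with
all signals planted simultaneously, because that is the joint signature
the combined score exists to catch.

## Numerical choices and degenerate inputs

- Histogram binning by index arithmetic with a 1e-9 tolerance so values on
  a bin boundary land deterministically in the upper bin.
- Alternate-location atoms: highest-occupancy alternative per atom name.
- Empty neighbourhood ⇒ missing B difference ⇒ median imputation; chains
  with zero reported RSCC values likewise impute the probability column.
- All-missing columns raise rather than silently score.
- Empty alignment (score 0) is distinct from alignment failure only in
  `local_align`; `map_modeled_residues` treats zero aligned pairs as
  failure and the pipeline excludes and counts such chains.
- Cohort sizes in the shipped tests (e.g. 100 entries / 200 chains for the
  recovery check, 500 alignment oracle pairs, 10⁶ Monte-Carlo draws) were
  chosen to make the statistical assertions decisive while keeping a full
  run in the order of a minute.

## Known limitations

- No symmetry-aware neighbourhoods; no assemblies.
- One validation-XML dialect version; unknown attributes ignored.
- Cohort-relative columns mean a chain's score changes with the cohort it
  is scored in; cross-run comparability requires a shared cohort or a
  frozen f₁ (the `EmpiricalPDF` text serialization exists for that).
- The RSCC-sum probability inherits the i.i.d. assumption; chains whose
  poor fit is concentrated at termini are penalized identically to chains
  uniformly poor, even though the former are often partially supported.
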