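# peptriage

Triage of **peptide-ligand chains** in protein crystal structures: find the
short peptides bound to larger protein targets, score each one by how
plausible its crystallographic evidence is, and rank the whole cohort so
the chains most worthy of manual examination come out on top.

A peptide modelled into weak or absent electron density leaves a
characteristic multi-signal fingerprint: the refinement program inflates
its atomic B factors to damp the unsupported scattering contribution, the
per-residue real-space correlation coefficients (RSCC) drop, and — because
peptide backbone torsions are essentially unrestrained — the chain
accumulates Ramachandran, rotamer and covalent-geometry outliers.
`peptriage` quantifies each signal separately and combines them by rank
aggregation.

## What is computed

A *peptide-ligand chain* is a protein chain with **fewer than 50 residues**
that is also **shorter than one fifth of the longest protein chain** of the
multimer, in entries with at least two protein chains and no DNA/RNA.
For every such chain, seven score columns are built:

1. **Geometry fractions** — counts of bond-length and bond-angle deviations
   beyond 5σ, Ramachandran-outlier residues and rotamer-outlier residues,
   each divided by the number of scored residues (from the wwPDB
   validation-report XML).
2. **RSRZ fraction** — residues with real-space R-value Z-score RSRZ > 2,
   divided by the residues for which an RSRZ is reported.
3. **B-factor environment contrast** — the occupancy-weighted mean B factor
   of the chain's non-hydrogen atoms minus that of all non-hydrogen atoms
   of *other* chains within 6 Å, expressed as a percentile of the cohort's
   difference distribution.
4. **RSCC sum probability** — pool the per-residue RSCC values of every
   scored chain into an empirical density f₁ on [−1, 1] (bin width 0.01).
   A chain of length *n* with observed values r₁…rₙ is treated as *n*
   i.i.d. draws from f₁; the density fₙ of the sum Sₙ = R₁ + … + Rₙ is the
   n-fold self-convolution of f₁, and the chain's score is the chance
   probability P(Sₙ ≤ sₙ) of its observed sum sₙ *or anything lower*.
   Residues come from a local alignment of the canonical SEQRES tokens
   against the coordinate-derived residue tokens, so unmodelled residues
   and buffer molecules sharing the chain ID are excluded.

Missing measurements are replaced by the column median (which leaves the
median unchanged).  Each column is then ranked with its most suspicious
value at rank 1, ranks are divided by the number of scored chains, and the
combined score is the (weighted) sum of natural logarithms of these
normalized ranks.  Sorting ascending gives the final ranking: **rank 1 is
the most suspect chain**.  A low combined score is a reason to look at the
electron density — never, by itself, a verdict on the model.

## Worked example

Generate a small synthetic cohort with one planted pathological peptide
(inflated B factors, degraded RSCC, frequent torsion outliers), score it,
and list the top chains:

```sh
$ peptriage simulate --spec spec.yaml --out cohort    # spec plants pathology in entry s000 chain B
wrote 6 entries to cohort
$ peptriage score --structures cohort --reports cohort --out scores.tsv
entries read: 6  candidate chains: 10  scored: 10  alignment-failed: 0  without validation: 0
wrote 10 chain scores to scores.tsv
$ peptriage rank scores.tsv --top 5
rank	entry	chain	n_res	combined_score	rscc_prob	bdiff_pct
1	s000	B	9	-13.9780	6.95e-05	95.0
2	s003	B	6	-6.8716	0.382	85.0
3	s004	B	25	-5.2622	0.1167	55.0
4	s000	C	12	-4.5690	0.4686	25.0
5	s005	B	22	-4.4512	0.9969	75.0
```

The planted chain (`s000` B) lands at rank 1: its RSCC sum has chance
probability ~7·10⁻⁵ under the cohort distribution, its B-factor difference
sits at the 95th cohort percentile, and its combined score (−13.98, the sum
of log normalized ranks across all seven columns) is far below every clean
chain.  The same pipeline is available as a library call
(`peptriage.score_cohort` / `peptriage.score_directories`) returning a
`ScoreTable` plus per-stage counters.

## Scope notes

Distances are computed in the deposited asymmetric unit only (no symmetry
mates).  Electron-density maps are never computed or read: all density
statistics come from validation-report XML.  Scores depend on the cohort
scored together, since the B-difference percentile and f₁ are
cohort-relative.  See `docs/methods.md` for the model, parameter and
design details.
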