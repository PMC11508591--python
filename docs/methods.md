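# Methods

This note records the models, algorithms, parameter choices and numerical
decisions behind `resistkit`, and what its synthetic-data generator does and
does not emulate.

## 1. Protein alignment

**Model.** Global (end-to-end) pairwise alignment of protein sequences with
affine gap penalties: a gap run of length *L* costs `open + extend·(L−1)`,
defaults `open = 11`, `extend = 1`, substitution scores from BLOSUM62.
Terminal gaps are charged like internal gaps; a truncated protein therefore
*pays* for its missing end, which is what lets truncation artifacts show up
as distinctive terminal gap runs downstream.

**Algorithm.** Three-state Gotoh dynamic programming (match, gap-in-A,
gap-in-B) with full traceback, JIT-compiled with numba. Ties in the traceback
break deterministically (diagonal, then gap in the second sequence, then gap
in the first) so identical inputs always give the identical alignment, not
just the same score. A linear-memory score-only variant backs the best-hit
ortholog search.

**The `X` residue** (unknown amino acid) scores 0 against everything,
including itself; columns containing `X` are never classified as mutations.

**Verification.** The implementation is checked against three independent
oracles: exhaustive enumeration of all gapped alignments for short pairs, a
separately written plain-Python DP, and Biopython's `PairwiseAligner`
configured with the same convention.

## 2. Triple alignment and ortholog assignment

The screen needs a three-row alignment (susceptible, resistant, reference).
Rather than full multiple alignment, the susceptible sequence is used as an
anchor: susceptible–resistant and susceptible–reference are aligned pairwise,
then merged column-wise on the anchor. Columns where the resistant row has an
insertion are emitted before reference insertions at the same anchor
position; the merge is exact for the two-indel case and deterministic always.
With no reference ortholog, the reference row is all gaps and the transcript
is flagged `no_reference` and excluded (a two-strain difference cannot be
polarized).

Reference orthologs come from one of three sources, in order of preference:
an explicit transcript→reference map, shared transcript IDs (the default,
matching annotation-transfer workflows where IDs carry over), or a best-hit
search by alignment score over the reference proteome (ties break to the
lexicographically smallest ID; scores below a floor, default 0, are
rejected).

## 3. Column classification and site collapsing

Each alignment column is assigned one label from a fixed partition:
`conserved`, `resistant_specific_sub`, `resistant_specific_gap`,
`susceptible_specific`, `reference_specific`, `triallelic`,
`terminal_artifact`, `unclassified`. Resistance-specific means the
susceptible and reference rows agree and the resistant row differs.
A maximal run of `resistant_specific_gap` columns collapses to **one** indel
site by default (`indel_counting: run`), since one mutational event produced
it; `per_column` counting is available as an option.

## 4. Truncation-artifact filtering

Annotation transfer between assemblies truncates gene models at contig ends.
The generator and the filter both model the signature: transferred attributes
`matches_ref_protein: False` (colon and `=` dialects both parsed), a missing
start or stop codon, and a gene within `window_bp` (default 1000 bp) of a
contig end. When that signature is present, terminal gap runs in the
resistant row are reclassified as `terminal_artifact` and their sites
dropped; a terminal run is the maximal terminal gap run separated from the
sequence end only by fully conserved columns, which makes the detection
robust to alignment aliasing where the cut boundary coincidentally matches.
Internal sites on the same transcript are kept. A transcript is *included*
(reported as resistance-specific) when at least one site survives filtering
and a reference ortholog exists.

## 5. Synthetic data generator

The generator is the study-condition oracle for the screen: its defaults are
the experiment, not tuning knobs.

- **Ancestral proteome:** uniform random sequences over the 20 amino acids,
  methionine start, default lengths 40–60 residues. Lengths are a package
  choice to keep desk-scale runs fast; real proteomes are longer but the
  classification logic is length-independent.
- **Planting:** mutations of five classes (resistant-specific substitution
  and indel, susceptible-specific, reference-specific, triallelic) placed
  uniformly with a 5-residue margin from either end and a 1-residue buffer
  between events, so planted truth maps one-to-one onto alignment columns.
  Indels are 1–5 residues. Placement failure after 10,000 attempts raises a
  capacity error rather than silently under-planting.
- **Truncation artifacts:** a fraction of transcripts lose 1–5 residues from
  one end; the truth records the side and cut, the transferred attributes the
  missing codon, and the contig context places the gene within 500 bp of a
  contig end on a 1 Mb contig — inside the filter's 1000 bp window by
  construction, not by tuning.
- **Genome-shaped fixture:** 4,500 transcripts (562 background, 3,938
  mismatched, 729 with resistance-specific substitutions, 496 with exactly
  one site, one with 54). Substitution-only planting makes the expected
  screen counts alignment-exact.
- **Bioassay:** binomial deaths with
  `p(d) = c + (1−c)·Φ(slope·(log₁₀ d − log₁₀ LD₅₀))`, optional natural
  response `c`, strictly increasing doses.

**Not emulated:** sequencing error, assembly errors other than end
truncation, alternative splicing, paralogy/gene family confusion, codon-level
evolution (the generator works directly at the protein level), and
between-replicate overdispersion in bioassays.

## 6. Probit dose–response statistics

**Fit.** Maximum-likelihood probit regression of mortality on log₁₀ dose via
a binomial GLM with probit link (statsmodels), group sizes as weights.
Natural response is removed beforehand with Abbott's correction
`p′ = (p − c)/(1 − c)`, floored at 0; a control group with 100% mortality is
an error. Complete separation (all-dead/all-alive) raises `SeparationError`
rather than returning a divergent fit. Goodness of fit is Pearson χ² with
`n_groups − 2` degrees of freedom (two fitted parameters), so a six-dose
assay reports df = 4.

**LD₅₀ interval (Fieller).** `log₁₀ LD₅₀ = −α/β` is a ratio of jointly
normal estimates; its interval is the set of *m* with
`(α + βm)² ≤ z²·Var(α + βm)` using the full fitted covariance, solved in
closed form from the quadratic. The interval is *valid* only when the slope
is significant at the interval's level (`g = z²·Var(β)/β² < 1`); otherwise
bounds are reported as infinite and flagged. Bounds are exponentiated to the
dose scale.

**Resistance ratio.** `RR = LD₅₀(R)/LD₅₀(S)` with Fieller again, this time on
the dose scale with delta-method variances of the two LD₅₀s and zero
cross-covariance (independent experiments). Closed-form quadratic
`θ²(L_S² − z²v_S) − 2θL_R L_S + (L_R² − z²v_R) = 0`.

**Verification.** The probit fit is checked against a coarse-to-fine grid
search of the likelihood and against analytically invertible data; Fieller
bounds against dense grid scans of the defining inequality; the 95% ratio
interval against Monte-Carlo coverage (nominal 95%, accepted 93–97% over
2,000 replicates); and scale-equivariance (doses × k ⇒ LD₅₀ × k exactly)
holds to machine precision.

## 7. Numerical and design choices

- numba-compiled DP kernels (`cache=True`) keep the genome-shaped screen
  (4,500 transcripts) under a few seconds on one CPU.
- All randomness flows through `numpy.random.default_rng(seed)`; every CLI
  run echoes its resolved configuration, version and seed, and the same seed
  reproduces byte-identical outputs. Omitting the seed for simulation is a
  hard error.
- Configuration is YAML with unknown-key rejection per section, so typos fail
  loudly instead of silently using defaults.
- The pipeline is a function pipeline, not a fit/transform estimator: the
  screen has no learned state and the probit fit's "predict" has no role in
  the workflow, so the estimator interface would be shape without substance.

## 8. Open design decisions and limitations

- The anchor-merge triple alignment is exact when indels in the resistant and
  reference rows do not overlap on the anchor; overlapping indels can produce
  adjacent rather than stacked gap columns. A true three-sequence DP would
  remove this, at cubic cost.
- Best-hit ortholog assignment is one-directional (query → reference);
  reciprocal-best-hit would be stricter for paralog-rich families.
- Fieller validity is reported, not repaired: for very shallow slopes the
  interval is correctly flagged unbounded rather than replaced by a bootstrap.
- The per-site report uses alignment-column coordinates; mapping back to
  genomic coordinates is out of scope.
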