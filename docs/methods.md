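# Methods

## Model and procedure

The screen treats each protein's spectral counts as draws from a
multinomial over proteins within each group's pooled runs. Differential
expression between two groups is a test of independence on the 2×2 table
(protein vs all other proteins) × (group A vs group B), using the
likelihood-ratio statistic G = 2 Σ O′ ln(O′/E) with one degree of freedom.
The Yates continuity correction shifts every observed cell 0.5 toward its
expectation, computed from the *uncorrected* margins, and clamps at the
expectation when the observed deviation is below 0.5; this is the textbook
2×2 form. The correction makes G usable down to zero counts but renders the
test conservative there (see "Operating characteristics"). A protein counted
in neither group of a pair is assigned G = 0, p = 1 by convention.

Fold changes use the pseudocount-regularised log2 spectral-count ratio

    R_SC = log2((n_A + f)/(n_B + f)) + log2((t_B − n_B + f)/(t_A − n_A + f)),

whose second term offsets unequal pooled depth. Candidates require both
p < α and |R_SC| above a threshold. No multiple-testing correction is
applied by default: the screen is a raw p < 0.05 filter whose survivors are
verified by exact tests; a Benjamini–Hochberg column can be added post hoc
by the caller from the returned p-values.

Exact verification uses (i) the one-sided Fisher hypergeometric tail in the
direction of enrichment on the same 2×2 table — one-sided because a
screened candidate's direction is fixed by the screen, and because this
convention reproduces all four published exact p-values, which a two-sided
rule does not; and (ii) an exact permutational Mann-Whitney test applied to
per-run (or per-patient pooled) counts. A rank test "on the contingency
table" itself is undefined; the per-sample variant is this package's
documented interpretation. The full permutation distribution of the
mid-rank sum is enumerated when both sides have ≤ 10 observations.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `f` | 1.25 | R_SC pseudocount; reproduces every fixture R_SC to < 0.006 |
| `alpha` | 0.05 | significance threshold on the χ²(1) tail of G |
| `rsc_threshold` | 1.0 | candidate filter: more than two-fold change |
| `g_crit` | 3.84 | χ²(1) critical value at p = 0.05, the 3D plane rule |

All are dimensionless. `g_crit` and `alpha` express the same cut on two
scales; they are exposed separately because the 3D rule is applied to G
values, not p-values.

## Calibration of effective totals

The packaged 95-protein table prints pooled per-protein counts, G, p and
R_SC, but not the group totals t_g entering every table. The totals are
recovered by least squares: each printed R_SC row is one equation in
(t_LCNEC, t_SCLC) through the exact R_SC identity, giving an overdetermined
system (95 equations, 2 unknowns) solved in log-coordinates by
Levenberg–Marquardt. The objective is nearly scale-invariant — G and R_SC
depend essentially on the totals *ratio* once totals dwarf per-protein
counts — so a weak penalty pins t_LCNEC near 7664 (4 patients × 1916 mean
counts per patient, the study's printed scale). The fit yields a ratio
t_SCLC/t_LCNEC ≈ 1.428 (log2 offset ≈ 0.514) and reproduces all 95 printed
R_SC values within 0.006 and all printed G values within 0.4%. Taking the
per-patient means at face value (5 × 1879 / 4 × 1916 = 1.23) reproduces
neither column; the fitted ratio was preferred as the faithful choice.

The LCC total has no printed per-protein counts at all; it is anchored by
inverting a single published coordinate — the AK1C3 LCNEC-vs-LCC G value of
40.8 with LCC count 0 (its LCC-vs-SCLC coordinate is exactly 0, which under
the zero-zero convention implies zero counts in both groups) — via Brent
root-finding on the monotone map t_LCC ↦ G. The deduced LCC count of 1 for
AL1A1 (which reproduces its published x = 8.75) is stored as a synthetic
fixture annotation, clearly marked as derived rather than printed.

Numerical notes: the anchor scale is not perfectly immaterial — doubling it
moves zero-count-row G values by up to ~2%, because the Yates shift and the
focal-row log terms are not scale-free — but the fitted ratio and the
quality of the reproduction are unaffected at the tolerances above.

## Synthetic data

The generator mirrors the study design: three groups (4, 5, 5 patients),
triplicate runs per patient, ~1,500 proteins by default. Per-protein
relative abundance is log-normal (σ = 1.5, a few-orders-of-magnitude
dynamic range), normalised so the expected spectra per run equal `depth`
(default 633, making pooled per-patient totals ≈ 1,900, the study's scale).
Counts are Poisson per run, or negative-binomial with variance m + φm² when
between-patient biological variability is wanted. Group-specific fold
changes multiply the rate of designated proteins; the generator returns the
truth (rates, flags, folds) alongside the matrix, and identical seeds give
bit-identical output.

What the generator does not emulate: peptide-level sampling and shared
peptides, detection censoring, run order and retention drift, and
search-engine identification error. Passing recovery tests therefore
validate the statistical machinery on its own assumptions, not end-to-end
behaviour on real spectra.

## Operating characteristics

Under seeded all-null Poisson simulations at study scale (2,000 long-tailed
proteins, pooled per-patient totals ≈ 1,900), the flagged fraction at
α = 0.05 is ≈ 0.01: most per-protein pooled counts are small, and the
continuity-corrected G-test is strongly conservative there. This is the
intended trade-off — the screen under-calls rather than over-calls at the
depths it was designed for — and the acceptance suite checks the one-sided
bound (flagged fraction at or below the binomial band's upper edge), since
a two-sided band around the nominal level is incompatible with a
deliberately conservative test. With per-protein counts in the hundreds the
test approaches its nominal level (checked separately).

Pooling triplicates before testing produces fewer null discoveries than
testing each replicate separately and flagging any hit (144 vs 198 in
10 × 800-protein null simulations) while increasing per-test power; note a
*single*-replicate test is even more conservative than the pooled one (73
null flags in the same setting) simply because its counts are smaller —
"pooling reduces false positives" is true against per-replicate testing,
not against throwing data away. Planted 8-fold changes on proteins expected
at ≥ 5 spectra per patient are recovered with power above 0.9. With
negative-binomial (overdispersed) nulls the pooled G-test becomes
anticonservative — between-patient variance violates the multinomial
assumption; this is a documented limitation, not corrected for.

## Design choices and limitations

* Pooling is plain summation across all runs and patients of a group; no
  per-run normalisation (NSAF-style measures are out of scope).
* The 3D "near or on the plane" rule is operationalised as: both
  focal-group coordinates > g_crit with enrichment favouring that group,
  and the third coordinate < g_crit. This reproduces all published positive
  and negative example points. G is unsigned, so directions are read from
  pooled counts; without the direction check, a protein elevated in the
  *other* two groups could satisfy a plane rule.
* Fisher's exact test defaults to one-sided (see above); two-sided is
  available.
* The identification-overlap partition is computed by set algebra; the
  study's own printed per-group totals for two of the three groups are
  internally inconsistent with its printed region sizes (they appear
  swapped), so totals here are always derived from regions.
* Williams-corrected G, >2-group tables, and peptide-level testing are out
  of scope. Gene-ontology summaries only tally caller-supplied annotation
  maps; no ontology retrieval.
* A handful of large-count fixture rows recompute ~0.5–1% below the printed
  G under any single totals pair, suggesting the original analysis used
  slightly different (unprinted) totals per comparison; the residual is
  reported by `reproduce_table2`, not hidden.

## Problem sizes in the test suite

Unit and property tests run on matrices up to 2,000 proteins; the
distributional acceptance checks use 200 seeded null simulations of 2,000
proteins and an exhaustive Fisher enumeration over all 2×2 tables with
total ≤ 40. These sizes were chosen to estimate the relevant fractions to
well within the asserted bands.
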