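# speccount

Label-free spectral-counting differential expression for small-cohort
shotgun proteomics: replicate pooling, pseudocount-regularised log2 fold
changes (R_SC), Yates-corrected pairwise G-tests on 2×2 contingency tables,
exact-test verification, and a 3D G-statistic screen that nominates proteins
specific to one of three disease groups.

The package was built around a concrete use case — finding protein markers
that distinguish large cell neuroendocrine carcinoma of the lung (LCNEC)
from small cell lung carcinoma (SCLC) and large cell carcinoma (LCC) in
laser-microdissected FFPE tissue — and ships that study's printed tables as
fixtures so every statistic can be recomputed offline. The machinery itself
is generic: any protein × run spectral-count matrix with group/patient/
replicate annotations works.

## The statistics

**Spectral counts.** The number of confidently assigned peptide MS/MS
spectra per protein per LC-MS/MS run, a proxy for abundance. Triplicate
runs of every patient are pooled by summation into per-group counts
*n*<sub>g</sub> and group totals *t*<sub>g</sub> = Σ<sub>proteins</sub> *n*.

**Fold change.** For groups A and B with pseudocount *f* = 1.25:

```
R_SC = log2((n_A + f) / (n_B + f)) + log2((t_B − n_B + f) / (t_A − n_A + f))
```

finite for zero counts, exactly antisymmetric in (A, B); |R_SC| > 1 means
more than a two-fold change.

**G-test.** Each protein's 2×2 table has rows "this protein" / "all other
proteins" and columns for the two groups: (a, b, c, d) =
(n_A, t_A − n_A, n_B, t_B − n_B). The likelihood-ratio statistic
G = 2 Σ O′ ln(O′/E) uses expected counts E from the margins and observed
counts shifted 0.5 toward E (Yates continuity correction, clamped at E),
and is referred to χ²(1 df). A protein counted in neither group is assigned
G = 0. Because the χ² approximation deserves caution at small counts,
one-sided Fisher exact probabilities and an exact permutational
Mann-Whitney test on per-run counts are available as verification.

**3D specificity.** With three groups, each protein maps to the triple of
pairwise G values (x: A vs C, y: C vs B, z: A vs B). A protein specific to
one group lies on or near the coordinate plane of the two comparisons
involving it, beyond the χ²<sub>0.05</sub> critical value 3.84 on both, with
enrichment favouring that group in both.

## Worked example

The packaged differential table lists 95 proteins significant between LCNEC
and SCLC, with pooled counts but not the group totals the tests used. The
totals are recovered by least squares from the printed R_SC column:

```python
>>> import speccount as sc
>>> totals = sc.fit_effective_totals()
>>> print(f"t_LCNEC = {totals.t_lcnec:.0f}, t_SCLC = {totals.t_sclc:.0f}, "
...       f"ratio = {totals.ratio:.3f}")
t_LCNEC = 7662, t_SCLC = 10942, ratio = 1.428
```

With those totals, the top-ranked protein (aldo-keto reductase 1C3, pooled
counts 25 vs 0):

```python
>>> t = sc.Contingency2x2(25, round(totals.t_lcnec) - 25, 0, round(totals.t_sclc))
>>> r = sc.g_test(t)
>>> print(f"G = {r.g:.2f}, p = {r.p_chi2:.2e}")
G = 39.14, p = 3.94e-10
>>> print(f"R_SC = {sc.rsc_value(25, 0, totals.t_lcnec, totals.t_sclc):.2f}")
R_SC = 4.91
>>> print(f"one-sided Fisher p = {sc.fisher_exact(t):.2e}")
one-sided Fisher p = 2.28e-10
```

G = 39.14 and R_SC = 4.91 match the published 39.1 and 4.91; the exact
Fisher probability 2.28×10⁻¹⁰ confirms the asymptotic call. The whole-table
reproduction is one command:

```
$ speccount reproduce --out reproduction
Rows reproducing printed G within 1%: 95/95
Rows reproducing printed R_SC within 0.03: 95/95
Rows with recomputed p < 0.05: 95/95
```

The CLI also exposes `simulate` (synthetic count matrices with known ground
truth), `pool`, `difftest`, `classify` (the 3D screen) and `run` (a full
pipeline from a YAML config).

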