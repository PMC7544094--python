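# Methods

This note records the statistical conventions the package implements, why
each was chosen, and where they are approximations.

## The excess-burden statistic

For one disease with odds ratio `OR` per SD of genetically predicted telomere
length (gTL) and an age-standardized rate `V` (incidence or DALYs per
100,000 persons):

```
excess = (OR − 1) × V
```

interpreted as cases or DALYs per 100,000 persons per SD of gTL in excess of
baseline. The implicit approximation is `OR ≈ RR`: for a rare disease the
odds ratio approximates the risk ratio, and `(RR − 1) × V` is the excess rate
a one-SD shift would induce if the whole population shifted. For common
outcomes (coronary heart disease here) the OR overstates the RR, so the
statistic is an upper-leaning approximation; we keep it because it is the
published studies' own convention and the package's purpose is a faithful,
testable implementation of that convention. The statistic is linear in `V`,
which is what makes proportional allocation commute with it (tested as a
property).

## Confidence bounds

Per-disease bounds propagate only the OR's confidence interval against the
point rate:

```
(lower, upper) = ((OR_L − 1) × V, (OR_U − 1) × V)
```

Rate uncertainty is ignored by default because MR sampling error dominates
registry-rate error by an order of magnitude in these tables. One source
study prints ORs without CIs; for it the convention inverts — the OR point
estimate is applied to the rate's CI bounds (`ci_source="auto"` selects per
row, `"or"`/`"burden"` force one). When the effect is protective
(`OR < 1`), the rate-CI fallback swaps bounds so the interval stays ordered.

Group totals sum values and like bounds:

```
total_L = Σ lower_i,   total_U = Σ upper_i
```

This is a perfect-dependence convention — it assumes all OR errors move
together — and is conservative in width. It is demonstrably the published
convention: the printed per-row lower bounds of the long-gTL incidence
section sum exactly to the printed total lower bound (45.49), which the test
suite asserts from the printed fixture. An independence-style root-sum-square
alternative (`bounds="rss"`) is provided and is always narrower; it is an
option, not the default, because totals must reproduce the source.

Sums use `math.fsum` to make totals independent of summation order at full
precision. Rounding to two decimals is display-only (half-even via
`decimal.Decimal.quantize`); internal values are never rounded.

## Definition mapping

Registry cause categories are broader than MR case definitions. We allocate
a broad category's burden onto a narrow definition proportionally by case
counts: `fraction = narrow_count / broad_count`, and the narrow burden is
`fraction × V` with bounds scaled the same way. Linearity of the excess
statistic guarantees allocation before or after attribution gives the same
answer, and a partition of counts conserves the broad total — both are
tested properties, not assumptions.

Sensitivity analyses subtract a sub-condition's share from a total:
`adjusted = total − fraction × component`, applied to value and both bounds.
The bundled case removes the idiopathic-pulmonary-fibrosis share (26.8% of
interstitial-lung-disease cases, Danish national registry) from the
short-gTL totals.

## Direction handling and OR inversion

Every OR carries an explicit direction, per SD *longer* or per SD *shorter*
gTL. Harmonizing to a target direction uses the exact transform

```
OR′ = 1/OR,   CI′ = (1/OR_U, 1/OR_L)
```

which is an involution (round-trip identity to 1e-12, property-tested) and
preserves CI coverage. Multiple ORs for one disease collapse by weighted
arithmetic mean on the OR scale by default (matching source behavior);
a geometric (log-scale) option exists for users who prefer symmetry under
inversion.

## LD clustering and the independent-variant count

SNP pairs with R² ≥ 0.5 are linked; clusters of linked SNPs are counted as
one independent variant, with the lowest-position member as sentinel.
The grouping rule is genuinely ambiguous and both readings are implemented:

- **connected components** (default): transitive closure of the R² ≥ 0.5
  relation — order-invariant and monotone in the cutoff (fewer clusters as
  the cutoff drops; property-tested against a brute-force union-find oracle).
- **greedy sentinel**: each unclaimed SNP in table order claims its unclaimed
  R² ≥ 0.5 partners — order-dependent (a chain A–B–C splits differently if B
  is visited first) and *not* monotone in the cutoff, since a lower cutoff
  can let an early sentinel strand a later one's neighbours.

On the bundled 106-SNP panel the two rules give 68 and 71 independent
variants respectively. The panel's source reports a count between these; its
exact tie-handling is not specified, so the package reports both counts and
pins neither to the published figure. Missing R² cells default to "no edge"
(conservative: more clusters); an error policy is available.

## Synthetic data

The generator emits the same artifact tables the pipeline consumes, with
exact ground truth: log-normal ORs (`exp|N(μ, σ)|`, guaranteeing
direction-consistent OR ≥ 1), gamma incidence rates, a log-normal DALY
severity multiplier, symmetric relative CI half-widths, multinomial case
counts (so realized fractions are exact ratios), and block-diagonal LD with
validated unambiguous within/between R² ranges (within ≥ cutoff, between <
cutoff), so planted clusters are recoverable by construction — recovery is
asserted at 100% over 100 seeds. One integer seed feeds one named
pseudo-random stream per artifact table (`SeedSequence` spawn keys), so
adding a table never perturbs the others. Limits: independence across
diseases, symmetric CIs, and no confounding structure — it validates
pipeline arithmetic and bookkeeping, not MR assumptions.

## Known irreproducibility

The second bundled study's printed excess-DALY total (840.28) is not
reproducible to ±0.5 from its printed two-decimal ORs, which yield 838.48.
Back-solving per-row printed excesses implies the source computed rows from
unrounded ORs (e.g. its lymphoma row implies OR ≈ 1.655 where 1.66 is
printed) and summed before rounding. The incidence-side total reproduces
(231.80 vs 231.42 at ±0.5). The corresponding test asserts the published
value at its stated tolerance and is left failing rather than loosened; the
reproduction CLI flags the same cells with this explanation in its footer.
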