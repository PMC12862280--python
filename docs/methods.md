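# Methods

## Problem and approach

The package locates census tracts where elevated flood risk spatially
coincides with elevated structural disadvantage or chronic-disease burden.
The unit of analysis is the tract; the inferential tool is the local Moran
statistic in its bivariate form, which asks whether a tract's flood risk and
its *neighbors'* inequality are jointly extreme relative to a conditional
permutation null. Everything else — index construction, weights, profiling —
exists to feed or interpret that statistic.

## Tract-level variables

**Flood risk.** Each property carries an ordinal FloodFactor score 1–10.
Tract variables are the shares of properties that are low (FF ≤ 2), moderate
(FF 3–6), and high (FF ≥ 7) risk; sensitivity runs use the share at each
single level FF = 7, 8, 9, 10. A tract with no properties is flagged missing
(NaN), never imputed as zero risk.

**Index of Concentration at the Extremes.** ICE = (A − P)/T with A the
privileged-extreme count, P the deprived-extreme count, T the total: −1 means
the whole population is in the deprived extreme, +1 the privileged one. The
three variants use households ≤ $25,000 vs ≥ $125,000 (income), Black or
non-white-Hispanic vs white residents (race), and the cross of both
(race + income). Note the sign convention: some applied papers write the
formula with the deprived group first while still describing −1 as fully
deprived; this package fixes the *score semantics* (−1 = deprived) and names
the function arguments by group role so the two cannot be confused. For
analysis the scores are inverted (× −1) so high values mean high inequality;
the stored `ice_*` columns are post-inversion (raw scores are kept in
`ice_*_raw`), and HH therefore always reads "high flood risk surrounded by
high inequality". The inversion flag on `IndexVector` makes double inversion
an error rather than a silent sign flip.

**Gini coefficient (grouped).** Household income arrives in brackets, so the
Gini uses the Lorenz-trapezoid estimator on grouped data with brackets valued
at their midpoints; the open-top bracket is valued at 1.5× its lower bound.
This is the standard grouped estimator; any fixed bracket valuation leaves
the estimator scale-invariant and inside [0, (n−1)/n]. The midpoint
convention means a tract with all households in one bracket scores exactly 0.

**Index of Dissimilarity.** D = ½ Σ_k |b_k/B − w_k/W| needs subunits k
inside an enclosing region. With tracts as the subunits, the package computes
D per enclosing region and assigns each tract its region's value. Synthetic
data uses lattice quadrants as regions ("synthetic counties", or an explicit
`region` column when supplied); this is a stated convention, since a purely
tract-level D is not defined without a subunit structure.

**Prevalences.** Asthma, COPD, depression, diabetes, and kidney-disease
prevalences pass through unchanged and enter the bivariate analysis as lag
variables exactly like the inequality indices.

## Spatial weights

Queen contiguity: tracts are neighbors when their boundaries share at least
one point, including a lone corner; the diagonal is zero; tracts with no
neighbors are islands, reported as such and excluded from inference (they
never receive a p-value — the label `ISLAND` marks them in output).
Adjacency uses exact geometry predicates via an STR-tree; a `tolerance`
option (default 0) bridges small gaps in dirty real-world geometry.

Rows are standardized to sum to one by default. The analysis software used
in this literature defaults to row standardization, and it buys the clean
identity mean(I_i) = I used as a test invariant; binary weights remain
available (`weights_mode="queen-binary"`). On an r×c lattice (r, c ≥ 3) the
queen graph has corner/edge/interior degrees 3/5/8, which the test-suite
asserts, alongside an O(n²) all-pairs brute-force comparison.

## Moran statistics and inference

Variables are population-standardized (divide-by-n SD) over the non-island
tract set, so Σ z² = n and, with row-standardized weights, the global
bivariate statistic reduces to the mean over tracts of z_x,i · lag_i(z_y).
Degenerate (constant) variables raise an explicit error.

Pseudo p-values come from conditional permutation: for tract i, z_x,i stays
fixed and M random draws of |N(i)| values from the remaining tracts' z_y are
placed on its neighbor positions. Implementation detail: the k positions are
drawn as random k-subsets via argpartition of uniform keys, which is valid
because within-row weights are equal for both queen modes; per-tract
generator streams are spawned from (seed, tract index), so results are
independent of iteration order. A tract adjacent to every other tract has a
permutation-invariant lag — a degenerate null — and is reported p = 1.

The default p-value is one-sided in the direction of the observed statistic,
p = (R+1)/(M+1) with R the count of permuted statistics at least as extreme
on the observed side. This is the convention of the GeoDa lineage and is
what practitioners' cluster maps show, but because the tail is chosen after
seeing the statistic its effective false-positive level is about twice
nominal: under complete spatial randomness ~9.5% of tracts fall below
p = 0.05 (measured over 50 seeds on a 15×15 lattice, M = 999). The
`alternative="two-sided"` option doubles and caps the directed p and is
calibrated (~4.9% under the same null). The default stays directed for
comparability with the field's cluster maps; calibration-sensitive use
should prefer the two-sided option. No multiple-testing correction is
applied by default — results are reported at the conventional 0.05 / 0.01 /
0.001 thresholds — matching standard LISA practice.

Classification: significant tracts with z_x > 0 and lag > 0 are HH, both
negative LL, and the mixed signs HL / LH; the sign reference is the
standardized mean (z = 0), and exact zeros are deterministically NS. In the
bivariate scheme only the y (lagged) variable is permuted while x stays in
place, matching the construction "flood risk at each tract against the
spatially lagged inequality of its neighbors"; joint-pair permutation is a
known alternative not implemented here.

## Synthetic tract generator

The generator emulates the *statistical structure* of the real inputs —
spatially autocorrelated composition, ordinal property scores, bracketed
incomes, prevalences, concentric urban-to-rural RUCA structure — not their
geography. Latent fields are simultaneous-autoregressive draws
u = (I − ρW)⁻¹ε on the same row-standardized queen W the analysis uses, so ρ
directly controls the autocorrelation the Moran statistics see. Four
independent fields drive flood propensity, nonwhite share, low-income share,
and prevalence.

Reference conditions (the defaults): a 20×20 lattice (400 tracts), ρ = 0.6,
4,000 persons and 50 properties per tract, ACS-style brackets with $25k/$125k
extremes, and one planted 6×6 block whose flood and inequality propensities
are shifted by +2.5 latent SD — an unambiguous joint extreme emulating a
disadvantaged coastal flood zone, sized so block-edge tracts still have
mostly in-block neighbors. Property scores are a monotone decile binning
(standard-normal edges) of 0.7·tract-propensity + 0.3-weighted property
noise, which guarantees all ten score levels occur at background settings.
Counts are deterministic logistic transforms of the latents rounded to
integers (largest-remainder for brackets) so parameter-recovery tests are
low-variance; `stochastic_counts=True` switches to binomial/multinomial
sampling. Propensities beyond ±8 are clipped with a logged warning. RUCA
codes follow concentric rings from the lattice center (urban 1–3, suburban
4–7, rural 8–10). All randomness flows from the single config seed;
identical configs give bit-identical tables.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: ACS sampling error and margins of error,
property-level geolocation within tracts, irregular tract shapes and sizes,
coastal-vs-inland flood mechanisms, and realistic correlation between
income, race, and flood exposure beyond the planted blocks. Tests on this
generator validate the *statistical machinery*, not substantive conclusions
about any real region.

## Profiling conventions

"Compared to state averages" is operationalized as: the printed delta is
cluster mean minus the mean over all tracts (cluster included), matching how
the published profile tables tabulate it, while the significance test is a
Welch two-sample t-test of member vs non-member tracts (a one-sample mode
against the fixed statewide mean is provided, since published table notes
rarely say which was used). Tract-level means are unweighted across tracts;
population weighting is a flag. Cluster density is ratio-of-sums
(Σ population / Σ area), not the mean of tract densities. RUCA percentages
are reported to one decimal. Constant-within-group indicators report a
missing t, or the numerical p floor when the two groups are constant at
different values.

The bundled reference tables (`floodlisa.reference`) are transcriptions of
published statewide results used purely for arithmetic round-trip checks.
Two of the 36 RUCA percentage cells are internally inconsistent with their
own printed counts (no rounding convention reproduces them; one row's
percentages were evidently computed from a total that differs by one from
the printed membership count), and the printed percentages mix rounding and
truncation. The validation suite asserts agreement within one unit in the
printed decimal and documents the two discrepant cells in
`reference.TABLE3_KNOWN_DISCREPANT` rather than silently accommodating them.

## Numerical and reproducibility choices

Population (ddof = 0) standardization throughout; aggregation identity
asserted to 1e−9 and oracle agreement to 1e−10. Pseudo p-values are floored
at 1/(M+1) by construction; M < 99 is rejected. The orchestrated `run-all`
writes CSV/GeoJSON/GAL plus a manifest (config hash, seed, version,
exclusion counts) with no timestamps, so identical configs produce
byte-identical output trees. Validation simulations use M = 999 with 50
(null calibration) and 20 (planted recovery) replicate seeds on 15×15 and
20×20 lattices respectively — sizes chosen to keep Monte-Carlo error on the
reported rates near ±0.01 while the whole validation run stays around a
minute on one CPU.

## Known limitations

Dense (I − ρW)⁻¹ solves limit the generator to a few thousand tracts; the
LISA permutation loop is O(n·M·n) and sized for thousands of tracts, not
millions; the directed pseudo-p miscalibration discussed above is inherited
from the field's convention; islands and missing-data tracts are excluded
(with logged counts) rather than modeled; and the statistics are descriptive
— cluster membership identifies priority areas, not causal effects.
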