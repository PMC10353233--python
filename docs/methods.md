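# Methods

## Model and assumptions

The package estimates spatial price-level differences for medical services
across M regions that price a common basket of N matched services. The
underlying model is the standard two-stage PPP construction:

1. **Basic-heading stage.** Services are partitioned into basic headings
   (default: the four categories of the Chinese national specification —
   general medical, medical diagnosis, clinical treatment, traditional
   medicine). Within a heading, the PPP of region j with base k is the
   Jevons index, the unweighted geometric mean of price ratios
   `prod_i (P_ij/P_ik)^(1/N_h)`. The country-product-dummy (CPD) estimator —
   least squares on `log p_ir = alpha_r + beta_i + eps` with the base
   region's effect fixed at 0 — is provided as an alternative; on a complete
   tableau the two are algebraically identical (the CPD region effect is the
   mean log price of the region minus the mean service effects, which
   cancel), and the package tests assert this identity to 1e-10. CPD's
   dummy coding is equivalent up to normalization to sum-to-zero coding;
   only effect *differences* enter the PPP matrix.

2. **Aggregation stage.** Expenditure weights exist only at the heading
   level (four shares per region summing to 1), so aggregation is exactly
   heading-level: Laspeyres is the weighted arithmetic mean of heading PPPs
   under the base region's weights, Paasche the weighted harmonic mean under
   the compared region's weights, Fisher their geometric mean. Quantities
   are never observed; the weight-form expressions are the definitions used.
   The Paasche–Laspeyres spread `PLS = |log(L/P)|` measures how much the two
   weighting perspectives disagree for a pair.

3. **Multilateral stage.** GEKS takes the geometric mean of indirect
   comparisons over all bridge regions and is the transitive matrix closest
   to the Fisher matrix in log least squares (verified in tests against
   direct numerical minimization at M=3). The MST method builds the minimum
   spanning tree over the complete region graph with PLS weights and chains
   Fisher links along tree paths, preserving tree-adjacent bilateral
   comparisons exactly.

Key assumptions: every matched service is priced in every region (the
tableau is complete — the package enforces this and excludes, with a count,
any matched service priced ≤ 0 anywhere, because a geometric mean of ratios
needs positive prices); matched codes denote the same service everywhere
(no quality adjustment is attempted); weights are exogenous shares.

## Orientation and presentation conventions

All matrices are oriented row = compared region, column = base region:
entry (j, k) is region j's price level with k as base. Presentation tables
multiply by 100 and round half-even to 2 decimals; rounding is never fed
back into computation. Rebasing only selects a reading column — transitive
levels are base-invariant by construction.

## Numerical choices

* Every product of ratios (Jevons, GEKS, tree chaining) is accumulated in
  log space and exponentiated once; with thousands of services a raw
  product over- or underflows.
* Diagonals are pinned exactly: 1 for L/P/F and level matrices, 0 for PLS.
* The PLS matrix is symmetrized (`(S + S')/2`) purely to cancel last-bit
  rounding asymmetry; the reversal identity `L_jk = 1/P_kj` makes it
  symmetric analytically.
* The MST uses Kruskal's algorithm over edges sorted by
  `(weight, region pair)`, so ties — measure-zero on real data — break
  lexicographically and the tree is reproducible.
* CPD is solved by `numpy.linalg.lstsq` on the dummy design; rank
  deficiency (e.g. two regions with no commonly priced service) raises
  rather than returning an arbitrary pseudo-inverse solution.
* Quartiles in descriptive statistics use linear interpolation between
  order statistics, recorded in the output record.
* Weight vectors are renormalized to sum to 1 on load; a deviation beyond
  1e-6 is recorded and warned about, beyond 1e-9 silently corrected.

## Back-casting

A comparison benchmarked in a reference year is moved to earlier years by
pure deflation: `level(r, t) = level(r, ref) / prod_{s=t+1..ref} CPI_r(s)/100`
under the previous-year = 100 convention (a fixed-base switch is provided),
then the panel is re-expressed with the reference region at the reference
year = 100. Cross-region comparability in earlier years is therefore
inherited from the reference year; this is a preliminary estimate by
design, not a year-by-year re-matching, and the package makes no claim that
relative levels in earlier years reflect those years' schedules.

## Synthetic systems

Real schedules and weights are administrative data that cannot be shipped,
so testing uses a generator with known ground truth. Price of service i in
region r is `base_i * lambda_r * tilt(r, heading_i) * exp(noise)`:

* `lambda_r` — true price-level multipliers; default (1.28, 0.93, 1.00,
  1.03) for four regions named after the Yangtze River Delta, reference
  region 1.00, mirroring the magnitude of differences the published
  comparison found.
* `base_i` — log-normal with median 150 CNY and log-scale 2.0, matching the
  heavy right skew of real fee schedules (medians near 150 CNY, means an
  order of magnitude higher). The extreme upper tail is heavier than a real
  schedule's administrative price caps; index estimates are invariant to
  the base-price distribution, so this does not affect recovery tests.
* `noise` — Normal(0, sigma²) per (item, region), multiplicative so prices
  stay positive and proportionality holds in expectation on the log scale;
  default sigma 0.3.
* `tilt` — optional per-(region, heading) multipliers; default none, so a
  single multiplier per region makes every heading PPP equal, L = P = F,
  and the full pipeline recovers lambda ratios *exactly* with zero noise.
  Tests that need genuine Laspeyres–Paasche spread (hence non-trivial
  spanning trees) switch tilts on explicitly.
* weights — one Dirichlet(4, 4, 4, 4) draw per region (moderate spread
  around equal shares), drawn once per region and held fixed across
  replicates in replicate experiments.
* 750 services per heading by default, ≈ 3,000 matched items, the scale of
  the real matched basket.

What passing tests show: the estimators are exact in the noise-free limit
and unbiased for log level ratios under item-level log-normal noise, with
sampling error `sigma * sqrt(2/N)` per heading PPP. What they do not show:
robustness to non-random item selection, quality differences across
regions, erroneous matches, or weight mismeasurement — none of which the
generator models.

## Packaged benchmark fixture

The published four-region bilateral Fisher matrix (base 100, December-2020
schedules) is shipped as a fixture, and the multilateral stage re-derives
the published GEKS table from it to ±0.02 index points (the slack of
2-decimal printed inputs). The spanning tree behind the published MST table
is not derivable from printed data (the PLS values are unpublished); the
shipped tree {Jiangsu–Shanghai, Shanghai–Zhejiang, Zhejiang–Anhui} is
*inferred* as the unique tree whose chained Fisher links reproduce that
table, and is flagged as inferred in all reports.

## Problem sizes in tests

Deterministic checks run on the 4×4 fixture. Property suites use 3–7
regions (MST optimality is checked against exhaustive spanning-tree
enumeration up to M = 7). Replicate experiments use 200 synthetic systems
at the full scale of 4 regions × 3,000 items, which complete in well under
a minute; unit tests use 20–200 items per heading.

## Known limitations

* No quality adjustment: a matched code is assumed comparable everywhere.
* No item-level expenditure weighting — weights enter at the heading level
  only, as the weight data exist.
* No standard errors for the index estimates (a stochastic-index extension
  point); uncertainty statements in tests come from the generator's known
  noise model.
* Back-cast levels are deflated, not re-estimated.
* No CCD/Geary–Khamis or regionalized GEKS variants; no alternative tree
  dissimilarity measures.
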