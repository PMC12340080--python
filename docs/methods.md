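# Methods

This note documents the models, numerical choices and limitations behind
`omegamap`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Shorthand, labels and masses

Chains follow the common shorthand `C:D(n−x)` with optional `O-`/`P-`
ether/vinyl-ether prefixes and an optional single-capital-letter SIL
prefix. The built-in label registry (`data/labels.yaml`) maps

| code | element | atoms | implied ω |
|------|---------|-------|-----------|
| A | D | 17 | n−9 |
| B | D | 11 | n−6 |
| C | D | 5 | n−3 |
| D | ¹³C | 16 | n−7 |
| E | D | 19 | n−10 |

Both registries are data, not code: `data/classes.yaml` stores per-class
backbone formulas (the molecule minus all chain residues), chain counts
and default adducts for the 14 phospholipid classes in scope (PC, PC O-,
PC P-, LPC, PI, LPI, BMP, PG, LPG, PE, PE P-, LPE, PS, LPS). An ester
chain c:d contributes C(c)H(2c−2−2d)O to the neutral formula, an alkyl
ether C(c)H(2c−2d), an alkenyl chain C(c)H(2c−2−2d). Monoisotopic
masses, including heavy-isotope substitutions, come from pyteomics'
isotope tables; m/z is (M + adduct Δ − z·mₑ)/|z|. Double-bond geometry
(cis/trans) is not modeled; the scope is ω positions only.

Parsing accepts both the Unicode minus and the ASCII hyphen in `(n−x)`
and emits the Unicode form. Label codes `O` and `P` are rejected at
registry load because they would collide with the linkage prefixes.

The default precursor-match tolerance is 10 ppm, appropriate for
Orbitrap-class accuracy and configurable everywhere it is used.

## Isotope-effect model and RT correction

Retention factors are k = (t_R − t₀)/t₀. The adjusted total isotope
effect is aTIE = ((k_H/k_D) − 1)/f_a + 1, with f_a a per-method scalar
(default 1) since no closed form ties it to a gradient program. The
column dead time t₀ is a required per-method configuration value
(default 0.5 min for the 30-min-like fixtures); retention factors are
undefined at or below t₀ and such inputs raise an error.

The per-compound ratio is reduced to a **per-deuterium geometric model**:
k_H/k_D = r^n_D, with r the geometric mean of per-pair per-deuterium
ratios over all standard pairs. This choice is multiplicative in k yet
yields an additive RT shift per chain, (t_obs − t₀)(r^n_D − 1), so
multi-chain corrections are simple sums of per-chain shifts — the
additivity that labeled-pair experiments support. ¹³C labels leave RT
uncorrected (their effect is negligible at chromatographic precision).
The correction is exactly invertible: the simulator's forward model
t_obs = t₀ + (t_true − t₀)/(1 + Σ(r^{n_i} − 1)) round-trips through the
correction to < 1e−6 min, and the estimate-then-correct loop is
unbiased under Gaussian RT noise (checked at 200 replicates).

## ω-combination grouping

Within one molecular species (ω ignored), corrected identifications are
clustered by single linkage with a 5 s default tolerance. Each cluster
becomes one entry: reference RT = member median (robust to a straggler
replicate; mean available via configuration), source batches unioned,
evidence tier = best among members (standard > orthogonal >
SIL-experiment). Per-chain ω assignments are combined
union-consistently: chains are matched on (carbons, double bonds,
linkage) over all pairings, a known ω fills an unknown, and a cluster
that forces two different ω values onto the same chain is flagged
`conflict` and excluded from anchor use and annotation rather than
silently averaged. Grouping is idempotent and order-invariant; merging
batch DBs never invents species and never exceeds the summed input
counts. Outlier curation is exposed as an explicit exclusion set of
ω-level keys, not a hidden heuristic.

## Calibration

Anchor species must be present on both sides. Three selection
strategies are provided: (1) count prioritized — all shared species,
with standard anchors (when present) screening biological anchors whose
residual against a standards-only interpolation exceeds 0.5 min;
(2) reliability prioritized — replicate RT SD ≤ 0.05 min and a single
chromatographic peak per species; (3) take-all, intended for standards,
where a multi-peak standard contributes each peak as a candidate.
Species producing multiple target peaks are otherwise dropped.

Anchors are binned per group along the source RT axis (default bin
0.5 min — coarser than replicate jitter, finer than gradient
curvature); each bin yields a knot at the (median source, median
target). Floor-binning makes knot sources increasing by construction;
knots closer than a minimal spacing (degenerate duplicates at a bin
boundary) are re-merged weighted by occupancy.

The mapping is a **natural interpolating cubic spline** through the
knots — interpolation rather than penalized smoothing, because it is
exact at the knots and performs well when noise is low; robustness to
noise comes from the median-per-bin knots. Groups need ≥ 4 knots for a
cubic; sparser classes fall back along class → user group → global (the
global model accepts a piecewise-linear interpolant at 2–3 knots).
Outside the knot range the boundary slope continues linearly and the
result is flagged `extrapolated`; fallback resolutions are flagged
`fallback`. Non-monotone spline segments on monotone warps are possible
in principle with noisy knots; they are reported through the mapped
values rather than silently re-shaped, and the fixture warps are
verified monotone after mapping.

## Annotation policy

Candidates are RT-DB entries with the peak's molecular-species key (ω
and labels stripped, chains unordered — an assignment can therefore
never cross molecular species, which is what resolves coeluting
isomeric peaks per species). Policy defaults: match window 5 s
(mirroring the grouping tolerance), suggestion window 15 s, margin
factor 2 (competitors must sit ≥ 10 s away, the typical ω-isomer
separation). `automated` = exactly one candidate inside the match
window and margin satisfied; two candidates inside the window =
`ambiguous`; candidates only in the wide window or margin failure =
`suggested`; otherwise `none`. Confidence = max(0, 1 − |ΔRT|/match_s)
is a package-defined convenience score, monotone in the RT deviation,
not a calibrated probability. Peaks identified only at sum-composition
level are outside the input contract: RT cannot disambiguate ω without
molecular-species evidence.

## Synthetic data

The generator emulates: per-class elution profiles linear in the
equivalent carbon number (ECN = C − 2·DB) with small class offsets and
jitter — a fixture convention reproducing the qualitative
reverse-phase trend (RT up with carbons, down with double bonds), not a
chromatographic model; one ω-isomer family per molecular species with
pairwise separations ≥ 10 s by construction; gradient warps (identity,
affine, piecewise-linear stretch with total factor 2 emulating a
30-min-like → 60-min-like transfer, smooth logistic drift); truncated
Gaussian RT noise (default SD 2 s); and labeled runs whose retention
factors shrink by r^n_D per D-labeled chain with exact m/z label
shifts. Study-condition defaults: 5 diacyl classes × 16 species,
ω ∈ {3, 6, 7, 9, 10}, 35-min span, t₀ = 0.5 min, r = 1.001 (a D17
label then shifts a mid-gradient peak by ≈ 20 s), plus an
authentic-standard trio (PC 16:0_20:4(n−6) and the PC 16:0_18:1
n−9/n−10 pair).

What passing synthetic tests do *not* show: real chromatography has
peak shapes, co-eluting interferences, class-dependent warp
differences, and identification errors upstream of this package; the
generator models none of these, so the benchmark numbers characterize
the algorithms under the stated noise model, not instrument
performance.

The benchmark harness (20 seeds by default) pools anchors into the
global model because the simulated warp is class-independent;
per-class splines are exercised by their own tests. Problem sizes
(≈ 90 species/DB, 40 anchors, 3 replicates) were chosen as the
smallest that give stable pooled medians.

## Design choices made where the design was open

- t₀ and f_a are explicit per-method configuration, since neither has a
  universal value; sensitivity to t₀ enters only through the retention
  factor and cancels in the round trip.
- Per-deuterium normalization of the isotope effect (rather than
  per-compound) — documented above; the reported k_ratio is scaled to
  the calibration standard's deuterium count.
- Spline flavor: natural boundary conditions (second derivative zero),
  minimum 4 knots for a cubic.
- RT-DB files double as annotated mass lists: one row per ω-resolved
  species with reference RT, batches, evidence and flags, in both
  tab-separated and spreadsheet dialects; the column layout is
  versioned with the package rather than bit-compatible with any
  external tool.
- The mass-list generator keeps chains unordered (MS¹ cannot resolve
  sn-positions); sn-resolution enters only through input identification
  tables.

## Known limitations

- Only deuterium and ¹³C labels are modeled; no other isotope effects.
- No MS/MS fragment scoring and no raw-file parsing: inputs are
  identification tables from upstream software.
- Extension to lipids with more than two chains is structurally
  possible via the class registry but untested; combinatorics and
  chromatographic separation both worsen.
- Odd-chain and geometry (cis/trans) isomers are out of scope.
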