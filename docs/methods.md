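# Methods

This note records the model, the numerical conventions, the synthetic study
conditions, and the design choices made where the problem was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Packing density and lattice expansion

An atom's packing density is the number of non-hydrogen atoms within a
7 Å closed ball (ties at exactly the cutoff count as inside) in the
crystalline context. The implementation applies every space-group operator
to the asymmetric unit in fractional coordinates, wraps each image into
[0, 1), replicates the filled cell over the 3×3×3 block of lattice
translations, orthogonalises, and trims to the asymmetric unit's bounding
box inflated by radius + 0.5 Å (the margin guards against floating-point
edge loss; its cost is negligible). Distance queries use a k-d tree
(`scipy.spatial.cKDTree`); a brute-force all-pairs scan over the untrimmed
27-copy expansion is kept in the package as the reference implementation
and the two must agree to exact integer equality.

Conventions, stated once and tested:

- the atom's own identity-copy is excluded from its count (a constant +1
  would not change the ranking, but self-exclusion is the plain reading of
  "atoms within a radius");
- every other modelled non-hydrogen scatterer counts 1 — symmetry mates,
  heteroatoms, waters, metals, and each altloc copy — regardless of
  partial occupancy; occupancy-zero atoms are excluded everywhere (they
  carry no density evidence);
- deuterium counts as hydrogen;
- an atom on a special position (a symmetry copy within 0.5 Å of itself)
  produces a warning, not an error, and the coincident copy is counted.

## B_Damage

Atoms are sorted by (packing density, serial); the serial tie-break makes
the ranking deterministic. The "similar environment" of atom *j* is the
contiguous window of `w = max(11, round(0.02 N))` atoms centred on *j*'s
rank, shifted inward at the ends so it always contains exactly `w` members
(`w` capped at `N`; structures with fewer than 11 included atoms are
rejected as too small for the metric). `B_Damage_j = B_j / mean(B over the
window, j included)`. Including *j* in its own window keeps every window
mean positive and damps the self-ratio of extreme atoms; both the window
shape and this inclusion are conventions — no published value for "similar
packing density environment" exists to recover — so they are fixed in
`RunConfig`, echoed into every output artifact, and the independent test
oracle implements the same stated convention.

B_Damage is scale-free (multiplying all B-factors by k > 0 changes
nothing) and deterministic; both are asserted by tests.

## B_net

From the `B_Damage` values of the Asp/Glu side-chain carboxyl oxygens
(OD1/OD2 of ASP and D-isomer DAS; OE1/OE2 of GLU/DGL; at least 20 required,
matching the cohort filter — overridable but loudly warned):

1. Scott bandwidth `h = σ̂ · n^(−1/5)` with Bessel-corrected σ̂ (the
   common 1-D reading of "the Scott method"; this is also exactly what
   `scipy.stats.gaussian_kde` computes by default, which the
   implementation uses — the test oracle evaluates the Gaussian mixture
   explicitly instead).
2. Evaluate the KDE on 100 equally spaced points spanning
   `[min − 3h, max + 3h]` of the selected values. The range is a design
   choice: with 3 bandwidths of padding at least 99.7% of each kernel's
   mass is on-grid, which makes the conservation check (total trapezium
   area ∈ [0.95, 1.0]) meaningful.
3. Integrate the 99 trapeziums; the below-median area A collects every
   trapezium left of the all-atom median `B_Damage` *plus the trapezium
   the median falls into*; `B_net = B/A` with B the remainder. The median
   uses the conventional average-of-middle-two for even N.

Degenerate cases are explicit: all selected values identical → error
naming the value (zero bandwidth); median left of the grid → A = 0 →
`B_net = +inf` with a warning flag (and such rows are flagged suspect);
median right of the grid → `B_net = 0` with a warning.

The median-trapezium rule has a real consequence worth knowing: relative
to an exact split at the median, it shifts B/A by up to ~10% whenever the
density at the median is high compared to A — precisely the damaged
regime. It also bounds the metric's dynamic range: once the damaged tail
is far right of the median, further inflation stretches the tail without
moving mass across the split, so `B_net` saturates (on the default
synthetic crystal, strict growth holds up to ≈ 1.5× carboxyl-oxygen
inflation and flattens beyond — mirroring the plateau seen in real
high-dose series). Human-facing output rounds to 3 significant figures;
machine output keeps full precision.

The Asn/Gln control variant uses the single amide oxygen of ASN (OD1) and
GLN (OE1). Its own minimum is 10 oxygens: the control is advisory rather
than an eligibility gate, but below ~10 points a KDE area ratio is too
unstable to interpret, so the control is reported absent instead. Note the
control estimate remains noisy near its minimum; its stability under
Asp/Glu-only damage (< 10% shift while the Asp/Glu metric rises several
fold) is established on the default fixture in the moderate-damage regime
the dose series covers, not at extreme (≥ 2×) inflation, where the
all-atom median shift feeds back into any all-atom-referenced statistic.

## Eligibility, percentile and cohort statistics

Eligibility follows the standard screen with closed boundaries: resolution
≤ 3.5 Å, R_free ≤ 0.4, temperature in [80, 120] K, no nucleic-acid residue
codes in the model, every Asp/Glu atom site summing to occupancy 1 across
conformers (tolerance 1e−3; an A/B altloc pair at 0.5 + 0.5 passes), ≥ 20
Asp/Glu side-chain oxygens, and per-atom B-factors. Flat-B detection is
`sd(B) < 1e−6 Å²`; per-residue refinement is detected heuristically (every
multi-atom residue internally constant while the structure-wide sd is
nonzero) and reported as such. Missing metadata makes a criterion unknown
and the structure ineligible with an explicit reason; the report never
raises.

`B_net`-percentile: for each structure, the `window_size` (default 1000)
structures closest in resolution — all distance ties at the boundary
included — define a closed resolution range; the comparison set is every
cohort structure in that range; the percentile is the fraction of the
comparison set with `bnet ≤ bnet(s)`. This ≤-inclusive convention makes
the top structure of its window score exactly 1 and lets ties share a
value. Dose-series fits are ordinary least squares of `B_net` on dose
(MGy), requiring ≥ 3 points after any high-dose plateau exclusion;
cross-series consistency is the sample SD divided by |mean| of the
gradients and intercepts. Correlations are Spearman's ρ (average ranks on
ties, pairwise-complete per covariate, undefined for constant covariates),
chosen because the relationships of interest are monotone, not linear.
The advisory suspect flag is `B_net > 3.0` or percentile > 0.95, strict
inequalities, never used to filter data.

## Synthetic study conditions

The generator builds pseudo-protein chains on a coarse self-avoiding
lattice path (6 Å node spacing, boustrophedon through a cubic grid) inside
a P1 cell padded 15 Å beyond the chain extent, so lattice copies sit
outside the 7 Å packing radius and the ground truth stays analytic;
symmetry correctness is exercised separately with hand-built two-operator
cells. Defaults, chosen once as a realistic small crystal:

- 2 chains × 75 residues; Asp/Glu/Asn/Gln at their typical frequencies in
  globular proteins (5.5 / 6.8 / 4 / 4%), with Leu/Ala standing in for the
  bulk — ~1040 atoms, 36 carboxyl oxygens (≈ 3.5% of atoms, matching real
  proteins), 12 amide-oxygen controls;
- baseline B 20 Å² with Gaussian noise of 3 Å² (~15%, a realistic
  per-atom B heterogeneity) and a −4 Å²-per-z-score coupling to local
  crowding, so the packing-density normalisation has a real mobility
  gradient to remove;
- damage: each carboxyl-oxygen site carries a fixed bimodal
  susceptibility u (30% of sites strong, u ∈ [0.7, 1]; the rest barely
  affected, u ∈ [0, 0.25]), and its B is multiplied by
  `1 + (damage_factor − 1)·u`. Sites with u ≥ 0.5 are the labelled
  ground-truth damaged atoms. This mirrors the site-selective recruitment
  of real decarboxylation; a single uniform inflation of all selected
  oxygens was rejected because it detaches the whole selected
  distribution from the all-atom median, which is not the phenomenon the
  metric measures.
- dose series map dose (MGy) to the damage factor through the fixed
  monotone calibration `factor = 1 + 0.3 · slope · dose`, set so the
  fitted `B_net`-vs-dose gradient approximates the requested slope on the
  default crystal; an optional factor cap reproduces the high-dose
  plateau. All members of a series share one seed, hence one backbone and
  baseline B-field.
- cohorts span a resolution grid with an optional monotone
  damage–resolution coupling plus independent per-structure noise on
  temperature, R-factors, mass and restraint weight; single-chain members
  of 90–105 residues keep every entry above the 20-oxygen floor.

Everything is driven by one integer seed through `numpy`'s `default_rng`;
identical specs give bit-identical structures and files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no real refinement (B-factors are drawn, not
fitted, so there are no restraint-induced correlations between neighbouring
atoms beyond the crowding term), no anisotropy, no TLS partitioning, no
solvent or ligands, no alternate conformations, no genuine electron
density. Tests on these fixtures validate the *computation* of the metrics
and their internal behaviour (normalisation, monotone dose response,
control specificity, resolution decorrelation of the percentile), not the
biological detection performance on deposited structures.

## Scale of the shipped analyses

The packaged tests and the acceptance script run desk-scale versions of
the cohort analyses: 500-structure cohorts (percentile window 50, scaled
with the cohort so that windows remain a small fraction of the whole —
with a window as large as the cohort the percentile degenerates to a
monotone transform of `B_net`), three 5-point dose series, and ~1000-atom
crystals. These sizes were chosen so the full suite completes in well
under a minute while every statistic retains a comfortable margin over its
decision threshold.

## Known limitations

- B-factors are taken as recorded; files with TLS-partitioned ADPs are not
  detected or reconstructed — use total-B files (e.g. PDB-REDO
  `*_final.cif`) for trustworthy results.
- The window convention for "similar packing density" is this package's
  pinned choice; absolute `B_net` values from other implementations of the
  same idea may differ by more than rounding, so compare like with like.
- The Asn/Gln control needs ≥ 10 amide oxygens and stays noisy near that
  floor.
- `B_net` saturates at extreme damage (see above); within-series ordering
  at very high dose is better read from the per-atom `B_Damage` tail than
  from `B_net` differences.
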