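# Methods

This note records the models, numerical choices, and deliberate
simplifications behind `quatmass`, in the spirit of the methods pages of
packages like statsmodels or msprime: what is computed, under which
assumptions, and what the synthetic tests do and do not demonstrate.

## Electrospray charging model and mass estimation

Ions are assumed protonated only (m_p = 1.007276 Da); in ammonium-acetate
native electrospray, salt adducts are treated as mass heterogeneity (peak
broadening), not as charge carriers. All masses are average masses: at
~211 kDa the isotope envelope is far narrower than the instrument peak
width, so monoisotopic bookkeeping would be spurious precision. Tolerances
are relative (ppm) in m/z space and absolute (Da) in mass space.

Charge assignment walks the centroided peak list from high to low m/z. For
an adjacent pair, z = (mz_low − m_p)/(mz_high − mz_low) is rounded to the
two nearest integers; a candidate joins the current envelope only if the
implied neutral masses agree within `tol_ppm` (default 100 ppm for clean
lists, looser for noisy synthetic data). Between two admissible charges the
one with the smaller mass disagreement wins, then the lower charge —
deterministic by construction. Envelopes need ≥ 2 members; a single peak is
logged as ambiguous and dropped.

The neutral mass is the intensity-weighted mean of z·(mz − m_p) over the
envelope; its `sd` is the weighted standard deviation across charge states
(inter-state scatter, not peak width), and the mass-domain width is the
median of per-peak FWHM × z. The FWHM→mass conversion is exactly
`fwhm_mz · z`, linear in both arguments.

## Peak picking

Profile spectra are centroided with local-maximum detection
(`scipy.signal.find_peaks`) under two thresholds relative to the base peak:
minimum height and minimum prominence. The apex is refined to sub-grid
accuracy by the intensity-weighted centroid of the points above half
maximum (baseline-subtracted at the half level); this is exact for
symmetric peaks and, unlike a 3-point parabola, averages down additive
noise. FWHM comes from linear interpolation to half maximum on both
flanks; a flank truncated by the spectrum edge leaves FWHM = 0, which
downstream code treats as "width unknown".

Profile/centroid mode is auto-detected: a spectrum is profile when ≥ 5% of
adjacent spacings are below 0.05 Th (finely sampled traces) *or* when the
spacing is nearly uniform (coefficient of variation < 5% over ≥ 50 points —
a sampling grid at any step, the regime of isotope-unresolved complexes
sampled coarsely). The second clause was added because a fixed 0.05 Th
threshold misclassifies wide-peak profile data on a ~1 Th grid; the
detection is overridable with the `profile` flag everywhere.

## Metal-adduct occupancy

A satellite series at one charge state is anchored at its lowest-m/z member
(defined as apo, occupancy 0); satellites are expected at +k·δ/z, with
δ = 63.546 Da for Cu by default. Whether a bound Cu(II) displaces 0, 1 or 2
protons is not observable at this resolution, so the convention is exposed
as configuration (`copper_adduct_delta(displaced_protons)`, default 0).
Matched peak intensities, normalised, give the occupancy distribution;
expected positions with no peak contribute zero, and trailing zeros beyond
the last match are trimmed. Modification-shifted series (gluconoylation
+176 Da, AEBSF +183 Da) are handled by running the detector once per
configured anchor shift.

## Stoichiometry solving

Exhaustive bounded enumeration, not branch-and-bound: realistic catalogs
here have ≤ 3–4 subunit types with small copy bounds, the full product
space is tiny, and exhaustiveness makes the brute-force oracle test an
exact equivalence. A guard refuses search spaces above 10⁸ states.
Ranking is |mass error| ascending, then fewer subunit copies, then fewer
adducts, then lexicographic — deterministic and invariant to catalog entry
order. Mass-degenerate swaps (e.g. two ~12 kDa subunits) are *not*
resolved silently; the full ambiguity set is returned and the caller (or
an independent measurement such as a stripped-metal fragment mass) must
discriminate. Default tolerance for an intact-complex assignment is the
envelope's mass-domain FWHM; for sub-10 kDa species the default is 2 Da.

## Topology enumeration and scoring

Arrangement families and their size caps:

| family            | equivalence                     | cap |
|-------------------|---------------------------------|-----|
| ring              | bracelet (rotation+reflection)  | 10  |
| ring_plus_pendant | graph isomorphism (labels kept) | 10  |
| tree              | graph isomorphism               | 7   |
| connected         | graph isomorphism               | 6   |

Rings are enumerated as label strings canonicalised to the
lexicographically smallest rotation/reflection; this canonical string is
the stable identifier used in reports and ties. Trees come from Prüfer
sequences and general connected graphs from edge subsets, both deduplicated
by label-respecting isomorphism; the caps keep those enumerations
affordable and are stated in the refusal message. The pendant subunit
(default: attached to every ring node, a single super-interface) models a
large catalytic subunit riding on a ring whose attachment map is unknown;
its interface is assumed weakest, so first-cleavage products are
{pendant, intact ring}.

Fragment prediction enumerates all connected induced subgraphs (for a ring:
the n contiguous arcs of every size k < n plus the full ring). Scoring sums
w(predicted?, class) over the union of predicted and observed labels, with
unobserved-but-predicted labels classed "absent". Default weights:

    predicted ∧ major +2   predicted ∧ minor +1   predicted ∧ trace 0
    predicted ∧ absent −2  ¬predicted ∧ major −3  ¬predicted ∧ minor −1
    ¬predicted ∧ trace 0   ¬predicted ∧ absent 0

These encode the qualitative elimination logic — a predicted-but-missing
homodimer is disqualifying, an unpredicted trace species is excusable — and
are fully exposed. With `secondary_dissociation` on, unpredicted trace
species that are sub-compositions of a predicted fragment contribute
exactly zero (second-generation pieces). Predicted multiplicities are *not*
compared to intensities by default: observed arc ratios need not follow the
symmetric multiplicities of an alternating ring (interface energetics and
secondary dissociation skew them), so multiplicity correlation is offered
only as an optional diagnostic, never used for elimination.

Abundance classes from raw intensities or event counts: major ≥ 20% of the
most abundant fragment, minor ≥ 2%, trace ≥ 0.5%, else absent. These cuts
are invented defaults, configurable.

## CCS calibration

Standard TWIMS practice: corrected drift time t′ = t_d − EDC·√(m/z)/1000,
reduced-mass- and charge-normalised cross section CCS′ = CCS·√μ/z with
μ = m·m_gas/(m + m_gas), and an ordinary least-squares fit of
ln CCS′ = ln a + b·ln t′. A power law in log-log space is the simplest
defensible calibration form; no polynomial extension is attempted.
Defaults: nitrogen drift gas (28.0134 Da), EDC coefficient 1.57 — both
instrument settings, both configurable. Two calibrants define a perfect
line (R² = 1); coincident drift times are an error.

## Synthetic ground truth

The default `mnx_ground_truth()` emulates the Mnx-like study system:
MnxG 139,783.0 Da, MnxE 12,112.0 Da, MnxF 11,699.0 Da, so that G₁E₃F₃ sums
to exactly 211,216 Da and the E₃F₃ ring to 71,433 Da (~71 kDa). The E−F
mass gap of 413 Da is deliberately 6.5 × the Cu mass, the point farthest
from any integer multiple of 63.546 Da: an E↔F swap is then never
mass-degenerate with a change in Cu count, so composition recovery tests
measure the solver, not an accident of the mass grid. Metal occupancies:
E ~ point mass at 1 Cu with 5% spill to 0 and 2 (tight binding), F ~
triangular on {0, 1, 2} (loose binding).

The spectrum forward model places Gaussian peaks for every (charge state,
total-metal variant) pair — envelope weights from a discretised Gaussian
over z (σ = n_states/3), variant weights from the independent convolution
of per-subunit occupancies — on a grid of FWHM/50 (default 1.1 Th), with
additive uniform noise. `z_spread` counts charge states (1 = single state).
The dissociation model: low-energy SID emits the pendant-cleavage pair;
high-energy SID samples contiguous ring arcs with size bias
P(k) ∝ exp(−|k − n/2|/τ), τ = 1.5 (chosen so every size from monomer to
full ring appears); CID ejects one uniform monomer plus the stripped
complex. Metals are retained per copy with probability 0.9 in SID and 0.1
in CID — a two-level caricature of fold-preserving vs unfolding
activation. Calibrant generation inverts the calibration power law for
log-uniform masses with native-like charges (z ≈ 0.078·√m).

Every generator is a pure function of (parameters, seed) via
`numpy.random.default_rng`; no global state.

What the synthetic data does *not* emulate: real peak-shape asymmetry and
baseline drift, overlapping envelopes from co-purified species, adduct tails
from incomplete desolvation, continuous SID/CID energy dependence, isotope
structure, and detector saturation. Passing the end-to-end tests therefore
demonstrates correctness of the inference chain under its own model
assumptions, not robustness to every instrument artifact.

## Problem sizes in the shipped tests

The end-to-end recovery study runs 200 seeded simulated experiments
(9-charge-state spectra at 0.5% noise; 1,000 SID events each) and requires
composition recovery at rank 1 in ≥ 95% and ring-arrangement recovery in
≥ 90% of runs; these rates are package acceptance properties chosen when
the generator was designed. The acceptance script reports the same
quantities over 50 experiments. The brute-force solver equivalence uses
randomly drawn catalogs with product spaces up to ~10⁴ states; bracelet
counts are verified exhaustively against a dihedral-orbit oracle for all
two-label splits up to ring size 8.

## Known limitations

* Overlapping charge envelopes from mixtures are split greedily by
  adjacency; a dedicated mixture deconvolution (and anything Bayesian) is
  out of scope.
* The ring-arc scoring treats abundance classes ordinally; it does not
  model interface energies, and fragment intensities are never used to
  eliminate arrangements.
* The pendant attachment map is a free choice (default: all ring nodes);
  with a known attachment count the `pendant_degree` option enumerates
  contiguous attachments only.
* Residual mass (observed − theoretical, e.g. from unknown modifications)
  is reported, never interpreted.
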