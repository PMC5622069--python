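# quatmass

Native mass spectrometry of intact protein complexes, for people who need to
turn a peak list into a quaternary-structure model: charge-state
deconvolution, integer subunit stoichiometry, surface-induced-dissociation
(SID) connectivity inference, metal-adduct occupancy, and traveling-wave ion
mobility (TWIMS) CCS calibration. The package was built around the analysis
of the bacterial Mn-oxidase complex Mnx — a ~211 kDa assembly of one
multicopper-oxidase subunit (MnxG) and six small accessory subunits (MnxE,
MnxF) — but every stage is generic and a synthetic forward model lets the
whole chain run and be tested without instrument data.

## The analysis chain

**Mass.** Electrospray of a folded complex yields a run of consecutive
charge states; each appears at m/z = (M + z·m_p)/z. Adjacent peaks fix the
charge without knowing M: z = (mz_low − m_p)/(mz_high − mz_low). The
intensity-weighted mean of z·(mz − m_p) over the envelope gives the neutral
mass M. At 211 kDa the isotope structure is unresolved, so the peak width
sets the mass uncertainty: a FWHM of w Th at charge z is w·z Da in the mass
domain (55 Th at 29+ → ≈1.6 kDa).

**Stoichiometry.** Given a catalog of subunit masses m_i with copy bounds
(and adduct masses δ_j), the solver enumerates every integer vector (n, a)
with |M − Σ n_i m_i − Σ a_j δ_j| ≤ tol, ranked by mass error then parsimony.
Near-degenerate alternatives (two subunits of almost equal mass) are kept as
an explicit ambiguity set.

**Topology.** SID cleaves the weakest inter-subunit interfaces, so released
subcomplexes are connected pieces of the connectivity graph. Candidate
arrangements of a composition (rings up to bracelet symmetry, a ring plus a
pendant subunit, trees, general connected graphs) each predict the multiset
of connected induced subgraphs; predictions are scored against observed
fragment compositions classed as major/minor/trace/absent. A ring that
groups like subunits predicts homodimers — if none are seen, it is
eliminated; for the Mnx hexamer this singles out the alternating EFEFEF
ring.

**Metals.** Bound metals shift a subunit peak by δ/z per copy (Cu: 63.546
Da). Matching satellite intensities at +k·δ/z gives an occupancy
distribution over metal counts; SID (gentle, fold-preserving) retains
metals, collision-induced dissociation (CID) strips them.

**CCS.** TWIMS drift times are converted to collision cross sections through
calibrants: ln(CCS·√μ/z) = ln a + b·ln t′ with t′ the EDC-corrected drift
time, fit by least squares and inverted for unknowns.

## Worked example

Simulate a data set from the default ground truth (alternating E/F hexamer
plus pendant G, 211,216 Da) and run the pipeline on it:

```
quatmass simulate --out-dir sim --seed 7
printf 'name,mass,min,max,symbol\nMnxG,139783.0,0,1,G\nMnxE,12112.0,0,8,E\nMnxF,11699.0,0,8,F\n' > catalog.csv
cat > config.toml <<EOF
peaks = "sim/peaks.tsv"
catalog_csv = "catalog.csv"
observations = "sim/observations.csv"
zmin = 20
zmax = 40
tol_ppm = 300
pendant = "G"
EOF
quatmass run --config config.toml --out report.json
```

The report's key numbers (seed 7):

* `mass_estimate.mass` = 211216.1 — the neutral mass recovered from the
  five-peak charge envelope (truth: 211,216 Da);
* `compositions[0].label` = `E3F3G1` — the best integer composition within
  the ~1.6 kDa mass-width tolerance, i.e. one MnxG plus three MnxE and
  three MnxF;
* `topology.ranking[0].canonical` = `EFEFEF` with score 18.0 — of the three
  distinct 3E+3F bracelets (EEEFFF, EEFEFF, EFEFEF), only the alternating
  ring predicts every observed mixed fragment while predicting none of the
  missing homo-oligomers.

The same stages are available as library functions
(`quatmass.assign_charges`, `solve_compositions`, `rank_topologies`, …) and
as individual subcommands (`quatmass peaks|deconvolve|adducts|assign|topology|ccs`).

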