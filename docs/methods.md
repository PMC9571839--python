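# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through it.

## Interaction-energy statistics (`energy_stats`)

MD samples of ligand–environment interaction energies are strongly
autocorrelated, so plain standard deviations underestimate the uncertainty
of the state averages. We use block averaging: a series is split into
`n_blocks` contiguous equal blocks (default 10, mirroring a production
protocol of ten consecutive simulation segments), and the *sample* SD
(divisor n−1) of the block means is reported as the fluctuation statistic.
The reported mean is the mean of block means, which equals the plain mean
of all retained samples; trailing samples that do not fill a block are
discarded with a warning (the reference 10 × 5M-step protocol divides
evenly, so this only affects ad-hoc inputs).

Bound-minus-free difference columns are computed from unrounded means, and
their SDs combine bound and free SDs in quadrature. When a summary is
instead transcribed from a printed table, the printed difference columns
are stored verbatim: independent rounding makes them disagree with
differences of printed means by ~0.1 kcal/mol in general, and by 1.1
kcal/mol for compound 4, whose published row is internally inconsistent
(its difference column, not its state means, reproduces the published
prediction, so both are kept as printed and the inconsistency is
documented rather than "corrected").

Energies are kcal/mol throughout; readers reject other declared units.
The charged/neutral grouping used for fluctuation comparisons follows the
energy table's markers (compounds 2, 4, 5, 7, 8, 11 charged).

## LIE engine (`lie_engine`)

* `ΔG = RT ln Ki` with R = 1.987204×10⁻³ kcal/(mol·K), standard state 1 M.
  Default T = 303.15 K — the assay temperature implied by the published
  experimental free energies, which it reproduces to one decimal for all
  11 compounds (the 298 K simulation temperature does not, e.g. −7.5 vs
  −7.6 for compound 1). T is a parameter everywhere.
* Experimental uncertainty: first-order propagation `RT·σ_Ki/Ki`. This
  reproduces 10 of the 11 published uncertainties; compound 11's published
  ±0.01 is inconsistent with its Ki error (propagation gives ≈0.13) and is
  kept verbatim in the fixture with a warning at pipeline level.
* Prediction uncertainty: `sqrt((α·σ_ΔvdW)² + (β·σ_Δel)²)`, treating the
  two energy components as independent.
* The thermodynamic cycle object tracks the two decoupling legs
  (`ΔG_dec(Q) = −ΔG_solv(Q)`, with `ΔG_solv(Q) = α⟨V_vdW⟩_Q + β⟨V_el⟩_Q + γ`)
  and closes identically. Note γ cancels between the legs, so the cycle's
  binding leg equals the LIE prediction *minus* γ; the γ-including equation
  is the operational estimator, the cycle is bookkeeping.
* Calibration is ordinary least squares of ΔG_exp on (ΔvdW, Δel, 1),
  solved with a rank-checked `lstsq`; γ is always fitted unless pinned.
  Exact recovery of the published coefficients from the printed tables is
  impossible (inputs are rounded); OLS lands within ~0.01–0.02 of them.
* Reported tables round half away from zero to one decimal (the convention
  of the published tables; banker's rounding would disagree on ties);
  machine outputs keep full precision.

## Trajectories (`trajectory`)

Input formats are topology PDB plus multi-model PDB or XYZ trajectories,
parsed with MDAnalysis after a light atom-count prepass that reports the
offending frame index on mismatch. Atom roles (protein / ligand / water /
cofactor / ion) come from residue names; the ligand residue name is
configurable (default HRM). The simulated systems are spherical droplets,
so no periodic imaging is applied anywhere.

* Superposition is least-squares rigid-body (Kabsch). RMSD convention:
  align each frame on frame 0 using protein Cα atoms, measure ligand heavy
  atoms — the standard pose-stability metric; both selections are
  configurable, and the trajectory mean is the per-compound summary value.
* Distance series use the per-frame *minimum* over the two selections, so
  a residue-level selection means "nearest heavy atom", the natural
  reading for e.g. the pyrrole-N–Asn181 distance. Block averages default
  to 0.1 ns windows (1000 blocks covering a 100 ns run); where a published
  caption ambiguously mixes 1 ns and 0.1 ns, 0.1 ns is chosen because
  1000 × 0.1 ns matches the stated totals.
* Water counting: water-residue oxygens within a radius (default 5.0 Å,
  not specified upstream) of the centroid of a center selection, default
  the FAD N5 atom that anchors the binding-cavity coordinate system.

## Interaction profiling (`profiler`)

The dynophore reimplementation is deliberately geometric and declarative:
ligand features come from a text annotation table, not cheminformatic
perception, and environment donor/acceptor/hydrophobe atoms are built-in
tables over the 20 standard residues, FAD and water. Default criteria:
heavy-atom H-bond distance 3.0 Å (anchored to the ~2.9 Å donor–acceptor
switching distance observed for the pyrrole-N–Asn181 contact), D–H⋯A angle
≥ 130° when an explicit hydrogen is present (distance-only otherwise),
hydrophobic contact 4.5 Å, ionic/cation-π 5.0 Å. Aromatic stacking is
folded into the hydrophobic rule without a ring-plane test, matching how
such contacts are reported upstream. The original dynophore tool's
thresholds are unpublished, so published occurrence percentages are not a
reproduction surface; the contract here is exact consistency between
barcodes and percentages, equality with a brute-force all-pairs oracle,
and monotonicity under cutoff shrinkage. Waters are aggregated under a
single "water" partner label.

## Synthetic data (`synthetic`)

The generators define the test conditions:

* **Energy series**: AR(1) Gaussian process (default φ = 0.95, mimicking
  the slow wander of MD energy traces; not derivable from published data,
  configurable) rescaled affinely *after* generation so the block-mean
  sample SD and mean hit their targets exactly. This makes
  `gen_energy_series ∘ block_statistics` an exact right-inverse for
  (mean, block SD) and keeps fixture tests deterministic. Default length
  5000 steps per series — two orders of magnitude below the 2.5M samples
  of a real 100 ns run, chosen so the full 44-series round trip stays
  sub-second while leaving ≥ 500 samples per block.
* **LIE datasets**: ΔG from known coefficients plus seeded Gaussian noise,
  for parameter-recovery studies.
* **Toy pockets**: seven pseudo-residues (Asn181, Tyr407/444, Leu337,
  Met350, Phe352, FAD) carrying only the atoms the detection tables need,
  a 15-atom β-carboline-like ligand, scheduled contacts (ligand atom
  pinned at the target distance from its partner while active, 8 Å away
  otherwise, with a collinear hydrogen for donors), an optional rigid pose
  shift from a given frame, and fixed or Poisson water occupancy. Thermal
  jitter (σ = 0.05 Å) is added to unscheduled ligand atoms and waters;
  scheduled atoms are left exact so occupancy ground truth is exact, and
  the pocket residues are static so alignment is noiseless. Default
  1000 frames at 100 ps, the frame budget of the reference dynophore
  analysis.

What the generators do *not* emulate: force-field physics, correlated
protein motion, water exchange kinetics, or realistic ligand internal
dynamics. Passing tests therefore demonstrate the correctness of the
analysis operators (detection, block statistics, superposition,
calibration) against known ground truth — not the accuracy of LIE on new
chemistry.

## Numerical choices and degenerate inputs

* Sample SD (n−1) everywhere an SD of block means is taken; n_blocks ≥ 2.
* Rank-deficient calibration designs raise a dedicated error rather than
  returning a pseudo-inverse fit.
* H-atoms are associated to donors by a 1.25 Å nearest-heavy-atom rule.
* Tie-breaking in reported pair ordering: descending occurrence, then
  lexicographic.
* Zero-variance series, single-compound groups, radius → 0 water counts
  and identical bound/free states are all exercised explicitly in tests.

## Known limitations

* No binary trajectory formats (DCD/XTC/TRR) and no native MD-engine
  energy-log parsers; conversion to the documented TSV dialect is the
  caller's job.
* The profiler has no aromatic plane-angle test and no 3D feature-density
  output; occurrence statistics and barcodes only.
* First-order Ki error propagation is symmetric and breaks down for
  relative errors approaching 1.
* The calibration assumes homoscedastic experimental errors; no weighted
  fit is provided.
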