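# Methods

This note documents the models, parameter choices and numerical conventions
behind `lmdlipidomics`, and what the synthetic data generator does and does not
emulate.

## Chemistry model

Every lipid class is defined by an elemental *backbone* — the composition of a
virtual species with zero chain carbons and zero double bonds — so that a
species' composition is `backbone + C×CH2 − DB×H2 (+ OH×O)`. Backbones are
fixed against the standard sum-composition formulas (PC(34:2) → C42H80NO8P,
SM(34:1:2) → C39H79N2O6P, CL(72:8) → C81H142O17P2, etc.), which makes the
chain arithmetic (homolog ladders, lyso relations) exact identities rather
than approximations. Atomic masses are embedded constants from a standard
monoisotopic table; nothing is fetched at run time, so all masses are
bit-stable across machines.

Merged isomeric entries follow direct-infusion MS1 reality: `PC-O(x:y)` also
represents `PC-P(x:y−1)` (the parser accepts both spellings and shifts the
double-bond index), `PE-P` likewise absorbs `PE-O`, and `PG/BMP` is one
collective class. Chloride adducts use ³⁵Cl for the monoisotopic peak — that
is what "monoisotopic" means — and carry the ³⁷Cl isotopologue in the
envelope.

Isotope envelopes model ¹³C (abundance 0.0107) for every composition and ³⁷Cl
(0.2424) when chlorine is present. Other elements' heavy isotopes (²H, ¹⁵N,
¹⁸O, ³⁴S) contribute well under a percent at these compositions and are left
out; the corrections that consume the envelope are insensitive at that level.

The resolution model is Orbitrap-like: R = 240,000 at m/z 200 with
R ∝ 1/√(m/z), hence FWHM(m/z) = m/z^1.5 / (240,000·√200). Two consequences
shape the whole pipeline: the (C:DB+1) homolog's two-neutron isotopologue
(0.0089/|z| below the (C:DB) monoisotopic peak) becomes unresolvable above
m/z ≈ 975 for singly charged ions and everywhere in range for cardiolipin
[M−2H]²⁻; and the sodiated-PC/protonated-PC isobar (Δm/z = 0.0024) is
unresolvable throughout.

## Synthetic acquisition

The generator emulates the study conditions the pipeline is designed for:

* **Geometry.** LMD spots of 5,000–160,000 µm² from 10 µm cryosections;
  tissue density 1 g/cm³ (this single convention reproduces both a 0.3 µg
  30,000 µm² spot and a 490 µg 7×7 mm section). Cell-culture ground truth is
  stated per cell and converted through the typical mammalian cell volume of
  4000 µm³, so a 5,000 µm² spot corresponds to ~12.5 cells and holds under
  1 pmol of membrane lipid at the default 0.06 pmol/cell.
* **Lipidomes.** ~184 species over 23 classes (8 per class by default) drawn
  from realistic per-class C/DB grids, with log-normal abundances (σ = 1)
  around liver-like class weights; the membrane classes sum to 20 pmol/µg
  (= 20 nmol/mg) wet weight by default. Cardiolipin and monolyso-cardiolipin
  use even-DB grids (the mammalian CL pool is dominated by tetra-18:1/18:2
  combinations) and GM3 an (x:1) grid (d18:1 base with predominantly
  saturated fatty acids). Besides realism, these grids leave the
  sodiated-PC family as the only systematic monoisotopic-level isobar, which
  is the interference structure the correction stages are built for.
* **Ionization.** Each class carries its quantification adduct (negative mode
  for glycerophospholipids, Cer/HexCer/Sulf/GM3, [M−2H]²⁻ for CL; positive
  mode [M+H]⁺ for SM and [M+NH4]⁺ for DG/TG/CE). Choline lipids additionally
  ionize as [M+H]⁺ and [M+Na]⁺ (default sodiation fraction f_Na = 0.10, the
  level reached with 0.3 mM ammonium chloride additive) in positive mode and
  as [M+Cl]⁻ (fraction 0.5) in negative mode. Response factors default to 1
  per class; they cancel in ratio-to-standard quantification by design.
* **Signal.** Intensities are `pmol × 10⁴ counts/pmol`, perturbed by
  mean-preserving multiplicative log-normal noise (CV 5% default — the
  reproducibility scale of replicate LMD spots), distributed over the fine
  isotope envelope (4 isotopologues), shifted by a per-ion Gaussian mass error
  (0.5 ppm SD — sub-ppm calibration, comfortably inside the 2 ppm matching
  gate), windowed to m/z 400–1300 and cut at a floor of 20 counts
  (≈ 2 fmol).
* **Centroid coalescence.** Peaks closer than the local FWHM are peak-picked
  as a Gaussian mixture: each local maximum becomes one centroid carrying the
  summed area of its nearest components. A dominated neighbour therefore
  shifts the apex slightly (the realistic case — matching survives within
  2 ppm and the correction stage removes the bias), while near-equal peaks
  within ~2σ genuinely collapse to one centroid between them, exactly as a
  profile-mode peak picker behaves.
* **Degradation channel.** A fraction δ of each diacyl glycerophospholipid is
  rerouted half to its lyso class (round(C/2) carbons, DB//2 double bonds)
  and half to PA(C:DB); total pmol is conserved. Internal standards are added
  after this step, as they are spiked with the extraction solvent after
  ablation.

What the generator does **not** emulate: chromatography or acquisition-time
structure, profile-mode peak shapes (only their centroid-level consequences),
electronic/chemical noise peaks, cross-class response differences, in-source
fragmentation, and ion statistics at very low counts. Passing tests therefore
demonstrate the correctness of the computational pipeline under a faithful
interference model — not robustness to every artefact of real spectra.

## Corrections

Corrections run in a fixed order on matched monoisotopic intensities:

1. **Type I**: divide by the ion's monoisotopic envelope fraction
   (0.9893^nC · 0.7576^nCl), which restores species-total intensities and
   makes species of different carbon number comparable.
2. **Type II**: in ascending-m/z order, subtract from each monoisotopic peak
   the predicted heavy isotopologues of every lighter matched ion that
   coalesced with it. Ascending order makes the cascade exact: a
   contaminator's monoisotopic peak always lies below its isotopologues, so it
   is fully corrected before it is used. (Stated on the homolog family, this
   is the familiar rule that (C:DB+1) contaminates (C:DB) — the more
   unsaturated species is corrected first; the same cascade also removes a
   singly charged ion's A1 sitting on a cardiolipin [M−2H]²⁻ monoisotopic
   peak, and zeroes "ghost" matches where an isotopologue of a present species
   falls on an absent candidate's position.) When the original peak lists are
   available, coalescence is decided by the data: an isotopologue belongs to a
   target peak iff the observed centroid nearest to its theoretical position
   is the target's matched peak — this also captures chains of coalescence
   that a pairwise FWHM test misses. Without peak lists the pairwise test is
   the fallback.
3. **Sodiation estimate**: f̂_Na is the median of I([M+Na]⁺)/I([M+H]⁺) over
   interference-free PC species. Interference-free means the chloride-adduct
   profile of the same sample shows neither the species whose protonated ion
   would sit on the sodiated peak (x+2:y+3) nor the species whose sodiated ion
   would sit on the protonated peak (x−2:y−3) above 1% of the species' own
   chloride signal. A missing sodiated match counts as a zero ratio only when
   the protonated peak is ≥ 20× the weakest matched positive-mode peak — i.e.
   when a percent-level sodiated peak could not have been floor-censored;
   weaker species are skipped. Without usable species the estimator falls
   back to a configured default (0.10) with a warning. The median is used for
   robustness against residual interference; a full algebraic deconvolution
   is out of scope, and on simulated data the cascade subtraction achieves
   the same correction.
4. **Na-overlap correction**: iterating choline-lipid species in ascending
   mass, f̂_Na times the already-corrected protonated intensity of PC(x:y),
   rescaled by the sodiated/protonated ions' monoisotopic-fraction ratio
   (≈ 1.02 for the two-carbon difference — included so the noiseless cascade
   is exact), is subtracted at the [PC(x+2:y+3)+H]⁺ position whenever the two
   theoretical positions fall within one FWHM. The correction is a switchable
   stage (`na_correction=False` disables it), since PC can equally be
   quantified from the chloride adduct in negative mode, where the overlap
   does not enter; `positive_pc_registry()` provides the positive-mode
   quantification variant in which the correction matters.

Any subtraction that would drive an intensity negative clips to zero and sets
a flag rather than propagating negative signal.

## Quantification and normalization

`amount = I/I_std × pmol_std` per class, one standard per class, sphingolipid
classes against their own class standard; no cross-class response modelling.
A class with a missing or zero standard is marked unquantifiable for that
sample and its species flagged; other classes are unaffected. mol% is taken
over the membrane denominator (all classes except DG/TG/CE, which are
reported relative to the membrane total); pmol/µg equals nmol/mg, so the
wet-weight-normalized output is a direct ratio. The internal-standard
species/amounts shipped in `data/standards.yaml` are editable defaults
(odd-carbon or otherwise off-grid species, 1–10 pmol per sample), not
reference values.

## QC statistics

CV% uses the sample SD (n−1); eligibility is CV ≤ 30, with CV ≤ 20 reported
as the good-to-excellent band. CVs are computed on mol% by default
(configurable — the amount scale gives slightly larger CVs because standard
noise does not cancel). Linearity regressions keep a free intercept
(`fit_intercept=False` forces the origin) and report R² per species and for
the membrane total, eligibility R² > 0.7. A species counts as quantifiable at
an area level when it is above the floor in at least half of the replicates
there.

## Spatial analysis

ROI replicates (successive sections) are clustered individually rather than
averaged, so the dendrogram displays section-to-section reproducibility
alongside regional structure. The matrix is z-scored per species (ddof = 1;
zero-variance columns dropped with a warning), distances are Euclidean,
linkage is Ward; scipy's deterministic merge ordering (ties resolved by
original observation order) makes results reproducible for a given input
order, and the partition is row-order invariant. Dendrograms export to Newick
via scikit-bio; heatmaps reuse the computed linkage through seaborn. ROI
geometry travels as centroids (polygons optional); map export needs only
centroids.

The default ROI panel mirrors a hippocampus-style design: 11 ROIs of
50,000–130,000 µm² over six anatomical layers, three successive-section
replicates each. Region profiles share one species backbone and differ by
log-normal per-species factors (σ = 0.6), so clustering has true structure to
recover; in the noiseless limit the cut at the number of true profiles
reproduces the region partition exactly.

## Problem sizes and determinism

The reference computations use 20-seed medians for the stochastic quantities
(area-series R² at CV 5%/4%, sodiation recovery at CV 5%), a 24-spot area
series per seed, and single 30,000 µm² spots for the estimator — sizes at
which the reported medians are stable to well inside their acceptance bands.
All randomness flows through numpy Generators seeded explicitly; identical
seeds give byte-identical peak lists.

## Known limitations

* Sum-composition annotation only; no MS2/MS3 fragment prediction and no
  resolution of fatty-acyl isomers beyond the merged-entry convention.
* Ambiguity resolution at matching is nearest-|ppm| with flags, a declared
  convention rather than a reconstruction of any particular software's rule.
* Two near-equal-intensity ions closer than ~2σ of the peak width genuinely
  coalesce; no correction can split a single centroid without envelope-level
  deconvolution, which is out of scope.
* The chloride-guided sodiation estimator needs at least a handful of
  interference-free PC species; heavily congested PC profiles fall back to
  the configured default.
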