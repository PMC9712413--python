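# Methods

This note records the model implemented by `ramapeak`, the defaults and
why they were chosen, the numerical choices, and the limitations. It is
written so that every number in the package can be traced to a stated
reason.

## 1. Physical picture

A conformationally arrested sample freezes each molecule in one backbone
conformation. Backbone chemical shifts (amide H, amide N, Cα, Cβ) depend
on the local dihedral angles (φ, ψ), so the residue's 4D cross-peak is
the shift-space image of the conformational ensemble: a heterogeneously
broadened intensity distribution `I(δ_H, δ_N, δ_Cα, δ_Cβ)`. The task is
the inverse map — from the peak back to a probability distribution over
(φ, ψ) — plus scalar scores that make heterogeneity comparable across
residues and samples.

Two independent branches solve the inverse problem; their agreement on
synthetic ground truth is the package's main internal consistency check.

## 2. Prediction branch

**Grid sampling.** The peak is sampled on a regular chemical-shift
lattice anchored at the peak maximum, default spacings
(0.4, 1.5, 1.0, 1.5) ppm in (H, N, Cα, Cβ) order, keeping points whose
multilinearly interpolated intensity reaches 20 % of the maximum. The
spacings are of the order of the homogeneous linewidths, so the lattice
resolves the heterogeneous structure without oversampling noise; the
20 % threshold excludes the noise floor and the far Gaussian tails.
Lattice points beyond an axis edge are clipped to the edge (the axes are
expected to generously bracket the peak; clipping only guards the
boundary lattice step). Negative interpolated intensities (noise) are
clipped to zero.

**Shift translation.** A shift→angle predictor needs shifts for a
stretch of residues, but the conformer-resolved shifts of the neighbors
are unobservable — there is no way to tell which part of a neighbor's
(equally broadened) peak belongs to the same conformer. Pinning
neighbors at their peak maxima would bias every prediction toward the
majority conformation. Instead, the residue of interest (ROI) keeps the
grid point's shifts verbatim, and its secondary-shift deviation

    r = (grid-point shifts) − (neighbor-corrected random-coil shifts of the ROI)

is propagated onto the j±1 and j±2 neighbors on top of *their*
neighbor-corrected random-coil values, rescaled per nucleus by the ratio
of helix−extended center-of-gravity spans,
`span(neighbor type) / span(ROI type)` — the assumption being that
within one molecule the neighbors share the ROI's local secondary
structure, and the span ratio converts the ROI's deviation into the
neighbor's expected deviation for the same structure. Nuclei a neighbor
type lacks (glycine Cβ, proline amide H) stay at random coil (factor 0);
a vanishing ROI span raises `DegenerateSpanError` rather than dividing
by ~0. Residues beyond ±2 and optional terminal padding (default one
glycine per terminus) sit at plain neighbor-corrected random-coil
values. Output is a TALOS-style `.tab` shift table per grid point.

**Aggregation (map formula).** Each grid point i yields an 18×18
probability grid `D_ki` over 20° (φ, ψ) bins; the ensemble map is the
intensity-weighted sum

    D_k = Σ_i D_ki · I_i ,

normalized to unit mass. This is linear in the maps and invariant under
overall intensity rescaling — both properties are tested.

## 3. Database branch

Entries of a shift/structure database (per-residue shift quadruple,
known φ/ψ, secondary-structure class from a 7-letter assignment
alphabet, and a per-protein quality flag) are: (i) quality-filtered;
(ii) class-simplified (H/G/I→helix, E→extended, T/B/b→other, C→coil);
(iii) selected if their interpolated peak intensity reaches the same
20 % threshold — coil entries are excluded by default because their
shifts reflect conformational averaging in solution, which does not
occur in a rigidified sample; (iv) weighted by

    w_i = I_i / P_i ,

with `P_i` the local density of database entries at entry i in 4D shift
space; and (v) histogrammed on the same 18×18 angular lattice. The
`1/P_i` factor removes database-coverage bias: duplicating every entry
k-fold leaves the reconstructed map *exactly* unchanged (the
self-inclusive kernel density estimate scales by k, the counts scale by
k; this exact invariance is an acceptance test).

`P_i` defaults to a product-Gaussian KDE with per-nucleus bandwidths
equal to the grid-sampling spacings (the scale on which the peak is
resolved), evaluated self-inclusively at each selected entry; a
k-nearest-neighbor estimate (k = √n) is available as a cross-check. By
default the density is estimated from the entries inside the envelope
(`density_scope="envelope"`): the quantity being corrected is the
sampling bias *within* the selection; a switch to all quality-filtered
entries is provided. Fewer than 20 selected entries triggers a
low-confidence warning rather than an error.

## 4. Folding and binning

Maps live on 20° bins with centers at −180° + 20°·j (j = 0…17) per
angle. **This bin-center convention is a deliberate package choice**: a
lattice containing both −180° and 0° is closed under the point
reflection (φ, ψ) → (−φ, −ψ) mod 360°, so folding — merging the
sparsely populated left-handed-helical half-plane φ > 0 into its mirror
image — maps bin centers onto bin centers and yields exactly 10 φ
columns (−180°…0°) × 18 ψ rows = 180 folded bins, with the φ = −180°
and φ = 0° columns self-paired. A convention centered at ±170° would
pair 18 columns into 9, not 10, and thus not match the 10/18/180 bin
counts used by the scores. Folding conserves probability mass to
machine precision (tested).

## 5. Scores

On the folded, normalized map D (bins k):

* **Circular variance** per angle: `V = 1 − |Σ_k D_k e^{iθ_k}|` with
  θ_k the marginal's bin centers. After folding, φ spans only a 180°
  period; both the verbatim convention (`"raw"`, default) and the
  axial-data convention (`"doubled"`, θ→2θ) are implemented, and every
  score record names the convention used. Closed forms used as test
  oracles: delta → 0; uniform ψ → 1; uniform folded φ (raw) →
  `1 − sin 100° / (10 sin 10°) ≈ 0.433`; uniform folded φ (doubled) →
  0.9 exactly.
* **Entropies** (nats): `S = −Σ_k D_k ln D_k` on the 180-bin map and on
  the 10-bin φ and 18-bin ψ marginals, with 0·ln 0 := 0. Maxima ln 10 ≈
  2.30, ln 18 ≈ 2.89, ln 180 ≈ 5.19. **Excess entropy** `ΔS = S − S_ref`
  against a confined-helix reference map or an explicit `S_ref`; with a
  3.17-nat reference the maximal possible excess is 2.02.
* **Flatness** from the highest-probability bin's relative abundance
  `max(D)/ΣD`. Whether "flatness" denotes that peak fraction or its
  complement is genuinely ambiguous in common usage, so both are
  computed and stored; the reported `F` defaults to the complement
  (larger = flatter) and the record names the convention.
* **Region ratio** `R = max(H, E)/min(H, E) ≥ 1` over rectangular
  helical (φ ∈ [−120, −40], ψ ∈ [−70, 10]) and extended
  (φ ∈ [−180, −80], ψ ∈ [100, 180]) bin-center masks — deliberately
  conservative rectangles, user-replaceable, required to be disjoint. A
  zero minor-region mass flags R as infinite instead of raising.

## 6. Synthetic test bed and its calibration

The closed loop needs a generator whose ground truth the pipeline can
actually recover *for the right reasons*, under study conditions
resembling a strongly heterogeneous peak (a near-continuum spanning
several ppm in the heavy-atom dimensions).

**Forward model.** Simplified classes map to shift centroids with the
canonical anti-correlated Cα/Cβ secondary-shift pattern (helix: high
Cα / low Cβ; extended: the reverse — enforced by a validator), modal
angles (−63, −42), (−135, 140), (−80, 60), homogeneous linewidths
(0.5, 0.3, 0.5, 0.5) ppm FWHM for H/N/Cα/Cβ as expected under fast
magic-angle spinning at a high field, and a 12° angular scatter within a
class.

**Why not two Gaussian blobs.** In 4D, more than half of a Gaussian's
intensity integral lies below 20 % of its own maximum
(`P(χ²₄ ≤ 2 ln 5) ≈ 0.48`), so a 20 % threshold applied to a mixture of
two compact 4D Gaussians clips the minor class's volume
disproportionately and biases any population estimate *by
construction* — verified both analytically and numerically during
development. A realistic strongly heterogeneous peak is not two blobs
but a plateau-like continuum per class.

**Conformer clouds.** `class_cloud_ensemble` therefore models each
class as a cell-centered regular grid of `n_per_dim⁴` (default 6⁴)
narrow sub-conformer Gaussians spanning centroid ± half-widths, each of
width 0.55 × grid spacing — a soft-edged plateau carrying the class
population. Default half-widths (0.7, 2.2, 1.8, 2.0) ppm for H/N/Cα/Cβ
were chosen so the composite two-class peak spans roughly 8 ppm in the
carbon and nitrogen dimensions and about 2 ppm in H at the 20 % level —
the regime the method targets, in which H/N widths are dominated by
class-independent broadening. These defaults were fixed from that
physical reasoning and not revisited afterwards; with them both
branches recover helix fractions 0.3/0.5/0.7 within ≈3 % relative
error.

**Mock database and predictor.** The mock database draws classes from a
stated composition (independent of the peak under test), shifts from the
class centroid + scatter, and angles from wrapped normals around the
class mode; coil entries sit at the centroid average with broad angular
scatter, and quality-flag failures are mixed in. The mock predictor
computes Gaussian class posteriors of the shift quadruple under the
forward model (flat prior, plus a constant-likelihood background
component so shift combinations far from every centroid tend toward a
uniform map) and returns the posterior-weighted mixture of wrapped
angular kernels. Both are desk-scale stand-ins wired to the same
forward model — which is exactly what a closed loop requires, and also
their main limitation (Section 8).

**Problem sizes** (mock database of 4000 entries, ~2600-conformer
clouds, 20×24×24×24 spectra) are package choices made for seconds-scale
runtimes on one CPU, not physical constants.

## 7. Numerical choices

* Multilinear (separable piecewise-linear) interpolation on the ppm
  lattice, exact on multilinear fields (tested against that closed
  form); descending-ppm axes are flipped internally.
* Peak simulation sums separable per-nucleus Gaussian factors via a
  chunked `einsum`, keeping memory flat and simulating ~2600-conformer
  ensembles in about one second; it matches a dense direct evaluation to
  1e−10 relative (tested).
* The KDE normalization is `Σ_j exp(−½‖(x_i − x_j)/bw‖²) / (n · Π bw ·
  (2π)²)` — a proper 4D density (ppm⁻⁴), self-inclusive (j = i
  included), which is what makes duplication invariance exact.
* All stochastic generators take explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  outputs, including the acceptance report.
* Entropy treats empty bins as contributing zero; densities are
  validated to be non-negative and unit-sum before scoring.

## 8. Open design decisions and limitations

* **Reference tables are approximate.** The shipped random-coil,
  neighbor-correction, and center-of-gravity CSVs carry standard
  textbook-level values with provenance headers marking them
  approximate; production use should substitute published
  neighbor-corrected random-coil and conformation-specific
  center-of-gravity tables via the documented schemas. Numerical tests
  construct their own tables and do not depend on the shipped values.
* **The closed loop shares the forward model.** Mock predictor and mock
  database are generated from the same class centroids as the synthetic
  peaks; recovery therefore validates the pipeline's bookkeeping,
  weighting, and bias-correction logic, not the real-world accuracy of
  any external predictor or database.
* **Flatness and φ-period conventions** are configurable because the
  community usage is ambiguous; every output records the conventions
  used.
* **Region masks** are coarse rectangles on bin centers; polygonal
  basins would be more faithful and can be supplied as custom masks.
* **Single-residue scope.** The package analyzes one ROI peak at a
  time; cross-residue consistency (e.g. joint analysis of overlapping
  fragments) is out of scope.
* **NMRPipe support is minimal**: single-file 4D frequency-domain
  hypercubes with the documented header fields only; the portable HDF5
  container is the primary interchange format.
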