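# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `atriascar`. It is the authoritative account of *why* the
package computes what it computes; the README shows *how* to run it.

## Measurement model

A subject's LA endocardium is represented once, as a closed triangle mesh in
world millimetres, and shared by all of that subject's LGE acquisitions
("identical shell" design): per-face comparisons between acquisitions are
then meaningful without any surface correspondence problem. Each
acquisition is a 3D scalar volume with voxel spacing and an index→world
affine; all geometry (projection rays, registration, ICP) is done in world
mm, voxel indices are 0-based.

### Projection

For each face, SI samples are taken along the outward unit normal at the
face centroid, from 1 mm inside to 3 mm beyond the surface at 0.5 mm steps
(9 samples), trilinearly interpolated. The per-face value is the sample
maximum (MIP; standard for bright post-ablation scar) or mean (used by the
baseline-fibrosis thresholding variant). Samples falling outside the voxel
grid take a −∞ sentinel so they can never win a maximum and are excluded
from means; a face with no in-grid samples is marked missing (NaN) and is
never designated scar, and missing faces are dropped listwise from
face-by-face panels.

Choices the measurement itself does not pin down, fixed here: ray origin at
the face centroid (not vertices), direction the face normal (no averaging),
step 0.5 mm. A slab/band sampler (all voxels within the −1..+3 mm offset
band of each face) was considered and not implemented: at these step sizes
the centroid ray approximates the slab maximum well on meshes whose faces
are smaller than the slab width, and a single interrogator keeps the
surface and its tests simple.

### Reference statistics and normalisation

All normalisation denominators come from one reference slice: a 200 mm²
disc in the LA blood pool, a 50 mm² disc in homogeneous septal myocardium,
and a 5 mm² disc on the most intense scar. ROI statistics use the
*population* SD (divide by N) — they describe the voxels actually sampled —
whereas within-subject SDs in reproducibility statistics use the sample
convention (k−1). The best-scar disc is placed by local search: candidate
centres on a half-voxel grid within 8 mm of a user/phantom-supplied hint,
maximising disc mean (operationalising manual "most intense region"
placement). Skew and kurtosis of the reference distributions are
deliberately not corrected; none of the four indexing schemes uses them.

Thresholding designates scar at BP-Z ≥ 3.3 by default. The implementation
normalises internally and compares, so thresholding raw SI at
μ_bp + 3.3·σ_bp and thresholding a BP-Z shell at 3.3 produce identical
masks. The boundary value is included (≥). The baseline-fibrosis variant
(BP-IIR ≥ 0.97 on a mean projection) and arbitrary (method, cutoff) rules
are available.

### Scar metrics

**%LA PAAS** is area-weighted: 100 × scar area / included area, where
included faces are the anatomical LA body — PV ostium stubs, appendage and
mitral-region faces are excluded from the denominator (a face-count variant
is available behind a flag). **Dice** is area-weighted on the common shell;
two empty masks give 1.0 by the identity-of-empty-sets convention, flagged
in output.

**PVE.** The WACA route around a PV pair ({LSPV, LIPV} or {RSPV, RIPV}) is
defined as the minimum-cost closed cycle in the face-adjacency graph of the
peri-ostial band — faces whose graph-geodesic distance from the pair's
ostial rims lies in [3, 15] mm — that is non-contractible around the pair.
Edge cost is the centroid-to-centroid distance, with each face's half
weighted ×1 on scar and ×λ (default 10) off scar, so the route follows
uninterrupted scar wherever it exists and crosses gaps only where it must.

Non-contractibility is enforced with two parity seams, one per ostium: each
seam is a steepest-ascent vertex path of the distance field from that
ostium's rim out beyond the band. A cycle encircling the whole pair crosses
each seam an odd number of times; the minimum such cycle is found as a
shortest path in the four-state parity cover of the band graph (Dijkstra
from faces incident to seam crossings). Requiring odd parity at *both*
seams is essential: the band is topologically a pair of pants (the carina
between the veins belongs to it), and with a single seam the optimal route
can degenerate to a loop around one vein.

Route segments are scored scar/non-scar by the underlying face mask. PVE
and gap lengths are measured along the *ring centreline*: each band face
gets a normalised arc coordinate (azimuth-binned, circularly smoothed band
centroids, rescaled so the ring spans 360 units), and a route face's length
contribution is its arc increment × ring length / 360. This is deliberate:
the optimal route may cross a gap slightly inside the nominal ring, and the
WACA-line share of a gap is its extent along the line, not the length of
the shortcut chord. The published PVE derivation is not public; this
formulation is this package's concrete definition, and equivalence with any
other implementation is not claimed. Gap reporting is morphologically
cleaned at the mesh-edge scale (2 mm): a single-face scar island does not
split a gap and sub-2-mm gaps are not reported, suppressing voxelisation
speckle; PVE itself is always the raw scar-length fraction.

### Registration

Volume-to-volume rigid registration maximises NCC over 6 DOF (intrinsic XYZ
Euler angles in degrees + translation in mm) by Powell search on a
stride-subsampled grid. It is a local method intended for the ~2 mm / <1°
corrections of shell-to-acquisition alignment; a result with NCC < 0.2 is
flagged low-confidence. ICP fusion is classic point-to-point: closest-point
pairing against the fixed shell's vertices alternated with the closed-form
Kabsch fit, until the RMS improvement falls below 1e-6 mm or 50 iterations;
vertices are subsampled to ≤20k with a fixed seed; no outlier trimming
(shells arrive near-aligned). ICP uses geometry only and is therefore
blinded to scar.

### Reproducibility statistics

WCV = sqrt((1/n) Σ s_i²/m_i²) with sample SDs — for ratio-scale measures
under identical acquisition parameters. ICCs follow McGraw–Wong ICC(C,1)
and ICC(A,1) from two-way ANOVA mean squares; negative values are reported,
not clipped. Agreement bands: 0.41–0.60 moderate, 0.61–0.80 good, >0.81
excellent. Note the often-quoted "consistency ≥ agreement" holds only when
both MSR ≥ MSE and the rater mean square exceeds the residual mean square;
with negligible rater offsets the A-1 denominator correction is negative
and A-1 can exceed C-1. The tests assert the exact property. Face-by-face
ICCs treat faces as targets within one subject and are summarised across
subjects by median and IQR. Bland–Altman limits are bias ± 1.96 × sample SD
of paired differences.

## Synthetic phantom

The phantom emulates the study substrate, not cardiac anatomy: an
ellipsoidal LA body (semi-axes 30 × 25 × 22 mm), four cylindrical PV stubs
placed symmetrically on the posterior aspect (radius 5 mm, length 12 mm),
one appendage stub, and a labelled mitral region. The surface is the zero
level set of an approximate signed distance (ellipsoid ∪ capsules)
triangulated by marching cubes (2 mm grid, ~8k faces), so it is closed and
consistently oriented by construction.

The scar band is the set of body faces at 4–10 mm geodesic distance from a
pair's ostial rims — a closed ribbon encircling the pair, including the
carina bridge, as a chronic WACA lesion set appears. Configured gaps are
cut in *normalised ring-arc units* (360 = full centreline length of that
pair's ring), so a gap of extent g interrupts exactly g/360 of the ring's
length and the ground truth `pve_true = (360 − Σgaps)/360` is a length
fraction — on an eccentric ring an azimuth-angle parameterisation would
not be. Overlapping gap arcs are merged with a warning; arcs totalling the
full circle give pve_true = 0.

Voxelisation renders blood pool, a wall-thickness (3 mm) rind, and scar
intensity where the rind's nearest face is scar; a separate 16 mm block of
myocardium-intensity tissue away from the LA stands in for the ventricular
septum so septal reference ROIs can be taken exactly as from a real
reference slice (the phantom has no aorta; ROI centres are exposed in
metadata, ROI areas honour the 200/50/5 mm² protocol). Default voxel size
is 0.94 × 0.94 × 2 mm — the reconstructed voxel of the emulated 3D LGE
protocol (acquired 1.3 × 1.3 × 4 mm). Additive white Gaussian noise,
seeded; Rician physics, motion and navigator artefacts are out of scope.

Default intensities (arbitrary SI): blood pool 100, nulled wall 80, scar
150, background 30, noise SD 10 — placing scar at +5 blood-pool SDs and
wall at −2, i.e. a well-nulled acquisition with clearly separable scar, as
at 20–30 min post contrast. Acquisition arms re-render the same subject:
`repro` redraws noise; `half_gad` halves contrast enhancement (blood pool
over background, scar over blood pool); `half_slice` halves the z voxel at
fixed coverage; `contrast_time` applies scar-contrast growth factors
0.55 / 0.85 / 1.0 for 10/20/30-minute equivalents — monotone stand-ins for
gadolinium washout kinetics, not a fitted model. Per-acquisition seeds are
namespaced from the subject seed so deleting one acquisition never shifts
another's noise.

What passing on this phantom does **not** show: robustness to real LA
anatomy (wall-thickness variation, appendage trabeculation, adjacent
enhancing structures such as the aorta), to registration error between MRA
segmentation and LGE, or to non-Gaussian noise. The phantom validates the
measurement chain's correctness, not its clinical accuracy.

## Numerical choices and degenerate inputs

- Geodesics are shortest paths on the mesh edge graph; accurate to a
  fraction of the ~2 mm edge length, well inside every band tolerance.
- The ring centreline uses 2° azimuth bins and a 9-bin circular moving
  average; unsmoothed bin centroids jitter radially across the band's width
  and would inflate the centreline length severely.
- Rotations are intrinsic XYZ Euler angles in degrees (documented to avoid
  convention drift); transform files store tx ty tz rx ry rz.
- Constant volumes are rejected by registration ("no intensity structure");
  zero-variance ROIs warn and zero SDs make z-score normalisation an error
  naming the method; degenerate (zero-variance) ICC panels are an error.
- On noise-free phantoms the blood-pool SD is exactly zero, so validation
  of area recovery thresholds raw SI midway between blood-pool and scar
  intensities instead of using the (undefined) z-score rule.
- Scar-width calibration for a target area fraction uses secant iteration
  on the near-linear width→fraction map; the recovered truth is always the
  spec's own exact ground truth, so the calibration need only be close.

## Known limitations

- PVE gap borders erode by roughly one voxel per side through partial-volume
  blending in the projection (a gap's measured length is biased long by
  ~1–2 mm); visible as ±1–2 point PVE error at 1 mm voxels.
- The min-cost route is exact for the stated cost, but the cost itself is a
  model; very wide gaps (>180 units) make the "route" mostly a penalised
  geodesic and PVE correspondingly less meaningful.
- The NCC registration has no multi-resolution pyramid and will not recover
  large misalignments; supply an initial transform or use ICP on shells.
- Face-level ICC panels assume the identical shell; there is no surface
  correspondence machinery for shells segmented independently.
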