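# Methods

## System model

A system is a per-particle topology table (lipid id, species, chain role,
bead name, mass, head flag) joined to frames of coordinates in nm with an
orthorhombic box. The bilayer normal is the z axis; coordinates are wrapped
in x–y and unwrapped (monotone) in z. Analyses that need contiguous chains
(directors, tail centers of mass) undo lateral wrapping per chain by
minimum image relative to the first bead.

Species follow the CER NS C24 / CHOL / FFA C24 ternary system. Headgroup
beads in the coarse-grained representation are MHEAD2, AMIDE, OH1, OH2
(CER NS), HEAD (FFA) and CHEAD (CHOL); every other bead is a chain (tail)
bead. CER NS carries an acyl and a sphingosine chain, counted separately in
all tail-level analyses.

### Leaflet detection

The head-bead centroid z of every lipid is histogrammed (0.1 nm bins),
smoothed with a 3-bin moving average, and the n_leaflets tallest local
maxima — greedily selected with a 0.5 nm minimum separation so that a head
plane split by lateral thickness domains still counts once — are the
leaflet head planes. Basin boundaries between adjacent peaks sit at the
midpoint of the minimal plateau of the smoothed histogram (the
inter-leaflet gap has zero head density, so this cut is deterministic).
Leaflets are numbered bottom-to-top; consecutive pairs form bilayers and
the middle pair by mean z is the central bilayer.

A CER chain belongs to the leaflet containing its terminal (chain-end)
bead; one-chain lipids belong to the leaflet of their head centroid. A CER
is **extended** when its two termini fall in different leaflets and
**hairpin** otherwise. Terminal beads were chosen over whole-chain
centroids because an extended ceramide is defined by where its chains end,
and the choice makes classification exact on constructed configurations;
chains whose termini sit within ~0.5 nm of a basin boundary are the only
ambiguous cases.

## Local structure

Thickness and composition are evaluated on a G×G grid (default 50) across
the x–y plane. At each grid point the lipids with center of mass within a
**circular** periodic neighborhood of radius 0.8 nm are isolated (a square
window would overweight diagonals). Local thickness is the separation of
the two head-bead mass-density peaks (0.1 nm z-bins) flanking the
central-bilayer midplane; the search for each peak is restricted to the
central leaflet's own watershed basin and takes the dominant maximum there,
so stray single beads cannot masquerade as head planes, and each peak
position is refined by the mass-weighted centroid of the argmax bin and its
two neighbors (sub-bin accuracy independent of bin-grid alignment).
Head beads only are histogrammed: the peaks being measured are headgroup
planes, and tail density between them would only blur the maxima.

Composition counts central-bilayer tails (by tail center of mass,
conformer-agnostic) within the same neighborhood and reports the four
tail-type fractions, which sum to 1 at every valid point. Grid points with
fewer than 3 contributors or without two detectable peaks are masked (two
peaks cannot be estimated from fewer lipids). Pooled histograms use 0.05 nm
(thickness) and 0.01 (fraction-deviation) bins.

Correlations between local thickness and each tail fraction use
scipy's Pearson r and Spearman ρ (average ranks for ties); zero-variance
inputs return a flagged null. Domain identification fits a 2-component
full-covariance Gaussian mixture by EM on the joint standardized
(thickness, 4 fractions) vector — a single labeling per grid point is
needed for domain-composition tables, which per-type 2-D fits would not
give — with 10 restarts at a fixed seed (EM is initialization-sensitive);
components are relabeled so "larger" has the greater mean thickness, and a
mean-thickness gap below 0.1 nm is flagged as no separation.

## Neighbor statistics

Tails are classified into six classes (extended/hairpin CER acyl and
sphingosine, CHOL, FFA; 21 unordered pairs). Each tail's k nearest other
tails by full 3-D minimum-image center-of-mass distance are found with a
vectorized distance matrix; exact ties break by particle index. k = 6,
except 7 for CHOL queries (CHOL has ~7 lateral neighbors on average).
No leaflet restriction is applied: z-separation naturally suppresses
cross-leaflet pairs.

Counting is **directed**: every query→neighbor relation increments its
unordered pair bin. Observed relative frequencies are divided by the
perfect-mixing null, weight NᵢNⱼ for unlike and N(N−1)/2 for like pairs
normalized over the 21 pairs. The factor 2 between directed counts and
unordered-pair weights cancels in this ratio. One approximation is
deliberate and documented: the null ignores the unequal k of CHOL, so in a
perfectly mixed system pairs involving CHOL sit above 1 by the analytic
factors (13/12)/c̄ (cross) and (7/6)/c̄ (self) with c̄ = 1 + N_CHOL/(6N),
while all other pairs sit at 1/c̄ ≈ 0.98; the grand mean over the 21 pairs
remains 1. The test suite asserts these factors rather than hiding them.

Coordination numbers divide the mean count of type-j neighbors of a type-i
tail by k·N′ⱼ/(N−1) with N′ⱼ = Nⱼ − δᵢⱼ; they rank pair preferences
consistently with the normalized pair counts.

## Thermotropic metrics

* **S2**: per chain, the director u is the dominant principal axis of a
  12-carbon section (carbons 4–15 from the head-proximal end, clamped with
  a warning for shorter chains) — a principal axis is robust to mid-chain
  kinks where an end-to-end vector is not, and the section avoids the
  headgroup-adjacent and interdigitated chain ends. S2 is the largest
  eigenvalue of Q = ⟨(3uuᵀ−I)/2⟩, computed per chain class per inner
  leaflet and averaged. Bands: ≥0.8 ordered, 0.3–0.8 fluid, <0.3 isotropic.
* **S_CH** = ½⟨3cos²θ−1⟩ over both hydrogens of each CH₂ against z,
  bounded by −0.5 (perpendicular) and 1 (parallel). For bead models without
  hydrogens, a pseudo-hydrogen construction places two H per interior
  carbon perpendicular to the local chain axis (C_{k+1}−C_{k−1}) at the
  tetrahedral half-angle, |C–H| = 0.109 nm.
* **NLA** = (n_acyl + n_sph + n_FFA + 1.9·n_CHOL)/(Lx·Ly) per leaflet,
  averaged over the central bilayer. Both NLA (nm⁻²) and its reciprocal
  (area per weighted tail, nm²) are reported, since "lipid area" trends are
  quoted in both conventions.
* **Membrane thickness**: water mass-density profile along z (0.1 nm bins);
  bulk density is the mean over the outermost 0.5 nm of each slab; each
  inner interface is the half-bulk crossing found by scanning outward from
  the dry membrane region (the longest zero-density run) and interpolating
  linearly — scanning from the membrane side makes the crossing immune to
  density fluctuations deep inside the slab. Water on one side only is an
  error.

Temperature series are block-averaged in half-open [T, T+5) °C windows.
Two-regime fits are continuous two-segment linear least squares with the
breakpoint searched exhaustively over midpoints between consecutive blocks
(≥3 blocks per segment); a fit whose SSE improvement over a single line is
below 5 % — or whose single line is already at numerical zero SSE — is
flagged "no transition".

## Scattering

Spacing = 2π/q; repeat distance d = 2πn/qₙ. Peaks are fit as Pearson VII
profiles A[1+((q−q₀)/w)²(2^{1/m}−1)]^{−m} + constant background — w is the
half-width at half maximum and m the shape exponent (m = 1 Lorentzian,
m→∞ Gaussian) — by bounded least squares (ftol 1e-10, m ≥ 0.51). Phase
assignment generates candidate d values from every (peak, order ≤ 4)
combination, keeps candidates whose first order lies on an observed peak
and which match ≥2 orders within 0.02 nm⁻¹, refines d by least squares over
matched orders, deduplicates by member set, and reports greedily by
explained-peak count then SSE; peaks may be shared between phases
(overlapping diffraction orders), and unmatched peaks are listed as
unknown-phase spacings. Requiring an observed first order is what keeps a
2d "super-period" from being invented for every lamellar series while
still allowing a genuine long period that shares its even orders with a
shorter phase. Reported d is rounded to 0.1 nm.

Note on printed precision: spacings recomputed from rounded q values
reproduce published one-decimal spacings only where rounding is benign
(2π/1.08 = 5.8; 2π/0.63 and 2π/1.8 give 9.97 and 3.49).

## Synthetic data

The generator emulates self-assembled three-bilayer stacks: 2000 lipids at
a chosen molar ratio, six leaflets, ~0.20 nm² per chain on a jittered
triangular lattice (~10×10 nm in plane), head beads at leaflet head planes
(base bilayer thickness 5.4 nm, inter-bilayer head gap 0.8 nm), straight
bead chains (0.47 nm spacing; atomistic-style 0.127 nm carbon rise behind a
resolution switch), flanking water slabs at bulk density (40 waters per
lipid, 4 per CG bead), and 35 % of interior-leaflet CERs extended —
outer-leaflet CERs face water and are always hairpin. Hairpin chains occupy
adjacent lattice sites; an extended sphingosine chain enters the adjacent
leaflet at native depth (offset by the head gap). Orientational disorder is
a von Mises–Fisher tilt about z with concentration κ, mapped to the
expected S2 by the closed form E[P2] = 1 − 3(coth κ − 1/κ)/κ and inverted
numerically, so sweeps can target S2 trajectories; the default hinge model
holds S2 ≈ 0.91 below a 65 °C breakpoint and melts at −6×10⁻³/°C above it,
crossing the ordered/fluid boundary near 80 °C, with a matching lateral
area expansion.

Domains are imposed, not emergent: half-plane or disc regions of the
central bilayer carry their own head-plane separation and per-tail-type
sampling weights, realized by weighted sampling without replacement (global
composition stays exact). `table2_like_domains()` is the frozen two-domain
preset (5.16/5.78 nm; CHOL+sphingosine enriched thin side, FFA+acyl
enriched thick side). Everything is deterministic per seed; temperature
sweeps reuse the structural random stream so only tilt disorder and box
area vary across frames.

What the generator does **not** emulate: self-assembly, energetics,
pressure/temperature coupling, chain conformational disorder (beads are
collinear), headgroup chemistry, or emergent domain boundaries. Passing
tests therefore demonstrate that the analysis machinery recovers known
ground truth under realistic geometry and noise — not that it would resolve
the subtler, fluctuation-broadened structure of real trajectories.

## Desk-scale sizes

The test and calibration workloads use: 2000-lipid systems for map and
conformer recovery; a 600-tail, 20-seed mixed bilayer for the mixing-null
calibration; a 420-lipid, 37-frame sweep (35–125 °C in 2.5 °C steps) for
transition recovery; 20-seed Gaussian point clouds for mixture-model
recovery. These sizes give sampling errors comfortably inside the asserted
tolerances while keeping the full suite under a minute of compute.

## Known limitations

* The unequal-k mixing-null approximation above (characterized, not
  corrected).
* Leaflet watershed assumes resolvable head-plane bands; strongly
  interdigitated or undulating membranes would need a curvature-aware
  reference surface.
* Two-regime fits assume exactly one breakpoint; multi-step transitions
  report the dominant hinge.
* The Gaussian-mixture feature space is the joint 5-vector; per-type 2-D
  mixtures are a reasonable alternative the package does not implement.
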