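# Methods

## Lobule geometry and the zonal coordinate

A lobule is idealised as a regular hexagon on the pixel raster: the
central vein at the centre, six portal triads at the vertices (radius
0.48 × the shorter grid dimension, default grid 40 × 40 at 50 μm). Every
pixel inside the hexagon receives the porto-central coordinate

    u = d_vertex / (d_vertex + d_center),

where `d_vertex` is the distance to the nearest portal triad and
`d_center` the distance to the central vein; u = 0 on a portal triad and
u = 1 on the central vein. Zones are u-thresholded: Z1 (periportal)
below t₁, Z2 (midzone) between, Z3 (pericentral) above t₂. The default
thresholds (1/3, 1/2) are the empirical terciles of u over the hexagon,
so the three zones cover comparable areas (within a few percent on grids
from 40² to 120²); equal-width thresholds in u would make Z3 a small
disc around the vein because u is strongly nonlinear in space. Both
thresholds are configuration values.

## Generative model of the synthetic acquisition

Intensity of lipid L in pixel p of mouse m (one polarity mode):

    I(L, p, m) = base_L · profile_L[zone(p)] · g_m · ε(L, p) · t(p)

- `base_L` — per-species abundance (arbitrary units); within each class a
  geometric ladder (factor 1.25 over 7 steps) provides realistic dynamic
  range.
- `profile_L` — zonal profile normalised to mean 1. Differential species
  have a single dominant zone at fold 3 (phospholipid classes) or 4
  (FA, TG, DG, Cer) over the other two zones; flat species are (1,1,1).
- `g_m ~ logN(0, 0.15²)` — mouse random intercept, shared by all lipids
  and both modes of one mouse.
- `ε ~ logN(0, 0.15²)` — per-(pixel, lipid) multiplicative measurement
  noise; `t ~ logN(0, 0.10²)` — per-pixel total-ion-count scale. The
  log-normal form is the natural model for positive intensities whose
  reproducibility is reported as percent CV: 0.15 on the log scale
  corresponds to ≈15% CV per pixel, and ROI medians of 10 pixels come
  out near 3–5% CV across replicate acquisitions, comfortably inside the
  20% acceptance band customary for bioanalytical validation.
- Adduct split: positive mode 0.60/0.25/0.15 for [M+H]⁺/[M+Na]⁺/[M+NH₄]⁺,
  except the neutral glycerolipids TG and DG which cationise as
  0.50/0.45/0.03/0.02 for [M+Na]⁺/[M+NH₄]⁺/[M+H]⁺/[M+K]⁺ (ammonium-rich
  preparation; protonated and potassiated forms minor); negative mode is
  [M−H]⁻ only. The M+0 adduct intensities of a lipid sum exactly to
  I(L, p, m); each adduct additionally carries an M+1 isotopologue at
  0.0107 per carbon. Peak m/z values receive Gaussian jitter with
  SD 2 ppm; spectra are truncated to m/z 100–1,200.
- Seeding: a single seed drives `numpy` `SeedSequence` substreams per
  (mouse, mode) and per ROI draw, so identical configurations reproduce
  byte-identical datasets and stages can be rerun independently.

### The default library

269 sum-composition species over FA, LPL (LPA/LPC/LPE), PA, PC, PE, PG,
PI, PS, DG, TG, Cer and SL (SM); 117 carry non-flat profiles. Formulas
follow the standard constitution of each class, so monoisotopic masses
are always recomputable from the formula. Zonal assignments follow the
known lobule biology: polyunsaturated FAs and most phospholipid classes
periportal; a phosphatidylinositol subset midzone; DG, TG, Cer and most
SMs pericentral; PGs flat. A small PC subset is assigned to the midzone
so that positive mode, like negative mode, has dominant species in all
three zones (see TIC balancing below). Each species is detected in the
single polarity mode canonical for its class (PC/LPC/DG/TG/SM positive;
acids and ethanolamines negative).

Two constructive constraints make the library a clean ground truth:

1. **Peak separation.** Species are admitted greedily only if every
   theoretical peak — simulated adducts, their M+1 isotopologues, *and*
   every adduct mass the annotation stage searches — lies ≥ 25 ppm from
   all previously admitted peaks of the same mode. Without the
   search-space part of this rule, an M+1 feature of one lipid can fall
   within the 10 ppm matching tolerance of another lipid's
   never-simulated [M+K]⁺ mass and be mis-annotated, leaking zonal
   signal into nominally flat species (sodiated/protonated homologs
   offset by 2 carbons and 3 double bonds collide at ~3 ppm, a genuine
   ambiguity of accurate-mass lipidomics). Rejected curated species are
   replaced from per-class fallback pools carrying the same zonal role.
2. **Per-zone TIC balance.** Within each mode the base abundances of the
   three dominant-zone groups are rescaled so the expected pixel TIC
   (isotopologues included) is exactly zone-independent. TIC
   normalisation divides every pixel by its total signal; if zones
   differed in expected total, every flat lipid would inherit an
   artifactual zonal profile and the null distribution of the
   differential test would be badly inflated. Balance also makes the
   noiseless pipeline exact: ROI medians equal base × profile to
   rounding.

## Preprocessing

The generator emits centroided spectra, which go straight to alignment;
moving-average smoothing (window 5), rolling-minimum baseline
subtraction (half-window 50) and SNR-3 peak picking (noise = MAD,
centroid = intensity-weighted mean over the above-half-max window) are
applied per pixel when profile-mode input is declared. Alignment pools
all pixels of one mode across mice, sorts centroids and bins them
single-linkage: a peak joins the current bin while it is within 10 ppm
of the bin's running intensity-weighted mean. The implementation splits
the sorted list at gaps > tolerance (exact, since the running mean never
exceeds the previous centroid) and applies the literal scan only inside
the rare blocks wider than the tolerance. The mass filter keeps
m/z ∈ [100, 1200] inclusive. TIC normalisation rescales each pixel's row
to the mean pre-normalisation TIC (rather than 1, keeping magnitudes
interpretable); zero-TIC pixels (background) are dropped with a warning.
Positive and negative mode are processed separately end to end and meet
only at the lipid level, since consensus m/z are mode-specific.

## Annotation

Each feature is compared against all mode-compatible (lipid, adduct)
pairs within 10 ppm; candidates are ranked by |ppm error|, ties broken
by the isotope score and then lexically. The isotope score compares the
observed M+1/M intensity ratio (the feature nearest m/z + 1.00335 within
tolerance, totalled over pixels) to 0.0107 · nC and is
max(0, 1 − |obs − exp|/exp); a missing M+1 scores 0 and is flagged.
Annotations are reported at sum-composition level — chain-resolved names
are synonyms at accurate-mass evidence. Unannotated features stay in the
matrix but never enter the zonal statistics.

## ROI sampling and quantification

Per mouse and zone, three disjoint 10-pixel 4-connected ROIs are grown
breadth-first from random in-zone seed pixels (pathologist-guided manual
placement is not reproducible; the seeds are recorded). A zone smaller
than 30 eligible pixels raises an explicit error naming the zone. For
each (lipid, ROI), the lipid's rank-1 adduct feature columns are summed
per pixel first — the adduct split is instrumental, not biological —
and the ROI value is the median over its 10 pixels (even count: mean of
the two central order statistics). This yields 45 observations per lipid
(5 mice × 3 zones × 3 ROIs).

## Differential testing

Per lipid, log median intensity is modelled with a mouse random
intercept; the variance ratio λ = var_mouse/var_resid is profiled on
{0} ∪ a 40-point log grid over [10⁻⁴, 10³] with bounded scalar
refinement of the best grid point. For fixed λ the model whitens per
mouse (v → v − θ·mean, θ = 1 − (1 + n_g λ)^(−1/2)) and solves ordinary
least squares, giving the concentrated ML log-likelihood in closed form.
ML (not REML) is used because the zone term is tested by a
likelihood-ratio test between nested fixed-effect structures: χ² = 2Δll
clipped at 0, referred to χ²₂. Zero medians are offset by half the
lipid's smallest positive median before the log (logged). BH step-up
q-values control FDR at α = 0.05. The ML choice has two quantifiable
consequences kept in mind by the tests: the between-mouse variance
estimate carries the (g−1)/g shrinkage (0.8 at five mice), and the LRT
is mildly anticonservative at n = 45 (empirical size ≈ 0.06 at nominal
0.05 — inside the 0.03–0.08 calibration band checked by simulation).
The dominant zone of a lipid is the zone with the largest mean ROI
median across mice; exact ties go to the lower zone index and are
flagged.

## Pathway scoring

Pathways are small undirected graphs over compound and reaction nodes
(a PathBank-style toy fixture of 12 liver-lipid pathways plus decoys is
packaged; any JSON in the same shape can be supplied). Relative node
betweenness is Σ σ_st(v)/σ_st over unordered pairs divided by
(N−1)(N−2)/2, computed per connected component with the component-level
normaliser (components under 3 nodes contribute zeros). A pathway's
score for a hit list is the fraction of total compound-node centrality
carried by hit compounds, in [0, 1]; reaction nodes shape the topology
but are never hits, and a pathway whose compounds all have zero
centrality scores 0 (flagged). Because centrality aggregation to a
pathway score admits several defensible definitions, the hit-mass
fraction was chosen for being bounded, monotone in hits and exactly 1
when every central compound is implicated. Lipids map to class-level
compound identifiers (all TGs → "TG"), matching the species-generic
nodes of curated pathway databases. Over-representation uses the exact
hypergeometric upper tail with the union of all pathway compounds as
background. Ranking is by descending score, ties by ascending ORA p,
then name.

## Problem sizes and defaults

The default study is 5 mice × 2 modes on a 40 × 40 grid (≈970 in-lobule
pixels per section), chosen so the full pipeline — ~4 million simulated
peaks in positive mode — completes in well under a minute while leaving
every zone with hundreds of pixels for ROI placement. The replicate-CV
study simulates three acquisitions of one section (same ground truth,
mouse effect off, fresh measurement noise) and reports per-lipid %CV of
zone-median intensities averaged over zones.

## What the synthetic data does and does not show

The generator reproduces the features that drive the statistics: zonal
abundance structure, between-mouse variation, multiplicative pixel
noise, TIC drift, adduct and isotopologue structure, and ppm-scale mass
error. It deliberately omits profile-mode peak shapes, in-source
fragments, chimeric features, matrix/suppression effects that correlate
with histology, and spatial noise correlation between neighbouring
pixels. Passing tests therefore validate the pipeline's logic and
calibration, not instrument-specific behaviour: on real sections,
zone masks come from histology co-registration (out of scope here), and
annotation ambiguity is worse than the separation-guarded library
allows, so the 100%-recovery results should be read as "the pipeline
adds no errors of its own", not as an expected field performance.

## Known limitations

- The hexagon is a single idealised lobule; real sections tile many
  irregular lobules and the porto-central coordinate is noisier.
- Lipid identity is sum-composition only; isomeric lipids within 10 ppm
  are genuinely unresolvable without MS/MS.
- The mixed model assumes homoscedastic log-normal noise across zones;
  TIC normalisation introduces a small shared denominator that mildly
  inflates the null tail beyond the stats-level calibration (observed
  as a handful of moderate-χ² false discoveries in the default run,
  within the FDR target).
- The pathway fixture is a topological miniature; scores on it
  demonstrate the method, not mouse-liver biology.
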