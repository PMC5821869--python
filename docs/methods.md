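# Methods

## Scope and model

`hepaquant` quantifies stained liver-biopsy fields of view (FOVs) in
four stages — stain unmixing, cell detection and measurement, phenotype
and region classification, and surrogate necroinflammatory scoring —
and ships a synthetic-histology generator that renders FOVs with
complete ground truth so every stage can be validated without patient
material.

### Optical density and stain unmixing

Transmitted brightfield intensity follows Beer–Lambert:
`OD_c = −log₁₀(max(I_c, ε)/I₀)` per RGB channel, with background
intensity `I₀ = 255` for 8-bit scans and floor `ε = I₀/255` so saturated
pixels map to a finite OD (≈2.4) instead of infinity.  ODs of
co-localised stains add, so a pixel's OD vector is modelled as a
non-negative combination of unit stain vectors.  Unmixing solves the
per-pixel least-squares problem with the pseudo-inverse of the stacked
stain matrix and clips negative concentrations to zero; two-stain
systems are solved directly as 3×2 problems rather than inventing a
third residual stain.  Stain systems with condition number above 10⁶
are rejected as degenerate.

Default vectors are the published Ruifrok–Johnston values for
haematoxylin, DAB and eosin.  No published vector was adopted for
Sirius Red; the shipped default is a unit vector estimated from
synthetic pure-stain swatches (a red stain absorbs green and blue) and,
like all vectors, can be overridden by a plain-text stain config
(`name r g b` per line).  Automatic stain-vector estimation from whole
slides (Macenko-style) is out of scope.

### Nuclei segmentation and measurement

Nuclei are segmented from the haematoxylin OD map (brightfield) or the
DAPI channel (fluorescence): threshold → fill holes → minimum-area
filter → distance-transform watershed with deterministic marker
detection (local maxima of the smoothed EDT at a minimum separation of
3 µm).  The default threshold is Rosin's triangle method rather than
Otsu: liver fields mix faint small HPC nuclei with dark ductal nuclei
over a dominant cytoplasm background, and Otsu's two-class criterion
then lands between the nuclear classes, dropping the faint ones; the
triangle threshold tracks the foot of the background peak and detects
both.  Otsu and fixed thresholds remain available
(`SegmentationParams.method` / `od_threshold`).

Per cell we record the centroid (0-based, pixel-centre convention,
x rightward / y downward), nuclear area in px and µm², and the mean of
each stain OD (or channel intensity) over two compartments: the nucleus
mask shrunk by 2 px (avoiding partial-volume boundary pixels, which
otherwise dilute dark-nucleus means by up to ≈0.08 OD) and a 3-px
cytoplasmic ring grown from the nucleus and clipped at neighbouring
cells.  Minimum nuclear area defaults to 10 µm² (debris at 20×).
Fluorescence channels are normalised per channel by their 99.9th
percentile, making thresholds exposure-invariant.

### Phenotyping

Marker positivity is a strict threshold on a single feature, fixed or
data-driven (Otsu, or a two-component 1-D Gaussian mixture cut where
the weighted component densities cross).  Data-driven modes carry a
coefficient-of-variation guard: a near-constant feature distribution is
declared unimodal and all cells negative — protecting marker-free FOVs
from spurious splits at the cost of mislabelling a hypothetical
all-positive FOV, which the batch workflow avoids by fitting one
threshold on the pooled cells of a batch and applying it per FOV.
Counts follow the contract *positive cells as a percentage of total
cells*; double-IF labels partition cells into green⁺/red⁺/double⁺/
negative with double-positives counted in neither single tally.

Ductal vs non-ductal discrimination uses a Fisher linear discriminant
over (nucleus area, nuclear haematoxylin OD, cytoplasmic DAB OD) — the
three features on which ductal cells exceed non-ductal presumptive
HPCs.  The published account reports the three marginal differences
without stating a rule; a joint linear discriminant is the minimal
deterministic model.  Training needs ≥5 exemplars per class; the
direction is oriented so ductal scores higher; the model serialises to
JSON (features, weights, intercept, class means).  FOV-level ductality
is a majority vote of cell calls, ties resolved to portal-like since
the claim is about predominance; an FOV with no positive cells returns
the explicit sentinel `undetermined`.

### Region detection

*Tissue* is total OD above 0.05, closed, with enclosed unstained holes
up to 20 000 µm² filled — so fat vacuoles and necrotic drop-out stay
inside the tissue mask and feature fractions are well defined.

*Necrosis and fat* both read as low haematoxylin OD.  The map is
smoothed (σ = 1 µm), thresholded from below, hole-filled and min-area
filtered (100 µm²).  Three threshold modes exist; the default is
`relative` — 0.5× the median smoothed haematoxylin OD of the tissue —
which is self-calibrating against staining intensity and leaves
feature-free parenchyma empty without needing a bimodality test.  The
guarded-Otsu mode (CV floor 0.35, returning an empty mask on
homogeneous images) and a fixed threshold remain available; guarded
Otsu is the default for collagen, where the high-OD tail is either
clearly present or absent.  Candidates are split geometrically:
connected components with circularity `4πA/P² ≥ 0.7` (Crofton
perimeter) and equivalent diameter 5–100 µm are steatotic vacuoles, the
rest confluent necrosis.  The published pipelines distinguish the two
only by cohort (NAFLD vs hepatitis); the geometric rule makes this
pipeline cohort-agnostic, and both thresholds are configurable.

*Foci* are single-linkage clusters of CD45⁺ centroids at a 30 µm
linking distance; clusters of ≥5 cells are foci, the rest singles.
Single linkage (not density-based clustering) was chosen because it is
order-independent and admits an exact brute-force oracle, used in the
tests.  *Periportal bands* are exact-EDT dilations of the portal mask
(default width 25 µm) minus the mask, clipped to tissue — so narrower
bands are always nested in wider ones.  Portal processing regions are
supplied as annotation masks, mirroring pathologist-marked regions; the
generator provides them as truth.

### Surrogate scoring

Four continuous measures per FOV: piecemeal = CD45⁺ cells/mm² of
periportal band; confluent = necrotic fraction of tissue; lobular =
foci/mm² of lobular tissue (tissue − portal − band); portal = CD45⁺
cells/mm² of portal regions.  Densities are zero when their region is
empty.  Samples aggregate FOV measures as area-weighted means (a plain
mean for equal-size FOVs) before binning.

Each measure maps to an ordinal as the count of thresholds *strictly*
below it — boundary values fall in the lower bin (conservative
scoring) — over Ishak-style ranges 0–4 (piecemeal), 0–6 (confluent),
0–4 (lobular), 0–4 (portal); the composite is the exact integer sum,
0–18.  Four categories are scored; the composite is the hepatic
activity index analogue.  The original mapping from surrogate measures
to ordinals is not public, so thresholds are explicit configuration
(`data/default_bins.yaml`), calibrated once as even partitions of the
synthetic severity ladder's planted measure ranges (severity 0–10:
CD45 densities 25–775 /mm², necrotic fractions 0–0.06, focus densities
0–≈46 /mm² of lobular tissue) and overridable per run.

## Synthetic-data generator

The generator defines the study conditions the package is validated
under.  Defaults emulate a 20× scan: 512×512 px at 0.5 µm/px
(0.066 mm²), ~1500 parenchymal nuclei/mm² placed by a hard-core
(minimum-distance) dart process, one portal tract (60 µm radius disc,
possibly edge-clipped) ringed by ductal cells.  Populations (nuclear
area µm², nuclear haematoxylin OD): hepatocytes 40 / 0.55, HPCs 25 /
0.40, ductal 60 / 0.80, CD45 20 / 0.60, each with ~10% spread.
Cytoplasmic DAB is painted per cell over its territory (nucleus + 6 px,
Voronoi-clipped at neighbours so positive and negative neighbours do
not contaminate each other): negatives 0.10 ± 0.05, HPC⁺ 0.60, ductal⁺
0.70, CD45⁺ 0.65.  Confluent necrosis is an elongated low-OD arc
(gently curving disk chain — a straight-ish walk cannot fold into a
vacuole-like clump; area iteratively scaled to the target fraction,
overlap with portal tracts allowed), fat a set of round vacuoles
(15–40 µm), collagen a set of Sirius-Red random-walk ribbons.  Stain
maps get 1 px Gaussian blur and OD noise (σ = 0.02) inside tissue, then
compose through the stain matrix to 8-bit RGB.  IF scenes draw each
cell's four-way label from a multinomial and paint DAPI/green/red
intensities analogously.

Placement counts are deterministic (`round(density × area)`), so the
severity ladder's planted measures are monotone by construction;
severity `s` adds 75·s CD45 cells/mm², 3·s foci/mm² and 0.006·s
necrotic fraction on top of base rates 25 /mm², 2 /mm² and 0.  All
randomness flows through one seeded generator; identical spec + seed
reproduces truth tables and images bit-for-bit.

What the generator does *not* emulate — and hence what passing tests do
not establish about patient material: stain variability between
laboratories and scanners, chromatin texture and nucleolar structure,
out-of-focus and fixation artefacts, touching-cell clusters denser than
the hard-core process allows, genuinely ambiguous cell phenotypes, and
tissue distortion from sectioning.  Results on synthetic truth bound
the pipeline's algorithmic error, not its robustness to histological
variability.

## Validation designs and problem sizes

The test battery re-runs the package's validation designs on synthetic
truth: 15 IHC FOVs spanning 0–60% positive fraction (percent-positive
r², detection precision/recall); 12 double-IF FOVs (per-channel and
double⁺ r²); 100 labelled exemplars + 16 portal-seeded vs 16
central-seeded FOVs (ductal discrimination); planted necrosis/fat/
collagen scenes (area errors) and a brute-force focus oracle; and
twenty replicates of an 11-sample severity ladder, two FOVs per sample,
scored end to end (Spearman of composite vs severity).  FOVs are
512×512 px except in unit tests, which use 256×256 px where the check
is scale-free.  `scripts/acceptance.py --seed N --out results.json`
re-computes all of it from scratch in a few minutes on one CPU.

## Numerical choices and degenerate inputs

Blank images yield empty cell tables, not errors; empty portal masks
yield empty bands and zero densities; zero-cell FOVs report 0% positive
and `undetermined` ductality.  Boundary measures bin downward.  Ties in
FOV ductality go to portal-like.  Watershed markers derive from a
smoothed EDT with a fixed footprint, making segmentation deterministic;
focus clustering sorts members and foci, making results independent of
cell order.  Scenes that cannot be packed (hard-core retry budget
exhausted) raise a generation error rather than silently thinning.

## Known limitations

* Equivalence to the original proprietary pipeline is functional, not
  numerical: its spectral unmixing parameters, segmentation internals
  and surrogate-to-ordinal mapping are not public.
* Ordinal bins are calibrated to the generator's severity ladder; real
  cohorts need recalibration against pathologist scores.
* Portal regions should be annotated (or taken from generator truth);
  the optional fallback (`infer_portal_regions`, dilated convex hulls
  of ductal-cell clusters) only sees the ductal reaction, not vessels
  or stroma, and is deliberately not part of the scored pipeline.
* Single 2-D FOVs only: no whole-slide tiling, 3-D stacks, >2-marker
  multiplexing, or fibrosis *staging* (the composite covers
  necroinflammatory grading only).
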