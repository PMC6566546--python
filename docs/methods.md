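# Methods

## Problem and pipeline

Five mechanical-damage classes of polished monogerm sugar beet seed are
distinguished by which seed-coat layer the polisher broke through:
(1) partially broken pericarp/outer testa, inner testa intact;
(2) pericarp and outer testa completely broken, intact inner testa
exposed; (3) fractured coat with a partially crushed inner testa, sound
embryo; (4) partially broken coat with a damaged inner testa, embryo
intact; (5) embryo severely damaged or absent. Only class 1 is accepted
for pelleting, so the classifier is deliberately conservative about it.

The pipeline is: 19-band reflectance stacks → seed segmentation →
pixel-level normalized canonical discriminant transform (nCDA) →
19 per-seed variables → factor-analytic scoring → one-dimensional
score-range classification of ventral/dorsal pairs → misclassification
table. Every stage boundary is a file, so stages re-run independently
and bit-reproducibly.

## Pixel discriminant (nCDA)

Training pixels are spectra labelled by tissue role (here from synthetic
ground truth: intact surface = pericarp/outer testa vs damage-exposed =
inner testa/embryo; any labelled mask works). With between- and
within-class scatter `S_B`, `S_W` of centered pixel vectors, the weights
solve `S_B w = λ S_W w` for the largest λ, using
`S_W + 1e-6·tr(S_W)/19·I` for numerical invertibility with strongly
correlated bands. Only the leading direction is kept — one channel
suffices for damage highlighting. "Normalized" is implemented as an
affine map of the 1st/99th percentiles of projected training pixels onto
[0, 1] (percentiles rather than min/max for robustness to outlier
pixels), clipped outside. The sign convention makes damage project high.

The damage threshold stored with the model — used by the binary features
— is the midpoint between the two lowest per-class mean transformed
footprint values of the calibration set, i.e. the boundary between the
least-damaged class and its nearest neighbour: "damaged" means any
surface beyond class-1-typical abrasion. (The alternative midpoint
between the two extreme classes would classify the intact-but-exposed
inner testa of class 2 as undamaged, which contradicts the intended
semantics of the damaged-area fraction.)

## Features (19 variables)

The published variable list is known only as "seed shape, color and
binary features"; the reconstruction here freezes, in one place, a
defensible set in that taxonomy — downstream scoring only requires a
fixed-length informative vector:

* shape (7): area, Crofton perimeter (4 directions; near-unbiased on
  digitized smooth outlines, so a rasterized disc scores circularity
  ≈ 1), major/minor axis lengths, aspect ratio, circularity `4πA/P²`
  (clipped at 1.05), compactness = area / convex-hull area;
* color (9): footprint mean reflectance at 450, 525, 590, 660, 780,
  940 nm, and CIELab L*, a*, b* from broadband pseudo-RGB channels (each
  the mean of three neighbouring visible bands, damping per-band noise)
  under a fixed nominal sRGB/D65 transform — relative, not colorimetric;
* binary (3): interior-hole count of the pre-fill segmentation mask,
  damaged-area fraction (footprint pixels above the damage threshold in
  the transformed image), damaged-patch count (8-connected components of
  that damage mask).

Geometry is computed on the bbox-cropped mask, so features are exactly
translation invariant; area/perimeter scale as s²/s under integer
upscaling within estimator discretization error.

## Scoring and classification

Calibration features are standardized (sample SD, n−1); the correlation
matrix's leading eigenpair (λ₁, v₁) gives scoring coefficients `v₁/√λ₁`,
so calibration scores have variance exactly 1 ("united variance"). The
number of eigenvalues > 1 is reported for diagnostics only; the score is
one-dimensional because the range rule is. The sign is fixed so class 5
scores above class 1.

Per class, the provisional score range is mean ± sample SD; classes are
ordered by ascending mean (ties abort with an error — no defensible
order exists), and each upper class's lower bound is replaced by the
lower class's upper bound, eliminating gaps and overlaps so the five
ranges tile an interval. For classification the outermost bounds act as
±∞ (a reject mode is available behind a flag). Each side maps to the
class whose range contains its score; the seed takes the numerically
larger (more severe) side class. This severity-max rule implements the
stated class-1 conservatism: a seed is called plantable only when both
sides look plantable. It also guarantees — structurally, not just
empirically — that class-1 false positives never exceed those of a
side-averaging rule: if both side scores lie below the class-1 upper
bound, so does their mean.

## Evaluation

Entry (t, p) of the 5×5 table counts seeds of true class t predicted p.
Overall accuracy = 100·trace/n; per-class accuracy = 100·diagonal/row
total (the only definition consistent with the overall formula applied
per class); FN% and FP% divide each class's off-diagonal row/column sum
by the total evaluated seeds. Percentages are carried as exact rationals
(`fractions.Fraction`) so accuracy% + Σ FN% = 100 holds to the digit;
display rounds to one decimal. The published table's three internally
inconsistent cells (class-1 FN, class-4/5 FP, which disagree with their
own row/column sums) are not reproduced; all rates are recomputed from
counts.

## Synthetic data: what it emulates, and what it does not

Each seed side is an ellipse (sieve-graded window, 4.0–4.5 mm equivalent
diameter at 10 px/mm, in a 72×72 px frame) of pericarp in which the
damage exposes deeper tissue as disjoint angular sectors — the sector of
parametric angle 2πf covers exactly the area fraction f, so severity
fractions are honoured exactly. Per class: exposed-area fraction,
crushed-through fraction (exposing embryo, or the collapsed interior
when the embryo is absent), number of damage sectors, fractured-edge
chips and dark fracture pits all grade with severity; severity fractions
get Gaussian jitter (SD 0.01) per side.

Tissue reflectance follows the structure seen in real beet-seed spectra:
very little between-tissue diversity in the visible region and most of
the contrast in the NIR. Concretely, the corky pericarp is relatively
bright in the visible while exposed interior tissues are slightly darker
in the visible but strongly reflective above 700 nm, increasingly so
with damage severity (crushed/collapsed tissue brightens). Two
consequences are deliberate: the band-mean image is nearly uniform
across the seed, which keeps the parameter-free global Otsu segmentation
at ≥ 0.95 Jaccard against truth for every class; and the per-class
footprint-mean NIR ladder (≈ 40/50/60/70/82 % at 940 nm) is roughly
evenly spaced, giving adjacent-class score separations of ≈ 3–10
calibration SDs under the default noise (additive Gaussian, 1 % SD,
band-independent — the simplest defensible model). Varieties carry a
fixed per-band color offset (SD 0.15 %) emulating pericarp-color
differences among varieties; 18 varieties are filled round-robin.

What the generator does **not** emulate: real texture (tissue is
piecewise-constant plus noise), optical effects of the integrating
sphere, touching seeds, within-tissue gradients, or any particular
cultivar's true spectra. Passing tests therefore demonstrate that the
*method* is implemented correctly and behaves as published under the
assumed structure — not that the accuracy figures would transfer to any
particular real seed lot.

## The accuracy ceiling of the range rule

One replication finding deserves emphasis. The range rule places every
class's upper boundary at its own mean + 1 SD. For any roughly unimodal
within-class score distribution, the probability that a side scores
above its class's upper boundary is then ≈ 9–21 % (15.9 % for a
Gaussian) — *independent of how far apart the classes are* — and the
severity-max rule compounds two sides. In the synthetic runs the
class-1/class-2 boundary is ~9 calibration SDs wide, yet class 1 still
loses ~17 % of its seeds one class upward. Overall accuracy therefore
saturates near 78–84 % no matter how separable the spectra are, which is
strikingly consistent with the published 82 % and with the published
table's one-class-up leak pattern. For the same reason accuracy is
nearly flat as synthetic noise grows (the pipeline re-calibrates at each
noise level and footprint averaging suppresses pixel noise), rather than
degrading monotonically. Any future accuracy improvement must change the
boundary placement (e.g. midpoints between adjacent class means), not
the imaging or the features.

## Numerical and design choices

* Scatter-matrix ridge `1e-6·tr/19`; generalized eigenproblem solved by
  `scipy.linalg.eigh`; the fitted direction agrees with the closed-form
  two-class Fisher direction (same regularized scatter, solved linearly)
  to < 1e-6 and with the unregularized formula to < 1e-4.
* Segmentation: Otsu on the band-mean image, 8-connectivity, min_area
  50 px (debris rejection); touching seeds are not separated (seeds are
  imaged singly); coordinates 0-based, boxes half-open.
* Sample SDs use n−1 throughout.
* Score ranges are half-open [low, high); the last class is closed.
* Calibration and validation sets derive from one master seed through
  independent seed-sequence spawns; every output file records the seed.
* Default problem sizes: 60 calibration seeds/class and 40 validation
  seeds/class (200 mixed seeds across 18 varieties), two sides each;
  one full run takes ~20 s and the acceptance script ~3 minutes on a
  single CPU.

## Known limitations

* The 19-variable set is a reconstruction of an unpublished list; the
  order is frozen and models are portable, but real deployments would
  re-derive their own calibration.
* The class-range classifier is one-dimensional by design; classes whose
  factor-1 means tie cannot be ordered and abort.
* Per-variety accuracies on synthetic data reflect the simple constant
  color-shift variety model, not real varietal structure.
* The embryo-damaged (rather than embryo-absent) class-5 variant is
  supported by the renderer but is not part of the default profile set.
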