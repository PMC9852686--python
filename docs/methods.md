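# Methods

## The pathway being modelled

Large-bowel biopsy reporting in a digital pathology laboratory follows a
fixed pipeline: slides are scanned at ×40 and rendered down to an
effective ×5 magnification (about 2 µm/pixel), tissue-rich regions are cut
into 512×512 tiles, each tile receives a diagnostic class and probability
score from an image classifier, and the tile labels are rolled up to a
single diagnosis per slide, per specimen, and per case. The case-level AI
diagnosis drives triage: cases read as neoplasia (adenoma or
adenocarcinoma) or inflammation are reported ahead of the first-in
first-out queue; a control arm (allocation by the parity of the numeric
case identifier: odd → AI pathway, even → routine) measures the effect on
turnaround time. `histotriage` implements this whole pathway as a library
plus CLI, and ships a synthetic slide generator so every stage can be
exercised and measured without access to patient material.

## Dominant-diagnosis aggregation

Tiles with probability score below 0.75 are excluded (a score of exactly
0.75 survives). The surviving labels are ranked by a strict clinical
hierarchy — adenocarcinoma, adenoma, anal mucosa, HP/SSL, inflammation,
normal small bowel, artifact, immunohistochemistry, connective tissue,
normal large bowel — and the slide's diagnosis is the highest-ranked label
present. Specimen and case diagnoses are the hierarchy maximum of their
children, so one confidently classified adenocarcinoma tile anywhere in a
case makes the case adenocarcinoma. Design choices in this module:

- **Connective tissue rank.** The clinical hierarchy enumerates nine
  classes; connective tissue (present in the training-class table but in
  practice never a dominant slide diagnosis) needs a slot for the order to
  be total. It sits at rank 9, below immunohistochemistry and above
  normal large bowel; the rank table is overridable.
- **All-tiles-filtered fallback.** A slide is never left undiagnosed. If
  no tile clears the threshold, the hierarchy is applied to the unfiltered
  labels and the result is flagged `low_confidence`. A slide with no
  tissue tiles at all is reported as normal large bowel, low-confidence.
- **Artifact handling.** By default artifact keeps its hierarchy rank 7.
  Workflows that prefer to ignore artifact tiles entirely can pass
  `exclude_classes=[artifact]`, which drops those tiles before ranking and
  falls back (low-confidence) if nothing remains.

## Tissue detection and tiling

Tissue is found by gray-scaling, inverting, and filtering with a
Laplacian of Gaussian (σ = 4 px at ×5). The absolute response is averaged
with a Gaussian at 3σ — this closes the gaps between crypts, glands and
nuclei inside a section — and thresholded. The threshold is calibrated
per image from its near-white pixels (gray > 0.92): their median response
plus 5 scaled median absolute deviations. Images with fewer than 25%
near-white pixels are treated as essentially all tissue and keep
everything above the faintest 2% of responses. The mask is finished by
hole filling and removal of objects below (8σ)² pixels.

Tiles are cut on a non-overlapping grid (stride = tile size) anchored at
the tissue bounding-box origin, which maximizes tissue per tile. Edge
tiles that would overhang the image are shifted inward; a shifted tile
that would then overlap an already-kept tile is dropped, so the grid is
always pairwise disjoint. A tile is kept iff at least 10% of its pixels
are tissue (permissive by design — slides with very little tissue still
yield a result, and an empty tile list is valid). Downscaling between
magnifications is area-average resampling (exact block means for integer
factors, box-filter otherwise); no colour normalization anywhere.

## Classifiers

Every classifier maps a square RGB tile to a probability vector over the
ten classes; the label is the argmax and the score the maximum
probability (softmax maximum, uncalibrated).

**Mock classifier.** The primary test double. It recovers a synthetic
tile's true class by nearest-centroid matching of seven texture
statistics (mean R/G/B, red–blue chroma, gray-level SD, horizontal
gradient energy, dark-nucleus fraction) computed over the largest
connected tissue component of the tile — so a tile straddling two
sections reports the dominant one. With probability `error_rate` it
substitutes a wrong label drawn from a configurable confusion profile
(default uniform over the other nine classes). Per-tile randomness is
seeded from (seed, slide id, tile coordinates), so classifications are
reproducible tile by tile. Scores are drawn uniformly from [0.80, 0.99]
by default — above the 0.75 cut so threshold behaviour is controlled
explicitly in tests via the score-range parameter.

**Trainable classifier.** A compact feed-forward network (one hidden
layer of 64 units, scikit-learn `MLPClassifier` driven by an explicit
epoch loop) over the same texture statistics concatenated with an 8×8
area-averaged RGB thumbnail. The training recipe mirrors the study
protocol: 25% of tiles randomly held out for validation, random
horizontal/vertical flip augmentation each epoch, Adam at 3·10⁻³,
early stopping on validation log-loss (patience 5 epochs, minimum
improvement 10⁻³) with the best weights restored, at most 50 epochs.
Flip variants of each tile's features are precomputed once so per-epoch
augmentation is an index lookup. Training warns about but retains classes
with fewer than 10 tiles — rare classes are clinically important even
when data is thin. The active-learning loop is modelled by a
`TrainingStore`: pathologist corrections are appended with
`origin="correction"`, and `retrain_due` fires once a threshold (default
200) of corrections has accumulated; training resets the counter.

## Synthetic slides and cohorts

A synthetic slide is a near-white background with Gaussian pixel noise
(σ = 3/255, so tissue detection is non-trivial) carrying by default three
wobbly-edged tissue sections — the three levels cut from a paraffin block
and mounted together. Each section is rendered with a class-distinctive
procedural texture: a regular circular crypt lattice for normal
large-bowel mucosa, crowded elongated dark glands for adenoma, fragmented
irregular gland clusters for adenocarcinoma, dense basophilic stippling
for inflammation, serrated star-shaped lumens for HP/SSL, villous fringes
for small bowel, layered shade bands for anal mucosa, a uniform pink
fibre field for connective tissue, DAB-brown blobs on a blue counterstain
for immunohistochemistry, and gray folds for the artifact class. Each
class also has a distinct dominant stain colour; colour plus structure
makes the classes separable by construction — the mean texture-statistic
vectors of any two classes differ by more than five within-class standard
deviations in at least one feature (a tested invariant). This is what
gives both classifiers signal; it is also the generator's main departure
from reality, where class appearance overlaps heavily. Passing tests
therefore demonstrate that the *pipeline machinery* is correct, not that
any classifier would reach similar accuracy on real H&E slides. Other
idealizations: sections never touch, at most two distinct true classes
per slide, stain intensity does not drift between slides, and focus is
uniform.

Default slide geometry is 3072×3072 at ×5 with section radius one
seventh of the image side, sized so a typical slide yields 10–50 tiles of
512×512. Optical slide artifacts (coverslip edge, air bubble, printed
text, tissue fold, dust, diathermy smear) can be overlaid; they perturb
pixels only and never the ground-truth label raster.

Cohorts follow laboratory identifier conventions: consecutive case
numbers formatted `SP<digits>`, specimens lettered A, B, …, slides
numbered from 1. Case-level diagnoses are drawn from a configurable class
mix; one slide per case always carries the case class and the others
carry either the case class or normal large-bowel mucosa, which (being
the hierarchy minimum) leaves the case-level truth equal to the sampled
class. Scan-completion timestamps are uniform over a two-week accrual
window by default — arrivals in the modelled backlog have no declared
process, so the simplest stationary choice is used.

## Reporting-queue simulation

Reporting is modelled as discrete sessions with a fixed number of
reportable cases (the real process is pathologists' sessions, not a
queue; this simulator exists to exercise the triage policy). At each
session, slots go first to urgent AI-pathway cases (FIFO by scan
completion within the band), then to everything else FIFO. Routine-arm
cases are never prioritized regardless of diagnosis, and urgency is
derived from the AI case diagnosis only, never the truth label. Cases
left over when capacity runs out are flagged unreported. Turnaround is
report authorization minus scan completion, truncated to whole hours and
rendered `dd:hh`. Under zero backlog priority has no effect (everyone is
reported at the next session); under backlog the urgent band strictly
reduces mean turnaround for neoplasia/inflammation cases — both tested.

## Evaluation

Confusion matrices (rows = truth, columns = AI) and binary
sensitivity/specificity for the four reported aggregates — adenoma +
adenocarcinoma; + inflammation; + HP/SSL; normal small or large bowel —
at specimen and case level. The positive set may be neither empty nor the
whole class universe; a rate whose denominator is empty in the data is
NaN rather than an error. Concordance is exact agreement with the
percentage rounded half-up for display (the raw counts are retained).
Turnaround comparison uses a two-tailed two-sample t-test, Welch
(unequal-variance) form by default with a pooled option, since the
pooled/unpooled choice is not dictated by the protocol; groups with fewer
than two cases in either arm report means only. No multiple-testing
correction is applied across diagnosis groups.

## Numerical and scale choices

- All randomness flows through `numpy.random.default_rng` seeds carried
  in the specs; generators are pure functions of (spec, seed) and
  pipeline runs are byte-identical for identical config and seed.
- Test and acceptance cohorts use scaled-down slides (640–1024 px, one
  to two sections, larger relative section radius) so a full
  cohort→tile→classify→aggregate→triage→evaluate loop runs in minutes;
  the aggregation, triage and evaluation logic is size-independent.
- The trainable classifier's convergence measurement uses 110 tiles per
  class at 96 px. Texture statistics are computed over tissue pixels
  only, which makes them stable across tile sizes; the artifact-class
  fold density scales with tile area for the same reason.
- Ties in the hierarchy are impossible (strict total order). Ties in the
  queue (equal scan timestamps) break by case number.

## Known limitations

- Procedural textures are linearly separable in a handful of summary
  statistics; real-slide accuracy claims cannot be transferred.
- The trainable model is a small feed-forward network over engineered
  features, not a deep CNN; it fulfils the same training contract but is
  not a drop-in for transfer-learned residual networks on real tiles.
- The queue simulator has deterministic session capacity; real reporting
  capacity varies and includes outsourcing, which is out of scope.
- Pyramidal/proprietary WSI formats are not read; inputs are flat
  TIFF/PNG already near the working magnification.
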