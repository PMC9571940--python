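# Methods

This note documents the models implemented in `eitgesture`, the choices
made where the design was genuinely open, and what the synthetic
benchmarks can and cannot show about real EIT gesture data.

## Measurement protocol

Eight electrodes sit on the boundary of the forearm cross-section,
labelled A–H counterclockwise with A at angle 0 (the absolute
orientation is a convention; only the orientation relative to the
phantom matters). Every drive pattern produces exactly 40 voltage
amplitudes per gesture. Fixed patterns hold one excitation pair and
repeat a short cycle of passive adjacent measurement pairs (8 or 10
times); the cyclic pattern advances the excitation pair around the ring
and, for each position, measures the five adjacent pairs that contain
no excitation electrode, in ascending electrode order (the traversal
order within a cycle is a documented convention — classification is
order-sensitive only through feature indexing). One schedule step is
one time sample of the evolving gesture; the physical step duration is
a property of the phantom trajectory, not of the protocol.

## Forward model

The quasi-static EIT forward problem div(σ∇u) = 0 is solved on an
unstructured P1 triangle mesh of an ellipse (Delaunay triangulation of
concentric rings in normalised coordinates, mapped affinely; the
boundary node count is rounded to a multiple of 8 so electrode arcs are
sampled symmetrically). Element conductivities are assigned by a
point-in-ellipse test against two bone inclusions.

- **Geometry** (configurable; exact dimensions are model assumptions):
  outer ellipse 40 × 30 mm; bones 7 × 5 mm at (−14, 4) and 6 × 4.5 mm
  at (13, 2), slightly rotated.
- **Conductivities**: muscle 0.5448 S/m, bone 0.02043 S/m.
- **Drive**: 300 µA RMS; the 30 kHz carrier is metadata — the solver is
  real-valued, representing RMS magnitude detection. Voltages are
  per-unit-depth (2-D); absolute scale is therefore nominal, which is
  irrelevant to classification of amplitude patterns.
- **Electrodes**: gap model — the injected current is distributed
  uniformly over a boundary arc (default width: 1/4 of the electrode
  spacing); voltages are arc-averaged node potentials. Measurement
  weights equal injection weights, so discrete reciprocity is exact up
  to solver precision. Contact impedance (complete electrode model) is
  not modelled: the classifier consumes amplitude patterns and the real
  system mitigates contact impedance with gelled electrodes and
  four-terminal measurement.
- **Reference**: potential fixed at the boundary node opposite
  electrode A; differential measurements cancel it.
- **Mesh sizes**: ~2500 elements ("fine", physics validation: analytic
  disk agreement ≲ 0.1%, reciprocity ~1e−15) and ~650 elements
  ("coarse", dataset simulation; one solve ≈ 1 ms).

Validation oracles: the closed-form homogeneous-disk solution
u = (I/πσ)·ln(|x−d|/|x−s|) for boundary point drive/sink; reciprocity;
linearity in current; monotonicity of dissipated power in conductivity;
and the qualitative field-uniformity ordering (interior current-density
CV is smallest for the opposite drive pair, largest for the adjacent
pair).

## Synthetic gesture generator

The generator emulates the study design: 5 participants × 5 gestures ×
40 sets × 4 iterations (4000 samples) under normal conditions, 6
sessions for re-worn electrodes (6000), and 3 days with 40/40/50 sets
(3250) for cross-day, with session-based train/test splits (all
sessions but the last train; the last tests): 3000/1000, 5000/1000,
2000/1250.

**Gesture classes.** Each gesture is a set of circular muscle
sub-regions whose conductivity ramps from baseline to a peak Δσ
(±0.08–0.22 S/m) along a smoothstep activation; regions within a class
engage sequentially (distinct ramp windows), giving each class a
multi-phase temporal signature. The pistol and "six" classes share
their dominant region with identical onset and differ only through
weaker secondary regions; their mean measurement vectors are ~1.7
per-dimension noise units apart — the closest class pair by a factor of
~3 — so they form a partially confusable pair, while the other classes
are well separated. A practical constraint discovered during design:
regions near the section center are electrically shielded (near-zero
boundary sensitivity), so distinguishing regions must sit near the
boundary.

**Participant variation.** Anatomy axes and baseline muscle
conductivity each scale by ~N(1, 0.05), clipped to ±10%, drawn once per
participant.

**Execution timing.** Each sample's trajectory runs at a random speed
(~N(1, 0.08), clipped ±20%) with a random onset shift (~N(0, 0.04),
clipped ±0.1), since volunteers never repeat a dynamic gesture with
identical timing. Implemented exactly via a time-resolved measurement
grid G[t, k] (the value step k would read at physical time t), sampled
along the warped time axis; fixed patterns need 40 forward solves per
cached (participant, session, class) grid, the cyclic pattern 320.

**Noise.** Per reading: multiplicative Gaussian (σ_rel = 0.02) plus an
additive 1 µV floor. Readings taken immediately after the excitation
pair switches carry an extra multiplicative transient (σ = 0.10),
modelling the unsettled constant-current source and RMS detector
against a changing load — one step per cycle block for cyclic
excitation, a single step for fixed patterns. This is the mechanism
that penalises cyclic excitation on dynamic gestures.

**Interference conditions** (drawn per session):

- *shake*: the arm swings during acquisition — soft tissue rotates
  relative to the ring (ramp from 0 to ±(π/32..π/16)) and baseline
  conductivity drifts by 1–3%;
- *electrode_move*: the re-worn ring is rotated by up to half the
  electrode spacing (±π/8);
- *cross_day*: a per-day baseline conductivity factor (lognormal,
  σ = 0.02 — day-to-day bioimpedance drift of a few percent) plus a
  small ring jitter (±π/32).

**Seeding.** All randomness derives from `SeedSequence([master, tag,
participant, iteration, class, set])` key paths; the full pipeline is
bit-reproducible from the master seed.

## CG-SVM

Architecture as in the README. Implementation choices:

- Losses are batch **sums** as written (no 1/m averaging); the defaults
  λ₁ = 0.003, λ₂ = 0.01 are tuned for that scale. Adam (lr 1e−3,
  batch 32, 100 epochs) is invariant to overall gradient scale.
- The GRU branch is a single layer, hidden size 64, final hidden state
  as output ("multiple GRU units" read as unrolled time steps); its
  input is the first-order difference of the standardized sequence,
  length-preserved by prepending 0 so both branches see 40 inputs.
- Dropout (0.5) applies to the concatenated features on the auxiliary
  softmax path only; the center terms and the SVM head see the clean
  features, which are the inference-time representation.
- Class centers are not optimizer parameters: they follow the
  mini-batch moving-average rule
  c_j ← c_j − α·Σ_{y_i=j}(c_j − x_i)/(1 + n_j) (α = 0.5), plus an
  explicit gradient step on λ₂·Ld — without that step the penalty would
  influence nothing, since Ld depends only on the centers.
- Ld sums the hinge over **all** other-class centers per sample; a
  `nearest`-center variant is available behind `penalty_mode`.
- K defaults to the median pairwise squared center distance measured
  after a one-epoch warm-up, then frozen ("specified through
  experience" made reproducible); an explicit K is honoured as-is.
- The SVM head (RBF, C = 1, γ = 1/(d·var)) consumes the concatenate
  layer, not the dense activations.
- Inputs are standardized per feature index with statistics from the
  training split only.
- Gradients are hand-derived (conv, GRU BPTT, dense) and verified
  against central finite differences; note that exact ReLU kinks
  (possible with zero-initialised biases and zero inputs) are excluded
  from the checks because central differences are invalid there.

Baselines: KNN (k = 5), RBF SVM (C = 1), Gini decision tree — all on
standardized raw 40-vectors — and CNN-softmax (the upper branch with a
softmax head, trained with softmax loss only).

## Benchmark scale and what the results show

Directional comparisons run at desk scale: 1 participant, 20 sets per
session, 3 replicate seeds. Pattern comparisons and the confusion
analysis use 2 sessions; the classifier comparisons keep the study's
session structure scaled down (6 sessions for electrode_move, 3 days of
20/20/25 for cross_day), because learning position/day invariance
requires multiple training sessions — with a single training session
every classifier is at chance and the comparison is uninformative.

Reproduced directional results (seeds 1–3):

- fixed-opposite ≥ cyclic excitation accuracy under shake and
  electrode displacement (the excitation-switch transient and the
  spatial-temporal confound penalise cyclic excitation);
- CG-SVM with center distance loss ≥ the same network with plain
  softmax loss, and ≥ CNN-softmax, under both interference conditions;
- the pistol/"six" pair owns the largest off-diagonal confusion cell
  under softmax training, and the center distance loss shrinks that
  cell while raising accuracy on every seed;
- with λ₁ > 0 the mean within-class feature-to-center distance falls
  over training; with λ₂ > 0 the minimum pairwise squared center gap at
  convergence is at least that of the λ₂ = 0 run; center-distance
  features score at least as high a 2-D silhouette as softmax features.

**Known negative result.** The deep networks do *not* beat the raw
RBF-SVM baseline on these synthetic benchmarks, at desk scale or at the
full study size. The phantom's class signal is a smooth, essentially
low-dimensional function of 40 well-registered features — a regime
where an RBF kernel is close to optimal and a 250k-parameter network
has no representational advantage. The advantage reported for deep
extractors on real recordings plausibly rests on the complex nonlinear
variability of human data (skin/contact dynamics, posture coupling,
non-stationary artefacts) that this simulator does not model. Passing
synthetic tests therefore validates the implementation and the relative
behaviour of the loss terms, not absolute classifier rankings on real
data.

## Numerical notes and limitations

- Degenerate bone ellipses (zero axes) mean "no inclusion"; bones must
  lie strictly inside the arm and be disjoint, else construction fails.
- `measure` reuses a factorisation across consecutive steps with
  unchanged excitation, conductivity and ring rotation.
- Voltages are clipped at 0 after noise (amplitudes are non-negative).
- 2-D cross-section physics: no out-of-plane current spreading, no
  complex impedance/phase, no contact-impedance dynamics, no image
  reconstruction.
- The gesture-conductivity model is phenomenological (ramped regional
  Δσ), not an EMG-coupled muscle model; absolute accuracies on the
  synthetic benchmarks are not predictions of real-world accuracy.
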