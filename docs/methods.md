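# Methods

## Problem setting

Gliomas are imaged with four complementary MRI contrasts: T1 and
contrast-enhanced T1 (T1ce) delineate the tumor core and its enhancing rim,
while T2 and FLAIR make the surrounding vasogenic edema salient.  Clinical
acquisitions are frequently incomplete — often only a single contrast is
available — and a segmenter trained on all four contrasts degrades badly
when three of them are missing.  This package implements a
teacher–assistant–student framework for that setting: a full-modality
*teacher* is trained first and frozen; a single-modality *student* is then
trained to match both the ground truth and the teacher's softened output;
a trainable single-modality *assistant* supplies structural knowledge the
frozen teacher cannot update, and a *competitive* term rewards the student
for beating the teacher–assistant on individual samples.

Segmentation is 2-D and slice-based, over the standard BraTS label set
{0 background, 1 necrotic/non-enhancing core, 2 edema, 4 enhancing tumor},
evaluated on the nested regions WT = {1,2,4}, TC = {1,4}, ET = {4} with the
Dice coefficient 2TP/(2TP+FP+FN).

## Architecture

**Teacher.**  The two clinically paired inputs (T1‖T1ce and T2‖FLAIR) are
channel-concatenated, lifted to a common width by a 3×3 convolution, and
fused by content-guided attention (CGA): channel weights from global
average pooling through a two-layer 1×1 bottleneck, spatial weights from
channel-mean/max maps through a 7×7 convolution, added into coarse weights,
interleaved with the input by a channel shuffle, refined by a 7×7 depthwise
convolution and a sigmoid.  The final weight gates a convex blend of the
two streams, so each fused value lies between the two input values.  The
fused map passes through a multihead mixture of convolutional experts
(MHMoE): channels are split into heads; each head has its own bank of
two-conv experts and a 1×1-conv gate whose per-pixel softmax over experts
weights a soft mixture (no sparse routing).  A 4-level U-Net with
double-conv blocks (each conv followed by batch norm and ReLU) produces
4-class logits.

**Assistant.**  A single-modality network mimicking peripheral vision: a
two-stage stem downsamples 4× so attention runs on a small grid; the map is
split into four quadrants (saccade-like decomposition); each region passes
through standard multihead self-attention (global content) and through an
MPA convolution whose 3×3 kernel is modulated by a learnable mask — center
emphasized via a fixed center-1/off-center-0.5 matrix, a U(−1,1)-initialized
learnable mask, a learnable scalar θ and the per-filter weight sum — so that
θ=0 recovers a plain convolution.  The L2-normalized MPA map multiplies the
attention output; the four regions then interact (channel-concatenate →
3×3 conv+ReLU → channel partition → spatial reassembly → 3×3 conv+sigmoid →
per-region residual product followed by a channel softmax), and a compact
3-level encoder–decoder restores full resolution.  The named encoder–decoder
behind the assistant and student is implemented as this compact double-conv
design and is swappable behind the module interface.

**Student.**  The same compact encoder–decoder on one modality; all of its
advantage over plain supervision comes from the distillation objective.

## Objectives

Per-sample task loss (teacher, assistant, student alike): mean pixelwise
cross-entropy plus Σ over the three tumor classes of (1 − soft Dice) with
smoothing ε = 1e-5 in numerator and denominator.

Teacher–assistant output: probabilities blended as
w·p_T + (1−w)·p_A (renormalized), w = `ta_weight`.

Knowledge distillation: L_KD = mean over samples and pixels of
‖softmax(z_TA/τ) − softmax(z_S/τ)‖², the squared distance of
temperature-softened class probabilities.  The student objective is the
convex combination L_student = α·L_task + (1−α)·L_KD.

Competitive term, per sample i, from the scalar task losses of the raw
teacher (L_T), the teacher–assistant blend (L_TA) and the student (L_S):

    r_i     = λ (L_TA,i − L_S,i)          reward, λ = 0.1
    γ_i     = L_T,i / (L_T,i + L_S,i)     relative difficulty ∈ (0,1)
    δ_i     = exp(L_TA,i / μ)             emphasis ≥ 1, μ = 10
    L_comp  = Σ_i γ_i δ_i r_i

The reward is positive exactly when the student beats the teacher–assistant
on a sample.  The training objective **maximizes** the weighted reward
(the negated reward enters the total loss) — this is the direction that
drives the student's loss below the teacher–assistant's; minimizing the
summed reward itself would do the opposite.  γ, δ and L_TA are treated as
constants in the gradient so the assistant cannot degrade itself to inflate
rewards.  The reported `L_comp` is the summed γδr above.

Total: L_total = λ_student·L_student + λ_comp·(competitive term)
+ λ_res·L_assistant.  Gradients reach the student and the assistant (the
latter through its own loss and through the blended distillation target),
never the frozen teacher.

### Default scalars

λ = 0.1 and μ = 10 are the published scales.  The remaining scalars are
unspecified in the source method and are this package's defaults, chosen so
the objective behaves as intended at desk scale:

* τ = 4 — softens confident teacher maps enough that the squared-probability
  gradient does not vanish where the student is confidently wrong.  The
  saturation is structural: a student trained on the KD term *alone*
  collapses to the background class (its probabilities saturate and the
  squared-probability gradient vanishes exactly on the disagreement
  pixels), so the KD term can only act as a regularizer next to the task
  loss, never as the main signal.
* α = 0.8 with λ_student = 1.25 — keeps the absolute supervised weight
  (λ_student·α = 1) equal to a task-only student's and gives the KD term a
  mild weight of 1/4; heavier KD weights measurably interfere with
  supervision for the reason above.
* λ_comp = λ_res = 1; ta_weight = 0.9 — the assistant contributes to the
  target but a partially trained assistant must not dominate it.
* The assistant is built twice as wide as the student by default: a weak
  assistant pollutes the blended distillation target.

## Training recipe

SGD with momentum 0.9, weight decay 1e-4, polynomial decay
lr·(1 − t/T)^0.9, global gradient-norm clipping at 10, and an exponential
moving average (decay 0.98) of the weights taken over the last 40% of
steps, with batch-norm statistics re-estimated against the averaged weights
before evaluation.  Averaged-iterate evaluation and clipping remove most of
the endpoint noise that small-batch training otherwise shows; both are
applied identically to every training arm, so paired comparisons are
unaffected.  The reference configuration records the published schedule
(lr 2e-4, batch 160, 1000 epochs, 160×160 crops); the desk profile used by
tests and the acceptance script scales this to CPU size (lr 0.05, batch 8,
40 student epochs / 120 teacher epochs, 64×64 phantoms, width 4; the
teacher is pretrained once and reused across paired student seeds).  Steps:
(1) pretrain and freeze the teacher; (2–3) train student and assistant
jointly under the full objective.

## Synthetic phantoms

The generator emulates the statistical structure the framework assumes,
not MRI physics.  Each phantom is a 2-D slice with a smooth elliptical
"brain" plus low-amplitude smoothed texture; a tumor consisting of an
elliptical core (with an enhancing outer shell) placed off-center inside an
irregular, independently oriented, lobulated edema region (smoothed-noise
boundary perturbation); per-modality mean intensities follow the clinical
contrast roles — core/enhancing salient on T1/T1ce, edema salient on
T2/FLAIR and only faintly hypointense on T1/T1ce; Gaussian pixel noise
(σ = 0.08 by default) and light smoothing of tissue boundaries.  The edema
boundary is deliberately *not* inferable from the core's geometry: in an
early design with concentric ellipses a T1-only supervised baseline matched
the full-modality teacher, which contradicts the premise the generator must
emulate (single-modality segmentation being materially harder than
multimodal).  Labels keep the exact nesting ET ⊆ TC ⊆ WT.

What the phantoms do not model: 3-D continuity, bias fields, anatomy
(ventricles, skull), multi-focal lesions, scanner variation.  Passing tests
therefore demonstrate the *mechanics* of the framework — correct losses,
information flow, frozen-teacher contract, a reproducible distillation
benefit under the intended missing-modality structure — not clinical
performance.

## Numerical choices and degenerate inputs

* Min–max normalization of a constant slice returns zeros.
* Dice with both masks empty returns 1.0 (configurable to NaN/skip).
* Softmax/log-softmax are computed with constant max-shifts.
* The soft-Dice smoothing ε bounds the loss of a perfect prediction away
  from 0 by O(ε).
* Quadrant partition requires even spatial dims; the U-Net requires dims
  divisible by 16 (4 poolings), the compact encoder–decoder by 8.
* A max tumor radius of 0 yields a tumor-free slice (all-background label).
* θ is initialized at 0.1, not 0: at exactly 0 the learnable MPA mask
  receives no gradient.
* The source describes the MPA center mask both as 3×1 and as 3×3 with
  off-center 0.5; the 3×3 form is implemented (it is the one that
  type-checks against a 3×3 kernel).

## Known limitations

* The tensor engine is CPU/float32 only; runtimes limit experiments to
  desk scale, and the published BraTS benchmark numbers are out of reach by
  design (gated data, GPU-scale schedules).
* The desk-scale distillation benefit is at best a small effect measured on
  3-slice validation splits, where a single missed tumor moves the mean WT
  Dice by ~0.1-0.3.  In our paired experiments the per-seed deltas are
  dominated by this discreteness: the full objective wins on some seeds and
  loses on others, and the mean delta is within the noise floor.  The
  experiment therefore reports per-seed paired outcomes and the win
  fraction rather than a single mean, and no desk-scale claim is made that
  the full objective consistently beats plain supervision; the published
  gains were obtained at three orders of magnitude more training steps and
  data.
* Attention cost is quadratic in tokens; the assistant's stem keeps token
  grids small rather than implementing windowed attention.
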