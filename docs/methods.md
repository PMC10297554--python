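# Methods

This note documents the models, parameters and design choices behind
`gastwin`: a pipeline that (1) generates synthetic ICU patient states,
(2) labels them with a mechanistic steady-state pulmonary gas-exchange
simulator, (3) trains a small 1D-convolutional network as a fast surrogate
of the simulator, and (4) compares four hyperparameter-search schedulers on
the tuning task.

## 1. Synthetic cohort generation

A patient state is a vector of 19 simulator inputs (see
`gastwin.cohort.INPUT_COLUMNS`). Eight of them — BE_a, Hb, Vt, PEEP, P_EI,
FiO2, SvO2, RR — carry a published summary (mean, SD, min, max) of an ICU
source dataset; the other eleven are simulator-internal parameters
(compartment resistance slopes/intercepts, closed-compartment count,
anatomical shunt, respiratory quotient, O2 uptake, deadspace, cardiac
output, I:E ratio) for which no source summary exists. Those use stand-in
distributions chosen to be plausible for ventilated adults:

| parameter | distribution | units |
|---|---|---|
| v_sR, v_inR, v_sVR, v_inVR | uniform [0.5, 2.0] | — |
| v_nc | integer-uniform [0, 30] of 100 compartments | count |
| asht | uniform [0.01, 0.15] | fraction |
| RQ | trunc. normal (0.8, 0.05) on [0.7, 1.0] | — |
| VO2 | trunc. normal (0.25, 0.05) on [0.15, 0.50] | L/min |
| VD_phys | trunc. normal (0.15, 0.03) on [0.08, 0.30] | L |
| CO | trunc. normal (5.0, 1.0) on [2.5, 9.0] | L/min |
| IE_ratio | uniform [0.33, 1.0] | insp/exp |

**Moment matching.** The published mean/SD summarize the *bounded* source
data, i.e. the truncated law itself. Sampling a parent normal at those
parameters and truncating would bias the moments (for FiO2, truncation at
20% sits 1.7 SD below the mean and would inflate the sample mean by ~3%).
The generator therefore solves for the parent (μ, σ) whose truncated
distribution has exactly the target mean and SD (two-dimensional root find
on `scipy.stats.truncnorm` moments, cached per parameter) and samples the
exact truncated density via inverse-CDF. Values never violate the bounds
and the bound density is not inflated; all twelve truncated-normal
parameters recover their target mean and SD to <0.1% at n = 200,000.
A target SD above the uniform limit `(max−min)/√12` is unattainable for a
truncated normal and raises a configuration error, as does a parent whose
mass on [min, max] is below 1e-3 (the rejection-sampling acceptance bound).

Parameters are sampled independently (each from its own child seed stream,
so a column's draw does not depend on the others). No inter-parameter
correlation is imposed: the source summary is marginal-only, and the
correlation structure of the original dataset is unknown. A correlated
sampler can be added by replacing `ParameterDistribution.sample`; nothing
downstream assumes independence.

Splitting shuffles with a seeded permutation and partitions
train/val/test as `n − ⌊n·f_val⌋ − ⌊n·f_test⌋ / ⌊n·f_val⌋ / ⌊n·f_test⌋`
(flooring remainder to the training split, the largest partition).

## 2. The steady-state gas-exchange simulator

The simulator is a deliberately compact steady-state ventilation–perfusion
model with the same input/output contract as a full dynamic virtual-patient
simulator: 19 inputs in, four arterial markers out (PaO2, PaCO2, HCO3, pH).
It is not a reimplementation of any existing dynamic simulator — it has no
intra-breath dynamics, so `IE_ratio` and `P_EI` are carried as inputs but
are inert (they remain available to the surrogate, which must learn their
irrelevance).

Model components (constants in `OracleConstants`):

* **O2 carriage** — Severinghaus saturation
  `S(P) = (23400·(P³+150P)⁻¹ + 1)⁻¹`; content
  `C_O2 = 1.34 · (1.611·Hb[mmol/L]) · S(P) + 0.003·P` mL/dL.
* **CO2 carriage** — linearized content curve
  `C_CO2 = 48 + 0.7·(P − 40)` mL/dL. Bohr/Haldane O2–CO2 interaction and
  the Hb dependence of CO2 carriage are omitted; for a surrogate-training
  target only a physiologically shaped, smooth, monotone map is required.
* **Ventilation** — `VA = RR · max(Vt − VD_phys, 0.2·Vt)` L/min; the floor
  prevents non-positive fresh-gas flow when the sampled deadspace exceeds
  the tidal volume.
* **Compartments** — `N_comp = 100` parallel units on the grid `x_i = i/N`;
  flow resistance `v_inR + v_sR·x_i` and vascular resistance
  `v_inVR + v_sVR·x_i`; ventilation and perfusion shares proportional to the
  reciprocal resistances. The affine-in-grid form is the simplest profile
  producing a controllable V̇A/Q̇ spread.
* **Venous admixture** — `Qs/Qt = clamp(asht + (v_nc/N)·(1 − min(PEEP/20,1)),
  0, 0.95)`: anatomical shunt plus closed compartments, linearly recruited
  away as PEEP rises to 20 cmH2O.
* **Per-compartment steady state** — bisection (55 iterations) on the CO2
  mass balance `V̇A/Q̇ = 8.63·(CvCO2 − C_CO2(PACO2))/PACO2` on the bracket
  (0.1 mmHg, venous-equivalent pressure); alveolar O2 from
  `PAO2 = FiO2/100·(760−47) − PACO2/RQ` (floored at 0.5 mmHg).
  The linear CO2 curve admits a closed form, but bisection is kept: it is
  derivative-free, robust for any monotone content curve, and vectorizes
  over all compartments and patients at once.
* **Whole-patient loop** — mixed-venous O2 is anchored to the SvO2 input
  (PvO2 by inverting the saturation curve); venous CO2 content exceeds the
  arterial by `100·RQ·VO2/CO` (Fick). The outer fixed point on PaCO2 is
  affine (every CO2-side map is linear), so it is solved by secant
  acceleration and verified against `tol_P = 0.01` mmHg; `max_iter = 200`.
  Arterial contents are the flow-weighted end-capillary mixture plus the
  shunted venous fraction; pressures are recovered by inverting the content
  curves (bisection for O2, exact inverse for CO2).
* **Acid–base** — Henderson–Hasselbalch `HCO3 = 0.03·PaCO2·10^(pH−6.1)` with
  the Van Slyke relation `BE_a = 0.9287·[HCO3 − 24.4 + 14.83·(pH − 7.4)]`,
  solved for pH by bisection on [6.5, 7.9] (the left side is strictly
  increasing, so the root is unique).

**Mass-balance bookkeeping.** At convergence the CO2 eliminated across
compartments equals the metabolic production `RQ·VO2` (by construction of
the fixed point), and the compartmental O2 uptake equals the arterial Fick
computation exactly (a mixing identity). The O2 uptake itself does *not*
equal the VO2 input: SvO2 is an independent input parameter, so the O2 Fick
balance is over-determined and is intentionally not enforced. Both
bookkeeping quantities are exposed via `simulate(..., full_output=True)`
and checked in the tests (CO2 closure within 2%).

**Unsolvable states.** Extreme draws (very low alveolar ventilation with
high CO2 production) have no steady state inside the solvable envelope
(equilibrium PaCO2 outside (5, 250) mmHg, or no acid–base root in
pH [6.5, 7.9]). `simulate_batch` drops such rows with a logged count —
about 1–2% at the default cohort settings — rather than imputing values;
`simulate` raises for them. Batch labelling preserves input row order for
any worker count (rows are chunked, solved, and re-concatenated in order).

## 3. The surrogate network

The 19 inputs are treated as a length-19 single-channel sequence feeding
four 1D convolution layers (filter counts 64/128/128/128, spatial kernel
width 3, same padding, ReLU), a flatten, inverted dropout, an optional
64-unit ReLU layer, and a linear 4-unit head. The "64 then 128" layer sizes
are filter counts: a spatial kernel cannot exceed the sequence length 19,
so the kernel width is a separate, configurable parameter (default 3;
receptive field 9 after four layers — the optional fully connected layer
provides the global mixing).

The network, backpropagation, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) and
checkpointing are implemented in NumPy (float32) in `gastwin.nn`; weight
initialization (He for ReLU layers, Glorot for the head), batch shuffling
and dropout masks are all seeded, so training is bit-reproducible.
Checkpoints capture weights, optimizer moments, the epoch counter and the
shuffle RNG state, so a paused trial resumes on exactly the trajectory it
would have followed uninterrupted.

Inputs *and* outputs are standardized with statistics fitted on the
training split only (scale floored at 1e-8): the four targets span three
orders of magnitude (PaO2 in the hundreds of mmHg, pH near 7.4), and
standardizing the outputs makes them contribute comparably to the MAE/MSE
loss. Reported MAEs are in standardized units; predictions are
de-standardized back to physical units, and R² is computed in physical
units (for per-output affine standardization the value is identical either
way). The per-epoch training MAE is the running mean over batches (dropout
active, the usual convention); validation MAE is computed at each epoch end
in inference mode — dropout is inactive outside training, which is also why
validation error can sit below training error at high dropout rates.
Training is a fixed 50 epochs by default; early stopping is available as an
optional flag but off by default.

## 4. Hyperparameter-search schedulers

The tuned parameters are learning rate (log-uniform [1e-5, 1e-3]), batch
size {64, 128, 256}, dropout rate (uniform [0.3, 0.6]), loss {MAE, MSE} and
the presence of the intermediate fully connected layer. The objective is
the final *validation* MAE. All four schedulers drive the same trainable
contract and draw their configurations from the same seeded stream, so on
a given seed they search the same candidates:

* **FIFO** — every trial runs `max_t` epochs; the control.
* **HyperBand** — classic bracket plan: `s_max = ⌊log_η max_t⌋`, bracket
  `s` starts `⌈(s_max+1)/(s+1)·η^s⌉` configs at `max_t·η^{−s}` epochs and
  successively keeps the top `⌊n/η⌋` while multiplying the budget by η.
  The sampled configs fill the brackets in plan order (cycling if more
  configs remain than one pass uses); a config that survives its bracket
  always reaches `max_t`.
* **ASHA** — rungs at `grace_period·η^k` epochs; every trial runs to a rung
  and pauses; any paused trial ranking in the top `⌊n_rung/η⌋` of its rung
  resumes. With the floor rule a rung needs at least η results before
  anything is promoted, so small populations stall at low rungs — accepted
  behaviour, documented rather than patched, since the budget ordering and
  optimum-identification properties are unaffected.
* **PBT** — the population trains in lock-step; every `perturb_interval`
  epochs the bottom `exploit_quantile` clones the full checkpoint (weights
  and configuration) of a uniformly chosen top-quantile trial, then
  multiplies the learning rate by a factor from {0.8, 1.25}. Every trial
  consumes the full budget, so PBT's total cost equals FIFO's.

Scheduler meta-parameters (η = 3, grace 5, perturb interval 5, exploit
quantile 0.25) are standard literature defaults. Execution is
process-local and order-preserving; with one worker every scheduler is
exactly reproducible from `(seed, space, policy)`. On identical seeds the
epoch budgets order as HyperBand ≤ ASHA < FIFO = PBT = `n_trials·max_t`,
mirroring the early-stopping design rather than any wall-clock measurement.

## 5. Evaluation

Per-output R² (`1 − SS_res/SS_tot`) and MAE are computed on a held-out test
split in physical units; a model passes when every output exceeds
R² = 0.90. Test/train overlap is detected by row hashing and raises.
Overfitting is flagged when, over the final third of training, the
least-squares slope of validation MAE is positive while that of training
MAE is negative — a deliberately simple, configurable detector.

## 6. Problem sizes and numerical settings

The shipped full-scale configuration mirrors the study design
(1,000,000-state cohort, 64 trials, 50-epoch budget). Desk-scale runs —
the package's own test and acceptance defaults — use a 30,000-state cohort
for surrogate fidelity, 200,000 draws for distribution recovery, and a
2,000-row/2-epoch budget for scheduler bookkeeping; sizes chosen so a
complete check runs on a single CPU in minutes while leaving the
statistical conclusions unchanged. Solver tolerances: compartment and
acid–base bisections run 55–60 halvings (bracket below 1e-12 of its width);
the outer PaCO2 loop converges to 0.01 mmHg.

## 7. What the synthetic data does and does not show

The generator emulates the *marginal* statistics of the source ICU data
plus plausible stand-in ranges for simulator-internal parameters; it does
not reproduce inter-parameter correlations, longitudinal trajectories,
measurement noise, or missingness patterns of real EHR data. The simulator
labels are smooth, deterministic functions of the inputs. Passing the
fidelity criterion therefore demonstrates that the surrogate can distill
this mechanistic map to R² > 0.90 at desk scale — it does not demonstrate
diagnostic validity on real patients, and no clinical claim is made.

## Known limitations

* The gas-exchange model omits O2–CO2 carriage interaction, haemoglobin
  dependence of CO2 content, and all intra-breath/cardiovascular dynamics.
* SvO2 is an input, so the O2 Fick balance is not closed (see §2).
* With more than one worker, ASHA/PBT outcomes depend on completion order;
  reproducibility is guaranteed only at `workers=1`.
* The CNN treats an arbitrary feature ordering as a spatial axis; this
  mirrors the surrogate's published architecture choice, and the optional
  dense layer supplies the global connectivity the convolutions lack.
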