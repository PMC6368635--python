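# Methods

## Model

The respiratory system is a single linear compartment: alveolar pressure
`p_alv = V/C + Pmus`, flow `V̇ = (p_aw − p_alv)/R`, with airway-opening
pressure `p_aw = p_source − ΔP_app(V̇)`.  Defaults model a 3-kg
post-cardiac-surgery neonate: C = 1.5 mL/cmH₂O (0.5 mL/cmH₂O/kg),
R = 40 cmH₂O/(L/s), target tidal volume 30 mL, rates 24–36/min.  There is
no upper-airway model: the "bare" condition is the lung chamber open to
atmosphere through its wide 22-mm port, which is why its work of breathing
is a lower bound on post-extubation work.

**Effort.** Pmus is a half-wave per cycle: half-sine descent to
−amplitude over the rise window (30 % of the cycle), no hold, then an
exponential release re-anchored to end exactly at zero (30 % of the cycle,
decay constant 1.5).  The amplitude is not a free parameter: a bisection
controller (`calibrate_constant_vt`) emulates the bench's constant-V_T mode
and sets it so the steady-state delivered V_T is within 0.1 mL of 30 mL.
The rise/release fractions were fixed once against the bench's printed
inspiratory flows: unassisted mean flow ≈ 3.5–3.6 L/min at 36/min, T-piece
mean flow ≈ 3.2–3.3 L/min (printed band 3.1–3.3; the simulated 3.5-mm value
is 3.31).

**Apparatus.** Tubes follow the Rohrer form ΔP = k₁V̇ + k₂V̇|V̇|,
sign-symmetric in flow.  The default coefficients are *effective* values
for the clinically curved tube plus the 9-mm adapter duct and connectors,
calibrated to the bench's flow band and sweep behaviour rather than to
bare-tube Poiseuille theory: k₁ = 15 (3.5 mm) / 20 (3.0 mm) cmH₂O/(L/s),
k₂ = 850 cmH₂O/(L/s)² for both.  They are plain config fields and can be
overridden per run.

**Ventilator.** PSV is flow-triggered: a patient-induced inspiratory flow
above 0.25 L/min (the bias-flow deviation the bench's sensitivity setting
detects) arms pressurization after a 40-ms actuation delay.  The source
pressure relaxes first-order (τ = 50 ms) toward PEEP + PS while
pressurizing and toward PEEP (4 cmH₂O) while exhaling.  Cycling occurs at
30 % of the breath's peak inspiratory flow (evaluated after a 50-ms
minimum) or at 45 % of the cycle, whichever comes first; re-triggering is
blocked until expiratory flow has been seen.  Bias flow enters only
through the trigger threshold; circuit pneumatics are not modelled.

**Expiratory pathway.** Passive emptying through tube + lung alone has a
time constant of ~0.1 s, which can never produce end-expiratory
hyperinflation at 24–36/min.  The bench nevertheless develops auto-PEEP
under PSV, so the model includes the one element that can slow late
expiration there: the expiratory limb and exhalation valve, a linear
resistance (default 180 cmH₂O/(L/s)) seen only by expiratory flow in PSV
mode.  The default was calibrated so auto-PEEP appears for the 3.0-mm tube
at 24/min and grows with rate, while T-piece and bare breathing (no
circuit) stay auto-PEEP-free.  This is the model's largest structural
assumption; the value is effective, not a measured valve property.

## Numerics

Fixed-step explicit-midpoint (RK2) integration at dt = 0.5 ms.  The flow
at each stage is the exact root of the quadratic Rohrer balance, and the
source pressure uses the exact exponential relaxation, so halving dt
changes per-breath WOB by ~1e-4 % (the contract is < 0.5 %).  A
zero-resistance configuration is given a small numerical floor
(0.5 cmH₂O/(L/s), time constant ≈ dt), which realises the quasi-static
limit V = C·|Pmus|.  Four transient breaths are discarded; metrics are
means/SDs over 10 steady-state breaths (per-breath V_T spread < 1 %).
Divergence (|V| beyond 10·V_T above the pressurization equilibrium) raises
an error naming the offending parameters.  The simulator is deterministic;
an optional seeded multiplicative noise layer (off by default) can emulate
measurement jitter for SD-bearing outputs.

## Metrics conventions

- WOB integrates −Pmus dV (effort positive) with the trapezoid rule over
  the window from 0.5 mL inhaled to 0.5 mL exhaled from peak inspiratory
  volume; 1 cmH₂O·L = 98.0665 mJ, applied in exactly one place
  (`units.py`).  The quasi-static elastic limit V_T²/2C = 29.4 mJ is
  verified at 5/min, where the residual resistive work (+1 %) and the
  window truncation near peak volume (−1 %) largely cancel; the simulated
  value agrees within 2 %.
- TW shares the WOB integrand and start point and ends where airway
  pressure first recovers to set PEEP after dipping below it.  TW is
  capped at WOB: at very low PS the recovery point approaches the window
  end, and the truncated integral can exceed the full-window WOB by the
  small negative 0.5-mL exhaled tail.  Set PEEP (not total PEEP) is the
  baseline; the unclipped end-expiratory pressure is logged separately.
- Dynamic distending pressure is PIP − Pmus with Pmus the breath's most
  negative value; PIP is the inspiratory-phase maximum of p_aw (onset to
  peak volume), so the expiratory-valve pressure transient is excluded.
  For unassisted breathing no ventilator pressure is delivered: PIP = 0
  and the distending pressure reduces to |Pmus|.
- Mean flow is the mean of positive-flow samples in the breath (inspired
  volume over the positive-flow window); Reynolds numbers use the tube
  for intubated/T-piece breathing and the 22-mm port for bare breathing.
- auto-PEEP is p_alv at the next effort onset minus set PEEP, clipped at
  zero with the raw value logged.
- The flow-regime bands treat [1760, 2000] as a closed transitional band;
  the strict inequalities on either side are laminar-sustainable and
  turbulent.

Gas properties are dry FiO₂ 0.4 at 20 °C: ρ = 1.231 kg/m³,
η = 18.72×10⁻⁶ kg/(m·s).  The Reynolds module works in SI; the mechanics
module uses the self-consistent clinical system (cmH₂O, L, s), with all
cross-system constants in `units.py`.

## Experiments and fits

Sweeps re-calibrate the constant-V_T controller at every condition.  The
PS sweep runs 14 → 0 cmH₂O and stops at the first non-synchronous
condition (double-triggering: > 1 pressurization per effort;
mis-triggering: an effort with none).  The WOB-vs-PS regression uses mean
WOB over synchronous levels in PS 14 → 1; PS 0 is always excluded because
a PS 0 breath is not a pressure-supported breath.  Shape models — a
4-parameter logistic in rate, a 3-parameter decaying exponential in PS —
are fitted by `scipy.optimize.curve_fit`; model choice is the caller's,
never automatic.  The closed-form surface coefficients (1.24, 0.89,
anchor 14, scale 13) and the 30.7 mJ/breath reference define the
compensating-PS function; because support is set in whole cmH₂O and must
at least offset the tube load, the integer setting is the ceiling of the
raw value (both are reported).

## What the generator does and does not emulate

The simulator reproduces the bench's *structure*: constant-V_T effort,
flow triggering with delay, first-order pressurization, flow/time cycling,
nonlinear tube losses, and the resulting orderings and trends (T-piece >
bare > PSV work at every rate; rate-flat unassisted WOB; WOB rising as PS
falls, faster at 36/min; trigger work exploding exponentially below PS 9
at 36/min; auto-PEEP onset patterns; PS-sweep intersections with the
unassisted reference in the low-PS range).  It does not claim the bench's
exact milli-joules: hardware servo dynamics, sensor filtering, and jitter
are not modelled, SDs are near zero with the noise layer off, and the
per-condition hardware means are reproduced only at the level of these
properties.  Two known behavioural gaps: (1) with a calibrated effort the
simulator stays synchronous down to PS 0, so the bench's protocol stop
from double-/mis-triggering at low PS is exercised only on constructed
low-amplitude conditions; (2) peak inspiratory flows under-shoot the
bench's (the effort template is smoother than the hardware's), so
peak-flow Reynolds numbers of simulated breaths sit below the printed
ones — the flow-regime analysis therefore evaluates Re at the printed
flows directly.  Passing tests show the physics and the analysis pipeline
are self-consistent and bracket the bench's behaviour, not that a specific
hardware unit would print identical numbers.

## Limitations

Single linear compartment (no nonlinear compliance, no recruitment, no
leak — the bench used cuffed tubes); no upper-airway resistance; no
humidifier thermodynamics beyond the kinematic-viscosity sensitivity
(15.1 → 16.6 ×10⁻⁶ m²/s, a ~9 % Re decrease); no gas-composition mixing;
the expiratory-valve resistance is an effective calibrated value; the
4.0/4.5-mm tubes and inter-group significance testing are out of scope.
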