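# Methods

## Model

The gametophore is a 1-D file of metamers growing from a terminal apex.
State per metamer: auxin concentration `c_i` (arbitrary units) and a
permanent branch flag. The apex is not a metamer; it is a boundary
vertex clamped at `H_apex`. Each simulation step applies, synchronously
from the pre-step values,

    c_i <- c_i + K_B (c_above - c_i) + K_A (c_below - c_i) - v c_i

where `c_above` of the topmost metamer is `H_apex` and `c_below` of
metamer 1 is `c_1` itself (no-flux base). After the transport update,
every unflagged metamer with `c_i` strictly below its effective
threshold becomes a branch; equality does not trigger. A branch
acquires a lateral apex — a separate vertex clamped at `H` — and from
that step on receives one extra basipetal influx `K_B (H - c_i)` while
continuing to obey the transport equation. Lateral axes are represented
by this clamped apex only; their own metamer files are not simulated
(higher-order branching is out of scope, and a growing lateral file
would progressively disconnect the source from the main axis).

The insertion metamer is deliberately *not* clamped at `H`. With
clamping, wild-type simulations give a mean minimum inter-branch
distance of ~5.9 metamers; with the lateral-apex influx they give
~4.5, matching the value measured on real wild-type shoots
(4.48 ± 1.48), and occasional adjacent-metamer initiations appear, as
observed. The lateral apex level acts through one transport edge, so
the local concentration around a branch settles below `H`, tightening
the spacing the new source imposes.

### Rate-constant semantics

`K_A`, `K_B` and `v` are per-simulation-step increments. `dt` expresses
the fraction of a plastochron covered by one step, so
`round(plastochron/dt)` steps make one plastochron (200 at dt = 0.005;
the refitted transport-rate scenarios use dt = 0.001, i.e. 1000 steps,
with correspondingly smaller per-step constants — per-plastochron decay
is the invariant quantity across the two parameter families).
Explicit-Euler stability is enforced as `K_A + 2 K_B + v < 1` (the
factor 2 covers a branch metamer's extra lateral edge); all shipped
presets satisfy it with wide margin. Concentrations then remain
non-negative and relax monotonically to the steady state given by the
tridiagonal transport-decay balance (verified in tests against a direct
banded solve, relative tolerance 1e-6).

### Growth, stochasticity, stopping

Each gametophore starts as the apex plus one metamer at `c = 0`; new
metamers are inserted below the apex at `c = 0` (they fill within a few
steps from the adjacent apex). Per gametophore, `H_apex`, `H` and `T`
are drawn once from normal distributions truncated at zero by
resampling (`sigma = 0` gives the mean exactly); the per-shoot draw is
what makes different shoots of one series branch at different depths.
The published spread values are treated as standard deviations (a
"variance" of 20 on a mean of 80 is only coherent as an SD). Growth
begins after a delay drawn uniformly from 0–4000 steps (0–20
plastochrons) and the simulation stops after 40 plastochrons' worth of
steps, which spreads final lengths approximately uniformly over 21–40
metamers, emulating the 20–40-leaf series reported for measured and
simulated shoots. Shoots outside the admissible length range are
discarded and redrawn. Each gametophore consumes an independent
deterministic substream derived from (dataset seed, index), so datasets
are reproducible and a prefix of a larger dataset equals the smaller
one.

### Basal inhibitor

Without it, the most basal metamer — oldest, farthest from the apex —
branches in essentially every shoot, which real plants do not show. The
inhibitor multiplies `T` by `basal_T_factor` (default 0.1) in the
`basal_zone_depth` (default 5) most basal metamers. The response to the
factor is nearly all-or-nothing (0% of shoots branch basally at ≤ 0.2,
~100% at ≥ 0.3) because the basal concentration minimum is tightly
determined by the profile; 0.1 places wild-type simulations firmly on
the suppressed side. Both knobs are exposed per scenario;
`basal_T_factor = 1` disables the inhibitor.

### Transport-direction variants

Only the ratio `K_A/K_B` is specified for the direction experiments;
the presets hold the total `K_A + K_B` at the wild-type 0.1 and set the
ratio, so direction varies without changing total transport capacity.
Basipetal bias (ratio < 1) deepens the apical inhibition zone; acropetal
bias erodes it until, at ratio 100, branches initiate next to the apex
and inhibition is lost.

## Null models

The stochastic null draws a length (uniform on 20–40 or copied from a
reference dataset) and branches each metamer independently with
probability `p` (default 0.05, chosen to match wild-type branch
numbers); counts are exactly Binomial(L, p). The competency variant
gates each metamer's single Bernoulli trial on reaching a minimum age
in plastochrons, which imposes an apical branch-free zone of at least
that many metamers while leaving within-zone spacing Bernoulli-random —
reproducing the apical gap but not the even dispersion.

## Synthetic patterns

The generator emulates measured-pattern structure without mechanism:
length uniform in range, an apical branch-free zone drawn
truncated-normal (default 18 ± 2 metamers, the observed pre-branching
leaf count), and branches placed in the remaining zone by sequential
hard-core sampling — uniform proposals rejected within `min_spacing` of
an accepted branch (default 3), up to 1000 proposals per branch, target
count Binomial(zone, density). With `min_spacing = 1` and no apical
zone this is exactly the Bernoulli null; with spacing it is
over-dispersed like real shoots. It does not emulate the shape of the
per-position frequency curve beyond zone + density + spacing, nor any
length–branch-number correlation beyond what zone geometry induces, so
tests passing on synthetic data validate the statistics, not the
biology.

## Statistics

Per shoot: branch number `B`; AIZ = `L − max(position)`, undefined (and
excluded from means) when branch-free — counting it as `L` would
inflate sparse genotypes; mean nearest-neighbour branch distance,
undefined below two branches ("n.d."). Dataset level: means ± SD over
defined shoots (per-shoot-first averaging, matching the ± SD reporting
convention; a pooled variant is provided), adjacent-branch shoot
fraction, basal-branch fraction (default depth 5), and per-position
frequencies conditioned on `L` ≥ position (avoiding artefactual decay
at high positions in mixed-length series), with an apex-indexed
companion. Frequency profiles can be fitted with OLS polynomials
(degree 7 default, 5 as the alternative used for heavy basal-activation
patterns).

Genotype comparison: `B = (a0 + a1 X) + (a2 + a3 X) L`, `X = 1` for the
reference group, fitted by OLS; backward stepwise elimination removes
the removable term with the largest p-value above alpha = 0.05,
interaction strictly before the main effects (hierarchy), intercept
always kept; the groups differ if `a1` or `a3` survives. Two properties
follow and are verified by simulation: each term's own test is
calibrated at ~alpha, and the *verdict* rate under the null is
necessarily ~`1 − (1 − alpha)^2` ≈ 0.0975 (two chances at alpha) — a
family-wise property of the published decision rule itself, not an
implementation artefact. With a zero-residual (noiseless) fit,
coefficient p-values are undefined; terms with zero estimates are then
treated as removable so nested noiseless data reduces to the generating
model exactly.

## Problem sizes and runtime

Simulated comparisons use 60 shoots per arm (the study's series size);
null-model moment checks use 10,000 shoots; regression calibration uses
1000 replicates of 40 shoots per group. The full test suite runs in a
few minutes on one CPU.

## Known limitations

- The basal inhibitor cannot produce intermediate basal-branching
  frequencies (see above); wild-type simulations show 0% rather than
  the few percent seen on plants.
- Adjacent-branch initiations are rarer in expectation (~5 of 60
  shoots) than the single published model dataset reports (7 of 60),
  though well within the per-dataset spread (2–9).
- Lateral axes do not grow; branch outgrowth dynamics, 2-D/3-D
  geometry, phyllotaxis and rhizoids are out of scope.
- The model is phenomenological: `H_apex`, `H`, `T` summarise synthesis,
  transport and sensitivity; no molecular transport mechanism (PIN,
  plasmodesmata) is represented beyond the rate constants.
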