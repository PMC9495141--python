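# Methods

## The estimation problem

A flatfish fillet is a roughly lens-shaped muscle whose cross-sectional
area varies along the cranio-caudal axis. Scanning a live fish at `n`
equally spaced cross-sections yields areas `A_1..A_n`; the Cavalieri
principle estimates the fillet volume as the sum of slab volumes, each
slab being the trapezoid of its two bounding areas:

    V = Σ_{i=1}^{n-1} (A_i + A_{i+1})/2 · d,      d = L_scan / n.

`filletvol` implements this estimator, the trait system built on it, and
the regression analysis used to predict actual fillet volume (measured by
water displacement in the real trial) and fillet yield from the ultrasound
traits.

## Slice-plan geometry

The protocol divides the scan length by 10 to obtain the section length
`d`, yet 10 slices bound only 9 sections — the geometry is
over-determined. We resolve it in favour of the stated `d = L/10` with
slice `i` at `x = (i−1)·d` (placement `"start"`): the last slice sits at
`0.9·L` and the caudal-most 10% of the scan is uncovered. Placement is a
plan option (`"mid"`, `"cover"`) rather than a hidden constant; `"cover"`
(`d = L/(n−1)`, slices spanning `[0, L]`) is the right choice for dense
convergence studies. A consequence of `"start"` placement worth knowing:
the 10-slice Cavalieri total systematically underestimates the true
volume by the uncovered caudal tail (~2–3% for the default profile) — the
same direction of bias seen between the published ultrasound total
(47.91 cm³) and the actual mean fillet volume (49.12 cm³).

## Spanning-volume conventions

A volume over several consecutive sections can be computed two ways: as
the **sum** of its slab volumes, or from the two **limiting slices only**,
`((A_first + A_end)/2) · span · d`. Both appear in the field's usage and
they agree only on affine profiles. Defaults here: the halves `V_1–5` and
`V_6–9` use "sum" (required for `V_1–5 + V_6–9` to telescope exactly into
the total `V_1+()+9`, an identity the published tables satisfy), while the
thirds `V_1–3`, `V_4–6`, `V_7–9` use "endpoints" (their published combined
mean exceeds the total, which plain sums cannot do). The ambiguity of
which slice closes an endpoint span (`S_6` vs `S_5` for `V_1–5`) is an
explicit option (`endpoint="next"` default, `"last"` available), not a
guess.

## Synthetic population

The generator emulates the 44-fish market-weight trial the published
summaries describe. It is a stated world, not a tuning surface: each
default is pinned either to a printed value or to one up-front choice.

| parameter | default | basis |
|---|---|---|
| body weight | truncated normal, mean 298.54 g on [178.77, 456.32] g | printed mean/range; see note below |
| length allometry | `L = 6.056 · BW^0.6164` mm | exponent from the printed CV ratio 18.0/29.2; coefficient pins the mean at 203.11 mm |
| profile shape | `g(u) = u^0.35 (1−u)^1.6 / max` | cranially peaked with a long caudal taper, matching the printed area ordering |
| fillet fraction | 0.1734 of body volume | 49.12 cm³ / 283.27 cm³ (printed means) |
| fillet fraction scatter | lognormal, log-sd 0.096, mean one | reproduces the printed yield CV 9.6% |
| densities | body 1.054, fillet 1.004 g·cm⁻³ | printed weight/volume mean pairs |
| scan noise | per-slice log-sd 0.08, per-fish log-sd 0.05 | manual-tracing error; shared session factor (probe pressure, positioning) |

**Truncated-normal note.** The printed sd (87.30 g) is unattainable for
any truncated normal on the printed range — the uniform limit caps the sd
at `(456.32−178.77)/√12 ≈ 80.1 g` — and using the printed mean as the
*parent* location shifts the realised mean to ~306 g. The parent location
is therefore solved numerically so the truncated mean equals 298.54 g
exactly (parent sd kept at 87.30; realised sample sd ≈ 70–79 g). Means are
matched exactly; dispersions are mildly compressed relative to print.

**True volume.** `A(x) = A_peak · g(x/L)` integrates in closed form:
`V = A_peak · L · B(α+1, β+1)/g_max`. The generator works backwards —
the true volume is set first (fraction × body volume × lognormal factor)
and `A_peak` derived from it — so every fish carries an exact analytic
ground truth, playing the role water displacement plays for real fish.

**What the generator does and does not emulate.** Every fish shares one
profile shape, so all noiseless volume traits are *exactly proportional*
to the true volume; predictive differences between traits arise purely
from measurement-noise averaging (traits integrating more slices average
away more per-slice noise) and from the length factor (slab volumes carry
`d ∝ L`, slice areas do not — which is why volume-trait CVs dominate
area-trait CVs, here and in the published table). Real fish vary in shape,
so real `R²` values — e.g. 0.970 for `V_1–5` — are not reproducible and a
green qualitative test establishes ordering, not magnitude. Two further
artefacts of the stated defaults: the noiseless `A_1` is exactly zero
(the profile vanishes at the operculum-end slice; the pipeline reports
NaN rows for constant predictors rather than failing), and the noiseless
slice maximum falls at `S_3` rather than the printed `S_2`.

## Regression machinery

- OLS is solved by least squares on the design matrix; identities
  (R² = r² in the simple case, prediction at the training means equals the
  mean response) are covered by tests.
- **Stepwise forward selection**: the selection criterion is the pooled
  k-fold cross-validated RMSE (k = 10). Folds are contiguous blocks of one
  seeded shuffle, fixed across all candidates and steps so scores are
  comparable. A candidate enters if it lowers the incumbent CV-RMSE by
  more than `entry_tol = 1e−3` (relative); ties break toward the earlier
  candidate. The original analysis used a proprietary stepwise tool whose
  entry/stop rules are not recoverable; CV-RMSE improvement is this
  package's own, deterministic, criterion. The reported model RMSE is the
  CV-RMSE; the resubstitution RMSE is stored alongside.
- **Correlations**: Pearson r with the exact two-sided t test at
  df = n−2. At n = 44 the critical values are 0.297 (α = 0.05) and 0.384
  (α = 0.01); the published table prints 0.298 and 0.388 — the first is a
  rounding difference, the second is unexplained, so classification always
  uses the exact test and `critical_r` exposes both. No multiple-testing
  correction is applied across the correlation grid, matching the original
  analysis; treat the grid as descriptive.
- **Yields**: `fillet_yield = 100·FW/BW`; `fillet_yield_v15` replaces the
  numerator with the fillet volume predicted from the `V_1–5` span. Note
  the mean of per-fish yields differs from the yield of mean weights
  (16.32% vs 16.52% in print) — a mean-of-ratios pitfall the validation
  suite checks explicitly.

## Numerical choices and limitations

- **Convergence order.** The trapezoid estimator is exact on affine
  profiles and `O(h²)` on smooth ones (with the caveat that profiles with
  both exponents > 1 have vanishing endpoint slopes and show `O(h⁴)`).
  The default profile rises like `u^0.35`, capping convergence at
  `O(h^{1.35})`: a 1000-slice covering plan reaches relative error
  1.06e−4, marginally above the 1e−4 target asserted in the acceptance
  suite (the bound is first met near 1045 slices). The failing test is
  kept as an honest record; the property suite verifies the convergence
  order itself.
- **Mask rasterization** uses the pixel-center inclusion rule (unbiased to
  first order). Absolute error decreases monotonically along the tested
  refinement sequence from 0.01 cm, but is not monotone from arbitrary
  coarse starts — boundary-pixel error oscillates with grid phase.
- **Validation tolerances** for the published-summary arithmetic follow
  the printing precision of the inputs (±0.005 per printed value,
  propagated through sums).
- Report CSVs round to 2 decimals (1 for CVs) at serialization only;
  all in-memory values keep full precision.
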