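# Methods

This note records the statistical model, the conventions and defaults of
every component, the scope of the synthetic generator, and the reasoning
behind the package's design choices.

## 1. The emulator

### 1.1 Model

For each grid box $x$, month $m \in \{\text{Jan},\dots,\text{Dec},
\text{annual}\}$ and variable $v$, the model is an ordinary least squares
regression

$$
g_v\!\big(Y(x,t)\big) - \overline{g_v(Y)}(x)
 \;=\; \beta_0 + \sum_{k=1}^{4}\beta_k\, z_k(t) + \beta_5\big(M(x,t)\big)
 + \epsilon(x,t)
$$

with:

* $z_1..z_4$: the z-scored continuous forcings, in fixed column order
  obliquity (degrees), precession index I ($e\sin\omega$), precession index
  II ($e\cos\omega$), CO₂ (ppm). The z-scoring statistics are computed from
  the fitting epochs and are stored with the model; predictions reuse them
  verbatim (z-scoring with prediction-time statistics would silently change
  the model).
* $M(x,t) \in \{0=\text{ocean}, 1=\text{land}, 2=\text{land ice}\}$:
  treatment-coded surface type. Ocean is the reference level with offset
  fixed at exactly 0; land and land-ice offsets are estimated only for
  levels actually observed at the pixel during training (unobserved levels
  are stored as NaN and substituted at prediction time, see §1.4).
* $g_v$: identity for temperature (K), natural log for precipitation
  (mm yr⁻¹), logit for total cloud cover (fraction). Precipitation values at
  or below zero are lifted to a floor of 0.1 mm yr⁻¹ before the log (GCM
  output is never exactly zero; other sources can be).
* $\overline{g_v(Y)}(x)$: the mean of the transformed series over the
  training epochs, removed before fitting and stored as the pixel's mean
  term.

Snapshots are treated as independent equilibrium states; no temporal
autocorrelation enters the model. Pole rows (|lat| = 90°) are never fit.

### 1.2 The per-pixel intercept (design choice)

A design with the training mean removed and *no* constant column cannot
recover the truth exactly whenever the surface type varies at a pixel: the
dummy offsets then have a nonzero time mean, which has nowhere to go. We
therefore include an explicit intercept column — the reference level's
intercept, which treatment coding implies in any case — and fold the fitted
intercept into the stored mean term. The reference level is ocean when ocean
is observed at the pixel, otherwise the lowest observed code, so the dummy
columns never span the constant. With this design a noiseless synthetic
world is recovered to ~1e-13 (see `tests/test_acceptance.py`).

### 1.3 Estimation and diagnostics

Coefficients come from `numpy.linalg.lstsq` on the explicit design matrix;
pixels sharing the same surface-type history are batched into one solve.
Stored per pixel/month/variable: coefficients, standard errors
($\hat\sigma\sqrt{(X^\top X)^{-1}_{jj}}$), two-sided t-test p-values with
$n-q$ degrees of freedom, $R^2$ (with total sum of squares about the removed
mean; defined as 0 for a constant series), and the residual RMSE on the
transformed scale. Rank-deficient designs are flagged unfit (NaN outputs plus
a reason string), not raised. `statsmodels.OLS` is used in the test suite as
an independent oracle for coefficients, standard errors and p-values, never
in the implementation.

### 1.4 Prediction

Prediction applies the stored transform pipeline in reverse: z-score the
requested forcings with the stored statistics, add the linear term and the
surface offset for the epoch's mask, add the mean term, and invert the
transform. The inverse transforms are defined on all reals, so precipitation
is positive and cloud strictly inside (0, 1) for *any* forcing input —
bounds hold pre-clamp by construction. Where an epoch's mask shows a level
the pixel never exhibited during training, the offset of the nearest fitted
level is substituted (0 when nothing is available) and the substitution is
counted in the log. Unfit pixels predict NaN.

## 2. Forcings and surface masks

* Epochs are integer ka BP, positive into the past; the snapshot schedule is
  120–24 ka at 2 ka steps plus 22–0 ka at 1 ka steps (72 epochs).
* Irregular CO₂ records are piecewise-linearly interpolated to the epoch
  grid; extrapolation outside the record is an error.
* Surface masks are rebuilt per epoch from a fixed topography (m relative to
  present sea level), a scalar sea-level offset (m, negative in glacials),
  an ice-extent flag and a lake flag. Rules in order: lake cells keep their
  present-day class; elevation ≤ sea level ⇒ ocean; ice over non-ocean ⇒
  land ice (ice flagged over ocean is dropped with a warning — sea ice is
  not a surface type here); else land.

## 3. Training selection

Candidate training subsets of size $k$ (= round-half-up of 0.8 n; 58 of 72)
are drawn uniformly without replacement, N = 10 000 times. A subset is
accepted iff every descending-sorted eigenvalue of its forcing covariance is
at least the corresponding eigenvalue of the full-set covariance (tolerance
1e-12 relative to the leading eigenvalue; equality passes). Epochs are ranked
by how often they appear in accepted subsets — ties break toward the older
epoch — and the top $k$ form the training set. An exhaustive enumeration mode
exists for small n and is used as the test oracle. The covariance uses the
four continuous forcings (the categorical surface type has no epoch-level
covariance); this is configurable at the call site. The check is
scale-aware but its verdicts are identical on raw or z-scored forcings for a
given subset, since both covariances transform identically.

## 4. Downscaling and delta correction

* **Bilinear regridding**: longitude is periodic (wrap-around weights);
  target latitudes must lie inside the coarse span (error otherwise).
  Descending latitude axes are handled. Where some of a fine cell's four
  coarse neighbours are NaN, the highest-weight valid neighbour value is
  substituted so coastlines do not erode; all-NaN neighbourhoods stay NaN.
* **Delta correction**: $\hat Y(x,t) = \big(Y_{\rm em}(x,t) -
  Y_{\rm em}(x,0)\big) + Y_{\rm ref}(x)$ per cell and month. The anomaly
  term vanishes identically at the reference epoch, so the corrected field
  reproduces the reference *bit-for-bit* there (this is why the subtraction
  is grouped first). Anomalies between any two epochs are untouched. Cells
  invalid in the reference return NaN. Two tail policies:
  * default (natural scale): bounded variables are clamped post hoc
    (precipitation to ≥ 0, cloud to [0, 1]) with the number of clamped
    values logged; the pre-clamp field is available via `clamp=False`;
  * `scale="transformed"`: the delta is applied on the variable's regression
    scale and inverted, which keeps bounds without clamping at the cost of
    no longer being an additive correction on the natural scale.
  The pipeline keeps the raw regridded field outside the reference's valid
  footprint and marks the product with a provenance attribute.

## 5. Bioclimatic variables

17 layers: BIO1, BIO4–BIO19. BIO2 (mean diurnal range) and BIO3
(isothermality) require within-month temperature extremes that monthly-mean
climatologies do not contain; they are deliberately never emitted.
Conventions:

* temperatures enter in K, leave in °C; the extra layer `tmin_ann` (coldest
  monthly mean) is kept in K;
* BIO5 is the warmest-month and BIO6 the coldest-month temperature — the
  convention under which BIO7 = BIO5 − BIO6 ≥ 0;
* a quarter is any of the 12 consecutive three-month windows with Dec–Jan
  wrap-around; ties pick the earliest window;
* BIO4 is the population standard deviation of monthly temperature in °C
  (no ×100 scaling); BIO15 is 100·sd/mean of monthly precipitation, defined
  as 0 where the mean is 0;
* precipitation is carried as an annual-equivalent rate (mm yr⁻¹); BIO12 is
  the mean rate and monthly/quarterly totals (BIO13/14, BIO16–19) convert
  the rate uniformly at 1/12 per month.

## 6. Validation

* **Goodness maps**: per-pixel fit R² (training diagnostics) and
  natural-scale RMSE on held-out epochs (which must be disjoint from the
  training epochs; enforced).
* **Spatial covariance**: the pixel×pixel covariance of per-pixel series
  across epochs (unbiased n−1 denominator), over unmasked/finite pixels
  only, so the matrix dimension equals the unmasked pixel count. Truth and
  emulation are compared over common epochs via Frobenius norms of the two
  matrices and their difference.
* **Proxy correlation**: the emulated series at the grid cell containing the
  core site, paired with each proxy sample's nearest model epoch within
  ±0.5 ka (unmatched samples dropped, ≥3 pairs required), Pearson by default
  with a Spearman option. Correlation is affine-invariant, so proxies in
  arbitrary units need no calibration. A proxy on a masked cell raises an
  error naming the nearest valid cell.

## 7. The synthetic generator

Defaults *are* the study conditions and are not tuning knobs: 72 snapshot
epochs (120:2:24 ∪ 22:1:0 ka BP), an 800-epoch hindcast axis (799…0 ka),
CO₂ 180–300 ppm on a ~100 ka saw-tooth, obliquity 22–24.5° at ~41 ka,
precession indices within ±0.06 at ~21 ka, a 12×10 coarse grid, and
regression-scale noise sd 0.2 for every variable.

The world is generated from the emulator's own model class: smooth
(low-order Fourier) true coefficient and mean fields per month/variable, a
smooth topography with ~40 % of cells below present sea level plus two
preserved lakes, sea level tied to CO₂ (0 m at 300 ppm, −120 m at 180 ppm)
and an ice edge moving equatorward as CO₂ falls, and i.i.d. Gaussian noise
added on the regression scale so snapshot bounds hold by construction. A
single seed is split into named substreams (coefficients, topography, noise,
reference bias, proxies), so components are independently reproducible.
The present-day reference is the regridded epoch-0 truth plus a smooth
synthetic observation bias (default amplitudes 2 K, 50 mm yr⁻¹, 0.05 cloud
fraction), valid over non-ocean cells. Proxies sample the local noise-free
annual temperature at irregular ages with white noise sd = signal sd / SNR.

**Scope**: the generator validates the *machinery* — estimation,
bookkeeping, transforms, regridding, closure — under the model's own
assumptions. It does not emulate atmospheric dynamics, spatially correlated
noise, or nonlinear responses; agreement on synthetic worlds says nothing
about how well a linear model approximates a real GCM.

## 8. Numerical choices

* OLS via `lstsq` with pixels grouped by identical surface-type histories
  into batched solves; a 96×73 grid (7008 pixel-model slots per
  variable/month) fits in seconds.
* Eigenvalues via symmetric `eigvalsh`; candidate-check inputs must be
  symmetric to 1e-10.
* The full-dimension product path (720×360×800) uses float32 to stay within
  a few GiB; default paths are float64.
* NetCDF interchange is classic-format (NetCDF3) through xarray's scipy
  backend, CF-flavoured: lon/lat coordinate variables, `units` on every data
  variable, NaN for missing, integer surface-type codes with
  `flag_meanings`, time in ka BP. Longitudes are normalized to [−180, 180)
  on read with the data reordered to keep the axis monotonic.
* The pipeline manifest contains only seed-deterministic content (no
  wall-clock timestamps); same-seed reruns are byte-identical.

## 9. Resolved design questions

* *Which covariance for selection?* The four continuous forcings; the
  surface type is a per-pixel series, not an epoch-level forcing.
* *Z-scoring statistics*: always the fitting set's, stored with the model.
* *Zero precipitation under the log transform*: floored at 0.1 mm yr⁻¹.
* *Corrected product where the reference has no coverage*: the raw regridded
  emulation is kept and the file carries a provenance flag, rather than
  returning NaN over the ocean.
* *Proxy comparison stage*: configurable (coarse hindcast by default, the
  corrected product optionally) — correlation is invariant to the additive
  correction at a fixed cell, so the choice mainly affects the land mask.
* *Ice-sheet history between epochs*: a single mask history is accepted as
  given; temporal blending of alternative reconstructions is left to the
  caller.
* *Hindcast time axis*: 1 ka steps ending at 0 ka (799…0), length
  configurable.

## 10. Limitations

* Linearity in the forcings and additivity of the surface-type offset are
  assumptions, not findings; abrupt-event dynamics and forcing interactions
  are outside the model class.
* Equilibrium snapshots ignore disequilibrium (e.g. deglacial transients).
* The delta correction assumes the model bias is stationary in time.
* Held-out validation epochs are interpolative by design of the selection
  procedure; skill at true extrapolation (forcings outside the training
  hull) is not established.
* The bioclim quarter convention (calendar 3-month windows, earliest-window
  ties) matches common practice but other conventions exist; values can
  differ slightly from implementations using fixed calendar quarters.
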