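# Methods

## Morphometry

Cell outlines are closed simple polygons in micrometre coordinates, one per
CD163+ macrophage, tagged with a slide and an invasive-margin zone. Area is
the absolute shoelace sum, perimeter the Euclidean edge sum including the
closing edge; both are exact for the stored vertices — outlines are never
smoothed or resampled, because the trace itself is the measurement. Polygons
with fewer than 3 vertices, non-finite coordinates, zero signed area or
self-intersections are rejected rather than repaired; silent repair would
corrupt the morphometry. Files in pixel units are converted on load by a
microns-per-pixel factor (default 1.0).

The sampling protocol mirrors the microscope workflow: per slide, 3 zones
and 7 cells per zone drawn uniformly without replacement (configurable), so
21 cells are measured per slide. Each slide's random draw is seeded by a
CRC32 hash of its id combined with the global seed, which makes the
selection per-slide stable: adding or removing other slides never changes an
existing slide's sample. The patient readout is the unweighted mean of the
zone means — *not* the pooled cell mean; with unequal zone sizes these
differ, and the zone average is the protocol's definition. Slide summaries
carry both the zone-averaged means and the pooled per-cell SD, labelled
explicitly, because the two dispersions answer different questions.

## Cutoff and classification

The ROC uses slide-mean area as the marker for recurrence, test-positive
meaning area ≥ threshold. The AUC is trapezoidal over the full empirical
curve and therefore equals the tie-corrected Mann–Whitney concordance
U/(n₁n₀) exactly (a property the tests assert to 1e-12). Its CI comes from
DeLong's structural-components variance by default, or a patient-level
bootstrap.

`optimal_cutoff` is the classical Youden argmax with ties broken toward the
smaller threshold. The pipeline's classification stage, however, uses a
**one-SE rule**: the smallest candidate threshold whose J lies within one
binomial standard error of the maximum (trivial all-positive/all-negative
operating points excluded). Reasoning: with few non-events the empirical
Youden argmax is erratic — crossing one censored high-area patient buys
1/n_nonevents of specificity against only 1/n_events of sensitivity, so the
argmax performs a nearly-critical random walk into the large-area
population, and every high-risk patient it strips from the L-TAM class
dilutes the small S-TAM reference group disproportionately. Among
statistically indistinguishable operating points the rule prefers the most
sensitive one, which is also the clinically sensible direction (missing a
high-risk patient costs more than over-calling one) and matches the
sensitivity-favoring operating points such analyses report in practice.
The SE multiplier is configurable (`cutoff_se_factor`; 0 restores the plain
argmax), and a fixed cutoff (default 151.38 µm², the published reference
value) can be used instead of deriving one. A patient whose mean area
equals the cutoff is classified L-TAM; the boundary convention is arbitrary
but must be deterministic and documented.

## Survival analysis

Kaplan–Meier estimation, the Mantel–Cox log-rank test and the Cox partial
likelihood are delegated to lifelines; ties use Efron's method, the better
approximation at monthly time resolution (Breslow is not exposed). The
3-year DFS readout is the right-continuous KM step function evaluated at
t = 36 months. The univariate screen reports uncorrected χ² (no Yates) for
binary variables — matching common clinical-statistics defaults — with
Fisher's exact test when any expected cell is below 5, and a two-sided
Mann–Whitney U for continuous variables, exact by full enumeration when
both groups have ≤ 8 observations. Raw p-values are reported without
multiplicity correction, as such screening tables conventionally are; this
is a presentation choice, stated here.

Variables with univariate p < 0.05 enter the multivariable Cox model
alongside the TAM class. Overfitting control follows the internal-validation
bootstrap: patients are resampled with replacement (default 1000 draws),
giving percentile CIs per covariate and an optimism estimate of the
concordance index (mean of bootstrap-apparent minus bootstrap-model-on-
original concordance; corrected C = apparent − optimism). Constant
covariates raise a degeneracy error before fitting; non-convergence and
separation warnings are surfaced, not swallowed. Records with missing
modelled covariates are dropped with a warning, never imputed.

## Spatial analysis

The peritumoral band is the outward offset of the tumor contour by 500 µm
(round joins, 32 arc segments per quadrant — the polygonal approximation
error on a circular contour is ≈ 0.05%, well inside the 0.5% the tests
allow) minus the tumor interior. Density maps rasterise the band at 20 µm;
each in-band pixel counts centroids within a closed Euclidean ball of the
count radius (500 µm for display maps), computed exactly with a k-d tree —
no kernel smoothing, no approximation in the counts. Foci are 8-connected
components of in-band pixels whose radius-200-µm count reaches 100; the
count field is recomputed at 200 µm rather than rescaled from the 500-µm
map, since counts at different radii are not proportional. Per-focus area
is pixel count × pixel-size²; the 20-µm default sits far below both radii,
and halving it changes total foci area by < 5% on smooth clusters (asserted
in tests). A cell's position is its polygon centroid, and a cell counts as
L-TAM for spatial purposes when its *own* area reaches the cohort cutoff —
a per-cell rule, since one slide contains both populations. Total foci
areas are compared between outcome groups with a two-sided Mann–Whitney
test, exact by enumerating all C(n₁+n₂, n₁) group assignments when both
groups have ≤ 8 slides (the subset design is 6 vs 6), asymptotic above.

## Synthetic cohort generator

The generator emulates, at annotation level, the structures the analysis
assumes; it produces no pixel images.

* **Area model.** Patient slide-mean areas are a two-component lognormal
  mixture with medians 150 µm² (favorable) and 217 µm² (unfavorable) and
  component log-SD 0.10; the unfavorable mixture weight is 66/84. Per-cell
  areas are lognormal around the patient mean (log-SD 0.22), mean-anchored
  so the measured slide mean is unbiased for the generated one. The spreads
  follow from decomposing a pooled per-cell CV of ≈ 0.31 (≈ 68.6/217.7)
  into between-patient and within-slide parts; with 21 cells averaged per
  slide the measurement noise on a slide mean is ≈ 5%, giving two clearly
  separable patient populations. Real cohorts overlap more (reported AUCs
  sit near 0.73); both spreads are configurable.
* **Outlines.** Cells render as star-shaped polygons (12–40 vertices,
  jittered angles and radii, irregularity 0.25) rescaled to the target area
  exactly; irregularity 0 gives a regular polygon.
* **Survival.** DFS times are exponential with hazard h₀·HR^{1(L)} (h₀ =
  0.02/month, HR = 5), censored by an independent U(0, 60 months) time —
  the true censoring mechanism of any real cohort is unknowable, so the
  simplest independent mechanism is used. OS adds an exponential
  recurrence-to-death lag (mean 18 months) under the same censoring time,
  which guarantees DFS ≤ OS. Binary clinical covariates are drawn at
  configurable prevalences, independent of class by default.
* **Spatial subset.** Mirroring the subset design, the 6 patients with the
  earliest recurrences receive Thomas-clustered L-TAM centroids in the band
  (Poisson(4) parents, Poisson(150) offspring each, Gaussian σ = 50 µm) and
  the 6 longest event-free patients receive homogeneous Poisson L-TAMs at
  the same expected total (600); S-TAM centroids are homogeneous Poisson
  (600) in both arms. A ~150-cell cluster of σ = 50 µm concentrates ≈ 100+
  cells within 200 µm and reliably crosses the focus threshold, while 600
  dispersed cells put only ~14 in any 200-µm ball.
* **Truth sidecar.** True class labels, slide means and spatial arms are
  written to `truth.json`, which analysis modules never read — only tests
  use it for recovery checks. Generation is byte-reproducible from the seed.

What passing tests on this generator do **not** show: performance under
realistic class overlap (where misclassification attenuates the hazard
ratio toward the *measured-class* estimand rather than the latent one),
informative censoring, annotation noise (truncated or duplicated traces),
or irregular tumor contours; the spatial model also ignores intratumoral
macrophages entirely, as does the analysis.

## Numerical and design notes

* Coordinates are slide-frame (x right, y down), µm after scaling.
* Counting uses closed balls (≤ radius); component labelling is
  8-connected; both are conventions where the source protocol is silent,
  chosen and tested.
* Density-map pixels store exact integer counts; the only approximations
  in the spatial stage are the polygonal arc segments of the band and the
  raster discretisation of foci areas.
* The toy/oracle problem sizes in the test suite (1,000 random polygons,
  200 ROC instances, 1,000 null Cox replicates at n = 100, 200 recovery
  replicates at n = 84, 100 seeds of the 6-vs-6 spatial contrast) were
  chosen to bound Monte-Carlo error at the asserted tolerances while
  keeping the suite runnable in a few minutes.
* Known limitations: no time-dependent ROC (censored patients count as
  non-events when deriving the cutoff — the instability this induces is
  exactly why the one-SE rule exists); no competing risks; no intratumoral
  analysis; no multiplicity correction in the univariate screen.
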