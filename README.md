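# tammorph

Quantitative morphometry of tumor-associated macrophages (TAMs) as a
prognostic marker in resected colorectal liver metastases, implemented as a
tested, reusable analysis pipeline.

Pathology groups have shown that the *size* of CD163+ macrophages at the
invasive margin of a liver metastasis stratifies recurrence risk: patients
whose macrophages are small (S-TAMs) do far better after hepatectomy than
patients with large macrophages (L-TAMs). `tammorph` implements the full
analysis chain behind that observation for anyone who has traced cell
outlines (e.g. QuPath/NDP.view2 annotation exports) and a clinical follow-up
table — and, because such datasets are rarely shareable, ships a synthetic
cohort generator that emulates the statistical structure of a study cohort
so the entire pipeline can be exercised and validated without external data.

## What it computes

1. **Morphometry** — per-cell area (shoelace) and perimeter (edge sum) of
   traced outlines in µm; the bench protocol of 3 invasive-margin zones × 7
   randomly sampled cells per slide; slide mean = unweighted mean of zone
   means.
2. **Classification** — ROC of slide-mean area against recurrence; AUC with
   DeLong (or bootstrap) CI; Youden-J optimal cutoff with a sensitivity-
   favoring one-SE selection rule; patients with mean area ≥ cutoff are
   L-TAM, below it S-TAM (a fixed published cutoff of 151.38 µm² can be used
   instead).
3. **Survival** — Kaplan–Meier curves per class with the 3-year DFS readout,
   Mantel–Cox log-rank test, χ²/Fisher and Mann–Whitney univariate screens,
   and a multivariable Cox proportional-hazards model (Efron ties) with
   patient-level bootstrap percentile CIs and an optimism-corrected
   concordance index.
4. **Spatial statistics** — the 500-µm peritumoral band (polygon offset of
   the tumor contour), density maps counting L-TAM centroids within a fixed
   radius of each pixel, detection of high-density *foci* (≥ 100 cells
   within 200 µm, 8-connected components), and an exact Mann–Whitney
   comparison of total foci area between outcome groups.

In the standard notation: with per-cell areas \(A_{ij}\) in zone \(j\), the
patient readout is \(\bar A = \tfrac1Z \sum_j \overline{A_{\cdot j}}\); the
cutoff \(c^\*\) maximizes Youden's \(J(c) = \mathrm{se}(c) +
\mathrm{sp}(c) - 1\); survival is modelled as \(h(t \mid \text{L-TAM}) =
h_0(t)\, e^{\beta}\) with \(\mathrm{HR} = e^{\beta}\); a density map is
\(D(p) = \#\{i : \lVert x_i - p \rVert \le r\}\) on a 20-µm grid over the
band, and a focus is a connected component of \(\{p : D_{200}(p) \ge
100\}\).

## Worked example

```bash
python examples/02_roc_survival.py
```

```
AUC 0.72 (95% CI 0.58-0.85); cutoff 166.04 um^2
L-TAM: n=71, 3-year DFS 7.8%
S-TAM: n=13, 3-year DFS 60.6%
log-rank chi2=13.11, p=0.00029
Cox HR (L-TAM vs S-TAM) 5.60 [1.99-15.79], p=0.0011
bootstrap 95% CI [2.26-32.58]; concordance 0.59 (optimism-corrected 0.67)
```

The simulated cohort has a true hazard ratio of 5 for the large-macrophage
class: an 84-patient cohort discriminates the classes with AUC ≈ 0.7,
derives a cutoff between the two area populations (~150 vs ~217 µm²
medians), and the fitted Cox CI covers the generating hazard ratio. The
other examples demonstrate the sampling protocol (`01`), the density-map /
foci contrast between clustered and dispersed L-TAM patterns (`03`), and
the end-to-end report bundle (`04`).

The same stages are available from the shell:

```bash
tammorph simulate --seed 5 --n 84 --out cohort/
tammorph run-all --input-dir cohort/ --out report/
tammorph report --bundle report/
```

## Layout

```
src/tammorph/
  morphometry.py   cell outlines, area/perimeter, sampling protocol, slide means
  cohort.py        ROC/cutoff, classification, KM, log-rank, Cox + bootstrap
  spatial.py       peritumoral band, density maps, foci, group comparison
  simulate.py      synthetic cohort generator (+ truth sidecar for tests)
  io.py            GeoJSON/CSV/raster readers and writers, pipeline config
  pipeline.py      stage driver: simulate/load -> measure -> classify ->
                   survive -> spatial -> report
  cli.py           thin click CLI (simulate, measure, classify, survive,
                   spatial, run-all, report)
docs/methods.md    model assumptions, parameter choices, limitations
examples/          one narrative script per capability
```
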