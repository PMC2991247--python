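# intmark

**Association between retroviral integration sites and chromatin markers.**

Retroviruses copy their genome into host chromosomal DNA, and where they land
is far from random: gammaretroviruses such as MLV strongly prefer chromatin
carrying particular histone modifications (H3K4me1/me3, H3K9ac) and
transcription-factor binding sites.  Quantifying that preference from an
integration-site list and a set of ChIP-seq peak files is statistically
awkward — the datasets are extremely skewed (a few hundred proviruses against
a genome of marker peaks), p-values scale with dataset size, and ROC AUC is
blind to the absolute number of false positives.  `intmark` is a toolkit for
doing this analysis properly, for virologists, gene-therapy safety analysts
and regulatory genomicists:

* **Matched controls.** Cloning integration sites relies on restriction
  digestion, which biases where sites can be observed.  Each experimental
  site is matched by (default) 10 in-silico controls placed at the same
  distance from a randomly chosen recognition site of the cloning enzyme.
* **Normalized F<sub>β</sub> score.** A site is *associated* with a marker
  when it lies within a window *w* (default 2 kb) of the nearest peak.
  Counting experimental sites (*V*) and controls (*C*) inside the window
  gives tp/fn/fp/tn, and the false positives are normalized to the control
  ratio, fp′ = fp·*V*/*C*, making the score independent of how many controls
  were drawn:

      P = tp / (tp + fp′),   R = tp / V,
      F_β = (1 + β²)·P·R / (β²·P + R),   β = 0.5

  β = 0.5 weights Precision over Recall, which suits genome-scale marker
  sets.  A degenerate marker covering every base gives P = ½, R = 1; markers
  with F ∈ (0.5, 1] are called associated.  Significance comes from the
  two-sided Fisher exact test (χ² for large, well-populated tables),
  Bonferroni-corrected, computed in log space so values such as 10⁻³⁵⁰
  survive.
* **Metric bench.** AUC, AUPR, F₀.₅/F₁/F₂, odds ratio, Shannon mutual
  information and difference of proportions, each compared with the ranking
  by significance through the pairwise agreement score *D*.
* **Supermarker.** Each marker becomes a Gaussian mixture centered on its
  peak summits (kernel scale = mean peak width); markers combine with
  weights F/(1−F); local maxima of the composite are ranked by amplitude and
  thresholded to the top-k* that maximizes the training F score.  The
  resulting reduced peak set Γ* predicts integration probability for any
  locus at base-pair resolution (closed-form Gaussian integrals) and supports
  10-fold cross-validation and density/site-count correlation.
* **Mandala plots.** A circular genome view: angle = genomic position,
  radius = log distance (1 bp … 1 Mb) to the nearest marker.
* **Synthetic data.** Toy genomes with planted association structure so the
  whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from intmark import synthetic as syn
from intmark.core_io import SiteSet
from intmark import (generate_matched_controls, associate, fit_supermarker,
                     crossvalidate, locus_probability, Region)

layout, resites = syn.simulate_genome(n_chrom=2, chrom_length=5_000_000, seed=42)
m1 = syn.simulate_peakset(layout, 300, 400, seed=11, label="H3K4me3")
m2 = syn.simulate_peakset(layout, 300, 400, seed=12, label="H3K9ac")
noise = syn.simulate_peakset(layout, 300, 400, seed=13, label="CTCF")
s1, _ = syn.simulate_integrations(layout, m1, 150, 0.9, 400, seed=21)
s2, _ = syn.simulate_integrations(layout, m2, 150, 0.9, 400, seed=22)
sites = SiteSet("MLV-like", layout,
                np.concatenate([s1.chrom_ids, s2.chrom_ids]),
                np.concatenate([s1.pos, s2.pos]))
controls = generate_matched_controls(sites, resites, ratio=10, seed=43)

for m in (m1, m2, noise):
    r = associate(sites, controls, m, w=2000)
    print(f"{r.marker:8s} wi2kB = {100*r.wi:5.1f}%  P = {r.precision:.3f}  "
          f"R = {r.recall:.3f}  F0.5 = {r.f:.3f}  p = {r.p}  "
          f"associated = {r.associated}")

fit = fit_supermarker([m1, m2, noise], sites, controls)
mod = fit.model
print(f"supermarker: {'+'.join(mod.marker_labels)}  k* = {mod.k_star}  "
      f"train F0.5 = {mod.f_train:.3f}")
cv = crossvalidate([m1, m2], sites, controls, folds=10, seed=7)
print(f"10-fold CV: mean held-out F0.5 = {cv.mean_f:.3f} (sd {cv.std_f:.3f})")
print(f"P(integration in chr1:1,000,000-1,100,000) = "
      f"{locus_probability(mod, Region('chr1', 1_000_000, 1_100_000)):.2e}")
```

prints

```
H3K4me3  wi2kB =  52.0%  P = 0.828  R = 0.520  F0.5 = 0.740  p = 5E-60  associated = True
H3K9ac   wi2kB =  50.7%  P = 0.839  R = 0.507  F0.5 = 0.742  p = 9E-62  associated = True
CTCF     wi2kB =   9.3%  P = 0.442  R = 0.093  F0.5 = 0.253  p = 3E-1  associated = False
supermarker: H3K4me3+H3K9ac  k* = 574  train F0.5 = 0.845
10-fold CV: mean held-out F0.5 = 0.845 (sd 0.015)
P(integration in chr1:1,000,000-1,100,000) = 6.71e-03
```

Half the sites were planted around each of the two informative markers, so
each single marker recalls ~50% at high precision (F₀.₅ ≈ 0.74); the
irrelevant marker sits at background (F ≈ 0.25, not significant).  The
exhaustive subset search combines exactly the two informative markers and
drops the irrelevant one; the cross-validated F of the combined supermarker
(0.845) beats either single marker, and held-out performance matches training,
showing the amplitude threshold k* is not overfit.

The same operations are exposed as a CLI (`intmark simulate`,
`make-controls`, `associate`, `sweep-window`, `rank-metrics`,
`supermarker-fit`, `supermarker-cv`, `supermarker-predict`,
`supermarker-corr`, `mandala`); every run writes a manifest with input
checksums and the seed, making outputs reproducible byte for byte.

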