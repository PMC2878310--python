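# wavequant

Wavelet signal-threshold de-noising for light/heavy peptide ratio
quantification in LC-MS.

## The problem

Quantitative proteomics with differential stable-isotope labeling
(ICAT/SILAC-style) measures a peptide's relative abundance as the ratio
of chromatographic peak areas of its isotopically *light* and *heavy*
forms. Both areas come from extracted-ion chromatograms (XICs) —
intensity of a narrow m/z window traced across successive spectra — and
XICs are noisy. Classical smoothing filters (moving average,
Savitzky-Golay, Gaussian, Butterworth) either flatten genuine peak
structure or leave background noise that biases the integrated areas,
and they routinely merge a peptide's peak with a neighbouring peak that
elutes immediately after it. Both failure modes corrupt the ratio.

`wavequant` is for proteomics tool builders and computational method
developers who need an accurate, scriptable quantification engine:
a library first, with a thin `wavequant` command-line wrapper.

## The method

The observed trace is modeled as x(t) = s(t) + n(t) with Gaussian white
noise n(t). In an orthonormal wavelet basis (Daubechies-4 by default,
J = 4 decomposition levels) white noise stays white while the peak
concentrates into few coefficients, and orthogonality preserves energy
(Parseval), so coefficient-domain thresholds translate directly to the
trace. De-noising composes three ingredients:

1. **Universal threshold.** The noise level is estimated robustly as
   σ̂ = median(|W₁|)/0.6745 from the finest-scale detail coefficients,
   and the Donoho–Johnstone threshold T = σ̂·√(2 ln N) bounds the
   maximum of N Gaussian noise coefficients with high probability.

2. **Hybrid hard/soft shrinkage.** Coefficients with |w| ≤ T are
   zeroed; survivors become sign(w)·(|w| − λT) with λ ∈ [0, 1]. λ = 0
   is exactly hard thresholding (shape-preserving but jagged), λ = 1
   exactly soft (smooth but biased); the default λ = 0.25 sits in the
   documented operating range [0.1, 0.4].

3. **Spatial-adaptive cross-scale correlation.** A true singularity
   (peak edge) is large across adjacent scales while noise fades as
   scale coarsens, so the product Corr₂(j, n) = W(j, n)·W(j+1, n),
   rescaled per scale to the energy of W, amplifies signal and
   suppresses noise. Positions whose correlation evidence dominates the
   coefficient *and* exceeds the universal threshold are extracted as
   signal and bypass shrinkage — rescuing exactly the sharp features
   plain thresholding would erode.

Around the de-noiser sits the quantification machinery: XIC extraction
from mzML/mzXML, peak-region location with a noise-aware boundary walk,
valley-based separation of overlapping peaks, flank-median background
subtraction, trapezoidal integration over retention time, weighted
merging of charge states, and protein-level aggregation that averages
unique peptides' L/H ratios after recursively eliminating outliers
(round 1: keep ratios within median ± √median; later rounds: mean ±
√mean of the survivors, until stable).

A first-class synthetic-data module generates light/heavy chromatogram
pairs and toy spectra with analytically known areas and ratios, so the
whole pipeline is testable without instrument data.

## Worked example

`examples/quantify_ratio_sweep.py` regenerates the standard validation
design — 20 synthetic peptide pairs per mixing ratio, 5% apex noise —
and runs the full pipeline on each:

```
 true L/H  recovered  rel. error
     0.50     0.5005       0.10%
     0.67     0.6654       0.69%
     1.00     0.9988       0.12%
     1.50     1.4903       0.65%
     2.00     1.9924       0.38%
```

Each row is one mixing ratio: the protein-level ratio recovered by the
pipeline and its relative error, 100·|recovered − true|/true. Errors of
a percent or less across the 1:2 … 2:1 range mean area integration and
outlier-pruned aggregation are unbiased over the usable dynamic range
of this kind of experiment.

The other examples each demonstrate one capability with printed
numbers: `denoise_trace.py` (error halved at SNR 5),
`separate_overlapping_peaks.py` (a 30% area error from a merged
neighbour peak drops to 0.5% after the split), and
`protein_outlier_elimination.py` (the elimination audit trail).

## Command line

```sh
wavequant simulate --out sim --ratio 1.5 --noise-sigma 5   # synthetic fixture
wavequant quantify --input sim/synthetic.mzML --targets sim/targets.tsv --out results
wavequant denoise trace.tsv smooth.tsv                     # single-trace utility
```

`quantify` writes `peptides.tsv` (per charge state: areas, ratio,
weight, flags), `proteins.tsv` (aggregated ratios with survivor counts)
and `run_config.json` (the complete parameterization). All tunables —
wavelet, levels, λ, boundary mode, thresholds, m/z tolerance, valley
fraction — are flags or JSON config keys.

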