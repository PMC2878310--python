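# Methods

## Signal model and transform layer

A single-ion chromatogram is modeled as x(t) = s(t) + n(t): a smooth
elution profile plus Gaussian white noise of standard deviation σ.
All de-noising happens in an orthonormal discrete wavelet basis,
computed by PyWavelets behind the `wavequant.wavelets` surface. Only
orthogonal banks are accepted (Haar, Daubechies, symlets, coiflets):
orthogonality gives exact energy conservation (Parseval), which is what
lets a noise level estimated on coefficients be compared against the
trace, and guarantees that zeroing a coefficient removes exactly its
energy from the reconstruction.

Conventions and numerical choices:

* **Default bank db4, J = 4 levels.** Daubechies-4 is the standard
  compactly supported orthogonal choice; four levels separate
  noise-dominated fine scales from the peak-carrying coarse scales for
  peak widths of a few to a few dozen scans.
* **Boundary handling**: periodic ("periodization") by default, the
  only mode with exact energy conservation and exact length halving;
  symmetric extension is available behind `boundary_mode`.
* **Lengths not a multiple of 2^J** are padded by edge replication to
  the next multiple; the pad is recorded and stripped after inverse
  transform. Energy statements apply to the padded signal.
* **Scale indexing**: `details[0]` is the finest scale (scale 1), the
  scale used for noise estimation.
* **Highpass sign**: the stored filter pair is exactly what the
  transform applies (PyWavelets convention, highpass =
  (−1)^(k+1)·reversed lowpass). The opposite global sign is equally
  common in the literature; it flips detail-coefficient signs and
  nothing observable, so tests check the quadrature-mirror relation up
  to overall sign.

## Noise estimation and thresholding

σ is estimated as median(|W₁|)/0.6745 — the median absolute deviation
of the finest-scale details, rescaled so that it is unbiased for
Gaussian noise and robust to the few signal-carrying coefficients. The
universal threshold T = σ·√(2 ln N) (N the padded signal length) is the
Donoho–Johnstone bound under which the maximum of N Gaussian noise
coefficients falls with probability → 1.

Shrinkage is the hybrid rule: 0 for |w| ≤ T, else sign(w)·(|w| − λT).
This is the unique linear-in-λ interpolation that reproduces hard
thresholding at λ = 0 and soft thresholding at λ = 1. λ defaults to
0.25, the midpoint of the documented operating range [0.1, 0.4]; it is
a bias/variance dial (smaller λ preserves peak height, larger λ gives
smoother output) and is exposed in every configuration surface.

**Threshold scope.** By default one global σ̂, estimated from the
finest scale (after removing masked signal coefficients), sets the
threshold applied at every scale — the convention implied by estimating
MAD "in the first scale" and correct for white noise, which has equal
σ at all scales of an orthonormal transform. A per-scale mode
(σ̂ re-estimated on each scale's own unmasked coefficients) exists
behind `threshold_scope="per-scale"` for noise whose level varies with
frequency; it is *not* the default because on coarse scales the signal
dominates the median, inflating σ̂_j and systematically over-smoothing
— in testing this filled the valley between overlapping peaks enough to
defeat the overlap splitter even on noiseless input.

Approximation coefficients are never thresholded.

## Spatial-adaptive cross-scale correlation

Noise energy fades as scale coarsens while a genuine edge stays large
across scales, so the product of bordered scales,
Corr₂(j, n) = W(j, n)·W(j+1, n) for j = 1..J−1 (coarser coefficient at
position ⌊n/2⌋, reflecting dyadic decimation), amplifies edges and
suppresses noise. Per scale, Corr₂ is rescaled to the energy of W
(NewCorr₂ = Corr₂·√(ΣW²/ΣCorr₂²)) so the two are directly comparable;
a scale with zero correlation energy carries no evidence and is flagged.

The classification loop marks position (j, n) as signal when

1. |NewCorr₂(j, n)| ≥ |W(j, n)|, and
2. |NewCorr₂(j, n)| ≥ σ̂_j·√(2 ln N) — the correlation evidence itself
   clears the universal threshold.

Condition 2 is what gives the mask its meaning: the mask exists to
rescue coefficients that thresholding would wrongly zero, so membership
demands evidence at the same significance the threshold itself uses.
Without it roughly a third of pure-noise positions pass condition 1 on
every pass (the product of two noise coefficients, rescaled to
coefficient energy, exceeds a small coefficient easily), and noise
marked as signal is noise kept forever. Marked coefficients are zeroed
in a working copy, energies and correlations recomputed, and the pass
repeats; every scale receives at least one pass, then retires once its
residual energy falls to the noise floor stop_factor·σ̂_j²·L_j
(`stop_factor` default 1, `max_iterations` default 20). Checking the
floor only *after* a first pass matters: for a weak isolated edge the
scale's total energy is statistically indistinguishable from noise, and
a pre-gated loop would miss it about half the time even though the
pointwise correlation evidence is decisive.

Masked coefficients bypass shrinkage entirely; everything else is
shrunk with the threshold re-estimated from the unmasked coefficients.
Ties (|NewCorr₂| = |W|) classify as signal, favouring retention.

`locate_edge` turns the mask into a sample-domain position: the masked
position with the strongest correlation evidence (in units of its
scale's σ̂_j) is refined to one sample by the largest finest-scale
coefficient magnitude inside its dyadic support. Localization is
sharpest for edges off the coarse dyadic grid; a step aligned exactly
to a 2^j boundary has identically zero detail below scale j in a
decimated transform and can only be located to that support —
translation-invariant transforms would remove this artifact but are out
of scope.

## Peak regions, backgrounds, areas

Regions are closed scan-number intervals found on the **de-noised**
trace. The apex is the maximum within ±`search_window` (50) scans of
the seed scan, ties to the earlier scan. Boundaries walk outward until
the trace decays to background + max(boundary_factor·(apex−background),
2·noise_level), with `boundary_factor` = 0.05 (the region ends where
the peak has decayed to 5% of its background-subtracted height). The
noise term matters on real noisy traces: smoothed residual noise rides
the baseline in bumps of roughly the residual σ, and a stop level
inside that band lets the walk sprawl far past the peak; requiring the
level to clear twice the residual noise stops it within a bump length.
For a clean trace the term is zero and the rule reduces to the plain 5%
decay.

The production protocol (`locate_region`) is two-pass: a provisional
region (background boot-strapped from the trace's lower decile) yields
flank statistics — background as the median, noise as 1.4826·MAD of the
flanking `flank_width` (10) scans each side — and the boundaries are
re-walked with those; the background is then re-estimated from the
final flanks. With no flanks at all the background falls back to the
in-region lower decile.

A valley inside a region whose depth below the smaller flanking apex
exceeds `valley_fraction` (0.5) of that apex's height above background
splits the region at the valley minimum; the sub-region whose apex
retention time is closest to the expected elution time is kept and
flagged. Boundary maxima count as flanking apexes so a region that
starts mid-slope can still split. The deliberate design split: region
finding *never* ends a region at an above-level valley, so overlapping
peaks land in one region for the splitter to handle.

Areas are trapezoidal integrals of max(denoised − background, 0) over
retention time in seconds, so they carry physical units and tolerate
uneven scan spacing. Integrating the de-noised rather than the raw
trace does not by itself reduce area error — integration already
averages white noise — but it makes boundary and background
determination dramatically more stable; under the same region protocol
at SNR 5 the de-noised route roughly halves the median area error.

## Ratios and aggregation

Per charge state, ratio = light area / heavy area, undefined (flagged,
not zero) when the heavy area is zero. In the pipeline, the heavy
partner's expected elution time is anchored to the light partner's apex
(isotopic partners co-elute), so an overlapping foreign peak on the
heavy trace is split off rather than absorbed. Charge states of one
peptide merge by weighted arithmetic mean with weight = light + heavy
area — larger combined signal, more reliable ratio; the weight
definition is this package's choice. Undefined ratios are excluded, not
imputed.

Protein ratios average unique peptides' ratios (distinct sequences;
charge states already merged) after recursive outlier elimination:
round 1 keeps ratios in [m − √m, m + √m] with m the median; subsequent
rounds use the mean A of the survivors and [A − √A, A + √A]; the
recursion stops when the survivor set is unchanged or a single ratio
remains. Intervals are closed (a ratio exactly at the bound survives).
Each non-final round strictly shrinks the set, so termination is
bounded by the number of peptides. A round that would eliminate every
ratio (possible for a far-separated bimodal set) instead keeps the
single ratio nearest the round's centre, guaranteeing a survivor; ties
break to the smaller ratio. Ratios are averaged on the natural scale —
matching the describe-then-average convention of this assay — with the
caveat that L/H and H/L are then treated asymmetrically; a log-space
variant would be symmetric but is not the default.

## Synthetic data: what it emulates and what it does not

The generator produces Gaussian elution peaks (closed-form true areas
A = amplitude·σ_seconds·√(2π)) on a constant baseline with additive
Gaussian white noise, clipped at zero because intensities are
physically non-negative. Clipping slightly biases the noise where the
baseline is within ~3σ of zero, so standard fixtures keep baseline ≥
3·noise_sigma (defaults: baseline 15, noise σ 5, amplitude 100 — 5%
apex noise, the noise regime of a clear LC-MS peak). A light/heavy pair
shares peak geometry exactly; light amplitudes are scaled by the mixing
ratio and each partner draws independent noise (seeds s and s+1). The
standard ratio sweep uses mixing ratios {0.5, 0.67, 1.0, 1.5, 2.0} —
1:2 through 2:1, the dynamic range over which this kind of measurement
is considered reliable — with 20 pairs per ratio.

Deliberately not modeled: isotope envelopes, chemical/correlated noise,
retention-time drift between partners, peak tailing (an
exponentially-modified-Gaussian profile would be the natural
extension), and ionization suppression. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model,
not robustness to every artifact of real chromatography.

Toy spectra place two sticks per scan at the light and heavy m/z; a
minimal mzML writer (base64 64-bit float arrays, no compression)
round-trips them through the package's own mzML reader so the full
file-based path is exercised end to end. mzXML is read via pyteomics;
mzML parsing is implemented in-package with lxml.

## Problem sizes and determinism

Monte-Carlo checks use 25–100 realizations per property (50 for the
SNR-5 de-noising benefit and edge localization; 20 pairs per mixing
ratio in the sweep), with explicitly seeded generators throughout —
fixed inputs reproduce byte-identical output tables. The acceptance
script derives every stream from its `--seed` argument.

## Known limitations

* The spatial-adaptive mask covers scales 1..J−1; the coarsest detail
  scale has no coarser neighbour to correlate with and is protected
  only by the (mild) hybrid shrinkage.
* Edge localization degrades for steps aligned to coarse dyadic
  boundaries (see above) — an artifact of decimated transforms.
* Area accuracy at low SNR is dominated by background uncertainty times
  region width, for raw and de-noised traces alike; the de-noiser's
  contribution is stable regions, not noise cancellation in the
  integral.
* The elimination recursion assumes ratios on the natural scale;
  extremely asymmetric ratio distributions are better served by the
  log-space option.
* Quantification confidence measures (p-values, error bars per protein)
  are out of scope.
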