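# Methods

This note documents the models, estimators and design choices behind
`anesthnet`, a pipeline that analyzes the central and autonomic nervous
systems in parallel across five stages of propofol anesthesia — baseline
(Bas), early induction (Ind1), pre-loss-of-consciousness (Ind2), early
recovery (Rec1) and pre-recovery-of-consciousness (Rec2).

## EEG preprocessing and relative power

Recordings are 19-channel 10-20 montages sampled at 256 Hz. Preprocessing
applies a common average reference and a zero-phase Butterworth band-pass
(0.5–48 Hz, order 6; the order was chosen so that steady-state stopband
leakage at 60 Hz stays below 5% in amplitude). For power analysis the epoch
is further band-passed 1–40 Hz with a 2nd-order (12 dB/octave) zero-phase
Butterworth, split into non-overlapping 2-s segments, and each segment's
one-sided FFT periodogram is computed without a taper (a Hann window is
available as an option). Relative power in delta (1–4), theta (4–8), alpha
(8–13) and beta (13–30 Hz) is band power divided by total power over the
1–40 Hz analysis band, with half-open frequency bins `[f_lo, f_hi)` so
shared band edges are counted once; the four bands therefore do not sum
to 1 (the 30–40 Hz remainder belongs to the denominator only). RP is
averaged across segments and, for regional summaries, across the electrodes
of each ROI (frontal, central, parietal, occipital, temporal; Fz belongs to
no ROI, so montages lacking Fz produce identical ROI values).

## Directed connectivity: MVAR and partial directed coherence

Connectivity works on 3-s non-overlapping segments, each linearly
detrended, mean-centered and divided by its variance. A multivariate
autoregressive (MVAR) model

    x[t] = sum_{r=1..p} A_r x[t-r] + e[t]

is fitted per segment by ordinary least squares on the lag-stacked design
(one equation per channel, shared regressors), with the innovation
covariance taken as the residual covariance and
`BIC = n log det(Sigma) + log(n) n_ch^2 p`. The study-wide order is the
mode of per-segment BIC minima (ties break toward the smaller order); a
fixed order can be configured instead. Partial directed coherence is the
column-normalized frequency-domain coefficient magnitude

    pi_ij(f) = |A_bar_ij(f)| / sqrt(sum_k |A_bar_kj(f)|^2),
    A_bar(f) = I − sum_r A_r e^{−i 2 pi f r / fs},

the original (non-generalized) variant, appropriate because segments are
variance-normalized first. The column normalization identity
`sum_i pi_ij(f)^2 = 1` holds exactly at every frequency and is enforced by
test.

Significance of each (target, source, frequency) cell is assessed against
amplitude-preserving, per-channel-independent Fourier phase-randomization
surrogates: each surrogate destroys all cross-channel phase relations while
keeping every channel's spectrum, is refitted with the same order, and the
cell threshold is the empirical `1 − alpha` quantile over surrogates
(default 200 surrogates, alpha 0.05, per-cell thresholds). Non-significant
cells are zeroed, PDC is averaged over each band's frequency bins and then
across segments, giving one weighted directed network per band with the
diagonal removed; global mean and directed ROI-to-ROI means summarize it.
The default frequency grid is 1–40 Hz in 0.5 Hz steps (coarser grids are a
config knob used to keep large simulation studies fast).

One methodological caveat is load-bearing: after common average
referencing the channels sum identically to zero, so the full-montage MVAR
design matrix is exactly rank-deficient and the model is unidentifiable.
The pipeline therefore feeds the connectivity branch the band-passed but
*not* re-referenced signals. The reference question for PDC is genuinely
unsettled in the literature; this choice is the only one compatible with a
full-rank joint model of all 19 channels.

## Graph reduction

Within each band the cohort's networks are thresholded to a common edge
count: k strongest weights per network (ties broken deterministically by
source/target labels), with k the smallest count for which every network's
undirected collapse is connected; a network that stays disconnected even
with all its nonzero edges aborts the band with the offending subjects
named. On the binarized directed graph the package computes global
efficiency (mean inverse shortest-path length over ordered pairs,
unreachable pairs contributing zero), characteristic path length (mean
finite distance), local efficiency (mean over nodes of the global
efficiency of the subgraph induced by the union of in- and out-neighbors)
and the directed clustering coefficient (Fagiolo's triangle closure with
the reciprocal-edge correction). Degree-type node metrics count binary
edges; strength-type metrics sum retained weights; the in-degree fraction
in/(in+out) is reported as missing for isolated nodes (which thresholding
precludes anyway). All indices are verified exactly against a brute-force
Floyd-Warshall/triangle-enumeration oracle on random digraphs. Path-based
indices use binary distances by default; weighted (1/weight) distances are
deliberately non-default because count-based indices are the primary
target here.

## HRV: symbolic dynamics and corrected conditional entropy

The cardiac chain starts from an RR-interval series (ms). Beats annotated
ectopic, or deviating more than 20% from the median of their ten nearest
neighbors, are replaced by linear interpolation between surrounding normal
beats (length preserved, replacements flagged); a series with more than
20% flagged beats is rejected as unusable. The first 250 beats (or the
whole series when it is between 200 and 250 beats long) form the analysis
segment.

The segment is quantized into 6 uniform levels over its observed range
(range-relative, hence invariant to affine rescaling). Overlapping 3-beat
windows are classified by their two consecutive differences: none nonzero
(0V), exactly one (1V), two with equal signs (2LV), two with opposite
signs (2UV); the four percentages sum to 100 exactly. 0V% tracks cardiac
sympathetic modulation; 2LV% and 2UV% track vagal modulation.

Complexity uses the corrected conditional entropy in bits:
`CCE(L) = SE(L) − SE(L−1) + perc(L)·SE(1)` with `CCE(1) = SE(1)`, where
`SE(L)` is the Shannon entropy of length-L symbol patterns and `perc(L)`
the fraction of patterns observed exactly once. The correction charges
undersampled pattern lengths, so the curve turns upward once patterns
become unique and has an interior minimum; past the support it may
transiently overshoot SE(1) before settling back, which is expected
estimator behavior. The regularity index is `Ro = 1 − min_L CCE(L)/SE(1)`
(clipped to [0,1]; a constant series is flagged degenerate with Ro = 1).
`L_max = 12` by default — beyond the support of 200–300-beat segments, so
the minimum search is unconstrained in practice.

## Statistics

For every scalar index the subject-by-condition table is tested with a
fixed ladder: Shapiro-Wilk per condition; if any condition rejects
normality at alpha the omnibus is Friedman's rank test, otherwise a one-way
repeated-measures ANOVA with Mauchly's sphericity test (chi-square
approximation with Box's second-order series correction) and
Greenhouse-Geisser degree-of-freedom correction when sphericity is
rejected. A significant omnibus triggers all 10 pairwise contrasts —
paired t-tests on the parametric branch, Wilcoxon signed-rank on the rank
branch — Bonferroni-corrected within the stratum (one index in one
band/ROI), matching per-figure correction practice. The strictest
normality gate ("any condition non-normal") was chosen deliberately. The
closed-form implementation is cross-checked against pingouin in the test
suite; its type-I error over thousands of simulated null tables sits at
the nominal 5%.

## The synthetic cohort: what it emulates and what it does not

No recordings ship with the package; every claim is tested against
synthetic data with known ground truth.

**EEG.** Each condition is a stable MVAR(2) process over the 19-electrode
montage. Diagonal terms are damped AR(2) oscillators whose per-ROI peak
frequency and pole radius encode the condition's band-power profile
(posterior alpha at baseline, widespread delta at deep induction, partial
recovery afterward; individual channels may override their ROI — Pz keeps
a beta-range generator in Ind2/Rec1). Directed coupling is a per-condition
edge list; each edge adds band-pass (pole radius 0.8) lag-1/lag-2 terms
from source to target, resonant at the edge frequency. Three construction
rules keep the ground truth both stable and recoverable, and were the
product of explicit design iteration:

* every condition's coupling graph is acyclic under one fixed node order,
  so the coupled model keeps exactly the diagonal poles and is stable for
  any gain (feedback between channels sharing a resonance splits poles
  outward like the square root of the loop gain);
* coupling is injected at innovation scale — the band-passed source signal
  is renormalized so a gain of 0.3 contributes like 30% of the target's
  own driving noise — which bounds variance amplification along coupling
  chains (naive output-scale coupling amplified variance by orders of
  magnitude down-chain, which both destroys the scale-sensitive PDC of
  downstream edges and ill-conditions the OLS fit);
* per-edge gains are then calibrated (capped multiplier) until every
  programmed edge reaches a closed-form PDC of about 0.2 at its resonance,
  and the final model is rescaled channel-wise to a common 30 uV
  stationary amplitude, the scale real ongoing EEG occupies.

The edge sets encode the qualitative connectivity physiology of propofol
induction as ground truth: frontal alpha in-edges accumulate monotonically from
baseline through loss of consciousness, parietal beta out-edges rise and
persist into recovery, delta coupling emerges with induction, and the Ind2
edge set strictly contains the baseline set.

What the generator does not emulate: volume conduction and a recording
reference, non-stationarity within an epoch, artifacts (ocular, muscle,
electrode), 1/f broadband background, and patient-to-patient variability
beyond realization noise (all subjects share each condition's generating
model). Passing recovery tests therefore demonstrates that the estimation
chain is correct and well-calibrated under its own model class — not that
it would survive volume-conducted, artifact-laden clinical data.

**RR series.** Beat-to-beat intervals are a mean level plus beat-domain
sinusoids near 0.1 Hz (LF) and 0.25 Hz (HF) with seeded phases, plus white
noise, evaluated on the mean-RR time lattice — a deliberate simplification
of integral-pulse-frequency-modulation models, sufficient for symbolic and
entropy indices which see only the interval sequence. Ectopy splits a
random interval into a 0.4/0.6 short-long pair (total time preserved, the
short beat flagged), reproducing the signature the cleaning stage must
remove. Condition parameters encode progressive bradycardia (mean RR
850 -> 1010 ms across the protocol, not recovering), maximal regularity at
Ind2 (low noise, low HF gain) and a complexity overshoot at Rec1. Defaults
are 300 beats per condition at 2% ectopy.

## Problem sizes in the validation studies

The packaged validation experiments run the full five-condition,
11-subject cohort for network recovery with 10 connectivity segments (30-s
epochs), 200 surrogates and a 1-Hz frequency grid; surrogate calibration
uses 50 seeds of 4-channel white noise; order recovery 20 seeds of a true
order-5 process (20 segments x 2048 samples, BIC over orders 1–10);
the statistics calibration 2000 null tables of 11 x 5; the autonomic trend
20 seeded cohorts; determinism a 2-subject end-to-end double run. These
sizes were chosen so the whole battery completes in minutes while leaving
each check statistically decisive at its stated tolerance.

## Known limitations

* PDC is estimated at sensor level; nothing here addresses source-space
  connectivity or volume conduction.
* The surrogate threshold is per-cell; a global-null variant would be more
  conservative across the 342 x 79 cell family. The observed per-cell
  false-positive rate is calibrated by construction of the quantile.
* The magnitude (not squared) PDC is averaged into networks; squared
  averaging would compress small values but not reorder edges.
* Mean RP and PDC summaries assume the epoch is stationary; the generator
  honors this, clinical epochs only approximately.
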