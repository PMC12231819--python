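# Methods

`resteeg` implements a resting-state EEG biomarker pipeline for three-group
genetic-risk cohort designs (no-risk N, single-risk A+P-, double-risk A+P+):
spectral slowing via relative band power, signal complexity via Higuchi's
fractal dimension (HFD) with a two-stage choice of its tuning parameter,
inter-channel multitaper coherence with FDR-corrected contrasts, and an
assumption-gated statistical decision tree. A synthetic resting-EEG
generator with known ground truth makes every stage testable end to end.

## Signal model and conditioning

Recordings are channels x samples matrices in microvolts with an explicit
sampling rate; analysis-ready data are assumed to be ~6 min of clean
eyes-closed EEG at 250 Hz under an average reference. The conditioning
steps the pipeline itself performs are: zero-phase FIR band-pass (default
0.1-40 Hz; transition bandwidths follow the firwin defaults, i.e. 25 % of
each cutoff with the usual bounds), polyphase resampling, common-average
re-referencing, and segmentation into non-overlapping 4-s epochs (trailing
partial samples dropped). Artifact removal (bad channels, ASR, ICA) is a
manual, tool-assisted process upstream of this package and is out of scope;
the generator produces artifact-free signals accordingly.

Group labels come from a BIDS-style `participants.tsv` sidecar, never from
EEG headers. BrainVision and EDF files are read through MNE; the package's
own minimal EDF/BrainVision writers exist solely to materialise synthetic
fixtures and are round-trip tested against the MNE readers (16-bit formats
to within one quantisation step).

## Relative band power

Per channel, Welch PSD with 4-s Hamming windows, 50 % overlap and
per-segment linear detrend (0.25 Hz resolution at 250 Hz). Band powers for
delta (0.5-4 Hz), theta (4-7 Hz), alpha-1 (7.5-9.5 Hz) and alpha-2
(10-12 Hz) are rectangle-quadrature integrals over half-open bands
[lo, hi): each bin contributes its density times the bin width, and shared
edges such as delta/theta at 4 Hz belong to exactly one band. With this
rule a band set that tiles the denominator range reproduces the denominator
power exactly, which is the invariant the test suite asserts; the price is
a one-bin edge effect for spectral peaks sitting exactly on a band
boundary. Relative power divides by total power in 1-30 Hz. The delta
band's 0.5-1 Hz portion lies outside that denominator by convention, so
relative powers are not formally constrained to sum below one; this
asymmetry is reproduced deliberately.

Cluster values are arithmetic means of member-channel relative powers over
twelve anatomical regions (MF, FL, FR, C, CTL, CTR, PC, PTL, PTR, OC, OL,
OR; a default 10-10 assignment ships with the package and any YAML map can
be substituted); the global value averages all channels. The logit
transform t(x) = log(x/(1-x)) is applied to the aggregated proportions —
the quantities that enter the statistics — not to per-channel
intermediates.

## Higuchi fractal dimension and k_max selection

For scales k = 1..k_max and offsets m = 1..k the normalised curve length is

    L_m(k) = [ sum_{i=1..n} |x(m+ik) - x(m+(i-1)k)| ] * (N-1)/(nk) / k,
    n = floor((N-m)/k),

L(k) is the mean over m, and FD is minus the OLS slope of ln L(k) on
ln k. The implementation is vectorised (offset sums via reshape, FD for all
prefixes of the k grid via cumulative OLS) and is held to 1e-10 agreement
with a literal triple-loop reference. Admissible series need N >= 3 k_max;
constant series raise an error rather than returning a value. Calibration:
a linear ramp gives FD 1 (exact up to fit error), white noise ~2, and
fractional Brownian motion with Hurst index H gives 2 - H, which the fBm
generator below turns into a closed-form oracle.

Per subject, the FD is computed per channel — by default per 4-s epoch and
averaged, configurably on the whole series (the two agree to within a few
hundredths on stationary synthetic signals) — then averaged into cluster
and global scopes.

k_max is chosen in two stages from the group-mean global FD-vs-k curves on
the integer grid k = 2..100:

1. **Plateau.** On the grand-average curve (unweighted mean of group
   curves; subject-pooled weighting is available as an option), the
   consecutive absolute percentage change 100|g(k)-g(k-1)|/|g(k-1)| is
   scanned; the plateau start is the smallest k from which the change stays
   below 0.05 % all the way to the search bound (default 100). The first k
   whose change merely dips below the threshold is reported for
   transparency but never used: dips can be transient. If no persistent
   plateau exists the selection raises an explicit error instead of
   defaulting to the bound. The percentage change is indexed from the
   second grid point onward, since each value needs a predecessor.
2. **Discrimination.** Within the plateau, the selected k_max maximises
   D(k) = sum over unordered group pairs of |mean_a(k) - mean_b(k)|, ties
   resolving to the smallest k. With identical groups D vanishes and the
   plateau start is returned.

The selection is invariant to uniform positive rescaling of the curves.

## Multitaper coherence

Magnitude-squared coherence (MSC) per channel pair on non-overlapping 4-s
segments: each demeaned segment is multiplied by K DPSS tapers
(time-half-bandwidth product T*W; K = 2TW - 1, so the default +-1 Hz
smoothing on 4-s segments gives 7 tapers), cross- and auto-spectra are
summed over all segment x taper estimates, and

    MSC(f) = |sum S_xy|^2 / (sum S_xx * sum S_yy),

averaged over the bins of each half-open band. MSC is 1 for a channel with
itself (special-cased to be exact), invariant under pure delays, and under
independence has a sampling floor of roughly 1/(n_segments * n_tapers).
Fewer than two segments is an error: MSC from a single estimate is
identically 1. The default pair set is all pairs of the 19-channel 10-20
subset present in the montage (Fp1, Fp2, F7, F3, Fz, F4, F8, T7, C3, Cz,
C4, T8, P7, P3, Pz, P4, P8, O1, O2) — the subset and the +-1 Hz
half-bandwidth are package defaults, stated here as assumptions, and both
are configurable.

Group contrasts are Welch two-sample t-tests per (pair, band), with
Benjamini-Hochberg FDR applied over the whole family of pair x band tests
within each group contrast.

## Statistical decision tree

For each outcome (band x scope, or HFD x scope): Shapiro-Wilk on residuals
about the cell means and median-centred Levene across groups, both gated at
p < 0.05. Non-normal residuals route to Kruskal-Wallis with Dunn post-hocs
(tie-corrected z-tests, Holm adjustment — implemented in-package as no
installed library provides Dunn's test); normal but heteroscedastic data
route to Welch's ANOVA with Games-Howell post-hocs; otherwise a one-way
ANOVA — or, when sex labels are supplied, a two-way ANOVA with sex as a
fixed factor (full factorial, type-II group effect) — with Tukey-HSD
post-hocs. The Welch-corrected path is recorded as a flag on the result
rather than a separate design category. When both gates fail, non-normality
wins and the test is Kruskal-Wallis. Labels: p <= 0.05 significant,
0.05 < p <= 0.09 trend. No multiplicity correction is applied across the
cluster x band outcome family by default (coherence contrasts are the only
FDR-corrected family); a global-BH option can be layered on by the caller.

Q-Q plot inspection, which usually accompanies Shapiro-Wilk in practice, is
inherently visual and is omitted; the gate is the test alone.

## Synthetic data

Each latent source is synthesised in the frequency domain (random complex
coefficients shaped by an amplitude profile, then inverse FFT), avoiding
AR-filter edge transients: a 1/f^beta aperiodic background with a 1 Hz
knee (power ~ 1/(1 + f^beta), so sub-delta power stays bounded as in
empirical eyes-closed spectra), an alpha oscillation as a Gaussian spectral
bump (sigma = 1 Hz, height 2.5x the local aperiodic amplitude at unit
gain) rather than a sinusoid so that coherence and band power behave like
real EEG, and a delta-band amplitude multiplier over 0.5-4 Hz. Channels
mix a shared latent source with per-channel sources as
sqrt(c) * shared + sqrt(1-c) * own, so coupling c in [0, 1] spans
independent channels (MSC at the sampling floor) to identical channels
(MSC 1). Channel names follow a standard 10-10 ordering. One RNG stream per
subject is derived from (group seed, subject index), so enlarging a group
never perturbs existing subjects.

The risk-cohort preset encodes the expected direction of Alzheimer's-risk
effects relative to N: A+P+ has aperiodic exponent +0.3 (smoother, less
complex signal), delta amplitude x1.5 and alpha amplitude x0.7; A+P- sits
halfway (+0.15, x1.2, x0.85). Defaults elsewhere: beta = 1.0, alpha peak
10 Hz, coupling 0.3, 6-min recordings at 250 Hz. These effect sizes are
deliberately strong enough to be detectable at 20-30 subjects per group;
the generator does not simulate artifacts, volume conduction, electrode
drift, alpha-peak slowing, or between-subject variability in effect
magnitude, so passing tests demonstrate correctness of the analysis chain
on data with the assumed statistical structure, not sensitivity on real
recordings.

Fractional Brownian motion is generated by exact circulant embedding
(Davies-Harte) of the fractional Gaussian noise covariance; a numerically
negative embedding eigenvalue raises an error rather than being silently
truncated. Its graph dimension 2 - H calibrates the HFD estimator.

## Validation studies and problem sizes

The replicated studies in `resteeg.experiments` fix their conditions once:
cohorts of 25 subjects per group; four channels (Fz, Cz, Pz, Oz); 60 s per
subject at 250 Hz; HFD at k_max = 82 on the whole channel series. The
shorter-than-6-min recordings and small montage keep a 200-replicate study
tractable on a single core while leaving every per-replicate test with the
same sampling structure (15 Welch windows per channel, ~75 subjects per
ANOVA). The type-I calibration uses 1,000 replicates of null normal data;
power uses a 2-pooled-SD shift in one group. `scripts/acceptance.py` reruns
the same studies at 100 replicates (headline recovery) and 600 replicates
(type-I) and reports every calibration quantity as JSON.

## Numerical choices and edge cases

- Band integration: rectangle rule over half-open bins; bands must overlap
  the PSD grid or an error names the offending range.
- Logit requires proportions strictly inside (0, 1); values outside raise.
- Percentage-change denominators are guarded against zero even though HFD
  curves live near [1, 2].
- Welch t-tests on zero-variance cells (identical groups) return t = 0,
  p = 1 rather than NaN.
- CSV output uses 12-significant-digit floats; a run's outputs are
  byte-identical across repeats of the same config and seed, and every
  table carries the config hash (output directory excluded from the hash).

## Known limitations

- The generator's group effects act uniformly across channels; there is no
  spatial topography of effects, so cluster-level results mirror global
  ones on synthetic data.
- Epoch-wise HFD and whole-series HFD differ slightly on nonstationary
  data; both are exposed, per-epoch is the default.
- The 10-20 coherence subset and taper bandwidth are conventions, not
  fitted quantities.
- No age covariate handling: the cohort design this targets matches groups
  on age by construction.
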