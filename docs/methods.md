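# Methods

## Scope and data model

`ccframan` analyses one-dimensional Raman spectra of circulating cell-free
DNA (ccfDNA): a strictly increasing wavenumber axis in cm⁻¹ and an intensity
vector in arbitrary counts. The working range is 300–3100 cm⁻¹ at ~1 cm⁻¹
resolution (2801 channels), matching a 532 nm dispersive micro-Raman
acquisition of dried ccfDNA droplets. Groups follow a subjects × technical
replicates design, by default 3 subjects × 5 replicates = 15 spectra per
group.

The unit of biological interpretation is the *reference window*: one of 25
wavenumber intervals, each carrying a literature assignment label (treated as
an opaque annotation) and per-group presence flags. A group's *fingerprint*
is the set of windows in which its corrected average spectrum shows a called
peak. All group contrasts are set algebra over fingerprints; no intensity
quantitation or statistical testing of spectral differences is attempted
(the upstream methodology defines none).

## Reference table encoding

The shipped table (`ccframan/data/reference_windows.tsv`) encodes the 25
windows with eleven printed study-group presence columns plus a twelfth,
`Seq BRCA`, for the sequential breast-cancer sampling context. Three windows
— (11) 1101, (17) 1372 and (18) 1399 cm⁻¹ — carry no flag in any printed
column yet belong to the 13 bands reported for sequential samples; the extra
column records them without altering the printed columns. One further known
tension is left as encoded: the 1574–1578 cm⁻¹ window (21) is described in
prose as also appearing in healthy groups, but the healthy columns carry no
flag for it; the table follows the flags.

Each window carries a *representative position* used as the synthetic band
center: the single assignment wavenumber when the source text gives exactly
one and it falls inside the window (e.g. 746 for 740–769 cm⁻¹), otherwise
the window midpoint. Three degenerate single-point windows whose assignment
value lies 1 cm⁻¹ outside the printed bound — (3), (17), (18) — use the
printed bound, keeping `low ≤ representative ≤ high` as an invariant.

## Synthetic spectra

The generator emulates the features of real acquisitions the pipeline must
cope with, and only those:

* **Band shape** — pseudo-Voigt (Gaussian/Lorentzian blend, default mix 0.5),
  the standard Raman band model; default FWHM 12 cm⁻¹, typical for
  condensed-phase biomolecular bands. Apex amplitude is the parameter.
* **Amplitudes** — the source spectra publish no absolute intensities, so
  amplitudes are a convention: log-uniform in [50, 200] counts, drawn
  deterministically per (group, window) from a CRC32-derived stream so a
  group's configuration is stable without a seed argument, and overridable
  via an explicit amplitude policy.
* **Background** — a smooth polynomial; the default decreases from 800 to
  350 counts across the range (quadratic in the normalised axis), a
  fluorescence-like shape well inside what the degree-5 correction handles.
* **Noise** — i.i.d. additive Gaussian, default σ = 5 counts, giving SNR ≈ 20
  for a median band; no Poisson shot-noise model is attempted.
* **Cosmic spikes** — single-channel positive deltas, count Poisson(1.0) per
  spectrum, amplitude uniform in [500, 2000] counts: the simplest artifact a
  despiker must remove.
* **Subject structure** — each subject's band centers are jittered once by
  Normal(0, 1.5 cm⁻¹) and shared across that subject's replicates, so
  inter-subject variance exceeds intra-subject variance as in real data.

What the generator does **not** emulate: instrument response and étendue,
water/substrate bands, photobleaching drift within an acquisition,
band-shape asymmetry, correlated (pink) noise, and intensity differences
between groups. Passing end-to-end tests therefore demonstrate that the
pipeline recovers presence/absence structure under realistic noise, spikes
and background — not that it would quantify band intensities on instrument
data.

Determinism: all randomness derives from `numpy.random.default_rng` seeded
with `(seed, subject, replicate)` tuples; identical inputs give bitwise
identical spectra. Subject jitter is seeded by `(seed, subject)` only, so a
single simulated spectrum is consistent with its group.

## Preprocessing

**Despiking.** A running median (window 7 channels) is subtracted; channels
whose modified z-score, 0.6745·(r − median r)/MAD(r), exceeds 8 are replaced
by the running-median value. When the MAD degenerates to zero (constant
input), the mean absolute residual substitutes as scale. Window 7 spans half
a default band FWHM, so smooth band apexes produce residual z ≈ 1–3 and are
never touched at the default threshold, while spikes of a few hundred counts
reach z in the hundreds. The operation is idempotent and is the exact
identity on spike-free input.

**Baseline.** Iteratively clipped polynomial least squares (the ModPoly
scheme): fit, replace the working signal by min(signal, fit), refit, until
the fitted curve changes by < 10⁻³ (relative ℓ₂) or 100 iterations. Degree 5
by default — flexible enough for broad fluorescence, too stiff to follow
12 cm⁻¹ bands. The fit is computed in a Chebyshev basis on the normalised
axis (QR factorised once; only the clipped ordinates change per iteration)
for conditioning, and reported coefficients are converted to raw-wavenumber
powers. The silent region (1800–2800 cm⁻¹) is deliberately included in the
fit: it anchors the polynomial. Clipping biases the converged curve slightly
below the noise mean (≲ 1σ ≈ 5 counts against a ≥ 350-count background,
i.e. ~1%); on noise-free input of polynomial degree ≤ the fit order the
result equals the direct least-squares fit to machine precision.

**Averaging.** Element-wise mean with *population* SD (divisor n; the choice
is a convention, recorded here). Spectra must share an identical axis; a
mismatch is an error, never a silent resample (`RamanSpectrum.resample`
exists for explicit opt-in). The pipeline contract is linear: a unit impulse
in one of n inputs moves the mean by exactly 1/n at that channel when the
nonlinear stages (despike, baseline clipping) are disabled, and the output
mean is always exactly the mean of the individually corrected spectra — no
smoothing of any kind.

Stage order is despike → baseline → average: spikes would otherwise distort
the polynomial fit, and correction precedes pooling so that per-spectrum
backgrounds cannot survive into the group average.

## Peak calling and assignment

A robust noise scale is estimated as 1.4826·MAD(Δy)/√2 (differencing removes
smooth structure). Local maxima are called when **both** their prominence
and their height above the spectrum median reach 5× this scale, with a
minimum separation of 8 cm⁻¹. The height condition is a deliberate addition
to plain prominence thresholding: on long flat segments between bands, the
prominence contour of the tallest noise bump spans the full local noise
range (≈ 6–7σ) and would regularly clear a 5σ prominence-only cut, while its
height stays near 3σ; requiring both suppresses these false calls without
affecting real bands (≥ 50 counts against ≈ 1.3 counts of averaged noise).
Apex positions are refined by a three-point parabolic fit (clamped to ±1
channel); FWHM comes from the half-prominence width.

Assignment matches each peak to the reference window whose closed interval,
expanded by a 4 cm⁻¹ tolerance, contains it — nearest interval first, ties
broken by distance to the window midpoint. The tolerance matches the spread
the same band shows across groups in the source material (e.g. 758–769 cm⁻¹
for the thymine ring-breathing band). Each window accepts one peak (highest
prominence wins; displaced peaks are returned explicitly unassigned), so
fingerprint size is bounded by the table size and "major peak" counts are
window counts. Peaks in the silent region (1800–2800 cm⁻¹, where no
reference window lies) are reported by `silent_region_audit` — e.g. an
alkyne stretch near 2110 cm⁻¹ — but never assigned.

## Group comparison semantics

`compare_groups` computes: windows present in **all** compared groups
(shared); windows present in exactly one group **within the compared set**
(unique — the contrasts in the source are always per comparison, not global
across all eleven groups); and, for every window present somewhere, the
groups lacking it. The report is invariant under input permutation, collapses
duplicate fingerprints, and treats a self-comparison as "everything shared,
nothing unique". Fingerprints built over different window universes cannot be
compared.

## Numerical and design choices

* Closed window intervals; boundary positions assign with distance 0.
* `silent_region_audit` uses open interval bounds, so a zero-width region is
  empty by construction.
* Spectrum CSV is comma-separated, dot-decimal, UTF-8, one header line;
  values are written with 12 significant digits so files round-trip within
  1e-9 relative. JCAMP-DX support covers the `(X++(Y..Y))` form with X/Y
  factors; descending axes are reversed on load.
* Degenerate despike inputs (constant + spike) are restored exactly; a zero
  spectrum has a zero baseline; an empty spectrum list is an error, not an
  empty average.
* Problem sizes: validation simulates full-size groups (15 spectra of 2801
  channels); the 20-seed × 12-group recovery study used in the tests runs in
  well under a minute on one core, so nothing is scaled down.

## Known limitations

* Fingerprints are binary. Band intensities, areas and ratios are computed
  per peak but never enter group comparisons, so the package cannot grade
  partial responses or monitor quantitative shifts over time.
* Overlapping bands are not deconvolved; two true bands closer than the
  8 cm⁻¹ separation (or inside one window) collapse to one call.
* The despiker targets single-channel transients; multi-channel detector
  artifacts would survive at reduced amplitude.
* The polynomial baseline assumes a smooth background expressible at degree
  ≤ 5 over the full range; strongly structured backgrounds (substrate bands)
  would need piecewise fitting, which is intentionally not provided.
* Synthetic amplitudes and SNR are conventions, not reconstructions of any
  instrument's response; absolute intensities in simulated output carry no
  physical meaning.
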