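# Methods

## Data model

A *spectral library* is a set of K labeled signatures: a reflectance vector
over a shared wavelength grid plus a tissue label and a patient ID. The
default grid is 500–995 nm at 5 nm (L = 100), matching clinical push-broom
HSI cameras. Patient IDs are mandatory because every evaluation protocol in
this package splits by patient: spectra from one patient are strongly
correlated (shared illumination, geometry and physiology), and any split
that ignores this leaks information. Small annotated cubes
(x, y, band + integer label mask) are supported for completeness;
`extract_labeled` turns them into libraries.

## Preprocessing

The chain is Savitzky–Golay smoothing → standard normal variate (SNV) →
Min-Max rescale, applied per spectrum in that order.

* **SG filter** — polynomial order 3, window 9 bands (45 nm). The window is
  a package choice: wide enough to suppress band-to-band sensor noise,
  narrow enough not to flatten the hemoglobin absorption features at
  540–580 nm. Edges use the polynomial fitted to the last full window
  (scipy's `mode="interp"`), so no reflectance is fabricated outside the
  recorded range.
* **SNV** — subtract the spectrum mean, divide by its sample standard
  deviation (ddof = 1, the chemometrics convention). Removes per-spectrum
  affine illumination effects. Constant spectra are rejected (detected by
  an exact max = min test, which is robust to the floating-point artifact
  where the sd of a "constant" vector is a nonzero multiple of machine
  epsilon).
* **Min-Max** — affine map of [min, max] onto [ε, 1] with ε = 10⁻⁶. The
  lower bound is deliberately not 0: the divergence-based measures take
  logs, and an exact zero would recreate the log(0) failure the rescale
  exists to prevent. Min-Max is per spectrum; a global (whole-dataset) mode
  is conceivable but not implemented.

## Measures — numerical choices

* **SID** uses natural logarithms (nats) and floors probabilities at 10⁻¹²
  (then renormalizes), making it total even on raw inputs with empty bands.
  The floor is SID-specific; the Bhattacharyya coefficient handles zeros
  natively (√0 = 0) and is not floored, so JM attains exactly 2 on disjoint
  support.
* **JM exponent.** JM is computed as 2(1 − e^(−B)) with B = −ln BC the
  Bhattacharyya *distance*, which simplifies to 2(1 − BC) and spans the
  full [0, 2] range. The variant with the *coefficient* in the exponent,
  2(1 − e^(−BC)), caps at 2(1 − 1/e) ≈ 1.264 and contradicts the measure's
  standard range; it remains available via `literal_exponent=True`.
* **SCA** is arccos((σ+1)/2) (no square root); the square-root variant
  found in part of the SCA literature is behind `sqrt_variant=True`.
* **Angles near 0** are computed through chord/arcsin identities
  (SAM = 2 arcsin(‖â−b̂‖/2), SCA = 2 arcsin(√(1−σ)/2) with 1−σ formed
  stably) rather than arccos of a rounded cosine. This makes the measures
  *exactly* zero on identical inputs — which matters because RSDPW treats a
  zero measure value as the degenerate "reference equals target" case.
* **tan at π/2** saturates at tan(π/2 − 10⁻⁹) ≈ 10⁹ so hybrids stay finite
  and order-preserving for exactly orthogonal or anticorrelated spectra.

## Discrimination statistics

RSDPW, RSDPB and RSDE follow their definitions directly. RSDE uses base-2
logarithms (bits), bounded by log₂K; RSDPB is invariant to scaling the
measure by any positive constant, which is what makes these statistics
comparable across measures with different units. `discrimination_report`
computes RSDPW over all unordered pairs of non-target tissue mean spectra
against the target tissue mean, and RSDPB/RSDE against per-patient mean
references — consistent with the patient-mean evaluation protocol.

## Annotation QC

Reference spectra are clustered per tissue by K-means (k = 2 default) in
Euclidean space on the preprocessed spectra — K-means is Euclidean by
definition — while thresholds and decisions use the chosen spectral
measure. Cluster centers are recomputed as exact bandwise member means and
ordered deterministically (by mean reflectance). The threshold of a cluster
is the mean measure value between its center and its members; a singleton
cluster gets T = 0 (confirmation impossible — warned, with the advice to
lower k).

A claimed label is confirmed only if the target's measure value is strictly
below the threshold of **every** cluster of the claimed tissue. This
all-centers rule is implemented literally; it is intentionally strict. A
direct consequence, worth stating plainly: the probability that a fresh
same-tissue spectrum falls strictly below the *mean* within-cluster
distance for *both* cluster centers is roughly 0.25–0.5 (distances in
100-band space concentrate around their mean, and the far cluster's
threshold reflects its own members, which are by construction closer to it
than an arbitrary same-tissue point). Confirmation rates for correctly
labeled spectra therefore sit well below 100% even on clean synthetic
data — the package's tests observe ~20–40%. The procedure's value is on the
other side: a spectrum carrying a *wrong* label is flagged almost surely
(its distance to the claimed tissue's clusters is far above threshold when
classes are separated), and the suggestion step — the tissue of the
globally nearest cluster center, ties broken lexicographically and
recorded — recovers the true label at ≥ 90% on the shipped suite at its
default noise. An `any-center` relaxation exists for users who prefer
higher confirmation rates at the cost of weaker checking.

Accuracy is the proportion of correct final labels: claimed label if
confirmed, suggested label if flagged, compared against ground truth.

## Cross-validation

LOPOCV builds one fold per patient. The patient-grouped k-fold balances
class proportions greedily: patients are seed-shuffled, sorted by spectra
count (descending), the first k seed the folds, and each remaining patient
joins the fold with the largest weighted deficit of the classes it carries
(ties to the emptiest fold). Exact stratification is impossible with
patient-level atoms; greedy balancing is a deterministic, seed-reproducible
approximation. By default decisions are evaluated on per-(tissue, patient)
mean spectra; a per-spectrum mode serves pixel-level rates.

## Synthetic data

Each tissue is a smooth baseline — a flat offset plus Gaussian bumps
(center nm, width nm, amplitude) — with three variance layers: a
multiplicative per-(patient, tissue) scale (sd 0.08 around 1), an additive
per-(patient, tissue) shift (sd 0.02), and bandwise Gaussian pixel noise
(sd 0.01), all in reflectance units; draws are clipped to a 10⁻⁶ floor.
The shipped 11-model suite shapes its bumps on visible hemoglobin dips
(540–580 nm) and NIR plateaus, with thyroid/parathyroid and
colon/small-intestine/stomach built as near-neighbour pairs and
fat/gauze/instrument as far outliers, so the separability ordering the
discrimination experiments assume holds by construction. Mislabeling swaps
a chosen fraction of labels uniformly to another tissue and records the
truth separately.

What the generator does *not* emulate: wavelength-correlated noise,
specular highlights, moisture/blood films, inter-patient covariance shared
across tissues, and real biochemical absorption line shapes. Passing tests
on this data therefore demonstrate the correctness and internal logic of
the measures and procedures — not clinical performance, which depends on
exactly the structure the generator idealizes away.

Default study sizes (QC experiments): 8 tissues × 10 patients × 5 spectra
per tissue per patient, 5% mislabeled; the shuffled-label null uses 2
balanced classes over 50 patients with one spectrum each, so decisions are
patient-independent and the binomial error model applies.

## Determinism

Every stochastic step (sampling, mislabeling, K-means init, fold shuffling)
derives from an explicit integer seed; identical config + seed reproduces
libraries, cluster models, decisions and CLI outputs byte-for-byte (floats
are serialized with `repr`, which round-trips exactly).

## Known limitations

* The all-centers confirmation rule makes confirmation rates pessimistic by
  design (see above); users wanting a lenient check must opt into the
  any-center relaxation.
* Libraries must share one wavelength grid; no resampling between grids.
* K-means clusters in Euclidean space even when decisions use a divergence
  measure; a measure-consistent clustering (k-medoids under m) would be a
  natural extension.
* The CSV dialect stores one spectrum per row and is meant for libraries up
  to ~10⁵ spectra, not whole cubes.
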