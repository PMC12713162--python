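# Methods

## Scales and conventions

All internal computation is on the **fractional inhibition** scale in
[0, 1]: inhibition = 1 − viability. Viability/percent inputs are converted
at the file boundary (`io.read_matrix_csv` takes an `orientation`
declaration; the `fit` CLI takes `--response-scale`). Doses are µM
everywhere and modeled linearly; only the EC50 parameter is optimized on a
log10 scale. δ synergy scores are computed fractionally and reported ×100,
matching the percent-scale magnitudes practitioners expect from
SynergyFinder-style tools (numerical identity with any web tool is a
non-goal; the conventions here are self-contained and documented).

## Dose-response fitting

Model: y(d) = emax·d^H/(ec50^H + d^H), bottom pinned at zero. Zero-dose
wells participate as exact y(0) = 0 anchors. Loss is ordinary (unweighted)
least squares on the inhibition scale — the convention of the standard
three-parameter "log(inhibitor) vs response, zero bottom" fit in Prism-like
software.

* Bounds: emax ∈ (0, 1.2], ec50 ∈ [10⁻⁶, 10³] µM, H ∈ [0.1, 10]. The 1.2
  ceiling tolerates normalization overshoot; the slope cap keeps
  near-threshold data from degenerating into step functions.
* Multi-start: 5 deterministic starts with EC50 initialized at the 10–90%
  quantiles of the observed nonzero doses, emax at the response maximum,
  H at 1. The best least-squares solution wins; identical inputs always
  give identical fits.
* Preconditions: ≥ 4 points, ≥ 3 distinct nonzero doses, non-constant
  response; violations raise `UnfittableCurveError` naming the compound.
  Low-efficacy and unfittable compounds are excluded from pair screening
  rather than forced.

EC_F interprets F as percent **of the fitted span** (so EC_F(50) = EC50
exactly, any slope); that is what the closed-form EC_F algebra implies. An
absolute-inhibition reading would instead solve y(d) = F/100 and is what
`absolute_ic50` provides for the F = 50 case. The 8×8 matrix design anchors
on the **relative** IC50 by default (`design_matrix(ic50_a, ic50_b)` takes
whichever the caller passes).

## Primary screen statistics

Replicates are technical quadruplicates paired by index; the Bliss excess
is computed per replicate and tested with a two-sided one-sample t-test
against zero. The hit rule is directional (p < α and mean excess < 0), so
the effective type-I rate under the null is about α/2 — the Monte-Carlo
acceptance bound of 7.5% at α = 0.05 is deliberately generous to sampling
error. Zero-variance excess vectors with nonzero mean report p = 0 and a
`degenerate` flag instead of crashing. No multiple-testing correction is
applied: the matrix stage is the confirmation step, mirroring two-tier
screening practice. Significant *positive*-excess pairs are reported by
`antagonistic_significant` but never counted as hits.

## Surface scoring

δ matrices cover only the 49 off-axis cells; monotherapy rows/columns are
identically zero for Bliss/HSA and would only dilute the mean. Bliss and
HSA use the **observed** monotherapy axes; Loewe and ZIP use **fitted**
marginals, since both are undefined without an invertible curve. When a
margin cannot be fit, Loewe/ZIP are reported unavailable (NaN) and the
classification is flagged partial, which reproduces the known failure mode
of Loewe on drugs without a well-defined monotherapy response.

* **Loewe**: y* solves dA/DA(y*) + dB/DB(y*) = 1 on (0, min(emaxA, emaxB))
  with `brentq` (bracketed, xtol 10⁻¹²; comfortably within the 10⁻⁹ effect
  tolerance and deterministic). Cells with no bracketed sign change
  (combination beyond both curves' reach) are flagged NaN and excluded from
  all means.
* **ZIP**: per off-axis row/column, a conditional Hill curve is refit for
  EC50 and slope only, with the baseline fixed at the partner's fitted
  marginal effect and the ceiling fixed at the titrated drug's marginal
  emax. The cell's fitted effect is the mean of its row- and column-
  conditional predictions; δ subtracts the Bliss combination of the fitted
  marginals, making the no-potency-change null exactly zero. A failed
  conditional fit falls back to the observed values on that line.
* **MSA**: exhaustive scan of the 25 3×3 windows in the off-axis 7×7
  region, ties to the smallest (row, col). Partially flagged windows
  average their valid cells.
* **CSS**: per direction, trapezoidal AUC of observed inhibition over
  log10 dose along the grid line where the partner is nearest (in log
  space) to its relative IC50, normalized by the full-inhibition area over
  the same span, ×100; the two directions are averaged. An off-range IC50
  uses the nearest edge line.
* **Classification**: strict all-models rule at τ = 5 percent-scale points;
  monotone in every score by construction.

## Synthetic worlds

Noise is Gaussian and homoscedastic on the inhibition-fraction scale —
the simplest defensible model for normalized plate readouts; defaults are
σ = 0.02 with quadruplicate arms (primary screen) and 3 replicates per
matrix cell. Planted synergy is an additive δ offset inside a 3×3 off-axis
block on a chosen null (Bliss/HSA/Loewe of the true curves); a potency-
shift construction (halved conditional EC50) is exercised in the tests for
ZIP. DE tables simulate padj directly rather than running a testing
pipeline, since the scorer consumes padj as given. Non-reversed signature
genes are made significant in their disease direction so the planted
reversal fraction of *detected* genes closes exactly with the scorer; a
`detected_fraction` knob covers the variant where they drop out of
detection instead. With σ = 0 every generator closes exactly against its
scorer (excess, δ, reversal fraction); generators are byte-deterministic in
the seed.

What a green synthetic suite does **not** establish: real plates have
position and edge effects, heteroscedastic and occasionally non-Gaussian
noise, drifting controls, and dose-dispensing error; real DE tables have
correlated genes and independent-filtering artifacts. The suite validates
the statistics and the scoring machinery, not robustness to those
artifacts.

## Plate normalization

With no-cell minimum controls (absorbance assays):
viability% = 100·(signal − min̄)/(vehiclē − min̄); without them
(nuclei-count assays): 100·signal/vehiclē. A vehicle mean at or below the
minimum-control mean is a plate failure and raises. Positive-control wells
are summarized as QC (mean inhibition) and never enter normalization.

## Known limitations

* Single-agent curves only; no biphasic/two-site models (biphasic inputs
  fit to the dominant phase within bounds).
* No bootstrap confidence intervals on δ; no ≥ 3-drug surfaces.
* The reversal stage consumes DE tables; it does not run differential
  expression, and ships no literature signature — signatures are user
  input or synthetic.
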