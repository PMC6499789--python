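# Methods

## Model

Species interact only through chemicals. Each of `N` species has a basal
net per-capita growth rate `r_i0` (death folded in); each of `M` mediators
carries influence links (mediator → species) and production links
(species → mediator). Influences are additive across mediators.
Facilitation follows the Monod form `ρ⁺ C/(C+K)`; the Moser generalisation
`ρ⁺ Cⁿ/(Cⁿ+Kⁿ)` is available (`n = 1` recovers Monod). Inhibition defaults
to the linear form `ρ⁻ C/K`, motivated by dose-response measurements of
acids and antibiotics on bacterial growth; a thresholded variant and a
saturating "growth inhibition" variant (`r0 − r_inh/(1 + K/(C−C_th))`)
are selectable. Growth rates may go negative; densities are floored at
zero. Shared resources are assumed in excess and are not modelled.

Production is proportional to live producer density (`β S`). Consumption
happens only on *depletable* influence links — a species only removes
mediators that affect its own growth. Two uptake kinetics are implemented:

* `growth_coupled` (default): removal `α · max(r_i, 0) · C/(C+K) · S_i`.
  `α` is a per-new-cell consumption factor (fmol/cell): cells take up the
  mediator as they divide. This is the dimensionally consistent reading of
  a consumption factor quoted in fmol, and it is the variant under which
  the package reproduces the published ensemble statistics (see
  "Calibration evidence" below).
* `monod`: removal `α · C/(C+K) · S_i` with `α` a fixed maximum uptake
  rate (fmol/cell/h) independent of growth.

The distinction matters: with `monod` kinetics at the reference values
(`α = 1`, `β = 0.1`) depletable mediators equilibrate near `0.1 K`, keeping
all influences weak (≈ 10% of `ρ`); with growth-coupled uptake the balance
point sits near saturation whenever producers outnumber consumers, which
puts the reference parameters in the strong-interaction regime the
strength sweeps identify (`ρ/σ_r0 ≈ 10`).

Mediator decay is exposed (`decay`, 1/h) and defaults to zero; results are
insensitive except at extreme decay rates.

## Enrichment protocol

All pool species start at equal proportions with `ΣS = 10⁴/ml` and zero
mediators. Growth runs until `ΣS ≥ 10¹⁰/ml`; the culture is then diluted
back to `10⁴/ml` into fresh medium, mediators co-diluted by the same
factor (carryover turns out to be immaterial: resetting mediators at
transfer changes ensemble MER by < 1%). One round spans `log₂ 10⁶ ≈ 19.9`
generations; ten rounds ≈ 200 generations. A species dropping below
0.1 cells/ml — one cell in a 10 ml inoculum — at any point is extinct and
stays at zero. After the last round, any species whose post-dilution
density fell by strictly more than 10% relative to one round earlier
(≈ the final 20 generations) is removed as a slow decliner; the remainder
is the derived community. A round that never reaches the dilution trigger
within 10⁴ h marks the run as stalled (scored as no coexistence).

The 10% decline filter deliberately retains near-neutral ties: two species
whose basal rates differ by less than ≈ 9×10⁻⁴/h decline too slowly to be
caught in a single-round window. In the no-interaction control this leaves
~45% of enrichments with two or more survivors — competitive exclusion in
the strict single-survivor sense emerges only on longer horizons.

## Integration

Forward Euler at `dt = 0.01 h` (the update-and-uptake timescale):
`S ← S(1 + r dt)` and `C ← C + dC dt`, with `C` clamped at zero when a
step would overshoot the available mass. The long growth phases run in a
numba-compiled kernel that iterates over sparse link lists; `step()` is
the plain-numpy reference implementation and the test suite asserts the
two paths agree step-for-step to 1e-9. Self-convergence: halving `dt`
moves end-of-round frequencies by `O(dt)`; against `dt = 0.001`,
end-of-enrichment compositions agree to < 1 percentage point absolute and
derived sets are identical on random 5-species communities. Relative
frequency errors can be large for *marginal* members (a species drifting
toward extinction at frequency ~0.01 amplifies the Euler rate bias
exponentially over ~1,400 h), which is why the convergence criterion is
stated on composition, not per-species relative error.

## Pool generation

Binomial bipartite networks: production links with probability
`q_p = 0.2`, influence links with `q_c = 0.2`, independently per
species–mediator pair; no producer/recipient trade-off, so self-links
(a species producing a mediator that influences itself) arise at the
background rate. Parameters: `|ρ| ~ U(0, 0.2)/h` (an `alternative`
weak-biased distribution is selectable), sign facilitative with
probability `fac_fraction`, `K ~ U(0.5, 1.5)·10⁴ fmol/ml`,
`β ~ U(0.5, 1.5)·0.1 fmol/h`, `α ~ U(0.5, 1.5)·1 fmol` on links flagged
depletable (probability `depletable_fraction` per influence link),
`r_0 ~ U(0.08, 0.12)/h`. Defaults use 20 species and 15 mediators (the
figure-scale setting; the reference table lists 10 mediators).

All randomness for one pool is drawn in a fixed order for the full `N×M`
matrices *before* masking. Pools sampled at the same seed under different
mask parameters (sign ratio, depletable fraction, strength scale) are
therefore coupled: the comparison screens (mechanism, strength,
perturbation sweeps) isolate the swept parameter by reusing seeds.

## Screens and statistics

Influences are classified by sign and locus: self iff the recipient also
produces the mediator (`β > 0`), giving self-facilitation,
other-facilitation, self-restraint, other-inhibition. An influence is
*active* in a derived community iff its recipient survived and at least
one producer of its mediator survived. Category statistics score only
derived communities with ≥ 2 species and ≥ 1 active influence (a
community retaining no influences has undefined category fractions).
"Favored" means the derived fraction strictly exceeds the initial
fraction; ties count as unchanged.

Mean excess richness: `MER = Σ_i (i−1) p_i` over the empirical richness
distribution, with a 3,000-resample nonparametric bootstrap 95% CI
(percentile method).

Knockout screens delete a single influence link. Deletion zeroes only the
growth-rate influence `ρ` and keeps the consumption link: losing the
receptor does not stop the metabolism. (Removing the consumption too makes
other-inhibition knockouts spuriously disruptive — the de-sensitised
species stops degrading the toxin, raising everyone else's exposure — and
inverts the observed category ordering.) `from_pool` mode removes the link
from the initial pool and re-runs the whole enrichment; `from_derived`
mode continues the assembled community from its final post-dilution state
for a further ten rounds and scores disruption when any member is lost or
fails the decline filter. Baselines that do not maintain themselves
unperturbed are excluded. The separate `stability_check` operation instead
restarts the derived community at equal proportions (a harsher,
assembly-from-scratch notion of stability).

Ensemble sizes: the category statistics use 3,000 pooled-ratio pools in
the acceptance script and 450 in the test suite; knockout screens
accumulate ≥ 120 (script) or ≈ 50 (tests) tested self-restraint links.
These desk-scale ensembles carry sampling errors of a few percentage
points, reported alongside each statistic as `n`.

## Chemostat heuristic

Under continuous dilution with all influences saturating, each mediator
either accumulates far above `K` (`θ_l = 1`, full-strength influence) or
is held near zero (`θ_l = 0`). We close `θ` per candidate species subset:
`θ_l = 1` iff some member produces mediator `l` and no member depletes it.
The effective growth matrix of a subset puts `r_i0` on the diagonal and,
for each saturated mediator, its full influence strength in the columns of
its producers; the predicted sub-community is the subset with the largest
leading eigenvalue whose leading eigenvector is strictly positive
(eigenvalue ties go to the larger subset; the matched dilution rate equals
the eigenvalue). Exhaustive enumeration is capped at 12 species.

The heuristic is validated only against simulation on small hand-built
communities and has known blind spots: depleted mediators contribute
nothing under the θ-closure even though partially depleted mediators exert
real influence (so depletable mutualisms are predicted as singletons), the
producer-column attribution pretends influence scales with producer
density, linear inhibition is unbounded in the simulation but capped at
`ρ⁻` in the θ-model, and the enumeration ignores invasion history (it will
pick a toxin-sensitive fast grower that could never invade against the
toxin producer). The concordance suite therefore draws its cases from the
heuristic's stated validity domain — reusable, saturated, strong
influences — plus one deliberate bistability counter-example.

## Growth-curve utilities

Plate-reader series are reduced to rates the standard way: drop the first
two reads, estimate the per-well background as the mean of reads 3–10,
and fit a line to log(OD) over the window 0.002 < OD < 0.02 (≥ 3 points
required; an optional time cap supports short fluorescence assays). The
background window assumes negligible growth over the first ~10 reads; for
fast growers at high inocula this biases the rate upward, so the synthetic
fixtures default to a small initial amplitude (10⁻⁵ OD above background).
Dose-response tables are fitted to the five response laws by bounded
least squares (`scipy.optimize.curve_fit`); the Moser exponent is
constrained to its admissible range 1 ≤ n ≤ 3, and for the linear law
only the slope `r_inh/K_inh` is identifiable and reported. Fixtures
generate both plate series (exponential or logistic-capped) and
dose-response tables with known ground truth and Gaussian noise,
deterministic under a seed.

## Calibration evidence and known deviations

The printed model equation and the printed unit of the consumption factor
are mutually inconsistent (the flux term needs fmol/(cell·h); the table
says fmol). Both readings are implemented; the growth-coupled default was
selected because the equation-as-printed reading yields ~68%
facilitation-only derived communities against the published ~90%, while
the growth-coupled reading yields ~89% and simultaneously matches the
self-restraint prevalence and favored/disfavored tallies. No other
parameter was adjusted.

Two quantitative deviations remain and are reported rather than tuned
away. First, the no-interaction control retains ≥ 2 species in ~45% of
enrichments (near-ties passing the decline filter, in agreement with an
order-statistics calculation), so strict single-species dominance in the
control is not reproduced. Second, the derived-richness distribution has
a heavier tail than the published one; since knockout disruption rises
steeply with richness, the self-restraint knockout disruption rate comes
out at ~25–43% depending on the seed batch (richness-2 communities alone:
~18%) against the published ~17%. The categorical ordering — facilitation
knockouts disrupt most, other-inhibition least — is robust throughout.

What passing the synthetic screens does *not* show: real communities have
structured (non-binomial) networks, energetically ordered byproducts,
resource limitation, spatial and temporal heterogeneity, and evolving
phenotypes, all outside this model.
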