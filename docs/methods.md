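# Methods

## The forced-bending energy model

A nucleosome placement is scored on the 129-bp histone-contacted stretch
centred on its dyad (the 147-bp footprint minus the terminal stretches
that make no histone contact). Dinucleotide steps are indexed
$i = \pm1 \dots \pm64$ from the dyad; there is no step 0, because step
$\pm1$ already sits half a step away from the central base pair. Twist is
uniform ($\omega = 34.8°$ per step, the crystallographic average for
nucleosome-bound DNA), so the phase of step $i$ is
$\Omega_i = \mathrm{sign}(i)(|i| - \tfrac12)\omega$ — the model has no
twist degree of freedom, and slide/shift/rise are not deformed at all:
bending lives entirely in roll and tilt.

Each step type carries four empirical constants ($k_\rho, k_\tau$ in
energy·degree⁻², $\rho_0, \tau_0$ in degrees), shipped as
`src/nucbend/data/step_params.tsv` with 10 canonical rows. The table is
expanded to all 16 steps by strand symmetry: roll is invariant under
reading the step on the other strand while tilt changes sign, so the
reverse complement of a step shares $k_\rho, k_\tau, \rho_0$ and takes
$-\tau_0$. This is forced by physics — the same double helix must have
the same deformation energy whichever strand you read — and is consistent
with the palindromic steps (AT, TA, GC, CG) all having $\tau_0 = 0$. The
package validates these invariants at table construction and the test
suite verifies the resulting energy is strand-symmetric numerically.

The torque $F_b$ is not a free parameter: it is solved per placement from
the constraint that the deformed roll/tilt profile bends the contacted
stretch by a fixed $\alpha = 579°$. Substituting the linear-response
deformations into the bend-angle sum gives the closed form in the README;
the energy then reduces to $E = (\alpha - B - C)^2 / (2A)$ with
$A = \sum_i(\cos^2\Omega_i/k_\rho + \sin^2\Omega_i/k_\tau)$,
$B = \sum_i \rho_0\cos\Omega_i$, $C = \sum_i \tau_0\sin\Omega_i$. The
implementation precomputes per-slot lookup rows for $A, B, C$ over the 16
step codes, so a whole chromosome is scored with 128 vectorized gathers;
`tests/oracle.py` holds an independent loop-by-loop transcription of the
equations that the suite compares against at 1e-9 relative tolerance.
Bend-angle conservation (re-deforming the angles and summing back to
$\alpha$) is checked to 1e-6 degrees — it is analytic, so the test guards
the bookkeeping, not the physics.

Ambiguous bases (N or any non-ACGT) inside the contacted stretch have no
step parameterization; such placements are reported as NaN and propagate
as missing occupancy rather than being imputed. Energies are in the
arbitrary units implied by the force constants; only relative energies
matter downstream, which is also why $\beta = 1$.

## Occupancy

$S_j = e^{-\beta E_j}$ at every dyad with a full contact window;
$O_j$ is the mean of the defined $S$ over the 51-bp window centred at
$j$. Near sequence ends (and next to runs of ambiguous bases) the window
is truncated to the defined potentials it contains, so the boundary
regions — the object of study — are not discarded; a strict full-window
mode is available via `BoltzmannConfig(require_full_window=True)`. A
position whose window holds no defined potential is missing.

Normalization is the natural-log ratio against a reference mean; "log"
is underdetermined in this kind of analysis and any base is a monotone
rescaling, so the base is fixed to $e$ and recorded in track metadata.
The reference defaults to the mean over the defined positions of the
track at hand; a precomputed mean (e.g. over a whole analysis set) can be
passed instead, since a genome-wide mean is not available in general.
With the auto reference, $\mathrm{mean}(e^{O^{nor}}) = 1$ exactly.

Absolute occupancies are numerically tiny ($e^{-E}$ with $E$ of order
150): everything downstream is ratio- or rank-based, so this is harmless,
and the bedGraph writer emits full precision.

## Experimental-track interpolation

Coarse tracks (bedGraph or fixedStep/variableStep wiggle; 10-bp bins in
the data this was built for) are upsampled to per-bp with a cubic spline.
Two choices here are package decisions, not facts about the upstream
data: knots sit at bin midpoints (a bin value summarizes its whole bin),
and the boundary condition is natural (zero second derivative at the free
ends). Bins separated by more than one bin width split the track into
independent runs — no curve bridges a data gap; runs with fewer than 4
knots fall back to linear interpolation with a logged warning; positions
outside the outermost knots are missing (no extrapolation).

## Metaprofiles

Coordinates are 0-based half-open throughout (BED-native). "Upstream"
and "downstream" are transcriptional, so the start anchor of a
minus-strand feature is its highest coordinate and its window is read
reversed: positive offsets always point into the body at a start anchor
and away from it at an end anchor. Features whose window leaves the
track contribute only where signal exists; per-offset counts record this,
and no smoothing is applied to the emitted means. The default flank is
1000 bp and is configurable. Per-offset counts of group-stratified
profiles sum exactly to the unstratified counts — a property test.

## Family statistics

Per-feature mean occupancy averages the defined per-bp values inside the
feature. For sequence-predicted occupancy, features shorter than 129 bp
(one contact window) are excluded as unscoreable rather than scored from
partial windows. Within each family, Spearman correlations (average
ranks on ties) of occupancy against GC content, identity and divergence
are computed with two-sided p-values from the large-sample t
approximation; a permutation option enumerates all pairings exhaustively
for n ≤ 7 and uses 10,000 seeded resamples above that. Significance is
p < 0.05, uncorrected — the analysis reports raw per-family counts, and
the threshold is configurable. Families with fewer than 5 usable pairs
for a cell, or zero variance in either variable, are reported untested
rather than silently absorbed. The cohort roll-up counts tested,
significant, and significant-positive families and averages the
significant coefficients only. The group comparison is a one-way ANOVA
on per-feature means; the degenerate all-identical case returns F = 0,
p = 1 explicitly.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with ground
truth recorded in a JSON manifest, and its defaults are the package's
study conditions:

- **Genome**: i.i.d. bases at a configurable GC (default 0.5), one 250-kb
  chromosome.
- **Boundary cohort**: 50 features (25 transcribed, 25 nontranscribed,
  random strand, 500–1500 bp) with a 150-bp poly-dA:dT element written
  immediately upstream of each biological start and downstream of each
  biological end. Poly-dA:dT is used because under the step parameters it
  is genuinely stiff (high $k_\rho$), so the depletion the profile stage
  recovers is a real sequence-energy signal, not a painted one.
- **Family cohort**: 50 families × 20 members × 500 bp. Member $j$ of
  $m$ mutates at per-site rate $0.4\,j/(m{-}1)$ — graded from an exact
  copy to heavily decayed — with substitutions landing on A/T with
  probability 0.9, so GC and identity co-decay the way pseudogene
  sequences drift after losing function. Recorded identity and GC are
  exact; divergence is the applied rate. A `null_attributes` switch
  replaces the attributes with independent uniform draws, giving exact
  independence from occupancy for significance calibration (100 families
  × 30 members × 400 bp in the calibration runs).
- **Mock experimental track**: 10-bp bins, baseline 1.0, Gaussian noise
  (sd 0.1), with Gaussian dips (depth 0.5, scale 50 bp) painted at the
  ground-truth element midpoints *independently of sequence*, mimicking
  in vivo occupancy that reflects factors beyond sequence.

Every generator draws from its own stream seeded from
`(SimConfig.seed, stream-id)`, so outputs are deterministic and
independent of call order. What the generator does **not** emulate:
indels, retrotransposition mechanics, phylogenetic structure within
families, chromatin-remodeler or methylation effects, mappability bias in
the mock track. Passing recovery tests therefore demonstrate that the
pipeline's stages are correct and sensitive under known ground truth —
not that the model's predictions are accurate for real chromatin.

## Problem sizes and numerical choices

The recovery analyses run on the cohorts above (250-kb genome, 1000- and
3000-member family cohorts), sizes at which every planted effect is
comfortably detectable and the full suite completes in well under a
minute of compute per analysis. Tolerances: 1e-9 relative for oracle and
strand-symmetry equivalence (float64 headroom over 128-term sums), 1e-6
degrees for bend-angle conservation, knot-exactness at 1e-9 for the
spline. Type-I calibration bands are 3 binomial standard errors around
alpha.

## Known limitations

- No nucleosome-nucleosome exclusion or equilibrium competition: the
  occupancy is a window-averaged Boltzmann weight, not a statistical-
  mechanics lattice model.
- The energy model deforms roll and tilt only, with uniform twist; step
  parameters are a fixed empirical table, not refit to data.
- Experimental-track interpolation trusts the deposited coarse profile;
  no read-level processing is provided.
- Divergence is consumed as a supplied attribute (or the generator's
  rate); the package does not compute evolutionary distances from
  alignments.
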