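# Methods

This note documents the models and procedures implemented in `pcbdechlor`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## Congener structural model

A PCB congener is a pair of ring substitution patterns, each a subset of
ring carbons {2,…,6} (carbon 1 carries the ring–ring bond).  Two
patterns describe the same molecule under the order-8 symmetry group
generated by flipping either ring about its 1–4 axis (2↔6, 3↔5) and
swapping the rings.  Canonical form: each ring is replaced by its
flip-minimal digit string, and the lexicographically smaller ring is
written first (an unsubstituted ring renders as `0` and always second,
e.g. `245-0`).  Reducing all 2⁵ × 2⁵ = 1024 raw patterns modulo this group
and excluding the unchlorinated pattern yields the classical 209
congeners with homolog counts (3, 12, 24, 42, 46, 42, 24, 12, 3, 1) for
mono- through decachlorobiphenyl; the test suite verifies this against an
independent orbit-counting oracle.

Positions 2/6 are *ortho*, 3/5 *meta*, 4 *para*.  A chlorine's flanking
context counts its chlorinated ring neighbors (adjacency 2–3, 3–4, 4–5,
5–6): unflanked, singly- or doubly-flanked.  Single-dechlorination
channels remove one chlorine; channels equivalent under the symmetry
group are merged with an integer multiplicity (so total multiplicity
equals the chlorine count), which prevents double-counting of kinetic
channels.  Fully dechlorinated biphenyl is a distinguished terminal node,
not a congener, keeping the 209-set invariant clean.  Official
Ballschmiter–Zell congener numbers are not computed or shipped: their
historical ordering irregularities make any generated table unreliable,
and ring notation is unambiguous.

## Dechlorination statistics

Cl/PCB = Σᵢ xᵢ·nᵢ over mole fractions of detected congeners; congeners
below detection are treated as absent, not censored (this matches GC
reporting practice but biases Cl/PCB slightly when daughters sit below
detection).  ΔCl/PCB(t) = Cl/PCB(0) − Cl/PCB(t), decomposed identically
per position class; the decomposition is exact by construction and
asserted to 1e-9.

Activity is called when ΔCl/PCB ever reaches the threshold, default 0.05
chlorines per biphenyl (the abiotic-control scale); the comparison is
inclusive (≥) because the threshold is stated as a boundary value, and an
inclusive rule is reproducible.  A linked abiotic-control series, when
present, replaces the default with its own maximum ΔCl/PCB.  No temporal
interpolation is performed: with roughly monthly sampling a point
estimate of onset would be spurious, so the lag is reported as the
interval (previous sample, first sample at threshold].

Preference classification compares the final para vs meta positional
removals across replicate series by one-way ANOVA at α = 0.05:
significant and para > meta → para-preferential, significant and
meta > para → meta-preferential, otherwise comparable.  Identical
removals short-circuit to comparable; a single replicate raises unless an
effect-size fallback is explicitly requested.  Replicate summary
statistics are computed per replicate and then averaged.

The pathway graph has a node per congener observed above the detection
limit and a directed edge for every single-dechlorination relation
between observed nodes, annotated with position class, flanking context
and channel multiplicity.  Daughters absent at day 0 with no observed
parent are flagged orphan (their precursor fell below detection).  Flux
attribution solves, per consecutive timepoint pair, a non-negative
least-squares problem: minimize ‖A f − Δc‖² + λ·Σf over f ≥ 0, where A is
the node–edge incidence matrix and Δc the per-node concentration changes.
The tiny L1 term (λ = 1e-6 µM²) breaks the degeneracy of converging
pathway motifs toward fewer active edges; the solver is L-BFGS-B with an
analytic gradient, initialized at the scipy NNLS solution.  Mass-balance
residuals above 1e-3 µM per interval produce a warning with the residual
report, not a failure — unobserved intermediates and non-dechlorination
losses are outside the model.

## qPCR quantification

Standard curves are ordinary least squares of Cq on log₁₀(copies/mL) over
a dilution series spanning at least three levels (typically 10²–10⁸
copies/mL); amplification efficiency is E = 10^(−1/slope) − 1.  A curve
is flagged unacceptable when r² < 0.99 or E leaves the configured bounds
(defaults 90–110 %; stricter published bounds such as 92.0–101.9 % can be
configured).  Quantification inverts the curve,
copies/mL = dilution · 10^((Cq − b)/m), and flags results whose
per-reaction copies (undiluted copies/mL × template volume, default 2 µL)
fall below the limit of detection.  The LOD is a configured scalar,
default 6 copies/reaction — the conservative end of the typical 6–9
copies/reaction band for these assays.  Genus-level 16S copies are
reported as cells/mL assuming one 16S copy per genome (appropriate for
Dehalococcoidia-type genomes; configurable per genus).

The RDase/OHRB ratio sums pcbA1 + pcbA4 + pcbA5 copies over
Dehalococcoides + Dehalogenimonas + Dehalobacter cells.  Band boundaries
are strict: ratio > 10 (above the ~10-fold quantification uncertainty)
and ratio < 0.1 (suggesting RDase genes not captured by the assayed
panel); a zero denominator yields an explicit undefined flag rather than
infinity, since low OHRB abundance biases the ratio.  Missing panel
targets count as zero with a warning — partial panels are common.
Dominance is called solely-dominated when one genus strictly exceeds 90 %
of the OHRB sum.

## Community ecology

OHRB screening matches genus-level taxonomy labels case-insensitively
against a configurable list (three cultured genera plus the uncultivated
Dehalococcoidia lineages S085, vadinBA26, GIF9, DscP2, t0.6.f).  Alpha
diversity: richness, Shannon H (natural log), Pielou J = H/ln(richness).
Bray–Curtis is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); PCoA is classical scaling
(double-centering of −D²/2, symmetric eigendecomposition), with explained
fractions over the positive eigenvalue mass and negative eigenvalues
reported, not corrected.

Networks: genera detected in strictly more than 50 % of a group's samples
(singletons — total count 1 — excluded) are tested pairwise by Spearman
correlation on relative abundances.  Ties receive average ranks.
p-values use the t approximation for n ≥ 10 samples and exact rank
permutation below that (the permutation null is enumerable at small n and
the t approximation is poor there).  All tested pairs are
Benjamini–Hochberg adjusted; an edge requires |ρ| > 0.6 **and** adjusted
p < 0.01.  Network nodes are the genera incident to at least one edge, so
an empty graph has (n, L, ⟨k⟩) = (0, 0, 0); average degree is 2L/n.

NST: for each group, the regional pool assigns each taxon a probability
proportional to its summed abundance across the group's samples; B
(default 1000) null communities per sample are drawn multinomially at the
sample's observed depth.  For every sample pair the observed Bray–Curtis
dissimilarity D_obs is compared with the null mean Ē_null through the
magnitude ratio min(D_obs, Ē_null)/max(D_obs, Ē_null), and NST is the
group mean × 100 %.  This is a deliberately simple normalization with the
defining behavior of the statistic: data generated by the null model
itself scores near 100 % (stochastic-dominated, > 50 %), while strongly
structured groups whose observed dissimilarities depart from the null
expectation in either direction score low (deterministic-dominated,
< 50 %).  Published NST variants normalize differently; values from this
implementation should be compared against its own 50 % boundary, which
the test suite validates in both directions.  A single seed drives all
null draws and is recorded in the output.  Group assignment for networks
and NST follows sample activity quartiles (equal-sized groups ranked by
ΔCl/PCB) when explicit groups are absent.

## Synthetic-data generators

*Kinetics.*  Dechlorination is modeled as first-order in the parent
congener: each symmetry-merged chlorine channel is removed at rate
k[position class][flank context] × multiplicity (per day), zero before a
configurable lag phase.  Default rates put doubly-flanked para and meta
chlorines first (1.2e-3 and 1.0e-3 d⁻¹ per channel), singly-flanked
about half that, and ortho/unflanked one to two orders lower — producing
ΔCl/PCB ≈ 0.3–0.4 over 180 days on the default mixture, the activity
scale typical of active sludge microcosms.  The default mixture is a
synthetic hexa/hepta-dominated composition (Cl/PCB ≈ 6.4) standing in for
a highly chlorinated commercial formulation; it is a plausible
construction, not a measured formulation table, and is fully
configurable.  Because the system is linear, it is propagated exactly
with matrix exponentials on the state vector augmented with concentration
integrals, which yields machine-exact mass balance and exact per-edge
cumulative fluxes (k·∫c_parent dt) with no step-size considerations; the
noise-free truth is cached per configuration.  Measurements add
per-congener, per-timepoint multiplicative lognormal noise (mean 1,
CV default 5 %); the terminal biphenyl is excluded from observed series,
as congener-specific chromatography would not report it.

*qPCR.*  Cq = b + m·log₁₀(copies/mL) + N(0, σ_Cq) for standards
(10²–10⁸ copies/mL) and unknowns; non-positive true copies become
non-detects.

*Communities.*  Stochastic assembly draws every sample multinomially from
a lognormal regional pool — exactly the NST null-model process, so NST on
such tables scores high.  Deterministic assembly gives each group two
strongly distinct fixed templates (large lognormal perturbations of the
pool) and builds samples from them with only small multiplicative noise
(CV 2 %) and rounding, so observed dissimilarities depart strongly from
the null expectation and NST scores low.  Designated OHRB taxa can be
planted in a fraction of samples and scaled by 1 + coupling·activity to
plant abundance–activity correlations.  Pairwise rank correlations are
planted through a Gaussian copula with the Greiner inverse
(ρ_latent = 2·sin(πρ_s/6)) so the requested value is the target Spearman
correlation; planted taxa are raised to at least the pool's 75th
percentile so the signal is identifiable above counting noise.  Realized
sample correlations still shrink slightly (~0.85–0.9 for a planted 0.9)
through compositional closure and multinomial sampling — real effects
that the analysis must tolerate.

What the generators do **not** emulate: chromatographic co-elution and
congener mis-assignment, qPCR inhibition and primer mismatch,
compositional sequencing artifacts beyond multinomial sampling, temporal
autocorrelation of communities, and any taxon–taxon interaction structure
beyond the planted pairs.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated models, not
robustness to every artifact of real measurements.

## Problem sizes and determinism

The test and acceptance workloads use miniature study sizes chosen for
desk-scale reproducibility: 8 microcosms × 2 replicates plus one control
in the fixture study; 100 seeded studies for recovery rates; 21-sample
groups (the canonical group size for activity-quartile networks) with
30–120 taxa and depths of 5 000–50 000 reads; B = 1000 NST
randomizations.  All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical seeds give bit-identical results,
and the pipeline records seed, thresholds, versions and input checksums
in its manifest.

## Known limitations

- Flux attribution is identifiable only up to the null space of the
  incidence matrix on converging motifs; the L1 tie-break selects the
  sparsest consistent explanation, which may differ from the true channel
  split when parallel routes carry comparable flux.
- Cl/PCB treats below-detection congeners as absent; heavy censoring
  biases ΔCl/PCB downward.
- The NST normalization is the package's own simple variant (see above);
  absolute values are not interchangeable with other NST software,
  although the 50 % classification boundary behaves as required.
- Genus 16S copy number is assumed 1; multi-copy taxa would need the
  per-genus configuration.
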