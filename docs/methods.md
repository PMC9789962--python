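# Methods

This note records the model, the numerical choices, what the simulator does
and does not emulate, and the problem sizes used by the test suite and the
acceptance script.

## Signal model and HMM

An event-aligned read is a sequence of current events, each attributed to a
6-mer dwell. Relative to the reference pore model N(μₖ, σₖ²), a read is
distorted by a shift a (pA), scale b and variance scale d: a match event for
k-mer k is modelled as N(a + b·μₖ, (d·σₖ)²). (a, b) are the ordinary
least-squares fit of event means against model means over labelled events
(≥ 30 required; fewer raises an error); d is the root mean squared
σ-standardised residual, floored at 0.01 so a perfect fit cannot produce a
degenerate zero-variance model.

The HMM has one block per k-mer of the candidate sequence: a *match* state
(Gaussian emission, self-transition allowed so one k-mer can emit several
events), a *bad* state (the same Gaussian with σ multiplied by 10,
absorbing outliers), silent *skip* moves between blocks, and flat-emission
*softclip* states at both ends. Transition constants (p_stay = 0.1,
p_skip = 0.01, p_bad = 0.001, p_softclip = 0.05, softclip emission 1e-3)
are declared defaults in `HmmConfig` — squiggle-HMM convention, not
reproductions of any published values; every property the package asserts
holds for any fixed constants in (0, 1). The geometric skip chain is
evaluated exactly (cumulative log-sum/ running-max scans), never truncated,
which is what makes the forward and Viterbi passes match an exhaustive
path-enumeration oracle to 1e-9 on small instances.

For multi-component entries the emission is, by default, the maximum
component density per event ("max" mode) — the trained parameter set that
maximises the likelihood is selected, per event. Whether that selection
should be per event or once per substring is not determined by the source
procedure; a mixture-marginal ("marginal", log-sum-exp with weights) mode
is available in `HmmConfig.component_mode` for sensitivity analysis.

## Six-letter alphabet

M (5mC) is only meaningful in CpG context: a k-mer containing M followed by
anything but G is invalid; M at the final position is valid because its G
lies in the next k-mer. Partial adenine labelling makes the Z placement
within a k-mer unidentifiable, so k-mers differing only by A↔Z pool into
one class keyed `<base>+6mA` in model tables. At k = 6 the alphabet yields
46,656 strings, of which the {A,C,G,T} restriction is 4,096.

## Site windows

CpG substrings are maximal CpG clusters (merged when separated by fewer
than 10 CpG-free bases) padded by 10 bp beyond the outermost CpG; clusters
whose padding would leave the read span are dropped, since the flank
guarantee cannot be met. Adenine windows are non-overlapping 50-bp tiles
anchored at the read's reference start; a terminal remainder shorter than
50 bp is dropped. Tiling (rather than sliding) is used because the
downstream proportion statistics require non-double-counted windows.
Hypothesised modifications (M substitution, 6mA flags) apply only to CpGs
and adenines inside the tested interval; the context sequence extends k−1
k-mers beyond the window's k-mer support on each side, and the events
passed to the likelihood are exactly those assigned to that support — which
makes a window's LLR invariant to all other events of the read.

## Training

Per k-mer/class, shift/scale-transformed events e′ᵢ = (eᵢ − aᵢ)/bᵢ are
pooled across reads with per-event variance factors dᵢ/bᵢ (the read-level
d and b of the event's read). EM fits a Gaussian mixture with
heteroscedastic per-event scaling; the σ̂ update uses residuals rescaled by
bᵢ/dᵢ. The initialisation grid is fixed: first component at μₖ, the others
at distinct offsets from {±5, ±10} pA; all σ at σₖ or σₖ+1; weights
(0.95, 0.05), (0.5, 0.3, 0.2) or (0.25,)×4 by component count. EM stops at
max |Δμ̂| < 1e-3 pA or 1000 iterations. A component with σ̂ < 0.05 pA or
ω̂ < 0.01 is dropped and the rest renormalised (collapse otherwise
destabilises the σ̂ update).

Component counts: 2 for methylated-CpG k-mers and single-adenine classes;
1 + (2^m − 1) capped at 4 for classes pooling m adenine positions — a
deterministic proxy for choosing the count by inspecting the distribution.
When a pool is small the count is reduced to n_events // 10 (minimum 2), so
scaled-down datasets still train rather than fail.

Assignment requires grid consistency: converged fits agreeing (sorted
means, elementwise) within 1.0 pA on at least half of all grid points.
Two-component entries receive the component furthest from the reference
mean; pooled classes receive every component whose mean differs from the
reference by more than the tolerance, weights renormalised. Two guards are
applied, both documented design choices where the procedure is otherwise
underdetermined:

- **Assignment weight floor (0.1).** The methylated fraction is large in
  every training library (96.2% CpG completeness; tens of percent per
  class under partial labelling), so a near-empty component is a stray
  cluster — without the floor, a two-event outlier cluster far from μ_ref
  can out-deviate the true methylated component and be assigned (observed
  in testing: an 11 pA error on one entry).
- **Alignment model with parent components.** The outer loop realigns
  events by Viterbi under the current model; during realignment each
  trained modified entry additionally carries its unmodified parent
  component. Under partial labelling the events at a class position are a
  modified/unmodified mixture, and realigning against a modified-only
  entry misaligns the unmodified majority, degrading the next round's
  pools. Classification does *not* use this union — the hypotheses must
  discriminate modified from unmodified.

Entries with no consistent fit keep their seeded values (parent mean,
σ + 2 pA) and provenance "initialized". Before training, the *entire*
modified lexicon derivable from the base model is seeded, so classification
can always score every hypothesis; untrained entries simply contribute
near-zero log-likelihood ratio. The outer loop runs a fixed 5 rounds by
default. Training is deterministic given its inputs — it consumes no
random numbers.

## Classification

The LLR sums log-max-likelihoods over two hypotheses per side exactly as
specified (a product of likelihoods, not a mixture marginal); windows
lacking one mark degenerate to a simple two-hypothesis ratio. LLRs are
natural logs, and the thresholds (±1.5 for CpG; 8/32 for 6mA windows,
boundary inclusive) are interpreted on the natural-log scale. 6mA calls are
window-level only — the pooled classes deliberately give up base-resolution
adenine calls.

## Aggregation and allelic statistics

Per-CpG frequencies count methylated/unmethylated calls (no_calls excluded;
a joint substring call applies to each CpG it covers). Background
correction is R_f = R_s − (C_s/C_i)·R_b with R_f floored at 0 — negative
corrected counts are meaningless for count tracks; the floor is a
deviation by necessity. Linker distances are measured between midpoints of
consecutive 6mA-positive windows within a read (anchor points are otherwise
undefined).

Allelic analysis gates regions at combined coverage ≥ 20. CpG: two-sided
Fisher exact test on the 2×2 call-count table by haplotype. 6mA: each
allele's reads are segmented into non-overlapping 250-bp windows flagged
6mA-containing or not; each of 100 bootstrap replications draws 30 windows
per allele **with replacement** (implied by "bootstrap"), and the pooled
replication counts form one 2×2 Fisher table — the pooling is a declared
interpretation, since how 100 replications become a single test is
otherwise ambiguous; the bootstrap distribution is retained alongside.
Alleles offering fewer than 30 windows are skipped, not sampled with
shortfall. Benjamini–Hochberg q-values; significant iff p < 0.01 and
q ≤ 0.10. Note the pooled table has 3000 pseudo-draws per allele, so the
test is sensitive to small true differences between the allele window
sets; its type-I behaviour is verified only under exchangeable nulls
(identical allelic window sets).

## Simulator

The generator emulates: reference sequences with controllable GC content
and CpG density (±5% planting/breaking loop); per-site endogenous 5mC
truth; the four training conditions — untreated, CpG methylation at the
treated completeness 0.962, partial adenine labelling at 0.4 per adenine,
and both; footprint-style reads labelling adenines only inside accessible
linkers (147-bp protected / 30-bp linker alternation); per-read (a, b, d)
drawn from N(0, 2 pA), N(1, 0.02), N(1, 0.05); stay/skip event structure
(0.1 / 0.01); and eventalign-dialect output accepted unmodified by the
parser. Modified k-mer shifts default to 3σₖ scaled by a positional decay
peaking mid-k-mer, with a stable per-k-mer hash sign; the decay can be
switched off. All randomness flows through one seeded PCG64 generator.

It does **not** emulate: raw current waveforms or segmentation error,
basecalling/mapping error, neighbour-dependent correlated pore-model
levels, non-CpG cytosine methylation, strand asymmetries, or coverage
biases. Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under the stated generative model — not
calling accuracy on real flow-cell data.

## Problem sizes

Chosen so training pools average tens of events per k-mer on one CPU:

- End-to-end benchmark (`poremeth.benchmark.run_end_to_end`): 800-bp
  reference, 60 training reads × 350 bp per condition (~26× coverage),
  5 realignment rounds, 35 test reads × 500 bp per library (sized so every
  ROC class holds at least 200 windows); the 6mA
  window-length sweep is evaluated at {12, 24, 50, 100} bp. CpG ROC
  positives are treated-library substrings whose molecule realised full
  methylation (a joint all-or-none call has no defined truth on mixed
  substrings); 6mA ROC positives are treatment-level — every window of a
  treated read counts, including those the partial labelling reaction
  missed, exactly as on real data where molecule truth is unknowable. The
  missed-label fraction is what makes short windows harder than long ones
  and produces the length trend.
- EM recovery: 20 seeds × 5000 events, components (80, 2) and (86, 2) at
  weights 0.5/0.5.
- Read-scaling recovery: 500 events at (a, b, d) = (10, 1.05, 1.2).
- HMM oracle equivalence: every shape with ≤ 4 k-mers and ≤ 6 events.
- Null bootstrap: 500 regions of 50 windows with identical allelic sets.

Unit and loop tests additionally run a miniature 3-mer pipeline (the HMM,
training and calling are k-agnostic), which keeps the full suite within a
typical CI budget.

## Known limitations

- EM mean estimates are biased toward each other when the effective
  separation is below ~2.5σ (edge-position modifications under the decay
  model); recovery there is ~1–2 pA rather than the ~0.5 pA achieved at
  full separation. This is the estimator, not a bug: the bias vanishes
  with separation and shrinks with pool size.
- The per-substring variant of the max-likelihood parameter selection is
  not implemented as a separate mode; "marginal" emission mode is the
  available alternative.
- Minus-strand reads are consumed on the forward reference strand (as
  event tables are reference-anchored); no strand-specific pore model is
  used.
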