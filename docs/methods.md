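# Methods

## Model overview

The pipeline answers a single scientific question: which isoprenoid route —
mevalonate (MVA) or methylerythritol phosphate (MEP) — produced the
ergosterol observed in a culture fed positionally labeled
[1-¹³C]glucose, judged from the integer mass shifts of its tandem-MS
product ions. It is organized as four layers:

1. **Atom-map atlas** (`ergolabel.atlas`): molecules, atom-mapped reactions
   and routes as a validated YAML document. Carbon provenance is computed by
   composing the per-reaction substrate→product carbon maps forward from
   glucose; branch probabilities multiply along convergent pool splits.
2. **Labeling model** (`ergolabel.labeling`): per-carbon ¹³C probabilities
   under a tracer and hypothesis, and Poisson-binomial shift envelopes for
   carbon subsets.
3. **Fragment model** (`ergolabel.fragments`): candidate fragment structures
   (connected carbon subsets of the sterol skeleton) for a nominal m/z,
   either enumerated or ingested as annotations.
4. **Classifier** (`ergolabel.classify`) and **synthetic generator**
   (`ergolabel.simulate`): verdicts for observed shift pairs, and
   simulate-then-classify parameter recovery.

## Atom maps and their assumptions

The packaged atlas encodes textbook carbon maps: EMP glycolysis split into
its two aldolase branches, pyruvate dehydrogenase, the
thiolase/HMGS/HMGR/decarboxylation chain of the MVA route, DXS/DXR and the
skeleton-preserving downstream MEP steps, head-to-tail FPP assembly,
head-to-head squalene synthase, oxidosqualene cyclization including its two
1,2-methyl migrations (protosterol 14-Me → C13, 8-Me → C14), and a single
net sterol-maturation map (lose both C4 methyls as CO₂ and the 14α-methyl
as formate; gain the C24-methyl, C28, from SAM). Only net carbon provenance
matters for labeling, so sterol-maturation intermediates are not modeled
individually; maps live in data files so corrections never require code
changes.

Stated model assumptions:

- **Single-pass EMP glycolysis.** No pentose-phosphate or TCA/gluconeogenic
  scrambling; these pathways would smear label into additional positions at
  low levels. Toggleable only by editing the atlas.
- **Complete triose-phosphate equilibration.** GAP drawn by any reaction is
  50% derived from glucose C1–C3 (via DHAP) and 50% from C4–C6, encoded as
  an explicit merge reaction with 0.5/0.5 weights.
- **SAM methyl unlabeled by default.** One-carbon metabolism is not
  modeled; `TracerSpec.sam_enrichment` exists for sensitivity analysis.
- **Per-position independence.** Each molecule assembles from independently
  drawn precursor units, and within a unit each precursor contributes at
  most one labelable carbon, so the Bernoulli independence behind the
  Poisson-binomial envelope is exact for both routes under this tracer.
- **DMAPP gem-methyl convention.** The two methyls of the chain-terminal
  isopropylidene descend from IPP C4 and C5; which one becomes the
  squalene main-chain terminus is a stereochemical (E/Z) assignment the
  nominal-mass data cannot resolve. The atlas fixes IPP C5 → main-chain
  terminus (ergosterol C26) and IPP C4 → branch methyl (C27). The choice
  only affects which of C26/C27 is MEP-labelable — both are MVA-labelable —
  and no packaged fragment separates the pair.

Resulting predictions (computed, and frozen as test oracles): IPP labelable
at {C2, C4, C5} (MVA) and {C1, C5} (MEP), each position with probability
½·*e*; ergosterol labelable at 15 positions (MVA) and 10 (MEP), with
{C18, C19, C21, C26} shared; C28 is the single SAM carbon; the 27 isoprenoid
carbons partition into 6 units missing 3 unit positions (the demethylation
losses).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `TracerSpec.enrichment` | 0.985 | isotopic purity of the tracer (98–99% commercial grade, midpoint) |
| `TracerSpec.labeled_positions` | {C1} | tracer label positions on glucose |
| `Hypothesis.alpha` | — | MEP flux fraction for mixture hypotheses |
| `labelable_positions(eps)` | 1e-9 | floating-point floor; "theoretically labeled" means p > 0, not a probability cutoff |
| `fragment_shift_distribution(a13)` | 0.0107 | ¹³C natural abundance; convolution off by default for classification (nominal-shift comparison), available for generator realism as qᵢ = pᵢ + (1−pᵢ)·a13 |
| `enumerate_fragments(max_cleavages)` | 3 | skeleton bond breaks (ring fragments need ≥ 2) |
| `enumerate_fragments(hydrogen_slack)` | ±2 | hydride shifts / H₂ losses around the retained skeleton hydrogens; tighter drops true sterol fragments, looser explodes candidates |
| `SimulationConfig.n_molecules` | 1e5 | synthetic population size |
| `SimulationConfig.noise_cv` | 0.1 | multiplicative lognormal intensity noise (standard MS error model) |
| `SimulationConfig.detection_threshold` | 0.05 | relative-intensity floor standing in for the instrument limit that truncates weak high-shift isotopologues |

## Fragment structures

The observed fragments are reported only as nominal masses, and the
original structure assignments are not available in machine-readable form,
so the packaged annotation table
(`fragment_annotations_synthetic.tsv`) is a reconstruction: for each mass a
connected ergosterol carbon subset whose hydrocarbon formula lies within
the rearrangement slack and whose per-hypothesis labelable counts are
consistent with the reported per-condition verdicts
(69 = C24–C28 side-chain terminus, C5H9⁺; 95 = C20–C25+C28, C7H11⁺;
121 = C17+C20–C27, C9H13⁺; 143 = C1–C11 ring-A/B fragment, C11H11⁺;
379 = whole skeleton, C28H43⁺). Every reconstruction appears among the
combinatorially enumerated candidates for its mass; classification can run
annotation-free in `top-candidate` or `any-candidate` mode.

## Classification rules

The match criterion is exact equality of the observed shift with the
predicted labeled-position count (full incorporation); a pathway verdict
additionally requires exclusivity (exactly one hypothesis explains the
shift). A +1 shift on a singly-MEP-labelable fragment is therefore
MEP-exclusive even though it could in principle also be partial
incorporation of a multiply labelable fragment; because the nominal data
cannot distinguish these, a partial-incorporation mode (`allow_partial`:
shift explained when 1 ≤ Δ ≤ count) is available but off by default —
under it, the same +1 observation becomes ambiguous. Both modes are
pure functions of (Δ, counts) exposed as `verdict_from_counts`.

## Synthetic spectra and what recovery shows

The generator draws n molecules with independent per-position Bernoulli
labels, histograms each fragment's labeled-carbon count, applies lognormal
noise, renormalizes to base peak 1 and applies the detection threshold.
Envelopes are read with the `max-mz` rule by default (the largest surviving
shift — how a labeled parent ion read as the "maximum" observed m/z is
obtained); `max-intensity` is available, but at ~50% per-position enrichment
the modal shift of a single-position fragment is 0, which is not how the
reported shifts behave.

What the generator does *not* emulate: chromatography, peak picking,
natural-abundance envelopes of the neutral culture (off by default),
intensity differences between fragments, detector saturation, or correlated
noise. Passing recovery therefore shows the inference chain is
self-consistent under its own noise model, not that it is robust to real
instrument artifacts.

Recovery under the default conditions (seed 1): at e = 0.985, 4 of 5
fragments recover the generating hypothesis; the whole-skeleton parent
envelope (10–15 labelable positions) loses its full-incorporation peak to
the detection threshold and stays unexplained — the same truncation that
makes a labeled parent read below its theoretical maximum shift. One
fragment (121, six MVA-labelable positions) sits near the threshold under
MVA at full enrichment, so its verdict is seed-sensitive there; the frozen
regression values in the tests pin one realization. Recovery is monotone in
enrichment by construction of the threshold truncation, and is asserted as
such, not assumed.

## Numerical choices

- Shift distributions by iterative convolution: exact, O(n²) in fragment
  size, verified against exhaustive 2ⁿ enumeration to 1e-12 for n ≤ 12.
- Candidate enumeration deletes every ≤ k edge combination of the skeleton
  graph and keeps components whose boundary fits the budget — complete by
  construction and verified against power-set search on ≤ 10-carbon toys.
- Ranking ties break deterministically: cleavage count, side-chain-terminus
  preference, lexicographic carbon set.
- All simulation randomness flows from one integer seed through
  `numpy.random.SeedSequence`; per-grid-cell child seeds stay below 2³¹.
- Degenerate inputs: empty carbon subsets give a point mass at +0; empty
  observation/annotation files give empty outputs; a mixture hypothesis has
  no predicted count and is rejected where a count is required.

## Known limitations

- The reconstruction of fragment carbon subsets is the main epistemic gap:
  verdicts in annotated mode are conditional on those subsets. Any
  disagreement with an authoritative assignment is traceable to a single
  row of the annotation table.
- No flux quantitation: a mixture hypothesis predicts envelope shapes, but
  the classifier works on single read-off shifts and deliberately refuses
  mixtures.
- Label scrambling through the pentose-phosphate and TCA pathways is
  ignored; at high pentose-phosphate flux the MVA/MEP patterns would blur.
- Nominal (unit) masses throughout; isotope fine structure and exact masses
  are out of scope.
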