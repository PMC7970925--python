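# ergolabel

Stable-isotope labeling inference for isoprenoid-pathway discrimination in
yeast: given product-ion mass shifts of ergosterol from cultures grown on
[1-¹³C]glucose, decide whether each fragment's shift is explained by the
mevalonate (MVA) route, the methylerythritol-phosphate (MEP) route, or
neither.

## The problem

Yeasts are textbook MVA-only organisms, but the oleaginous yeast *Yarrowia
lipolytica* shows signs of MEP-pathway activity under nitrogen limitation.
The two routes assemble the universal C5 isoprenoid precursors (IPP/DMAPP)
from different glycolytic intermediates, so a positionally labeled carbon
source marks different carbons of the final sterol:

- On [1-¹³C]glucose, the label reaches the triose pool only through the
  DHAP branch of aldolase, so GAP C3 (→ pyruvate C3) is ¹³C with
  probability ½·*e*, where *e* ≈ 0.985 is the tracer's isotopic enrichment.
- **MVA route** (3 × acetyl-CoA → mevalonate → IPP): the label sits on the
  acetyl methyl, giving IPP labeled at **C2, C4, C5**.
- **MEP route** (pyruvate + GAP → DXP → MEP → IPP): the label enters via
  DXP C1 and C5, giving IPP labeled at **C1, C5**.

Six such C5 units build squalene → lanosterol → ergosterol (losing three
methyl carbons during sterol maturation and gaining C28 from SAM), so the
two hypotheses predict different labelable ergosterol carbons: 15 positions
under MVA, 10 under MEP. A product ion retaining carbon subset *F* should
shift by |labelable ∩ *F*| mass units at full incorporation; comparing the
observed shift Δ of each fragment with the two predicted counts yields a
pathway verdict (MVA-exclusive, MEP-exclusive, ambiguous, or unexplained).

The per-fragment shift envelope is modeled as a Poisson-binomial over
independent per-position Bernoulli labels, which also powers a synthetic
spectrum generator used to validate the whole chain by parameter recovery.

## Worked example

`python analysis/03_classify_observed_shifts.py` classifies the observed
neutral→labeled shift pairs from the two culture conditions:

```
 nitrogen-limited: m/z 69 -> 70 (shift +1; predicted MVA 3, MEP 1) => MEP
 nitrogen-limited: m/z 121 -> 124 (shift +3; predicted MVA 6, MEP 3) => MEP
 nitrogen-limited: m/z 143 -> 146 (shift +3; predicted MVA 5, MEP 3) => MEP
           normal: m/z 69 -> 70 (shift +1; predicted MVA 3, MEP 1) => MEP
           normal: m/z 95 -> 98 (shift +3; predicted MVA 3, MEP 2) => MVA
```

Each line compares the observed shift with the number of theoretically
labelable positions the fragment retains under each hypothesis: the three
nitrogen-limited fragments match the MEP prediction exclusively, while the
normal condition splits one verdict per pathway — MEP support is higher
under nitrogen limitation by two verdicts.

The other drivers: `01_trace_labeling.py` (per-carbon provenance and
isoprene-unit decomposition), `02_fragment_candidates.py` (candidate
enumeration for the observed masses), `04_recovery_simulation.py`
(parameter recovery on synthetic spectra). A `ergolabel` CLI exposes the
same stages (`validate-atlas`, `trace`, `fragments`, `classify`,
`simulate`, `recover`).

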