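# coamscreen

Coamorphous (COAM) systems — single-phase amorphous mixtures of an
active pharmaceutical ingredient (API) and a small-molecule coformer —
keep the dissolution advantage of the amorphous state while resisting
recrystallization. Screening which API–coformer pairs will actually
form a COAM phase is expensive, so formulation groups use descriptor
models to rank candidates before any wet-lab work.

`coamscreen` is a Python library for that screening workflow. It covers:

- **Pair descriptors**: average molecular weight, the summed
  donor–acceptor difference Σ(HBD−HBA) over both components, the excess
  enthalpies of mixing (ΔH_mix) and hydrogen bonding (ΔH_hb) of the
  pair, and the API-minus-coformer differences Δδh (Hansen
  hydrogen-bonding parameter) and Δμ (pseudo-chemical potential).
  MW and Lipinski donor/acceptor counts can be derived from SMILES/SDF
  via RDKit; an open Hoftyzer–Van Krevelen group-contribution surrogate
  is provided for δh.
- **PLS-DA core, written from scratch**: autoscaling, NIPALS
  latent-variable extraction with X and y deflation, a continuous COAM
  value ŷ = ȳ + x'·b (b = W(P'W)⁻¹q) on the {not COAM: 0, COAM: 1}
  coding, inclusive classification at ŷ ≥ 0.5, and the LV1/LV2 decision
  boundary used in score plots.
- **Screen evaluation**: confusion table (predicted COAM positive),
  integer accuracy percentage, one-sided Fisher exact probability of
  positive association, per-pair agreement flags, and score-plot export
  (experimental COAM green, not-COAM red, wrong calls hollow, dashed
  boundary).
- **Synthetic screens and printed fixtures**: a two-class multivariate
  normal descriptor generator (the class split lives in the enthalpy
  coordinates), plus two packaged validation screens of the bislactam
  coformer bisVCap: a seven-system comelt screen and a thirteen-system
  predictive screen with continuous COAM values.

## Worked example

```python
from coamscreen import (
    evaluate_screen, fixture_new_screen, fixture_prior_screen,
    predictions_from_printed,
)

for name, screen in (("prior comelt screen", fixture_prior_screen()),
                     ("predictive screen", fixture_new_screen())):
    result = evaluate_screen(screen, predictions_from_printed(screen))
    print(name, result.confusion.correct, result.accuracy_percent,
          round(result.fisher_p, 4))
```

Running `python examples/01_evaluate_printed_screens.py` prints:

```
prior comelt screen: n=7
  predicted COAM: 1
  correct: 5/7 -> accuracy 71%
  one-sided Fisher p = 0.4286
  confusion (tp,fp,fn,tn) = (1,0,2,4)
predictive screen: n=13
  predicted COAM: 10
  correct: 11/13 -> accuracy 85%
  one-sided Fisher p = 0.1084
  confusion (tp,fp,fn,tn) = (9,1,1,2)
```

Five of the seven comelt systems are called correctly (71%); the Fisher
probability 0.43 says an association at least this strong arises by
chance in 3 of 7 random label assignments with the same margins. In the
predictive screen, classifying the thirteen continuous COAM values at
the inclusive 0.5 threshold marks ten pairs as coamorphous and matches
the melt-quench outcome for eleven of thirteen (85%), counting
decomposed-on-melting systems as not-COAM.

The other examples show the full synthetic train/predict/plot loop
(`examples/02_train_predict_synthetic.py`) and structure-derived
descriptors (`examples/03_descriptors_from_structure.py`). A thin CLI
wraps the same library calls:

```bash
coamscreen simulate --seed 1 --out-dir sim/
coamscreen train --components sim/components.csv --pairs sim/pairs.csv --model model.json
coamscreen predict --model model.json --components sim/components.csv \
    --pairs sim/pairs.csv --out predictions.csv --plot scores.svg
coamscreen evaluate --fixture prior
```

## Scope

The quantum-chemical computation of ΔH_mix, ΔH_hb, δh and μ is out of
scope: those values are inputs (measured, solver-derived, or synthetic).
The package does not model ionic compounds (salts), stability over
time, temperature or humidity, or drug-loading ratios.
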