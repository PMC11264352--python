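# repcost

Tools for asking whether reproduction carries a *survival cost* in a
long-lived seabird, and whether that cost is mediated by energy
expenditure. The package grew out of a long-term mark–resight study of
pelagic cormorants (*Phalacrocorax pelagicus*) breeding on a single
colony structure, where each banded bird is scored every season as a
failed/non-breeder (state 1) or a successful breeder that fledged at
least one nestling (state 2), and where a subset of chick-rearing males
carried GPS–pressure loggers or accelerometers.

It is aimed at population ecologists who want a tested, scriptable
version of the full analysis chain:

1. **Multi-state capture–mark–recapture.** The two-observable-state
   Arnason–Schwarz model written as a hidden Markov model over latent
   states {1, 2, dead}, conditioned on first capture. Per interval a bird
   in state *r* survives with probability Φʳₜ and, given survival, moves
   with probability ψʳˢₜ (survive-then-move); a live bird in state *s* is
   detected at an occasion with probability pˢₜ. Detection may depend on a
   trap class — "first after release" vs "later" — which corrects the
   trap-happiness typical of faithful colony birds. Effect structures
   (State, Time, Sex, TrapClass with interactions) are declarative,
   fitting is by quasi-Newton on the logit scale with an analytic
   forward–backward gradient, and model selection uses AICc with Akaike
   weights `w_i = exp(-Δ_i/2)/Σ_j exp(-Δ_j/2)` in a three-stage cascade
   (p, then ψ, then Φ).
2. **Cost-of-reproduction verdicts.** A season is *costly* when
   successful breeders survived the following interval worse than
   failed/non-breeders, the ±1 SE intervals being disjoint; *beneficial*
   when reversed; *equal* when they overlap.
3. **Time–energy budgets.** Logger tracks are classified into rest on
   land / surface swim / dive / flight by threshold rules; budgets of
   ≥24 h feed `DEE = 24 · Σₐ fₐ · MRₐ` (kJ/day) with activity-specific
   metabolic rates supplied as calibrated inputs.
4. **Covariate models.** All-subsets AICc over
   `DEE ~ Year * BroodSize * BroodAge * AdultAge` (two-way interactions,
   hierarchical), Tukey-adjusted year contrasts at covariate means, and
   Poisson/binomial GLMs linking DEE to productivity and apparent
   survival.
5. **Synthetic data with known truth** for every input, so the whole
   chain is testable without any field download.

## Worked example

```python
import numpy as np
from repcost.capture_data import OccasionSet, pool_identical_histories
from repcost.multistate_cmr import FitOptions, ModelSpec, Params, fit_model
from repcost.survival_cost import classify_all_years, extract_state_survival
from repcost.synthetic_data import CmrTruth, simulate_histories

occ = OccasionSet.from_years(range(2000, 2008))
phi = np.full((2, occ.n_intervals, 2), 0.85)
phi[1, 3, :] = 0.55                      # one costly season (2003)
truth = Params.constant(occ, phi=[0.85, 0.85], p=[0.75, 0.75],
                        psi=[0.3, 0.25])
truth.phi = phi

sim = pool_identical_histories(
    simulate_histories(CmrTruth(truth, seed=200), 2500, occ))
fit = fit_model(sim, ModelSpec(phi="State*Time", p="State", psi="State"),
                FitOptions(multistart_n=1))
for label in classify_all_years(extract_state_survival(fit)):
    print(label.year, label.verdict)
```

```
2000 equal
2001 equal
2002 beneficial
2003 costly
2004 equal
2005 equal
2006 not_comparable
```

The injected survival deficit of successful breeders in 2003 is flagged
`costly`; the final interval is `not_comparable` because terminal
survival and detection are only identifiable as a product.

A command-line front end mirrors the library:

```bash
repcost run --seed 5 --out out all      # simulate -> fit -> verdicts -> DEE
```

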