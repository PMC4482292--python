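# rabswitch

Automated structural identification of the Rab5–Rab7 conversion switch in
early endocytosis: enumerate a combinatorial space of kinetic ODE model
structures, fit every candidate to two-channel fluorescence time series by
Differential Evolution, rank the candidates under domain-independent and
domain-specific model-selection criteria, measure how many of them remain
indistinguishable (the error-profile *plateau*), and probe practical
parameter identifiability by bootstrap refitting.

The package is aimed at systems biologists and methods researchers studying
model selection for dynamical systems under limited observability: only the
scaled *total* (active + passive) concentration of each Rab protein is
observable, while the dynamics are driven by the hidden active states.

## Model

Each candidate follows a fixed two-protein template.  With `r5, r7` the
passive (GDP-bound) and `R5, R7` the active (GTP-bound) concentrations:

```
dr5/dt = K1 − (k1 + GEF5(R5,R7))·r5 + GAP5(R5,R7)·R5
dR5/dt = GEF5(R5,R7)·r5 − GAP5(R5,R7)·R5
dr7/dt = K2 − (k2 + GEF7(R5,R7))·r7 + GAP7(R5,R7)·R7
dR7/dt = GEF7(R5,R7)·r7 − GAP7(R5,R7)·R7
```

`K1, K2` are GDI association fluxes and `k1, k2` GDI dissociation rates.  A
*structure* chooses one kinetic functional form per regulatory slot —
GEF5 (3 alternatives), GAP5 (3), GEF7 (7: cross-activation by R5 optionally
combined with auto-activation by R7), GAP7 (2) — giving 3·3·7·2 = 126
candidates.  Forms are intrinsic (constant), Michaelis–Menten `V·X/(Km+X)`,
Hill/sigmoidal `V·X³/(Km³+X³)`, exchange inhibition `V·Km/(Km+X)`, and
linear `k·X`.  Observation model: `Rab5 = K·(r5+R5)`, `Rab7 = K·(r7+R7)`
with a free intensity scale `K`, plus an onset offset `td` aligning the
simulation clock with the first measurement.

Candidates are scored by (smaller is better):

- `E` — average relative RMSE of the two observed channels, normalised so a
  per-channel mean predictor scores exactly 1;
- `R` — disagreement between hidden active states and observed totals,
  `½·[min(1−r(R̂5,Rab5),1) + min(1−r(R̂7,Rab7),1)]` with Pearson `r`;
- `X` — normalised distance between measured and simulated Rab5→Rab7
  dominance switch times;
- convex combinations `RX, ER, EX, ERX` (trade-off `α`) and
  complexity-penalised variants `EC, ERC, EXC, ERXC` (trade-off `β`, process
  count `C`).

Fitting uses Differential Evolution, strategy rand/1/bin, population 81,
F = 0.942, Cr = 0.915, evaluation budget 20,000 per free parameter, box
bounds `[1e−3, 4]` for kinetic parameters, `[0, 2]` for initial values,
`[1e3, 1e5]` for `K` and `[5, 195] s` for `td`.  A profile's plateau ends at
the first consecutive pair of sorted criterion values differing by more
than 10 %.

## Worked example

The numbered scripts under `analysis/` run the study at desk scale and
write tables under `results/`.  Generating the reference synthetic dataset
and the candidate catalog:

```
$ python analysis/01_generate_data.py
truth structure : m072 (gef5=sigmoidal_auto|gap5=sigmoidal_by_R7|gef7=mm_cross+mm_auto|gap7=intrinsic)
switch time     : noiseless 128.4 s, detected on noisy data 149.7 s
passive r5 CV   : 0.0064
passive r7 CV   : 0.0033
corr(Rab5 active, total): 0.9997
corr(Rab7 active, total): 1.0000

$ python analysis/02_enumerate_models.py
126 candidate structures
  C = 8: 54 structures
  C = 9: 72 structures
parameter-space sizes: [15, 16, 17, 18, 19, 20]
```

The scenario reproduces the qualitative signature of the measured system: a
single Rab5-to-Rab7 dominance switch in the interior of the window,
near-constant passive states (coefficients of variation below 0.01), and
active states that track the observed totals almost perfectly — which is
exactly why limited observability makes the structures hard to tell apart.
`03_fit_models.py` then fits a seeded ten-structure sweep under ERX
(α = 0.5), and `04_rank_models.py` ranks it:

```
$ python analysis/04_rank_models.py
E (alpha=1.0): plateau 3 of 10
ER (alpha=0.5): plateau 2 of 10
EX (alpha=0.9): plateau 3 of 10
ERX (alpha=0.5): plateau 1 of 10
```

Folding domain knowledge into the criterion shrinks the set of mutually
indistinguishable structures — here from 3 models under pure error `E` down
to a single model under the combined `ERX`.  Finally,
`05_identifiability.py` bootstrap-refits the generating structure on
re-noised data (20 replicates, 10 % noise):

```
$ python analysis/05_identifiability.py
parameters flagged at bounds: 7 of 19
estimate pairs with |r| > 0.8: 1
  K2 ~ k2: r = +0.890
```

The strongly correlated pair is the GDI association/dissociation couple of
Rab7 — the classic practically-non-identifiable combination for this
observation model, since the observable total feels them only through
`K2 − k2·r7`.

The same machinery is available as a CLI
(`rabswitch enumerate | synth | fit | rank | identify`) for user-supplied
measurement files in space-delimited `t Rab5 Rab7` format.

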