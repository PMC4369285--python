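# solvcoef

Tools for working with Abraham-model solvent coefficients: predicting
partition coefficients and solubilities, recalibrating published coefficient
tables to a zero-intercept convention so solvents can be compared directly,
screening solvent-replacement candidates (including sustainable "green"
solvents), diagnosing coefficient-model error, and training random-forest
models that predict a solvent's coefficients from its structure.

It is aimed at solvent-selection and process-chemistry work: given a solute's
Abraham descriptors, which solvents dissolve it comparably well, and what can
substitute a problematic solvent?

## The model

The Abraham general solvation model is a linear free-energy relationship.
For a solvent/water partition coefficient (molarity standard state),

```
log P = c + e·E + s·S + a·A + b·B + v·V
```

and for solubility transfer from water into the solvent,

```
log Ss = log Sw + c + e·E + s·S + a·A + b·B + v·V
```

where (c, e, s, a, b, v) are solvent coefficients and (E, S, A, B, V) are
solute descriptors: excess molar refractivity ((cm³/mol)/10),
dipolarity/polarizability, summation H-bond acidity and basicity, and McGowan
volume ((cm³/mol)/100).

Because the fitted intercept c varies with the training set, solvents are
made directly comparable by refitting each row with c forced to zero over a
solute population ("zero-intercept" convention, coefficients e0…v0).  Two
solvents are then compared through the replacement distance

```
d = (e01−e02)·E_ave + (s01−s02)·S_ave + (a01−a02)·A_ave + (b01−b02)·B_ave + (v01−v02)·V_ave
```

(the difference in predicted log P for the average solute, with
(E_ave, S_ave, A_ave, B_ave, V_ave) = (0.884, 1.002, 0.173, 0.486, 1.308)),
or through the same difference evaluated at a specific solute.  Small |d|
marks a candidate replacement.

The package ships a measured coefficient table (91 solvents, both
conventions), a model-predicted table for 118 sustainable-solvent candidates,
and curated SMILES for the structural solvents, so everything below runs
offline.

## Worked example

How well does methanol dissolve benzoic acid (E = 0.730, S = 0.90, A = 0.59,
B = 0.40, V = 0.9317), and what could replace methanol in general?

```
$ solvcoef predict --solvent methanol --solute "0.730,0.90,0.59,0.40,0.9317"
methanol        logP    1.935
```

Benzoic acid is predicted to partition into methanol about 86-fold
(10^1.935) relative to water, i.e. it is far more soluble in methanol.

```
$ solvcoef replace --query methanol --threshold 0.08
query,candidate,d,abs_d,mode,provenance
methanol,diisobutyl succinate,0.004,0.004,general,predicted
methanol,nitromethane,-0.005,0.005,general,measured
methanol,2-pentanol,0.006,0.006,general,measured
...
methanol,"1,2-propylene glycol",-0.074,0.074,general,predicted
...
```

Each row is a candidate whose average-solute solubility behaviour is within
0.08 log units of methanol; d is signed (negative: the candidate is predicted
to be the slightly better solubilizer) and `provenance` says whether the
candidate's coefficients are measured or model-predicted.  1,2-propylene
glycol — a low-toxicity, bio-derivable liquid — sits at |d| ≈ 0.07, making it
a credible general replacement for methanol.

For a specific solute, the screen is sharper:

```
$ solvcoef replace --query sulfolane --solute "0.730,0.90,0.59,0.40,0.9317" --threshold 0.001
query,candidate,d,abs_d,mode,provenance
sulfolane,ethylene glycol,0.0,0.0,solute-specific,measured
```

For benzoic acid work, ethylene glycol is predicted to behave almost
identically to sulfolane (|d| ≈ 0.0004 log units).

The same operations are available as a library (`solvcoef.eval_logp`,
`solvcoef.general_distance`, `solvcoef.screen_replacements`,
`solvcoef.recalibrate_table`, `solvcoef.train`, …); the CLI is a thin layer
over it.

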