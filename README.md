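# combonet

Reconstruct perturbed signaling networks of two cell lines, map short-term
signaling response to cell viability, and prioritize selective low-dose
multi-drug combinations at unseen concentrations.

The pipeline has five stages:

1. **Comparative network reconstruction** (`combonet.cnr`) — jointly fit
   per-cell-line interaction matrices `r` (modular-response-analysis local
   response coefficients, diagonal fixed at −1) and direct perturbation
   effects `s` to measured log2 fold-change response matrices, by a penalized
   mixed-integer quadratic program: squared residuals + η per edge + θ per
   between-line difference, with binary indicator variables controlling
   topology and differences, and dose-ordering constraints
   0 > s(IC50) > s(IC90). The program decomposes exactly per network node and
   is solved natively by branch and bound with constrained least-squares
   subproblems — no external MIP solver needed. An exhaustive-enumeration
   backend serves as the optimum oracle for small instances.
2. **Significance** (`combonet.nulls`) — random-topology, node-permutation
   and random-difference ensembles; empirical p-value (k+1)/(n+1).
3. **Signaling → viability** (`combonet.viability`) — six candidate model
   forms (two linear, four saturating nonlinear), per-cell-line fits,
   leave-one-out model comparison, bootstrap confidence intervals.
4. **Dose interpolation** (`combonet.dose`) — per (drug, target, cell line)
   saturating inhibition curves `s(c) = Imax·c/(KI+c)` through the two
   reconstructed anchor points; interpolation only (0 ≤ c ≤ 1).
5. **Combination optimization** (`combonet.combos`) — simulate any 3-drug
   combination at arbitrary concentrations, optimize (anti-)selectivity
   subject to a protected-line viability floor (default 0.8) and per-drug
   IC10 caps, select non-selective controls, rank all triples, and run the
   noise-based power analysis.

`combonet.synthetic` generates ground-truth two-cell-line networks, study
designs (9 nodes, 9 inhibitors at two doses each — one single-dose drug —
plus two-drug combinations; 34 conditions by default) and noisy
response/viability datasets, so the whole pipeline is testable without
external data.

## Command-line usage

```sh
# generate a synthetic dataset
combonet synth --edges 16 --diffs 13 --noise 0.1 --seed 1 -o data/

# reconstruct networks (theta may be a number or 'inf')
combonet reconstruct --responses data/responses_parental.tsv \
    --responses data/responses_mutant.tsv \
    --prior prior.tsv --map drugs.yaml --eta 0.1 --theta 2.0 -o out/

# null ensembles, viability fit, dose curves, optimization, power
combonet nulls --responses ... --prior ... --map ... --mode random_topology --n 1000
combonet fit-viability --responses ... --viability data/viability.tsv --form 4c
combonet dose-fit --network out/network.json --map drugs.yaml -o dose_params.tsv
combonet optimize --network out/network.json --dose dose_params.tsv \
    --viab viability_fit.json --map drugs.yaml --direction anti_selective -o ranked.tsv
combonet power --groups groups.tsv --noise 0.25 --nsims 1000 --seed 1

# or everything at once from a YAML config (synthetic end-to-end)
combonet run --config config.yaml --synthetic --seed 1 -o run/
```

Formats: response matrices and tables are TSV; condition identifiers are
strings like `DRUG1@IC50+DRUG2@IC50`; designs, networks and fits are JSON;
configuration is YAML (`targets:` drug → target-node list, `dose_levels:`
drug → {IC10, IC50, IC90} normalized concentrations with IC90 = 1).

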