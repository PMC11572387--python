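# paleotip

Dated phylogenetics for discrete morphological matrices with fossil taxa —
built for datasets like Neogene hamster (Cricetinae) dental characters, where
almost every tip is a fossil with an uncertain age and the questions are
"what is the tree, when did the clades split, and which tooth characters
diagnose them?"

One package covers the whole workflow:

* **Parsimony** — tree length by Hartigan's polytomy-safe dynamic program on
  state-set cells, equal weights and implied weights (fit `Σ k/(k+hᵢ)`,
  default concavity k = 12), random-addition + SPR/TBR search, bootstrap,
  ensemble CI/RI.
* **Mkv likelihood** — the k-state symmetric Markov model with discrete-gamma
  rate heterogeneity and the ascertainment correction for matrices that never
  code constant characters.
* **Tip dating** — Bayesian MCMC under the fossilized birth–death (FBD) tree
  prior with `fossiltip` (fossils as terminal tips) or `random` (sampled
  ancestors allowed) sampling strategies, strict/IGR/TK02 clocks, uniform
  tip-age priors, an offset-exponential root prior, a clock-rate prior
  derived from a preceding non-clock run, stepping-stone marginal likelihoods
  and Bayes factors, MCC summaries with 95% HPDs.
* **Tree-set hygiene** — majority-rule consensus, greedy rogue-taxon
  detection by consensus information content, pruning with age preservation.
* **Stratigraphic congruence** — basic time-scaling against first
  appearances; RCI, GER and MSM* with permutation significance tests.
* **Ancestral states** — parsimony character mapping (with explicit
  ambiguity), per-character ER/SYM/ARD model selection by AIC, stochastic
  character mapping, synapomorphy extraction with exclusivity checks.
* **Synthetic data** — a forward FBD + Mk + relaxed-clock simulator so every
  stage is testable end-to-end without any downloads.

## Worked example

Simulate a fossil-rich dataset and push it through the full preset:

```bash
cat > sim.json <<'JSON'
{"min_tips": 18, "max_tips": 22, "origin": 18,
 "fbd": {"lam": 0.4, "mu": 0.3, "psi": 0.4, "rho": 0.1111}}
JSON
paleotip simulate --out-prefix demo --seed 7 --config sim.json
cat > run.json <<'JSON'
{"matrix_path": "demo.nex", "ages_path": "demo_ages.csv",
 "out_dir": "demo_out", "seed": 7, "mp_n_starts": 4,
 "generations": 6000, "nonclock_generations": 3000,
 "clocks": ["igr"], "strategies": ["fossiltip"], "rho": 0.1111,
 "asr_chars": [0, 1, 2, 3, 4, 5]}
JSON
paleotip run --config run.json
```

On this simulated 22-taxon, 116-character dataset the run prints (output of
the commands above, ~4 minutes on one core):

```json
{
 "out_dir": "demo_out",
 "parsimony": {
  "ew": {"length": 393, "ci": 0.438, "ri": 0.553, "fit": 101.22, "n_trees": 3, "seed": 7},
  "iw": {"length": 393, "ci": 0.438, "ri": 0.553, "fit": 101.35, "n_trees": 1, "seed": 7}
 },
 "rogues": ["fossil_11", "fossil_7", "fossil_8"]
}
```

meaning: the equal-weights optimum needs 393 steps (three distinct optimal
topologies) with ensemble consistency index 0.438 and retention index 0.553;
implied weighting at k = 12 finds a tree of the same length with a slightly
better total fit; and three fossils were unstable enough across the clock
posterior to be pruned before the consensus summaries. `demo_out/summary.json`
carries the rest: the clock prior derived from the non-clock run (rate
0.2013 changes/character/My here), the tip-dated root age (posterior median
30.6 Ma, 95% HPD 29.3–32.9 — with every ESS flagged below 200 at this short
chain length, as the diagnostics report), the stratigraphic fit of each
consensus (IW consensus: GER 0.447, MSM* 0.135, permutation p ≈ 0.21), and
per-clade synapomorphies. `demo_out/` also holds every tree set (NEXUS), the
MCMC trace (CSV) and a seeded per-stage log.

Every stage is also a library call (`paleotip.parsimony.search`,
`paleotip.tipdating.run_mcmc`, `paleotip.stratcon.strat_indices`, ...) and a
subcommand (`paleotip mp|lnl|bayes|ss|rogues|prune|consensus|stratfit|asr`).

To analyse a published matrix, point `matrix_path` at a NEXUS file
(datatype=standard, `?` missing, `(..)` polymorphisms) and `ages_path` at a
`taxon,min_ma,max_ma` CSV. The empirical checks in
`tests/test_acceptance.py` expect the 44-taxon/116-character cricetine
dental matrix and its tip ages under `data/cricetinae_44x116.nex` and
`data/cricetinae_tip_ages.csv`; those files are journal supplementary
material and are not bundled here.

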