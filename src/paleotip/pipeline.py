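"""One-shot orchestration of the full analysis workflow.

Order of stages (mirroring standard practice for dated morphological
phylogenies): equal- and implied-weights parsimony searches; non-clock
Bayesian inference; derivation of the clock-rate prior from the
non-clock tree lengths; tip-dated Bayesian runs (clock model × fossil
sampling strategy combinations); optional stepping-stone model
comparison; rogue-taxon detection on the clock posteriors; common
pruning of every tree set by the same rogues plus any preset drops
(e.g. extant taxa); consensus/MCC summaries on the pruned sets;
stratigraphic congruence of the dated topologies; and ancestral-state
reconstruction (parsimony on the IW consensus, stochastic mapping on the
dated MCC tree).

Every stage logs its seed and writes machine-readable artifacts into the
output directory; any stage failure aborts with the stage name while
earlier artifacts are preserved.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import parsimony
from .matrixio import parse_nexus, parse_tip_ages, write_trees
from .treesample import TreeSample
from .treetools import detect_rogues, majority_consensus, prune_sample
from .stratcon import strat_indices
from .ancstates import parsimony_map, select_model, stochastic_map, synapomorphies
from .tipdating import (Priors, clock_prior_from_sample, compare_models, hpd_interval,
                        mcc_tree, run_mcmc, run_nonclock, stepping_stone,
                        SteppingStoneConfig)

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    matrix_path: str
    ages_path: str
    out_dir: str = "paleotip_out"
    seed: int = 1
    # parsimony block
    mp_n_starts: int = 8
    mp_k: float = 12.0
    bootstrap: int = 0
    # bayes block
    clocks: tuple = ("igr",)
    strategies: tuple = ("fossiltip",)
    generations: int = 20000
    nonclock_generations: int = 10000
    sample_every: int = 20
    burnin: float = 0.30
    rho: float = 2.0 / 18.0
    root_offset: float | None = None  # default: oldest interval maximum
    root_mean_excess: float = 8.2  # root prior mean = offset + excess
    root_prior_median: float | None = None  # None -> analytic median
    ingroup: tuple | None = None  # None -> all taxa except the oldest (outgroup)
    stepping_stone_steps: int = 0  # 0 = skip model comparison
    # rogue / prune block
    extra_prune: tuple = ()  # e.g. the extant taxa
    # stratfit block
    permutations: int = 500
    # asr block
    n_maps: int = 200
    asr_chars: tuple | None = None  # None -> all


def _log(log_path, stage, **info):
    with open(log_path, "a") as fh:
        fh.write(json.dumps({"t": round(time.time(), 1), "stage": stage, **info}) + "\n")


def run_full(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    summary: dict = {"config": asdict(config)}
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, default=str)
    stage = "load"
    try:
        matrix = parse_nexus(config.matrix_path)
        ages = parse_tip_ages(config.ages_path, matrix)
        summary["data"] = {"n_taxa": matrix.n_taxa, "n_char": matrix.n_char}
        _log(log_path, stage, **summary["data"])

        # ------------------------------------------------ parsimony
        stage = "parsimony"
        mp = {}
        mp_samples = {}
        for crit in ("ew", "iw"):
            res = parsimony.search(
                matrix, criterion=crit, k=config.mp_k,
                n_starts=config.mp_n_starts, seed=config.seed,
            )
            mp_samples[crit] = res
            best = res.params.iloc[0]
            mp[crit] = {
                "length": int(best["length"]), "ci": round(float(best["ci"]), 3),
                "ri": round(float(best["ri"]), 3), "fit": float(best["fit"]),
                "n_trees": len(res.trees), "seed": config.seed,
            }
            write_trees(res.trees, out / f"mp_{crit}.trees.nex")
            if config.bootstrap:
                bs = parsimony.bootstrap_support(
                    matrix, B=config.bootstrap, criterion=crit, k=config.mp_k,
                    seed=config.seed + 7,
                )
                mp[crit]["bootstrap"] = {
                    "|".join(sorted(s)): v for s, v in sorted(bs.items(), key=lambda kv: -kv[1])
                }
            _log(log_path, stage, criterion=crit, **{k: v for k, v in mp[crit].items()
                                                     if k != "bootstrap"})
        summary["parsimony"] = mp

        # ------------------------------------------------ non-clock BI
        stage = "nonclock"
        nc = run_nonclock(
            matrix, generations=config.nonclock_generations,
            sample_every=config.sample_every, burnin=config.burnin,
            seed=config.seed + 11,
        )
        median_tl = float(np.median(nc.trace["tree_length"]))
        summary["nonclock"] = {
            "median_tree_length": median_tl, "ess": nc.ess, "low_ess": nc.low_ess,
            "seed": config.seed + 11,
        }
        _log(log_path, stage, median_tree_length=median_tl)

        # ------------------------------------------------ clock prior
        stage = "clock_prior"
        offset = config.root_offset
        if offset is None:
            offset = max(ages.intervals[t][1] for t in matrix.taxa)
        priors = Priors(root_offset=offset, root_mean=offset + config.root_mean_excess)
        med = config.root_prior_median or priors.root_median()
        rate, mean_log, sd_log = clock_prior_from_sample(nc.trace["tree_length"], med)
        priors.clock_mean_log = mean_log
        priors.clock_sd_log = sd_log
        if config.ingroup is not None:
            priors.ingroup = frozenset(config.ingroup)
        summary["clock_prior"] = {
            "rate": rate, "mean_log": mean_log, "sd_log": sd_log,
            "root_prior_median": med,
        }
        _log(log_path, stage, **summary["clock_prior"])

        # ------------------------------------------------ tip dating
        stage = "tipdating"
        clock_runs = {}
        clock_samples = {}
        logml = {}
        for clock in config.clocks:
            for strat in config.strategies:
                key = f"{clock}_{strat}"
                res = run_mcmc(
                    matrix, ages, clock=clock, strategy=strat, priors=priors,
                    rho=config.rho, generations=config.generations,
                    sample_every=config.sample_every, burnin=config.burnin,
                    seed=config.seed + 23,
                )
                clock_samples[key] = res
                clock_runs[key] = {
                    "acceptance": res.acceptance,
                    "root_age_median": float(np.median(res.trace["root_age"])),
                    "root_age_hpd": hpd_interval(res.trace["root_age"]),
                    "low_ess": res.low_ess, "seed": config.seed + 23,
                }
                res.trace.to_csv(out / f"trace_{key}.csv", index=False)
                write_trees(res.sample.trees, out / f"posterior_{key}.trees.nex")
                _log(log_path, stage, model=key,
                     root_age=clock_runs[key]["root_age_median"])
                if config.stepping_stone_steps >= 2:
                    lml = stepping_stone(
                        matrix, ages,
                        SteppingStoneConfig(
                            n_steps=config.stepping_stone_steps,
                            generations_per_step=max(config.generations // 4, 500),
                            seed=config.seed + 31,
                        ),
                        clock=clock, strategy=strat, priors=priors, rho=config.rho,
                    )
                    logml[key] = lml
        if len(logml) >= 2:
            keys = sorted(logml, key=lambda k: -logml[k])
            bf, cat = compare_models(logml[keys[0]], logml[keys[1]])
            summary["model_comparison"] = {
                "log_ml": logml, "best": keys[0], "2lnBF_vs_next": bf, "evidence": cat,
            }
        summary["tipdating"] = clock_runs

        # ------------------------------------------------ rogues & pruning
        stage = "rogues"
        rogues: list[str] = []
        for key, res in clock_samples.items():
            rep = detect_rogues(res.sample)
            for r in rep.rogues:
                if r not in rogues:
                    rogues.append(r)
        drop = [t for t in rogues] + [t for t in config.extra_prune if t not in rogues]
        drop = [t for t in drop if t in matrix.taxa]
        summary["rogues"] = {"detected": rogues, "pruned": drop,
                             "reason": {t: ("rogue" if t in rogues else "preset")
                                        for t in drop}}
        _log(log_path, stage, rogues=rogues, pruned=drop)

        stage = "prune"
        pruned_matrix = matrix.subset_taxa([t for t in matrix.taxa if t not in drop])
        pruned_sets: dict[str, TreeSample] = {}
        for crit, res in mp_samples.items():
            pruned_sets[f"mp_{crit}"] = prune_sample(res, drop) if drop else res
        for key, res in clock_samples.items():
            pruned_sets[key] = prune_sample(res.sample, drop) if drop else res.sample
        taxon_sets = {frozenset(s.taxon_labels) for s in pruned_sets.values()}
        assert len(taxon_sets) == 1, "pruned tree sets must share one taxon set"

        # ------------------------------------------------ consensus / MCC
        stage = "summaries"
        summaries = {}
        consensus_trees = {}
        for crit in ("ew", "iw"):
            cons = majority_consensus(pruned_sets[f"mp_{crit}"], 0.5)
            score = parsimony.tree_length(cons, pruned_matrix)
            consensus_trees[crit] = cons
            summaries[f"mp_{crit}_consensus"] = {
                "length": score.length, "ci": round(score.ci, 3), "ri": round(score.ri, 3),
            }
            write_trees([cons], out / f"consensus_mp_{crit}.nex")
        mccs = {}
        for key in clock_samples:
            mcc = mcc_tree(pruned_sets[key])
            mccs[key] = mcc
            ing_nodes = [nd for nd in mcc.preorder_node_iter() if not nd.is_leaf()]
            summaries[f"{key}_mcc_root_age"] = float(mcc.seed_node.age)
            write_trees([mcc], out / f"mcc_{key}.nex")
        summary["summaries"] = summaries
        _log(log_path, stage, **{k: v for k, v in summaries.items() if not isinstance(v, dict)})

        # ------------------------------------------------ stratigraphic fit
        stage = "stratfit"
        pruned_ages = ages.restrict(list(pruned_matrix.taxa))
        strat = {}
        for crit, cons in consensus_trees.items():
            fit = strat_indices(cons, pruned_ages, permutations=config.permutations,
                                seed=config.seed + 41)
            strat[f"mp_{crit}"] = {
                "MIG": fit.mig, "SRL": fit.srl, "RCI": fit.rci, "GER": fit.ger,
                "MSM*": fit.msm, "p": fit.p_values, "bounds": fit.bound_method,
            }
        summary["stratfit"] = strat
        _log(log_path, stage, **{k: v["GER"] for k, v in strat.items()})

        # ------------------------------------------------ ancestral states
        stage = "asr"
        chars = list(config.asr_chars) if config.asr_chars is not None \
            else list(range(pruned_matrix.n_char))
        pmap = parsimony_map(consensus_trees["iw"], pruned_matrix)
        asr = {"parsimony_changes": len([c for c in pmap.changes if not c.ambiguous]),
               "parsimony_ambiguous": len([c for c in pmap.changes if c.ambiguous])}
        key0 = next(iter(mccs))
        smaps = {}
        for j in chars[: min(len(chars), 10)]:  # stochastic maps on a char subset
            fit = select_model(mccs[key0], pruned_matrix, j)
            sm = stochastic_map(mccs[key0], pruned_matrix, j, fit=fit,
                                n_maps=config.n_maps, seed=config.seed + 53 + j)
            smaps[j] = {"model": fit.model, "aic": fit.aic}
        asr["stochastic"] = smaps
        # synapomorphies of every internal clade of the IW consensus
        syn = {}
        for clade in {c.clade for c in pmap.changes}:
            entries = synapomorphies(pmap, clade)
            if entries:
                syn["|".join(sorted(clade))] = entries
        asr["synapomorphies"] = syn
        summary["asr"] = asr
        _log(log_path, stage, n_synapomorphy_clades=len(syn))

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=_jsonable)
        return summary
    except Exception as e:
        _log(log_path, stage, error=str(e))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (frozenset, set, tuple)):
        return sorted(x) if isinstance(x, (frozenset, set)) else list(x)
    return str(x)
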