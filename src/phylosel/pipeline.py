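"""End-to-end simulation conditions: simulate -> fit -> select -> evaluate.

The study's 14 nucleotide conditions (parameter set x tree height x taxa x
sequence length) and the codon condition are declared here as data, with the
two generating parameter sets:

* set A: frequencies 0.35/0.22/0.18/0.25 (A/C/G/T); exchangeabilities
  relative to GT 2.675 (AC), 7.35 (AG), 6.125 (AT), 0.225 (CG), 30.7 (CT);
  kappa 2.0; gamma shape 0.67256; p_inv 0.25.
* set B: frequencies 0.35/0.15/0.25/0.25; exchangeabilities 2/4/1.8/1.4/6;
  kappa 2.0; gamma shape 0.5; p_inv 0.5.

A condition is run per generating model x replicate: simulate an alignment
on the condition's guide tree, build the NJ tree, fit all 56 candidates,
apply the four criteria, then aggregate the evaluation tables.  Results are
cached at dataset granularity so interrupted runs resume.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .criteria import CRITERIA, select_all
from .evaluation import (
    agreement_profile,
    dissimilarity_table,
    model_bias_tables,
    performance_table,
    randomized_block_anova,
)
from .models import (
    ModelParameters,
    ModelSpec,
    generating_models,
    parse_model_name,
)
from .phylo_engine import fit_all_candidates, jc_distance_matrix, neighbor_joining
from .seqsim import Alignment, CodonSimConfig, simulate_alignment, simulate_codon_alignment
from .treesim import PhyloTree, build_nonclock_tree, scale_to_height, simulate_birth_death_tree

__all__ = [
    "ParameterSet",
    "PARAMETER_SETS",
    "params_for_model",
    "SimulationCondition",
    "TABLE1_CONDITIONS",
    "condition",
    "guide_tree",
    "run_condition",
    "run_codon_condition",
]


@dataclass(frozen=True)
class ParameterSet:
    name: str
    base_freqs: tuple[float, float, float, float]
    rates: tuple[float, float, float, float, float, float]  # AC AG AT CG CT GT
    kappa: float
    gamma_shape: float
    p_inv: float


PARAMETER_SETS = {
    "A": ParameterSet("A", (0.35, 0.22, 0.18, 0.25),
                      (2.675, 7.35, 6.125, 0.225, 30.7, 1.0),
                      kappa=2.0, gamma_shape=0.67256, p_inv=0.25),
    "B": ParameterSet("B", (0.35, 0.15, 0.25, 0.25),
                      (2.0, 4.0, 1.8, 1.4, 6.0, 1.0),
                      kappa=2.0, gamma_shape=0.5, p_inv=0.5),
}


def params_for_model(spec: ModelSpec, pset: ParameterSet) -> ModelParameters:
    """Generating parameter values for one model, as appropriate for it.

    JC/F81 use equal exchangeabilities; K80/HKY use the set's kappa; SYM/GTR
    use the full six rates.  Unequal-frequency models take the set's base
    frequencies; +G models the set's gamma shape; +I models the set's p_inv.
    """
    if spec.base in ("JC", "F81"):
        ex = np.ones(6)
    elif spec.base in ("K80", "HKY"):
        ex = np.array([1.0, pset.kappa, 1.0, 1.0, pset.kappa, 1.0])
    else:
        ex = np.array(pset.rates)
    freqs = np.array(pset.base_freqs) if not spec.equal_freqs else np.full(4, 0.25)
    return ModelParameters(
        base_freqs=freqs, exchangeabilities=ex,
        gamma_shape=pset.gamma_shape if spec.has_gamma else None,
        p_inv=pset.p_inv if spec.has_inv else 0.0)


@dataclass(frozen=True)
class SimulationCondition:
    """One row of the study's simulation design."""

    id: str
    parameter_set: str
    tree: str            # "ultrametric" or "nonclock"
    tree_height: float | None
    ntaxa: int
    length: int
    n_replicates: int = 100
    master_seed: int = 2010
    seed_offset: int = 0  # distinguishes independent runs of one process

    def config_dict(self) -> dict:
        return asdict(self)


def _table1() -> dict[str, SimulationCondition]:
    rows = [
        ("I-1", "A", 0.7, 30, 1000, 0),
        ("I-2", "A", 0.5, 30, 1000, 0),
        ("I-3", "A", 0.3, 30, 1000, 0),
        ("I-4", "A", 0.1, 30, 1000, 0),
        ("I-5", "B", 0.7, 30, 1000, 0),
        ("I-6", "B", 0.5, 30, 1000, 0),
        ("I-7", "B", 0.3, 30, 1000, 0),
        ("I-8", "B", 0.1, 30, 1000, 0),
        ("II-1", "A", 0.5, 22, 1000, 0),
        ("II-2", "A", 0.5, 50, 1000, 0),
        # III-1 repeats the II-1 generating process with an independent seed
        # (the original used a second simulation program for the same model)
        ("III-1", "A", 0.5, 22, 1000, 1),
        ("V-1", "A", 0.5, 30, 300, 0),
        ("V-2", "A", 0.5, 30, 2000, 0),
    ]
    out = {}
    for cid, pset, height, ntaxa, length, off in rows:
        out[cid] = SimulationCondition(cid, pset, "ultrametric", height,
                                       ntaxa, length, seed_offset=off)
    out["IV-1"] = SimulationCondition("IV-1", "A", "nonclock", None, 22, 1000)
    return out


TABLE1_CONDITIONS = _table1()


def condition(cid: str, **overrides) -> SimulationCondition:
    """Look up a built-in condition, optionally overriding fields
    (e.g. ``replicates``/``ntaxa``/``length`` for scaled-down runs)."""
    base = TABLE1_CONDITIONS[cid]
    if not overrides:
        return base
    cfg = base.config_dict()
    if "replicates" in overrides:
        overrides["n_replicates"] = overrides.pop("replicates")
    cfg.update(overrides)
    return SimulationCondition(**cfg)


# -- seeding ----------------------------------------------------------------


def _derive_seed(*words: int) -> int:
    """Deterministic per-purpose seed below 2**31 (documented counter scheme)."""
    ss = np.random.SeedSequence(entropy=list(words))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def tree_seed(cond: SimulationCondition) -> int:
    return _derive_seed(cond.master_seed, cond.seed_offset, 1)


def dataset_seed(cond: SimulationCondition, model_index: int, replicate: int) -> int:
    return _derive_seed(cond.master_seed, cond.seed_offset, 2,
                        model_index, replicate)


def guide_tree(cond: SimulationCondition) -> PhyloTree:
    """The condition's guide tree, drawn once per condition."""
    seed = tree_seed(cond)
    if cond.tree == "nonclock":
        return build_nonclock_tree(seed=seed, ntaxa=cond.ntaxa)
    tree = simulate_birth_death_tree(cond.ntaxa, birth=0.1, death=0.1,
                                     sampling=1.0, seed=seed)
    return scale_to_height(tree, cond.tree_height)


# -- running ----------------------------------------------------------------


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _select_one(alignment: Alignment, dataset_id: str, fit_kwargs: dict,
                alpha: float = 0.01) -> dict:
    topology = neighbor_joining(jc_distance_matrix(alignment))
    fits = fit_all_candidates(alignment, topology, **fit_kwargs)
    sel = select_all(fits, alignment.nsites, alpha=alpha, dataset_id=dataset_id)
    return {crit: sel[crit].chosen.name for crit in CRITERIA}


def _dataset_cache(out_dir: Path | None, dataset_id: str):
    if out_dir is None:
        return None
    return out_dir / "datasets" / f"{dataset_id}.json"


def run_condition(cond: SimulationCondition, output_dir: str | Path | None = None,
                  replicates: int | None = None,
                  models: list[ModelSpec] | None = None,
                  fit_kwargs: dict | None = None,
                  save_alignments: bool = False,
                  progress: bool = False) -> dict:
    """Run one simulation condition end to end and aggregate its statistics.

    Returns a bundle with the per-dataset selections and every evaluation
    table.  When ``output_dir`` is given, per-dataset selections are cached
    as JSON (runs resume at dataset granularity) and the summary tables are
    written as TSV; a manifest records seeds and the config hash, and a
    directory holding a run with a different config is refused.
    """
    import warnings as _warnings

    pset = PARAMETER_SETS[cond.parameter_set]
    models = list(models) if models is not None else generating_models()
    n_rep = replicates if replicates is not None else cond.n_replicates
    fit_kwargs = dict(fit_kwargs or {})
    out = Path(output_dir) if output_dir is not None else None

    config = {"condition": cond.config_dict(),
              "replicates": n_rep,
              "models": [m.name for m in models],
              "fit_kwargs": {k: repr(v) for k, v in sorted(fit_kwargs.items())},
              "kind": "nucleotide"}
    chash = _config_hash(config)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "datasets").mkdir(exist_ok=True)
        manifest_path = out / "manifest.json"
        if manifest_path.exists():
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") != chash:
                raise RuntimeError(
                    f"output dir {out} holds a run with a different config "
                    f"({old.get('config_hash')} != {chash}); use a fresh directory")

    tree = guide_tree(cond)
    rows = []
    for mi, spec in enumerate(models):
        params = params_for_model(spec, pset)
        for rep in range(n_rep):
            dataset_id = f"{cond.id}_{spec.name}_{rep:03d}"
            cache = _dataset_cache(out, dataset_id)
            if cache is not None and cache.exists():
                rows.append(json.loads(cache.read_text()))
                continue
            seed = dataset_seed(cond, mi, rep)
            aln = simulate_alignment(tree, spec, params, cond.length, seed=seed)
            if save_alignments and out is not None:
                aln.to_fasta(str(out / "datasets" / f"{dataset_id}.fasta"))
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # saturated-distance caps
                chosen = _select_one(aln, dataset_id, fit_kwargs)
            row = {"dataset_id": dataset_id, "true_model": spec.name,
                   "seed": seed, **chosen}
            if cache is not None:
                cache.write_text(json.dumps(row))
            rows.append(row)
            if progress:
                print(f"[{cond.id}] {dataset_id}: " +
                      " ".join(f"{c}={row[c]}" for c in CRITERIA), flush=True)

    selections = pd.DataFrame(rows)
    bundle = _evaluate_nucleotide(selections, cond.id)
    bundle["selections"] = selections
    bundle["tree_newick"] = tree.to_newick()
    bundle["config"] = config
    if out is not None:
        _write_bundle(out, bundle, config, chash, tree)
    return bundle


def _evaluate_nucleotide(selections: pd.DataFrame, cid: str) -> dict:
    perf = performance_table(selections, cid)
    acc = perf.pivot(index="true_model", columns="criterion",
                     values="accuracy_pct")[list(CRITERIA)]
    prec = perf.pivot(index="true_model", columns="criterion",
                      values="precision")[list(CRITERIA)]
    profile = agreement_profile(
        selections[list(CRITERIA)].itertuples(index=False))
    bundle = {
        "performance": perf,
        "accuracy_by_model": acc,
        "precision_by_model": prec,
        "dissimilarity": dissimilarity_table(selections, cid),
        "dissimilarity_overall": dissimilarity_table(selections, cid,
                                                     by_model=False),
        "agreement_profile": profile,
        "bias_category": model_bias_tables(selections, "category"),
        "bias_nparams": model_bias_tables(selections, "nparams"),
    }
    if acc.shape[0] > 1:
        bundle["anova_accuracy"] = randomized_block_anova(acc)
        bundle["anova_precision"] = randomized_block_anova(prec)
    return bundle


def _write_bundle(out: Path, bundle: dict, config: dict, chash: str,
                  tree: PhyloTree) -> None:
    sel = bundle["selections"]
    sel.to_csv(out / "selections.tsv", sep="\t", index=False)
    if "performance" in bundle:
        bundle["performance"].to_csv(out / "performance.tsv", sep="\t",
                                     index=False)
    for key in ("dissimilarity", "dissimilarity_overall"):
        if key in bundle:
            bundle[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
    if "agreement_profile" in bundle:
        pd.DataFrame({"n_models": [1, 2, 3, 4],
                      "percent": bundle["agreement_profile"]}).to_csv(
            out / "agreement_profile.tsv", sep="\t", index=False)
    (out / "guide_tree.nwk").write_text(tree.to_newick() + "\n")
    (out / "manifest.json").write_text(json.dumps(
        {"config": config, "config_hash": chash,
         "n_datasets": int(len(sel))}, indent=2))


def run_codon_condition(omega: float = 0.016, mutation_rate: float = 0.001,
                        length_nt: int = 999, ntaxa: int = 30,
                        tree_height: float = 0.5,
                        replicates: int = 100,
                        models: list[ModelSpec] | None = None,
                        master_seed: int = 2010,
                        output_dir: str | Path | None = None,
                        fit_kwargs: dict | None = None,
                        progress: bool = False) -> dict:
    """Codon-model condition (generating model outside the candidate set).

    Data are simulated under GY94 crossed with each generating GTR-family
    model's nucleotide settings (parameter set A), then pushed through the
    same fit/select path.  Because the true model is not a candidate,
    evaluation is restricted to the agreement profile and pairwise
    dissimilarity — no accuracy or precision tables are produced.
    """
    import warnings as _warnings

    pset = PARAMETER_SETS["A"]
    models = list(models) if models is not None else generating_models()
    fit_kwargs = dict(fit_kwargs or {})
    out = Path(output_dir) if output_dir is not None else None
    cond = SimulationCondition("VI-1", "A", "ultrametric", tree_height,
                               ntaxa, length_nt, replicates, master_seed)
    config = {"condition": cond.config_dict(), "omega": omega,
              "mutation_rate": mutation_rate,
              "models": [m.name for m in models],
              "fit_kwargs": {k: repr(v) for k, v in sorted(fit_kwargs.items())},
              "kind": "codon"}
    chash = _config_hash(config)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "datasets").mkdir(exist_ok=True)
        manifest_path = out / "manifest.json"
        if manifest_path.exists():
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") != chash:
                raise RuntimeError(
                    f"output dir {out} holds a run with a different config; "
                    "use a fresh directory")

    tree = guide_tree(cond)
    rows = []
    for mi, spec in enumerate(models):
        nuc_params = params_for_model(spec, pset)
        cfg = CodonSimConfig(omega=omega, nucleotide_params=nuc_params,
                             length_nt=length_nt, mutation_rate=mutation_rate,
                             spec=spec)
        for rep in range(replicates):
            dataset_id = f"VI_{spec.name}_{rep:03d}"
            cache = _dataset_cache(out, dataset_id)
            if cache is not None and cache.exists():
                rows.append(json.loads(cache.read_text()))
                continue
            seed = dataset_seed(cond, mi, rep)
            aln = simulate_codon_alignment(tree, cfg, seed=seed)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                chosen = _select_one(aln, dataset_id, fit_kwargs)
            row = {"dataset_id": dataset_id, "true_model": spec.name,
                   "seed": seed, **chosen}
            if cache is not None:
                cache.write_text(json.dumps(row))
            rows.append(row)
            if progress:
                print(f"[VI] {dataset_id}: " +
                      " ".join(f"{c}={row[c]}" for c in CRITERIA), flush=True)

    selections = pd.DataFrame(rows)
    profile = agreement_profile(
        selections[list(CRITERIA)].itertuples(index=False))
    bundle = {
        "selections": selections,
        "agreement_profile": profile,
        "dissimilarity": dissimilarity_table(selections, "VI"),
        "dissimilarity_overall": dissimilarity_table(selections, "VI",
                                                     by_model=False),
        "tree_newick": tree.to_newick(),
        "config": config,
    }
    if out is not None:
        _write_bundle(out, bundle, config, chash, tree)
    return bundle
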