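"""End-to-end study orchestration.

``run_study`` reproduces the simulation study: simulate drift replicates,
subsample individuals, fit the K = n_pops admixture model per replicate and
generation, align all fits to a final-generation reference, average Q
within populations, build the two regression responses (distinct-cluster
and hatchery-cluster assignment), and rank the nested beta regressions.
``fst_trajectory`` runs the dense every-generation frequency-level
simulation used to locate the generation at which global F_ST first
reaches an empirical reference value.  ``run_empirical`` applies the
single-dataset analysis chain (diversity, Ne, F_ST, NJ, IBD, ancestry) to
user-supplied genotypes.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, betareg, ldne, popstats
from .genotypes import DistanceMatrix, GenotypeMatrix, subsample_individuals
from .simulate import (
    HATCHERY_LABEL,
    SimulationConfig,
    initialize,
    run_replicate,
    step_generation,
)

log = logging.getLogger("popdrift")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the full simulation -> ancestry -> regression study."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    subsample_n: int = 25
    k_fit: int | None = None  # default: number of simulated populations
    k_range: tuple[int, ...] = tuple(range(1, 16))
    cv_folds: int = 5
    cv_generations: tuple[int, ...] = ()  # checkpoints at which to scan K
    n_restarts: int = 1
    fst_threshold: float = 0.118
    hatchery_label: str = HATCHERY_LABEL
    em_tol: float = 1e-6
    em_max_iter: int = 1000
    #: decimal places of the per-run Q matrices consumed downstream,
    #: emulating the fixed-precision Q files the field's clustering
    #: programs emit; tiny ancestry fractions become exact zeros, which in
    #: turn engage the boundary transform of the beta regressions
    q_decimals: int | None = 6
    #: include the hatchery analog's own assignment rows in both
    #: regressions (its distinct cluster is the hatchery cluster); the
    #: default models the wild analogs only
    include_hatchery_rows: bool = False

    def stage_seed(self, replicate: int, stage: str, k: int = 0) -> int:
        """Reproducible per-(replicate, stage, K) seed from the master seed."""
        h = zlib.crc32(f"{stage}:{k}".encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(entropy=self.sim.seed, spawn_key=(replicate, h))
        return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class StudyResult:
    """Bundle of study outputs (DataFrames keyed like the report files)."""

    mean_q: dict[int, pd.DataFrame]
    assignments: pd.DataFrame  # population, generation, distinct & hatchery
    distinct_table: pd.DataFrame
    hatchery_table: pd.DataFrame
    trajectory: pd.DataFrame
    fst_first_crossing: float
    cv_errors: pd.DataFrame | None = None
    best_k_by_generation: dict[int, int] | None = None
    timings: dict[str, float] = field(default_factory=dict)


def fst_trajectory(
    sim: SimulationConfig,
    max_generation: int,
    n_replicates: int | None = None,
    materialize: bool = True,
) -> pd.DataFrame:
    """Mean global theta per generation on a dense (every-generation) grid.

    Frequency-level simulation only; when ``materialize`` is set,
    Hardy-Weinberg genotypes for the full population are sampled each
    generation before computing the Weir-Cockerham estimator, otherwise the
    HW expectations are used directly.
    """
    reps = n_replicates if n_replicates is not None else sim.n_replicates
    rows = {g: [] for g in range(max_generation + 1)}
    for r in range(reps):
        rng = np.random.default_rng(sim.replicate_seed(r))
        freqs = initialize(sim, rng)
        for gen in range(max_generation + 1):
            if gen > 0:
                freqs = step_generation(freqs, sim.pop_sizes, rng)
            theta = popstats.global_theta_from_freqs(
                freqs, sim.pop_sizes, rng=rng if materialize else None
            )
            rows[gen].append(theta)
    out = []
    for gen in sorted(rows):
        arr = np.asarray(rows[gen])
        out.append(
            {"generation": gen, "global_fst_mean": float(arr.mean()),
             "global_fst_sd": float(arr.std(ddof=1)) if len(arr) > 1 else np.nan,
             "n_replicates": len(arr)}
        )
    return pd.DataFrame(out)


def _ne_lookup(cfg: StudyConfig) -> dict[str, int]:
    return dict(zip(cfg.sim.pop_labels, cfg.sim.pop_sizes))


def run_study(cfg: StudyConfig, outdir: str | Path | None = None) -> StudyResult:
    """Run the full drift-confounding study.

    Per replicate and checkpoint generation: subsample individuals, fit the
    K = n_pops admixture model; align every fit to a reference fit from the
    final generation; average Q within populations and across replicates
    per generation; map populations to their eventual distinct clusters on
    the final generation; regress both assignment responses on Ne,
    generations and their interaction.  All randomness derives from the
    master seed.
    """
    t0 = time.time()
    sim = cfg.sim
    k_fit = cfg.k_fit if cfg.k_fit is not None else sim.n_pops
    timings: dict[str, float] = {}

    # -- simulate and fit ---------------------------------------------------
    fits_by_gen: dict[int, list[ancestry.AncestryFit]] = {g: [] for g in sim.checkpoints}
    genos_by_gen_rep: dict[tuple[int, int], GenotypeMatrix] = {}
    pop_labels_ref: np.ndarray | None = None
    for rep in range(sim.n_replicates):
        for rec in run_replicate(sim, rep):
            sub = subsample_individuals(
                rec.genotypes,
                min(cfg.subsample_n, min(sim.pop_sizes)),
                cfg.stage_seed(rep, "subsample", rec.generation),
            )
            genos_by_gen_rep[(rec.generation, rep)] = sub
            if pop_labels_ref is None:
                pop_labels_ref = sub.pop_labels
            fit = ancestry.fit_admixture(
                sub,
                k_fit,
                seed=cfg.stage_seed(rep, "admixture", rec.generation),
                tol=cfg.em_tol,
                max_iter=cfg.em_max_iter,
                n_restarts=cfg.n_restarts,
            )
            fits_by_gen[rec.generation].append(fit)
        log.info("replicate %d fitted (%.1fs elapsed)", rep, time.time() - t0)
    timings["simulate_and_fit"] = time.time() - t0

    # -- align everything to a final-generation reference -------------------
    t1 = time.time()
    final_gen = max(sim.checkpoints)
    reference = fits_by_gen[final_gen][0]
    mean_q: dict[int, pd.DataFrame] = {}
    for gen in sim.checkpoints:
        aligned, _ = ancestry.align_replicates(fits_by_gen[gen], reference=reference)
        if cfg.q_decimals is not None:
            for f in aligned:
                f.Q = np.round(f.Q, cfg.q_decimals)
        mean_q[gen] = ancestry.average_q(aligned, pop_labels_ref)
    timings["align_average"] = time.time() - t1

    # -- regression responses ------------------------------------------------
    t2 = time.time()
    mapping = ancestry.map_populations_to_clusters(mean_q[final_gen])
    ne_of = _ne_lookup(cfg)
    hatchery_cluster = mapping[cfg.hatchery_label]
    rows = []
    for gen in sim.checkpoints:
        mq = mean_q[gen]
        for pop, k in mapping.items():
            if pop == cfg.hatchery_label and not cfg.include_hatchery_rows:
                continue
            i = list(mq.index).index(pop)
            rows.append(
                {"population": pop, "ne": ne_of[pop], "gen": gen,
                 "distinct": float(mq.iloc[i, k]),
                 "hatchery": float(mq.iloc[i, hatchery_cluster])}
            )
    assignments = pd.DataFrame(rows)
    distinct_table = betareg.model_table(assignments, response="distinct")
    hatchery_table = betareg.model_table(assignments, response="hatchery")
    timings["regressions"] = time.time() - t2

    # -- trajectories and first crossing ------------------------------------
    t3 = time.time()
    dense = fst_trajectory(sim, max_generation=final_gen)
    crossing = popstats.first_crossing(dense, cfg.fst_threshold)
    timings["fst_trajectory"] = time.time() - t3

    # -- optional cross-validated K scan ------------------------------------
    cv_df = None
    best_k = None
    if cfg.cv_generations:
        t4 = time.time()
        cv_rows = []
        best_k = {}
        for gen in cfg.cv_generations:
            per_rep_best = []
            for rep in range(sim.n_replicates):
                sub = genos_by_gen_rep[(gen, rep)]
                res = ancestry.cv_scan(
                    sub, list(cfg.k_range), folds=cfg.cv_folds,
                    seed=cfg.stage_seed(rep, "cv", gen),
                    tol=cfg.em_tol, max_iter=cfg.em_max_iter,
                )
                per_rep_best.append(res.best_K)
                for K, e in res.errors.items():
                    cv_rows.append(
                        {"generation": gen, "replicate": rep, "K": K, "cv_error": e}
                    )
            vals, counts = np.unique(per_rep_best, return_counts=True)
            best_k[gen] = int(vals[np.argmax(counts)])  # replicate mode
        cv_df = pd.DataFrame(cv_rows)
        timings["cv_scan"] = time.time() - t4

    result = StudyResult(
        mean_q=mean_q,
        assignments=assignments,
        distinct_table=distinct_table,
        hatchery_table=hatchery_table,
        trajectory=dense,
        fst_first_crossing=crossing,
        cv_errors=cv_df,
        best_k_by_generation=best_k,
        timings=timings,
    )
    if outdir is not None:
        _write_study(result, cfg, Path(outdir))
    return result


def _write_study(res: StudyResult, cfg: StudyConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for gen, mq in res.mean_q.items():
        mq.to_csv(outdir / f"mean_q_gen{gen:03d}.csv")
    res.assignments.to_csv(outdir / "assignments.csv", index=False)
    res.distinct_table.to_csv(outdir / "model_table_distinct.csv", index=False)
    res.hatchery_table.to_csv(outdir / "model_table_hatchery.csv", index=False)
    res.trajectory.to_csv(outdir / "fst_trajectory.csv", index=False)
    ne_grid = np.arange(25, 536, 10)
    gen_grid = np.arange(0, 51)
    for name, table in (("distinct", res.distinct_table),
                        ("hatchery", res.hatchery_table)):
        best = table.attrs["fits"][table.iloc[0].model]
        betareg.predict_surface(best, ne_grid, gen_grid).to_csv(
            outdir / f"prediction_surface_{name}.csv", index=False
        )
    if res.cv_errors is not None:
        res.cv_errors.to_csv(outdir / "cv_errors.csv", index=False)
    manifest = {
        "schema_version": 1,
        "seed": cfg.sim.seed,
        "n_replicates": cfg.sim.n_replicates,
        "checkpoints": list(cfg.sim.checkpoints),
        "pop_sizes": dict(zip(cfg.sim.pop_labels, cfg.sim.pop_sizes)),
        "fst_threshold": cfg.fst_threshold,
        "fst_first_crossing": res.fst_first_crossing,
        "best_k_by_generation": res.best_k_by_generation,
        "timings_s": {k: round(v, 2) for k, v in res.timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# empirical-data path


@dataclass
class EmpiricalResult:
    diversity: pd.DataFrame
    ne: pd.DataFrame
    fst: popstats.FstResult | None
    nj_newick: str | None
    mantel: popstats.MantelResult | None
    cv: ancestry.CVResult | None
    warnings: list[str]


def run_empirical(
    g: GenotypeMatrix,
    distances: DistanceMatrix | None = None,
    k_range: tuple[int, ...] = tuple(range(1, 21)),
    cv_folds: int = 5,
    nj_bootstrap: int = 1000,
    maf: float = 0.02,
    seed: int = 0,
    run_cv: bool = True,
) -> EmpiricalResult:
    """Single-dataset analysis chain on a (filtered) genotype matrix.

    Stages that need multiple populations (F_ST, NJ, IBD) are skipped with
    a warning on single-population input; IBD is skipped without a distance
    matrix.
    """
    warnings: list[str] = []
    div = popstats.diversity(g)
    ne_rows = []
    by_pop = g.by_population()
    for pop, idx in by_pop.items():
        try:
            est = ldne.estimate_ne(g.take_individuals(idx), maf=maf)
            ne_rows.append(
                {"population": pop, "ne_point": est.ne_point, "ci_low": est.ci_low,
                 "ci_high": est.ci_high, "n_pairs": est.n_pairs, "maf": est.maf_threshold}
            )
        except ValueError as e:
            warnings.append(f"Ne estimation failed for {pop}: {e}")
    ne_df = pd.DataFrame(ne_rows)

    fst = nj_newick = mantel = None
    if len(by_pop) >= 2:
        fst = popstats.wc_fst(g)
        if len(by_pop) >= 3:
            da = popstats.nei_da(g)
            nj_newick = popstats.nj_tree(da, bootstrap=nj_bootstrap, g=g, seed=seed)
        else:
            warnings.append("fewer than 3 populations: NJ tree skipped")
        if distances is not None and fst is not None:
            try:
                mantel = popstats.mantel_ibd(fst.pairwise, distances, seed=seed)
            except ValueError as e:
                warnings.append(f"IBD Mantel test skipped: {e}")
        elif distances is None:
            warnings.append("no distance matrix supplied: IBD stage skipped")
    else:
        warnings.append("single population: FST/NJ/IBD stages skipped")

    cv = None
    if run_cv:
        cv = ancestry.cv_scan(g, list(k_range), folds=cv_folds, seed=seed)
    return EmpiricalResult(div, ne_df, fst, nj_newick, mantel, cv, warnings)
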