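"""Forward Wright-Fisher simulation of pure drift from a common source.

Thirteen isolated populations are founded from one gene pool (every locus at
the same initial frequency, realized per population with binomial sampling
error) and drift independently: no mutation, no migration, no selection.
Population sizes are the empirical LD-based effective-size point estimates
for twelve wild brook trout populations plus the St. Croix Falls hatchery
strain; drift is therefore as fast as the field data say it is.

Two simulation schemes are provided:

* frequency-level (default): per generation and locus, the next allele count
  is Binomial(2N, p).  Loci are exchangeable and develop no genotypic
  associations; diploid genotypes are materialized at checkpoints by
  Hardy-Weinberg sampling.  This matches a model of independent, freely
  recombining loci and is what the study pipeline uses.
* individual-based (:func:`simulate_individuals`): offspring draw two
  parents per generation and one allele per locus from each parent.  The
  shared, finite parent pool couples loci within individuals, producing the
  drift-generated linkage disequilibrium that single-sample LD methods for
  effective size rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .genotypes import GenotypeMatrix

#: Empirical LD-based Ne point estimates used as simulated census sizes:
#: twelve wild population analogs plus the hatchery strain analog (last).
#: The unnamed-tributary population is excluded (its Ne estimate is biased
#: low by recent admixture).
DEFAULT_POP_SIZES: dict[str, int] = {
    "Ash": 26,
    "Byrds": 31,
    "Fancy": 65,
    "Gault": 114,
    "Harker": 128,
    "Horse": 48,
    "Lawrence": 535,
    "Lowery": 79,
    "Marshall": 54,
    "Melancthon": 45,
    "SFHay": 294,
    "WBMill": 89,
    "SCF": 137,
}

#: Label of the hatchery-strain analog within :data:`DEFAULT_POP_SIZES`.
HATCHERY_LABEL = "SCF"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the drift simulation.

    Defaults reproduce the study design: 13 populations sized by the
    empirical Ne point estimates, 500 biallelic loci founded at frequency
    0.5, genotypes emitted after 0, 5, 10, 20, 30, 40, and 50 generations,
    100 replicates.
    """

    pop_sizes: tuple[int, ...] = tuple(DEFAULT_POP_SIZES.values())
    pop_labels: tuple[str, ...] = tuple(DEFAULT_POP_SIZES)
    n_loci: int = 500
    init_freq: float = 0.5
    checkpoints: tuple[int, ...] = (0, 5, 10, 20, 30, 40, 50)
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != len(self.pop_labels):
            raise ValueError("pop_sizes and pop_labels lengths differ")
        if any(n < 2 for n in self.pop_sizes):
            raise ValueError("each population size must be >= 2")
        if not 0.0 < self.init_freq < 1.0:
            raise ValueError("init_freq must be in (0, 1)")
        cps = self.checkpoints
        if list(cps) != sorted(set(cps)) or any(c < 0 for c in cps):
            raise ValueError("checkpoints must be sorted, unique, non-negative")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)

    def replicate_seed(self, replicate: int) -> int:
        """Derive a per-replicate seed from the master seed."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(replicate,))
        return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class TrajectoryRecord:
    """State emitted at one checkpoint of one replicate."""

    replicate: int
    generation: int
    freqs: np.ndarray  # (n_pops, n_loci) allele frequencies
    genotypes: GenotypeMatrix | None = None


def initialize(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Found each population independently from the common gene pool.

    Each of the 2N gene copies at each locus is an independent Bernoulli
    draw with success probability ``init_freq``, so realized founding
    frequencies vary around the target by binomial sampling error.
    Returns the (n_pops, n_loci) founding frequency matrix.
    """
    freqs = np.empty((cfg.n_pops, cfg.n_loci))
    for i, N in enumerate(cfg.pop_sizes):
        counts = rng.binomial(2 * N, cfg.init_freq, size=cfg.n_loci)
        freqs[i] = counts / (2 * N)
    return freqs


def step_generation(
    freqs: np.ndarray, pop_sizes: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """One Wright-Fisher generation: Binomial(2N, p) per population and locus.

    Fixed loci (p in {0, 1}) stay fixed forever — there is no mutation.
    """
    out = np.empty_like(freqs)
    for i, N in enumerate(pop_sizes):
        out[i] = rng.binomial(2 * N, freqs[i]) / (2 * N)
    return out


def sample_genotypes(
    freqs: np.ndarray,
    pop_sizes: tuple[int, ...],
    pop_labels: tuple[str, ...],
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Materialize Hardy-Weinberg diploid genotypes from population frequencies.

    Each individual draws two independent gene copies per locus.
    """
    blocks = []
    labels = []
    for i, N in enumerate(pop_sizes):
        p = freqs[i]
        d = rng.binomial(1, p, size=(N, len(p))) + rng.binomial(1, p, size=(N, len(p)))
        blocks.append(d.astype(np.int8))
        labels.extend([pop_labels[i]] * N)
    L = freqs.shape[1]
    return GenotypeMatrix(
        dosages=np.vstack(blocks),
        pop_labels=np.array(labels, dtype=object),
        locus_ids=np.array([f"L{j:04d}" for j in range(L)], dtype=object),
    )


def run_replicate(
    cfg: SimulationConfig, replicate: int, emit_genotypes: bool = True
) -> Iterator[TrajectoryRecord]:
    """Run one replicate, yielding a record at every checkpoint.

    The replicate's generator is derived from the master seed by replicate
    index, so any replicate is reproducible in isolation.
    """
    rng = np.random.default_rng(cfg.replicate_seed(replicate))
    freqs = initialize(cfg, rng)
    gen = 0
    for cp in cfg.checkpoints:
        while gen < cp:
            freqs = step_generation(freqs, cfg.pop_sizes, rng)
            gen += 1
        geno = None
        if emit_genotypes:
            geno = sample_genotypes(freqs, cfg.pop_sizes, cfg.pop_labels, rng)
        yield TrajectoryRecord(replicate, gen, freqs.copy(), geno)


def run_simulation(
    cfg: SimulationConfig, emit_genotypes: bool = True
) -> Iterator[TrajectoryRecord]:
    """Run all replicates (lazily), yielding checkpoint records in order."""
    for r in range(cfg.n_replicates):
        yield from run_replicate(cfg, r, emit_genotypes=emit_genotypes)


def simulate_individuals(
    N: int,
    n_loci: int,
    generations: int,
    init_freq: float = 0.5,
    seed: int = 0,
    label: str = "pop1",
) -> GenotypeMatrix:
    """Individual-based monoecious WF simulation of one population.

    Each offspring draws two parents uniformly (selfing allowed, the
    idealized WF model) and inherits one allele per locus from each parent
    with free recombination.  Unlike the frequency-level scheme, the finite
    shared parent pool generates linkage disequilibrium among unlinked loci
    at the level expected for an ideal population of size N — the signal
    used by LD-based Ne estimation.
    """
    rng = np.random.default_rng(seed)
    # haplotypes: (N, 2, n_loci) biallelic 0/1
    hap = rng.binomial(1, init_freq, size=(N, 2, n_loci)).astype(np.int8)
    for _ in range(generations):
        parents = rng.integers(0, N, size=(N, 2))
        which = rng.integers(0, 2, size=(N, 2, n_loci))
        new = np.empty_like(hap)
        new[:, 0, :] = np.take_along_axis(hap[parents[:, 0]], which[:, :1, :], axis=1)[:, 0, :]
        new[:, 1, :] = np.take_along_axis(hap[parents[:, 1]], which[:, 1:, :], axis=1)[:, 0, :]
        hap = new
    dosages = hap.sum(axis=1).astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        pop_labels=np.array([label] * N, dtype=object),
        locus_ids=np.array([f"L{j:04d}" for j in range(n_loci)], dtype=object),
    )


def expected_heterozygosity_decay(h0: float, N: int, t: int) -> float:
    """Closed-form drift expectation H_t = H_0 (1 - 1/(2N))^t."""
    return h0 * (1.0 - 1.0 / (2 * N)) ** t
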