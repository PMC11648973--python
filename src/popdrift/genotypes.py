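"""Genotype data model, genepop I/O, and sequential genotype filters.

The central container is :class:`GenotypeMatrix`: an individuals x loci
matrix of diploid allele dosages (0/1/2, with a missing sentinel) plus
per-individual population labels and per-locus metadata (linkage group,
contig).  Dosage counts the lexicographically larger genepop allele code,
so orientation is deterministic and internal to the file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1
"""Sentinel for a missing diploid genotype; never a valid dosage."""


class GenepopParseError(ValueError):
    """Raised when a genepop file violates the dialect this reader accepts."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for one or more populations.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_loci)`` integer array with entries in
        ``{0, 1, 2, MISSING}``; dosage is the count of the lexicographically
        larger allele code.
    pop_labels
        Population identifier per individual (length ``n_individuals``).
    locus_ids
        Unique locus identifiers (length ``n_loci``).
    ind_ids
        Optional individual identifiers; autogenerated when omitted.
    linkage_group
        Optional per-locus linkage-group labels (used by LD-based Ne to
        exclude within-group locus pairs).
    contig_id
        Optional per-locus contig labels (used by the one-SNP-per-contig
        filter).
    """

    dosages: np.ndarray
    pop_labels: np.ndarray
    locus_ids: np.ndarray
    ind_ids: np.ndarray | None = None
    linkage_group: np.ndarray | None = None
    contig_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        n, L = self.dosages.shape
        if len(self.pop_labels) != n:
            raise ValueError("pop_labels length does not match individuals")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match loci")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus_ids must be unique")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or MISSING")
        if self.ind_ids is None:
            self.ind_ids = np.array(
                [f"{p}_{i}" for i, p in enumerate(self.pop_labels)], dtype=object
            )
        else:
            self.ind_ids = np.asarray(self.ind_ids, dtype=object)
            if len(self.ind_ids) != n:
                raise ValueError("ind_ids length does not match individuals")
        for name in ("linkage_group", "contig_id"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=object)
                if len(v) != L:
                    raise ValueError(f"{name} length does not match loci")
                setattr(self, name, v)

    # -- basic properties -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        return list(pd.unique(self.pop_labels))

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_freq(self) -> np.ndarray:
        """Per-locus frequency of the counted allele among non-missing genes."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        with np.errstate(invalid="ignore"):
            p = d.mean(axis=0).filled(np.nan) / 2.0
        return p

    @property
    def maf(self) -> np.ndarray:
        """Per-locus minor allele frequency in [0, 0.5]; NaN if all missing."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def minor_allele_count(self) -> np.ndarray:
        """Per-locus count of the rarer allele among non-missing gene copies."""
        d = self.dosages
        obs = d != MISSING
        tot = 2 * obs.sum(axis=0)
        cnt = np.where(obs, d, 0).sum(axis=0)
        return np.minimum(cnt, tot - cnt)

    # -- selection helpers ------------------------------------------------

    def take_individuals(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[idx],
            pop_labels=self.pop_labels[idx],
            ind_ids=self.ind_ids[idx],
        )

    def take_loci(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            locus_ids=self.locus_ids[idx],
            linkage_group=None if self.linkage_group is None else self.linkage_group[idx],
            contig_id=None if self.contig_id is None else self.contig_id[idx],
        )

    def by_population(self) -> dict:
        """Map population label -> row indices, in order of first appearance."""
        out: dict = {}
        for i, p in enumerate(self.pop_labels):
            out.setdefault(p, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.pop_labels, other.pop_labels)
            and np.array_equal(self.locus_ids, other.locus_ids)
        )


@dataclass(frozen=True)
class FilterConfig:
    """Sequential genotype filters: minor-allele count, per-population locus
    call rate, individual call rate, then (optionally) one SNP per contig
    keeping the highest-MAF SNP."""

    min_mac: int = 3
    min_locus_call_rate_per_pop: float = 0.7
    min_ind_call_rate: float = 0.5
    one_snp_per_contig: bool = False

    def __post_init__(self) -> None:
        if self.min_mac < 0:
            raise ValueError("min_mac must be >= 0")
        for r in (self.min_locus_call_rate_per_pop, self.min_ind_call_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("call rates must be in [0, 1]")


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("values must be square and match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major pair order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# genepop I/O


def _parse_genepop_genotype(tok: str, lineno: int) -> tuple[str, str]:
    tok = tok.strip()
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"line {lineno}: genotype token '{tok}' is not 4 or 6 digits"
        )
    if not tok.isdigit():
        raise GenepopParseError(f"line {lineno}: non-numeric genotype token '{tok}'")
    return tok[:w], tok[w:]


def read_genepop(path) -> GenotypeMatrix:
    """Read a genepop file into a :class:`GenotypeMatrix`.

    Accepts 2- or 3-digit allele codes; allele code ``00``/``000`` means
    missing.  Dosage counts the lexicographically larger of the two allele
    codes observed at each locus.  A locus with more than two observed
    alleles is an error.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty genepop file")
    # locus names: one per line until first POP, possibly comma-separated
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                locus_ids.append(name)
        i += 1
    if not locus_ids:
        raise GenepopParseError("no locus names before first POP line")
    L = len(locus_ids)
    alleles: list[tuple[str, str]] = [("", "") for _ in range(L)]  # raw genotype pairs
    raw: list[list[tuple[str, str]]] = []
    pops: list[str] = []
    ind_ids: list[str] = []
    pop_idx = 0
    while i < len(lines):
        line = lines[i]
        if line.strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        if not line.strip():
            i += 1
            continue
        if pop_idx == 0:
            raise GenepopParseError(f"line {i + 1}: genotype data before any POP line")
        if "," not in line:
            raise GenepopParseError(f"line {i + 1}: expected 'id , genotypes'")
        ind_id, _, geno_part = line.partition(",")
        toks = geno_part.split()
        if len(toks) != L:
            raise GenepopParseError(
                f"line {i + 1}: expected {L} genotypes, found {len(toks)}"
            )
        raw.append([_parse_genepop_genotype(t, i + 1) for t in toks])
        ind_ids.append(ind_id.strip())
        pops.append(f"pop{pop_idx}")
        i += 1
    n = len(raw)
    dosages = np.full((n, L), MISSING, dtype=np.int8)
    for j, locus in enumerate(locus_ids):
        seen: set[str] = set()
        for row in raw:
            for a in row[j]:
                if int(a) != 0:
                    seen.add(a)
        if len(seen) > 2:
            raise GenepopParseError(
                f"locus '{locus}' has more than two alleles: {sorted(seen)}"
            )
        counted = max(seen) if seen else None
        for r, row in enumerate(raw):
            a1, a2 = row[j]
            if int(a1) == 0 or int(a2) == 0:
                continue
            dosages[r, j] = (a1 == counted) + (a2 == counted)
    return GenotypeMatrix(
        dosages=dosages,
        pop_labels=np.array(pops, dtype=object),
        locus_ids=np.array(locus_ids, dtype=object),
        ind_ids=np.array(ind_ids, dtype=object),
    )


def write_genepop(g: GenotypeMatrix, path, title: str = "popdrift export") -> None:
    """Write a genepop file with 2-digit allele codes (01/02, missing 0000).

    Output is deterministic for a fixed input.  Population blocks follow the
    order of first appearance of ``pop_labels``.
    """
    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    out = [title]
    out.extend(str(l) for l in g.locus_ids)
    for pop, idx in g.by_population().items():
        out.append("POP")
        for i in idx:
            genos = " ".join(code[int(d)] for d in g.dosages[i])
            out.append(f"{g.ind_ids[i]} , {genos}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# delimited dosage matrix I/O (CSV: id, pop, then one column per locus)


def write_dosage_csv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages.astype(float), columns=list(g.locus_ids))
    df[df == MISSING] = np.nan
    df.insert(0, "pop", g.pop_labels)
    df.insert(0, "id", g.ind_ids)
    df.to_csv(path, index=False)


def read_dosage_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    loci = [c for c in df.columns if c not in ("id", "pop")]
    d = df[loci].to_numpy(dtype=float)
    d = np.where(np.isnan(d), MISSING, d).astype(np.int8)
    return GenotypeMatrix(
        dosages=d,
        pop_labels=df["pop"].to_numpy(dtype=object),
        locus_ids=np.array(loci, dtype=object),
        ind_ids=df["id"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# filters


@dataclass
class FilterReport:
    """Counts removed at each sequential filter step."""

    loci_removed_mac: int = 0
    loci_removed_call_rate: int = 0
    individuals_removed_call_rate: int = 0
    loci_removed_one_per_contig: int = 0
    steps: list = field(default_factory=list)


def filter_genotypes(
    g: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the sequential genotype filters.

    Order is fixed: (1) drop loci with minor allele count below ``min_mac``;
    (2) drop loci genotyped in fewer than ``min_locus_call_rate_per_pop`` of
    individuals in any population; (3) drop individuals genotyped at fewer
    than ``min_ind_call_rate`` of the remaining loci; (4) optionally keep one
    SNP per contig, preferring the highest minor allele frequency.

    Raises
    ------
    ValueError
        If every locus is removed.
    """
    rep = FilterReport()

    mac = g.minor_allele_count()
    keep = mac >= cfg.min_mac
    rep.loci_removed_mac = int((~keep).sum())
    rep.steps.append(("min_mac", rep.loci_removed_mac))
    g = g.take_loci(np.nonzero(keep)[0])

    obs = g.dosages != MISSING
    keep_locus = np.ones(g.n_loci, dtype=bool)
    for pop, idx in g.by_population().items():
        rate = obs[idx].mean(axis=0)
        keep_locus &= rate >= cfg.min_locus_call_rate_per_pop
    rep.loci_removed_call_rate = int((~keep_locus).sum())
    rep.steps.append(("locus_call_rate", rep.loci_removed_call_rate))
    g = g.take_loci(np.nonzero(keep_locus)[0])
    if g.n_loci == 0:
        raise ValueError("all loci removed by filters")

    obs = g.dosages != MISSING
    ind_rate = obs.mean(axis=1)
    keep_ind = ind_rate >= cfg.min_ind_call_rate
    rep.individuals_removed_call_rate = int((~keep_ind).sum())
    rep.steps.append(("ind_call_rate", rep.individuals_removed_call_rate))
    g = g.take_individuals(np.nonzero(keep_ind)[0])

    if cfg.one_snp_per_contig and g.contig_id is not None:
        maf = g.maf
        best: dict = {}
        for j, c in enumerate(g.contig_id):
            if c not in best or maf[j] > maf[best[c]]:
                best[c] = j
        keep_j = np.zeros(g.n_loci, dtype=bool)
        keep_j[list(best.values())] = True
        rep.loci_removed_one_per_contig = int((~keep_j).sum())
        rep.steps.append(("one_snp_per_contig", rep.loci_removed_one_per_contig))
        g = g.take_loci(np.nonzero(keep_j)[0])

    if g.n_loci == 0:
        raise ValueError("all loci removed by filters")
    return g, rep


def subsample_individuals(g: GenotypeMatrix, n_per_pop: int, seed: int) -> GenotypeMatrix:
    """Draw ``n_per_pop`` individuals per population, reproducibly.

    Row order within a population follows the original matrix; populations
    keep their order of first appearance.
    """
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for pop, idx in g.by_population().items():
        if len(idx) < n_per_pop:
            raise ValueError(
                f"population '{pop}' has {len(idx)} individuals, need {n_per_pop}"
            )
        sel = rng.choice(idx, size=n_per_pop, replace=False)
        chosen.append(np.sort(sel))
    return g.take_individuals(np.concatenate(chosen))
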