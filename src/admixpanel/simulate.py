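"""Synthetic three-way admixed cattle-like data.

Generates divergent ancestral populations under the Balding-Nichols model,
admixed crossbreds with known ancestry vectors, and parent-offspring
families with genotyping error, so every downstream stage is testable
without external data.

The default per-population divergence parameters were calibrated once by
simulation so that realized pairwise Hudson-style differentiation lands
centrally in the target ranges (AFT-EUT 0.211-0.332, EUT-BI 0.301-0.427,
AFT-BI 0.372-0.492).  Under Balding-Nichols with a shared ancestral
frequency, pairwise differentiation is approximately (F_i + F_j) / 2, which
gives F_EUT = 0.20, F_AFT = 0.34, F_BI = 0.52.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .freqs import AlleleFrequencyTable
from .io import (
    MISSING,
    GenotypeMatrix,
    make_sample_table,
    make_variant_table,
)

EUT = "EUT"
AFT = "AFT"
BI = "BI"

DEFAULT_DIVERGENCE: dict[str, float] = {EUT: 0.20, AFT: 0.34, BI: 0.52}
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = tuple(
    (str(i), 85_000_000) for i in range(1, 30)
)


@dataclass(frozen=True)
class AdmixtureLaw:
    """Distribution of crossbred ancestry vectors on the simplex.

    The exotic-dairy fraction is Beta distributed; the remainder is split
    between the two indigenous ancestries by an independent Beta draw.  The
    default Beta(2.7, 1.8) gives mean 0.6 and s.d. 0.21, matching the
    means (0.49-0.79) and between-animal spreads (~0.17-0.21) observed in
    real crossbred dairy cohorts.
    """

    populations: tuple[str, str, str] = (EUT, AFT, BI)
    dairy_population: str = EUT
    dairy_beta: tuple[float, float] = (2.7, 1.8)
    split_beta: tuple[float, float] = (2.0, 2.0)

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        dairy = rng.beta(*self.dairy_beta, size=n)
        split = rng.beta(*self.split_beta, size=n)
        others = [p for p in self.populations if p != self.dairy_population]
        q = pd.DataFrame(0.0, index=range(n), columns=list(self.populations))
        q[self.dairy_population] = dairy
        q[others[0]] = (1.0 - dairy) * split
        q[others[1]] = (1.0 - dairy) * (1.0 - split)
        return q


@dataclass
class SimulationConfig:
    seed: int = 0
    n_snps: int = 2000
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    ancestral_maf_law: tuple = ("uniform", 0.05, 0.95)
    divergence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERGENCE)
    )
    admixture_law: AdmixtureLaw = field(default_factory=AdmixtureLaw)
    n_reference: int = 60
    n_crossbred: int = 200
    n_families: int = 10
    error_rate: float = 0.01
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for label, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {label!r} has non-positive length")
        for pop, f in self.divergence.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"divergence F for {pop!r} must be in (0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple(
                (str(label), int(length)) for label, length in raw["chromosomes"]
            )
        if "ancestral_maf_law" in raw:
            raw["ancestral_maf_law"] = tuple(raw["ancestral_maf_law"])
        if "admixture_law" in raw:
            law = raw["admixture_law"]
            for key in ("populations", "dairy_beta", "split_beta"):
                if key in law:
                    law[key] = tuple(law[key])
            raw["admixture_law"] = AdmixtureLaw(**law)
        return cls(**raw)


@dataclass
class TruthRecord:
    """Ground truth for simulated data: ancestry vectors and/or pedigree."""

    q_true: pd.DataFrame | None = None
    pedigree: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.q_true is not None:
            vals = self.q_true.to_numpy(dtype=float)
            if (vals < -1e-12).any() or np.abs(vals.sum(axis=1) - 1.0).max() > 1e-8:
                raise ValueError("q_true rows must lie on the simplex")
        if self.pedigree is not None:
            need = {"parent_id", "offspring_id"}
            if not need <= set(self.pedigree.columns):
                raise ValueError(f"pedigree must have columns {sorted(need)}")

    def write(self, base: str | Path) -> None:
        base = Path(base)
        if self.q_true is not None:
            self.q_true.rename_axis("sample_id").to_csv(
                base.with_suffix(base.suffix + ".q_true.tsv"), sep="\t"
            )
        if self.pedigree is not None:
            self.pedigree.to_csv(
                base.with_suffix(base.suffix + ".pedigree.tsv"), sep="\t", index=False
            )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_variant_map(config: SimulationConfig) -> pd.DataFrame:
    """Uniform SNP positions allocated to chromosomes proportional to length."""
    rng = _rng(config.seed, 0)
    lengths = np.array([length for _, length in config.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    counts = np.floor(config.n_snps * weights).astype(int)
    remainder = config.n_snps - counts.sum()
    if remainder > 0:
        frac = config.n_snps * weights - np.floor(config.n_snps * weights)
        order = np.argsort(-frac, kind="stable")
        counts[order[:remainder]] += 1
    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    for (label, length), cnt in zip(config.chromosomes, counts):
        if cnt > length:
            raise ValueError(
                f"chromosome {label!r}: {cnt} SNPs requested but only "
                f"{length} distinct positions exist"
            )
        pos = np.sort(rng.choice(int(length), size=int(cnt), replace=False) + 1)
        for k, p in enumerate(pos):
            chroms.append(label)
            positions.append(int(p))
            ids.append(f"snp_{label}_{k}")
    return make_variant_table(ids, chroms, positions)


def _draw_p0(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    kind = config.ancestral_maf_law[0]
    if kind == "uniform":
        _, lo, hi = config.ancestral_maf_law
        return rng.uniform(lo, hi, size=config.n_snps)
    if kind == "beta":
        _, a, b = config.ancestral_maf_law
        return rng.beta(a, b, size=config.n_snps)
    raise ValueError(f"unknown ancestral_maf_law {config.ancestral_maf_law!r}")


def simulate_ancestral_frequencies(config: SimulationConfig) -> AlleleFrequencyTable:
    """Balding-Nichols draw of per-population frequencies around shared p0."""
    variants = simulate_variant_map(config)
    rng = _rng(config.seed, 1)
    p0 = _draw_p0(config, rng)
    cols = {}
    for pop, f in config.divergence.items():
        scale = (1.0 - f) / f
        p = rng.beta(p0 * scale, (1.0 - p0) * scale)
        cols[pop] = np.clip(p, 1e-9, 1.0 - 1e-9)
    freq = pd.DataFrame(cols, index=variants["snp_id"].tolist())
    return AlleleFrequencyTable(freq=freq, counts=None, variants=variants)


def simulate_genotypes_from_freqs(
    freqs: AlleleFrequencyTable,
    population: str,
    n: int,
    seed: int,
    id_prefix: str | None = None,
    role: str = "reference",
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Hardy-Weinberg sampling: dosages Binomial(2, p) per SNP."""
    if population not in freqs.populations:
        raise KeyError(f"unknown population {population!r}")
    rng = _rng(seed, 2)
    p = freqs.freq[population].to_numpy(dtype=float)
    m = len(p)
    dosage = rng.binomial(2, p, size=(n, m)).astype(np.int8) if n else np.empty(
        (0, m), dtype=np.int8
    )
    if missing_rate > 0 and n:
        dosage[rng.random((n, m)) < missing_rate] = MISSING
    prefix = id_prefix or population
    samples = make_sample_table(
        [f"{prefix}_{i}" for i in range(n)], populations=population, roles=role
    )
    variants = freqs.require_variants()
    return GenotypeMatrix(dosage=dosage, samples=samples, variants=variants)


def simulate_crossbreds(
    freqs: AlleleFrequencyTable,
    admixture_law: AdmixtureLaw,
    n: int,
    seed: int,
    id_prefix: str = "xb",
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Admixed individuals: dosage Binomial(2, sum_k q_k p_kj), truth kept."""
    law_pops = list(admixture_law.populations)
    missing_pops = [p for p in law_pops if p not in freqs.populations]
    if missing_pops:
        raise ValueError(
            f"admixture law populations {missing_pops} absent from frequency table"
        )
    rng = _rng(seed, 3)
    q = admixture_law.sample(n, rng)
    p = freqs.freq[law_pops].to_numpy(dtype=float)  # M x K
    theta = np.clip(q.to_numpy() @ p.T, 1e-12, 1.0 - 1e-12)  # n x M
    dosage = rng.binomial(2, theta).astype(np.int8) if n else np.empty(
        (0, p.shape[0]), dtype=np.int8
    )
    if missing_rate > 0 and n:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    ids = [f"{id_prefix}_{i}" for i in range(n)]
    q.index = ids
    samples = make_sample_table(ids, populations="crossbred", roles="crossbred")
    g = GenotypeMatrix(dosage=dosage, samples=samples, variants=freqs.require_variants())
    return g, TruthRecord(q_true=q)


def simulate_families(
    parent_pool: GenotypeMatrix,
    freqs: AlleleFrequencyTable,
    population: str,
    n_pairs: int,
    seed: int,
    id_prefix: str = "prog",
) -> tuple[GenotypeMatrix, TruthRecord]:
    """One offspring per selected parent; the other parent is drawn from
    the named population's allele frequencies.

    Before any error injection every true (parent, offspring) pair has zero
    opposing homozygotes: the offspring inherits one allele from its
    genotyped parent at every SNP.
    """
    if parent_pool.n_samples == 0:
        raise ValueError("parent pool is empty")
    if n_pairs > parent_pool.n_samples:
        raise ValueError("n_pairs exceeds parent pool size")
    if population not in freqs.populations:
        raise KeyError(f"unknown population {population!r}")
    if freqs.freq.index.tolist() != parent_pool.snp_ids:
        raise ValueError("frequency table SNPs do not match parent pool")
    rng = _rng(seed, 4)
    pick = rng.choice(parent_pool.n_samples, size=n_pairs, replace=False)
    p = freqs.freq[population].to_numpy(dtype=float)
    d_par = parent_pool.dosage[pick]  # n_pairs x M
    m = d_par.shape[1]

    from_parent = np.where(
        d_par == 2,
        1,
        np.where(d_par == 0, 0, (rng.random(d_par.shape) < 0.5).astype(np.int8)),
    ).astype(np.int8)
    # parent uncalled: fall back to a population draw (pair not comparable there)
    uncalled = d_par == MISSING
    if uncalled.any():
        from_parent[uncalled] = (
            rng.random(uncalled.sum()) < np.broadcast_to(p, d_par.shape)[uncalled]
        ).astype(np.int8)
    from_population = (rng.random(d_par.shape) < p).astype(np.int8)
    dosage = (from_parent + from_population).astype(np.int8)

    parent_ids = [parent_pool.sample_ids[i] for i in pick]
    ids = [f"{id_prefix}_{i}" for i in range(n_pairs)]
    samples = make_sample_table(ids, populations="crossbred", roles="crossbred")
    g = GenotypeMatrix(dosage=dosage, samples=samples, variants=parent_pool.variants.copy())
    pedigree = pd.DataFrame({"parent_id": parent_ids, "offspring_id": ids})
    return g, TruthRecord(pedigree=pedigree)


def add_genotyping_errors(
    g: GenotypeMatrix, error_rate: float, seed: int
) -> GenotypeMatrix:
    """Replace each called genotype, with probability ``error_rate``, by a
    uniformly chosen different legal value.  Missing entries are untouched."""
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    out = g.copy()
    if error_rate == 0.0 or out.dosage.size == 0:
        return out
    rng = _rng(seed, 5)
    called = out.dosage != MISSING
    hit = called & (rng.random(out.dosage.shape) < error_rate)
    n_hit = int(hit.sum())
    if n_hit:
        # adding 1 or 2 mod 3 maps a value to one of the two other values
        shift = rng.integers(1, 3, size=n_hit).astype(np.int8)
        out.dosage[hit] = (out.dosage[hit] + shift) % 3
    return out


def hudson_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Hudson-style differentiation from two population frequency vectors
    (ratio of averages); used only to calibrate/check simulation defaults."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return float(num.sum() / den.sum())


def realized_divergence(freqs: AlleleFrequencyTable) -> dict[tuple[str, str], float]:
    """Pairwise Hudson-style differentiation of every population pair."""
    pops = freqs.populations
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            out[(a, b)] = hudson_fst(
                freqs.freq[a].to_numpy(), freqs.freq[b].to_numpy()
            )
    return out
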