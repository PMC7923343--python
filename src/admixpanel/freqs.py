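"""Population allele frequencies and frequency-based SNP scores.

Houses the per-population frequency table plus the three scores the panel
designs are built from: minor allele frequency, the absolute frequency
difference |pA_i - pA_j| between two populations, and the weighted pooled
frequency of a hypothetical two-way ancestral population.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass
class AlleleFrequencyTable:
    """Frequency of the counted allele per (population, SNP).

    ``freq`` is indexed by snp_id with one column per population; entries
    are in [0, 1] or NaN where no genotype was called.  ``counts`` holds the
    number of called genotypes behind each frequency (None for frequencies
    that are exact by construction, e.g. simulated truth).
    """

    freq: pd.DataFrame
    counts: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.freq.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < -1e-12 or np.nanmax(vals, initial=0.0) > 1 + 1e-12:
                raise ValueError("frequencies must lie in [0, 1]")
        if self.counts is not None and not self.counts.shape == self.freq.shape:
            raise ValueError("counts shape must match freq shape")

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.freq.index)

    def require_variants(self) -> pd.DataFrame:
        if self.variants is None:
            raise ValueError("this frequency table carries no variant map")
        return self.variants.copy()

    def add_population(self, name: str, freq: pd.Series) -> None:
        if name in self.freq.columns:
            raise ValueError(f"population {name!r} already present")
        self.freq[name] = freq.reindex(self.freq.index)
        if self.counts is not None:
            self.counts[name] = np.nan

    def subset(self, snp_ids: Sequence[str]) -> "AlleleFrequencyTable":
        freq = self.freq.loc[list(snp_ids)].copy()
        counts = self.counts.loc[list(snp_ids)].copy() if self.counts is not None else None
        variants = None
        if self.variants is not None:
            variants = (
                self.variants.set_index("snp_id")
                .loc[list(snp_ids)]
                .reset_index()
            )
        return AlleleFrequencyTable(freq=freq, counts=counts, variants=variants)

    def to_tsv(self, path: str | Path) -> None:
        out = self.freq.rename_axis("snp_id")
        if self.counts is not None:
            counts = self.counts.add_suffix(".n_called")
            out = pd.concat([out, counts], axis=1)
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleFrequencyTable":
        df = pd.read_csv(path, sep="\t", index_col="snp_id", na_values="NA")
        df.index = df.index.astype(str)
        freq_cols = [c for c in df.columns if not c.endswith(".n_called")]
        count_cols = [c for c in df.columns if c.endswith(".n_called")]
        counts = None
        if count_cols:
            counts = df[count_cols]
            counts.columns = [c[: -len(".n_called")] for c in count_cols]
            counts = counts[freq_cols]
        return cls(freq=df[freq_cols], counts=counts)


def population_allele_frequencies(
    g: GenotypeMatrix,
    grouping: Mapping[str, str] | None = None,
) -> AlleleFrequencyTable:
    """Frequencies of the counted allele per group over non-missing calls.

    ``grouping`` maps sample_id -> group label; samples not mentioned are
    excluded.  With no grouping, each sample's ``population`` label is its
    group.  Groups therefore pool individuals, not breed means.
    """
    if grouping is None:
        grouping = dict(zip(g.sample_ids, g.samples["population"]))
    unknown = set(grouping) - set(g.sample_ids)
    if unknown:
        raise KeyError(f"grouped samples absent from dataset: {sorted(unknown)[:5]}")
    groups: dict[str, list[int]] = {}
    index_of = {s: i for i, s in enumerate(g.sample_ids)}
    for sample, group in grouping.items():
        groups.setdefault(str(group), []).append(index_of[sample])
    for name, rows in groups.items():
        if not rows:
            raise ValueError(f"group {name!r} is empty")

    called = g.called_mask()
    dos = np.where(called, g.dosage, 0).astype(np.int64)
    freq_cols: dict[str, np.ndarray] = {}
    count_cols: dict[str, np.ndarray] = {}
    for name in sorted(groups):
        rows = groups[name]
        n_called = called[rows].sum(axis=0)
        total = dos[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_called > 0, total / (2.0 * np.maximum(n_called, 1)), np.nan)
        freq_cols[name] = f
        count_cols[name] = n_called
    index = pd.Index(g.snp_ids, name="snp_id")
    return AlleleFrequencyTable(
        freq=pd.DataFrame(freq_cols, index=index),
        counts=pd.DataFrame(count_cols, index=index),
        variants=g.variants.copy(),
    )


def unweighted_pool_frequencies(
    freqs: AlleleFrequencyTable, populations: Sequence[str]
) -> pd.Series:
    """Unweighted mean of breed frequency columns (sensitivity alternative
    to individual-level pooling)."""
    missing = [p for p in populations if p not in freqs.populations]
    if missing:
        raise KeyError(f"unknown populations {missing}")
    return freqs.freq[list(populations)].mean(axis=1, skipna=False)


def minor_allele_frequency(freqs: AlleleFrequencyTable, population: str) -> pd.Series:
    """MAF = min(p, 1 - p); NaN where the frequency is undefined."""
    if population not in freqs.populations:
        raise KeyError(f"unknown population {population!r}")
    p = freqs.freq[population]
    return np.minimum(p, 1.0 - p)


def absolute_frequency_difference(
    freqs: AlleleFrequencyTable, pop_i: str, pop_j: str
) -> pd.Series:
    """|pA_i - pA_j| per SNP; NaN wherever either frequency is undefined."""
    for pop in (pop_i, pop_j):
        if pop not in freqs.populations:
            raise KeyError(f"unknown population {pop!r}")
    return (freqs.freq[pop_i] - freqs.freq[pop_j]).abs()


def weighted_hypothetical_frequency(
    freqs: AlleleFrequencyTable, pop_a: str, pop_b: str, w: float
) -> pd.Series:
    """w * p_a + (1 - w) * p_b per SNP: the frequency vector of a
    hypothetical pooled ancestral population."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight must be in [0, 1], got {w}")
    for pop in (pop_a, pop_b):
        if pop not in freqs.populations:
            raise KeyError(f"unknown population {pop!r}")
    return w * freqs.freq[pop_a] + (1.0 - w) * freqs.freq[pop_b]
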