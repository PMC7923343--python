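"""SNP panel construction: score-based ranking plus stepwise physical
distance pruning, emitting nested panels.

The breed-proportion default relaxes the minimum inter-SNP distance as the
panel grows -- 3.5 Mb for the first 100 accepted SNPs, 3 Mb up to 300, and
1.25 Mb afterwards -- while the parentage default is a single 1 Mb stage.
Distances are |pos_i - pos_j| in bp; SNPs on different chromosomes never
conflict.  Larger panels always contain the smaller ones: any prefix of a
panel's order is itself a valid panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .freqs import (
    AlleleFrequencyTable,
    absolute_frequency_difference,
    minor_allele_frequency,
    weighted_hypothetical_frequency,
)

DEFAULT_PANEL_SIZES: tuple[int, ...] = (100, 200, 300, 400, 500, 1000, 1500)


class PanelShortfallWarning(UserWarning):
    """Fewer eligible SNPs than the requested panel size."""


@dataclass(frozen=True)
class PruningSchedule:
    """Ordered stages of (max cumulative accepted count, min distance bp).

    The stage that applies to a candidate is determined by how many SNPs
    have been accepted so far overall; the final stage is unbounded
    (``None``).
    """

    stages: tuple[tuple[int | None, int], ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        prev = 0
        for i, (cum, dist) in enumerate(self.stages):
            if dist <= 0:
                raise ValueError("stage distances must be positive")
            last = i == len(self.stages) - 1
            if last:
                if cum is not None:
                    raise ValueError("final stage must be unbounded (None)")
            else:
                if cum is None or cum <= prev:
                    raise ValueError("cumulative counts must be strictly increasing")
                prev = cum

    def distance_for(self, n_accepted: int) -> int:
        """Minimum distance required of the (n_accepted + 1)-th acceptance."""
        for cum, dist in self.stages:
            if cum is None or n_accepted < cum:
                return dist
        raise AssertionError("unreachable: final stage is unbounded")


BREED_PROPORTION_SCHEDULE = PruningSchedule(
    ((100, 3_500_000), (300, 3_000_000), (None, 1_250_000))
)
PARENTAGE_SCHEDULE = PruningSchedule(((None, 1_000_000),))


def rank_by_score(scores: pd.Series, variants: pd.DataFrame) -> list[str]:
    """SNP ids by descending score; ties broken by (chromosome,
    position_bp, snp_id).  SNPs with undefined (NaN) scores are excluded."""
    df = variants.set_index("snp_id")[["chromosome", "position_bp"]].copy()
    df["score"] = scores.reindex(df.index)
    df = df.dropna(subset=["score"]).reset_index()
    df = df.sort_values(
        by=["score", "chromosome", "position_bp", "snp_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    return df["snp_id"].tolist()


def stepwise_prune(
    ranked: Sequence[str],
    variants: pd.DataFrame,
    schedule: PruningSchedule,
    max_snps: int | None = None,
) -> list[str]:
    """Greedy scan of ``ranked``: accept a SNP iff it is at least the
    current stage's distance away from every accepted SNP on the same
    chromosome.  Rank order is preserved among accepted SNPs."""
    vmap = variants.set_index("snp_id")
    missing = [s for s in ranked if s not in vmap.index]
    if missing:
        raise KeyError(f"ranked SNPs missing from variant table: {missing[:5]}")
    chrom = vmap["chromosome"]
    pos = vmap["position_bp"]
    accepted: list[str] = []
    by_chrom: dict[str, list[int]] = {}
    for snp in ranked:
        if max_snps is not None and len(accepted) >= max_snps:
            break
        d = schedule.distance_for(len(accepted))
        c = chrom[snp]
        p = int(pos[snp])
        taken = by_chrom.get(c)
        if taken is not None and any(abs(p - q) < d for q in taken):
            continue
        accepted.append(snp)
        by_chrom.setdefault(c, []).append(p)
    return accepted


def satisfies_schedule(
    snp_ids: Sequence[str], variants: pd.DataFrame, schedule: PruningSchedule
) -> bool:
    """Stage-wise distance check of an ordered panel (used on emission)."""
    vmap = variants.set_index("snp_id")
    seen: list[tuple[str, int]] = []
    for snp in snp_ids:
        d = schedule.distance_for(len(seen))
        c = vmap.at[snp, "chromosome"]
        p = int(vmap.at[snp, "position_bp"])
        if any(cc == c and abs(p - pp) < d for cc, pp in seen):
            return False
        seen.append((c, p))
    return True


@dataclass
class SnpPanel:
    """An ordered, score-annotated SNP subset.  The first ``n`` rows form
    the size-``n`` panel, so panels of increasing size are nested."""

    criterion: dict
    table: pd.DataFrame  # rank, snp_id, chromosome, position_bp, score, source
    sizes: tuple[int, ...] = DEFAULT_PANEL_SIZES

    def __post_init__(self) -> None:
        if self.table["snp_id"].duplicated().any():
            raise ValueError("panel contains duplicate SNPs")
        self.sizes = tuple(sorted(int(s) for s in self.sizes))

    def __len__(self) -> int:
        return len(self.table)

    def ids(self, n: int | None = None) -> list[str]:
        ids = self.table["snp_id"].tolist()
        return ids if n is None else ids[:n]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, criterion: dict | None = None) -> "SnpPanel":
        table = pd.read_csv(
            path, sep="\t", dtype={"snp_id": str, "chromosome": str, "source": str}
        )
        sizes = (len(table),)
        return cls(criterion=criterion or {}, table=table, sizes=sizes)


def _build_panel(
    criterion: dict,
    ordered_ids: Sequence[str],
    scores: pd.Series,
    variants: pd.DataFrame,
    sizes: Sequence[int],
    sources: Sequence[str] | None = None,
) -> SnpPanel:
    n_max = max(sizes)
    taken = list(ordered_ids[:n_max])
    if len(taken) < n_max:
        warnings.warn(
            f"only {len(taken)} eligible SNPs for requested size {n_max}",
            PanelShortfallWarning,
            stacklevel=3,
        )
    vmap = variants.set_index("snp_id")
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(taken) + 1),
            "snp_id": taken,
            "chromosome": [vmap.at[s, "chromosome"] for s in taken],
            "position_bp": [int(vmap.at[s, "position_bp"]) for s in taken],
            "score": [float(scores[s]) for s in taken],
            "source": list(sources[: len(taken)]) if sources is not None
            else [criterion.get("mode", "")] * len(taken),
        }
    )
    return SnpPanel(criterion=criterion, table=table, sizes=tuple(sizes))


def select_panel_weighted(
    freqs: AlleleFrequencyTable,
    w: float,
    sizes: Sequence[int] = DEFAULT_PANEL_SIZES,
    schedule: PruningSchedule | None = BREED_PROPORTION_SCHEDULE,
    pop_eut: str = "EUT",
    pop_aft: str = "AFT",
    pop_bi: str = "BI",
) -> SnpPanel:
    """Rank by |p_EUT - (w p_AFT + (1 - w) p_BI)|, prune, emit nested panels."""
    if not 0.0 < w < 1.0:
        raise ValueError(f"w must be in (0, 1), got {w}")
    pooled = weighted_hypothetical_frequency(freqs, pop_aft, pop_bi, w)
    scores = (freqs.freq[pop_eut] - pooled).abs()
    variants = freqs.require_variants()
    ranked = rank_by_score(scores, variants)
    if schedule is not None:
        ranked = stepwise_prune(ranked, variants, schedule, max_snps=max(sizes))
    criterion = {"mode": "weighted_pool", "w": w,
                 "populations": [pop_eut, pop_aft, pop_bi]}
    return _build_panel(criterion, ranked, scores, variants, sizes)


def select_panel_maf(
    freqs: AlleleFrequencyTable,
    target_population: str,
    sizes: Sequence[int] = DEFAULT_PANEL_SIZES,
    pruned: bool = True,
    schedule: PruningSchedule = PARENTAGE_SCHEDULE,
) -> SnpPanel:
    """Rank by MAF in the target (crossbred) population; optional 1 Mb prune."""
    scores = minor_allele_frequency(freqs, target_population)
    variants = freqs.require_variants()
    ranked = rank_by_score(scores, variants)
    if pruned:
        ranked = stepwise_prune(ranked, variants, schedule, max_snps=max(sizes))
    criterion = {"mode": "maf", "target": target_population, "pruned": pruned}
    return _build_panel(criterion, ranked, scores, variants, sizes)


def select_panel_split(
    freqs: AlleleFrequencyTable,
    f: float,
    sizes: Sequence[int] = DEFAULT_PANEL_SIZES,
    schedule: PruningSchedule = BREED_PROPORTION_SCHEDULE,
    pop_eut: str = "EUT",
    pop_aft: str = "AFT",
    pop_bi: str = "BI",
) -> SnpPanel:
    """Split-fraction panels: at size n, ceil(f*n) SNPs come from the
    AFT-vs-EUT frequency-difference ranking and the rest from the
    BI-vs-EUT ranking.

    Each ranking is pruned with the schedule, then the two streams are
    interleaved to hold the quota at every size; a SNP appearing in both
    rankings is attributed to the stream that reaches it first, and the
    combined panel is re-validated against the schedule as it grows (a
    conflicting lower-ranked SNP is replaced by the next eligible one from
    its stream).
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must be in (0, 1), got {f}")
    variants = freqs.require_variants()
    score_a = absolute_frequency_difference(freqs, pop_aft, pop_eut)
    score_b = absolute_frequency_difference(freqs, pop_bi, pop_eut)
    n_max = max(sizes)
    margin = n_max + 200  # spare depth for SNPs lost to combined-panel conflicts
    stream_a = stepwise_prune(rank_by_score(score_a, variants), variants,
                              schedule, max_snps=margin)
    stream_b = stepwise_prune(rank_by_score(score_b, variants), variants,
                              schedule, max_snps=margin)

    vmap = variants.set_index("snp_id")
    chrom = vmap["chromosome"]
    pos = vmap["position_bp"]
    used: set[str] = set()
    by_chrom: dict[str, list[int]] = {}
    taken: list[str] = []
    sources: list[str] = []
    scores_taken: list[float] = []

    def next_eligible(stream: list[str]) -> str | None:
        d = schedule.distance_for(len(taken))
        for snp in stream:
            if snp in used:
                continue
            c = chrom[snp]
            p = int(pos[snp])
            placed = by_chrom.get(c)
            if placed is not None and any(abs(p - q) < d for q in placed):
                continue
            return snp
        return None

    a_count = 0
    while len(taken) < n_max:
        want_a = a_count < math.ceil(f * (len(taken) + 1))
        first, second = (stream_a, stream_b) if want_a else (stream_b, stream_a)
        snp = next_eligible(first)
        source_is_a = want_a
        if snp is None:
            snp = next_eligible(second)
            source_is_a = not want_a
        if snp is None:
            break
        used.add(snp)
        taken.append(snp)
        by_chrom.setdefault(chrom[snp], []).append(int(pos[snp]))
        if source_is_a:
            a_count += 1
            sources.append(f"{pop_aft}vs{pop_eut}")
            scores_taken.append(float(score_a[snp]))
        else:
            sources.append(f"{pop_bi}vs{pop_eut}")
            scores_taken.append(float(score_b[snp]))

    criterion = {"mode": "split_fraction", "f": f,
                 "populations": [pop_eut, pop_aft, pop_bi]}
    scores = pd.Series(scores_taken, index=taken)
    return _build_panel(criterion, taken, scores, variants, sizes, sources=sources)
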