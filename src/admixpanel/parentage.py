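"""Opposing-homozygote parentage statistics.

A SNP is an opposing homozygote (opH) for a pair when one individual is
dosage 0 and the other dosage 2 (both called); true parent-offspring pairs
can only show opH through genotyping error.  Assignment uses a strict
threshold: a pair is assigned iff opH < threshold_fraction * n_markers,
where n_markers is the panel size (not the per-pair comparable count).

The separation value sv = min(opH over false pairs) - max(opH over true
pairs); a positive sv means some threshold separates all true from all
false pairs.  Pa and Pe are the powers of assignment and exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass
class CandidatePairs:
    """Unordered candidate pairs held as index pairs into ``sample_ids``."""

    sample_ids: list[str]
    pairs: np.ndarray  # (n_pairs, 2) int indices
    scenario: int

    def __len__(self) -> int:
        return int(self.pairs.shape[0])

    def id_pairs(self) -> Iterable[tuple[str, str]]:
        ids = self.sample_ids
        for i, j in self.pairs:
            yield ids[i], ids[j]


def candidate_pairs(
    samples: pd.DataFrame,
    scenario: int,
    parent_ids: Sequence[str] | None = None,
    progeny_ids: Sequence[str] | None = None,
) -> CandidatePairs:
    """Scenario 1: all N(N-1)/2 unordered pairs among all samples.
    Scenario 2: all |parents| x |progeny| pairs, parent and progeny sets
    disjoint."""
    ids = samples["sample_id"].tolist()
    if scenario == 1:
        n = len(ids)
        iu = np.triu_indices(n, k=1)
        pairs = np.column_stack(iu).astype(np.int32)
        return CandidatePairs(sample_ids=ids, pairs=pairs, scenario=1)
    if scenario == 2:
        if not parent_ids:
            raise ValueError("scenario 2 requires a non-empty parent set")
        if progeny_ids is None:
            progeny_ids = [s for s in ids if s not in set(parent_ids)]
        overlap = set(parent_ids) & set(progeny_ids)
        if overlap:
            raise ValueError(
                f"parent and progeny sets overlap: {sorted(overlap)[:5]}"
            )
        index_of = {s: i for i, s in enumerate(ids)}
        try:
            par = np.array([index_of[s] for s in parent_ids], dtype=np.int32)
            pro = np.array([index_of[s] for s in progeny_ids], dtype=np.int32)
        except KeyError as exc:
            raise KeyError(f"unknown sample_id {exc.args[0]!r}") from None
        pairs = np.column_stack(
            [np.repeat(par, len(pro)), np.tile(pro, len(par))]
        )
        return CandidatePairs(sample_ids=ids, pairs=pairs, scenario=2)
    raise ValueError(f"scenario must be 1 or 2, got {scenario}")


def opposing_homozygote_counts(
    g: GenotypeMatrix,
    snp_ids: Sequence[str] | None = None,
    pairs: CandidatePairs | Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """opH and comparable-SNP counts for the requested pairs.

    Returns a DataFrame with columns (id_1, id_2, oph, n_comparable); the
    counts are symmetric in the pair.  With ``pairs`` None, all unordered
    pairs are evaluated.
    """
    sub = g if snp_ids is None else g.subset(snp_ids=list(snp_ids))
    d = sub.dosage
    hom0 = (d == 0).astype(np.float64)
    hom2 = (d == 2).astype(np.float64)
    called = (d != MISSING).astype(np.float64)
    oph_mat = hom0 @ hom2.T
    oph_mat += oph_mat.T
    cmp_mat = called @ called.T

    if pairs is None:
        pairs = candidate_pairs(g.samples, scenario=1)
    if isinstance(pairs, CandidatePairs):
        if pairs.sample_ids != g.sample_ids:
            raise ValueError("candidate pairs built over different samples")
        idx = pairs.pairs
        ids = g.sample_ids
        id1 = [ids[i] for i in idx[:, 0]]
        id2 = [ids[j] for j in idx[:, 1]]
    else:
        index_of = {s: i for i, s in enumerate(g.sample_ids)}
        try:
            idx = np.array(
                [(index_of[a], index_of[b]) for a, b in pairs], dtype=np.int64
            ).reshape(-1, 2)
        except KeyError as exc:
            raise KeyError(f"unknown sample_id {exc.args[0]!r}") from None
        id1 = [a for a, _ in pairs]
        id2 = [b for _, b in pairs]
    return pd.DataFrame(
        {
            "id_1": id1,
            "id_2": id2,
            "oph": oph_mat[idx[:, 0], idx[:, 1]].astype(np.int64),
            "n_comparable": cmp_mat[idx[:, 0], idx[:, 1]].astype(np.int64),
        }
    )


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _truth_set(truth_pairs: Iterable[tuple[str, str]] | pd.DataFrame) -> set[tuple[str, str]]:
    if isinstance(truth_pairs, pd.DataFrame):
        truth_pairs = zip(truth_pairs["parent_id"], truth_pairs["offspring_id"])
    return {_pair_key(a, b) for a, b in truth_pairs}


def reconstruct_pairs(
    counts: pd.DataFrame,
    threshold_fraction: float = 0.01,
    n_markers: int | None = None,
) -> list[tuple[str, str]]:
    """Pairs assigned as parent-offspring: opH strictly below
    threshold_fraction * n_markers (the panel's marker count)."""
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if n_markers is None or n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    cut = threshold_fraction * n_markers
    sel = counts[counts["oph"] < cut]
    return [_pair_key(a, b) for a, b in zip(sel["id_1"], sel["id_2"])]


def separation_value(
    counts: pd.DataFrame,
    truth_pairs: Iterable[tuple[str, str]] | pd.DataFrame,
) -> int:
    """sv = min(opH over false pairs) - max(opH over true pairs)."""
    truth = _truth_set(truth_pairs)
    keys = [_pair_key(a, b) for a, b in zip(counts["id_1"], counts["id_2"])]
    is_true = np.array([k in truth for k in keys], dtype=bool)
    tr = counts.loc[is_true, "oph"]
    fr = counts.loc[~is_true, "oph"]
    if tr.empty or fr.empty:
        raise ValueError("both true and false pair classes must be non-empty")
    return int(fr.min() - tr.max())


def power_statistics(
    assigned: Iterable[tuple[str, str]],
    truth_pairs: Iterable[tuple[str, str]] | pd.DataFrame,
    total_parents: int,
) -> tuple[float, float]:
    """(Pa, Pe): Pa = correct assignments / total_parents and
    Pe = 1 - incorrect assignments / total_parents (floored at 0).

    Pairs are the unit of analysis: a true pair assigned counts as one
    correct assignment, every assigned non-truth pair as one incorrect
    assignment.
    """
    if total_parents < 1:
        raise ValueError("total_parents must be >= 1")
    truth = _truth_set(truth_pairs)
    assigned_set = {_pair_key(a, b) for a, b in assigned}
    correct = len(assigned_set & truth)
    incorrect = len(assigned_set - truth)
    pa = correct / total_parents
    pe = max(0.0, 1.0 - incorrect / total_parents)
    return pa, pe
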