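"""Genotype dataset container and text I/O.

Dosage matrices are stored as ``int8`` arrays whose entries count copies of
``allele_a`` (0, 1 or 2); :data:`MISSING` (-1) marks a no-call.

Two text dialects are supported:

* ``plink_text`` -- a ``.ped``/``.map`` pair.  The ``.map`` carries
  (chromosome, snp_id, genetic distance (ignored), position); the ``.ped``
  carries two allele columns per SNP, with ``0 0`` meaning missing.  PLINK
  text files do not designate a counted allele, so on read the
  lexicographically smaller observed allele becomes ``allele_a``; round
  trips are exact for datasets already in that normal form.
* ``tsv_matrix`` -- a native trio of TSV files (``<base>.geno.tsv``,
  ``<base>.variants.tsv``, ``<base>.samples.tsv``) that round-trips a
  dataset exactly, including allele designation, sample roles and tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

LEGAL_DOSAGES = frozenset({-1, 0, 1, 2})

VARIANT_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "population", "role", "group_tags"]
ROLES = frozenset({"reference", "crossbred"})


class GenotypeParseError(ValueError):
    """Malformed input file; message names the offending file/line."""


class MergeError(ValueError):
    """Datasets cannot be merged (allele or coordinate conflict)."""


def make_variant_table(
    snp_ids: Sequence[str],
    chromosomes: Sequence[str],
    positions_bp: Sequence[int],
    allele_a: Sequence[str] | None = None,
    allele_b: Sequence[str] | None = None,
) -> pd.DataFrame:
    n = len(snp_ids)
    df = pd.DataFrame(
        {
            "snp_id": [str(s) for s in snp_ids],
            "chromosome": [str(c) for c in chromosomes],
            "position_bp": np.asarray(positions_bp, dtype=np.int64),
            "allele_a": list(allele_a) if allele_a is not None else ["A"] * n,
            "allele_b": list(allele_b) if allele_b is not None else ["B"] * n,
        }
    )
    validate_variants(df)
    return df


def make_sample_table(
    sample_ids: Sequence[str],
    populations: Sequence[str] | str,
    roles: Sequence[str] | str = "crossbred",
    group_tags: Sequence[str] | str = "",
) -> pd.DataFrame:
    n = len(sample_ids)
    if isinstance(populations, str):
        populations = [populations] * n
    if isinstance(roles, str):
        roles = [roles] * n
    if isinstance(group_tags, str):
        group_tags = [group_tags] * n
    df = pd.DataFrame(
        {
            "sample_id": [str(s) for s in sample_ids],
            "population": list(populations),
            "role": list(roles),
            "group_tags": list(group_tags),
        }
    )
    validate_samples(df)
    return df


def validate_variants(variants: pd.DataFrame) -> None:
    missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing_cols:
        raise ValueError(f"variant table is missing columns {missing_cols}")
    if variants["snp_id"].duplicated().any():
        dup = variants.loc[variants["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicated snp_id {dup!r}")
    if (variants["position_bp"] < 1).any():
        raise ValueError("position_bp must be >= 1 (1-based coordinates)")
    if variants.duplicated(subset=["chromosome", "position_bp"]).any():
        raise ValueError("duplicated (chromosome, position_bp) pair")
    same = variants["allele_a"] == variants["allele_b"]
    if same.any():
        raise ValueError(
            f"allele_a == allele_b at {variants.loc[same, 'snp_id'].iloc[0]!r}"
        )


def validate_samples(samples: pd.DataFrame) -> None:
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"sample table is missing columns {missing_cols}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id {dup!r}")
    bad_roles = set(samples["role"]) - ROLES
    if bad_roles:
        raise ValueError(f"unknown sample roles {sorted(bad_roles)}; expected {sorted(ROLES)}")


@dataclass
class GenotypeMatrix:
    """Samples-by-SNPs dosage matrix plus its variant and sample tables."""

    dosage: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        validate_samples(self.samples)
        validate_variants(self.variants)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        values = np.unique(self.dosage) if self.dosage.size else np.array([], dtype=np.int8)
        illegal = set(values.tolist()) - LEGAL_DOSAGES
        if illegal:
            raise ValueError(f"illegal dosage values {sorted(illegal)}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def snp_ids(self) -> list[str]:
        return self.variants["snp_id"].tolist()

    def called_mask(self) -> np.ndarray:
        return self.dosage != MISSING

    def snp_call_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return self.called_mask().mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return self.called_mask().mean(axis=1)

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        snp_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted (and reordered) to the requested ids."""
        rows = np.arange(self.n_samples)
        cols = np.arange(self.n_snps)
        if sample_ids is not None:
            idx = {s: i for i, s in enumerate(self.sample_ids)}
            try:
                rows = np.array([idx[s] for s in sample_ids], dtype=int)
            except KeyError as exc:
                raise KeyError(f"unknown sample_id {exc.args[0]!r}") from None
        if snp_ids is not None:
            idx = {s: i for i, s in enumerate(self.snp_ids)}
            try:
                cols = np.array([idx[s] for s in snp_ids], dtype=int)
            except KeyError as exc:
                raise KeyError(f"unknown snp_id {exc.args[0]!r}") from None
        dosage = self.dosage[np.ix_(rows, cols)]
        return GenotypeMatrix(
            dosage=dosage.copy(),
            samples=self.samples.iloc[rows].reset_index(drop=True),
            variants=self.variants.iloc[cols].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage.copy(), self.samples.copy(), self.variants.copy()
        )


def concat_samples(parts: Iterable[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack datasets that share an identical variant table (same order)."""
    parts = list(parts)
    if not parts:
        raise ValueError("nothing to concatenate")
    head = parts[0]
    for p in parts[1:]:
        if p.snp_ids != head.snp_ids:
            raise ValueError("variant tables differ; use merge_on_common_snps")
    return GenotypeMatrix(
        dosage=np.vstack([p.dosage for p in parts]),
        samples=pd.concat([p.samples for p in parts], ignore_index=True),
        variants=head.variants.copy(),
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def filter_call_rate(
    g: GenotypeMatrix,
    snp_threshold: float = 0.9,
    sample_threshold: float = 0.9,
) -> GenotypeMatrix:
    """Drop low-call-rate SNPs, then low-call-rate samples.

    A SNP/sample is retained iff its call rate is strictly greater than the
    threshold ("higher than" the cutoff).  The SNP pass runs first; sample
    call rates are then computed on the surviving SNPs.  Thresholds of 0
    leave a fully observed dataset unchanged.
    """
    for name, t in (("snp_threshold", snp_threshold), ("sample_threshold", sample_threshold)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    keep_snps = np.flatnonzero(g.snp_call_rates() > snp_threshold) if snp_threshold > 0 \
        else np.arange(g.n_snps)
    trimmed = GenotypeMatrix(
        g.dosage[:, keep_snps],
        g.samples.copy(),
        g.variants.iloc[keep_snps],
    )
    keep_samples = np.flatnonzero(trimmed.sample_call_rates() > sample_threshold) \
        if sample_threshold > 0 else np.arange(trimmed.n_samples)
    return GenotypeMatrix(
        trimmed.dosage[keep_samples, :],
        trimmed.samples.iloc[keep_samples],
        trimmed.variants.copy(),
    )


def merge_on_common_snps(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two datasets on their SNP intersection (sample union).

    Shared SNPs are matched by ``snp_id``; where the second dataset counts
    the opposite allele its dosages are flipped (``2 - g``).  An allele pair
    that matches neither orientation is a :class:`MergeError`.
    """
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise MergeError(f"sample_id collision: {sorted(overlap)[:5]}")
    common = [s for s in a.snp_ids if s in set(b.snp_ids)]
    av = a.variants.set_index("snp_id").loc[common]
    bv = b.variants.set_index("snp_id").loc[common]
    coord_bad = [
        s for s in common
        if av.at[s, "chromosome"] != bv.at[s, "chromosome"]
        or av.at[s, "position_bp"] != bv.at[s, "position_bp"]
    ]
    if coord_bad:
        raise MergeError(f"coordinate mismatch at shared SNPs {coord_bad[:5]}")
    same = (av["allele_a"] == bv["allele_a"]) & (av["allele_b"] == bv["allele_b"])
    swapped = (av["allele_a"] == bv["allele_b"]) & (av["allele_b"] == bv["allele_a"])
    bad = [s for s, ok in zip(common, (same | swapped)) if not ok]
    if bad:
        raise MergeError(f"irreconcilable alleles at shared SNPs {bad[:10]}")

    a_sub = a.subset(snp_ids=common)
    b_sub = b.subset(snp_ids=common)
    flip = swapped.to_numpy()
    d_b = b_sub.dosage.copy()
    called = d_b != MISSING
    cols = np.flatnonzero(flip)
    for j in cols:
        c = called[:, j]
        d_b[c, j] = 2 - d_b[c, j]
    return GenotypeMatrix(
        dosage=np.vstack([a_sub.dosage, d_b]),
        samples=pd.concat([a_sub.samples, b_sub.samples], ignore_index=True),
        variants=a_sub.variants.copy(),
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_FORMATS = ("plink_text", "tsv_matrix")


def read_genotypes(path: str | Path, format: str = "tsv_matrix") -> GenotypeMatrix:
    """Read a dataset from ``path`` (a base prefix without extension)."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    base = Path(path)
    if format == "plink_text":
        return _read_plink_text(base)
    return _read_tsv_matrix(base)


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "tsv_matrix") -> None:
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink_text":
        _write_plink_text(g, base)
    else:
        _write_tsv_matrix(g, base)


def _read_tsv_matrix(base: Path) -> GenotypeMatrix:
    geno_path = base.with_suffix(base.suffix + ".geno.tsv")
    var_path = base.with_suffix(base.suffix + ".variants.tsv")
    smp_path = base.with_suffix(base.suffix + ".samples.tsv")
    for p in (geno_path, var_path, smp_path):
        if not p.exists():
            raise FileNotFoundError(p)
    variants = pd.read_csv(
        var_path, sep="\t", dtype={"snp_id": str, "chromosome": str,
                                   "allele_a": str, "allele_b": str}
    )
    samples = pd.read_csv(
        smp_path, sep="\t", dtype=str, keep_default_na=False
    )
    if "group_tags" not in samples.columns:
        samples["group_tags"] = ""

    with open(geno_path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if not cols or cols[0] != "sample_id":
            raise GenotypeParseError(f"{geno_path}:1: header must start with 'sample_id'")
        snp_ids = cols[1:]
        rows: list[np.ndarray] = []
        ids: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise GenotypeParseError(
                    f"{geno_path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            ids.append(fields[0])
            row = np.empty(len(snp_ids), dtype=np.int8)
            for j, cell in enumerate(fields[1:]):
                if cell == "NA":
                    row[j] = MISSING
                elif cell in ("0", "1", "2"):
                    row[j] = int(cell)
                else:
                    raise GenotypeParseError(
                        f"{geno_path}:{lineno}: illegal genotype code {cell!r}"
                    )
            rows.append(row)
    if snp_ids != variants["snp_id"].tolist():
        raise GenotypeParseError(
            f"{geno_path}: SNP columns do not match {var_path}"
        )
    if ids != samples["sample_id"].tolist():
        raise GenotypeParseError(
            f"{geno_path}: sample rows do not match {smp_path}"
        )
    dosage = (
        np.vstack(rows) if rows else np.empty((0, len(snp_ids)), dtype=np.int8)
    )
    return GenotypeMatrix(dosage=dosage, samples=samples, variants=variants)


def _write_tsv_matrix(g: GenotypeMatrix, base: Path) -> None:
    geno_path = base.with_suffix(base.suffix + ".geno.tsv")
    var_path = base.with_suffix(base.suffix + ".variants.tsv")
    smp_path = base.with_suffix(base.suffix + ".samples.tsv")
    g.variants[VARIANT_COLUMNS].to_csv(var_path, sep="\t", index=False)
    g.samples[SAMPLE_COLUMNS].to_csv(smp_path, sep="\t", index=False)
    with open(geno_path, "w") as fh:
        fh.write("\t".join(["sample_id"] + g.snp_ids) + "\n")
        codes = np.array(["0", "1", "2"])
        for i, sid in enumerate(g.sample_ids):
            row = g.dosage[i]
            cells = np.where(row == MISSING, "NA", codes[np.clip(row, 0, 2)])
            fh.write(sid + ("\t" + "\t".join(cells) if len(cells) else "") + "\n")


def _read_plink_text(base: Path) -> GenotypeMatrix:
    ped_path = base.with_suffix(base.suffix + ".ped")
    map_path = base.with_suffix(base.suffix + ".map")
    for p in (ped_path, map_path):
        if not p.exists():
            raise FileNotFoundError(p)

    chroms: list[str] = []
    snp_ids: list[str] = []
    positions: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chroms.append(fields[0])
            snp_ids.append(fields[1])
            try:
                positions.append(int(fields[3]))
            except ValueError:
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: non-integer position {fields[3]!r}"
                ) from None
    m = len(snp_ids)

    sample_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            populations.append(fields[0])
            sample_ids.append(fields[1])
            allele_rows.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(m)]
            )

    # Infer the counted allele per SNP: lexicographically smaller observed
    # allele.  '0' is the missing code and never a real allele.
    allele_a: list[str] = []
    allele_b: list[str] = []
    for j in range(m):
        observed = sorted(
            {a for row in allele_rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise GenotypeParseError(
                f"{ped_path}: SNP {snp_ids[j]!r} has more than two alleles {observed}"
            )
        if len(observed) == 2:
            allele_a.append(observed[0])
            allele_b.append(observed[1])
        elif len(observed) == 1:
            allele_a.append(observed[0])
            allele_b.append("0")  # second allele unobserved
        else:
            allele_a.append("A")
            allele_b.append("B")

    dosage = np.empty((len(sample_ids), m), dtype=np.int8)
    for i, row in enumerate(allele_rows):
        for j, (x, y) in enumerate(row):
            if x == "0" or y == "0":
                if x != y:
                    raise GenotypeParseError(
                        f"{ped_path}: half-missing genotype at sample "
                        f"{sample_ids[i]!r}, SNP {snp_ids[j]!r}"
                    )
                dosage[i, j] = MISSING
            else:
                dosage[i, j] = (x == allele_a[j]) + (y == allele_a[j])

    samples = make_sample_table(sample_ids, populations, roles="crossbred")
    variants = make_variant_table(snp_ids, chroms, positions, allele_a, allele_b)
    return GenotypeMatrix(dosage=dosage, samples=samples, variants=variants)


def _write_plink_text(g: GenotypeMatrix, base: Path) -> None:
    ped_path = base.with_suffix(base.suffix + ".ped")
    map_path = base.with_suffix(base.suffix + ".map")
    with open(map_path, "w") as fh:
        for _, v in g.variants.iterrows():
            fh.write(f"{v.chromosome}\t{v.snp_id}\t0\t{v.position_bp}\n")
    aa = g.variants["allele_a"].to_numpy()
    ab = g.variants["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, (_, s) in enumerate(g.samples.iterrows()):
            fields = [s.population, s.sample_id, "0", "0", "0", "-9"]
            row = g.dosage[i]
            for j in range(g.n_snps):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [ab[j], ab[j]]
                elif d == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [aa[j], aa[j]]
            fh.write(" ".join(fields) + "\n")
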