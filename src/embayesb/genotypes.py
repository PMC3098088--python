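"""Genotype, phenotype and map table I/O, MAF filtering and standardization.

File formats (whitespace-delimited text, lines starting with ``#`` ignored):

* genotype table — ``ID g1 g2 ... gm`` with codes in {0, 1, 2} counting the
  reference allele,
* phenotype table — ``ID phenotype [generation]``,
* map — ``snp_id chromosome position_cM``.

The standardized matrix ``B`` has one column per SNP, centred to sum zero;
under the default ``empirical`` scheme each column's sum of squares equals
the number of individuals ``n`` (the identity the Gauss-Seidel algebra
relies on), while the ``theoretical`` scheme divides by the binomial
standard deviation ``sqrt(2 p (1-p))`` and satisfies it only under exact
Hardy-Weinberg proportions.  Validation genotypes are standardized with the
training-derived centre and scale, never re-centred on their own data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawGenotypes",
    "TraitData",
    "GenotypeMatrix",
    "read_genotype_table",
    "read_phenotype_table",
    "write_genotype_table",
    "write_phenotype_table",
    "write_map",
    "allele_frequency",
    "maf_filter",
    "standardize",
    "apply_training_scaling",
]

# 17 significant digits round-trips any float64
_FLOAT_FMT = "%.17g"


@dataclass
class RawGenotypes:
    """Unstandardized genotype codes plus identifiers and genetic map.

    ``codes`` is ``n x m`` with entries in {0, 1, 2}; ``chrom``/``pos_cm``
    (each length ``m``) carry the map, with chromosomes 1-based and
    positions in centimorgans.
    """

    codes: np.ndarray
    individual_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray | None = None
    pos_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        n, m = self.codes.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match rows")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual IDs")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP IDs")
        bad = ~np.isin(self.codes, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype code {self.codes[i, j]!r} not in {{0,1,2}} "
                f"(individual {self.individual_ids[i]!r}, SNP {self.snp_ids[j]!r})"
            )
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom, dtype=int)
            self.pos_cm = np.asarray(self.pos_cm, dtype=float)
            if len(self.chrom) != m or len(self.pos_cm) != m:
                raise ValueError("map length does not match number of SNP")
            for c in np.unique(self.chrom):
                p = self.pos_cm[self.chrom == c]
                if np.any(np.diff(p) < 0):
                    raise ValueError(
                        f"map positions decrease within chromosome {c}"
                    )

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def subset_snps(self, idx: np.ndarray) -> "RawGenotypes":
        idx = np.asarray(idx)
        return RawGenotypes(
            codes=self.codes[:, idx],
            individual_ids=list(self.individual_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos_cm=None if self.pos_cm is None else self.pos_cm[idx],
        )


@dataclass
class TraitData:
    """Phenotypic records (trait units) with an optional generation label."""

    y: np.ndarray
    individual_ids: list[str] | None = None
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotypes must be finite")
        if self.generation is not None:
            self.generation = np.asarray(self.generation, dtype=int)
            if len(self.generation) != len(self.y):
                raise ValueError("generation labels length mismatch")


@dataclass
class GenotypeMatrix:
    """Standardized n x m genotype matrix with its scaling recorded.

    ``B[:, j] = (codes[:, j] - center[j]) / scale[j]``.  Keeping
    ``center``/``scale`` allows validation genotypes to be put on the
    training scale exactly.
    """

    B: np.ndarray
    p: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    scheme: str
    snp_ids: list[str] = field(default_factory=list)
    chrom: np.ndarray | None = None
    pos_cm: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.B.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no individuals in {str(path)!r} (empty table)") from None
    if df.empty:
        raise ValueError(f"no individuals in {str(path)!r} (empty table)")
    return df


def read_genotype_table(path, map_path=None) -> RawGenotypes:
    """Read a whitespace-delimited genotype table (and optional map file).

    Each row is an individual ID followed by ``m`` codes in {0, 1, 2}; row
    order is preserved.  Raises on ragged rows, non-{0,1,2} codes, duplicate
    IDs and empty files.
    """
    df = _read_table(path)
    if df.isna().any().any():
        raise ValueError(f"ragged rows in genotype table {path!r}")
    ids = df.iloc[:, 0].tolist()
    try:
        codes = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric genotype code in {path!r}: {exc}") from exc
    if codes.shape[1] == 0:
        raise ValueError(f"no SNP columns in {path!r}")
    if not np.all(codes == np.round(codes)):
        raise ValueError(f"non-integer genotype code in {path!r}")
    codes = codes.astype(np.int8)
    chrom = pos = None
    snp_ids = [f"snp{j + 1}" for j in range(codes.shape[1])]
    if map_path is not None:
        snp_ids, chrom, pos = read_map(map_path)
        if len(snp_ids) != codes.shape[1]:
            raise ValueError(
                f"map has {len(snp_ids)} SNP but genotype table has "
                f"{codes.shape[1]} columns"
            )
    return RawGenotypes(codes, ids, snp_ids, chrom, pos)


def read_map(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    df = _read_table(path)
    if df.shape[1] < 3:
        raise ValueError(f"map file {path!r} needs columns: snp_id chromosome cM")
    return (
        df.iloc[:, 0].tolist(),
        df.iloc[:, 1].to_numpy(dtype=int),
        df.iloc[:, 2].to_numpy(dtype=float),
    )


def read_phenotype_table(path) -> TraitData:
    df = _read_table(path)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    gen = df.iloc[:, 2].to_numpy(dtype=int) if df.shape[1] > 2 else None
    return TraitData(y=y, individual_ids=df.iloc[:, 0].tolist(), generation=gen)


def write_genotype_table(path, raw: RawGenotypes) -> None:
    with open(path, "w") as fh:
        for i, iid in enumerate(raw.individual_ids):
            fh.write(iid + " " + " ".join(map(str, raw.codes[i])) + "\n")


def write_phenotype_table(path, trait: TraitData) -> None:
    ids = trait.individual_ids or [str(i + 1) for i in range(len(trait.y))]
    with open(path, "w") as fh:
        for i, iid in enumerate(ids):
            line = f"{iid} {_FLOAT_FMT % trait.y[i]}"
            if trait.generation is not None:
                line += f" {trait.generation[i]}"
            fh.write(line + "\n")


def write_map(path, raw: RawGenotypes) -> None:
    if raw.chrom is None:
        raise ValueError("RawGenotypes carries no map")
    with open(path, "w") as fh:
        for sid, c, p in zip(raw.snp_ids, raw.chrom, raw.pos_cm):
            fh.write(f"{sid} {c} {_FLOAT_FMT % p}\n")


def allele_frequency(raw: RawGenotypes) -> np.ndarray:
    """Frequency of the reference allele '1' per SNP: column sum / 2n."""
    return raw.codes.sum(axis=0, dtype=float) / (2.0 * raw.n)


def maf_filter(
    raw: RawGenotypes, threshold: float = 0.05
) -> tuple[RawGenotypes, np.ndarray]:
    """Keep SNP whose minor allele frequency strictly exceeds ``threshold``.

    Returns the filtered genotypes and the retained column indices (into
    the input).  Monomorphic SNP are removed even at threshold 0.
    """
    if not 0.0 <= threshold < 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5)")
    p = allele_frequency(raw)
    keep = np.flatnonzero(np.minimum(p, 1.0 - p) > threshold)
    if keep.size == 0:
        raise ValueError("no SNP remain after MAF filtering")
    return raw.subset_snps(keep), keep


def standardize(raw: RawGenotypes, scheme: str = "empirical") -> GenotypeMatrix:
    """Build the standardized matrix B from genotype codes.

    ``empirical``: centre = column mean, scale = column standard deviation
    (divisor n), so every column has sum 0 and sum of squares n.
    ``theoretical``: centre = 2p, scale = sqrt(2p(1-p)).
    """
    codes = raw.codes.astype(float)
    p = allele_frequency(raw)
    if scheme == "theoretical":
        center = 2.0 * p
        scale = np.sqrt(2.0 * p * (1.0 - p))
    elif scheme == "empirical":
        center = codes.mean(axis=0)
        scale = codes.std(axis=0)  # divisor n
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if np.any(scale == 0.0):
        j = int(np.flatnonzero(scale == 0.0)[0])
        raise ValueError(
            f"SNP {raw.snp_ids[j]!r} is monomorphic (zero scale); "
            "apply maf_filter first"
        )
    B = (codes - center) / scale
    return GenotypeMatrix(
        B=B,
        p=p,
        center=center,
        scale=scale,
        scheme=scheme,
        snp_ids=list(raw.snp_ids),
        chrom=raw.chrom,
        pos_cm=raw.pos_cm,
    )


def apply_training_scaling(raw_val: RawGenotypes, gm: GenotypeMatrix) -> np.ndarray:
    """Standardize validation genotypes with the training centre/scale.

    The SNP set must match the training matrix; no re-centring is done on
    the validation data.
    """
    if raw_val.snp_ids != gm.snp_ids:
        missing = sorted(set(gm.snp_ids) - set(raw_val.snp_ids))
        raise ValueError(
            "validation SNP set does not match training matrix"
            + (f"; missing: {missing[:10]}" if missing else " (order differs)")
        )
    return (raw_val.codes.astype(float) - gm.center) / gm.scale
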