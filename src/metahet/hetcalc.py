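"""Genotype tables and heterozygosity estimation.

Genotypes are biallelic SNP calls coded as alternate-allele counts
{0, 1, 2}, with -1 for missing.  A :class:`GenotypeTable` pairs a metadata
frame (individual, nest, patch, year) with an int8 call matrix.

Heterozygosity is computed per *unit* — a nest, or a population defined as
all genotyped individuals in a patch-year — at two levels:

* observed heterozygosity Ho: fraction of heterozygous calls, averaged over
  loci;
* expected heterozygosity He: Nei & Chesser's small-sample-corrected gene
  diversity per locus,

      He_l = n/(n-1) * (1 - sum_a p_a^2 - Ho_l/(2n)),

  with n the number of individuals with a non-missing call at that locus,
  averaged over loci.  Monomorphic loci contribute He = 0 (they are averaged,
  not skipped).

Inclusion rules mirror the field protocol: individuals with a genotype call
rate below 95% are excluded, and any unit with fewer than two genotyped
individuals is dropped (two is the minimum sample for He).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "GenotypeParseError",
    "read_genotypes",
    "filter_individuals",
    "filter_units",
    "heterozygosity",
]

META_COLUMNS = ["individual_id", "nest_id", "patch_id", "year"]
MISSING = -1


class GenotypeParseError(ValueError):
    """Raised when a genotype file contains malformed calls."""


@dataclass
class GenotypeTable:
    """Individual metadata plus an (n_individuals x n_loci) int8 call matrix."""

    meta: pd.DataFrame
    calls: np.ndarray
    locus_names: list[str]

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.meta), len(self.locus_names)):
            raise ValueError("call matrix shape does not match metadata/loci")

    @property
    def n_individuals(self) -> int:
        return len(self.meta)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def call_rate(self) -> np.ndarray:
        """Per-individual fraction of non-missing calls."""
        if self.n_loci == 0:
            return np.zeros(self.n_individuals)
        return (self.calls != MISSING).mean(axis=1)

    def unit_labels(self, level: str) -> pd.Series:
        """Unit identifier per individual: nest_id, or 'patch:year' string."""
        if level == "nest":
            return self.meta["nest_id"].astype(str)
        if level == "population":
            return self.meta["patch_id"].astype(str) + ":" + self.meta["year"].astype(str)
        raise ValueError(f"level must be 'nest' or 'population', got {level!r}")

    def subset(self, row_mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            meta=self.meta.loc[row_mask].reset_index(drop=True),
            calls=self.calls[row_mask],
            locus_names=list(self.locus_names),
        )

    def subset_loci(self, loci: list[str]) -> "GenotypeTable":
        idx = [self.locus_names.index(l) for l in loci]
        return GenotypeTable(
            meta=self.meta.copy(),
            calls=self.calls[:, idx],
            locus_names=list(loci),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide frame with locus columns; missing as pandas NA."""
        g = pd.DataFrame(self.calls, columns=self.locus_names).astype("Int8")
        g = g.mask(g == MISSING)
        return pd.concat([self.meta.reset_index(drop=True), g], axis=1)


def read_genotypes(path) -> GenotypeTable:
    """Read a wide genotypes.csv (individual_id,nest_id,patch_id,year,locus_*).

    Calls must be 0, 1, 2 or empty/NA; anything else raises
    :class:`GenotypeParseError` naming the offending row and column.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "nest_id": str, "patch_id": str})
    missing_cols = [c for c in META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GenotypeParseError(f"missing metadata columns: {missing_cols}")
    locus_names = [c for c in df.columns if c not in META_COLUMNS]
    raw = df[locus_names].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    # a cell is malformed if it is non-numeric text other than NA, or a
    # number outside {0, 1, 2}
    text_na = df[locus_names].isna().to_numpy()
    bad = (~text_na & np.isnan(raw)) | (
        ~np.isnan(raw) & ~np.isin(raw, (0.0, 1.0, 2.0))
    )
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"invalid genotype code {df[locus_names].iat[i, j]!r} "
            f"at row {i}, column {locus_names[j]!r}"
        )
    calls = np.where(np.isnan(raw), MISSING, raw).astype(np.int8)
    meta = df[META_COLUMNS].copy()
    meta["year"] = meta["year"].astype(int)
    return GenotypeTable(meta=meta, calls=calls, locus_names=locus_names)


def filter_individuals(gt: GenotypeTable, min_call_rate: float = 0.95) -> GenotypeTable:
    """Drop individuals whose fraction of non-missing calls is < min_call_rate."""
    return gt.subset(gt.call_rate() >= min_call_rate)


def filter_units(gt: GenotypeTable, level: str, min_individuals: int = 2) -> GenotypeTable:
    """Drop individuals in units with fewer than ``min_individuals`` genotypes."""
    labels = gt.unit_labels(level)
    counts = labels.map(labels.value_counts())
    return gt.subset((counts >= min_individuals).to_numpy())


def _unit_stats(gt: GenotypeTable, labels: pd.Series):
    """Per-unit per-locus call counts, het counts and alt-allele sums."""
    codes, uniques = pd.factorize(labels, sort=True)
    n_units, L = len(uniques), gt.n_loci
    called = gt.calls != MISSING
    het = gt.calls == 1
    alt = np.where(called, gt.calls, 0)
    n_mat = np.zeros((n_units, L))
    het_mat = np.zeros((n_units, L))
    alt_mat = np.zeros((n_units, L))
    np.add.at(n_mat, codes, called.astype(float))
    np.add.at(het_mat, codes, het.astype(float))
    np.add.at(alt_mat, codes, alt.astype(float))
    return uniques, codes, n_mat, het_mat, alt_mat


def heterozygosity(gt: GenotypeTable, level: str) -> pd.DataFrame:
    """He and Ho per unit (nest or population).

    Returns a frame with columns unit_id, level, year, he, ho,
    n_individuals, n_loci_used.  Loci with fewer than two non-missing calls
    in a unit are excluded from that unit's average; a unit where no locus
    has two calls raises ValueError.
    """
    labels = gt.unit_labels(level)
    uniques, codes, n_mat, het_mat, alt_mat = _unit_stats(gt, labels)

    usable = n_mat >= 2
    if not usable.any(axis=1).all():
        bad = [str(uniques[i]) for i in np.where(~usable.any(axis=1))[0]]
        raise ValueError(f"units with no locus having >=2 calls: {bad}")

    with np.errstate(divide="ignore", invalid="ignore"):
        n = n_mat
        p = alt_mat / (2.0 * n)
        ho_l = het_mat / n
        sum_p2 = p**2 + (1.0 - p) ** 2
        he_l = (n / (n - 1.0)) * (1.0 - sum_p2 - ho_l / (2.0 * n))
    he_l = np.where(usable, he_l, np.nan)
    ho_l = np.where(usable, ho_l, np.nan)
    # numerical guard: the estimator is non-negative in exact arithmetic
    he = np.clip(np.nanmean(he_l, axis=1), 0.0, 1.0)
    ho = np.nanmean(ho_l, axis=1)

    counts = pd.Series(codes).value_counts().sort_index()
    meta = gt.meta.copy()
    meta["_unit"] = labels.to_numpy()
    # groupby(sort=True) index order matches factorize(sort=True) uniques
    years = meta.groupby("_unit", sort=True)["year"].first()
    return pd.DataFrame(
        {
            "unit_id": [str(u) for u in uniques],
            "level": level,
            "year": years.to_numpy(),
            "he": he,
            "ho": ho,
            "n_individuals": counts.to_numpy(),
            "n_loci_used": usable.sum(axis=1),
        }
    )
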