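"""The genotype panel: the universal in-memory container of this package.

A :class:`GenotypePanel` holds a diploid biallelic SNP matrix coded as
alternate-allele dosage (0, 1, 2, with :data:`MISSING` = -1 for no-calls),
together with per-sample population labels and per-SNP locus metadata.
Every analysis module consumes and returns this container.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel genotype code for a missing (uncalled) genotype.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclasses.dataclass
class GenotypePanel:
    """Diploid biallelic SNP genotypes for a set of labelled individuals.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``genotypes``).
    populations
        Mapping sample id -> population label, stored as a pandas Series
        indexed by sample id in panel order.
    loci
        DataFrame with one row per SNP (columns of ``genotypes``) and columns
        ``locus_id`` (the ddRAD tag the SNP belongs to), ``snp_id`` (e.g.
        ``"23095_6"``), ``chrom`` and ``pos`` (1-based).
    genotypes
        ``(n_samples, n_loci)`` int8 array of alt-allele dosages; ``-1``
        encodes a missing call.
    """

    samples: list[str]
    populations: pd.Series
    loci: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise PanelError("genotypes must be a 2-D (samples x loci) array")
        if self.genotypes.shape[0] != len(self.samples):
            raise PanelError(
                f"{len(self.samples)} samples but genotype matrix has "
                f"{self.genotypes.shape[0]} rows"
            )
        if self.genotypes.shape[1] != len(self.loci):
            raise PanelError(
                f"{len(self.loci)} locus records but genotype matrix has "
                f"{self.genotypes.shape[1]} columns"
            )
        codes = np.unique(self.genotypes)
        bad = set(codes.tolist()) - _VALID_CODES
        if bad:
            raise PanelError(f"invalid genotype codes {sorted(bad)}; expected -1/0/1/2")
        self.populations = pd.Series(self.populations)
        missing_pop = [s for s in self.samples if s not in self.populations.index]
        if missing_pop:
            raise PanelError(f"samples without a population label: {missing_pop[:5]}")
        self.populations = self.populations.loc[self.samples].astype(str)
        self.loci = pd.DataFrame(self.loci).reset_index(drop=True)
        required = {"locus_id", "snp_id", "chrom", "pos"}
        if not required.issubset(self.loci.columns):
            raise PanelError(f"loci table must have columns {sorted(required)}")
        if (self.loci["locus_id"].astype(str) == "").any():
            raise PanelError("empty locus_id")
        dup = self.loci.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise PanelError(
                f"duplicate (chrom, pos): {self.loci.loc[dup, 'snp_id'].tolist()[:5]}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_names(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations.tolist()))

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each population's individuals."""
        labels = self.populations.to_numpy()
        return {p: np.flatnonzero(labels == p) for p in self.pop_names}

    @property
    def snp_ids(self) -> np.ndarray:
        return self.loci["snp_id"].to_numpy(dtype=object)

    # -- views -----------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        """Boolean (samples x loci) mask, True where the call is missing."""
        return self.genotypes == MISSING

    def dosage(self) -> np.ndarray:
        """Float dosage matrix with missing calls as NaN."""
        d = self.genotypes.astype(float)
        d[self.genotypes == MISSING] = np.nan
        return d

    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            samples=self.samples,
            populations=self.populations.copy(),
            loci=self.loci.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[:, index].copy(),
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        samples = [self.samples[i] for i in index]
        return GenotypePanel(
            samples=samples,
            populations=self.populations.loc[samples].copy(),
            loci=self.loci.copy(),
            genotypes=self.genotypes[index, :].copy(),
        )

    def select_populations(self, pops: Iterable[str]) -> "GenotypePanel":
        pops = set(pops)
        idx = np.flatnonzero(self.populations.isin(pops).to_numpy())
        return self.subset_samples(idx)

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.samples == other.samples
            and self.populations.equals(other.populations)
            and len(self.loci) == len(other.loci)
            and self.loci[["locus_id", "snp_id", "chrom"]]
            .astype(str)
            .equals(other.loci[["locus_id", "snp_id", "chrom"]].astype(str))
            and np.array_equal(
                self.loci["pos"].to_numpy(int), other.loci["pos"].to_numpy(int)
            )
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypePanel({self.n_samples} samples, {self.n_loci} SNPs, "
            f"{len(self.pop_names)} populations)"
        )
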