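"""Core in-memory containers shared by every analysis stage.

The common currency is :class:`GenotypeDataset` — an ordered table of biallelic
SNP sites with a diploid dosage matrix — plus :class:`SampleMetadata`, a thin
wrapper over a pandas DataFrame mapping each sample to its analysis group
(P1/P2/P3/outgroup), deme, coordinates and collection year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid dosage or depth value.
MISSING = -1


@dataclass
class GenotypeDataset:
    """Biallelic SNP sites and a diploid allele-dosage matrix.

    Attributes
    ----------
    chrom : array of str, one label per site
    pos : int array, 1-based positions, strictly increasing within a chromosome
    ref, alt : arrays of single-base strings
    ancestral : array of single-base strings, ``"."`` when unknown
    qual : float array, phred-scaled site quality (NaN when absent)
    genotypes : (n_sites, n_samples) int8 matrix of alt-allele dosage
        in {0, 1, 2}, with :data:`MISSING` (−1) for uncalled genotypes
    depth : (n_sites, n_samples) int matrix of per-genotype read depth,
        :data:`MISSING` when unknown
    samples : list of sample identifiers (column order of ``genotypes``)
    is_biallelic : bool array; False marks records flagged for exclusion
        (multiallelic or indel) that were read but must not enter analyses
    callable_length : mapping window→bp used as a π/dxy denominator; when a
        window is absent the window length itself is used
    region_length : total bp of the simulated/called region (0 = unknown)
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray
    qual: np.ndarray
    genotypes: np.ndarray
    depth: np.ndarray
    samples: list[str]
    is_biallelic: np.ndarray = None  # type: ignore[assignment]
    callable_length: dict = field(default_factory=dict)
    region_length: int = 0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.qual = np.asarray(self.qual, dtype=float)
        if self.is_biallelic is None:
            self.is_biallelic = np.ones(len(self.pos), dtype=bool)
        if self.depth is None:
            self.depth = np.full(self.genotypes.shape, MISSING, dtype=np.int32)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in dataset: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def take_sites(self, mask_or_index) -> "GenotypeDataset":
        """Subset sites, preserving sample columns and metadata."""
        idx = np.asarray(mask_or_index)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ancestral=self.ancestral[idx],
            qual=self.qual[idx],
            genotypes=self.genotypes[idx],
            depth=self.depth[idx],
            is_biallelic=self.is_biallelic[idx],
        )

    def alt_frequency(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing chromosomes.

        Returns NaN at sites where no genotype is called.
        """
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        called = g != MISSING
        n_chrom = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)


class SampleMetadata:
    """Sample → (group, deme, latitude, longitude, year) mapping.

    Backed by a DataFrame with columns ``sample, group, deme, lat, lon, year``
    and optional extras (e.g. truth tracts from the simulator).
    """

    COLUMNS = ["sample", "group", "deme", "lat", "lon", "year"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        bad_lat = table["lat"].dropna().abs() > 90
        bad_lon = table["lon"].dropna().abs() > 180
        if bad_lat.any() or bad_lon.any():
            raise ValueError("latitude/longitude out of range")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def group(self, label: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == label, "sample"])

    def deme(self, label: str) -> list[str]:
        return list(self.table.loc[self.table["deme"] == label, "sample"])

    @property
    def demes(self) -> list[str]:
        vals = self.table["deme"].dropna()
        return sorted(v for v in vals.unique() if v != "")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Simulation scenario configuration


@dataclass(frozen=True)
class SimConfig:
    """Size/seed plumbing for every generator."""

    n_individuals: int
    n_sites: int
    region_length: int
    seed: int = 0
    callable_length_per_window: int = 0  # 0 → use window length

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_sites < 0 or self.region_length < 1:
            raise ValueError("sizes must be positive")
        if self.n_sites > self.region_length:
            raise ValueError("n_sites exceeds region_length")


@dataclass(frozen=True)
class IntrogressionScenario:
    """Donor-species haplotype tracts injected into designated P2 samples.

    ``divergence`` is the per-site probability of a fixed difference between
    the donor (P3) and recipient (P1/P2) pools; tract intervals are 0-based
    half-open bp on the simulated region.
    """

    divergence: float
    admixed_sample_ids: tuple = ()
    tract_intervals: tuple = ()  # tuple of tuples of (start, end) per admixed sample
    donor_tract_ploidy: int = 2
    n_p1: int = 13
    n_p2: int = 16
    n_p3: int = 25
    n_outgroup: int = 7

    def __post_init__(self):
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.donor_tract_ploidy not in (1, 2):
            raise ValueError("donor_tract_ploidy must be 1 or 2")
        for tracts in self.tract_intervals:
            ivs = sorted(tracts)
            for s, e in ivs:
                if s < 0 or e <= s:
                    raise ValueError("tract intervals must be non-negative, non-empty")
            for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError("overlapping tracts in one sample")


@dataclass(frozen=True)
class DemeScenario:
    """Balding–Nichols demes with distance-dependent differentiation."""

    n_demes: int
    deme_coords: tuple  # ((lat, lon), ...) per deme
    F_of_distance: Callable[[float], float]
    n_per_deme: int

    def __post_init__(self):
        if self.n_demes < 2:
            raise ValueError("need at least 2 demes")
        if len(self.deme_coords) != self.n_demes:
            raise ValueError("one coordinate pair per deme required")
        for lat, lon in self.deme_coords:
            if abs(lat) > 90 or abs(lon) > 180:
                raise ValueError("invalid deme coordinates")
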