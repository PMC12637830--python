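"""Core data model, readers and cohort construction.

Coordinates are 1-based inclusive throughout, matching VCF. Genotypes are
stored as alternate-allele counts in {0, 1, 2} with ``MISSING`` (-1) as the
sentinel for uncalled genotypes; missing calls are excluded from every
allele-frequency denominator, never treated as reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

#: Columns a sample metadata table must carry.
SAMPLE_COLUMNS = [
    "sample_id",
    "location",
    "year",
    "sex",
    "median_coverage",
    "genome_fraction",
    "contamination_pct",
]

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive genomic interval on a single contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse ``"contig:start-end"``; thousands separators are accepted,
        e.g. ``"2L:20,528,089-42,165,182"``.
        """
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {text!r}")
        contig, start, end = m.groups()
        return cls(contig, int(start.replace(",", "")), int(end.replace(",", "")))

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end


@dataclass
class VariantDataset:
    """Biallelic SNP genotypes for one contig region.

    Parameters
    ----------
    contig
        Contig / chromosome-arm name.
    positions
        1-based positions, strictly increasing.
    ref, alt
        Single-base reference and alternate alleles.
    genotypes
        ``(n_samples, n_variants)`` alternate-allele counts in
        {0, 1, 2, MISSING}.
    sample_ids
        Ordered sample identifiers, one per genotype row.
    haplotypes
        Optional ``(2 * n_samples, n_variants)`` binary matrix of phased
        alleles; rows ``2i`` and ``2i + 1`` belong to sample ``i`` and sum
        to its genotype row.
    """

    contig: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    sample_ids: list[str]
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        self.sample_ids = list(self.sample_ids)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, m = self.genotypes.shape if self.genotypes.size else (len(self.sample_ids), 0)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x variants matrix")
        if self.genotypes.shape[0] != len(self.sample_ids):
            raise ValueError("genotype rows must match sample_ids")
        if self.genotypes.shape[1] != self.positions.size:
            raise ValueError("genotype columns must match positions")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype values must be in {0, 1, 2, MISSING}")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (2 * n, m):
                raise ValueError("haplotype matrix must be (2*samples) x variants")
            collapsed = self.haplotypes[0::2] + self.haplotypes[1::2]
            called = self.genotypes != MISSING
            if not np.array_equal(collapsed[called], self.genotypes[called]):
                raise ValueError("haplotypes do not collapse to genotypes")

    # -- basic properties ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return int(self.positions.size)

    def is_phased(self) -> bool:
        return self.haplotypes is not None

    # -- counting --------------------------------------------------------
    def allele_counts(self, sample_indices: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (alt-allele copies, called allele copies)."""
        g = self.genotypes if sample_indices is None else self.genotypes[sample_indices]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), (2 * called.sum(axis=0)).astype(np.int64)

    def minor_allele_frequency(self) -> np.ndarray:
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return (self.genotypes == MISSING).mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "VariantDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            positions=self.positions[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[:, index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "VariantDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        hap = None
        if self.haplotypes is not None:
            hap_rows = np.stack([2 * index, 2 * index + 1], axis=1).ravel()
            hap = self.haplotypes[hap_rows]
        return replace(
            self,
            genotypes=self.genotypes[index],
            sample_ids=[self.sample_ids[i] for i in index],
            haplotypes=hap,
        )

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample {exc.args[0]!r} not in dataset") from exc

    def restrict(self, region: RegionSpec) -> "VariantDataset":
        if region.contig != self.contig:
            return self.take_variants(np.zeros(self.n_variants, dtype=bool))
        mask = (self.positions >= region.start) & (self.positions <= region.end)
        return self.take_variants(mask)


class VcfParseError(RuntimeError):
    """Raised when a VCF record cannot be interpreted."""


def load_variant_data(vcf_path: str | Path, region: RegionSpec) -> VariantDataset:
    """Load biallelic SNPs inside ``region`` from a VCF file.

    Multi-allelic records and non-SNP alleles are excluded. Genotypes are
    encoded as alt-allele counts; a genotype with any uncalled allele is
    MISSING. If every retained record is phased for every sample the phased
    haplotype matrix is populated as well. An empty region yields an empty
    dataset, not an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)

    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    geno_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True

    try:
        for v in vcf:
            if v.CHROM != region.contig:
                continue
            if v.POS < region.start or v.POS > region.end:
                continue
            if len(v.ALT) != 1:
                continue  # multi-allelic excluded
            if len(v.REF) != 1 or len(v.ALT[0]) != 1:
                continue  # indels excluded
            gts = np.asarray(v.genotype.array())
            a = gts[:, 0]
            b = gts[:, 1]
            phased = gts[:, 2].astype(bool)
            called = (a >= 0) & (b >= 0)
            col = np.where(called, a + b, MISSING).astype(np.int8)
            geno_cols.append(col)
            if all_phased and called.all() and phased.all():
                hap = np.empty(2 * n, dtype=np.int8)
                hap[0::2] = a
                hap[1::2] = b
                hap_cols.append(hap)
            else:
                all_phased = False
            positions.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0])
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {vcf_path}: {exc}") from exc
    finally:
        vcf.close()

    m = len(positions)
    genotypes = (
        np.stack(geno_cols, axis=1) if m else np.zeros((n, 0), dtype=np.int8)
    )
    haplotypes = None
    if m and all_phased:
        haplotypes = np.stack(hap_cols, axis=1)
    return VariantDataset(
        contig=region.contig,
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype="U1"),
        alt=np.array(alts, dtype="U1"),
        genotypes=genotypes,
        sample_ids=sample_ids,
        haplotypes=haplotypes,
    )


# ---------------------------------------------------------------------------
# Sample metadata and QC
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV and validate its schema."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "location": str, "sex": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")
    if ((df["genome_fraction"] < 0) | (df["genome_fraction"] > 1)).any():
        raise ValueError("genome_fraction must be in [0, 1]")
    if (df["contamination_pct"] < 0).any():
        raise ValueError("contamination_pct must be >= 0")
    return df


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def apply_sample_qc(
    samples: pd.DataFrame,
    min_coverage: float = 10.0,
    min_genome_fraction: float = 0.5,
    max_contamination: float = 4.5,
) -> pd.DataFrame:
    """Filter samples on sequencing QC.

    Retains samples with median coverage at or above ``min_coverage``,
    genome fraction strictly above ``min_genome_fraction`` and
    cross-contamination strictly below ``max_contamination`` percent (a
    sample at exactly the contamination threshold is excluded).
    """
    if min(min_coverage, min_genome_fraction, max_contamination) < 0:
        raise ValueError("QC thresholds must be non-negative")
    keep = (
        (samples["median_coverage"] >= min_coverage)
        & (samples["genome_fraction"] > min_genome_fraction)
        & (samples["contamination_pct"] < max_contamination)
    )
    return samples.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cohort:
    cohort_id: str
    location: str
    year: int
    sample_ids: tuple[str, ...]
    eligible: bool

    @property
    def size(self) -> int:
        return len(self.sample_ids)


@dataclass
class CohortSet:
    """Population cohorts keyed by (location, year).

    Cohorts below the minimum size are retained for listing but flagged
    ineligible for statistics.
    """

    cohorts: list[Cohort] = field(default_factory=list)
    min_size: int = 10

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)

    def __getitem__(self, cohort_id: str) -> Cohort:
        for c in self.cohorts:
            if c.cohort_id == cohort_id:
                return c
        raise KeyError(cohort_id)

    def eligible(self) -> list[Cohort]:
        return [c for c in self.cohorts if c.eligible]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort_id": [c.cohort_id for c in self.cohorts],
                "location": [c.location for c in self.cohorts],
                "year": [c.year for c in self.cohorts],
                "n_samples": [c.size for c in self.cohorts],
                "eligible": [c.eligible for c in self.cohorts],
            }
        )


def build_cohorts(samples: pd.DataFrame, min_size: int = 10) -> CohortSet:
    """Group samples into (location, year) population cohorts.

    Every grouping is returned; those with fewer than ``min_size`` members
    are flagged ``eligible=False`` and are skipped by cohort statistics.
    """
    if samples["location"].isna().any() or samples["year"].isna().any():
        raise ValueError("location and year must be populated for all samples")
    cohorts = []
    grouped = samples.groupby(["location", "year"], sort=True)
    for (location, year), sub in grouped:
        cid = f"{location}_{int(year)}".replace(" ", "_")
        cohorts.append(
            Cohort(
                cohort_id=cid,
                location=str(location),
                year=int(year),
                sample_ids=tuple(sub["sample_id"]),
                eligible=len(sub) >= min_size,
            )
        )
    return CohortSet(cohorts=cohorts, min_size=min_size)


# ---------------------------------------------------------------------------
# SNP selection
# ---------------------------------------------------------------------------

def select_snps(
    ds: VariantDataset,
    min_maf: float = 0.002,
    max_missing: float = 0.0,
    target_count: int = 100_000,
) -> VariantDataset:
    """Select analysis SNPs: MAF strictly above ``min_maf``, missingness at
    most ``max_missing``, evenly thinned to ``target_count`` variants.

    Thinning is deterministic index striding (variant ``i`` of the output is
    input variant ``floor(i * m / target_count)`` among the ``m`` passing
    variants), so repeat runs select identical sites without a seed.
    """
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")
    if target_count <= 0:
        raise ValueError("target_count must be positive")
    maf = ds.minor_allele_frequency()
    with np.errstate(invalid="ignore"):
        passing = (maf > min_maf) & (ds.missing_fraction() <= max_missing)
    passing &= ~np.isnan(maf)
    idx = np.flatnonzero(passing)
    if idx.size > target_count:
        stride = (np.arange(target_count) * idx.size) // target_count
        idx = idx[stride]
    return ds.take_variants(idx)
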