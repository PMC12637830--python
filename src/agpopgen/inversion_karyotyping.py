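"""Inversion karyotyping from tag SNPs.

Chromosomal inversions (2La, 2Rb, ...) suppress recombination in
heterozygotes, so SNPs inside the inverted region stay tightly correlated
with orientation. A sample's karyotype — 0 standard homozygote, 1
heterozygote, 2 inverted homozygote — is estimated as the rounded mean
count of inversion-associated alleles across the tag panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from agpopgen.core_io import MISSING, CohortSet, RegionSpec, VariantDataset

KARYOTYPE_LABELS = {0: "standard_hom", 1: "heterozygote", 2: "inverted_hom"}


@dataclass
class TagSnpPanel:
    """Tag SNPs for one inversion; ``inverted_allele`` is the base carried
    on the inverted arrangement at each tag."""

    inversion: str
    region: RegionSpec
    positions: np.ndarray
    inverted_allele: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if np.unique(self.positions).size != self.positions.size:
            raise ValueError("tag positions must be unique")
        inside = (self.positions >= self.region.start) & (
            self.positions <= self.region.end
        )
        if not inside.all():
            raise ValueError("tag SNPs must lie inside the inversion region")

    def __len__(self) -> int:
        return int(self.positions.size)

    @classmethod
    def from_tsv(cls, path: str | Path) -> dict[str, "TagSnpPanel"]:
        """Read a tag-SNP TSV (inversion, contig, position, inverted_allele,
        region_start, region_end) into one panel per inversion."""
        df = pd.read_csv(path, sep="\t")
        panels = {}
        for inv, sub in df.groupby("inversion"):
            region = RegionSpec(
                str(sub["contig"].iloc[0]),
                int(sub["region_start"].iloc[0]),
                int(sub["region_end"].iloc[0]),
            )
            panels[str(inv)] = cls(
                inversion=str(inv),
                region=region,
                positions=sub["position"].to_numpy(),
                inverted_allele=sub["inverted_allele"].to_numpy(),
            )
        return panels


@dataclass
class KaryotypeCalls:
    """Per-sample karyotype estimates for one inversion. ``score`` is the
    mean inverted-allele count over usable tags (NaN when no tag was
    usable); ``karyotype`` rounds the score half-up, -1 for uncalled."""

    inversion: str
    sample_ids: list[str]
    score: np.ndarray
    karyotype: np.ndarray
    n_tags_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "inversion": self.inversion,
                "score": self.score,
                "karyotype": self.karyotype,
                "n_tags_used": self.n_tags_used,
            }
        )


def karyotype_individuals(
    ds: VariantDataset, panel: TagSnpPanel, min_tags: int = 1
) -> KaryotypeCalls:
    """Estimate karyotypes as the rounded mean inversion-allele count.

    Missing tag genotypes reduce ``n_tags_used`` rather than being imputed;
    samples with fewer than ``min_tags`` usable tags are left uncalled
    (karyotype -1). A score at exactly .5 rounds up.
    """
    pos_to_col = {int(p): j for j, p in enumerate(ds.positions)}
    cols, inv_is_alt = [], []
    for k in range(len(panel)):
        j = pos_to_col.get(int(panel.positions[k]))
        if j is None or ds.contig != panel.region.contig:
            continue
        if panel.inverted_allele[k] == ds.alt[j]:
            inv_is_alt.append(True)
        elif panel.inverted_allele[k] == ds.ref[j]:
            inv_is_alt.append(False)
        else:
            continue
        cols.append(j)
    if not cols:
        raise ValueError(
            f"no usable tag SNPs for inversion {panel.inversion!r} in dataset"
        )
    g = ds.genotypes[:, cols].astype(np.float64)
    called = g != MISSING
    inv_count = np.where(np.asarray(inv_is_alt)[None, :], g, 2 - g)
    inv_count[~called] = np.nan
    n_used = called.sum(axis=1)
    import warnings

    with warnings.catch_warnings():
        # samples with zero usable tags produce an all-NaN row: intended
        warnings.simplefilter("ignore", RuntimeWarning)
        score = np.nanmean(np.where(called, inv_count, np.nan), axis=1)
    score[n_used < min_tags] = np.nan
    karyotype = np.where(np.isnan(score), -1, np.floor(score + 0.5)).astype(np.int8)
    return KaryotypeCalls(
        inversion=panel.inversion,
        sample_ids=list(ds.sample_ids),
        score=score,
        karyotype=karyotype,
        n_tags_used=n_used,
    )


def karyotype_frequencies(
    calls: KaryotypeCalls, cohorts: CohortSet
) -> pd.DataFrame:
    """Percentage of each karyotype class per cohort, over karyotyped
    members only. Cohorts with no karyotyped member are omitted with a
    warning. Rows sum to 100 within floating-point rounding."""
    import warnings

    by_sample = dict(zip(calls.sample_ids, calls.karyotype))
    rows = []
    for cohort in cohorts:
        ks = [by_sample.get(s, -1) for s in cohort.sample_ids]
        ks = [k for k in ks if k >= 0]
        if not ks:
            warnings.warn(
                f"cohort {cohort.cohort_id}: no karyotyped members for "
                f"{calls.inversion}; row omitted"
            )
            continue
        total = len(ks)
        rows.append(
            {
                "cohort_id": cohort.cohort_id,
                "inversion": calls.inversion,
                "pct_standard_hom": 100.0 * ks.count(0) / total,
                "pct_heterozygote": 100.0 * ks.count(1) / total,
                "pct_inverted_hom": 100.0 * ks.count(2) / total,
                "n_karyotyped": total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cohort_id",
            "inversion",
            "pct_standard_hom",
            "pct_heterozygote",
            "pct_inverted_hom",
            "n_karyotyped",
        ],
    )


def allele_freq_by_karyotype(
    ds: VariantDataset,
    position: int,
    calls: KaryotypeCalls,
    cohorts: CohortSet | None = None,
) -> pd.DataFrame:
    """Alt-allele frequency at one substitution site, stratified by
    karyotype class (and cohort when given). Strata with no called allele
    copies get a null frequency."""
    j = np.flatnonzero(ds.positions == position)
    if j.size != 1:
        raise ValueError(f"substitution site {position} not present in dataset")
    g = ds.genotypes[:, j[0]]
    by_sample = dict(zip(calls.sample_ids, calls.karyotype))
    groups: list[tuple[str, list[str]]]
    if cohorts is None:
        groups = [("all", list(ds.sample_ids))]
    else:
        groups = [(c.cohort_id, list(c.sample_ids)) for c in cohorts]
    sample_pos = {s: i for i, s in enumerate(ds.sample_ids)}
    rows = []
    for cohort_id, members in groups:
        for k in (0, 1, 2):
            idx = [
                sample_pos[s]
                for s in members
                if s in sample_pos and by_sample.get(s, -1) == k
            ]
            sub = g[idx]
            called = sub[sub != MISSING]
            freq = float(called.sum() / (2 * called.size)) if called.size else None
            rows.append(
                {
                    "cohort_id": cohort_id,
                    "karyotype": k,
                    "karyotype_label": KARYOTYPE_LABELS[k],
                    "frequency": freq,
                    "n_samples": len(idx),
                }
            )
    out = pd.DataFrame(
        rows, columns=["cohort_id", "karyotype", "karyotype_label", "frequency", "n_samples"]
    )
    return out[out["n_samples"] > 0].reset_index(drop=True)
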