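"""Insecticide-resistance allele frequency tables.

Amino-acid substitution frequencies are tabulated per cohort at target-site
and metabolic resistance loci (Vgsc, Rdl, Ace1, Gste2 and the P450 /
carboxylesterase CNV clusters). Effect annotations are consumed from a
TSV — the package does not predict coding effects. Nucleotide variants
sharing an amino-acid label within a gene are pooled by summing alt-allele
copies, matching amino-acid-level reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from agpopgen.core_io import MISSING, CohortSet, VariantDataset

#: Default surveillance loci: target-site genes and CNV gene clusters.
DEFAULT_LOCI = {
    "Vgsc": ["AGAP004707"],
    "Rdl": ["AGAP006028"],
    "Ace1": ["AGAP001356"],
    "Gste2": ["AGAP009194"],
    "Cyp6aa/p_cluster": [f"AGAP00{i}" for i in range(2862, 2871)],
    "Cyp9k1": ["AGAP000818"],
    "Cyp6m/z_cluster": [f"AGAP00{i}" for i in range(8212, 8220)],
    "Coeae1f": ["AGAP006228"],
    "Coeae2g-7g": [f"AGAP00{i}" for i in range(6723, 6729)],
}


@dataclass
class LocusPanel:
    """Named gene sets under surveillance; ``genes`` maps a locus name to
    its AGAP gene identifiers."""

    genes: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_LOCI))

    def __post_init__(self) -> None:
        all_ids = [g for ids in self.genes.values() for g in ids]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("gene_ids must be unique across loci")

    def gene_ids(self) -> set[str]:
        return {g for ids in self.genes.values() for g in ids}


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read an effect-annotation TSV (contig, position, alt, gene_id,
    aa_change, effect; optional gene_name)."""
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "position", "alt", "gene_id", "aa_change", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if df.duplicated(subset=["contig", "position", "alt"]).any():
        raise ValueError("annotation (position, alt) keys must be unique")
    return df


def aa_substitution_frequencies(
    datasets: VariantDataset | list[VariantDataset],
    annotation: pd.DataFrame,
    cohorts: CohortSet,
    panel: LocusPanel | None = None,
) -> pd.DataFrame:
    """Per-cohort allele frequencies of non-synonymous substitutions in
    panel genes.

    For each annotated non-synonymous variant found in the data, the
    frequency in a cohort is alt copies / called copies; variants sharing
    (gene_id, aa_change) are pooled by summing alt and called copies.
    Only statistics-eligible cohorts are tabulated. Long format:
    gene_id, aa_change, cohort_id, frequency, n_alt, n_called.
    """
    panel = panel or LocusPanel()
    if isinstance(datasets, VariantDataset):
        datasets = [datasets]
    ann = annotation[annotation["effect"] == "non-synonymous"]
    ann = ann[ann["gene_id"].isin(panel.gene_ids())]

    # accumulate copies per (gene, aa_change, cohort)
    acc: dict[tuple[str, str, str], list[int]] = {}
    for ds in datasets:
        sub = ann[ann["contig"] == ds.contig]
        pos_to_col = {int(p): j for j, p in enumerate(ds.positions)}
        for _, row in sub.iterrows():
            j = pos_to_col.get(int(row["position"]))
            if j is None or ds.alt[j] != row["alt"]:
                continue
            g = ds.genotypes[:, j]
            sample_pos = {s: i for i, s in enumerate(ds.sample_ids)}
            for cohort in cohorts.eligible():
                idx = [sample_pos[s] for s in cohort.sample_ids if s in sample_pos]
                sub_g = g[idx]
                called = sub_g[sub_g != MISSING]
                key = (str(row["gene_id"]), str(row["aa_change"]), cohort.cohort_id)
                tally = acc.setdefault(key, [0, 0])
                tally[0] += int(called.sum())
                tally[1] += int(2 * called.size)
    rows = []
    for (gene_id, aa_change, cohort_id), (n_alt, n_called) in sorted(acc.items()):
        freq = n_alt / n_called if n_called else np.nan
        if n_called and not 0 <= freq <= 1:  # pragma: no cover - invariant
            raise AssertionError("pooled frequency outside [0, 1]")
        rows.append(
            {
                "gene_id": gene_id,
                "aa_change": aa_change,
                "cohort_id": cohort_id,
                "frequency": freq,
                "n_alt": n_alt,
                "n_called": n_called,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "aa_change", "cohort_id", "frequency", "n_alt", "n_called"]
    )


def filter_reportable(table: pd.DataFrame, min_freq: float = 0.05) -> pd.DataFrame:
    """Keep substitutions whose frequency strictly exceeds ``min_freq`` in
    at least one cohort; all cohort rows of a retained substitution are
    kept so tables stay rectangular. A substitution at exactly the
    threshold everywhere is dropped."""
    if table.empty:
        return table
    key = ["gene_id", "aa_change"] if "aa_change" in table.columns else ["gene_id"]
    peak = table.groupby(key)["frequency"].transform("max")
    return table.loc[peak > min_freq].reset_index(drop=True)
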