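"""Species assignment from ancestry-informative markers (AIMs).

Two marker panels are used in sequence: a large panel separating the
*An. gambiae* / *An. coluzzii* sister pair from the more divergent
*An. arabiensis*, and a second panel separating *gambiae* from *coluzzii*.
A sample is scored by the fraction of its called allele copies at panel
sites that match the scored taxon's diagnostic allele; thresholds are
strict inequalities, so a fraction sitting exactly on a threshold falls to
the unlabelled ("intermediate") side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from agpopgen.core_io import MISSING, VariantDataset

ARAB_FRACTION_MIN = 0.6  # arabiensis-like fraction above which -> arabiensis
GAMB_FRACTION_MAX = 0.12  # coluzzii-like fraction below which -> gambiae
COLU_FRACTION_MIN = 0.9  # coluzzii-like fraction above which -> coluzzii


@dataclass
class AimPanel:
    """A panel of diagnostic markers for one taxon contrast.

    ``diagnostic_allele``/``background_allele`` are the bases carried by the
    scored taxon and the contrasting taxon respectively, per marker.
    """

    name: str
    contig: np.ndarray
    positions: np.ndarray
    diagnostic_allele: np.ndarray
    background_allele: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        key = list(zip(np.asarray(self.contig), self.positions))
        if len(set(key)) != len(key):
            raise ValueError("panel markers must be unique")

    def __len__(self) -> int:
        return int(self.positions.size)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str) -> "AimPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(
            name=name,
            contig=df["contig"].to_numpy(),
            positions=df["position"].to_numpy(),
            diagnostic_allele=df["diagnostic_allele"].to_numpy(),
            background_allele=df["background_allele"].to_numpy(),
        )


@dataclass
class AimFractions:
    """Per-sample diagnostic-allele fraction for one panel; NaN when no
    usable site was found (sample unclassifiable on this panel)."""

    panel: str
    sample_ids: list[str]
    fraction: np.ndarray
    n_sites_used: np.ndarray


def aim_fractions(ds: VariantDataset, panel: AimPanel) -> AimFractions:
    """Fraction of diagnostic-taxon allele copies over called copies at
    panel sites. Sites with a missing genotype are skipped per sample;
    markers whose alleles do not match the dataset's ref/alt pair are
    ignored."""
    pos_to_col = {(ds.contig, int(p)): j for j, p in enumerate(ds.positions)}
    cols, diag_is_alt = [], []
    for k in range(len(panel)):
        key = (str(panel.contig[k]), int(panel.positions[k]))
        j = pos_to_col.get(key)
        if j is None:
            continue
        if panel.diagnostic_allele[k] == ds.alt[j] and panel.background_allele[k] == ds.ref[j]:
            diag_is_alt.append(True)
        elif panel.diagnostic_allele[k] == ds.ref[j] and panel.background_allele[k] == ds.alt[j]:
            diag_is_alt.append(False)
        else:
            continue
        cols.append(j)
    if not cols:
        raise ValueError(f"panel {panel.name!r} shares no usable sites with dataset")
    g = ds.genotypes[:, cols]
    diag_is_alt = np.asarray(diag_is_alt)
    called = g != MISSING
    diag_copies = np.where(diag_is_alt[None, :], g, 2 - g)
    diag_total = np.where(called, diag_copies, 0).sum(axis=1)
    copies_total = (2 * called).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(copies_total > 0, diag_total / np.maximum(copies_total, 1), np.nan)
    return AimFractions(
        panel=panel.name,
        sample_ids=list(ds.sample_ids),
        fraction=frac,
        n_sites_used=called.sum(axis=1),
    )


def classify_taxon(
    f_arab: float,
    f_col: float,
    arab_min: float = ARAB_FRACTION_MIN,
    gamb_max: float = GAMB_FRACTION_MAX,
    col_min: float = COLU_FRACTION_MIN,
) -> str:
    """Classify one sample from its two panel fractions.

    ``arabiensis`` when the arabiensis-like fraction exceeds ``arab_min``;
    otherwise ``gambiae`` below ``gamb_max`` coluzzii-like calls,
    ``coluzzii`` above ``col_min``, ``intermediate`` in between, and
    ``unassigned`` when either fraction is undefined.
    """
    if math.isnan(f_arab) or math.isnan(f_col):
        return "unassigned"
    if f_arab > arab_min:
        return "arabiensis"
    if f_col < gamb_max:
        return "gambiae"
    if f_col > col_min:
        return "coluzzii"
    return "intermediate"


def assign_taxa(
    ds: VariantDataset,
    arab_panel: AimPanel,
    colu_panel: AimPanel,
    arab_min: float = ARAB_FRACTION_MIN,
    gamb_max: float = GAMB_FRACTION_MAX,
    col_min: float = COLU_FRACTION_MIN,
) -> pd.DataFrame:
    """Score both panels and classify every sample.

    Returns a table with columns sample_id, f_arab, f_col, n_sites_arab,
    n_sites_col and taxon.
    """
    fr_arab = aim_fractions(ds, arab_panel)
    fr_col = aim_fractions(ds, colu_panel)
    taxa = [
        classify_taxon(fa, fc, arab_min, gamb_max, col_min)
        for fa, fc in zip(fr_arab.fraction, fr_col.fraction)
    ]
    return pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "f_arab": fr_arab.fraction,
            "f_col": fr_col.fraction,
            "n_sites_arab": fr_arab.n_sites_used,
            "n_sites_col": fr_col.n_sites_used,
            "taxon": taxa,
        }
    )
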