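"""Selection scans: H12 haplotype homozygosity and diplotype clustering.

H12 pools the two most frequent distinct haplotypes in a window before
summing squared frequencies — with sorted frequencies p1 >= p2 >= ...,
H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2 — which makes it sensitive to both
hard sweeps (one common haplotype) and soft sweeps (two). The window size
(in SNPs) is calibrated on neutral expectations: the smallest size whose
genome-wide 95th-percentile H12 drops below 0.1.

Diplotype clustering groups samples by city-block distance over a region's
alt-count vectors with complete linkage; clusters with low mean
heterozygosity are sweep candidates and are reported with the variants
that distinguish them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from agpopgen.core_io import MISSING, VariantDataset


# ---------------------------------------------------------------------------
# H12
# ---------------------------------------------------------------------------


def h12(window: np.ndarray) -> tuple[float, float]:
    """H12 and H1 for one window of haplotypes (n_haplotypes x n_snps,
    binary). Rows are hashed to count distinct haplotypes; at least two
    haplotypes are required."""
    window = np.asarray(window)
    n = window.shape[0]
    if n < 2:
        raise ValueError("H12 needs at least 2 haplotypes")
    _, counts = np.unique(window, axis=0, return_counts=True)
    p = np.sort(counts / n)[::-1]
    h1 = float(np.sum(p**2))
    p2 = p[1] if p.size > 1 else 0.0
    h12_val = float((p[0] + p2) ** 2 + np.sum(p[2:] ** 2))
    return h12_val, h1


@dataclass
class H12Profile:
    """Windowed H12 values for one contig; windows are consecutive blocks
    of ``window_size`` SNPs, trailing partial window dropped."""

    contig: str
    window_size: int
    start: np.ndarray  # first SNP position per window
    end: np.ndarray  # last SNP position per window
    h12: np.ndarray
    h1: np.ndarray
    cohort: str = "all"

    def __len__(self) -> int:
        return int(self.h12.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig,
                "start": self.start,
                "end": self.end,
                "n_snps": self.window_size,
                "h12": self.h12,
                "h1": self.h1,
            }
        )


def h12_scan(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    window_size: int = 1500,
    contig: str = "unknown",
    cohort: str = "all",
) -> H12Profile:
    """Non-overlapping H12 scan over consecutive ``window_size``-SNP
    windows. An input with fewer SNPs than one window yields an empty
    profile (with a warning)."""
    import warnings

    if window_size < 2:
        raise ValueError("window_size must be >= 2 SNPs")
    haplotypes = np.asarray(haplotypes)
    positions = np.asarray(positions)
    m = haplotypes.shape[1]
    n_windows = m // window_size
    if n_windows == 0:
        warnings.warn(f"fewer than {window_size} SNPs: empty H12 profile")
    starts, ends, h12s, h1s = [], [], [], []
    for w in range(n_windows):
        sl = slice(w * window_size, (w + 1) * window_size)
        v12, v1 = h12(haplotypes[:, sl])
        starts.append(int(positions[sl.start]))
        ends.append(int(positions[sl.stop - 1]))
        h12s.append(v12)
        h1s.append(v1)
    return H12Profile(
        contig=contig,
        window_size=window_size,
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        h12=np.array(h12s),
        h1=np.array(h1s),
        cohort=cohort,
    )


def calibrate_window_size(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    candidate_sizes: list[int],
    percentile: float = 95.0,
    threshold: float = 0.1,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest candidate window size whose genome-wide H12
    percentile falls below ``threshold``.

    Returns (chosen size, full percentile-vs-size table for plotting).
    Raises if no candidate qualifies, listing the table in the message.
    """
    if sorted(candidate_sizes) != list(candidate_sizes):
        raise ValueError("candidate sizes must be sorted ascending")
    rows = []
    chosen = None
    for size in candidate_sizes:
        profile = h12_scan(haplotypes, positions, window_size=size)
        if len(profile) == 0:
            value = np.nan
        else:
            value = float(np.percentile(profile.h12, percentile))
        rows.append({"window_size": size, "h12_percentile": value})
        if chosen is None and np.isfinite(value) and value < threshold:
            chosen = size
    table = pd.DataFrame(rows)
    if chosen is None:
        raise ValueError(
            f"no candidate window size reaches {percentile:g}th-percentile H12 "
            f"< {threshold}:\n{table.to_string(index=False)}"
        )
    return chosen, table


def detect_peaks(
    profile: H12Profile,
    known_loci: pd.DataFrame | None = None,
    percentile: float = 99.0,
) -> pd.DataFrame:
    """Windows above the contig-wide H12 percentile, merged when adjacent,
    annotated with overlapping known loci (columns name/contig/start/end)
    or ``novel``."""
    if len(profile) == 0:
        raise ValueError("empty H12 profile")
    threshold = float(np.percentile(profile.h12, percentile))
    above = profile.h12 > threshold
    rows = []
    idx = np.flatnonzero(np.diff(np.r_[0, above.astype(np.int8), 0]))
    for s, e in zip(idx[0::2], idx[1::2] - 1):
        start = int(profile.start[s])
        end = int(profile.end[e])
        names = []
        if known_loci is not None:
            for _, locus in known_loci.iterrows():
                if (
                    locus["contig"] == profile.contig
                    and start <= locus["end"]
                    and end >= locus["start"]
                ):
                    names.append(str(locus["name"]))
        rows.append(
            {
                "contig": profile.contig,
                "start": start,
                "end": end,
                "n_windows": int(e - s + 1),
                "max_h12": float(profile.h12[s : e + 1].max()),
                "annotation": ",".join(names) if names else "novel",
            }
        )
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "n_windows", "max_h12", "annotation"]
    )


# ---------------------------------------------------------------------------
# Diplotype clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Complete-linkage dendrogram over samples' region diplotypes.

    ``merge`` is the scipy linkage matrix (heights are city-block
    distances and are non-decreasing under complete linkage);
    ``heterozygosity`` is each sample's fraction of heterozygous calls in
    the region; overlays list the substitution labels / CNV gene ids each
    sample carries.
    """

    sample_ids: list[str]
    merge: np.ndarray
    leaf_order: np.ndarray
    heterozygosity: np.ndarray
    substitutions: dict[str, list[str]] = field(default_factory=dict)
    cnvs: dict[str, list[str]] = field(default_factory=dict)

    def cut(self, height: float) -> np.ndarray:
        """Flat cluster labels at a distance cut."""
        return fcluster(self.merge, t=height, criterion="distance")

    def to_newick(self) -> str:
        """Serialise the dendrogram as a rooted newick string with branch
        lengths derived from merge heights."""
        n = len(self.sample_ids)
        heights = {i: 0.0 for i in range(n)}
        labels = {i: self.sample_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merge):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            node = n + k
            labels[node] = f"({labels[a]}:{la:.6g},{labels[b]}:{lb:.6g})"
            heights[node] = h
        return labels[n + len(self.merge) - 1] + ";"


def diplotype_cluster(
    ds: VariantDataset,
    annotation: pd.DataFrame | None = None,
    cnv_calls: list | None = None,
) -> Dendrogram:
    """Hierarchically cluster samples on a region's alt-count vectors with
    city-block distance and complete linkage.

    ``annotation`` (effect TSV rows for this region) and ``cnv_calls``
    (retained amplification calls) become per-leaf overlays naming the
    non-synonymous substitutions and amplified genes each sample carries.
    Missing genotypes must be filtered out beforehand.
    """
    from scipy.cluster.hierarchy import leaves_list

    if ds.n_samples < 2:
        raise ValueError("diplotype clustering needs at least 2 samples")
    if (ds.genotypes == MISSING).any():
        raise ValueError("region contains missing genotypes; filter first")
    x = ds.genotypes.astype(np.float64)
    merge = linkage(x, method="complete", metric="cityblock")
    het = (ds.genotypes == 1).mean(axis=1)

    substitutions: dict[str, list[str]] = {s: [] for s in ds.sample_ids}
    if annotation is not None:
        ann = annotation[
            (annotation["effect"] == "non-synonymous")
            & (annotation["contig"] == ds.contig)
        ]
        pos_to_col = {int(p): j for j, p in enumerate(ds.positions)}
        for _, row in ann.iterrows():
            j = pos_to_col.get(int(row["position"]))
            if j is None or ds.alt[j] != row["alt"]:
                continue
            carriers = np.flatnonzero(ds.genotypes[:, j] > 0)
            for i in carriers:
                substitutions[ds.sample_ids[i]].append(str(row["aa_change"]))
    cnvs: dict[str, list[str]] = {s: [] for s in ds.sample_ids}
    if cnv_calls:
        for call in cnv_calls:
            if call.sample_id in cnvs:
                cnvs[call.sample_id].append(f"{call.contig}:{call.start}-{call.end}")
    return Dendrogram(
        sample_ids=list(ds.sample_ids),
        merge=merge,
        leaf_order=leaves_list(merge),
        heterozygosity=het,
        substitutions=substitutions,
        cnvs=cnvs,
    )


def low_het_clusters(
    dendrogram: Dendrogram,
    ds: VariantDataset,
    cut_height: float,
    het_max: float = 0.1,
    min_size: int = 2,
    inside_min: float = 0.8,
    outside_max: float = 0.2,
) -> list[dict]:
    """Cut the dendrogram and report clusters of >= ``min_size`` samples
    whose mean heterozygosity is at most ``het_max``.

    Each reported cluster lists its distinguishing variants: positions
    whose alt-allele frequency is >= ``inside_min`` inside the cluster and
    <= ``outside_max`` outside it.
    """
    labels = dendrogram.cut(cut_height)
    sample_pos = {s: i for i, s in enumerate(ds.sample_ids)}
    out = []
    for label in np.unique(labels):
        members = [
            s for s, l in zip(dendrogram.sample_ids, labels) if l == label
        ]
        if len(members) < min_size:
            continue
        het = np.mean(
            [dendrogram.heterozygosity[dendrogram.sample_ids.index(s)] for s in members]
        )
        if het > het_max:
            continue
        inside = np.array([sample_pos[s] for s in members if s in sample_pos])
        outside = np.array(
            [i for s, i in sample_pos.items() if s not in set(members)], dtype=int
        )
        g = ds.genotypes.astype(np.float64)
        f_in = g[inside].mean(axis=0) / 2.0
        f_out = (
            g[outside].mean(axis=0) / 2.0 if outside.size else np.zeros(ds.n_variants)
        )
        distinguishing = np.flatnonzero((f_in >= inside_min) & (f_out <= outside_max))
        out.append(
            {
                "cluster": int(label),
                "sample_ids": members,
                "mean_heterozygosity": float(het),
                "distinguishing_positions": [int(ds.positions[j]) for j in distinguishing],
            }
        )
    return out
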