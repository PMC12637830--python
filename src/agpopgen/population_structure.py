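"""Population structure: PCA, neighbour-joining trees, Hudson's FST and
per-cohort diversity statistics.

Allele-frequency denominators count called allele copies only (two per
called diploid genotype). Hudson's FST is computed as a ratio of sums: the
per-variant numerators and denominators are summed across variants before
dividing, the standard recommendation for combining the estimator over
many sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode, nj

from agpopgen.core_io import MISSING, CohortSet, VariantDataset


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------


def cityblock_distance(ds: VariantDataset) -> skbio.DistanceMatrix:
    """Pairwise city-block (Manhattan) distance between samples' alt-count
    vectors: d(i,j) = sum_v |g_iv - g_jv|. Missing genotypes are not
    interpretable as counts; filter them out first (``select_snps`` with
    ``max_missing=0``)."""
    if (ds.genotypes == MISSING).any():
        raise ValueError(
            "dataset contains missing genotypes; run select_snps(max_missing=0) first"
        )
    if ds.n_samples < 2:
        raise ValueError("need at least two samples")
    d = pdist(ds.genotypes.astype(np.float64), metric="cityblock")
    return skbio.DistanceMatrix(squareform(d), ids=ds.sample_ids)


def nj_tree(dm: skbio.DistanceMatrix) -> TreeNode:
    """Unrooted neighbour-joining tree (Saitou–Nei agglomeration).

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch. Serialise with ``tree.write(path)`` (newick).
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbour joining needs at least 3 leaves")
    return nj(dm, neg_as_zero=True)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_components), mean-centred
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.scores.shape[1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


def pca(ds: VariantDataset, n_components: int = 10) -> PCAResult:
    """Principal components of the mean-centred alt-count matrix.

    Variants are centred but not variance-scaled; components come from a
    full SVD so results are deterministic. All-identical samples carry no
    variance and are rejected.
    """
    from sklearn.decomposition import PCA as SkPCA

    if ds.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    max_comp = min(ds.n_samples - 1, ds.n_variants)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, variants)={max_comp}"
        )
    x = ds.genotypes.astype(np.float64)
    x[x == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean, x)
    if np.allclose(x, x[0]):
        raise ValueError("all samples identical: explained variance undefined")
    model = SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return PCAResult(
        sample_ids=list(ds.sample_ids),
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# Hudson's FST
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    cohort1: str
    cohort2: str
    fst: float
    numerators: np.ndarray  # per retained variant
    denominators: np.ndarray
    n_variants: int


def cohort_allele_counts(ds: VariantDataset, sample_ids: list[str]) -> np.ndarray:
    """(n_variants, 2) array of [ref, alt] allele-copy counts in a cohort,
    missing genotypes excluded from the totals."""
    idx = ds.sample_index(list(sample_ids))
    alt, total = ds.allele_counts(idx)
    return np.stack([total - alt, alt], axis=1)


def hudson_fst(
    ac1: np.ndarray, ac2: np.ndarray, cohort1: str = "pop1", cohort2: str = "pop2"
) -> FstResult:
    """Hudson's pairwise FST from two cohorts' allele counts.

    Per variant, with sample frequencies p1, p2 and allele-copy totals
    n1, n2::

        N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        D = p1(1-p2) + p2(1-p1)

    and the estimate is sum(N) / sum(D) over variants with at least two
    called copies in each cohort. The finite-sample terms make N an
    unbiased estimate of the squared frequency difference, so the estimator
    is centred even for small cohorts.
    """
    ac1 = np.asarray(ac1, dtype=np.float64)
    ac2 = np.asarray(ac2, dtype=np.float64)
    if ac1.shape != ac2.shape or ac1.ndim != 2 or ac1.shape[1] != 2:
        raise ValueError("allele counts must be matching (n_variants, 2) arrays")
    n1 = ac1.sum(axis=1)
    n2 = ac2.sum(axis=1)
    keep = (n1 >= 2) & (n2 >= 2)
    n1, n2 = n1[keep], n2[keep]
    p1 = ac1[keep, 1] / n1
    p2 = ac2[keep, 1] / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    total_den = den.sum()
    if total_den == 0:
        raise ZeroDivisionError(
            "FST undefined: no between-cohort heterozygosity at retained variants"
        )
    return FstResult(
        cohort1=cohort1,
        cohort2=cohort2,
        fst=float(num.sum() / total_den),
        numerators=num,
        denominators=den,
        n_variants=int(keep.sum()),
    )


def pairwise_fst(ds: VariantDataset, cohorts: CohortSet) -> pd.DataFrame:
    """Hudson's FST for every pair of statistics-eligible cohorts, long
    format (cohort1, cohort2, fst, n_variants)."""
    eligible = cohorts.eligible()
    counts = {
        c.cohort_id: cohort_allele_counts(ds, list(c.sample_ids)) for c in eligible
    }
    rows = []
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            res = hudson_fst(
                counts[a.cohort_id], counts[b.cohort_id], a.cohort_id, b.cohort_id
            )
            rows.append(
                {
                    "cohort1": a.cohort_id,
                    "cohort2": b.cohort_id,
                    "fst": res.fst,
                    "n_variants": res.n_variants,
                }
            )
    return pd.DataFrame(rows, columns=["cohort1", "cohort2", "fst", "n_variants"])


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    cohort: str
    theta_pi: float  # mean pairwise differences per accessible site
    theta_w: float  # Watterson's estimator per accessible site
    tajima_d: float | None  # None when S = 0
    n_segregating: int
    n_copies: int
    accessible_sites: int


def tajima_constants(n: int) -> dict[str, float]:
    """The Tajima (1989) normalising constants for ``n`` allele copies."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def diversity_stats(
    ds: VariantDataset,
    sample_ids: list[str],
    accessible_sites: int | None = None,
    cohort: str = "cohort",
) -> DiversitySummary:
    """Nucleotide diversity, Watterson's theta and Tajima's D for a cohort.

    theta_pi sums per-variant mean pairwise differences a(n_v - a) /
    C(n_v, 2) over called copies n_v; theta_w is S / a1 with a1 the
    harmonic number over the cohort's full copy count. ``accessible_sites``
    (default: the spanned region length) converts both to per-site values.
    Tajima's D uses the 1989 constants and is None for monomorphic data.
    """
    idx = ds.sample_index(list(sample_ids))
    alt, total = ds.allele_counts(idx)
    ok = total >= 2
    alt, total = alt[ok], total[ok]
    seg = (alt > 0) & (alt < total)
    s = int(seg.sum())
    n = 2 * len(sample_ids)
    if accessible_sites is None:
        accessible_sites = (
            int(ds.positions[-1] - ds.positions[0] + 1) if ds.n_variants else 0
        )
    if accessible_sites <= 0:
        raise ValueError("accessible_sites must be positive")
    pairs = total * (total - 1) / 2.0
    pi_total = float(np.sum(alt * (total - alt) / pairs))
    const = tajima_constants(n)
    theta_w_total = s / const["a1"]
    if s == 0:
        d = None
    else:
        var = const["e1"] * s + const["e2"] * s * (s - 1)
        d = float((pi_total - theta_w_total) / np.sqrt(var))
    return DiversitySummary(
        cohort=cohort,
        theta_pi=pi_total / accessible_sites,
        theta_w=theta_w_total / accessible_sites,
        tajima_d=d,
        n_segregating=s,
        n_copies=n,
        accessible_sites=accessible_sites,
    )


def cohort_diversity(
    ds: VariantDataset, cohorts: CohortSet, accessible_sites: int | None = None
) -> pd.DataFrame:
    """Diversity summaries for every statistics-eligible cohort."""
    rows = []
    for c in cohorts.eligible():
        summ = diversity_stats(
            ds, list(c.sample_ids), accessible_sites, cohort=c.cohort_id
        )
        rows.append(
            {
                "cohort_id": summ.cohort,
                "theta_pi": summ.theta_pi,
                "theta_w": summ.theta_w,
                "tajima_d": summ.tajima_d,
                "n_segregating": summ.n_segregating,
                "n_copies": summ.n_copies,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cohort_id", "theta_pi", "theta_w", "tajima_d", "n_segregating", "n_copies"],
    )
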