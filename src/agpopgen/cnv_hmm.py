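"""Copy-number variant calling from windowed coverage with a Gaussian HMM.

Per sample, normalised window depth is modelled by a hidden Markov chain
over copy-number states 0..max_cn with Gaussian emissions whose means are
proportional to copy number (c / 2 on autosomes, c on the male X). Calls
are maximal runs of at least ``min_windows`` windows decoded above the
baseline copy number, retained when the decoded path beats the forced
all-baseline path by a likelihood ratio above ``likelihood_min`` and the
normalised-depth variance inside the call is below ``variance_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class CoverageMatrix:
    """Windowed depth for one contig: fixed-width contiguous windows,
    ``depth[sample, window]``, with per-sample sex for X-baseline logic."""

    contig: str
    window_starts: np.ndarray  # 1-based start of each window
    window_size: int
    depth: np.ndarray  # (n_samples, n_windows), >= 0
    sample_ids: list[str]
    sex: np.ndarray  # 'F' or 'M' per sample

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=float)
        self.sex = np.asarray(self.sex, dtype="U1")
        if self.depth.shape != (len(self.sample_ids), self.window_starts.size):
            raise ValueError("depth must be samples x windows")
        if self.window_starts.size > 1:
            steps = np.diff(self.window_starts)
            if not np.all(steps == self.window_size):
                raise ValueError("windows must be contiguous with fixed width")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_windows(self) -> int:
        return int(self.window_starts.size)

    def baseline_copy(self, i: int) -> int:
        """Expected copy number of sample ``i`` on this contig."""
        return 1 if (self.contig == "X" and self.sex[i] == "M") else 2

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.depth.T, columns=self.sample_ids)
        df.insert(0, "window_start", self.window_starts)
        df.insert(0, "contig", self.contig)
        with open(path, "w") as fh:
            fh.write(f"#window_size={self.window_size}\n")
            fh.write(f"#sex={','.join(self.sex)}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.5f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoverageMatrix":
        with open(path) as fh:
            window_size = int(fh.readline().strip().split("=")[1])
            sex = fh.readline().strip().split("=")[1].split(",")
            df = pd.read_csv(fh, sep="\t")
        sample_ids = list(df.columns[2:])
        return cls(
            contig=str(df["contig"].iloc[0]),
            window_starts=df["window_start"].to_numpy(),
            window_size=window_size,
            depth=df[sample_ids].to_numpy().T,
            sample_ids=sample_ids,
            sex=np.array(sex, dtype="U1"),
        )


@dataclass
class CNVCall:
    """A retained amplification call for one sample."""

    sample_id: str
    contig: str
    start_window: int  # window indices, inclusive
    end_window: int
    start: int  # 1-based genomic coordinates, inclusive
    end: int
    copy_number: int  # modal decoded copy number inside the call
    likelihood: float  # likelihood ratio of decoded vs baseline path
    log_likelihood_ratio: float
    coverage_variance: float

    @property
    def n_windows(self) -> int:
        return self.end_window - self.start_window + 1


@dataclass
class HmmParams:
    """Gaussian-HMM parameters. Emission means are ``copy / baseline`` for
    copies 0..max_cn; a single emission variance is estimated per sample
    from the spread of its normalised depths (robust MAD about the modal
    state) unless ``emission_sd`` is given. The transition matrix has
    probability ``self_transition`` of staying in a state and spreads the
    remainder uniformly."""

    max_cn: int = 12
    self_transition: float = 0.96
    emission_sd: float | None = None
    min_emission_sd: float = 0.02


def normalize_coverage(raw: CoverageMatrix) -> CoverageMatrix:
    """Scale each sample so its median window depth sits at the baseline
    copy number's expected value (1.0 for diploid, likewise for male-X
    baseline since the median is taken on this contig). Samples with zero
    median are dropped with a warning. Doubling a sample's raw depths
    leaves its normalised row unchanged."""
    medians = np.median(raw.depth, axis=1)
    keep = medians > 0
    if not keep.all():
        dropped = [s for s, k in zip(raw.sample_ids, keep) if not k]
        warnings.warn(f"dropping samples with zero median coverage: {dropped}")
    depth = raw.depth[keep] / medians[keep, None]
    return replace(
        raw,
        depth=depth,
        sample_ids=[s for s, k in zip(raw.sample_ids, keep) if k],
        sex=raw.sex[keep],
    )


def _estimate_sd(x: np.ndarray, params: HmmParams) -> float:
    # robust spread about 1.0 (the normalised baseline); MAD * 1.4826
    mad = np.median(np.abs(x - np.median(x)))
    return max(1.4826 * mad, params.min_emission_sd)


def _viterbi(
    obs: np.ndarray, means: np.ndarray, sd: float, params: HmmParams
) -> tuple[np.ndarray, float]:
    """Viterbi path over copy states via hmmlearn's Gaussian HMM."""
    from hmmlearn.hmm import GaussianHMM

    k = means.size
    model = GaussianHMM(n_components=k, covariance_type="spherical")
    model.startprob_ = np.full(k, 1.0 / k)
    off = (1.0 - params.self_transition) / (k - 1)
    model.transmat_ = np.full((k, k), off) + np.eye(k) * (
        params.self_transition - off
    )
    model.means_ = means[:, None]
    model.covars_ = np.full(k, sd**2)
    logprob, path = model.decode(obs[:, None], algorithm="viterbi")
    return path, float(logprob)


def _path_loglik(
    obs: np.ndarray, path: np.ndarray, means: np.ndarray, sd: float, params: HmmParams
) -> np.ndarray:
    """Per-window log p(obs, state) contributions along a fixed path
    (emission plus transition-from-previous terms)."""
    k = means.size
    emit = norm.logpdf(obs, loc=means[path], scale=sd)
    off = (1.0 - params.self_transition) / (k - 1)
    trans = np.zeros_like(emit)
    same = path[1:] == path[:-1]
    trans[1:] = np.where(same, np.log(params.self_transition), np.log(off))
    return emit + trans


def fit_copy_number_hmm(
    cov: CoverageMatrix, params: HmmParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Decode per-sample copy-number paths from normalised coverage.

    Returns ``(paths, sds)`` where ``paths[sample, window]`` is the decoded
    copy number and ``sds`` the per-sample emission standard deviations
    used. Input must already be normalised (baseline near 1.0).
    """
    params = params or HmmParams()
    if cov.n_windows < 1:
        raise ValueError("need at least one coverage window")
    if not np.isfinite(cov.depth).all():
        raise ValueError("non-finite depths in coverage matrix")
    paths = np.empty((cov.n_samples, cov.n_windows), dtype=np.int16)
    sds = np.empty(cov.n_samples)
    for i in range(cov.n_samples):
        baseline = cov.baseline_copy(i)
        means = np.arange(params.max_cn + 1) / baseline
        sd = params.emission_sd or _estimate_sd(cov.depth[i], params)
        paths[i], _ = _viterbi(cov.depth[i], means, sd, params)
        sds[i] = sd
    return paths, sds


def call_cnvs(
    paths: np.ndarray,
    cov: CoverageMatrix,
    sds: np.ndarray | None = None,
    min_windows: int = 5,
    likelihood_min: float = 1000.0,
    variance_max: float = 0.35,
    params: HmmParams | None = None,
) -> list[CNVCall]:
    """Extract retained amplification calls from decoded paths.

    A call is a maximal run of >= ``min_windows`` contiguous windows with
    decoded copy number above the sample's baseline (2 on autosomes, 1 on
    the male X). The likelihood score is the ratio of the decoded path's
    joint probability to the forced all-baseline path's over the call span;
    calls need likelihood > ``likelihood_min`` and normalised-depth
    variance inside the call < ``variance_max``.
    """
    params = params or HmmParams()
    calls: list[CNVCall] = []
    for i in range(paths.shape[0]):
        baseline = cov.baseline_copy(i)
        means = np.arange(params.max_cn + 1) / baseline
        sd = (
            sds[i]
            if sds is not None
            else (params.emission_sd or _estimate_sd(cov.depth[i], params))
        )
        elevated = paths[i] > baseline
        for s, e in _runs(elevated):
            if e - s + 1 < min_windows:
                continue
            span = slice(s, e + 1)
            obs = cov.depth[i, span]
            decoded = _path_loglik(obs, paths[i, span], means, sd, params).sum()
            base = _path_loglik(
                obs, np.full(e - s + 1, baseline), means, sd, params
            ).sum()
            llr = decoded - base
            with np.errstate(over="ignore"):
                ratio = float(np.exp(llr))
            variance = float(np.var(obs))
            if ratio > likelihood_min and variance < variance_max:
                states, counts = np.unique(paths[i, span], return_counts=True)
                calls.append(
                    CNVCall(
                        sample_id=cov.sample_ids[i],
                        contig=cov.contig,
                        start_window=s,
                        end_window=e,
                        start=int(cov.window_starts[s]),
                        end=int(cov.window_starts[e] + cov.window_size - 1),
                        copy_number=int(states[np.argmax(counts)]),
                        likelihood=ratio,
                        log_likelihood_ratio=float(llr),
                        coverage_variance=variance,
                    )
                )
    return calls


def _runs(mask: np.ndarray):
    """Yield (start, end) index pairs of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
    for s, e in zip(idx[0::2], idx[1::2]):
        yield int(s), int(e - 1)


def detect_cnvs(
    raw: CoverageMatrix,
    params: HmmParams | None = None,
    min_windows: int = 5,
    likelihood_min: float = 1000.0,
    variance_max: float = 0.35,
) -> list[CNVCall]:
    """Normalise, decode and filter in one step."""
    cov = normalize_coverage(raw)
    paths, sds = fit_copy_number_hmm(cov, params)
    return call_cnvs(
        paths,
        cov,
        sds,
        min_windows=min_windows,
        likelihood_min=likelihood_min,
        variance_max=variance_max,
        params=params,
    )


# ---------------------------------------------------------------------------
# Gene-level amplification frequencies
# ---------------------------------------------------------------------------


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of gene intervals (0-based half-open) into 1-based
    inclusive coordinates with columns contig/start/end/gene_id."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "gene_id"]
    )
    df["start"] = df["start"] + 1
    return df


def gene_cnv_frequencies(
    calls: list[CNVCall],
    genes: pd.DataFrame,
    cohorts,
    report_min: float = 0.05,
) -> pd.DataFrame:
    """Per gene and cohort, the fraction of members carrying at least one
    retained call overlapping the gene (any base overlap). Genes must reach
    a frequency strictly above ``report_min`` in at least one eligible
    cohort to be reported."""
    carriers: dict[str, set[str]] = {g: set() for g in genes["gene_id"]}
    for _, g in genes.iterrows():
        for c in calls:
            if c.contig == g["contig"] and c.start <= g["end"] and c.end >= g["start"]:
                carriers[g["gene_id"]].add(c.sample_id)
    rows = []
    for gene_id, members in carriers.items():
        for cohort in cohorts.eligible():
            hit = sum(1 for s in cohort.sample_ids if s in members)
            rows.append(
                {
                    "gene_id": gene_id,
                    "cohort_id": cohort.cohort_id,
                    "frequency": hit / cohort.size,
                    "n_carriers": hit,
                    "n_samples": cohort.size,
                }
            )
    table = pd.DataFrame(rows, columns=["gene_id", "cohort_id", "frequency", "n_carriers", "n_samples"])
    if table.empty:
        return table
    keep = table.groupby("gene_id")["frequency"].transform("max") > report_min
    return table.loc[keep].reset_index(drop=True)


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    cols = [
        "sample_id",
        "contig",
        "start",
        "end",
        "start_window",
        "end_window",
        "copy_number",
        "likelihood",
        "log_likelihood_ratio",
        "coverage_variance",
    ]
    return pd.DataFrame([{c: getattr(call, c) for c in cols} for call in calls], columns=cols)
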