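"""Synthetic cohort generator.

Produces data with the statistical structure each downstream stage assumes,
so the full pipeline is testable without any sequencing data:

* two demes with tunable differentiation (Balding–Nichols allele
  frequencies, binomial genotypes);
* phased haplotypes with background linkage disequilibrium (founder-mosaic
  copying model) into which hard or soft sweeps are planted;
* chromosomal-inversion karyotypes in imperfect linkage with tag SNPs;
* windowed coverage with planted copy-number amplifications in Gaussian
  noise;
* ancestry-informative-marker genotypes with per-taxon allele purity;
* resistance substitutions at set per-deme allele frequencies.

Every generator is deterministic given the config seed, and a TruthSet
records the planted signal so downstream calls can be scored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from agpopgen.core_io import MISSING, RegionSpec, VariantDataset
from agpopgen.cnv_hmm import CoverageMatrix

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class InversionSpec:
    """One simulated inversion: per-deme inverted-allele frequencies and a
    tag-SNP panel in imperfect linkage with karyotype.

    ``tag_ld`` is the probability, per chromosome copy and per tag, that the
    tag allele matches the copy's true orientation.
    """

    name: str = "2La"
    contig: str = "2L"
    start: int = 20_528_089
    end: int = 42_165_182
    inverted_freq: tuple[float, ...] = (0.98, 0.08)
    n_tag_snps: int = 20
    tag_ld: float = 0.95


@dataclass
class SweepSpec:
    """A selective sweep planted into phased haplotypes.

    ``start_snp``/``end_snp`` index the SNP columns of the target region
    (inclusive); a fraction ``swept_fraction`` of haplotypes is replaced by
    ``n_core`` identical core haplotypes (1 = hard sweep, >1 = soft).
    """

    start_snp: int = 3000
    end_snp: int = 4499
    swept_fraction: float = 0.6
    n_core: int = 1
    deme: int = 0


@dataclass
class CnvSpec:
    """A planted amplification in windowed coverage."""

    contig: str = "2R"
    start_window: int = 300
    n_windows: int = 12
    copy_number: int = 3
    carrier_freq: tuple[float, ...] = (0.7, 0.1)
    gene_id: str = "AGAP002862"


@dataclass
class CoverageSpec:
    n_windows: int = 600
    window_size: int = 300
    contig: str = "2R"
    start: int = 28_400_000
    noise_sd: float = 0.25
    cnvs: list[CnvSpec] = field(default_factory=lambda: [CnvSpec()])


@dataclass
class AimSpec:
    n_markers_arab: int = 2612
    n_markers_colu: int = 700
    purity: float = 0.99
    contig: str = "3R"


@dataclass
class ResistanceSpec:
    """One amino-acid substitution segregating at set per-deme frequencies."""

    gene_id: str = "AGAP004707"
    gene_name: str = "Vgsc"
    aa_change: str = "L995F"
    contig: str = "2L"
    position: int = 2_422_652
    deme_freq: tuple[float, ...] = (0.6, 0.9)


def _default_resistance() -> list[ResistanceSpec]:
    return [
        ResistanceSpec("AGAP004707", "Vgsc", "L995F", "2L", 2_422_652, (0.6, 0.9)),
        ResistanceSpec("AGAP004707", "Vgsc", "V402L", "2L", 2_391_228, (0.4, 0.15)),
        ResistanceSpec("AGAP006028", "Rdl", "A296S", "2L", 25_429_236, (0.5, 0.0)),
        ResistanceSpec("AGAP006028", "Rdl", "A296G", "2L", 25_429_235, (0.0, 0.4)),
        ResistanceSpec("AGAP001356", "Ace1", "G280S", "2R", 3_492_074, (0.0, 0.2)),
        ResistanceSpec("AGAP009194", "Gste2", "I114T", "3R", 28_598_166, (0.5, 0.35)),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; ``seed`` fixes every draw."""

    n_demes: int = 2
    samples_per_deme: int = 50
    n_variants: int = 5000
    target_fst: float = 0.01
    seed: int = 0
    contig: str = "3L"
    region_start: int = 15_000_000
    snp_spacing: int = 250
    deme_names: tuple[str, ...] = ("Upper East", "Greater Accra")
    year: int = 2018
    # haplotype-background model (used by the sweep generator)
    n_founders: int = 8
    switch_rate: float = 0.002
    inversions: list[InversionSpec] = field(
        default_factory=lambda: [
            InversionSpec("2La", "2L", 20_528_089, 42_165_182, (0.98, 0.08), 20, 0.95),
            InversionSpec("2Rb", "2R", 19_444_433, 26_313_071, (0.50, 0.03), 20, 0.95),
        ]
    )
    sweep: SweepSpec = field(default_factory=SweepSpec)
    coverage: CoverageSpec = field(default_factory=CoverageSpec)
    aims: AimSpec = field(default_factory=AimSpec)
    resistance: list[ResistanceSpec] = field(default_factory=_default_resistance)

    def __post_init__(self) -> None:
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0, 1)")
        if self.n_demes < 1 or self.samples_per_deme < 1 or self.n_variants < 1:
            raise ValueError("cohort dimensions must be positive")
        for inv in self.inversions:
            if any(not 0 <= f <= 1 for f in inv.inverted_freq):
                raise ValueError("inversion frequencies must be in [0, 1]")
            if not 0 <= inv.tag_ld <= 1:
                raise ValueError("tag_ld must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_demes * self.samples_per_deme

    def sample_ids(self) -> list[str]:
        return [
            f"D{d}S{i:04d}"
            for d in range(self.n_demes)
            for i in range(self.samples_per_deme)
        ]

    def deme_of_samples(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_demes), self.samples_per_deme)


@dataclass
class TruthSet:
    """Planted ground truth, JSON-serialisable, sufficient to score every
    downstream stage."""

    deme: dict[str, int] = field(default_factory=dict)
    taxon: dict[str, str] = field(default_factory=dict)
    karyotype: dict[str, dict[str, int]] = field(default_factory=dict)
    cnv_intervals: list[dict] = field(default_factory=list)
    sweep: dict = field(default_factory=dict)
    resistance_freq: list[dict] = field(default_factory=list)
    target_fst: float | None = None
    schema_version: int = 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _positions(start: int, n: int, spacing: int) -> np.ndarray:
    return start + spacing * np.arange(n, dtype=np.int64)


def _ref_alt(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return bases[ref_i], bases[alt_i]


def simulate_two_deme_genotypes(
    cfg: SimulationConfig,
) -> tuple[VariantDataset, pd.DataFrame, TruthSet]:
    """Phased genotypes under the Balding–Nichols model.

    Ancestral frequencies are Uniform(0.05, 0.95); each deme's frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target FST, and haplotype
    alleles are Bernoulli draws at the deme frequency, so the expectation of
    Hudson's ratio-of-sums estimator equals F.
    """
    rng = np.random.default_rng(cfg.seed)
    m, F = cfg.n_variants, cfg.target_fst
    p_anc = rng.uniform(0.05, 0.95, size=m)
    scale = (1.0 - F) / F
    deme_p = np.stack(
        [rng.beta(p_anc * scale, (1.0 - p_anc) * scale) for _ in range(cfg.n_demes)]
    )
    n = cfg.n_samples
    hap = np.empty((2 * n, m), dtype=np.int8)
    demes = cfg.deme_of_samples()
    for d in range(cfg.n_demes):
        rows = np.flatnonzero(np.repeat(demes, 2) == d)
        hap[rows] = (rng.random((rows.size, m)) < deme_p[d]).astype(np.int8)
    genotypes = hap[0::2] + hap[1::2]
    ref, alt = _ref_alt(rng, m)
    sample_ids = cfg.sample_ids()
    ds = VariantDataset(
        contig=cfg.contig,
        positions=_positions(cfg.region_start, m, cfg.snp_spacing),
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        sample_ids=sample_ids,
        haplotypes=hap,
    )
    samples = _sample_metadata(cfg, rng)
    truth = TruthSet(
        deme={s: int(d) for s, d in zip(sample_ids, demes)},
        taxon={s: "coluzzii" for s in sample_ids},
        target_fst=F,
    )
    return ds, samples, truth


def _sample_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    demes = cfg.deme_of_samples()
    return pd.DataFrame(
        {
            "sample_id": cfg.sample_ids(),
            "location": [cfg.deme_names[d % len(cfg.deme_names)] for d in demes],
            "year": cfg.year,
            "sex": rng.choice(["F", "M"], size=n, p=[0.8, 0.2]),
            "median_coverage": np.round(rng.normal(35, 5, size=n).clip(12, 60), 1),
            "genome_fraction": np.round(rng.uniform(0.85, 0.99, size=n), 3),
            "contamination_pct": np.round(rng.uniform(0.0, 2.0, size=n), 2),
        }
    )


def simulate_sweep_haplotypes(
    cfg: SimulationConfig,
    n_haplotypes: int | None = None,
    neutral: bool = False,
) -> tuple[np.ndarray, np.ndarray, TruthSet]:
    """Phased haplotypes with background LD and an optional planted sweep.

    The neutral background is a founder-mosaic copying model: each haplotype
    copies one of ``cfg.n_founders`` founder haplotypes and switches founder
    with probability ``cfg.switch_rate`` per SNP. Short windows therefore
    contain few distinct haplotypes (high H12) while long windows break
    identity — the structure the window-size calibration relies on. Inside
    the sweep window a fraction ``swept_fraction`` of rows is replaced by
    ``n_core`` identical core haplotypes.

    Returns ``(haplotypes, positions, truth)``; ``neutral=True`` skips the
    sweep.
    """
    rng = np.random.default_rng(cfg.seed)
    n_hap = 2 * cfg.n_samples if n_haplotypes is None else n_haplotypes
    m = cfg.n_variants
    sw = cfg.sweep
    if not neutral and not (0 <= sw.start_snp <= sw.end_snp < m):
        raise ValueError("sweep window outside the simulated contig")
    if sw.swept_fraction > 1:
        raise ValueError("swept_fraction must be <= 1")

    founders = (rng.random((cfg.n_founders, m)) < rng.uniform(0.1, 0.9, size=m)).astype(
        np.int8
    )
    # mosaic copying: switch founder with prob switch_rate at each SNP
    switches = rng.random((n_hap, m)) < cfg.switch_rate
    choices = rng.integers(0, cfg.n_founders, size=(n_hap, m))
    path = np.empty((n_hap, m), dtype=np.int64)
    path[:, 0] = choices[:, 0]
    for j in range(1, m):
        path[:, j] = np.where(switches[:, j], choices[:, j], path[:, j - 1])
    hap = founders[path, np.arange(m)]
    # site-wise noise so founders are not exactly recoverable
    flip = rng.random((n_hap, m)) < 0.002
    hap = np.where(flip, 1 - hap, hap).astype(np.int8)

    truth = TruthSet()
    if not neutral and sw.swept_fraction > 0:
        n_swept = int(round(sw.swept_fraction * n_hap))
        swept_rows = rng.choice(n_hap, size=n_swept, replace=False)
        cols = slice(sw.start_snp, sw.end_snp + 1)
        width = sw.end_snp - sw.start_snp + 1
        cores = (rng.random((sw.n_core, width)) < 0.5).astype(np.int8)
        assignment = swept_rows % sw.n_core
        hap[swept_rows, cols] = cores[assignment]
        truth.sweep = {
            "start_snp": sw.start_snp,
            "end_snp": sw.end_snp,
            "swept_fraction": sw.swept_fraction,
            "n_core": sw.n_core,
        }
    positions = _positions(cfg.region_start, m, cfg.snp_spacing)
    return hap, positions, truth


def simulate_neutral_sfs_haplotypes(
    n_haplotypes: int, n_snps: int, seed: int
) -> np.ndarray:
    """Haplotypes whose site-frequency spectrum follows the standard
    neutral expectation P(derived count = c) proportional to 1/c, with
    carriers assigned independently per site (no LD). Under this spectrum
    the expected pairwise diversity equals Watterson's estimator, so
    Tajima's D is centred near zero by construction."""
    rng = np.random.default_rng(seed)
    c = np.arange(1, n_haplotypes)
    weights = 1.0 / c
    counts = rng.choice(c, size=n_snps, p=weights / weights.sum())
    hap = np.zeros((n_haplotypes, n_snps), dtype=np.int8)
    for j, k in enumerate(counts):
        hap[rng.choice(n_haplotypes, size=k, replace=False), j] = 1
    return hap


def simulate_inversion_cohort(
    cfg: SimulationConfig, inversion: InversionSpec | None = None
) -> tuple[VariantDataset, TruthSet]:
    """Karyotypes drawn per deme under Hardy–Weinberg, with tag SNPs whose
    alleles match the chromosome copy's orientation with probability
    ``tag_ld`` (independently per copy and per tag)."""
    inv = inversion if inversion is not None else cfg.inversions[0]
    rng = np.random.default_rng(cfg.seed + 1)
    demes = cfg.deme_of_samples()
    n = cfg.n_samples
    q = np.array([inv.inverted_freq[d % len(inv.inverted_freq)] for d in demes])
    copies = (rng.random((n, 2)) < q[:, None]).astype(np.int8)  # orientation per copy
    karyotype = copies.sum(axis=1)

    t = inv.n_tag_snps
    # per copy, per tag: allele equals orientation with prob tag_ld
    match = rng.random((n, 2, t)) < inv.tag_ld
    alleles = np.where(match, copies[:, :, None], 1 - copies[:, :, None])
    hap = np.empty((2 * n, t), dtype=np.int8)
    hap[0::2] = alleles[:, 0, :]
    hap[1::2] = alleles[:, 1, :]
    genotypes = hap[0::2] + hap[1::2]

    span = inv.end - inv.start
    positions = inv.start + (span // (t + 1)) * np.arange(1, t + 1, dtype=np.int64)
    ref, alt = _ref_alt(rng, t)
    sample_ids = cfg.sample_ids()
    ds = VariantDataset(
        contig=inv.contig,
        positions=positions,
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        sample_ids=sample_ids,
        haplotypes=hap,
    )
    truth = TruthSet(
        deme={s: int(d) for s, d in zip(sample_ids, demes)},
        karyotype={inv.name: {s: int(k) for s, k in zip(sample_ids, karyotype)}},
    )
    return ds, truth


def simulate_coverage(
    cfg: SimulationConfig, sex: np.ndarray | None = None
) -> tuple[CoverageMatrix, TruthSet]:
    """Raw windowed coverage with planted amplifications.

    Normalised depth for copy number ``c`` is Normal(c / baseline, noise_sd)
    where baseline is 2 on autosomes (and female X) and 1 on the male X;
    each sample's raw depth is that times a sample-specific scale, so the
    normalisation step downstream does real work. Carriers of each planted
    CNV are drawn per deme at ``carrier_freq``.
    """
    cov = cfg.coverage
    rng = np.random.default_rng(cfg.seed + 2)
    n, w = cfg.n_samples, cov.n_windows
    demes = cfg.deme_of_samples()
    sample_ids = cfg.sample_ids()
    if sex is None:
        sex = np.array(["F"] * n)
    is_male_x = (np.asarray(sex) == "M") & (cov.contig == "X")
    baseline = np.where(is_male_x, 1, 2)

    copy_state = np.tile(baseline[:, None], (1, w)).astype(np.int16)
    truth = TruthSet(deme={s: int(d) for s, d in zip(sample_ids, demes)})
    window_starts = cov.start + cov.window_size * np.arange(w, dtype=np.int64)
    for c in cov.cnvs:
        freq = np.array([c.carrier_freq[d % len(c.carrier_freq)] for d in demes])
        carriers = np.flatnonzero(rng.random(n) < freq)
        sl = slice(c.start_window, c.start_window + c.n_windows)
        for i in carriers:
            copy_state[i, sl] = c.copy_number
            truth.cnv_intervals.append(
                {
                    "sample_id": sample_ids[i],
                    "contig": cov.contig,
                    "start_window": c.start_window,
                    "end_window": c.start_window + c.n_windows - 1,
                    "start": int(window_starts[c.start_window]),
                    "end": int(window_starts[sl.stop - 1] + cov.window_size - 1),
                    "copy_number": c.copy_number,
                }
            )
    normalised = rng.normal(copy_state / baseline[:, None], cov.noise_sd).clip(min=0.0)
    scale = rng.uniform(15, 45, size=n)
    raw = normalised * scale[:, None]
    matrix = CoverageMatrix(
        contig=cov.contig,
        window_starts=window_starts,
        window_size=cov.window_size,
        depth=raw,
        sample_ids=sample_ids,
        sex=np.asarray(sex, dtype="U1"),
    )
    return matrix, truth


def simulate_aim_panel(
    cfg: SimulationConfig, taxa: list[str] | None = None
) -> tuple[VariantDataset, "pd.DataFrame", "pd.DataFrame", TruthSet]:
    """Genotypes at ancestry-informative markers.

    Two panels are emitted: one separating the gambiae/coluzzii pair from
    arabiensis (default 2612 markers) and one separating gambiae from
    coluzzii (default 700). Each allele copy carries the taxon-diagnostic
    allele with probability ``purity``; a sample with taxon ``intermediate``
    draws coluzzii-like alleles with probability 0.5.

    Returns (dataset over all panel sites, arab-panel table, colu-panel
    table, truth). Panel tables have columns contig/position/
    diagnostic_allele/background_allele where the diagnostic allele is the
    scored taxon's (arabiensis for the first panel, coluzzii for the second).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    sample_ids = cfg.sample_ids()
    if taxa is None:
        taxa = ["coluzzii"] * cfg.n_samples
    if len(taxa) != cfg.n_samples:
        raise ValueError("taxa must have one entry per sample")
    a = cfg.aims
    n1, n2 = a.n_markers_arab, a.n_markers_colu
    m = n1 + n2
    positions = np.concatenate(
        [
            1_000_000 + 10 * np.arange(n1, dtype=np.int64),
            2_000_000 + 10 * np.arange(n2, dtype=np.int64),
        ]
    )
    ref, alt = _ref_alt(rng, m)
    # which allele (0=ref, 1=alt) is diagnostic for the scored taxon
    diag_is_alt = rng.random(m) < 0.5

    # probability each allele copy is the scored taxon's diagnostic allele
    p_diag = np.empty((cfg.n_samples, m))
    taxa_arr = np.asarray(taxa)
    arab_cols = np.arange(n1)
    colu_cols = np.arange(n1, m)
    for i, t in enumerate(taxa_arr):
        if t == "arabiensis":
            p_diag[i, arab_cols] = a.purity
            p_diag[i, colu_cols] = 0.5  # colu panel uninformative for arabiensis
        elif t == "coluzzii":
            p_diag[i, arab_cols] = 1.0 - a.purity
            p_diag[i, colu_cols] = a.purity
        elif t == "gambiae":
            p_diag[i, arab_cols] = 1.0 - a.purity
            p_diag[i, colu_cols] = 1.0 - a.purity
        elif t == "intermediate":
            p_diag[i, arab_cols] = 1.0 - a.purity
            p_diag[i, colu_cols] = 0.5
        else:
            raise ValueError(f"unknown taxon {t!r}")
    hap = np.empty((2 * cfg.n_samples, m), dtype=np.int8)
    for copy in (0, 1):
        is_diag = rng.random((cfg.n_samples, m)) < p_diag
        hap[copy::2] = np.where(is_diag, diag_is_alt, ~diag_is_alt).astype(np.int8)
    genotypes = hap[0::2] + hap[1::2]
    ds = VariantDataset(
        contig=a.contig,
        positions=positions,
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        sample_ids=sample_ids,
        haplotypes=hap,
    )
    diag_base = np.where(diag_is_alt, alt, ref)
    back_base = np.where(diag_is_alt, ref, alt)
    arab_panel = pd.DataFrame(
        {
            "contig": a.contig,
            "position": positions[:n1],
            "diagnostic_allele": diag_base[:n1],
            "background_allele": back_base[:n1],
        }
    )
    colu_panel = pd.DataFrame(
        {
            "contig": a.contig,
            "position": positions[n1:],
            "diagnostic_allele": diag_base[n1:],
            "background_allele": back_base[n1:],
        }
    )
    truth = TruthSet(taxon={s: t for s, t in zip(sample_ids, taxa)})
    return ds, arab_panel, colu_panel, truth


def simulate_resistance_sites(
    cfg: SimulationConfig,
) -> tuple[dict[str, VariantDataset], pd.DataFrame, TruthSet]:
    """Genotypes at resistance substitutions, binomial at per-deme allele
    frequencies, plus the matching effect-annotation table."""
    rng = np.random.default_rng(cfg.seed + 4)
    demes = cfg.deme_of_samples()
    sample_ids = cfg.sample_ids()
    truth = TruthSet(deme={s: int(d) for s, d in zip(sample_ids, demes)})
    by_contig: dict[str, list] = {}
    ann_rows = []
    for spec in cfg.resistance:
        freq = np.array([spec.deme_freq[d % len(spec.deme_freq)] for d in demes])
        hap = (rng.random((cfg.n_samples, 2)) < freq[:, None]).astype(np.int8)
        ref, alt = _ref_alt(rng, 1)
        by_contig.setdefault(spec.contig, []).append(
            (spec.position, ref[0], alt[0], hap)
        )
        ann_rows.append(
            {
                "contig": spec.contig,
                "position": spec.position,
                "alt": alt[0],
                "gene_id": spec.gene_id,
                "gene_name": spec.gene_name,
                "aa_change": spec.aa_change,
                "effect": "non-synonymous",
            }
        )
        truth.resistance_freq.append(
            {
                "gene_id": spec.gene_id,
                "aa_change": spec.aa_change,
                "contig": spec.contig,
                "position": spec.position,
                "deme_freq": list(spec.deme_freq),
            }
        )
    datasets = {}
    for contig, rows in by_contig.items():
        rows.sort(key=lambda r: r[0])
        hap = np.empty((2 * cfg.n_samples, len(rows)), dtype=np.int8)
        for j, (_, _, _, h) in enumerate(rows):
            hap[0::2, j] = h[:, 0]
            hap[1::2, j] = h[:, 1]
        datasets[contig] = VariantDataset(
            contig=contig,
            positions=np.array([r[0] for r in rows], dtype=np.int64),
            ref=np.array([r[1] for r in rows], dtype="U1"),
            alt=np.array([r[2] for r in rows], dtype="U1"),
            genotypes=hap[0::2] + hap[1::2],
            sample_ids=sample_ids,
            haplotypes=hap,
        )
    annotation = pd.DataFrame(ann_rows)
    return datasets, annotation, truth


# ---------------------------------------------------------------------------
# Full-study assembly and fixture bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    structure: VariantDataset  # phased, with planted sweep
    samples: pd.DataFrame
    inversions: dict[str, tuple[VariantDataset, InversionSpec]]
    coverage: CoverageMatrix
    aims: VariantDataset
    arab_panel: pd.DataFrame
    colu_panel: pd.DataFrame
    resistance: dict[str, VariantDataset]
    annotation: pd.DataFrame
    genes: pd.DataFrame
    known_loci: pd.DataFrame
    truth: TruthSet


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Assemble a coherent synthetic study: structured genotypes carrying a
    planted sweep, inversion tag SNPs, coverage with amplifications, AIM
    panels and resistance sites, all for one shared set of samples."""
    ds, samples, truth = simulate_two_deme_genotypes(cfg)
    # overlay the sweep on deme `sw.deme` haplotype rows of the 3L data
    sw = cfg.sweep
    if sw.swept_fraction > 0 and sw.end_snp < cfg.n_variants:
        rng = np.random.default_rng(cfg.seed + 5)
        demes2 = np.repeat(cfg.deme_of_samples(), 2)
        rows = np.flatnonzero(demes2 == sw.deme)
        n_swept = int(round(sw.swept_fraction * rows.size))
        swept_rows = rng.choice(rows, size=n_swept, replace=False)
        cols = slice(sw.start_snp, sw.end_snp + 1)
        width = sw.end_snp - sw.start_snp + 1
        cores = (rng.random((sw.n_core, width)) < 0.5).astype(np.int8)
        hap = ds.haplotypes.copy()
        hap[swept_rows, cols] = cores[swept_rows % sw.n_core]
        ds = VariantDataset(
            contig=ds.contig,
            positions=ds.positions,
            ref=ds.ref,
            alt=ds.alt,
            genotypes=hap[0::2] + hap[1::2],
            sample_ids=ds.sample_ids,
            haplotypes=hap,
        )
        truth.sweep = {
            "contig": cfg.contig,
            "start": int(ds.positions[sw.start_snp]),
            "end": int(ds.positions[sw.end_snp]),
            "start_snp": sw.start_snp,
            "end_snp": sw.end_snp,
            "swept_fraction": sw.swept_fraction,
            "n_core": sw.n_core,
            "deme": sw.deme,
        }

    inversions = {}
    for k, inv in enumerate(cfg.inversions):
        sub = _with_seed(cfg, cfg.seed + 10 + k)
        inv_ds, inv_truth = simulate_inversion_cohort(sub, inv)
        inversions[inv.name] = (inv_ds, inv)
        truth.karyotype.update(inv_truth.karyotype)

    coverage, cov_truth = simulate_coverage(cfg, sex=samples["sex"].to_numpy())
    truth.cnv_intervals = cov_truth.cnv_intervals

    aims, arab_panel, colu_panel, aim_truth = simulate_aim_panel(cfg)
    truth.taxon = aim_truth.taxon

    resistance, annotation, res_truth = simulate_resistance_sites(cfg)
    truth.resistance_freq = res_truth.resistance_freq

    genes = _gene_table(cfg)
    known_loci = _known_loci(cfg, truth)
    return StudyData(
        config=cfg,
        structure=ds,
        samples=samples,
        inversions=inversions,
        coverage=coverage,
        aims=aims,
        arab_panel=arab_panel,
        colu_panel=colu_panel,
        resistance=resistance,
        annotation=annotation,
        genes=genes,
        known_loci=known_loci,
        truth=truth,
    )


def _with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    import copy

    out = copy.deepcopy(cfg)
    out.seed = seed
    return out


def _gene_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene intervals covering the planted CNVs plus the resistance loci."""
    rows = []
    cov = cfg.coverage
    starts = cov.start + cov.window_size * np.arange(cov.n_windows)
    for c in cov.cnvs:
        g_start = int(starts[c.start_window])
        g_end = int(starts[c.start_window + c.n_windows - 1] + cov.window_size - 1)
        rows.append(
            {"contig": cov.contig, "start": g_start, "end": g_end, "gene_id": c.gene_id}
        )
    for spec in cfg.resistance:
        rows.append(
            {
                "contig": spec.contig,
                "start": spec.position - 1000,
                "end": spec.position + 1000,
                "gene_id": spec.gene_id,
            }
        )
    return pd.DataFrame(rows).drop_duplicates(subset="gene_id").reset_index(drop=True)


def _known_loci(cfg: SimulationConfig, truth: TruthSet) -> pd.DataFrame:
    rows = [
        {"name": "Vgsc", "contig": "2L", "start": 2_358_158, "end": 2_431_617},
        {"name": "Rdl", "contig": "2L", "start": 25_363_652, "end": 25_434_556},
        {"name": "Ace1", "contig": "2R", "start": 3_484_107, "end": 3_495_790},
        {"name": "Gste2", "contig": "3R", "start": 28_597_652, "end": 28_598_416},
    ]
    if truth.sweep:
        rows.append(
            {
                "name": "planted_sweep",
                "contig": truth.sweep["contig"],
                "start": truth.sweep["start"],
                "end": truth.sweep["end"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=agpopgen-synthetic
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(datasets: list[VariantDataset], path: str | Path) -> None:
    """Write one or more single-contig datasets (same samples, ordered by
    contig then position) as an uncompressed VCF 4.2 file."""
    if not datasets:
        raise ValueError("no datasets to write")
    sample_ids = datasets[0].sample_ids
    for ds in datasets:
        if ds.sample_ids != sample_ids:
            raise ValueError("all datasets must share the same samples")
    contigs = "".join(
        f"##contig=<ID={ds.contig}>\n" for ds in datasets
    )
    lines = [_VCF_HEADER.format(contigs=contigs, samples="\t".join(sample_ids))]
    for ds in datasets:
        phased = ds.haplotypes is not None
        for j in range(ds.n_variants):
            if phased:
                a = ds.haplotypes[0::2, j]
                b = ds.haplotypes[1::2, j]
                gt = [f"{x}|{y}" for x, y in zip(a, b)]
            else:
                g = ds.genotypes[:, j]
                gt = ["./." if x == MISSING else ("0/0", "0/1", "1/1")[x] for x in g]
            lines.append(
                f"{ds.contig}\t{ds.positions[j]}\t.\t{ds.ref[j]}\t{ds.alt[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt)
                + "\n"
            )
    Path(path).write_text("".join(lines))


def write_fixture_bundle(study: StudyData, directory: str | Path) -> dict[str, Path]:
    """Write the study to a directory of plain-text files.

    Layout: ``variants.vcf`` (all contigs, phased), ``samples.tsv``,
    ``coverage.tsv``, ``annotation.tsv``, ``aim_panel_arab.tsv``,
    ``aim_panel_colu.tsv``, ``tag_snps.tsv``, ``genes.bed`` (0-based
    half-open), ``known_loci.tsv`` and ``truth.json``. Deterministic given
    the config seed: no timestamps are embedded.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}

    all_ds = [study.structure] + [ds for ds, _ in study.inversions.values()]
    all_ds += list(study.resistance.values()) + [study.aims]
    # merge datasets sharing a contig (e.g. tag SNPs and resistance on 2L)
    merged = _merge_by_contig(all_ds)
    paths["vcf"] = d / "variants.vcf"
    write_vcf(merged, paths["vcf"])

    paths["samples"] = d / "samples.tsv"
    study.samples.to_csv(paths["samples"], sep="\t", index=False)

    paths["coverage"] = d / "coverage.tsv"
    study.coverage.to_tsv(paths["coverage"])

    paths["annotation"] = d / "annotation.tsv"
    study.annotation.to_csv(paths["annotation"], sep="\t", index=False)

    paths["aim_panel_arab"] = d / "aim_panel_arab.tsv"
    study.arab_panel.to_csv(paths["aim_panel_arab"], sep="\t", index=False)
    paths["aim_panel_colu"] = d / "aim_panel_colu.tsv"
    study.colu_panel.to_csv(paths["aim_panel_colu"], sep="\t", index=False)

    tag_rows = []
    for name, (ds, inv) in study.inversions.items():
        for j in range(ds.n_variants):
            tag_rows.append(
                {
                    "inversion": name,
                    "contig": ds.contig,
                    "position": int(ds.positions[j]),
                    "inverted_allele": ds.alt[j],
                    "region_start": inv.start,
                    "region_end": inv.end,
                }
            )
    paths["tag_snps"] = d / "tag_snps.tsv"
    pd.DataFrame(tag_rows).to_csv(paths["tag_snps"], sep="\t", index=False)

    paths["genes"] = d / "genes.bed"
    bed = study.genes.copy()
    bed["start"] = bed["start"] - 1  # BED is 0-based half-open
    bed[["contig", "start", "end", "gene_id"]].to_csv(
        paths["genes"], sep="\t", index=False, header=False
    )

    paths["known_loci"] = d / "known_loci.tsv"
    study.known_loci.to_csv(paths["known_loci"], sep="\t", index=False)

    paths["truth"] = d / "truth.json"
    study.truth.to_json(paths["truth"])
    return paths


def _merge_by_contig(datasets: list[VariantDataset]) -> list[VariantDataset]:
    by_contig: dict[str, list[VariantDataset]] = {}
    for ds in datasets:
        by_contig.setdefault(ds.contig, []).append(ds)
    out = []
    for contig in sorted(by_contig):
        group = by_contig[contig]
        if len(group) == 1:
            out.append(group[0])
            continue
        pos = np.concatenate([g.positions for g in group])
        order = np.argsort(pos)
        if np.unique(pos).size != pos.size:
            raise ValueError(f"position collision on contig {contig}")
        hap = (
            np.concatenate([g.haplotypes for g in group], axis=1)[:, order]
            if all(g.haplotypes is not None for g in group)
            else None
        )
        geno = np.concatenate([g.genotypes for g in group], axis=1)[:, order]
        out.append(
            VariantDataset(
                contig=contig,
                positions=pos[order],
                ref=np.concatenate([g.ref for g in group])[order],
                alt=np.concatenate([g.alt for g in group])[order],
                genotypes=geno,
                sample_ids=group[0].sample_ids,
                haplotypes=hap,
            )
        )
    return out
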