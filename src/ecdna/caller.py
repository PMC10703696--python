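"""Per-cell detection of focal amplifications from single-nucleus ATAC fragments.

A cell carries an extrachromosomal amplification when its fragment coverage at
the amplicon, scaled to region length, is extreme relative to a Monte Carlo
null of length-matched random genomic regions. Per cell, the empirical p-value
is (r + 1) / (n + 1) where r counts null regions whose scaled coverage is at
least the observed value; Benjamini-Hochberg correction is applied across
cells separately per amplicon and cells with q below the FDR threshold
(default 0.10) are called positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, GenomeExhaustedError
from .genome import FragmentIndex, Genome, GenomicInterval, RegionSet


@dataclass(frozen=True)
class CellQCThresholds:
    """Barcode retention thresholds for the multiome assay."""

    mito_frac_max: float = 0.1
    atac_min: int = 1_000
    atac_max: int = 70_000
    rna_min: int = 500
    rna_max: int = 25_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.mito_frac_max <= 1.0):
            raise ValueError("mito_frac_max must be in [0, 1]")
        if self.atac_min >= self.atac_max or self.rna_min >= self.rna_max:
            raise ValueError("QC ranges must satisfy min < max")


@dataclass(frozen=True)
class CellQCStats:
    barcode: str
    atac_fragments: int
    mito_fragments: int
    rna_counts: int | None = None

    def __post_init__(self) -> None:
        if self.mito_fragments > self.atac_fragments:
            raise ValueError(
                f"{self.barcode}: mito fragments exceed total ATAC fragments"
            )


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1_000
    q_threshold: float = 0.10
    seed: int = 0
    region_length_mode: str = "match_amplicon"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q_threshold must be in (0, 1)")
        if self.region_length_mode != "match_amplicon":
            raise ValueError(
                f"unsupported region_length_mode {self.region_length_mode!r}"
            )


@dataclass(frozen=True)
class CellAmpliconResult:
    """One cell's coverage test at one amplicon."""

    barcode: str
    amplicon_name: str
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN flags an indeterminate (zero-variance null) cell
    r_exceed: int
    p_emp: float
    q: float
    called: bool


@dataclass
class CoOccurrenceSummary:
    """Cells partitioned by the combination of amplicons they were called for."""

    counts: dict[str, int] = field(default_factory=dict)
    total_cells: int = 0

    def __post_init__(self) -> None:
        if self.counts and sum(self.counts.values()) != self.total_cells:
            raise ValueError("category counts must partition the cells")


def apply_cell_qc(
    stats_seq: Sequence[CellQCStats],
    thresholds: CellQCThresholds = CellQCThresholds(),
) -> list[str]:
    """Return barcodes passing QC, in input order.

    A barcode is retained iff mito fraction < mito_frac_max, the ATAC fragment
    count lies in [atac_min, atac_max], and — when an RNA count is present —
    it lies in [rna_min, rna_max]. A cell with zero ATAC fragments is
    rejected, not an error.
    """
    if not stats_seq:
        raise ValueError("empty QC stats")
    kept: list[str] = []
    for s in stats_seq:
        if s.atac_fragments == 0:
            continue
        if s.mito_fragments / s.atac_fragments >= thresholds.mito_frac_max:
            continue
        if not (thresholds.atac_min <= s.atac_fragments <= thresholds.atac_max):
            continue
        if s.rna_counts is not None and not (
            thresholds.rna_min <= s.rna_counts <= thresholds.rna_max
        ):
            continue
        kept.append(s.barcode)
    return kept


def qc_stats_from_frame(frame: pd.DataFrame) -> list[CellQCStats]:
    """Build QC records from a table with columns barcode, atac_fragments,
    mito_fragments and optionally rna_counts."""
    has_rna = "rna_counts" in frame.columns
    return [
        CellQCStats(
            barcode=str(row.barcode),
            atac_fragments=int(row.atac_fragments),
            mito_fragments=int(row.mito_fragments),
            rna_counts=int(row.rna_counts) if has_rna else None,
        )
        for row in frame.itertuples(index=False)
    ]


def _admissible_start_segments(
    chrom_len: int, length: int, exclusions: list[GenomicInterval]
) -> list[tuple[int, int]]:
    """Half-open segments of admissible start positions on one chromosome.

    A start s is admissible when [s, s+length) lies inside the chromosome and
    is disjoint from every exclusion; an exclusion [a, b) forbids starts in
    [a - length + 1, b).
    """
    limit = chrom_len - length + 1  # starts live in [0, limit)
    if limit <= 0:
        return []
    blocked = sorted(
        (max(0, iv.start - length + 1), min(iv.end, limit)) for iv in exclusions
    )
    segments: list[tuple[int, int]] = []
    cursor = 0
    for a, b in blocked:
        if b <= cursor:
            continue
        if a > cursor:
            segments.append((cursor, min(a, limit)))
        cursor = max(cursor, b)
        if cursor >= limit:
            break
    if cursor < limit:
        segments.append((cursor, limit))
    return [(a, b) for a, b in segments if b > a]


def sample_null_regions(
    genome: Genome,
    exclusions: RegionSet,
    length: int,
    n: int,
    seed: int | np.random.Generator,
) -> RegionSet:
    """Draw n random contiguous regions of a fixed length, avoiding exclusions.

    Chromosomes are chosen with probability proportional to their admissible
    start space, so placement is uniform over all admissible positions
    genome-wide. Deterministic given the seed.
    """
    if length < 1:
        raise ValueError("region length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclusions.intervals:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)

    chrom_segments: list[tuple[str, list[tuple[int, int]], int]] = []
    for chrom, size in genome.items():
        segs = _admissible_start_segments(size, length, excl_by_chrom.get(chrom, []))
        total = sum(b - a for a, b in segs)
        if total > 0:
            chrom_segments.append((chrom, segs, total))
    grand_total = sum(t for _, _, t in chrom_segments)
    if grand_total == 0:
        raise GenomeExhaustedError(
            f"no admissible placement for a {length} bp region given the exclusions"
        )

    weights = np.array([t for _, _, t in chrom_segments], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(chrom_segments), size=n, p=weights)
    intervals: list[GenomicInterval] = []
    for ci in chrom_idx:
        chrom, segs, total = chrom_segments[ci]
        offset = int(rng.integers(total))
        for a, b in segs:
            span = b - a
            if offset < span:
                start = a + offset
                break
            offset -= span
        intervals.append(GenomicInterval(chrom, start, start + length))
    return RegionSet(name=f"null_L{length}", intervals=tuple(intervals))


def scaled_coverage(
    index: FragmentIndex, region: GenomicInterval | RegionSet
) -> np.ndarray:
    """Per-barcode fragments-per-bp over a region or multi-segment amplicon.

    Multi-segment amplicons pool counts over segments and divide by the summed
    segment length.
    """
    if isinstance(region, GenomicInterval):
        intervals: Sequence[GenomicInterval] = [region]
        total_len = region.length
    else:
        intervals = region.intervals
        total_len = region.total_length
    if total_len <= 0:
        raise ValueError("region length must be positive")
    return index.count_overlaps(list(intervals)) / float(total_len)


def empirical_pvalue(
    observed: float, null_values: Sequence[float] | np.ndarray
) -> tuple[int, float]:
    """Monte Carlo empirical p-value (r + 1)/(n + 1); ties count as exceeding."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    r = int(np.sum(null >= observed))
    return r, (r + 1) / (null.size + 1)


def zscore(observed: float, null_values: Sequence[float] | np.ndarray) -> float:
    """Standardized coverage against the Monte Carlo null (sd with ddof=1).

    Returns NaN when the null has zero variance; callers must treat that cell
    as indeterminate rather than as evidence either way.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size < 2:
        raise ValueError("need >= 2 null values for a z-score")
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        return float("nan")
    return (observed - float(null.mean())) / sd


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_cells(
    index: FragmentIndex,
    amplicons: Mapping[str, RegionSet],
    exclusions: RegionSet,
    genome: Genome,
    config: PermutationConfig = PermutationConfig(),
) -> tuple[pd.DataFrame, CoOccurrenceSummary]:
    """Run the Monte Carlo permutation test for every cell at every amplicon.

    One shared set of ``n_permutations`` null regions is drawn per amplicon,
    length-matched to the amplicon's total footprint; the exclusion set always
    includes every declared amplicon in addition to the user's exclusions.
    BH correction is applied across cells separately per amplicon.

    Returns a tidy per-(cell, amplicon) results table plus a co-occurrence
    summary partitioning cells by the set of amplicons they were called for.
    """
    if not amplicons:
        raise ValueError("no amplicons supplied")
    for name, amp in amplicons.items():
        for seg in amp.intervals:
            if not genome.contains(seg):
                raise ConfigurationError(f"amplicon {name} segment outside genome")
            for excl in exclusions.intervals:
                if seg.overlaps(excl):
                    raise ConfigurationError(
                        f"amplicon {name} overlaps exclusion region "
                        f"{excl.chrom}:{excl.start}-{excl.end}"
                    )

    amplicon_footprint = [seg for amp in amplicons.values() for seg in amp.intervals]
    sampler_exclusions = RegionSet(
        name="exclusions+amplicons",
        intervals=tuple(exclusions.intervals) + tuple(amplicon_footprint),
    )

    seed_seq = np.random.SeedSequence(config.seed)
    child_seeds = seed_seq.spawn(len(amplicons))

    frames: list[pd.DataFrame] = []
    called_sets: dict[str, set[str]] = {b: set() for b in index.barcodes}
    for (name, amp), child in zip(amplicons.items(), child_seeds):
        rng = np.random.default_rng(child)
        nulls = sample_null_regions(
            genome, sampler_exclusions, amp.total_length, config.n_permutations, rng
        )
        observed = scaled_coverage(index, amp)
        null_matrix = np.empty((index.n_barcodes, config.n_permutations))
        for j, region in enumerate(nulls.intervals):
            null_matrix[:, j] = scaled_coverage(index, region)

        null_mean = null_matrix.mean(axis=1)
        null_sd = null_matrix.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
        r_exceed = (null_matrix >= observed[:, None]).sum(axis=1)
        p_emp = (r_exceed + 1) / (config.n_permutations + 1)
        q = bh_adjust(p_emp)
        called = q < config.q_threshold

        frames.append(
            pd.DataFrame(
                {
                    "barcode": index.barcodes,
                    "amplicon": name,
                    "observed": observed,
                    "null_mean": null_mean,
                    "null_sd": null_sd,
                    "z": z,
                    "r_exceed": r_exceed,
                    "p_emp": p_emp,
                    "q": q,
                    "called": called,
                }
            )
        )
        for barcode, flag in zip(index.barcodes, called):
            if flag:
                called_sets[barcode].add(name)

    results = pd.concat(frames, ignore_index=True)

    counts: dict[str, int] = {}
    for barcode in index.barcodes:
        names = sorted(called_sets[barcode])
        key = "none" if not names else "+".join(names)
        counts[key] = counts.get(key, 0) + 1
    summary = CoOccurrenceSummary(counts=counts, total_cells=index.n_barcodes)
    return results, summary


def correlate_scores(
    z_by_cell: Mapping[str, float], score_by_cell: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation of per-cell z-scores with an external per-cell score
    (e.g. a gene-set enrichment score), over the barcode intersection."""
    shared = sorted(set(z_by_cell) & set(score_by_cell))
    if len(shared) < 3:
        raise ValueError("need >= 3 cells present in both mappings")
    x = np.array([z_by_cell[b] for b in shared], dtype=float)
    y = np.array([score_by_cell[b] for b in shared], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in z-scores or scores")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
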