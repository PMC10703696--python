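"""WGS sample fingerprinting by allele-fraction correlation at a SNP panel.

Biosamples from the same patient share germline genotypes, so their variant
allele fractions across ~1,000 common polymorphic sites correlate strongly;
pairs with Pearson r above 0.80 are flagged as same-patient duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PanelLocus:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str


@dataclass(frozen=True)
class AllelePanel:
    loci: tuple[PanelLocus, ...]

    def __post_init__(self) -> None:
        keys = [(l.chrom, l.pos) for l in self.loci]
        if len(set(keys)) != len(keys):
            raise ValueError("panel loci must be unique")

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class SampleAlleleCounts:
    sample_id: str
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if self.ref_counts.shape != self.alt_counts.shape:
            raise ValueError("ref and alt count arrays must align")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("allele counts must be non-negative")


@dataclass
class FingerprintResult:
    sample_ids: list[str]
    correlation: pd.DataFrame  # sample x sample Pearson r (NaN = indeterminate)
    shared_loci: pd.DataFrame  # co-observed locus counts per pair
    duplicate_pairs: list[tuple[str, str]]
    indeterminate_pairs: list[tuple[str, str]]
    threshold: float


def vaf_vector(
    counts: SampleAlleleCounts, min_depth: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus variant allele fraction and an observed (depth >= min_depth) mask."""
    depth = counts.ref_counts + counts.alt_counts
    observed = depth >= max(min_depth, 1)
    vaf = np.full(depth.shape, np.nan)
    np.divide(counts.alt_counts, depth, out=vaf, where=observed)
    return vaf, observed


def pairwise_fingerprint(
    samples: Sequence[SampleAlleleCounts],
    threshold: float = 0.80,
    min_shared: int = 100,
    min_depth: int = 1,
) -> FingerprintResult:
    """Pairwise Pearson correlation of VAF vectors over co-observed loci.

    Pairs with fewer than ``min_shared`` co-observed loci, or with zero VAF
    variance in either sample over the shared loci, are indeterminate (r is
    NaN). Duplicate pairs are those with r > threshold.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    vafs, masks = zip(*(vaf_vector(s, min_depth) for s in samples))

    k = len(samples)
    r_mat = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    duplicates: list[tuple[str, str]] = []
    indeterminate: list[tuple[str, str]] = []
    for i in range(k):
        if np.nanstd(vafs[i][masks[i]]) > 0 if masks[i].any() else False:
            r_mat[i, i] = 1.0
        n_mat[i, i] = int(masks[i].sum())
        for j in range(i + 1, k):
            both = masks[i] & masks[j]
            n_shared = int(both.sum())
            n_mat[i, j] = n_mat[j, i] = n_shared
            x, y = vafs[i][both], vafs[j][both]
            if n_shared < min_shared or x.std() == 0 or y.std() == 0:
                indeterminate.append((ids[i], ids[j]))
                continue
            r, _ = stats.pearsonr(x, y)
            r_mat[i, j] = r_mat[j, i] = float(r)
            if r > threshold:
                duplicates.append((ids[i], ids[j]))

    return FingerprintResult(
        sample_ids=ids,
        correlation=pd.DataFrame(r_mat, index=ids, columns=ids),
        shared_loci=pd.DataFrame(n_mat, index=ids, columns=ids),
        duplicate_pairs=duplicates,
        indeterminate_pairs=indeterminate,
        threshold=threshold,
    )


def read_panel(path) -> AllelePanel:
    """Read a BED-like panel TSV: chrom, pos0, pos1, ref, alt."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos0", "pos1", "ref", "alt"],
        comment="#",
    )
    loci = tuple(
        PanelLocus(str(r.chrom), int(r.pos0), str(r.ref), str(r.alt))
        for r in frame.itertuples(index=False)
    )
    return AllelePanel(loci)


def read_counts(path, panel_size: int | None = None) -> list[SampleAlleleCounts]:
    """Read a long-format counts TSV: sample, locus_index, ref_count, alt_count."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample", "locus_index", "ref_count", "alt_count"}
    if not required.issubset(frame.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    size = panel_size or int(frame["locus_index"].max()) + 1
    out = []
    for sample_id, grp in frame.groupby("sample", sort=False):
        ref = np.zeros(size, dtype=np.int64)
        alt = np.zeros(size, dtype=np.int64)
        idx = grp["locus_index"].to_numpy()
        ref[idx] = grp["ref_count"].to_numpy()
        alt[idx] = grp["alt_count"].to_numpy()
        out.append(SampleAlleleCounts(str(sample_id), ref, alt))
    return out
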