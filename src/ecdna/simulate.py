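"""Synthetic input generators with known ground truth.

Every generator is a pure function of its config and seed, and emulates one
of the pipeline's four input kinds: single-nucleus ATAC fragments with
elevated amplicon coverage in ecDNA+ cells, FISH images of nuclei with
Gaussian hybridization spots, binomial allele counts at a SNP panel, and
survival cohorts drawn from a log-normal AFT model with a binary mediator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genome import FragmentIndex, Genome, GenomicInterval, RegionSet
from .survival import ContingencyTable2x2

# ---------------------------------------------------------------------------
# snATAC fragments
# ---------------------------------------------------------------------------

DEFAULT_GENOME = Genome(
    {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000, "chrM": 16_569}
)
DEFAULT_AMPLICONS = {
    "amp1": RegionSet("amp1", (GenomicInterval("chr1", 3_000_000, 3_300_000),)),
    "amp2": RegionSet("amp2", (GenomicInterval("chr2", 5_000_000, 5_200_000),)),
}


@dataclass
class FragmentSimConfig:
    """Toy-genome snATAC simulation: Poisson background coverage everywhere,
    with per-bp fragment rate multiplied by CN/2 inside the amplicon for
    ecDNA+ cells at heterogeneous integer copy number."""

    n_cells: int = 2_000
    fraction_positive: float = 0.10  # per amplicon, independent assignment
    cn_log_mean: float = float(np.log(20.0))  # integer log-normal, median 20
    cn_log_sd: float = 0.4
    cn_min: int = 5
    background_mean: float = 5_000.0  # Poisson fragments per cell
    frag_len_range: tuple[int, int] = (100, 300)
    mito_chrom: str = "chrM"
    mito_beta: tuple[float, float] = (2.0, 48.0)  # mito fraction ~ Beta(a, b)
    rna_log_mean: float = float(np.log(5_000.0))
    rna_log_sd: float = 0.3
    seed: int = 0


@dataclass
class FragmentSim:
    """Generated fragments plus QC table and per-cell copy-number truth."""

    genome: Genome
    amplicons: dict[str, RegionSet]
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    barcodes: np.ndarray
    supports: np.ndarray
    barcode_universe: list[str]
    qc: pd.DataFrame  # barcode, atac_fragments, mito_fragments, rna_counts
    truth: pd.DataFrame  # barcode, amplicon, copy_number
    config: FragmentSimConfig

    def fragment_index(self) -> FragmentIndex:
        return FragmentIndex.from_arrays(
            self.chroms, self.starts, self.ends, self.barcodes, self.barcode_universe
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "barcode": self.barcodes,
                "count": self.supports,
            }
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(
            outdir / "fragments.tsv", sep="\t", header=False, index=False
        )
        self.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth" / "copy_number.tsv", sep="\t", index=False)
        with open(outdir / "chrom.sizes", "wt") as fh:
            for name, size in self.genome.items():
                fh.write(f"{name}\t{size}\n")
        with open(outdir / "amplicons.bed", "wt") as fh:
            for name, amp in self.amplicons.items():
                for iv in amp.intervals:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
        _write_manifest(outdir, asdict(self.config))


def gen_fragments(
    config: FragmentSimConfig = FragmentSimConfig(),
    genome: Genome = DEFAULT_GENOME,
    amplicons: Mapping[str, RegionSet] | None = None,
) -> FragmentSim:
    """Simulate a fragments table, QC table and copy-number truth.

    Background fragments are uniform over the non-mitochondrial genome with a
    Poisson per-cell total; a cell positive for an amplicon at copy number k
    receives additional amplicon fragments so its expected per-bp rate there
    is k/2 times the background rate. Mitochondrial fragments are appended so
    the per-cell mito fraction follows the configured Beta distribution.
    """
    amplicons = dict(amplicons if amplicons is not None else DEFAULT_AMPLICONS)
    for name, amp in amplicons.items():
        for iv in amp.intervals:
            if not genome.contains(iv):
                raise ConfigurationError(f"amplicon {name} outside the genome")
            if iv.chrom == config.mito_chrom:
                raise ConfigurationError(f"amplicon {name} on the mitochondrial contig")

    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    barcode_universe = [f"CELL{i:05d}" for i in range(n)]

    nuclear = [(c, genome[c]) for c in genome if c != config.mito_chrom]
    nuc_names = np.array([c for c, _ in nuclear])
    nuc_lengths = np.array([s for _, s in nuclear], dtype=np.int64)
    genome_len = int(nuc_lengths.sum())

    # --- background fragments
    n_bg = rng.poisson(config.background_mean, size=n)
    total_bg = int(n_bg.sum())
    bg_cell = np.repeat(np.arange(n), n_bg)
    chrom_idx = rng.choice(len(nuclear), size=total_bg, p=nuc_lengths / genome_len)
    lo, hi = config.frag_len_range
    bg_len = rng.integers(lo, hi + 1, size=total_bg)
    bg_start = (rng.random(total_bg) * (nuc_lengths[chrom_idx] - bg_len)).astype(np.int64)
    bg_chrom = nuc_names[chrom_idx]
    bg_end = bg_start + bg_len

    # --- amplicon truth and extra fragments
    truth_rows = []
    extra_chrom, extra_start, extra_end, extra_cell = [], [], [], []
    for name, amp in amplicons.items():
        positive = rng.random(n) < config.fraction_positive
        cn = np.full(n, 2, dtype=np.int64)
        raw = np.exp(rng.normal(config.cn_log_mean, config.cn_log_sd, size=n))
        cn[positive] = np.maximum(np.rint(raw[positive]), config.cn_min).astype(np.int64)
        lam = (
            config.background_mean
            * (amp.total_length / genome_len)
            * np.clip(cn / 2.0 - 1.0, 0.0, None)
        )
        n_extra = rng.poisson(lam)
        total_extra = int(n_extra.sum())
        if total_extra:
            seg_lengths = np.array([iv.length for iv in amp.intervals], dtype=float)
            seg_idx = rng.choice(
                len(amp.intervals), size=total_extra, p=seg_lengths / seg_lengths.sum()
            )
            flen = rng.integers(lo, hi + 1, size=total_extra)
            for i, iv in enumerate(amp.intervals):
                sel = seg_idx == i
                cnt = int(sel.sum())
                if cnt == 0:
                    continue
                # keep extra fragments inside the segment so they all overlap it
                span = np.maximum(iv.length - flen[sel], 1)
                s = iv.start + (rng.random(cnt) * span).astype(np.int64)
                extra_start.append(s)
                extra_end.append(s + flen[sel])
                extra_chrom.append(np.full(cnt, iv.chrom))
                extra_cell.append(np.repeat(np.arange(n), n_extra)[sel])
        truth_rows.append(
            pd.DataFrame(
                {"barcode": barcode_universe, "amplicon": name, "copy_number": cn}
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)

    # --- mitochondrial fragments
    mito_frac = rng.beta(*config.mito_beta, size=n)
    n_mito = rng.poisson(n_bg * mito_frac / (1.0 - mito_frac))
    total_mito = int(n_mito.sum())
    mito_len_cap = min(hi, genome[config.mito_chrom] - 1)
    m_len = rng.integers(lo, mito_len_cap + 1, size=total_mito) if total_mito else np.array([], dtype=np.int64)
    m_start = (
        (rng.random(total_mito) * (genome[config.mito_chrom] - m_len)).astype(np.int64)
        if total_mito
        else np.array([], dtype=np.int64)
    )

    chroms = np.concatenate(
        [bg_chrom]
        + (extra_chrom or [np.array([], dtype=bg_chrom.dtype)])
        + [np.full(total_mito, config.mito_chrom)]
    )
    starts = np.concatenate(
        [bg_start] + (extra_start or [np.array([], dtype=np.int64)]) + [m_start]
    )
    ends = np.concatenate(
        [bg_end] + (extra_end or [np.array([], dtype=np.int64)]) + [m_start + m_len]
    )
    cells = np.concatenate(
        [bg_cell]
        + (extra_cell or [np.array([], dtype=np.int64)])
        + [np.repeat(np.arange(n), n_mito)]
    )
    supports = 1 + rng.poisson(0.3, size=len(starts))

    # deterministic file order: chrom, start, cell
    order = np.lexsort((cells, starts, chroms))
    chroms, starts, ends = chroms[order], starts[order], ends[order]
    cells, supports = cells[order], supports[order]
    barcodes = np.array(barcode_universe, dtype=object)[cells]

    extra_per_cell = np.zeros(n, dtype=np.int64)
    np.add.at(extra_per_cell, np.concatenate(extra_cell) if extra_cell else np.array([], dtype=np.int64), 1)
    rna = np.rint(np.exp(rng.normal(config.rna_log_mean, config.rna_log_sd, size=n))).astype(int)
    qc = pd.DataFrame(
        {
            "barcode": barcode_universe,
            "atac_fragments": n_bg + extra_per_cell + n_mito,
            "mito_fragments": n_mito,
            "rna_counts": rna,
        }
    )
    return FragmentSim(
        genome=genome,
        amplicons=amplicons,
        chroms=chroms,
        starts=starts,
        ends=ends,
        barcodes=barcodes,
        supports=supports,
        barcode_universe=barcode_universe,
        qc=qc,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# FISH images
# ---------------------------------------------------------------------------


@dataclass
class FishSimConfig:
    """Nuclei as disjoint disks; per-cell spot counts from a background/
    amplified Poisson mixture; spots rendered as small Gaussian peaks."""

    canvas: tuple[int, int] = (1_200, 1_200)
    n_nuclei: int = 10
    radius_range: tuple[int, int] = (45, 55)
    background_mean: float = 2.0  # Poisson spot count, non-amplified cells
    amplified_mean: float = 20.0
    amplified_fraction: float = 0.3
    spot_amplitude: float = 200.0
    spot_sd: float = 1.0
    min_separation: float = 12.0  # 4x the detector's smoothing sd
    nucleus_intensity: float = 8.0  # faint FISH-channel background in nuclei
    noise_sd: float = 0.0
    seed: int = 0
    max_placement_tries: int = 200


@dataclass
class FishSim:
    image: np.ndarray  # uint8 FISH channel
    mask: np.ndarray  # uint16 labels, 0 = background
    dapi: np.ndarray  # uint8 nucleus channel, for fallback segmentation
    truth: pd.DataFrame  # cell_id, spot_count (achieved), amplified
    config: FishSimConfig

    def write(self, outdir: str | Path) -> None:
        import tifffile

        outdir = Path(outdir)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / "fish.tif", self.image)
        tifffile.imwrite(outdir / "mask.tif", self.mask)
        tifffile.imwrite(outdir / "dapi.tif", self.dapi)
        self.truth.to_csv(outdir / "truth" / "spot_counts.tsv", sep="\t", index=False)
        _write_manifest(outdir, asdict(self.config))


def gen_fish_image(config: FishSimConfig = FishSimConfig()) -> FishSim:
    """Render a synthetic FISH field with a labeled mask and per-cell truth.

    Spot centers keep a global minimum pairwise separation so that the
    detector's smoothed super-threshold regions never merge; when a nucleus
    cannot host its sampled count at that separation, the count is reduced
    and the truth records the achieved value.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.canvas
    r_lo, r_hi = config.radius_range

    # place disjoint nuclei
    centers: list[tuple[float, float, float]] = []
    for _ in range(config.n_nuclei):
        for _ in range(config.max_placement_tries):
            r = rng.uniform(r_lo, r_hi)
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + 4.0) ** 2
                for oy, ox, orad in centers
            ):
                centers.append((cy, cx, r))
                break
        else:
            raise ConfigurationError("cannot place disjoint nuclei on the canvas")

    mask = np.zeros((h, w), dtype=np.uint16)
    yy, xx = np.mgrid[0:h, 0:w]
    for label, (cy, cx, r) in enumerate(centers, start=1):
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = label

    image = np.zeros((h, w), dtype=float)
    image[mask > 0] = config.nucleus_intensity

    amplified = rng.random(len(centers)) < config.amplified_fraction
    target_counts = np.where(
        amplified,
        rng.poisson(config.amplified_mean, size=len(centers)),
        rng.poisson(config.background_mean, size=len(centers)),
    )

    all_spots: list[tuple[float, float]] = []
    achieved = np.zeros(len(centers), dtype=int)
    margin = 4.0 * config.spot_sd + 1.0
    for i, (cy, cx, r) in enumerate(centers):
        placed = 0
        inner = r - margin
        tries = 0
        while placed < target_counts[i] and tries < config.max_placement_tries * (
            target_counts[i] + 1
        ):
            tries += 1
            rho = inner * np.sqrt(rng.random())
            theta = rng.uniform(0, 2 * np.pi)
            sy, sx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            if all(
                (sy - oy) ** 2 + (sx - ox) ** 2 >= config.min_separation**2
                for oy, ox in all_spots
            ):
                all_spots.append((sy, sx))
                _render_spot(image, sy, sx, config.spot_amplitude, config.spot_sd)
                placed += 1
        achieved[i] = placed

    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape)
    image8 = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    dapi = np.zeros((h, w), dtype=np.uint8)
    dapi[mask > 0] = 200

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(centers) + 1),
            "spot_count": achieved,
            "amplified": achieved > 5,
        }
    )
    return FishSim(image=image8, mask=mask, dapi=dapi, truth=truth, config=config)


def _render_spot(image: np.ndarray, cy: float, cx: float, amp: float, sd: float) -> None:
    half = int(np.ceil(5 * sd))
    y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, image.shape[0])
    x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, image.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    image[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sd**2)
    )


# ---------------------------------------------------------------------------
# Fingerprint panels and allele counts
# ---------------------------------------------------------------------------


@dataclass
class FingerprintSimConfig:
    n_patients: int = 20
    n_duplicate_pairs: int = 2  # first k patients contribute two samples each
    panel_size: int = 1_000
    depth_mean: float = 30.0
    error_rate: float = 0.01
    seed: int = 0


@dataclass
class FingerprintSim:
    panel: pd.DataFrame  # chrom, pos0, pos1, ref, alt
    counts: pd.DataFrame  # sample, locus_index, ref_count, alt_count
    truth: pd.DataFrame  # sample, patient
    config: FingerprintSimConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        self.panel.to_csv(outdir / "panel.tsv", sep="\t", header=False, index=False)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth" / "patients.tsv", sep="\t", index=False)
        _write_manifest(outdir, asdict(self.config))


def gen_fingerprints(
    config: FingerprintSimConfig = FingerprintSimConfig(),
) -> FingerprintSim:
    """Simulate allele counts at a SNP panel for a cohort with known duplicates.

    Per-locus population allele frequencies are Uniform(0.05, 0.95); each
    patient's genotype VAF in {0, 0.5, 1} follows Hardy-Weinberg; duplicate
    samples reuse their patient's genotype; alt counts are Binomial over a
    Poisson per-locus depth with a small base-calling error rate.
    """
    rng = np.random.default_rng(config.seed)
    L = config.panel_size
    freq = rng.uniform(0.05, 0.95, size=L)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=L)
    ref_base = bases[ref_idx]
    alt_base = bases[(ref_idx + rng.integers(1, 4, size=L)) % 4]
    pos = np.sort(rng.choice(50_000_000, size=L, replace=False))
    panel = pd.DataFrame(
        {"chrom": "chr1", "pos0": pos, "pos1": pos + 1, "ref": ref_base, "alt": alt_base}
    )

    genotypes = {}
    for p in range(config.n_patients):
        u = rng.random(L)
        hw = np.column_stack([(1 - freq) ** 2, 2 * freq * (1 - freq)])
        g = np.where(u < hw[:, 0], 0.0, np.where(u < hw[:, 0] + hw[:, 1], 0.5, 1.0))
        genotypes[p] = g

    samples: list[tuple[str, int]] = []
    for p in range(config.n_patients):
        samples.append((f"P{p:02d}_a", p))
        if p < config.n_duplicate_pairs:
            samples.append((f"P{p:02d}_b", p))

    rows = []
    for sample_id, patient in samples:
        g = genotypes[patient]
        p_alt = g * (1 - config.error_rate) + (1 - g) * config.error_rate
        depth = rng.poisson(config.depth_mean, size=L)
        alt = rng.binomial(depth, p_alt)
        rows.append(
            pd.DataFrame(
                {
                    "sample": sample_id,
                    "locus_index": np.arange(L),
                    "ref_count": depth - alt,
                    "alt_count": alt,
                }
            )
        )
    counts = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {"sample": [s for s, _ in samples], "patient": [p for _, p in samples]}
    )
    return FingerprintSim(panel=panel, counts=counts, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Log-normal AFT cohort with a binary mediator on the exposure->outcome
    path (exposure = TP53 alteration, mediator = ecDNA presence)."""

    n_patients: int = 500
    p_exposure: float = 0.25
    a0: float = -2.5  # logit P(M=1 | E=0)
    a1: float = 3.5  # log-odds increase for E=1
    beta0: float = 7.0  # log-days intercept (~1100 days median)
    beta_e: float = -0.3  # direct exposure effect on log-time
    beta_m: float = -0.8  # mediator effect on log-time
    sigma: float = 0.8
    censor_window: float = 4_000.0  # censoring time ~ Uniform(0, window)
    seed: int = 0


def gen_cohort(config: CohortSimConfig = CohortSimConfig()) -> tuple[pd.DataFrame, dict]:
    """Simulate a patient cohort CSV-shaped table plus the generating truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    e = (rng.random(n) < config.p_exposure).astype(int)
    logit = config.a0 + config.a1 * e
    m = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    log_t = config.beta0 + config.beta_e * e + config.beta_m * m + config.sigma * rng.normal(size=n)
    t_event = np.exp(log_t)
    t_censor = rng.uniform(0.0, config.censor_window, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    # half-open guard: survival fitters require strictly positive times
    time = np.maximum(time, 1e-6)

    subgroup = rng.choice(
        ["SHH", "Group3", "Group4", "WNT"], size=n, p=[0.3, 0.25, 0.38, 0.07]
    )
    age = np.clip(rng.normal(8.0, 4.0, size=n), 0.5, None)
    sex = rng.integers(0, 2, size=n)
    frame = pd.DataFrame(
        {
            "sample_id": [f"PT{i:04d}" for i in range(n)],
            "time_days": time,
            "event": event,
            "ecDNA": m,
            "tp53": e,
            "subgroup": subgroup,
            "age": np.round(age, 2),
            "sex": sex,
        }
    )
    truth = asdict(config)
    truth["n_events"] = int(event.sum())
    return frame, truth


@dataclass
class CoxSimConfig:
    """Single-binary-covariate cohort with exponential baseline hazard, for
    Cox coefficient recovery checks."""

    n_patients: int = 500
    p_covariate: float = 0.5
    log_hr: float = float(np.log(2.5))
    baseline_rate: float = 1.0 / 1_000.0
    censor_window: float = 3_000.0  # gives roughly 30% censoring overall
    seed: int = 0


def gen_cox_cohort(config: CoxSimConfig = CoxSimConfig()) -> tuple[pd.DataFrame, dict]:
    """Exponential proportional-hazards data: h(t|x) = rate * exp(beta x)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    x = (rng.random(n) < config.p_covariate).astype(int)
    rate = config.baseline_rate * np.exp(config.log_hr * x)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0, config.censor_window, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    frame = pd.DataFrame({"time_days": time, "event": event, "x": x})
    return frame, {"log_hr": config.log_hr, "n_events": int(event.sum())}


# ---------------------------------------------------------------------------
# Published contingency tables
# ---------------------------------------------------------------------------


def fixture_tables() -> dict[str, ContingencyTable2x2]:
    """The cohort's 2x2 association tables, built from printed subgroup counts.

    SHH vs the other subgroups by ecDNA status (30/112 SHH ecDNA+ vs 45/298
    elsewhere), and TP53 alteration by ecDNA status within SHH (12/23 vs 2/69).
    """
    return {
        "shh_vs_rest_ecdna": ContingencyTable2x2(
            30, 82, 45, 265,
            row_labels=("SHH", "other subgroups"),
            col_labels=("ecDNA+", "ecDNA-"),
        ),
        "tp53_vs_ecdna_shh": ContingencyTable2x2(
            12, 11, 2, 67,
            row_labels=("ecDNA+", "ecDNA-"),
            col_labels=("TP53 altered", "TP53 wild-type"),
        ),
    }


def _write_manifest(outdir: Path, config: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(Path(outdir) / "manifest.json", "wt") as fh:
        json.dump(config, fh, indent=2, default=_default)
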