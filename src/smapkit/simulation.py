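"""Synthetic data generation and the genotype-shuffling benchmark.

Two generators live here. ``generate_genotype_matrix`` draws a
Hardy-Weinberg panel with per-SNP minor allele frequencies, standing in
for a real cohort's genotype matrix. ``simulate_quant_batch`` emulates an
11-plex TMT batch: one variant-peptide row per SNP whose per-channel log2
reporter intensity depends on the carried genotype (noise mode for AA,
signal mode for BB, midpoint for AB), plus a pooled internal-control
channel and multiplicative channel loading biases.

The shuffling benchmark measures how much genotype corruption identity
matching tolerates: a chosen sample has ``round(alpha% x n_snps)``
positions resampled from the panel's per-SNP genotype frequencies
(``replacement_policy="any_class"``, the default, so a resampled position
may keep its class by chance) and is then scored against every candidate.
The alternative ``"different_class"`` policy forces every resampled
position to a different class drawn from the renormalized remaining
frequencies, making alpha the exact realized error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AA, AB, BB, CONTROL_LABEL, GenotypeMatrix, PeptideRow, QuantBatch
from .matching import ScoreConfig, cscore_matrix

logger = logging.getLogger(__name__)

#: Log2-intensity modes of the reporter-ion noise and signal distributions
#: (means and SDs) used as generator defaults.
NOISE_MEAN, NOISE_SD = 14.06, 1.39
SIGNAL_MEAN, SIGNAL_SD = 18.22, 1.29


@dataclass
class IntensityParams:
    """Genotype-dependent log2 intensity model for one variant peptide.

    AA channels draw from the noise mode, BB channels from the signal mode
    and AB channels from the midpoint with the average SD.
    """

    mean_noise: float = NOISE_MEAN
    sd_noise: float = NOISE_SD
    mean_signal: float = SIGNAL_MEAN
    sd_signal: float = SIGNAL_SD

    @property
    def mean_het(self) -> float:
        return 0.5 * (self.mean_noise + self.mean_signal)

    @property
    def sd_het(self) -> float:
        return 0.5 * (self.sd_noise + self.sd_signal)


@dataclass
class SimulationConfig:
    """Shuffling-benchmark configuration (panel size, alpha grid, seed)."""

    n_samples: int = 420
    n_snps: int = 500
    alphas: list[int] = field(default_factory=lambda: list(range(10, 101)))
    replicates: int = 50
    seed: int = 0
    maf_low: float = 0.05
    maf_high: float = 0.5
    replacement_policy: str = "any_class"

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need n_samples >= 2")
        if any(a < 0 or a > 100 for a in self.alphas):
            raise ValueError("alpha must be in [0, 100]")
        if self.replacement_policy not in ("any_class", "different_class"):
            raise ValueError(f"unknown replacement_policy {self.replacement_policy!r}")


@dataclass
class SimulationResult:
    """Per-replicate records and the per-alpha recovery summary."""

    records: pd.DataFrame  # alpha, replicate, sample, true_rank, true_cscore, best_cscore, recovered
    summary: pd.DataFrame  # alpha, recovery_rate, mean_true_cscore, mean_best_cscore

    def recovery_at(self, alpha: int) -> float:
        row = self.summary[self.summary["alpha"] == alpha]
        return float(row["recovery_rate"].iloc[0])


def generate_genotype_matrix(
    cfg: SimulationConfig | None = None,
    n_samples: int | None = None,
    n_snps: int | None = None,
    seed: int | None = None,
    maf: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw a Hardy-Weinberg genotype panel.

    Per SNP, the minor allele frequency p is uniform on
    [``maf_low``, ``maf_high``] (or supplied explicitly) and genotypes are
    i.i.d. across samples with probabilities ((1-p)^2, 2p(1-p), p^2).
    """
    cfg = cfg or SimulationConfig()
    n_samples = n_samples if n_samples is not None else cfg.n_samples
    n_snps = n_snps if n_snps is not None else cfg.n_snps
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if maf is None:
        maf = rng.uniform(cfg.maf_low, cfg.maf_high, n_snps)
    else:
        maf = np.asarray(maf, dtype=float)
        n_snps = maf.size
    probs = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2], axis=1)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n_samples, n_snps))
    calls = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
    width = len(str(n_samples))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n_samples)]
    snp_ids = [f"chr1:{1000 + 10 * j}:A:G" for j in range(n_snps)]
    return GenotypeMatrix(sample_ids, snp_ids, calls)


def shuffle_genotypes(
    matrix: GenotypeMatrix,
    sample: str,
    alpha: float,
    seed: int | np.random.Generator = 0,
    replacement_policy: str = "any_class",
) -> GenotypeMatrix:
    """Corrupt one sample's genotypes at an alpha-percent rate.

    Exactly ``round(alpha/100 * n_snps)`` distinct SNP positions of the
    chosen sample are resampled from the panel's per-SNP genotype class
    frequencies (estimated across all samples). Under
    ``"different_class"`` the current class is excluded and the remaining
    frequencies renormalized, so every resampled position changes; SNPs
    monomorphic in the panel are then skipped and replaced by other
    positions. Other samples are untouched.
    """
    if not 0 <= alpha <= 100:
        raise ValueError("alpha must be in [0, 100]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = matrix.copy()
    si = out.sample_index(sample)
    n_snps = out.n_snps
    k = round(alpha / 100 * n_snps)
    if k == 0:
        return out
    freqs = matrix.class_frequencies()  # (n_snps, 3)
    positions = rng.permutation(n_snps)
    row = out.calls[si]
    if replacement_policy == "any_class":
        pos = positions[:k]
        ok = np.isfinite(freqs[pos]).all(axis=1)
        pos = pos[ok]
        cum = np.cumsum(freqs[pos], axis=1)
        u = rng.random(pos.size)
        row[pos] = (u[:, None] > cum).sum(axis=1).astype(np.int8)
        if pos.size < k:
            logger.warning(
                "only %d/%d positions eligible for shuffling in sample %s",
                pos.size, k, sample,
            )
        return out
    n_done = 0
    for j in positions:
        if n_done == k:
            break
        f = freqs[j].copy()
        if not np.isfinite(f).all():
            continue
        if replacement_policy == "different_class":
            cur = row[j]
            if cur >= 0:
                f[cur] = 0.0
            total = f.sum()
            if total == 0:  # monomorphic in panel: cannot change class
                continue
            f = f / total
        row[j] = rng.choice(3, p=f)
        n_done += 1
    if n_done < k:
        logger.warning(
            "only %d/%d positions eligible for shuffling in sample %s",
            n_done, k, sample,
        )
    return out


def run_recovery_curve(
    cfg: SimulationConfig | None = None,
    score_cfg: ScoreConfig | None = None,
) -> SimulationResult:
    """Identity-recovery benchmark over the alpha grid.

    Per alpha and replicate: pick a sample at random, shuffle alpha% of its
    genotypes, score the shuffled vector against every candidate in the
    panel, and record whether the true sample ranks first (ties broken
    against recovery). Summarizes the recovery rate per alpha.
    """
    cfg = cfg or SimulationConfig()
    score_cfg = score_cfg or ScoreConfig()
    rng = np.random.default_rng(cfg.seed)
    panel = generate_genotype_matrix(cfg, seed=int(rng.integers(2 ** 31)))
    rows = []
    for alpha in cfg.alphas:
        for rep in range(cfg.replicates):
            si = int(rng.integers(cfg.n_samples))
            sample = panel.sample_ids[si]
            shuffled = shuffle_genotypes(
                panel, sample, alpha, rng, cfg.replacement_policy
            )
            scores = cscore_matrix(shuffled.calls[si], panel.calls, score_cfg)
            true_score = float(scores[si])
            best_score = float(np.nanmax(scores))
            # rank 1 = best; ties count against the true sample
            true_rank = int(1 + (scores > true_score).sum() + (
                (scores == true_score).sum() - 1
            ))
            recovered = true_rank == 1
            rows.append(
                {
                    "alpha": alpha,
                    "replicate": rep,
                    "sample": sample,
                    "true_rank": true_rank,
                    "true_cscore": true_score,
                    "best_cscore": best_score,
                    "recovered": recovered,
                }
            )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby("alpha")
        .agg(
            recovery_rate=("recovered", "mean"),
            mean_true_cscore=("true_cscore", "mean"),
            mean_best_cscore=("best_cscore", "mean"),
        )
        .reset_index()
    )
    return SimulationResult(records=records, summary=summary)


def minimum_intact_percent(
    result: SimulationResult, recovery_min: float = 0.95
) -> float:
    """Smallest percentage of intact genotypes at which the true sample is
    ranked first in at least ``recovery_min`` of replicates.

    Scans the summary for the largest alpha whose recovery rate meets the
    bound and returns ``100 - alpha``.
    """
    ok = result.summary[result.summary["recovery_rate"] >= recovery_min]
    if ok.empty:
        return float("nan")
    return float(100 - ok["alpha"].max())


def simulate_quant_batch(
    genotypes: GenotypeMatrix,
    channel_samples: list[str],
    params: IntensityParams | None = None,
    seed: int = 0,
    batch_id: str = "batch1",
    snp_subset: list[str] | None = None,
    include_control: bool = True,
    loading_bias_sd: float = 0.25,
) -> QuantBatch:
    """Emulate one multiplexed TMT batch from a genotype panel.

    One variant-peptide row is generated per SNP; each channel's log2
    intensity is drawn from the mode matching its sample's genotype. When
    ``include_control`` a pooled channel is appended whose log2 intensity
    is the across-channel mean plus noise-scale jitter. Multiplicative
    loading biases (log2-normal, SD ``loading_bias_sd``) are applied per
    channel. Intensities are returned on the raw linear scale.
    """
    params = params or IntensityParams()
    rng = np.random.default_rng(seed)
    sub = genotypes.subset_samples(channel_samples)
    if snp_subset is not None:
        idx = [genotypes.snp_index(s) for s in snp_subset]
        snp_ids = list(snp_subset)
        calls = sub.calls[:, idx]
    else:
        snp_ids = genotypes.snp_ids
        calls = sub.calls
    n_snps = len(snp_ids)
    n_ch = len(channel_samples)

    means = np.empty((n_snps, n_ch))
    sds = np.empty((n_snps, n_ch))
    table = {
        AA: (params.mean_noise, params.sd_noise),
        AB: (params.mean_het, params.sd_het),
        BB: (params.mean_signal, params.sd_signal),
    }
    for g, (m, s) in table.items():
        mask = calls.T == g
        means[mask] = m
        sds[mask] = s
    miss = calls.T == -1
    means[miss], sds[miss] = params.mean_noise, params.sd_noise

    log2 = rng.normal(means, sds)
    channels = [f"ch{i + 1:02d}" for i in range(n_ch)]
    manifest = dict(zip(channels, channel_samples))
    controls: set[str] = set()
    if include_control:
        ctrl = f"ch{n_ch + 1:02d}"
        ctrl_log2 = log2.mean(axis=1, keepdims=True) + rng.normal(
            0, 0.25 * params.sd_noise, (n_snps, 1)
        )
        log2 = np.concatenate([log2, ctrl_log2], axis=1)
        channels.append(ctrl)
        manifest[ctrl] = CONTROL_LABEL
        controls = {ctrl}

    bias = 2.0 ** rng.normal(0, loading_bias_sd, len(channels))
    intensities = (2.0 ** log2) * bias[None, :]

    peptides = [
        PeptideRow(sequence=f"PEPTIDE{j:04d}K", snp_id=snp_ids[j], n_psms=1)
        for j in range(n_snps)
    ]
    return QuantBatch(
        batch_id=batch_id,
        peptides=peptides,
        channels=channels,
        intensities=intensities,
        manifest=manifest,
        control_channels=controls,
    )
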