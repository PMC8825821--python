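"""Noise/signal separation of reporter intensities.

The minimum log2 intensity of each variant peptide across channels is
bimodal: a noise mode (channels where the peptide's allele is absent) and a
signal mode. A two-component Gaussian mixture fit by EM separates the two;
the minimum-signal cutoff is ``noise mean + k * noise SD`` (default k=1.5)
and peptides are further filtered by S/N ratio and the panel minor allele
frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import GenotypeMatrix, QuantBatch
from .preprocess import log2_with_floor

logger = logging.getLogger(__name__)


@dataclass
class MixtureFit:
    """Fitted two-component 1-D Gaussian mixture, components labeled so that
    ``mean_noise < mean_signal``."""

    weight_noise: float
    weight_signal: float
    mean_noise: float
    sd_noise: float
    mean_signal: float
    sd_signal: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


@dataclass
class FilterConfig:
    """Peptide filtering thresholds.

    cutoff_multiplier
        k in ``cutoff = noise mean + k * noise SD`` (log2 units).
    snr_min
        Minimum linear-scale signal-to-noise ratio per peptide.
    maf_min
        Minimum panel minor allele frequency; the strict inequality
        ``maf > maf_min`` is applied.
    """

    cutoff_multiplier: float = 1.5
    snr_min: float = 3.0
    maf_min: float = 0.01
    em_max_iter: int = 500
    em_tol: float = 1e-8
    cutoff_scope: str = "per_batch"  # or "global"

    def __post_init__(self):
        if self.cutoff_multiplier <= 0:
            raise ValueError("cutoff_multiplier must be > 0")
        if self.snr_min < 1:
            raise ValueError("snr_min must be >= 1")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")


def fit_two_gaussian_em(
    values,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> MixtureFit:
    """Fit a 2-component 1-D Gaussian mixture by EM.

    Initialization is deterministic: the data are split at the sample
    median; component means/SDs/weights start as the per-side moments.
    Seeded jitter is used only to restart after a degenerate iteration.
    Components are relabeled on return so the lower-mean one is "noise".
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance input")

    rng = np.random.default_rng(seed)
    data_range = float(np.ptp(x))
    sd_floor = 1e-3 * data_range

    def init_params(jitter: float = 0.0):
        split = np.median(x) + jitter
        lo, hi = x[x <= split], x[x > split]
        if lo.size == 0 or hi.size == 0:
            lo, hi = np.sort(x)[: x.size // 2], np.sort(x)[x.size // 2 :]
        mu = np.array([lo.mean(), hi.mean()])
        sd = np.maximum(np.array([lo.std(), hi.std()]), sd_floor)
        w = np.array([lo.size, hi.size]) / x.size
        return w, mu, sd

    w, mu, sd = init_params()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_pdf = stats.norm.logpdf(x[:, None], mu[None, :], sd[None, :])
        log_weighted = log_pdf + np.log(w)[None, :]
        log_total = np.logaddexp(log_weighted[:, 0], log_weighted[:, 1])
        loglik = float(log_total.sum())
        trace.append(loglik)
        resp = np.exp(log_weighted - log_total[:, None])
        # M-step
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            logger.debug("degenerate EM iteration; jittered restart")
            w, mu, sd = init_params(jitter=rng.normal(0, 0.1 * data_range))
            continue
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    return MixtureFit(
        weight_noise=float(w[0]),
        weight_signal=float(w[1]),
        mean_noise=float(mu[0]),
        sd_noise=float(sd[0]),
        mean_signal=float(mu[1]),
        sd_signal=float(sd[1]),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )


def derive_noise_cutoff(fit: MixtureFit, k: float = 1.5) -> float:
    """Minimum-signal cutoff in log2 units: ``noise mean + k * noise SD``."""
    return fit.mean_noise + k * fit.sd_noise


def peptide_min_signal(batch: QuantBatch) -> np.ndarray:
    """Per-peptide minimum log2 intensity across non-control channels.

    All-missing rows are excluded; the returned list is the EM input.
    """
    log2, _ = log2_with_floor(batch.intensities)
    cols = [batch.channels.index(c) for c in batch.sample_channels]
    sub = log2[:, cols]
    mins = np.nanmin(np.where(np.isfinite(sub), sub, np.inf), axis=1)
    return mins[np.isfinite(mins)]


def compute_snr(peptide_row, cutoff: float) -> float:
    """Linear-scale signal-to-noise ratio of one peptide's log2 channel values.

    S/N = mean(2**x for x >= cutoff) / mean(2**x for x < cutoff); returns 0
    if every value is below the cutoff and +inf if every value is above.
    """
    x = np.asarray(peptide_row, dtype=float)
    x = x[np.isfinite(x)]
    above, below = x[x >= cutoff], x[x < cutoff]
    if above.size == 0:
        return 0.0
    if below.size == 0:
        return float("inf")
    return float(np.mean(2.0 ** above) / np.mean(2.0 ** below))


def filter_peptides(
    batch: QuantBatch,
    genotypes: GenotypeMatrix,
    fit: MixtureFit,
    cfg: FilterConfig | None = None,
) -> QuantBatch:
    """Apply the MAF, noise-floor and S/N peptide filters.

    Keeps peptides whose SNP has panel MAF > ``maf_min``, whose S/N is at
    least ``snr_min``, and which have at least one channel above the noise
    cutoff. Removal counts per criterion are logged.
    """
    cfg = cfg or FilterConfig()
    cutoff = derive_noise_cutoff(fit, cfg.cutoff_multiplier)
    log2, _ = log2_with_floor(batch.intensities)
    maf = genotypes.maf

    keep = np.ones(batch.n_peptides, dtype=bool)
    n_maf = n_noise = n_snr = 0
    for i, pep in enumerate(batch.peptides):
        if pep.snp_id is None or pep.snp_id not in genotypes._snp_index:
            keep[i] = False
            n_maf += 1
            continue
        snp_maf = maf[genotypes.snp_index(pep.snp_id)]
        if not snp_maf > cfg.maf_min:
            keep[i] = False
            n_maf += 1
            continue
        snr = compute_snr(log2[i], cutoff)
        if snr == 0.0:
            keep[i] = False
            n_noise += 1
        elif snr < cfg.snr_min:
            keep[i] = False
            n_snr += 1
    logger.info(
        "filter_peptides batch %s: kept %d/%d (removed: maf %d, noise %d, snr %d)",
        batch.batch_id, int(keep.sum()), batch.n_peptides, n_maf, n_noise, n_snr,
    )
    if not keep.any():
        logger.warning("batch %s: no peptides passed filtering", batch.batch_id)
    return batch.subset_peptides(keep)
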