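"""Genotype calling from scaled reporter intensities.

For each variant peptide the min-max-scaled channel intensities are
converted to genotype calls. When the reference panel shows all three
classes at a SNP, the scaled values are split at their 25th/75th
percentiles: below Q1 -> AA, within [Q1, Q3] -> AB, above Q3 -> BB. When
the panel shows only two classes, a fixed 0.5 cutoff separates them (class
order AA < AB < BB), excluding the class the panel rules out. Monomorphic
SNPs cannot discriminate samples and are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AA, AB, BB, MISSING, GenotypeMatrix, QuantBatch
from .noise_model import FilterConfig
from .preprocess import scale_minmax_matrix

logger = logging.getLogger(__name__)


@dataclass
class CallProvenance:
    peptide: str
    scaled: float
    rule: str  # "quartile3" | "binary05"


@dataclass
class InferredGenotypeMatrix:
    """Per-batch genotype calls inferred from intensities: channels x SNPs."""

    batch_id: str
    channels: list[str]
    snp_ids: list[str]
    calls: np.ndarray  # (n_channels, n_snps) int8
    provenance: dict[tuple[str, str], list[CallProvenance]] = field(
        default_factory=dict
    )

    @property
    def n_calls(self) -> int:
        return int((self.calls != MISSING).sum())


def dosage_classes(ref_calls_at_snp) -> set[int]:
    """Distinct non-missing genotype classes observed in the reference panel
    at one SNP; this is the dosage prior for inference."""
    classes = {int(c) for c in np.asarray(ref_calls_at_snp).ravel() if c != MISSING}
    if not classes:
        raise ValueError("all reference calls missing at SNP")
    return classes


def infer_genotypes_quartile(scaled, classes: set[int]) -> np.ndarray:
    """Call genotypes for one peptide's scaled channel values.

    Three-class mode uses the 25th/75th percentiles of the scaled values
    (linear-interpolation quantiles); the interquartile class is closed, so
    a value exactly at Q1 or Q3 is called AB. Two-class mode splits at 0.5,
    values >= 0.5 taking the higher class. NaN inputs give MISSING.
    """
    y = np.asarray(scaled, dtype=float)
    calls = np.full(y.shape, MISSING, dtype=np.int8)
    finite = np.isfinite(y)
    if len(classes) < 2:
        raise ValueError("inference requires >= 2 dosage classes")
    if len(classes) == 3:
        q1, q3 = np.quantile(y[finite], [0.25, 0.75])
        calls[finite & (y < q1)] = AA
        calls[finite & (y >= q1) & (y <= q3)] = AB
        calls[finite & (y > q3)] = BB
    else:
        lo, hi = sorted(classes)
        calls[finite & (y < 0.5)] = lo
        calls[finite & (y >= 0.5)] = hi
    return calls


def aggregate_snp_calls(per_peptide_calls) -> np.ndarray:
    """Majority vote across peptides covering one SNP, per channel; ties and
    all-missing channels give MISSING."""
    stack = np.asarray(per_peptide_calls, dtype=np.int8)
    if stack.ndim == 1:
        stack = stack[None, :]
    out = np.full(stack.shape[1], MISSING, dtype=np.int8)
    for j in range(stack.shape[1]):
        votes = stack[:, j]
        votes = votes[votes != MISSING]
        if votes.size == 0:
            continue
        counts = np.bincount(votes, minlength=3)
        best = counts.max()
        winners = np.flatnonzero(counts == best)
        if winners.size == 1:
            out[j] = winners[0]
    return out


def infer_batch(
    batch: QuantBatch,
    genotypes: GenotypeMatrix,
    cfg: FilterConfig | None = None,
    log2_matrix: np.ndarray | None = None,
    dosage_scope: str = "batch",
) -> InferredGenotypeMatrix:
    """Infer the channels x SNPs genotype matrix for one preprocessed batch.

    ``log2_matrix`` may carry already-normalized log2 intensities aligned to
    the batch; otherwise the raw intensities are log2-transformed in place.
    Scaling, the dosage prior, per-peptide inference and per-SNP majority
    aggregation are applied in order. Monomorphic SNPs emit no calls.

    ``dosage_scope`` selects whose reference genotypes define the dosage
    prior at each SNP: ``"batch"`` (default) uses the samples named in the
    batch manifest, so a SNP where those samples carry only two classes is
    called with the sharper two-class rule; ``"panel"`` uses the whole
    cohort. The batch scope mirrors how inference is done one multiplexed
    batch at a time and markedly reduces heterozygote/homozygote confusion.
    """
    from .preprocess import log2_with_floor

    if log2_matrix is None and batch.n_peptides > 0:
        log2_matrix, _ = log2_with_floor(batch.intensities)
    elif log2_matrix is None:
        log2_matrix = batch.intensities
    scaled, informative = scale_minmax_matrix(log2_matrix)

    if dosage_scope not in ("batch", "panel"):
        raise ValueError(f"unknown dosage_scope {dosage_scope!r}")
    if dosage_scope == "batch":
        labels = [
            batch.manifest[c]
            for c in batch.sample_channels
            if batch.manifest[c] in genotypes._sample_index
        ]
        prior_rows = (
            [genotypes.sample_index(s) for s in labels]
            if labels
            else list(range(genotypes.n_samples))
        )
    else:
        prior_rows = list(range(genotypes.n_samples))

    by_snp: dict[str, list[int]] = {}
    for i, pep in enumerate(batch.peptides):
        if pep.snp_id is None or not informative[i]:
            continue
        by_snp.setdefault(pep.snp_id, []).append(i)

    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    provenance: dict = {}
    n_mono = 0
    for snp_id, rows in by_snp.items():
        if snp_id not in genotypes._snp_index:
            continue
        ref_col = genotypes.calls[prior_rows, genotypes.snp_index(snp_id)]
        try:
            classes = dosage_classes(ref_col)
        except ValueError:
            continue
        if len(classes) < 2:
            n_mono += 1
            continue
        rule = "quartile3" if len(classes) == 3 else "binary05"
        pep_calls = [infer_genotypes_quartile(scaled[i], classes) for i in rows]
        agg = aggregate_snp_calls(pep_calls)
        snp_ids.append(snp_id)
        columns.append(agg)
        for i in rows:
            for j, ch in enumerate(batch.channels):
                provenance.setdefault((ch, snp_id), []).append(
                    CallProvenance(
                        peptide=batch.peptides[i].sequence,
                        scaled=float(scaled[i, j]),
                        rule=rule,
                    )
                )
    if n_mono:
        logger.info("batch %s: skipped %d monomorphic SNP(s)", batch.batch_id, n_mono)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(batch.channels), 0), dtype=np.int8)
    )
    if not snp_ids:
        logger.warning("batch %s: no SNPs inferred", batch.batch_id)
    result = InferredGenotypeMatrix(
        batch_id=batch.batch_id,
        channels=list(batch.channels),
        snp_ids=snp_ids,
        calls=calls,
        provenance=provenance,
    )
    logger.info(
        "batch %s: %d genotypes inferred over %d SNPs x %d channels",
        batch.batch_id, result.n_calls, len(snp_ids), len(batch.channels),
    )
    return result
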