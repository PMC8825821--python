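"""Readers and writers for genotype panels, quantification batches and match reports.

Genotype calls are coded as small integers throughout the package:
``AA=0`` (non-mutant homozygote), ``AB=1`` (heterozygote), ``BB=2``
(mutant homozygote), ``MISSING=-1``. The string labels are used in all
on-disk representations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AA, AB, BB, MISSING = 0, 1, 2, -1

CALL_LABELS = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
LABEL_CALLS = {"AA": AA, "AB": AB, "BB": BB, "NA": MISSING, ".": MISSING, "": MISSING}

CONTROL_LABEL = "CONTROL"

MATCH_REPORT_COLUMNS = [
    "batch",
    "channel",
    "original_label",
    "best_match",
    "cscore",
    "delta_cscore",
    "status",
]


class GenotypeMatrix:
    """A samples x SNPs panel of diploid genotype calls.

    Parameters
    ----------
    sample_ids, snp_ids
        Unique ordered identifiers. SNP ids follow the ``chrom:pos:ref:alt``
        convention with 1-based positions.
    calls
        ``(n_samples, n_snps)`` int8 array over ``{AA, AB, BB, MISSING}``.
    """

    def __init__(self, sample_ids, snp_ids, calls):
        sample_ids = list(sample_ids)
        snp_ids = list(snp_ids)
        calls = np.asarray(calls, dtype=np.int8)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(snp_ids)) != len(snp_ids):
            raise ValueError("duplicate SNP ids")
        if calls.shape != (len(sample_ids), len(snp_ids)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(sample_ids)}, {len(snp_ids)})"
            )
        valid = np.isin(calls, (AA, AB, BB, MISSING))
        if not valid.all():
            raise ValueError("calls contain values outside {AA, AB, BB, MISSING}")
        self.sample_ids = sample_ids
        self.snp_ids = snp_ids
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        self._snp_index = {s: i for i, s in enumerate(snp_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def snp_index(self, snp_id: str) -> int:
        return self._snp_index[snp_id]

    @property
    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, folded to <= 0.5.

        Computed as (2 * #BB + #AB) / (2 * #non-missing); missing calls are
        excluded from the denominator. SNPs with no non-missing call get NaN.
        """
        calls = self.calls
        nonmiss = (calls != MISSING).sum(axis=0)
        alt = (2 * (calls == BB) + (calls == AB)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = alt / (2 * nonmiss)
        return np.minimum(freq, 1.0 - freq)

    def class_frequencies(self) -> np.ndarray:
        """``(n_snps, 3)`` observed frequencies of AA/AB/BB among non-missing calls."""
        counts = np.stack(
            [(self.calls == c).sum(axis=0) for c in (AA, AB, BB)], axis=1
        ).astype(float)
        total = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return counts / total

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        missing = [s for s in sample_ids if s not in self._sample_index]
        if missing:
            raise KeyError(f"samples not in panel: {missing}")
        idx = [self._sample_index[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.snp_ids, self.calls[idx])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, self.snp_ids, self.calls.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PeptideRow:
    """One variant-peptide row of a quantification table."""

    sequence: str
    snp_id: str | None
    n_psms: int = 1


@dataclass
class QuantBatch:
    """One multiplexed TMT batch: variant peptides x channels raw intensities.

    ``intensities`` is on the raw reporter-ion (linear) scale; NaN marks a
    missing cell, literal 0 is a recorded zero signal. ``manifest`` maps each
    channel label to the sample label it was assigned at bench time;
    ``control_channels`` flags pooled internal-control channels.
    """

    batch_id: str
    peptides: list[PeptideRow]
    channels: list[str]
    intensities: np.ndarray
    manifest: dict[str, str]
    control_channels: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.peptides), len(self.channels)):
            raise ValueError("intensities shape does not match peptides x channels")
        if np.nanmin(self.intensities, initial=0.0) < 0:
            raise ValueError("negative intensities")
        if set(self.manifest) != set(self.channels):
            raise ValueError("manifest must cover all channels exactly once")

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def sample_channels(self) -> list[str]:
        return [c for c in self.channels if c not in self.control_channels]

    def subset_peptides(self, keep: np.ndarray) -> "QuantBatch":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return QuantBatch(
            batch_id=self.batch_id,
            peptides=[self.peptides[i] for i in idx],
            channels=self.channels,
            intensities=self.intensities[idx],
            manifest=dict(self.manifest),
            control_channels=set(self.control_channels),
        )


@dataclass
class SampleMatch:
    """Match result for one proteomic channel."""

    batch: str
    channel: str
    original_label: str
    best_match: str | None
    cscore: float
    cscore_second: float
    delta_cscore: float
    status: str  # matched | corrected | unassignable | control
    best_candidate: str | None = None  # argmax identity regardless of thresholds


@dataclass
class MatchReport:
    """Per-channel identity assignments for one or more batches.

    ``cscore_min`` records the Cscore threshold that produced the statuses
    (possibly calibrated from internal controls).
    """

    matches: list[SampleMatch]
    genotype_counts: dict[str, int] = field(default_factory=dict)
    cscore_min: float | None = None

    def __post_init__(self):
        self.matches = sorted(self.matches, key=lambda m: (m.batch, m.channel))

    @property
    def corrected(self) -> list[SampleMatch]:
        return [m for m in self.matches if m.status == "corrected"]

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.matches:
            out[m.status] = out.get(m.status, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "batch": m.batch,
                "channel": m.channel,
                "original_label": m.original_label,
                "best_match": m.best_match if m.best_match is not None else ".",
                "cscore": m.cscore,
                "delta_cscore": m.delta_cscore,
                "status": m.status,
            }
            for m in self.matches
        ]
        return pd.DataFrame(rows, columns=MATCH_REPORT_COLUMNS)


def _snp_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def read_genotype_vcf(path, sample_subset=None) -> GenotypeMatrix:
    """Load a diploid genotype panel from a VCF (GT field only).

    ``0/0 -> AA``, ``0/1`` or ``1/0 -> AB``, ``1/1 -> BB``, ``./. -> MISSING``;
    phased separators are accepted and treated as unphased. Multi-allelic
    records are skipped with a warning, since the variant-peptide table keys
    on a single alternate allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        absent = [s for s in sample_subset if s not in all_samples]
        if absent:
            raise KeyError(f"samples not present in VCF: {absent}")
        keep = [all_samples.index(s) for s in sample_subset]
        sample_ids = list(sample_subset)
    else:
        keep = list(range(len(all_samples)))
        sample_ids = all_samples

    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for record in vcf:
        if len(record.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = np.asarray(record.gt_types)[keep].astype(np.int8)
        g[g == 3] = MISSING
        snp_ids.append(_snp_id(record.CHROM, record.POS, record.REF, record.ALT[0]))
        columns.append(g)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic VCF record(s)")
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, snp_ids, calls)


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a genotype matrix TSV (rows = samples, columns = SNP ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    calls = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, v in enumerate(df[col]):
            try:
                calls[i, j] = LABEL_CALLS[v]
            except KeyError:
                raise ValueError(f"unrecognized genotype label {v!r} at {df.index[i]}/{col}")
    return GenotypeMatrix(list(df.index), list(df.columns), calls)


def write_genotype_tsv(matrix: GenotypeMatrix, path) -> None:
    labels = np.vectorize(CALL_LABELS.get)(matrix.calls)
    df = pd.DataFrame(labels, index=matrix.sample_ids, columns=matrix.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_manifest(path) -> pd.DataFrame:
    """Read a channel manifest TSV with columns batch, channel, sample_label, is_control."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"batch", "channel", "sample_label", "is_control"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    df["is_control"] = df["is_control"].str.lower().isin({"1", "true", "yes"})
    return df


def read_quant_table(path, manifest_path, batch_id: str | None = None) -> QuantBatch:
    """Read a variant-peptide quantification TSV plus its channel manifest.

    The table has columns ``peptide``, ``snp_id``, ``n_psms`` followed by one
    column per channel; empty cells or ``.`` are missing, literal ``0`` is a
    recorded zero. Every channel must appear in the manifest.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta_cols = [c for c in ("peptide", "snp_id", "n_psms") if c in df.columns]
    if "peptide" not in meta_cols:
        raise ValueError("quant table must have a 'peptide' column")
    channel_cols = [c for c in df.columns if c not in meta_cols]

    manifest_df = read_manifest(manifest_path)
    if batch_id is None:
        batches = manifest_df["batch"].unique()
        if len(batches) != 1:
            raise ValueError(
                "manifest covers multiple batches; pass batch_id explicitly"
            )
        batch_id = batches[0]
    manifest_df = manifest_df[manifest_df["batch"] == batch_id]
    known = set(manifest_df["channel"])
    unknown = [c for c in channel_cols if c not in known]
    if unknown:
        raise ValueError(f"channels missing from manifest: {unknown}")

    intensities = np.full((len(df), len(channel_cols)), np.nan)
    for j, col in enumerate(channel_cols):
        for i, v in enumerate(df[col]):
            if v in ("", "."):
                continue
            x = float(v)
            if x < 0:
                raise ValueError(
                    f"negative intensity {v} at row {i} column {col!r}"
                )
            intensities[i, j] = x

    peptides = [
        PeptideRow(
            sequence=row["peptide"],
            snp_id=(row.get("snp_id") or None) if "snp_id" in meta_cols else None,
            n_psms=int(row["n_psms"]) if "n_psms" in meta_cols else 1,
        )
        for _, row in df.iterrows()
    ]
    manifest = dict(zip(manifest_df["channel"], manifest_df["sample_label"]))
    controls = set(manifest_df.loc[manifest_df["is_control"], "channel"])
    manifest = {c: manifest[c] for c in channel_cols}
    return QuantBatch(
        batch_id=batch_id,
        peptides=peptides,
        channels=channel_cols,
        intensities=intensities,
        manifest=manifest,
        control_channels=controls & set(channel_cols),
    )


def write_quant_table(batch: QuantBatch, path) -> None:
    df = pd.DataFrame(
        {
            "peptide": [p.sequence for p in batch.peptides],
            "snp_id": [p.snp_id if p.snp_id is not None else "." for p in batch.peptides],
            "n_psms": [p.n_psms for p in batch.peptides],
        }
    )
    for j, c in enumerate(batch.channels):
        col = batch.intensities[:, j]
        df[c] = ["" if np.isnan(v) else repr(float(v)) for v in col]
    df.to_csv(path, sep="\t", index=False)


def write_manifest(batch: QuantBatch, path) -> None:
    df = pd.DataFrame(
        {
            "batch": batch.batch_id,
            "channel": batch.channels,
            "sample_label": [batch.manifest[c] for c in batch.channels],
            "is_control": [
                "1" if c in batch.control_channels else "0" for c in batch.channels
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_match_report(report: MatchReport, path) -> None:
    """Write a match report TSV, one row per channel, ordered by (batch, channel)."""
    report.to_frame().to_csv(path, sep="\t", index=False)


def read_match_report(path) -> MatchReport:
    df = pd.read_csv(path, sep="\t", dtype={"batch": str, "channel": str})
    matches = [
        SampleMatch(
            batch=row["batch"],
            channel=row["channel"],
            original_label=row["original_label"],
            best_match=None if row["best_match"] == "." else row["best_match"],
            cscore=float(row["cscore"]),
            cscore_second=float("nan"),
            delta_cscore=float(row["delta_cscore"]),
            status=row["status"],
        )
        for _, row in df.iterrows()
    ]
    return MatchReport(matches)
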