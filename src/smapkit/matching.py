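"""Identity matching by genotype concordance.

Every proteomic channel's inferred genotype vector is scored against every
candidate sample in the reference panel. The concordance score (Cscore) of
a candidate is the fraction of compared SNPs (both calls non-missing) with
identical genotype classes; the specificity score (delta-Cscore) is
(best - second best) / best. A channel is "matched" when its best candidate
is its bench label and both thresholds pass, "corrected" when the best
candidate differs from the label and both thresholds pass, and
"unassignable" otherwise. Internal-control channels are never assigned.

A weighted scoring mode is also available, where a matched position
contributes a per-class weight (defaults 1/2/3 for AA/AB/BB by mutant
dosage) instead of 1, yielding scores on a >1 scale comparable to
published concordance values; thresholds are configured per mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import (
    AA,
    AB,
    BB,
    MISSING,
    GenotypeMatrix,
    MatchReport,
    SampleMatch,
)
from .genotype_inference import InferredGenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_CSCORE_MIN = {"fraction": 0.80, "weighted": 1.50}


@dataclass
class ScoreConfig:
    """Scoring mode, per-class match weights and assignment thresholds.

    ``cscore_min=None`` (the default) requests control calibration: the
    Cscore threshold is set to the mean best score of the pooled
    internal-control channels, which by construction match no individual
    and hence trace the background concordance level. When no control
    channels are available the mode-specific constant is used instead.
    """

    mode: str = "fraction"
    weights: dict[int, float] = field(
        default_factory=lambda: {AA: 1.0, AB: 2.0, BB: 3.0}
    )
    cscore_min: float | None = None  # None -> calibrate from controls
    delta_min: float = 0.20
    min_compared: int = 20

    def __post_init__(self):
        if self.mode not in ("fraction", "weighted"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be > 0")
        if self.cscore_min is not None and self.cscore_min < 0:
            raise ValueError("thresholds must be >= 0")
        if self.delta_min < 0:
            raise ValueError("thresholds must be >= 0")

    def fallback_cscore_min(self) -> float:
        return DEFAULT_CSCORE_MIN[self.mode]


def cscore(inferred, reference, cfg: ScoreConfig | None = None) -> float:
    """Concordance of two aligned genotype call vectors.

    Only positions where both calls are non-missing are compared. Fraction
    mode returns matches/compared in [0, 1]; weighted mode returns the sum
    of per-class weights over matched positions divided by the number
    compared. Returns NaN when fewer than ``min_compared`` positions
    overlap.
    """
    cfg = cfg or ScoreConfig()
    a = np.asarray(inferred, dtype=np.int8)
    b = np.asarray(reference, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("call vectors must be aligned on the same SNP set")
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0 or n < cfg.min_compared:
        return float("nan")
    matched = both & (a == b)
    if cfg.mode == "fraction":
        return float(matched.sum() / n)
    w = np.zeros(3)
    for c, wc in cfg.weights.items():
        w[c] = wc
    return float(w[a[matched]].sum() / n)


def cscore_matrix(
    inferred: np.ndarray, references: np.ndarray, cfg: ScoreConfig | None = None
) -> np.ndarray:
    """Cscore of one inferred call vector against every row of a panel.

    Vectorized equivalent of calling :func:`cscore` per candidate; used by
    the matcher and the simulation's recovery curves.
    """
    cfg = cfg or ScoreConfig()
    a = np.asarray(inferred, dtype=np.int8)[None, :]
    refs = np.asarray(references, dtype=np.int8)
    both = (a != MISSING) & (refs != MISSING)
    n = both.sum(axis=1)
    matched = both & (a == refs)
    if cfg.mode == "fraction":
        contrib = matched.astype(float)
    else:
        w = np.zeros(3)
        for c, wc in cfg.weights.items():
            w[c] = wc
        contrib = np.where(matched, w[np.clip(refs, 0, 2)], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = contrib.sum(axis=1) / n
    scores[n < max(cfg.min_compared, 1)] = np.nan
    return scores


def delta_cscore(scores) -> float:
    """Specificity of the top score: (best - second best) / best.

    A single candidate gives 1.0 (maximal specificity by convention); a
    best score of 0 or no finite score gives NaN.
    """
    s = np.asarray(scores, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        return float("nan")
    s = np.sort(s)[::-1]
    if s[0] == 0:
        return float("nan")
    if s.size == 1:
        return 1.0
    return float((s[0] - s[1]) / s[0])


def match_samples(
    inferred: InferredGenotypeMatrix,
    genotypes: GenotypeMatrix,
    cfg: ScoreConfig | None = None,
    control_channels: set[str] | None = None,
    manifest: dict[str, str] | None = None,
) -> MatchReport:
    """Assign an identity to every channel of one inferred batch.

    Each channel is scored against all candidate samples in the panel (the
    whole cohort, not only the batch). Candidate order breaks ties
    deterministically; an exact tie for best gives delta-Cscore 0 and hence
    an unassignable channel.
    """
    cfg = cfg or ScoreConfig()
    if genotypes.n_samples < 2:
        raise ValueError("need >= 2 candidate genotype samples")
    control_channels = control_channels or set()
    manifest = manifest or {c: c for c in inferred.channels}

    snp_idx = [genotypes.snp_index(s) for s in inferred.snp_ids]
    panel = genotypes.calls[:, snp_idx]

    matches = []
    for ci, channel in enumerate(inferred.channels):
        original = manifest.get(channel, channel)
        vec = inferred.calls[ci]
        scores = cscore_matrix(vec, panel, cfg)
        finite = np.isfinite(scores)
        is_control = channel in control_channels or original == "CONTROL"
        if not finite.any():
            matches.append(
                SampleMatch(
                    batch=inferred.batch_id,
                    channel=channel,
                    original_label=original,
                    best_match=None,
                    cscore=float("nan"),
                    cscore_second=float("nan"),
                    delta_cscore=float("nan"),
                    status="control" if is_control else "unassignable",
                )
            )
            continue
        order = np.argsort(-np.where(finite, scores, -np.inf), kind="stable")
        best_i = int(order[0])
        best = float(scores[best_i])
        second = float(scores[order[1]]) if finite.sum() >= 2 else float("nan")
        matches.append(
            SampleMatch(
                batch=inferred.batch_id,
                channel=channel,
                original_label=original,
                best_match=None,
                cscore=best,
                cscore_second=second,
                delta_cscore=delta_cscore(scores),
                status="control" if is_control else "unassignable",
                best_candidate=None if is_control else genotypes.sample_ids[best_i],
            )
        )
    cscore_min = calibrate_cscore_min(matches, cfg)
    assign_statuses(matches, cscore_min, cfg.delta_min)
    report = MatchReport(
        matches,
        genotype_counts={inferred.batch_id: inferred.n_calls},
        cscore_min=cscore_min,
    )
    logger.info(
        "batch %s: cscore_min %.3f, status counts %s",
        inferred.batch_id, cscore_min, report.status_counts(),
    )
    return report


def calibrate_cscore_min(matches, cfg: ScoreConfig) -> float:
    """Resolve the Cscore threshold for a set of scored channels.

    An explicit ``cfg.cscore_min`` wins; otherwise the threshold is the
    mean best Cscore of the internal-control channels (the background
    concordance level, since pooled controls match no individual); with no
    controls the mode-specific constant is used.
    """
    if cfg.cscore_min is not None:
        return cfg.cscore_min
    control_scores = [
        m.cscore for m in matches if m.status == "control" and np.isfinite(m.cscore)
    ]
    if control_scores:
        return float(np.mean(control_scores))
    logger.warning(
        "no internal controls to calibrate cscore_min; using %s-mode default",
        cfg.mode,
    )
    return cfg.fallback_cscore_min()


def assign_statuses(matches, cscore_min: float, delta_min: float) -> None:
    """(Re)assign matched/corrected/unassignable statuses in place.

    A channel passes when its best Cscore reaches ``cscore_min`` and its
    delta-Cscore reaches ``delta_min``; control channels are untouched.
    """
    for m in matches:
        if m.status == "control" or m.best_candidate is None:
            continue
        passed = (
            np.isfinite(m.cscore)
            and m.cscore >= cscore_min
            and np.isfinite(m.delta_cscore)
            and m.delta_cscore >= delta_min
        )
        if not passed:
            m.status = "unassignable"
            m.best_match = None
        else:
            m.best_match = m.best_candidate
            m.status = "matched" if m.best_candidate == m.original_label else "corrected"


@dataclass
class SwapComponent:
    samples: list[str]
    edges: list[tuple[str, str]]
    kind: str  # reciprocal | one-way | cyclic | complex


@dataclass
class SwapGraph:
    """Correction topology: directed edges original_label -> assigned identity
    over corrected channels, decomposed into weakly connected components."""

    components: list[SwapComponent]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.components:
            out[c.kind] = out.get(c.kind, 0) + 1
        return out


def _classify_component(g: nx.DiGraph) -> str:
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 2 and e == 2:
        return "reciprocal"
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle is not None and len(cycle) == n and e == n:
        return "cyclic" if n >= 3 else "reciprocal"
    if cycle is None:
        # simple path: connected acyclic with max undirected degree 2
        degrees = sorted(d for _, d in nx.Graph(g.to_undirected()).degree())
        if e == n - 1 and degrees[-1] <= 2:
            return "one-way"
    return "complex"


def classify_swaps(report: MatchReport) -> SwapGraph:
    """Classify the corrected channels' label->identity mapping into
    reciprocal pairs, one-way redirections and cycles of length >= 3."""
    g = nx.DiGraph()
    for m in report.corrected:
        g.add_edge(m.original_label, m.best_match)
    components = []
    for nodes in nx.weakly_connected_components(g):
        sub = g.subgraph(nodes).copy()
        components.append(
            SwapComponent(
                samples=sorted(nodes),
                edges=sorted(sub.edges),
                kind=_classify_component(sub),
            )
        )
    components.sort(key=lambda c: c.samples)
    return SwapGraph(components)
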