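"""Scoring of aberration calls against truth.

Three marker-level concordance criteria of increasing coarseness (total copy
number + LOH status; unordered per-haplotype gain/loss pattern; presence of
allelic imbalance), binary aberrant-vs-normal sensitivity/specificity, ROC
curves from posterior aberrance probabilities, over-represented-allele
accuracy against a naive BAF-dichotomization rule, and a detection-length
ladder that measures the smallest cn-LOH region the engine can localize at a
given purity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("haplomix")

__all__ = [
    "CallComparison",
    "concordance",
    "sens_spec",
    "roc",
    "allele_accuracy",
    "detection_ladder",
]

NORMAL_CATEGORY = "1-1"


def _parse_category(label: str) -> tuple[int, int]:
    try:
        hi, lo = label.split("-")
        return int(hi), int(lo)
    except Exception as exc:
        raise ValueError(f"unknown category label {label!r}") from exc


def _criterion_key(label: str, criterion: str):
    hi, lo = _parse_category(label)
    if criterion == "cn_loh":
        # equal total copy number AND equal LOH status
        return (hi + lo, lo == 0)
    if criterion == "gain_loss":
        # unordered per-haplotype gain/normal/loss pattern
        return tuple(sorted((np.sign(hi - 1), np.sign(lo - 1))))
    if criterion == "ai":
        return hi != lo
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class CallComparison:
    """Aligned predicted and truth category labels with an inclusion mask."""

    predicted: np.ndarray
    truth: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=object)
        self.truth = np.asarray(self.truth, dtype=object)
        if self.mask is None:
            self.mask = np.ones(len(self.predicted), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not len(self.predicted) == len(self.truth) == len(self.mask):
            raise ValueError("predicted, truth and mask must have equal length")


def concordance(cmp: CallComparison, criterion: str) -> float:
    """Fraction of included markers whose call matches truth under a criterion.

    ``cn_loh``: equal total copy number and LOH indicator; ``gain_loss``:
    equal unordered gain/normal/loss pattern of the two haplotypes; ``ai``:
    equal allelic-imbalance indicator.
    """
    pred = cmp.predicted[cmp.mask]
    truth = cmp.truth[cmp.mask]
    if len(pred) == 0:
        return float("nan")
    match = np.array(
        [
            _criterion_key(p, criterion) == _criterion_key(t, criterion)
            for p, t in zip(pred, truth)
        ]
    )
    return float(match.mean())


def sens_spec(cmp: CallComparison) -> tuple[float, float]:
    """Binary aberrant-vs-normal sensitivity and specificity.

    A marker is called/truth "aberrant" when its category is not the normal
    diploid '1-1'.  Sensitivity is NaN when no truth-aberrant markers are
    included, specificity likewise for truth-normal.
    """
    pred = cmp.predicted[cmp.mask]
    truth = cmp.truth[cmp.mask]
    pred_ab = pred != NORMAL_CATEGORY
    truth_ab = truth != NORMAL_CATEGORY
    n_ab = int(truth_ab.sum())
    n_norm = int((~truth_ab).sum())
    sens = float(pred_ab[truth_ab].mean()) if n_ab else float("nan")
    spec = float((~pred_ab[~truth_ab]).mean()) if n_norm else float("nan")
    return sens, spec


def roc(
    p_aberrant: np.ndarray,
    truth_aberrant: np.ndarray,
    thresholds: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoid AUC from per-marker aberrance posteriors.

    A marker is called aberrant when ``p_aberrant >= threshold``; thresholds
    default to a dense grid including the degenerate endpoints (0, 0) and
    (1, 1).
    """
    p = np.asarray(p_aberrant, dtype=float)
    t = np.asarray(truth_aberrant, dtype=bool)
    if mask is not None:
        p, t = p[mask], t[mask]
    if thresholds is None:
        thresholds = np.unique(np.concatenate([[0.0], np.linspace(0, 1, 201), [1.0 + 1e-12]]))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    rows = []
    for thr in thresholds:
        call = p >= thr
        tpr = float((call & t).sum() / n_pos) if n_pos else float("nan")
        fpr = float((call & ~t).sum() / n_neg) if n_neg else float("nan")
        rows.append({"threshold": thr, "fpr": fpr, "tpr": tpr})
    points = pd.DataFrame(rows)
    auc = float(np.trapezoid(points["tpr"], points["fpr"]))
    return points, auc


def allele_accuracy(
    p_a_over: np.ndarray,
    p_b_over: np.ndarray,
    baf: np.ndarray,
    truth_over: np.ndarray,
    mask: np.ndarray,
) -> tuple[float, float]:
    """Over-represented-allele accuracy of the model and of the naive rule.

    Both are computed over the same markers (``mask``: heterozygous markers
    in truth-imbalanced regions).  The model calls the allele with the larger
    posterior over-representation probability; the naive rule calls B
    over-represented when BAF > 0.5.
    """
    pa = np.asarray(p_a_over, dtype=float)[mask]
    pb = np.asarray(p_b_over, dtype=float)[mask]
    b = np.asarray(baf, dtype=float)[mask]
    t = np.asarray(truth_over, dtype=object)[mask]
    if len(t) == 0:
        return float("nan"), float("nan")
    model_call = np.where(pb >= pa, "B", "A")
    naive_call = np.where(b > 0.5, "B", "A")
    return float((model_call == t).mean()), float((naive_call == t).mean())


@dataclass
class LadderResult:
    """Outcome of a detection-length ladder scan."""

    purity: float
    table: pd.DataFrame  # length_mb, n_markers, detected_replicates, replicates
    smallest_detected_mb: float | None
    detail: dict = field(default_factory=dict)


def detection_ladder(
    purity: float,
    lengths_mb,
    replicates: int = 5,
    seed: int = 0,
    *,
    spacing_bp: int = 9000,
    markers_per_chrom: int = 11000,
    K: int = 5,
    n_panel_haplotypes: int = 60,
    sigma_b: float = 0.03,
    sigma_r: float = 0.18,
    detect_any_ai: bool = True,
    stop_at_first: bool = True,
) -> LadderResult:
    """Smallest single cn-LOH region detected at a given purity.

    For each candidate length (ascending), a single cn-LOH region is placed
    mid-chromosome on a 370K-density simulated chromosome; the engine decodes
    the sample at the design emission parameters, and the region counts as
    detected when more than half of its markers receive an aberrant modal
    category (restricted to the cn-LOH category when ``detect_any_ai`` is
    False).  A length is "detected" when the majority of seeded replicates
    detect it; by default the scan stops at the first detected length, which
    is the reported minimum.
    """
    from .emission import TumorParams
    from .engine import call_states, forward_backward
    from .io import call_genotypes, intersect_markers
    from .simulate import Region, SimulationSpec, simulate_panel, simulate_sample
    from .states import AberrationState
    from .cluster import fit_cluster_model

    lengths_mb = sorted(lengths_mb)
    panel, _ = simulate_panel(
        n_panel_haplotypes, markers_per_chrom, K, seed=seed,
        n_chromosomes=1, spacing_bp=spacing_bp,
    )
    model = fit_cluster_model(panel, K=K, n_starts=1, max_iter=20, seed=seed)[0]
    rows = []
    smallest = None
    detail: dict = {}
    for li, mb in enumerate(lengths_mb):
        n_mark = max(int(round(mb * 1e6 / spacing_bp)), 2)
        if n_mark > markers_per_chrom:
            raise ValueError(f"region of {mb} Mb exceeds the simulated chromosome")
        start = (markers_per_chrom - n_mark) // 2
        n_det = 0
        fracs = []
        for rep in range(replicates):
            rep_seed = seed + 7919 * (li + 1) + rep
            state = AberrationState(2, 0) if rep % 2 == 0 else AberrationState(0, 2)
            spec = SimulationSpec(
                purity=purity, n_chromosomes=1,
                markers_per_chrom=markers_per_chrom, spacing_bp=spacing_bp,
                regions=[Region("chr1", start, start + n_mark, state)],
                sigma_b=sigma_b, sigma_r=sigma_r, seed=rep_seed,
            )
            table, truth, _ = simulate_sample(spec, model)
            table = call_genotypes(table)
            table_i, model_i = intersect_markers(table, model)
            jp = forward_backward(
                table_i, model_i, TumorParams(w=purity, sigma_b=sigma_b, sigma_r=sigma_r)
            )
            calls, _ = call_states(jp)
            in_region = slice(start, start + n_mark)
            cat = calls["category"].to_numpy(dtype=object)[in_region]
            if detect_any_ai:
                hit = cat != NORMAL_CATEGORY
            else:
                hit = cat == "2-0"
            frac = float(hit.mean())
            fracs.append(frac)
            if frac > 0.5:
                n_det += 1
        detected = n_det > replicates / 2
        rows.append(
            {
                "length_mb": mb,
                "n_markers": n_mark,
                "detected_replicates": n_det,
                "replicates": replicates,
                "detected": detected,
            }
        )
        detail[mb] = fracs
        logger.info(
            "ladder purity=%.2f length=%.1f Mb: %d/%d replicates detected",
            purity, mb, n_det, replicates,
        )
        if detected:
            smallest = mb
            if stop_at_first:
                break
    return LadderResult(
        purity=purity,
        table=pd.DataFrame(rows),
        smallest_detected_mb=smallest,
        detail=detail,
    )
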