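"""Validation harnesses: internal (OOB / k-fold) validation, flanking-window
sweep, call-threshold sweep, and per-CN-class diagnostic metrics.

The primary accuracy metric is the unordered CN-pair match; total-CN accuracy
and confusion are reported alongside, since the two coincide only when every
total decomposes uniquely within the allowed per-haplotype range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CNGenotype, GenotypeMatrix, select_flanking, snp_qc
from .em_haplotype import PosteriorDistribution
from .classifier import prediction_correct
from .ensemble import (
    EnsembleConfig,
    LIBAGModel,
    PredictionResult,
    RegionConfig,
    aggregate,
    build_model,
    predict,
)
from .em_haplotype import posterior_cn_many


@dataclass
class ConfusionTable:
    """Square confusion matrix over CN classes (pairs or totals)."""

    classes: list  # class labels, sorted; pairs are tuples, totals ints
    counts: np.ndarray  # rows = truth, cols = prediction
    mode: str = "pair"  # "pair" or "total"

    @classmethod
    def from_calls(cls, truths: list, preds: list, mode: str = "pair") -> "ConfusionTable":
        classes = sorted(set(truths) | set(preds))
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(truths, preds):
            counts[idx[t], idx[p]] += 1
        return cls(classes=classes, counts=counts, mode=mode)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else math.nan


def class_metrics(ct: ConfusionTable) -> dict:
    """One-vs-rest SEN/SPE/PPV/NPV per CN class.

    Undefined ratios (0/0) are reported as NaN — "not available", never 0.
    """
    if ct.total == 0:
        raise ValueError("empty confusion table")
    out = {}
    grand = ct.counts.sum()
    for i, klass in enumerate(ct.classes):
        tp = ct.counts[i, i]
        fn = ct.counts[i, :].sum() - tp
        fp = ct.counts[:, i].sum() - tp
        tn = grand - tp - fn - fp

        def ratio(num, den):
            return float(num / den) if den > 0 else math.nan

        out[klass] = {
            "SEN": ratio(tp, tp + fn),
            "SPE": ratio(tn, tn + fp),
            "PPV": ratio(tp, tp + fp),
            "NPV": ratio(tn, tn + fn),
        }
    return out


@dataclass
class ValidationResult:
    accuracy: float  # unordered CN-pair accuracy (primary)
    accuracy_total: float  # total-CN accuracy
    confusion_pair: ConfusionTable
    confusion_total: ConfusionTable
    n_scored: int
    n_unscored: int  # samples never out-of-bag (OOB mode only)
    model: LIBAGModel | None = None


def _score_calls(
    label_list: list[CNGenotype], pred_pairs: list[tuple[int, int] | None]
) -> ValidationResult:
    truths_pair, preds_pair, truths_total, preds_total = [], [], [], []
    n_correct_pair = n_correct_total = 0
    n = 0
    for label, pred in zip(label_list, pred_pairs):
        if pred is None:
            continue
        n += 1
        if prediction_correct(pred, label):
            n_correct_pair += 1
        if sum(pred) == label.total:
            n_correct_total += 1
        truths_pair.append(label.cn_pair if label.known_phase_split else ("total", label.total))
        preds_pair.append(tuple(sorted(pred)))
        truths_total.append(label.total)
        preds_total.append(sum(pred))
    return ValidationResult(
        accuracy=n_correct_pair / n if n else math.nan,
        accuracy_total=n_correct_total / n if n else math.nan,
        confusion_pair=ConfusionTable.from_calls(truths_pair, preds_pair, mode="pair"),
        confusion_total=ConfusionTable.from_calls(truths_total, preds_total, mode="total"),
        n_scored=n,
        n_unscored=len(label_list) - n,
    )


def internal_validation(
    panel: GenotypeMatrix,
    labels: dict[str, CNGenotype] | list[CNGenotype],
    region: RegionConfig,
    cfg: EnsembleConfig | None = None,
    mode: str = "oob",
    folds: int = 5,
    model: LIBAGModel | None = None,
) -> ValidationResult:
    """Internal validation of imputation accuracy on a labeled panel.

    ``oob`` mode builds one model and scores each sample by aggregating only
    the classifiers whose out-of-bag set contains it; ``kfold`` mode runs
    cross-validation stratified by CN genotype (falling back to unstratified
    when a class has fewer members than folds).
    """
    cfg = cfg or EnsembleConfig()
    label_list = (
        [labels[s] for s in panel.samples] if isinstance(labels, dict) else list(labels)
    )
    if mode == "oob":
        if model is None:
            model = build_model(panel, label_list, region, cfg)
        per_cls = []
        oob_masks = []
        for c in model.classifiers:
            subset = c.hap_set.snp_subset
            per_cls.append(posterior_cn_many(c.hap_set, panel.codes[:, subset]))
            mask = np.zeros(panel.n_samples, dtype=bool)
            mask[c.split.out_of_bag] = True
            oob_masks.append(mask)
        pred_pairs: list[tuple[int, int] | None] = []
        for i in range(panel.n_samples):
            posts = [pc[i] for pc, m in zip(per_cls, oob_masks) if m[i]]
            if not posts:
                pred_pairs.append(None)  # never out-of-bag
                continue
            agg, _ = aggregate(posts)
            pred_pairs.append(agg.best_pair()[0] if agg.defined else None)
        result = _score_calls(label_list, pred_pairs)
        result.model = model
        return result

    if mode != "kfold":
        raise ValueError(f"unknown validation mode {mode!r}")

    n = panel.n_samples
    strata: dict = {}
    for i, lab in enumerate(label_list):
        key = lab.cn_pair if lab.known_phase_split else ("total", lab.total)
        strata.setdefault(key, []).append(i)
    rng = np.random.default_rng(cfg.rng_seed)
    if min(len(v) for v in strata.values()) < 2:
        warnings.warn("a CN class has <2 samples; folds are unstratified", stacklevel=2)
        order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[order] = np.arange(n) % folds
    else:
        fold_of = np.empty(n, dtype=int)
        for members in strata.values():
            members = rng.permutation(members)
            fold_of[members] = np.arange(len(members)) % folds
    pred_pairs = [None] * n
    for f in range(folds):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        if len(test) == 0:
            continue
        sub_model = build_model(
            panel.subset_samples(train), [label_list[i] for i in train], region, cfg
        )
        calls, _ = predict(sub_model, panel.subset_samples(test), ct=0.0)
        for i, call in zip(test, calls):
            pred_pairs[i] = call.best_cn_pair
    return _score_calls(label_list, pred_pairs)


@dataclass
class WindowSweepRow:
    window_kb: float
    n_snps: int
    accuracy: float
    n_called: int


@dataclass
class CTSweepRow:
    ct: float
    call_rate: float
    accuracy: float
    n_called: int


def window_sweep(
    panel: GenotypeMatrix,
    labels: dict[str, CNGenotype] | list[CNGenotype],
    region: RegionConfig,
    cfg: EnsembleConfig | None = None,
    windows: list[float] | None = None,
    qc: bool = True,
    mode: str = "oob",
) -> list[WindowSweepRow]:
    """Internal-validation accuracy as a function of the flanking window.

    For each window: select flanking SNPs, apply QC, build a model, validate.
    """
    cfg = cfg or EnsembleConfig()
    windows = list(windows) if windows is not None else [float(w) for w in range(10, 101, 10)]
    rows = []
    for w in windows:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = select_flanking(panel, region.chrom, region.center, w)
            if qc and sub.n_snps > 0:
                sub, _ = snp_qc(sub)
        if sub.n_snps == 0:
            rows.append(WindowSweepRow(window_kb=w, n_snps=0, accuracy=math.nan, n_called=0))
            continue
        sub_region = RegionConfig(region.gene, region.chrom, region.center, w)
        res = internal_validation(sub, labels, sub_region, cfg, mode=mode)
        rows.append(
            WindowSweepRow(
                window_kb=w, n_snps=sub.n_snps, accuracy=res.accuracy, n_called=res.n_scored
            )
        )
    return rows


def ct_sweep(
    predictions: list[PredictionResult],
    truth: dict[str, CNGenotype] | list[CNGenotype],
    grid: list[float] | None = None,
) -> list[CTSweepRow]:
    """Call rate and accuracy-among-called across a call-threshold grid.

    Accuracy is computed only among called samples; call rate is asserted to
    be monotone non-increasing in CT.
    """
    if grid is None:
        grid = [round(0.05 * i, 2) for i in range(20)]  # 0.00 .. 0.95
    truth_list = (
        [truth[p.sample] for p in predictions] if isinstance(truth, dict) else list(truth)
    )
    n = len(predictions)
    if n == 0:
        raise ValueError("no predictions to sweep")
    rows = []
    prev_rate = 1.0 + 1e-12
    for ct in grid:
        n_called = 0
        n_correct = 0
        for pred, label in zip(predictions, truth_list):
            if pred.best_cn_pair is None or pred.aggregated_prob < ct:
                continue
            n_called += 1
            if prediction_correct(pred.best_cn_pair, label):
                n_correct += 1
        rate = n_called / n
        assert rate <= prev_rate, "call rate must be non-increasing in CT"
        prev_rate = rate
        rows.append(
            CTSweepRow(
                ct=float(ct),
                call_rate=rate,
                accuracy=n_correct / n_called if n_called else math.nan,
                n_called=n_called,
            )
        )
    return rows


def sweep_to_frame(rows: list) -> pd.DataFrame:
    """Tabulate sweep rows (window or CT) for TSV output."""
    return pd.DataFrame([vars(r) for r in rows])
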