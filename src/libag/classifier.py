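"""Training of a single attribute-bagged classifier.

One classifier is built from one bootstrap replicate of the reference panel:
the individuals drawn in-bag (with replacement) supply the EM training data,
the out-of-bag (OOB) individuals — roughly 37% of the panel in expectation,
(1 - 1/n)^n exactly — act as that classifier's built-in validation set.  The
SNP subset S_k is grown greedily: starting from the single best SNP among a
random draw of ``mtry`` candidates, additions are accepted only when they
strictly improve OOB accuracy, with one redraw of fresh candidates allowed
after a failed round before growth stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, sqrt

import numpy as np

from .data_io import CNGenotype, GenotypeMatrix
from .em_haplotype import (
    HaplotypeSet,
    TooManyConfigurationsError,
    em_fit,
    posterior_cn_many,
)


@dataclass
class BootstrapSplit:
    """One bootstrap replicate: in-bag multiset and its out-of-bag complement."""

    in_bag: np.ndarray  # n indices drawn with replacement
    out_of_bag: np.ndarray  # sorted indices absent from in_bag
    seed: int

    @property
    def n(self) -> int:
        return len(self.in_bag)

    @property
    def oob_fraction(self) -> float:
        return len(self.out_of_bag) / self.n


@dataclass
class Classifier:
    """A trained ensemble member: bootstrap split, fitted haplotypes, history."""

    split: BootstrapSplit
    hap_set: HaplotypeSet
    oob_accuracy: float
    history: list[tuple[int, float]] = field(default_factory=list)  # (snp index, OOB acc)
    seed: int = 0


def bootstrap_sample(n: int, rng_seed: int) -> BootstrapSplit:
    """Draw n individuals uniformly with replacement; deterministic given the seed."""
    if n < 2:
        raise ValueError("bootstrap requires n >= 2")
    rng = np.random.default_rng(rng_seed)
    in_bag = rng.integers(0, n, size=n)
    out_of_bag = np.setdiff1d(np.arange(n), in_bag)
    return BootstrapSplit(in_bag=in_bag, out_of_bag=out_of_bag, seed=int(rng_seed))


def prediction_correct(pred_pair: tuple[int, int], label: CNGenotype) -> bool:
    """Unordered-pair match; labels with unknown phase split compare on totals."""
    if label.known_phase_split:
        return tuple(sorted(pred_pair)) == label.cn_pair
    return sum(pred_pair) == label.total


def _accuracy(hs: HaplotypeSet, codes: np.ndarray, labels: list[CNGenotype]) -> float:
    posteriors = posterior_cn_many(hs, codes)
    n_correct = 0
    for post, label in zip(posteriors, labels):
        if not post.defined:
            continue  # abstention counts as incorrect
        pair, _ = post.best_pair()
        if prediction_correct(pair, label):
            n_correct += 1
    return n_correct / len(labels)


def oob_accuracy(
    c: Classifier, g: GenotypeMatrix, labels: list[CNGenotype]
) -> float:
    """Fraction of out-of-bag individuals whose argmax posterior CN pair
    matches the truth; abstentions count as incorrect."""
    oob = c.split.out_of_bag
    if len(oob) == 0:
        raise ValueError("empty out-of-bag set")
    subset = c.hap_set.snp_subset
    codes = g.codes[np.ix_(oob, subset)]
    return _accuracy(c.hap_set, codes, [labels[i] for i in oob])


def grow_snp_subset(
    g: GenotypeMatrix,
    labels: list[CNGenotype],
    split: BootstrapSplit,
    candidate_pool: list[int] | np.ndarray | None = None,
    mtry: int | None = None,
    max_snps: int | None = None,
    rng_seed: int = 0,
    cn_range: tuple[int, int] = (0, 4),
    em_tol: float = 1e-6,
    em_max_iter: int = 200,
    prune_freq: float | None = None,
) -> Classifier:
    """Grow the SNP subset of one classifier by greedy OOB-accuracy search.

    Each round draws ``mtry`` candidates from the SNPs not yet in the subset, fits EM
    on the in-bag data for every tentative addition, and keeps the best
    addition if it strictly improves OOB accuracy (ties between candidates
    broken by higher in-bag log-likelihood, then lower SNP index).  Growth
    stops after two consecutive failed rounds (one "patience" redraw), when
    the pool is exhausted, or at ``max_snps``.
    """
    pool = (
        np.arange(g.n_snps) if candidate_pool is None else np.asarray(candidate_pool)
    )
    if len(pool) == 0:
        raise ValueError("candidate pool is empty")
    p = len(pool)
    if mtry is None:
        mtry = ceil(sqrt(p))
    if max_snps is None:
        max_snps = min(p, 25)
    if len(split.out_of_bag) == 0:
        raise ValueError("empty out-of-bag set; redraw the bootstrap first")
    rng = np.random.default_rng(rng_seed)

    # in-bag multiset as unique rows + multiplicity weights (equivalent, faster)
    ib_idx, ib_counts = np.unique(split.in_bag, return_counts=True)
    ib_labels = [labels[i] for i in ib_idx]
    ib_ids = [g.samples[i] for i in ib_idx]
    oob = split.out_of_bag
    oob_labels = [labels[i] for i in oob]

    def fit_and_score(subset: list[int]) -> tuple[float, float, HaplotypeSet] | None:
        try:
            hs = em_fit(
                g.codes[np.ix_(ib_idx, subset)],
                ib_labels,
                cn_range=cn_range,
                tol=em_tol,
                max_iter=em_max_iter,
                prune_freq=prune_freq,
                weights=ib_counts.astype(float),
                sample_ids=ib_ids,
                snp_subset=subset,
            )
        except TooManyConfigurationsError:
            return None  # subset too ambiguous; treat as a non-improving candidate
        acc = _accuracy(hs, g.codes[np.ix_(oob, subset)], oob_labels)
        return acc, hs.log_lik, hs

    # "unused" = not yet in S_k; candidates rejected in one round stay drawable,
    # so mtry >= |pool| reduces to deterministic greedy forward selection
    unused = list(np.sort(pool))
    history: list[tuple[int, float]] = []

    def draw(k: int) -> list[int]:
        take = min(k, len(unused))
        chosen = rng.choice(len(unused), size=take, replace=False)
        return [unused[i] for i in sorted(chosen)]

    # seed subset: best single SNP among the initial draw
    best_state = None
    for cand in draw(mtry):
        scored = fit_and_score([cand])
        if scored is None:
            continue
        acc, ll, hs = scored
        if best_state is None or (acc, ll, -cand) > (
            best_state[0], best_state[1], -best_state[3]
        ):
            best_state = (acc, ll, hs, cand)
    if best_state is None:
        raise ValueError("no candidate SNP could be fit")
    best_acc, _, best_hs, first = best_state
    subset = [first]
    unused.remove(first)
    history.append((first, best_acc))

    failures = 0
    while len(subset) < max_snps and unused and failures < 2:
        round_best = None
        for cand in draw(mtry):
            scored = fit_and_score(subset + [cand])
            if scored is None:
                continue
            acc, ll, hs = scored
            if round_best is None or (acc, ll, -cand) > (
                round_best[0], round_best[1], -round_best[3]
            ):
                round_best = (acc, ll, hs, cand)
        if round_best is not None and round_best[0] > best_acc:
            best_acc, _, best_hs, added = round_best
            subset.append(added)
            unused.remove(added)
            history.append((added, best_acc))
            failures = 0
        else:
            failures += 1

    return Classifier(
        split=split,
        hap_set=best_hs,
        oob_accuracy=best_acc,
        history=history,
        seed=int(rng_seed),
    )
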