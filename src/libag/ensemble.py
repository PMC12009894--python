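"""The K-classifier ensemble: build, SNP matching against a target, prediction.

The ensemble prediction averages the per-classifier posterior CN-pair
distributions arithmetically (classifiers whose posterior is undefined for a
sample abstain and are excluded from the mean); the pair with the highest
aggregated probability is the call, reported only when that probability
reaches the call threshold (CT, default 0.5).

Before prediction the model's SNP universe is matched to the target dataset
by snp_id (falling back to chrom+position), reconciling allele coding:
swapped alleles recode genotypes g -> 2 - g, complementary alleles are
strand-flipped and re-compared, and palindromic (A/T, C/G) SNPs whose
orientation cannot be resolved are dropped by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, CNGenotype, GenotypeMatrix, SNPMeta
from .em_haplotype import ExtendedHaplotype, HaplotypeSet, PosteriorDistribution, posterior_cn_many
from .classifier import BootstrapSplit, Classifier, bootstrap_sample, grow_snp_subset

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class RegionConfig:
    """The gene/region a model is built for."""

    gene: str
    chrom: str
    center: int  # 1-based bp
    window_kb: float


@dataclass
class EnsembleConfig:
    """Build parameters for the ensemble."""

    n_classifiers: int = 25
    mtry: int | None = None  # default ceil(sqrt(P)) at build time
    max_snps: int | None = None  # default min(P, 25)
    em_tol: float = 1e-6
    em_max_iter: int = 200
    prune_freq: float | None = None  # default 1 / (4 * N_inbag)
    rng_seed: int = 0
    cn_min: int = 0
    cn_max: int = 4

    def __post_init__(self) -> None:
        if self.n_classifiers < 1:
            raise ValueError("need at least one classifier")
        if self.cn_min > self.cn_max:
            raise ValueError("cn_min must not exceed cn_max")

    @property
    def cn_range(self) -> tuple[int, int]:
        return (self.cn_min, self.cn_max)


def classifier_seed(rng_seed: int, k: int) -> int:
    """Stable per-classifier seed: numpy SeedSequence(rng_seed, spawn_key=(k,)).

    Platform-independent and documented so parallel builds reproduce."""
    ss = np.random.SeedSequence(entropy=int(rng_seed), spawn_key=(int(k),))
    return int(ss.generate_state(1)[0])


@dataclass
class LIBAGModel:
    """A trained copy-number imputation model for one gene."""

    region: RegionConfig
    snps: list[SNPMeta]  # the SNP universe classifiers index into
    classifiers: list[Classifier]
    config: EnsembleConfig

    def to_dict(self) -> dict:
        return {
            "gene": self.region.gene,
            "chrom": self.region.chrom,
            "center": self.region.center,
            "window_kb": self.region.window_kb,
            "cn_min": self.config.cn_min,
            "cn_max": self.config.cn_max,
            "config": {
                "n_classifiers": self.config.n_classifiers,
                "mtry": self.config.mtry,
                "max_snps": self.config.max_snps,
                "em_tol": self.config.em_tol,
                "em_max_iter": self.config.em_max_iter,
                "prune_freq": self.config.prune_freq,
                "rng_seed": self.config.rng_seed,
            },
            "snps": [
                {
                    "snp_id": s.snp_id,
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "allele_a": s.allele_a,
                    "allele_b": s.allele_b,
                }
                for s in self.snps
            ],
            "classifiers": [
                {
                    "seed": c.seed,
                    "bootstrap_seed": c.split.seed,
                    "in_bag": [int(i) for i in c.split.in_bag],
                    "oob_accuracy": c.oob_accuracy,
                    "history": [[int(j), float(a)] for j, a in c.history],
                    "snp_subset": [int(j) for j in c.hap_set.snp_subset],
                    "log_lik": c.hap_set.log_lik,
                    "haplotypes": [
                        {
                            "alleles": list(h.snp_alleles),
                            "cn": h.cn_allele,
                            "freq": h.freq,
                        }
                        for h in c.hap_set.haplotypes
                    ],
                }
                for c in self.classifiers
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LIBAGModel":
        cfg_doc = doc["config"]
        cfg = EnsembleConfig(
            n_classifiers=cfg_doc["n_classifiers"],
            mtry=cfg_doc["mtry"],
            max_snps=cfg_doc["max_snps"],
            em_tol=cfg_doc["em_tol"],
            em_max_iter=cfg_doc["em_max_iter"],
            prune_freq=cfg_doc["prune_freq"],
            rng_seed=cfg_doc["rng_seed"],
            cn_min=doc["cn_min"],
            cn_max=doc["cn_max"],
        )
        region = RegionConfig(
            gene=doc["gene"], chrom=doc["chrom"], center=doc["center"],
            window_kb=doc["window_kb"],
        )
        snps = [
            SNPMeta(s["snp_id"], s["chrom"], s["pos"], s["allele_a"], s["allele_b"])
            for s in doc["snps"]
        ]
        classifiers = []
        for cd in doc["classifiers"]:
            in_bag = np.asarray(cd["in_bag"], dtype=np.int64)
            split = BootstrapSplit(
                in_bag=in_bag,
                out_of_bag=np.setdiff1d(np.arange(len(in_bag)), in_bag),
                seed=cd["bootstrap_seed"],
            )
            hs = HaplotypeSet(
                snp_subset=[int(j) for j in cd["snp_subset"]],
                haplotypes=[
                    ExtendedHaplotype(
                        snp_alleles=tuple(h["alleles"]),
                        cn_allele=int(h["cn"]),
                        freq=float(h["freq"]),
                    )
                    for h in cd["haplotypes"]
                ],
                log_lik=float(cd["log_lik"]),
            )
            classifiers.append(
                Classifier(
                    split=split,
                    hap_set=hs,
                    oob_accuracy=float(cd["oob_accuracy"]),
                    history=[(int(j), float(a)) for j, a in cd["history"]],
                    seed=int(cd["seed"]),
                )
            )
        return cls(region=region, snps=snps, classifiers=classifiers, config=cfg)


@dataclass
class SNPMatchReport:
    """Outcome of aligning a target dataset to a model's SNP universe."""

    status: list[str]  # per model SNP, one of the five statuses below
    STATUSES = (
        "matched",
        "matched_swapped",
        "matched_strand_flipped",
        "ambiguous_dropped",
        "missing_in_target",
    )

    def counts(self) -> dict[str, int]:
        return {s: self.status.count(s) for s in self.STATUSES}

    @property
    def n_usable(self) -> int:
        return sum(1 for s in self.status if s.startswith("matched"))


@dataclass
class PredictionResult:
    """One sample's aggregated call."""

    sample: str
    best_cn_pair: tuple[int, int] | None
    total_cn: int | None
    aggregated_prob: float
    called: bool
    n_abstained: int


def build_model(
    panel: GenotypeMatrix,
    labels: dict[str, CNGenotype] | list[CNGenotype],
    region: RegionConfig,
    cfg: EnsembleConfig | None = None,
) -> LIBAGModel:
    """Train K classifiers on a QC'd, flank-selected reference panel.

    Every panel sample must carry a CN label.  Per-classifier seeds derive
    deterministically from ``cfg.rng_seed``; an empty out-of-bag draw is
    retried with an offset seed (up to 10 times) before erroring.
    """
    cfg = cfg or EnsembleConfig()
    if panel.n_snps == 0:
        raise ValueError("panel has no SNPs after filtering")
    if isinstance(labels, dict):
        missing = [s for s in panel.samples if s not in labels]
        if missing:
            raise ValueError(f"samples without CN labels: {missing[:5]}")
        label_list = [labels[s] for s in panel.samples]
    else:
        if len(labels) != panel.n_samples:
            raise ValueError("label list length must match the panel")
        label_list = list(labels)

    n = panel.n_samples
    classifiers = []
    for k in range(cfg.n_classifiers):
        seed_k = classifier_seed(cfg.rng_seed, k)
        split = bootstrap_sample(n, seed_k)
        for attempt in range(1, 11):
            if len(split.out_of_bag) > 0:
                break
            split = bootstrap_sample(n, seed_k + attempt)
        else:
            raise RuntimeError("could not draw a bootstrap with a non-empty OOB set")
        c = grow_snp_subset(
            panel,
            label_list,
            split,
            candidate_pool=np.arange(panel.n_snps),
            mtry=cfg.mtry,
            max_snps=cfg.max_snps,
            rng_seed=seed_k,
            cn_range=cfg.cn_range,
            em_tol=cfg.em_tol,
            em_max_iter=cfg.em_max_iter,
            prune_freq=cfg.prune_freq,
        )
        classifiers.append(c)
    return LIBAGModel(region=region, snps=list(panel.snps), classifiers=classifiers, config=cfg)


def _reconcile(model_snp: SNPMeta, target_snp: SNPMeta, keep_palindromic: bool):
    """Return (status, flip_codes) or None when alleles cannot be reconciled."""
    ma, mb = model_snp.allele_a, model_snp.allele_b
    ta, tb = target_snp.allele_a, target_snp.allele_b
    palindromic = ma == _COMPLEMENT[mb]
    if palindromic and not keep_palindromic:
        return ("ambiguous_dropped", False)
    if (ta, tb) == (ma, mb):
        return ("matched", False)
    if (ta, tb) == (mb, ma):
        return ("matched_swapped", True)
    ca, cb = _COMPLEMENT[ta], _COMPLEMENT[tb]
    if (ca, cb) == (ma, mb):
        return ("matched_strand_flipped", False)
    if (ca, cb) == (mb, ma):
        return ("matched_strand_flipped", True)
    return None


def match_snps(
    model: LIBAGModel, target: GenotypeMatrix, keep_palindromic: bool = False
) -> tuple[GenotypeMatrix, SNPMatchReport]:
    """Align a target dataset to the model's SNP universe.

    Returns a genotype matrix over the model's SNPs (in model order, model
    allele coding); unmatched or unresolvable columns are all-MISSING.
    """
    by_id = {s.snp_id: j for j, s in enumerate(target.snps)}
    by_pos = {(s.chrom, s.pos): j for j, s in enumerate(target.snps)}
    n = target.n_samples
    codes = np.full((n, len(model.snps)), MISSING, dtype=np.int8)
    status: list[str] = []
    for j, snp in enumerate(model.snps):
        tj = by_id.get(snp.snp_id)
        if tj is None:
            tj = by_pos.get((snp.chrom, snp.pos))
        if tj is None:
            status.append("missing_in_target")
            continue
        rec = _reconcile(snp, target.snps[tj], keep_palindromic)
        if rec is None:
            status.append("ambiguous_dropped")
            continue
        st, flip = rec
        if st == "ambiguous_dropped":
            status.append(st)
            continue
        col = target.codes[:, tj].copy()
        if flip:
            known = col != MISSING
            col[known] = 2 - col[known]
        codes[:, j] = col
        status.append(st)
    aligned = GenotypeMatrix(samples=list(target.samples), snps=list(model.snps), codes=codes)
    return aligned, SNPMatchReport(status=status)


def aggregate(posteriors: list[PosteriorDistribution]) -> tuple[PosteriorDistribution, int]:
    """Arithmetic mean of the non-abstaining distributions, renormalized.

    Returns the aggregate and the abstention count; all-abstain yields an
    undefined distribution (a no-call upstream).
    """
    voting = [p for p in posteriors if p.defined]
    n_abstained = len(posteriors) - len(voting)
    if not voting:
        return PosteriorDistribution(probs={}, defined=False), n_abstained
    acc: dict[tuple[int, int], float] = {}
    for p in voting:
        for pair, prob in p.probs.items():
            acc[pair] = acc.get(pair, 0.0) + prob
    total = sum(acc.values())
    probs = {pair: v / total for pair, v in acc.items()}
    return PosteriorDistribution(probs=probs), n_abstained


def predict(
    model: LIBAGModel,
    target: GenotypeMatrix,
    ct: float = 0.5,
    keep_palindromic: bool = False,
) -> tuple[list[PredictionResult], SNPMatchReport]:
    """Impute CN genotypes for every target sample.

    A classifier with no usable SNP after matching abstains for all samples;
    a sample whose aggregated maximum probability falls below the call
    threshold ``ct`` is reported as a no-call (still a row, ``called`` False).
    """
    aligned, report = match_snps(model, target, keep_palindromic=keep_palindromic)
    usable = np.array([s.startswith("matched") for s in report.status])
    per_classifier: list[list[PosteriorDistribution] | None] = []
    any_usable = False
    for c in model.classifiers:
        subset = c.hap_set.snp_subset
        if not usable[subset].any():
            per_classifier.append(None)  # abstains everywhere
            continue
        any_usable = True
        per_classifier.append(posterior_cn_many(c.hap_set, aligned.codes[:, subset]))
    if not any_usable:
        raise ValueError("no classifier has any usable SNP in the target dataset")

    results = []
    abstain_all = PosteriorDistribution(probs={}, defined=False)
    for i, sample in enumerate(target.samples):
        posts = [
            (pc[i] if pc is not None else abstain_all) for pc in per_classifier
        ]
        agg, n_abstained = aggregate(posts)
        if not agg.defined:
            results.append(
                PredictionResult(
                    sample=sample, best_cn_pair=None, total_cn=None,
                    aggregated_prob=0.0, called=False, n_abstained=n_abstained,
                )
            )
            continue
        pair, prob = agg.best_pair()
        results.append(
            PredictionResult(
                sample=sample,
                best_cn_pair=pair,
                total_cn=sum(pair),
                aggregated_prob=prob,
                called=prob >= ct,
                n_abstained=n_abstained,
            )
        )
    return results, report
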