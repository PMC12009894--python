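"""EM estimation of joint SNP + CN-allele ("extended") haplotype frequencies.

The gene's copy-number allele is treated as one extra multiallelic locus
appended to a vector of biallelic SNP alleles.  Frequencies of these extended
haplotypes are estimated from unphased SNP genotypes plus per-individual CN
labels by expectation–maximization over the latent phase, assuming
Hardy–Weinberg equilibrium (random pairing of haplotypes): the likelihood of
individual i is  L_i = sum over compatible ordered pairs (h1, h2) of
f(h1) * f(h2).

Missing SNP genotypes are marginalized (the site is unconstrained), never
imputed.  CN labels may be a known per-haplotype pair or a diploid total with
the decomposition latent.

Internally a haplotype over a SNP subset S is a pair ``(bits, cn)`` where bit
j of ``bits`` is the allele at the j-th SNP of S; this caps |S| at 60, far
above any subset the greedy growth produces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data_io import MISSING, CNGenotype, GenotypeMatrix

_MAX_BITS = 60

#: Safety cap on per-individual configuration enumeration (2^het * 4^missing
#: * CN decompositions).  Exceeding it signals a subset too ambiguous to fit.
DEFAULT_MAX_CONFIGS = 65536


class TooManyConfigurationsError(RuntimeError):
    """Per-individual latent-configuration enumeration exceeded the cap."""


class IncompatibleSampleError(ValueError):
    """An individual admits no haplotype configuration (corrupt label)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtendedHaplotype:
    """A phased SNP allele vector plus the CN allele it carries."""

    snp_alleles: tuple[int, ...]
    cn_allele: int
    freq: float


@dataclass
class HaplotypeSet:
    """The fitted object of one classifier: subset, haplotypes, frequencies."""

    snp_subset: list[int]  # indices into the model's SNP universe
    haplotypes: list[ExtendedHaplotype]
    log_lik: float

    # cached arrays for fast posterior evaluation
    _bits: np.ndarray | None = field(default=None, repr=False, compare=False)
    _cn: np.ndarray | None = field(default=None, repr=False, compare=False)
    _freq: np.ndarray | None = field(default=None, repr=False, compare=False)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._bits is None:
            bits = np.array(
                [_alleles_to_bits(h.snp_alleles) for h in self.haplotypes], dtype=np.uint64
            )
            self._bits = bits
            self._cn = np.array([h.cn_allele for h in self.haplotypes], dtype=np.int64)
            self._freq = np.array([h.freq for h in self.haplotypes], dtype=np.float64)
        return self._bits, self._cn, self._freq


@dataclass
class PosteriorDistribution:
    """Probabilities over unordered CN pairs; ``defined`` is False when no
    haplotype pair in the set is compatible with the genotype (abstention)."""

    probs: dict[tuple[int, int], float]
    defined: bool = True

    def best_pair(self) -> tuple[tuple[int, int], float]:
        """Argmax pair; exact probability ties broken by lexicographically
        smallest pair."""
        if not self.defined or not self.probs:
            raise ValueError("posterior is undefined")
        best_p = max(self.probs.values())
        best = min(pair for pair, p in self.probs.items() if p == best_p)
        return best, best_p


# ---------------------------------------------------------------------------
# Configuration enumeration
# ---------------------------------------------------------------------------


def _alleles_to_bits(alleles: tuple[int, ...]) -> int:
    bits = 0
    for j, a in enumerate(alleles):
        if a:
            bits |= 1 << j
    return bits


def _bits_to_alleles(bits: int, n: int) -> tuple[int, ...]:
    return tuple((bits >> j) & 1 for j in range(n))


_SITE_OPTIONS = {
    0: ((0, 0),),
    1: ((0, 1), (1, 0)),
    2: ((1, 1),),
    MISSING: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


def _cn_pair_options(
    cn: CNGenotype | None, cn_range: tuple[int, int]
) -> list[tuple[int, int]]:
    """Ordered (c1, c2) options consistent with the label (or all, if None)."""
    lo, hi = cn_range
    if cn is None:
        return [(c1, c2) for c1 in range(lo, hi + 1) for c2 in range(lo, hi + 1)]
    if cn.known_phase_split:
        a, b = cn.cn_pair
        if not (lo <= a <= hi and lo <= b <= hi):
            return []  # corrupt label: no compatible configuration
        return [(a, b)] if a == b else [(a, b), (b, a)]
    total = cn.total
    return [(c, total - c) for c in range(lo, hi + 1) if lo <= total - c <= hi]


def _enumerate_bit_pairs(
    genotype: np.ndarray,
    cn: CNGenotype | None,
    cn_range: tuple[int, int],
    max_configs: int = DEFAULT_MAX_CONFIGS,
) -> list[tuple[int, int, int, int]]:
    """All ordered ((bits1, c1), (bits2, c2)) configurations as flat tuples."""
    s = len(genotype)
    if s > _MAX_BITS:
        raise ValueError(f"SNP subset too large ({s} > {_MAX_BITS})")
    cn_opts = _cn_pair_options(cn, cn_range)
    n_allele = 1
    site_opts = []
    for g in genotype:
        opts = _SITE_OPTIONS[int(g)]
        site_opts.append(opts)
        n_allele *= len(opts)
    if n_allele * max(len(cn_opts), 1) > max_configs:
        raise TooManyConfigurationsError(
            f"{n_allele * len(cn_opts)} configurations exceed cap {max_configs}"
        )
    out = []
    for combo in itertools.product(*site_opts):
        b1 = 0
        b2 = 0
        for j, (a1, a2) in enumerate(combo):
            if a1:
                b1 |= 1 << j
            if a2:
                b2 |= 1 << j
        for c1, c2 in cn_opts:
            out.append((b1, c1, b2, c2))
    return out


def enumerate_configurations(
    snp_genotype: np.ndarray | list[int],
    cn: CNGenotype | None,
    cn_range: tuple[int, int],
    max_configs: int = DEFAULT_MAX_CONFIGS,
) -> list[tuple[tuple[tuple[int, ...], int], tuple[tuple[int, ...], int]]]:
    """Enumerate ordered haplotype pairs consistent with one individual.

    Each element is ``((alleles1, cn1), (alleles2, cn2))`` such that the
    allele vectors sum to the genotype at every non-missing SNP and the CN
    alleles reproduce the label (pair match when the split is known, total
    match otherwise; unconstrained over ``cn_range`` when ``cn`` is None).
    """
    genotype = np.asarray(snp_genotype)
    s = len(genotype)
    pairs = _enumerate_bit_pairs(genotype, cn, cn_range, max_configs)
    return [
        ((_bits_to_alleles(b1, s), c1), (_bits_to_alleles(b2, s), c2))
        for b1, c1, b2, c2 in pairs
    ]


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------


def em_fit(
    genotypes: GenotypeMatrix | np.ndarray,
    labels: list[CNGenotype | None],
    cn_range: tuple[int, int] = (0, 4),
    tol: float = 1e-6,
    max_iter: int = 200,
    prune_freq: float | None = None,
    weights: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
    snp_subset: list[int] | None = None,
    max_configs: int = DEFAULT_MAX_CONFIGS,
) -> HaplotypeSet:
    """Fit extended-haplotype frequencies by EM.

    Parameters
    ----------
    genotypes
        N x |S| genotype codes restricted to the SNP subset (a
        :class:`GenotypeMatrix` or a plain code array).
    labels
        One CN label per individual (None leaves the CN unconstrained).
    weights
        Optional per-individual multiplicities (bootstrap counts); default 1.
    prune_freq
        Haplotypes below this frequency are removed once, at convergence, and
        the remainder renormalized.  Default ``1 / (4 * sum(weights))``.

    The haplotype state space is initialized to the union, over individuals,
    of haplotypes appearing in at least one compatible configuration, with
    uniform starting frequencies.  The observed-data log-likelihood is
    non-decreasing across iterations (asserted).
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    if codes.ndim != 2:
        raise ValueError("genotypes must be 2-D (individuals x SNPs)")
    n, s = codes.shape
    if n < 1 or s < 1:
        raise ValueError("em_fit requires >= 1 individual and >= 1 SNP")
    if len(labels) != n:
        raise ValueError("labels length must match individuals")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=np.float64)
    n_eff = float(w.sum())
    if prune_freq is None:
        prune_freq = 1.0 / (4.0 * n_eff)

    # enumerate per-individual configurations, building the support on the fly
    support: dict[tuple[int, int], int] = {}
    i1_parts: list[list[int]] = []
    i2_parts: list[list[int]] = []
    for i in range(n):
        pairs = _enumerate_bit_pairs(codes[i], labels[i], cn_range, max_configs)
        if not pairs:
            sid = sample_ids[i] if sample_ids else f"#{i}"
            raise IncompatibleSampleError(
                f"sample {sid}: no haplotype configuration is compatible with "
                f"its genotype and CN label"
            )
        a, b = [], []
        for b1, c1, b2, c2 in pairs:
            for key, acc in (((b1, c1), a), ((b2, c2), b)):
                idx = support.get(key)
                if idx is None:
                    idx = len(support)
                    support[key] = idx
                acc.append(idx)
        i1_parts.append(a)
        i2_parts.append(b)

    h = len(support)
    i1 = np.concatenate([np.asarray(p, dtype=np.int64) for p in i1_parts])
    i2 = np.concatenate([np.asarray(p, dtype=np.int64) for p in i2_parts])
    counts_per = np.array([len(p) for p in i1_parts])
    owner = np.repeat(np.arange(n), counts_per)
    w_owner = w[owner]

    freq = np.full(h, 1.0 / h)
    log_lik = -np.inf
    for _ in range(max_iter):
        pair_w = freq[i1] * freq[i2]
        lik = np.bincount(owner, weights=pair_w, minlength=n)
        new_ll = float(w @ np.log(lik))
        assert new_ll >= log_lik - 1e-9, "EM log-likelihood decreased"
        converged = new_ll - log_lik < tol and np.isfinite(log_lik)
        log_lik = new_ll
        if converged:
            break
        resp = w_owner * pair_w / lik[owner]
        counts = np.bincount(i1, weights=resp, minlength=h) + np.bincount(
            i2, weights=resp, minlength=h
        )
        freq = counts / (2.0 * n_eff)
    else:  # max_iter reached after an M-step: refresh the likelihood
        pair_w = freq[i1] * freq[i2]
        lik = np.bincount(owner, weights=pair_w, minlength=n)
        log_lik = float(w @ np.log(lik))

    # prune numerically-zero haplotypes once, at convergence; never orphan an
    # individual — each one keeps its most probable configuration
    keep = freq >= prune_freq
    keep[int(np.argmax(freq))] = True
    pair_score = freq[i1] * freq[i2]
    for _ in range(h):
        mask = keep[i1] & keep[i2]
        covered = np.zeros(n, dtype=bool)
        covered[owner[mask]] = True
        if covered.all():
            break
        for i in np.flatnonzero(~covered):
            rows = np.flatnonzero(owner == i)
            best = rows[int(np.argmax(pair_score[rows]))]
            keep[i1[best]] = True
            keep[i2[best]] = True
    if not keep.all():
        kept = np.flatnonzero(keep)
        remap = -np.ones(h, dtype=np.int64)
        remap[kept] = np.arange(len(kept))
        mask = keep[i1] & keep[i2]
        i1p, i2p, ownp = remap[i1[mask]], remap[i2[mask]], owner[mask]
        freq = freq[kept] / freq[kept].sum()
        pair_w = freq[i1p] * freq[i2p]
        lik = np.bincount(ownp, weights=pair_w, minlength=n)
        log_lik = float(w @ np.log(lik))
        support = {k: remap[v] for k, v in support.items() if keep[v]}

    inv = sorted(support.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    haps = [
        ExtendedHaplotype(
            snp_alleles=_bits_to_alleles(bits, s), cn_allele=cn, freq=float(freq[idx])
        )
        for (bits, cn), idx in inv
    ]
    return HaplotypeSet(
        snp_subset=list(snp_subset) if snp_subset is not None else list(range(s)),
        haplotypes=haps,
        log_lik=log_lik,
    )


# ---------------------------------------------------------------------------
# Posterior over CN genotypes
# ---------------------------------------------------------------------------


def _genotype_masks(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual bitmasks of hom-a, het, and hom-b sites (missing sites
    appear in none, i.e. are unconstrained)."""
    n, s = codes.shape
    weightbits = (np.uint64(1) << np.arange(s, dtype=np.uint64))[None, :]
    m0 = np.where(codes == 0, weightbits, np.uint64(0)).sum(axis=1, dtype=np.uint64)
    m1 = np.where(codes == 1, weightbits, np.uint64(0)).sum(axis=1, dtype=np.uint64)
    m2 = np.where(codes == 2, weightbits, np.uint64(0)).sum(axis=1, dtype=np.uint64)
    return m0, m1, m2


def posterior_cn_many(hs: HaplotypeSet, codes: np.ndarray) -> list[PosteriorDistribution]:
    """Posterior CN-pair distribution for each row of an N x |S| code matrix.

    P((c1, c2) | g) is proportional to the sum of f(h1) f(h2) over ordered
    compatible haplotype pairs whose CN alleles form the unordered pair
    {c1, c2}; an individual with no compatible pair gets an undefined
    distribution (classifier abstention).
    """
    codes = np.atleast_2d(np.asarray(codes))
    n, s = codes.shape
    bits, cn, freq = hs._arrays()
    h = len(bits)
    if s != len(hs.snp_subset):
        raise ValueError("genotype width does not match the haplotype subset")

    or_ = bits[:, None] | bits[None, :]
    and_ = bits[:, None] & bits[None, :]
    xor_ = bits[:, None] ^ bits[None, :]
    m0, m1, m2 = _genotype_masks(codes)
    zero = np.uint64(0)
    compat = (
        ((or_[None] & m0[:, None, None]) == zero)
        & ((xor_[None] & m1[:, None, None]) == m1[:, None, None])
        & ((and_[None] & m2[:, None, None]) == m2[:, None, None])
    )  # (n, h, h)

    pair_keys = {}
    key_idx = np.empty((h, h), dtype=np.int64)
    for a in range(h):
        for b in range(h):
            key = (min(cn[a], cn[b]), max(cn[a], cn[b]))
            if key not in pair_keys:
                pair_keys[key] = len(pair_keys)
            key_idx[a, b] = pair_keys[key]
    n_keys = len(pair_keys)
    onehot = np.zeros((h * h, n_keys))
    onehot[np.arange(h * h), key_idx.ravel()] = 1.0

    w = (freq[:, None] * freq[None, :]).ravel()
    contrib = compat.reshape(n, -1) * w
    scores = contrib @ onehot  # (n, n_keys)
    totals = scores.sum(axis=1)

    keys = [None] * n_keys
    for key, idx in pair_keys.items():
        keys[idx] = (int(key[0]), int(key[1]))
    out = []
    for i in range(n):
        if totals[i] <= 0.0:
            out.append(PosteriorDistribution(probs={}, defined=False))
        else:
            probs = {
                keys[j]: float(scores[i, j] / totals[i])
                for j in range(n_keys)
                if scores[i, j] > 0.0
            }
            out.append(PosteriorDistribution(probs=probs))
    return out


def posterior_cn(hs: HaplotypeSet, snp_genotype: np.ndarray | list[int]) -> PosteriorDistribution:
    """Posterior CN-pair distribution for a single genotype vector."""
    return posterior_cn_many(hs, np.asarray(snp_genotype).reshape(1, -1))[0]
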