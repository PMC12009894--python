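"""Shared fixtures: small simulated panels and handcrafted haplotype sets."""

import numpy as np
import pytest

import libag

CENTER = 54_700_000
REGION = libag.RegionConfig(gene="LILRA6", chrom="19", center=CENTER, window_kb=100.0)


@pytest.fixture(scope="session")
def small_panel():
    """120 samples x 12 SNPs, strong LD — enough signal to train on quickly."""
    cfg = libag.SimConfig(
        n_samples=120, n_snps=12, ld_strength=0.9, missing_rate=0.02, rng_seed=3
    )
    pool = libag.simulate_pool(cfg)
    g, labels = libag.simulate_panel(pool, cfg)
    return g, labels, pool, cfg


@pytest.fixture(scope="session")
def small_model(small_panel):
    g, labels, _, _ = small_panel
    cfg = libag.EnsembleConfig(n_classifiers=4, rng_seed=3)
    return libag.build_model(g, labels, REGION, cfg)


@pytest.fixture(scope="session")
def tagged_panel():
    """Perfect-tag panel: one indicator SNP per CN allele, full LD elsewhere."""
    cfg = libag.SimConfig(
        n_samples=150,
        n_snps=10,
        ld_strength=1.0,
        missing_rate=0.0,
        cn_allele_freqs={0: 0.2, 1: 0.6, 2: 0.2},
        tag_snp_positions=[CENTER - 15_000, CENTER + 15_000, CENTER - 20_000, CENTER + 20_000],
        tag_cn_alleles=[0, 1, 2, 1],
        rng_seed=11,
    )
    pool = libag.simulate_pool(cfg)
    g, labels = libag.simulate_panel(pool, cfg)
    return g, labels, pool, cfg


def oracle_posterior(haplotypes, genotype):
    """Independent brute-force posterior: loop over every ordered haplotype
    pair, per-site compatibility check, accumulate f(h1)*f(h2) per unordered
    CN pair.  Returns None when nothing is compatible."""
    probs = {}
    for h1 in haplotypes:
        for h2 in haplotypes:
            ok = True
            for j, gcode in enumerate(genotype):
                if gcode == libag.MISSING:
                    continue
                if h1.snp_alleles[j] + h2.snp_alleles[j] != gcode:
                    ok = False
                    break
            if not ok:
                continue
            key = tuple(sorted((h1.cn_allele, h2.cn_allele)))
            probs[key] = probs.get(key, 0.0) + h1.freq * h2.freq
    total = sum(probs.values())
    if total <= 0:
        return None
    return {k: v / total for k, v in probs.items()}


def random_haplotype_set(rng, max_snps=4, max_haps=6):
    """A random valid HaplotypeSet for property tests."""
    s = int(rng.integers(1, max_snps + 1))
    n_h = int(rng.integers(2, max_haps + 1))
    seen = set()
    haps = []
    while len(haps) < n_h:
        alleles = tuple(int(a) for a in rng.integers(0, 2, size=s))
        cn = int(rng.integers(0, 3))
        if (alleles, cn) in seen:
            continue
        seen.add((alleles, cn))
        haps.append((alleles, cn))
    freqs = rng.dirichlet(np.ones(len(haps)))
    hs = libag.HaplotypeSet(
        snp_subset=list(range(s)),
        haplotypes=[
            libag.ExtendedHaplotype(snp_alleles=a, cn_allele=c, freq=float(f))
            for (a, c), f in zip(haps, freqs)
        ],
        log_lik=0.0,
    )
    return hs
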