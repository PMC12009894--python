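"""Genotype/label input, SNP quality control, flanking-window selection, model (de)serialization.

Conventions used throughout the package:

* Genotype codes count copies of ``allele_b`` of each SNP: 0 = homozygous
  ``allele_a``, 1 = heterozygous, 2 = homozygous ``allele_b``, ``MISSING``
  (-1) = no call.  PLINK dialects differ on which allele is counted, so the
  convention is fixed here and applied identically when a model is matched
  against a target dataset.
* Coordinates are 1-based inclusive (PLINK/VCF convention); flanking
  intervals are closed on both ends.
* The TSV genotype dialect is tab-separated with a header row; the missing
  token is ``NA``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

#: Genotype code for a missing call.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")

MODEL_FORMAT_VERSION = "libag-model-1"


class DataFormatError(ValueError):
    """A file could not be parsed or failed validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SNPMeta:
    """Metadata for one biallelic SNP."""

    snp_id: str
    chrom: str
    pos: int  # 1-based bp
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataFormatError(f"SNP {self.snp_id}: position must be >= 1, got {self.pos}")
        if self.allele_a not in _VALID_BASES or self.allele_b not in _VALID_BASES:
            raise DataFormatError(
                f"SNP {self.snp_id}: alleles must be single nucleotides in ACGT, "
                f"got {self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise DataFormatError(f"SNP {self.snp_id}: alleles must differ")


@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotypes for N individuals at P SNPs.

    ``codes`` is an N x P integer matrix over {0, 1, 2, MISSING}, counting
    copies of each SNP's ``allele_b``.
    """

    samples: list[str]
    snps: list[SNPMeta]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.snps)):
            raise DataFormatError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.codes[~valid][0]
            raise DataFormatError(f"invalid genotype code {bad}; expected 0/1/2/{MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, keep: np.ndarray | list[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in keep],
            codes=self.codes[:, keep].copy(),
        )

    def subset_samples(self, keep: np.ndarray | list[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            snps=list(self.snps),
            codes=self.codes[keep, :].copy(),
        )


@dataclass(frozen=True)
class CNGenotype:
    """Diploid copy-number genotype of one gene for one individual.

    ``cn_pair`` is the unordered pair of per-haplotype CN alleles, stored
    sorted.  When only the diploid total is known (``known_phase_split``
    False) the pair holds ``(total, 0)`` placeholder-free as ``(0, total)``
    is *not* implied; instead ``total`` alone is authoritative and the pair
    decomposition is treated as latent by the estimation code.
    """

    cn_pair: tuple[int, int]
    known_phase_split: bool = True

    def __post_init__(self) -> None:
        pair = tuple(sorted(int(c) for c in self.cn_pair))
        object.__setattr__(self, "cn_pair", pair)
        if any(c < 0 for c in pair):
            raise DataFormatError(f"negative CN allele in {pair}")

    @property
    def total(self) -> int:
        return int(sum(self.cn_pair))

    @classmethod
    def from_total(cls, total: int) -> "CNGenotype":
        # decomposition latent; pair stored as (0, total) for bookkeeping only
        return cls(cn_pair=(0, int(total)), known_phase_split=False)


@dataclass
class QCReport:
    """Per-SNP quality-control statistics and pass/fail decisions."""

    table: pd.DataFrame  # columns: snp_id, maf, call_rate, hwe_p, passed, reasons

    @property
    def n_passed(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def n_failed(self) -> int:
        return int((~self.table["passed"]).sum())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    snp_info: str | Path | None = None,
) -> GenotypeMatrix:
    """Read unphased genotypes from disk.

    Parameters
    ----------
    path
        For ``format="plink-bed"``: the fileset prefix (``prefix.bed/.bim/.fam``).
        For ``format="tsv"``: a tab-separated file whose first column is
        ``sample`` and remaining columns are SNP ids, values in
        ``{0, 1, 2, NA}``.
    format
        ``"plink-bed"`` or ``"tsv"``.
    snp_info
        Required for TSV input: a tab-separated file with columns
        ``snp_id, chrom, pos, allele_a, allele_b`` covering every SNP column.
    """
    if format == "tsv":
        return _read_tsv(Path(path), None if snp_info is None else Path(snp_info))
    if format == "plink-bed":
        return _read_plink(Path(path))
    raise DataFormatError(f"unknown genotype format {format!r}")


def _check_unique_snp_ids(snps: list[SNPMeta], source: str) -> None:
    seen: set[str] = set()
    for s in snps:
        if s.snp_id in seen:
            raise DataFormatError(f"{source}: duplicated snp_id {s.snp_id!r}")
        seen.add(s.snp_id)


def _read_tsv(path: Path, snp_info: Path | None) -> GenotypeMatrix:
    if snp_info is None:
        raise DataFormatError("TSV genotype input requires a snp_info file")
    try:
        geno = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise DataFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if geno.columns[0] != "sample":
        raise DataFormatError(f"{path}: first column must be 'sample', got {geno.columns[0]!r}")
    with open(path) as fh:  # pandas mangles duplicate headers, so check the raw line
        header_cols = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = {c for c in header_cols if header_cols.count(c) > 1}
    if dupes:
        raise DataFormatError(f"{path}: duplicated snp_id {sorted(dupes)[0]!r}")
    info = pd.read_csv(snp_info, sep="\t", dtype={"snp_id": str, "chrom": str, "pos": int})
    required = {"snp_id", "chrom", "pos", "allele_a", "allele_b"}
    if not required.issubset(info.columns):
        raise DataFormatError(f"{snp_info}: missing columns {sorted(required - set(info.columns))}")
    meta_by_id = {r.snp_id: r for r in info.itertuples(index=False)}

    snp_ids = list(geno.columns[1:])
    snps: list[SNPMeta] = []
    for sid in snp_ids:
        if sid not in meta_by_id:
            raise DataFormatError(f"{snp_info}: no metadata for SNP column {sid!r}")
        r = meta_by_id[sid]
        snps.append(SNPMeta(r.snp_id, str(r.chrom), int(r.pos), r.allele_a, r.allele_b))
    _check_unique_snp_ids(snps, str(path))

    samples = geno["sample"].tolist()
    codes = np.full((len(samples), len(snps)), MISSING, dtype=np.int8)
    for j, sid in enumerate(snp_ids):
        col = geno[sid]
        for i, v in enumerate(col):
            if pd.isna(v) or v == "NA":
                continue
            if v not in ("0", "1", "2"):
                raise DataFormatError(
                    f"{path}: line {i + 2}: invalid genotype {v!r} for SNP {sid}"
                )
            codes[i, j] = int(v)
    return GenotypeMatrix(samples=samples, snps=snps, codes=codes)


# PLINK .bed 2-bit codes (variant-major): 00=hom A1, 01=missing, 10=het, 11=hom A2.
# With allele_a = A1 and allele_b = A2, the count of allele_b is 0/MISSING/1/2.
_PLINK_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise DataFormatError(f"{p}: file not found")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str},
    )
    snps = [
        SNPMeta(r.snp_id, str(r.chrom), int(r.pos), str(r.a1), str(r.a2))
        for r in bim.itertuples(index=False)
    ]
    _check_unique_snp_ids(snps, str(bim_path))

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    samples = fam[1].tolist()  # IID column
    n, p = len(samples), len(snps)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise DataFormatError(f"{bed_path}: not a PLINK .bed file (bad magic)")
    if raw[2] != 0x01:
        raise DataFormatError(f"{bed_path}: only variant-major .bed files are supported")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_variant * p:
        raise DataFormatError(
            f"{bed_path}: size mismatch — expected {bytes_per_variant * p} data bytes "
            f"for {n} samples x {p} variants, found {len(body)}"
        )
    blocks = body.reshape(p, bytes_per_variant)
    # expand each byte into four 2-bit fields, little-end first
    two_bit = np.stack([(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = _PLINK_DECODE[two_bit.reshape(p, -1)[:, :n]].T
    return GenotypeMatrix(samples=samples, snps=snps, codes=codes)


def read_cn_labels(path: str | Path, cn_min: int = 0, cn_max: int = 4) -> dict[str, CNGenotype]:
    """Read per-individual CN labels from a TSV with columns ``sample, cn1[, cn2]``.

    Rows with both ``cn1`` and ``cn2`` give the per-haplotype pair; rows with
    only ``cn1`` give the diploid total with the pair decomposition unknown.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "cn1" not in df.columns:
        raise DataFormatError(f"{path}: required columns 'sample' and 'cn1'")
    has_cn2 = "cn2" in df.columns
    labels: dict[str, CNGenotype] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        sample = row.sample
        if sample in labels:
            raise DataFormatError(f"{path}: line {i + 2}: duplicated sample {sample!r}")
        cn1 = int(row.cn1)
        cn2_raw = getattr(row, "cn2", None) if has_cn2 else None
        if cn2_raw is None or (isinstance(cn2_raw, float) and np.isnan(cn2_raw)) or (
            isinstance(cn2_raw, str) and cn2_raw in ("", "NA")
        ):
            total = cn1
            if not (2 * cn_min <= total <= 2 * cn_max):
                raise DataFormatError(
                    f"{path}: line {i + 2}: total CN {total} outside "
                    f"[{2 * cn_min}, {2 * cn_max}]"
                )
            labels[sample] = CNGenotype.from_total(total)
        else:
            cn2 = int(cn2_raw)
            for c in (cn1, cn2):
                if not (cn_min <= c <= cn_max):
                    raise DataFormatError(
                        f"{path}: line {i + 2}: CN allele {c} outside [{cn_min}, {cn_max}]"
                    )
            labels[sample] = CNGenotype(cn_pair=(cn1, cn2), known_phase_split=True)
    return labels


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg equilibrium test.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more probable
    than the observed one.  Returns 1.0 for monomorphic input.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0

    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n, n_a) up to a common constant
    logp = (
        hets * np.log(2.0)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_b - hets) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_ab)]
    pval = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(1.0, pval))


# ---------------------------------------------------------------------------
# SNP quality control
# ---------------------------------------------------------------------------


def snp_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    cr_min: float = 0.95,
    hwe_min: float = 1e-5,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply per-SNP quality control.

    A SNP is retained iff MAF > ``maf_min`` AND call rate > ``cr_min`` AND
    HWE exact p >= ``hwe_min`` (removal at "frequency <= 5%, call <= 95%,
    HWE p < 1e-5").
    """
    if g.n_snps == 0:
        raise DataFormatError("snp_qc requires a non-empty genotype matrix")
    codes = g.codes
    n = g.n_samples
    rows = []
    keep = np.zeros(g.n_snps, dtype=bool)
    for j, snp in enumerate(g.snps):
        col = codes[:, j]
        called = col != MISSING
        n_called = int(called.sum())
        call_rate = n_called / n
        if n_called == 0:
            maf, hwe_p = 0.0, 1.0
        else:
            n0 = int((col == 0).sum())
            n1 = int((col == 1).sum())
            n2 = int((col == 2).sum())
            freq_b = (n1 + 2 * n2) / (2 * n_called)
            maf = min(freq_b, 1.0 - freq_b)
            hwe_p = hwe_exact_test(n0, n1, n2)
        reasons = []
        if maf <= maf_min:
            reasons.append("maf")
        if call_rate <= cr_min:
            reasons.append("call_rate")
        if hwe_p < hwe_min:
            reasons.append("hwe")
        passed = not reasons
        keep[j] = passed
        rows.append(
            {
                "snp_id": snp.snp_id,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "passed": passed,
                "reasons": ",".join(reasons),
            }
        )
    report = QCReport(table=pd.DataFrame(rows))
    if not keep.any():
        warnings.warn("all SNPs removed by QC", stacklevel=2)
    return g.subset_snps(keep), report


def select_flanking(
    g: GenotypeMatrix, chrom: str, center: int, window_kb: float
) -> GenotypeMatrix:
    """Retain SNPs on ``chrom`` within ``center +/- window_kb * 1000`` bp (closed interval)."""
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    half = int(round(window_kb * 1000))
    lo, hi = center - half, center + half
    keep = np.array(
        [s.chrom == chrom and lo <= s.pos <= hi for s in g.snps], dtype=bool
    )
    if not keep.any():
        warnings.warn(
            f"no SNPs within {window_kb} kb of {chrom}:{center}", stacklevel=2
        )
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# Model (de)serialization
# ---------------------------------------------------------------------------


def serialize_model(model, path: str | Path) -> None:
    """Write a trained model to versioned JSON.

    Frequencies round-trip exactly: Python's float repr (used by ``json``) is
    the shortest string that parses back to the identical double.
    """
    from .ensemble import LIBAGModel  # local import to avoid a cycle

    if not isinstance(model, LIBAGModel):
        raise TypeError("serialize_model expects a LIBAGModel")
    if not model.classifiers:
        raise ValueError("model must contain at least one classifier")
    doc = model.to_dict()
    doc["format_version"] = MODEL_FORMAT_VERSION
    Path(path).write_text(json.dumps(doc, indent=1))


def deserialize_model(path: str | Path):
    """Load a model written by :func:`serialize_model`."""
    from .ensemble import LIBAGModel

    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise DataFormatError(
            f"model format version mismatch: file has {version!r}, "
            f"this build reads {MODEL_FORMAT_VERSION!r}"
        )
    return LIBAGModel.from_dict(doc)
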