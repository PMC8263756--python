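"""Minimal VCF container and I/O.

Sites are held as :class:`SiteRecord` objects with per-sample genotype
arrays (GT allele pair, DP, GQ, AD) plus site-level QUAL and the AQ
(alternate-allele quality) INFO field.  Reading goes through cyvcf2; the
writer emits plain-text VCF v4.2 with the fixed ``GT:DP:GQ:AD`` FORMAT
schema used throughout this package.  Missing integers are encoded as -1
in memory and ``.`` on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF

MISSING = -1


@dataclass
class SiteRecord:
    """One VCF site with per-sample genotype-level fields.

    ``gt`` is (n_samples, 2) allele indices with -1 for missing; ``ad`` is
    (n_samples, 1 + n_alts) allelic depths.  ``qual`` and ``aq`` are
    Phred-scaled site-level qualities.
    """

    chrom: str
    pos: int              # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    aq: float
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad: np.ndarray

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{','.join(self.alts)}"

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    def allele_keys(self) -> list[str]:
        """One key per ALT allele (positional split of multi-allelic sites)."""
        return [f"{self.chrom}:{self.pos}:{self.ref}:{a}" for a in self.alts]

    def is_indel(self, alt_index: int = 0) -> bool:
        return len(self.ref) != len(self.alts[alt_index])

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    def called_mask(self) -> np.ndarray:
        """Samples with a non-missing genotype call."""
        return (self.gt[:, 0] != MISSING) & (self.gt[:, 1] != MISSING)

    def copy(self) -> "SiteRecord":
        return SiteRecord(self.chrom, self.pos, self.ref, self.alts, self.qual,
                          self.aq, self.gt.copy(), self.dp.copy(),
                          self.gq.copy(), self.ad.copy())


_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AQ,Number=A,Type=Integer,Description="Allele quality score (Phred)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (Phred)">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt ...)">
"""


def write_vcf(path: str, samples: list[str], sites: list[SiteRecord]) -> None:
    """Write sites as uncompressed VCF v4.2 (sorted by chrom, pos as given)."""
    chroms = []
    for s in sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in sites:
            aq = ",".join(str(int(round(s.aq))) for _ in s.alts)
            cols = [s.chrom, str(s.pos), ".", s.ref, ",".join(s.alts),
                    f"{s.qual:g}", "PASS", f"AQ={aq}", "GT:DP:GQ:AD"]
            gt_fields = []
            for i in range(s.n_samples):
                a, b = int(s.gt[i, 0]), int(s.gt[i, 1])
                if a == MISSING or b == MISSING:
                    gt_fields.append("./.:.:.:.")
                else:
                    dp = "." if s.dp[i] == MISSING else str(int(s.dp[i]))
                    gq = "." if s.gq[i] == MISSING else str(int(s.gq[i]))
                    ad = ",".join(str(int(x)) for x in s.ad[i])
                    gt_fields.append(f"{a}/{b}:{dp}:{gq}:{ad}")
            fh.write("\t".join(cols) + "\t" + "\t".join(gt_fields) + "\n")


def _clean_int(arr: np.ndarray) -> np.ndarray:
    """Map cyvcf2's negative sentinels to MISSING."""
    out = np.asarray(arr, dtype=np.int64).copy()
    out[out < 0] = MISSING
    return out


def read_vcf(path: str) -> tuple[list[str], list[SiteRecord]]:
    """Read a (plain-text or bgzipped) VCF into SiteRecord objects."""
    vcf = VCF(path)
    samples = list(vcf.samples)
    n = len(samples)
    sites: list[SiteRecord] = []
    for v in vcf:
        garr = v.genotype.array()
        gt = np.asarray(garr[:, :2], dtype=np.int64)
        gt[gt < 0] = MISSING
        dp = v.format("DP")
        dp = _clean_int(dp[:, 0]) if dp is not None else np.full(n, MISSING)
        gq = v.format("GQ")
        gq = _clean_int(gq[:, 0]) if gq is not None else np.full(n, MISSING)
        ad = v.format("AD")
        n_alleles = 1 + len(v.ALT)
        ad = _clean_int(ad[:, :n_alleles]) if ad is not None \
            else np.full((n, n_alleles), MISSING)
        aq_info = v.INFO.get("AQ")
        if aq_info is None:
            aq = float("nan")
        elif isinstance(aq_info, tuple):
            aq = float(aq_info[0])
        else:
            aq = float(aq_info)
        sites.append(SiteRecord(
            chrom=v.CHROM, pos=v.POS, ref=v.REF, alts=tuple(v.ALT),
            qual=float(v.QUAL) if v.QUAL is not None else float("nan"),
            aq=aq, gt=gt, dp=dp, gq=gq, ad=ad,
        ))
    vcf.close()
    return samples, sites
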