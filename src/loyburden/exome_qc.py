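"""Variant-site and genotype-level exome QC.

Implements the site/genotype quality control applied to released
whole-exome VCFs before burden testing:

* on-target flagging against a capture BED (0-based half-open intervals);
* allele-balance (ABratio) screening of heterozygous calls at on-target
  bi-allelic sites — a call with ABratio ≤ 0.25 or ≥ 0.8 is excluded
  (set missing);
* per-site summary metrics (missingness; DP and GQ min/quartiles/max/mean;
  GQ<20 counts; ABratio summaries; QUAL and AQ are recorded and summarised
  but never filtered on);
* three site-level exclusion filters with strict boundary semantics:
  filter 1 missingness > 5%, filter 2 max called DP < 10, filter 3
  GQ<20 fraction of called genotypes > 20%.

Missingness is computed *after* genotype-level ABratio exclusion; the
quartile estimator is linear interpolation between order statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .vcfio import SiteRecord, read_vcf, write_vcf, MISSING


class InputError(ValueError):
    pass


class BedParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED / on-target flagging
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Parse a BED3 file (0-based half-open); malformed lines raise with
    their line number.  Unsorted and overlapping intervals are accepted
    (union semantics downstream)."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{ln}: expected at least 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise BedParseError(f"{path}:{ln}: non-integer interval bounds") from e
            if end < start:
                raise BedParseError(f"{path}:{ln}: interval end < start")
            regions.append((parts[0], start, end))
    return regions


def _build_trees(regions) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        if end > start:  # zero-length intervals contain nothing
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def flag_on_target(sites: list[SiteRecord], bed_regions) -> np.ndarray:
    """Boolean flag per site: 1-based position, converted to 0-based,
    falls inside the union of the BED intervals."""
    if isinstance(bed_regions, str):
        bed_regions = read_bed(bed_regions)
    trees = _build_trees(bed_regions)
    out = np.zeros(len(sites), dtype=bool)
    for i, s in enumerate(sites):
        tree = trees.get(s.chrom)
        if tree is not None and tree.overlaps_point(s.pos - 1):
            out[i] = True
    return out


# ---------------------------------------------------------------------------
# ABratio / heterozygous-call exclusion
# ---------------------------------------------------------------------------

def compute_abratio(gt_pair, ad) -> tuple[float | None, bool]:
    """ABratio for one genotype call at a bi-allelic site.

    Defined only for heterozygous (0/1) calls as
    ``AD_alt / (AD_ref + AD_alt)``.  Returns ``(ratio, malformed)``:
    ratio is None for non-het calls; a het call with zero total depth is
    undefined and flagged malformed.
    """
    a, b = int(gt_pair[0]), int(gt_pair[1])
    if a == MISSING or b == MISSING or {a, b} != {0, 1}:
        return None, False
    total = int(ad[0]) + int(ad[1])
    if total == 0:
        return None, True
    return int(ad[1]) / total, False


def filter_het_imbalance(abratio: float) -> bool:
    """True (exclude) iff ABratio ≤ 0.25 or ≥ 0.8 — boundaries inclusive."""
    return abratio <= 0.25 or abratio >= 0.8


def site_abratios(site: SiteRecord) -> np.ndarray:
    """Vector of ABratios for one bi-allelic site (NaN where undefined)."""
    n = site.n_samples
    out = np.full(n, np.nan)
    if site.is_multiallelic:
        return out
    het = (site.gt[:, 0] != MISSING) & (np.minimum(site.gt[:, 0], site.gt[:, 1]) == 0) \
        & (np.maximum(site.gt[:, 0], site.gt[:, 1]) == 1)
    tot = site.ad[:, 0] + site.ad[:, 1]
    ok = het & (tot > 0)
    out[ok] = site.ad[ok, 1] / tot[ok]
    return out


def apply_het_exclusions(
    sites: list[SiteRecord],
    on_target: np.ndarray,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Exclude imbalanced het calls in place (genotype set to missing).

    Applies only to heterozygous calls at on-target bi-allelic sites, per
    the ABratio definition.  Returns a table of the excluded calls.
    """
    rows = []
    for i, site in enumerate(sites):
        if not on_target[i] or site.is_multiallelic:
            continue
        ratios = site_abratios(site)
        exclude = np.zeros(site.n_samples, dtype=bool)
        defined = ~np.isnan(ratios)
        exclude[defined] = (ratios[defined] <= 0.25) | (ratios[defined] >= 0.8)
        for idx in np.flatnonzero(exclude):
            rows.append({"variant_key": site.key,
                         "iid": samples[idx] if samples else idx,
                         "abratio": ratios[idx]})
        site.gt[exclude, :] = MISSING
        site.dp[exclude] = MISSING
        site.gq[exclude] = MISSING
        site.ad[exclude, :] = MISSING
    return pd.DataFrame(rows, columns=["variant_key", "iid", "abratio"])


# ---------------------------------------------------------------------------
# Site metrics and filters
# ---------------------------------------------------------------------------

def _summary(values: np.ndarray, prefix: str) -> dict:
    """min / q1 / median / q3 / max / mean with linear-interpolation quartiles."""
    if values.size == 0:
        return {f"{prefix}_{k}": np.nan for k in
                ("min", "q1", "median", "q3", "max", "mean")}
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return {f"{prefix}_min": float(values.min()), f"{prefix}_q1": float(q1),
            f"{prefix}_median": float(med), f"{prefix}_q3": float(q3),
            f"{prefix}_max": float(values.max()), f"{prefix}_mean": float(values.mean())}


def compute_site_metrics(
    sites: list[SiteRecord],
    samples: list[str],
    on_target: np.ndarray | None = None,
    sample_subset: list[str] | None = None,
    carriers_only: bool = False,
) -> pd.DataFrame:
    """Per-site (per ALT allele) QC metrics.

    Multi-allelic sites are split positionally, one row per ALT allele;
    genotype-level metrics (missingness, DP, GQ) are shared across the
    split rows, while ABratio is only defined at bi-allelic sites.  With
    ``sample_subset`` metrics are restricted to those samples (e.g. females
    for chromosome X); with ``carriers_only`` they are further restricted,
    per allele, to samples carrying that ALT allele.
    """
    if on_target is None:
        on_target = np.ones(len(sites), dtype=bool)
    if sample_subset is not None:
        idx = np.flatnonzero(np.isin(np.asarray(samples), np.asarray(sample_subset)))
        if idx.size == 0:
            raise InputError("sample subset shares no samples with the VCF")
    else:
        idx = np.arange(len(samples))

    rows = []
    for si, site in enumerate(sites):
        gt = site.gt[idx]
        dp = site.dp[idx]
        gq = site.gq[idx]
        miss = gt[:, 0] == MISSING
        ratios_all = site_abratios(site)[idx]
        for ai, alt in enumerate(site.alts):
            allele = ai + 1
            if carriers_only:
                keep = np.any(gt == allele, axis=1)
            else:
                keep = np.ones(len(idx), dtype=bool)
            m = miss[keep]
            n_sub = int(keep.sum())
            called = ~m
            dp_c = dp[keep][called]
            dp_c = dp_c[dp_c != MISSING].astype(float)
            gq_c = gq[keep][called]
            gq_c = gq_c[gq_c != MISSING].astype(float)
            ratios = ratios_all[keep]
            ratios = ratios[~np.isnan(ratios)]
            row = {
                "variant_key": site.allele_keys()[ai],
                "chrom": site.chrom, "pos": site.pos, "ref": site.ref, "alt": alt,
                "on_target": bool(on_target[si]),
                "multiallelic": site.is_multiallelic,
                "indel": site.is_indel(ai),
                "qual": site.qual, "aq": site.aq,
                "n_samples": n_sub,
                "n_missing": int(m.sum()),
                "missingness": float(m.sum()) / n_sub if n_sub else np.nan,
                "n_called": int(called.sum()),
                "n_gq_lt20": int((gq_c < 20).sum()),
            }
            row.update(_summary(dp_c, "dp"))
            row.update(_summary(gq_c, "gq"))
            row.update(_summary(ratios, "abratio"))
            rows.append(row)
    return pd.DataFrame(rows)


def apply_site_filters(metrics: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the three site-level filters (strict boundary semantics).

    fail_missingness: missingness > 0.05; fail_maxdp: max called DP < 10
    (a site with no called genotypes fails); fail_gqfrac: GQ<20 fraction of
    called genotypes > 0.20.  A site is excluded if any filter fails.
    Returns the metrics with verdict columns plus a summary count dict.
    """
    out = metrics.copy()
    out["fail_missingness"] = out["missingness"] > 0.05
    no_calls = out["n_called"] == 0
    out["fail_maxdp"] = np.where(no_calls, True, out["dp_max"].fillna(0) < 10)
    with np.errstate(invalid="ignore"):
        frac = out["n_gq_lt20"] / out["n_called"].replace(0, np.nan)
    out["fail_gqfrac"] = (frac > 0.20).fillna(False)
    out["excluded"] = out[["fail_missingness", "fail_maxdp", "fail_gqfrac"]].any(axis=1)
    summary = {
        "n_alleles": int(len(out)),
        "n_fail_missingness": int(out["fail_missingness"].sum()),
        "n_fail_maxdp": int(out["fail_maxdp"].sum()),
        "n_fail_gqfrac": int(out["fail_gqfrac"].sum()),
        "n_excluded": int(out["excluded"].sum()),
    }
    return out, summary


# ---------------------------------------------------------------------------
# Pipeline entry point
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    samples: list[str]
    sites: list[SiteRecord]          # post het-exclusion genotypes
    on_target: np.ndarray
    metrics: pd.DataFrame            # per ALT allele, with filter verdicts
    excluded_hets: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def passing_sites(self, on_target_only: bool = True) -> list[SiteRecord]:
        """Sites where no ALT allele is excluded by the three filters."""
        per_site = self.metrics.groupby(["chrom", "pos", "ref"], sort=False)["excluded"].any()
        keep = []
        for i, s in enumerate(self.sites):
            if on_target_only and not self.on_target[i]:
                continue
            if not per_site.loc[(s.chrom, s.pos, s.ref)]:
                keep.append(s)
        return keep

    def write(self, outdir: str, prefix: str = "qc") -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "metrics": os.path.join(outdir, f"{prefix}.site_metrics.tsv"),
            "excluded_hets": os.path.join(outdir, f"{prefix}.excluded_hets.tsv"),
            "filtered_vcf": os.path.join(outdir, f"{prefix}.filtered.vcf"),
        }
        self.metrics.to_csv(paths["metrics"], sep="\t", index=False)
        self.excluded_hets.to_csv(paths["excluded_hets"], sep="\t", index=False)
        write_vcf(paths["filtered_vcf"], self.samples, self.passing_sites())
        return paths


def run_qc(
    vcf_path: str,
    bed_path: str | None = None,
    sample_subset: list[str] | None = None,
    carrier_list: list[str] | None = None,
) -> QCResult:
    """Full site/genotype QC on a VCF.

    Order of operations: parse → on-target flagging → ABratio exclusion of
    imbalanced het calls (on-target bi-allelic sites) → site metrics on the
    post-exclusion genotypes → the three site filters.
    """
    samples, sites = read_vcf(vcf_path)
    if bed_path is not None:
        on_target = flag_on_target(sites, bed_path)
    else:
        on_target = np.ones(len(sites), dtype=bool)
    excluded = apply_het_exclusions(sites, on_target, samples)
    metrics = compute_site_metrics(sites, samples, on_target,
                                   sample_subset=sample_subset)
    metrics, summary = apply_site_filters(metrics)
    if carrier_list is not None:
        carrier_metrics = compute_site_metrics(
            sites, samples, on_target,
            sample_subset=carrier_list, carriers_only=True)
        metrics = metrics.merge(
            carrier_metrics[["variant_key", "n_called", "dp_median", "gq_median",
                             "abratio_median"]].rename(columns=lambda c: f"carrier_{c}"
                                                       if c != "variant_key" else c),
            on="variant_key", how="left")
    summary["n_sites"] = len(sites)
    summary["n_on_target"] = int(on_target.sum())
    summary["n_excluded_het_calls"] = int(len(excluded))
    return QCResult(samples=samples, sites=sites, on_target=on_target,
                    metrics=metrics, excluded_hets=excluded, summary=summary)
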