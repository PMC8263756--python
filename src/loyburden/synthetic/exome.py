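"""Rare-variant exome simulation with QC structure.

Writes a multi-sample VCF (FORMAT ``GT:DP:GQ:AD``, INFO ``AQ``, site QUAL),
a BED of on-target capture regions, a VEP-style annotation table and truth
sidecar tables.  The simulation plants, deliberately and recoverably:

* carrier genes with a fixed variant plan (e.g. one 10-carrier frameshift,
  4 doubletons, 22 singletons carried by 40 distinct men);
* sites violating each of the three site-level QC filters (missingness,
  max depth, low-GQ fraction) plus exact boundary sites that must *pass*;
* heterozygous calls with allele balance outside (0.25, 0.8);
* multi-allelic sites, indels and off-target sites.

Truth tables are computed from the generated genotype arrays themselves
(not from planting intent), so they match any faithful re-parse exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import SimulationConfig, ConfigurationError
from ..vcfio import SiteRecord, write_vcf, MISSING

_STAGE_EXOME = 3

_GENE_SPAN = 20_000
_GENE_STRIDE = 100_000
_BED_PAD = 500

# background consequence mixture (probabilities) — a caricature of an exome
_BACKGROUND_CONSEQUENCES = (
    ("synonymous_variant", 0.35),
    ("missense_variant", 0.30),
    ("intron_variant", 0.15),
    ("stop_gained", 0.06),
    ("frameshift_variant", 0.03),
    ("splice_donor_variant", 0.03),
    ("inframe_deletion", 0.04),
    ("inframe_insertion", 0.04),
)

_SNV_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass
class ExomeSimulation:
    """In-memory result of :func:`simulate_exome`."""

    samples: list[str]
    sites: list[SiteRecord]
    bed: list[tuple[str, int, int]]
    annotations: pd.DataFrame
    genes: pd.DataFrame
    truth_sites: pd.DataFrame
    truth_carriers: pd.DataFrame
    truth_hets: pd.DataFrame

    def write(self, outdir: str, prefix: str = "sim") -> dict[str, str]:
        """Write VCF/BED/annotation/truth files; returns the path map."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, f"{prefix}.vcf"),
            "bed": os.path.join(outdir, f"{prefix}.targets.bed"),
            "annotations": os.path.join(outdir, f"{prefix}.annotations.tsv"),
            "genes": os.path.join(outdir, f"{prefix}.genes.tsv"),
            "truth_sites": os.path.join(outdir, f"{prefix}.truth_sites.tsv"),
            "truth_carriers": os.path.join(outdir, f"{prefix}.truth_carriers.tsv"),
            "truth_hets": os.path.join(outdir, f"{prefix}.truth_hets.tsv"),
        }
        write_vcf(paths["vcf"], self.samples, self.sites)
        with open(paths["bed"], "w") as fh:
            for chrom, start, end in self.bed:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.genes.to_csv(paths["genes"], sep="\t", index=False)
        self.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        self.truth_carriers.to_csv(paths["truth_carriers"], sep="\t", index=False)
        self.truth_hets.to_csv(paths["truth_hets"], sep="\t", index=False)
        return paths


def _draw_qual(rng: np.random.Generator) -> int:
    """Phred site quality in [20, 99], right-skewed like released WES data."""
    return int(np.clip(np.round(20.0 + rng.exponential(25.0)), 20, 99))


def _clamp_balanced(alt: int, dp: int) -> int:
    """Clamp a het alt-read count so ABratio falls strictly inside (0.25, 0.8)."""
    lo = int(np.floor(0.25 * dp)) + 1
    hi = int(np.ceil(0.8 * dp)) - 1
    lo = max(lo, 1)
    hi = max(hi, lo)
    return int(np.clip(alt, lo, min(hi, dp)))


def simulate_exome(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ExomeSimulation:
    """Simulate the exome, annotations, capture BED and truth sidecars.

    Gene g occupies a contiguous interval on chr1; variant positions are
    unique within the gene.  Carrier-gene variants follow the configured
    variant plan exactly (all carriers heterozygous, never missing, allele
    balance kept in-range so no planted carrier is lost to genotype QC).
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), _STAGE_EXOME])
    config.validate()
    n = len(cohort)
    samples = list(cohort["iid"])
    chrom = "chr1"

    # ---------------- gene layout ----------------
    carrier_genes = [s.gene for s in config.carrier_gene_specs]
    gene_names = list(carrier_genes)
    i = 1
    while len(gene_names) < max(config.n_genes, len(carrier_genes)):
        name = f"GENE{i:04d}"
        if name not in gene_names:
            gene_names.append(name)
        i += 1
    gene_rows = []
    for gi, gene in enumerate(gene_names):
        start = _GENE_STRIDE * (gi + 1)
        gene_rows.append({"gene": gene, "chrom": chrom, "start": start,
                          "end": start + _GENE_SPAN})
    genes = pd.DataFrame(gene_rows)

    # ---------------- per-variant skeleton ----------------
    # each entry: dict with pos, gene, planned consequence, planned carriers ...
    variants: list[dict] = []
    spec_by_gene = {s.gene: s for s in config.carrier_gene_specs}
    for row in gene_rows:
        gene = row["gene"]
        if gene in spec_by_gene:
            spec = spec_by_gene[gene]
            plan = spec.resolved_plan()
            n_planted = sum(k for _, k in plan)
            n_bg = int(rng.poisson(3))
            m = n_planted + n_bg
        else:
            spec = None
            m = max(config.min_variants_per_gene, int(rng.poisson(config.mean_variants_per_gene)))
        pos = np.sort(rng.choice(np.arange(row["start"], row["end"]), size=m, replace=False))
        vi = 0
        if spec is not None:
            col = f"carrier_{gene}"
            if col not in cohort:
                raise ConfigurationError(
                    f"cohort lacks column {col!r}; simulate the cohort with the same "
                    "carrier_gene_specs before simulating the exome")
            carriers_idx = np.flatnonzero(cohort[col].to_numpy() == 1)
            if len(carriers_idx) != spec.n_carriers:
                raise ConfigurationError(
                    f"cohort has {len(carriers_idx)} planted carriers for {gene}, "
                    f"config requests {spec.n_carriers}")
            ptr = 0
            order = rng.permutation(len(carriers_idx))
            shuffled = carriers_idx[order]
            for block_i, (mac, k) in enumerate(spec.resolved_plan()):
                for _ in range(k):
                    carriers = shuffled[ptr:ptr + mac]
                    ptr += mac
                    if block_i == 0 and spec.frameshift:
                        csq, is_indel = "frameshift_variant", True
                    else:
                        csq = str(rng.choice(["stop_gained", "splice_acceptor_variant",
                                              "frameshift_variant"], p=[0.6, 0.2, 0.2]))
                        is_indel = csq == "frameshift_variant"
                    variants.append({"gene": gene, "pos": int(pos[vi]), "csq": csq,
                                     "carriers": carriers, "planted_carrier": True,
                                     "indel": is_indel, "protected": True})
                    vi += 1
            # background non-qualifying variants in the carrier gene
            for _ in range(m - vi):
                mac = _draw_mac(rng, config)
                variants.append({"gene": gene, "pos": int(pos[vi]),
                                 "csq": str(rng.choice(["synonymous_variant",
                                                        "missense_variant",
                                                        "intron_variant"])),
                                 "carriers": rng.choice(n, size=min(mac, n), replace=False),
                                 "planted_carrier": False, "indel": False,
                                 "protected": True})
                vi += 1
        else:
            terms = [t for t, _ in _BACKGROUND_CONSEQUENCES]
            probs = np.array([p for _, p in _BACKGROUND_CONSEQUENCES])
            for _ in range(m):
                mac = _draw_mac(rng, config)
                csq = str(rng.choice(terms, p=probs / probs.sum()))
                variants.append({"gene": gene, "pos": int(pos[vi]), "csq": csq,
                                 "carriers": rng.choice(n, size=min(mac, n), replace=False),
                                 "planted_carrier": False,
                                 "indel": csq in ("frameshift_variant", "inframe_deletion",
                                                  "inframe_insertion"),
                                 "protected": False})
                vi += 1

    # ---------------- off-target extra sites ----------------
    n_gene_sites = len(variants)
    n_off = int(round(config.off_target_fraction * n_gene_sites))
    used_pos = {v["pos"] for v in variants}
    for j in range(n_off):
        gi = int(rng.integers(0, len(gene_rows)))
        gap_start = gene_rows[gi]["end"] + 2 * _BED_PAD + 100
        pos_off = gap_start + int(rng.integers(0, _GENE_STRIDE - _GENE_SPAN - 5000))
        while pos_off in used_pos:
            pos_off += 1
        used_pos.add(pos_off)
        mac = _draw_mac(rng, config)
        variants.append({"gene": ".", "pos": pos_off, "csq": "intergenic_variant",
                         "carriers": rng.choice(n, size=min(mac, n), replace=False),
                         "planted_carrier": False, "indel": False, "protected": False,
                         "off_target": True})
    for v in variants:
        v.setdefault("off_target", False)

    # ---------------- plant QC categories ----------------
    eligible = [v for v in variants
                if not v["protected"] and not v["off_target"] and not v["indel"]]
    rng.shuffle(eligible)
    cursor = 0

    def take(k: int) -> list[dict]:
        nonlocal cursor
        if cursor + k > len(eligible):
            raise ConfigurationError(
                "not enough eligible background sites to plant the requested "
                "QC failures; increase n_genes or lower the planted fractions")
        out = eligible[cursor:cursor + k]
        cursor += k
        return out

    if config.plant_boundary_sites:
        for cat in ("boundary_missingness", "boundary_maxdp", "boundary_gqfrac",
                    "boundary_abratio"):
            take(1)[0]["planted"] = cat
    n_total = len(variants)
    f1, f2, f3 = config.qc_fail_fractions
    for cat, frac in (("fail_missingness", f1), ("fail_maxdp", f2), ("fail_gqfrac", f3)):
        for v in take(int(round(frac * n_total))):
            v["planted"] = cat
    n_multi = int(round(config.multiallelic_fraction * n_total))
    for v in take(n_multi):
        v["multiallelic"] = True
    n_indel_extra = int(round(config.indel_fraction * n_total)) - sum(v["indel"] for v in variants)
    for v in take(max(0, n_indel_extra)):
        v["indel"] = True
        v["csq"] = str(rng.choice(["inframe_deletion", "inframe_insertion",
                                   "frameshift_variant"], p=[0.4, 0.4, 0.2]))
    for v in variants:
        v.setdefault("planted", "none")
        v.setdefault("multiallelic", False)

    # ---------------- genotype-level simulation ----------------
    variants.sort(key=lambda v: v["pos"])
    sites: list[SiteRecord] = []
    anno_rows: list[dict] = []
    carrier_rows: list[dict] = []
    sample_arr = np.asarray(samples)

    for v in variants:
        planted = v["planted"]
        protected = v["protected"] or planted.startswith("boundary")
        ref_base = str(rng.choice(list("ACGT")))
        if v["indel"]:
            if rng.random() < 0.5:
                ref, alt = ref_base, ref_base + str(rng.choice(list("ACGT")))
            else:
                ref, alt = ref_base + str(rng.choice(list("ACGT"))), ref_base
        else:
            ref, alt = ref_base, _SNV_ALT[ref_base]
        alts: list[str] = [alt]
        alt2_carriers = np.empty(0, dtype=int)
        if v["multiallelic"]:
            alt2 = next(b for b in "ACGT" if b not in (ref, alt))
            alts.append(alt2)
            pool = np.setdiff1d(np.arange(n), v["carriers"], assume_unique=False)
            alt2_carriers = rng.choice(pool, size=min(int(rng.integers(1, 4)), len(pool)),
                                       replace=False)
        n_alleles = 1 + len(alts)

        gt = np.zeros((n, 2), dtype=np.int64)
        gt[v["carriers"], 1] = 1
        gt[alt2_carriers, 1] = 2

        # missingness
        if planted == "fail_missingness":
            n_miss = int(np.ceil(0.08 * n))
        elif planted == "boundary_missingness":
            n_miss = int(np.floor(0.05 * n))
        elif planted == "boundary_gqfrac":
            n_miss = 0
        else:
            n_miss = int(rng.binomial(n, config.genotype_missing_rate))
        if n_miss > 0:
            if v["planted_carrier"]:
                pool = np.setdiff1d(np.arange(n), v["carriers"])
            else:
                pool = np.arange(n)
            miss_idx = rng.choice(pool, size=min(n_miss, len(pool)), replace=False)
            gt[miss_idx, :] = MISSING

        called = gt[:, 0] != MISSING

        # depth
        if planted == "fail_maxdp":
            dp = np.clip(rng.poisson(3.0, size=n), 1, 9)
        elif planted == "boundary_maxdp":
            dp = np.clip(rng.poisson(6.0, size=n), 2, 9)
            # pin the maximum at exactly 10 on a called hom-ref sample so a
            # downstream het-balance exclusion cannot move the site maximum
            homref_called = np.flatnonzero(called & (gt[:, 1] == 0))
            dp[rng.choice(homref_called)] = 10
        else:
            dp = np.maximum(rng.poisson(config.target_depth, size=n), 1)
        dp = dp.astype(np.int64)

        # genotype quality
        gq = np.clip(np.round(rng.normal(config.gq_mean, config.gq_sd, size=n)), 1, 99)
        if planted == "fail_gqfrac":
            n_low = int(np.ceil(0.30 * called.sum()))
        elif planted == "boundary_gqfrac":
            gq = np.clip(gq, 20, 99)
            n_low = int(np.floor(0.20 * called.sum()))
        else:
            n_low = 0
        if n_low > 0:
            low_idx = rng.choice(np.flatnonzero(called), size=n_low, replace=False)
            gq[low_idx] = rng.integers(2, 20, size=n_low)
        gq = gq.astype(np.int64)

        # allelic depths
        ad = np.zeros((n, n_alleles), dtype=np.int64)
        ad[:, 0] = dp
        het1 = called & (gt[:, 1] == 1) & (gt[:, 0] == 0)
        het2 = called & (gt[:, 1] == 2)
        for idx in np.flatnonzero(het1):
            d = int(dp[idx])
            a = int(rng.binomial(d, 0.5))
            if protected or len(alts) > 1:
                a = _clamp_balanced(a, d)
            elif rng.random() < config.het_imbalance_fraction:
                a = int(round(d * (0.12 if rng.random() < 0.5 else 0.88)))
                a = int(np.clip(a, 0, d))
            ad[idx, 0] = d - a
            ad[idx, 1] = a
        for idx in np.flatnonzero(het2):
            d = int(dp[idx])
            a = _clamp_balanced(int(rng.binomial(d, 0.5)), d)
            ad[idx, 0] = d - a
            ad[idx, 2] = a

        if planted == "boundary_abratio":
            hets = np.flatnonzero(het1)
            if len(hets) < 2:
                extra = rng.choice(np.flatnonzero(called & (gt[:, 1] == 0)),
                                   size=2 - len(hets), replace=False)
                gt[extra, 1] = 1
                hets = np.flatnonzero(called & (gt[:, 1] == 1) & (gt[:, 0] == 0))
            dp[hets[0]], ad[hets[0], 0], ad[hets[0], 1] = 8, 6, 2      # ABratio 0.25
            dp[hets[1]], ad[hets[1], 0], ad[hets[1], 1] = 5, 1, 4      # ABratio 0.80
            v["carriers"] = np.flatnonzero(gt[:, 1] == 1)

        gt_missing = gt[:, 0] == MISSING
        dp[gt_missing] = MISSING
        gq[gt_missing] = MISSING
        ad[gt_missing, :] = MISSING

        site = SiteRecord(chrom=chrom, pos=v["pos"], ref=ref, alts=tuple(alts),
                          qual=float(_draw_qual(rng)), aq=float(_draw_qual(rng)),
                          gt=gt, dp=dp, gq=gq, ad=ad)
        v["site"] = site
        sites.append(site)

        # annotations: one row per ALT allele, sometimes with an extra
        # lower-severity transcript row to exercise most-severe selection
        for ai, a in enumerate(alts):
            csq = v["csq"] if ai == 0 else "synonymous_variant"
            anno_rows.append(_make_annotation(rng, site, a, v["gene"], csq))
            if v["gene"] != "." and rng.random() < 0.3:
                extra = dict(_make_annotation(rng, site, a, v["gene"], "intron_variant"))
                anno_rows.append(extra)

        if v["planted_carrier"]:
            for idx in v["carriers"]:
                carrier_rows.append({"gene": v["gene"], "variant_key": site.allele_keys()[0],
                                     "iid": sample_arr[idx]})

    # ---------------- BED ----------------
    bed = [(r["chrom"], r["start"] - _BED_PAD, r["end"] + _BED_PAD) for r in gene_rows]

    annotations = pd.DataFrame(anno_rows)
    truth_sites, truth_hets = _compute_truth(variants, bed, sample_arr)
    truth_carriers = pd.DataFrame(carrier_rows,
                                  columns=["gene", "variant_key", "iid"])
    return ExomeSimulation(samples=samples, sites=sites, bed=bed,
                           annotations=annotations, genes=genes,
                           truth_sites=truth_sites, truth_carriers=truth_carriers,
                           truth_hets=truth_hets)


def _draw_mac(rng: np.random.Generator, config: SimulationConfig) -> int:
    """Minor-allele count from a neutral-ish spectrum, P(MAC = m) ∝ 1/m."""
    m = np.arange(1, config.mac_max + 1)
    p = 1.0 / m
    return int(rng.choice(m, p=p / p.sum()))


def _make_annotation(rng, site: SiteRecord, alt: str, gene: str, csq: str) -> dict:
    high = csq in ("frameshift_variant", "stop_gained", "splice_acceptor_variant",
                   "splice_donor_variant", "transcript_ablation", "stop_lost")
    missense = csq == "missense_variant"
    if high:
        impact, cadd = "HIGH", float(rng.uniform(25, 45))
        loftee = "HC" if rng.random() < 0.8 else "LC"
    elif missense or csq in ("inframe_deletion", "inframe_insertion",
                             "protein_altering_variant"):
        impact, cadd = "MODERATE", float(rng.uniform(15, 35))
        loftee = "."
    else:
        impact, cadd = "LOW" if gene != "." else "MODIFIER", float(rng.uniform(0, 10))
        loftee = "."
    return {
        "chrom": site.chrom, "pos": site.pos, "ref": site.ref, "alt": alt,
        "gene": gene, "consequence": csq, "impact": impact,
        "sift": str(rng.choice(["deleterious", "tolerated"])) if missense else ".",
        "polyphen": str(rng.choice(["probably_damaging", "possibly_damaging",
                                    "benign"])) if missense else ".",
        "cadd_phred": round(cadd, 2), "loftee": loftee,
    }


def _compute_truth(variants: list[dict], bed, sample_arr: np.ndarray):
    """Recompute QC truth from the generated arrays with plain loops.

    Mirrors the QC definitions: heterozygous calls at on-target bi-allelic
    sites with ABratio ≤ 0.25 or ≥ 0.8 become missing, then missingness,
    max called DP and the GQ<20 fraction are evaluated with the strict
    boundary semantics of the three site filters.
    """
    site_rows = []
    het_rows = []
    for v in variants:
        site: SiteRecord = v["site"]
        n = site.n_samples
        on_target = not v["off_target"]
        biallelic = len(site.alts) == 1
        excluded_het = np.zeros(n, dtype=bool)
        if on_target and biallelic:
            for i in range(n):
                a, b = site.gt[i]
                if a == MISSING or {int(a), int(b)} != {0, 1}:
                    continue
                tot = int(site.ad[i, 0]) + int(site.ad[i, 1])
                if tot == 0:
                    continue
                ratio = int(site.ad[i, 1]) / tot
                exc = ratio <= 0.25 or ratio >= 0.8
                excluded_het[i] = exc
                het_rows.append({"variant_key": site.key, "iid": sample_arr[i],
                                 "abratio": ratio, "excluded": exc})
        miss = (site.gt[:, 0] == MISSING) | excluded_het
        n_missing = int(miss.sum())
        called = ~miss
        n_called = int(called.sum())
        missingness = n_missing / n
        if n_called > 0:
            max_dp = int(site.dp[called].max())
            n_gq_lt20 = int(((site.gq[called] != MISSING) & (site.gq[called] < 20)).sum())
            fail_maxdp = max_dp < 10
            fail_gqfrac = n_gq_lt20 / n_called > 0.20
        else:
            max_dp, n_gq_lt20 = -1, 0
            fail_maxdp, fail_gqfrac = True, False
        fail_missingness = missingness > 0.05
        site_rows.append({
            "variant_key": site.key, "chrom": site.chrom, "pos": site.pos,
            "gene": v["gene"], "on_target": on_target,
            "multiallelic": len(site.alts) > 1,
            "indel": any(len(site.ref) != len(a) for a in site.alts),
            "planted": v["planted"],
            "n_missing": n_missing, "missingness": missingness,
            "n_called": n_called, "max_dp": max_dp, "n_gq_lt20": n_gq_lt20,
            "fail_missingness": fail_missingness, "fail_maxdp": fail_maxdp,
            "fail_gqfrac": fail_gqfrac,
            "excluded": fail_missingness or fail_maxdp or fail_gqfrac,
        })
    return (pd.DataFrame(site_rows),
            pd.DataFrame(het_rows, columns=["variant_key", "iid", "abratio", "excluded"]))
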