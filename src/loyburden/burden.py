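"""Gene burden sets: qualifying-variant selection and rare-allele collapse.

A gene's burden set collects its rare (MAF-thresholded) variants of the
requested impact model and collapses them into a per-individual binary
carrier indicator — "carries none vs. one or more rare alleles" — plus the
per-variant dosage matrix used by variance-component set tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .consequences import classify_impact, severity_rank
from .vcfio import SiteRecord, MISSING

VALID_MODELS = ("loss_of_function", "moderate")
VALID_EXCLUSIONS = ("multi_allelic", "indel", "non_HC_loftee")


# ---------------------------------------------------------------------------
# annotation handling
# ---------------------------------------------------------------------------

def most_severe(annotations: pd.DataFrame) -> pd.DataFrame:
    """Retain one annotation row per variant-gene pair: the transcript with
    the most severe consequence.

    Ties are broken deterministically: severity rank, then consequence term
    alphabetically, then original row order.  Unknown consequence terms
    warn and rank below all known terms.
    """
    df = annotations.copy()
    df["_rank"] = [severity_rank(t) for t in df["consequence"]]
    df["_order"] = np.arange(len(df))
    df = df.sort_values(["_rank", "consequence", "_order"], kind="stable")
    key_cols = ["chrom", "pos", "ref", "alt", "gene"]
    out = df.drop_duplicates(subset=key_cols, keep="first")
    out = out.sort_values("_order").drop(columns=["_rank", "_order"]).reset_index(drop=True)
    return out


def annotation_variant_keys(annotations: pd.DataFrame) -> pd.Series:
    return (annotations["chrom"].astype(str) + ":" + annotations["pos"].astype(str)
            + ":" + annotations["ref"] + ":" + annotations["alt"])


# ---------------------------------------------------------------------------
# dosages and allele frequencies
# ---------------------------------------------------------------------------

def dosages_from_sites(
    sites: list[SiteRecord],
    samples: list[str],
    sample_subset: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ALT-allele dosage matrix (individuals × variant alleles).

    Multi-allelic sites are split positionally: one column per ALT allele,
    dosage = number of copies of that allele; missing genotypes are NaN.
    Returns ``(dosages, flags)`` where flags carries per-allele
    ``multiallelic`` and ``indel`` indicators.
    """
    if sample_subset is not None:
        idx = np.flatnonzero(np.isin(np.asarray(samples), np.asarray(sample_subset)))
        kept = [samples[i] for i in idx]
    else:
        idx = np.arange(len(samples))
        kept = list(samples)
    cols: dict[str, np.ndarray] = {}
    flag_rows = []
    for site in sites:
        gt = site.gt[idx]
        miss = gt[:, 0] == MISSING
        for ai, key in enumerate(site.allele_keys()):
            dos = (gt == ai + 1).sum(axis=1).astype(float)
            dos[miss] = np.nan
            cols[key] = dos
            flag_rows.append({"variant_key": key,
                              "multiallelic": site.is_multiallelic,
                              "indel": site.is_indel(ai)})
    dosages = pd.DataFrame(cols, index=kept)
    flags = pd.DataFrame(flag_rows).set_index("variant_key") if flag_rows \
        else pd.DataFrame(columns=["multiallelic", "indel"])
    return dosages, flags


def compute_maf(dosage_column: np.ndarray) -> tuple[float, int]:
    """Minor allele frequency and count from a dosage column (0/1/2, NaN ok).

    The ALT frequency is computed over non-missing calls; MAF folds it to
    ``min(f, 1-f)``.  An all-missing column is undefined and raises.
    """
    d = np.asarray(dosage_column, dtype=float)
    ok = ~np.isnan(d)
    n_called = int(ok.sum())
    if n_called == 0:
        raise ValueError("all-missing dosage column: MAF undefined")
    alt = int(d[ok].sum())
    total = 2 * n_called
    f = alt / total
    maf = min(f, 1.0 - f)
    mac = min(alt, total - alt)
    return maf, mac


# ---------------------------------------------------------------------------
# burden sets
# ---------------------------------------------------------------------------

@dataclass
class BurdenSet:
    """Qualifying rare variants of one gene under one impact model."""

    gene: str
    model: str
    variant_keys: list[str]
    mafs: np.ndarray
    macs: np.ndarray
    cadd: np.ndarray                 # per-variant CADD Phred (NaN if absent)
    dosages: pd.DataFrame            # individuals × qualifying variants
    carrier: pd.Series               # 0/1 indicator, NaN if all dosages missing

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    @property
    def n_carriers(self) -> int:
        return int((self.carrier == 1).sum())

    def drop_variant(self, key: str) -> "BurdenSet":
        """Rebuild the set without one variant (leave-one-out)."""
        if key not in self.variant_keys:
            raise KeyError(f"variant {key!r} not in set for {self.gene}")
        keep = [k for k in self.variant_keys if k != key]
        mask = np.array([k != key for k in self.variant_keys])
        dos = self.dosages[keep]
        return BurdenSet(gene=self.gene, model=self.model, variant_keys=keep,
                         mafs=self.mafs[mask], macs=self.macs[mask],
                         cadd=self.cadd[mask], dosages=dos,
                         carrier=carrier_indicator(dos))


def carrier_indicator(dosages: pd.DataFrame) -> pd.Series:
    """Collapse dosages to the carrier indicator.

    1 if the individual carries ≥1 minor allele at ≥1 variant; missing only
    if *all* qualifying dosages are missing; otherwise 0.
    """
    if dosages.shape[1] == 0:
        return pd.Series(np.nan, index=dosages.index)
    arr = dosages.to_numpy(dtype=float)
    any_carrier = np.nansum(arr, axis=1) > 0
    all_missing = np.all(np.isnan(arr), axis=1)
    out = np.where(any_carrier, 1.0, 0.0)
    out[all_missing & ~any_carrier] = np.nan
    return pd.Series(out, index=dosages.index)


def build_burden_set(
    gene: str,
    annotations: pd.DataFrame,
    dosages: pd.DataFrame,
    model: str = "loss_of_function",
    maf_max: float = 0.005,
    maf_inclusive: bool = False,
    exclusions: tuple[str, ...] = (),
    variant_flags: pd.DataFrame | None = None,
) -> BurdenSet:
    """Select a gene's qualifying rare variants and collapse them.

    Parameters
    ----------
    annotations : DataFrame
        Most-severe annotation rows (chrom, pos, ref, alt, gene,
        consequence, cadd_phred, loftee, ...).
    dosages : DataFrame
        Individuals × variant-allele dosage matrix, restricted to the
        analysis sample set (MAF is computed on exactly these samples).
    model : {"loss_of_function", "moderate"}
        HIGH-impact or MODERATE-impact variants; the moderate model never
        includes HIGH-impact (loss of function) variants.
    maf_max : float
        Rare threshold; strict ``<`` by default, ``≤`` if ``maf_inclusive``.
    exclusions : tuple of str
        Any of ``multi_allelic``, ``indel``, ``non_HC_loftee`` plus explicit
        variant keys to drop.
    variant_flags : DataFrame
        Per-variant ``multiallelic``/``indel`` flags indexed by variant key
        (required for those exclusion schemes).
    """
    if model not in VALID_MODELS:
        raise ConfigurationError(f"model must be one of {VALID_MODELS}, got {model!r}")
    explicit: set[str] = set()
    for tok in exclusions:
        if tok in VALID_EXCLUSIONS:
            continue
        if ":" in tok:
            explicit.add(tok)
        else:
            raise ConfigurationError(f"unknown exclusion token {tok!r}")
    want_impact = "HIGH" if model == "loss_of_function" else "MODERATE"

    ann = annotations[annotations["gene"] == gene].copy()
    ann["variant_key"] = annotation_variant_keys(ann)
    keys, mafs, macs, cadds = [], [], [], []
    for _, row in ann.iterrows():
        key = row["variant_key"]
        if key in explicit or key not in dosages.columns:
            continue
        if classify_impact(row["consequence"]) != want_impact:
            continue
        if variant_flags is not None and key in variant_flags.index:
            fl = variant_flags.loc[key]
            if "multi_allelic" in exclusions and bool(fl["multiallelic"]):
                continue
            if "indel" in exclusions and bool(fl["indel"]):
                continue
        elif ("multi_allelic" in exclusions or "indel" in exclusions) \
                and variant_flags is None:
            raise ConfigurationError(
                "multi_allelic/indel exclusions require variant_flags")
        if "non_HC_loftee" in exclusions and str(row.get("loftee", ".")) != "HC":
            continue
        col = dosages[key].to_numpy(dtype=float)
        if np.all(np.isnan(col)):
            continue  # undefined MAF; variant dropped
        maf, mac = compute_maf(col)
        if mac == 0:
            continue  # monomorphic in the analysis sample
        if (maf <= maf_max) if maf_inclusive else (maf < maf_max):
            keys.append(key)
            mafs.append(maf)
            macs.append(mac)
            cadds.append(float(row.get("cadd_phred", np.nan)))
    dos = dosages[keys]
    return BurdenSet(gene=gene, model=model, variant_keys=keys,
                     mafs=np.asarray(mafs), macs=np.asarray(macs, dtype=int),
                     cadd=np.asarray(cadds), dosages=dos,
                     carrier=carrier_indicator(dos))


def build_all_sets(
    annotations: pd.DataFrame,
    dosages: pd.DataFrame,
    models: tuple[str, ...] = ("loss_of_function", "moderate"),
    **kwargs,
) -> list[BurdenSet]:
    """Burden sets for every annotated gene × model; empty sets are kept
    (downstream tests decide whether to skip them)."""
    genes = [g for g in annotations["gene"].unique() if g not in (".", "", None)]
    out = []
    for gene in sorted(genes):
        for model in models:
            out.append(build_burden_set(gene, annotations, dosages, model=model, **kwargs))
    return out


# ---------------------------------------------------------------------------
# pseudo-genotype files
# ---------------------------------------------------------------------------

def write_burden_genotypes(sets: list[BurdenSet], path: str) -> None:
    """One pseudo-variant per gene-model, carrier indicator as dosage.

    Wide TSV: gene, model, n_variants, n_carriers then one column per
    individual (0/1, NA for missing).  Round-trips losslessly through
    :func:`read_burden_genotypes`.
    """
    rows = []
    for s in sets:
        row = {"gene": s.gene, "model": s.model,
               "n_variants": s.n_variants, "n_carriers": s.n_carriers}
        for iid, v in s.carrier.items():
            row[iid] = "" if np.isnan(v) else int(v)
        rows.append(row)
    cols = ["gene", "model", "n_variants", "n_carriers"]
    if sets:
        cols += list(sets[0].carrier.index)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, na_rep="")


def read_burden_genotypes(path: str) -> pd.DataFrame:
    """Read a pseudo-genotype file; sample columns come back as float
    (NaN = missing carrier status)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except OSError as e:
        raise OSError(f"cannot read burden genotype file {path}: {e}") from e
    meta = ["gene", "model", "n_variants", "n_carriers"]
    for c in df.columns:
        if c not in meta:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df
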