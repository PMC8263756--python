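"""End-to-end pipeline: simulate → score → QC → burden → associate → sensitivity.

One config, one seed, one log, one machine-readable run manifest.  Each
stage records the checksums of its inputs and outputs; re-running with an
unchanged config skips stages whose outputs are already present with
matching checksums, so deleting a downstream output re-executes only the
downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SimulationConfig, ConfigurationError
from .synthetic import simulate_cohort, simulate_loy_inputs, simulate_exome, simulate_phenotypes
from .exome_qc import run_qc
from .burden import most_severe, dosages_from_sites, build_all_sets, write_burden_genotypes
from .association import NullTraitModel, exome_scan, EXOME_WIDE_ALPHA
from .sensitivity import leave_one_out, subset_analysis, confounding_check

logger = logging.getLogger("loyburden.pipeline")

STAGES = ("simulate", "score_loy", "qc", "burden", "assoc", "sensitivity")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        if not os.path.exists(path_or_dict):
            raise ConfigurationError(f"config file not found: {path_or_dict}")
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("simulate", {})
    cfg.setdefault("pipeline", {})
    p = cfg["pipeline"]
    p.setdefault("trait", "par_loyq")
    p.setdefault("family", "gaussian")
    p.setdefault("models", ["loss_of_function", "moderate"])
    p.setdefault("maf_max", 0.005)
    p.setdefault("maf_inclusive", True)
    p.setdefault("alpha", EXOME_WIDE_ALPHA)
    p.setdefault("analysis_sex", "M")
    p.setdefault("sensitivity_gene", "auto")
    for path_key in ("vcf", "bed", "annotations"):
        if path_key in p and not os.path.exists(p[path_key]):
            raise ConfigurationError(f"pipeline input {path_key} not found: {p[path_key]}")
    return cfg


class PipelineRunner:
    """Executes the stages, maintaining the manifest as it goes."""

    def __init__(self, config, outdir: str, seed: int | None = None):
        self.cfg = load_config(config)
        if seed is not None:
            self.cfg["simulate"]["seed"] = int(seed)
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.manifest_path = os.path.join(outdir, "manifest.json")
        self.prev = self._load_previous()
        self._data = None
        self.manifest = {
            "config_hash": _config_hash(self.cfg),
            "seed": int(self.cfg["simulate"].get("seed", 0)),
            "version": __version__,
            "stages": [],
        }

    def _load_previous(self) -> dict | None:
        if os.path.exists(self.manifest_path):
            try:
                with open(self.manifest_path) as fh:
                    return json.load(fh)
            except (OSError, json.JSONDecodeError):
                return None
        return None

    # -- stage bookkeeping -------------------------------------------------
    def _can_skip(self, name: str, inputs: list[str], outputs: list[str]) -> bool:
        if self.prev is None or self.prev.get("config_hash") != self.manifest["config_hash"]:
            return False
        rec = next((s for s in self.prev.get("stages", []) if s["name"] == name), None)
        if rec is None:
            return False
        for path in outputs:
            if not os.path.exists(path) or _sha256(path) != rec["outputs"].get(path):
                return False
        for path in inputs:
            if not os.path.exists(path) or _sha256(path) != rec["inputs"].get(path):
                return False
        return True

    def _record(self, name: str, inputs: list[str], outputs: list[str],
                counts: dict, skipped: bool) -> None:
        rec = {
            "name": name,
            "skipped": skipped,
            "inputs": {p: _sha256(p) for p in inputs if os.path.exists(p)},
            "outputs": {p: _sha256(p) for p in outputs if os.path.exists(p)},
            "counts": counts,
        }
        self.manifest["stages"].append(rec)
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        for key, val in counts.items():
            logger.info("[%s] %s=%s", name, key, val)

    def _path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    # -- stages ------------------------------------------------------------
    def run(self) -> dict:
        t0 = time.time()
        sim_cfg = SimulationConfig.from_dict(self.cfg["simulate"])
        p = self.cfg["pipeline"]

        # stage 1: simulate ------------------------------------------------
        cohort_path = self._path("cohort.tsv")
        measures_path = self._path("loy_measures.tsv")
        pheno_path = self._path("phenotypes.tsv")
        sim_outputs = [cohort_path, measures_path, pheno_path,
                       self._path("sim.vcf"), self._path("sim.targets.bed"),
                       self._path("sim.annotations.tsv"),
                       self._path("sim.truth_sites.tsv"),
                       self._path("sim.truth_carriers.tsv")]
        if self._can_skip("simulate", [], sim_outputs):
            logger.info("[simulate] outputs up to date; skipping")
            self._record("simulate", [], sim_outputs, {}, skipped=True)
        else:
            cohort = simulate_cohort(sim_cfg)
            measures = simulate_loy_inputs(cohort, sim_cfg)
            sim = simulate_exome(cohort, sim_cfg)
            carrier = (sim_cfg.carrier_gene_specs[0].gene
                       if sim_cfg.carrier_gene_specs else np.zeros(len(cohort)))
            pheno = simulate_phenotypes(cohort, carrier, sim_cfg)
            cohort.to_csv(cohort_path, sep="\t", index=False)
            measures.to_csv(measures_path, sep="\t", index=False)
            pheno.to_csv(pheno_path, sep="\t", index=False)
            sim.write(self.outdir, prefix="sim")
            self._record("simulate", [], sim_outputs,
                         {"n_individuals": len(cohort), "n_sites": len(sim.sites),
                          "n_genes": len(sim.genes)}, skipped=False)

        # stage 2: LOY scoring ----------------------------------------------
        scores_path = self._path("loy_scores.tsv")
        if self._can_skip("score_loy", [measures_path], [scores_path]):
            self._record("score_loy", [measures_path], [scores_path], {}, skipped=True)
        else:
            from .loy_scores import score_measures
            measures = pd.read_csv(measures_path, sep="\t")
            scored = score_measures(measures.drop(columns=["par_loyq"], errors="ignore"))
            scored.to_csv(scores_path, sep="\t", index=False)
            self._record("score_loy", [measures_path], [scores_path],
                         {"n_scored": int(scored["par_loyq"].notna().sum())}, skipped=False)

        # stage 3: QC --------------------------------------------------------
        vcf_in = p.get("vcf", self._path("sim.vcf"))
        bed_in = p.get("bed", self._path("sim.targets.bed"))
        qc_outputs = [self._path("qc.site_metrics.tsv"), self._path("qc.filtered.vcf"),
                      self._path("qc.excluded_hets.tsv")]
        if self._can_skip("qc", [vcf_in, bed_in], qc_outputs):
            self._record("qc", [vcf_in, bed_in], qc_outputs, {}, skipped=True)
        else:
            qc = run_qc(vcf_in, bed_in)
            qc.write(self.outdir, prefix="qc")
            self._record("qc", [vcf_in, bed_in], qc_outputs, qc.summary, skipped=False)

        # stage 4: burden sets ------------------------------------------------
        anno_in = p.get("annotations", self._path("sim.annotations.tsv"))
        qc_vcf = self._path("qc.filtered.vcf")
        sets_path = self._path("burden_sets.tsv")
        pseudo_path = self._path("burden_genotypes.tsv")
        if self._can_skip("burden", [qc_vcf, anno_in], [sets_path, pseudo_path]):
            self._record("burden", [qc_vcf, anno_in], [sets_path, pseudo_path],
                         {}, skipped=True)
            sets = None
        else:
            sets = self._build_sets(qc_vcf, anno_in, p)
            write_burden_genotypes(sets, pseudo_path)
            pd.DataFrame([{"gene": s.gene, "model": s.model,
                           "n_variants": s.n_variants, "n_carriers": s.n_carriers}
                          for s in sets]).to_csv(sets_path, sep="\t", index=False)
            self._record("burden", [qc_vcf, anno_in], [sets_path, pseudo_path],
                         {"n_sets": len(sets),
                          "n_nonempty": sum(1 for s in sets if s.n_variants)},
                         skipped=False)
        if sets is None:
            sets = self._build_sets(qc_vcf, anno_in, p)

        # stage 5: association ------------------------------------------------
        results_path = self._path("assoc_results.tsv")
        null, data = self._fit_null(p)
        results = exome_scan(sets, null, alpha=float(p["alpha"]))
        results.to_csv(results_path, sep="\t", index=False)
        n_sig = int(results["significant"].sum()) if "significant" in results else 0
        self._record("assoc", [sets_path], [results_path],
                     {"n_tested": len(results), "n_significant": n_sig}, skipped=False)

        # stage 6: sensitivity -------------------------------------------------
        gene = p["sensitivity_gene"]
        if gene == "auto":
            nonempty = results[results["n_variants"] >= 2]
            gene = nonempty.iloc[0]["gene"] if len(nonempty) else None
        counts = {}
        if gene is not None:
            target = next((s for s in sets
                           if s.gene == gene and s.n_variants >= 2), None)
            if target is not None:
                loo = leave_one_out(target, null)
                loo.to_csv(self._path("sensitivity_loo.tsv"), sep="\t", index=False)
                counts["loo_rows"] = len(loo)
                conf = confounding_check(
                    target.carrier.to_numpy(dtype=float),
                    data[[c for c in data.columns if c.startswith("PC")]])
                conf.to_csv(self._path("sensitivity_confounding.tsv"),
                            sep="\t", index=False)
                counts["gene"] = gene
        self._record("sensitivity", [results_path],
                     [self._path("sensitivity_loo.tsv")], counts, skipped=False)

        self.manifest["elapsed_seconds"] = round(time.time() - t0, 2)
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.manifest

    # -- helpers -----------------------------------------------------------
    def _analysis_data(self, p: dict) -> pd.DataFrame:
        """Merged cohort/score/phenotype table restricted to the analysis
        sample set: the configured sex with complete trait and covariates.
        Burden sets, MAF and the null model all use exactly these rows."""
        if getattr(self, "_data", None) is not None:
            return self._data
        cohort = pd.read_csv(self._path("cohort.tsv"), sep="\t")
        scores = pd.read_csv(self._path("loy_scores.tsv"), sep="\t")
        pheno = pd.read_csv(self._path("phenotypes.tsv"), sep="\t")
        data = cohort.merge(scores, on="iid").merge(pheno, on="iid")
        sex = p.get("analysis_sex")
        if sex in ("M", "F"):
            data = data[data["sex"] == sex]
        trait = p["trait"]
        covars = [c for c in ("age", "chip") if c in data.columns]
        covars += [c for c in data.columns if c.startswith("PC")]
        data = data.dropna(subset=[trait] + covars).set_index("iid")
        self._data = data
        return data

    def _build_sets(self, qc_vcf: str, anno_in: str, p: dict):
        from .vcfio import read_vcf
        samples, sites = read_vcf(qc_vcf)
        analysis = list(self._analysis_data(p).index)
        dosages, flags = dosages_from_sites(sites, samples, sample_subset=analysis)
        anno = most_severe(pd.read_csv(anno_in, sep="\t"))
        return build_all_sets(anno, dosages, models=tuple(p["models"]),
                              maf_max=float(p["maf_max"]),
                              maf_inclusive=bool(p["maf_inclusive"]),
                              variant_flags=flags)

    def _fit_null(self, p: dict):
        data = self._analysis_data(p)
        model = NullTraitModel.from_dataframe(data, p["trait"], family=p["family"])
        return model.fit(), data


def run_all(config, outdir: str, seed: int | None = None) -> dict:
    """Execute the full pipeline; returns the run manifest (also written to
    ``<outdir>/manifest.json``).  Fails fast on invalid configuration
    before any stage executes."""
    return PipelineRunner(config, outdir, seed=seed).run()
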