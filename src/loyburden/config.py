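"""Simulation and pipeline configuration.

All scenario parameters for the synthetic cohort/exome generator live in
:class:`SimulationConfig`.  Defaults emulate the structure of a UK-Biobank-like
male cohort with array-derived mosaic loss-of-Y (LOY) measurements and
exome-sequencing genotype QC fields.  Every field is validated eagerly so a
bad scenario fails before any data is generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration field is invalid."""


@dataclass(frozen=True)
class CarrierGeneSpec:
    """A gene with deliberately planted rare-allele carriers.

    Parameters
    ----------
    gene : str
        Gene identifier (must match a simulated gene).
    n_carriers : int
        Number of distinct carrier individuals.
    effect_quantitative : float
        Carrier effect on the quantitative trait, in units of the
        non-carrier phenotype standard deviation.
    effect_binary : float
        Carrier odds ratio on the binary trait (1.0 = null).
    loy_risk_log_odds : float
        Carrier effect on the log-odds of harbouring a LOY clone.
    variant_plan : tuple of (int, int)
        ``(minor_allele_count, n_variants)`` blocks describing how the
        carriers are spread over variants.  ``None`` means a default plan
        of one multi-carrier variant plus singletons.
    frameshift : bool
        Whether the multi-carrier variant is emitted as a 1-bp insertion
        frameshift (otherwise a stop-gained SNV).
    """

    gene: str
    n_carriers: int
    effect_quantitative: float = 0.0
    effect_binary: float = 1.0
    loy_risk_log_odds: float = 0.0
    variant_plan: tuple[tuple[int, int], ...] | None = None
    frameshift: bool = True

    def resolved_plan(self) -> tuple[tuple[int, int], ...]:
        """Return the (MAC, n_variants) blocks, defaulting to one
        multi-carrier variant of MAC 10 plus singletons."""
        if self.variant_plan is not None:
            return tuple((int(m), int(k)) for m, k in self.variant_plan)
        multi = min(10, self.n_carriers)
        rest = self.n_carriers - multi
        plan = [(multi, 1)]
        if rest > 0:
            plan.append((1, rest))
        return tuple(plan)

    def planned_carriers(self) -> int:
        return sum(mac * k for mac, k in self.resolved_plan())

    def validate(self) -> None:
        if self.n_carriers <= 0:
            raise ConfigurationError("carrier_gene_specs: n_carriers must be positive")
        if self.effect_binary <= 0:
            raise ConfigurationError("carrier_gene_specs: effect_binary (odds ratio) must be > 0")
        plan = self.resolved_plan()
        if any(mac <= 0 or k <= 0 for mac, k in plan):
            raise ConfigurationError("carrier_gene_specs: variant_plan entries must be positive")
        if self.planned_carriers() != self.n_carriers:
            raise ConfigurationError(
                f"carrier_gene_specs: variant plan for {self.gene} sums to "
                f"{self.planned_carriers()} carriers, expected {self.n_carriers}"
            )


def gigyf1_like_spec(
    gene: str = "GENE_GIGYF1",
    effect_quantitative: float = 0.93,
    effect_binary: float = 1.0,
    loy_risk_log_odds: float = 0.0,
) -> CarrierGeneSpec:
    """The flagship planted scenario: one 10-carrier single-base-insertion
    frameshift, 4 doubletons and 22 singletons — 27 variants carried by
    40 distinct individuals."""
    return CarrierGeneSpec(
        gene=gene,
        n_carriers=40,
        effect_quantitative=effect_quantitative,
        effect_binary=effect_binary,
        loy_risk_log_odds=loy_risk_log_odds,
        variant_plan=((10, 1), (2, 4), (1, 22)),
        frameshift=True,
    )


_FRACTION_FIELDS = (
    "prop_male",
    "smoking_prevalence",
    "chip_fraction",
    "genotype_missing_rate",
    "het_imbalance_fraction",
    "multiallelic_fraction",
    "indel_fraction",
    "off_target_fraction",
    "binary_trait_baseline_prevalence",
    "detection_false_positive_rate",
)


@dataclass
class SimulationConfig:
    """Scenario parameters for the synthetic cohort, LOY measurements,
    exome genotypes and phenotypes.

    Fractions are proportions in [0, 1]; ages are years; effect sizes are
    phenotype-SD units (quantitative) or odds ratios (binary).
    """

    # --- cohort ---
    n_individuals: int = 5000
    prop_male: float = 1.0
    age_range: tuple[int, int] = (40, 70)
    smoking_prevalence: float = 0.45
    chip_fraction: float = 0.10
    n_pcs: int = 10

    # --- latent LOY clone model ---
    clone_baseline_prevalence: float = 0.20   # at the mean age, non-smoker
    clone_age_log_odds_per_decade: float = 1.1
    clone_smoking_log_odds: float = 0.336     # ~ OR 1.4
    clone_fraction_beta: tuple[float, float] = (1.0, 4.0)

    # --- array LOY measurement model ---
    n_probes: int = 20
    lrr_probe_sd: float = 0.15
    lrr_slope: float = 0.5                    # mean probe LRR = -slope * cell fraction
    detection_midpoint: float = 0.05          # cell fraction at 50% PAR-LOY sensitivity
    detection_steepness: float = 0.015
    detection_sensitivity: float | None = None  # constant sensitivity override (1.0 = perfect)
    detection_false_positive_rate: float = 0.0
    af_loy_noise_sd: float = 0.02
    af_loy_undetected: str = "zero"           # "zero" | "missing"

    # --- exome ---
    n_genes: int = 50
    mean_variants_per_gene: float = 8.0
    min_variants_per_gene: int = 2
    mac_max: int = 20                         # background spectrum: P(MAC=m) ∝ 1/m
    target_depth: float = 30.0
    genotype_missing_rate: float = 0.005
    gq_mean: float = 60.0
    gq_sd: float = 15.0
    het_imbalance_fraction: float = 0.01
    qc_fail_fractions: tuple[float, float, float] = (0.02, 0.02, 0.02)
    multiallelic_fraction: float = 0.05
    indel_fraction: float = 0.10
    off_target_fraction: float = 0.05
    plant_boundary_sites: bool = True
    carrier_gene_specs: tuple[CarrierGeneSpec, ...] = ()

    # --- phenotypes ---
    quant_age_effect: float = 0.1             # SD units per decade of age
    quant_sex_effect: float = 0.0
    binary_trait_baseline_prevalence: float = 0.071
    binary_age_log_odds_per_decade: float = 0.3

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_individuals", "n_genes", "n_probes", "n_pcs", "mac_max",
                     "min_variants_per_gene"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v}")
        if not (0.0 < self.clone_baseline_prevalence < 1.0):
            raise ConfigurationError("clone_baseline_prevalence must be in (0, 1)")
        lo, hi = self.age_range
        if lo >= hi:
            raise ConfigurationError(f"age_range must satisfy min < max, got {self.age_range}")
        a, b = self.clone_fraction_beta
        if a <= 0 or b <= 0:
            raise ConfigurationError("clone_fraction_beta shapes must be positive")
        if self.mean_variants_per_gene <= 0:
            raise ConfigurationError("mean_variants_per_gene must be positive")
        if any(not (0.0 <= f <= 1.0) for f in self.qc_fail_fractions):
            raise ConfigurationError("qc_fail_fractions must each be in [0, 1]")
        if len(self.qc_fail_fractions) != 3:
            raise ConfigurationError("qc_fail_fractions must have exactly 3 entries")
        if self.af_loy_undetected not in ("zero", "missing"):
            raise ConfigurationError("af_loy_undetected must be 'zero' or 'missing'")
        if self.lrr_probe_sd < 0 or self.af_loy_noise_sd < 0 or self.gq_sd < 0:
            raise ConfigurationError("noise standard deviations must be non-negative")
        if self.target_depth <= 0:
            raise ConfigurationError("target_depth must be positive")
        specs = tuple(
            s if isinstance(s, CarrierGeneSpec) else CarrierGeneSpec(**s)
            for s in self.carrier_gene_specs
        )
        self.carrier_gene_specs = specs
        seen: set[str] = set()
        for s in specs:
            s.validate()
            if s.gene in seen:
                raise ConfigurationError(f"carrier_gene_specs: duplicate gene {s.gene}")
            seen.add(s.gene)
            if s.n_carriers > self.n_individuals:
                raise ConfigurationError(
                    f"carrier_gene_specs: gene {s.gene} requests {s.n_carriers} carriers "
                    f"but the cohort has only {self.n_individuals} individuals"
                )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "carrier_gene_specs" in d:
            d["carrier_gene_specs"] = tuple(
                s if isinstance(s, CarrierGeneSpec) else CarrierGeneSpec(**s)
                for s in d["carrier_gene_specs"]
            )
        for key in ("age_range", "clone_fraction_beta", "qc_fail_fractions"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "simulate" in payload:
            payload = payload["simulate"]
        return cls.from_dict(payload)
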