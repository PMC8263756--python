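"""Gene-level rare-variant dosage simulation.

Lightweight generators used for statistical studies (calibration, power,
parameter recovery) that need per-gene dosage matrices and carrier
indicators without materialising a VCF.  All carriers are heterozygous,
which is the overwhelmingly common state for variants at MAF < 0.5%.
"""

from __future__ import annotations

import numpy as np


def simulate_null_gene(
    rng: np.random.Generator,
    n: int,
    n_variants: int,
    maf_low: float = 0.00125,
    maf_high: float = 0.005,
) -> np.ndarray:
    """Dosage matrix (n × m, 0/1) for one gene with no phenotype effect.

    Per variant the minor-allele count is ``round(2·n·MAF)`` with MAF drawn
    uniformly from [maf_low, maf_high]; carriers are sampled without
    replacement, independently across variants.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    G = np.zeros((n, n_variants), dtype=np.int8)
    for j in range(n_variants):
        maf = rng.uniform(maf_low, maf_high)
        mac = max(1, int(round(2 * n * maf)))
        G[rng.choice(n, size=min(mac, n), replace=False), j] = 1
    return G


def planted_dosage_matrix(
    rng: np.random.Generator,
    n: int,
    variant_plan: tuple[tuple[int, int], ...] = ((10, 1), (2, 4), (1, 22)),
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix with carriers planted on *distinct* individuals.

    ``variant_plan`` lists (carriers_per_variant, n_variants) blocks; the
    default mirrors the flagship scenario — one 10-carrier variant, 4
    doubletons and 22 singletons, i.e. 27 variants carried by 40 distinct
    individuals.  Returns ``(G, carrier)`` with carrier the 0/1 indicator.
    """
    total = sum(mac * k for mac, k in variant_plan)
    if total > n:
        raise ValueError(f"plan requires {total} distinct carriers but n={n}")
    m = sum(k for _, k in variant_plan)
    carriers = rng.choice(n, size=total, replace=False)
    G = np.zeros((n, m), dtype=np.int8)
    j = 0
    pos = 0
    for mac, k in variant_plan:
        for _ in range(k):
            G[carriers[pos:pos + mac], j] = 1
            pos += mac
            j += 1
    carrier = (G.sum(axis=1) > 0).astype(np.int8)
    return G, carrier


def simulate_planted_gene(
    rng: np.random.Generator,
    n: int,
    effect: float,
    variant_plan: tuple[tuple[int, int], ...] = ((10, 1), (2, 4), (1, 22)),
    covariates: np.ndarray | None = None,
    covariate_effects: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted gene plus a quantitative trait.

    The trait is covariate effects plus unit-normal noise, standardised to
    SD 1 in non-carriers, plus ``effect`` (in non-carrier SD units) for
    carriers.  Returns ``(G, carrier, y)``.
    """
    G, carrier = planted_dosage_matrix(rng, n, variant_plan)
    y = rng.standard_normal(n)
    if covariates is not None and covariate_effects is not None:
        y = y + covariates @ np.asarray(covariate_effects, dtype=float)
    nc = carrier == 0
    y = (y - y[nc].mean()) / y[nc].std(ddof=1)
    y = y + effect * carrier
    return G, carrier, y
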