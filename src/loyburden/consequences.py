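"""Variant consequence vocabulary: severity ranking and impact classes.

The severity table follows the standard Ensembl/VEP ordering (most severe
first) and is frozen here so "most severe consequence" selection is
reproducible.  Impact classes follow the loss-of-function / moderate-impact
definitions used for burden-set construction:

* HIGH (loss of function): frameshift, transcript ablation/amplification,
  splice acceptor/donor, stop lost, start lost/gained, stop gained.
  ``start_gained`` is non-standard VEP vocabulary (the conventional term is
  ``start_lost``); both are kept and mapped to HIGH.
* MODERATE: missense, inframe deletion/insertion, protein-altering.

Everything else maps to "other".
"""

from __future__ import annotations

import warnings

SEVERITY_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "start_gained",
    "transcript_amplification",
    "feature_elongation",
    "feature_truncation",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_donor_5th_base_variant",
    "splice_region_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "intergenic_variant",
    "sequence_variant",
)

SEVERITY_RANK: dict[str, int] = {t: i for i, t in enumerate(SEVERITY_ORDER)}

HIGH_IMPACT: frozenset[str] = frozenset({
    "frameshift_variant",
    "transcript_ablation",
    "transcript_amplification",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_lost",
    "start_lost",
    "start_gained",   # non-standard; kept alongside start_lost
    "stop_gained",
})

MODERATE_IMPACT: frozenset[str] = frozenset({
    "missense_variant",
    "inframe_deletion",
    "inframe_insertion",
    "protein_altering_variant",
})


def severity_rank(term: str, warn_unknown: bool = True) -> int:
    """Rank of a consequence term (0 = most severe); unknown terms rank
    below every known term, with a warning."""
    rank = SEVERITY_RANK.get(term)
    if rank is None:
        if warn_unknown:
            warnings.warn(f"unknown consequence term {term!r}; ranked least severe",
                          stacklevel=2)
        return len(SEVERITY_ORDER)
    return rank


def classify_impact(term: str) -> str:
    """Map a consequence term to {'HIGH', 'MODERATE', 'other'}."""
    if term in HIGH_IMPACT:
        return "HIGH"
    if term in MODERATE_IMPACT:
        return "MODERATE"
    return "other"
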