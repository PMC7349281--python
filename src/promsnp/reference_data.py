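"""Published benchmark reference values used for arithmetic cross-checks.

These figures come from a published GBS-based promoter/rSNP study of faba
bean whose workflow this package reimplements on synthetic data: the
cross-species promoter-classification accuracy grid of eight plant
species, and the bookkeeping counts of the study's GBS processing.  They
are inputs for reproducibility arithmetic (column means, coverage and
filter ledgers), never training data.
"""

from __future__ import annotations

import pandas as pd

#: Cross-species promoter-classification accuracies (rows = species the CNN
#: was trained on, columns = species evaluated; diagonal = intra-species).
CROSS_SPECIES_ACC = pd.DataFrame(
    [
        [0.901, 0.767, 0.690, 0.746, 0.797, 0.765, 0.633, 0.733],
        [0.837, 0.864, 0.915, 0.847, 0.863, 0.724, 0.914, 0.856],
        [0.545, 0.611, 0.981, 0.720, 0.586, 0.493, 0.974, 0.709],
        [0.755, 0.797, 0.959, 0.876, 0.789, 0.715, 0.951, 0.841],
        [0.845, 0.842, 0.888, 0.834, 0.898, 0.748, 0.880, 0.853],
        [0.822, 0.764, 0.696, 0.751, 0.794, 0.840, 0.689, 0.736],
        [0.510, 0.607, 0.971, 0.715, 0.583, 0.494, 0.977, 0.712],
        [0.741, 0.812, 0.937, 0.827, 0.825, 0.675, 0.928, 0.904],
    ],
    index=[
        "Arabidopsis thaliana", "Glycine max", "Lupinus angustifolius",
        "Medicago truncatula", "Phaseolus vulgaris", "Trifolium pratense",
        "Vigna angularis", "Vigna radiata",
    ],
    columns=[
        "Arabidopsis thaliana", "Glycine max", "Lupinus angustifolius",
        "Medicago truncatula", "Phaseolus vulgaris", "Trifolium pratense",
        "Vigna angularis", "Vigna radiata",
    ],
)

#: GBS processing bookkeeping of the reference study.
GBS_STUDY = {
    "partial_genome_bp": 100_037_292,
    "genome_size_bp": 13_000_000_000,
    "snps_called": 1_880_592,
    "snps_retained": 685_215,
    "quality_threshold": 400,
    "n_lines": 20,
    "n_low_lines": 6,
    "n_high_lines": 14,
    "n_target_region_snps": 14,
}


def column_mean_acc(species: str) -> float:
    """Mean accuracy with which the other models predict ``species`` promoters
    (the full 8-value column mean, intra-species value included)."""
    return float(CROSS_SPECIES_ACC[species].mean())


def partial_genome_coverage_percent() -> float:
    """Partial-genome span as a percentage of the estimated genome size."""
    return 100.0 * GBS_STUDY["partial_genome_bp"] / GBS_STUDY["genome_size_bp"]


def snps_discarded_by_quality_filter() -> int:
    """Called SNPs minus retained SNPs = discarded by the quality filter."""
    return GBS_STUDY["snps_called"] - GBS_STUDY["snps_retained"]
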