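"""Published summary numbers from the canine oral-niche survey this
pipeline models, used as reference inputs.

The survey sampled four oral niches (supragingival plaque, buccal
mucosa, tongue dorsum mucosa, stimulated saliva) from 14 Labrador
retrievers on three occasions.  The study-wide abundance ranking of the
most abundant OTUs is published as total read counts, which lets the
pipeline's proportion arithmetic be checked against the printed
percentages.
"""

from __future__ import annotations

#: Total assembled reads retained after sample QC.
TOTAL_QC_READS = 3_739_825

#: Design constants: dogs x occasions, with plaque and buccal sampled on
#: both sides of the mouth.
N_DOGS = 14
N_OCCASIONS = 3
SAMPLES_PER_VISIT = {"plaque": 2, "buccal": 2, "tongue": 1, "saliva": 1}

#: The most abundant OTUs across the study (all >1% of total reads):
#: (otu_id, taxonomy label, percent identity, total reads, printed %).
TOP_OTUS: list[tuple[str, str, float, int, float]] = [
    ("21524", "unclassified Pasteurellaceae sp. [novel 1]", 100.0, 197_672, 5.29),
    ("4989", "unclassified Bergeyella sp. [novel 1]", 100.0, 139_841, 3.74),
    ("10354", "Conchiformibius sp. COT-286", 100.0, 138_694, 3.71),
    ("11671", "Porphyromonas cangingivalis", 100.0, 126_836, 3.39),
    ("21526", "Conchiformibius steedae [novel 1]", 99.77, 109_642, 2.93),
    ("30042", "unclassified Escherichia-Shigella sp. [novel 1]", 100.0, 100_307, 2.68),
    ("1431", "Filifactor villosus", 100.0, 99_658, 2.66),
    ("25622", "unclassified Frederiksenia sp. [novel 1]", 100.0, 83_649, 2.24),
    ("11144", "unclassified Neisseria sp. [novel 1]", 100.0, 79_361, 2.12),
    ("31443", "unclassified Proteocatella sp. [novel 1]", 100.0, 75_675, 2.02),
    ("1382", "Streptococcus minor", 100.0, 75_553, 2.02),
    ("10651", "Moraxella sp. FOT-350", 100.0, 74_779, 2.00),
    ("20323", "Neisseria weaveri", 100.0, 72_670, 1.94),
    ("12643", "unclassified Capnocytophaga sp. [novel]", 100.0, 68_468, 1.83),
    ("31690", "unclassified Porphyromonas sp. [novel 1]", 100.0, 66_309, 1.77),
    ("2753", "Synergistales bacterium COT-178", 100.0, 62_658, 1.68),
    ("26919", "Peptostreptococcaceae bacterium COT-005/004", 100.0, 60_786, 1.63),
    ("30902", "Clostridiales bacterium FOT-072", 100.0, 60_116, 1.61),
    ("9772", "Peptostreptococcaceae bacterium COT-047", 100.0, 58_199, 1.56),
    ("28248", "Peptostreptococcaceae bacterium COT-019", 100.0, 56_013, 1.50),
    ("30023", "TM7 phylum sp. COT-305", 100.0, 53_472, 1.43),
]


def recompute_top_otu_percentages() -> list[tuple[str, float, float]]:
    """Recompute study-wide percentages from the published read counts.

    Returns (otu_id, recomputed %, printed %) triples; the recomputed
    value is reads / total QC'd reads * 100.
    """
    return [
        (otu, 100.0 * reads / TOTAL_QC_READS, printed)
        for otu, _label, _pid, reads, printed in TOP_OTUS
    ]
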