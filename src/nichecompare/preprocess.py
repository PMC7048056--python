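"""Sample QC and rare-taxon grouping.

Two rules produce the analysis-ready table: samples with fewer than
1000 total reads are excluded (strict inequality), and OTUs that are
either below a 0.05% mean proportion in every niche or present in fewer
than two samples are pooled into a single "RARE" unit appended to the
table.  Grouping conserves column totals, so per-sample totals used by
the binomial models are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_model import (
    NICHES,
    CountTable,
    SampleRecord,
    TaxonRecord,
    ValidationError,
)

__all__ = ["FilterReport", "exclude_low_count_samples", "group_rare_taxa", "RARE_ID"]

#: Identifier of the pooled rare-taxa unit.
RARE_ID = "RARE"


@dataclass
class FilterReport:
    """What was removed or pooled, and why."""

    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    rare_otus: list[str] = field(default_factory=list)
    n_units_after: int = 0

    def to_dict(self) -> dict:
        return {
            "excluded_samples": [{"sample_id": s, "reason": r} for s, r in self.excluded_samples],
            "rare_otus": list(self.rare_otus),
            "n_units_after": self.n_units_after,
        }


def exclude_low_count_samples(
    ct: CountTable,
    samples: list[SampleRecord],
    threshold: int = 1000,
) -> tuple[CountTable, FilterReport]:
    """Drop samples whose total read count is strictly below ``threshold``."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    totals = ct.column_totals()
    keep = totals >= threshold
    if ct.n_samples and not keep.any():
        raise ValidationError("all samples fall below the read-count threshold")
    report = FilterReport(
        excluded_samples=[
            (sid, f"total reads {int(t)} < {threshold}")
            for sid, t, k in zip(ct.sample_ids, totals, keep)
            if not k
        ],
        n_units_after=ct.n_otus,
    )
    kept_ids = [s for s, k in zip(ct.sample_ids, keep) if k]
    return ct.select_samples(kept_ids), report


def group_rare_taxa(
    ct: CountTable,
    samples: list[SampleRecord],
    prop_cutoff: float = 0.0005,
    min_samples: int = 2,
    taxa: list[TaxonRecord] | None = None,
    average: str = "per_sample",
) -> tuple[CountTable, list[TaxonRecord], FilterReport]:
    """Pool rare OTUs into one "RARE" row.

    An OTU is rare iff its average proportion is below ``prop_cutoff``
    in *every* niche, or it has a nonzero count in fewer than
    ``min_samples`` samples.  ``average`` selects how the per-niche
    average is formed: ``per_sample`` (default) is the unweighted mean
    of per-sample proportions; ``pooled`` is the niche's pooled-count
    ratio.  Run after sample QC.  A pre-existing "RARE" row is never a
    grouping candidate, making the operation idempotent.
    """
    if average not in ("per_sample", "pooled"):
        raise ValueError("average must be 'per_sample' or 'pooled'")
    niche_of = {s.sample_id: s.niche for s in samples}
    unknown = [sid for sid in ct.sample_ids if sid not in niche_of]
    if unknown:
        raise ValidationError(f"samples missing metadata: {unknown[:5]}")

    totals = ct.column_totals().astype(float)
    if np.any(totals == 0):
        raise ValidationError("zero-total sample present; run QC first")

    # mean proportion of each OTU within each niche
    niche_mean = np.zeros((ct.n_otus, len(NICHES)))
    has_niche = np.zeros(len(NICHES), dtype=bool)
    for g, niche in enumerate(NICHES):
        cols = [j for j, sid in enumerate(ct.sample_ids) if niche_of[sid] == niche]
        if not cols:
            continue
        has_niche[g] = True
        sub = ct.counts[:, cols].astype(float)
        if average == "per_sample":
            niche_mean[:, g] = (sub / totals[cols]).mean(axis=1)
        else:
            niche_mean[:, g] = sub.sum(axis=1) / totals[cols].sum()

    below_everywhere = np.all(niche_mean[:, has_niche] < prop_cutoff, axis=1) if has_niche.any() else np.zeros(ct.n_otus, dtype=bool)
    n_present = (ct.counts > 0).sum(axis=1)
    rare = below_everywhere | (n_present < min_samples)
    for i, otu in enumerate(ct.otu_ids):
        if otu == RARE_ID:
            rare[i] = False

    rare_ids = [o for o, r in zip(ct.otu_ids, rare) if r]
    keep_ids = [o for o, r in zip(ct.otu_ids, rare) if not r]

    if rare_ids:
        rare_row = ct.counts[rare, :].sum(axis=0, keepdims=True)
        new_counts = np.vstack([ct.counts[~rare, :], rare_row])
        new_ct = CountTable(keep_ids + [RARE_ID], list(ct.sample_ids), new_counts)
    else:
        new_ct = CountTable(keep_ids, list(ct.sample_ids), ct.counts[~rare, :])

    new_taxa: list[TaxonRecord] = []
    if taxa is not None:
        rare_set = set(rare_ids)
        for t in taxa:
            new_taxa.append(replace(t, is_rare=t.otu_id in rare_set))
        if rare_ids and not any(t.otu_id == RARE_ID for t in taxa):
            new_taxa.append(
                TaxonRecord(
                    otu_id=RARE_ID,
                    taxonomy_label="pooled rare taxa",
                    phylum="unknown",
                    gram="unknown",
                    oxygen="unknown",
                    is_rare=True,
                )
            )

    report = FilterReport(rare_otus=rare_ids, n_units_after=new_ct.n_otus)
    return new_ct, new_taxa, report
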