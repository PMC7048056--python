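"""Niche-sharing membership (UpSet-style) and core-microbiota detection.

Membership: an OTU is "present" in a niche when its mean proportion
across that niche's samples is strictly above a threshold (0.5% by
default); exclusive intersection counts are computed over the 15
non-empty niche combinations.

Core microbiota: within a niche, an OTU is core at prevalence q when it
reaches the detection threshold (>= 0.5% by default, inclusive) in at
least ceil(q * n) of the niche's QC-passing samples.  The cross-niche
core uses the pooled sample set.  Note the deliberate asymmetry: the
membership rule is strict ">", the detection rule is ">=", both as
conventionally printed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .io_model import NICHES, ProportionTable, SampleRecord, ValidationError

__all__ = ["SetMembership", "upset_membership", "CoreReport", "core_microbiota"]


@dataclass
class SetMembership:
    """Per-niche presence flags and exclusive-intersection counts."""

    presence: pd.DataFrame                      # OTUs x niches, bool
    exclusive_counts: dict[tuple[str, ...], int]  # all 15 non-empty combos

    def n_present_anywhere(self) -> int:
        return int(self.presence.any(axis=1).sum())


def _niche_mean_proportions(pt: ProportionTable, samples: list[SampleRecord]) -> pd.DataFrame:
    meta = {s.sample_id: s for s in samples}
    missing = [sid for sid in pt.sample_ids if sid not in meta]
    if missing:
        raise ValidationError(f"samples missing metadata: {missing[:5]}")
    niches = np.array([meta[sid].niche for sid in pt.sample_ids])
    out = {}
    for niche in NICHES:
        mask = niches == niche
        if mask.any():
            out[niche] = pt.values[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=pt.otu_ids)


def upset_membership(
    pt: ProportionTable,
    samples: list[SampleRecord],
    threshold: float = 0.005,
) -> SetMembership:
    """Presence/absence of OTUs per niche with exclusive intersections.

    Presence means the niche-mean proportion is strictly greater than
    ``threshold``.  The exclusive counts partition the OTUs present in
    at least one niche, so they sum to that number.
    """
    means = _niche_mean_proportions(pt, samples)
    presence = means > threshold
    niches = list(presence.columns)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(niches) + 1):
        for combo in itertools.combinations(niches, r):
            in_combo = presence[list(combo)].all(axis=1)
            out_combo = (
                ~presence[[n for n in niches if n not in combo]].any(axis=1)
                if len(combo) < len(niches)
                else pd.Series(True, index=presence.index)
            )
            counts[combo] = int((in_combo & out_combo).sum())
    return SetMembership(presence=presence, exclusive_counts=counts)


@dataclass
class CoreReport:
    """Core-microbiota lists per niche and across niches."""

    detection: float
    per_niche: dict[str, dict[float, list[str]]]   # niche -> prevalence -> OTUs
    cross_niche: dict[float, list[str]]            # prevalence -> OTUs


def _core_at(values: np.ndarray, otu_ids: list[str], detection: float, q: float) -> list[str]:
    n = values.shape[1]
    need = ceil(q * n)
    hits = (values >= detection).sum(axis=1)
    return [otu for otu, h in zip(otu_ids, hits) if h >= need]


def core_microbiota(
    pt: ProportionTable,
    samples: list[SampleRecord],
    detection: float = 0.005,
    prevalence: tuple[float, ...] = (1.0, 0.75, 0.5),
) -> CoreReport:
    """Core OTUs at the given detection threshold and prevalence levels.

    Within each niche and across the pooled sample set, an OTU is core
    at prevalence q when its proportion reaches ``detection``
    (inclusive) in at least ceil(q * n_samples) samples.
    """
    if any(not (0.0 < q <= 1.0) for q in prevalence):
        raise ValidationError("prevalence levels must be in (0, 1]")
    meta = {s.sample_id: s for s in samples}
    missing = [sid for sid in pt.sample_ids if sid not in meta]
    if missing:
        raise ValidationError(f"samples missing metadata: {missing[:5]}")
    niches = np.array([meta[sid].niche for sid in pt.sample_ids])

    per_niche: dict[str, dict[float, list[str]]] = {}
    for niche in NICHES:
        mask = niches == niche
        if not mask.any():
            continue
        per_niche[niche] = {
            q: _core_at(pt.values[:, mask], pt.otu_ids, detection, q) for q in prevalence
        }
    cross = {q: _core_at(pt.values, pt.otu_ids, detection, q) for q in prevalence}
    return CoreReport(detection=detection, per_niche=per_niche, cross_niche=cross)
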