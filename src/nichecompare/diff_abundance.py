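"""Per-taxon differential abundance across niches.

For every analysis unit (OTU, phylum, Gram level or oxygen level) a
binomial GLMM with crossed dog/day random intercepts is fitted to the
unit's count out of each sample's total reads.  Inference does not rely
on the model's distributional assumptions: niche labels are permuted
within each dog (preserving that dog's multiset of labels), the model
is refitted per permutation, and the two-sided permutation p-value of
each pairwise Wald statistic is computed with the add-one estimator

    p = (1 + #{|z_perm| >= |z_obs|}) / (n_perm + 1).

Within each niche pair, p-values are adjusted across all units by the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .glmm import GlmmDesign, GlmmFit, fit_binomial_glmm_arrays, pairwise_contrasts
from .io_model import NICHES, CountTable, SampleRecord, TaxonRecord, ValidationError

__all__ = [
    "ContrastResult",
    "build_design",
    "fit_binomial_glmm",
    "permutation_test",
    "bh_adjust",
    "differential_abundance",
    "pairwise_summary",
    "aggregate_and_test",
    "PAIRS",
]

#: The six niche pairs, in canonical order.
PAIRS: list[tuple[str, str]] = list(itertools.combinations(NICHES, 2))


@dataclass
class ContrastResult:
    """One unit x niche-pair inference record."""

    unit_id: str
    niche_pair: tuple[str, str]
    log_odds_diff: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    wald_stat: float
    perm_p: float
    adj_p: float = np.nan


def build_design(ct: CountTable, samples: list[SampleRecord]) -> GlmmDesign:
    """Integer-coded niche/dog/day design for the table's samples."""
    meta = {s.sample_id: s for s in samples}
    missing = [sid for sid in ct.sample_ids if sid not in meta]
    if missing:
        raise ValidationError(f"samples missing metadata: {missing[:5]}")
    present = sorted({meta[sid].niche for sid in ct.sample_ids}, key=NICHES.index)
    niche_idx = {n: i for i, n in enumerate(present)}
    dogs = sorted({meta[sid].dog_id for sid in ct.sample_ids})
    dog_idx = {d: i for i, d in enumerate(dogs)}
    days = sorted({meta[sid].occasion for sid in ct.sample_ids})
    day_idx = {t: i for i, t in enumerate(days)}
    return GlmmDesign(
        niche_codes=np.array([niche_idx[meta[sid].niche] for sid in ct.sample_ids]),
        dog_codes=np.array([dog_idx[meta[sid].dog_id] for sid in ct.sample_ids]),
        day_codes=np.array([day_idx[meta[sid].occasion] for sid in ct.sample_ids]),
        niche_levels=present,
    )


def fit_binomial_glmm(
    unit_counts: np.ndarray,
    totals: np.ndarray,
    design: GlmmDesign,
    **kwargs,
) -> GlmmFit:
    """Fit the crossed-intercept binomial GLMM for one unit."""
    return fit_binomial_glmm_arrays(np.asarray(unit_counts, float), np.asarray(totals, float), design, **kwargs)


def _permuted_niche_codes(
    design: GlmmDesign,
    rng: np.random.Generator,
    sides: np.ndarray | None,
) -> np.ndarray:
    """Shuffle niche labels within each dog.

    With ``sides`` given (block mode), left/right pairs keep their label
    together: labels are permuted among the dog's paired units and,
    separately, among its single-sample units, so unit sizes stay
    consistent.
    """
    out = design.niche_codes.copy()
    for d in range(design.n_dogs):
        idx = np.flatnonzero(design.dog_codes == d)
        if idx.size < 2:
            continue
        if sides is None:
            out[idx] = out[idx[rng.permutation(idx.size)]]
        else:
            # group the dog's samples into (occasion, niche, [side]) units
            units: dict[tuple, list[int]] = {}
            for i in idx:
                key = (design.day_codes[i], design.niche_codes[i])
                units.setdefault(key, []).append(int(i))
            paired = [v for v in units.values() if len(v) == 2]
            single = [v for v in units.values() if len(v) != 2]
            for bucket in (paired, single):
                if len(bucket) < 2:
                    continue
                labels = [design.niche_codes[v[0]] for v in bucket]
                perm = rng.permutation(len(bucket))
                for unit, pi in zip(bucket, perm):
                    for i in unit:
                        out[i] = labels[pi]
    return out


def permutation_test(
    unit_counts: np.ndarray,
    totals: np.ndarray,
    design: GlmmDesign,
    n_perm: int = 999,
    seed: int = 0,
    block: str = "sample",
    _rng: np.random.Generator | None = None,
) -> dict:
    """Within-dog permutation p-values for all pairwise niche contrasts.

    Returns the observed fit, observed contrasts and per-pair ``perm_p``.
    Permutation refits that fail to converge are dropped and counted;
    more than 20% failures raises.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if block not in ("sample", "pair"):
        raise ValueError("block must be 'sample' or 'pair'")
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    y = np.asarray(unit_counts, float)
    n = np.asarray(totals, float)

    obs_fit = fit_binomial_glmm_arrays(y, n, design)
    obs = pairwise_contrasts(obs_fit)
    obs_abs = np.array([abs(c["wald_stat"]) for c in obs])
    sigma_warm = (np.sqrt(obs_fit.var_dog) + 0.01, np.sqrt(obs_fit.var_day) + 0.01)

    sides = np.zeros(design.niche_codes.size) if block == "pair" else None
    exceed = np.zeros(obs_abs.size)
    n_ok = 0
    n_fail = 0
    for _ in range(n_perm):
        perm_codes = _permuted_niche_codes(design, rng, sides)
        perm_design = GlmmDesign(perm_codes, design.dog_codes, design.day_codes, design.niche_levels)
        try:
            fit = fit_binomial_glmm_arrays(
                y, n, perm_design,
                sigma_start=sigma_warm, xatol=0.03, maxfev=60,
            )
            if not fit.converged:
                raise RuntimeError("refit did not converge")
        except (RuntimeError, np.linalg.LinAlgError, ValueError):
            n_fail += 1
            continue
        stats = np.abs([c["wald_stat"] for c in pairwise_contrasts(fit)])
        exceed += stats >= obs_abs
        n_ok += 1
    if n_ok == 0 or n_fail > 0.2 * n_perm:
        raise RuntimeError(f"{n_fail}/{n_perm} permutation refits failed")
    perm_p = (1.0 + exceed) / (n_ok + 1.0)
    return {
        "fit": obs_fit,
        "contrasts": obs,
        "perm_p": {tuple(c["niche_pair"]): float(p) for c, p in zip(obs, perm_p)},
        "n_perm_used": n_ok,
        "n_perm_failed": n_fail,
    }


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with enforced monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    ct: CountTable,
    samples: list[SampleRecord],
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    block: str = "sample",
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full per-unit GLMM + permutation + BH pipeline.

    The BH family is all units within one niche-pair comparison (six
    families).  Returns one row per unit x pair with odds ratio, CI,
    permutation p and adjusted p.
    """
    design = build_design(ct, samples)
    totals = ct.column_totals().astype(float)
    if np.any(totals <= 0):
        raise ValidationError("zero-total sample present; run QC first")
    rng = np.random.default_rng(seed)
    rows: list[ContrastResult] = []
    for i, unit in enumerate(ct.otu_ids):
        if progress and i % 25 == 0:  # pragma: no cover
            print(f"  unit {i + 1}/{ct.n_otus}", flush=True)
        res = permutation_test(
            ct.counts[i], totals, design, n_perm=n_perm, block=block, _rng=rng
        )
        for c in res["contrasts"]:
            pair = tuple(c["niche_pair"])
            rows.append(
                ContrastResult(
                    unit_id=unit,
                    niche_pair=pair,
                    log_odds_diff=c["log_odds_diff"],
                    odds_ratio=c["odds_ratio"],
                    or_ci_low=c["or_ci_low"],
                    or_ci_high=c["or_ci_high"],
                    wald_stat=c["wald_stat"],
                    perm_p=res["perm_p"][pair],
                )
            )
    df = pd.DataFrame([vars(r) for r in rows])
    df["adj_p"] = np.nan
    for pair, idx in df.groupby("niche_pair").groups.items():
        df.loc[idx, "adj_p"] = bh_adjust(df.loc[idx, "perm_p"].to_numpy())
    return df


def pairwise_summary(results: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Number of units with adjusted p below alpha, per niche pair."""
    if "adj_p" not in results:
        raise ValueError("adjusted p-values missing; run differential_abundance first")
    counts = {}
    for pair in PAIRS:
        sub = results[results["niche_pair"].apply(tuple) == pair]
        counts[f"{pair[0]}/{pair[1]}"] = int((sub["adj_p"] < alpha).sum())
    return pd.Series(counts, name="n_significant")


def aggregate_counts(
    ct: CountTable, taxa: list[TaxonRecord], level: str
) -> CountTable:
    """Sum unit counts within each category of ``level``.

    ``level`` is one of phylum / gram / oxygen; units annotated
    "unknown" (or unannotated) are excluded from every category sum.
    """
    if level not in ("phylum", "gram", "oxygen"):
        raise ValueError("level must be phylum, gram or oxygen")
    ann = {t.otu_id: getattr(t, level if level != "phylum" else "phylum") for t in taxa}
    cats: dict[str, np.ndarray] = {}
    for i, otu in enumerate(ct.otu_ids):
        cat = ann.get(otu, "unknown") or "unknown"
        if cat == "unknown":
            continue
        if cat not in cats:
            cats[cat] = np.zeros(ct.n_samples, dtype=np.int64)
        cats[cat] += ct.counts[i]
    if not cats:
        raise ValidationError(f"no unit has a known {level} annotation")
    names = sorted(cats)
    return CountTable(names, list(ct.sample_ids), np.vstack([cats[c] for c in names]))


def aggregate_and_test(
    ct: CountTable,
    taxa: list[TaxonRecord],
    samples: list[SampleRecord],
    level: str,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    block: str = "sample",
) -> pd.DataFrame:
    """Category-level differential abundance (phylum / gram / oxygen).

    Category counts are sums of member-unit counts; the denominator
    stays the sample's total read count, so each category is modelled
    as its proportion of all reads.
    """
    agg = aggregate_counts(ct, taxa, level)
    totals = ct.column_totals()  # category out of ALL reads in the sample
    agg_full = CountTable(agg.otu_ids, agg.sample_ids, agg.counts)
    design = build_design(agg_full, samples)
    rng = np.random.default_rng(seed)
    rows: list[ContrastResult] = []
    for i, cat in enumerate(agg_full.otu_ids):
        res = permutation_test(
            agg_full.counts[i], totals.astype(float), design, n_perm=n_perm, block=block, _rng=rng
        )
        for c in res["contrasts"]:
            pair = tuple(c["niche_pair"])
            rows.append(
                ContrastResult(
                    unit_id=cat,
                    niche_pair=pair,
                    log_odds_diff=c["log_odds_diff"],
                    odds_ratio=c["odds_ratio"],
                    or_ci_low=c["or_ci_low"],
                    or_ci_high=c["or_ci_high"],
                    wald_stat=c["wald_stat"],
                    perm_p=res["perm_p"][pair],
                )
            )
    df = pd.DataFrame([vars(r) for r in rows])
    for pair, idx in df.groupby("niche_pair").groups.items():
        df.loc[idx, "adj_p"] = bh_adjust(df.loc[idx, "perm_p"].to_numpy())
    return df
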