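"""Synthetic OTU-table generator with exported ground truth.

Emulates the structure of the four-niche canine oral study: 14 dogs
sampled on 3 occasions; supragingival plaque and buccal mucosa collected
on both sides of the mouth, tongue dorsum and stimulated saliva once per
visit; one never-collected saliva sample; a handful of amplification
failures and sub-1000-read samples.  Compositions follow niche-specific
expected profiles — plaque distinct and most diverse, buccal and tongue
nearly identical, saliva concentrated on few taxa and highly variable —
perturbed on the logit scale by per-dog and per-occasion random
intercepts, overdispersed with a Dirichlet draw, and sampled
multinomially at a log-normal read depth.

The logit-normal perturbation makes the dog/day intercepts exactly the
random effects the downstream binomial GLMM estimates, so parameter
recovery is a well-posed test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .io_model import (
    NICHES,
    CountTable,
    SampleRecord,
    TaxonRecord,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "EffectSpec",
    "default_niche_profiles",
    "default_taxa",
    "simulate_dataset",
    "null_dataset",
    "power_config",
]

_PHYLA = [
    "Proteobacteria",
    "Firmicutes",
    "Bacteroidetes",
    "Actinobacteria",
    "Fusobacteria",
    "Synergistetes",
    "Spirochaetes",
    "Tenericutes",
    "Chlorobi",
    "Saccharibacteria",
    "Absconditabacteria",
    "Gracilibacteria",
    "WS6",
]


@dataclass
class EffectSpec:
    """A planted differential-abundance effect.

    The log-odds of ``otu_id`` in the first niche of ``niche_pair`` is
    shifted by ``log_odds`` relative to every other niche, so the pair's
    true contrast equals ``log_odds`` on the logit scale.
    """

    otu_id: str
    niche_pair: tuple[str, str]
    log_odds: float


@dataclass
class SimConfig:
    """Generator settings; the defaults encode the study design.

    ``dirichlet_concentration`` controls between-sample compositional
    overdispersion per niche (smaller = more variable); the low saliva
    value makes saliva the most variable niche, as observed.
    """

    n_dogs: int = 14
    n_occasions: int = 3
    n_otus: int = 224
    seed: int = 0
    depth_log_mean: float = 9.48  # median depth ~ 13k reads
    depth_log_sd: float = 0.55
    dirichlet_concentration: dict[str, float] = field(
        default_factory=lambda: {"plaque": 2000.0, "buccal": 200.0, "tongue": 200.0, "saliva": 2.0}
    )
    niche_profiles: dict[str, np.ndarray] | None = None
    effect_otus: list[EffectSpec] = field(default_factory=list)
    sigma_dog: float = 0.5
    sigma_day: float = 0.25
    missing_saliva: int = 1
    fail_amp: dict[str, int] = field(default_factory=lambda: {"buccal": 2, "tongue": 6})
    low_count_samples: int = 5

    def __post_init__(self) -> None:
        if self.sigma_dog < 0 or self.sigma_day < 0:
            raise ValidationError("random-intercept SDs must be >= 0")
        if any(c <= 0 for c in self.dirichlet_concentration.values()):
            raise ValidationError("dirichlet_concentration must be > 0")
        if self.niche_profiles is not None:
            for niche, prof in self.niche_profiles.items():
                prof = np.asarray(prof, dtype=float)
                if prof.shape != (self.n_otus,):
                    raise ValidationError(
                        f"profile for {niche} has length {prof.size}, expected {self.n_otus}"
                    )
                if abs(prof.sum() - 1.0) > 1e-8:
                    raise ValidationError(f"profile for {niche} must sum to 1")
                self.niche_profiles[niche] = prof


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    niche_profiles: dict[str, np.ndarray]
    dog_effects: np.ndarray  # (n_dogs, n_otus) logit-scale intercepts
    day_effects: np.ndarray  # (n_occasions, n_otus)
    differential: list[EffectSpec]
    sigma_dog: float
    sigma_day: float

    def to_json(self, path: str | Path) -> None:
        doc = {
            "niche_profiles": {k: np.asarray(v).tolist() for k, v in self.niche_profiles.items()},
            "dog_effects": self.dog_effects.tolist(),
            "day_effects": self.day_effects.tolist(),
            "differential": [
                {"otu_id": e.otu_id, "niche_pair": list(e.niche_pair), "log_odds": e.log_odds}
                for e in self.differential
            ],
            "sigma_dog": self.sigma_dog,
            "sigma_day": self.sigma_day,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            niche_profiles={k: np.asarray(v) for k, v in doc["niche_profiles"].items()},
            dog_effects=np.asarray(doc["dog_effects"]),
            day_effects=np.asarray(doc["day_effects"]),
            differential=[
                EffectSpec(d["otu_id"], tuple(d["niche_pair"]), d["log_odds"])
                for d in doc["differential"]
            ],
            sigma_dog=doc["sigma_dog"],
            sigma_day=doc["sigma_day"],
        )


def _power_law(n: int, gamma: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-gamma)
    return w / w.sum()


def default_niche_profiles(n_otus: int = 224) -> dict[str, np.ndarray]:
    """Deterministic niche composition profiles.

    Ranked power-law abundance curves with niche-specific decay:
    plaque flattest (most diverse), saliva steepest (least diverse),
    buccal and tongue intermediate.  Rank-to-OTU assignment differs by
    niche: buccal and tongue share the same ordering up to a few
    adjacent swaps (near-identical communities); plaque interleaves a
    plaque-specific OTU set with the shared set (distinct community);
    saliva is topped by its own small dominant set.
    """
    if n_otus < 12:
        raise ValidationError("need at least 12 OTUs for the default profiles")
    k = n_otus
    idx = np.arange(k)

    # index pools
    n_shared = min(60, k // 3)
    n_plaque = min(40, k // 4)
    n_saliva_top = min(5, k // 8)
    shared = idx[:n_shared]
    plaque_specific = idx[n_shared : n_shared + n_plaque]
    saliva_top = idx[n_shared + n_plaque : n_shared + n_plaque + n_saliva_top]
    used = set(shared) | set(plaque_specific) | set(saliva_top)
    rest = np.array([i for i in idx if i not in used], dtype=int)

    tongue_order = np.concatenate([shared, rest, plaque_specific, saliva_top])

    buccal_order = tongue_order.copy()
    for i in range(0, min(12, n_shared - 1), 2):  # adjacent swaps in the top ranks
        buccal_order[i], buccal_order[i + 1] = buccal_order[i + 1], buccal_order[i]

    inter = np.empty(2 * n_plaque, dtype=int)
    inter[0::2] = plaque_specific
    inter[1::2] = shared[:n_plaque]
    plaque_order = np.concatenate(
        [inter, shared[n_plaque:], rest, saliva_top]
    )

    saliva_order = np.concatenate([saliva_top, shared, rest, plaque_specific])

    gammas = {"plaque": 0.75, "buccal": 1.05, "tongue": 1.05, "saliva": 1.45}
    orders = {"plaque": plaque_order, "buccal": buccal_order, "tongue": tongue_order, "saliva": saliva_order}
    profiles = {}
    for niche in NICHES:
        w = _power_law(k, gammas[niche])
        prof = np.empty(k)
        prof[orders[niche]] = w
        profiles[niche] = prof
    return profiles


def default_taxa(n_otus: int = 224) -> list[TaxonRecord]:
    """Deterministic OTU annotations aligned with the default profiles.

    The plaque-specific pool is Gram-positive Firmicutes/Actinobacteria
    (mostly anaerobic), the shared surface pool Gram-negative
    Proteobacteria/Bacteroidetes, and the saliva-dominant pool
    facultative Proteobacteria, mirroring the niche signatures the
    default profiles encode.  A sprinkling of taxa have unknown
    Gram/oxygen status.
    """
    k = n_otus
    n_shared = min(60, k // 3)
    n_plaque = min(40, k // 4)
    n_saliva_top = min(5, k // 8)
    taxa: list[TaxonRecord] = []
    for i in range(k):
        otu = f"OTU{i:04d}"
        if n_shared <= i < n_shared + n_plaque:
            phylum = "Firmicutes" if i % 3 else "Actinobacteria"
            gram = "positive"
            oxygen = "anaerobe" if i % 4 else "facultative"
            label = f"Peptostreptococcaceae bacterium sp{i}"
        elif n_shared + n_plaque <= i < n_shared + n_plaque + n_saliva_top:
            phylum = "Proteobacteria"
            gram = "negative"
            oxygen = "facultative"
            label = f"Enterobacteriaceae sp{i}"
        elif i < n_shared:
            phylum = "Proteobacteria" if i % 2 else "Bacteroidetes"
            gram = "negative"
            oxygen = "aerobe" if i % 3 else "anaerobe"
            label = f"surface taxon sp{i}"
        else:
            phylum = _PHYLA[i % len(_PHYLA)]
            gram = ("positive", "negative")[i % 2]
            oxygen = ("aerobe", "anaerobe", "facultative")[i % 3]
            label = f"tail taxon sp{i}"
        if i % 17 == 13:
            gram = "unknown"
        if i % 19 == 11:
            oxygen = "unknown"
        taxa.append(
            TaxonRecord(
                otu_id=otu,
                taxonomy_label=label,
                phylum=phylum,
                percent_identity=100.0 if i % 7 else 98.5,
                oral_taxon_id=f"COT-{i:03d}" if i % 5 == 0 else "",
                gram=gram,
                oxygen=oxygen,
            )
        )
    return taxa


def _sample_plan(cfg: SimConfig) -> list[SampleRecord]:
    """Enumerate collected samples in deterministic order."""
    plan: list[SampleRecord] = []
    code = {"plaque": "P", "buccal": "B", "tongue": "T", "saliva": "S"}
    missing_left = cfg.missing_saliva
    for d in range(1, cfg.n_dogs + 1):
        for t in range(1, cfg.n_occasions + 1):
            for niche in NICHES:
                sides = ("left", "right") if niche in ("plaque", "buccal") else ("none",)
                for side in sides:
                    if niche == "saliva" and t == 1 and missing_left > 0:
                        # lack of compliance on the first collection round
                        missing_left -= 1
                        continue
                    sid = f"D{d:02d}O{t}{code[niche]}" + ("L" if side == "left" else "R" if side == "right" else "")
                    plan.append(
                        SampleRecord(
                            sample_id=sid,
                            dog_id=f"dog{d:02d}",
                            niche=niche,
                            occasion=t,
                            side=side,
                        )
                    )
    return plan


_LOW_COUNT_NICHE_CYCLE = ("plaque", "plaque", "tongue", "saliva", "saliva")


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[CountTable, list[SampleRecord], list[TaxonRecord], SimTruth]:
    """Draw one synthetic dataset under the configured design.

    Returns the count table over successfully amplified samples, the
    full collected-sample metadata (with amplification/QC flags), the
    taxon annotations and the generating ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_otus

    if k == 0 or cfg.n_dogs == 0:
        truth = SimTruth({n: np.zeros(k) for n in NICHES}, np.zeros((cfg.n_dogs, k)),
                         np.zeros((cfg.n_occasions, k)), [], cfg.sigma_dog, cfg.sigma_day)
        return CountTable([], [], np.zeros((0, 0), dtype=int)), [], [], truth

    profiles = cfg.niche_profiles or default_niche_profiles(k)
    taxa = default_taxa(k)
    otu_index = {t.otu_id: i for i, t in enumerate(taxa)}
    for eff in cfg.effect_otus:
        if eff.otu_id not in otu_index:
            raise ValidationError(f"effect OTU {eff.otu_id!r} not in the taxon set")

    plan = _sample_plan(cfg)

    # deterministic-but-seeded amplification failures
    failed: set[str] = set()
    for niche, n_fail in cfg.fail_amp.items():
        cands = [s.sample_id for s in plan if s.niche == niche]
        if n_fail > len(cands):
            raise ValidationError(f"cannot fail {n_fail} {niche} samples out of {len(cands)}")
        chosen = rng.choice(len(cands), size=n_fail, replace=False)
        failed.update(cands[i] for i in sorted(chosen))

    sequenced = [s for s in plan if s.sample_id not in failed]

    # forced sub-QC-depth samples, cycled over the niches the study saw them in
    low_ids: set[str] = set()
    for j in range(cfg.low_count_samples):
        niche = _LOW_COUNT_NICHE_CYCLE[j % len(_LOW_COUNT_NICHE_CYCLE)]
        cands = [s.sample_id for s in sequenced if s.niche == niche and s.sample_id not in low_ids]
        if not cands:
            cands = [s.sample_id for s in sequenced if s.sample_id not in low_ids]
        low_ids.add(cands[int(rng.integers(len(cands)))])

    # random intercepts (logit scale), shared by left/right replicates
    dog_eff = rng.normal(0.0, cfg.sigma_dog, size=(cfg.n_dogs, k))
    day_eff = rng.normal(0.0, cfg.sigma_day, size=(cfg.n_occasions, k))

    logit_prof = {n: logit(np.clip(profiles[n], 1e-12, 1 - 1e-12)) for n in NICHES}
    eff_shift = {n: np.zeros(k) for n in NICHES}
    for eff in cfg.effect_otus:
        eff_shift[eff.niche_pair[0]][otu_index[eff.otu_id]] += eff.log_odds

    dog_num = {f"dog{d:02d}": d - 1 for d in range(1, cfg.n_dogs + 1)}
    counts = np.zeros((k, len(sequenced)), dtype=np.int64)
    for j, s in enumerate(sequenced):
        if s.sample_id in low_ids:
            depth = int(rng.integers(1, 1000))
        else:
            depth = max(1000, int(round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd))))
        eta = (
            logit_prof[s.niche]
            + dog_eff[dog_num[s.dog_id]]
            + day_eff[s.occasion - 1]
            + eff_shift[s.niche]
        )
        m = expit(eta)
        m = m / m.sum()
        alpha = cfg.dirichlet_concentration[s.niche] * m
        comp = rng.dirichlet(alpha)
        if not np.all(np.isfinite(comp)) or comp.sum() <= 0:
            comp = m
        else:
            comp = comp / comp.sum()
        counts[:, j] = rng.multinomial(depth, comp)
        s.total_reads = depth
        s.qc_pass = depth >= 1000

    # annotate the non-sequenced plan entries
    samples_out: list[SampleRecord] = []
    seq_ids = {s.sample_id for s in sequenced}
    for s in plan:
        if s.sample_id not in seq_ids:
            s.amplified = False
            s.total_reads = 0
            s.qc_pass = False
        samples_out.append(s)

    ct = CountTable([t.otu_id for t in taxa], [s.sample_id for s in sequenced], counts)
    truth = SimTruth(
        niche_profiles={n: profiles[n].copy() for n in NICHES},
        dog_effects=dog_eff,
        day_effects=day_eff,
        differential=list(cfg.effect_otus),
        sigma_dog=cfg.sigma_dog,
        sigma_day=cfg.sigma_day,
    )
    return ct, samples_out, taxa, truth


def null_dataset(
    cfg: SimConfig,
    concentration: float = 200.0,
) -> tuple[CountTable, list[SampleRecord], list[TaxonRecord], SimTruth]:
    """Dataset with no niche differences at all.

    All four niches share one expected profile AND one Dirichlet
    concentration (unequal concentrations would break within-dog niche
    exchangeability and the data would not be null for the blocked
    permutation test).  Planted effects are cleared; the returned truth
    lists no differential pairs.
    """
    prof = _power_law(cfg.n_otus, 1.0) if cfg.n_otus else np.zeros(0)
    null_cfg = SimConfig(
        n_dogs=cfg.n_dogs,
        n_occasions=cfg.n_occasions,
        n_otus=cfg.n_otus,
        seed=cfg.seed,
        depth_log_mean=cfg.depth_log_mean,
        depth_log_sd=cfg.depth_log_sd,
        dirichlet_concentration={n: concentration for n in NICHES},
        niche_profiles={n: prof.copy() for n in NICHES} if cfg.n_otus else None,
        effect_otus=[],
        sigma_dog=cfg.sigma_dog,
        sigma_day=cfg.sigma_day,
        missing_saliva=cfg.missing_saliva,
        fail_amp=dict(cfg.fail_amp),
        low_count_samples=cfg.low_count_samples,
    )
    return simulate_dataset(null_cfg)


def power_config(
    n_otus: int = 60,
    n_effects: int = 10,
    log_odds: float = 1.386,
    niche_pair: tuple[str, str] = ("plaque", "buccal"),
    seed: int = 0,
    concentration: float = 200.0,
) -> SimConfig:
    """Config for power studies: a shared null backbone with planted effects.

    Effects are planted on mid-abundance OTUs (ranks 10..) so the planted
    log-odds, not baseline abundance, drives detectability.  The default
    log-odds of 1.386 is an odds ratio of 4.
    """
    prof = _power_law(n_otus, 1.0)
    target_idx = [10 + 2 * i for i in range(n_effects)]
    if target_idx and target_idx[-1] >= n_otus:
        raise ValidationError("n_otus too small for the requested number of effects")
    effects = [EffectSpec(f"OTU{i:04d}", niche_pair, log_odds) for i in target_idx]
    return SimConfig(
        n_otus=n_otus,
        seed=seed,
        dirichlet_concentration={n: concentration for n in NICHES},
        niche_profiles={n: prof.copy() for n in NICHES},
        effect_otus=effects,
    )
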