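"""Shannon diversity with mixed-model comparison, and dog-blocked PCA.

Diversity: the Shannon index H = -sum p_i ln p_i (natural log) is
computed per sample and compared across niches with a Gaussian linear
mixed model (niche fixed; dog and sampling day as crossed random
intercepts, fitted by REML through statsmodels MixedLM).

Ordination: multi-group PCA on the log10 proportions with dog as the
grouping variable — each dog's mean log-profile is removed before the
singular value decomposition, so the components capture within-dog
(between-niche) variation rather than between-dog differences.  95%
bivariate confidence ellipses per niche are derived from the sample
covariance of the PC1/PC2 scores scaled by the chi-square(2) quantile.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_model import NICHES, ProportionTable, SampleRecord, ValidationError

__all__ = [
    "shannon",
    "shannon_per_sample",
    "DiversityResult",
    "diversity_lmm",
    "PcaResult",
    "multigroup_pca",
    "EllipseParams",
    "confidence_ellipse",
    "ellipse_overlap_area",
    "plot_pca",
]


def shannon(proportions: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity index of one sample's taxon proportions.

    Natural log (nats) by default; pass ``base=2`` for bits.  Zero
    proportions contribute nothing.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValidationError("empty proportion vector")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError("proportions must be non-negative and sum to 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_per_sample(pt: ProportionTable, base: float | None = None) -> pd.Series:
    """Shannon index for every sample in a proportion table."""
    vals = [shannon(pt.values[:, j], base=base) for j in range(len(pt.sample_ids))]
    return pd.Series(vals, index=pt.sample_ids, name="shannon")


@dataclass
class DiversityResult:
    """Mixed-model comparison of per-sample Shannon indices."""

    indices: pd.Series
    niche_means: pd.DataFrame        # mean, ci_low, ci_high per niche
    pairwise: pd.DataFrame           # diff, ci_low, ci_high, p, significant
    var_dog: float
    var_day: float
    converged: bool


def diversity_lmm(
    indices: pd.Series,
    samples: list[SampleRecord],
    alpha: float = 0.05,
) -> DiversityResult:
    """Compare Shannon indices across niches with a crossed-intercept LMM.

    ``indices`` is indexed by sample_id; only samples present in both
    inputs are modelled.  Means per niche and all pairwise differences
    are reported with 95% Wald intervals.
    """
    import statsmodels.api as sm  # deferred: slow import

    meta = {s.sample_id: s for s in samples}
    missing = [sid for sid in indices.index if sid not in meta]
    if missing:
        raise ValidationError(f"samples missing metadata: {missing[:5]}")
    df = pd.DataFrame(
        {
            "h": indices.values,
            "niche": [meta[s].niche for s in indices.index],
            "dog": [meta[s].dog_id for s in indices.index],
            "day": [str(meta[s].occasion) for s in indices.index],
        },
        index=indices.index,
    )
    present = sorted(df["niche"].unique(), key=NICHES.index)
    if len(present) < 2:
        raise ValidationError("at least two niches are required")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "h ~ 0 + C(niche)",
            data=df,
            groups=np.ones(len(df)),
            vc_formula={"dog": "0 + C(dog)", "day": "0 + C(day)"},
        )
        fit = model.fit(reml=True)

    names = [f"C(niche)[{n}]" for n in present]
    beta = np.array([fit.params[nm] for nm in names])
    cov = fit.cov_params().loc[names, names].to_numpy()
    z = 1.959963984540054
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))  # guard exact-zero variance
    niche_means = pd.DataFrame(
        {"mean": beta, "ci_low": beta - z * se, "ci_high": beta + z * se},
        index=present,
    )

    from scipy.stats import norm

    rows = []
    for i, j in itertools.combinations(range(len(present)), 2):
        d = beta[i] - beta[j]
        sed = np.sqrt(max(cov[i, i] + cov[j, j] - 2 * cov[i, j], 0.0))
        zstat = d / sed if sed > 0 else 0.0
        p = 2 * norm.sf(abs(zstat))
        rows.append(
            {
                "niche_a": present[i],
                "niche_b": present[j],
                "diff": d,
                "ci_low": d - z * sed,
                "ci_high": d + z * sed,
                "p": p,
                "significant": p < alpha,
            }
        )
    vcs = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp).ravel())) if len(fit.vcomp) else {}
    return DiversityResult(
        indices=indices,
        niche_means=niche_means,
        pairwise=pd.DataFrame(rows),
        var_dog=float(vcs.get("dog", np.nan)),
        var_day=float(vcs.get("day", np.nan)),
        converged=bool(getattr(fit, "converged", True)),
    )


@dataclass
class EllipseParams:
    """A bivariate confidence ellipse: center, semi-axes and rotation."""

    center: np.ndarray
    semi_axes: np.ndarray   # (a, b), a >= b
    angle: float            # radians, orientation of the major axis
    cov: np.ndarray
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether each 2-D point lies inside the ellipse (Mahalanobis test)."""
        pts = np.atleast_2d(points) - self.center
        q = chi2.ppf(self.level, df=2) if self.level > 0 else 0.0
        inv = np.linalg.inv(self.cov)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= q

    def polygon(self, n: int = 128) -> np.ndarray:
        """Boundary points, for plotting or area computations."""
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        circ = np.column_stack([self.semi_axes[0] * np.cos(t), self.semi_axes[1] * np.sin(t)])
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, -s], [s, c]])
        return circ @ R.T + self.center


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.95) -> EllipseParams:
    """95% (by default) bivariate normal confidence region of 2-D scores.

    Centered at the mean, shaped by the sample covariance scaled by the
    chi-square quantile with 2 degrees of freedom.
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need at least 3 two-dimensional points")
    if not 0.0 <= level < 1.0:
        raise ValidationError("level must be in [0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0:
        raise ValidationError("degenerate covariance; ellipse undefined")
    q = chi2.ppf(level, df=2) if level > 0 else 0.0
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = np.sqrt(evals * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return EllipseParams(center=center, semi_axes=semi, angle=angle, cov=cov, level=level)


def ellipse_overlap_area(e1: EllipseParams, e2: EllipseParams, n: int = 256) -> float:
    """Intersection area of two ellipses (polygonal approximation)."""
    from shapely.geometry import Polygon

    p1 = Polygon(e1.polygon(n))
    p2 = Polygon(e2.polygon(n))
    return float(p1.intersection(p2).area)


@dataclass
class PcaResult:
    """Dog-blocked PCA of log10 proportions."""

    sample_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_pct: np.ndarray
    pseudocount: float
    niche_ellipses: dict[str, EllipseParams] = field(default_factory=dict)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def multigroup_pca(
    pt: ProportionTable,
    samples: list[SampleRecord],
    pseudocount: float | str = "auto",
    n_components: int | None = None,
    ellipse_level: float = 0.95,
) -> PcaResult:
    """Within-dog PCA of log10-transformed proportions.

    Zeros are offset by ``pseudocount`` before the log; "auto" uses half
    the smallest nonzero proportion in the table.  Each dog's mean
    log-profile is subtracted (single-sample dogs contribute nothing
    after centering and trigger a warning), then the centered
    samples-by-taxa matrix is decomposed by SVD.
    """
    meta = {s.sample_id: s for s in samples}
    missing = [sid for sid in pt.sample_ids if sid not in meta]
    if missing:
        raise ValidationError(f"samples missing metadata: {missing[:5]}")
    V = pt.values.T  # samples x taxa
    if pseudocount == "auto":
        nz = V[V > 0]
        if nz.size == 0:
            raise ValidationError("all-zero proportion table")
        pseudocount = float(nz.min() / 2.0)
    L = np.log10(V + float(pseudocount))

    dogs = np.array([meta[sid].dog_id for sid in pt.sample_ids])
    M = L.copy()
    for d in np.unique(dogs):
        mask = dogs == d
        if mask.sum() == 1:
            warnings.warn(
                f"dog {d} has a single sample; it contributes nothing after centering"
            )
        M[mask] -= L[mask].mean(axis=0)

    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    k = n_components or min(M.shape)
    scores = U[:, :k] * S[:k]
    tot = float((S**2).sum())
    expl = 100.0 * S[:k] ** 2 / tot if tot > 0 else np.zeros(k)

    ellipses: dict[str, EllipseParams] = {}
    if scores.shape[1] >= 2:
        niches = np.array([meta[sid].niche for sid in pt.sample_ids])
        for niche in NICHES:
            mask = niches == niche
            if mask.sum() >= 3:
                try:
                    ellipses[niche] = confidence_ellipse(scores[mask, :2], level=ellipse_level)
                except ValidationError:
                    pass
    return PcaResult(
        sample_ids=list(pt.sample_ids),
        scores=scores,
        loadings=Vt[:k].T,
        explained_variance_pct=expl,
        pseudocount=float(pseudocount),
        niche_ellipses=ellipses,
    )


_NICHE_COLORS = {"buccal": "#d4b106", "plaque": "#2e7d32", "saliva": "#6a1b9a", "tongue": "#c2185b"}


def plot_pca(result: PcaResult, samples: list[SampleRecord], path: str) -> None:
    """Score plot of PC1/PC2 with per-niche confidence ellipses (PDF/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = {s.sample_id: s for s in samples}
    fig, ax = plt.subplots(figsize=(6, 5))
    niches = np.array([meta[sid].niche for sid in result.sample_ids])
    for niche in NICHES:
        mask = niches == niche
        if not mask.any():
            continue
        ax.scatter(
            result.scores[mask, 0], result.scores[mask, 1],
            s=12, label=niche, color=_NICHE_COLORS.get(niche),
        )
        if niche in result.niche_ellipses:
            poly = result.niche_ellipses[niche].polygon()
            ax.plot(
                np.append(poly[:, 0], poly[0, 0]),
                np.append(poly[:, 1], poly[0, 1]),
                color=_NICHE_COLORS.get(niche), lw=1.2,
            )
    ax.set_xlabel(f"PC1 ({result.explained_variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.explained_variance_pct[1]:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
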