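"""Differential abundance and enrichment statistics.

Cluster abundances (SI_N) are compared across sample groups with Welch's
heteroscedastic ANOVA, whose null distribution is obtained by a within-group
bootstrap (each group centered at its own mean, resampled with replacement).
P-values are Benjamini-Hochberg adjusted; significant features get
Games-Howell pairwise post-hoc comparisons.  Pathway enrichment of a feature
set against a background uses the two-tailed Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("metaspectra")


@dataclass(frozen=True)
class GroupDesign:
    """Mapping sample_id -> group label; needs >=2 groups of >=2 samples."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        sizes = pd.Series(list(self.groups.values())).value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            raise ValueError("design needs >=2 groups with >=2 samples each")

    @classmethod
    def from_tsv(cls, path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise ValueError("design TSV must have columns: sample_id, group")
        return cls(dict(zip(df["sample_id"], df["group"])))

    def split(self, samples: list[str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in samples:
            if s not in self.groups:
                raise KeyError(f"sample {s!r} missing from design")
            out.setdefault(self.groups[s], []).append(s)
        return out


@dataclass
class PosthocResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p: float


@dataclass
class FeatureTestResult:
    feature_id: str
    welch_f: float
    df1: float
    df2: float
    p_boot: float
    q: float = float("nan")
    posthoc: list[PosthocResult] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    pathway_id: str
    k: int   # pathway hits in foreground
    n: int   # foreground size
    K: int   # pathway hits in background
    N: int   # background size
    p_two_tailed: float
    q: float = float("nan")


# ---------------------------------------------------------------------------
# Welch ANOVA
# ---------------------------------------------------------------------------

def welch_f(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Welch's heteroscedastic F statistic and degrees of freedom.

    With group weights w_i = n_i / s_i^2 and weighted grand mean x̄_w:

        F = [Σ w_i (x̄_i − x̄_w)² / (k−1)] / [1 + 2(k−2)/(k²−1) · Λ],
        Λ = Σ (1 − w_i/Σw)² / (n_i − 1),   df1 = k−1,  df2 = (k²−1)/(3Λ).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([a.size for a in arrays], dtype=float)
    if (n < 2).any():
        raise ValueError("every group needs n >= 2")
    means = np.array([a.mean() for a in arrays])
    variances = np.array([a.var(ddof=1) for a in arrays])
    if (variances <= 0).any():
        raise ValueError("zero within-group variance; cannot compute Welch F")
    w = n / variances
    sw = w.sum()
    grand = (w * means).sum() / sw
    lam = (((1 - w / sw) ** 2) / (n - 1)).sum()
    numer = (w * (means - grand) ** 2).sum() / (k - 1)
    denom = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    df2 = (k**2 - 1) / (3 * lam)
    return float(numer / denom), float(k - 1), float(df2)


def _welch_f_vectorized(
    means: np.ndarray, variances: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Welch F for B bootstrap datasets at once; inputs are (B, k) arrays."""
    k = means.shape[1]
    w = n[None, :] / variances
    sw = w.sum(axis=1, keepdims=True)
    grand = (w * means).sum(axis=1, keepdims=True) / sw
    lam = (((1 - w / sw) ** 2) / (n[None, :] - 1)).sum(axis=1)
    numer = (w * (means - grand) ** 2).sum(axis=1) / (k - 1)
    denom = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    return numer / denom


def bootstrap_welch_anova(
    groups: list[np.ndarray],
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap p-value for Welch's ANOVA.

    The null is enforced by centering each group at its own mean; bootstrap
    datasets resample each centered group with replacement, and

        p = (1 + #{F_boot >= F_obs}) / (n_boot + 1).

    Returns (F_obs, p).  Resolution is 1/(n_boot+1), so the smallest
    attainable p at the default n_boot = 10,000 is about 1e-4.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    f_obs, _, _ = welch_f(arrays)
    n = np.array([a.size for a in arrays], dtype=float)
    means_b = np.empty((n_boot, len(arrays)))
    vars_b = np.empty((n_boot, len(arrays)))
    for i, a in enumerate(arrays):
        centered = a - a.mean()
        resampled = rng.choice(centered, size=(n_boot, a.size), replace=True)
        means_b[:, i] = resampled.mean(axis=1)
        vars_b[:, i] = resampled.var(axis=1, ddof=1)
    # resamples where some group collapses to zero variance leave F undefined;
    # they are excluded and the denominator reduced accordingly (negligible
    # except for very small groups)
    ok = (vars_b > 0).all(axis=1)
    n_valid = int(ok.sum())
    if n_valid == 0:
        raise ValueError("no valid bootstrap resamples; groups too small/degenerate")
    f_boot = _welch_f_vectorized(means_b[ok], vars_b[ok], n)
    p = (1 + int((f_boot >= f_obs).sum())) / (n_valid + 1)
    return f_obs, float(p)


# ---------------------------------------------------------------------------
# Multiple testing and post hoc
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def games_howell(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> list[PosthocResult]:
    """Games-Howell pairwise comparisons for unequal variances and sizes.

    For each pair, t is the Welch t statistic, df by Welch-Satterthwaite,
    and p comes from the studentized-range distribution with k groups at
    q = |t|·√2.
    """
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[labels[i]], arrays[labels[j]]
            va, vb = a.var(ddof=1), b.var(ddof=1)
            if va == 0 and vb == 0:
                raise ValueError(
                    f"zero variance in both {labels[i]!r} and {labels[j]!r}"
                )
            se2 = va / a.size + vb / b.size
            t = (a.mean() - b.mean()) / np.sqrt(se2)
            df = se2**2 / (
                (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
            )
            p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2), k, df))
            out.append(PosthocResult(labels[i], labels[j], float(t), float(df), min(p, 1.0)))
    return out


# ---------------------------------------------------------------------------
# Feature-level differential pipeline
# ---------------------------------------------------------------------------

def differential_abundance(
    profile: pd.DataFrame,
    design: GroupDesign,
    n_boot: int = 10_000,
    seed: int | None = None,
    fdr: float = 0.05,
    posthoc_alpha: float = 0.05,
) -> list[FeatureTestResult]:
    """Bootstrap Welch ANOVA per feature with BH correction and post hoc.

    Features with zero variance inside any group are skipped with a warning
    (they carry no within-group information for the F denominator).
    Games-Howell runs only for features passing the FDR cut.
    """
    rng = np.random.default_rng(seed)
    split = design.split(list(profile.columns))
    results: list[FeatureTestResult] = []
    skipped = 0
    for feature, row in profile.iterrows():
        groups = [row[cols].to_numpy(dtype=float) for cols in split.values()]
        try:
            f, df1, df2 = welch_f(groups)
        except ValueError:
            skipped += 1
            continue
        _, p = bootstrap_welch_anova(groups, n_boot=n_boot, seed=rng)
        results.append(FeatureTestResult(str(feature), f, df1, df2, p))
    if skipped:
        logger.warning("%d feature(s) skipped for zero within-group variance", skipped)
    if results:
        q = bh_adjust([r.p_boot for r in results])
        for r, qi in zip(results, q):
            r.q = float(qi)
            if r.q < fdr:
                named = {
                    g: profile.loc[r.feature_id, cols].to_numpy(dtype=float)
                    for g, cols in split.items()
                }
                r.posthoc = games_howell(named, alpha=posthoc_alpha)
    return results


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    foreground_ids: set[str] | list[str],
    background_ids: set[str] | list[str],
    annotation: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """Two-tailed Fisher exact enrichment of pathways in a feature set.

    ``annotation`` maps feature_id -> set of pathway ids.  For each pathway
    the 2x2 table is (in/out foreground) x (in/out pathway) over the
    background universe; the two-tailed p sums hypergeometric probabilities
    not exceeding that of the observed table.  Results carry BH-adjusted q.
    """
    fg = set(foreground_ids)
    bg = set(background_ids)
    if not fg:
        raise ValueError("foreground is empty")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    pathways: dict[str, set[str]] = {}
    for feat in bg:
        for pw in annotation.get(feat, ()):
            pathways.setdefault(pw, set()).add(feat)
    results = []
    N, n = len(bg), len(fg)
    for pw in sorted(pathways):
        members = pathways[pw]
        K = len(members)
        k = len(members & fg)
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
        results.append(EnrichmentResult(pw, k, n, K, N, min(p, 1.0)))
    if results:
        q = bh_adjust([r.p_two_tailed for r in results])
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results
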