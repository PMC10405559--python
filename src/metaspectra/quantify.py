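"""Per-sample quantification of spectrum clusters: SC, SI, SI_N, TMM.

Two label-free abundance measures are computed for every cluster in every
sample.  Spectral count (SC) is the number of the cluster's replicate spectra
observed in the sample, normalized by the sample's total count.  The spectral
index (SI) is the cumulative fragment-ion intensity of replicate peaks that
align (|dm/z| <= 0.4 Th) with the cluster's consensus peaks,

    SI = sum_k sum_j I_j   over aligned peaks j of replicate k,

normalized by a pseudo-length, the consensus neutral mass divided by the
average amino-acid residue mass of 110 Da:

    SI_N = SI / (MW / 110).

SI_N profiles are then made comparable across samples with trimmed-mean-of-
M-values (TMM) scaling factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ConsensusSpectrum, SpectrumCluster
from .spectra_io import Spectrum

#: Weighted average amino-acid residue mass (Da); divisor of the pseudo-length.
RESIDUE_MASS = 110.0

#: Fragment alignment tolerance for SI, in Th (closed interval).
DEFAULT_ALIGN_TOL = 0.4


@dataclass
class ProfileMatrix:
    """Clusters x samples quantitative community profile.

    ``values`` is a pandas DataFrame (rows cluster_ids, columns sample_ids);
    ``metric`` tags what the entries are ("SC", "SC_raw", "SI_N", ...);
    ``tmm_normalized`` records whether TMM scaling has been applied.
    """

    values: pd.DataFrame
    metric: str
    tmm_normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("profile entries must be non-negative")
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("row/column labels must be unique")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#metric={self.metric}\t#tmm={str(self.tmm_normalized).lower()}\n")
            self.values.to_csv(fh, sep="\t", index_label="cluster_id")

    @classmethod
    def from_tsv(cls, path) -> "ProfileMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(tok.lstrip("#").split("=", 1) for tok in header.split("\t"))
            df = pd.read_csv(fh, sep="\t", index_col="cluster_id")
        df.index.name = None
        return cls(df, metric=meta.get("metric", "?"), tmm_normalized=meta.get("tmm") == "true")


@dataclass(frozen=True)
class TmmParams:
    """TMM estimator settings: symmetric trims on M and A, optional fixed reference."""

    trim_m: float = 0.30
    trim_a: float = 0.05
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.trim_m < 0.5 and 0 <= self.trim_a < 0.5):
            raise ValueError("trims must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# Spectral count
# ---------------------------------------------------------------------------

def raw_spectral_counts(
    clusters: list[SpectrumCluster],
    sample_of: dict[str, str],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Raw SC matrix: SC(c, s) = number of members of cluster c from sample s."""
    if samples is None:
        samples = sorted(set(sample_of.values()))
    known = set(samples)
    counts = pd.DataFrame(
        0, index=[c.cluster_id for c in clusters], columns=samples, dtype=float
    )
    for c in clusters:
        for sid in c.member_ids:
            try:
                sample = sample_of[sid]
            except KeyError:
                raise KeyError(f"spectrum {sid!r} has no sample assignment") from None
            if sample not in known:
                raise KeyError(f"unknown sample_id {sample!r} for spectrum {sid!r}")
            counts.at[c.cluster_id, sample] += 1
    return counts


def spectral_count_profile(
    clusters: list[SpectrumCluster],
    sample_of: dict[str, str],
    samples: list[str] | None = None,
) -> ProfileMatrix:
    """Sum-normalized SC profile; each non-empty sample column sums to 1."""
    counts = raw_spectral_counts(clusters, sample_of, samples)
    sums = counts.sum(axis=0)
    empty = sums[sums == 0].index.tolist()
    if empty:
        import logging

        logging.getLogger("metaspectra").warning(
            "samples with zero spectra: %s", ", ".join(map(str, empty))
        )
    norm = counts.div(sums.replace(0, np.nan), axis=1).fillna(0.0)
    return ProfileMatrix(norm, metric="SC")


# ---------------------------------------------------------------------------
# Spectral index
# ---------------------------------------------------------------------------

def spectral_index(
    consensus: ConsensusSpectrum,
    member_spectra: list[Spectrum],
    align_tol: float = DEFAULT_ALIGN_TOL,
) -> float:
    """SI: summed intensity of replicate peaks aligned to the consensus.

    A replicate peak is counted once iff it lies within ``align_tol`` Th
    (closed interval) of at least one consensus peak; the sum runs over all
    supplied replicates.  No members -> 0.
    """
    cons_mz = consensus.mz_array
    if cons_mz.size == 0:
        return 0.0
    total = 0.0
    for sp in member_spectra:
        mz = sp.mz_array
        if mz.size == 0:
            continue
        # distance to the nearest consensus peak, via sorted-side search
        idx = np.searchsorted(cons_mz, mz)
        left = cons_mz[np.clip(idx - 1, 0, cons_mz.size - 1)]
        right = cons_mz[np.clip(idx, 0, cons_mz.size - 1)]
        dist = np.minimum(np.abs(mz - left), np.abs(mz - right))
        total += float(sp.intensity_array[dist <= align_tol].sum())
    return total


def normalized_spectral_index(si: float, neutral_mw: float) -> float:
    """SI_N = SI / (MW / 110 Da); the divisor is the cluster's pseudo-length."""
    if neutral_mw <= 0:
        raise ValueError(f"neutral MW must be positive, got {neutral_mw}")
    return si / (neutral_mw / RESIDUE_MASS)


def spectral_index_profile(
    clusters: list[SpectrumCluster],
    spectra_by_id: dict[str, Spectrum],
    samples: list[str] | None = None,
    align_tol: float = DEFAULT_ALIGN_TOL,
) -> ProfileMatrix:
    """Raw SI_N matrix: per cluster and sample, SI over that sample's members."""
    if samples is None:
        samples = sorted({sp.sample_id for sp in spectra_by_id.values()})
    mat = pd.DataFrame(
        0.0, index=[c.cluster_id for c in clusters], columns=samples
    )
    for c in clusters:
        members = [spectra_by_id[sid] for sid in c.member_ids]
        for sample in samples:
            in_sample = [m for m in members if m.sample_id == sample]
            if not in_sample:
                continue
            si = spectral_index(c.consensus, in_sample, align_tol)
            mat.at[c.cluster_id, sample] = normalized_spectral_index(
                si, c.consensus.neutral_mw
            )
    return ProfileMatrix(mat, metric="SI_N")


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M values)
# ---------------------------------------------------------------------------

def _choose_reference(mat: np.ndarray) -> int:
    """Column whose 75th-percentile proportion is closest to the mean of those."""
    props = mat / mat.sum(axis=0, keepdims=True)
    q75 = np.quantile(props, 0.75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def tmm_factors(
    raw_matrix: pd.DataFrame, params: TmmParams | None = None
) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean rescaled to 1).

    For each non-reference sample, over features positive in both it and the
    reference: M = log2 ratio of proportions, A = mean log2 proportion; the
    top/bottom ``trim_m`` of M-ranks and ``trim_a`` of A-ranks are discarded
    and the factor is 2 to the precision-weighted mean of the surviving M,
    with weights the inverse asymptotic (delta-method) variance of M.
    """
    params = params or TmmParams()
    mat = raw_matrix.to_numpy(dtype=float)
    samples = list(raw_matrix.columns)
    lib = mat.sum(axis=0)
    usable = lib > 0
    if usable.sum() < 2:
        raise ValueError("TMM needs at least 2 samples with positive totals")
    if params.reference_sample is not None:
        ref = samples.index(params.reference_sample)
    else:
        ref = _choose_reference(mat[:, usable])
        ref = np.flatnonzero(usable)[ref]

    import logging

    factors = np.ones(len(samples))
    x_r, n_r = mat[:, ref], lib[ref]
    for j in range(len(samples)):
        if j == ref or not usable[j]:
            continue
        x_j, n_j = mat[:, j], lib[j]
        both = (x_j > 0) & (x_r > 0)
        if not both.any():
            logging.getLogger("metaspectra").warning(
                "sample %s shares no positive features with the TMM reference; factor 1",
                samples[j],
            )
            continue
        pj, pr = x_j[both] / n_j, x_r[both] / n_r
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        n = m.size
        # doubly trimmed: survive both the M-rank and the A-rank trim
        # (mid-ranks so tied values are kept or dropped together)
        from scipy.stats import rankdata

        rank_m = rankdata(m, method="average")
        rank_a = rankdata(a, method="average")
        lo_m = np.floor(n * params.trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * params.trim_a) + 1
        hi_a = n + 1 - lo_a
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        w = 1.0 / ((n_j - x_j[both]) / (n_j * x_j[both]) + (n_r - x_r[both]) / (n_r * x_r[both]))
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    # rescale so the geometric mean over usable samples is exactly 1
    log_f = np.log(factors[usable])
    factors[usable] = np.exp(log_f - log_f.mean())
    return pd.Series(factors, index=samples, name="tmm_factor")


def apply_normalization(profile: ProfileMatrix, factors: pd.Series) -> ProfileMatrix:
    """Divide each column by (column sum x TMM factor); tags the result."""
    if list(factors.index) != list(profile.values.columns):
        raise ValueError("factors must be indexed exactly by the profile's samples")
    if (factors <= 0).any():
        raise ValueError("TMM factors must be positive")
    sums = profile.values.sum(axis=0).replace(0, np.nan)
    out = profile.values.div(sums * factors, axis=1).fillna(0.0)
    return ProfileMatrix(out, metric=profile.metric, tmm_normalized=True)


def tmm_normalized_profile(
    raw: ProfileMatrix, params: TmmParams | None = None
) -> ProfileMatrix:
    """Convenience: estimate TMM factors from the raw matrix and apply them."""
    factors = tmm_factors(raw.values, params)
    return apply_normalization(raw, factors)
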