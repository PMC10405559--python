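"""Greedy spectral-similarity clustering and consensus-spectrum construction.

MS/MS spectra are grouped purely by spectral similarity, with no peptide
identification involved: spectra are binned into sparse unit vectors, scored
by normalized dot product, and inserted greedily in ascending precursor-m/z
order into the best-matching compatible cluster.  Each cluster's replicate
spectra are merged into one consensus spectrum that serves as the unified
quantification basis across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra_io import PROTON_MASS, Peak, Spectrum


@dataclass(frozen=True)
class ClusterParams:
    """Clustering and consensus parameters.

    Defaults are conventional for centroided HCD/Orbitrap data: 1 Th bins
    over the top 50 peaks, square-root intensity transform, dot-product
    threshold 0.7, 20 ppm precursor tolerance within one charge state, two
    passes (one greedy build pass plus one reassignment round), 0.05 Th
    fragment alignment for consensus building, and a peak kept in the
    consensus only when at least half the replicates carry it.
    """

    precursor_tol_ppm: float = 20.0
    bin_width: float = 1.0
    top_n_peaks: int = 50
    similarity_threshold: float = 0.7
    fragment_tol: float = 0.05
    min_peak_fraction: float = 0.5
    passes: int = 2
    require_same_charge: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")
        if min(self.precursor_tol_ppm, self.bin_width, self.fragment_tol) <= 0:
            raise ValueError("tolerances and bin width must be positive")
        if self.top_n_peaks < 1 or self.passes < 1:
            raise ValueError("top_n_peaks and passes must be >= 1")
        if not 0 < self.min_peak_fraction <= 1:
            raise ValueError("min_peak_fraction must be in (0, 1]")


@dataclass
class ConsensusSpectrum:
    """Representative spectrum merged from a cluster's replicate spectra."""

    peaks: list[Peak]
    precursor_mz: float
    charge: int
    replicate_count: int
    neutral_mw: float

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)


@dataclass
class SpectrumCluster:
    cluster_id: str
    member_ids: list[str]
    consensus: ConsensusSpectrum

    @property
    def replicate_count(self) -> int:
        return len(self.member_ids)


def neutral_mass(precursor_mz: float, charge: int | None) -> float:
    """Neutral (uncharged) mass in Da: charge x (m/z - proton mass)."""
    if charge is None:
        raise ValueError(
            "spectrum has no charge; assign one first (see assign_default_charge)"
        )
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return charge * (precursor_mz - PROTON_MASS)


# ---------------------------------------------------------------------------
# Binned vector representation and similarity
# ---------------------------------------------------------------------------

def preprocess_vector(
    peaks_mz: np.ndarray,
    peaks_intensity: np.ndarray,
    bin_width: float = 1.0,
    top_n_peaks: int = 50,
) -> dict[int, float]:
    """Sparse unit-norm binned representation of a peak list.

    The ``top_n_peaks`` most intense peaks are kept, intensities square-root
    transformed, summed into bins of ``bin_width`` Th (bin = floor(mz/width)),
    and the resulting sparse vector L2-normalized.  The square-root transform
    de-emphasizes dominant peaks so the dot product reflects shared peak
    pattern rather than one base peak.
    """
    mz = np.asarray(peaks_mz, dtype=float)
    inten = np.asarray(peaks_intensity, dtype=float)
    if mz.size == 0:
        raise ValueError("cannot vectorize an empty peak list")
    if mz.size > top_n_peaks:
        keep = np.sort(np.argsort(inten, kind="stable")[-top_n_peaks:])
        mz, inten = mz[keep], inten[keep]
    bins = np.floor(mz / bin_width).astype(int)
    vec: dict[int, float] = {}
    for b, x in zip(bins, np.sqrt(inten)):
        vec[b] = vec.get(b, 0.0) + x
    norm = math.sqrt(sum(v * v for v in vec.values()))
    if norm == 0:
        raise ValueError("peak list has zero total intensity")
    return {b: v / norm for b, v in vec.items()}


def spectrum_vector(spectrum: Spectrum, params: ClusterParams) -> dict[int, float]:
    return preprocess_vector(
        spectrum.mz_array, spectrum.intensity_array, params.bin_width, params.top_n_peaks
    )


def similarity(vec_a: dict[int, float], vec_b: dict[int, float]) -> float:
    """Normalized dot product of two sparse unit vectors, in [0, 1]."""
    if len(vec_b) < len(vec_a):
        vec_a, vec_b = vec_b, vec_a
    score = sum(v * vec_b.get(b, 0.0) for b, v in vec_a.items())
    return min(max(score, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def build_consensus(
    members: list[Spectrum], params: ClusterParams | None = None
) -> ConsensusSpectrum:
    """Merge replicate spectra into one consensus spectrum.

    Peaks from all members are aligned greedily by m/z proximity: a sweep in
    ascending m/z opens a new aligned group whenever the next peak is more
    than ``fragment_tol`` from the group's running intensity-weighted mean or
    its member already contributed (one peak per replicate per group).  A
    group is retained iff it occurs in at least ceil(min_peak_fraction x rn)
    members.  Consensus peak m/z is the intensity-weighted mean of the group;
    intensity is the arithmetic mean over all rn members, counting absent
    peaks as zero.  The consensus precursor is the median member precursor.
    """
    params = params or ClusterParams()
    if not members:
        raise ValueError("cannot build a consensus from zero members")
    rn = len(members)
    charge = members[0].charge
    if charge is None:
        raise ValueError("members must have a charge (assign a default first)")
    precursor = float(np.median([m.precursor_mz for m in members]))

    if rn == 1:
        sp = members[0]
        return ConsensusSpectrum(
            peaks=list(sp.peaks),
            precursor_mz=sp.precursor_mz,
            charge=charge,
            replicate_count=1,
            neutral_mw=neutral_mass(sp.precursor_mz, charge),
        )

    # (mz, intensity, member index), sorted by m/z; secondary keys make the
    # sweep invariant to the order the member list was supplied in.
    all_peaks = sorted(
        (p.mz, p.intensity, k)
        for k, m in enumerate(sorted(members, key=lambda s: s.spectrum_id))
        for p in m.peaks
    )
    groups: list[list[tuple[float, float, int]]] = []
    open_groups: list[tuple[float, float, list[tuple[float, float, int]]]] = []
    # open_groups holds (weighted mean mz, total weight, peaks); closed lazily
    for mz, inten, k in all_peaks:
        best = None
        best_dist = params.fragment_tol
        for gi, (gmz, _, gpeaks) in enumerate(open_groups):
            if any(pk == k for _, _, pk in gpeaks):
                continue
            d = abs(mz - gmz)
            if d <= best_dist:
                best, best_dist = gi, d
        if best is None:
            open_groups.append((mz, inten if inten > 0 else 1e-12, [(mz, inten, k)]))
        else:
            gmz, gw, gpeaks = open_groups[best]
            w = inten if inten > 0 else 1e-12
            open_groups[best] = ((gmz * gw + mz * w) / (gw + w), gw + w, gpeaks + [(mz, inten, k)])
        # close groups the sweep has moved past (no future peak can join)
        still_open = []
        for g in open_groups:
            if mz - g[0] > params.fragment_tol:
                groups.append(g[2])
            else:
                still_open.append(g)
        open_groups = still_open
    groups.extend(g[2] for g in open_groups)

    min_members = math.ceil(params.min_peak_fraction * rn)
    peaks: list[Peak] = []
    for g in groups:
        n_members = len({k for _, _, k in g})
        if n_members < min_members:
            continue
        weights = np.array([i if i > 0 else 1e-12 for _, i, _ in g])
        mzs = np.array([m for m, _, _ in g])
        mean_mz = float(np.average(mzs, weights=weights))
        mean_intensity = float(sum(i for _, i, _ in g) / rn)
        peaks.append(Peak(mean_mz, mean_intensity))

    return ConsensusSpectrum(
        peaks=peaks,
        precursor_mz=precursor,
        charge=charge,
        replicate_count=rn,
        neutral_mw=neutral_mass(precursor, charge),
    )


# ---------------------------------------------------------------------------
# Greedy clustering
# ---------------------------------------------------------------------------

def _precursor_compatible(
    mz_a: float, mz_b: float, charge_a: int | None, charge_b: int | None,
    params: ClusterParams,
) -> bool:
    if params.require_same_charge and charge_a != charge_b:
        return False
    tol = params.precursor_tol_ppm * 1e-6 * mz_b
    return abs(mz_a - mz_b) <= tol


def cluster_spectra(
    spectra: list[Spectrum], params: ClusterParams | None = None
) -> list[SpectrumCluster]:
    """Partition spectra into clusters of replicate spectra.

    Pass 1 inserts spectra greedily in ascending precursor-m/z order (ties by
    spectrum_id): each spectrum joins the best-scoring existing cluster whose
    consensus precursor is compatible and whose similarity reaches the
    threshold, else founds a singleton; the joined cluster's consensus is
    rebuilt immediately.  Each of the remaining ``passes - 1`` rounds freezes
    the consensus list and re-seats every spectrum against it, then rebuilds
    all consensus spectra.  Deterministic given input and params.
    """
    params = params or ClusterParams()
    if not spectra:
        return []
    by_id = {sp.spectrum_id: sp for sp in spectra}
    if len(by_id) != len(spectra):
        raise ValueError("spectrum_ids must be unique within the run set")
    order = sorted(spectra, key=lambda s: (s.precursor_mz, s.spectrum_id))
    vectors = {sp.spectrum_id: spectrum_vector(sp, params) for sp in order}

    def consensus_vec(c: ConsensusSpectrum) -> dict[int, float]:
        return preprocess_vector(
            c.mz_array,
            np.array([p.intensity for p in c.peaks]),
            params.bin_width,
            params.top_n_peaks,
        )

    def best_match(
        sp: Spectrum,
        consensi: list[ConsensusSpectrum],
        cons_vecs: list[dict[int, float]],
    ) -> int | None:
        vec = vectors[sp.spectrum_id]
        best_i, best_s = None, params.similarity_threshold
        for i, cons in enumerate(consensi):
            if not _precursor_compatible(
                sp.precursor_mz, cons.precursor_mz, sp.charge, cons.charge, params
            ):
                continue
            s = similarity(vec, cons_vecs[i])
            if s > best_s or (s == best_s and best_i is None):
                best_i, best_s = i, s
        return best_i

    # pass 1: greedy build; each cluster is represented by its consensus,
    # which during this pass is the founding spectrum (consensus spectra are
    # rebuilt once the pass completes)
    members: list[list[Spectrum]] = []
    consensi: list[ConsensusSpectrum] = []
    cons_vecs: list[dict[int, float]] = []
    for sp in order:
        i = best_match(sp, consensi, cons_vecs)
        if i is None:
            members.append([sp])
            consensi.append(build_consensus([sp], params))
            cons_vecs.append(consensus_vec(consensi[-1]))
        else:
            members[i].append(sp)
    consensi = [build_consensus(m, params) for m in members]
    cons_vecs = [consensus_vec(c) for c in consensi]

    # reassignment rounds: re-seat every spectrum against the frozen
    # consensus list, then rebuild all consensus spectra
    for _ in range(params.passes - 1):
        new_members: list[list[Spectrum]] = [[] for _ in consensi]
        extra_members: list[list[Spectrum]] = []
        for sp in order:
            i = best_match(sp, consensi, cons_vecs)
            if i is None:
                extra_members.append([sp])
            else:
                new_members[i].append(sp)
        members = [m for m in new_members if m] + extra_members
        consensi = [build_consensus(m, params) for m in members]
        cons_vecs = [consensus_vec(c) for c in consensi]

    clusters = []
    # stable ids: ascending consensus precursor m/z, ties by first member id
    order_idx = sorted(
        range(len(members)),
        key=lambda i: (consensi[i].precursor_mz, min(s.spectrum_id for s in members[i])),
    )
    for rank, i in enumerate(order_idx):
        clusters.append(
            SpectrumCluster(
                cluster_id=f"C{rank:06d}",
                member_ids=[s.spectrum_id for s in members[i]],
                consensus=consensi[i],
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def reduction_percent(n_spectra: int, n_clusters: int) -> float:
    """Percent data-size reduction achieved by clustering: 100 x (1 - clusters/spectra)."""
    if n_spectra <= 0:
        raise ValueError("n_spectra must be positive")
    return 100.0 * (1.0 - n_clusters / n_spectra)


def multi_member_percent(n_multi: int, n_clusters: int) -> float:
    """Percent of clusters with at least two replicate spectra."""
    if n_clusters <= 0:
        raise ValueError("n_clusters must be positive")
    return 100.0 * n_multi / n_clusters


def cluster_summary(clusters: list[SpectrumCluster]) -> dict[str, float]:
    """Headline clustering statistics: sizes, reduction, multi-member share."""
    n_spectra = sum(c.replicate_count for c in clusters)
    n_clusters = len(clusters)
    n_multi = sum(1 for c in clusters if c.replicate_count >= 2)
    return {
        "n_spectra": n_spectra,
        "n_clusters": n_clusters,
        "n_multi_member": n_multi,
        "reduction_percent": reduction_percent(n_spectra, n_clusters),
        "multi_member_percent": multi_member_percent(n_multi, n_clusters),
    }
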