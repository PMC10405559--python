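"""Synthetic peptide-like MS/MS datasets with ground truth.

The generator emulates what the clustering/quantification pipeline consumes:
a set of template peptides (tryptic-like, ending in K/R) with theoretical
singly-charged b/y fragment ladders, replicated per sample with Gaussian m/z
jitter, multiplicative intensity noise and uniform noise peaks, plus
occasional junk (non-peptide) spectra, and per-spectrum identification
tables with a controlled error rate.  A designed template-by-sample
abundance matrix (expected replicate counts) with group-specific marker
templates provides ground truth for clustering recovery, quantification,
sample-grouping and differential-abundance tests.

The fragment model is deliberately minimal — singly charged b/y ions only —
which is sufficient to exercise spectral clustering and quantification; it
makes no claim of realistic HCD intensity prediction.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .clustering import SpectrumCluster
from .spectra_io import PROTON_MASS, Peak, Spectrum, write_mgf

WATER_MASS = 18.010565
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE = {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults: 20 templates, 3 groups x 2 samples, an
    average of 5 expected replicate spectra per template and sample
    (per-template expectations spread log-uniformly over [2, 16] so the
    abundance design has a recoverable gradient), 3 marker templates per
    group at 6-fold elevated abundance, 0.002 Th fragment jitter, 20%
    intensity CV, 10% noise peaks, 5% junk spectra, 10% identification
    errors."""

    n_templates: int = 20
    n_samples: int = 6
    n_groups: int = 3
    markers_per_group: int = 3
    marker_fold: float = 6.0
    mean_replicates: float = 5.0
    abundance_spread: tuple[float, float] = (2.0, 16.0)
    length_range: tuple[int, int] = (8, 16)
    mz_jitter_sd: float = 0.002
    intensity_cv: float = 0.2
    noise_peak_rate: float = 0.10
    junk_spectrum_rate: float = 0.05
    id_error_rate: float = 0.10
    charge: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.noise_peak_rate, self.junk_spectrum_rate, self.id_error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_samples % self.n_groups:
            raise ValueError("n_samples must divide evenly into n_groups")


@dataclass
class Template:
    template_id: str
    sequence: str
    peaks: list[Peak]
    precursor_mz: float
    charge: int


@dataclass
class GroundTruth:
    """Bookkeeping linking emitted spectra back to the design."""

    templates: dict[str, Template]
    design: dict[str, str]                      # sample_id -> group
    designed_abundance: pd.DataFrame            # templates x samples, expected counts
    realized_counts: pd.DataFrame               # templates x samples, emitted counts
    spectrum_template: dict[str, str | None]    # spectrum_id -> template_id (None = junk)
    markers: dict[str, list[str]]               # group -> marker template_ids

    @property
    def differential_templates(self) -> set[str]:
        return {t for tids in self.markers.values() for t in tids}


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def fragment_ladder(sequence: str) -> list[float]:
    """Singly protonated b- and y-ion m/z values for a peptide.

    b_i = sum of the first i residues + proton; y_i = sum of the last i
    residues + water + proton, for i = 1 .. L-1.
    """
    res = [_RESIDUE[aa] for aa in sequence]
    b = np.cumsum(res[:-1]) + PROTON_MASS
    y = np.cumsum(res[::-1][:-1]) + WATER_MASS + PROTON_MASS
    return sorted(float(x) for x in np.concatenate([b, y]))


def peptide_mz(sequence: str, charge: int) -> float:
    neutral = sum(_RESIDUE[aa] for aa in sequence) + WATER_MASS
    return (neutral + charge * PROTON_MASS) / charge


def generate_templates(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[Template]:
    """Random tryptic-like template peptides with fixed fragment intensities.

    Fragment intensities are drawn once per template (log-normal around
    1000) and reused for every replicate, so replicate spectra of a template
    differ only by the configured noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.length_range
    templates = []
    seen = set()
    while len(templates) < config.n_templates:
        length = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
        seq = body + ("K" if rng.random() < 0.5 else "R")
        if seq in seen:
            continue
        seen.add(seq)
        mzs = fragment_ladder(seq)
        intensities = rng.lognormal(mean=math.log(1000.0), sigma=0.5, size=len(mzs))
        peaks = [Peak(m, float(i)) for m, i in zip(mzs, intensities)]
        templates.append(
            Template(
                template_id=f"T{len(templates):03d}",
                sequence=seq,
                peaks=peaks,
                precursor_mz=peptide_mz(seq, config.charge),
                charge=config.charge,
            )
        )
    return templates


def design_abundance(
    config: SimulationConfig, templates: list[Template], rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, str], dict[str, list[str]]]:
    """Designed expected-replicate-count matrix with group markers.

    Base expectations are log-uniform over ``abundance_spread`` (mean close
    to ``mean_replicates``); each group's marker templates are multiplied by
    ``marker_fold`` in that group's samples only.
    """
    samples = [f"S{i:02d}" for i in range(config.n_samples)]
    per_group = config.n_samples // config.n_groups
    groups = [f"G{i + 1}" for i in range(config.n_groups)]
    design = {s: groups[i // per_group] for i, s in enumerate(samples)}
    lo, hi = config.abundance_spread
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(templates)))
    base *= config.mean_replicates / base.mean()
    mat = pd.DataFrame(
        np.tile(base[:, None], (1, len(samples))),
        index=[t.template_id for t in templates],
        columns=samples,
    )
    markers: dict[str, list[str]] = {g: [] for g in groups}
    tids = [t.template_id for t in templates]
    pick = rng.permutation(len(tids))[: config.markers_per_group * config.n_groups]
    for i, idx in enumerate(pick):
        g = groups[i % config.n_groups]
        markers[g].append(tids[idx])
        cols = [s for s in samples if design[s] == g]
        mat.loc[tids[idx], cols] *= config.marker_fold
    return mat, design, markers


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

def _replicate(template: Template, sid: str, sample: str, config: SimulationConfig,
               rng: np.random.Generator) -> Spectrum:
    mz = np.array([p.mz for p in template.peaks])
    inten = np.array([p.intensity for p in template.peaks])
    mz = mz + rng.normal(0.0, config.mz_jitter_sd, size=mz.size)
    if config.intensity_cv > 0:
        sigma = math.sqrt(math.log(1 + config.intensity_cv**2))
        inten = inten * rng.lognormal(-0.5 * sigma**2, sigma, size=inten.size)
    n_noise = int(round(config.noise_peak_rate * mz.size))
    if n_noise:
        noise_mz = rng.uniform(150.0, 1400.0, size=n_noise)
        noise_int = rng.lognormal(math.log(100.0), 0.5, size=n_noise)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    pmz = template.precursor_mz + rng.normal(0.0, config.mz_jitter_sd)
    return Spectrum(
        spectrum_id=sid,
        sample_id=sample,
        precursor_mz=pmz,
        charge=template.charge,
        peaks=[Peak(float(m), float(i)) for m, i in zip(mz, inten)],
        source="simulated",
    )


def _junk(sid: str, sample: str, config: SimulationConfig, rng: np.random.Generator) -> Spectrum:
    n = int(rng.integers(1, 4))
    mz = rng.uniform(150.0, 1400.0, size=n)
    inten = rng.lognormal(math.log(200.0), 0.5, size=n)
    return Spectrum(
        spectrum_id=sid,
        sample_id=sample,
        precursor_mz=float(rng.uniform(300.0, 1500.0)),
        charge=config.charge,
        peaks=[Peak(float(m), float(i)) for m, i in zip(mz, inten)],
        source="simulated-junk",
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[Spectrum], GroundTruth]:
    """Emit replicate spectra per the designed abundance matrix.

    Per sample and template the replicate count is Poisson with the designed
    expectation; junk spectra are appended at ``junk_spectrum_rate`` relative
    to the number of real spectra.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    templates = generate_templates(config, rng)
    abundance, design, markers = design_abundance(config, templates, rng)
    samples = list(abundance.columns)
    realized = pd.DataFrame(0, index=abundance.index, columns=samples, dtype=int)
    spectra: list[Spectrum] = []
    spectrum_template: dict[str, str | None] = {}
    counter = 0
    for sample in samples:
        for t in templates:
            count = int(rng.poisson(abundance.at[t.template_id, sample]))
            realized.at[t.template_id, sample] = count
            for _ in range(count):
                sid = f"{sample}.scan{counter:06d}"
                counter += 1
                spectra.append(_replicate(t, sid, sample, config, rng))
                spectrum_template[sid] = t.template_id
    n_junk = int(round(config.junk_spectrum_rate * len(spectra)))
    for j in range(n_junk):
        sample = samples[int(rng.integers(len(samples)))]
        sid = f"{sample}.junk{j:05d}"
        spectra.append(_junk(sid, sample, config, rng))
        spectrum_template[sid] = None
    truth = GroundTruth(
        templates={t.template_id: t for t in templates},
        design=design,
        designed_abundance=abundance,
        realized_counts=realized,
        spectrum_template=spectrum_template,
        markers=markers,
    )
    return spectra, truth


def simulate_identifications(
    assignments: dict[str, str],
    error_rate: float,
    rng: np.random.Generator,
    method: str = "database",
) -> pd.DataFrame:
    """Identification-table rows for spectra with known true sequences.

    Each spectrum receives one passing record of ``method``; with
    probability ``error_rate`` the sequence is replaced by a random decoy
    peptide (decoys are freshly random, so errors rarely coincide).
    """
    rows = []
    for sid, true_seq in assignments.items():
        if rng.random() < error_rate:
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=len(true_seq) - 1)) + "K"
        else:
            seq = true_seq
        rows.append(
            {"spectrum_id": sid, "method": method, "peptide": seq,
             "score": round(float(rng.uniform(0.5, 1.0)), 4), "passes": "true"}
        )
    return pd.DataFrame(rows)


def write_dataset(
    spectra: list[Spectrum], truth: GroundTruth, out_dir, config: SimulationConfig
) -> None:
    """Write per-sample MGF files plus truth/design/identification TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample in truth.designed_abundance.columns:
        write_mgf(
            [sp for sp in spectra if sp.sample_id == sample], out / f"{sample}.mgf"
        )
    pd.DataFrame(
        [
            {"spectrum_id": sid, "template_id": tid or "", "sample_id": sid.split(".")[0]}
            for sid, tid in truth.spectrum_template.items()
        ]
    ).to_csv(out / "spectrum_truth.tsv", sep="\t", index=False)
    truth.designed_abundance.to_csv(out / "designed_abundance.tsv", sep="\t")
    truth.realized_counts.to_csv(out / "realized_counts.tsv", sep="\t")
    pd.DataFrame(
        [{"sample_id": s, "group": g} for s, g in truth.design.items()]
    ).to_csv(out / "design.tsv", sep="\t", index=False)
    rng = np.random.default_rng(config.seed + 1)
    assignments = {
        sid: truth.templates[tid].sequence
        for sid, tid in truth.spectrum_template.items()
        if tid is not None
    }
    simulate_identifications(assignments, config.id_error_rate, rng).to_csv(
        out / "identifications.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def evaluate_clustering(
    clusters: list[SpectrumCluster], truth: GroundTruth
) -> tuple[float, float, float]:
    """(purity, completeness, adjusted Rand index) of a clustering vs truth.

    Purity: spectrum-weighted mean over clusters of the largest single-
    template fraction.  Completeness: the same over templates, i.e. the
    fraction of each template's spectra captured by its best cluster.
    Junk spectra are excluded from all three metrics.
    """
    from sklearn.metrics import adjusted_rand_score

    pred: list[int] = []
    true: list[str] = []
    for i, c in enumerate(clusters):
        for sid in c.member_ids:
            if sid not in truth.spectrum_template:
                raise KeyError(f"spectrum {sid!r} unknown to ground truth")
            tid = truth.spectrum_template[sid]
            if tid is None:
                continue
            pred.append(i)
            true.append(tid)
    n = len(pred)
    if n == 0:
        raise ValueError("no non-junk spectra in the clustering")
    df = pd.DataFrame({"cluster": pred, "template": true})
    purity = float(
        sum(
            grp["template"].value_counts().iloc[0]
            for _, grp in df.groupby("cluster")
        ) / n
    )
    completeness = float(
        sum(
            grp["cluster"].value_counts().iloc[0]
            for _, grp in df.groupby("template")
        ) / n
    )
    ari = float(adjusted_rand_score(true, pred))
    return purity, completeness, ari
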