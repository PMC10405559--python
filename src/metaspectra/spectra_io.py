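"""Reading, writing and quality filtering of MS2 spectra.

Spectra arrive as centroided MS/MS scans in mzML (instrument exports) or MGF
(exchange format used for fixtures and for consensus spectra).  Every reader
returns :class:`Spectrum` records with peaks sorted by ascending m/z; a
pre-clustering quality filter drops scans unlikely to be peptide spectra.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

logger = logging.getLogger("metaspectra")

#: Mass of a proton in Da, used wherever m/z is converted to neutral mass.
PROTON_MASS = 1.00728


@dataclass(frozen=True)
class Peak:
    """A single fragment peak: m/z in Thomson, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """One experimental MS2 scan.

    Peaks are kept strictly sorted by ascending m/z; the constructor sorts
    and validates.  ``charge`` may be ``None`` when the instrument did not
    report a precursor charge; downstream code assigns a default and flags it.
    """

    spectrum_id: str
    sample_id: str
    precursor_mz: float
    charge: int | None
    peaks: list[Peak]
    retention_time: float | None = None
    source: str = ""
    charge_defaulted: bool = False

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)


@dataclass(frozen=True)
class QualityParams:
    """Thresholds for the pre-clustering low-quality-spectrum filter.

    Defaults target centroided HCD data acquired over a 300-1500 Th full-scan
    range: at least ``min_peaks`` peaks total, of which ``min_signal_peaks``
    must reach ``signal_fraction`` of the base peak, and a precursor inside
    the scan window.
    """

    min_peaks: int = 10
    min_signal_peaks: int = 5
    signal_fraction: float = 0.01
    min_precursor_mz: float = 300.0
    max_precursor_mz: float = 1500.0

    def __post_init__(self) -> None:
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")
        if not 0 < self.signal_fraction < 1:
            raise ValueError("signal_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

# mzML controlled-vocabulary accessions this reader understands
_CV_MS_LEVEL = "MS:1000511"
_CV_SELECTED_MZ = "MS:1000744"
_CV_CHARGE = "MS:1000041"
_CV_SCAN_START = "MS:1000016"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"


def _cv_accessions(element) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in element.iter("{*}cvParam")
    }


def _decode_array(bda) -> np.ndarray:
    acc = _cv_accessions(bda)
    text = bda.findtext("{*}binary") or ""
    raw = base64.b64decode(text)
    if _CV_ZLIB in acc:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_FLOAT32 in acc else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path, sample_id: str | None = None) -> list[Spectrum]:
    """Read MS level-2 scans from an mzML file.

    A purpose-built streaming parser (lxml iterparse) covering centroided
    MSConvert-style mzML: ms level, selected-ion m/z and charge, scan start
    time, and base64 m/z / intensity arrays (32/64-bit float, zlib or
    uncompressed).  ``sample_id`` defaults to the file stem.  MS1 scans are
    ignored; MS2 scans lacking a precursor m/z are skipped with a warning.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    out: list[Spectrum] = []
    try:
        context = etree.iterparse(str(path), events=("end",), tag="{*}spectrum")
        for _, el in context:
            acc = {
                cv.get("accession"): cv.get("value", "")
                for cv in el.findall("{*}cvParam")
            }
            scan_id = el.get("id", f"scan={len(out)}")
            if acc.get(_CV_MS_LEVEL) == "2":
                ion = el.find(
                    "{*}precursorList/{*}precursor/{*}selectedIonList/{*}selectedIon"
                )
                ion_acc = _cv_accessions(ion) if ion is not None else {}
                if _CV_SELECTED_MZ not in ion_acc:
                    logger.warning(
                        "%s: MS2 scan %s lacks precursor m/z; skipped", path, scan_id
                    )
                    el.clear()
                    continue
                pmz = float(ion_acc[_CV_SELECTED_MZ])
                charge = (
                    int(float(ion_acc[_CV_CHARGE])) if _CV_CHARGE in ion_acc else None
                )
                rt = None
                scan = el.find("{*}scanList/{*}scan")
                if scan is not None:
                    for cv in scan.findall("{*}cvParam"):
                        if cv.get("accession") == _CV_SCAN_START:
                            unit = (cv.get("unitName") or "minute").lower()
                            rt = float(cv.get("value")) * (
                                60.0 if unit.startswith("minute") else 1.0
                            )
                mzs = ints = None
                for bda in el.findall("{*}binaryDataArrayList/{*}binaryDataArray"):
                    arr_acc = _cv_accessions(bda)
                    if _CV_MZ_ARRAY in arr_acc:
                        mzs = _decode_array(bda)
                    elif _CV_INT_ARRAY in arr_acc:
                        ints = _decode_array(bda)
                if mzs is None or ints is None:
                    logger.warning(
                        "%s: MS2 scan %s lacks peak arrays; skipped", path, scan_id
                    )
                    el.clear()
                    continue
                out.append(
                    Spectrum(
                        spectrum_id=scan_id,
                        sample_id=sid,
                        precursor_mz=pmz,
                        charge=charge,
                        peaks=[Peak(m, i) for m, i in zip(mzs, ints)],
                        retention_time=rt,
                        source=f"{path.name}#{scan_id}",
                    )
                )
            el.clear()
    except (OSError, etree.XMLSyntaxError) as exc:
        raise IOError(f"cannot read mzML file {path}: {exc}") from exc
    if not out:
        logger.warning("%s: no MS2 spectra found", path)
    return out


def read_mgf(path: str | Path, sample_id: str | None = None) -> list[Spectrum]:
    """Read spectra from an MGF file; TITLE carries the spectrum_id.

    Blocks without PEPMASS are rejected with a warning; a missing CHARGE
    yields a spectrum with ``charge=None``.
    """
    path = Path(path)
    sid_default = sample_id if sample_id is not None else path.stem
    out: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"{path.stem}.{i}"))
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                logger.warning("%s: MGF block %r lacks PEPMASS; rejected", path, title)
                continue
            pmz = float(pepmass[0])
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else None
            sid = str(params.get("sample", sid_default))
            rt = params.get("rtinseconds")
            peaks = [
                Peak(float(m), float(it))
                for m, it in zip(entry["m/z array"], entry["intensity array"])
            ]
            out.append(
                Spectrum(
                    spectrum_id=title,
                    sample_id=sid,
                    precursor_mz=pmz,
                    charge=charge,
                    peaks=peaks,
                    retention_time=float(rt) if rt is not None else None,
                    source=f"{path.name}#{title}",
                )
            )
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF. m/z printed to 5 decimals so read∘write is identity."""
    path = Path(path)
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.5f}\n")
            if sp.charge is not None:
                fh.write(f"CHARGE={sp.charge}+\n")
            fh.write(f"SAMPLE={sp.sample_id}\n")
            if sp.retention_time is not None:
                fh.write(f"RTINSECONDS={sp.retention_time:.3f}\n")
            for p in sp.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.6g}\n")
            fh.write("END IONS\n")


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write MS2 spectra as minimal mzML 1.1.0 (uncompressed 64-bit arrays).

    Covers exactly what :func:`read_mzml` consumes: ms level, selected-ion
    m/z, charge state and the two binary data arrays.
    """
    path = Path(path)
    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element(f"{{{NS}}}mzML", version="1.1.0", nsmap={None: NS})
    etree.SubElement(root, f"{{{NS}}}cvList", count="1")
    run = etree.SubElement(root, f"{{{NS}}}run", id=path.stem)
    slist = etree.SubElement(run, f"{{{NS}}}spectrumList", count=str(len(spectra)))

    def cv(parent, accession, name, value="", **extra):
        etree.SubElement(
            parent, f"{{{NS}}}cvParam", cvRef="MS", accession=accession, name=name,
            value=str(value), **extra,
        )

    for idx, sp in enumerate(spectra):
        el = etree.SubElement(
            slist, f"{{{NS}}}spectrum", index=str(idx), id=sp.spectrum_id,
            defaultArrayLength=str(len(sp.peaks)),
        )
        cv(el, "MS:1000511", "ms level", 2)
        cv(el, "MS:1000580", "MSn spectrum")
        plist = etree.SubElement(el, f"{{{NS}}}precursorList", count="1")
        prec = etree.SubElement(plist, f"{{{NS}}}precursor")
        ilist = etree.SubElement(prec, f"{{{NS}}}selectedIonList", count="1")
        ion = etree.SubElement(ilist, f"{{{NS}}}selectedIon")
        cv(ion, "MS:1000744", "selected ion m/z", repr(sp.precursor_mz))
        if sp.charge is not None:
            cv(ion, "MS:1000041", "charge state", sp.charge)
        blist = etree.SubElement(el, f"{{{NS}}}binaryDataArrayList", count="2")
        for name, acc, arr in (
            ("m/z array", "MS:1000514", sp.mz_array),
            ("intensity array", "MS:1000515", sp.intensity_array),
        ):
            raw = struct.pack(f"<{len(arr)}d", *arr)
            b64 = base64.b64encode(raw).decode("ascii")
            bda = etree.SubElement(
                blist, f"{{{NS}}}binaryDataArray", encodedLength=str(len(b64))
            )
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name)
            etree.SubElement(bda, f"{{{NS}}}binary").text = b64
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Sample map and quality filter
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a TSV mapping source file (stem or name) to sample_id."""
    df = pd.read_csv(path, sep="\t")
    if not {"file", "sample_id"} <= set(df.columns):
        raise ValueError("sample map must have columns: file, sample_id")
    return {Path(str(f)).stem: str(s) for f, s in zip(df["file"], df["sample_id"])}


def apply_sample_map(spectra: Iterable[Spectrum], mapping: dict[str, str]) -> list[Spectrum]:
    """Override sample_id where the mapping covers the spectrum's sample."""
    return [
        replace(sp, sample_id=mapping.get(sp.sample_id, sp.sample_id)) for sp in spectra
    ]


def assign_default_charge(spectra: Iterable[Spectrum], default_charge: int = 2) -> list[Spectrum]:
    """Give chargeless spectra a default charge and flag them.

    Charge is needed for neutral-mass computation and (optionally) cluster
    compatibility, so spectra without one are kept rather than dropped.
    """
    out = []
    for sp in spectra:
        if sp.charge is None:
            out.append(replace(sp, charge=default_charge, charge_defaulted=True))
        else:
            out.append(sp)
    return out


def quality_filter(
    spectra: Sequence[Spectrum], params: QualityParams | None = None
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Partition spectra into (kept, rejected) by peptide-likeness heuristics.

    A spectrum is kept iff it has at least ``min_peaks`` peaks, at least
    ``min_signal_peaks`` of them reach ``signal_fraction`` of the base peak,
    and its precursor m/z lies inside the configured window.
    """
    params = params or QualityParams()
    kept: list[Spectrum] = []
    rejected: list[Spectrum] = []
    for sp in spectra:
        ok = len(sp.peaks) >= params.min_peaks
        if ok:
            threshold = params.signal_fraction * sp.base_peak_intensity
            n_signal = sum(1 for p in sp.peaks if p.intensity >= threshold)
            ok = n_signal >= params.min_signal_peaks
        if ok:
            ok = params.min_precursor_mz <= sp.precursor_mz <= params.max_precursor_mz
        (kept if ok else rejected).append(sp)
    return kept, rejected
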