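"""MS2 spectrum containers and I/O, energy pairing, oxonium screening and
TMT reporter extraction.

Runs are read either from mzML (via pyteomics) or from an internal JSON run
format (one object with a ``spectra`` list; each scan carries scan id,
precursor m/z and charge, energy tag, retention time in seconds and the
peak arrays).  mzML output is produced by a minimal serializer writing
uncompressed base64 float64 peak arrays with the standard PSI-MS cvParams,
which pyteomics reads back bit-identically.
"""

from __future__ import annotations

import base64
import json
import logging
import struct
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .glyco import PROTON

logger = logging.getLogger(__name__)

# 10-plex TMT reporter ion m/z (published values); the study uses 4 channels.
TMT10_REPORTER_MZ = {
    "126": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.137790,
    "130N": 130.134825,
    "130C": 130.141145,
    "131": 131.138180,
}
STUDY_CHANNELS = ("129C", "130C", "130N", "131")

# Default oxonium screen list: HexNAc fragment series, HexNAc-Hex, NeuAc
# (with water loss) and the HexNAc2 diagnostic.
DEFAULT_OXONIUM_MZ = (
    126.055,
    138.055,
    168.066,
    186.076,
    204.087,
    274.092,
    292.103,
    366.140,
    407.166,
)


@dataclass
class Ms2Spectrum:
    scan_id: int
    precursor_mz: float
    precursor_charge: int
    energy: str  # "low" | "high"
    mz: np.ndarray
    intensity: np.ndarray
    rt: float = 0.0  # seconds

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def precursor_neutral_mass(self) -> float:
        return (self.precursor_mz - PROTON) * self.precursor_charge

    def top_n_mz(self, n: int) -> np.ndarray:
        idx = np.argsort(self.intensity, kind="stable")[::-1][:n]
        return self.mz[idx]


@dataclass
class SpectrumPair:
    low: Ms2Spectrum
    high: Ms2Spectrum

    @property
    def precursor_neutral_mass(self) -> float:
        return self.low.precursor_neutral_mass

    @property
    def pair_id(self) -> str:
        return f"{self.low.scan_id}/{self.high.scan_id}"


# ---------------------------------------------------------------------------
# Run I/O


def write_run_json(spectra: list[Ms2Spectrum], path) -> None:
    payload = {
        "format": "glycosite-run/1",
        "spectra": [
            {
                "scan_id": s.scan_id,
                "precursor_mz": s.precursor_mz,
                "precursor_charge": s.precursor_charge,
                "energy": s.energy,
                "rt": s.rt,
                "mz": [float(x) for x in s.mz],
                "intensity": [float(x) for x in s.intensity],
            }
            for s in spectra
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _read_run_json(path) -> list[Ms2Spectrum]:
    with open(path) as fh:
        payload = json.load(fh)
    spectra = []
    for rec in payload["spectra"]:
        spectra.append(
            Ms2Spectrum(
                scan_id=int(rec["scan_id"]),
                precursor_mz=float(rec["precursor_mz"]),
                precursor_charge=int(rec["precursor_charge"]),
                energy=rec["energy"],
                mz=np.array(rec["mz"], dtype=float),
                intensity=np.array(rec["intensity"], dtype=float),
                rt=float(rec.get("rt", 0.0)),
            )
        )
    spectra.sort(key=lambda s: s.scan_id)
    return spectra


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(arr)}d", *arr)).decode()


def write_run_mzml(spectra: list[Ms2Spectrum], path, low_energy=20.0, high_energy=37.0) -> None:
    """Minimal mzML serializer (uncompressed 64-bit float arrays)."""
    E = etree.Element
    root = E("mzML", nsmap={None: _MZML_NS}, version="1.1.0")
    run = etree.SubElement(root, "run", id="run")
    slist = etree.SubElement(run, "spectrumList", count=str(len(spectra)))

    def cv(parent, accession, name, value="", unit=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
        if unit:
            attrs["unitName"] = unit
        etree.SubElement(parent, "cvParam", **attrs)

    for i, s in enumerate(spectra):
        sp = etree.SubElement(
            slist,
            "spectrum",
            index=str(i),
            id=f"scan={s.scan_id}",
            defaultArrayLength=str(len(s.mz)),
        )
        cv(sp, "MS:1000511", "ms level", "2")
        cv(sp, "MS:1000580", "MSn spectrum")
        scan_list = etree.SubElement(sp, "scanList", count="1")
        scan = etree.SubElement(scan_list, "scan")
        cv(scan, "MS:1000016", "scan start time", repr(s.rt), unit="second")
        plist = etree.SubElement(sp, "precursorList", count="1")
        prec = etree.SubElement(plist, "precursor")
        silist = etree.SubElement(prec, "selectedIonList", count="1")
        si = etree.SubElement(silist, "selectedIon")
        cv(si, "MS:1000744", "selected ion m/z", repr(s.precursor_mz), unit="m/z")
        cv(si, "MS:1000041", "charge state", str(s.precursor_charge))
        act = etree.SubElement(prec, "activation")
        cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        energy = low_energy if s.energy == "low" else high_energy
        cv(act, "MS:1000045", "collision energy", repr(energy), unit="electronvolt")
        balist = etree.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name in (
            (s.mz, "MS:1000514", "m/z array"),
            (s.intensity, "MS:1000515", "intensity array"),
        ):
            encoded = _b64(arr)
            ba = etree.SubElement(balist, "binaryDataArray", encodedLength=str(len(encoded)))
            cv(ba, "MS:1000523", "64-bit float")
            cv(ba, "MS:1000576", "no compression")
            cv(ba, acc, name)
            etree.SubElement(ba, "binary").text = encoded
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def _decode_binary(ba_element) -> np.ndarray:
    accessions = {
        cv.get("accession") for cv in ba_element.findall(f"{{{_MZML_NS}}}cvParam")
    }
    text = ba_element.findtext(f"{{{_MZML_NS}}}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_run_mzml(path, low_energy_max: float = 30.0) -> list[Ms2Spectrum]:
    """mzML reader (lxml) for the PSI-MS cvParam subset this package writes."""
    ns = f"{{{_MZML_NS}}}"
    spectra = []
    for _, sp in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        params = {
            cv.get("accession"): cv
            for cv in sp.iterfind(f".//{ns}cvParam")
        }
        level = params.get("MS:1000511")
        if level is not None and int(level.get("value")) != 2:
            sp.clear()
            continue
        ion = sp.find(f".//{ns}selectedIon")
        if ion is None:
            logger.warning("scan %s: missing precursor info, skipped", sp.get("id"))
            sp.clear()
            continue
        ion_params = {cv.get("accession"): cv for cv in ion.findall(f"{ns}cvParam")}
        if "MS:1000744" not in ion_params:
            logger.warning("scan %s: missing precursor m/z, skipped", sp.get("id"))
            sp.clear()
            continue
        pmz = float(ion_params["MS:1000744"].get("value"))
        charge = int(ion_params.get("MS:1000041").get("value")) if "MS:1000041" in ion_params else 0
        energy = ""
        if "MS:1000045" in params:
            energy = "low" if float(params["MS:1000045"].get("value")) <= low_energy_max else "high"
        rt = 0.0
        if "MS:1000016" in params:
            cv = params["MS:1000016"]
            rt = float(cv.get("value"))
            if cv.get("unitName") == "minute":
                rt *= 60.0
        mz_arr = intensity_arr = np.array([])
        for ba in sp.iterfind(f".//{ns}binaryDataArray"):
            acc = {c.get("accession") for c in ba.findall(f"{ns}cvParam")}
            if "MS:1000514" in acc:
                mz_arr = _decode_binary(ba)
            elif "MS:1000515" in acc:
                intensity_arr = _decode_binary(ba)
        scan_id = int(str(sp.get("id")).rsplit("=", 1)[-1])
        spectra.append(
            Ms2Spectrum(
                scan_id=scan_id,
                precursor_mz=pmz,
                precursor_charge=charge,
                energy=energy,
                mz=mz_arr,
                intensity=intensity_arr,
                rt=rt,
            )
        )
        sp.clear()
    spectra.sort(key=lambda s: s.scan_id)
    untagged = [s for s in spectra if not s.energy]
    if untagged:
        # alternating-scan fallback: odd scans low, even scans high
        for s in untagged:
            s.energy = "low" if s.scan_id % 2 == 1 else "high"
        logger.warning(
            "%d scans lacked collision-energy metadata; energy tags assigned "
            "by alternating-scan heuristic",
            len(untagged),
        )
    return spectra


def read_run(path, fmt: str | None = None) -> list[Ms2Spectrum]:
    """Read all MS2 scans of a run; format inferred from the extension."""
    p = str(path)
    if fmt is None:
        fmt = "mzml" if p.lower().endswith(("mzml", ".mzml.xml")) else "json"
    if fmt.lower() == "mzml":
        return _read_run_mzml(path)
    return _read_run_json(path)


def write_run(spectra: list[Ms2Spectrum], path, fmt: str | None = None) -> None:
    p = str(path)
    if fmt is None:
        fmt = "mzml" if p.lower().endswith("mzml") else "json"
    if fmt.lower() == "mzml":
        write_run_mzml(spectra, path)
    else:
        write_run_json(spectra, path)


# ---------------------------------------------------------------------------
# Pairing, screening, reporters


def pair_spectra(run: list[Ms2Spectrum], ppm: float = 10.0) -> list[SpectrumPair]:
    """Pair each low-energy scan with the nearest-in-time unused high-energy
    scan of equal charge whose precursor m/z agrees within ``ppm``."""
    lows = [s for s in run if s.energy == "low"]
    highs = [s for s in run if s.energy == "high"]
    used: set[int] = set()
    pairs = []
    for lo in lows:
        best = None
        for hi in highs:
            if hi.scan_id in used or hi.precursor_charge != lo.precursor_charge:
                continue
            if abs(hi.precursor_mz - lo.precursor_mz) / lo.precursor_mz * 1e6 > ppm:
                continue
            key = (abs(hi.rt - lo.rt), abs(hi.scan_id - lo.scan_id), hi.scan_id)
            if best is None or key < best[0]:
                best = (key, hi)
        if best is not None:
            used.add(best[1].scan_id)
            pairs.append(SpectrumPair(low=lo, high=best[1]))
    dropped = len(lows) - len(pairs) + len(highs) - len(pairs)
    if dropped:
        logger.info("pair_spectra: %d unpaired scans dropped", dropped)
    return pairs


def oxonium_screen(
    spectrum: Ms2Spectrum,
    min_matches: int = 2,
    top_n: int = 10,
    tol_ppm: float = 20.0,
    oxonium_mz: tuple[float, ...] = DEFAULT_OXONIUM_MZ,
) -> tuple[bool, list[float]]:
    """Require >= min_matches oxonium ions among the top_n most intense peaks."""
    top = spectrum.top_n_mz(top_n)
    matched = []
    for ref in oxonium_mz:
        if len(top) and np.min(np.abs(top - ref)) / ref * 1e6 <= tol_ppm:
            matched.append(ref)
    return len(matched) >= min_matches, matched


@dataclass
class ReporterVector:
    """Per-channel reporter intensities; a missing channel is absent (not 0)."""

    intensities: dict[str, float] = field(default_factory=dict)

    def get(self, channel: str) -> float | None:
        return self.intensities.get(channel)

    def __contains__(self, channel: str) -> bool:
        return channel in self.intensities


def extract_reporters(
    spectrum: Ms2Spectrum,
    channels: tuple[str, ...] = STUDY_CHANNELS,
    tol_mz: float = 0.003,
) -> ReporterVector:
    """Most intense peak within +/- tol of each channel's reporter m/z."""
    out = {}
    for ch in channels:
        ref = TMT10_REPORTER_MZ[ch]
        lo = np.searchsorted(spectrum.mz, ref - tol_mz, side="left")
        hi = np.searchsorted(spectrum.mz, ref + tol_mz, side="right")
        if hi > lo:
            out[ch] = float(np.max(spectrum.intensity[lo:hi]))
    return ReporterVector(out)
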