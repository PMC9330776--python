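"""Spectrum container and file I/O (MGF, mzML, annotation tables).

A :class:`Spectrum` is one picked feature's MS/MS record.  Intensities are
kept raw and exposed base-peak normalised (max = 100), which is the scale the
diagnostic-ion logic reasons on; relative abundance is all that negative-mode
phenolic annotation needs.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "ANNOTATION_COLUMNS",
    "write_annotations",
    "read_annotations",
]


@dataclass(frozen=True)
class Spectrum:
    """One feature's MS/MS record (negative mode, charge -1 by default)."""

    feature_id: str
    precursor_mz: float
    retention_time: float = 0.0  # minutes
    charge: int = -1
    mz: tuple[float, ...] = field(default=())
    intensity: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity lengths differ")
        if any(i < 0 for i in self.intensity):
            raise ValueError("negative intensity")
        order = sorted(range(len(self.mz)), key=lambda k: self.mz[k])
        object.__setattr__(self, "mz", tuple(self.mz[k] for k in order))
        object.__setattr__(self, "intensity", tuple(self.intensity[k] for k in order))

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    @property
    def is_empty(self) -> bool:
        return not self.mz

    def normalized(self) -> "Spectrum":
        """Copy with the base peak scaled to 100."""
        if not self.mz:
            return self
        top = max(self.intensity)
        if top == 0:
            return self
        return replace(self, intensity=tuple(100.0 * i / top for i in self.intensity))

    def base_peak(self) -> float:
        """m/z of the most intense fragment."""
        if not self.mz:
            raise ValueError("empty spectrum has no base peak")
        return self.mz[int(np.argmax(self.intensity))]

    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz, self.intensity))


def _coerce_rt_minutes(params: dict) -> float:
    rt = params.get("rtinseconds")
    if rt is None:
        return float(params.get("rtinminutes", 0.0))
    return float(rt) / 60.0


def read_mgf(path) -> list[Spectrum]:
    """Read a Mascot generic format file: one Spectrum per BEGIN/END IONS block.

    RT is converted from RTINSECONDS to minutes.  A malformed block raises a
    ``ValueError`` naming the block index.
    """
    out: list[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, entry in enumerate(reader):
            try:
                params = entry["params"]
                pepmass = params["pepmass"][0]
                charge = params.get("charge")
                charge = int(charge[0]) if charge else -1
                spec = Spectrum(
                    feature_id=str(params.get("title", f"scan_{idx}")),
                    precursor_mz=float(pepmass),
                    retention_time=_coerce_rt_minutes(params),
                    charge=charge,
                    mz=tuple(float(x) for x in entry["m/z array"]),
                    intensity=tuple(float(x) for x in entry["intensity array"]),
                )
            except (KeyError, TypeError, ValueError, IndexError) as e:
                raise ValueError(f"malformed MGF block {idx}: {e}") from e
            out.append(spec)
    return out


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Write spectra as MGF; float m/z kept to 6 decimals (round-trip safe)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": np.asarray(s.mz, dtype=float),
                "intensity array": np.asarray(s.intensity, dtype=float),
                "params": {
                    "title": s.feature_id,
                    "pepmass": (round(s.precursor_mz, 6), None),
                    "rtinseconds": round(s.retention_time * 60.0, 4),
                    "charge": s.charge,
                },
            }
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh, key_order=("title", "pepmass", "rtinseconds", "charge"))


def _decode_binary_array(array_el) -> np.ndarray:
    accessions = {cv.get("accession") for cv in array_el.iter()
                  if cv.tag.endswith("cvParam")}
    data = b""
    for child in array_el.iter():
        if child.tag.endswith("binary") and child.text:
            data = base64.b64decode(child.text)
    if "MS:1000574" in accessions:  # zlib compression
        data = zlib.decompress(data)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(data, dtype=dtype)


def read_mzml(path) -> list[Spectrum]:
    """Read centroided MS2 scans from an mzML file (MS1 scans are skipped).

    Minimal, namespace-agnostic reader for MSConvert-style centroid files:
    64/32-bit float arrays, plain or zlib-compressed.
    """
    out: list[Spectrum] = []
    tree = etree.parse(str(path))
    spectra = [el for el in tree.iter() if el.tag.endswith("}spectrum")
               or el.tag == "spectrum"]
    for idx, sp in enumerate(spectra):
        try:
            cv = {c.get("accession"): c for c in sp.iter()
                  if c.tag.endswith("cvParam")}
            if cv.get("MS:1000511") is None or cv["MS:1000511"].get("value") != "2":
                continue
            ion = cv.get("MS:1000744")
            if ion is None:
                raise KeyError("no selected ion m/z")
            pmz = float(ion.get("value"))
            charge_el = cv.get("MS:1000041")
            charge = -abs(int(charge_el.get("value"))) if charge_el is not None else -1
            rt = 0.0
            rt_el = cv.get("MS:1000016")
            if rt_el is not None:
                rt = float(rt_el.get("value"))
                if rt_el.get("unitName") == "second":
                    rt /= 60.0
            mz_arr = np.array([])
            int_arr = np.array([])
            for arr in sp.iter():
                if not (arr.tag.endswith("binaryDataArray")):
                    continue
                acc = {c.get("accession") for c in arr.iter()
                       if c.tag.endswith("cvParam")}
                if "MS:1000514" in acc:
                    mz_arr = _decode_binary_array(arr)
                elif "MS:1000515" in acc:
                    int_arr = _decode_binary_array(arr)
            spec = Spectrum(
                feature_id=str(sp.get("id", f"scan_{idx}")),
                precursor_mz=pmz,
                retention_time=rt,
                charge=charge,
                mz=tuple(float(x) for x in mz_arr),
                intensity=tuple(float(x) for x in int_arr),
            )
        except (KeyError, TypeError, ValueError, IndexError) as e:
            raise ValueError(f"malformed mzML spectrum {idx}: {e}") from e
        out.append(spec)
    return out


#: Stable column order of the annotation table (TSV).
ANNOTATION_COLUMNS = [
    "feature_id",
    "retention_time",
    "precursor_mz",
    "formula",
    "ppm_error",
    "compound_class",
    "aglycone",
    "glycosylation",
    "galloyl_count",
    "tannin_groups",
    "moieties",
    "candidates",
    "evidence",
]


def write_annotations(table: pd.DataFrame, path) -> None:
    """Write an annotation table as UTF-8 TSV with a stable column order."""
    df = table.copy()
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[ANNOTATION_COLUMNS]
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8", keep_default_na=False,
                     comment="#")
    for col in ("retention_time", "precursor_mz", "ppm_error"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["galloyl_count"] = pd.to_numeric(df["galloyl_count"], errors="coerce").astype("Int64")
    return df
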