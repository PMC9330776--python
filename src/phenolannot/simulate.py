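"""Synthetic negative-mode MS/MS spectra with known ground truth.

Emulates what a QToF acquisition hands the annotation pipeline after feature
picking: deprotonated phenolic spectra built from the library's fragment
templates (exact theoretical m/z), perturbed by Gaussian m/z jitter at the
few-ppm scale, base-peak-normalised intensities, a Poisson number of random
noise peaks, and decoy features with random peak lists and CHO-plausible
precursors.  A fixed seed makes the output byte-for-byte reproducible.

It does not emulate chromatographic peak shape, MS1 isotope structure,
co-elution chimeras or detector saturation, so recovery rates measured on
these spectra bound the rule engine's behaviour, not instrument artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import deprotonated_mz, rdbe, Formula
from .library import LibraryEntry, load_library, resolve_fragments
from .spectra import Spectrum, write_mgf

__all__ = ["SimulationConfig", "spectrum_from_library", "make_decoy",
           "generate_spectra", "generate_dataset", "fixture_spectra"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the acquisition the pipeline targets: m/z 100-1200
    negative mode, few-ppm mass accuracy, a few spurious peaks per spectrum.
    """

    seed: int = 0
    n_spectra: int = 200
    decoy_fraction: float = 0.2
    jitter_ppm: float = 5.0          # Gaussian sd of the m/z error
    noise_mean: float = 3.0          # Poisson mean of noise-peak count
    noise_max_intensity: float = 30.0
    intensity_low: float = 5.0       # non-base peaks: log-uniform in
    intensity_high: float = 80.0     # [intensity_low, intensity_high]
    rt_range: tuple[float, float] = (1.0, 20.0)  # decoy RT, minutes
    mz_range: tuple[float, float] = (100.0, 1200.0)
    noise_exclusion: float = 0.05    # keep noise this far from true peaks


def _jitter(rng: np.random.Generator, mz: float, ppm_sd: float) -> float:
    if ppm_sd <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm_sd) * 1e-6)


def spectrum_from_library(entry: LibraryEntry, cfg: SimulationConfig,
                          rng: np.random.Generator | None = None,
                          feature_id: str | None = None) -> Spectrum:
    """One simulated spectrum from a library template.

    Precursor and fragments sit at theoretical m/z plus ppm jitter; the
    template's base peak gets intensity 100, the rest are log-uniform in
    [intensity_low, intensity_high]; noise peaks avoid the exclusion window
    around true peaks.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    resolved = resolve_fragments(entry)
    mzs: list[float] = []
    ints: list[float] = []
    for f in resolved:
        mzs.append(_jitter(rng, f.mz, cfg.jitter_ppm))
        if f.is_base_peak:
            ints.append(100.0)
        else:
            ints.append(float(np.exp(rng.uniform(np.log(cfg.intensity_low),
                                                 np.log(cfg.intensity_high)))))
    precursor = _jitter(rng, entry.mz_theoretical, cfg.jitter_ppm)
    n_noise = int(rng.poisson(cfg.noise_mean))
    lo = cfg.mz_range[0]
    for _ in range(n_noise):
        for _attempt in range(50):
            mz = float(rng.uniform(lo, max(precursor, lo + 1.0)))
            if all(abs(mz - t) > cfg.noise_exclusion for t in mzs):
                mzs.append(mz)
                ints.append(float(rng.uniform(1.0, cfg.noise_max_intensity)))
                break
    return Spectrum(
        feature_id=feature_id or f"lib_{entry.peak}",
        precursor_mz=precursor,
        retention_time=entry.rt,
        charge=-1,
        mz=tuple(mzs),
        intensity=tuple(ints),
    )


def make_decoy(cfg: SimulationConfig, rng: np.random.Generator,
               feature_id: str) -> Spectrum:
    """A decoy feature: CHO-plausible precursor, random peak list."""
    while True:
        c = int(rng.integers(7, 41))
        o = int(rng.integers(2, min(c, 28) + 1))
        h = int(rng.integers(2, 2 * c + 3))
        f = Formula.from_dict({"C": c, "H": h, "O": o})
        if rdbe(f) < 0:
            continue
        precursor = deprotonated_mz(f)
        if cfg.mz_range[0] + 50 < precursor < cfg.mz_range[1]:
            break
    n_peaks = int(rng.integers(5, 16))
    mzs = sorted(float(rng.uniform(cfg.mz_range[0], precursor - 20.0))
                 for _ in range(n_peaks))
    ints = [float(rng.uniform(5.0, 100.0)) for _ in range(n_peaks)]
    ints[int(rng.integers(0, n_peaks))] = 100.0
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=precursor,
        retention_time=float(rng.uniform(*cfg.rt_range)),
        charge=-1,
        mz=tuple(mzs),
        intensity=tuple(ints),
    )


def generate_spectra(cfg: SimulationConfig,
                     library: list[LibraryEntry] | None = None
                     ) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate ``cfg.n_spectra`` features and their ground-truth table."""
    if library is None:
        library = load_library()
    rng = np.random.default_rng(cfg.seed)
    spectra: list[Spectrum] = []
    rows = []
    for i in range(cfg.n_spectra):
        fid = f"sim_{i:04d}"
        if rng.uniform() < cfg.decoy_fraction:
            spectra.append(make_decoy(cfg, rng, fid))
            rows.append({"feature_id": fid, "kind": "decoy", "peak": -1,
                         "name": "", "compound_class": "unknown"})
        else:
            entry = library[int(rng.integers(0, len(library)))]
            spectra.append(spectrum_from_library(entry, cfg, rng, fid))
            rows.append({"feature_id": fid, "kind": "library", "peak": entry.peak,
                         "name": entry.name, "compound_class": entry.compound_class})
    return spectra, pd.DataFrame(rows)


def generate_dataset(cfg: SimulationConfig, mgf_path, truth_path,
                     library: list[LibraryEntry] | None = None) -> int:
    """Write a simulated MGF plus its truth table TSV; returns n spectra."""
    spectra, truth = generate_spectra(cfg, library)
    write_mgf(spectra, mgf_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    return len(spectra)


def fixture_spectra(library: list[LibraryEntry] | None = None) -> list[Spectrum]:
    """The 44 library entries as noiseless spectra at exact theoretical m/z.

    The base peak gets intensity 100 and the remaining fragments a
    deterministic decaying series, so classification (which is intensity
    scale-free apart from the radical/neutral ratio) is reproducible.
    """
    if library is None:
        library = load_library()
    out = []
    for entry in library:
        resolved = resolve_fragments(entry)
        ints = [100.0 if f.is_base_peak else 80.0 * 0.9 ** i
                for i, f in enumerate(resolved)]
        out.append(Spectrum(
            feature_id=f"lib_{entry.peak}",
            precursor_mz=entry.mz_theoretical,
            retention_time=entry.rt,
            charge=-1,
            mz=tuple(f.mz for f in resolved),
            intensity=tuple(ints),
        ))
    return out
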