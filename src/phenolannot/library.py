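"""Internal compound library and nominal-to-exact fragment resolution.

The library encodes 44 phenolics characterised in a *Margaritaria nobilis*
leaf extract: retention time, experimental ``[M-H]-`` m/z, neutral molecular
formula, the characteristic MS2 product ions (printed at nominal mass, the
most intense one flagged), putative name and compound class.

Published fragment lists give nominal (integer) m/z.  To build realistic
fixture spectra, and to do 0.02 Da containment matching, each nominal
fragment is resolved to its exact theoretical m/z by searching bounded chains
of catalogued losses from the theoretical deprotonated precursor (class-
specific loss vocabulary, depth <= 5), falling back to diagnostic product
anions and their short H2O/CO/CO2 cascades.  A handful of positions where
two chemically distinct chains collide on the same nominal mass carry
explicit overrides following the compound's fragmentation proposal.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .chem import Formula, deprotonated_mz, monoisotopic_mass, parse_formula
from .rules import LossRule, default_catalogue

__all__ = ["LibraryEntry", "ResolvedFragment", "load_library", "resolve_fragments"]


@dataclass(frozen=True)
class ResolvedFragment:
    nominal: int
    mz: float
    is_base_peak: bool
    resolved: bool  # False -> no chain/diagnostic explains it; nominal used


@dataclass(frozen=True)
class LibraryEntry:
    peak: int
    rt: float  # minutes
    mz_exp: float
    ppm_printed: float
    formula: Formula
    formula_printed: str
    fragments: tuple[int, ...]  # nominal, as printed
    base_peak: int
    name: str
    compound_class: str

    @property
    def mz_theoretical(self) -> float:
        return deprotonated_mz(self.formula)

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


# class-specific loss vocabularies used by the resolver (rule names)
_VOCAB: dict[str, tuple[str, ...]] = {
    "phenolic": (
        "water", "carbon_monoxide", "carbon_dioxide", "methyl_radical",
        "ethyl_radical", "ethene", "ketene", "methanol",
        "coumaric_acid", "coumaroyl", "ferulic_acid", "feruloyl",
        "pentose", "pentosyl_radical", "deoxyhexose", "deoxyhexosyl_radical",
        "hexose", "hexosyl_radical",
    ),
    "flavonoid": (
        "water", "carbon_monoxide", "carbon_dioxide", "ketene",
        "formaldehyde", "formic_acid", "glyoxal",
        "pentose", "pentosyl_radical", "deoxyhexose", "deoxyhexosyl_radical",
        "hexose", "hexosyl_radical",
        "rhamnosyl_xyloside", "rhamnosyl_xylosyl_radical",
        "xylosyl_glucoside", "xylosyl_glucosyl_radical",
        "rhamnosyl_glucoside", "rhamnosyl_glucosyl_radical",
        "glucosyl_glucoside", "glucosyl_glucosyl_radical",
    ),
    "tannin": (
        "water", "carbon_monoxide", "carbon_dioxide", "ketene", "methanol",
        "propenone", "galloyl", "gallic_acid", "hhdp", "dhhdp_residue",
        "chebuloyl_residue", "phyllanthusiin_residue",
        "phyllanthusiin_residue_dehydro", "methylchebulate_residue",
        "galloyl_methylacetate", "hexose", "pentose", "deoxyhexose",
        "cinnamic_acid", "cinnamoyl",
    ),
}

_DIAG_ROOTS: dict[str, tuple[str, ...]] = {
    "phenolic": (
        "gallate_anion", "gallate_decarboxylated", "coumarate_anion",
        "coumarate_decarboxylated", "galactarate_anion",
        "galactarate_dehydrated", "ellagate_anion", "ellagate_radical_anion",
        "methylellagate_anion", "dimethylellagate_radical_anion",
        "methylellagate_core_anion", "ellagate_core_anion",
    ),
    "flavonoid": (
        "quercetin_anion", "quercetin_radical_anion", "kaempferol_anion",
        "kaempferol_radical_anion", "methylquercetin_anion",
        "methylquercetin_radical_anion", "flavonoid_151", "flavonoid_179",
        "flavonoid_227", "flavonoid_243", "flavonoid_255", "flavonoid_271",
        "flavonoid_273", "flavonoid_121", "flavonoid_107",
    ),
    "tannin": (
        "gallate_anion", "gallate_decarboxylated", "galloylglycoside_rda",
        "urolithin_anion", "ellagate_anion", "phyllanthusiin_anion",
        "methylchebulate_anion", "chebulate_dehydrated_anion",
        "chebulate_didehydrated_anion", "chebulate_decarboxylated_anion",
        "ellagitannin_249", "ellagitannin_247",
    ),
}

_CLASS_TO_VOCAB = {
    "phenolic_acid_derivative": "phenolic",
    "flavonoid_O_glycoside": "flavonoid",
    "gallotannin": "tannin",
    "ellagitannin": "tannin",
}

# (peak, nominal fragment) -> anion composition; positions where distinct
# loss chains collide on the same printed nominal mass and the compound's
# fragmentation proposal dictates which product is meant.
_OVERRIDES: dict[tuple[int, int], str] = {
    (2, 313): "C13H13O9",   # coumaroylgalactarate - ketene
    (2, 129): "C5H5O4",     # galactarate - coumaroyl - H2O - CO2 - H2O
    (5, 763): "C34H19O21",  # - gallic acid - H2O
    (5, 443): "C20H11O12",  # - gallic acid - HHDP - 2 H2O
    (7, 481): "C20H17O14",  # chebuloyl-removed core - galloyl
    (7, 765): "C34H21O21",  # - gallic acid - 2 H2O
    (17, 481): "C20H17O14",
    (17, 765): "C34H21O21",
    (18, 201): "C11H5O4",   # ellagate - 2 CO - CO2
    (18, 185): "C11H5O3",   # ellagate - CO - 2 CO2
    (18, 173): "C10H5O3",   # ellagate - 3 CO - CO2
    (27, 285): "C14H5O7",   # dimethylellagic radical anion - CH3. - CO
    (27, 270): "C13H2O7",   # fully demethylated core - CO
    (38, 465): "C20H17O13", # - HHDP - gallic acid (digalloyl-glucose anion)
    (43, 445): "C20H13O12", # - cinnamic - gallic - H2O (HHDP-glucose - H2O)
    (44, 257): "C13H5O6",   # trimethylellagic - 2 CH3. - 2 CO
    (44, 242): "C12H2O6",   # ... - CH3. once more
}

_MAX_DEPTH = 5
_DIAG_DEPTH = 2
_MIN_MZ = 90.0
_WINDOW = 0.4  # how far an exact candidate may sit from the printed nominal


def _expand(roots: list[tuple[float, int]], losses: list[LossRule],
            max_depth: int, floor: float) -> dict[float, int]:
    """BFS over loss chains; returns {mass rounded to 1e-4: min depth}."""
    seen: dict[float, int] = {}
    frontier = list(roots)
    for m, d in frontier:
        key = round(m, 4)
        if key not in seen or d < seen[key]:
            seen[key] = d
    while frontier:
        nxt: list[tuple[float, int]] = []
        for m, d in frontier:
            if d >= max_depth:
                continue
            for rule in losses:
                child = m - rule.mass
                if child < floor:
                    continue
                key = round(child, 4)
                if key in seen and seen[key] <= d + 1:
                    continue
                seen[key] = d + 1
                nxt.append((child, d + 1))
        frontier = nxt
    return seen


def resolve_fragments(entry: LibraryEntry,
                      catalogue: list[LossRule] | None = None) -> tuple[ResolvedFragment, ...]:
    """Assign exact theoretical m/z to each printed nominal fragment."""
    if catalogue is None:
        catalogue = default_catalogue()
    byname = {r.name: r for r in catalogue}
    vocab_key = _CLASS_TO_VOCAB[entry.compound_class]
    losses = [byname[n] for n in _VOCAB[vocab_key] if n in byname]
    diag = [byname[n] for n in _DIAG_ROOTS[vocab_key] if n in byname]
    small = [byname[n] for n in ("water", "carbon_monoxide", "carbon_dioxide")]

    reach = _expand([(entry.mz_theoretical, 0)], losses, _MAX_DEPTH, _MIN_MZ)
    diag_reach = _expand([(r.mass, 0) for r in diag], small, _DIAG_DEPTH, _MIN_MZ)
    for m, d in diag_reach.items():
        if m not in reach or d < reach[m]:
            reach[m] = d

    out: list[ResolvedFragment] = []
    for nominal in entry.fragments:
        key = (entry.peak, nominal)
        if key in _OVERRIDES:
            mz = monoisotopic_mass(parse_formula(_OVERRIDES[key]))
            out.append(ResolvedFragment(nominal, mz, nominal == entry.base_peak, True))
            continue
        cands = [(d, abs(m - nominal), m) for m, d in reach.items()
                 if abs(m - nominal) <= _WINDOW]
        if cands:
            cands.sort()
            mz = cands[0][2]
            out.append(ResolvedFragment(nominal, mz, nominal == entry.base_peak, True))
        else:
            out.append(ResolvedFragment(nominal, float(nominal),
                                        nominal == entry.base_peak, False))
    return tuple(out)


def _library_path():
    return resources.files("phenolannot") / "data" / "library.tsv"


def load_library(path=None) -> list[LibraryEntry]:
    """Load the internal 44-compound library (or a user TSV of same layout)."""
    df = pd.read_csv(path if path is not None else _library_path(),
                     sep="\t", keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            LibraryEntry(
                peak=int(row.peak),
                rt=float(row.rt),
                mz_exp=float(row.mz),
                ppm_printed=float(row.ppm_printed),
                formula=parse_formula(row.formula),
                formula_printed=str(row.formula_printed),
                fragments=tuple(int(x) for x in str(row.fragments).split(";") if x),
                base_peak=int(row.base_peak),
                name=str(row.name),
                compound_class=str(row.compound_class),
            )
        )
    if not entries:
        raise ValueError("empty library")
    return entries
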