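"""Diagnostic neutral-loss / fragment catalogue and loss detection.

Negative-mode phenolic MS/MS is read through a catalogue of exact-mass rules:

* ``neutral_loss`` — an even-electron neutral ejected between a parent and a
  child ion (CO2, H2O, sugars, galloyl, gallic acid, the 302 Da
  hexahydroxydiphenoyl (HHDP) unit, ...).
* ``radical_loss`` — a homolytic cleavage ejecting an odd-electron species
  (methyl radical, glycosyl radicals); the child is a radical anion.
* ``diagnostic_fragment`` — an absolute product-ion m/z whose presence is
  class evidence by itself (gallate 169, ellagate 301, urolithin 275,
  chebuloyl-derived 337/319/293, flavonoid aglycone anions, ...).

Each rule carries an ``evidence`` tag consumed by the classifier.  The
catalogue ships as a versioned TSV and is user-extensible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .chem import Formula, monoisotopic_mass, parse_formula

__all__ = [
    "LossRule",
    "LossMatch",
    "default_catalogue",
    "read_catalogue",
    "write_catalogue",
    "detect_losses",
    "loss_signature",
    "FRAGMENT_TOL",
]

#: Fragment-ion tolerance in Da (the value used for network construction too).
FRAGMENT_TOL = 0.02


@dataclass(frozen=True)
class LossRule:
    """One diagnostic loss or fragment with exact mass and class evidence."""

    name: str
    mass: float
    kind: str  # neutral_loss | radical_loss | diagnostic_fragment
    evidence: str
    formula: Formula | None = None
    tol: float | None = None  # per-rule tolerance override (nominal-mass rules)

    def __post_init__(self) -> None:
        if self.kind not in ("neutral_loss", "radical_loss", "diagnostic_fragment"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.mass <= 0:
            raise ValueError("rule mass must be positive")


@dataclass(frozen=True)
class LossMatch:
    """A detected rule instance: a mass delta or an absolute fragment hit."""

    rule: LossRule
    parent_mz: float | None
    child_mz: float
    delta: float
    error: float
    tier: str  # precursor | fragment | diagnostic


# name, formula (None for nominal-mass rules), kind, evidence, per-rule tol
_CATALOGUE_SPEC: list[tuple[str, str | None, str, str, float | None]] = [
    # --- small neutral losses -------------------------------------------
    ("water", "H2O", "neutral_loss", "generic", None),
    ("carbon_monoxide", "CO", "neutral_loss", "generic", None),
    ("carbon_dioxide", "CO2", "neutral_loss", "carboxyl", None),
    ("ketene", "C2H2O", "neutral_loss", "generic", None),
    ("formaldehyde", "CH2O", "neutral_loss", "generic", None),
    ("formic_acid", "CH2O2", "neutral_loss", "generic", None),
    ("glyoxal", "C2H2O2", "neutral_loss", "generic", None),
    ("methanol", "CH4O", "neutral_loss", "generic", None),
    ("ethene", "C2H4", "neutral_loss", "generic", None),
    ("propenone", "C3H2O", "neutral_loss", "dhhdp_cascade", None),
    # --- radical losses -------------------------------------------------
    ("methyl_radical", "CH3", "radical_loss", "methyl", None),
    ("ethyl_radical", "C2H5", "radical_loss", "methyl", None),
    # --- hydroxycinnamoyl / phenolic acyl -------------------------------
    ("coumaric_acid", "C9H8O3", "neutral_loss", "coumaroyl", None),
    ("coumaroyl", "C9H6O2", "neutral_loss", "coumaroyl", None),
    ("ferulic_acid", "C10H10O4", "neutral_loss", "feruloyl", None),
    ("feruloyl", "C10H8O3", "neutral_loss", "feruloyl", None),
    ("cinnamic_acid", "C9H8O2", "neutral_loss", "cinnamoyl", None),
    ("cinnamoyl", "C9H6O", "neutral_loss", "cinnamoyl", None),
    # --- glycoside losses (heterolytic: neutral sugar; homolytic: radical)
    ("pentose", "C5H8O4", "neutral_loss", "sugar:pentose", None),
    ("pentosyl_radical", "C5H9O4", "radical_loss", "sugar:pentose:radical", None),
    ("deoxyhexose", "C6H10O4", "neutral_loss", "sugar:deoxyhexose", None),
    ("deoxyhexosyl_radical", "C6H11O4", "radical_loss", "sugar:deoxyhexose:radical", None),
    ("hexose", "C6H10O5", "neutral_loss", "sugar:hexose", None),
    ("hexosyl_radical", "C6H11O5", "radical_loss", "sugar:hexose:radical", None),
    ("rhamnosyl_xyloside", "C11H18O8", "neutral_loss", "sugar:rhamnosyl-xyloside", None),
    ("rhamnosyl_xylosyl_radical", "C11H19O8", "radical_loss", "sugar:rhamnosyl-xyloside:radical", None),
    ("xylosyl_glucoside", "C11H18O9", "neutral_loss", "sugar:xylosyl-glucoside", None),
    ("xylosyl_glucosyl_radical", "C11H19O9", "radical_loss", "sugar:xylosyl-glucoside:radical", None),
    ("rhamnosyl_glucoside", "C12H20O9", "neutral_loss", "sugar:rhamnosyl-glucoside", None),
    ("rhamnosyl_glucosyl_radical", "C12H21O9", "radical_loss", "sugar:rhamnosyl-glucoside:radical", None),
    ("glucosyl_glucoside", "C12H20O10", "neutral_loss", "sugar:glucosyl-glucoside", None),
    ("glucosyl_glucosyl_radical", "C12H21O10", "radical_loss", "sugar:glucosyl-glucoside:radical", None),
    # --- hydrolysable tannin building blocks ----------------------------
    ("galloyl", "C7H4O4", "neutral_loss", "galloyl", None),
    ("gallic_acid", "C7H6O5", "neutral_loss", "galloyl", None),
    ("hhdp", "C14H6O8", "neutral_loss", "HHDP", None),
    ("dhhdp_residue", "C14H6O9", "neutral_loss", "DHHDP", None),
    ("chebuloyl_residue", "C14H8O9", "neutral_loss", "Che", None),
    ("phyllanthusiin_residue", "C13H10O9", "neutral_loss", "oxidized_congener", None),
    ("phyllanthusiin_residue_dehydro", "C13H8O9", "neutral_loss", "oxidized_congener", None),
    ("methylchebulate_residue", "C15H12O10", "neutral_loss", "oxidized_congener", None),
    # composition of the 242 Da loss is not established; nominal-mass rule
    ("galloyl_methylacetate", None, "neutral_loss", "galloyl_methylacetate", 0.05),
    # --- diagnostic product anions (formulas are anion compositions) -----
    ("gallate_anion", "C7H5O5", "diagnostic_fragment", "galloyl", None),
    ("gallate_decarboxylated", "C6H5O3", "diagnostic_fragment", "phenolic_acid", None),
    ("coumarate_anion", "C9H7O3", "diagnostic_fragment", "phenolic_acid", None),
    ("coumarate_decarboxylated", "C8H7O", "diagnostic_fragment", "phenolic_acid", None),
    ("galactarate_anion", "C6H9O8", "diagnostic_fragment", "phenolic_acid", None),
    ("galactarate_dehydrated", "C6H7O7", "diagnostic_fragment", "phenolic_acid", None),
    ("galloylglycoside_rda", "C9H7O6", "diagnostic_fragment", "gallotannin_rda", None),
    ("urolithin_anion", "C13H7O7", "diagnostic_fragment", "HHDP", None),
    ("ellagate_anion", "C14H5O8", "diagnostic_fragment", "HHDP", None),
    ("ellagate_radical_anion", "C14H4O8", "diagnostic_fragment", "ellagic_derivative", None),
    ("methylellagate_anion", "C15H7O8", "diagnostic_fragment", "ellagic_derivative", None),
    ("dimethylellagate_radical_anion", "C16H8O8", "diagnostic_fragment", "ellagic_derivative", None),
    ("methylellagate_core_anion", "C15H5O8", "diagnostic_fragment", "ellagic_derivative", None),
    ("ellagate_core_anion", "C14H2O8", "diagnostic_fragment", "ellagic_derivative", None),
    ("phyllanthusiin_anion", "C13H9O9", "diagnostic_fragment", "oxidized_congener", None),
    ("methylchebulate_anion", "C15H11O10", "diagnostic_fragment", "oxidized_congener", None),
    ("chebulate_dehydrated_anion", "C14H9O10", "diagnostic_fragment", "Che", None),
    ("chebulate_didehydrated_anion", "C14H7O9", "diagnostic_fragment", "Che", None),
    ("chebulate_decarboxylated_anion", "C13H9O8", "diagnostic_fragment", "Che", None),
    ("ellagitannin_249", "C12H9O6", "diagnostic_fragment", "tannin_secondary", None),
    ("ellagitannin_247", "C12H7O6", "diagnostic_fragment", "tannin_secondary", None),
    ("quercetin_anion", "C15H9O7", "diagnostic_fragment", "aglycone:quercetin", None),
    ("quercetin_radical_anion", "C15H8O7", "diagnostic_fragment", "aglycone:quercetin:radical", None),
    ("kaempferol_anion", "C15H9O6", "diagnostic_fragment", "aglycone:kaempferol", None),
    ("kaempferol_radical_anion", "C15H8O6", "diagnostic_fragment", "aglycone:kaempferol:radical", None),
    ("methylquercetin_anion", "C16H11O7", "diagnostic_fragment", "aglycone:methylquercetin", None),
    ("methylquercetin_radical_anion", "C16H10O7", "diagnostic_fragment", "aglycone:methylquercetin:radical", None),
    ("flavonoid_151", "C7H3O4", "diagnostic_fragment", "flavonoid_secondary", None),
    ("flavonoid_179", "C8H3O5", "diagnostic_fragment", "flavonoid_secondary", None),
    ("flavonoid_227", "C13H7O4", "diagnostic_fragment", "flavonoid_secondary", None),
    ("flavonoid_243", "C13H7O5", "diagnostic_fragment", "flavonoid_secondary", None),
    ("flavonoid_255", "C14H7O5", "diagnostic_fragment", "flavonoid_secondary", None),
    ("flavonoid_271", "C14H7O6", "diagnostic_fragment", "flavonoid_secondary", None),
    ("flavonoid_273", "C14H9O6", "diagnostic_fragment", "flavonoid_secondary", None),
    ("flavonoid_121", "C7H5O2", "diagnostic_fragment", "flavonoid_secondary", None),
    ("flavonoid_107", "C6H3O2", "diagnostic_fragment", "flavonoid_secondary", None),
]

_NOMINAL_MASSES = {"galloyl_methylacetate": 242.043}


def _build_default() -> list[LossRule]:
    rules: list[LossRule] = []
    for name, ftext, kind, evidence, tol in _CATALOGUE_SPEC:
        if ftext is None:
            rules.append(LossRule(name, _NOMINAL_MASSES[name], kind, evidence, None, tol))
        else:
            f = parse_formula(ftext)
            rules.append(LossRule(name, monoisotopic_mass(f), kind, evidence, f, tol))
    return rules


def default_catalogue() -> list[LossRule]:
    """The built-in catalogue of diagnostic losses and fragments."""
    return _build_default()


def write_catalogue(rules: list[LossRule], path) -> None:
    df = pd.DataFrame(
        {
            "name": [r.name for r in rules],
            "formula": [str(r.formula) if r.formula else "" for r in rules],
            "mass": [round(r.mass, 6) for r in rules],
            "kind": [r.kind for r in rules],
            "evidence": [r.evidence for r in rules],
            "tol": [r.tol if r.tol is not None else "" for r in rules],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_catalogue(path) -> list[LossRule]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    rules = []
    for row in df.itertuples(index=False):
        f = parse_formula(row.formula) if row.formula else None
        tol = float(row.tol) if str(row.tol) != "" else None
        rules.append(LossRule(row.name, float(row.mass), row.kind, row.evidence, f, tol))
    return rules


def catalogue_path() -> Path:
    """Location of the packaged catalogue TSV."""
    return Path(resources.files("phenolannot") / "data" / "loss_catalogue.tsv")


def detect_losses(spectrum, catalogue: list[LossRule] | None = None,
                  tol: float = FRAGMENT_TOL) -> list[LossMatch]:
    """Find every catalogued loss/fragment in a spectrum.

    Mass deltas are evaluated at two tiers: precursor -> fragment and
    fragment -> fragment (cascades).  ``diagnostic_fragment`` rules are
    matched against absolute fragment m/z.  Result is independent of peak
    order and intensity scale.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    mzs = list(spectrum.mz)
    out: list[LossMatch] = []
    pairs: list[tuple[float | None, float, str]] = []
    for child in mzs:
        pairs.append((spectrum.precursor_mz, child, "precursor"))
    for i in range(len(mzs)):
        for j in range(i + 1, len(mzs)):
            pairs.append((mzs[j], mzs[i], "fragment"))  # parent is heavier
    for rule in catalogue:
        rtol = rule.tol if rule.tol is not None else tol
        if rule.kind == "diagnostic_fragment":
            for child in mzs:
                err = abs(child - rule.mass)
                if err <= rtol:
                    out.append(LossMatch(rule, None, child, child, err, "diagnostic"))
            continue
        for parent, child, tier in pairs:
            delta = parent - child
            err = abs(delta - rule.mass)
            if err <= rtol:
                out.append(LossMatch(rule, parent, child, delta, err, tier))
    return out


def loss_signature(matches: list[LossMatch]) -> Counter:
    """Order-independent multiset of evidence tags carried by the matches."""
    return Counter(m.rule.evidence for m in matches)
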