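"""Compound-class assignment, moiety inference and library matching.

The classifier reads a spectrum's detected losses/diagnostic ions and walks
an ordered cascade, most specific evidence first:

1. **ellagitannin** — hexahydroxydiphenoyl (HHDP) evidence (ellagate anion
   m/z 301, urolithin anion 275 for deoxygenated sugar cores, or the 302 Da
   HHDP loss), or DHHDP / chebuloyl (Che) / oxidatively-modified-congener
   evidence, together with galloyl evidence.  Ellagitannins routinely also
   shed galloyl (152) and gallic acid (170), which is why they are tested
   before gallotannins.
2. **gallotannin** — galloyl evidence plus an integer galloyl count: the
   neutral mass must equal a sugar core (glucose or dideoxyglucose) plus
   n x 152.0110 within 0.05 Da.
3. **flavonoid (O-glycoside or aglycone)** — a kaempferol / quercetin /
   methylquercetin anion (285.0399 / 301.0348 / 315.0505) or its radical
   anion (284 / 300 / 314) among the fragments, or as the precursor itself.
4. **ellagic-acid derivative** — ellagate-type diagnostic ions (301/300
   anion or radical, methylated cores) without tannin context; reported as
   a phenolic acid derivative, which is how such compounds are counted.
5. **phenolic acid derivative** — at least two independent pieces of simple
   phenolic evidence (CO2 / methyl-radical / hydroxycinnamoyl losses,
   decarboxylation products, galloyl/coumaroyl diagnostics).
6. otherwise **unknown**.

Class precedence resolves evidence overlap deterministically; intensities
only enter through the glycosylation-position ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import Formula, H_ATOM, enumerate_formulas, monoisotopic_mass, ppm_error
from .library import LibraryEntry, resolve_fragments
from .rules import FRAGMENT_TOL, LossMatch, LossRule, default_catalogue, detect_losses
from .spectra import Spectrum

__all__ = [
    "Annotation",
    "LibraryMatch",
    "CLASSES",
    "AGLYCONE_IONS",
    "identify_aglycone",
    "glycosylation_position",
    "count_galloyl",
    "infer_galloyl",
    "detect_tannin_groups",
    "classify",
    "match_library",
    "annotate_spectrum",
]

CLASSES = (
    "phenolic_acid_derivative",
    "flavonoid_O_glycoside",
    "gallotannin",
    "ellagitannin",
    "unknown",
)

#: aglycone name -> (anion m/z, radical anion m/z)
AGLYCONE_IONS: dict[str, tuple[str, str]] = {
    "kaempferol": ("kaempferol_anion", "kaempferol_radical_anion"),
    "quercetin": ("quercetin_anion", "quercetin_radical_anion"),
    "methylquercetin": ("methylquercetin_anion", "methylquercetin_radical_anion"),
}

#: sugar cores of gallotannins (neutral monoisotopic masses)
GALLOYL = 152.010959
SUGAR_CORES = {
    "glucose": monoisotopic_mass("C6H12O6"),
    "dideoxyglucose": monoisotopic_mass("C6H12O4"),
}

_ELLAGIC_DIAGS = (
    "ellagate_anion",
    "ellagate_radical_anion",
    "methylellagate_anion",
    "dimethylellagate_radical_anion",
    "methylellagate_core_anion",
    "ellagate_core_anion",
)
# precursor anions of free (methylated) ellagic acids
_ELLAGIC_PRECURSORS = ("C14H5O8", "C15H7O8", "C16H9O8", "C17H11O8")

_PHENOLIC_LOSS_TAGS = ("carboxyl", "methyl", "coumaroyl", "feruloyl")
_PHENOLIC_DIAG_TAGS = ("phenolic_acid", "galloyl")


@dataclass
class LibraryMatch:
    name: str
    peak: int
    score: float  # containment: fraction of library fragments found
    ppm: float
    rt_delta: float | None = None


@dataclass
class Annotation:
    """The classifier's verdict for one feature, with its evidence trail."""

    feature_id: str
    compound_class: str = "unknown"
    formula: Formula | None = None
    ppm: float | None = None
    aglycone: str = "none"
    glycosylation: str = "unknown"  # 3-O | unknown
    sugars: tuple[str, ...] = ()
    galloyl_count: int = 0
    sugar_core: str = ""
    tannin_groups: frozenset[str] = frozenset()
    moieties: tuple[str, ...] = ()
    candidates: list[LibraryMatch] = field(default_factory=list)
    evidence: list[LossMatch] = field(default_factory=list)


def _rule_mass(catalogue: list[LossRule], name: str) -> float:
    for r in catalogue:
        if r.name == name:
            return r.mass
    raise KeyError(name)


def identify_aglycone(s: Spectrum, matches: list[LossMatch],
                      tol: float = FRAGMENT_TOL) -> tuple[str, int]:
    """Flavonoid aglycone whose anion or radical anion appears.

    The anion may appear as a fragment (glycosides) or be the precursor
    itself (bare aglycones).  Returns (name, score) where the score counts
    matched secondary diagnostic ions (151, 179, 227, 243, 255, 271, 273);
    ('none', 0) when no aglycone ion is present.
    """
    catalogue = default_catalogue()
    diag_hits = {m.rule.name for m in matches if m.tier == "diagnostic"}
    secondary = sum(1 for m in matches
                    if m.rule.evidence == "flavonoid_secondary" and m.tier == "diagnostic")
    found: list[tuple[float, str]] = []
    for name, (anion, radical) in AGLYCONE_IONS.items():
        present = anion in diag_hits or radical in diag_hits
        if not present:  # bare aglycone: precursor is the anion
            if abs(s.precursor_mz - _rule_mass(catalogue, anion)) <= tol:
                present = True
        if present:
            # strongest summed intensity of its ions breaks multi-aglycone ties
            strength = sum(
                i for mz, i in zip(s.mz, s.intensity)
                if min(abs(mz - _rule_mass(catalogue, anion)),
                       abs(mz - _rule_mass(catalogue, radical))) <= tol
            )
            found.append((strength, name))
    if not found:
        return "none", 0
    found.sort(reverse=True)
    return found[0][1], secondary


def glycosylation_position(s: Spectrum, aglycone: str,
                           tol: float = FRAGMENT_TOL,
                           ratio_threshold: float = 1.0) -> str:
    """3-O glycosylation call from the radical/neutral aglycone ion ratio.

    Homolytic O-glycosidic cleavage dominating the heterolytic one (radical
    ion at least as intense as the even-electron ion, default ratio >= 1)
    indicates attachment at the aglycone's 3-O position.
    """
    if aglycone not in AGLYCONE_IONS:
        return "unknown"
    catalogue = default_catalogue()
    anion_mz = _rule_mass(catalogue, AGLYCONE_IONS[aglycone][0])
    radical_mz = _rule_mass(catalogue, AGLYCONE_IONS[aglycone][1])
    i_anion = max((i for mz, i in zip(s.mz, s.intensity)
                   if abs(mz - anion_mz) <= tol), default=0.0)
    i_radical = max((i for mz, i in zip(s.mz, s.intensity)
                     if abs(mz - radical_mz) <= tol), default=0.0)
    if i_anion <= 0 or i_radical <= 0:
        return "unknown"
    return "3-O" if i_radical / i_anion >= ratio_threshold else "unknown"


def count_galloyl(neutral_mass: float, core: str, tol: float = 0.05) -> int:
    """Galloyl count n with |mass - core - n x 152.0110| <= tol, n >= 0."""
    if core not in SUGAR_CORES:
        raise ValueError(f"unknown sugar core {core!r}")
    core_mass = SUGAR_CORES[core]
    if neutral_mass < core_mass - tol:
        raise ValueError("neutral mass below the sugar core mass")
    n = round((neutral_mass - core_mass) / GALLOYL)
    if n < 0 or abs(neutral_mass - core_mass - n * GALLOYL) > tol:
        raise ValueError(f"no integer galloyl count fits {neutral_mass:.4f} on {core}")
    return n


def infer_galloyl(neutral_mass: float, tol: float = 0.05) -> tuple[int, str] | None:
    """Best (count, core) over the known sugar cores, or None if none fits."""
    fits = []
    for core in SUGAR_CORES:
        try:
            n = count_galloyl(neutral_mass, core, tol)
        except ValueError:
            continue
        resid = abs(neutral_mass - SUGAR_CORES[core] - n * GALLOYL)
        fits.append((resid, n, core))
    if not fits:
        return None
    fits.sort()
    return fits[0][1], fits[0][2]


def detect_tannin_groups(s: Spectrum, matches: list[LossMatch]) -> frozenset[str]:
    """Subset of {HHDP, DHHDP, Che, oxidized_congener, cinnamoyl} supported.

    HHDP needs the ellagate anion (301), the urolithin anion (275, deoxy
    cores) or the 302 Da loss.  The oxidatively modified congeners are
    recognised by their residue anions (309/351), residue losses, the
    CO2-then-C3H2O cascade off the precursor, or - for HHDP tannins without
    chebuloyl evidence - a bare precursor decarboxylation, which intact
    galloyl/HHDP esters do not undergo.
    """
    groups: set[str] = set()
    names_by_tier: dict[str, set[str]] = {"precursor": set(), "fragment": set(),
                                          "diagnostic": set()}
    for m in matches:
        names_by_tier[m.tier].add(m.rule.name)
    all_names = set().union(*names_by_tier.values())
    diag = names_by_tier["diagnostic"]

    if {"ellagate_anion", "urolithin_anion"} & diag or "hhdp" in all_names:
        groups.add("HHDP")
    if "dhhdp_residue" in all_names:
        groups.add("DHHDP")
    # the chebuloyl residue mass C14H8O9 equals HHDP + H2O, so the loss alone
    # is degenerate on ellagitannins; Che needs the chebulate product-ion pair
    che_diags = {"chebulate_dehydrated_anion", "chebulate_didehydrated_anion",
                 "chebulate_decarboxylated_anion"}
    if len(che_diags & diag) >= 2:
        groups.add("Che")
    if any(m.rule.evidence == "cinnamoyl" for m in matches):
        groups.add("cinnamoyl")

    oxidized = bool({"phyllanthusiin_anion", "methylchebulate_anion"} & diag)
    oxidized |= bool({"phyllanthusiin_residue", "phyllanthusiin_residue_dehydro",
                      "methylchebulate_residue"} & all_names)
    # CO2 off the precursor followed by C3H2O (44 then 54 Da cascade)
    co2_children = {round(m.child_mz, 3) for m in matches
                    if m.tier == "precursor" and m.rule.name == "carbon_dioxide"}
    if co2_children:
        for m in matches:
            if (m.tier == "fragment" and m.rule.name == "propenone"
                    and m.parent_mz is not None
                    and round(m.parent_mz, 3) in co2_children):
                oxidized = True
        if "HHDP" in groups and "Che" not in groups:
            oxidized = True
    if oxidized:
        groups.add("oxidized_congener")
    return frozenset(groups)


def _galloyl_evidence(matches: list[LossMatch]) -> bool:
    return any(m.rule.evidence == "galloyl" for m in matches)


def classify(s: Spectrum, formula: Formula | None = None,
             matches: list[LossMatch] | None = None,
             catalogue: list[LossRule] | None = None,
             tol: float = FRAGMENT_TOL,
             position_threshold: float = 1.0) -> Annotation:
    """Run the ordered class cascade on one spectrum."""
    if matches is None:
        matches = detect_losses(s, catalogue, tol)
    ann = Annotation(feature_id=s.feature_id, formula=formula, evidence=matches)
    if formula is not None:
        ann.ppm = ppm_error(s.precursor_mz, formula)
    neutral_mass = s.precursor_mz + H_ATOM  # observed neutral mass

    groups = detect_tannin_groups(s, matches)
    galloyl = _galloyl_evidence(matches)
    sugars = tuple(sorted({m.rule.evidence.split(":")[1] for m in matches
                           if m.tier == "precursor"
                           and m.rule.evidence.startswith("sugar:")}))

    if groups & {"HHDP", "DHHDP", "Che", "oxidized_congener"} and galloyl:
        ann.compound_class = "ellagitannin"
        ann.tannin_groups = groups
        n_galloyl_losses = len({m.rule.name for m in matches
                                if m.rule.evidence == "galloyl"
                                and m.rule.kind == "neutral_loss"})
        ann.galloyl_count = max(1, n_galloyl_losses)
        ann.moieties = tuple(sorted(groups)) + sugars
        if any(m.rule.name == "galloyl_methylacetate" for m in matches):
            ann.moieties += ("galloyl_methylacetate",)
        return ann

    if galloyl:
        fit = infer_galloyl(neutral_mass)
        if fit is not None and fit[0] >= 1:
            n, core = fit
            ann.compound_class = "gallotannin"
            ann.galloyl_count = n
            ann.sugar_core = core
            ann.moieties = (f"{n}x galloyl", core)
            return ann

    aglycone, _score = identify_aglycone(s, matches, tol)
    if aglycone != "none":
        ann.compound_class = "flavonoid_O_glycoside"
        ann.aglycone = aglycone
        ann.sugars = sugars
        ann.glycosylation = glycosylation_position(
            s, aglycone, tol, position_threshold)
        ann.moieties = (aglycone,) + sugars
        return ann

    diag_names = {m.rule.name for m in matches if m.tier == "diagnostic"}
    ellagic = bool(set(_ELLAGIC_DIAGS) & diag_names)
    if not ellagic:
        ellagic = any(abs(s.precursor_mz - monoisotopic_mass(f)) <= tol
                      for f in _ELLAGIC_PRECURSORS)
    if ellagic:
        ann.compound_class = "phenolic_acid_derivative"
        ann.moieties = ("ellagic_acid_derivative",) + sugars
        ann.sugars = sugars
        return ann

    phenolic_pieces = sum(
        1 for m in matches
        if (m.tier in ("precursor", "fragment") and m.rule.evidence in _PHENOLIC_LOSS_TAGS)
        or (m.tier == "diagnostic" and m.rule.evidence in _PHENOLIC_DIAG_TAGS)
    )
    if phenolic_pieces >= 2:
        ann.compound_class = "phenolic_acid_derivative"
        acyl = tuple(sorted({m.rule.evidence for m in matches
                             if m.rule.evidence in ("coumaroyl", "feruloyl")}))
        ann.moieties = acyl + sugars
        return ann

    return ann  # unknown


def annotations_to_table(annotations: list[Annotation],
                         spectra: list[Spectrum]) -> "pd.DataFrame":
    """Flatten annotations into the TSV-ready table layout."""
    import pandas as pd

    by_id = {s.feature_id: s for s in spectra}
    rows = []
    for a in annotations:
        s = by_id.get(a.feature_id)
        rows.append({
            "feature_id": a.feature_id,
            "retention_time": round(s.retention_time, 3) if s else "",
            "precursor_mz": round(s.precursor_mz, 4) if s else "",
            "formula": str(a.formula) if a.formula else "",
            "ppm_error": a.ppm if a.ppm is not None else "",
            "compound_class": a.compound_class,
            "aglycone": a.aglycone,
            "glycosylation": a.glycosylation,
            "galloyl_count": a.galloyl_count,
            "tannin_groups": ";".join(sorted(a.tannin_groups)),
            "moieties": ";".join(a.moieties),
            "candidates": ";".join(f"{c.name} ({c.score:.2f})" for c in a.candidates),
            "evidence": ";".join(sorted({m.rule.name for m in a.evidence})),
        })
    return pd.DataFrame(rows)


def match_library(s: Spectrum, formula: Formula | None,
                  library: list[LibraryEntry],
                  prec_tol_ppm: float = 10.0,
                  frag_tol: float = FRAGMENT_TOL) -> list[LibraryMatch]:
    """Rank library candidates by fragment containment.

    A candidate must agree in precursor m/z within ``prec_tol_ppm`` (and in
    formula, when one is assigned).  Score is the fraction of the entry's
    resolved fragments found in the spectrum; ties are ordered by |ppm| and,
    when the query has a retention time, by RT proximity.  Isomers (same
    formula, same fragments) tie and are returned together.
    """
    out: list[LibraryMatch] = []
    for entry in library:
        theo = entry.mz_theoretical
        ppm = (s.precursor_mz - theo) / theo * 1e6
        if abs(ppm) > prec_tol_ppm:
            continue
        if formula is not None and formula != entry.formula:
            continue
        resolved = resolve_fragments(entry)
        if resolved:
            hits = sum(1 for f in resolved
                       if any(abs(mz - f.mz) <= frag_tol for mz in s.mz))
            score = hits / len(resolved)
        else:
            score = 0.0
        if score <= 0:
            continue
        rt_delta = abs(s.retention_time - entry.rt) if s.retention_time > 0 else None
        out.append(LibraryMatch(entry.name, entry.peak, score, round(abs(ppm), 1), rt_delta))
    out.sort(key=lambda m: (-m.score, m.ppm,
                            m.rt_delta if m.rt_delta is not None else 0.0))
    return out


def annotate_spectrum(s: Spectrum, library: list[LibraryEntry] | None = None,
                      catalogue: list[LossRule] | None = None,
                      formula_tol_ppm: float = 10.0,
                      frag_tol: float = FRAGMENT_TOL,
                      position_threshold: float = 1.0) -> Annotation:
    """Full per-spectrum pipeline: formula -> losses -> class -> library."""
    s = s.normalized()
    candidates = enumerate_formulas(s.precursor_mz, formula_tol_ppm)
    formula = candidates[0] if candidates else None
    matches = detect_losses(s, catalogue, frag_tol)
    ann = classify(s, formula, matches, catalogue, frag_tol, position_threshold)
    if library:
        ann.candidates = match_library(s, formula, library, formula_tol_ppm, frag_tol)
    return ann
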