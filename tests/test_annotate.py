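"""Classifier cascade, moiety inference and library matching."""

import random
from collections import Counter

import pytest

from phenolannot.annotate import (
    annotate_spectrum,
    classify,
    count_galloyl,
    detect_tannin_groups,
    glycosylation_position,
    identify_aglycone,
    infer_galloyl,
    match_library,
)
from phenolannot.chem import parse_formula
from phenolannot.library import resolve_fragments
from phenolannot.rules import detect_losses
from phenolannot.simulate import fixture_spectra
from phenolannot.spectra import Spectrum


def _spec(prec, peaks, base=None, rt=0.0):
    ints = tuple(100.0 if base is not None and abs(m - base) < 1e-6 else 50.0
                 for m in peaks)
    return Spectrum("t", prec, rt, -1, tuple(peaks), ints)


class TestIdentifyAglycone:
    def test_quercetin(self):
        s = _spec(463.0888, [301.0348, 300.0270, 271.0243, 255.0293,
                             243.0293, 178.9980, 151.0031], base=300.0270)
        name, score = identify_aglycone(s, detect_losses(s))
        assert name == "quercetin"
        assert score >= 4

    def test_kaempferol(self):
        s = _spec(447.0927, [285.0399, 284.0321, 255.0293, 227.0344, 151.0031],
                  base=284.0321)
        name, _ = identify_aglycone(s, detect_losses(s))
        assert name == "kaempferol"

    def test_bare_aglycone_via_precursor(self):
        s = _spec(285.0399, [255.0293, 227.0344, 151.0031])
        name, _ = identify_aglycone(s, detect_losses(s))
        assert name == "kaempferol"

    def test_gallate_ions_are_not_an_aglycone(self):
        s = _spec(169.0137, [125.0239])
        assert identify_aglycone(s, detect_losses(s))[0] == "none"


class TestGlycosylationPosition:
    def test_radical_base_peak_calls_3_O(self):
        s = Spectrum("t", 447.0927, 0, -1, (285.0399, 284.0321), (40.0, 100.0))
        assert glycosylation_position(s, "kaempferol") == "3-O"

    def test_near_equal_ratio_still_3_O(self):
        s = Spectrum("t", 463.0888, 0, -1, (301.0348, 300.0270), (90.0, 100.0))
        assert glycosylation_position(s, "quercetin") == "3-O"

    def test_radical_absent_is_unknown(self):
        s = Spectrum("t", 447.0927, 0, -1, (285.0399,), (100.0,))
        assert glycosylation_position(s, "kaempferol") == "unknown"

    def test_weak_radical_is_unknown(self):
        s = Spectrum("t", 447.0927, 0, -1, (285.0399, 284.0321), (100.0, 30.0))
        assert glycosylation_position(s, "kaempferol") == "unknown"


class TestCountGalloyl:
    @pytest.mark.parametrize(
        "mass, core, n",
        [(636.0963, "glucose", 3),      # trigalloyl-glucose
         (788.1072, "glucose", 4),      # tetragalloyl-glucose
         (180.0634, "glucose", 0)],     # bare core
    )
    def test_counts(self, mass, core, n):
        assert count_galloyl(mass, core) == n

    def test_no_integer_fit_raises(self):
        with pytest.raises(ValueError):
            count_galloyl(500.0, "glucose")

    def test_mass_below_core_raises(self):
        with pytest.raises(ValueError):
            count_galloyl(100.0, "glucose")

    def test_core_inferred_from_mass_alone(self):
        # trigalloyl-dideoxyglucose: only the dideoxy core fits
        assert infer_galloyl(604.1065) == (3, "dideoxyglucose")
        assert infer_galloyl(636.0963) == (3, "glucose")


class TestDetectTanninGroups:
    def _groups(self, peak, library):
        entry = next(e for e in library if e.peak == peak)
        spec = fixture_spectra([entry])[0]
        return detect_tannin_groups(spec, detect_losses(spec))

    def test_phyllanthusiin_type(self, library):
        assert self._groups(12, library) == {"HHDP", "oxidized_congener"}

    def test_cinnamoyl_type(self, library):
        assert self._groups(43, library) == {"HHDP", "cinnamoyl"}

    def test_co2_then_c3h2o_cascade(self, library):
        assert "oxidized_congener" in self._groups(39, library)

    def test_dhhdp(self, library):
        assert "DHHDP" in self._groups(5, library)

    def test_chebuloyl(self, library):
        assert "Che" in self._groups(7, library)

    def test_no_evidence_no_groups(self):
        s = _spec(447.0927, [285.0399, 284.0321])
        assert detect_tannin_groups(s, detect_losses(s)) == set()


class TestClassify:
    def test_galloyl_hhdp_glucose_is_ellagitannin(self, library):
        entry = next(e for e in library if e.peak == 6)
        spec = fixture_spectra([entry])[0]
        ann = classify(spec, entry.formula)
        assert ann.compound_class == "ellagitannin"
        assert "HHDP" in ann.tannin_groups
        assert ann.galloyl_count >= 1

    def test_trigalloyl_glucose_is_gallotannin(self, library):
        entry = next(e for e in library if e.peak == 8)
        spec = fixture_spectra([entry])[0]
        ann = classify(spec, entry.formula)
        assert ann.compound_class == "gallotannin"
        assert ann.galloyl_count == 3
        assert ann.sugar_core == "glucose"

    def test_isobaric_433_pair_split(self, library):
        ell = next(e for e in library if e.peak == 13)
        fla = next(e for e in library if e.peak == 29)
        s_ell, s_fla = fixture_spectra([ell, fla])
        a_ell = classify(s_ell, ell.formula)
        a_fla = classify(s_fla, fla.formula)
        assert a_ell.compound_class == "phenolic_acid_derivative"
        assert "ellagic_acid_derivative" in a_ell.moieties
        assert a_fla.compound_class == "flavonoid_O_glycoside"
        assert a_fla.aglycone == "quercetin"

    def test_gallic_acid_is_phenolic(self):
        s = _spec(169.0138, [125.0239])
        ann = classify(s, parse_formula("C7H6O5"))
        assert ann.compound_class == "phenolic_acid_derivative"

    def test_random_peaks_are_unknown(self):
        s = _spec(500.0, [111.1111, 222.2222, 333.3333])
        assert classify(s).compound_class == "unknown"

    def test_deterministic_and_order_invariant(self, library):
        rng = random.Random(5)
        for entry in library[:10]:
            spec = fixture_spectra([entry])[0]
            ref = classify(spec, entry.formula).compound_class
            order = list(range(spec.n_peaks))
            rng.shuffle(order)
            shuffled = Spectrum(spec.feature_id, spec.precursor_mz,
                                spec.retention_time, -1,
                                tuple(spec.mz[i] for i in order),
                                tuple(spec.intensity[i] * 3.7 for i in order))
            assert classify(shuffled, entry.formula).compound_class == ref

    def test_full_partition(self, library, fixture_specs):
        counts = Counter(
            classify(s, e.formula).compound_class
            for e, s in zip(library, fixture_specs))
        assert counts["phenolic_acid_derivative"] == 12
        assert counts["flavonoid_O_glycoside"] == 16
        assert counts["gallotannin"] == 3
        assert counts["ellagitannin"] == 13

    def test_radical_base_peak_rows_are_3_O(self, library, fixture_specs):
        # flavonoid glycosides whose printed base peak is the radical ion
        radical_nominal = {284, 300, 314}
        for entry, spec in zip(library, fixture_specs):
            if (entry.compound_class == "flavonoid_O_glycoside"
                    and entry.base_peak in radical_nominal
                    and entry.peak not in (40, 42)):  # bare aglycones
                ann = classify(spec, entry.formula)
                assert ann.glycosylation == "3-O", entry.name


class TestMatchLibrary:
    def test_gallic_acid_ranks_first(self, library):
        entry = next(e for e in library if e.peak == 1)
        spec = fixture_spectra([entry])[0]
        hits = match_library(spec, entry.formula, library)
        assert hits and hits[0].name == "Gallic acid"

    def test_containment_score_matches_brute_force(self, library):
        entry = next(e for e in library if e.peak == 8)
        spec = fixture_spectra([entry])[0]
        hits = match_library(spec, None, library)
        for h in hits:
            cand = next(e for e in library if e.peak == h.peak)
            frags = [f.mz for f in resolve_fragments(cand)]
            brute = sum(any(abs(mz - f) <= 0.02 for mz in spec.mz)
                        for f in frags) / len(frags)
            assert h.score == pytest.approx(brute)

    def test_glucoside_isomers_tie(self, library):
        entry = next(e for e in library if e.peak == 30)
        spec = fixture_spectra([entry])[0]
        hits = match_library(spec, entry.formula, library)
        names = {h.name for h in hits if h.score == hits[0].score}
        assert names == {"Kaempferol 3-O-glucoside Isomer I",
                         "Kaempferol 3-O-glucoside Isomer II"}
        # with RT supplied, isomer I (RT 9.70) is closer to the query RT
        assert hits[0].name == "Kaempferol 3-O-glucoside Isomer I"

    def test_decoy_matches_nothing(self, library):
        s = _spec(500.0, [111.1, 222.2, 333.3])
        assert match_library(s, None, library) == []

    def test_empty_library(self):
        s = _spec(169.0138, [125.0239])
        assert match_library(s, None, []) == []


class TestAnnotateSpectrum:
    def test_end_to_end_single(self, library):
        entry = next(e for e in library if e.peak == 21)
        spec = fixture_spectra([entry])[0]
        ann = annotate_spectrum(spec, library)
        assert ann.compound_class == "flavonoid_O_glycoside"
        assert ann.formula == entry.formula
        assert ann.aglycone == "quercetin"
        assert ann.glycosylation == "3-O"
        assert "hexose" in ann.sugars
        assert any("Quercetin 3-O-glucoside" in c.name for c in ann.candidates)
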