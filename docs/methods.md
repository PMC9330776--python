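# Methods

## Scope and model

`phenolannot` annotates picked MS/MS features from negative-mode
electrospray LC-MS of phenolic-rich plant extracts. It assumes: singly
deprotonated precursors ([M−H]⁻) in m/z 100–1200; centroided product-ion
spectra; compounds drawn from three chemistries — phenolic acid
derivatives, flavonoid *O*-glycosides, hydrolysable tannins — whose
fragmentation is dominated by a small grammar of neutral/radical losses
and diagnostic product anions. It performs putative annotation
(Metabolomics Standards Initiative level 2/3): class, moieties and
library candidates with an explicit evidence trail, never a definitive
structure.

## Mass arithmetic

Monoisotopic masses come from the NIST isotope table shipped with
pyteomics (H 1.00782503, C 12, O 15.9949146). The [M−H]⁻ convention is
**neutral mass − m(H atom)**, electron mass ignored; this is the
convention under which the reference table's printed ppm errors reproduce
exactly (gallic acid 0.6 ppm, quercetin 4.7 ppm, kaempferol 0.0 ppm). The
physically stricter alternative — subtract a proton, add the electron —
shifts every theoretical m/z by +0.00055 Da (≈ 1–2 ppm at low mass), gives
systematic offsets against that table, and is exposed as
`deprotonated_mz(..., electron_correction=True)` but not used for library
comparison.

Formula enumeration is a bounded CHO search (defaults C 0–45, H 0–45,
O 0–30; configurable for other chemistries) with RDBE = C − H/2 + 1 ≥ 0
and no upper RDBE cut (large ellagitannins legitimately reach RDBE 27).
Default assignment tolerance is 10 ppm: the largest error printed in the
reference table is 6.8 ppm. At these masses CHO formulas are ≥ 30 ppm
apart, so assignment is effectively unique; the isobaric pair at nominal
m/z 433 (433.0410 C₁₉H₁₄O₁₂ vs 433.0765 C₂₀H₁₈O₁₁) separates already at
5 ppm. Isotope-pattern scoring and fragmentation trees are out of scope;
the enumerator replaces them for CHO phenolics, where the precursor mass
plus the class rules carry the discrimination.

## Loss catalogue

Rules are triples (exact mass, kind, evidence tag). Kinds:
`neutral_loss` (even-electron neutral), `radical_loss` (odd-electron:
•CH₃, •C₂H₅, glycosyl radicals), `diagnostic_fragment` (absolute product
m/z). The catalogue ships as a versioned TSV; a consistency test pins
every stored mass to its formula within 0.001 Da and checks the
odd/even-electron bookkeeping (odd H count for CHO radicals).

Fragment tolerance is 0.02 Da throughout (detection, library containment,
cosine matching) — the value used by the feature-based molecular
networking workflow this pipeline mirrors. At 0.02 Da the 1.0078 Da
radical/neutral distinction and the ellagate-vs-quercetin anion
distinction (300.9984 vs 301.0348) are both safe. Two rules deviate: the
242 Da "galloyl-methylacetate" loss has no established composition and is
encoded at 242.043 with a 0.05 Da window; the galloyl-count residual uses
0.05 Da because the count formula is nominal-mass arithmetic (the
exact-mass residual stays < 0.02 Da for n ≤ 5).

Loss detection evaluates precursor→fragment and fragment→fragment deltas
(cascades such as 451 → 433 by water appear at the second tier) and is
invariant to peak order and intensity scale.

## Class cascade and its tie-breaks

Precedence: ellagitannin → gallotannin → flavonoid → ellagic-acid
derivative → phenolic acid derivative → unknown. Rationale and the
non-obvious choices:

- **Ellagitannin** needs tannin-group evidence (HHDP / DHHDP / Che /
  oxidized congener) *and* galloyl evidence. The second condition keeps
  ellagic-acid *O*-glycosides — which also show the ellagate anion and a
  catalogued sugar loss — in the phenolic branch, matching how such
  compounds are conventionally counted.
- **Chebuloyl (Che)** requires at least two of the chebulate-derived ions
  337.0196 / 319.0090 / 293.0297. The chebuloyl residue mass C₁₄H₈O₉
  equals HHDP + H₂O exactly, so the loss alone is degenerate on any
  ellagitannin that dehydrates; the product-ion pair is not.
- **Oxidized congeners** are called on the CO₂-then-C₃H₂O precursor
  cascade, the residue anions 309.0247 / 351.0352 (or their complementary
  losses), or a precursor-tier CO₂ loss on an HHDP tannin without Che
  evidence — intact galloyl/HHDP esters do not decarboxylate, the
  ring-opened oxidized groups do.
- **Gallotannin** demands an integer galloyl count (n × 152.0110 over a
  glucose 180.0634 or dideoxyglucose 148.0736 core, ±0.05 Da) computed
  from the *observed* neutral mass, so the call does not depend on which
  formula the enumerator ranked first.
- **Flavonoids** are recognised by the kaempferol / quercetin /
  methylquercetin anion (285.0399 / 301.0348 / 315.0505) or radical anion
  (284.0321 / 300.0270 / 314.0427) among the fragments or as the
  precursor; bare aglycones therefore land in the same class as their
  glycosides, which is how the class is tallied.
- **Phenolic acid derivative** requires two independent evidence pieces
  (losses among CO₂ / •CH₃ / coumaroyl / feruloyl, diagnostics among
  125 / 119 / 169 / 191 / 209 / 163). A single accidental 44 Da delta in
  an arbitrary spectrum is too cheap; two pieces keep the decoy
  false-annotation rate below a few percent while every genuine phenolic
  template still carries at least two.
- **3-O glycosylation** is called when the radical aglycone ion is at
  least as intense as the even-electron ion (ratio threshold 1.0,
  configurable): the literature criterion is qualitative, and threshold
  1.0 makes "the radical ion is the base peak of the pair" the operative
  reading.
- **Isomers** (e.g. the two kaempferol 3-*O*-glucosides) are returned as
  tied candidate sets; only retention-time proximity orders them. MS²
  alone cannot separate constitutional isomers of ellagitannins, and the
  annotator never pretends otherwise.

## Library and fixture encoding

The internal library transcribes 44 characterised compounds (RT, observed
[M−H]⁻, neutral formula, nominal product-ion list with the base peak
flagged, name, class). One entry's printed formula is the anion
composition (odd hydrogen count); the library stores the corrected
neutral form and preserves the printed text in a separate column.

Published fragment lists are nominal-mass. The fixture encoder assigns
each printed fragment an exact theoretical m/z by breadth-first search
over chains of catalogued losses (depth ≤ 5) from the theoretical
precursor, using a class-specific loss vocabulary, with diagnostic anions
(plus short H₂O/CO/CO₂ cascades from them) as fallback roots. Where two
chemically distinct chains collide on one nominal mass, an explicit
per-compound override records the intended product (e.g. the
methyl-radical cascade of methylated ellagic acids, or the dehydrated
HHDP-glucose anion of the cinnamoyl ellagitannin whose nominal neighbour
would mimic a DHHDP loss). Unresolvable fragments would fall back to
their nominal value and be flagged; in the shipped library every fragment
resolves.

## Synthetic data

The generator emulates what feature picking hands the annotator:
precursor and fragments at theoretical m/z with Gaussian jitter in ppm
(instrument-like, default sd 5 ppm); base peak at 100 with remaining
intensities log-uniform in [5, 80]; a Poisson(3) number of noise peaks
uniform in m/z over [100, precursor] with intensity ≤ 30, excluded from
±0.05 Da around true peaks so base-peak logic stays meaningful (the
exclusion and the intensity caps are acknowledged simplifications);
decoys with CHO-plausible random precursors and 5–15 random peaks; decoy
fraction 0.2; RT uniform over 1–20 min for decoys, library RT otherwise.
A seed fixes the output byte-for-byte.

What passing recovery tests shows — and does not. At these conditions the
rule engine recovers the true class for essentially all library-derived
spectra and leaves ≥ 95 % of decoys unannotated. The generator does not
simulate co-eluting chimeric spectra, in-source fragmentation, isotope
interference or intensity-dependent mass error, so those failure modes of
real data are not covered by the benchmark.

## Networking

Modified cosine with sqrt intensity weighting; candidate peak pairs match
directly or offset by the precursor mass difference; assignment is greedy
by descending weight product with a fixed tie-break (direct before
shifted, then lower m/z), which equals the exhaustive optimum on all
≤ 6-peak test instances and is never above it. matchms's implementation
of the same statistic serves as an independent cross-check in the tests
(at intensity power 1.0, its convention). Topology: edges need score
> 0.65 and strictly more than 4 matched peaks ("more than 4" read as
≥ 5; configurable); mutual top-10 rank filter; families larger than 100
are trimmed by deleting their lowest-scoring edges until the cap holds —
pruning terminates and is idempotent.

## I/O

MGF through pyteomics (RT converted to minutes; malformed blocks raise
with the block index). mzML through a deliberately narrow internal
reader for centroided MS2 scans (64/32-bit float arrays, plain or
zlib-compressed, namespace-agnostic); MS1 scans are skipped. Annotation
tables are UTF-8 TSV with a stable column order and round-trip through
the reader; the CLI prepends the effective configuration as `#` comment
lines for provenance. Networks export to GraphML and edge-list TSV.

## Problem sizes and determinism

The shipped analyses are desk-scale by construction: the 44-spectrum
fixture annotates in ~2 s, the 200-spectrum benchmark in ~3 s, and the
full network over the fixture in well under a second. All randomness
flows through a single integer seed; fixture construction and
classification are fully deterministic.

## Known limitations

- CHO-only enumeration by default; N/S-containing metabolites need wider
  bounds and would weaken the uniqueness argument above.
- The class cascade is tuned to the fragmentation grammar of this
  compound family; condensed tannins, C-glycosides or methylated
  flavonoids beyond methylquercetin would need new rules, not new code.
- Nominal-mass fragment resolution is a reconstruction; where the
  original instrument m/z values differ from the proposed compositions,
  containment scores against real spectra will differ accordingly.
- Raw-data processing (peak picking, deconvolution) is upstream and out
  of scope; the pipeline consumes picked features.
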