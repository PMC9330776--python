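"""Elemental formulas, monoisotopic masses and CHO formula enumeration.

Everything downstream (loss rules, library matching, the classifier) runs on
exact monoisotopic arithmetic.  Two conventions matter here:

* Masses are monoisotopic, from the NIST table shipped with pyteomics.
* ``[M-H]-`` m/z is computed as *neutral monoisotopic mass minus one hydrogen
  atom*, deliberately ignoring the electron mass.  High-resolution QToF work
  on phenolics customarily reports errors under this convention; the stricter
  proton-subtraction alternative shifts every value by ~0.5 mDa (~1-2 ppm at
  low mass) and is available via ``electron_correction=True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

__all__ = [
    "Formula",
    "parse_formula",
    "monoisotopic_mass",
    "deprotonated_mz",
    "ppm_error",
    "rdbe",
    "enumerate_formulas",
    "H_ATOM",
    "ELECTRON",
]

#: Monoisotopic mass of one hydrogen atom (Da).
H_ATOM: float = _pmass.nist_mass["H"][0][0]
#: Electron rest mass (Da).
ELECTRON: float = 0.00054857990907

_TOKEN = re.compile(r"([A-Z][a-z]?)[_]*(\d*)[_]*")


def _element_mass(symbol: str) -> float:
    try:
        return _pmass.nist_mass[symbol][0][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


@dataclass(frozen=True)
class Formula:
    """An elemental composition (non-negative integer counts per element).

    Hashable and immutable; supports ``+`` / ``-`` for mass bookkeeping of
    neutral losses.  ``str()`` renders Hill order (C, H, then alphabetical).
    """

    counts: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        cleaned = tuple(sorted((el, int(n)) for el, n in self.counts if n))
        for el, n in cleaned:
            _element_mass(el)  # validates the symbol
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        if not cleaned:
            raise ValueError("empty formula")
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Formula":
        return cls(tuple(d.items()))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __add__(self, other: "Formula") -> "Formula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return Formula.from_dict(d)

    def __sub__(self, other: "Formula") -> "Formula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise ValueError(f"subtraction yields negative {el} count")
        return Formula.from_dict(d)

    def __str__(self) -> str:
        d = self.as_dict()
        parts: list[str] = []
        # Hill order: C, H first when carbon present, then alphabetical.
        order: list[str] = []
        if "C" in d:
            order.append("C")
            if "H" in d:
                order.append("H")
        order += sorted(el for el in d if el not in order)
        for el in order:
            n = d[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> Formula:
    """Parse Hill-notation text (``"C27H22O18"``).

    Tolerant of the underscore style some tables use (``"C_27_H_22_O_18_"``).
    """
    s = text.strip().replace(" ", "")
    if not s:
        raise ValueError("empty formula")
    pos = 0
    d: dict[str, int] = {}
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        _element_mass(el)
        d[el] = d.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return Formula.from_dict(d)


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a composition, in Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(n * _element_mass(el) for el, n in f.counts)


def deprotonated_mz(f: Formula | str, electron_correction: bool = False) -> float:
    """Theoretical ``[M-H]-`` m/z of a neutral composition.

    Default convention: neutral mass minus one H atom.  With
    ``electron_correction`` the electron mass is added back (charge -1).
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if f["H"] < 1:
        raise ValueError(f"{f} has no hydrogen to remove")
    mz = monoisotopic_mass(f) - H_ATOM
    if electron_correction:
        mz += ELECTRON
    return mz


def ppm_error(observed_mz: float, f: Formula | str, signed: bool = False) -> float:
    """Mass error of an observed ``[M-H]-`` m/z against a neutral formula.

    Returns |error| rounded to one decimal (the usual table precision) unless
    ``signed`` is set, in which case the raw signed ppm is returned.
    """
    if observed_mz <= 0:
        raise ValueError("observed m/z must be positive")
    theo = deprotonated_mz(f)
    e = (observed_mz - theo) / theo * 1e6
    return e if signed else round(abs(e), 1)


def rdbe(f: Formula | str) -> float:
    """Ring-and-double-bond equivalents of a CHO composition: C - H/2 + 1."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f["C"] - f["H"] / 2.0 + 1.0


_DEFAULT_BOUNDS = {"C": (0, 45), "H": (0, 45), "O": (0, 30)}


def enumerate_formulas(
    mz: float,
    tol_ppm: float = 10.0,
    bounds: dict[str, tuple[int, int]] | None = None,
) -> list[Formula]:
    """All neutral CHO formulas whose ``[M-H]-`` m/z falls within ``tol_ppm``.

    Candidates must have RDBE >= 0 (no upper cut: large hydrolysable tannins
    legitimately reach RDBE 27).  Sorted by |ppm error|, ties by mass.
    Hydrogen-free compositions are excluded (cannot deprotonate).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    mC = _element_mass("C")
    mH = _element_mass("H")
    mO = _element_mass("O")
    target = mz + H_ATOM  # neutral monoisotopic mass window
    tol = mz * tol_ppm * 1e-6
    out: list[tuple[float, float, Formula]] = []
    for c in range(b["C"][0], b["C"][1] + 1):
        base_c = c * mC
        if base_c > target + tol:
            break
        for o in range(b["O"][0], b["O"][1] + 1):
            rest = target - base_c - o * mO
            if rest < -tol:
                break
            # hydrogen count bracket from the remaining mass
            h_lo = max(b["H"][0], 1, int((rest - tol) / mH))
            h_hi = min(b["H"][1], int((rest + tol) / mH) + 1)
            for h in range(h_lo, h_hi + 1):
                neutral = base_c + h * mH + o * mO
                theo = neutral - H_ATOM
                err = (mz - theo) / theo * 1e6
                if abs(err) <= tol_ppm and c - h / 2.0 + 1.0 >= 0 and (c or o):
                    d = {el: n for el, n in (("C", c), ("H", h), ("O", o)) if n}
                    out.append((abs(err), neutral, Formula.from_dict(d)))
    out.sort(key=lambda t: (t[0], t[1]))
    return [f for _, _, f in out]
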