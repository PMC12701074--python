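"""Monoisotopic-mass model for K-C cross-linked peptides and their MS-cleavage products.

A heterobifunctional lysine-cysteine (K-C) cross-linker couples a lysine
side-chain amine (via an NHS ester) to a cysteine thiol (via a haloacetamide).
The resulting thioether is not MS-cleavable, but oxidation of the cross-linked
cysteine sulfur to a sulfoxide introduces a labile C-S bond.  Collisional
activation of the oxidized cross-link then splits the precursor into two
single-peptide fragments:

* ``alpha_S`` -- the lysine-side peptide carrying a sulfenic-acid remnant,
* ``alpha_T`` -- its dehydration product (unsaturated-thiol remnant),
* ``beta_A``  -- the cysteine-side peptide carrying an alkene (dehydroalanine)
  remnant; the sulfur leaves with the alpha fragment, so this remnant is a
  loss of H2S (-33.987721 Da) for every K-C linker.

All masses are monoisotopic.  Composition arithmetic is delegated to
:mod:`pyteomics.mass`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from pyteomics import mass as _pmass

Composition = _pmass.Composition

#: Proton mass used for all charge arithmetic (standard MS convention; not
#: the hydrogen atom mass).
PROTON: float = 1.007276

WATER: float = _pmass.calculate_mass(formula="H2O")
H2S: float = _pmass.calculate_mass(formula="H2S")

#: Neutral loss of RSOH (R = carbamidomethyl, HS(O)CH2CONH2) from an oxidized
#: carbamidomethyl cysteine -- the diagnostic ~107 Da loss that signals the
#: MS-cleavable site.
RSOH_LOSS: float = _pmass.calculate_mass(formula="C2H5NO2S")

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASSES: Mapping[str, float] = dict(_pmass.std_aa_mass)

#: Named variable/fixed modifications (delta compositions).
MODIFICATIONS: Mapping[str, Composition] = {
    "acetyl": Composition(formula="C2H2O"),
    "carbamidomethyl": Composition(formula="C2H3NO"),
    # oxidized carbamidomethyl cysteine (the MS-cleavable species)
    "carbamidomethyl_ox": Composition(formula="C2H3NO2"),
    "oxidation": Composition(formula="O"),
}


class UnknownResidueError(KeyError):
    """Raised for a one-letter code absent from the residue mass table."""


def composition_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition (counts may be negative).

    Raises ``UnknownResidueError`` for an element symbol the nuclide table
    does not know.
    """
    total = 0.0
    for element, count in comp.items():
        if count == 0:
            continue
        try:
            total += _pmass.calculate_mass(composition=Composition({element: 1})) * count
        except Exception as exc:  # pyteomics raises PyteomicsError
            raise UnknownResidueError(f"unknown element symbol {element!r}") from exc
    return total


def _mod_mass(mod: str | float | Mapping[str, int]) -> float:
    if isinstance(mod, str):
        try:
            return composition_mass(MODIFICATIONS[mod])
        except KeyError:
            raise KeyError(f"unknown modification name {mod!r}") from None
    if isinstance(mod, Mapping):
        return composition_mass(mod)
    return float(mod)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with an optional N-terminal modification and a list
    of site-localized modifications.

    ``mods`` entries are ``(position, modification)`` with 1-based positions;
    a modification is a name from :data:`MODIFICATIONS`, an elemental
    composition, or a bare delta mass in Da (used for cross-link remnants).
    """

    sequence: str
    nterm: str | None = None
    mods: tuple[tuple[int, str | float], ...] = ()

    def __post_init__(self) -> None:
        for code in self.sequence:
            if code not in RESIDUE_MASSES:
                raise UnknownResidueError(f"unknown residue {code!r} in {self.sequence!r}")
        for pos, _ in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )

    def with_mod(self, position: int, mod: str | float) -> "ModifiedPeptide":
        return ModifiedPeptide(self.sequence, self.nterm, self.mods + ((position, mod),))

    @property
    def neutral_mass(self) -> float:
        return peptide_neutral_mass(self)


def peptide_neutral_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residues + water + N-terminal and site mods."""
    total = WATER
    for code in p.sequence:
        total += RESIDUE_MASSES[code]
    if p.nterm is not None:
        total += _mod_mass(p.nterm)
    for _, mod in p.mods:
        total += _mod_mass(mod)
    if total <= 0:
        raise ValueError("peptide neutral mass must be positive")
    return total


@dataclass(frozen=True)
class Linker:
    """A heterobifunctional K-C cross-linker.

    ``bridge`` is the net atom composition sitting between the lysine Nzeta
    and the cysteine Sgamma after both coupling reactions and before
    oxidation.  Shipped definitions: SIA C2H2O, SBAP C5H7NO2, SIAB C9H7NO2.
    """

    name: str
    spacer_angstrom: float
    bridge: Composition
    amine_side: str = "NHS ester"
    thiol_side: str = "haloacetamide"

    def __post_init__(self) -> None:
        if self.spacer_angstrom <= 0:
            raise ValueError("spacer length must be positive")
        if composition_mass(self.bridge) <= 0:
            raise ValueError("bridge composition mass must be positive")


BUILTIN_LINKERS: Mapping[str, Linker] = {
    "SIA": Linker("SIA", 4.2, Composition(formula="C2H2O")),
    "SBAP": Linker("SBAP", 9.0, Composition(formula="C5H7NO2")),
    "SIAB": Linker("SIAB", 10.6, Composition(formula="C9H7NO2")),
}


def get_linker(name: str) -> Linker:
    try:
        return BUILTIN_LINKERS[name]
    except KeyError:
        raise KeyError(
            f"unknown linker {name!r}; register it via load_linkers()"
        ) from None


def load_linkers(path: str | Path) -> dict[str, Linker]:
    """Load user linker definitions from a JSON or TOML config.

    Each entry needs ``name``, ``spacer_angstrom`` and ``bridge`` (an
    element -> count map).  Returns name -> Linker.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    entries = data["linkers"] if isinstance(data, dict) and "linkers" in data else data
    if isinstance(entries, dict):
        entries = [dict(v, name=k) for k, v in entries.items()]
    out: dict[str, Linker] = {}
    for entry in entries:
        linker = Linker(
            name=entry["name"],
            spacer_angstrom=float(entry["spacer_angstrom"]),
            bridge=Composition(dict(entry["bridge"])),
            amine_side=entry.get("amine_side", "NHS ester"),
            thiol_side=entry.get("thiol_side", "haloacetamide"),
        )
        out[linker.name] = linker
    return out


class RemnantSet(NamedTuple):
    """Delta masses (Da) produced by oxidation and C-S cleavage of a K-C link."""

    intact_ox_addition: float
    alpha_S_mod: float
    alpha_T_mod: float
    beta_A_mod: float
    rsoh_loss: float


def remnants_for(linker: Linker) -> RemnantSet:
    """Remnant masses for an oxidized K-C cross-link of ``linker``.

    The intact oxidized link adds ``bridge + O - 2H`` to the sum of the two
    peptide neutral masses (one H lost from the lysine amine at NHS coupling,
    one from the cysteine thiol at alkylation, one O gained on sulfur).
    Homolysis of the C-S bond with H rearrangement puts ``-H2S`` on the
    cysteine peptide (alkene remnant) and the remainder on the lysine peptide
    (sulfenic acid remnant); dehydration of the latter gives the
    unsaturated-thiol remnant.
    """
    intact = (
        composition_mass(linker.bridge)
        + composition_mass(Composition(formula="O"))
        - composition_mass(Composition(formula="H2"))
    )
    beta_a = -H2S
    alpha_s = intact - beta_a
    return RemnantSet(
        intact_ox_addition=intact,
        alpha_S_mod=alpha_s,
        alpha_T_mod=alpha_s - WATER,
        beta_A_mod=beta_a,
        rsoh_loss=RSOH_LOSS,
    )


def preoxidation_addition(linker: Linker) -> float:
    """Mass added by the non-cleavable (pre-oxidation) cross-link: bridge - 2H."""
    return composition_mass(linker.bridge) - composition_mass(Composition(formula="H2"))


def deadend_hydrolyzed_mod(linker: Linker) -> float:
    """Lysine mono-link with the thiol-reactive side hydrolyzed: bridge + O."""
    return composition_mass(linker.bridge) + composition_mass(Composition(formula="O"))


def deadend_cysteine_quenched_mod(linker: Linker) -> float:
    """Lysine mono-link quenched by free cysteine: bridge - 2H + Cys(C3H7NO2S)."""
    return (
        composition_mass(linker.bridge)
        - composition_mass(Composition(formula="H2"))
        + _pmass.calculate_mass(formula="C3H7NO2S")
    )


@dataclass(frozen=True)
class CrossLinkedPair:
    """An alpha (lysine-side) / beta (cysteine-side) cross-linked peptide pair."""

    alpha: ModifiedPeptide
    alpha_site: int
    beta: ModifiedPeptide
    beta_site: int
    linker: Linker
    oxidized: bool = True

    def __post_init__(self) -> None:
        if self.alpha.sequence[self.alpha_site - 1] != "K":
            raise ValueError(f"alpha position {self.alpha_site} is not K")
        if self.beta.sequence[self.beta_site - 1] != "C":
            raise ValueError(f"beta position {self.beta_site} is not C")

    @property
    def neutral_mass(self) -> float:
        addition = (
            remnants_for(self.linker).intact_ox_addition
            if self.oxidized
            else preoxidation_addition(self.linker)
        )
        return peptide_neutral_mass(self.alpha) + peptide_neutral_mass(self.beta) + addition


def neutral_to_mz(neutral: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral + charge * PROTON) / charge


def mz_to_neutral(mz: float, charge: int) -> float:
    """Invert protonation: neutral = z*mz - z*proton."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return charge * (mz - PROTON)


def precursor_mz(pair: CrossLinkedPair, charge: int) -> float:
    return neutral_to_mz(pair.neutral_mass, charge)


class SignatureMzs(NamedTuple):
    alpha_S: float
    alpha_T: float
    beta_A: float


def signature_fragment_neutrals(pair: CrossLinkedPair) -> tuple[float, float, float]:
    """Neutral masses of the alpha_S, alpha_T and beta_A cleavage fragments."""
    rem = remnants_for(pair.linker)
    a = peptide_neutral_mass(pair.alpha)
    b = peptide_neutral_mass(pair.beta)
    return a + rem.alpha_S_mod, a + rem.alpha_T_mod, b + rem.beta_A_mod


def signature_fragment_mzs(
    pair: CrossLinkedPair, charge_alpha: int, charge_beta: int
) -> SignatureMzs:
    """m/z of the three signature fragments at the given charges."""
    n_as, n_at, n_ba = signature_fragment_neutrals(pair)
    return SignatureMzs(
        alpha_S=neutral_to_mz(n_as, charge_alpha),
        alpha_T=neutral_to_mz(n_at, charge_alpha),
        beta_A=neutral_to_mz(n_ba, charge_beta),
    )


def remnant_peptide(pair: CrossLinkedPair, kind: str) -> ModifiedPeptide:
    """The single-peptide species carrying the named remnant (for MS3 ladders).

    ``kind`` is one of ``alpha_S``, ``alpha_T``, ``beta_A``.
    """
    rem = remnants_for(pair.linker)
    if kind == "alpha_S":
        return pair.alpha.with_mod(pair.alpha_site, rem.alpha_S_mod)
    if kind == "alpha_T":
        return pair.alpha.with_mod(pair.alpha_site, rem.alpha_T_mod)
    if kind == "beta_A":
        return pair.beta.with_mod(pair.beta_site, rem.beta_A_mod)
    raise ValueError(f"unknown remnant kind {kind!r}")


class FragmentIon(NamedTuple):
    series: str  # 'b' or 'y'
    index: int
    charge: int
    mz: float


def fragment_ladder(
    p: ModifiedPeptide,
    series: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[FragmentIon]:
    """Theoretical b/y sequence ions with site modifications kept in place.

    N-terminal modifications travel with the b series; site modifications
    shift every fragment that contains their residue.
    """
    n = len(p.sequence)
    res = [RESIDUE_MASSES[c] for c in p.sequence]
    site_mod = [0.0] * n
    for pos, mod in p.mods:
        site_mod[pos - 1] += _mod_mass(mod)
    nterm_mass = _mod_mass(p.nterm) if p.nterm is not None else 0.0

    ions: list[FragmentIon] = []
    series = tuple(series)
    if "b" in series:
        running = nterm_mass
        for i in range(1, n):  # b_n is not a sequence ion
            running += res[i - 1] + site_mod[i - 1]
            for z in range(1, max_charge + 1):
                ions.append(FragmentIon("b", i, z, neutral_to_mz(running, z)))
    if "y" in series:
        running = WATER
        for i in range(1, n + 1):
            running += res[n - i] + site_mod[n - i]
            if n - i == 0:  # y_n contains residue 1 and its N-terminal mod
                running += nterm_mass
            for z in range(1, max_charge + 1):
                ions.append(FragmentIon("y", i, z, neutral_to_mz(running, z)))
    return ions


def ppm_error(measured: float, theoretical: float) -> float:
    return (measured - theoretical) / theoretical * 1e6


def within_ppm(measured: float, theoretical: float, tol_ppm: float) -> bool:
    return abs(ppm_error(measured, theoretical)) <= tol_ppm
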