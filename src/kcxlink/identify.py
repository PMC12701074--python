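"""Cross-link identification: digestion, signature-pair detection, MS3 and
stepped-HCD MS2 search, target-decoy FDR, and linkage aggregation.

Two acquisition modes are supported.  In the MSn mode, an oxidized K-C
cross-link precursor cleaves in MS2 into an alpha_S/beta_A signature fragment
pair whose neutral masses sum to the precursor neutral; the fragments are then
sequenced in MS3 and both identifications are integrated with the MS1 mass.
In the MS2 (stepped-HCD) mode a single spectrum carries both the signature
doublet and the sequence ions of both peptides, and candidate alpha/beta pairs
are enumerated directly against the precursor mass.

Matches are scored with a binomial-tail score: given ``n`` theoretical b/y
ions of which ``k`` match within tolerance, and a per-ion random-match
probability ``p`` estimated from the spectrum's peak density, the score is
``-log10 P(X >= k)`` for ``X ~ Binomial(n, p)``.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .chemistry import (
    MODIFICATIONS,
    PROTON,
    WATER,
    Linker,
    ModifiedPeptide,
    composition_mass,
    fragment_ladder,
    mz_to_neutral,
    remnants_for,
)
from .spectra import Run, Spectrum

CAM: float = composition_mass(MODIFICATIONS["carbamidomethyl"])

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Tolerances:
    """Mass tolerances (all configurable; defaults suit an Orbitrap MS1/MS2
    with ion-trap MS3)."""

    precursor_ppm: float = 10.0
    ms2_ppm: float = 20.0
    ms3_da: float = 0.6
    alpha_t_da: float = 0.02


@dataclass(frozen=True)
class IndexedPeptide:
    """One digested peptide (target or decoy).

    ``locations`` are ``(protein_id, start)`` pairs, 1-based start, for every
    protein sharing the sequence.  ``k_sites``/``c_sites`` are 1-based
    positions within the peptide that can carry the cross-link (a linkable K
    must be internal, or terminal only at the protein C-terminus, because a
    cross-linked K is not cleaved).  ``mass_all_cam`` is the neutral mass with
    fixed carbamidomethyl on every cysteine.  Decoy coordinates refer to the
    source target peptide.
    """

    sequence: str
    locations: tuple[tuple[str, int], ...]
    missed_cleavages: int
    k_sites: tuple[int, ...]
    c_sites: tuple[int, ...]
    is_decoy: bool
    shared_with_target: bool = False

    @property
    def mass_all_cam(self) -> float:
        return ModifiedPeptide(
            self.sequence,
            mods=tuple((i, "carbamidomethyl") for i in self.c_sites),
        ).neutral_mass

    @property
    def n_cys(self) -> int:
        return len(self.c_sites)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(loc[0] for loc in self.locations)


class PeptideIndex:
    """Mass-sorted access to digested peptides."""

    def __init__(self, entries: Sequence[IndexedPeptide], proteins: Mapping[str, str]):
        self.entries = list(entries)
        self.proteins = dict(proteins)
        self._masses = np.array([e.mass_all_cam for e in self.entries])
        self._order = np.argsort(self._masses, kind="stable")
        self._sorted = self._masses[self._order]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def has_decoys(self) -> bool:
        return any(e.is_decoy for e in self.entries)

    def lookup(self, mass_all_cam: float, tol_ppm: float) -> list[IndexedPeptide]:
        """Entries whose all-CAM mass lies within ``tol_ppm`` of the query."""
        delta = mass_all_cam * tol_ppm * 1e-6
        lo = np.searchsorted(self._sorted, mass_all_cam - delta, side="left")
        hi = np.searchsorted(self._sorted, mass_all_cam + delta, side="right")
        return [self.entries[i] for i in self._order[lo:hi]]

    def alpha_candidates(self) -> list[IndexedPeptide]:
        return [e for e in self.entries if e.k_sites]

    def beta_candidates(self) -> list[IndexedPeptide]:
        return [e for e in self.entries if e.c_sites]


def _cleavage_points(seq: str) -> list[int]:
    # trypsin: cleave after K/R unless followed by P
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def _reverse_keep_terminus(seq: str) -> str:
    return seq[:-1][::-1] + seq[-1] if len(seq) > 1 else seq


def _read_fasta(path: str | Path) -> dict[str, str]:
    from pyteomics import fasta as _fasta

    out: dict[str, str] = {}
    with _fasta.FASTA(str(path)) as reader:
        for header, seq in reader:
            out[header.split()[0]] = seq
    return out


def digest(
    fasta: str | Path | Mapping[str, str],
    enzyme: str = "trypsin",
    missed_cleavages: int = 2,
    length_range: tuple[int, int] = (5, 50),
    decoy_mode: str | None = "reverse",
) -> PeptideIndex:
    """In-silico digestion of a FASTA database (or id -> sequence mapping).

    Cross-linked lysines are not cleaved, so linkable K positions are
    restricted to internal residues (or the protein C-terminus) and an
    internal K already counts as a missed cleavage.  Decoys (``reverse``
    mode) are full-sequence reversals keeping the C-terminal residue; a decoy
    colliding with a target sequence is flagged ``shared_with_target`` and
    excluded from decoy accounting downstream.
    """
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    proteins = dict(fasta) if isinstance(fasta, Mapping) else _read_fasta(fasta)
    if not proteins:
        raise ValueError("empty sequence database")

    lo, hi = length_range
    peptides: dict[tuple[str, bool], dict] = {}

    def add(seq: str, pid: str, start: int, missed: int, protein_len: int, decoy: bool):
        if not (lo <= len(seq) <= hi):
            return
        key = (seq, decoy)
        if key not in peptides:
            end_in_protein = start + len(seq) - 1
            k_sites = tuple(
                i + 1
                for i, c in enumerate(seq)
                if c == "K" and (i + 1 < len(seq) or end_in_protein == protein_len)
            )
            c_sites = tuple(i + 1 for i, c in enumerate(seq) if c == "C")
            peptides[key] = {
                "locations": [],
                "missed": missed,
                "k_sites": k_sites,
                "c_sites": c_sites,
            }
        peptides[key]["locations"].append((pid, start))
        peptides[key]["missed"] = min(peptides[key]["missed"], missed)

    for pid, seq in proteins.items():
        if not seq or set(seq) - _VALID_RESIDUES:
            warnings.warn(f"skipping protein {pid!r}: non-standard residues")
            continue
        for decoy in ([False, True] if decoy_mode == "reverse" else [False]):
            pseq = _reverse_keep_terminus(seq) if decoy else seq
            dpid = f"DECOY_{pid}" if decoy else pid
            cuts = [0] + _cleavage_points(pseq) + [len(pseq)]
            for i in range(len(cuts) - 1):
                for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
                    add(
                        pseq[cuts[i] : cuts[j]],
                        dpid,
                        cuts[i] + 1,
                        j - i - 1,
                        len(pseq),
                        decoy,
                    )

    target_seqs = {seq for (seq, decoy) in peptides if not decoy}
    entries = [
        IndexedPeptide(
            sequence=seq,
            locations=tuple(sorted(set(info["locations"]))),
            missed_cleavages=info["missed"],
            k_sites=info["k_sites"],
            c_sites=info["c_sites"],
            is_decoy=decoy,
            shared_with_target=decoy and seq in target_seqs,
        )
        for (seq, decoy), info in peptides.items()
    ]
    if not any(not e.is_decoy for e in entries):
        raise ValueError("digestion produced no target peptides")
    return PeptideIndex(entries, proteins)


# ---------------------------------------------------------------------------
# signature-pair detection (MS2)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignaturePair:
    """An alpha_S/beta_A candidate peak pair whose neutral masses sum to the
    precursor neutral.  ``alpha_assigned`` is True only when an alpha_T
    corroborating peak (alpha_S - H2O) fixed the orientation; otherwise the
    alpha/beta designation is provisional and both orientations are tried
    downstream."""

    scan_id: int
    alpha_mz: float
    alpha_charge: int
    alpha_intensity: float
    beta_mz: float
    beta_charge: int
    beta_intensity: float
    precursor_neutral: float
    ppm_error: float
    linker: str
    alpha_t_mz: float | None = None
    alpha_assigned: bool = False

    @property
    def alpha_neutral(self) -> float:
        return mz_to_neutral(self.alpha_mz, self.alpha_charge)

    @property
    def beta_neutral(self) -> float:
        return mz_to_neutral(self.beta_mz, self.beta_charge)

    @property
    def summed_intensity(self) -> float:
        return self.alpha_intensity + self.beta_intensity


def detect_signature_pairs(
    ms2: Spectrum,
    linker: Linker | str,
    tol: Tolerances = Tolerances(),
    max_fragment_charge: int | None = None,
) -> list[SignaturePair]:
    """All peak pairs (over charge hypotheses) consistent with C-S cleavage.

    Charge hypotheses run over 1..z-1 per fragment with the pair summing to
    at most the precursor charge; the mass constraint is
    ``|neutral(a) + neutral(b) - neutral(precursor)| <= tol`` (ppm of the
    precursor neutral).  Pairs are ranked by summed intensity.
    """
    linker_name = linker if isinstance(linker, str) else linker.name
    z = ms2.precursor_charge
    if not z or ms2.precursor_mz is None or ms2.n_peaks < 2:
        return []
    M = mz_to_neutral(ms2.precursor_mz, z)
    zmax = max_fragment_charge or z - 1
    tol_da = M * tol.ms2_ppm * 1e-6

    mz = ms2.mz
    inten = ms2.intensity
    # candidate neutrals: (peak index, charge, neutral)
    cand: list[tuple[int, int, float]] = []
    for zc in range(1, min(zmax, z - 1) + 1):
        for i in range(ms2.n_peaks):
            cand.append((i, zc, mz_to_neutral(mz[i], zc)))
    neutrals = np.array([c[2] for c in cand])
    order = np.argsort(neutrals)
    sorted_neutrals = neutrals[order]

    pairs: list[SignaturePair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for a_idx, (i, za, na) in enumerate(cand):
        need = M - na
        lo = np.searchsorted(sorted_neutrals, need - tol_da, side="left")
        hi = np.searchsorted(sorted_neutrals, need + tol_da, side="right")
        for pos in range(lo, hi):
            j, zb, nb = cand[order[pos]]
            if j == i or za + zb > z:
                continue
            key = (min((i, za), (j, zb)), max((i, za), (j, zb)))
            flat = (key[0][0], key[0][1], key[1][0], key[1][1])
            if flat in seen:
                continue
            seen.add(flat)
            ppm = (na + nb - M) / M * 1e6
            # alpha_T corroboration: a peak at candidate alpha_S - H2O
            def _t_peak(mz_s: float, z_s: int) -> float | None:
                target = mz_s - WATER / z_s
                k = np.searchsorted(mz, target)
                for kk in (k - 1, k):
                    if 0 <= kk < mz.size and abs(mz[kk] - target) <= tol.alpha_t_da:
                        return float(mz[kk])
                return None

            t_i = _t_peak(mz[i], za)
            t_j = _t_peak(mz[j], zb)
            if t_j is not None and t_i is None:
                ai, az, bi, bz, t_mz, assigned = j, zb, i, za, t_j, True
            else:
                ai, az, bi, bz, t_mz, assigned = i, za, j, zb, t_i, t_i is not None
            pairs.append(
                SignaturePair(
                    scan_id=ms2.scan_id,
                    alpha_mz=float(mz[ai]),
                    alpha_charge=az,
                    alpha_intensity=float(inten[ai]),
                    beta_mz=float(mz[bi]),
                    beta_charge=bz,
                    beta_intensity=float(inten[bi]),
                    precursor_neutral=M,
                    ppm_error=ppm,
                    linker=linker_name,
                    alpha_t_mz=t_mz,
                    alpha_assigned=assigned,
                )
            )
    pairs.sort(key=lambda p: -p.summed_intensity)
    return pairs


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _match_count(
    peaks_mz: np.ndarray, theory_mz: Sequence[float], tol_da: float | None, tol_ppm: float | None
) -> int:
    """Number of theoretical ions with at least one peak within tolerance."""
    k = 0
    for t in theory_mz:
        tol = tol_da if tol_da is not None else t * tol_ppm * 1e-6
        idx = np.searchsorted(peaks_mz, t)
        hit = False
        for ii in (idx - 1, idx):
            if 0 <= ii < peaks_mz.size and abs(peaks_mz[ii] - t) <= tol:
                hit = True
        k += hit
    return k


def binomial_score(k: int, n: int, p: float) -> float:
    """-log10 of the binomial tail P(X >= k) for X ~ B(n, p)."""
    if k <= 0 or n <= 0:
        return 0.0
    p = min(max(p, 1e-9), 0.999)
    tail = _stats.binom.sf(k - 1, n, p)
    return float(-np.log10(max(tail, 1e-300)))


def _random_match_p(spectrum: Spectrum, tol_da: float) -> float:
    if spectrum.n_peaks < 2:
        return 1e-6
    span = float(spectrum.mz[-1] - spectrum.mz[0])
    if span <= 0:
        return 1e-6
    return min(0.5, max(1e-6, spectrum.n_peaks * 2.0 * tol_da / span))


def score_peptide_on_spectrum(
    spectrum: Spectrum,
    peptide: ModifiedPeptide,
    tol_da: float | None = None,
    tol_ppm: float | None = None,
    max_fragment_charge: int = 2,
) -> tuple[float, int, int]:
    """(score, matched, total) for b/y ions of ``peptide`` in ``spectrum``."""
    ions = fragment_ladder(peptide, ("b", "y"), max_charge=max_fragment_charge)
    theory = [ion.mz for ion in ions]
    k = _match_count(spectrum.mz, theory, tol_da, tol_ppm)
    mean_tol = (
        tol_da
        if tol_da is not None
        else float(np.mean(theory)) * tol_ppm * 1e-6
    )
    return binomial_score(k, len(theory), _random_match_p(spectrum, mean_tol)), k, len(theory)


# ---------------------------------------------------------------------------
# MS3 peptide matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    scan_id: int
    peptide: IndexedPeptide
    site: int
    remnant: str  # alpha_S | alpha_T | beta_A
    score: float
    matched: int
    total: int
    precursor_ppm: float

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy and not self.peptide.shared_with_target


def _remnant_modified(entry: IndexedPeptide, site: int, remnant: str, rem_mass: float) -> ModifiedPeptide:
    """Peptide with the remnant at ``site`` and fixed CAM on other cysteines."""
    mods: list[tuple[int, str | float]] = [(site, rem_mass)]
    for c in entry.c_sites:
        if not (remnant == "beta_A" and c == site):
            mods.append((c, "carbamidomethyl"))
    return ModifiedPeptide(entry.sequence, mods=tuple(mods))


def _psm_sort_key(psm: PeptideSpectrumMatch):
    return (-psm.score, abs(psm.precursor_ppm), psm.peptide.sequence)


def match_ms3(
    ms3: Spectrum,
    index: PeptideIndex,
    linker: Linker,
    tol: Tolerances = Tolerances(),
    remnants: Iterable[str] = ("alpha_S", "alpha_T", "beta_A"),
) -> list[PeptideSpectrumMatch]:
    """Match an MS3 spectrum of a remnant-carrying signature fragment.

    Candidates are peptides whose (all-CAM) mass plus the remnant delta
    equals the MS3 precursor neutral within the precursor ppm tolerance; the
    remnant localizes on a linkable K (alpha remnants) or on C (beta_A).
    Results are ranked by score with deterministic tie-breaking (smaller
    absolute precursor ppm error, then sequence).
    """
    rem = remnants_for(linker)
    sel_mz = ms3.selected_mz if ms3.selected_mz is not None else ms3.precursor_mz
    if sel_mz is None:
        return []
    charges = [ms3.precursor_charge] if ms3.precursor_charge else [1, 2]
    out: list[PeptideSpectrumMatch] = []
    for z in charges:
        prec_neutral = mz_to_neutral(sel_mz, z)
        for kind in remnants:
            if kind == "alpha_S":
                rem_mass, query_shift = rem.alpha_S_mod, 0.0
            elif kind == "alpha_T":
                rem_mass, query_shift = rem.alpha_T_mod, 0.0
            elif kind == "beta_A":
                # the linked C carries the remnant instead of CAM
                rem_mass, query_shift = rem.beta_A_mod, CAM
            else:
                raise ValueError(f"unknown remnant kind {kind!r}")
            query = prec_neutral - rem_mass + query_shift
            for entry in index.lookup(query, tol.precursor_ppm):
                sites = entry.k_sites if kind.startswith("alpha") else entry.c_sites
                for site in sites:
                    pep = _remnant_modified(entry, site, kind, rem_mass)
                    theo_prec = pep.neutral_mass
                    score, k, n = score_peptide_on_spectrum(
                        ms3, pep, tol_da=tol.ms3_da, max_fragment_charge=min(2, max(1, z))
                    )
                    out.append(
                        PeptideSpectrumMatch(
                            scan_id=ms3.scan_id,
                            peptide=entry,
                            site=site,
                            remnant=kind,
                            score=score,
                            matched=k,
                            total=n,
                            precursor_ppm=(prec_neutral - theo_prec) / theo_prec * 1e6,
                        )
                    )
    out.sort(key=_psm_sort_key)
    return out


# ---------------------------------------------------------------------------
# CSM assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossLinkSpectrumMatch:
    """One scored alpha-beta peptide-pair assignment for a precursor scan."""

    scan_id: int
    alpha: PeptideSpectrumMatch
    beta: PeptideSpectrumMatch
    score: float
    precursor_ppm: float
    linker: str
    replicate: str = ""
    mode: str = "msn"
    single_sided: bool = False

    @property
    def decoy_class(self) -> str:
        a, b = self.alpha.is_decoy, self.beta.is_decoy
        if a and b:
            return "DD"
        if a or b:
            return "TD"
        return "TT"


def _pair_precursor_ppm(
    alpha: IndexedPeptide, beta: IndexedPeptide, linker: Linker, M: float
) -> float:
    theo = alpha.mass_all_cam + beta.mass_all_cam - CAM + remnants_for(linker).intact_ox_addition
    return (M - theo) / theo * 1e6


def integrate_msn(
    run: Run,
    pairs_by_scan: Mapping[int, Sequence[SignaturePair]],
    psms_by_scan: Mapping[int, Sequence[PeptideSpectrumMatch]],
    linker: Linker,
    tol: Tolerances = Tolerances(),
) -> list[CrossLinkSpectrumMatch]:
    """Integrate MS1/MS2/MS3 evidence into cross-link spectrum matches.

    A CSM requires (i) an MS2 signature pair, (ii) MS3 identifications whose
    selected-fragment masses match the pair's alpha (alpha_S or alpha_T) and
    beta masses, and (iii) the alpha + beta + intact-addition sum matching
    the MS1 precursor neutral within tolerance.  Single-sided MS3 evidence is
    emitted with ``single_sided=True`` (excluded from default FDR reporting).
    """
    rem = remnants_for(linker)
    out: list[CrossLinkSpectrumMatch] = []
    for ms2 in run.by_level(2):
        pairs = pairs_by_scan.get(ms2.scan_id, [])
        if not pairs or ms2.precursor_mz is None or not ms2.precursor_charge:
            continue
        M = mz_to_neutral(ms2.precursor_mz, ms2.precursor_charge)
        children = [s for s in run.children_of(ms2.scan_id) if s.ms_level == 3]
        child_psms: list[PeptideSpectrumMatch] = []
        for child in children:
            child_psms.extend(psms_by_scan.get(child.scan_id, []))
        if not child_psms:
            continue
        sel_neutral: dict[int, float] = {}
        for child in children:
            sel = child.selected_mz if child.selected_mz is not None else child.precursor_mz
            z = child.precursor_charge or 1
            if sel is not None:
                sel_neutral[child.scan_id] = mz_to_neutral(sel, z)

        best_for_pair: list[CrossLinkSpectrumMatch] = []
        for pair in pairs:
            orientations = [(pair.alpha_neutral, pair.beta_neutral)]
            if not pair.alpha_assigned:
                orientations.append((pair.beta_neutral, pair.alpha_neutral))
            for n_alpha, n_beta in orientations:
                tol_da = max(n_alpha, n_beta) * tol.ms2_ppm * 1e-6

                def side_psms(target_neutral: float, kinds: tuple[str, ...], also: float | None = None):
                    sel: list[PeptideSpectrumMatch] = []
                    for psm in child_psms:
                        if psm.remnant not in kinds:
                            continue
                        nsel = sel_neutral.get(psm.scan_id)
                        if nsel is None:
                            continue
                        ok = abs(nsel - target_neutral) <= tol_da
                        if also is not None:
                            ok = ok or abs(nsel - also) <= tol_da
                        if ok:
                            sel.append(psm)
                    return sorted(sel, key=_psm_sort_key)

                alphas = side_psms(n_alpha, ("alpha_S", "alpha_T"), also=n_alpha - WATER)
                betas = side_psms(n_beta, ("beta_A",))
                if alphas and betas:
                    a, b = alphas[0], betas[0]
                    ppm = _pair_precursor_ppm(a.peptide, b.peptide, linker, M)
                    if abs(ppm) <= tol.precursor_ppm:
                        best_for_pair.append(
                            CrossLinkSpectrumMatch(
                                scan_id=ms2.scan_id,
                                alpha=a,
                                beta=b,
                                score=a.score + b.score,
                                precursor_ppm=ppm,
                                linker=linker.name,
                                replicate=run.replicate,
                                mode="msn",
                            )
                        )
                elif alphas or betas:
                    side = alphas[0] if alphas else betas[0]
                    best_for_pair.append(
                        CrossLinkSpectrumMatch(
                            scan_id=ms2.scan_id,
                            alpha=side if alphas else side,
                            beta=side,
                            score=side.score,
                            precursor_ppm=float("nan"),
                            linker=linker.name,
                            replicate=run.replicate,
                            mode="msn",
                            single_sided=True,
                        )
                    )
        if best_for_pair:
            two_sided = [c for c in best_for_pair if not c.single_sided]
            pool = two_sided or best_for_pair
            pool.sort(key=lambda c: (-c.score, abs(c.precursor_ppm) if c.precursor_ppm == c.precursor_ppm else 1e9))
            out.append(pool[0])
    return out


def search_msn(
    run: Run,
    index: PeptideIndex,
    linker: Linker,
    tol: Tolerances = Tolerances(),
    charge_range: tuple[int, int] = (1, 99),
) -> list[CrossLinkSpectrumMatch]:
    """Full MSn-mode search: signature pairs on MS2, peptide matching on MS3,
    MS1/MS2/MS3 integration.  ``charge_range`` restricts which MS2 precursors
    are considered (the acquisition already preselected 4+ to 8+)."""
    lo, hi = charge_range
    pairs_by_scan: dict[int, list[SignaturePair]] = {}
    for ms2 in run.by_level(2):
        if ms2.precursor_charge and lo <= ms2.precursor_charge <= hi:
            pairs_by_scan[ms2.scan_id] = detect_signature_pairs(ms2, linker, tol)
    psms_by_scan: dict[int, list[PeptideSpectrumMatch]] = {}
    for ms3 in run.by_level(3):
        if ms3.orphan:
            continue
        psms_by_scan[ms3.scan_id] = match_ms3(ms3, index, linker, tol)
    return integrate_msn(run, pairs_by_scan, psms_by_scan, linker, tol)


def search_ms2_stepped_hcd(
    ms2: Spectrum,
    index: PeptideIndex,
    linker: Linker,
    tol: Tolerances = Tolerances(),
    use_signature_constraint: bool = True,
    max_candidates: int = 2000,
) -> list[CrossLinkSpectrumMatch]:
    """Single-spectrum stepped-HCD search.

    Candidate alpha(K)/beta(C) pairs are enumerated so that
    ``mass(alpha) + mass(beta) + intact_ox_addition`` matches the precursor
    neutral within tolerance; when a signature doublet is detected it
    constrains the alpha-side mass.  Each side is scored on its
    remnant-modified sequence ions in the same spectrum; the combined score
    is the sum."""
    if ms2.precursor_mz is None or not ms2.precursor_charge:
        return []
    rem = remnants_for(linker)
    M = mz_to_neutral(ms2.precursor_mz, ms2.precursor_charge)
    target = M - rem.intact_ox_addition + CAM  # = alpha_all_cam + beta_all_cam
    tol_da = M * tol.precursor_ppm * 1e-6

    allowed_alpha: list[float] | None = None
    if use_signature_constraint:
        pairs = detect_signature_pairs(ms2, linker, tol)
        if pairs:
            allowed_alpha = []
            for p in pairs[:16]:
                for n in (p.alpha_neutral, p.beta_neutral):
                    allowed_alpha.append(n - rem.alpha_S_mod)
                    allowed_alpha.append(n - rem.alpha_T_mod)

    out: list[CrossLinkSpectrumMatch] = []
    n_eval = 0
    for alpha in index.alpha_candidates():
        ma = alpha.mass_all_cam
        if allowed_alpha is not None and not any(
            abs(ma - x) <= ma * 2 * tol.ms2_ppm * 1e-6 for x in allowed_alpha
        ):
            continue
        need = target - ma
        for beta in index.lookup(need, tol_da / max(need, 1.0) * 1e6):
            if not beta.c_sites:
                continue
            n_eval += 1
            if n_eval > max_candidates:
                break
            a_site = alpha.k_sites[0]
            b_site = beta.c_sites[0]
            best = None
            for a_site in alpha.k_sites:
                pa = _remnant_modified(alpha, a_site, "alpha_S", rem.alpha_S_mod)
                sa, ka, na = score_peptide_on_spectrum(ms2, pa, tol_ppm=tol.ms2_ppm)
                for b_site in beta.c_sites:
                    pb = _remnant_modified(beta, b_site, "beta_A", rem.beta_A_mod)
                    sb, kb, nb = score_peptide_on_spectrum(ms2, pb, tol_ppm=tol.ms2_ppm)
                    if best is None or sa + sb > best[0]:
                        best = (sa + sb, a_site, b_site, sa, ka, na, sb, kb, nb)
            if best is None:
                continue
            score, a_site, b_site, sa, ka, na, sb, kb, nb = best
            ppm = _pair_precursor_ppm(alpha, beta, linker, M)
            if abs(ppm) > tol.precursor_ppm:
                continue
            out.append(
                CrossLinkSpectrumMatch(
                    scan_id=ms2.scan_id,
                    alpha=PeptideSpectrumMatch(
                        ms2.scan_id, alpha, a_site, "alpha_S", sa, ka, na, ppm
                    ),
                    beta=PeptideSpectrumMatch(
                        ms2.scan_id, beta, b_site, "beta_A", sb, kb, nb, ppm
                    ),
                    score=score,
                    precursor_ppm=ppm,
                    linker=linker.name,
                    mode="ms2",
                )
            )
    out.sort(key=lambda c: (-c.score, abs(c.precursor_ppm), c.alpha.peptide.sequence, c.beta.peptide.sequence))
    return out


def search_ms2_run(
    run: Run,
    index: PeptideIndex,
    linker: Linker,
    tol: Tolerances = Tolerances(),
    charge_range: tuple[int, int] = (4, 8),
) -> list[CrossLinkSpectrumMatch]:
    """Rank-1 stepped-HCD CSM per selected MS2 spectrum."""
    out: list[CrossLinkSpectrumMatch] = []
    for ms2 in run.by_level(2):
        if not ms2.precursor_charge:
            continue
        if not (charge_range[0] <= ms2.precursor_charge <= charge_range[1]):
            continue
        ranked = search_ms2_stepped_hcd(ms2, index, linker, tol)
        if ranked:
            out.append(replace(ranked[0], replicate=run.replicate))
    return out


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


@dataclass
class FDRResult:
    """Target-decoy FDR over a CSM list: per-CSM q-values (aligned with the
    input order) and the score threshold achieving the requested level."""

    qvalues: np.ndarray
    scores: np.ndarray
    classes: list[str]
    threshold: float
    n_tt: int
    n_td: int
    n_dd: int


def estimate_fdr(
    csms: Sequence[CrossLinkSpectrumMatch],
    fdr_level: float = 0.01,
    decoys_searched: bool = True,
) -> FDRResult:
    """FDR(t) = max(0, TD(t) - DD(t)) / TT(t) over a descending score scan;
    q-values are the running minimum.  ``decoys_searched=False`` (a search
    run without decoy sequences) makes the estimator undefined and raises."""
    if not decoys_searched:
        raise ValueError("FDR is undefined for a search without decoys")
    if not csms:
        raise ValueError("cannot estimate FDR from an empty CSM list")
    csms = [c for c in csms]
    scores = np.array([c.score for c in csms])
    classes = [c.decoy_class for c in csms]
    order = np.argsort(-scores, kind="stable")
    tt = np.cumsum([classes[i] == "TT" for i in order])
    td = np.cumsum([classes[i] == "TD" for i in order])
    dd = np.cumsum([classes[i] == "DD" for i in order])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.maximum(td - dd, 0) / np.maximum(tt, 1)
    fdr = np.minimum(fdr, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    qvalues = np.empty(len(csms))
    qvalues[order] = q_sorted
    passing = q_sorted <= fdr_level
    threshold = float(scores[order][passing][-1]) if passing.any() else float("inf")
    n = int(passing.sum())
    return FDRResult(
        qvalues=qvalues,
        scores=scores,
        classes=classes,
        threshold=threshold,
        n_tt=int(tt[n - 1]) if n else 0,
        n_td=int(td[n - 1]) if n else 0,
        n_dd=int(dd[n - 1]) if n else 0,
    )


def filter_at_fdr(
    csms: Sequence[CrossLinkSpectrumMatch],
    fdr_level: float = 0.01,
    keep_decoys: bool = False,
) -> list[CrossLinkSpectrumMatch]:
    """CSMs passing the requested FDR (two-sided evidence only; TT unless
    ``keep_decoys``)."""
    pool = [c for c in csms if not c.single_sided]
    if not pool:
        return []
    result = estimate_fdr(pool)
    out = [c for c, q in zip(pool, result.qvalues) if q <= fdr_level]
    if not keep_decoys:
        out = [c for c in out if c.decoy_class == "TT"]
    return out


# ---------------------------------------------------------------------------
# linkage aggregation
# ---------------------------------------------------------------------------


@dataclass
class UniqueLinkage:
    """A residue-to-residue K-C link aggregated over CSMs/linkers/replicates."""

    protein_a: str
    residue_k: int
    protein_b: str
    residue_c: int
    is_intra: bool
    support: dict[tuple[str, str], int] = field(default_factory=dict)
    best_score: float = 0.0
    csm_count: int = 0
    ambiguous: bool = False
    protein_a_candidates: tuple[str, ...] = ()
    protein_b_candidates: tuple[str, ...] = ()

    @property
    def linkers(self) -> set[str]:
        return {linker for linker, _ in self.support}

    def replicates_for(self, linker: str) -> set[str]:
        return {rep for lk, rep in self.support if lk == linker}


def collapse_to_unique_linkages(
    csms: Sequence[CrossLinkSpectrumMatch],
    proteins: Mapping[str, str],
) -> list[UniqueLinkage]:
    """Group FDR-passing CSMs by (protein A, K residue, protein B, C residue).

    Peptide positions are mapped to 1-based protein coordinates (verified to
    be K and C; a mismatch means index corruption and raises).  Linkages whose
    peptide maps to several proteins carry ``ambiguous=True`` with all
    candidate ids listed; the lexicographically first location is canonical.
    """
    linkages: dict[tuple[str, int, str, int], UniqueLinkage] = {}
    for csm in csms:
        if csm.single_sided or csm.decoy_class != "TT":
            continue

        def resolve(psm: PeptideSpectrumMatch, expected: str) -> tuple[str, int, tuple[str, ...]]:
            pid, start = psm.peptide.locations[0]
            residue = start + psm.site - 1
            seq = proteins.get(pid)
            if seq is None or residue > len(seq) or seq[residue - 1] != expected:
                raise ValueError(
                    f"index corruption: {psm.peptide.sequence!r} site {psm.site} "
                    f"does not map to {expected} in {pid!r}"
                )
            return pid, residue, psm.peptide.protein_ids

        pid_a, res_k, cands_a = resolve(csm.alpha, "K")
        pid_b, res_c, cands_b = resolve(csm.beta, "C")
        key = (pid_a, res_k, pid_b, res_c)
        link = linkages.get(key)
        if link is None:
            link = UniqueLinkage(
                protein_a=pid_a,
                residue_k=res_k,
                protein_b=pid_b,
                residue_c=res_c,
                is_intra=pid_a == pid_b,
                ambiguous=len(set(cands_a)) > 1 or len(set(cands_b)) > 1,
                protein_a_candidates=cands_a,
                protein_b_candidates=cands_b,
            )
            linkages[key] = link
        skey = (csm.linker, csm.replicate)
        link.support[skey] = link.support.get(skey, 0) + 1
        link.best_score = max(link.best_score, csm.score)
        link.csm_count += 1
    return list(linkages.values())


def reproducibility_filter(
    linkages: Sequence[UniqueLinkage], min_replicates: int = 2
) -> list[UniqueLinkage]:
    """Keep linkages seen in >= ``min_replicates`` biological replicates with
    the same linker (for at least one linker)."""
    return [
        lk
        for lk in linkages
        if any(len(lk.replicates_for(linker)) >= min_replicates for linker in lk.linkers)
    ]
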