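"""Ground-truthed synthetic fixtures: proteomes with planted K-C cross-links,
MSn / stepped-HCD MS2 runs, and toy structures with known geometry.

The generator emulates the acquisition used for cross-linked peptides:
precursors carry charges 4-8, MS2 cleavage of an oxidized K-C link emits the
alpha_S/beta_A signature fragments at the charge splits of the precursor
(alpha_T as well, except for SIAB whose sulfenic-acid fragment resists
dehydration), and the top signature peaks are selected for MS3 sequencing of
their remnant-modified b/y ladders.  Peak m/z values receive Gaussian
relative (ppm) error; peaks are dropped independently at one minus the
detection probability; noise peaks are uniform in m/z with exponential
intensities.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chemistry import (
    CrossLinkedPair,
    ModifiedPeptide,
    get_linker,
    fragment_ladder,
    neutral_to_mz,
    remnants_for,
    signature_fragment_neutrals,
)
from .identify import digest
from .spectra import Run, Spectrum

#: Average amino-acid background frequencies (human-proteome-like); K and C
#: are overridden by the config.
_AA_BACKGROUND = {
    "A": 0.070, "D": 0.047, "E": 0.071, "F": 0.036, "G": 0.066, "H": 0.026,
    "I": 0.043, "L": 0.100, "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048,
    "R": 0.056, "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.012, "Y": 0.027,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults reflect the acquisition the package targets: 50-protein
    database, 100 planted links, precursor charges supported on 4-8, MSn
    acquisition with the top 4 signature-candidate peaks selected for MS3.
    The noiseless limit (``noise_peaks=0, detection_prob=1, mass_error_ppm=0``)
    closes the loop exactly; the noisy condition uses 100 noise peaks per
    spectrum, 5 ppm mass error and 0.9 detection probability.
    """

    seed: int = 0
    n_proteins: int = 50
    protein_length: tuple[int, int] = (150, 350)
    lysine_freq: float = 0.058
    cysteine_freq: float = 0.025
    n_crosslinks: int = 100
    intra_fraction: float = 0.5
    noise_peaks: int = 0
    noise_intensity_scale: float = 50.0
    detection_prob: float = 1.0
    mass_error_ppm: float = 0.0
    linker: str = "SIA"
    charge_support: tuple[int, ...] = (4, 5, 6, 7, 8)
    charge_weights: tuple[float, ...] = (0.40, 0.30, 0.15, 0.10, 0.05)
    mode: str = "msn"  # msn | ms2
    emit_alpha_t: bool = True
    ms3_top_n: int = 4
    max_fragment_charge: int = 4
    missed_cleavages: int = 2
    peptide_length: tuple[int, int] = (5, 50)

    def __post_init__(self) -> None:
        for p in (self.intra_fraction, self.detection_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mode not in ("msn", "ms2"):
            raise ValueError("mode must be 'msn' or 'ms2'")


@dataclass(frozen=True)
class PlantedLink:
    """Ground truth for one planted cross-link."""

    protein_a: str
    residue_k: int
    protein_b: str
    residue_c: int
    alpha_seq: str
    alpha_site: int
    beta_seq: str
    beta_site: int
    linker: str

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.protein_a, self.residue_k, self.protein_b, self.residue_c)


def _random_protein(rng: np.random.Generator, length: int, k_freq: float, c_freq: float) -> str:
    aas = list(_AA_BACKGROUND) + ["K", "C"]
    base = np.array([_AA_BACKGROUND[a] for a in _AA_BACKGROUND])
    probs = np.concatenate([base / base.sum() * (1.0 - k_freq - c_freq), [k_freq, c_freq]])
    return "".join(rng.choice(aas, size=length, p=probs / probs.sum()))


def simulate_proteome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[PlantedLink]]:
    """Random protein database plus a realizable planted cross-link table.

    Links are planted on digested peptides within the configured length
    bounds so every planted link survives in-silico digestion: the alpha
    side needs an internal (non-cleaved) lysine, the beta side a cysteine.
    Raises when the residue frequencies make planting infeasible.
    """
    if config.n_crosslinks > 0 and (config.lysine_freq <= 0 or config.cysteine_freq <= 0):
        raise ValueError("cannot plant K-C links with zero lysine or cysteine frequency")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length
    proteins = {
        f"SYN{i:04d}": _random_protein(
            rng, int(rng.integers(lo, hi + 1)), config.lysine_freq, config.cysteine_freq
        )
        for i in range(config.n_proteins)
    }
    if config.n_crosslinks == 0:
        return proteins, []

    index = digest(
        proteins,
        missed_cleavages=config.missed_cleavages,
        length_range=config.peptide_length,
        decoy_mode=None,
    )
    # unambiguous candidates only: peptides mapping to a single protein
    alphas = [e for e in index.entries if e.k_sites and len(e.locations) == 1]
    betas = [e for e in index.entries if e.c_sites and len(e.locations) == 1]
    if not alphas or not betas:
        raise ValueError("proteome admits no realizable planted cross-links")
    by_protein_beta: dict[str, list] = {}
    for e in betas:
        by_protein_beta.setdefault(e.locations[0][0], []).append(e)

    links: list[PlantedLink] = []
    used: set[tuple[str, int, str, int]] = set()
    attempts = 0
    while len(links) < config.n_crosslinks and attempts < config.n_crosslinks * 200:
        attempts += 1
        a = alphas[rng.integers(len(alphas))]
        pid_a, start_a = a.locations[0]
        want_intra = rng.random() < config.intra_fraction
        pool = by_protein_beta.get(pid_a, []) if want_intra else betas
        if not pool:
            pool = betas
        b = pool[rng.integers(len(pool))]
        pid_b, start_b = b.locations[0]
        site_a = a.k_sites[rng.integers(len(a.k_sites))]
        site_b = b.c_sites[rng.integers(len(b.c_sites))]
        if pid_a == pid_b and a.sequence == b.sequence:
            continue  # same peptide linked to itself is out of scope
        key = (pid_a, start_a + site_a - 1, pid_b, start_b + site_b - 1)
        if key in used:
            continue
        used.add(key)
        links.append(
            PlantedLink(
                protein_a=pid_a,
                residue_k=key[1],
                protein_b=pid_b,
                residue_c=key[3],
                alpha_seq=a.sequence,
                alpha_site=site_a,
                beta_seq=b.sequence,
                beta_site=site_b,
                linker=config.linker,
            )
        )
    if len(links) < config.n_crosslinks:
        raise ValueError(
            f"could only plant {len(links)}/{config.n_crosslinks} links; "
            "relax the constraints or enlarge the proteome"
        )
    return proteins, links


def write_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_truth_tsv(links: Sequence[PlantedLink], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([vars(l) for l in links]).to_csv(path, sep="\t", index=False)


def _planted_pair(link: PlantedLink) -> CrossLinkedPair:
    linker = get_linker(link.linker)
    alpha_mods = tuple(
        (i + 1, "carbamidomethyl") for i, c in enumerate(link.alpha_seq) if c == "C"
    )
    beta_mods = tuple(
        (i + 1, "carbamidomethyl")
        for i, c in enumerate(link.beta_seq)
        if c == "C" and i + 1 != link.beta_site
    )
    return CrossLinkedPair(
        alpha=ModifiedPeptide(link.alpha_seq, mods=alpha_mods),
        alpha_site=link.alpha_site,
        beta=ModifiedPeptide(link.beta_seq, mods=beta_mods),
        beta_site=link.beta_site,
        linker=linker,
    )


def _jitter(rng: np.random.Generator, mz: float, sigma_ppm: float) -> float:
    if sigma_ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6)


def _noise(
    rng: np.random.Generator, n: int, mz_range: tuple[float, float], scale: float
) -> list[tuple[float, float]]:
    return [
        (float(rng.uniform(*mz_range)), float(rng.exponential(scale)) + 1.0)
        for _ in range(n)
    ]


def simulate_msn_run(
    config: SimulationConfig,
    proteins: Mapping[str, str],
    links: Sequence[PlantedLink],
    replicate: str = "rep1",
    rng: np.random.Generator | None = None,
) -> tuple[Run, dict[int, PlantedLink]]:
    """MS1/MS2/MS3 (or stepped-HCD MS2) run with one precursor per planted
    link, plus per-MS2-scan provenance.  Deterministic given the rng state
    (default: seeded from ``config.seed`` and the replicate label)."""
    if rng is None:
        import zlib

        rng = np.random.default_rng([config.seed, zlib.crc32(replicate.encode())])
    spectra: list[Spectrum] = []
    provenance: dict[int, PlantedLink] = {}
    scan = 1
    weights = np.asarray(config.charge_weights, dtype=float)
    weights = weights / weights.sum()

    ms1_peaks: list[tuple[float, float]] = []
    pending: list[tuple[PlantedLink, CrossLinkedPair, int, float]] = []
    for link in links:
        pair = _planted_pair(link)
        z = int(rng.choice(config.charge_support, p=weights))
        prec_mz = _jitter(rng, neutral_to_mz(pair.neutral_mass, z), config.mass_error_ppm)
        ms1_peaks.append((prec_mz, float(rng.lognormal(12, 1))))
        pending.append((link, pair, z, prec_mz))

    ms1_id = scan
    mzs, intens = (
        zip(*sorted(ms1_peaks)) if ms1_peaks else ((), ())
    )
    spectra.append(Spectrum(scan_id=ms1_id, ms_level=1, mz=np.array(mzs), intensity=np.array(intens)))
    scan += 1

    for link, pair, z, prec_mz in pending:
        n_as, n_at, n_ba = signature_fragment_neutrals(pair)
        emit_t = config.emit_alpha_t and link.linker != "SIAB"
        sig_peaks: list[tuple[float, float, str, int]] = []  # mz, inten, kind, charge
        for za in range(max(1, z - config.max_fragment_charge), min(config.max_fragment_charge, z - 1) + 1):
            zb = z - za
            for kind, neutral, zc in (
                ("alpha_S", n_as, za),
                ("beta_A", n_ba, zb),
            ):
                if rng.random() > config.detection_prob:
                    continue
                sig_peaks.append(
                    (
                        _jitter(rng, neutral_to_mz(neutral, zc), config.mass_error_ppm),
                        float(rng.lognormal(10, 0.8)),
                        kind,
                        zc,
                    )
                )
            if emit_t and rng.random() <= config.detection_prob:
                sig_peaks.append(
                    (
                        _jitter(rng, neutral_to_mz(n_at, za), config.mass_error_ppm),
                        float(rng.lognormal(9, 0.8)),
                        "alpha_T",
                        za,
                    )
                )

        peaks = [(mz, it) for mz, it, _, _ in sig_peaks]
        if config.mode == "ms2":
            for remnant_kind in ("alpha_S", "beta_A"):
                pep = _remnant_species(pair, remnant_kind)
                for ion in fragment_ladder(pep, ("b", "y"), max_charge=2):
                    if rng.random() > config.detection_prob:
                        continue
                    peaks.append(
                        (
                            _jitter(rng, ion.mz, config.mass_error_ppm),
                            float(rng.lognormal(8, 1)),
                        )
                    )
        peaks += _noise(
            rng, config.noise_peaks, (150.0, max(1500.0, prec_mz * z)), config.noise_intensity_scale
        )
        if not peaks:
            continue
        pmz, pint = zip(*peaks)
        ms2_id = scan
        spectra.append(
            Spectrum(
                scan_id=ms2_id,
                ms_level=2,
                mz=np.array(pmz),
                intensity=np.array(pint),
                precursor_mz=prec_mz,
                precursor_charge=z,
                activation="stepped-HCD" if config.mode == "ms2" else "CID",
            )
        )
        provenance[ms2_id] = link
        scan += 1

        if config.mode == "msn":
            # MS3 targets the signature-candidate peaks: both members of a
            # complementary pair are sequenced, so the selection budget is
            # split between the alpha-side and beta-side fragments.
            alpha_side = sorted(
                (p for p in sig_peaks if p[2] != "beta_A"), key=lambda p: -p[1]
            )
            beta_side = sorted(
                (p for p in sig_peaks if p[2] == "beta_A"), key=lambda p: -p[1]
            )
            half = config.ms3_top_n - config.ms3_top_n // 2
            chosen = alpha_side[:half] + beta_side[: config.ms3_top_n // 2]
            leftover = alpha_side[half:] + beta_side[config.ms3_top_n // 2 :]
            chosen += sorted(leftover, key=lambda p: -p[1])[
                : config.ms3_top_n - len(chosen)
            ]
            for mz_obs, _, kind, zc in chosen:
                pep = _remnant_species(pair, kind)
                ions = fragment_ladder(pep, ("b", "y"), max_charge=min(2, zc))
                ms3_peaks = [
                    (
                        _jitter(rng, ion.mz, config.mass_error_ppm),
                        float(rng.lognormal(7, 1)),
                    )
                    for ion in ions
                    if rng.random() <= config.detection_prob
                ]
                ms3_peaks += _noise(
                    rng,
                    config.noise_peaks,
                    (100.0, max(ion.mz for ion in ions) + 100.0),
                    config.noise_intensity_scale,
                )
                if not ms3_peaks:
                    continue
                m3, i3 = zip(*ms3_peaks)
                spectra.append(
                    Spectrum(
                        scan_id=scan,
                        ms_level=3,
                        mz=np.array(m3),
                        intensity=np.array(i3),
                        precursor_mz=mz_obs,
                        precursor_charge=zc,
                        parent_scan=ms2_id,
                        selected_mz=mz_obs,
                        activation="CID",
                    )
                )
                scan += 1

    run = Run(
        spectra=spectra,
        source=f"synthetic::{config.linker}::{replicate}",
        linker=config.linker,
        replicate=replicate,
    )
    return run, provenance


def _remnant_species(pair: CrossLinkedPair, kind: str) -> ModifiedPeptide:
    rem = remnants_for(pair.linker)
    if kind == "alpha_S":
        return pair.alpha.with_mod(pair.alpha_site, rem.alpha_S_mod)
    if kind == "alpha_T":
        return pair.alpha.with_mod(pair.alpha_site, rem.alpha_T_mod)
    return pair.beta.with_mod(pair.beta_site, rem.beta_A_mod)


def entrapment_database(
    config: SimulationConfig, n_entrapment: int = 150
) -> tuple[dict[str, str], dict[str, str]]:
    """Signal proteome A (the one spectra are simulated from) plus an
    entrapment database A + B where B contains ``n_entrapment`` extra
    proteins never used for simulation."""
    proteins_a, _ = simulate_proteome(replace(config, n_crosslinks=0))
    rng = np.random.default_rng([config.seed, 7919])
    lo, hi = config.protein_length
    proteins_b = {
        f"ENT{i:04d}": _random_protein(
            rng, int(rng.integers(lo, hi + 1)), config.lysine_freq, config.cysteine_freq
        )
        for i in range(n_entrapment)
    }
    combined = dict(proteins_a)
    combined.update(proteins_b)
    return proteins_a, combined


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


def build_toy_structure(
    structure_id: str,
    sequence: str,
    spacing: float = 3.8,
    chain_offsets: Mapping[str, tuple[float, float, float]] = None,
    model_class: str = "experimental",
    plddt: Sequence[float] | None = None,
):
    """A straight-line Calpha chain (residue i at x = (i-1)*spacing), copied
    once per entry of ``chain_offsets`` with a rigid translation -- an exact
    geometry for distance oracles.  Returns a structmap.StructureModel."""
    from .structmap import StructureModel

    if chain_offsets is None:
        chain_offsets = {"A": (0.0, 0.0, 0.0)}
    chains: dict[str, dict[int, np.ndarray]] = {}
    names: dict[str, dict[int, str]] = {}
    plddt_map: dict[str, dict[int, float]] = {}
    for chain, offset in chain_offsets.items():
        coords = {}
        nm = {}
        pl = {}
        for i, aa in enumerate(sequence, start=1):
            coords[i] = np.array([(i - 1) * spacing, 0.0, 0.0]) + np.asarray(offset)
            nm[i] = aa
            pl[i] = float(plddt[i - 1]) if plddt is not None else 90.0
        chains[chain] = coords
        names[chain] = nm
        plddt_map[chain] = pl
    return StructureModel(
        structure_id=structure_id,
        chains=chains,
        residue_names=names,
        plddt=plddt_map if model_class == "predicted" else {},
        model_class=model_class,
    )


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def write_toy_pdb(model, path: str | Path) -> None:
    """Write a Calpha-only PDB file for a (toy) StructureModel."""
    lines = []
    serial = 1
    for chain, residues in model.chains.items():
        for num in sorted(residues):
            x, y, z = residues[num]
            aa = model.residue_names[chain][num]
            b = model.plddt.get(chain, {}).get(num, 0.0)
            lines.append(
                f"ATOM  {serial:5d}  CA  {_ONE_TO_THREE.get(aa, 'ALA'):3s} {chain}{num:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
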