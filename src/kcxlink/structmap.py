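"""Map unique K-C linkages onto structures and summarize distance satisfaction.

For every linkage the Calpha-Calpha distance is computed in every structure
and chain combination covering both residues and the minimal distance is
recorded.  For intra-protein linkages, inter-chain distances within
homo-oligomeric structures are also measured, so a link violated within one
chain can be "rescued" by a homomeric contact.  A linkage is satisfied when
its minimal distance is strictly below the threshold (default 30 A).

Predicted models carry AlphaFold confidence: per-residue pLDDT (B-factor
column) and a PAE matrix; records can be stratified or gated on these.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .identify import UniqueLinkage

SATISFACTION_THRESHOLD: float = 30.0  # Angstrom, strict <

#: DSSP label -> coarse class.  {H,G,I} helices, {E,B} sheets, rest loops.
SS_GROUPS: Mapping[str, str] = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "sheet", "B": "sheet",
    "T": "loop", "S": "loop", "P": "loop", "-": "loop", " ": "loop", "": "loop",
}
SS_CLASSES = ("helix", "sheet", "loop")


def group_ss_label(label: str) -> str:
    return SS_GROUPS.get(label, "loop")


@dataclass(frozen=True)
class MappingEntry:
    """protein residue number + offset = structure residue number (per chain)."""

    protein_id: str
    structure_id: str
    chain_id: str
    offset: int = 0


@dataclass
class ResidueMapping:
    entries: list[MappingEntry] = field(default_factory=list)

    def chains_for(self, protein_id: str, structure_id: str | None = None) -> list[MappingEntry]:
        return [
            e
            for e in self.entries
            if e.protein_id == protein_id
            and (structure_id is None or e.structure_id == structure_id)
        ]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueMapping":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                MappingEntry(
                    str(r.protein_id), str(r.structure_id), str(r.chain_id), int(r.offset)
                )
                for r in df.itertuples()
            ]
        )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class StructureModel:
    """Per-chain Calpha coordinates (A) with optional per-residue pLDDT."""

    structure_id: str
    chains: dict[str, dict[int, np.ndarray]]
    residue_names: dict[str, dict[int, str]]
    plddt: dict[str, dict[int, float]] = field(default_factory=dict)
    model_class: str = "experimental"  # or "predicted"

    def ca(self, chain: str, resnum: int) -> np.ndarray | None:
        return self.chains.get(chain, {}).get(resnum)

    def amino_acid(self, chain: str, resnum: int) -> str | None:
        return self.residue_names.get(chain, {}).get(resnum)

    def plddt_of(self, chain: str, resnum: int) -> float | None:
        return self.plddt.get(chain, {}).get(resnum)


def load_structure(
    path: str | Path, structure_id: str | None = None, model_class: str = "experimental"
) -> StructureModel:
    """Read a PDB or mmCIF file (first model only) into a StructureModel.

    For predicted models (``model_class='predicted'``) the B-factor column is
    interpreted as per-residue pLDDT.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if structure_id is None:
        structure_id = path.stem
    chains: dict[str, dict[int, np.ndarray]] = {}
    names: dict[str, dict[int, str]] = {}
    plddt: dict[str, dict[int, float]] = {}
    model = st[0]
    for chain in model:
        cmap: dict[int, np.ndarray] = {}
        nmap: dict[int, str] = {}
        pmap: dict[int, float] = {}
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue  # residue without Calpha is unmapped in this model
            num = res.seqid.num
            cmap[num] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
            nmap[num] = _THREE_TO_ONE.get(res.name.upper(), "X")
            pmap[num] = float(ca.b_iso)
        if cmap:
            chains[chain.name] = cmap
            names[chain.name] = nmap
            if model_class == "predicted":
                plddt[chain.name] = pmap
    return StructureModel(
        structure_id=structure_id,
        chains=chains,
        residue_names=names,
        plddt=plddt,
        model_class=model_class,
    )


@dataclass
class PAEMatrix:
    """Predicted-aligned-error matrix with a (chain, residue) index map."""

    matrix: np.ndarray
    index: dict[tuple[str, int], int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("PAE matrix must be square")
        if np.any(self.matrix < 0):
            raise ValueError("PAE values must be non-negative")
        if len(self.index) != self.matrix.shape[0]:
            raise ValueError("index map size must match the matrix dimension")

    @classmethod
    def from_json(
        cls, path: str | Path, chain_lengths: Mapping[str, int]
    ) -> "PAEMatrix":
        """Load the standard AlphaFold PAE JSON (``predicted_aligned_error``
        key, possibly wrapped in a one-element list); residues indexed in
        chain order with 1-based numbering."""
        data = json.loads(Path(path).read_text())
        if isinstance(data, list):
            data = data[0]
        mat = np.array(data.get("predicted_aligned_error") or data["pae"], dtype=float)
        index: dict[tuple[str, int], int] = {}
        i = 0
        for chain, length in chain_lengths.items():
            for res in range(1, length + 1):
                index[(chain, res)] = i
                i += 1
        return cls(mat, index)


def pae_for_pair(
    pae: PAEMatrix, residue_1: tuple[str, int], residue_2: tuple[str, int]
) -> float:
    """Symmetrized PAE: mean of the (i,j) and (j,i) directed entries."""
    try:
        i = pae.index[residue_1]
        j = pae.index[residue_2]
    except KeyError as exc:
        raise IndexError(f"residue {exc.args[0]!r} outside the PAE matrix") from None
    return float((pae.matrix[i, j] + pae.matrix[j, i]) / 2.0)


@dataclass
class DistanceRecord:
    """One measured Calpha-Calpha distance for a linkage in one structure."""

    protein_a: str
    residue_k: int
    protein_b: str
    residue_c: int
    structure_id: str
    chain_a: str
    chain_b: str
    struct_res_a: int
    struct_res_b: int
    distance: float
    context: str  # same-chain | inter-chain-homomer | inter-chain-heteromer
    satisfied: bool
    linker: str | None = None
    model_class: str = "experimental"
    pae: float | None = None
    min_plddt: float | None = None


def map_linkage(
    linkage: UniqueLinkage,
    mapping: ResidueMapping,
    models: Sequence[StructureModel],
    threshold: float = SATISFACTION_THRESHOLD,
    pae_matrices: Mapping[str, PAEMatrix] | None = None,
    check_residue_identity: bool = True,
) -> tuple[list[DistanceRecord], DistanceRecord | None]:
    """All distance records for a linkage plus the minimal one (None when
    neither residue maps to any model).

    Intra-protein linkages measure same-chain distances in every chain plus
    every inter-chain (homomer) combination; inter-protein linkages measure
    every chain-of-A x chain-of-B combination.  Chains whose residue identity
    disagrees with the expected amino acid are excluded (with a warning), not
    silently used.
    """
    records: list[DistanceRecord] = []
    linker = sorted(linkage.linkers)[0] if linkage.support else None
    by_id = {m.structure_id: m for m in models}
    for structure_id, model in by_id.items():
        ent_a = mapping.chains_for(linkage.protein_a, structure_id)
        ent_b = mapping.chains_for(linkage.protein_b, structure_id)
        for ea in ent_a:
            ra = linkage.residue_k + ea.offset
            ca = model.ca(ea.chain_id, ra)
            if ca is None:
                continue
            if check_residue_identity and model.amino_acid(ea.chain_id, ra) not in ("K", "X"):
                warnings.warn(
                    f"{structure_id}/{ea.chain_id}:{ra} is not lysine; excluded"
                )
                continue
            for eb in ent_b:
                rb = linkage.residue_c + eb.offset
                cb = model.ca(eb.chain_id, rb)
                if cb is None:
                    continue
                if check_residue_identity and model.amino_acid(eb.chain_id, rb) not in ("C", "X"):
                    warnings.warn(
                        f"{structure_id}/{eb.chain_id}:{rb} is not cysteine; excluded"
                    )
                    continue
                d = float(np.linalg.norm(ca - cb))
                if ea.chain_id == eb.chain_id:
                    context = "same-chain"
                elif linkage.is_intra:
                    context = "inter-chain-homomer"
                else:
                    context = "inter-chain-heteromer"
                pae_val = None
                if pae_matrices and structure_id in pae_matrices:
                    try:
                        pae_val = pae_for_pair(
                            pae_matrices[structure_id],
                            (ea.chain_id, ra),
                            (eb.chain_id, rb),
                        )
                    except IndexError:
                        pae_val = None
                pl_a = model.plddt_of(ea.chain_id, ra)
                pl_b = model.plddt_of(eb.chain_id, rb)
                min_plddt = min(pl_a, pl_b) if pl_a is not None and pl_b is not None else None
                records.append(
                    DistanceRecord(
                        protein_a=linkage.protein_a,
                        residue_k=linkage.residue_k,
                        protein_b=linkage.protein_b,
                        residue_c=linkage.residue_c,
                        structure_id=structure_id,
                        chain_a=ea.chain_id,
                        chain_b=eb.chain_id,
                        struct_res_a=ra,
                        struct_res_b=rb,
                        distance=d,
                        context=context,
                        satisfied=d < threshold,
                        linker=linker,
                        model_class=model.model_class,
                        pae=pae_val,
                        min_plddt=min_plddt,
                    )
                )
    if not records:
        return [], None
    minimal = min(records, key=lambda r: r.distance)
    return records, minimal


@dataclass
class SatisfactionSummary:
    threshold: float
    mapped: int
    satisfied: int
    rescued_by_homomer: int
    median_distance: float | None
    by_linker: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def rate(self) -> float | None:
        return self.satisfied / self.mapped if self.mapped else None


def satisfaction_summary(
    minimal_records: Sequence[DistanceRecord],
    threshold: float = SATISFACTION_THRESHOLD,
    all_records: Sequence[DistanceRecord] | None = None,
) -> SatisfactionSummary:
    """Satisfaction counts/rates over minimal per-linkage records.

    A linkage counts as homomer-rescued when its minimal distance satisfies
    the threshold through an inter-chain-homomer measurement while every
    same-chain measurement violates it (requires ``all_records``).
    """
    mapped = len(minimal_records)
    satisfied = sum(1 for r in minimal_records if r.distance < threshold)
    rescued = 0
    if all_records is not None:
        by_link: dict[tuple, list[DistanceRecord]] = {}
        for r in all_records:
            by_link.setdefault(
                (r.protein_a, r.residue_k, r.protein_b, r.residue_c), []
            ).append(r)
        for rec in minimal_records:
            if rec.context != "inter-chain-homomer" or rec.distance >= threshold:
                continue
            same = [
                r
                for r in by_link.get(
                    (rec.protein_a, rec.residue_k, rec.protein_b, rec.residue_c), []
                )
                if r.context == "same-chain"
            ]
            if same and all(r.distance >= threshold for r in same):
                rescued += 1
    distances = [r.distance for r in minimal_records]
    by_linker: dict[str, dict[str, float]] = {}
    for r in minimal_records:
        if r.linker is None:
            continue
        d = by_linker.setdefault(r.linker, {"mapped": 0, "satisfied": 0, "_distances": []})
        d["mapped"] += 1
        d["satisfied"] += r.distance < threshold
        d["_distances"].append(r.distance)
    for d in by_linker.values():
        d["median_distance"] = float(np.median(d.pop("_distances")))
    return SatisfactionSummary(
        threshold=threshold,
        mapped=mapped,
        satisfied=satisfied,
        rescued_by_homomer=rescued,
        median_distance=float(np.median(distances)) if distances else None,
        by_linker=by_linker,
    )


def confidence_stratified_satisfaction(
    records: Sequence[DistanceRecord],
    metric: str = "pae",
    cutoffs: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    threshold: float = SATISFACTION_THRESHOLD,
) -> list[dict]:
    """Satisfaction rate per confidence stratum (``pae`` ascending bins or
    ``plddt`` descending bins); empty strata report rate None."""
    if metric not in ("pae", "plddt"):
        raise ValueError("metric must be 'pae' or 'plddt'")
    valued = [
        (r, r.pae if metric == "pae" else r.min_plddt)
        for r in records
        if (r.pae if metric == "pae" else r.min_plddt) is not None
    ]
    edges = [0.0] + list(cutoffs) if metric == "pae" else list(cutoffs) + [100.0]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        inside = [r for r, v in valued if lo <= v < hi]
        mapped = len(inside)
        sat = sum(1 for r in inside if r.distance < threshold)
        rows.append(
            {
                "stratum": f"[{lo:g}, {hi:g})",
                "mapped": mapped,
                "satisfied": sat,
                "rate": sat / mapped if mapped else None,
            }
        )
    return rows


def filter_by_pae(
    records: Sequence[DistanceRecord], cutoff: float = 20.0
) -> list[DistanceRecord]:
    """Keep records whose symmetrized PAE is strictly below the cutoff."""
    return [r for r in records if r.pae is not None and r.pae < cutoff]


@dataclass
class SecondaryStructureProfile:
    lysine_counts: dict[str, int]
    cysteine_counts: dict[str, int]
    background_k: dict[str, int]
    background_c: dict[str, int]
    enrichment_k: dict[str, float | None]
    enrichment_c: dict[str, float | None]
    skipped: int


def _normalize(counts: dict[str, int], background: dict[str, int]) -> dict[str, float | None]:
    total_fg = sum(counts.values())
    total_bg = sum(background.values())
    out: dict[str, float | None] = {}
    for cls in SS_CLASSES:
        if background.get(cls, 0) == 0 or total_fg == 0:
            out[cls] = None
        else:
            out[cls] = (counts[cls] / total_fg) / (background[cls] / total_bg)
    return out


def secstruct_enrichment(
    records: Sequence[DistanceRecord],
    ss_labels: Mapping[tuple[str, str, int], str],
    background_k: Mapping[str, int],
    background_c: Mapping[str, int],
    threshold: float = SATISFACTION_THRESHOLD,
) -> SecondaryStructureProfile:
    """Class counts for cross-linked K and C (satisfied records only,
    distance < threshold) normalized by the background class frequency of
    that residue type over the model set.

    ``ss_labels`` maps (structure_id, chain, residue) to a DSSP letter;
    backgrounds are class -> residue counts for all K (resp. C) in the model
    set.  Residues without a label are skipped and counted.
    """
    k_counts = {c: 0 for c in SS_CLASSES}
    c_counts = {c: 0 for c in SS_CLASSES}
    skipped = 0
    for r in records:
        if r.distance >= threshold:
            continue
        lab_k = ss_labels.get((r.structure_id, r.chain_a, r.struct_res_a))
        lab_c = ss_labels.get((r.structure_id, r.chain_b, r.struct_res_b))
        if lab_k is None:
            skipped += 1
        else:
            k_counts[group_ss_label(lab_k)] += 1
        if lab_c is None:
            skipped += 1
        else:
            c_counts[group_ss_label(lab_c)] += 1
    bg_k = {c: int(background_k.get(c, 0)) for c in SS_CLASSES}
    bg_c = {c: int(background_c.get(c, 0)) for c in SS_CLASSES}
    return SecondaryStructureProfile(
        lysine_counts=k_counts,
        cysteine_counts=c_counts,
        background_k=bg_k,
        background_c=bg_c,
        enrichment_k=_normalize(k_counts, bg_k),
        enrichment_c=_normalize(c_counts, bg_c),
        skipped=skipped,
    )


def distance_by_secstruct(
    records: Sequence[DistanceRecord],
    ss_labels: Mapping[tuple[str, str, int], str],
) -> dict[tuple[str, str], dict]:
    """Distance distributions keyed by the (K-class, C-class) pair."""
    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        lab_k = ss_labels.get((r.structure_id, r.chain_a, r.struct_res_a), "-")
        lab_c = ss_labels.get((r.structure_id, r.chain_b, r.struct_res_b), "-")
        key = (group_ss_label(lab_k), group_ss_label(lab_c))
        groups.setdefault(key, []).append(r.distance)
    return {
        key: {"distances": vals, "median": float(np.median(vals)), "n": len(vals)}
        for key, vals in groups.items()
    }


def assign_secstruct_ca(model: StructureModel) -> dict[tuple[str, str, int], str]:
    """Fallback Calpha-only secondary-structure assigner for fixtures.

    Uses the i -> i+3 Calpha distance: ~5-6 A in an alpha helix, ~10 A in an
    extended strand, intermediate otherwise.  Coarse by design -- real
    assignments should come from a DSSP output table.
    """
    out: dict[tuple[str, str, int], str] = {}
    for chain, residues in model.chains.items():
        nums = sorted(residues)
        for num in nums:
            a, b = residues.get(num), residues.get(num + 3)
            if a is None or b is None:
                label = "-"
            else:
                d = float(np.linalg.norm(a - b))
                if d < 6.5:
                    label = "H"
                elif d > 9.0:
                    label = "E"
                else:
                    label = "-"
            out[(model.structure_id, chain, num)] = label
    return out


def background_ss_counts(
    models: Sequence[StructureModel],
    ss_labels: Mapping[tuple[str, str, int], str],
    residue: str,
) -> dict[str, int]:
    """Class counts of all residues of the given type over a model set."""
    counts = {c: 0 for c in SS_CLASSES}
    for model in models:
        for chain, names in model.residue_names.items():
            for num, aa in names.items():
                if aa != residue:
                    continue
                label = ss_labels.get((model.structure_id, chain, num))
                if label is not None:
                    counts[group_ss_label(label)] += 1
    return counts
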