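"""Inter-subunit Cβ–Cβ distances in C4-symmetric channel tetramers.

HCN-type channels are homotetramers arranged with fourfold symmetry around
the pore axis.  A donor on one subunit sees four copies of an acceptor
site: on the *same* subunit, on the two *adjacent* subunits, and on the
*diagonal* subunit.  Because Förster transfer falls off as r⁻⁶, the
shortest of these — typically the adjacent pair for transmembrane-to-C-linker
sites — dominates the measured efficiency.  This module extracts the four
symmetry-classified Cβ–Cβ distances from a structure, maps residue numbers
between homologous channels via pairwise alignment, quantifies which
relation dominates the total transfer rate, and exports harmonic distance
constraints for structure refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .forster_core import combined_efficiency

__all__ = [
    "ResidueSelector",
    "SubunitRelation",
    "ConstraintSpec",
    "ConstraintScheme",
    "NotATetramerError",
    "StructureQualityError",
    "UnmappedPositionError",
    "Tetramer",
    "load_tetramer",
    "build_residue_mapping",
    "map_residue",
    "cbeta_distance_table",
    "adjacent_distance",
    "adjacency_dominance_report",
    "write_constraints",
]

RELATIONS = ("same", "adjacent_1", "adjacent_2", "diagonal")


class NotATetramerError(ValueError):
    """Structure does not contain four protein chains of shared sequence."""


class StructureQualityError(ValueError):
    """A required residue or atom is missing from the structure."""


class UnmappedPositionError(KeyError):
    """Residue position falls in an alignment gap."""


@dataclass(frozen=True)
class ResidueSelector:
    """A (chain, residue number, atom) address; Cβ with Cα fallback for Gly."""

    chain_id: str
    residue_number: int
    atom_name: str = "CB"


@dataclass(frozen=True)
class ConstraintSpec:
    """One harmonic distance constraint between two atoms."""

    donor: ResidueSelector
    acceptor: ResidueSelector
    target_distance: float  # Å
    sd: float  # Å
    weight: float = 40.0  # kcal/mol/Å²
    constraint_class: str = "reference_experimental"

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValueError("target_distance must be > 0")
        if self.sd <= 0:
            raise ValueError("harmonic sd must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class ConstraintScheme:
    """Refinement weighting scheme recorded in constraint-file headers.

    Defaults: coordinate restraints at 1 kcal/mol/Å² on the rigid
    voltage-sensor region, atom-pair proximity restraints at 2 kcal/mol/Å²
    with a 6 Å cutoff, and experimental distance restraints at
    40 kcal/mol/Å².
    """

    coordinate_weight: float = 1.0
    atom_pair_weight: float = 2.0
    atom_pair_cutoff: float = 6.0
    experimental_weight: float = 40.0


class Tetramer:
    """Handle over a fourfold-symmetric structure with ring-ordered chains.

    ``ring_order`` lists the four chain names in angular order around the
    pore axis, so index distance 1 (mod 4) means adjacent subunits and 2
    means diagonal.
    """

    def __init__(self, structure: gemmi.Structure, ring_order: list[str]):
        self.structure = structure
        self.ring_order = ring_order
        self._model = structure[0]

    @property
    def chains(self) -> list[str]:
        return list(self.ring_order)

    def atom_position(self, sel: ResidueSelector) -> np.ndarray:
        """Coordinates (Å) of the selected atom, Cβ→Cα fallback for glycine."""
        chain = self._model.find_chain(sel.chain_id)
        if chain is None:
            raise StructureQualityError(f"chain {sel.chain_id!r} not found")
        res = None
        for r in chain:
            if r.seqid.num == sel.residue_number:
                res = r
                break
        if res is None:
            raise StructureQualityError(
                f"residue {sel.residue_number} not in chain {sel.chain_id}"
            )
        atom = res.find_atom(sel.atom_name, "A")
        if atom is None and sel.atom_name == "CB" and res.name == "GLY":
            atom = res.find_atom("CA", "A")
        if atom is None:
            raise StructureQualityError(
                f"atom {sel.atom_name} missing in {res.name}"
                f"{sel.residue_number}/{sel.chain_id} (no fallback)"
            )
        p = atom.pos
        return np.array([p.x, p.y, p.z])


def _polymer_chains(model: gemmi.Model) -> dict[str, str]:
    """Chain name → one-letter sequence for chains with >= 2 amino acids."""
    seqs: dict[str, str] = {}
    for chain in model:
        poly = chain.get_polymer()
        seq = gemmi.one_letter_code(poly.extract_sequence())
        if len(seq) >= 2:
            seqs[chain.name] = seq
    return seqs


def _chain_com(model: gemmi.Model, name: str) -> np.ndarray:
    chain = model.find_chain(name)
    coords = [
        (a.pos.x, a.pos.y, a.pos.z) for res in chain for a in res
    ]
    return np.asarray(coords, float).mean(axis=0)


def _ring_order(model: gemmi.Model, chain_names: Sequence[str]) -> list[str]:
    """Order chains by angular position of their centers of mass.

    The four centers of mass of a C4 tetramer lie on a circle around the
    pore axis; the axis direction is the normal of the best-fit plane
    through them (least singular vector of the centered coordinates).
    """
    coms = np.array([_chain_com(model, c) for c in chain_names])
    center = coms.mean(axis=0)
    centered = coms - center
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    # in-plane basis
    e1 = vt[0]
    e2 = np.cross(normal, e1)
    angles = np.arctan2(centered @ e2, centered @ e1)
    order = np.argsort(angles)
    return [chain_names[i] for i in order]


def load_tetramer(source) -> Tetramer:
    """Load a PDB/mmCIF structure and identify its C4 ring of chains.

    The first model is used; the four (or more) protein chains must share a
    sequence.  Raises :class:`NotATetramerError` when fewer than four
    matching chains are present.
    """
    structure = gemmi.read_structure(str(source))
    structure.setup_entities()
    model = structure[0]
    seqs = _polymer_chains(model)
    if not seqs:
        raise NotATetramerError(f"{source}: no protein chains found")
    # group chains by sequence; take the largest group
    by_seq: dict[str, list[str]] = {}
    for name, seq in seqs.items():
        by_seq.setdefault(seq, []).append(name)
    group = max(by_seq.values(), key=len)
    if len(group) < 4:
        raise NotATetramerError(
            f"{source}: found {len(group)} chains sharing a sequence; "
            "need >= 4 for a tetramer"
        )
    ring = _ring_order(model, group[:4] if len(group) == 4 else group)
    return Tetramer(structure, ring[:4])


def build_residue_mapping(seq_source: str, seq_target: str) -> dict[int, int]:
    """Residue-number mapping between homologs by global pairwise alignment.

    Both sequences are 1-based full-length protein sequences.  Returns
    {source position → target position} for non-gap columns only.  Uses
    BLOSUM62 with affine gaps (Needleman–Wunsch via Bio.Align).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_source, seq_target)[0]
    mapping: dict[int, int] = {}
    for (s_start, s_end), (t_start, t_end) in zip(*aln.aligned):
        for offset in range(s_end - s_start):
            mapping[s_start + offset + 1] = t_start + offset + 1
    return mapping


def map_residue(position: int, mapping: Mapping[int, int]) -> int:
    """Target residue number for a source position under an alignment mapping."""
    try:
        return int(mapping[position])
    except KeyError:
        raise UnmappedPositionError(
            f"position {position} falls in an alignment gap (unmapped)"
        ) from None


def cbeta_distance_table(
    tetramer: Tetramer,
    donor_res: int,
    acceptor_res: int,
    donor_chain: str | None = None,
    provenance: str = "",
) -> pd.DataFrame:
    """Cβ–Cβ distances from one donor to the acceptor site on all four chains.

    The donor sits on ``donor_chain`` (default: first chain in ring order);
    relations are labeled by ring-index offset: 0 same, ±1 adjacent,
    2 diagonal.  Returns a four-row tidy frame.
    """
    ring = tetramer.ring_order
    if donor_chain is None:
        donor_chain = ring[0]
    if donor_chain not in ring:
        raise ValueError(f"donor chain {donor_chain!r} not in ring {ring}")
    d_idx = ring.index(donor_chain)
    d_pos = tetramer.atom_position(ResidueSelector(donor_chain, donor_res))
    relation_by_offset = {0: "same", 1: "adjacent_1", 3: "adjacent_2", 2: "diagonal"}
    rows = []
    for offset in (0, 1, 2, 3):
        a_chain = ring[(d_idx + offset) % 4]
        a_pos = tetramer.atom_position(ResidueSelector(a_chain, acceptor_res))
        rows.append(
            {
                "donor_chain": donor_chain,
                "donor_res": donor_res,
                "acceptor_chain": a_chain,
                "acceptor_res": acceptor_res,
                "relation": relation_by_offset[offset],
                "distance_A": float(np.linalg.norm(d_pos - a_pos)),
                "provenance": provenance,
            }
        )
    return pd.DataFrame(rows)


def adjacent_distance(table: pd.DataFrame) -> float:
    """Single adjacent-subunit distance: the nearer of the two neighbors."""
    adj = table[table["relation"].isin(["adjacent_1", "adjacent_2"])]
    if adj.empty:
        raise ValueError("table has no adjacent rows")
    return float(adj["distance_A"].min())


def adjacency_dominance_report(table: pd.DataFrame, r0: float) -> pd.DataFrame:
    """Per-relation share of the total Förster transfer rate.

    Rates (r0/r)⁶ are summed within relation class (the two adjacent chains
    pool into one "adjacent" class) and normalized; the dominant class is
    flagged.  The share is independent of r0 (it cancels), but r0 sets the
    absolute combined efficiency, which is also reported.
    """
    if len(table) != 4 or set(table["relation"]) != set(RELATIONS):
        raise ValueError("need a complete 4-row distance table")
    dist = table["distance_A"].to_numpy(float)
    if np.any(dist <= 0):
        raise ValueError(
            "rate shares undefined at zero distance (donor and acceptor "
            "coincide); choose distinct donor/acceptor sites"
        )
    rates = (r0 / dist) ** 6
    total = rates.sum()
    rel_class = table["relation"].str.replace(r"adjacent_[12]", "adjacent", regex=True)
    shares = (
        pd.DataFrame({"relation": rel_class, "rate": rates})
        .groupby("relation", sort=False)["rate"]
        .sum()
        / total
    )
    report = shares.reset_index().rename(columns={"rate": "rate_share"})
    report["dominant"] = report["rate_share"] == report["rate_share"].max()
    report.attrs["combined_efficiency"] = combined_efficiency(dist, r0)
    return report


def write_constraints(
    constraints: Sequence[ConstraintSpec],
    path,
    scheme: ConstraintScheme | None = None,
) -> None:
    """Write harmonic atom-pair distance constraints as text.

    One record per line:
    ``AtomPair CB <res><chain> CB <res><chain> HARMONIC <distance> <sd>``.
    The weighting scheme is recorded in header comments.  Output is
    byte-stable for fixed input (no timestamps).
    """
    if scheme is None:
        scheme = ConstraintScheme()
    constraints = list(constraints)
    if not constraints:
        raise ValueError("no constraints to write")
    lines = [
        "# harmonic distance constraints from tmFRET-derived distances",
        f"# coordinate_weight {scheme.coordinate_weight:g} kcal/mol/A^2",
        f"# atom_pair_weight {scheme.atom_pair_weight:g} kcal/mol/A^2",
        f"# atom_pair_cutoff {scheme.atom_pair_cutoff:g} A",
        f"# experimental_weight {scheme.experimental_weight:g} kcal/mol/A^2",
    ]
    for c in constraints:
        lines.append(
            f"AtomPair {c.donor.atom_name} "
            f"{c.donor.residue_number}{c.donor.chain_id} "
            f"{c.acceptor.atom_name} "
            f"{c.acceptor.residue_number}{c.acceptor.chain_id} "
            f"HARMONIC {c.target_distance:.2f} {c.sd:.2f}"
        )
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
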