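"""Structure I/O, entity census, sequences, NPA motifs, and superposition.

Coordinates are Å throughout.  Author residue numbering is canonical
everywhere: analyses and reports never expose zero-based sequence indices.
Parsing is backed by gemmi (PDB and mmCIF; both ``label_*`` and ``auth_*``
atom_site items are read, ``auth_*`` is kept).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align

from ._geom import kabsch

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """File could not be parsed in the requested dialect."""


class EmptySelectionError(ValueError):
    """A selection matched no atoms."""


class MotifNotFoundError(ValueError):
    """Fewer than two NPA motifs in the sequence."""


@dataclass
class Atom:
    """One atom record (primary alternate conformer flagged, never dropped)."""

    element: str
    name: str
    alt_loc: str
    coords: np.ndarray
    b_factor: float
    occupancy: float
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    is_hetero: bool
    is_water: bool
    is_primary_alt: bool = True

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name and a.is_primary_alt:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)


@dataclass
class WaterSite:
    """A crystallographic water, optionally carrying a channel-water label."""

    oxygen: Atom
    label: str | None = None
    region: str = "unassigned"

    @property
    def coords(self) -> np.ndarray:
        return self.oxygen.coords


@dataclass
class StructureModel:
    identifier: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    waters: list[WaterSite] = field(default_factory=list)
    hetero_groups: list[Residue] = field(default_factory=list)
    space_group: str = ""
    cell: tuple[float, ...] = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)

    def iter_atoms(self, primary_only: bool = False):
        for residues in self.chains.values():
            for res in residues:
                for a in res.atoms:
                    if not primary_only or a.is_primary_alt:
                        yield a
        for w in self.waters:
            if not primary_only or w.oxygen.is_primary_alt:
                yield w.oxygen
        for grp in self.hetero_groups:
            for a in grp.atoms:
                if not primary_only or a.is_primary_alt:
                    yield a

    def polymer_atoms(self, primary_only: bool = True):
        for residues in self.chains.values():
            for res in residues:
                for a in res.atoms:
                    if not primary_only or a.is_primary_alt:
                        yield a

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(
                f"chain {chain_id!r} not found; available: {sorted(self.chains)}"
            )
        return self.chains[chain_id]

    def water_by_label(self, label: str) -> WaterSite:
        for w in self.waters:
            if w.label == label:
                return w
        raise KeyError(f"no water labelled {label!r}")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    alignment: list[tuple[tuple[int, str], tuple[int, str]]]


def _mark_primary_altlocs(residue_atoms: list[Atom]) -> None:
    """Flag, per atom name, the highest-occupancy conformer (ties: first seen)."""
    by_name: dict[str, list[Atom]] = {}
    for a in residue_atoms:
        by_name.setdefault(a.name, []).append(a)
    for group in by_name.values():
        if len(group) == 1:
            group[0].is_primary_alt = True
            continue
        best = max(group, key=lambda a: a.occupancy)  # max keeps first on ties
        for a in group:
            a.is_primary_alt = a is best


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are retained; the highest-occupancy conformer of each
    atom is flagged primary.  Author chain ids and residue numbering are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; use mmcif, pdb, or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    model = StructureModel(
        identifier=st.name or path.stem,
        space_group=st.spacegroup_hm or "",
        cell=(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma),
    )
    if len(st) == 0:
        logger.warning("%s contains no coordinate records", path)
        return model
    gmodel = st[0]
    for chain in gmodel:
        for res in chain:
            icode = res.seqid.icode.strip()
            is_water = res.is_water() or res.name in WATER_NAMES
            info = gemmi.find_tabulated_residue(res.name)
            is_polymer = res.entity_type == gemmi.EntityType.Polymer or (
                res.entity_type == gemmi.EntityType.Unknown
                and info is not None
                and info.is_amino_acid()
            )
            atoms = []
            for a in res:
                alt = a.altloc if a.altloc and a.altloc != "\0" else ""
                atoms.append(
                    Atom(
                        element=a.element.name,
                        name=a.name,
                        alt_loc=alt,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        b_factor=max(a.b_iso, 0.0),
                        occupancy=min(max(a.occ, 0.0), 1.0),
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=icode,
                        chain_id=chain.name,
                        is_hetero=(res.het_flag == "H"),
                        is_water=is_water,
                    )
                )
            _mark_primary_altlocs(atoms)
            residue = Residue(res.name, res.seqid.num, icode, chain.name, atoms)
            if is_water:
                oxy = residue.atom("O") or next(
                    (a for a in atoms if a.element == "O"), None
                )
                if oxy is not None:
                    model.waters.append(WaterSite(oxygen=oxy))
                else:
                    logger.warning("water %s has no oxygen atom", res.seqid.num)
            elif is_polymer:
                model.chains.setdefault(chain.name, []).append(residue)
            else:
                model.hetero_groups.append(residue)
    for residues in model.chains.values():
        residues.sort(key=lambda r: (r.number, r.insertion_code))
    total = sum(1 for _ in model.iter_atoms())
    if total == 0:
        logger.warning("%s parsed but contains zero atoms", path)
    return model


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.identifier
    st.spacegroup_hm = model.space_group or "P 1"
    st.cell = gemmi.UnitCell(*model.cell)
    gm = gemmi.Model("1")

    def add(chain_map, residue: Residue):
        ch = chain_map.setdefault(residue.chain_id, gemmi.Chain(residue.chain_id))
        gr = gemmi.Residue()
        gr.name = residue.name
        gr.seqid = gemmi.SeqId(residue.number, residue.insertion_code or " ")
        gr.het_flag = "H" if (residue.atoms and residue.atoms[0].is_hetero) else "A"
        for a in residue.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.altloc = a.alt_loc or "\0"
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            gr.add_atom(ga)
        ch.add_residue(gr)

    chain_map: dict[str, gemmi.Chain] = {}
    for residues in model.chains.values():
        for res in residues:
            add(chain_map, res)
    for grp in model.hetero_groups:
        add(chain_map, grp)
    for w in model.waters:
        res = Residue(
            w.oxygen.residue_name or "HOH",
            w.oxygen.residue_number,
            w.oxygen.insertion_code,
            w.oxygen.chain_id or "W",
            [w.oxygen],
        )
        add(chain_map, res)
    for ch in chain_map.values():
        gm.add_chain(ch)
    st.add_model(gm)
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model as PDB (coordinates to 3 decimals, B to 2)."""
    to_gemmi(model).write_pdb(str(path))


def count_entities(model: StructureModel) -> dict[str, int]:
    """Non-hydrogen entity census (alternate conformers counted once).

    Waters are counted both as molecules (``n_waters``) and as atoms; the
    atom totals satisfy macromolecule + ligand + water = non-H total.
    """
    census = {
        "non_h_atoms": 0,
        "macromolecule_atoms": 0,
        "ligand_atoms": 0,
        "water_atoms": 0,
        "n_waters": len(model.waters),
        "protein_residues": sum(len(r) for r in model.chains.values()),
    }
    for a in model.polymer_atoms(primary_only=True):
        if not a.is_hydrogen:
            census["macromolecule_atoms"] += 1
    for grp in model.hetero_groups:
        for a in grp.atoms:
            if a.is_primary_alt and not a.is_hydrogen:
                census["ligand_atoms"] += 1
    for w in model.waters:
        if w.oxygen.is_primary_alt and not w.oxygen.is_hydrogen:
            census["water_atoms"] += 1
    census["non_h_atoms"] = (
        census["macromolecule_atoms"] + census["ligand_atoms"] + census["water_atoms"]
    )
    return census


def mean_b_factor(model: StructureModel, selection: str = "all") -> float:
    """Unweighted mean isotropic B (Å²) over non-H primary-conformer atoms."""
    if selection == "all":
        atoms = model.iter_atoms(primary_only=True)
    elif selection == "macromolecule":
        atoms = model.polymer_atoms(primary_only=True)
    elif selection == "ligand":
        atoms = (a for g in model.hetero_groups for a in g.atoms if a.is_primary_alt)
    elif selection == "water":
        atoms = (w.oxygen for w in model.waters if w.oxygen.is_primary_alt)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    bs = [a.b_factor for a in atoms if not a.is_hydrogen]
    if not bs:
        raise EmptySelectionError(f"selection {selection!r} matched no atoms")
    return float(np.mean(bs))


def one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


@dataclass
class AnnotatedSequence:
    """One-letter sequence with parallel author numbering."""

    sequence: str
    numbering: list[tuple[int, str]]
    gaps: list[tuple[int, int]]  # numbering gaps (after, before)
    modified: list[tuple[int, str]]  # (author number, residue name) for nonstandard


def extract_sequence(model: StructureModel, chain_id: str) -> AnnotatedSequence:
    residues = model.chain(chain_id)
    seq, numbering, gaps, modified = [], [], [], []
    prev = None
    for res in residues:
        code = one_letter(res.name)
        std = gemmi.find_tabulated_residue(res.name)
        if std is None or not std.is_standard():
            modified.append((res.number, res.name))
        seq.append(code)
        numbering.append((res.number, res.insertion_code))
        if prev is not None and res.number > prev + 1:
            gaps.append((prev, res.number))
        prev = res.number
    if gaps:
        logger.info("chain %s has numbering gaps: %s", chain_id, gaps)
    return AnnotatedSequence("".join(seq), numbering, gaps, modified)


def npa_spacing(seq: AnnotatedSequence | str) -> dict:
    """Locate the two pore NPA motifs and count residues strictly between them.

    With more than two occurrences the pair is chosen whose spacing falls in
    [60, 200] and whose placement is most central; ambiguity (several pairs in
    the window with different spacings) raises rather than guesses.
    """
    if isinstance(seq, str):
        seq = AnnotatedSequence(seq, [(i + 1, "") for i in range(len(seq))], [], [])
    s = seq.sequence
    starts = [i for i in range(len(s) - 2) if s[i : i + 3] == "NPA"]
    if len(starts) < 2:
        raise MotifNotFoundError(f"found {len(starts)} NPA motif(s); need 2")
    if len(starts) == 2:
        pair = (starts[0], starts[1])
    else:
        center = (len(s) - 3) / 2
        candidates = []
        for i, a in enumerate(starts):
            for b in starts[i + 1 :]:
                spacing = b - (a + 3)
                if 60 <= spacing <= 200:
                    offcenter = abs(((a + b + 2) / 2) - center)
                    candidates.append((offcenter, a, b, spacing))
        if not candidates:
            raise MotifNotFoundError("no NPA pair with spacing in [60, 200]")
        candidates.sort()
        if len(candidates) > 1 and candidates[0][3] != candidates[1][3] and math.isclose(
            candidates[0][0], candidates[1][0], abs_tol=1e-9
        ):
            raise MotifNotFoundError("ambiguous NPA pair selection")
        _, a, b, _ = candidates[0]
        pair = (a, b)
        logger.info("selected NPA pair at indices %s of %s occurrences", pair, len(starts))
    a, b = pair
    return {
        "motif_positions": (seq.numbering[a][0], seq.numbering[b][0]),
        "motif_indices": pair,
        "spacing": b - (a + 3),
    }


def _aligned_pairs(seq_a: AnnotatedSequence, seq_b: AnnotatedSequence,
                   match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a.sequence, seq_b.sequence)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
    return pairs


def superpose(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str,
    chain_b: str,
    reject_outliers: bool = False,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> SuperpositionResult:
    """Sequence-align two chains and superpose their Cα atoms (Kabsch).

    ``reject_outliers`` applies one round of >2×RMSD pair rejection and
    refits; off by default.
    """
    seq_a = extract_sequence(model_a, chain_a)
    seq_b = extract_sequence(model_b, chain_b)
    res_a = model_a.chain(chain_a)
    res_b = model_b.chain(chain_b)
    pairs = _aligned_pairs(seq_a, seq_b, match, mismatch, gap)
    ca_a, ca_b, mapping = [], [], []
    for i, j in pairs:
        aa = res_a[i].atom("CA")
        ab = res_b[j].atom("CA")
        if aa is not None and ab is not None:
            ca_a.append(aa.coords)
            ca_b.append(ab.coords)
            mapping.append((res_a[i].key, res_b[j].key))
    if len(ca_a) < 3:
        raise ValueError(f"only {len(ca_a)} aligned Cα pairs; need >= 3")
    fixed = np.array(ca_a)
    moving = np.array(ca_b)
    rot, trans, rmsd = kabsch(moving, fixed)
    if reject_outliers and rmsd > 0:
        dev = np.linalg.norm(moving @ rot.T + trans - fixed, axis=1)
        keep = dev <= 2.0 * rmsd
        if keep.sum() >= 3 and keep.sum() < len(dev):
            rot, trans, rmsd = kabsch(moving[keep], fixed[keep])
            mapping = [m for m, k in zip(mapping, keep) if k]
            moving, fixed = moving[keep], fixed[keep]
    return SuperpositionResult(rot, trans, rmsd, len(mapping), mapping)
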