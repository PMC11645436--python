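"""Reading and writing of structures, sequences, site/pair tables and predictions.

Structures are parsed with :mod:`gemmi` (PDB and mmCIF). Only the first chain
of the first model is kept, restricted to standard amino acids; alternate
locations are collapsed to the highest-occupancy atom. Residue positions are
1-based and follow the numbering of the coordinate file (AlphaFold models
number 1..L along the UniProt sequence); no renumbering is attempted.

Pair tables and prediction tables are tab-separated text with a header row;
lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

PTM_TYPES = frozenset({
    "phosphorylation", "acetylation", "methylation", "ubiquitination",
    "sumoylation", "glycosylation", "other",
})

LABELS = ("positive", "negative", "unknown")


@dataclass
class Residue:
    """One standard amino-acid residue with named heavy-atom coordinates (Å)."""

    position: int              # 1-based
    name: str                  # 3-letter code
    atoms: dict                # atom name -> (3,) float array, heavy atoms only
    ca: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.ca is None:
            if "CA" not in self.atoms:
                raise ValueError(
                    f"residue {self.name}{self.position} has no CA atom")
            self.ca = np.asarray(self.atoms["CA"], dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if not np.all(np.isfinite(self.ca)):
            raise ValueError(f"non-finite CA at residue {self.position}")


@dataclass
class ProteinStructure:
    """A single-chain 3D model: sequence plus per-residue coordinates."""

    protein_id: str
    residues: list

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.protein_id}: structure has no residues")
        positions = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(
                f"{self.protein_id}: residue positions not strictly increasing")
        for r in self.residues:
            for xyz in r.atoms.values():
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(
                        f"{self.protein_id}: non-finite coordinate at "
                        f"residue {r.position}")

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list:
        return [r.position for r in self.residues]

    def residue_at(self, position: int) -> Residue:
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(f"{self.protein_id}: no residue at position {position}")

    def index_of(self, position: int) -> int:
        """0-based index into the residue list for a 1-based position."""
        for i, r in enumerate(self.residues):
            if r.position == position:
                return i
        raise KeyError(f"{self.protein_id}: no residue at position {position}")

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of Cα coordinates in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def heavy_atoms(self):
        """All heavy-atom coordinates as ((M, 3) array, (M,) residue-index array)."""
        coords, owner = [], []
        for i, r in enumerate(self.residues):
            for xyz in r.atoms.values():
                coords.append(xyz)
                owner.append(i)
        return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


@dataclass(frozen=True)
class PTMSiteRecord:
    """One modified residue: protein, 1-based position, PTM type."""

    protein_id: str
    position: int
    ptm_type: str = "other"

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class PTMPair:
    """Two PTM sites on one protein; the unit of prediction.

    Canonical order: ``site_a.position < site_b.position``.
    """

    site_a: PTMSiteRecord
    site_b: PTMSiteRecord
    label: str = "unknown"

    def __post_init__(self):
        if self.site_a.protein_id != self.site_b.protein_id:
            raise ValueError("pair spans two proteins")
        if self.site_a.position == self.site_b.position:
            raise ValueError(
                f"{self.site_a.protein_id}: pair positions coincide at "
                f"{self.site_a.position}")
        if self.site_a.position > self.site_b.position:
            # canonicalize via object.__setattr__ since frozen
            a, b = self.site_b, self.site_a
            object.__setattr__(self, "site_a", a)
            object.__setattr__(self, "site_b", b)
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def protein_id(self) -> str:
        return self.site_a.protein_id

    @property
    def positions(self):
        return (self.site_a.position, self.site_b.position)

    def key(self):
        return (self.protein_id, self.site_a.position, self.site_b.position)


@dataclass
class PairDataset:
    """PTM pairs plus a registry of the proteins they live on."""

    pairs: list
    proteins: dict = field(default_factory=dict)  # protein_id -> ProteinStructure

    def __post_init__(self):
        seen = set()
        unique = []
        for p in self.pairs:
            if p.key() in seen:
                warnings.warn(f"duplicate pair {p.key()} dropped")
                continue
            seen.add(p.key())
            unique.append(p)
        self.pairs = unique

    def __len__(self):
        return len(self.pairs)

    def structure(self, protein_id: str) -> ProteinStructure:
        return self.proteins[protein_id]

    def protein_ids(self):
        return sorted({p.protein_id for p in self.pairs})

    def labels(self) -> np.ndarray:
        return np.array([1 if p.label == "positive" else 0 for p in self.pairs])


# ---------------------------------------------------------------------------
# structure I/O

def read_structure(path, fmt: str | None = None, protein_id: str | None = None
                   ) -> ProteinStructure:
    """Parse a PDB or mmCIF file into a :class:`ProteinStructure`.

    Keeps the first chain of the first model, standard amino acids only.
    Alternate locations collapse to the highest-occupancy copy of each atom.
    Hydrogens, waters and heteroatoms are dropped.
    """
    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    if fmt == "pdb":
        st = gemmi.read_pdb(path)
    elif fmt == "mmcif":
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"{path}: no chains found")
    chain = st[0][0]
    residues = []
    for res in chain:
        if res.name not in THREE_TO_ONE:
            continue
        atoms: dict = {}
        occ: dict = {}
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            name = atom.name
            if name not in atoms or atom.occ > occ[name]:
                atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                occ[name] = atom.occ
        if not atoms:
            continue
        if "CA" not in atoms:
            raise ValueError(
                f"{path}: residue {res.name} {res.seqid.num} lacks a CA atom")
        residues.append(Residue(position=res.seqid.num, name=res.name,
                                atoms=atoms))
    if not residues:
        raise ValueError(f"{path}: no standard amino-acid residues")
    pid = protein_id or st.name or path
    return ProteinStructure(protein_id=pid, residues=residues)


def write_structure(structure: ProteinStructure, path) -> None:
    """Write a structure as a minimal single-chain PDB file."""
    st = gemmi.Structure()
    st.name = structure.protein_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for r in structure.residues:
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.position, " ")
        for aname, xyz in r.atoms.items():
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(aname[0])
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_fasta(path) -> dict:
    """Read a FASTA file into {record_id: sequence} (sequence-only operation)."""
    seqs: dict = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                seqs[current] = []
            elif current is not None:
                seqs[current].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# pair tables

PAIR_COLUMNS = ("protein_id", "pos_a", "ptm_a", "pos_b", "ptm_b", "label")


def read_pair_table(path) -> PairDataset:
    """Read a TSV of PTM pairs (columns protein_id, pos_a, ptm_a, pos_b,
    ptm_b, label). Pairs are canonically ordered; duplicates are dropped with
    a warning."""
    pairs = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(PAIR_COLUMNS) - set(header)
                if missing:
                    raise ValueError(f"{path}: missing columns {sorted(missing)}")
                idx = {c: header.index(c) for c in PAIR_COLUMNS}
                continue
            row = {c: fields[idx[c]] for c in PAIR_COLUMNS}
            label = row["label"].strip().lower()
            if label not in LABELS:
                raise ValueError(f"{path}: unknown label token {label!r}")
            pa, pb = int(row["pos_a"]), int(row["pos_b"])
            if pa == pb:
                raise ValueError(
                    f"{path}: pair with identical positions {pa} in "
                    f"{row['protein_id']}")
            site_a = PTMSiteRecord(row["protein_id"], pa, row["ptm_a"].strip())
            site_b = PTMSiteRecord(row["protein_id"], pb, row["ptm_b"].strip())
            pairs.append(PTMPair(site_a, site_b, label))
    return PairDataset(pairs=pairs)


def write_pair_table(dataset: PairDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in dataset.pairs:
            fh.write("\t".join([
                p.protein_id, str(p.site_a.position), p.site_a.ptm_type,
                str(p.site_b.position), p.site_b.ptm_type, p.label]) + "\n")


# ---------------------------------------------------------------------------
# predictions

PREDICTION_COLUMNS = ("protein_id", "pos_a", "pos_b", "p_seq", "p_graph",
                      "p_site", "p_str", "p_final", "call")


def write_predictions(results, path) -> None:
    """Write prediction results as a TSV; probabilities with 6 decimals."""
    results = list(results)
    if not results:
        raise ValueError("no prediction results to write")
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in results:
            fh.write("\t".join([
                r.protein_id, str(r.pos_a), str(r.pos_b),
                f"{r.p_seq:.6f}", f"{r.p_graph:.6f}", f"{r.p_site:.6f}",
                f"{r.p_str:.6f}", f"{r.p_final:.6f}", r.call]) + "\n")


def read_predictions(path):
    """Round-trip reader for prediction TSVs; returns a list of dicts."""
    out = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            for k in ("pos_a", "pos_b"):
                row[k] = int(row[k])
            for k in ("p_seq", "p_graph", "p_site", "p_str", "p_final"):
                row[k] = float(row[k])
            out.append(row)
    return out


# ---------------------------------------------------------------------------
# flat key=value configuration

def read_config(path) -> dict:
    """Parse a flat ``key = value`` configuration file (``#`` comments)."""
    cfg: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, _, value = line.partition("=")
            cfg[key.strip()] = _coerce(value.strip())
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value
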