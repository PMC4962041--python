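"""Readers and writers for the formats the pipeline touches.

FASTA for sequences (via Biopython), PDB for single- and multi-model
coordinate ensembles (via gemmi), and delimited tables (comma or tab,
auto-detected) for MS peptide-identification lists and NMR titration
peak tables.

Residue numbering is always taken verbatim from the source file; atom
selections refer to file numbering, never to a remapped index.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ddikit.csp import TitrationPoint, TitrationSeries
from ddikit.pics import IdentifiedPeptide, RUN_LABELS

logger = logging.getLogger("ddikit")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class FormatError(ValueError):
    """An input file violates the expected format."""


class EmptySelectionError(ValueError):
    """An atom selection matched no atoms."""


# ---------------------------------------------------------------------------
# sequences

@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence over the 20 canonical letters plus X."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"record {self.identifier!r}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FormatError(
                f"record {self.identifier!r}: illegal residue letter(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    Sequences are uppercased and ``*`` stop characters stripped.
    """
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper().replace("*", ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.residues), id=r.identifier, description="") for r in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# structures

@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom (chain, residue, name); shared by all models."""

    chain: str
    res_seq: int
    icode: str
    res_name: str
    name: str
    element: str

    @property
    def key(self) -> tuple:
        return (self.chain, self.res_seq, self.icode, self.res_name, self.name)


@dataclass
class StructureEnsemble:
    """One or more coordinate models over an identical ordered atom list."""

    atoms: list[AtomRecord]
    coords: np.ndarray  # (n_models, n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one model")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second dimension must match atom list length")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def model(self, i: int) -> "StructureEnsemble":
        return StructureEnsemble(self.atoms, self.coords[i : i + 1].copy())

    def subset(self, sel: "AtomSelection") -> "StructureEnsemble":
        """Restrict every model to the atoms matched by ``sel``."""
        idx = select_indices(self, sel)
        return StructureEnsemble([self.atoms[i] for i in idx], self.coords[:, idx, :].copy())


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest occupancy wins; ties go to the first conformer in file order."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-6:
            chosen[atom.name] = atom
    # preserve file order of first appearance
    seen: list[gemmi.Atom] = []
    names: set[str] = set()
    for atom in residue:
        if atom.name not in names:
            names.add(atom.name)
            seen.append(chosen[atom.name])
    return seen


def read_structure(path: str | Path) -> StructureEnsemble:
    """Read a PDB file into an ensemble (one model per MODEL record).

    Hydrogens are retained (select them away with an ``AtomSelection``);
    alternate locations resolve to the highest-occupancy conformer, ties
    to the first; insertion codes are kept as distinct residues.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    per_model_atoms: list[list[AtomRecord]] = []
    per_model_xyz: list[list[tuple[float, float, float]]] = []
    for model in st:
        atoms: list[AtomRecord] = []
        xyz: list[tuple[float, float, float]] = []
        for chain in model:
            for residue in chain:
                for atom in _resolve_altlocs(residue):
                    atoms.append(
                        AtomRecord(
                            chain=chain.name,
                            res_seq=residue.seqid.num,
                            icode=residue.seqid.icode.strip(),
                            res_name=residue.name,
                            name=atom.name,
                            element=atom.element.name.upper(),
                        )
                    )
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        per_model_atoms.append(atoms)
        per_model_xyz.append(xyz)
    ref = per_model_atoms[0]
    for m, atoms in enumerate(per_model_atoms[1:], start=2):
        if len(atoms) != len(ref) or any(a.key != b.key for a, b in zip(atoms, ref)):
            mismatch = next(
                (i for i, (a, b) in enumerate(zip(atoms, ref)) if a.key != b.key),
                min(len(atoms), len(ref)),
            )
            got = atoms[mismatch].key if mismatch < len(atoms) else "<missing>"
            want = ref[mismatch].key if mismatch < len(ref) else "<missing>"
            raise FormatError(
                f"{path}: model {m} atom list differs from model 1 at atom "
                f"{mismatch}: {got} != {want}"
            )
    return StructureEnsemble(ref, np.asarray(per_model_xyz, dtype=float))


def write_structure(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a PDB file (MODEL/ENDMDL when multi-model)."""
    st = gemmi.Structure()
    for m in range(ensemble.n_models):
        model = gemmi.Model(m + 1)
        chain: gemmi.Chain | None = None
        residue: gemmi.Residue | None = None
        res_key = None
        for i, rec in enumerate(ensemble.atoms):
            if chain is None or chain.name != rec.chain:
                chain = gemmi.Chain(rec.chain)
                model.add_chain(chain)
                chain = model[-1]
                res_key = None
            key = (rec.res_seq, rec.icode, rec.res_name)
            if key != res_key:
                residue = gemmi.Residue()
                residue.name = rec.res_name
                residue.seqid = gemmi.SeqId(rec.res_seq, rec.icode or " ")
                chain.add_residue(residue)
                residue = chain[-1]
                res_key = key
            atom = gemmi.Atom()
            atom.name = rec.name
            atom.element = gemmi.Element(rec.element)
            atom.occ = 1.0
            x, y, z = ensemble.coords[m, i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            residue.add_atom(atom)
        st.add_model(model)
    Path(path).write_text(st.make_pdb_string())


# ---------------------------------------------------------------------------
# atom selection

_SELECTION_RE = re.compile(r"^(?P<chain>[^:]*):(?P<lo>-?\d+)-(?P<hi>-?\d+):(?P<atoms>.+)$")


@dataclass(frozen=True)
class AtomSelection:
    """Chain (or wildcard) + inclusive residue range + atom-name set.

    ``atom_names`` may be an explicit set of names or one of the keywords
    ``"backbone"`` ({N, CA, C, O}), ``"heavy"`` (all non-hydrogen) or
    ``"all"``. Residue numbers follow the source file.
    """

    chain: str | None
    res_start: int
    res_end: int
    atom_names: frozenset[str] | str

    def __post_init__(self) -> None:
        if self.res_start > self.res_end:
            raise ValueError(
                f"selection residue range start {self.res_start} > end {self.res_end}"
            )
        if isinstance(self.atom_names, str):
            if self.atom_names not in ("backbone", "heavy", "all"):
                raise ValueError(f"unknown atom-set keyword {self.atom_names!r}")
        elif not self.atom_names:
            raise ValueError("atom-name set must be non-empty")

    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        """Parse ``"A:116-178:CA"``; chain ``*`` or empty = wildcard;
        atom field = keyword or comma-separated names."""
        m = _SELECTION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse selection {text!r} (expected chain:lo-hi:atoms)")
        chain = m.group("chain")
        atoms = m.group("atoms").strip()
        atom_names: frozenset[str] | str
        if atoms in ("backbone", "heavy", "all"):
            atom_names = atoms
        else:
            atom_names = frozenset(a.strip().upper() for a in atoms.split(",") if a.strip())
        return cls(
            chain=None if chain in ("", "*") else chain,
            res_start=int(m.group("lo")),
            res_end=int(m.group("hi")),
            atom_names=atom_names,
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if not (self.res_start <= atom.res_seq <= self.res_end):
            return False
        if self.atom_names == "all":
            return True
        if self.atom_names == "backbone":
            return atom.name in BACKBONE_ATOMS
        if self.atom_names == "heavy":
            return atom.element not in ("H", "D")
        return atom.name in self.atom_names


def select_indices(ensemble: StructureEnsemble, sel: AtomSelection) -> list[int]:
    idx = [i for i, a in enumerate(ensemble.atoms) if sel.matches(a)]
    if not idx:
        raise EmptySelectionError(f"selection {sel} matched no atoms")
    return idx


def select_coordinates(ensemble: StructureEnsemble, sel: AtomSelection) -> np.ndarray:
    """Per-model coordinate matrices, (n_models, n_selected, 3), in file order."""
    return ensemble.coords[:, select_indices(ensemble, sel), :].copy()


# ---------------------------------------------------------------------------
# tabular inputs

PEPTIDE_COLUMNS = ["sequence", "confidence", "nterm_labeled", "run_label"]

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _read_table(path: str | Path) -> pd.DataFrame:
    # comma- or tab-delimited, auto-detected from the header line
    return pd.read_csv(path, sep=None, engine="python")


def read_peptide_list(path: str | Path) -> list[IdentifiedPeptide]:
    """Read an MS peptide-identification list (CSV or TSV).

    Columns: sequence, confidence (fraction in [0, 1]), nterm_labeled
    (boolean), run_label (test/mock/inactive/library).
    """
    df = _read_table(path)
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty peptide table", path)
        return []
    peptides = []
    for row in df.itertuples(index=False):
        try:
            confidence = float(row.confidence)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric confidence {row.confidence!r}") from exc
        labeled = row.nterm_labeled
        if not isinstance(labeled, (bool, np.bool_)):
            try:
                labeled = _BOOL_MAP[str(labeled).strip().lower()]
            except KeyError as exc:
                raise FormatError(f"{path}: bad boolean {row.nterm_labeled!r}") from exc
        run_label = str(row.run_label).strip().lower()
        if run_label not in RUN_LABELS:
            raise FormatError(f"{path}: unknown run_label {row.run_label!r}")
        peptides.append(
            IdentifiedPeptide(
                sequence=str(row.sequence).strip().upper(),
                confidence=confidence,
                nterm_labeled=bool(labeled),
                run_label=run_label,
            )
        )
    return peptides


def write_peptide_list(peptides: Sequence[IdentifiedPeptide], path: str | Path) -> None:
    pd.DataFrame(
        [(p.sequence, p.confidence, p.nterm_labeled, p.run_label) for p in peptides],
        columns=PEPTIDE_COLUMNS,
    ).to_csv(path, index=False)


TITRATION_COLUMNS = ["point", "protein_mM", "ligand_mM", "residue", "shift_h_ppm", "shift_n_ppm"]


def read_titration_table(path: str | Path) -> TitrationSeries:
    """Read a long-format titration peak table into a :class:`TitrationSeries`.

    One row per (titration point, residue); per-point protein and ligand
    concentrations in mM. Points are ordered by increasing ligand:protein
    ratio; residues missing at some points are allowed and flagged on the
    series.
    """
    df = _read_table(path)
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if (df["protein_mM"] < 0).any() or (df["ligand_mM"] < 0).any():
        raise FormatError(f"{path}: negative concentration")
    dup = df.duplicated(subset=["point", "residue"])
    if dup.any():
        first = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate (point, residue) row: ({first['point']}, {first['residue']})"
        )
    points = []
    for _, grp in df.groupby("point", sort=True):
        p = float(grp["protein_mM"].iloc[0])
        l = float(grp["ligand_mM"].iloc[0])
        peaks = {
            str(row.residue): (float(row.shift_h_ppm), float(row.shift_n_ppm))
            for row in grp.itertuples(index=False)
        }
        points.append(TitrationPoint(protein_mM=p, ligand_mM=l, peaks=peaks))
    points.sort(key=lambda pt: pt.ligand_mM / pt.protein_mM if pt.protein_mM > 0 else 0.0)
    series = TitrationSeries(points=points)
    if series.incomplete_residues:
        logger.warning(
            "%s: residues missing at some points: %s", path, sorted(series.incomplete_residues)
        )
    return series


def write_titration_table(series: TitrationSeries, path: str | Path) -> None:
    rows = []
    for i, pt in enumerate(series.points):
        for residue, (dh, dn) in sorted(pt.peaks.items()):
            rows.append((i, pt.protein_mM, pt.ligand_mM, residue, dh, dn))
    pd.DataFrame(rows, columns=TITRATION_COLUMNS).to_csv(path, index=False)
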