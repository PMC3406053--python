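"""Reading coordinate files and per-residue annotations, and merging them
into validated chains.

Coordinates come from PDB-format files (ATOM records; read via gemmi).
Secondary structure and relative solvent accessibility are *inputs*, supplied
either as HSSP files or as a plain tab-separated annotation table; they are
never computed from coordinates here.

A residue survives validation only if it carries a Cα, every functional atom
its type prescribes, a known residue type, a secondary-structure code and a
finite solvent accessibility.  Residues failing any requirement are discarded
(counted per reason) while the rest of the chain is retained; the chain length
used downstream is the count of residues *after* discarding.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .residues import (
    AA1_TO_3,
    AA3,
    FUNCTIONAL_ATOMS,
    SS_CATEGORIES,
    map_ss_code,
)

logger = logging.getLogger(__name__)

_STANDARD_AA = set(AA3)


# ---------------------------------------------------------------------------
# Raw domain types
# ---------------------------------------------------------------------------

@dataclass
class RawResidue:
    name: str                      # 3-letter residue name from the file
    seq_key: str                   # author number + insertion code, e.g. "102" or "100A"
    author_num: int
    icode: str
    atoms: dict[str, np.ndarray]   # atom name -> xyz (Å)


@dataclass
class RawChain:
    chain_id: str
    residues: list[RawResidue]


@dataclass
class RawStructure:
    structure_id: str
    chains: list[RawChain]

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


@dataclass
class AnnotationRow:
    residue_type: str              # 3-letter code, or "UNK" if unrecognized
    ss_raw: str                    # single-character secondary-structure code
    sa: float                      # relative solvent accessibility, percent


@dataclass
class AnnotationTable:
    structure_id: str
    rows: dict[tuple[str, str], AnnotationRow]   # (chain_id, seq_key) -> row
    n_dropped: int = 0

    def get(self, chain_id: str, seq_key: str) -> AnnotationRow | None:
        return self.rows.get((chain_id, seq_key))


@dataclass
class ResidueRecord:
    """One fully validated residue."""

    aa: str                        # 3-letter code, one of the 20 standard types
    chain_id: str
    seq_index: int                 # 1-based ordinal among validated residues
    ca_xyz: np.ndarray
    functional_xyz: np.ndarray     # (k, 3), k per the functional-atom table
    ss: str                        # one of helix/strand/turn/coil
    sa: float
    provenance: tuple[str, str, str] = ("", "", "")  # (structure_id, author seq number, chain_id)


@dataclass
class ValidatedChain:
    structure_id: str
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def chain_length(self) -> int:
        return len(self.residues)

    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.residues:
            out[r.aa] = out.get(r.aa, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Coordinate file reading
# ---------------------------------------------------------------------------

def _looks_like_path(source: str | os.PathLike) -> bool:
    if isinstance(source, os.PathLike):
        return True
    return "\n" not in source


def read_structure(source: str | os.PathLike, structure_id: str | None = None) -> RawStructure:
    """Read a PDB-format coordinate source (path or raw text).

    HETATM records and non-standard residues are excluded; alternate locations
    resolve to the first conformer; only the first model of multi-model files
    is read.
    """
    if _looks_like_path(source):
        path = Path(source)
        text = path.read_text()
        default_id = path.stem[:4].upper()
    else:
        text = str(source)
        default_id = "XXXX"

    if not text.strip():
        raise ValueError("empty coordinate file")

    _prescan_atom_records(text)

    st = gemmi.read_pdb_string(text)
    st.remove_alternative_conformations()   # keeps the first conformer
    st.remove_hydrogens()
    if len(st) == 0:
        raise ValueError("coordinate file contains no models")

    sid = structure_id or (st.name.strip().upper() if st.name.strip() else default_id)

    model = st[0]
    chains: list[RawChain] = []
    for ch in model:
        residues: list[RawResidue] = []
        for res in ch:
            if res.het_flag != "A":
                continue
            if res.name not in _STANDARD_AA:
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.name not in atoms:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
            icode = res.seqid.icode.strip()
            residues.append(
                RawResidue(
                    name=res.name,
                    seq_key=f"{res.seqid.num}{icode}",
                    author_num=res.seqid.num,
                    icode=icode,
                    atoms=atoms,
                )
            )
        if residues:
            chains.append(RawChain(chain_id=ch.name, residues=residues))

    if not chains:
        raise ValueError("coordinate file contains no standard ATOM residues")
    return RawStructure(structure_id=sid, chains=chains)


def _prescan_atom_records(text: str) -> None:
    """Raise, naming the offending line, if an ATOM record is malformed."""
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise ValueError(f"malformed ATOM record at line {i}: too short")
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ValueError(f"malformed ATOM record at line {i}: bad coordinates") from exc
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise ValueError(f"malformed ATOM record at line {i}: non-finite coordinates")
        if not line[12:16].strip():
            raise ValueError(f"malformed ATOM record at line {i}: empty atom name")


# ---------------------------------------------------------------------------
# Annotation reading
# ---------------------------------------------------------------------------

def read_annotations(
    source: str | os.PathLike,
    dialect: str = "tsv",
    structure_id: str | None = None,
) -> AnnotationTable:
    """Read per-residue annotations.

    dialect="tsv": tab-separated with one header line and columns
    structure_id, chain_id, seq_number, insertion_code ("_" if none),
    aa_1letter, ss_code, sa_percent.

    dialect="hssp": HSSP-style residue lines (chain, PDB number, amino acid,
    secondary-structure code, accessibility).
    """
    if _looks_like_path(source):
        text = Path(source).read_text()
    else:
        text = str(source)

    if dialect == "tsv":
        table = _read_annotations_tsv(text, structure_id)
    elif dialect == "hssp":
        table = _read_annotations_hssp(text, structure_id)
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")

    if not table.rows:
        raise ValueError("annotation source contains no usable rows")
    return table


def _read_annotations_tsv(text: str, structure_id: str | None) -> AnnotationTable:
    rows: dict[tuple[str, str], AnnotationRow] = {}
    dropped = 0
    sid = structure_id or ""
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if fields[0] == "structure_id":   # header
            continue
        if len(fields) != 7:
            logger.warning("annotation TSV line %d: expected 7 fields, got %d; dropped",
                           i, len(fields))
            dropped += 1
            continue
        row_sid, chain_id, seq_number, icode, aa1, ss_code, sa_str = fields
        if structure_id is not None and row_sid != structure_id:
            dropped += 1
            continue
        sid = sid or row_sid
        try:
            sa = float(sa_str)
        except ValueError:
            logger.warning("annotation TSV line %d: bad SA %r; dropped", i, sa_str)
            dropped += 1
            continue
        if not math.isfinite(sa):
            logger.warning("annotation TSV line %d: non-finite SA; dropped", i)
            dropped += 1
            continue
        if not chain_id or not seq_number:
            dropped += 1
            continue
        aa3 = AA1_TO_3.get(aa1.upper(), "UNK")
        seq_key = seq_number + ("" if icode == "_" else icode)
        key = (chain_id, seq_key)
        if key in rows:
            logger.warning("annotation TSV line %d: duplicate key %s; keeping first", i, key)
            dropped += 1
            continue
        rows[key] = AnnotationRow(residue_type=aa3, ss_raw=ss_code, sa=sa)
    return AnnotationTable(structure_id=sid or "XXXX", rows=rows, n_dropped=dropped)


def _read_annotations_hssp(text: str, structure_id: str | None) -> AnnotationTable:
    """Parse HSSP residue lines, guided by the column header.

    The residue block starts at the header line containing '#' and 'RESIDUE';
    the positions of the STRUCTURE and BP1 header fields locate the
    secondary-structure character and the start of the numeric tail
    (BP1 BP2 ACC ...), from which accessibility is taken.
    """
    lines = text.splitlines()
    sid = structure_id
    header_idx = None
    for i, line in enumerate(lines):
        if sid is None and line.startswith("PDBID"):
            parts = line.split()
            if len(parts) >= 2:
                sid = parts[1].upper()
        if "#" in line and "RESIDUE" in line and "AA" in line:
            header_idx = i
            break
    if header_idx is None:
        raise ValueError("HSSP source: residue header line not found")

    header = lines[header_idx]
    try:
        col_ss = header.index("STRUCTURE")
        col_tail = header.index("BP1")
    except ValueError as exc:
        raise ValueError("HSSP source: header lacks STRUCTURE/BP1 columns") from exc

    rows: dict[tuple[str, str], AnnotationRow] = {}
    dropped = 0
    for line in lines[header_idx + 1:]:
        if not line.strip() or line.startswith("##"):
            break
        head = line[:col_ss].split()
        # seqno, pdb number (+ optional insertion code), chain, amino acid
        if len(head) < 4:
            dropped += 1
            continue
        _, pdb_num, chain_id, aa1 = head[0], head[1], head[2], head[3]
        if chain_id == "!" or aa1 == "!":   # chain-break marker
            dropped += 1
            continue
        ss_code = line[col_ss] if len(line) > col_ss else " "
        tail = line[col_tail:].split()
        if len(tail) < 3:
            logger.warning("HSSP residue line lacks accessibility: %r; dropped", line)
            dropped += 1
            continue
        try:
            sa = float(tail[2])
        except ValueError:
            dropped += 1
            continue
        if not math.isfinite(sa):
            dropped += 1
            continue
        aa3 = AA1_TO_3.get(aa1.upper(), "UNK")
        key = (chain_id, pdb_num)
        if key in rows:
            dropped += 1
            continue
        rows[key] = AnnotationRow(residue_type=aa3, ss_raw=ss_code, sa=sa)
    return AnnotationTable(structure_id=sid or "XXXX", rows=rows, n_dropped=dropped)


# ---------------------------------------------------------------------------
# Merge + validation
# ---------------------------------------------------------------------------

#: discard reasons reported by merge_and_validate
DISCARD_REASONS = (
    "no_annotation",
    "unknown_residue_type",
    "missing_ca",
    "missing_functional_atoms",
)


def merge_and_validate(
    structure: RawStructure,
    annotations: AnnotationTable,
    ss_map: dict[str, str] | None = None,
) -> tuple[list[ValidatedChain], dict[str, int]]:
    """Merge coordinates with annotations and apply the discard rules.

    The annotation's residue type wins on conflict with the coordinate file
    (logged).  Returns the validated chains plus a per-reason discard report
    (also containing 'validated' and 'input' totals).
    """
    report: dict[str, int] = {r: 0 for r in DISCARD_REASONS}
    report["input"] = 0
    report["validated"] = 0

    chains: list[ValidatedChain] = []
    for raw_chain in structure.chains:
        records: list[ResidueRecord] = []
        for res in raw_chain.residues:
            report["input"] += 1
            ann = annotations.get(raw_chain.chain_id, res.seq_key)
            if ann is None:
                report["no_annotation"] += 1
                continue
            aa = ann.residue_type
            if aa not in _STANDARD_AA:
                report["unknown_residue_type"] += 1
                continue
            if aa != res.name:
                logger.debug(
                    "%s %s %s: residue type %s (coords) vs %s (annotation); annotation wins",
                    structure.structure_id, raw_chain.chain_id, res.seq_key, res.name, aa,
                )
            if "CA" not in res.atoms:
                report["missing_ca"] += 1
                continue
            func_names = FUNCTIONAL_ATOMS[aa]
            if any(name not in res.atoms for name in func_names):
                report["missing_functional_atoms"] += 1
                continue
            ss = map_ss_code(ann.ss_raw, ss_map)
            assert ss in SS_CATEGORIES
            records.append(
                ResidueRecord(
                    aa=aa,
                    chain_id=raw_chain.chain_id,
                    seq_index=0,   # assigned below, after discarding
                    ca_xyz=res.atoms["CA"],
                    functional_xyz=np.stack([res.atoms[n] for n in func_names]),
                    ss=ss,
                    sa=ann.sa,
                    provenance=(structure.structure_id, res.seq_key, raw_chain.chain_id),
                )
            )
        if not records:
            logger.warning(
                "%s chain %s: no residue passed validation; chain omitted",
                structure.structure_id, raw_chain.chain_id,
            )
            continue
        for i, rec in enumerate(records, start=1):
            rec.seq_index = i
        report["validated"] += len(records)
        chains.append(
            ValidatedChain(
                structure_id=structure.structure_id,
                chain_id=raw_chain.chain_id,
                residues=records,
            )
        )
    return chains, report
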