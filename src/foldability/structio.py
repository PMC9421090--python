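"""Structure and annotation I/O.

Structure models are single-chain backbone coordinate sets with a per-residue
confidence (pLDDT, 0-100) carried in the PDB B-factor column, the convention
both AlphaFold2-style and RoseTTAFold-style predictors use.  The per-residue
value is read from the CA atom.  PDB is the normative dialect (mmCIF is
accepted on read through the same contract); parsing and serialisation are
delegated to gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import gemmi
import numpy as np
import pandas as pd
from Bio.SeqUtils import seq1

from .errors import (
    EmptyStructureError,
    FormatError,
    ValidationError,
)

VALID_LABELS = {"foldable", "unfoldable", "unknown"}

_ONE_LETTER_CACHE: dict[str, str] = {}


def _one_letter(residue_name: str) -> str:
    code = _ONE_LETTER_CACHE.get(residue_name)
    if code is None:
        code = _ONE_LETTER_CACHE[residue_name] = seq1(residue_name, undef_code="X")
    return code


class Atom(NamedTuple):
    residue_index: int  # 1-based, strictly increasing along the chain
    residue_name: str  # 3-letter code
    atom_name: str
    x: float
    y: float
    z: float
    bfactor: float


@dataclass
class StructureModel:
    """Atomic coordinates for one chain of one model."""

    model_id: str
    chain: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"model {self.model_id!r} has no atoms")
        xyz = np.array([(a.x, a.y, a.z) for a in self.atoms], dtype=float)
        if not np.isfinite(xyz).all():
            k = int(np.argwhere(~np.isfinite(xyz))[0, 0])
            a = self.atoms[k]
            raise ValidationError(
                f"non-finite coordinate on atom {a.atom_name} of residue {a.residue_index}"
            )
        res = np.array([a.residue_index for a in self.atoms])
        drops = np.nonzero(np.diff(res) < 0)[0]
        if drops.size:
            k = int(drops[0])
            raise FormatError(
                f"residue indices not monotonically increasing "
                f"({res[k]} followed by {res[k + 1]}) in model {self.model_id!r}"
            )
        self.__dict__["_coords"] = xyz

    # -- convenience views (models are treated as immutable; cached) --------

    def residue_indices(self) -> list[int]:
        cached = self.__dict__.get("_res_indices")
        if cached is None:
            seen: dict[int, None] = {}
            for a in self.atoms:
                seen.setdefault(a.residue_index, None)
            cached = self.__dict__["_res_indices"] = list(seen)
        return cached

    def residue_names(self) -> dict[int, str]:
        names: dict[int, str] = {}
        for a in self.atoms:
            names.setdefault(a.residue_index, a.residue_name)
        return names

    def sequence(self) -> str:
        """One-letter sequence over residues, in chain order."""
        cached = self.__dict__.get("_sequence")
        if cached is None:
            cached = self.__dict__["_sequence"] = "".join(
                _one_letter(name) for name in self.residue_names().values()
            )
        return cached

    def atom_lookup(self) -> dict[tuple[int, str], int]:
        """(residue_index, atom_name) -> position in ``atoms`` (first wins)."""
        cached = self.__dict__.get("_lookup")
        if cached is None:
            table: dict[tuple[int, str], int] = {}
            for k, a in enumerate(self.atoms):
                table.setdefault((a.residue_index, a.atom_name), k)
            cached = self.__dict__["_lookup"] = table
        return cached

    def coords(self) -> np.ndarray:
        cached = self.__dict__.get("_coords")
        if cached is None:
            cached = self.__dict__["_coords"] = np.array(
                [(a.x, a.y, a.z) for a in self.atoms], dtype=float
            )
        return cached

    def with_coords(self, xyz: np.ndarray, model_id: Optional[str] = None) -> "StructureModel":
        if xyz.shape != (len(self.atoms), 3):
            raise ValidationError("coordinate array shape mismatch")
        atoms = [
            a._replace(x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return StructureModel(model_id or self.model_id, self.chain, atoms)

    def with_bfactors(self, per_residue: dict[int, float]) -> "StructureModel":
        atoms = [
            a._replace(bfactor=float(per_residue.get(a.residue_index, a.bfactor)))
            for a in self.atoms
        ]
        return StructureModel(self.model_id, self.chain, atoms)

    @property
    def per_residue_confidence(self) -> dict[int, float]:
        """pLDDT per residue, taken from the CA atom's B-factor."""
        conf: dict[int, float] = {}
        for a in self.atoms:
            if a.atom_name == "CA" and a.residue_index not in conf:
                conf[a.residue_index] = a.bfactor
        return conf


@dataclass
class ModelSet:
    """An ensemble of models for one construct from one predictor."""

    construct_name: str
    predictor_tag: str
    models: list[StructureModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValidationError(
                f"empty model set for construct {self.construct_name!r}"
            )
        seqs = {m.sequence() for m in self.models}
        if len(seqs) != 1:
            raise ValidationError(
                f"models of construct {self.construct_name!r} do not share one sequence"
            )

    def __len__(self) -> int:
        return len(self.models)

    def sequence(self) -> str:
        return self.models[0].sequence()


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)


def read_structure(path, chain: Optional[str] = None, model_id: Optional[str] = None) -> StructureModel:
    """Read one chain of the first model of a PDB (or mmCIF) file.

    Alternate locations are resolved by keeping altloc ' ' or 'A'; insertion
    codes are rejected.  ``chain=None`` selects the first chain.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = st[0]
    ch = None
    for c in model:
        if chain is None or c.name == chain:
            ch = c
            break
    if ch is None:
        raise EmptyStructureError(f"chain {chain!r} not found in {path}")

    atoms: list[Atom] = []
    for res in ch:
        if res.seqid.icode not in (" ", "\x00", ""):
            raise FormatError(
                f"insertion code {res.seqid.icode!r} on residue "
                f"{res.seqid.num} in {path}: not supported"
            )
        for at in res:
            if at.altloc not in ("\x00", "", " ", "A"):
                continue
            atoms.append(
                Atom(
                    residue_index=res.seqid.num,
                    residue_name=res.name,
                    atom_name=at.name,
                    x=at.pos.x,
                    y=at.pos.y,
                    z=at.pos.z,
                    bfactor=at.b_iso,
                )
            )
    if not atoms:
        raise EmptyStructureError(f"empty selection for chain {ch.name!r} in {path}")
    return StructureModel(model_id=model_id or str(path), chain=ch.name, atoms=atoms)


_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S", "C": "C", "H": "H", "P": "P"}


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    chain = gemmi.Chain(model.chain or "A")
    res: Optional[gemmi.Residue] = None
    for a in model.atoms:
        if res is None or res.seqid.num != a.residue_index:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_index, " ")
            res.het_flag = "A"
            chain.add_residue(res)
            res = chain[-1]
        ga = gemmi.Atom()
        ga.name = a.atom_name
        ga.element = gemmi.Element(_ELEMENT_FROM_NAME.get(a.atom_name.lstrip("0123456789")[:1], "C"))
        ga.pos = gemmi.Position(a.x, a.y, a.z)
        ga.b_iso = a.bfactor
        ga.occ = 1.0
        res.add_atom(ga)
    gm.add_chain(chain)
    st.add_model(gm)
    return st


def structure_to_pdb_string(model: StructureModel) -> str:
    """Serialise to fixed-column PDB text (coordinates %.3f, B-factors %.2f)."""
    st = _to_gemmi(model)
    opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    return st.make_pdb_string(opts)


def write_structure(model: StructureModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(structure_to_pdb_string(model))


# ---------------------------------------------------------------------------
# Annotation tables


@dataclass
class AnnotationTable:
    """Per-construct experimental annotations.

    ``df`` is indexed by construct name with columns: label (foldable /
    unfoldable / unknown), precipitant_ratio, solubility, kcat, KM, deltaG,
    m_value (optional pass-through metadata).  ``overrides`` are explicit
    name -> label pairs that always win over derived labels.  ``ss_state`` is
    an optional per-residue secondary-structure string over the wild type
    ('H' helix, 'E' strand, 'C' coil).
    """

    df: pd.DataFrame
    overrides: dict[str, str] = field(default_factory=dict)
    ss_state: Optional[str] = None

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate construct_name rows: {dups}")
        for col in ("precipitant_ratio", "solubility"):
            if col in self.df.columns:
                vals = self.df[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    bad = vals[(vals < 0) | (vals > 1)].index.tolist()
                    raise ValidationError(f"{col} outside [0, 1] for {bad}")
        if "label" in self.df.columns:
            bad_labels = set(self.df["label"].dropna()) - VALID_LABELS
            if bad_labels:
                raise ValidationError(f"unrecognised labels: {sorted(bad_labels)}")
        for name, lab in self.overrides.items():
            if lab not in VALID_LABELS:
                raise ValidationError(f"override label {lab!r} for {name!r}")
        if self.ss_state is not None:
            bad = set(self.ss_state) - set("HEC")
            if bad:
                raise ValidationError(f"invalid secondary-structure codes: {sorted(bad)}")

    def labels(self) -> pd.Series:
        """Effective labels with overrides applied last."""
        lab = (
            self.df["label"].copy()
            if "label" in self.df.columns
            else pd.Series("unknown", index=self.df.index, dtype=object)
        )
        lab = lab.fillna("unknown")
        for name, value in self.overrides.items():
            if name in lab.index:
                lab.loc[name] = value
        return lab


_NUMERIC_COLS = ("precipitant_ratio", "solubility", "kcat", "KM", "deltaG", "m_value")


def read_annotations(path, overrides_path=None, ss_state: Optional[str] = None) -> AnnotationTable:
    """Load a per-construct annotation CSV (construct_name column required).

    Missing cells become unknown/absent; an overrides CSV (construct_name,label)
    is applied last and wins over everything derived downstream.
    """
    df = pd.read_csv(path)
    if "construct_name" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'construct_name'")
    df = df.set_index("construct_name")
    for col in _NUMERIC_COLS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    if "label" in df.columns:
        df["label"] = df["label"].where(df["label"].notna(), None)
    overrides: dict[str, str] = {}
    if overrides_path is not None:
        odf = pd.read_csv(overrides_path)
        overrides = dict(zip(odf["construct_name"], odf["label"]))
    return AnnotationTable(df=df, overrides=overrides, ss_state=ss_state)


def write_annotations(table: AnnotationTable, path) -> None:
    table.df.to_csv(path, index_label="construct_name")
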