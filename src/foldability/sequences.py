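"""Construct-library generation: circular permutants and single-residue insertions.

Circular permutation rearranges a protein chain: the native termini are joined
through a flexible linker (five glycines by default) and new termini are opened
at another peptide bond.  The permutant whose new N-terminus is wild-type
residue ``n`` is named ``<id>-n``; its chain reads ``n..L``, linker, ``1..n-1``.
An extra methionine is prepended whenever the new first residue is not already
Met (a requirement of recombinant expression), or when ``n`` is listed in an
explicit *forced-Met* set covering expression-specific exceptions such as
protection against methionyl-aminopeptidase cleavage.

Insertion mutants carry one extra residue (alanine by default) between
wild-type residues ``i`` and ``i+1``.  Inserting next to an existing run of the
same residue is sequence-degenerate: all sites touching the run yield one
product, which is kept once under the smallest (canonical) site index, with an
alias table so annotation rows keyed by any equivalent name still join.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_LINKER = "GGGGG"


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter wild-type sequence with 1-based residue numbering."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - CANONICAL_AA
        if bad:
            raise ValidationError(
                f"non-canonical residue letter(s) {sorted(bad)} in sequence {self.id!r}"
            )
        if len(self.residues) < 2:
            raise ValidationError(f"sequence {self.id!r} must have length >= 2")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, index: int) -> str:
        """1-based residue lookup."""
        if not 1 <= index <= len(self.residues):
            raise IndexError(f"residue index {index} outside 1..{len(self.residues)}")
        return self.residues[index - 1]


@dataclass(frozen=True)
class PermutantConstruct:
    """A circular permutant: engineered sequence plus a map back to wild type.

    ``residue_map[k]`` gives the wild-type index (1-based) of construct
    position ``k+1``, or ``None`` for linker positions and a prepended Met.
    """

    name: str
    n: int
    linker: str
    met_prepended: bool
    sequence: str
    residue_map: tuple[Optional[int], ...]

    @property
    def site(self) -> int:
        return self.n

    @property
    def kind(self) -> str:
        return "permutant"


@dataclass(frozen=True)
class InsertionConstruct:
    """A single-residue insertion mutant with degeneracy-aware naming."""

    name: str
    site: int
    canonical_site: int
    inserted_residue: str
    sequence: str
    residue_map: tuple[Optional[int], ...]

    @property
    def kind(self) -> str:
        return "insertion"


def build_circular_permutant(
    wt: ProteinSequence,
    n: int,
    linker: str = DEFAULT_LINKER,
    forced_met_sites: frozenset[int] | set[int] = frozenset(),
) -> PermutantConstruct:
    """Build the permutant whose new N-terminus is wild-type residue ``n``.

    The sequence is ``[M] + wt[n..L] + linker + wt[1..n-1]``; the leading Met
    is added iff ``wt[n] != 'M'`` or ``n`` is in ``forced_met_sites``.  For
    ``n=1`` this is the reference construct: wild type plus linker, no
    cleavage.
    """
    L = len(wt)
    if not 1 <= n <= L:
        raise IndexError(f"permutation site {n} outside 1..{L}")
    bad = set(linker) - CANONICAL_AA
    if bad:
        raise ValidationError(f"non-canonical residue letter(s) {sorted(bad)} in linker")

    met_prepended = (wt[n] != "M") or (n in forced_met_sites)
    core = wt.residues[n - 1 :] + linker + wt.residues[: n - 1]
    sequence = ("M" if met_prepended else "") + core
    residue_map: list[Optional[int]] = []
    if met_prepended:
        residue_map.append(None)
    residue_map.extend(range(n, L + 1))
    residue_map.extend([None] * len(linker))
    residue_map.extend(range(1, n))
    return PermutantConstruct(
        name=f"{wt.id}-{n}",
        n=n,
        linker=linker,
        met_prepended=met_prepended,
        sequence=sequence,
        residue_map=tuple(residue_map),
    )


def enumerate_circular_permutants(
    wt: ProteinSequence,
    linker: str = DEFAULT_LINKER,
    forced_met_sites: frozenset[int] | set[int] = frozenset(),
) -> list[PermutantConstruct]:
    """All ``L`` permutants, n = 1..L in ascending order (n=1 is the reference)."""
    return [
        build_circular_permutant(wt, n, linker, forced_met_sites)
        for n in range(1, len(wt) + 1)
    ]


def _canonical_insertion_site(wt: ProteinSequence, i: int, residue: str) -> int:
    # sites j < i collapse onto i iff wild-type residues j+1..i all equal the
    # inserted residue (inserting before or after a run is the same string)
    c = i
    while c > 1 and wt[c] == residue:
        c -= 1
    return c


def build_insertion(
    wt: ProteinSequence, i: int, residue: str = "A"
) -> InsertionConstruct:
    """Insert ``residue`` between wild-type residues ``i`` and ``i+1``."""
    L = len(wt)
    if not 1 <= i <= L - 1:
        raise IndexError(f"insertion site {i} outside 1..{L - 1}")
    if residue not in CANONICAL_AA:
        raise ValidationError(f"non-canonical inserted residue {residue!r}")
    sequence = wt.residues[:i] + residue + wt.residues[i:]
    residue_map = tuple(range(1, i + 1)) + (None,) + tuple(range(i + 1, L + 1))
    return InsertionConstruct(
        name=f"{wt.id}-{i}{residue}{i + 1}",
        site=i,
        canonical_site=_canonical_insertion_site(wt, i, residue),
        inserted_residue=residue,
        sequence=sequence,
        residue_map=residue_map,
    )


def build_alanine_insertion(wt: ProteinSequence, i: int) -> InsertionConstruct:
    return build_insertion(wt, i, "A")


@dataclass(frozen=True)
class InsertionLibrary:
    """Distinct insertion mutants plus the site-degeneracy bookkeeping."""

    constructs: tuple[InsertionConstruct, ...]
    n_sites: int
    aliases: Mapping[int, int] = field(default_factory=dict)  # site -> canonical site

    def __len__(self) -> int:
        return len(self.constructs)


def enumerate_insertions(wt: ProteinSequence, residue: str = "A") -> InsertionLibrary:
    """One construct per distinct product sequence over all ``L-1`` sites.

    Degenerate sites (insertions flanking a run of ``residue``) are collapsed
    onto the smallest site index; ``aliases`` maps every site to its canonical
    one so tables keyed by either name join correctly.
    """
    L = len(wt)
    constructs: list[InsertionConstruct] = []
    aliases: dict[int, int] = {}
    for i in range(1, L):
        c = build_insertion(wt, i, residue)
        aliases[i] = c.canonical_site
        if c.canonical_site == i:
            constructs.append(c)
    return InsertionLibrary(tuple(constructs), n_sites=L - 1, aliases=aliases)


def enumerate_alanine_insertions(wt: ProteinSequence) -> InsertionLibrary:
    return enumerate_insertions(wt, "A")


# ---------------------------------------------------------------------------
# FASTA / manifest I/O


def read_fasta(path) -> ProteinSequence:
    """Read a single-record wild-type FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    rec = records[0]
    return ProteinSequence(id=rec.id, residues=str(rec.seq).upper())


def constructs_to_fasta(constructs: Sequence) -> str:
    """Multi-record FASTA text for a construct library (record id = name)."""
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="") for c in constructs
    ]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def write_constructs_fasta(constructs: Sequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(constructs_to_fasta(constructs))


def library_manifest(constructs: Sequence) -> pd.DataFrame:
    """Tidy per-construct manifest: name, site, canonical_site, met, length."""
    rows = []
    for c in constructs:
        rows.append(
            {
                "name": c.name,
                "kind": c.kind,
                "site": c.site,
                "canonical_site": getattr(c, "canonical_site", c.site),
                "met_prepended": getattr(c, "met_prepended", False),
                "length": len(c.sequence),
            }
        )
    return pd.DataFrame(rows)
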