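"""Synthetic structures and libraries for exercising the pipeline end to end.

Real inputs to the analysis are predictor ensembles (AlphaFold2/RoseTTAFold
style) and experimental annotation tables; neither is desk-generable.  This
module emulates both:

* ``make_toy_structure`` builds an ideal-geometry backbone (N, CA, C, O and CB
  except for glycine) from canonical dihedrals: helix phi=-57, psi=-47;
  strand phi=-119, psi=+113; coil dihedrals drawn from broad basins using the
  seed.
* ``simulate_model_ensemble`` produces "predicted" models as smooth, chain-
  correlated perturbations of a reference backbone, rescaled so the backbone
  RMSD to the reference after optimal superposition matches a requested
  deviation, with per-residue pLDDT only weakly coupled to the local
  displacement (real predictors' confidence did not separate foldable from
  unfoldable constructs, and the generator mirrors that by default).
* ``simulate_construct_library`` wires a whole permutant library together:
  per-construct deviations drawn from a gamma distribution, two predictor-like
  ensembles per construct ("A" and "B", independent perturbation fields so the
  inter-model RMSD grows with the deviation), and labels / precipitant ratios /
  solubilities monotonically coupled to the deviation with Gaussian noise.

All randomness flows from a single seed; identical configs yield
byte-identical FASTA/PDB/CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3

_THREE_LETTER_CACHE: dict[str, str] = {}


def _three_letter(letter: str) -> str:
    code = _THREE_LETTER_CACHE.get(letter)
    if code is None:
        code = _THREE_LETTER_CACHE[letter] = seq3(letter).upper()
    return code

from .errors import ValidationError
from .sequences import (
    PermutantConstruct,
    ProteinSequence,
    enumerate_circular_permutants,
)
from .structio import AnnotationTable, Atom, ModelSet, StructureModel
from .superpose import kabsch  # noqa: F401  (re-exported for callers)
from .superpose import _fit_rigid

# ideal backbone geometry (Engh-Huber-like averages), Angstrom / degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
DIHEDRAL_CB = -122.6  # improper C-N-CA-CB
OMEGA = 180.0

PHI_PSI = {"H": (-57.0, -47.0), "E": (-119.0, 113.0)}


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d bonded to c."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + np.column_stack([bc, m, n]) @ d_local


def _coil_dihedrals(rng: np.random.Generator) -> tuple[float, float]:
    phi = float(rng.uniform(-160.0, -60.0))
    if rng.uniform() < 0.6:
        psi = float(rng.uniform(90.0, 170.0))
    else:
        psi = float(rng.uniform(-70.0, -10.0))
    return phi, psi


def make_toy_structure(
    sequence: str, ss_string: str, seed: int = 0, model_id: str = "toy", chain: str = "A"
) -> StructureModel:
    """Ideal-geometry backbone for ``sequence`` under a per-residue SS string."""
    if len(sequence) != len(ss_string):
        raise ValidationError("sequence and ss_string lengths differ")
    bad = set(ss_string) - set("HEC")
    if bad:
        raise ValidationError(f"invalid secondary-structure codes: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    dihedrals = [
        PHI_PSI[s] if s in PHI_PSI else _coil_dihedrals(rng) for s in ss_string
    ]

    atoms: list[Atom] = []
    theta = math.radians(ANGLE_N_CA_C)
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    C = CA + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
    for i, (letter, (phi, psi)) in enumerate(zip(sequence, dihedrals)):
        if i > 0:
            psi_prev = dihedrals[i - 1][1]
            N = _place_atom(prev_N, prev_CA, prev_C, BOND_C_N, ANGLE_CA_C_N, psi_prev)
            CA = _place_atom(prev_CA, prev_C, N, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            C = _place_atom(prev_C, N, CA, BOND_CA_C, ANGLE_N_CA_C, phi)
        O = _place_atom(N, CA, C, BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
        res_name = _three_letter(letter)
        coords = {"N": N, "CA": CA, "C": C, "O": O}
        if letter != "G":
            coords["CB"] = _place_atom(C, N, CA, BOND_CA_CB, ANGLE_N_CA_CB, DIHEDRAL_CB)
        for name in ("N", "CA", "C", "O", "CB"):
            if name in coords:
                x, y, z = coords[name]
                atoms.append(Atom(i + 1, res_name, name, float(x), float(y), float(z), 100.0))
        prev_N, prev_CA, prev_C = N, CA, C
    return StructureModel(model_id=model_id, chain=chain, atoms=atoms)


# ---------------------------------------------------------------------------
# Perturbed "predicted" ensembles


def _displacement_field(
    n_residues: int, rng: np.random.Generator, n_modes: int
) -> np.ndarray:
    """Smooth per-residue displacement: low-frequency sinusoids, random phases."""
    r = (np.arange(n_residues) + 0.5) / n_residues
    D = np.zeros((n_residues, 3))
    for m in range(1, n_modes + 1):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        phase = rng.uniform(0, 2 * math.pi)
        D += (1.0 / m) * np.sin(2 * math.pi * m * r + phase)[:, None] * u
    return D


def _perturb_reference(
    ref_xyz: np.ndarray,
    atom_res_pos: np.ndarray,
    n_residues: int,
    deviation_scale: float,
    rng: np.random.Generator,
    n_modes: int,
    jitter_frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Displaced reference coordinates calibrated so the superposed backbone
    RMSD to the reference equals ``deviation_scale``; also returns the
    per-residue displacement magnitude (for the pLDDT link)."""
    if deviation_scale == 0:
        return ref_xyz.copy(), np.zeros(n_residues)
    field = _displacement_field(n_residues, rng, n_modes)
    per_atom = field[atom_res_pos] + jitter_frac * rng.normal(size=(len(ref_xyz), 3))
    s = 1.0
    for _ in range(4):
        achieved = _fit_rigid(ref_xyz + s * per_atom, ref_xyz)[2]
        s *= deviation_scale / achieved
    disp = s * per_atom
    norms = np.linalg.norm(disp, axis=1)
    local = np.bincount(atom_res_pos, weights=norms, minlength=n_residues)
    counts = np.bincount(atom_res_pos, minlength=n_residues)
    return ref_xyz + disp, local / counts


def _construct_model(
    construct: PermutantConstruct,
    perturbed_wt_xyz: np.ndarray,
    reference: StructureModel,
    plddt: dict[int, float],
    model_id: str,
) -> StructureModel:
    """Assemble a construct-shaped model from perturbed wild-type coordinates.

    Mapped construct positions reuse the perturbed wild-type residue's atoms
    (renumbered); unmapped positions (linker, prepended Met) get deterministic
    placeholder coordinates extending from the last mapped CA.  Placeholders
    are never paired during map-based scoring.
    """
    ref_atoms_by_res = reference.__dict__.get("_atoms_by_res")
    if ref_atoms_by_res is None:
        ref_atoms_by_res = {}
        for k, a in enumerate(reference.atoms):
            ref_atoms_by_res.setdefault(a.residue_index, []).append((k, a))
        reference.__dict__["_atoms_by_res"] = ref_atoms_by_res
    offsets = {
        "N": np.array([-0.5, 0.9, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.8, 1.0, 0.3]),
        "O": np.array([0.7, 2.2, 0.3]),
        "CB": np.array([-0.6, -1.2, 0.9]),
    }
    atoms: list[Atom] = []
    last_ca = np.zeros(3)
    steps_from_anchor = 0
    for pos, (letter, wt_idx) in enumerate(
        zip(construct.sequence, construct.residue_map), start=1
    ):
        res_name = _three_letter(letter)
        if wt_idx is not None:
            b = plddt.get(wt_idx, 100.0)
            for k, a in ref_atoms_by_res[wt_idx]:
                x, y, z = perturbed_wt_xyz[k]
                atoms.append(Atom(pos, res_name, a.atom_name, float(x), float(y), float(z), b))
                if a.atom_name == "CA":
                    last_ca = perturbed_wt_xyz[k]
            steps_from_anchor = 0
        else:
            steps_from_anchor += 1
            base = last_ca + np.array([3.8 * steps_from_anchor, 0.0, 0.0])
            names = ("N", "CA", "C", "O") if letter == "G" else ("N", "CA", "C", "O", "CB")
            for name in names:
                x, y, z = base + offsets[name]
                atoms.append(Atom(pos, res_name, name, float(x), float(y), float(z), 50.0))
    return StructureModel(model_id=model_id, chain="A", atoms=atoms)


def simulate_model_ensemble(
    reference: StructureModel,
    deviation_scale: float,
    n_models: int = 5,
    seed: int = 0,
    predictor_tag: str = "A",
    construct: Optional[PermutantConstruct] = None,
    n_modes: int = 3,
    jitter_frac: float = 0.05,
    plddt_coupling: float = 2.0,
    plddt_noise: float = 2.0,
    construct_name: Optional[str] = None,
) -> ModelSet:
    """Simulate a predictor-like ensemble at a controlled deviation (Angstrom).

    Each model is the reference plus a smooth correlated displacement field
    (random low-frequency sinusoidal modes along the chain) rescaled so the
    superposed backbone RMSD to the reference equals ``deviation_scale``, plus
    small i.i.d. jitter.  Per-residue pLDDT is 100 minus a weak multiple of the
    local displacement, with noise, clipped to [0, 100]; a zero deviation gives
    exact copies at pLDDT 100.  When ``construct`` is given the models are
    assembled in construct residue order through its residue map.
    """
    if deviation_scale < 0:
        raise ValidationError("deviation_scale must be >= 0")
    rng = np.random.default_rng(seed)
    name = construct_name or (construct.name if construct else reference.model_id)
    res_ids = reference.residue_indices()
    res_pos = {r: k for k, r in enumerate(res_ids)}
    atom_res_pos = np.array([res_pos[a.residue_index] for a in reference.atoms])
    ref_xyz = reference.coords()
    models: list[StructureModel] = []
    for k in range(n_models):
        xyz, local = _perturb_reference(
            ref_xyz, atom_res_pos, len(res_ids), deviation_scale, rng, n_modes, jitter_frac
        )
        if deviation_scale == 0:
            plddt = {r: 100.0 for r in res_ids}
        else:
            noise = rng.normal(0.0, plddt_noise, size=len(res_ids))
            vals = np.clip(100.0 - plddt_coupling * local + noise, 0.0, 100.0)
            plddt = dict(zip(res_ids, vals.tolist()))
        model_id = f"{name}_{predictor_tag}_m{k + 1}"
        if construct is None:
            m = reference.with_coords(xyz, model_id=model_id).with_bfactors(plddt)
        else:
            m = _construct_model(construct, xyz, reference, plddt, model_id)
        models.append(m)
    return ModelSet(construct_name=name, predictor_tag=predictor_tag, models=models)


# ---------------------------------------------------------------------------
# Whole-library simulation


DEFAULT_SS_MOTIF = "CCCHHHHHHHHCCCCEEEEECCCC"


def default_ss_string(length: int) -> str:
    """Deterministic mixed helix/strand/coil pattern (~54% within SS)."""
    reps = -(-length // len(DEFAULT_SS_MOTIF))
    return (DEFAULT_SS_MOTIF * reps)[:length]


def random_protein_sequence(length: int, rng: np.random.Generator, id: str = "synt") -> ProteinSequence:
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    residues = "M" + "".join(rng.choice(letters, size=length - 1))
    return ProteinSequence(id=id, residues=residues)


def study_like_sequence(
    length: int = 159, n_ala: int = 13, seed: int = 0, id: str = "synthwt"
) -> ProteinSequence:
    """Synthetic stand-in for the study's wild type (its sequence is not
    reproduced here): ``length`` residues starting with Met, carrying exactly
    ``n_ala`` alanines, all isolated and at interior positions.  Under that
    arrangement every alanine collapses exactly one insertion site, so the
    distinct-insertion count is (length - 1) - n_ala.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list("CDEFGHIKLMNPQRSTVWY"))  # no alanine
    residues = list("M" + "".join(rng.choice(letters, size=length - 1)))
    positions: list[int] = []
    candidates = list(range(2, length))  # 1-based interior positions 2..length-1
    rng.shuffle(candidates)
    for p in candidates:
        if len(positions) == n_ala:
            break
        if all(abs(p - q) > 1 for q in positions):
            positions.append(p)
    if len(positions) < n_ala:
        raise ValidationError("could not place isolated alanines; length too small")
    for p in positions:
        residues[p - 1] = "A"
    return ProteinSequence(id=id, residues="".join(residues))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; every default is the condition the analyses assume.

    Deviations (Angstrom) are per-construct gamma draws (shape 2, scale 0.75;
    mean 1.5 A, spanning roughly 0.3-4 A as predictor ensembles of mixed
    quality do).  P(foldable) = logistic(-label_a * (deviation - label_b)).
    Precipitant ratio = clip01(precip_c0 + precip_c1 * deviation + noise);
    solubility has the analogous negative-slope link.
    """

    seed: int = 0
    wt_length: int = 100
    ss_string: Optional[str] = None  # default: deterministic pattern
    n_models_per_set: int = 5
    deviation_shape: float = 2.0
    deviation_scale_param: float = 0.75
    deviations: Optional[tuple[float, ...]] = None  # explicit override
    label_a: float = 3.0
    label_b: float = 1.5
    precip_c0: float = 0.2
    precip_c1: float = 0.25
    precip_sigma: float = 0.08
    solub_s0: float = 0.9
    solub_s1: float = 0.2
    solub_sigma: float = 0.08
    n_modes: int = 3
    jitter_frac: float = 0.05
    plddt_coupling: float = 2.0
    plddt_noise: float = 2.0


@dataclass
class SyntheticLibrary:
    """Everything the pipeline consumes, plus the generating ground truth."""

    config: SynthConfig
    wt: ProteinSequence
    ss_string: str
    reference: StructureModel
    constructs: list[PermutantConstruct]
    model_sets: dict[str, dict[str, ModelSet]]  # name -> {"A": ..., "B": ...}
    annotations: AnnotationTable
    truth: pd.DataFrame


def simulate_construct_library(config: SynthConfig) -> SyntheticLibrary:
    """Generate a full circular-permutant study: structures, ensembles, labels.

    One construct per permutation site (``wt_length`` constructs).  Ensembles
    "A" and "B" share the construct's true deviation but use independent
    perturbation fields, so their inter-model RMSD grows with the deviation.
    """
    ss_root = np.random.SeedSequence(config.seed)
    global_ss, *construct_ss = ss_root.spawn(config.wt_length + 1)
    rng = np.random.default_rng(global_ss)

    wt = random_protein_sequence(config.wt_length, rng)
    ss_string = config.ss_string or default_ss_string(config.wt_length)
    if len(ss_string) != config.wt_length:
        raise ValidationError("ss_string length != wt_length")
    reference = make_toy_structure(
        wt.residues, ss_string, seed=int(rng.integers(2**31)), model_id=f"{wt.id}_ref"
    )
    constructs = enumerate_circular_permutants(wt)

    if config.deviations is not None:
        if len(config.deviations) != len(constructs):
            raise ValidationError("explicit deviations length != construct count")
        deviations = np.asarray(config.deviations, dtype=float)
    else:
        deviations = rng.gamma(
            config.deviation_shape, config.deviation_scale_param, size=len(constructs)
        )

    model_sets: dict[str, dict[str, ModelSet]] = {}
    rows = []
    truth_rows = []
    for c, dev, child in zip(constructs, deviations, construct_ss):
        seed_a, seed_b, seed_ann = child.spawn(3)
        sets = {}
        for tag, s in (("A", seed_a), ("B", seed_b)):
            sets[tag] = simulate_model_ensemble(
                reference,
                float(dev),
                n_models=config.n_models_per_set,
                seed=s,
                predictor_tag=tag,
                construct=c,
                n_modes=config.n_modes,
                jitter_frac=config.jitter_frac,
                plddt_coupling=config.plddt_coupling,
                plddt_noise=config.plddt_noise,
            )
        model_sets[c.name] = sets

        ann_rng = np.random.default_rng(seed_ann)
        p_fold = 1.0 / (1.0 + math.exp(config.label_a * (dev - config.label_b)))
        label = "foldable" if ann_rng.uniform() < p_fold else "unfoldable"
        precip = float(
            np.clip(
                config.precip_c0 + config.precip_c1 * dev
                + ann_rng.normal(0.0, config.precip_sigma) * (config.precip_sigma > 0),
                0.0,
                1.0,
            )
        )
        solub = float(
            np.clip(
                config.solub_s0 - config.solub_s1 * dev
                + ann_rng.normal(0.0, config.solub_sigma) * (config.solub_sigma > 0),
                0.0,
                1.0,
            )
        )
        rows.append(
            {
                "construct_name": c.name,
                "label": label,
                "precipitant_ratio": precip,
                "solubility": solub,
            }
        )
        truth_rows.append(
            {
                "construct_name": c.name,
                "site": c.n,
                "true_deviation": float(dev),
                "p_foldable": p_fold,
            }
        )

    ann_df = pd.DataFrame(rows).set_index("construct_name")
    annotations = AnnotationTable(df=ann_df, ss_state=ss_string)
    truth = pd.DataFrame(truth_rows).set_index("construct_name")
    return SyntheticLibrary(
        config=config,
        wt=wt,
        ss_string=ss_string,
        reference=reference,
        constructs=constructs,
        model_sets=model_sets,
        annotations=annotations,
        truth=truth,
    )


def with_noise_free_links(config: SynthConfig) -> SynthConfig:
    """Copy of a config with all annotation noise switched off."""
    return replace(config, precip_sigma=0.0, solub_sigma=0.0)


def write_library(lib: SyntheticLibrary, out_dir) -> None:
    """Write a simulated study to disk in the layout the pipeline consumes.

    ``out_dir/`` gets wt.fasta, reference.pdb, constructs.fasta, manifest.csv,
    ss.txt, annotations.csv, truth.csv and models/<construct>/<tag>/model_k.pdb.
    """
    from pathlib import Path

    from .sequences import library_manifest, write_constructs_fasta
    from .structio import write_annotations, write_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "wt.fasta", "w") as fh:
        fh.write(f">{lib.wt.id}\n{lib.wt.residues}\n")
    write_structure(lib.reference, out / "reference.pdb")
    write_constructs_fasta(lib.constructs, out / "constructs.fasta")
    library_manifest(lib.constructs).to_csv(out / "manifest.csv", index=False)
    (out / "ss.txt").write_text(lib.ss_string + "\n")
    write_annotations(lib.annotations, out / "annotations.csv")
    lib.truth.to_csv(out / "truth.csv")
    for name, sets in lib.model_sets.items():
        for tag, model_set in sets.items():
            tag_dir = out / "models" / name / tag
            tag_dir.mkdir(parents=True, exist_ok=True)
            for k, model in enumerate(model_set.models, start=1):
                write_structure(model, tag_dir / f"model_{k}.pdb")
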