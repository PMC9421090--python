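"""End-to-end pipeline: score a construct library and run every analysis.

The pipeline consumes a directory layout of plain-text inputs (wild-type
FASTA, reference PDB, per-construct model ensembles, annotation CSV) and
produces ``records.csv`` (one row per construct), ``summaries.json`` (group
summaries, correlations, solubility analysis) and a plain-text ``report.txt``
whose header echoes every parameter verbatim.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import analysis
from .errors import ValidationError
from .sequences import (
    DEFAULT_LINKER,
    ProteinSequence,
    build_circular_permutant,
    build_insertion,
    read_fasta,
)
from .structio import ModelSet, read_annotations, read_structure
from .superpose import DEFAULT_ATOM_SET


@dataclass
class RunConfig:
    """Flat, strictly-validated run configuration (YAML on disk)."""

    wt_fasta: str
    reference_pdb: str
    models_dir: str
    annotations_csv: str
    manifest_csv: str
    out_dir: str
    overrides_csv: Optional[str] = None
    ss_file: Optional[str] = None
    linker: str = DEFAULT_LINKER
    atom_set: Sequence[str] = DEFAULT_ATOM_SET
    cycles: int = 5
    reject_factor: float = 2.0
    pairing: str = "map"  # "map" | "alignment"
    threshold_mode: str = "reference_construct"
    reference_name: Optional[str] = None
    fixed_threshold: Optional[float] = None
    score_field: str = "mean_rmsd"
    precipitant_cutoff: float = 0.60
    site_rule: str = "flank_right"
    solubility_cutoffs: Sequence[float] = (1.0, 2.0, 3.0, 4.0)
    soluble_cutoff: float = 0.60
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"incomplete config: {exc}") from exc


def _load_model_set(directory: Path, construct_name: str, tag: str) -> Optional[ModelSet]:
    tag_dir = directory / tag
    if not tag_dir.is_dir():
        return None
    paths = sorted(tag_dir.glob("*.pdb"))
    if not paths:
        return None
    models = [read_structure(p, model_id=p.stem) for p in paths]
    return ModelSet(construct_name=construct_name, predictor_tag=tag, models=models)


def _rebuild_construct(wt: ProteinSequence, row: pd.Series, linker: str):
    site = int(row["site"])
    if row["kind"] == "permutant":
        forced = {site} if bool(row.get("met_prepended")) and wt[site] == "M" else set()
        return build_circular_permutant(wt, site, linker, forced)
    return build_insertion(wt, site)


def run_pipeline(config: RunConfig) -> dict:
    """Execute scoring -> labels -> classification -> stratification ->
    correlations -> solubility analysis; write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    models_root = Path(config.models_dir)
    if not models_root.is_dir():
        raise ValidationError(f"model directory not found: {models_root}")

    wt = read_fasta(config.wt_fasta)
    reference = read_structure(config.reference_pdb, model_id="reference")
    manifest = pd.read_csv(config.manifest_csv)
    ss_state = None
    if config.ss_file:
        ss_state = Path(config.ss_file).read_text().strip()
    annotations = read_annotations(
        config.annotations_csv, overrides_path=config.overrides_csv, ss_state=ss_state
    )
    annotations = analysis.assign_labels_from_precipitant(
        annotations, cutoff=config.precipitant_cutoff
    )

    atom_set = tuple(config.atom_set)
    rows = []
    for _, mrow in manifest.iterrows():
        name = mrow["name"]
        cdir = models_root / str(name)
        if not cdir.is_dir():
            raise ValidationError(f"missing model directory for construct {name!r}: {cdir}")
        construct = _rebuild_construct(wt, mrow, config.linker)
        set_a = _load_model_set(cdir, name, "A")
        if set_a is None:
            raise ValidationError(f"no 'A' ensemble found under {cdir}")
        set_b = _load_model_set(cdir, name, "B")
        try:
            score = analysis.score_construct(
                set_a,
                reference,
                residue_map=construct.residue_map if config.pairing == "map" else None,
                atom_set=atom_set,
                cycles=config.cycles,
                reject_factor=config.reject_factor,
            )
            plddt = float(
                pd.Series([analysis.mean_plddt(m) for m in set_a.models]).mean()
            )
            imr = (
                analysis.inter_model_rmsd(set_a, set_b, atom_set=atom_set,
                                          cycles=config.cycles,
                                          reject_factor=config.reject_factor)
                if set_b is not None
                else None
            )
        except Exception as exc:
            raise ValidationError(f"stage scoring failed for construct {name!r}: {exc}") from exc
        rows.append(
            {
                "construct_name": name,
                "kind": mrow["kind"],
                "site": int(mrow["site"]),
                "length": int(mrow["length"]),
                "mean_rmsd": score.mean_rmsd,
                "sd_rmsd": score.sd_rmsd,
                "mean_plddt": plddt,
                "inter_model_rmsd": imr,
            }
        )
    records = pd.DataFrame(rows).set_index("construct_name")
    records["label"] = annotations.labels().reindex(records.index).fillna("unknown")
    for col in ("precipitant_ratio", "solubility"):
        if col in annotations.df.columns:
            records[col] = annotations.df[col].reindex(records.index)
    records = analysis.stratify_sites(records, ss_state, site_rule=config.site_rule)

    summaries: dict = {"parameters": _jsonable(asdict(config))}
    ref_name = config.reference_name
    if config.threshold_mode == "reference_construct" and ref_name is None:
        ref_name = records.index[0]
    group_summaries = {}
    for mode in ("reference_construct", "mean", "median"):
        try:
            gs = analysis.classify_by_threshold(
                records,
                score_field=config.score_field,
                mode=mode,
                reference_name=ref_name,
                fixed_value=config.fixed_threshold,
            )
        except ValidationError:
            continue
        group_summaries[mode] = {
            "threshold": gs.threshold_value,
            "groups": gs.groups,
        }
        if mode == config.threshold_mode:
            records["rmsd_group"] = gs.assignment
    summaries["group_summaries"] = group_summaries

    # stratified contingency: within/outside secondary structure x Low/High
    if "rmsd_group" in records.columns and ss_state is not None:
        strata = {}
        for cat in ("within_SS", "outside_SS"):
            for grp in ("Low", "High"):
                sel = records[(records["ss_category"] == cat) & (records["rmsd_group"] == grp)]
                f = int((sel["label"] == "foldable").sum())
                n = int(sel["label"].isin(["foldable", "unfoldable"]).sum())
                strata[f"{cat}/{grp}"] = analysis.contingency_summary(f, n)
        summaries["ss_stratified"] = strata

    if "precipitant_ratio" in records.columns:
        sub = records.dropna(subset=["mean_rmsd", "precipitant_ratio"])
        if len(sub) >= 3:
            rho, p = analysis.spearman(sub["mean_rmsd"], sub["precipitant_ratio"])
            summaries["spearman_rmsd_vs_precipitant"] = {"rho": rho, "p": p, "n": len(sub)}
    lab = records["label"]
    a = records.loc[lab == "foldable", "mean_rmsd"].dropna()
    b = records.loc[lab == "unfoldable", "mean_rmsd"].dropna()
    if len(a) >= 2 and len(b) >= 2:
        t, p = analysis.unpaired_t_test(a, b)
        summaries["t_test_foldable_vs_unfoldable"] = {
            "t": t, "p": p, "n_foldable": len(a), "n_unfoldable": len(b),
        }
    if "solubility" in records.columns and records["inter_model_rmsd"].notna().any():
        summaries["solubility"] = analysis.solubility_analysis(
            records,
            cutoffs=list(config.solubility_cutoffs),
            soluble_cutoff=config.soluble_cutoff,
        )

    records.to_csv(out_dir / "records.csv")
    with open(out_dir / "summaries.json", "w") as fh:
        json.dump(_jsonable(summaries), fh, indent=2, sort_keys=True)
    (out_dir / "report.txt").write_text(_format_report(config, records, summaries))
    return {"records": records, "summaries": summaries}


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def _format_report(config: RunConfig, records: pd.DataFrame, summaries: dict) -> str:
    lines = ["# Foldability pipeline report", "", "## Parameters"]
    for k, v in sorted(asdict(config).items()):
        lines.append(f"{k} = {v!r}")
    lines += ["", f"## Records ({len(records)} constructs)"]
    counts = records["label"].value_counts().to_dict()
    lines.append(f"labels: {counts}")
    for mode, gs in summaries.get("group_summaries", {}).items():
        lines += ["", f"## Low/High split ({mode}, threshold {gs['threshold']:.4f})"]
        for grp, g in gs["groups"].items():
            pct = g["percent_foldable"]
            pct_s = f"{pct:.1f} %" if pct is not None else "n/a"
            lines.append(
                f"{grp}: {g['foldable']} foldable / {g['labeled']} labeled "
                f"({pct_s}), {g['total']} total"
            )
    if "ss_stratified" in summaries:
        lines += ["", "## Secondary-structure stratification"]
        for key, c in summaries["ss_stratified"].items():
            pct = c["percent"]
            pct_s = f"{pct:.1f} %" if pct is not None else "n/a"
            lines.append(f"{key}: {c['foldable']}/{c['total']} foldable ({pct_s})")
    if "spearman_rmsd_vs_precipitant" in summaries:
        s = summaries["spearman_rmsd_vs_precipitant"]
        lines += ["", f"## Spearman mean_rmsd vs precipitant_ratio: "
                      f"rho={s['rho']:.4f}, p={s['p']:.3g}, n={s['n']}"]
    if "t_test_foldable_vs_unfoldable" in summaries:
        s = summaries["t_test_foldable_vs_unfoldable"]
        lines += ["", f"## Unpaired t test foldable vs unfoldable mean_rmsd: "
                      f"t={s['t']:.4f}, p={s['p']:.3g}"]
    lines.append("")
    return "\n".join(lines)
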