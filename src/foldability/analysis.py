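"""Construct-level statistics linking model RMSD to experimental foldability.

The row type of everything here is the *construct record*: one engineered
construct with its model-ensemble scores (mean and sample sd of the backbone
RMSD over the ensemble, mean Calpha pLDDT, inter-model RMSD between two
predictors' ensembles) joined with experimental annotations (foldable /
unfoldable label, precipitant ratio, solubility).  Records are carried as a
pandas DataFrame indexed by construct name.

Key conventions, all recorded in outputs:

* Low/High grouping: Low = score <= threshold, High = score > threshold.  The
  threshold is the score of a named reference construct (the wild-type-plus-
  linker permutant), or the mean, median, or a fixed value.
* Foldability from precipitant ratio: foldable iff ratio < 0.60 (strict),
  explicit overrides always win.
* Percentages are rounded half-away-from-zero to one decimal.
* sd is the sample standard deviation (ddof=1); a single-model ensemble
  reports sd 0 and is flagged.
* No multiple-testing correction is applied; p values are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ValidationError
from .structio import AnnotationTable, ModelSet, StructureModel
from .superpose import (
    DEFAULT_ATOM_SET,
    IterativeSuperimposer,
    align_sequences,
    pair_by_alignment,
    pair_by_map,
    _pair_from_residue_pairs,
)


# ---------------------------------------------------------------------------
# Per-construct scores


@dataclass
class ScoreResult:
    mean_rmsd: float
    sd_rmsd: float
    per_model: list[float]
    single_model: bool = False


def score_construct(
    models: ModelSet,
    reference: StructureModel,
    residue_map: Optional[Sequence[Optional[int]]] = None,
    atom_set: Sequence[str] = DEFAULT_ATOM_SET,
    cycles: int = 5,
    reject_factor: float = 2.0,
) -> ScoreResult:
    """Mean +- sd backbone RMSD of an ensemble against the reference structure.

    Each model is superposed independently (iterative fit with outlier
    rejection); pairing uses the construct's residue map when given, else a
    global sequence alignment.
    """
    rmsds: list[float] = []
    template = None  # pairing indices are reusable when models share atom layout
    for model in models.models:
        try:
            if template is None or len(model.atoms) != n_template_atoms:
                if residue_map is not None:
                    template = pair_by_map(model, reference, residue_map, atom_set)
                else:
                    template = pair_by_alignment(model, reference, atom_set)
                n_template_atoms = len(model.atoms)
            est = IterativeSuperimposer(cycles=cycles, reject_factor=reject_factor)
            est.fit(
                model.coords()[template.model_indices],
                reference.coords()[template.reference_indices],
            )
        except Exception as exc:
            raise ValidationError(
                f"superposition failed for model {model.model_id!r} of "
                f"construct {models.construct_name!r}: {exc}"
            ) from exc
        rmsds.append(float(est.rmsd_))
    single = len(rmsds) == 1
    if single:
        warnings.warn(
            f"construct {models.construct_name!r}: single-model ensemble, sd set to 0",
            stacklevel=2,
        )
    sd = 0.0 if single else float(np.std(rmsds, ddof=1))
    return ScoreResult(float(np.mean(rmsds)), sd, rmsds, single_model=single)


def mean_plddt(model: StructureModel) -> float:
    """Unweighted mean pLDDT over residues possessing a CA atom."""
    conf = model.per_residue_confidence
    if not conf:
        raise ValidationError(f"model {model.model_id!r} has no CA atoms")
    return float(np.mean(list(conf.values())))


INTER_MODEL_SCHEMES = ("all_pairs_mean", "rank_matched", "best_pair")


def inter_model_rmsd(
    set_a: ModelSet,
    set_b: ModelSet,
    scheme: str = "all_pairs_mean",
    atom_set: Sequence[str] = DEFAULT_ATOM_SET,
    cycles: int = 5,
    reject_factor: float = 2.0,
) -> float:
    """RMSD between two predictors' ensembles of the same construct.

    Residues are paired once by global sequence alignment of the two ensemble
    sequences, then each requested model pair is superposed.  Schemes:
    ``all_pairs_mean`` (default) averages all |A| x |B| cross pairs;
    ``rank_matched`` averages i-th vs i-th; ``best_pair`` takes the minimum.
    """
    if scheme not in INTER_MODEL_SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    idx_pairs = align_sequences(set_a.sequence(), set_b.sequence())
    if not idx_pairs:
        raise ValidationError(
            f"no aligned residues between ensembles of {set_a.construct_name!r}"
        )

    # models within one ensemble share an atom layout, so the atom-level
    # pairing is computed once and its index arrays reused for every pair
    m0a, m0b = set_a.models[0], set_b.models[0]
    a_res = m0a.residue_indices()
    b_res = m0b.residue_indices()
    residue_pairs = [(a_res[i], b_res[j]) for i, j in idx_pairs]
    template = _pair_from_residue_pairs(
        m0a, m0b, residue_pairs, atom_set, "sequence_alignment"
    )
    est = IterativeSuperimposer(cycles=cycles, reject_factor=reject_factor)

    def one(ma: StructureModel, mb: StructureModel) -> float:
        P = ma.coords()[template.model_indices]
        Q = mb.coords()[template.reference_indices]
        return float(est.fit(P, Q).rmsd_)

    if scheme == "rank_matched":
        if len(set_a) != len(set_b):
            raise ValidationError("rank_matched needs equal ensemble sizes")
        vals = [one(a, b) for a, b in zip(set_a.models, set_b.models)]
        return float(np.mean(vals))
    vals = [one(a, b) for a in set_a.models for b in set_b.models]
    return float(min(vals)) if scheme == "best_pair" else float(np.mean(vals))


# ---------------------------------------------------------------------------
# Labels


def assign_labels_from_precipitant(
    table: AnnotationTable, cutoff: float = 0.60
) -> AnnotationTable:
    """Derive foldable/unfoldable from the precipitant ratio (strict ``< cutoff``).

    Rows without a ratio keep their existing label; explicit overrides win.
    Returns a new table whose label column has the derived values applied.
    """
    df = table.df.copy()
    if "label" not in df.columns:
        df["label"] = None
    if "precipitant_ratio" in df.columns:
        has_ratio = df["precipitant_ratio"].notna()
        df.loc[has_ratio, "label"] = np.where(
            df.loc[has_ratio, "precipitant_ratio"] < cutoff, "foldable", "unfoldable"
        )
    df["label"] = df["label"].where(df["label"].notna(), "unknown")
    for name, lab in table.overrides.items():
        if name in df.index:
            df.loc[name, "label"] = lab
    return AnnotationTable(df=df, overrides=dict(table.overrides), ss_state=table.ss_state)


# ---------------------------------------------------------------------------
# Percentages and grouping


def round_percentage(f: int, n: int) -> tuple[float, float]:
    """(percentage rounded half-away-from-zero to 1 decimal, raw fraction)."""
    if n < 1:
        raise ValidationError("contingency denominator must be >= 1")
    if not 0 <= f <= n:
        raise ValidationError(f"count {f} outside 0..{n}")
    frac = f / n
    pct = float(Decimal(repr(100.0 * frac)).quantize(Decimal("0.1"), ROUND_HALF_UP))
    return pct, frac


def contingency_summary(foldable: int, total: int) -> dict:
    """Percentage of foldable constructs in a group or stratum."""
    if total == 0:
        return {"foldable": foldable, "total": 0, "percent": None, "fraction": None}
    pct, frac = round_percentage(foldable, total)
    return {"foldable": foldable, "total": total, "percent": pct, "fraction": frac}


@dataclass
class GroupSummary:
    """Low/High split of construct records at a score threshold."""

    threshold_mode: str
    threshold_value: float
    score_field: str
    groups: dict = field(default_factory=dict)  # "Low"/"High" -> counts + percents
    assignment: Optional[pd.Series] = None  # construct -> "Low"/"High"


THRESHOLD_MODES = ("reference_construct", "mean", "median", "fixed")


class RmsdThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier splitting constructs into Low/High score groups.

    The decision rule is ``Low`` iff score <= ``threshold_`` (the reference
    construct's own score places it in Low).  ``fit`` learns the threshold
    from the records according to ``mode``; ``predict`` assigns groups.
    """

    def __init__(
        self,
        score_field: str = "mean_rmsd",
        mode: str = "reference_construct",
        reference_name: Optional[str] = None,
        fixed_value: Optional[float] = None,
    ):
        self.score_field = score_field
        self.mode = mode
        self.reference_name = reference_name
        self.fixed_value = fixed_value

    def fit(self, X: pd.DataFrame, y=None):
        if self.mode not in THRESHOLD_MODES:
            raise ValidationError(f"unknown threshold mode {self.mode!r}")
        if self.score_field not in X.columns:
            raise ValidationError(f"records lack score field {self.score_field!r}")
        scores = X[self.score_field]
        if scores.isna().any():
            missing = scores.index[scores.isna()].tolist()
            raise ValidationError(f"missing {self.score_field} for {missing}")
        if self.mode == "reference_construct":
            if self.reference_name is None:
                raise ValidationError("reference_construct mode needs reference_name")
            if self.reference_name not in X.index:
                raise ValidationError(
                    f"reference construct {self.reference_name!r} not in records"
                )
            self.threshold_ = float(scores.loc[self.reference_name])
        elif self.mode == "mean":
            self.threshold_ = float(scores.mean())
        elif self.mode == "median":
            self.threshold_ = float(scores.median())
        else:
            if self.fixed_value is None:
                raise ValidationError("fixed mode needs fixed_value")
            self.threshold_ = float(self.fixed_value)
        self.classes_ = np.array(["High", "Low"])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = np.asarray(X[self.score_field], dtype=float)
        return np.where(scores <= self.threshold_, "Low", "High")

    def summarize(self, X: pd.DataFrame, labels: Optional[pd.Series] = None) -> GroupSummary:
        """Count foldable/unfoldable per group, with percentages to one decimal.

        Percentages use labeled records only; total counts (including
        unknown-label constructs) are reported alongside.
        """
        assignment = pd.Series(self.predict(X), index=X.index, name="group")
        if labels is None:
            labels = X["label"] if "label" in X.columns else pd.Series("unknown", index=X.index)
        groups = {}
        for g in ("Low", "High"):
            sel = labels[assignment == g]
            f = int((sel == "foldable").sum())
            u = int((sel == "unfoldable").sum())
            entry = {
                "foldable": f,
                "unfoldable": u,
                "labeled": f + u,
                "total": int((assignment == g).sum()),
            }
            entry["percent_foldable"] = (
                round_percentage(f, f + u)[0] if f + u else None
            )
            entry["percent_unfoldable"] = (
                round_percentage(u, f + u)[0] if f + u else None
            )
            groups[g] = entry
        return GroupSummary(
            threshold_mode=self.mode,
            threshold_value=self.threshold_,
            score_field=self.score_field,
            groups=groups,
            assignment=assignment,
        )


def classify_by_threshold(
    records: pd.DataFrame,
    score_field: str = "mean_rmsd",
    mode: str = "reference_construct",
    reference_name: Optional[str] = None,
    fixed_value: Optional[float] = None,
) -> GroupSummary:
    clf = RmsdThresholdClassifier(
        score_field=score_field,
        mode=mode,
        reference_name=reference_name,
        fixed_value=fixed_value,
    )
    return clf.fit(records).summarize(records)


# ---------------------------------------------------------------------------
# Secondary-structure stratification


SITE_RULES = ("flank_right", "flank_left", "both_strict")


def stratify_sites(
    records: pd.DataFrame,
    ss_state: Optional[str],
    site_rule: str = "flank_right",
) -> pd.DataFrame:
    """Attach an ss_category (within_SS / outside_SS / unknown) per construct.

    Records need ``kind`` ('permutant' | 'insertion') and ``site`` columns.  A
    permutant with new N-terminus n takes the state of residue n.  An
    insertion between residues i and i+1 takes residue i+1 (flank_right,
    default), residue i (flank_left), or is within_SS only when both flanks
    are helix/strand (both_strict).
    """
    if site_rule not in SITE_RULES:
        raise ValidationError(f"unknown site rule {site_rule!r}")
    out = records.copy()
    if ss_state is None:
        warnings.warn("no secondary-structure string: ss_category set to unknown", stacklevel=2)
        out["ss_category"] = "unknown"
        return out
    bad = set(ss_state) - set("HEC")
    if bad:
        raise ValidationError(f"invalid secondary-structure codes: {sorted(bad)}")
    L = len(ss_state)

    def categorize(kind: str, site) -> str:
        if pd.isna(site):
            return "unknown"
        site = int(site)
        if kind == "permutant":
            if not 1 <= site <= L:
                raise ValidationError(f"permutant site {site} outside 1..{L}")
            states = [ss_state[site - 1]]
        else:
            if not 1 <= site <= L - 1:
                raise ValidationError(f"insertion site {site} outside 1..{L - 1}")
            if site_rule == "flank_right":
                states = [ss_state[site]]  # residue site+1 at 0-based index site
            elif site_rule == "flank_left":
                states = [ss_state[site - 1]]
            else:  # both_strict
                states = [ss_state[site - 1], ss_state[site]]
        return "within_SS" if all(s in "HE" for s in states) else "outside_SS"

    out["ss_category"] = [
        categorize(k, s) for k, s in zip(records["kind"], records["site"])
    ]
    return out


# ---------------------------------------------------------------------------
# Correlation / group tests


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise ValidationError("need n >= 3 for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")  # undefined for a constant vector
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def unpaired_t_test(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided unpaired t test (pooled variance by default, Welch on flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0  # degenerate: identical constants
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Solubility


def _quartiles(values: np.ndarray) -> dict:
    # linear-interpolation (median-inclusive) quartile convention
    return {
        "q1": float(np.percentile(values, 25)),
        "median": float(np.percentile(values, 50)),
        "q3": float(np.percentile(values, 75)),
        "n": int(values.size),
    }


def solubility_analysis(
    records: pd.DataFrame,
    cutoffs: Sequence[float],
    soluble_cutoff: float = 0.60,
    score_field: str = "inter_model_rmsd",
) -> dict:
    """Solubility vs inter-model RMSD: cutoff sweep plus Low/High quartiles.

    For each cutoff, among records with score <= cutoff: the fraction with
    solubility >= ``soluble_cutoff`` and the mean residue length.  Separately,
    under mean- and median-threshold splits, the quartiles (linear
    interpolation) of solubility per group.
    """
    for col in (score_field, "solubility"):
        if col not in records.columns:
            raise ValidationError(f"records lack column {col!r}")
    sub = records.dropna(subset=[score_field, "solubility"])
    sweep = []
    for c in cutoffs:
        sel = sub[sub[score_field] <= c]
        if sel.empty:
            sweep.append(
                {"cutoff": float(c), "n": 0, "fraction_soluble": None, "mean_length": None}
            )
            continue
        frac = float((sel["solubility"] >= soluble_cutoff).mean())
        mean_len = (
            float(sel["length"].mean()) if "length" in sel.columns else None
        )
        sweep.append(
            {
                "cutoff": float(c),
                "n": int(len(sel)),
                "fraction_soluble": frac,
                "mean_length": mean_len,
            }
        )
    group_quartiles = {}
    for mode in ("mean", "median"):
        summary = classify_by_threshold(sub, score_field=score_field, mode=mode)
        per_group = {"threshold": summary.threshold_value}
        for g in ("Low", "High"):
            vals = sub.loc[summary.assignment == g, "solubility"].to_numpy()
            per_group[g] = _quartiles(vals) if vals.size else None
        group_quartiles[mode] = per_group
    return {
        "soluble_cutoff": soluble_cutoff,
        "score_field": score_field,
        "quartile_convention": "linear interpolation",
        "cutoff_sweep": sweep,
        "group_quartiles": group_quartiles,
    }
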