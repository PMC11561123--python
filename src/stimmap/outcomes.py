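"""Clinical outcome derivations and the cohort-level validation statistics.

Two outcome conventions coexist in this problem: a motor *progression* score
(follow-up minus baseline UPDRS-III; positive = worsening) for the training
cohort, and a *percent improvement* (positive = better) for the validation
cohort.  All correlations in this package are computed against improvement
polarity, so a positive rho always means "higher model score, better
outcome".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import ElectrodeStim

# ---------------------------------------------------------------------------
# Scalar outcome derivations


def progression_score(pre: float, post: float) -> float:
    """UPDRS-III change from baseline to follow-up; positive = worsening.

    Missing inputs (NaN/None) propagate as NaN.
    """
    if pre is None or post is None:
        return float("nan")
    return float(post) - float(pre)


def percent_improvement(pre: float, post: float) -> float:
    """100 * (pre - post) / pre; positive = improvement.  pre = 0 -> NaN."""
    if pre is None or post is None or (isinstance(pre, float) and math.isnan(pre)):
        return float("nan")
    if pre == 0:
        return float("nan")
    return 100.0 * (float(pre) - float(post)) / float(pre)


def _default_ledd_table() -> dict[str, float]:
    text = resources.files("stimmap").joinpath("data/ledd_factors.json").read_text()
    table = json.loads(text)
    return {k: float(v) for k, v in table.items() if not k.startswith("_")}


def ledd(
    entries: Iterable[tuple[str, float]], table: dict[str, float] | None = None
) -> float:
    """Levodopa equivalent daily dose: sum of dose_mg * conversion factor."""
    table = table if table is not None else _default_ledd_table()
    total = 0.0
    for drug, dose_mg in entries:
        key = drug.strip().lower().replace(" ", "_")
        if key not in table:
            raise InputError(f"no LEDD conversion factor for drug {drug!r}")
        total += float(dose_mg) * table[key]
    return total


# ---------------------------------------------------------------------------
# Rank correlation and permutation inference


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average-rank ties) and its t-approximation p-value.

    Zero variance in either vector -> (nan, nan), an undefined marker.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise InputError("spearman needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def permutation_p(
    scores: Sequence[float],
    improvements: Sequence[float],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    sided: str = "two",
) -> float:
    """Monte-Carlo permutation p for the Spearman correlation, +1 smoothed.

    two-sided: p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1);
    one-sided ("greater"): counts rho_perm >= rho_obs.
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    x = np.asarray(scores, dtype=float)
    y = np.asarray(improvements, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    denom_x = float(np.sqrt((rxc**2).sum()))

    def rho_of(ry_perm: np.ndarray) -> float:
        ryc = ry_perm - ry_perm.mean()
        return float(rxc @ ryc / (denom_x * np.sqrt((ryc**2).sum())))

    rho_obs = rho_of(ry)
    perms = np.stack([rng.permutation(ry) for _ in range(n_perm)])
    ryc = perms - perms.mean(axis=1, keepdims=True)
    rho_perm = ryc @ rxc / (denom_x * np.sqrt((ryc**2).sum(axis=1)))
    if sided == "two":
        hits = int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
    elif sided == "greater":
        hits = int(np.sum(rho_perm >= rho_obs - 1e-12))
    else:
        raise InputError(f"unknown sidedness {sided!r}")
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Cohort-level validation


@dataclass
class ValidationResult:
    pairs: pd.DataFrame  # patient_id, score, improvement
    rho: float
    p_asymptotic: float
    p_permutation: float
    n_used: int
    n_undefined_excluded: int
    label: str = ""

    def scatter_frame(self) -> pd.DataFrame:
        return self.pairs.copy()


def improvement_from_cohort(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    """Per-patient improvement-polarity outcome from a cohort table.

    outcome: "percent_improvement" (validation convention) or
    "progression" (training convention; returned negated so higher = better).
    """
    pre = cohort["updrs3_pre"].astype(float)
    post = cohort["updrs3_post"].astype(float)
    if outcome == "percent_improvement":
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 100.0 * (pre - post) / pre
        vals = vals.where(pre != 0)
    elif outcome == "progression":
        vals = -(post - pre)
    else:
        raise InputError(f"unknown outcome convention {outcome!r}")
    return pd.Series(np.asarray(vals, dtype=float), index=cohort.index, name="improvement")


def validate_cohort(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    outcome: str = "percent_improvement",
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    sided: str = "two",
    label: str = "",
) -> ValidationResult:
    """Correlate per-patient model scores with clinical improvement.

    ``scores`` needs columns patient_id and score; NaN scores (undefined
    markers) are excluded and counted, never imputed.  Refuses to report a
    correlation on fewer than 5 usable patients.
    """
    if not {"patient_id", "score"}.issubset(scores.columns):
        raise InputError("scores frame needs columns patient_id, score")
    cohort = cohort.copy()
    cohort["improvement"] = improvement_from_cohort(cohort, outcome)
    merged = scores.merge(cohort[["patient_id", "improvement"]], on="patient_id", how="inner")
    n_total = len(merged)
    usable = merged.dropna(subset=["score", "improvement"]).reset_index(drop=True)
    n_used = len(usable)
    if n_used < 5:
        raise InputError(f"only {n_used} usable patients; need at least 5")
    rho, p_asym = spearman(usable["score"].to_numpy(), usable["improvement"].to_numpy())
    p_perm = permutation_p(
        usable["score"].to_numpy(),
        usable["improvement"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
        sided=sided,
    )
    return ValidationResult(
        pairs=usable[["patient_id", "score", "improvement"]],
        rho=rho,
        p_asymptotic=p_asym,
        p_permutation=p_perm,
        n_used=n_used,
        n_undefined_excluded=n_total - n_used,
        label=label,
    )


# ---------------------------------------------------------------------------
# Responder-threshold / contact-distance analysis


def _mirror_to_reference(contact: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reflect a contact across x = 0 when it sits on the opposite side of the reference."""
    c = np.asarray(contact, dtype=float).copy()
    if reference[0] != 0 and np.sign(c[0]) != np.sign(reference[0]) and c[0] != 0:
        c[0] = -c[0]
    return c


@dataclass
class ResponderPartition:
    table: pd.DataFrame  # patient_id, progression, distance_mm, group
    threshold: float
    group_stats: pd.DataFrame  # per-group means
    empty_groups: list = field(default_factory=list)


def responder_partition(
    cohort: pd.DataFrame,
    contacts: Sequence[ElectrodeStim],
    threshold: float,
    reference_mm: np.ndarray,
) -> ResponderPartition:
    """Split a cohort into top responders (progression <= threshold) vs the rest.

    Reports each patient's Euclidean distance (mm) from their mirrored active
    contact to the reference coordinate (typically the R-map peak), and
    per-group means of progression, LEDD change and stimulation amplitude.
    """
    reference_mm = np.asarray(reference_mm, dtype=float)
    by_pid = {s.patient_id: s for s in contacts}
    rows = []
    for _, rec in cohort.iterrows():
        pid = rec["patient_id"]
        if pid not in by_pid:
            raise InputError(f"no electrode record for patient {pid!r}")
        stim = by_pid[pid]
        dist = float(
            np.linalg.norm(_mirror_to_reference(stim.contact_mm, reference_mm) - reference_mm)
        )
        prog = progression_score(rec["updrs3_pre"], rec["updrs3_post"])
        ledd_change = float(rec.get("ledd_post", np.nan)) - float(rec.get("ledd_pre", np.nan))
        rows.append(
            {
                "patient_id": pid,
                "progression": prog,
                "distance_mm": dist,
                "ledd_change": ledd_change,
                "amplitude": stim.amplitude,
                "group": "top" if prog <= threshold else "rest",
            }
        )
    table = pd.DataFrame(rows)
    stats_rows = []
    empty = []
    for grp in ("top", "rest"):
        sub = table[table["group"] == grp]
        if sub.empty:
            empty.append(grp)
            continue
        stats_rows.append(
            {
                "group": grp,
                "n": len(sub),
                "mean_progression": sub["progression"].mean(),
                "mean_distance_mm": sub["distance_mm"].mean(),
                "mean_ledd_change": sub["ledd_change"].mean(),
                "mean_amplitude": sub["amplitude"].mean(),
            }
        )
    return ResponderPartition(
        table=table,
        threshold=float(threshold),
        group_stats=pd.DataFrame(stats_rows),
        empty_groups=empty,
    )


def threshold_sweep(
    cohort: pd.DataFrame,
    contacts: Sequence[ElectrodeStim],
    thresholds: Sequence[float],
    reference_mm: np.ndarray,
) -> pd.DataFrame:
    """Responder partition repeated at several progression thresholds."""
    if len(thresholds) < 2:
        raise InputError("threshold_sweep needs at least 2 thresholds")
    rows = []
    for thr in thresholds:
        part = responder_partition(cohort, contacts, thr, reference_mm)
        rec: dict = {"threshold": float(thr)}
        for _, g in part.group_stats.iterrows():
            p = g["group"]
            rec[f"n_{p}"] = int(g["n"])
            rec[f"mean_distance_{p}"] = g["mean_distance_mm"]
            rec[f"mean_progression_{p}"] = g["mean_progression"]
            rec[f"mean_ledd_change_{p}"] = g["mean_ledd_change"]
            rec[f"mean_amplitude_{p}"] = g["mean_amplitude"]
        for p in part.empty_groups:
            rec[f"n_{p}"] = 0
        rows.append(rec)
    return pd.DataFrame(rows)
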