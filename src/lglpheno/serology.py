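"""Anti-cN1A ELISA processing: blank adjustment, fold changes, cutoffs.

Duplicate optical densities (OD, 450 nm) are averaged; every OD is
adjusted by the mean blank; the sample signal is expressed as a fold
change relative to the blank-adjusted healthy serum pool. Per-isotype
seropositivity cutoffs are the empirical 99th percentile of a healthy
reference cohort's fold changes (linear interpolation between order
statistics); a patient is seropositive when at least one isotype's fold
change strictly exceeds its cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SerologyCall", "fold_change", "derive_cutoffs", "process_plate",
           "call_samples", "call_cohort", "ISOTYPES"]

ISOTYPES = ("panIgGMA", "IgG", "IgM", "IgA")
DUPLICATE_CV_LIMIT = 0.20
PERCENTILE_METHOD = "linear"  # interpolation between order statistics


@dataclass
class SerologyCall:
    sample_id: str
    fold_changes: dict[str, float]
    cutoffs: dict[str, float]
    seropositive: bool
    flags: list[str] = field(default_factory=list)


def _dup_mean(ods, label: str, flags: list[str] | None = None) -> float:
    ods = np.asarray(ods, dtype=float)
    if len(ods) == 0:
        raise ValueError(f"no {label} wells present")
    if (ods < 0).any():
        raise ValueError(f"{label} ODs must be >= 0")
    m = float(ods.mean())
    if flags is not None and len(ods) > 1 and m > 0:
        if float(ods.std(ddof=1)) / m > DUPLICATE_CV_LIMIT:
            flags.append(f"high_cv_{label}")
    return m


def fold_change(sample_ods, blank_ods, pool_ods,
                flags: list[str] | None = None) -> float:
    """(mean(sample) - mean(blank)) / (mean(pool) - mean(blank)).

    A sample signal below blank floors at 0; a non-positive adjusted
    pool invalidates the plate.
    """
    blank = _dup_mean(blank_ods, "blank", flags)
    pool = _dup_mean(pool_ods, "pool", flags) - blank
    if pool <= 0:
        raise ValueError("adjusted pool OD must be > 0: plate invalid")
    sample = _dup_mean(sample_ods, "sample", flags) - blank
    return max(0.0, sample) / pool


def derive_cutoffs(healthy_fold_changes: dict[str, "np.ndarray"],
                   min_reference: int = 10) -> dict[str, float]:
    """Per-isotype empirical 99th-percentile cutoffs from healthy folds."""
    cutoffs = {}
    for iso, vals in healthy_fold_changes.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < min_reference:
            raise ValueError(
                f"{iso}: need >= {min_reference} reference samples, got {len(vals)}")
        if len(vals) < 100:
            warnings.warn(f"{iso}: fewer than 100 reference samples; "
                          "the 99th percentile is poorly determined")
        cutoffs[iso] = float(np.percentile(vals, 99, method=PERCENTILE_METHOD))
    return cutoffs


def process_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Fold changes per sample x isotype from a long-format plate table.

    Expects columns sample_id, isotype, replicate, od, well_role
    (sample / blank / pool / positive_control). Blank and pool wells are
    matched within sample_id and isotype.
    """
    rows = []
    for (sid, iso), grp in plate.groupby(["sample_id", "isotype"], sort=True):
        flags: list[str] = []
        fc = fold_change(
            grp.loc[grp.well_role == "sample", "od"],
            grp.loc[grp.well_role == "blank", "od"],
            grp.loc[grp.well_role == "pool", "od"],
            flags)
        rows.append({"sample_id": sid, "isotype": iso, "fold_change": fc,
                     "flags": ";".join(flags)})
    return pd.DataFrame(rows)


def call_samples(fold_changes: pd.DataFrame,
                 cutoffs: dict[str, float]) -> pd.DataFrame:
    """Seropositive iff any isotype's fold change strictly exceeds its cutoff."""
    rows = []
    for sid, grp in fold_changes.groupby("sample_id", sort=True):
        pos = False
        for _, r in grp.iterrows():
            if r["isotype"] in cutoffs and r["fold_change"] > cutoffs[r["isotype"]]:
                pos = True
        rows.append({"sample_id": sid, "seropositive": pos})
    return pd.DataFrame(rows)


def call_cohort(calls: pd.DataFrame, groups: pd.Series | dict,
                case: str = "HIGH", control: str = "LOW") -> dict:
    """Seroprevalence by group and the case-vs-control 2x2 association.

    ``calls`` has sample_id + seropositive; ``groups`` maps sample_id to
    group label. Returns per-group counts/percentages, overall patient
    prevalence, the sample odds ratio (Haldane-Anscombe corrected and
    flagged when a cell is zero), two-sided Fisher exact p, and the
    uncorrected Pearson chi-square p.
    """
    groups = pd.Series(groups)
    df = calls.copy()
    df["group"] = df["sample_id"].map(groups)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "sample_id"].tolist()
        raise ValueError(f"samples with unknown group label: {missing}")
    per_group = {}
    for g, grp in df.groupby("group"):
        n, k = len(grp), int(grp["seropositive"].sum())
        per_group[g] = {"n": n, "positive": k,
                        "pct": 100.0 * k / n if n else float("nan")}
    for g in (case, control):
        if g not in per_group:
            raise ValueError(f"group {g!r} absent from calls")
    a, n1 = per_group[case]["positive"], per_group[case]["n"]
    b, n2 = per_group[control]["positive"], per_group[control]["n"]
    table = np.array([[a, n1 - a], [b, n2 - b]])
    corrected = (table == 0).any()
    t = table + 0.5 if corrected else table
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    fisher_p = float(stats.fisher_exact(table).pvalue)
    chi2_p = (float(stats.chi2_contingency(table, correction=False).pvalue)
              if not corrected else float("nan"))
    patients = df[df["group"].isin([case, control])]
    prevalence = 100.0 * patients["seropositive"].sum() / len(patients)
    return {"per_group": per_group,
            "prevalence_pct": float(prevalence),
            "odds_ratio": float(odds_ratio),
            "haldane_corrected": bool(corrected),
            "fisher_p": fisher_p, "chi2_p": chi2_p,
            "case": case, "control": control,
            "percentile_method": PERCENTILE_METHOD}
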