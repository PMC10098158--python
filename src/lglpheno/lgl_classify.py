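"""T-LGL_HIGH / T-LGL_LOW multi-criteria classification.

Patients are classified by four criteria:

1. expansion: CD8+CD57+ cells exceed 3% of lymphocytes (the fixed
   cutoff; equivalently an HC-derived mean + 2 SD cutoff),
2. inverted CD4:CD8 ratio below 1.5,
3. aberrant immunophenotype within CD8+CD57+ cells: CD5-dim frequency
   above its HC-derived cutoff AND at least one NK-associated receptor
   (CD94, CD56 or KLRG1) above its cutoff,
4. persistence: the expansion and aberrancy hold at two visits at least
   183 days (six months) apart.

A patient meeting at least 3 determinate criteria is labelled HIGH.
Aberrancy cutoffs are healthy-control mean + 2 x sample SD per feature;
the empirical 95th percentile is recorded alongside as a diagnostic
(mean + 2 SD approximates the 97.7th percentile for normal data, so the
two conventions are reported, never silently reconciled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import pandas as pd

__all__ = ["ThresholdSet", "CriteriaFlags", "derive_thresholds",
           "evaluate_criteria", "assess_persistence", "classify_cohort",
           "ABERRANCY_FEATURES", "PERSISTENCE_WINDOW_DAYS"]

ABERRANCY_FEATURES = ("pct_cd5dim_cd8cd57", "pct_cd94_cd8cd57",
                      "pct_cd56_cd8cd57", "pct_klrg1_cd8cd57")
PERSISTENCE_WINDOW_DAYS = 183
LEUKEMIC_COUNT_PER_L = 0.5e9  # classical T-LGL leukemia count threshold (flag only)


@dataclass
class ThresholdSet:
    """Classification cutoffs, fixed or derived from healthy controls."""

    pct_cd8cd57_cutoff: float = 3.0
    ratio_cutoff: float = 1.5
    aberrancy_cutoffs: dict[str, float] = field(default_factory=dict)
    provenance: str = "fixed_from_paper"
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    n_hc: int | None = None

    def __post_init__(self) -> None:
        vals = [self.pct_cd8cd57_cutoff, self.ratio_cutoff,
                *self.aberrancy_cutoffs.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all cutoffs must be finite")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class CriteriaFlags:
    """Per-patient criterion outcomes; None marks an indeterminate criterion."""

    donor_id: str
    c1_expansion: bool | None
    c2_ratio: bool | None
    c3_aberrant: bool | None
    c4_persistent: bool | None
    leukemic_count_flag: bool = False

    @property
    def determinate(self) -> list[bool]:
        return [c for c in (self.c1_expansion, self.c2_ratio,
                            self.c3_aberrant, self.c4_persistent)
                if c is not None]

    @property
    def n_met(self) -> int:
        return sum(self.determinate)

    @property
    def label(self) -> str:
        return "HIGH" if self.n_met >= 3 else "LOW"


def _mean_2sd(values: np.ndarray) -> float:
    """Upper reference cutoff: mean + 2 x sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    return float(values.mean() + 2.0 * sd)


def derive_thresholds(hc_features: pd.DataFrame, min_donors: int = 10,
                      provenance: str = "fixed_from_paper") -> ThresholdSet:
    """Derive the cutoff set from a healthy-control feature table.

    One row per HC donor (first visit). Each aberrancy feature gets
    cutoff = HC mean + 2 x sample SD; the empirical 95th percentile is
    recorded per feature as a diagnostic. With
    ``provenance='fixed_from_paper'`` the expansion cutoff is
    max(3.0, derived); with ``'derived_from_HC'`` the derived value.
    """
    if len(hc_features) < min_donors:
        raise ValueError(
            f"need >= {min_donors} HC donors to derive thresholds, "
            f"got {len(hc_features)}")
    diagnostics: dict[str, dict[str, float]] = {}
    cutoffs: dict[str, float] = {}
    for feat in ABERRANCY_FEATURES:
        vals = hc_features[feat].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        cutoffs[feat] = _mean_2sd(finite)
        diagnostics[feat] = {
            "mean_plus_2sd": cutoffs[feat],
            "p95": float(np.percentile(finite, 95)) if len(finite) else float("nan"),
        }
    exp_vals = hc_features["pct_cd8cd57_of_lymph"].to_numpy(dtype=float)
    exp_vals = exp_vals[np.isfinite(exp_vals)]
    derived = _mean_2sd(exp_vals)
    diagnostics["pct_cd8cd57_of_lymph"] = {
        "mean_plus_2sd": derived,
        "p95": float(np.percentile(exp_vals, 95)),
    }
    if provenance == "fixed_from_paper":
        cd8cd57_cut = max(3.0, derived)
    elif provenance == "derived_from_HC":
        cd8cd57_cut = derived
    else:
        raise ValueError(f"unknown provenance {provenance!r}")
    return ThresholdSet(pct_cd8cd57_cutoff=cd8cd57_cut,
                        aberrancy_cutoffs=cutoffs, provenance=provenance,
                        diagnostics=diagnostics, n_hc=int(len(hc_features)))


def _flag(value: float, cutoff: float, greater: bool) -> bool | None:
    """Strict-inequality criterion; missing value -> indeterminate."""
    if value is None or not np.isfinite(value):
        return None
    return bool(value > cutoff) if greater else bool(value < cutoff)


def evaluate_criteria(features: pd.Series | dict,
                      thresholds: ThresholdSet) -> dict[str, bool | None]:
    """Criteria 1-3 for one donor-visit feature row (c4 needs visit history)."""
    f = dict(features)
    c1 = _flag(f.get("pct_cd8cd57_of_lymph"), thresholds.pct_cd8cd57_cutoff, True)
    c2 = _flag(f.get("cd4_cd8_ratio"), thresholds.ratio_cutoff, False)
    dim = _flag(f.get("pct_cd5dim_cd8cd57"),
                thresholds.aberrancy_cutoffs["pct_cd5dim_cd8cd57"], True)
    nkr = [_flag(f.get(feat), thresholds.aberrancy_cutoffs[feat], True)
           for feat in ABERRANCY_FEATURES[1:]]
    # three-valued (Kleene) AND/OR so missing markers propagate to
    # an indeterminate criterion instead of a spurious False
    if any(v is True for v in nkr):
        any_nkr: bool | None = True
    elif all(v is False for v in nkr):
        any_nkr = False
    else:
        any_nkr = None
    if dim is False or any_nkr is False:
        c3: bool | None = False
    elif dim is True and any_nkr is True:
        c3 = True
    else:
        c3 = None
    return {"c1_expansion": c1, "c2_ratio": c2, "c3_aberrant": c3}


def assess_persistence(visit_flags) -> bool | None:
    """Criterion 4 from time-ordered (date, c1, c3) visit records.

    True iff some visit pair >= 183 days apart has both the expansion
    (c1) and the aberrant phenotype (c3) criteria met at both visits;
    indeterminate (None) when no qualifying pair exists — including the
    single-visit case.
    """
    records = [(d, bool(c1) if c1 is not None else None,
                bool(c3) if c3 is not None else None)
               for d, c1, c3 in visit_flags]
    if not records:
        raise ValueError("at least one visit required")
    dates = [r[0] for r in records]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("visit dates must be strictly increasing")
    qualifying = [d for d, c1, c3 in records if c1 and c3]
    for i, a in enumerate(qualifying):
        for b in qualifying[i + 1:]:
            if (b - a).days >= PERSISTENCE_WINDOW_DAYS:
                return True
    return None


def classify_cohort(features: pd.DataFrame,
                    thresholds: ThresholdSet) -> pd.DataFrame:
    """Classify every donor in a donor-visit feature table.

    ``features`` needs columns ``donor_id``, ``visit_date``, the
    criterion features, and optionally ``cd8cd57_count_per_L`` (for the
    leukemic-count flag). Criteria 1-3 are evaluated on the first
    visit; persistence uses all visits. Returns one row per donor with
    flags, n_met, and label (HIGH iff n_met >= 3 among determinate
    criteria; indeterminate criteria are excluded from the denominator).
    """
    rows = []
    for donor_id, dv in features.groupby("donor_id", sort=True):
        dv = dv.sort_values("visit_date")
        first = dv.iloc[0]
        flags = evaluate_criteria(first, thresholds)
        visit_flags = []
        for _, row in dv.iterrows():
            vf = evaluate_criteria(row, thresholds)
            d = row["visit_date"]
            if isinstance(d, str):
                d = date.fromisoformat(d)
            elif isinstance(d, pd.Timestamp):
                d = d.date()
            visit_flags.append((d, vf["c1_expansion"], vf["c3_aberrant"]))
        c4 = assess_persistence(visit_flags) if len(visit_flags) >= 1 else None
        count = first.get("cd8cd57_count_per_L", float("nan"))
        cf = CriteriaFlags(donor_id=donor_id, c4_persistent=c4,
                           leukemic_count_flag=bool(
                               np.isfinite(count) and count > LEUKEMIC_COUNT_PER_L),
                           **flags)
        rows.append({"donor_id": donor_id, "c1_expansion": cf.c1_expansion,
                     "c2_ratio": cf.c2_ratio, "c3_aberrant": cf.c3_aberrant,
                     "c4_persistent": cf.c4_persistent, "n_met": cf.n_met,
                     "label": cf.label,
                     "leukemic_count_flag": cf.leukemic_count_flag})
    out = pd.DataFrame(rows)
    out.attrs["summary"] = classification_summary(out)
    return out


def classification_summary(classification: pd.DataFrame) -> dict:
    n = len(classification)
    counts = {c: int(classification[c].eq(True).sum())
              for c in ("c1_expansion", "c2_ratio", "c3_aberrant", "c4_persistent")}
    n_high = int((classification["label"] == "HIGH").sum())
    return {"n": n, "criterion_counts": counts, "n_high": n_high,
            "prevalence_high": (n_high / n if n else float("nan"))}
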