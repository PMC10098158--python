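"""HLA allele-frequency computation and case-control carriage association.

Allele frequency = occurrence count / (2 x number of typed patients)
(each patient carries two alleles per locus, G-group resolution).
Alleles at total frequency <= 2% are filtered before testing. The
association statistic is the carriage odds ratio — carriers are
patients with at least one copy, homozygotes counted once — with a
two-sided Fisher exact p on the 2x2 carriage table and the upper bound
of a 90% exact conditional confidence interval on the odds ratio.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _exact_or

__all__ = ["allele_frequency", "filter_minor", "carriage_odds_ratio",
           "association_scan", "ALLELE_PATTERN"]

ALLELE_PATTERN = re.compile(
    r"^(?P<gene>[A-Z]+[0-9]*)\*\d{2}:\d{2,3}(?::\d{2,3})?[Gi]?$")
MINOR_FREQ_THRESHOLD = 0.02
DISPLAY_FREQ_THRESHOLD = 0.05  # reporting rule: >=5% in either group


def validate_genotypes(genotypes: pd.DataFrame) -> None:
    required = {"patient_id", "locus", "allele1", "allele2"}
    missing = required - set(genotypes.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    for col in ("allele1", "allele2"):
        bad = [a for a in genotypes[col].dropna().unique()
               if not ALLELE_PATTERN.match(str(a))]
        if bad:
            raise ValueError(f"malformed allele names: {bad[:5]}")
    dup = genotypes.duplicated(["patient_id", "locus"])
    if dup.any():
        raise ValueError("more than one genotype row per patient and locus")


def allele_frequency(n: int, n_patients: int) -> float:
    """Occurrence count over 2 x patients typed at the locus."""
    if not 0 <= n <= 2 * n_patients:
        raise ValueError(
            f"occurrence count {n} outside [0, {2 * n_patients}]")
    return n / (2 * n_patients)


def filter_minor(stats_table: pd.DataFrame,
                 threshold: float = MINOR_FREQ_THRESHOLD) -> pd.DataFrame:
    """Keep alleles with total frequency strictly above ``threshold``."""
    return stats_table.loc[stats_table["freq_total"] > threshold].copy()


def display_filter(stats_table: pd.DataFrame,
                   threshold: float = DISPLAY_FREQ_THRESHOLD) -> pd.DataFrame:
    """Reporting view: alleles at >= 5% frequency in either group."""
    keep = ((stats_table["freq_high"] >= threshold)
            | (stats_table["freq_low"] >= threshold))
    return stats_table.loc[keep].copy()


def carriage_odds_ratio(carriers_high: int, n_high: int,
                        carriers_low: int, n_low: int,
                        ci_level: float = 0.90):
    """Carriage OR, two-sided Fisher exact p, and exact upper CI bound.

    OR = [a/(n1-a)] / [b/(n2-b)] on the carriage 2x2 table; zero cells
    get the Haldane-Anscombe 0.5 correction (OR and CI only, flagged);
    the Fisher p is always computed on the uncorrected table.
    """
    if n_high <= 0 or n_low <= 0:
        raise ValueError("group sizes must be > 0")
    if not (0 <= carriers_high <= n_high and 0 <= carriers_low <= n_low):
        raise ValueError("carrier counts must lie within group sizes")
    table = np.array([[carriers_high, n_high - carriers_high],
                      [carriers_low, n_low - carriers_low]])
    corrected = (table == 0).any()
    t = table + 0.5 if corrected else table.astype(float)
    orr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    p = float(stats.fisher_exact(table).pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ci_table = (table + 1 if corrected else table)  # integer table for exact CI
        ci = _exact_or(ci_table, kind="conditional").confidence_interval(ci_level)
    return {"odds_ratio": float(orr), "fisher_p": p,
            "ci_upper": float(ci.high), "haldane_corrected": bool(corrected)}


def _melt_alleles(genotypes: pd.DataFrame) -> pd.DataFrame:
    long = pd.concat([
        genotypes[["patient_id", "locus", "allele1"]].rename(
            columns={"allele1": "allele"}),
        genotypes[["patient_id", "locus", "allele2"]].rename(
            columns={"allele2": "allele"}),
    ])
    return long.dropna(subset=["allele"])


def association_scan(genotypes: pd.DataFrame, labels: pd.Series | dict,
                     case: str = "HIGH", control: str = "LOW",
                     min_freq: float = MINOR_FREQ_THRESHOLD,
                     ci_level: float = 0.90,
                     add_fdr: bool = True) -> pd.DataFrame:
    """Allele-by-allele case/control scan across all loci.

    ``labels`` maps patient_id to group; patients with other labels are
    ignored. Patients missing a locus are excluded from that locus's
    denominators (logged via warning). Returns one row per retained
    allele, sorted by Fisher p, with occurrence counts, frequencies,
    carrier counts, carriage OR + exact upper CI bound and raw p
    (optionally a Benjamini-Hochberg column; the headline call uses raw p).
    """
    validate_genotypes(genotypes)
    labels = pd.Series(labels)
    g = genotypes.copy()
    g["group"] = g["patient_id"].map(labels)
    g = g[g["group"].isin([case, control])]
    if g.empty:
        raise ValueError("no genotyped patients with case/control labels")

    patients = g["patient_id"].unique()
    rows = []
    for locus, gl in g.groupby("locus", sort=True):
        typed = gl["patient_id"].unique()
        missing = set(patients) - set(typed)
        if missing:
            warnings.warn(f"locus {locus}: {len(missing)} patients untyped; "
                          "excluded from this locus's denominators")
        n_by_group = gl.groupby("group")["patient_id"].nunique()
        n_high = int(n_by_group.get(case, 0))
        n_low = int(n_by_group.get(control, 0))
        long = _melt_alleles(gl.assign(group=gl["group"]))
        long = long.merge(gl[["patient_id", "group"]].drop_duplicates(),
                          on="patient_id")
        for allele, al in long.groupby("allele"):
            occ = al.groupby("group").size()
            n_occ_high = int(occ.get(case, 0))
            n_occ_low = int(occ.get(control, 0))
            carriers = al.groupby("group")["patient_id"].nunique()
            c_high = int(carriers.get(case, 0))
            c_low = int(carriers.get(control, 0))
            n_total = n_high + n_low
            if n_high > 0 and n_low > 0:
                res = carriage_odds_ratio(c_high, n_high, c_low, n_low,
                                          ci_level=ci_level)
                res["degenerate"] = False
            else:  # one group untyped at this locus: no association testable
                res = {"odds_ratio": float("nan"), "fisher_p": float("nan"),
                       "ci_upper": float("nan"), "haldane_corrected": False,
                       "degenerate": True}
            rows.append({
                "allele": allele, "locus": locus,
                "n_total": n_occ_high + n_occ_low,
                "n_high": n_occ_high, "n_low": n_occ_low,
                "freq_total": allele_frequency(n_occ_high + n_occ_low, n_total),
                "freq_high": (allele_frequency(n_occ_high, n_high)
                              if n_high else float("nan")),
                "freq_low": (allele_frequency(n_occ_low, n_low)
                             if n_low else float("nan")),
                "carriers_high": c_high, "carriers_low": c_low,
                "n_patients_high": n_high, "n_patients_low": n_low,
                **res,
            })
    out = pd.DataFrame(rows)
    out = filter_minor(out, min_freq)
    out = out.sort_values(["fisher_p", "allele"]).reset_index(drop=True)
    if add_fdr and len(out):
        from statsmodels.stats.multitest import multipletests
        out["fdr_bh"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    return out


def scan_report(scan: pd.DataFrame) -> pd.DataFrame:
    """Publication-shaped view: percentages and OR (upper CI bound)."""
    rep = pd.DataFrame({
        "allele": scan["allele"],
        "pct_total": (100 * scan["freq_total"]).round(2),
        "pct_high": (100 * scan["freq_high"]).round(2),
        "pct_low": (100 * scan["freq_low"]).round(2),
        "odds_ratio": scan["odds_ratio"].round(2),
        "or_ci_upper": scan["ci_upper"].round(2),
        "p_value": scan["fisher_p"].round(4),
    })
    return rep
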