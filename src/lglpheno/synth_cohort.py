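"""Synthetic IBM / T-LGL cohort generator.

Generates complete cohorts with the statistical structure the analysis
assumes: donor demographics and metadata, event-level flow cytometry
for three antibody panels (surface, intracellular cytokine, Ki67),
longitudinal visits, HLA class I/II genotypes and anti-cN1A ELISA
plates. Every donor carries planted ground-truth parameters and every
event a hidden ground-truth class label, both retained for testing only.

Donor-level subset fractions are drawn logit-normal around the
configured group locations; per-event marker states are Bernoulli given
the donor's fractions; fluorescence intensities are two-component
log-normal mixtures per channel (three-state for CD5 to represent CD5
downregulation). Count beads form a separate high side-scatter cluster,
bright on all fluorescence channels, at a number matching the planted
blood lymphocyte concentration through the bead-normalisation formula.

Determinism: all draws derive from ``config.seed``; a given
(donor, visit, panel) sample is generated from its own child seed, so
regeneration of any single sample is independent of iteration order and
byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (GROUPS, PANEL_CHANNELS, FluorModel, GeneratorConfig, expit)
from .cyto_gating import EventTable
from .fcs import write_events

__all__ = ["DonorRecord", "SyntheticCohort", "generate_cohort", "write_events"]

_BASE_DATE = date(2018, 1, 1)
_PANEL_CODE = {"surface": 0, "intracellular": 1, "ki67": 2}


@dataclass
class DonorRecord:
    """One synthetic donor with planted ground-truth parameters."""

    donor_id: str
    group_true: str
    age: float
    sex: str
    onset_age: float | None
    symptom_duration: float | None
    mobility_aid: str
    visit_dates: list[date]
    serostatus_true: bool
    planted: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.group_true not in GROUPS:
            raise ValueError(f"unknown group {self.group_true!r}")
        if any(b <= a for a, b in zip(self.visit_dates, self.visit_dates[1:])):
            raise ValueError("visit_dates must be strictly increasing")
        if self.group_true == "HC" and self.onset_age is not None:
            raise ValueError("HC donors have no onset age")
        if self.onset_age is not None and self.onset_age > self.age:
            raise ValueError("onset_age must not exceed age")


def _logit_normal(rng, spec, size=None):
    return expit_arr(rng.normal(spec["loc"], spec["scale"], size=size))


def expit_arr(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _lognormal(rng, spec, size=None):
    return np.exp(rng.normal(spec["log_median"], spec["sigma"], size=size))


def _plant_donor(rng, group: str, cfg: GeneratorConfig) -> dict:
    """Draw the per-donor ground-truth parameter set."""
    prof = cfg.marker_profile[group]
    p: dict = {}
    p["pct_cd8cd57_of_lymph"] = float(_logit_normal(rng, prof["pct_cd8cd57_of_lymph"]))
    p["cd4_cd8_ratio"] = float(_lognormal(rng, prof["cd4_cd8_ratio"]))
    p["lymph_per_uL"] = float(_lognormal(rng, prof["lymph_per_uL"]))
    p["t_frac"] = float(_logit_normal(rng, prof["t_frac_of_lymph"]))
    p["gd_frac"] = float(_logit_normal(rng, prof["gd_frac_of_t"]))
    p["dn_frac"] = prof["dn_frac_of_ab"]
    p["dp_frac"] = prof["dp_frac_of_ab"]
    r = p["cd4_cd8_ratio"]
    rest = 1.0 - p["dn_frac"] - p["dp_frac"]
    p["cd4_of_ab"] = rest * r / (1.0 + r)
    p["cd8_of_ab"] = rest / (1.0 + r)
    # CD57+ fraction of CD8 chosen so that the planted %CD8+CD57+ of
    # lymphocytes is internally consistent with the lineage fractions
    denom = p["t_frac"] * (1.0 - p["gd_frac"]) * p["cd8_of_ab"]
    p["cd57_in_cd8"] = float(np.clip(p["pct_cd8cd57_of_lymph"] / denom, 5e-4, 0.95))
    # keep the headline planted value exactly consistent after clipping
    p["pct_cd8cd57_of_lymph"] = p["cd57_in_cd8"] * denom
    p["cd57_in_cd4"] = float(_logit_normal(rng, prof["cd57_in_cd4"]))
    p["cd57_in_gd"] = float(_logit_normal(rng, prof["cd57_in_gd"]))
    for key in ("cd57_in_dndp", "nk_cd57", "nk_cd56"):
        p[key] = prof[key]
    for sub in ("cd8", "cd4", "gd"):
        p[f"markers_{sub}cd57"] = {
            k: float(_logit_normal(rng, spec))
            for k, spec in prof[f"markers_{sub}cd57"].items()}
    p["cd57neg_background"] = dict(prof["cd57neg_background"])
    p["cd45ra_frac"] = dict(prof["cd45ra_frac"])
    intra = prof["intracellular"]
    for sub in ("cd8", "cd4"):
        for marker, shift_key in (("ifng", "ra_shift_ifng"),
                                  ("perforin", "ra_shift_perforin")):
            base = float(rng.normal(intra[f"{marker}_{sub}"]["loc"],
                                    intra[f"{marker}_{sub}"]["scale"]))
            shift = intra[shift_key]
            p[f"{marker}_{sub}_ra_pos"] = float(expit(base + shift))
            p[f"{marker}_{sub}_ra_neg"] = float(expit(base - shift))
            ra = p["cd45ra_frac"][sub]
            p[f"{marker}_{sub}"] = (ra * p[f"{marker}_{sub}_ra_pos"]
                                    + (1 - ra) * p[f"{marker}_{sub}_ra_neg"])
    p["ki67_cd8"] = {k: float(_logit_normal(rng, spec))
                     for k, spec in prof["ki67_cd8"].items()}
    return p


def _make_donor(rng, group: str, idx: int, cfg: GeneratorConfig) -> DonorRecord:
    demo = cfg.demographics
    a = demo["age"][group]
    age = float(np.clip(rng.normal(a["mean"], a["sd"]),
                        demo["age"]["min"], demo["age"]["max"]))
    sex = "M" if rng.random() < demo["male_prob"][group] else "F"
    if group == "HC":
        onset, duration, aid = None, None, "none"
    else:
        duration = float(_lognormal(rng, demo["duration"][group]))
        duration = min(duration, age - 18.0)
        onset = age - duration
        if rng.random() < demo["mobility_aid_prob"][group]:
            aid = str(rng.choice(demo["aid_types"]))
        else:
            aid = "none"
    first = _BASE_DATE + timedelta(days=int(rng.integers(0, 1000)))
    dates = [first]
    for _ in range(cfg.n_visits - 1):
        lo, hi = cfg.visit_gap_days
        dates.append(dates[-1] + timedelta(days=int(rng.integers(lo, hi + 1))))
    sero = bool(rng.random() < cfg.serology_model["seropos_prob"][group])
    return DonorRecord(
        donor_id=f"{group}{idx:03d}", group_true=group, age=age, sex=sex,
        onset_age=onset, symptom_duration=duration, mobility_aid=aid,
        visit_dates=dates, serostatus_true=sero,
        planted=_plant_donor(rng, group, cfg))


# ---------------------------------------------------------------------------
# event-level generation
# ---------------------------------------------------------------------------

def _fluor(rng, channel, states, fluor: FluorModel):
    """Log-normal intensities given integer component state per event."""
    ch = fluor.channels[channel]
    med = ch.neg_median * ch.separation ** np.asarray(states, dtype=float)
    return np.exp(np.log(med) + ch.sigma * rng.standard_normal(len(med)))


def _scatter(rng, cluster_names, fluor: FluorModel):
    fsc = np.empty(len(cluster_names))
    ssc = np.empty(len(cluster_names))
    for name, cl in fluor.scatter.items():
        m = cluster_names == name
        n = int(m.sum())
        if n:
            fsc[m] = rng.normal(cl.fsc_mean, cl.fsc_sd, n)
            ssc[m] = rng.normal(cl.ssc_mean, cl.ssc_sd, n)
    return np.abs(fsc), np.abs(ssc)


def _lineage_labels(rng, n: int, p: dict, cfg: GeneratorConfig):
    """Cell-type labels for non-bead events: scatter cluster + T lineage."""
    u = rng.random(n)
    lymph = u < cfg.lymph_frac_of_events
    debris = (~lymph) & (u < cfg.lymph_frac_of_events + cfg.debris_frac_of_events)
    cluster = np.where(lymph, "lymphocyte", np.where(debris, "debris", "monocyte"))
    is_t = lymph & (rng.random(n) < p["t_frac"])
    is_gd = is_t & (rng.random(n) < p["gd_frac"])
    is_ab = is_t & ~is_gd
    v = rng.random(n)
    cd4 = is_ab & (v < p["cd4_of_ab"])
    cd8 = is_ab & ~cd4 & (v < p["cd4_of_ab"] + p["cd8_of_ab"])
    dp = is_ab & ~cd4 & ~cd8 & (v < p["cd4_of_ab"] + p["cd8_of_ab"] + p["dp_frac"])
    dn = is_ab & ~cd4 & ~cd8 & ~dp
    is_nk = lymph & ~is_t & (rng.random(n) < 0.3)
    return cluster, {"lymph": lymph, "t": is_t, "gd": is_gd, "ab": is_ab,
                     "cd4": cd4, "cd8": cd8, "dn": dn, "dp": dp, "nk": is_nk}


def _bernoulli_by_subset(rng, lab, p, key_map, default=0.0):
    """Per-event Bernoulli with subset-dependent probability."""
    n = len(lab["lymph"])
    prob = np.full(n, default)
    for mask_key, pr in key_map.items():
        prob[lab[mask_key]] = pr
    return rng.random(n) < prob


def _surface_events(rng, donor: DonorRecord, cfg: GeneratorConfig,
                    sample_id: str) -> EventTable:
    p = donor.planted
    fl = cfg.fluor_model
    n = cfg.events_per_sample
    cluster, lab = _lineage_labels(rng, n, p, cfg)

    # CD57 positivity by subset
    cd57 = _bernoulli_by_subset(rng, lab, p, {
        "cd8": p["cd57_in_cd8"], "cd4": p["cd57_in_cd4"], "gd": p["cd57_in_gd"],
        "dn": p["cd57_in_dndp"], "dp": p["cd57_in_dndp"]})
    cd57 |= lab["nk"] & (rng.random(n) < p["nk_cd57"])
    cd57 &= lab["lymph"]

    bg = p["cd57neg_background"]

    def marker_state(marker: str) -> np.ndarray:
        pos = np.zeros(n, dtype=bool)
        for sub in ("cd8", "cd4", "gd"):
            m57 = lab[sub] & cd57
            pos[m57] = rng.random(int(m57.sum())) < p[f"markers_{sub}cd57"][f"pct_{marker}"]
            mneg = lab[sub] & ~cd57
            bg_key = f"klrg1_{sub}" if marker == "klrg1" else marker
            pos[mneg] = rng.random(int(mneg.sum())) < bg.get(bg_key, bg.get(marker, 0.02))
        return pos

    cd94 = marker_state("cd94")
    cd56 = marker_state("cd56")
    cd56 |= lab["nk"] & (rng.random(n) < p["nk_cd56"])
    klrg1 = marker_state("klrg1")
    cd5dim = marker_state("cd5dim")
    cd5neg = lab["t"] & ~cd5dim & (rng.random(n) < 0.01)
    # CD5 state: 0 = negative (non-T and rare T), 1 = dim, 2 = bright
    cd5_state = np.zeros(n, dtype=int)
    cd5_state[lab["t"]] = 2
    cd5_state[cd5dim & lab["t"]] = 1
    cd5_state[cd5neg] = 0

    n_beads = max(1, int(rng.poisson(
        lab["lymph"].sum() * cfg.beads_per_uL / p["lymph_per_uL"])))
    total = n + n_beads
    is_bead = np.zeros(total, dtype=bool)
    is_bead[n:] = True

    cluster_all = np.concatenate([cluster, np.full(n_beads, "bead")])
    fsc, ssc = _scatter(rng, cluster_all, fl)

    def channel(name: str, states_cells: np.ndarray) -> np.ndarray:
        vals = np.empty(total)
        vals[:n] = _fluor(rng, name, states_cells, fl)
        vals[n:] = np.exp(np.log(fl.bead_fluor_median)
                          + fl.bead_fluor_sigma * rng.standard_normal(n_beads))
        return vals

    cols = {
        "FSC-A": fsc, "SSC-A": ssc,
        "CD3": channel("CD3", lab["t"].astype(int)),
        "CD4": channel("CD4", (lab["cd4"] | lab["dp"]).astype(int)),
        "CD5": channel("CD5", cd5_state),
        "CD8": channel("CD8", (lab["cd8"] | lab["dp"]).astype(int)),
        "CD56": channel("CD56", cd56.astype(int)),
        "CD57": channel("CD57", cd57.astype(int)),
        "CD94": channel("CD94", cd94.astype(int)),
        "TCRab": channel("TCRab", lab["ab"].astype(int)),
        "KLRG1": channel("KLRG1", klrg1.astype(int)),
    }
    data = pd.DataFrame({k: v.astype("float32") for k, v in cols.items()})

    def pad(x):
        return np.concatenate([x, np.zeros(n_beads, dtype=bool)])

    truth = pd.DataFrame({
        "celltype": cluster_all,
        "is_t": pad(lab["t"]), "is_gd_true": pad(lab["gd"]),
        "is_ab": pad(lab["ab"]), "cd4": pad(lab["cd4"]), "cd8": pad(lab["cd8"]),
        "dn": pad(lab["dn"]), "dp": pad(lab["dp"]),
        "cd57": pad(cd57), "cd94": pad(cd94), "cd56": pad(cd56),
        "klrg1": pad(klrg1), "cd5dim": pad(cd5dim & lab["t"]),
    })
    return EventTable(sample_id, "surface", data, is_bead=is_bead, truth=truth)


def _intracellular_events(rng, donor: DonorRecord, cfg: GeneratorConfig,
                          sample_id: str) -> EventTable:
    p = donor.planted
    fl = cfg.fluor_model
    n = cfg.events_per_sample
    cluster, lab = _lineage_labels(rng, n, p, cfg)
    ra = np.zeros(n, dtype=bool)
    for sub in ("cd8", "cd4"):
        m = lab[sub]
        ra[m] = rng.random(int(m.sum())) < p["cd45ra_frac"][sub]
    ifng = np.zeros(n, dtype=bool)
    perf = np.zeros(n, dtype=bool)
    for sub in ("cd8", "cd4"):
        for stratum, mask in (("ra_pos", lab[sub] & ra), ("ra_neg", lab[sub] & ~ra)):
            k = int(mask.sum())
            ifng[mask] = rng.random(k) < p[f"ifng_{sub}_{stratum}"]
            perf[mask] = rng.random(k) < p[f"perforin_{sub}_{stratum}"]

    fsc, ssc = _scatter(rng, cluster, fl)
    data = pd.DataFrame({
        "FSC-A": fsc, "SSC-A": ssc,
        "CD3": _fluor(rng, "CD3", lab["t"].astype(int), fl),
        "CD4": _fluor(rng, "CD4", (lab["cd4"] | lab["dp"]).astype(int), fl),
        "CD8": _fluor(rng, "CD8", (lab["cd8"] | lab["dp"]).astype(int), fl),
        "CD45RA": _fluor(rng, "CD45RA", ra.astype(int), fl),
        "CD56": _fluor(rng, "CD56", (lab["nk"]).astype(int), fl),
        "IFNg": _fluor(rng, "IFNg", ifng.astype(int), fl),
        "Perforin": _fluor(rng, "Perforin", perf.astype(int), fl),
    }).astype("float32")
    truth = pd.DataFrame({"celltype": cluster, "is_t": lab["t"],
                          "cd4": lab["cd4"], "cd8": lab["cd8"],
                          "cd45ra": ra, "ifng": ifng, "perforin": perf})
    return EventTable(sample_id, "intracellular", data, truth=truth)


def _ki67_events(rng, donor: DonorRecord, cfg: GeneratorConfig,
                 sample_id: str) -> EventTable:
    p = donor.planted
    fl = cfg.fluor_model
    n = cfg.events_per_sample
    cluster, lab = _lineage_labels(rng, n, p, cfg)
    cd57 = _bernoulli_by_subset(rng, lab, p, {
        "cd8": p["cd57_in_cd8"], "cd4": p["cd57_in_cd4"], "gd": p["cd57_in_gd"]})
    cd57 &= lab["lymph"]
    bg = p["cd57neg_background"]
    klrg1 = np.zeros(n, dtype=bool)
    for sub in ("cd8", "cd4", "gd"):
        m57 = lab[sub] & cd57
        klrg1[m57] = rng.random(int(m57.sum())) < p[f"markers_{sub}cd57"]["pct_klrg1"]
        mneg = lab[sub] & ~cd57
        klrg1[mneg] = rng.random(int(mneg.sum())) < bg[f"klrg1_{sub}"]
    ki67 = np.zeros(n, dtype=bool)
    strata = {
        ("cd57neg", "klrg1neg"): lab["cd8"] & ~cd57 & ~klrg1,
        ("cd57neg", "klrg1pos"): lab["cd8"] & ~cd57 & klrg1,
        ("cd57pos", "klrg1neg"): lab["cd8"] & cd57 & ~klrg1,
        ("cd57pos", "klrg1pos"): lab["cd8"] & cd57 & klrg1,
    }
    for (c57, kl), mask in strata.items():
        ki67[mask] = rng.random(int(mask.sum())) < p["ki67_cd8"][f"{c57}_{kl}"]
    other_t = lab["t"] & ~lab["cd8"]
    ki67[other_t] = rng.random(int(other_t.sum())) < 0.02

    fsc, ssc = _scatter(rng, cluster, fl)
    data = pd.DataFrame({
        "FSC-A": fsc, "SSC-A": ssc,
        "CD3": _fluor(rng, "CD3", lab["t"].astype(int), fl),
        "CD4": _fluor(rng, "CD4", (lab["cd4"] | lab["dp"]).astype(int), fl),
        "CD8": _fluor(rng, "CD8", (lab["cd8"] | lab["dp"]).astype(int), fl),
        "CD57": _fluor(rng, "CD57", cd57.astype(int), fl),
        "KLRG1": _fluor(rng, "KLRG1", klrg1.astype(int), fl),
        "Ki67": _fluor(rng, "Ki67", ki67.astype(int), fl),
    }).astype("float32")
    truth = pd.DataFrame({"celltype": cluster, "is_t": lab["t"], "cd8": lab["cd8"],
                          "cd57": cd57, "klrg1": klrg1, "ki67": ki67})
    return EventTable(sample_id, "ki67", data, truth=truth)


_PANEL_BUILDERS = {"surface": _surface_events,
                   "intracellular": _intracellular_events,
                   "ki67": _ki67_events}


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

class SyntheticCohort:
    """A generated cohort; event tables are produced lazily per sample."""

    def __init__(self, config: GeneratorConfig, donors: list[DonorRecord],
                 genotypes: pd.DataFrame, elisa: pd.DataFrame,
                 reference_elisa: pd.DataFrame):
        self.config = config
        self.donors = donors
        self.genotypes = genotypes
        self.elisa = elisa
        self.reference_elisa = reference_elisa
        self._index = {d.donor_id: i for i, d in enumerate(donors)}

    def donor(self, donor_id: str) -> DonorRecord:
        return self.donors[self._index[donor_id]]

    def events(self, donor_id: str, visit: int, panel: str) -> EventTable:
        """Generate the event table for one (donor, visit, panel) sample."""
        if panel not in _PANEL_BUILDERS:
            raise ValueError(f"unknown panel {panel!r}")
        d = self.donor(donor_id)
        if not 0 <= visit < len(d.visit_dates):
            raise IndexError(f"donor {donor_id} has no visit {visit}")
        rng = np.random.default_rng(
            [self.config.seed, 7, self._index[donor_id], visit, _PANEL_CODE[panel]])
        sample_id = f"{donor_id}_v{visit}_{panel}"
        return _PANEL_BUILDERS[panel](rng, d, self.config, sample_id)

    def iter_samples(self, panels=("surface",), visits: str = "all"):
        for d in self.donors:
            n_visits = 1 if visits == "first" else len(d.visit_dates)
            for v in range(n_visits):
                for panel in panels:
                    if panel != "surface" and d.group_true == "HC":
                        continue
                    yield d, v, panel, self.events(d.donor_id, v, panel)

    def donor_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "donor_id": d.donor_id, "group": d.group_true, "age": d.age,
            "sex": d.sex, "onset_age": d.onset_age,
            "symptom_duration": d.symptom_duration, "mobility_aid": d.mobility_aid,
            "visit_dates": ";".join(v.isoformat() for v in d.visit_dates),
            "serostatus_true": d.serostatus_true,
        } for d in self.donors])

    def truth(self) -> dict:
        return {d.donor_id: {"group_true": d.group_true,
                             "serostatus_true": d.serostatus_true,
                             **{k: v for k, v in d.planted.items()
                                if not isinstance(v, dict)}}
                for d in self.donors}

    def write(self, outdir, event_format: str = "csv",
              panels=("surface",), visits: str = "all") -> None:
        """Write donors/genotypes/elisa CSVs, truth JSON and event files."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.donor_frame().to_csv(out / "donors.csv", index=False)
        self.genotypes.to_csv(out / "genotypes.csv", index=False)
        self.elisa.to_csv(out / "elisa.csv", index=False)
        self.reference_elisa.to_csv(out / "reference_elisa.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth(), fh, indent=1, sort_keys=True)
        evdir = out / "events"
        evdir.mkdir(exist_ok=True)
        for d, v, panel, table in self.iter_samples(panels, visits):
            write_events(table, evdir / f"{table.sample_id}.{event_format}",
                         format=event_format)


# ---------------------------------------------------------------------------
# genotypes and ELISA plates
# ---------------------------------------------------------------------------

def _generate_genotypes(rng, donors: list[DonorRecord],
                        cfg: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for d in donors:
        if d.group_true == "HC":
            continue  # patients only are HLA-typed
        for locus, spec in cfg.hla_model.items():
            freqs = np.asarray(spec["freq"][d.group_true], dtype=float)
            a1, a2 = rng.choice(spec["alleles"], size=2, p=freqs / freqs.sum())
            rows.append({"patient_id": d.donor_id, "locus": locus,
                         "allele1": a1, "allele2": a2, "group": d.group_true})
    return pd.DataFrame(rows)


def _generate_elisa(rng, donors: list[DonorRecord], cfg: GeneratorConfig):
    sm = cfg.serology_model
    iso_list = sm["isotypes"]

    def well_pair(rng, mean):
        return np.maximum(0.0, rng.normal(mean, sm["well_sd"], size=2))

    def fold_draw(positive: bool):
        spec = sm["pos_fold"] if positive else sm["neg_fold"]
        return float(np.exp(rng.normal(spec["log_median"], spec["sigma"])))

    rows = []

    def add_sample(sample_id, group, serostatus):
        for iso in iso_list:
            if iso == "panIgGMA":
                pos = serostatus
            else:
                pos = serostatus and (rng.random() < sm["secondary_pos_prob"][iso])
            fold = fold_draw(pos)
            target = sm["blank_od"] + fold * sm["pool_adjusted_od"]
            for rep, od in enumerate(well_pair(rng, target), start=1):
                rows.append({"sample_id": sample_id, "group": group,
                             "isotype": iso, "replicate": rep,
                             "od": round(float(od), 5), "well_role": "sample"})
            for role, mean in (("blank", sm["blank_od"]),
                               ("pool", sm["blank_od"] + sm["pool_adjusted_od"]),
                               ("positive_control",
                                sm["blank_od"] + 6.0 * sm["pool_adjusted_od"])):
                for rep, od in enumerate(well_pair(rng, mean), start=1):
                    rows.append({"sample_id": sample_id, "group": group,
                                 "isotype": iso, "replicate": rep,
                                 "od": round(float(od), 5), "well_role": role})

    for d in donors:
        if d.group_true == "HC":
            continue  # ELISA run on patients; healthy reference is separate
        add_sample(d.donor_id, d.group_true, d.serostatus_true)
    patient_plate = pd.DataFrame(rows)

    rows = []
    for i in range(sm["n_reference"]):
        add_sample(f"REF{i:03d}", "REF", rng.random() < 0.005)
    reference_plate = pd.DataFrame(rows)
    return patient_plate, reference_plate


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort from ``config`` (deterministic)."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    donors: list[DonorRecord] = []
    for group in GROUPS:
        for i in range(cfg.group_sizes.get(group, 0)):
            donors.append(_make_donor(rng, group, i, cfg))
    genotypes = _generate_genotypes(np.random.default_rng([cfg.seed, 2]), donors, cfg)
    elisa, reference = _generate_elisa(np.random.default_rng([cfg.seed, 3]), donors, cfg)
    return SyntheticCohort(cfg, donors, genotypes, elisa, reference)
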