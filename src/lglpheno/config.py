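"""Generator configuration and cohort calibration defaults.

The default :class:`GeneratorConfig` encodes the study conditions of the
IBM / T-LGL cohort this package models: 56 healthy controls (HC), 51
T-LGL_LOW and 34 T-LGL_HIGH patients; per-donor subset fractions drawn
logit-normally with group locations at the published medians; 50,000
non-bead events per surface-panel sample; two visits separated by
210-960 days; HLA allele pools and ELISA seropositivity rates matching
the published group frequencies.

Donor-level positive fractions are modelled logit-normal: location =
logit(published group median), scale calibrated so the distribution's
95th percentile equals the published group 95th percentile
(scale = (logit(p95) - logit(median)) / 1.6449) where one is printed,
otherwise a fixed realistic dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

GROUPS = ("HC", "LOW", "HIGH")

SURFACE_CHANNELS = (
    "FSC-A", "SSC-A", "CD3", "CD4", "CD5", "CD8",
    "CD56", "CD57", "CD94", "TCRab", "KLRG1",
)
INTRACELLULAR_CHANNELS = (
    "FSC-A", "SSC-A", "CD3", "CD4", "CD8", "CD45RA", "CD56", "IFNg", "Perforin",
)
KI67_CHANNELS = (
    "FSC-A", "SSC-A", "CD3", "CD4", "CD8", "CD57", "KLRG1", "Ki67",
)

PANEL_CHANNELS = {
    "surface": SURFACE_CHANNELS,
    "intracellular": INTRACELLULAR_CHANNELS,
    "ki67": KI67_CHANNELS,
}


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def p95_scale(median: float, p95: float) -> float:
    """Logit-normal scale such that the 95th percentile sits at ``p95``."""
    return (logit(p95) - logit(median)) / 1.6448536269514722


@dataclass
class FluorChannel:
    """Two-component (or three-state for CD5) log-normal intensity model.

    ``neg_median`` is the negative-population median in arbitrary linear
    units; positives sit ``separation``-fold higher (each CD5 state one
    step); ``sigma`` is the log-scale spread of each component.
    """

    neg_median: float = 100.0
    separation: float = 10.0
    sigma: float = 0.35
    n_states: int = 2  # 3 for CD5: neg / dim / bright

    def state_median(self, state: int) -> float:
        return self.neg_median * self.separation ** state

    def cutpoint(self, below_state: int = 0) -> float:
        """Geometric midpoint between consecutive component medians."""
        return math.sqrt(self.state_median(below_state) * self.state_median(below_state + 1))


@dataclass
class ScatterCluster:
    fsc_mean: float
    fsc_sd: float
    ssc_mean: float
    ssc_sd: float


@dataclass
class FluorModel:
    channels: dict[str, FluorChannel] = field(default_factory=lambda: {
        name: FluorChannel() for name in
        ("CD3", "CD4", "CD8", "CD56", "CD57", "CD94", "TCRab", "KLRG1",
         "CD45RA", "IFNg", "Perforin", "Ki67")
    } | {"CD5": FluorChannel(n_states=3)})
    scatter: dict[str, ScatterCluster] = field(default_factory=lambda: {
        "lymphocyte": ScatterCluster(100_000, 12_000, 30_000, 8_000),
        "debris": ScatterCluster(25_000, 8_000, 15_000, 6_000),
        "monocyte": ScatterCluster(190_000, 18_000, 90_000, 12_000),
        "bead": ScatterCluster(60_000, 4_000, 200_000, 5_000),
    })
    bead_fluor_median: float = 50_000.0
    bead_fluor_sigma: float = 0.10
    # scatter rectangle used as the default lymphocyte gate
    lymph_gate_fsc: tuple[float, float] = (50_000.0, 160_000.0)
    lymph_gate_ssc: tuple[float, float] = (2_000.0, 70_000.0)
    bead_gate_ssc: float = 150_000.0


# ---------------------------------------------------------------------------
# Donor-level marker profile: (logit location, logit scale) per group.
# Locations are logit(published group median) wherever a median is printed;
# the remaining values are package calibration choices respecting the
# published ordering (HIGH >> LOW ~= HC, KLRG1 most prevalent, CD56 least).
# ---------------------------------------------------------------------------

def _ln(median: float, sigma: float) -> dict[str, float]:
    return {"log_median": math.log(median), "sigma": sigma}


def default_marker_profile() -> dict[str, dict[str, Any]]:
    prof: dict[str, dict[str, Any]] = {}
    # %CD8+CD57+ of lymphocytes: medians 1.10 / 1.23 / 9.12, p95 3 / 2.4 / 14.8
    cd8cd57 = {
        "HC": (logit(0.0110), p95_scale(0.0110, 0.030)),
        "LOW": (logit(0.0123), p95_scale(0.0123, 0.024)),
        "HIGH": (logit(0.0912), p95_scale(0.0912, 0.148)),
    }
    ratio = {  # CD4:CD8 ratio, log-normal (median, log-sd)
        "HC": _ln(2.8, 0.60), "LOW": _ln(2.4, 0.50), "HIGH": _ln(0.8, 0.45),
    }
    lymph_conc = {  # lymphocytes per microliter of blood
        "HC": _ln(980.0, 0.45), "LOW": _ln(880.0, 0.45), "HIGH": _ln(1240.0, 0.45),
    }
    for g in GROUPS:
        loc, scale = cd8cd57[g]
        prof[g] = {
            "pct_cd8cd57_of_lymph": {"loc": loc, "scale": scale},
            "cd4_cd8_ratio": ratio[g],
            "lymph_per_uL": lymph_conc[g],
            "t_frac_of_lymph": {"loc": logit(0.58), "scale": 0.30},
            "gd_frac_of_t": {"loc": logit(0.05), "scale": 0.40},
            "dn_frac_of_ab": 0.03,
            "dp_frac_of_ab": 0.01,
            "cd57_in_dndp": 0.10,
            "nk_cd57": 0.20,
            "nk_cd56": 0.85,
            "cd45ra_frac": {"cd8": 0.50, "cd4": 0.45},
        }
    # CD57+ fraction of CD4+ and of gammadelta T cells
    for g, c4, gd in (("HC", 0.030, 0.15), ("LOW", 0.035, 0.17), ("HIGH", 0.080, 0.30)):
        prof[g]["cd57_in_cd4"] = {"loc": logit(c4), "scale": 0.40}
        prof[g]["cd57_in_gd"] = {"loc": logit(gd), "scale": 0.40}
    # marker-positive fractions within CD57+ cells of each subset
    within57 = {
        #                 cd5dim  cd94   cd56   klrg1
        ("HC", "cd8"):   (0.060, 0.120, 0.100, 0.45),
        ("LOW", "cd8"):  (0.070, 0.130, 0.100, 0.47),
        ("HIGH", "cd8"): (0.450, 0.350, 0.250, 0.80),
        # CD4+CD57+ KLRG1 set so %CD57+KLRG1+ of CD4 hits the published
        # medians 0.24 / 0.36 / 3.08 (= cd57_in_cd4 x klrg1)
        ("HC", "cd4"):   (0.040, 0.030, 0.050, 0.080),
        ("LOW", "cd4"):  (0.050, 0.030, 0.050, 0.103),
        ("HIGH", "cd4"): (0.150, 0.080, 0.120, 0.385),
        ("HC", "gd"):    (0.060, 0.200, 0.150, 0.40),
        ("LOW", "gd"):   (0.070, 0.200, 0.150, 0.42),
        ("HIGH", "gd"):  (0.300, 0.400, 0.300, 0.70),
    }
    scales = {"cd8": 0.50, "cd4": 0.40, "gd": 0.40}
    for (g, sub), (dim, cd94, cd56, klrg1) in within57.items():
        sc = scales[sub] if sub != "cd8" else 0.50
        klsc = 0.40
        prof[g][f"markers_{sub}cd57"] = {
            "pct_cd5dim": {"loc": logit(dim), "scale": sc},
            "pct_cd94": {"loc": logit(cd94), "scale": sc},
            "pct_cd56": {"loc": logit(cd56), "scale": sc},
            "pct_klrg1": {"loc": logit(klrg1), "scale": klsc},
        }
    # markers within CD57- cells (low, non-aberrant background)
    for g in GROUPS:
        kl8 = {"HC": 0.12, "LOW": 0.13, "HIGH": 0.25}[g]
        kl4 = {"HC": 0.03, "LOW": 0.04, "HIGH": 0.08}[g]
        prof[g]["cd57neg_background"] = {
            "klrg1_cd8": kl8, "klrg1_cd4": kl4, "klrg1_gd": 0.10,
            "cd5dim": 0.02, "cd94": 0.03, "cd56": 0.03,
        }
    # intracellular cytokine content (overall fraction of subset)
    intra = {
        # (ifng_cd8, perf_cd8, ifng_cd4, perf_cd4) published medians (%)
        "HC": (0.195, 0.178, 0.073, 0.02215),
        "LOW": (0.471, 0.283, 0.118, 0.021),
        "HIGH": (0.571, 0.546, 0.176, 0.069),
    }
    for g, (i8, p8, i4, p4) in intra.items():
        prof[g]["intracellular"] = {
            "ifng_cd8": {"loc": logit(i8), "scale": 0.40},
            "perforin_cd8": {"loc": logit(p8), "scale": 0.40},
            "ifng_cd4": {"loc": logit(i4), "scale": 0.40},
            "perforin_cd4": {"loc": logit(p4), "scale": 0.40},
            # log-odds shift between CD45RA+ and CD45RA- fractions:
            # perforin enriched in CD45RA+ (TEMRA), IFN-g in CD45RA-
            "ra_shift_perforin": 0.5,
            "ra_shift_ifng": -0.5,
        }
    # Ki67 within CD8 strata (CD57-/+ x KLRG1-/+): published HIGH medians
    # 4.05% (57-K-) and 2.18% (57+K+); less differentiated > more
    ki = {
        "HC": (0.028, 0.026, 0.024, 0.022),
        "LOW": (0.030, 0.027, 0.025, 0.023),
        "HIGH": (0.0405, 0.032, 0.025, 0.0218),
    }
    for g, (a, b, c, d) in ki.items():
        prof[g]["ki67_cd8"] = {
            "cd57neg_klrg1neg": {"loc": logit(a), "scale": 0.30},
            "cd57neg_klrg1pos": {"loc": logit(b), "scale": 0.30},
            "cd57pos_klrg1neg": {"loc": logit(c), "scale": 0.30},
            "cd57pos_klrg1pos": {"loc": logit(d), "scale": 0.30},
        }
    return prof


# ---------------------------------------------------------------------------
# HLA allele pools per locus. Group-conditional frequencies are the
# published class I/II allele frequencies (HIGH / LOW patient groups);
# HC genotypes reuse the LOW pool. Remaining probability mass per locus
# is assigned to a pattern-valid filler allele.
# ---------------------------------------------------------------------------

HLA_TABLE: dict[str, list[tuple[str, float, float]]] = {
    # locus: [(allele, freq_HIGH, freq_LOW)]  (fractions)
    "A": [
        ("A*02:01:01G", 0.3793, 0.2674),
        ("A*11:01:01G", 0.0690, 0.0465),
        ("A*03:01:01G", 0.1897, 0.1512),
        ("A*01:01:01G", 0.2241, 0.2558),
    ],
    "B": [
        ("B*07:02:01G", 0.0862, 0.1395),
        ("B*08:01:01G", 0.2241, 0.2558),
        ("B*51:01:01G", 0.1034, 0.0814),
        ("B*35:01:01G", 0.0862, 0.0698),
        ("B*15:01:01G", 0.0517, 0.0581),
        ("B*44:02:01G", 0.0690, 0.0814),
    ],
    "C": [
        ("C*14:02:01G", 0.1207, 0.0349),
        ("C*04:01:01G", 0.1207, 0.0581),
        ("C*07:02:01G", 0.0690, 0.1395),
        ("C*07:01:01G", 0.2414, 0.3023),
        ("C*05:01:01G", 0.0862, 0.1047),
        ("C*03:03:01G", 0.0690, 0.0698),
    ],
    "DPB1": [
        ("DPB1*04:02:01G", 0.1724, 0.0814),
        ("DPB1*03:01:01G", 0.0172, 0.1047),
        ("DPB1*01:01:01G", 0.1207, 0.0814),
        ("DPB1*02:01:02G", 0.1552, 0.1395),
        ("DPB1*04:01:01G", 0.3621, 0.3721),
    ],
    "DQA1": [
        ("DQA1*05:01:01G", 0.4828, 0.3837),
        ("DQA1*01:02:01G", 0.0517, 0.0930),
        ("DQA1*03:01:01G", 0.0517, 0.0698),
        ("DQA1*01:01:01G", 0.2069, 0.2209),
        ("DQA1*01:03:01G", 0.1724, 0.1628),
    ],
    "DQB1": [
        ("DQB1*03:01:01i", 0.1207, 0.0814),
        ("DQB1*05:01:01i", 0.2069, 0.2093),
        ("DQB1*06:03:01i", 0.1379, 0.1395),
        ("DQB1*02:01:01i", 0.3621, 0.3605),
    ],
    "DRB1": [
        ("DRB1*01:01:01i", 0.1897, 0.1512),
        ("DRB1*13:01:01i", 0.1379, 0.1279),
    ],
    "DRB3": [
        ("DRB3*02:02:01i", 0.2759, 0.1977),
        ("DRB3*01:01:02i", 0.3103, 0.3372),
    ],
}


def default_hla_model() -> dict[str, dict[str, list]]:
    model: dict[str, dict[str, list]] = {}
    for locus, rows in HLA_TABLE.items():
        alleles = [a for a, _, _ in rows]
        hi = [f for _, f, _ in rows]
        lo = [f for _, _, f in rows]
        filler = f"{locus}*98:01:01{'i' if locus.startswith('DR') else 'G'}"
        alleles.append(filler)
        hi.append(max(0.0, 1.0 - sum(hi)))
        lo.append(max(0.0, 1.0 - sum(lo)))
        model[locus] = {
            "alleles": alleles,
            "freq": {"HIGH": hi, "LOW": lo, "HC": list(lo)},
        }
    return model


def default_serology_model() -> dict[str, Any]:
    return {
        "isotypes": ["panIgGMA", "IgG", "IgM", "IgA"],
        "seropos_prob": {"HC": 0.01, "LOW": 0.314, "HIGH": 0.382},
        # fold-change distributions relative to the healthy pool
        "neg_fold": _ln(0.9, 0.35),
        "pos_fold": _ln(4.0, 0.50),
        # probability a seropositive donor is positive on a secondary isotype
        "secondary_pos_prob": {"IgG": 0.8, "IgM": 0.3, "IgA": 0.3},
        "blank_od": 0.045,
        "pool_adjusted_od": 0.10,
        "well_sd": 0.006,
        "n_reference": 190,
    }


def default_demographics() -> dict[str, Any]:
    return {
        "age": {"HC": {"mean": 67.5, "sd": 9.0}, "LOW": {"mean": 72.0, "sd": 10.0},
                "HIGH": {"mean": 73.0, "sd": 10.0}, "min": 40, "max": 96},
        "male_prob": {"HC": 0.482, "LOW": 0.553, "HIGH": 0.553},
        # symptom duration (years): published medians 8 (LOW) and 11 (HIGH)
        "duration": {"LOW": _ln(8.0, 0.5), "HIGH": _ln(11.0, 0.5)},
        "mobility_aid_prob": {"HC": 0.0, "LOW": 0.38, "HIGH": 0.75},
        "aid_types": ["stick", "frame", "wheelchair"],
    }


@dataclass
class GeneratorConfig:
    """Complete specification of a synthetic cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 56, "LOW": 51, "HIGH": 34})
    events_per_sample: int = 50_000          # non-bead events
    beads_per_uL: float = 50.0
    lymph_frac_of_events: float = 0.80       # remainder debris + monocytes
    debris_frac_of_events: float = 0.10
    marker_profile: dict = field(default_factory=default_marker_profile)
    fluor_model: FluorModel = field(default_factory=FluorModel)
    n_visits: int = 2
    visit_gap_days: tuple[int, int] = (210, 960)
    hla_model: dict = field(default_factory=default_hla_model)
    serology_model: dict = field(default_factory=default_serology_model)
    demographics: dict = field(default_factory=default_demographics)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group_sizes[{g}] must be >= 1, got {n}")
        if self.events_per_sample < 1:
            raise ValueError("events_per_sample must be >= 1")
        if self.beads_per_uL <= 0:
            raise ValueError("beads_per_uL must be > 0")
        if not (0 < self.lymph_frac_of_events <= 1):
            raise ValueError("lymph_frac_of_events must be in (0, 1]")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        for g, prof in self.marker_profile.items():
            for key, val in prof.items():
                if isinstance(val, dict) and "scale" in val and val["scale"] < 0:
                    raise ValueError(
                        f"marker_profile[{g}][{key}]: scale must be >= 0")
                if isinstance(val, dict) and "sigma" in val and val["sigma"] < 0:
                    raise ValueError(
                        f"marker_profile[{g}][{key}]: sigma must be >= 0")
        for locus, spec in self.hla_model.items():
            for g, freqs in spec["freq"].items():
                if any(f < 0 for f in freqs):
                    raise ValueError(f"hla_model[{locus}] freq[{g}]: negative probability")
                if abs(sum(freqs) - 1.0) > 1e-6:
                    raise ValueError(
                        f"hla_model[{locus}] freq[{g}]: probabilities must sum to 1")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "fluor_model" in d and isinstance(d["fluor_model"], dict):
            fm = d["fluor_model"]
            channels = {k: FluorChannel(**v) for k, v in fm.get("channels", {}).items()}
            scatter = {k: ScatterCluster(**v) for k, v in fm.get("scatter", {}).items()}
            kwargs = {k: v for k, v in fm.items() if k not in ("channels", "scatter")}
            for key in ("lymph_gate_fsc", "lymph_gate_ssc"):
                if key in kwargs:
                    kwargs[key] = tuple(kwargs[key])
            d["fluor_model"] = FluorModel(channels=channels, scatter=scatter, **kwargs)
        if "visit_gap_days" in d:
            d["visit_gap_days"] = tuple(d["visit_gap_days"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
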