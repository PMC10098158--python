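"""Event-level gating and per-donor feature extraction.

Turns event-level cytometry samples into per-donor immunophenotype
features by hierarchical threshold gating: a scatter (FSC/SSC)
lymphocyte rectangle, CD3/TCRab lineage gates, CD4/CD8 subsetting,
CD57 and NK-receptor marker gates, and bead-based absolute counting.
Gammadelta T cells are identified as CD3+TCRab- events (the surrogate
gate used when no anti-TCRgd antibody is in the panel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .config import FluorModel, PANEL_CHANNELS

__all__ = [
    "EventTable", "GateSpec", "fit_cutpoint", "apply_gates",
    "absolute_count", "compute_features", "default_gates",
    "extract_cohort_features", "FEATURE_SUBSETS",
]

FEATURE_SUBSETS = ("cd8", "cd4", "gd")


@dataclass
class EventTable:
    """Per-event intensities for one sample and panel.

    ``data`` holds one named column per channel (linear arbitrary
    fluorescence units); ``is_bead`` flags count-bead events (set by the
    bead gate, or carried as ground truth by synthetic data); ``truth``
    optionally carries hidden per-event ground-truth labels, retained
    for testing only and never consulted by the gating code.
    """

    sample_id: str
    panel: str
    data: pd.DataFrame
    is_bead: np.ndarray = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.panel not in PANEL_CHANNELS:
            raise ValueError(f"unknown panel {self.panel!r}")
        expected = set(PANEL_CHANNELS[self.panel])
        got = set(self.data.columns)
        if not expected <= got:
            raise ValueError(
                f"panel {self.panel!r} missing channels: {sorted(expected - got)}")
        if self.is_bead is None:
            self.is_bead = np.zeros(len(self.data), dtype=bool)
        self.is_bead = np.asarray(self.is_bead, dtype=bool)
        if len(self.is_bead) != len(self.data):
            raise ValueError("is_bead length does not match event count")
        vals = self.data.to_numpy()
        if len(vals) and not np.isfinite(vals).all():
            raise ValueError("event intensities must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_beads(self) -> int:
        return int(self.is_bead.sum())

    def cells(self) -> pd.DataFrame:
        """Non-bead events."""
        return self.data.loc[~self.is_bead]


@dataclass
class GateSpec:
    """One node of a hierarchical gating tree.

    ``side`` is ``above``/``below`` (threshold on ``cutpoint``) or
    ``interval`` (``cutpoint`` is a (lo, hi) pair). ``parent`` names the
    enclosing gate, or None for the root population.
    """

    name: str
    channel: str
    side: str
    cutpoint: float | tuple[float, float]
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.side not in ("above", "below", "interval"):
            raise ValueError(f"gate {self.name}: unknown side {self.side!r}")
        cp = np.asarray(self.cutpoint, dtype=float)
        if not np.isfinite(cp).all():
            raise ValueError(f"gate {self.name}: cutpoint must be finite")
        if self.side == "interval" and cp.shape != (2,):
            raise ValueError(f"gate {self.name}: interval needs (lo, hi)")

    def predicate(self, values: np.ndarray) -> np.ndarray:
        if self.side == "above":
            return values > float(self.cutpoint)
        if self.side == "below":
            return values <= float(self.cutpoint)
        lo, hi = self.cutpoint
        return (values >= lo) & (values <= hi)


def gates_to_yaml(gates: Iterable[GateSpec], path) -> None:
    rows = [{"name": g.name, "channel": g.channel, "side": g.side,
             "cutpoint": (list(g.cutpoint) if g.side == "interval"
                          else float(g.cutpoint)),
             "parent": g.parent} for g in gates]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


def gates_from_yaml(path) -> list[GateSpec]:
    with open(path) as fh:
        rows = yaml.safe_load(fh)
    return [GateSpec(r["name"], r["channel"], r["side"],
                     tuple(r["cutpoint"]) if r["side"] == "interval" else r["cutpoint"],
                     r.get("parent")) for r in rows]


# ---------------------------------------------------------------------------
# cutpoint fitting
# ---------------------------------------------------------------------------

def fit_cutpoint(intensities, method: str = "valley", params: Mapping | None = None):
    """Place a 1-D gate threshold.

    ``fixed`` returns ``params['value']``; ``quantile`` the stated
    quantile; ``valley`` the minimum-density point between the two
    largest modes of a Gaussian KDE, falling back to
    ``params['default']`` with a warning when the density is unimodal.
    """
    params = dict(params or {})
    x = np.asarray(intensities, dtype=float)
    if method == "fixed":
        return float(params["value"])
    if method == "quantile":
        return float(np.quantile(x, params.get("q", 0.5)))
    if method != "valley":
        raise ValueError(f"unknown cutpoint method {method!r}")
    if len(x) < 100:
        raise ValueError("valley method needs >= 100 events")
    from scipy.stats import gaussian_kde

    if np.ptp(x) == 0:
        warnings.warn("constant input is unimodal; using configured default")
        return float(params.get("default", x[0]))
    grid = np.linspace(x.min(), x.max(), int(params.get("gridsize", 512)))
    dens = gaussian_kde(x)(grid)
    # interior local maxima of the density curve
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    modes = np.flatnonzero(interior) + 1
    if len(modes) < 2:
        warnings.warn("unimodal intensity distribution; using configured default")
        return float(params.get("default", np.median(x)))
    top2 = modes[np.argsort(dens[modes])[-2:]]
    lo, hi = np.sort(top2)
    return float(grid[lo + np.argmin(dens[lo:hi + 1])])


# ---------------------------------------------------------------------------
# gate application
# ---------------------------------------------------------------------------

def apply_gates(events: EventTable, gates: list[GateSpec]) -> pd.DataFrame:
    """Evaluate a gating tree; returns per-event boolean membership.

    An event belongs to a gate iff it belongs to the gate's parent and
    satisfies the gate's predicate; the root population is all non-bead
    events. Child membership is therefore always a subset of the parent's.
    """
    names = [g.name for g in gates]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gate names")
    for g in gates:
        if g.channel not in events.data.columns:
            raise KeyError(
                f"gate {g.name!r} references missing channel {g.channel!r}")
    root = ~events.is_bead
    member: dict[str, np.ndarray] = {}
    pending = list(gates)
    progressed = True
    while pending and progressed:
        progressed = False
        for g in list(pending):
            if g.parent is None:
                parent_mask = root
            elif g.parent in member:
                parent_mask = member[g.parent]
            else:
                continue
            vals = events.data[g.channel].to_numpy(dtype=float)
            member[g.name] = parent_mask & g.predicate(vals)
            pending.remove(g)
            progressed = True
    if pending:
        raise ValueError(
            f"unresolvable gate parents (missing or cyclic): "
            f"{[g.name for g in pending]}")
    return pd.DataFrame(member, index=events.data.index)


def absolute_count(gated_events: int, bead_events: int,
                   beads_per_uL: float, volume_uL: float | None = None) -> float:
    """Bead-normalised absolute count, in cells per liter.

    cells/uL = gated_events / bead_events x beads_per_uL; the bead ratio
    already normalises acquisition volume, so ``volume_uL`` is accepted
    for interface completeness but does not enter the formula.
    """
    if bead_events <= 0:
        raise ValueError("bead_events must be > 0: bead normalization impossible")
    cells_per_uL = gated_events / bead_events * beads_per_uL
    return cells_per_uL * 1e6


# ---------------------------------------------------------------------------
# default gate trees (cutpoints known from the intensity model midpoints)
# ---------------------------------------------------------------------------

def default_gates(panel: str, fluor: FluorModel | None = None) -> list[GateSpec]:
    fluor = fluor or FluorModel()

    def cut(ch: str, state: int = 0) -> float:
        return fluor.channels[ch].cutpoint(state)

    g: list[GateSpec] = [
        GateSpec("scatter_fsc", "FSC-A", "interval", tuple(fluor.lymph_gate_fsc)),
        GateSpec("lymph", "SSC-A", "interval", tuple(fluor.lymph_gate_ssc),
                 parent="scatter_fsc"),
        GateSpec("t", "CD3", "above", cut("CD3"), parent="lymph"),
    ]
    if panel == "surface":
        g += [
            GateSpec("ab", "TCRab", "above", cut("TCRab"), parent="t"),
            GateSpec("gd", "TCRab", "below", cut("TCRab"), parent="t"),
            GateSpec("ab_cd4pos", "CD4", "above", cut("CD4"), parent="ab"),
            GateSpec("ab_cd8pos", "CD8", "above", cut("CD8"), parent="ab"),
            GateSpec("cd4", "CD8", "below", cut("CD8"), parent="ab_cd4pos"),
            GateSpec("cd8", "CD4", "below", cut("CD4"), parent="ab_cd8pos"),
            GateSpec("gd_cd57", "CD57", "above", cut("CD57"), parent="gd"),
        ]
        for sub in ("cd4", "cd8"):
            g.append(GateSpec(f"{sub}_cd57", "CD57", "above", cut("CD57"), parent=sub))
        for sub in ("cd4", "cd8", "gd"):
            parent = f"{sub}_cd57"
            g += [
                GateSpec(f"{sub}_cd57_cd5dim", "CD5", "interval",
                         (cut("CD5", 0), cut("CD5", 1)), parent=parent),
                GateSpec(f"{sub}_cd57_cd94", "CD94", "above", cut("CD94"), parent=parent),
                GateSpec(f"{sub}_cd57_cd56", "CD56", "above", cut("CD56"), parent=parent),
                GateSpec(f"{sub}_cd57_klrg1", "KLRG1", "above", cut("KLRG1"), parent=parent),
            ]
    elif panel == "intracellular":
        g += [
            GateSpec("cd4pos", "CD4", "above", cut("CD4"), parent="t"),
            GateSpec("cd8pos", "CD8", "above", cut("CD8"), parent="t"),
            GateSpec("cd4", "CD8", "below", cut("CD8"), parent="cd4pos"),
            GateSpec("cd8", "CD4", "below", cut("CD4"), parent="cd8pos"),
        ]
        for sub in ("cd4", "cd8"):
            g += [
                GateSpec(f"{sub}_ra_pos", "CD45RA", "above", cut("CD45RA"), parent=sub),
                GateSpec(f"{sub}_ra_neg", "CD45RA", "below", cut("CD45RA"), parent=sub),
            ]
            for strat in (sub, f"{sub}_ra_pos", f"{sub}_ra_neg"):
                g += [
                    GateSpec(f"{strat}_ifng", "IFNg", "above", cut("IFNg"), parent=strat),
                    GateSpec(f"{strat}_perforin", "Perforin", "above",
                             cut("Perforin"), parent=strat),
                    GateSpec(f"{strat}_dual", "Perforin", "above", cut("Perforin"),
                             parent=f"{strat}_ifng"),
                ]
    elif panel == "ki67":
        g += [
            GateSpec("cd8pos", "CD8", "above", cut("CD8"), parent="t"),
            GateSpec("cd8", "CD4", "below", cut("CD4"), parent="cd8pos"),
        ]
        # CD57-/+ x KLRG1-/+ strata of CD8+ T cells
        for c57, cname in (("cd57neg", "below"), ("cd57pos", "above")):
            g.append(GateSpec(f"cd8_{c57}", "CD57", cname, cut("CD57"), parent="cd8"))
            for kl, kname in (("klrg1neg", "below"), ("klrg1pos", "above")):
                strat = f"cd8_{c57}_{kl}"
                g.append(GateSpec(strat, "KLRG1", kname, cut("KLRG1"),
                                  parent=f"cd8_{c57}"))
                g.append(GateSpec(f"{strat}_ki67", "Ki67", "above", cut("Ki67"),
                                  parent=strat))
    else:
        raise ValueError(f"unknown panel {panel!r}")
    return g


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _pct(num: int, den: int) -> float:
    """Percentage with zero-denominator flagged as missing (NaN), not 0."""
    return 100.0 * num / den if den > 0 else float("nan")


def compute_features(surface: EventTable,
                     intracellular: EventTable | None = None,
                     ki67: EventTable | None = None,
                     gates: Mapping[str, list[GateSpec]] | None = None,
                     beads_per_uL: float = 50.0,
                     fluor: FluorModel | None = None) -> dict[str, float]:
    """Per donor-visit immunophenotype features from gated events.

    Counts are bead-normalised to cells per liter of blood; percentages
    use the stated parent population as denominator and are flagged NaN
    (never 0) when the denominator is empty.
    """
    gates = gates or {}
    m = apply_gates(surface, gates.get("surface") or default_gates("surface", fluor))
    counts = m.sum(axis=0)
    feats: dict[str, float] = {}

    n_beads = surface.n_beads
    for name, gate in (("lymph_count_per_L", "lymph"), ("t_count_per_L", "t"),
                       ("cd4_count_per_L", "cd4"), ("cd8_count_per_L", "cd8")):
        feats[name] = (absolute_count(int(counts[gate]), n_beads, beads_per_uL)
                       if n_beads > 0 else float("nan"))
    feats["cd8cd57_count_per_L"] = (
        absolute_count(int(counts["cd8_cd57"]), n_beads, beads_per_uL)
        if n_beads > 0 else float("nan"))
    feats["cd4_cd8_ratio"] = (counts["cd4"] / counts["cd8"]
                              if counts["cd8"] > 0 else float("nan"))
    feats["pct_cd8cd57_of_lymph"] = _pct(counts["cd8_cd57"], counts["lymph"])
    # lineage composition within CD3+TCRab+ (CD4 / CD8 / DN / DP)
    ab = m["ab"].to_numpy()
    c4, c8 = m["ab_cd4pos"].to_numpy(), m["ab_cd8pos"].to_numpy()
    n_ab = int(ab.sum())
    feats["pct_cd4_of_ab"] = _pct(int((ab & c4 & ~c8).sum()), n_ab)
    feats["pct_cd8_of_ab"] = _pct(int((ab & c8 & ~c4).sum()), n_ab)
    feats["pct_dn_of_ab"] = _pct(int((ab & ~c4 & ~c8).sum()), n_ab)
    feats["pct_dp_of_ab"] = _pct(int((ab & c4 & c8).sum()), n_ab)
    feats["pct_gd_of_t"] = _pct(counts["gd"], counts["t"])
    for sub in FEATURE_SUBSETS:
        n57 = int(counts[f"{sub}_cd57"])
        feats[f"pct_cd57_of_{sub}"] = _pct(n57, counts[sub])
        for marker in ("cd5dim", "cd94", "cd56", "klrg1"):
            feats[f"pct_{marker}_{sub}cd57"] = _pct(
                int(counts[f"{sub}_cd57_{marker}"]), n57)
        feats[f"pct_cd57klrg1_of_{sub}"] = _pct(
            int(counts[f"{sub}_cd57_klrg1"]), counts[sub])

    if intracellular is not None:
        mi = apply_gates(intracellular,
                         gates.get("intracellular") or default_gates("intracellular", fluor))
        ci = mi.sum(axis=0)
        for sub in ("cd4", "cd8"):
            for strat, label in ((sub, ""), (f"{sub}_ra_pos", "_ra_pos"),
                                 (f"{sub}_ra_neg", "_ra_neg")):
                den = int(ci[strat])
                feats[f"pct_ifng_{sub}{label}"] = _pct(int(ci[f"{strat}_ifng"]), den)
                feats[f"pct_perforin_{sub}{label}"] = _pct(
                    int(ci[f"{strat}_perforin"]), den)
                feats[f"pct_dual_{sub}{label}"] = _pct(int(ci[f"{strat}_dual"]), den)

    if ki67 is not None:
        mk = apply_gates(ki67, gates.get("ki67") or default_gates("ki67", fluor))
        ck = mk.sum(axis=0)
        for c57 in ("cd57neg", "cd57pos"):
            for kl in ("klrg1neg", "klrg1pos"):
                strat = f"cd8_{c57}_{kl}"
                feats[f"pct_ki67_{c57}_{kl}"] = _pct(
                    int(ck[f"{strat}_ki67"]), int(ck[strat]))
    return feats


def extract_cohort_features(cohort, panels=("surface", "intracellular", "ki67"),
                            visits: str | None = "all",
                            beads_per_uL: float | None = None) -> pd.DataFrame:
    """Run gating + feature extraction over a synthetic cohort.

    Returns one row per donor-visit with donor metadata columns
    (``donor_id``, ``group``, ``visit``, ``visit_date``) followed by the
    feature columns. ``visits='first'`` restricts to each donor's first
    visit. Event tables are generated lazily and discarded sample by
    sample, so the full default cohort fits in ordinary memory.
    """
    beads = beads_per_uL if beads_per_uL is not None else cohort.config.beads_per_uL
    fluor = cohort.config.fluor_model
    rows = []
    for donor in cohort.donors:
        n_visits = 1 if visits == "first" else len(donor.visit_dates)
        for v in range(n_visits):
            surface = cohort.events(donor.donor_id, v, "surface")
            intra = ki = None
            if donor.group_true != "HC":
                if "intracellular" in panels:
                    intra = cohort.events(donor.donor_id, v, "intracellular")
                if "ki67" in panels:
                    ki = cohort.events(donor.donor_id, v, "ki67")
            feats = compute_features(surface, intra, ki,
                                     beads_per_uL=beads, fluor=fluor)
            rows.append({"donor_id": donor.donor_id, "group": donor.group_true,
                         "visit": v, "visit_date": donor.visit_dates[v], **feats})
    return pd.DataFrame(rows)
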