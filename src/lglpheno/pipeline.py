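"""End-to-end orchestration: simulate -> gate -> classify -> serology ->
hla -> stats, with a reproducible report bundle.

Every run is a pure function of (config, seed): output files carry the
config hash and seed in a manifest, and a rerun with the same config is
byte-identical. Stage outputs feed the next stage through the same CSV
contracts the CLI exposes, so stages can also be run separately.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, hla_assoc, serology
from .config import GeneratorConfig
from .cyto_gating import extract_cohort_features
from .lgl_classify import classify_cohort, classification_summary, derive_thresholds
from .synth_cohort import generate_cohort

log = logging.getLogger("lglpheno")

STAGES = ("simulate", "gate", "classify", "serology", "hla", "stats", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    generator: GeneratorConfig | None = None
    stages: tuple[str, ...] = STAGES
    threshold_provenance: str = "fixed_from_paper"
    visits: str = "all"
    panels: tuple[str, ...] = ("surface", "intracellular", "ki67")
    write_event_files: bool = False
    event_format: str = "csv"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        else:
            self.generator.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig.from_dict(gen)
        for key in ("stages", "panels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump({"seed": self.seed,
                               "generator": self.generator.to_dict(),
                               "threshold_provenance": self.threshold_provenance,
                               "visits": self.visits,
                               "panels": list(self.panels)},
                              sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_dump(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        return str(o)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the report bundle manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "stages_run": [], "outputs": {}, "skipped": []}
    state: dict = {}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path.relative_to(out))

    stage_fns = {
        "simulate": _stage_simulate, "gate": _stage_gate,
        "classify": _stage_classify, "serology": _stage_serology,
        "hla": _stage_hla, "stats": _stage_stats, "report": _stage_report,
    }
    for stage in STAGES:
        if stage not in config.stages:
            manifest["skipped"].append(stage)
            continue
        try:
            stage_fns[stage](config, out, state, record)
            manifest["stages_run"].append(stage)
        except Exception as exc:  # abort, naming the failing stage
            manifest["failed_stage"] = stage
            _json_dump(manifest, out / "manifest.json")
            raise PipelineError(stage, exc) from exc
    _json_dump(manifest, out / "manifest.json")
    state["manifest"] = manifest
    return state


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, state: dict, record) -> None:
    cohort = generate_cohort(cfg.generator)
    state["cohort"] = cohort
    log.info("simulate: %d donors (%s)", len(cohort.donors),
             ", ".join(f"{g}={n}" for g, n in cfg.generator.group_sizes.items()))
    cohort.donor_frame().to_csv(out / "donors.csv", index=False)
    cohort.genotypes.to_csv(out / "genotypes.csv", index=False)
    cohort.elisa.to_csv(out / "elisa.csv", index=False)
    cohort.reference_elisa.to_csv(out / "reference_elisa.csv", index=False)
    _json_dump(cohort.truth(), out / "truth.json")
    for name in ("donors", "genotypes", "elisa", "reference_elisa"):
        record(name, out / f"{name}.csv")
    record("truth", out / "truth.json")
    if cfg.write_event_files:
        cohort.write(out, event_format=cfg.event_format,
                     panels=cfg.panels, visits=cfg.visits)


def _stage_gate(cfg: RunConfig, out: Path, state: dict, record) -> None:
    cohort = state["cohort"]
    features = extract_cohort_features(cohort, panels=cfg.panels,
                                       visits=cfg.visits)
    state["features"] = features
    features.to_csv(out / "features.csv", index=False)
    record("features", out / "features.csv")
    log.info("gate: %d donor-visit feature rows", len(features))


def _stage_classify(cfg: RunConfig, out: Path, state: dict, record) -> None:
    features = state["features"]
    first = features.sort_values("visit").groupby("donor_id").head(1)
    hc = first[first["group"] == "HC"]
    thresholds = derive_thresholds(hc, provenance=cfg.threshold_provenance)
    patients = features[features["group"] != "HC"]
    classification = classify_cohort(patients, thresholds)
    state["thresholds"] = thresholds
    state["classification"] = classification
    thresholds.to_json(out / "thresholds.json")
    classification.to_csv(out / "classification.csv", index=False)
    record("thresholds", out / "thresholds.json")
    record("classification", out / "classification.csv")
    summ = classification_summary(classification)
    log.info("classify: %d/%d HIGH", summ["n_high"], summ["n"])


def _stage_serology(cfg: RunConfig, out: Path, state: dict, record) -> None:
    cohort = state["cohort"]
    folds = serology.process_plate(cohort.elisa)
    ref_folds = serology.process_plate(cohort.reference_elisa)
    cutoffs = serology.derive_cutoffs(
        {iso: grp["fold_change"].to_numpy()
         for iso, grp in ref_folds.groupby("isotype")})
    calls = serology.call_samples(folds, cutoffs)
    labels = state["classification"].set_index("donor_id")["label"]
    summary = serology.call_cohort(calls, labels)
    summary["cutoffs"] = cutoffs
    state["serology"] = summary
    merged = calls.merge(folds.pivot(index="sample_id", columns="isotype",
                                     values="fold_change"), on="sample_id")
    merged.to_csv(out / "serology_calls.csv", index=False)
    _json_dump(summary, out / "serology_summary.json")
    record("serology_calls", out / "serology_calls.csv")
    record("serology_summary", out / "serology_summary.json")
    log.info("serology: prevalence %.1f%%", summary["prevalence_pct"])


def _stage_hla(cfg: RunConfig, out: Path, state: dict, record) -> None:
    cohort = state["cohort"]
    labels = state["classification"].set_index("donor_id")["label"]
    scan = hla_assoc.association_scan(cohort.genotypes, labels)
    state["hla_scan"] = scan
    scan.to_csv(out / "hla_scan.csv", index=False)
    hla_assoc.scan_report(scan).to_csv(out / "hla_report.csv", index=False)
    record("hla_scan", out / "hla_scan.csv")
    record("hla_report", out / "hla_report.csv")
    log.info("hla: %d alleles tested, top p=%.3g", len(scan),
             scan["fisher_p"].iloc[0] if len(scan) else float("nan"))


def _summary_table(features: pd.DataFrame, labels: pd.Series,
                   cols: list[str]) -> pd.DataFrame:
    df = features.copy()
    df["label"] = df.apply(
        lambda r: "HC" if r["group"] == "HC" else labels.get(r["donor_id"]),
        axis=1)
    rows = []
    for col in cols:
        row: dict = {"feature": col}
        for g in ("HC", "LOW", "HIGH"):
            v = df.loc[df["label"] == g, col].dropna()
            if len(v):
                row[f"{g}_n"] = len(v)
                row[f"{g}_median"] = float(v.median())
                row[f"{g}_range"] = f"{v.min():.3g}-{v.max():.3g}"
        groups = [df.loc[df["label"] == g, col].dropna()
                  for g in ("HC", "LOW", "HIGH")]
        groups = [g for g in groups if len(g)]
        if len(groups) >= 3:
            from scipy import stats as ss
            row["kruskal_p"] = float(ss.kruskal(*groups).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_stats(cfg: RunConfig, out: Path, state: dict, record) -> None:
    features = state["features"]
    first = features.sort_values("visit").groupby("donor_id").head(1)
    labels = state["classification"].set_index("donor_id")["label"]
    donors = state["cohort"].donor_frame()
    donors["label"] = donors.apply(
        lambda r: "HC" if r["group"] == "HC" else labels.get(r["donor_id"]),
        axis=1)
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)

    # demographics (age / sex / counts)
    table1 = _summary_table(first, labels, [
        "lymph_count_per_L", "t_count_per_L", "cd4_count_per_L",
        "cd8_count_per_L", "cd4_cd8_ratio"])
    age = donors[["label", "age"]].rename(columns={"age": "value"})
    table1_demo = age.groupby("label")["value"].agg(["count", "median", "min", "max"])
    table1.to_csv(stats_dir / "table1_counts.csv", index=False)
    table1_demo.to_csv(stats_dir / "table1_age.csv")

    # T-LGL summary: the headline expansion quantities
    table2 = _summary_table(first, labels, [
        "lymph_count_per_L", "cd8cd57_count_per_L", "pct_cd8cd57_of_lymph"])
    table2.to_csv(stats_dir / "table2_lgl.csv", index=False)

    # rank factorial tests: marker frequency ~ group x T cell subset
    srh_rows = []
    long_frames = []
    for marker in ("cd5dim", "cd94", "cd56", "klrg1"):
        long = pd.concat([
            pd.DataFrame({
                "value": first[f"pct_{marker}_{sub}cd57"],
                "subset": sub,
                "label": [("HC" if g == "HC" else labels.get(d))
                          for g, d in zip(first["group"], first["donor_id"])],
            }) for sub in ("cd4", "cd8", "gd")
        ]).dropna()
        res = cohort_stats.scheirer_ray_hare(long["value"], long["label"],
                                             long["subset"])
        srh_rows.append({"marker": marker, "H_group": res.H_A,
                         "p_group": res.p_A, "H_subset": res.H_B,
                         "p_subset": res.p_B, "H_interaction": res.H_interaction,
                         "p_interaction": res.p_interaction,
                         "tie_correction": res.tie_correction})
        long_frames.append(long.assign(marker=marker))
    pd.DataFrame(srh_rows).to_csv(stats_dir / "srh_markers.csv", index=False)

    # PCA of the CD8+CD57+ marker phenotype
    pca = cohort_stats.pca_summary(first[[f"pct_{m}_cd8cd57" for m in
                                          ("cd5dim", "cd94", "cd56", "klrg1")]])
    _json_dump({"explained_variance_ratio": pca["explained_variance_ratio"],
                "cumulative_variance_ratio": pca["cumulative_variance_ratio"],
                "loadings": pca["loadings"]}, stats_dir / "pca_cd8cd57.json")

    # clinical comparisons: onset age, duration, mobility aids
    pts = donors[donors["group"] != "HC"].copy()
    from scipy import stats as ss
    clin = {}
    for col in ("onset_age", "symptom_duration"):
        hi = pts.loc[pts["label"] == "HIGH", col].dropna()
        lo = pts.loc[pts["label"] == "LOW", col].dropna()
        if len(hi) and len(lo):
            r = ss.mannwhitneyu(hi, lo, alternative="two-sided")
            clin[col] = {"median_high": float(hi.median()),
                         "median_low": float(lo.median()),
                         "p": float(r.pvalue)}
    aid = pd.crosstab(pts["label"], pts["mobility_aid"] != "none")
    if aid.shape == (2, 2):
        clin["mobility_aid"] = {
            "pct_high": float(100 * aid.loc["HIGH", True] / aid.loc["HIGH"].sum()),
            "pct_low": float(100 * aid.loc["LOW", True] / aid.loc["LOW"].sum()),
            "chi2_p": float(ss.chi2_contingency(aid, correction=False).pvalue)}
    _json_dump(clin, stats_dir / "clinical.json")

    state["stats"] = {"table2": table2, "srh": pd.DataFrame(srh_rows),
                      "pca": pca, "clinical": clin}
    for f in stats_dir.iterdir():
        record(f"stats/{f.stem}", f)
    log.info("stats: %d report tables", len(list(stats_dir.iterdir())))


def _stage_report(cfg: RunConfig, out: Path, state: dict, record) -> None:
    report = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    if "classification" in state:
        report["classification"] = classification_summary(state["classification"])
    if "serology" in state:
        report["serology"] = {k: v for k, v in state["serology"].items()
                              if k != "per_group"}
        report["serology_per_group"] = state["serology"]["per_group"]
    if "hla_scan" in state and len(state["hla_scan"]):
        top = state["hla_scan"].iloc[0]
        report["hla_top"] = {"allele": top["allele"],
                             "odds_ratio": float(top["odds_ratio"]),
                             "fisher_p": float(top["fisher_p"])}
    if "stats" in state:
        report["pca_pc12_variance"] = float(
            state["stats"]["pca"]["cumulative_variance_ratio"][1])
    _json_dump(report, out / "report.json")
    record("report", out / "report.json")
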