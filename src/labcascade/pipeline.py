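"""End-to-end orchestration: simulate -> link -> cascade -> standardize
-> regress -> report, with a reproducibility manifest.

Every stage writes delimited-text outputs into the run directory; the
manifest records the seed, a hash of the configuration, input/output
checksums and stage timings, so a rerun with the same configuration is
verifiable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import io as lio  # noqa: E402
from .cascade import (Thresholds, Windows, build_cascade,  # noqa: E402
                      build_cascade_table, testing_trend_summary)
from .linkage import LinkageConfig, cluster_records, evaluate_linkage  # noqa: E402
from .regression import fit_all_models, report_table  # noqa: E402
from .simulate import CorruptionSpec, SimConfig, corrupt_identities, generate_cohort  # noqa: E402
from .standardize import load_weights  # noqa: E402

ALL_STAGES = ("simulate", "link", "cascade", "regress", "report")


@dataclass
class RunConfig:
    """Single-file configuration for a pipeline run."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    use_linkage: bool = True       # False: use the truth identity column
    weights_path: str | None = None  # None: bundled synthetic weights
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    corruption: dict = field(default_factory=dict)   # CorruptionSpec overrides
    linkage: dict = field(default_factory=dict)      # LinkageConfig overrides
    thresholds: dict = field(default_factory=dict)   # Thresholds overrides
    windows: dict = field(default_factory=dict)      # Windows overrides
    diagnosis_mode: str = "window"
    tb_require_positive: bool = False
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.sim)
        if "enrollment_window" in kwargs:
            kwargs["enrollment_window"] = tuple(
                dt.date.fromisoformat(str(d)) for d in kwargs["enrollment_window"])
        kwargs.setdefault("seed", self.seed)
        cfg = SimConfig(**kwargs)
        if self.corruption:
            cfg.corruption = CorruptionSpec(**self.corruption)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "stages": [], "outputs": {}, "timings_s": {}}
    paths = {
        "extract": outdir / "extract.csv",
        "truth_map": outdir / "ground_truth_map.csv",
        "truth_patients": outdir / "ground_truth_patients.csv",
        "links": outdir / "links.csv",
        "linkage_eval": outdir / "linkage_eval.json",
        "rows": outdir / "cascade_rows.csv",
        "table": outdir / "cascade_table.csv",
        "exclusions": outdir / "exclusions.json",
        "trend": outdir / "testing_trend.csv",
        "shares": outdir / "testing_shares.json",
        "table3": outdir / "risk_ratios.csv",
        "figure": outdir / "cascade_figure.png",
        "manifest": outdir / "manifest.json",
    }

    def stage(name):
        return name in config.stages

    def done(name, t0, *outputs):
        manifest["stages"].append(name)
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        for p in outputs:
            manifest["outputs"][p.name] = _checksum(p)

    records = truth = None
    if stage("simulate"):
        t0 = time.perf_counter()
        sim_cfg = config.sim_config()
        records, truth = generate_cohort(sim_cfg)
        records = corrupt_identities(records, sim_cfg.corruption, seed=sim_cfg.seed + 1)
        lio.write_extract(records, paths["extract"])
        lio.write_ground_truth(truth, paths["truth_map"], paths["truth_patients"])
        done("simulate", t0, paths["extract"], paths["truth_map"],
             paths["truth_patients"])

    links = None
    if stage("link"):
        if records is None:
            if not paths["extract"].exists():
                raise FileNotFoundError(
                    "link stage requires an extract; run simulate first or "
                    f"provide {paths['extract']}")
            records = lio.read_extract(paths["extract"])
            records = records.merge(lio.read_ground_truth(
                paths["truth_map"], paths["truth_patients"]).record_map,
                on="record_id", how="left") if paths["truth_map"].exists() else records
        t0 = time.perf_counter()
        if config.use_linkage:
            link_cfg = LinkageConfig(**config.linkage)
            links = cluster_records(records.reset_index(drop=True), link_cfg)
            lio.write_linkage_map(links, paths["links"])
            outputs = [paths["links"]]
            if truth is not None or paths["truth_map"].exists():
                tmap = truth.record_map if truth is not None else \
                    pd.read_csv(paths["truth_map"], dtype=str)
                ev = evaluate_linkage(links, tmap)
                paths["linkage_eval"].write_text(json.dumps({
                    "sensitivity": ev.sensitivity, "ppv": ev.ppv,
                    "n_true_pairs": ev.n_true_pairs,
                    "n_predicted_pairs": ev.n_predicted_pairs,
                    "n_true_positive_pairs": ev.n_true_positive_pairs,
                    "degenerate_ppv": ev.degenerate_ppv}, indent=2))
                outputs.append(paths["linkage_eval"])
            done("link", t0, *outputs)
        else:
            if "true_patient_id" not in records.columns:
                raise ValueError("linkage disabled but no identity column present")
            done("link", t0)

    rows = None
    if stage("cascade"):
        t0 = time.perf_counter()
        thresholds = Thresholds(**config.thresholds)
        win_kwargs = dict(config.windows)
        if "enrollment" in win_kwargs:
            win_kwargs["enrollment"] = tuple(
                dt.date.fromisoformat(str(d)) for d in win_kwargs["enrollment"])
        windows = Windows(**win_kwargs)
        rows, excl = build_cascade(
            records, links=links if config.use_linkage else None,
            thresholds=thresholds, windows=windows,
            diagnosis_mode=config.diagnosis_mode,
            tb_require_positive=config.tb_require_positive)
        rows.to_csv(paths["rows"], index=False)
        paths["exclusions"].write_text(json.dumps(excl, indent=2))
        weights = load_weights(config.weights_path)
        table = build_cascade_table(rows, weights=weights)
        table.to_csv(paths["table"], index=False)
        trend, shares = testing_trend_summary(records)
        trend.to_csv(paths["trend"], index=False)
        paths["shares"].write_text(json.dumps(shares, indent=2))
        done("cascade", t0, paths["rows"], paths["table"], paths["exclusions"],
             paths["trend"], paths["shares"])

    if stage("regress"):
        if rows is None:
            rows = pd.read_csv(paths["rows"])
        t0 = time.perf_counter()
        fits = fit_all_models(rows)
        report_table(fits).to_csv(paths["table3"], index=False)
        done("regress", t0, paths["table3"])

    if stage("report"):
        t0 = time.perf_counter()
        if rows is not None:
            table = pd.read_csv(paths["table"])
            render_cascade_figure(table, paths["figure"])
            done("report", t0, paths["figure"])

    manifest["generated_at"] = dt.datetime.now().isoformat(timespec="seconds")
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return manifest


def render_cascade_figure(table: pd.DataFrame, path) -> None:
    """Bar-style cascade with conditional-transition annotations.

    Bars share the diagnosed denominator (diagnosed, retained, control);
    boxes above consecutive bars show the transition proportion whose
    denominator is the previous stage.
    """
    overall = table[(table["stratifier"] == "overall")].iloc[0]
    counts = [overall["n_diagnosed"], overall["n_retained_dm"],
              overall["n_controlled"]]
    denom = max(int(overall["n_diagnosed"]), 1)
    labels = ["Lab-diagnosed\ndiabetes", "Retained-in-care\n(24 mo)",
              "Glycaemic control\n(24 mo)"]

    fig, ax = plt.subplots(figsize=(7, 5))
    bars = ax.bar(labels, counts, color=["#1f5fa8", "#3b86c8", "#7fb3dc"])
    for bar, c in zip(bars, counts):
        ax.annotate(f"{c:,}\n({100 * c / denom:.1f}%)",
                    (bar.get_x() + bar.get_width() / 2, bar.get_height()),
                    ha="center", va="bottom", fontsize=9)
    # conditional transitions (denominator = previous stage)
    for i in (1, 2):
        prev = counts[i - 1]
        frac = counts[i] / prev if prev else 0.0
        ax.annotate(f"{100 * frac:.1f}% of previous stage",
                    ((bars[i - 1].get_x() + bars[i].get_x() + bars[i].get_width()) / 2,
                     max(counts) * (0.92 - 0.12 * i)),
                    ha="center", fontsize=8, color="#444",
                    bbox=dict(boxstyle="round", fc="#dbe9f6", ec="#7fb3dc"))
    ax.set_ylabel(f"Patients (denominator: {denom:,} lab-diagnosed)")
    ax.set_title("Diabetes care cascade from laboratory records")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
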