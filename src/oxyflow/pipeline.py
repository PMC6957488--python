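"""End-to-end orchestration: simulate (or load) a cohort, epoch it, compute
entropy curves and CAIs, run both correlation analyses and all group
comparisons, and write one reproducible results bundle.

Every output table is tidy TSV whose first line is a comment carrying the
package version and the run's config hash; a run manifest (JSON) records
the full configuration, the files written and any warnings, so two runs
with identical config and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import DEFAULT_PAIRS, cai_correlations, timecourse_correlations
from .entropy import EntropyParams, mfe_curve, mse_curve
from .errors import OxyflowError, ParameterError, PipelineStageError
from .group_stats import compare_conditions
from .records import CONDITIONS, EpochSpec, SignalRecord
from .signal_io import extract_window, minute_average, read_dataset
from .synthetic import StudyDesign, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "compute_cai_table"]

ANALYSIS_CHANNELS = ("oxy_sat", "V1", "V2", "V3")


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration.

    ``input`` is either the string ``"simulate"`` (generate the synthetic
    cohort from ``synthetic`` overrides and the design sizes) or a path to
    a canonical long CSV. ``after_window`` selects which window plays the
    role of "after stimulation": the heating epoch (default), the post
    epoch, or both concatenated.
    """

    output_dir: str
    input: str = "simulate"
    ts_subjects: int = 29
    bc_subjects: int = 30
    synthetic: dict = field(default_factory=dict)
    entropy: dict = field(default_factory=dict)
    after_window: str = "stimulation"
    kinds: tuple = ("MSE", "MFE")
    n_perm: int = 10_000
    seed: int = 0
    strict: bool = True
    epoch_minutes: tuple = (30.0, 30.0, 30.0)

    def __post_init__(self):
        if self.after_window not in ("stimulation", "post", "both"):
            raise ParameterError(f"unknown after_window {self.after_window!r}")
        for kind in self.kinds:
            if kind not in ("MSE", "MFE"):
                raise ParameterError(f"unknown entropy kind {kind!r}")

    def to_jsonable(self) -> dict:
        """Analysis configuration as plain JSON types; the output location
        is deliberately excluded (it does not affect the results)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        d["kinds"] = list(self.kinds)
        d["epoch_minutes"] = list(self.epoch_minutes)
        # tuple-keyed coupling overrides flatten to "condition:channel"
        synth = dict(d["synthetic"])
        if "coupling" in synth:
            synth["coupling"] = {
                (k if isinstance(k, str) else f"{k[0]}:{k[1]}"): v
                for k, v in synth["coupling"].items()}
        d["synthetic"] = synth
        return d

    @classmethod
    def from_dict(cls, d: dict, output_dir: str | None = None) -> "RunConfig":
        d = dict(d)
        if output_dir is not None:
            d["output_dir"] = output_dir
        synth = dict(d.get("synthetic", {}))
        if "coupling" in synth:
            synth["coupling"] = {
                (tuple(k.split(":")) if isinstance(k, str) else tuple(k)): v
                for k, v in synth["coupling"].items()}
        d["synthetic"] = synth
        for key in ("kinds", "epoch_minutes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def synthetic_config(self) -> SyntheticConfig:
        overrides = dict(self.synthetic)
        if "coupling" in overrides:
            overrides["coupling"] = {tuple(k) if not isinstance(k, tuple) else k: v
                                     for k, v in overrides["coupling"].items()}
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("epoch_minutes", tuple(self.epoch_minutes))
        return SyntheticConfig(**overrides)

    def entropy_params(self) -> EntropyParams:
        return EntropyParams(**self.entropy)

    def epoch_spec(self) -> EpochSpec:
        b, s, p = self.epoch_minutes
        return EpochSpec.from_minutes(b, s, p)


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def compute_cai_table(records: list[SignalRecord], spec: EpochSpec,
                      windows: dict, params: EntropyParams,
                      kinds=("MSE",), channels=ANALYSIS_CHANNELS) -> pd.DataFrame:
    """Per-scale entropy values and CAIs for every recording/channel/window.

    ``windows`` maps a label to a (start_s, end_s) window. Returns the pair
    of tidy frames (per-scale curve table, CAI table) as a dict with keys
    ``"curves"`` and ``"cai"``.
    """
    curve_rows = []
    cai_rows = []
    for rec in sorted(records, key=lambda r: r.key()):
        if rec.channel not in channels:
            continue
        for label, window in windows.items():
            seg = extract_window(rec, *window)
            for kind in kinds:
                fn = mse_curve if kind == "MSE" else mfe_curve
                curve = fn(seg.values, params)
                for tau, val, ne in zip(curve.scales, curve.values,
                                        curve.n_effective):
                    curve_rows.append({
                        "subject_id": rec.subject_id, "group": rec.group,
                        "condition": rec.condition, "channel": rec.channel,
                        "epoch": label, "kind": kind, "scale": int(tau),
                        "value": val, "n_effective": int(ne)})
                cai_rows.append({
                    "subject_id": rec.subject_id, "group": rec.group,
                    "condition": rec.condition, "channel": rec.channel,
                    "epoch": label, "kind": kind, "cai": curve.cai})
    return {"curves": pd.DataFrame(curve_rows), "cai": pd.DataFrame(cai_rows)}


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the in-memory results bundle.

    Writes (under ``config.output_dir``): ``timecourse.tsv`` (minute-mean
    oxygen time courses), ``entropy.tsv`` and ``cai.tsv`` (per-scale curves
    and CAIs, baseline and after-stimulation windows), ``correlations.tsv``
    (per-subject time-domain rho), ``comparisons.tsv`` (omnibus F and all
    pairwise permutation posttests per metric), ``cai_correlations.tsv``
    (cross-subject CAI rho per condition) and ``manifest.json``. Any stage
    failure removes the partial outputs and raises
    :class:`PipelineStageError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# oxyflow={__version__} config_hash={config.config_hash}\n"
    written: list[Path] = []
    collector = _WarningCollector()
    logging.getLogger("oxyflow").addHandler(collector)
    stage = "load"
    try:
        spec = config.epoch_spec()
        params = config.entropy_params()
        if config.input == "simulate":
            design = StudyDesign(ts_subjects=config.ts_subjects,
                                 bc_subjects=config.bc_subjects,
                                 seed=config.seed)
            records = generate_cohort(design, config.synthetic_config())
        else:
            records = read_dataset(config.input, strict=config.strict)
        windows = {"baseline": spec.window("baseline"),
                   "after": spec.after_window(config.after_window)}

        stage = "timecourse"
        rows = []
        for rec in sorted(records, key=lambda r: r.key()):
            if rec.channel != "oxy_sat":
                continue
            times, means = minute_average(rec)
            for t, mval in zip(times, means):
                rows.append({"subject_id": rec.subject_id, "group": rec.group,
                             "condition": rec.condition, "minute_s": t,
                             "mean_oxy": mval})
        timecourse = pd.DataFrame(rows)
        path = out / "timecourse.tsv"
        _write_tsv(timecourse, path, header)
        written.append(path)

        stage = "entropy"
        tables = compute_cai_table(records, spec, windows, params,
                                   kinds=config.kinds)
        for name, key in (("entropy.tsv", "curves"), ("cai.tsv", "cai")):
            path = out / name
            _write_tsv(tables[key], path, header)
            written.append(path)

        stage = "correlations"
        corr_frames = [
            timecourse_correlations(records, spec, epoch="baseline"),
            timecourse_correlations(records, spec,
                                    after_window=config.after_window),
        ]
        correlations = pd.concat(corr_frames, ignore_index=True)
        path = out / "correlations.tsv"
        _write_tsv(correlations, path, header)
        written.append(path)

        stage = "comparisons"
        comp_rows = []
        after_label = f"after:{config.after_window}"
        for chan, _oxy in DEFAULT_PAIRS:
            sub = correlations[(correlations["pair"] == f"{chan}~oxy_sat")
                               & (correlations["epoch"] == after_label)]
            metric = f"rho_{chan}"
            by_cond = {c: sub[sub["condition"] == c]["rho"].to_numpy()
                       for c in CONDITIONS}
            comp_rows.extend(_comparison_rows(metric, after_label, by_cond,
                                              config))
        cai_df = tables["cai"]
        for kind in config.kinds:
            for epoch in ("baseline", "after"):
                sub = cai_df[(cai_df["kind"] == kind)
                             & (cai_df["channel"] == "oxy_sat")
                             & (cai_df["epoch"] == epoch)]
                metric = f"{kind.lower()}_cai_oxy"
                by_cond = {c: sub[sub["condition"] == c]["cai"].dropna().to_numpy()
                           for c in CONDITIONS}
                comp_rows.extend(_comparison_rows(metric, epoch, by_cond,
                                                  config))
        comparisons = pd.DataFrame(comp_rows)
        path = out / "comparisons.tsv"
        _write_tsv(comparisons, path, header)
        written.append(path)

        stage = "cai_correlations"
        cc_rows = []
        for kind in config.kinds:
            sub = cai_df[(cai_df["kind"] == kind) & (cai_df["epoch"] == "after")]
            for condition in CONDITIONS:
                for res in cai_correlations(sub, condition):
                    cc_rows.append({"kind": kind, "condition": condition,
                                    "pair": f"{res.pair[0]}~{res.pair[1]}",
                                    "rho": res.rho, "n": res.n, "p": res.p})
        cai_corr = pd.DataFrame(cc_rows)
        path = out / "cai_correlations.tsv"
        _write_tsv(cai_corr, path, header)
        written.append(path)

        stage = "manifest"
        manifest = {
            "oxyflow_version": __version__,
            "config": config.to_jsonable(),
            "config_hash": config.config_hash,
            "n_records": len(records),
            "outputs": [p.name for p in written],
            "warnings": collector.messages,
        }
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    except OxyflowError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc
    finally:
        logging.getLogger("oxyflow").removeHandler(collector)

    return {"records": records, "timecourse": timecourse,
            "entropy": tables["curves"], "cai": tables["cai"],
            "correlations": correlations, "comparisons": comparisons,
            "cai_correlations": cai_corr, "manifest": manifest}


def _comparison_rows(metric: str, window: str, by_cond: dict,
                     config: RunConfig) -> list[dict]:
    comp = compare_conditions(by_cond, n_perm=config.n_perm, seed=config.seed)
    rows = [{
        "metric": metric, "window": window, "test": "oneway_F",
        "a": "all", "b": "all", "statistic": comp.anova.F,
        "df_between": comp.anova.df_between, "df_within": comp.anova.df_within,
        "p": comp.anova.p, "significant": bool(comp.anova.p < comp.alpha)
        if not np.isnan(comp.anova.p) else False,
    }]
    for (ca, cb), res in comp.pairwise.items():
        rows.append({"metric": metric, "window": window, "test": "permutation",
                     "a": ca, "b": cb, "statistic": res.statistic,
                     "df_between": "", "df_within": "", "p": res.p,
                     "significant": comp.significant[(ca, cb)]})
    return rows
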