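"""End-to-end analysis pipeline.

Stages, in fixed order, run independently for each event definition:

    read -> normalize drug names -> deduplicate -> flag event cases ->
    demographics table -> per-drug ROR screen (Bonferroni) -> ATC grouping ->
    LASSO drug selection -> multivariate logistic fit -> ROC/AUC ->
    onset-time summaries

All exports are delimited text written deterministically: identical config
and seed give a byte-identical output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import disproportionality as dp
from . import io as fio
from . import onset as onset_mod
from . import risk
from .errors import ConfigurationError
from .synthetic import GeneratorConfig, generate_reports, write_tables

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "atc_group",
           "summarize_demographics", "load_atc_map"]

_AGE_SUMMARY_BINS = ("<36", "36-53", "53-66", "66-80", "80-120", "missing")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: Path
    events: list[fio.EventDefinition]
    input_dir: Path | None = None
    synth: GeneratorConfig | None = None
    thresholds: dp.ScreenThresholds = field(
        default_factory=dp.ScreenThresholds)
    roles: tuple[str, ...] = fio.SUSPECT_ROLES
    age_edges: tuple[float, ...] = risk.AGE_EDGES
    cv_folds: int = 5
    lambda_rule: str = "min"
    alpha_univariate: float = 0.01
    alpha_multivariate: float = 0.01
    seed: int = 0
    dual_flag_policy: str = "keep"   # 'keep' or 'drop'
    synonym_map: dict[str, str] | None = None
    atc_map: dict[str, str] | None = None
    yates: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
        if (self.input_dir is None) == (self.synth is None):
            raise ConfigurationError(
                "exactly one of input_dir or synth must be set")
        if not self.events:
            raise ConfigurationError("at least one event definition required")
        if not 0 < self.alpha_univariate < 1 or not 0 < self.alpha_multivariate < 1:
            raise ConfigurationError("alpha levels must be in (0, 1)")
        if self.dual_flag_policy not in ("keep", "drop"):
            raise ConfigurationError("dual_flag_policy must be keep|drop")
        if self.lambda_rule not in ("min", "1se"):
            raise ConfigurationError("lambda_rule must be min|1se")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        events = []
        for ev in raw.get("events", []):
            if "terms_file" in ev:
                events.append(fio.EventDefinition.from_file(
                    ev["name"], _resolve(ev["terms_file"])))
            else:
                events.append(fio.EventDefinition(
                    ev["name"], frozenset(ev["terms"])))
        kwargs: dict = {
            "outdir": _resolve(raw["outdir"]),
            "events": events,
        }
        if "input_dir" in raw:
            kwargs["input_dir"] = _resolve(raw["input_dir"])
        if "synth" in raw:
            kwargs["synth"] = GeneratorConfig.from_dict(raw["synth"])
        if "thresholds" in raw:
            kwargs["thresholds"] = dp.ScreenThresholds(**raw["thresholds"])
        if "synonym_map_file" in raw:
            kwargs["synonym_map"] = fio.load_synonym_map(
                _resolve(raw["synonym_map_file"]))
        if "atc_map_file" in raw:
            kwargs["atc_map"] = load_atc_map(_resolve(raw["atc_map_file"]))
        for key in ("roles", "age_edges"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("cv_folds", "lambda_rule", "alpha_univariate",
                    "alpha_multivariate", "seed", "dual_flag_policy",
                    "yates", "make_plots"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def fingerprint(self) -> str:
        """Hash of the analysis-relevant configuration (where the outputs
        are written is deliberately excluded)."""
        def _enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: _enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)
                        if f.name != "outdir"}
            if isinstance(obj, (Path, frozenset)):
                return sorted(map(str, obj)) if isinstance(obj, frozenset) \
                    else str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {str(k): _enc(v) for k, v in sorted(obj.items())}
            if isinstance(obj, list):
                return [_enc(v) for v in obj]
            return obj
        blob = json.dumps(_enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage record counts and model diagnostics for one run."""

    counts: dict = field(default_factory=dict)
    per_event: dict = field(default_factory=dict)
    fingerprint: str = ""
    version: str = __version__
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "fingerprint": self.fingerprint,
            "seed": self.seed,
            "counts": self.counts,
            "per_event": self.per_event,
        }, indent=2, sort_keys=True, default=str)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


def summarize_demographics(cases: pd.DataFrame, flags: pd.Series,
                           age_edges: Sequence[float] = risk.AGE_EDGES
                           ) -> pd.DataFrame:
    """Counts and percentages (plus age/weight median and quartiles) for the
    flagged cases, with explicit Missing rows — the shape of a standard
    baseline-characteristics table."""
    sub = cases.loc[flags.reindex(cases.index, fill_value=False)]
    n = len(sub)
    rows: list[tuple[str, str, object]] = [("cases", "n", n)]

    def _counts(col: str, order: Sequence[str]) -> None:
        vc = sub[col].value_counts()
        for level in order:
            k = int(vc.get(level, 0))
            rows.append((col, level, k))
            rows.append((col, f"{level}_pct",
                         round(100.0 * k / n, 1) if n else 0.0))

    _counts("sex", ("female", "male", "missing"))
    age = sub["age_years"].to_numpy(dtype=float)
    valid = age[~np.isnan(age) & (age >= 0) & (age <= age_edges[-1])]
    if valid.size:
        q1, med, q3 = np.percentile(valid, [25, 50, 75])
        rows += [("age_years", "median", round(float(med), 1)),
                 ("age_years", "q1", round(float(q1), 1)),
                 ("age_years", "q3", round(float(q3), 1))]
    rows.append(("age_years", "missing", int(len(sub) - valid.size)))
    wt = sub["weight_kg"].to_numpy(dtype=float)
    wvalid = wt[~np.isnan(wt)]
    if wvalid.size:
        q1, med, q3 = np.percentile(wvalid, [25, 50, 75])
        rows += [("weight_kg", "median", round(float(med), 1)),
                 ("weight_kg", "q1", round(float(q1), 1)),
                 ("weight_kg", "q3", round(float(q3), 1))]
    rows.append(("weight_kg", "missing", int(len(sub) - wvalid.size)))
    _counts("occupation", ("consumer", "lawyer", "physician",
                           "other_health_professional", "pharmacist",
                           "missing"))
    return pd.DataFrame(rows, columns=["characteristic", "level", "value"])


def atc_group(signal_drugs: Sequence[str],
              mapping: Mapping[str, str] | None) -> pd.DataFrame:
    """Count screened signal drugs per ATC class; unmapped drugs pool under
    ``unmapped``.  Sorted by descending count, then class name."""
    mapping = {k.strip().lower(): v.strip() for k, v in (mapping or {}).items()}
    classes = [mapping.get(d.strip().lower(), "unmapped")
               for d in signal_drugs]
    counts = pd.Series(classes, dtype=object).value_counts()
    out = counts.rename_axis("atc_class").reset_index(name="count")
    return out.sort_values(["count", "atc_class"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def load_atc_map(path: str | Path) -> dict[str, str]:
    return fio.load_synonym_map(path)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline; returns the run report and writes all
    stage exports under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(fingerprint=config.fingerprint(), seed=config.seed)

    stage = "input"
    try:
        if config.synth is not None:
            tables = generate_reports(config.synth)
            input_dir = out / "input"
            write_tables(tables, input_dir)
        else:
            input_dir = config.input_dir
        stage = "read"
        rs = fio.read_quarter(input_dir)
        report.counts.update(rs.log)
        stage = "normalize"
        rs = fio.normalize_drug_names(rs, config.synonym_map)
        stage = "deduplicate"
        rs = fio.deduplicate(rs)
        report.counts["cases_after_dedup"] = rs.n_cases
        cases = fio.case_table(rs)
        pairs = fio.suspect_pairs(rs, config.roles)

        stage = "flag_events"
        flags = {ev.name: fio.flag_event_cases(rs, ev)
                 for ev in config.events}
        if config.dual_flag_policy == "drop" and len(flags) > 1:
            stacked = pd.DataFrame(flags)
            dual = stacked.sum(axis=1) > 1
            report.counts["dual_flagged_dropped"] = int(dual.sum())
            keep = stacked.index[~dual]
            cases = cases.loc[cases.index.isin(keep)]
            pairs = pairs[pairs["caseid"].isin(keep)].reset_index(drop=True)
            flags = {k: v.loc[v.index.isin(keep)] for k, v in flags.items()}

        for ev in config.events:
            _run_event(config, out, report, ev, rs, cases, pairs,
                       flags[ev.name])
    except Exception:
        (out / "run_report.json").write_text(report.to_json() + "\n")
        logger.error("pipeline aborted at stage %r", stage)
        raise

    (out / "run_report.json").write_text(report.to_json() + "\n")
    return report


def _run_event(config: RunConfig, out: Path, report: RunReport,
               ev: fio.EventDefinition, rs: fio.ReportSet,
               cases: pd.DataFrame, pairs: pd.DataFrame,
               flags: pd.Series) -> None:
    name = ev.name
    ev_report: dict = {"n_flagged": int(flags.sum())}
    report.per_event[name] = ev_report
    logger.info("event %s: %d flagged cases", name, flags.sum())

    _write(summarize_demographics(cases, flags, config.age_edges),
           out / f"demographics_{name}.txt")

    # --- univariate ROR screen ---------------------------------------
    thresholds = dataclasses.replace(config.thresholds,
                                     p_adjust_lt=config.alpha_univariate)
    results = dp.analyze(flags, pairs, thresholds, yates=config.yates)
    signals = dp.screen_signals(results, thresholds)
    ev_report["n_drugs_tested"] = len(results)
    ev_report["bonferroni_family_size"] = int(results.attrs["family_size"])
    ev_report["n_signals"] = len(signals)
    for row in signals.itertuples(index=False):
        logger.info("event %s: signal %s (a=%d, ROR_025=%.3g, p_adj=%.3g)",
                    name, row.drug, row.a, row.ror_lower, row.p_adjust)
    _write(results, out / f"signals_{name}.txt")
    _write(dp.volcano_table(results), out / f"volcano_{name}.txt")
    if config.atc_map is not None:
        _write(atc_group(signals["drug"], config.atc_map),
               out / f"atc_{name}.txt")

    # --- onset ---------------------------------------------------------
    records, counters = onset_mod.compute_onset(rs, flags, config.roles)
    ev_report["onset_exclusions"] = counters
    summary = pd.concat([
        onset_mod.summarize_onset(records, by="event", group_name=name),
        onset_mod.summarize_onset(records, by="drug"),
    ], ignore_index=True)
    _write(summary, out / f"onset_summary_{name}.txt")
    _write(records.drop(columns=["start_date"]),
           out / f"onset_records_{name}.txt")
    if not summary.empty:
        ev_report["onset_median_days"] = float(summary.iloc[0]["median"])

    # --- risk modelling -------------------------------------------------
    candidates = list(signals["drug"])
    ev_report["n_candidate_drugs"] = len(candidates)
    if not candidates or flags.sum() == 0 or flags.all():
        logger.warning("event %s: model stages skipped "
                       "(no candidates or degenerate outcome)", name)
        ev_report["model"] = "skipped"
        return
    exposures = fio.exposure_matrix(rs, candidates, config.roles)
    design = risk.build_design_matrix(
        cases, flags, exposures, candidates, config.age_edges)
    sel = risk.lasso_select(design, cv_folds=config.cv_folds,
                            seed=config.seed, rule=config.lambda_rule)
    ev_report["lasso"] = {
        "lambda_min": sel.lambda_min, "lambda_1se": sel.lambda_1se,
        "rule": sel.rule,
        "n_drugs_selected": len(sel.selected_drugs),
    }
    path_out = sel.path.rename_axis("covariate").reset_index()
    _write(path_out, out / f"lasso_path_{name}.txt")
    _write(sel.cv_deviance, out / f"lasso_cv_{name}.txt")

    fit = risk.logistic_fit(design, sel.selected,
                            alpha=config.alpha_multivariate)
    ev_report["model"] = {
        "auc": fit.auc, "converged": fit.converged,
        "separation_suspected": fit.separation_suspected,
        "n_used": fit.n_used,
        "n_significant": int(fit.table["significant"].sum()),
        "dropped": fit.dropped,
    }
    _write(forest := risk.forest_table(fit, alpha=config.alpha_multivariate),
           out / f"forest_{name}.txt")
    _, curve = risk.roc_auc(fit.fitted_probabilities, design.y)
    _write(curve, out / f"roc_{name}.txt")
    if config.make_plots:
        from . import plots
        plots.volcano(dp.volcano_table(results),
                      out / f"volcano_{name}.png")
        plots.forest(forest, out / f"forest_{name}.png")
        plots.onset_violin(records, out / f"onset_{name}.png")
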