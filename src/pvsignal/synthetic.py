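"""Synthetic FAERS-style spontaneous-report generator with planted effects.

Emits quarterly ASCII tables (DEMO/DRUG/REAC/THER, ``$``-delimited) in the
layout of the FDA Adverse Event Reporting System, for a simulated population
of individual case safety reports.  Every effect in the simulation is known:
each catalog drug carries a true case-level odds ratio for the target event,
and sex/age carry their own odds ratios, all combined multiplicatively on the
odds scale (a logistic model).  This makes the generator's output a ground
truth against which the whole downstream pipeline — deduplication, 2x2
disproportionality screening, LASSO/logistic risk modelling, onset-time
summaries — can be tested for recovery of the planted structure.

The simulated population mirrors a spontaneous-reporting database of
thyroid-dysfunction adverse events: roughly 60% female reports, median age
in the mid-fifties with ~30% of ages missing, weight mostly missing,
reporters dominated by physicians and consumers, and right-skewed
therapy-to-onset times (log-normal by default, median ≈ 40 days).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

__all__ = [
    "AGE_BIN_LABELS",
    "AGE_BIN_EDGES",
    "OnsetDistribution",
    "DrugSpec",
    "GeneratorConfig",
    "PlantedTruth",
    "SimulatedCases",
    "FaersTables",
    "simulate_cases",
    "generate_reports",
    "planted_truth",
    "write_tables",
]

# Age strata used throughout the package: reference <36, then 36-53, 53-66,
# 66-80, 80-120 (half-open [lo, hi) except the last bin, closed at 120).
AGE_BIN_LABELS = ("<36", "36-53", "53-66", "66-80", "80-120")
AGE_BIN_EDGES = (36.0, 53.0, 66.0, 80.0, 120.0)

_EPOCH = pd.Timestamp("2004-01-01")
_MAX_START_OFFSET = 7300  # therapy starts uniformly over 2004-2023

_OCCUPATIONS = ("MD", "CN", "OT", "PH", "LW")
_OCCUPATION_PROBS = (0.38, 0.32, 0.23, 0.045, 0.025)

_DEFAULT_MISSING_RATES = {
    "sex": 0.10,
    "age": 0.32,
    "weight": 0.70,
    "occupation": 0.06,
}

_DEFAULT_TARGET_TERMS = (
    "Hypothyroidism",
    "Blood thyroid stimulating hormone increased",
)
_DEFAULT_FILLER_TERMS = (
    "Nausea", "Headache", "Fatigue", "Rash", "Dizziness", "Diarrhoea",
)
_DEFAULT_FILLER_DRUGS = (
    "ASPIRIN", "METFORMIN", "LISINOPRIL", "OMEPRAZOLE", "ATORVASTATIN",
)


@dataclass(frozen=True)
class OnsetDistribution:
    """Days from therapy start to event onset.

    ``lognormal`` (params: mu, sigma of the underlying normal), ``gamma``
    (shape, scale) or ``exponential`` (scale).  Samples are rounded to whole
    non-negative days.
    """

    name: str = "lognormal"
    params: tuple[float, ...] = (3.7, 1.0)

    def validate(self, where: str) -> None:
        if self.name not in ("lognormal", "gamma", "exponential"):
            raise ConfigurationError(
                f"{where}: unknown onset distribution {self.name!r}")
        n_expected = {"lognormal": 2, "gamma": 2, "exponential": 1}[self.name]
        if len(self.params) != n_expected:
            raise ConfigurationError(
                f"{where}: {self.name} takes {n_expected} parameter(s)")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "lognormal":
            days = rng.lognormal(self.params[0], self.params[1], size)
        elif self.name == "gamma":
            days = rng.gamma(self.params[0], self.params[1], size)
        else:
            days = rng.exponential(self.params[0], size)
        return np.maximum(np.rint(days), 0.0).astype(np.int64)

    def median(self) -> float:
        if self.name == "lognormal":
            return math.exp(self.params[0])
        if self.name == "gamma":
            # no closed form; fine approximation for shape >= 1
            k, theta = self.params
            return k * theta * (1 - 1 / (9 * k)) ** 3
        return self.params[0] * math.log(2.0)


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: exposure probability and planted true odds ratio."""

    name: str
    exposure_prob: float
    true_or: float
    onset: OnsetDistribution | None = None


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic report stream.

    Defaults describe a thyroid-dysfunction-like reporting population:
    10% baseline probability that a report is a target-event report,
    female-predominant case mix, FAERS-like per-field missingness, and a
    log-normal onset distribution with median ~40 days.
    """

    n_cases: int
    drug_catalog: list[DrugSpec] = field(default_factory=list)
    baseline_event_prob: float = 0.10
    sex_effect_or: float = 1.0  # male vs female (reference)
    age_effects: dict[str, float] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSING_RATES))
    duplicate_rate: float = 0.0
    onset_dist: OnsetDistribution = field(default_factory=OnsetDistribution)
    partial_date_rate: float = 0.02
    start_date_missing_rate: float = 0.05
    concomitant_prob: float = 0.15
    male_fraction: float = 0.34
    target_terms: tuple[str, ...] = _DEFAULT_TARGET_TERMS
    filler_terms: tuple[str, ...] = _DEFAULT_FILLER_TERMS
    filler_drugs: tuple[str, ...] = _DEFAULT_FILLER_DRUGS
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        names = [d.name for d in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ConfigurationError("drug_catalog: drug names must be unique")
        for d in self.drug_catalog:
            if not 0.0 <= d.exposure_prob <= 1.0:
                raise ConfigurationError(
                    f"drug_catalog[{d.name}].exposure_prob must be in [0, 1]")
            if d.true_or < 0:
                raise ConfigurationError(
                    f"drug_catalog[{d.name}].true_or must be >= 0")
            if d.onset is not None:
                d.onset.validate(f"drug_catalog[{d.name}].onset")
        if not 0.0 < self.baseline_event_prob < 1.0:
            raise ConfigurationError("baseline_event_prob must be in (0, 1)")
        if self.sex_effect_or < 0:
            raise ConfigurationError("sex_effect_or must be >= 0")
        for bin_label, or_value in self.age_effects.items():
            if bin_label not in AGE_BIN_LABELS:
                raise ConfigurationError(
                    f"age_effects: unknown age bin {bin_label!r}")
            if or_value < 0:
                raise ConfigurationError(
                    f"age_effects[{bin_label}] must be >= 0")
        for fld in ("sex", "age", "weight", "occupation"):
            rate = self.missing_rates.get(fld, 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"missing_rates[{fld}] must be in [0, 1]")
        for fld in ("duplicate_rate", "partial_date_rate",
                    "start_date_missing_rate", "concomitant_prob",
                    "male_fraction"):
            if not 0.0 <= getattr(self, fld) <= 1.0:
                raise ConfigurationError(f"{fld} must be in [0, 1]")
        self.onset_dist.validate("onset_dist")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        catalog = []
        for item in d.pop("drugs", d.pop("drug_catalog", [])):
            onset = item.get("onset")
            if onset is not None:
                onset = OnsetDistribution(onset["name"],
                                          tuple(onset["params"]))
            catalog.append(DrugSpec(str(item["name"]),
                                    float(item["exposure_prob"]),
                                    float(item["true_or"]), onset))
        if "onset_dist" in d:
            od = d.pop("onset_dist")
            d["onset_dist"] = OnsetDistribution(od["name"], tuple(od["params"]))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown generator fields: {sorted(unknown)}")
        return cls(drug_catalog=catalog, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PlantedTruth:
    """The exact effect sizes the generator used (seed-independent)."""

    drug_or: dict[str, float]
    sex_effect_or: float
    age_effects: dict[str, float]
    onset: dict[str, OnsetDistribution]
    baseline_event_prob: float


@dataclass
class SimulatedCases:
    """Case-level ground truth before any FAERS formatting or missingness."""

    cases: pd.DataFrame       # caseid, male, age, weight, occp, event, onset_days, start_offset
    exposures: pd.DataFrame   # boolean, one column per catalog drug
    config: GeneratorConfig


@dataclass
class FaersTables:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    truth_cases: pd.DataFrame
    truth_params: pd.DataFrame


def planted_truth(config: GeneratorConfig) -> PlantedTruth:
    """Return the effect sizes the generator plants; independent of seed."""
    config.validate()
    age = {label: config.age_effects.get(label, 1.0)
           for label in AGE_BIN_LABELS[1:]}
    onset = {"default": config.onset_dist}
    for d in config.drug_catalog:
        if d.onset is not None:
            onset[d.name] = d.onset
    return PlantedTruth(
        drug_or={d.name: d.true_or for d in config.drug_catalog},
        sex_effect_or=config.sex_effect_or,
        age_effects=age,
        onset=onset,
        baseline_event_prob=config.baseline_event_prob,
    )


def _age_bin_labels(age: np.ndarray) -> np.ndarray:
    """Map true ages to the package's strata; <36 is the reference bin."""
    edges = (0.0,) + AGE_BIN_EDGES
    idx = np.digitize(age, edges[1:-1], right=False)
    return np.asarray(AGE_BIN_LABELS, dtype=object)[idx]


def _simulate(config: GeneratorConfig, rng: np.random.Generator) -> SimulatedCases:
    n = config.n_cases
    caseid = np.arange(10_000_001, 10_000_001 + n, dtype=np.int64)

    male = rng.random(n) < config.male_fraction
    age = np.clip(rng.normal(55.0, 18.0, n), 1.0, 119.0)
    weight = np.clip(rng.normal(72.0, 16.0, n), 35.0, 160.0)
    occp_idx = rng.choice(len(_OCCUPATIONS), size=n,
                          p=np.asarray(_OCCUPATION_PROBS) /
                          np.sum(_OCCUPATION_PROBS))
    occp = np.asarray(_OCCUPATIONS, dtype=object)[occp_idx]

    drugs = config.drug_catalog
    k = len(drugs)
    if k:
        probs = np.asarray([d.exposure_prob for d in drugs])
        exposed = rng.random((n, k)) < probs
        log_or = np.log(np.asarray([max(d.true_or, 1e-300) for d in drugs]))
    else:
        exposed = np.zeros((n, 0), dtype=bool)
        log_or = np.zeros(0)

    # Logistic event model: every planted effect is a conditional odds ratio.
    p0 = config.baseline_event_prob
    logit = np.full(n, math.log(p0 / (1.0 - p0)))
    if config.sex_effect_or > 0:
        logit += male * math.log(config.sex_effect_or)
    bins = _age_bin_labels(age)
    for label, or_value in config.age_effects.items():
        if label == AGE_BIN_LABELS[0]:
            continue  # reference bin
        logit += (bins == label) * math.log(max(or_value, 1e-300))
    if k:
        logit += exposed @ log_or
    event = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    # Therapy-start to onset days; drug-specific distributions take
    # precedence in catalog order for each case's first such exposure.
    onset = config.onset_dist.sample(rng, n)
    assigned = np.zeros(n, dtype=bool)
    for j, d in enumerate(drugs):
        if d.onset is None:
            continue
        mask = exposed[:, j] & ~assigned
        if mask.any():
            onset[mask] = d.onset.sample(rng, int(mask.sum()))
            assigned |= mask
    start_offset = rng.integers(0, _MAX_START_OFFSET, n)

    cases = pd.DataFrame({
        "caseid": caseid,
        "male": male,
        "age": age,
        "weight": weight,
        "occp": occp,
        "age_bin": bins,
        "event": event,
        "onset_days": onset,
        "start_offset": start_offset,
    })
    exposures = pd.DataFrame(exposed, columns=[d.name for d in drugs])
    exposures.insert(0, "caseid", caseid)
    exposures = exposures.set_index("caseid")
    return SimulatedCases(cases=cases, exposures=exposures, config=config)


def simulate_cases(config: GeneratorConfig) -> SimulatedCases:
    """Draw the case-level population (ground truth, no FAERS formatting)."""
    config.validate()
    return _simulate(config, np.random.default_rng(config.seed))


def _fmt_date(dates: pd.Series, partial: np.ndarray) -> np.ndarray:
    """FAERS integer dates: YYYYMMDD, degraded to YYYYMM where partial."""
    full = dates.dt.strftime("%Y%m%d").to_numpy(dtype=object)
    month = dates.dt.strftime("%Y%m").to_numpy(dtype=object)
    return np.where(partial, month, full)


def generate_reports(config: GeneratorConfig) -> FaersTables:
    """Generate the four FAERS-style tables plus the planted-truth tables.

    Identical config (including seed) yields byte-identical tables when
    written with :func:`write_tables`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sim = _simulate(config, rng)
    cases = sim.cases
    n = len(cases)
    rates = {**_DEFAULT_MISSING_RATES, **config.missing_rates}

    dup = rng.random(n) < config.duplicate_rate
    version = np.where(dup, 2, 1)
    caseid = cases["caseid"].to_numpy()
    primaryid = caseid * 10 + version

    # --- DEMO ---------------------------------------------------------
    sex_rec = np.where(cases["male"], "M", "F").astype(object)
    sex_rec[rng.random(n) < rates["sex"]] = ""

    age_missing = rng.random(n) < rates["age"]
    unit_draw = rng.random(n)
    age_val = np.round(cases["age"].to_numpy()).astype(int).astype(object)
    age_cod = np.full(n, "YR", dtype=object)
    mon = unit_draw < 0.03
    age_val[mon] = np.round(cases["age"].to_numpy()[mon] * 12).astype(int)
    age_cod[mon] = "MON"
    dec = (unit_draw >= 0.03) & (unit_draw < 0.05)
    age_val[dec] = [f"{a / 10:.1f}" for a in cases["age"].to_numpy()[dec]]
    age_cod[dec] = "DEC"
    age_val = age_val.astype(object)
    age_val[age_missing] = ""
    age_cod[age_missing] = ""

    wt = np.asarray([f"{w:.1f}" for w in cases["weight"]], dtype=object)
    wt[rng.random(n) < rates["weight"]] = ""
    occp = cases["occp"].to_numpy(dtype=object).copy()
    occp[rng.random(n) < rates["occupation"]] = ""

    event_date = _EPOCH + pd.to_timedelta(
        cases["start_offset"].to_numpy() + cases["onset_days"].to_numpy(),
        unit="D")
    event_dt = _fmt_date(pd.Series(event_date),
                         rng.random(n) < config.partial_date_rate)

    demo = pd.DataFrame({
        "primaryid": primaryid,
        "caseid": caseid,
        "caseversion": version,
        "event_dt": event_dt,
        "sex": sex_rec,
        "age": age_val,
        "age_cod": age_cod,
        "wt": wt,
        "occp_cod": occp,
    })

    # --- DRUG / THER --------------------------------------------------
    # Catalog exposures (PS for the first per case, SS after), a filler PS
    # drug for cases with no catalog exposure, and occasional concomitants.
    exposed = sim.exposures.to_numpy()
    drug_names = np.asarray([d.name.upper() for d in config.drug_catalog],
                            dtype=object)
    rows_case, rows_name, rows_role = [], [], []
    if exposed.size:
        case_idx, drug_idx = np.nonzero(exposed)
        first = np.cumsum(exposed, axis=1) == 1
        role = np.where(first[case_idx, drug_idx], "PS", "SS").astype(object)
        rows_case.append(case_idx)
        rows_name.append(drug_names[drug_idx])
        rows_role.append(role)
        any_exposure = exposed.any(axis=1)
    else:
        any_exposure = np.zeros(n, dtype=bool)
    filler_pool = np.asarray(config.filler_drugs, dtype=object)
    no_exp_idx = np.nonzero(~any_exposure)[0]
    rows_case.append(no_exp_idx)
    rows_name.append(filler_pool[rng.integers(0, len(filler_pool),
                                              len(no_exp_idx))])
    rows_role.append(np.full(len(no_exp_idx), "PS", dtype=object))
    conco_idx = np.nonzero(rng.random(n) < config.concomitant_prob)[0]
    rows_case.append(conco_idx)
    rows_name.append(filler_pool[rng.integers(0, len(filler_pool),
                                              len(conco_idx))])
    rows_role.append(np.full(len(conco_idx), "C", dtype=object))

    case_idx = np.concatenate(rows_case)
    drug = pd.DataFrame({
        "caseid": caseid[case_idx],
        "primaryid": primaryid[case_idx],
        "drugname": np.concatenate(rows_name),
        "role_cod": np.concatenate(rows_role),
        "_case_idx": case_idx,
        "_conco": np.concatenate([
            np.zeros(len(case_idx) - len(conco_idx), dtype=bool),
            np.ones(len(conco_idx), dtype=bool)]),
    })
    drug = drug.sort_values(["caseid", "_conco", "drugname"],
                            kind="mergesort").reset_index(drop=True)
    drug["drug_seq"] = drug.groupby("caseid").cumcount() + 1

    m = len(drug)
    start = _EPOCH + pd.to_timedelta(
        cases["start_offset"].to_numpy()[drug["_case_idx"]], unit="D")
    offset = rng.integers(-30, 31, m)
    offset[drug["drug_seq"].to_numpy() == 1] = 0
    start = start + pd.to_timedelta(offset, unit="D")
    start_dt = _fmt_date(pd.Series(start),
                         rng.random(m) < config.partial_date_rate)
    start_dt[rng.random(m) < config.start_date_missing_rate] = ""
    ther = pd.DataFrame({
        "primaryid": drug["primaryid"],
        "caseid": drug["caseid"],
        "dsg_drug_seq": drug["drug_seq"],
        "start_dt": start_dt,
    })
    ther = ther[ther["start_dt"] != ""].reset_index(drop=True)
    # concomitants carry no therapy record
    conco_keys = set(zip(drug.loc[drug["_conco"], "primaryid"],
                         drug.loc[drug["_conco"], "drug_seq"]))
    if conco_keys:
        keep = [
            (p, s) not in conco_keys
            for p, s in zip(ther["primaryid"], ther["dsg_drug_seq"])
        ]
        ther = ther[keep].reset_index(drop=True)
    drug = drug.drop(columns=["_case_idx", "_conco"])
    drug = drug[["primaryid", "caseid", "drug_seq", "drugname", "role_cod"]]

    # --- REAC ---------------------------------------------------------
    target_pool = np.asarray(config.target_terms, dtype=object)
    filler_terms = np.asarray(config.filler_terms, dtype=object)
    event = cases["event"].to_numpy()
    ev_idx = np.nonzero(event)[0]
    nev_idx = np.nonzero(~event)[0]
    parts = []
    parts.append(pd.DataFrame({
        "caseid": caseid[ev_idx],
        "primaryid": primaryid[ev_idx],
        "pt": target_pool[rng.integers(0, len(target_pool), len(ev_idx))],
    }))
    extra_ev = ev_idx[rng.random(len(ev_idx)) < 0.5]
    parts.append(pd.DataFrame({
        "caseid": caseid[extra_ev],
        "primaryid": primaryid[extra_ev],
        "pt": filler_terms[rng.integers(0, len(filler_terms), len(extra_ev))],
    }))
    parts.append(pd.DataFrame({
        "caseid": caseid[nev_idx],
        "primaryid": primaryid[nev_idx],
        "pt": filler_terms[rng.integers(0, len(filler_terms), len(nev_idx))],
    }))
    extra_nev = nev_idx[rng.random(len(nev_idx)) < 0.4]
    parts.append(pd.DataFrame({
        "caseid": caseid[extra_nev],
        "primaryid": primaryid[extra_nev],
        "pt": filler_terms[rng.integers(0, len(filler_terms), len(extra_nev))],
    }))
    reac = pd.concat(parts, ignore_index=True)
    reac = reac.drop_duplicates().sort_values(
        ["caseid", "pt"], kind="mergesort").reset_index(drop=True)
    reac = reac[["primaryid", "caseid", "pt"]]

    # --- superseded versions -----------------------------------------
    # Each duplicated case additionally emits caseversion 1 (primaryid
    # caseid*10+1) with the age fields blanked, so the latest-version
    # deduplication rule is observable downstream.
    if dup.any():
        old_demo = demo[dup].copy()
        old_demo["caseversion"] = 1
        old_demo["primaryid"] = old_demo["caseid"] * 10 + 1
        old_demo["age"] = ""
        old_demo["age_cod"] = ""
        demo = pd.concat([demo, old_demo], ignore_index=True)
        old_pid = dict(zip(caseid[dup] * 10 + version[dup], caseid[dup] * 10 + 1))
        for name in ("drug", "reac", "ther"):
            tbl = {"drug": drug, "reac": reac, "ther": ther}[name]
            old = tbl[tbl["primaryid"].isin(old_pid)].copy()
            old["primaryid"] = old["primaryid"].map(old_pid)
            merged = pd.concat([tbl, old], ignore_index=True)
            if name == "drug":
                drug = merged
            elif name == "reac":
                reac = merged
            else:
                ther = merged

    demo = demo.sort_values(["caseid", "primaryid"],
                            kind="mergesort").reset_index(drop=True)
    drug = drug.sort_values(["caseid", "primaryid", "drug_seq"],
                            kind="mergesort").reset_index(drop=True)
    reac = reac.sort_values(["caseid", "primaryid", "pt"],
                            kind="mergesort").reset_index(drop=True)
    ther = ther.sort_values(["caseid", "primaryid", "dsg_drug_seq"],
                            kind="mergesort").reset_index(drop=True)

    # --- truth tables -------------------------------------------------
    truth_cases = pd.DataFrame({
        "caseid": caseid,
        "primaryid": primaryid,
        "event": event.astype(int),
        "sex": np.where(cases["male"], "M", "F"),
        "age": [f"{a:.2f}" for a in cases["age"]],
        "age_bin": cases["age_bin"],
        "onset_days": cases["onset_days"],
    })
    for d in config.drug_catalog:
        truth_cases[f"exposed_{d.name}"] = sim.exposures[d.name].to_numpy().astype(int)

    truth = planted_truth(config)
    rows = [("baseline_event_prob", "", f"{truth.baseline_event_prob:.10g}"),
            ("sex_effect_or", "male_vs_female", f"{truth.sex_effect_or:.10g}")]
    for label, v in truth.age_effects.items():
        rows.append(("age_effect_or", label, f"{v:.10g}"))
    for name, v in truth.drug_or.items():
        rows.append(("drug_or", name, f"{v:.10g}"))
    for name, od in truth.onset.items():
        rows.append(("onset_dist", name,
                     od.name + ":" + ",".join(f"{p:.10g}" for p in od.params)))
    truth_params = pd.DataFrame(rows, columns=["kind", "name", "value"])

    return FaersTables(demo=demo, drug=drug, reac=reac, ther=ther,
                       truth_cases=truth_cases, truth_params=truth_params)


def standard_recovery_config(n_cases: int = 50_000,
                             seed: int = 20_240_704) -> GeneratorConfig:
    """The package's reference recovery benchmark: 10 drugs with a true
    odds ratio of 5 and 40 null drugs (all at 2% exposure), baseline event
    probability 0.10, male-vs-female odds ratio 0.7, 5% duplicate versions.

    Downstream recovery checks (screen, LASSO, logistic) are run against
    this population; the drugs named ``trudrug??`` are the planted positives.
    """
    catalog = [DrugSpec(f"trudrug{i:02d}", 0.02, 5.0) for i in range(10)]
    catalog += [DrugSpec(f"nuldrug{i:02d}", 0.02, 1.0) for i in range(40)]
    return GeneratorConfig(
        n_cases=n_cases, drug_catalog=catalog, baseline_event_prob=0.10,
        sex_effect_or=0.7, duplicate_rate=0.05, seed=seed)


def write_tables(tables: FaersTables, outdir: str | Path,
                 quarter: str = "24Q4") -> dict[str, Path]:
    """Write the $-delimited quarterly files plus the truth tables.

    File names follow the FAERS convention (``DEMO24Q4.txt`` etc.).  Output
    is deterministic: same tables, same bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, df in (("demo", tables.demo), ("drug", tables.drug),
                    ("reac", tables.reac), ("ther", tables.ther)):
        path = outdir / f"{key.upper()}{quarter}.txt"
        df.to_csv(path, sep="$", index=False, lineterminator="\n",
                  encoding="latin-1")
        paths[key] = path
    for key, df in (("truth_cases", tables.truth_cases),
                    ("truth_params", tables.truth_params)):
        path = outdir / f"{key.upper()}.txt"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        paths[key] = path
    return paths
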