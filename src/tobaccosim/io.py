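"""Plain-text persistence: bundles, scenarios and projection results.

Everything is long-format CSV (age, sex, [class/disease/measure], value)
plus a small JSON manifest naming the tables — diffable, language-neutral
and lossless (floats are written with shortest round-trip repr).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import PopulationState, ProjectionResult
from .types import (AgeSexTable, Demography, DiseaseDefinition, InputBundle,
                    MortalitySpec, ScenarioSpec, SEXES,
                    SmokingStateDistribution, TransitionRateSet, class_labels)
from .validate import BundleValidationError, Violation, raise_on_errors, validate_bundle

BUNDLE_MANIFEST = "manifest.json"
RESULT_MANIFEST = "run_manifest.json"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _age_sex_frame(table: AgeSexTable) -> pd.DataFrame:
    ages = table.ages
    return pd.DataFrame({
        "age": np.repeat(ages, 2),
        "sex": np.tile(SEXES, len(ages)),
        "value": table.values.ravel(),
    })


def _frame_to_age_sex(df: pd.DataFrame, table_name: str, age_max: int) -> AgeSexTable:
    pivot = df.pivot_table(index="age", columns="sex", values="value",
                           aggfunc="first").reindex(
        index=np.arange(age_max + 1), columns=list(SEXES))
    if pivot.isna().any().any():
        a, s = np.argwhere(pivot.isna().values)[0]
        raise BundleValidationError([Violation(
            table_name, f"age {int(pivot.index[a])}, {pivot.columns[s]}",
            "missing (age, sex) cell")])
    return AgeSexTable(pivot.values)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # %.17g guarantees exact float64 round trips through text
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def write_bundle(bundle: InputBundle, path: str | Path) -> None:
    """Write a bundle as a directory of long-format CSVs plus a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    labels = class_labels(bundle.n_quit_classes)
    tables: dict[str, str] = {}

    def put(name, df):
        fname = f"{name}.csv"
        _write_csv(df, path / fname)
        tables[name] = fname

    put("population", _age_sex_frame(bundle.demography.population))
    nb = bundle.demography.newborns
    put("newborns", pd.DataFrame({
        "step": np.repeat(np.arange(1, nb.shape[0] + 1), 2),
        "sex": np.tile(SEXES, nb.shape[0]),
        "value": nb.ravel(),
    }))
    put("mortality", _age_sex_frame(bundle.mortality.m_total))

    m = bundle.smoking.as_matrix()
    A, _, C = m.shape
    put("smoking", pd.DataFrame({
        "age": np.repeat(np.arange(A), 2 * C),
        "sex": np.tile(np.repeat(SEXES, C), A),
        "class": np.tile(labels, 2 * A),
        "value": m.ravel(),
    }))

    rate_frames = []
    for rname in ("start", "quit", "restart"):
        f = _age_sex_frame(getattr(bundle.rates, rname))
        f.insert(2, "rate", rname)
        rate_frames.append(f)
    put("rates", pd.concat(rate_frames, ignore_index=True))

    rr_cols = labels[1:]  # current, former_k (never is identically 1)
    ac = np.column_stack([bundle.mortality.rr_allcause_current,
                          bundle.mortality.rr_allcause_former])
    put("mortality_rr", pd.DataFrame({
        "age": np.repeat(np.arange(A), len(rr_cols)),
        "class": np.tile(rr_cols, A),
        "value": ac.ravel(),
    }))

    for d in bundle.diseases:
        ipm = []
        for measure, tab in (("incidence", d.incidence),
                             ("prevalence", d.prevalence),
                             ("excess_mortality", d.excess_mortality)):
            f = _age_sex_frame(tab)
            f.insert(2, "measure", measure)
            ipm.append(f)
        put(f"disease_{d.name}_ipm", pd.concat(ipm, ignore_index=True))
        rr = np.column_stack([d.rr_current, d.rr_former])
        put(f"disease_{d.name}_rr", pd.DataFrame({
            "age": np.repeat(np.arange(A), len(rr_cols)),
            "class": np.tile(rr_cols, A),
            "value": rr.ravel(),
        }))

    manifest = {
        "format": "tobaccosim-bundle",
        "version": 1,
        "baseline_year": bundle.baseline_year,
        "age_max": bundle.age_max,
        "n_quit_classes": bundle.n_quit_classes,
        "diseases": bundle.disease_names(),
        "tables": tables,
    }
    (path / BUNDLE_MANIFEST).write_text(json.dumps(manifest, indent=2) + "\n")


def _read_table(path: Path, tables: dict, name: str) -> pd.DataFrame:
    if name not in tables:
        raise BundleValidationError([Violation(name, "manifest",
                                               "table missing from manifest")])
    f = path / tables[name]
    if not f.exists():
        raise BundleValidationError([Violation(name, str(f), "table file missing")])
    return _read_csv(f)


def _read_rr(df: pd.DataFrame, table_name: str, age_max: int, labels):
    pivot = df.pivot_table(index="age", columns="class", values="value",
                           aggfunc="first").reindex(
        index=np.arange(age_max + 1), columns=labels)
    if pivot.isna().any().any():
        a, c = np.argwhere(pivot.isna().values)[0]
        raise BundleValidationError([Violation(
            table_name, f"age {int(pivot.index[a])}, class {pivot.columns[c]}",
            "missing relative-risk cell")])
    return pivot.values[:, 0], pivot.values[:, 1:]


def load_bundle(path: str | Path, validate: bool = True) -> InputBundle:
    """Load and validate a bundle directory written by :func:`write_bundle`.

    Raises :class:`~tobaccosim.validate.BundleValidationError` naming the
    offending table and cell on missing tables, missing cells or
    out-of-range values.
    """
    path = Path(path)
    mf = path / BUNDLE_MANIFEST
    if not mf.exists():
        raise FileNotFoundError(f"no bundle manifest at {mf}")
    manifest = json.loads(mf.read_text())
    age_max = int(manifest["age_max"])
    K = int(manifest["n_quit_classes"])
    labels = class_labels(K)

    population = _frame_to_age_sex(_read_table(path, manifest["tables"], "population"),
                                   "population", age_max)
    nb_df = _read_table(path, manifest["tables"], "newborns")
    nb = nb_df.pivot_table(index="step", columns="sex", values="value",
                           aggfunc="first")[list(SEXES)].values
    m_total = _frame_to_age_sex(_read_table(path, manifest["tables"], "mortality"),
                                "mortality", age_max)

    sm = _read_table(path, manifest["tables"], "smoking")
    smat = np.empty((age_max + 1, 2, 2 + K))
    pivot = sm.pivot_table(index=["age", "sex"], columns="class", values="value",
                           aggfunc="first").reindex(columns=labels)
    full_index = pd.MultiIndex.from_product(
        [np.arange(age_max + 1), SEXES], names=["age", "sex"])
    pivot = pivot.reindex(full_index)
    if pivot.isna().any().any():
        (a, s), c = next(
            (idx, col) for idx, row in pivot.iterrows()
            for col in pivot.columns if pd.isna(row[col]))
        raise BundleValidationError([Violation(
            "smoking", f"age {a}, {s}, class {c}", "missing cell")])
    smat = pivot.values.reshape(age_max + 1, 2, 2 + K)
    smoking = SmokingStateDistribution.from_matrix(smat)

    rt = _read_table(path, manifest["tables"], "rates")
    rate_tables = {}
    for rname in ("start", "quit", "restart"):
        rate_tables[rname] = _frame_to_age_sex(
            rt[rt["rate"] == rname], f"rates[{rname}]", age_max)
    rates = TransitionRateSet(rate_tables["start"], rate_tables["quit"],
                              rate_tables["restart"])

    rr_labels = labels[1:]
    ac_cur, ac_for = _read_rr(_read_table(path, manifest["tables"], "mortality_rr"),
                              "mortality_rr", age_max, rr_labels)
    mortality = MortalitySpec(m_total, ac_cur, ac_for)

    diseases = []
    for name in manifest["diseases"]:
        ipm = _read_table(path, manifest["tables"], f"disease_{name}_ipm")
        parts = {}
        for measure in ("incidence", "prevalence", "excess_mortality"):
            parts[measure] = _frame_to_age_sex(
                ipm[ipm["measure"] == measure], f"disease_{name}_ipm[{measure}]",
                age_max)
        rr_cur, rr_for = _read_rr(
            _read_table(path, manifest["tables"], f"disease_{name}_rr"),
            f"disease_{name}_rr", age_max, rr_labels)
        diseases.append(DiseaseDefinition(name, parts["incidence"],
                                          parts["prevalence"],
                                          parts["excess_mortality"],
                                          rr_cur, rr_for))

    bundle = InputBundle(demography=Demography(population, nb), smoking=smoking,
                         rates=rates, diseases=tuple(diseases),
                         mortality=mortality,
                         baseline_year=int(manifest["baseline_year"]))
    if validate:
        raise_on_errors(validate_bundle(bundle))
    return bundle


def bundle_hash(bundle: InputBundle) -> str:
    """Deterministic sha256 fingerprint of all bundle arrays."""
    h = hashlib.sha256()
    parts = [bundle.demography.population.values, bundle.demography.newborns,
             bundle.smoking.as_matrix(), bundle.rates.start.values,
             bundle.rates.quit.values, bundle.rates.restart.values,
             bundle.mortality.m_total.values,
             bundle.mortality.rr_allcause_current,
             bundle.mortality.rr_allcause_former]
    for d in bundle.diseases:
        parts += [d.incidence.values, d.prevalence.values,
                  d.excess_mortality.values, d.rr_current, d.rr_former]
    for a in parts:
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    h.update(str(bundle.baseline_year).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def load_scenario(path: str | Path) -> ScenarioSpec:
    """Read a scenario spec from a YAML or JSON file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    return ScenarioSpec.from_dict(data)


def write_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(result: ProjectionResult, path: str | Path,
                  seed: int | None = None) -> None:
    """Write a projection as tidy long-format tables plus a run manifest.

    The engine is deterministic, so two runs from the same bundle and
    scenario produce byte-identical data files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    C = result.states[0].n_classes
    labels = class_labels(C - 2)
    A = result.states[0].count.shape[0]

    occ_rows, prev_rows = [], []
    for year, state in zip(result.years, result.states):
        occ_rows.append(pd.DataFrame({
            "year": int(year),
            "age": np.repeat(np.arange(A), 2 * C),
            "sex": np.tile(np.repeat(SEXES, C), A),
            "class": np.tile(labels, 2 * A),
            "count": state.count.ravel(),
        }))
        for j, dname in enumerate(result.disease_names):
            prev_rows.append(pd.DataFrame({
                "year": int(year),
                "disease": dname,
                "age": np.repeat(np.arange(A), 2 * C),
                "sex": np.tile(np.repeat(SEXES, C), A),
                "class": np.tile(labels, 2 * A),
                "value": state.disease_prev[j].ravel(),
            }))
    _write_csv(pd.concat(occ_rows, ignore_index=True), path / "occupancy.csv")
    if prev_rows:
        _write_csv(pd.concat(prev_rows, ignore_index=True),
                   path / "disease_prevalence.csv")

    h = result.horizon
    _write_csv(pd.DataFrame({
        "year": np.repeat(result.years[:h], A * 2),
        "age": np.tile(np.repeat(np.arange(A), 2), h),
        "sex": np.tile(SEXES, h * A),
        "deaths": result.deaths.ravel(),
    }), path / "deaths.csv")
    _write_csv(pd.DataFrame({
        "year": np.repeat(result.years[:h], 2),
        "sex": np.tile(SEXES, h),
        "count": result.exits.ravel(),
    }), path / "exits.csv")

    manifest = {
        "format": "tobaccosim-result",
        "software_version": __version__,
        "scenario": result.scenario.to_dict(),
        "baseline_year": result.baseline_year,
        "horizon": h,
        "diseases": result.disease_names,
        "bundle_hash": result.bundle_hash,
        "seed": seed,
    }
    (path / RESULT_MANIFEST).write_text(json.dumps(manifest, indent=2) + "\n")


def read_results(path: str | Path) -> ProjectionResult:
    """Reload a result directory written by :func:`write_results`."""
    path = Path(path)
    manifest = json.loads((path / RESULT_MANIFEST).read_text())
    disease_names = list(manifest["diseases"])
    h = int(manifest["horizon"])
    base = int(manifest["baseline_year"])
    years = base + np.arange(h + 1)

    occ = _read_csv(path / "occupancy.csv")
    labels = list(occ["class"].unique())
    C = len(labels)
    A = int(occ["age"].max()) + 1
    prev = None
    if disease_names:
        prev = _read_csv(path / "disease_prevalence.csv")

    states = []
    for year in years:
        sub = occ[occ["year"] == year]
        count = sub["count"].to_numpy().reshape(A, 2, C)
        dprev = np.zeros((len(disease_names), A, 2, C))
        if prev is not None:
            psub = prev[prev["year"] == year]
            for j, dname in enumerate(disease_names):
                dprev[j] = psub[psub["disease"] == dname]["value"] \
                    .to_numpy().reshape(A, 2, C)
        states.append(PopulationState(count, dprev, int(year)))

    deaths = np.zeros((h, A, 2))
    exits = np.zeros((h, 2))
    if h > 0:
        ddf = _read_csv(path / "deaths.csv")
        deaths = ddf["deaths"].to_numpy().reshape(h, A, 2)
        xdf = _read_csv(path / "exits.csv")
        exits = xdf["count"].to_numpy().reshape(h, 2)

    return ProjectionResult(
        years=years, states=states, deaths=deaths, exits=exits,
        scenario=ScenarioSpec.from_dict(manifest["scenario"]),
        disease_names=disease_names,
        bundle_hash=manifest.get("bundle_hash", ""))
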