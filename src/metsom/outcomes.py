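"""Disease status derivation and subgroup outcome contrasts.

Events are matched to diseases by three-character ICD-10-style code
prefixes. The first matching event at or before baseline makes a disease
prevalent; the first matching event after baseline makes it incident with
time measured in years from baseline; everyone else is censored at the
earliest of the administrative censor date, their own follow-up end and
death. Prevalent cases are excluded from that disease's incident risk set.

Contrasts versus the reference subgroup are fitted one subgroup at a time:
logistic regression (odds ratios) for prevalent status and Cox proportional
hazards (Efron ties, Wald intervals) for incident status, both adjusted for
age, sex and assessment center.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from lifelines import CoxPHFitter

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseDefinition",
    "default_definitions",
    "load_definitions",
    "save_definitions",
    "expand_code_range",
    "derive_disease_status",
    "prevalence_odds_ratios",
    "incidence_hazard_ratios",
    "incidence_rates",
    "binary_panel",
    "CARDIOMETABOLIC",
]

_PREFIX_RE = re.compile(r"^[A-Z][0-9]{2}$")
CARDIOMETABOLIC = ("ihd", "stroke", "diabetes", "hypertension")
_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class DiseaseDefinition:
    name: str
    code_prefixes: tuple[str, ...]
    sources: tuple[str, ...] | None = None  # None = any source counts

    def __post_init__(self) -> None:
        if not self.code_prefixes:
            raise ValueError(f"disease {self.name!r} needs at least one code prefix")
        bad = [p for p in self.code_prefixes if not _PREFIX_RE.match(p)]
        if bad:
            raise ValueError(f"invalid ICD-10 prefix(es) for {self.name!r}: {bad}")


def expand_code_range(start: str, stop: str) -> tuple[str, ...]:
    """Inclusive range of three-character codes sharing a letter, e.g.
    ("I20", "I25") -> I20..I25."""
    if start[0] != stop[0]:
        raise ValueError("code range must stay within one letter")
    return tuple(f"{start[0]}{i:02d}" for i in range(int(start[1:]), int(stop[1:]) + 1))


def default_definitions() -> list[DiseaseDefinition]:
    """Editable defaults approximating common register phenotypes; real
    analyses should supply their own curated code lists."""
    return [
        DiseaseDefinition("ihd", expand_code_range("I20", "I25")),
        DiseaseDefinition("stroke", expand_code_range("I60", "I64")),
        DiseaseDefinition("diabetes", expand_code_range("E10", "E14")),
        DiseaseDefinition("hypertension", expand_code_range("I10", "I15")),
        DiseaseDefinition("dementia", expand_code_range("F00", "F03") + ("G30",)),
        DiseaseDefinition("rheumatoid_arthritis", expand_code_range("M05", "M06")),
        DiseaseDefinition("cancer", expand_code_range("C00", "C97")),
    ]


def load_definitions(path: str | Path) -> list[DiseaseDefinition]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for name, spec in raw.items():
        prefixes: list[str] = []
        for item in spec.get("codes", []):
            if isinstance(item, str) and "-" in item:
                a, b = item.split("-")
                prefixes.extend(expand_code_range(a.strip(), b.strip()))
            else:
                prefixes.append(str(item).strip())
        sources = tuple(spec["sources"]) if "sources" in spec else None
        defs.append(DiseaseDefinition(name, tuple(prefixes), sources))
    return defs


def save_definitions(defs: list[DiseaseDefinition], path: str | Path) -> None:
    raw = {
        d.name: {
            "codes": list(d.code_prefixes),
            **({"sources": list(d.sources)} if d.sources else {}),
        }
        for d in defs
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def derive_disease_status(
    events: pd.DataFrame,
    participants: pd.DataFrame,
    definitions: list[DiseaseDefinition],
    censor_date: str | pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Long person-disease table with prevalent/incident flags and follow-up.

    Columns: id, disease, prevalent, incident, time_years, event, at_risk.
    ``at_risk`` is False for prevalent cases (excluded from the incident risk
    set); for everyone else ``time_years``/``event`` describe the incident
    analysis (event time, or censoring at min(censor date, follow-up end,
    death)). Events with codes matching no definition, or dated after the
    censor limit, are ignored.
    """
    part = participants.set_index("id") if "id" in participants.columns else participants
    baseline = pd.to_datetime(part["baseline_date"])
    if censor_date is None:
        censor_date = pd.to_datetime(events["date"]).max() if len(events) else baseline.max()
    censor_date = pd.Timestamp(censor_date)
    if (baseline > censor_date).any():
        raise ValueError("censor_date precedes some baseline dates")
    person_censor = pd.Series(censor_date, index=part.index)
    for col in ("followup_end_date", "death_date"):
        if col in part.columns:
            other = pd.to_datetime(part[col])
            person_censor = person_censor.where(
                other.isna() | (person_censor <= other), other
            )

    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ev = ev[ev["id"].isin(part.index)]
    ev["prefix"] = ev["code"].astype(str).str[:3]
    known = set().union(*(d.code_prefixes for d in definitions))
    n_unmatched = int((~ev["prefix"].isin(known)).sum())
    if n_unmatched:
        logger.info("ignoring %d event(s) with codes matching no definition", n_unmatched)

    rows = []
    for d in definitions:
        sub = ev[ev["prefix"].isin(set(d.code_prefixes))]
        if d.sources is not None:
            sub = sub[sub["source"].isin(set(d.sources))]
        sub = sub[sub["date"] <= sub["id"].map(person_censor)]
        first = sub.groupby("id")["date"].min()
        first = first.reindex(part.index)
        prevalent = first.notna() & (first <= baseline)
        incident = first.notna() & (first > baseline)
        end = pd.Series(
            np.where(incident, first, person_censor), index=part.index
        )
        time_years = (pd.to_datetime(end) - baseline).dt.days / _DAYS_PER_YEAR
        time_years = time_years.clip(lower=0.0)
        time_years[prevalent] = np.nan
        rows.append(
            pd.DataFrame(
                {
                    "id": part.index,
                    "disease": d.name,
                    "prevalent": prevalent.to_numpy(),
                    "incident": incident.to_numpy(),
                    "time_years": time_years.to_numpy(),
                    "event": incident.to_numpy().astype(int),
                    "at_risk": (~prevalent).to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _covariate_design(covars: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=covars.index)
    X["age"] = covars["age"].astype(float)
    if covars["sex"].nunique() > 1:
        X["sex_male"] = (covars["sex"].astype(str) == "male").astype(float)
    if "center" in covars.columns and covars["center"].nunique() > 1:
        dummies = pd.get_dummies(covars["center"], prefix="center", drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def _contrast_rows(
    fit_one,
    disease_table: pd.DataFrame,
    subgroup_of: pd.Series,
    reference: str,
) -> pd.DataFrame:
    groups = sorted(subgroup_of.dropna().unique())
    if reference not in groups:
        raise ValueError(f"reference subgroup {reference!r} not present")
    records = []
    for disease, sub_dt in disease_table.groupby("disease"):
        sub_dt = sub_dt.set_index("id")
        records.append(
            {
                "disease": disease, "subgroup": reference, "estimate": 1.0,
                "ci_low": 1.0, "ci_high": 1.0, "p_value": np.nan, "n": int(
                    (subgroup_of == reference).sum()
                ), "note": "reference",
            }
        )
        for g in groups:
            if g == reference:
                continue
            rec = fit_one(disease, sub_dt, g)
            records.append(rec)
    out = pd.DataFrame(records)
    return out.sort_values(["disease", "subgroup"], ignore_index=True)


def prevalence_odds_ratios(
    disease_table: pd.DataFrame,
    subgroup_of: pd.Series,
    covariates: pd.DataFrame,
    reference: str,
) -> pd.DataFrame:
    """Adjusted odds ratios for prevalent disease, one subgroup versus the
    reference at a time (logistic regression, Wald 95% CIs)."""
    covariates = covariates.set_index("id") if "id" in covariates.columns else covariates

    def fit_one(disease: str, sub_dt: pd.DataFrame, g: str) -> dict:
        ids = subgroup_of[(subgroup_of == g) | (subgroup_of == reference)].index
        ids = ids.intersection(sub_dt.index)
        y = sub_dt.loc[ids, "prevalent"].astype(int)
        base = {"disease": disease, "subgroup": g, "n": int(len(ids))}
        if y.sum() == 0 or y.sum() == len(y):
            return {**base, "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "note": "non-estimable: no outcome variation"}
        X = _covariate_design(covariates.loc[ids])
        X.insert(0, "subgroup_ind", (subgroup_of.loc[ids] == g).astype(float))
        X = sm.add_constant(X, prepend=True)
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    res = sm.Logit(y, X).fit(disp=0, maxiter=500, method="bfgs")
            beta = res.params["subgroup_ind"]
            se = res.bse["subgroup_ind"]
            return {**base, "estimate": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                    "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                    "p_value": float(res.pvalues["subgroup_ind"]), "note": ""}
        except Exception as exc:  # separation etc.
            return {**base, "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "note": f"non-estimable: {exc}"}

    return _contrast_rows(fit_one, disease_table, subgroup_of, reference)


def incidence_hazard_ratios(
    disease_table: pd.DataFrame,
    subgroup_of: pd.Series,
    covariates: pd.DataFrame,
    reference: str,
) -> pd.DataFrame:
    """Adjusted hazard ratios for incident disease versus the reference
    subgroup (Cox proportional hazards, Efron tie handling, Wald CIs).
    Prevalent cases are excluded from the risk set."""
    covariates = covariates.set_index("id") if "id" in covariates.columns else covariates

    def fit_one(disease: str, sub_dt: pd.DataFrame, g: str) -> dict:
        ids = subgroup_of[(subgroup_of == g) | (subgroup_of == reference)].index
        ids = ids.intersection(sub_dt.index[sub_dt["at_risk"]])
        df = sub_dt.loc[ids, ["time_years", "event"]].copy()
        base = {"disease": disease, "subgroup": g, "n": int(len(ids))}
        ev_g = df.loc[subgroup_of.loc[ids] == g, "event"].sum()
        ev_ref = df.loc[subgroup_of.loc[ids] == reference, "event"].sum()
        if ev_g == 0 or ev_ref == 0:
            return {**base, "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "note": "non-estimable: no events in a stratum"}
        X = _covariate_design(covariates.loc[ids])
        X.insert(0, "subgroup_ind", (subgroup_of.loc[ids] == g).astype(float))
        df = pd.concat([df, X], axis=1)
        df = df[df["time_years"] > 0]
        try:
            import warnings as _w

            cph = CoxPHFitter()
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                cph.fit(df, duration_col="time_years", event_col="event")
            beta = cph.params_["subgroup_ind"]
            se = cph.standard_errors_["subgroup_ind"]
            return {**base, "estimate": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                    "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                    "p_value": float(cph.summary.loc["subgroup_ind", "p"]), "note": ""}
        except Exception as exc:
            return {**base, "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "note": f"non-estimable: {exc}"}

    return _contrast_rows(fit_one, disease_table, subgroup_of, reference)


def incidence_rates(disease_table: pd.DataFrame, subgroup_of: pd.Series) -> pd.DataFrame:
    """Crude incidence per 1000 person-years by subgroup and disease."""
    dt = disease_table[disease_table["at_risk"]].copy()
    dt = dt[dt["id"].isin(subgroup_of.index)]
    dt["subgroup"] = dt["id"].map(subgroup_of)
    out = (
        dt.groupby(["disease", "subgroup"])
        .apply(
            lambda g: pd.Series(
                {
                    "events": int(g["event"].sum()),
                    "person_years": float(g["time_years"].sum()),
                    "rate_per_1000py": (
                        1000.0 * g["event"].sum() / g["time_years"].sum()
                        if g["time_years"].sum() > 0
                        else np.nan
                    ),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return out


def binary_panel(
    disease_table: pd.DataFrame,
    kind: str,
    diseases: tuple[str, ...] = CARDIOMETABOLIC,
) -> pd.DataFrame:
    """Person x disease 0/1 indicator panel (the multimorbidity feed).

    ``kind`` is "prevalent" or "incident"."""
    if kind not in ("prevalent", "incident"):
        raise ValueError("kind must be 'prevalent' or 'incident'")
    sub = disease_table[disease_table["disease"].isin(diseases)]
    panel = sub.pivot(index="id", columns="disease", values=kind).astype(int)
    return panel[[d for d in diseases if d in panel.columns]]
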