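"""Synthetic cohort generator.

Produces tabular cohorts with the statistical structure the downstream
analysis assumes: blocks of correlated biomarkers shifted by latent
metabolic subgroup, truncated-normal ages, a configurable sex ratio,
prevalent disease drawn from a logistic model, incident disease drawn
from exponential hazards, and a shared per-person log-normal frailty
that multiplies all disease odds and hazards and thereby induces
disease co-occurrence beyond independence.

Every quantity is driven by a single integer seed; identical
configurations produce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

__all__ = [
    "ConfigurationError",
    "BiomarkerBlock",
    "DiseaseModel",
    "SimConfig",
    "Cohort",
    "default_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "load_sim_config",
]

_EPOCH = pd.Timestamp("2006-01-01")
_RECRUIT_DAYS = 5 * 365  # recruitment window 2006-2010
_SOURCES = ("hospital", "primary_care", "self_report", "death_register")


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


@dataclass(frozen=True)
class BiomarkerBlock:
    """A named block of biomarkers sharing an equicorrelation structure.

    ``rho`` is the within-block Pearson correlation on the latent Gaussian
    scale; ``transform`` may be ``"normal"`` or ``"lognormal"`` (a monotone
    map that leaves Spearman structure untouched).
    """

    name: str
    size: int
    rho: float
    transform: str = "normal"


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic prevalence and exponential incidence model for one disease.

    ``prevalence_logit`` is the baseline log-odds of prevalent disease at
    reference covariates; ``baseline_hazard`` is the reference hazard in
    events per person-year. ``subgroup_log_or``/``subgroup_log_hr`` give the
    per-subgroup additive effects on the log scale (length ``n_subgroups``).
    """

    name: str
    code: str
    prevalence_logit: float
    subgroup_log_or: tuple[float, ...]
    baseline_hazard: float
    subgroup_log_hr: tuple[float, ...]


@dataclass
class SimConfig:
    n_participants: int
    biomarker_blocks: list[BiomarkerBlock]
    subgroup_effects: np.ndarray  # (n_subgroups, n_blocks), SD units
    disease_models: list[DiseaseModel]
    n_subgroups: int = 6
    subgroup_probs: tuple[float, ...] | None = None
    age_mean: float = 57.0
    age_sd: float = 8.0
    age_bounds: tuple[float, float] = (37.0, 73.0)
    prop_female: float = 0.53
    n_centers: int = 10
    frailty_sd: float = 0.5
    followup_years_range: tuple[float, float] = (9.8, 11.8)
    death_hazard: float = 0.0058
    missing_rate: float = 0.03
    include_mets_markers: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be > 0")
        if self.n_subgroups <= 0:
            raise ConfigurationError("n_subgroups must be > 0")
        if not self.biomarker_blocks:
            raise ConfigurationError("biomarker_blocks must be non-empty")
        for b in self.biomarker_blocks:
            if b.size <= 0:
                raise ConfigurationError(f"biomarker_blocks[{b.name}].size must be > 0")
            if not (0.0 <= b.rho < 1.0):
                raise ConfigurationError(f"biomarker_blocks[{b.name}].rho must be in [0, 1)")
            if b.transform not in ("normal", "lognormal"):
                raise ConfigurationError(f"biomarker_blocks[{b.name}].transform unknown")
        eff = np.asarray(self.subgroup_effects, dtype=float)
        if eff.shape != (self.n_subgroups, len(self.biomarker_blocks)):
            raise ConfigurationError(
                "subgroup_effects must have shape (n_subgroups, n_blocks); got "
                f"{eff.shape}"
            )
        if self.subgroup_probs is not None:
            p = np.asarray(self.subgroup_probs, dtype=float)
            if len(p) != self.n_subgroups or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ConfigurationError("subgroup_probs must be a simplex of length n_subgroups")
        if not (0.0 < self.prop_female < 1.0):
            raise ConfigurationError("prop_female must be in (0, 1)")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be > 0")
        lo, hi = self.age_bounds
        if not lo < hi:
            raise ConfigurationError("age_bounds must be increasing")
        if self.n_centers <= 0:
            raise ConfigurationError("n_centers must be > 0")
        if self.frailty_sd < 0:
            raise ConfigurationError("frailty_sd must be >= 0")
        flo, fhi = self.followup_years_range
        if not 0 < flo <= fhi:
            raise ConfigurationError("followup_years_range must be positive and ordered")
        if self.death_hazard < 0:
            raise ConfigurationError("death_hazard must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for d in self.disease_models:
            if d.baseline_hazard <= 0:
                raise ConfigurationError(f"disease_models[{d.name}].baseline_hazard must be > 0")
            p0 = expit(d.prevalence_logit)
            if not (0.0 < p0 < 1.0):
                raise ConfigurationError(
                    f"disease_models[{d.name}].prevalence_logit implies prevalence outside (0,1)"
                )
            if len(d.subgroup_log_or) != self.n_subgroups:
                raise ConfigurationError(f"disease_models[{d.name}].subgroup_log_or length")
            if len(d.subgroup_log_hr) != self.n_subgroups:
                raise ConfigurationError(f"disease_models[{d.name}].subgroup_log_hr length")


@dataclass
class Cohort:
    """A simulated cohort: participants, biomarkers, long event table and
    the hidden truth (subgroup + frailty) retained for testing only."""

    participants: pd.DataFrame
    biomarkers: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    mets_markers: pd.DataFrame | None = None
    config: SimConfig | None = None


def default_config(n_participants: int = 20_000, seed: int = 0, **overrides) -> SimConfig:
    """The default study conditions: 45 biomarkers in 12 blocks (6 tight
    blocks that collapse to collinearity modules, 6 loose blocks that stay
    singletons), six latent subgroups with metabolic signatures and
    subgroup-dependent disease models for IHD, stroke, diabetes and
    hypertension."""
    blocks = [
        # tight blocks (collapse under the rho^2 > 0.5 rule)
        BiomarkerBlock("apob", 5, 0.85),
        BiomarkerBlock("hdl", 4, 0.85),
        BiomarkerBlock("adiposity", 4, 0.85),
        BiomarkerBlock("liver", 4, 0.85, transform="lognormal"),
        BiomarkerBlock("urinary", 3, 0.85),
        BiomarkerBlock("inflammation", 3, 0.85, transform="lognormal"),
        # loose blocks (stay singletons)
        BiomarkerBlock("blood_pressure", 2, 0.30),
        BiomarkerBlock("glycemia", 3, 0.30),
        BiomarkerBlock("kidney", 4, 0.30),
        BiomarkerBlock("hormones", 4, 0.30),
        BiomarkerBlock("vitamins", 3, 0.30),
        BiomarkerBlock("misc", 6, 0.30),
    ]
    # rows: SG1 (high apoB + BP), SG2 (liver/TG, diabetogenic), SG3
    # (adiposity + inflammation + kidney stress), SG4 (favorable, high HDL),
    # SG5 (hormones), SG6 (urinary excretion)
    effects = np.array(
        [
            #  apob  hdl  adip liver urin infl   bp  glyc  kidn horm  vit  misc
            [1.3, -0.3, 0.3, 0.2, 0.0, 0.1, 1.0, 0.2, 0.0, 0.0, 0.0, 0.0],
            [0.4, -0.8, 0.9, 1.4, 0.0, 0.3, 0.4, 1.0, 0.1, 0.0, -0.2, 0.0],
            [0.3, -0.6, 1.2, 0.3, 0.2, 1.3, 0.5, 0.6, 0.9, 0.0, -0.3, 0.0],
            [-0.5, 1.2, -0.8, -0.4, 0.0, -0.5, -0.5, -0.4, -0.2, 0.2, 0.5, 0.0],
            [0.0, 0.3, -0.4, -0.2, 0.1, -0.2, -0.2, -0.3, 0.0, 1.3, 0.2, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.4, 0.0, 0.0, 0.1, 0.3, 0.2, 0.0, 0.1],
        ]
    )
    diseases = [
        DiseaseModel(
            "ihd", "I25", -3.8, (0.7, 0.8, 1.1, 0.0, 0.2, 0.4),
            0.004, (0.4, 0.75, 0.75, 0.0, 0.1, 0.2),
        ),
        DiseaseModel(
            "stroke", "I63", -4.8, (0.5, 0.6, 0.9, 0.0, 0.1, 0.3),
            0.0012, (0.4, 0.5, 0.65, 0.0, 0.0, 0.2),
        ),
        DiseaseModel(
            "diabetes", "E11", -4.0, (0.5, 2.5, 1.8, 0.0, 0.2, 0.6),
            0.0010, (0.5, 2.7, 2.0, 0.0, 0.1, 0.5),
        ),
        DiseaseModel(
            "hypertension", "I10", -2.5, (1.0, 1.3, 1.3, 0.0, 0.2, 0.5),
            0.008, (0.7, 0.9, 0.9, 0.0, 0.1, 0.3),
        ),
    ]
    cfg = SimConfig(
        n_participants=n_participants,
        biomarker_blocks=blocks,
        subgroup_effects=effects,
        disease_models=diseases,
        seed=seed,
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigurationError(f"unknown SimConfig field: {k}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def _draw_ages(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.age_bounds
    a = (lo - cfg.age_mean) / cfg.age_sd
    b = (hi - cfg.age_mean) / cfg.age_sd
    dist = stats.truncnorm(a, b, loc=cfg.age_mean, scale=cfg.age_sd)
    return dist.ppf(rng.uniform(size=cfg.n_participants))


def _draw_block(
    n: int, block: BiomarkerBlock, shift: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Equicorrelated Gaussian block via a single-factor construction:
    x_j = sqrt(rho)*f + sqrt(1-rho)*e_j, each column shifted by the
    per-person subgroup effect. Returns (values, latent factor)."""
    f = rng.standard_normal(n)
    e = rng.standard_normal((n, block.size))
    x = np.sqrt(block.rho) * f[:, None] + np.sqrt(1.0 - block.rho) * e
    x = x + shift[:, None]
    if block.transform == "lognormal":
        x = np.exp(x)
    return x, f + shift


def _years_to_days(y: np.ndarray | float) -> np.ndarray:
    return np.asarray(np.round(np.asarray(y) * 365.25), dtype="timedelta64[D]")


def _mets_markers(
    cfg: SimConfig,
    latents: dict[str, np.ndarray],
    sex_female: np.ndarray,
    prevalent_htn: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Physical-unit clinical measures for metabolic-syndrome scoring,
    derived from the cohort's latent block factors (or fresh noise where a
    named block is absent)."""
    n = cfg.n_participants

    def lat(name: str) -> np.ndarray:
        return latents.get(name, rng.standard_normal(n))

    adip = lat("adiposity")
    lip = lat("apob") - 0.6 * lat("hdl")
    bp = lat("blood_pressure")
    gly = lat("glycemia")
    male = ~sex_female
    waist = 88.0 + 8.0 * male + 10.0 * adip + rng.normal(0, 5.0, n)
    tg = np.exp(0.30 + 0.45 * lip + rng.normal(0, 0.35, n))
    hdl = np.clip(1.30 + 0.22 * sex_female - 0.20 * lip + rng.normal(0, 0.22, n), 0.4, None)
    sbp = 132.0 + 13.0 * bp + rng.normal(0, 9.0, n)
    dbp = 80.0 + 8.0 * bp + rng.normal(0, 6.0, n)
    glucose = np.clip(5.05 + 0.65 * gly + rng.normal(0, 0.5, n), 2.5, None)
    on_meds = prevalent_htn & (rng.uniform(size=n) < 0.7)
    return pd.DataFrame(
        {
            "waist_cm": np.clip(waist, 50.0, None),
            "triglycerides_mmol_l": tg,
            "hdl_mmol_l": hdl,
            "sbp_mmhg": np.clip(sbp, 70.0, None),
            "dbp_mmhg": np.clip(dbp, 40.0, None),
            "glucose_mmol_l": glucose,
            "on_bp_meds": on_meds.astype(int),
        }
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full cohort from the configured generative model.

    The drawing order is fixed, so a given (config, seed) pair always yields
    a bit-identical cohort.
    """
    config.validate()
    cfg = config
    n = cfg.n_participants
    rng = np.random.default_rng(cfg.seed)

    ids = np.array([f"P{i + 1:06d}" for i in range(n)])
    age = _draw_ages(cfg, rng)
    sex_female = rng.uniform(size=n) < cfg.prop_female
    center = rng.integers(0, cfg.n_centers, size=n)
    baseline = _EPOCH + pd.to_timedelta(rng.integers(0, _RECRUIT_DAYS, size=n), unit="D")

    probs = (
        np.full(cfg.n_subgroups, 1.0 / cfg.n_subgroups)
        if cfg.subgroup_probs is None
        else np.asarray(cfg.subgroup_probs, dtype=float)
    )
    subgroup = rng.choice(cfg.n_subgroups, size=n, p=probs)
    frailty = rng.normal(0.0, cfg.frailty_sd, size=n) if cfg.frailty_sd > 0 else np.zeros(n)

    effects = np.asarray(cfg.subgroup_effects, dtype=float)
    cols: list[str] = []
    mats: list[np.ndarray] = []
    latents: dict[str, np.ndarray] = {}
    for b_idx, block in enumerate(cfg.biomarker_blocks):
        x, f = _draw_block(n, block, effects[subgroup, b_idx], rng)
        latents[block.name] = f
        mats.append(x)
        cols.extend(f"{block.name}_{j + 1}" for j in range(block.size))
    X = np.column_stack(mats)
    # mild age/sex structure so the residualization step has work to do
    age_z = (age - cfg.age_mean) / cfg.age_sd
    X = X + 0.15 * age_z[:, None] + 0.10 * np.where(sex_female, -1.0, 1.0)[:, None]
    if cfg.missing_rate > 0:
        X[rng.uniform(size=X.shape) < cfg.missing_rate] = np.nan
    biomarkers = pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=cols)

    followup_y = rng.uniform(*cfg.followup_years_range, size=n)
    death_y = (
        rng.exponential(1.0 / cfg.death_hazard, size=n)
        if cfg.death_hazard > 0
        else np.full(n, np.inf)
    )
    died = death_y <= followup_y
    end_y = np.minimum(followup_y, death_y)

    baseline_idx = pd.DatetimeIndex(baseline)
    ev_frames: list[pd.DataFrame] = []
    prevalent_by_disease: dict[str, np.ndarray] = {}
    for d in cfg.disease_models:
        logit = d.prevalence_logit + np.asarray(d.subgroup_log_or)[subgroup] + frailty
        prevalent = rng.uniform(size=n) < expit(logit)
        prevalent_by_disease[d.name] = prevalent
        back_y = rng.uniform(0.5, 20.0, size=n)
        rate = d.baseline_hazard * np.exp(np.asarray(d.subgroup_log_hr)[subgroup] + frailty)
        t_inc = rng.exponential(1.0 / rate)
        incident = (~prevalent) & (t_inc <= end_y)
        # occasionally emit 4-character codes to exercise prefix matching
        extra = rng.integers(0, 10, size=n).astype(str)
        codes = np.where(rng.uniform(size=n) < 0.5, d.code + pd.Index(extra), d.code)
        src = np.array(_SOURCES)[rng.integers(0, 3, size=n)]
        for mask, offset_y in ((prevalent, -back_y), (incident, t_inc)):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            dates = baseline_idx[idx] + pd.to_timedelta(_years_to_days(offset_y[idx]))
            ev_frames.append(
                pd.DataFrame(
                    {"id": ids[idx], "code": codes[idx], "date": dates, "source": src[idx]}
                )
            )

    death_dates = pd.Series(baseline_idx + pd.to_timedelta(_years_to_days(death_y.clip(max=end_y))))
    death_dates[~died] = pd.NaT
    participants = pd.DataFrame(
        {
            "id": ids,
            "age": np.round(age, 2),
            "sex": np.where(sex_female, "female", "male"),
            "center": [f"C{c + 1:02d}" for c in center],
            "baseline_date": baseline_idx,
            "followup_end_date": baseline_idx + pd.to_timedelta(_years_to_days(followup_y)),
            "death_date": death_dates,
        }
    )
    if ev_frames:
        events = pd.concat(ev_frames, ignore_index=True)
    else:
        events = pd.DataFrame(columns=["id", "code", "date", "source"])
    events = events.sort_values(["id", "date", "code"], kind="mergesort", ignore_index=True)
    truth = pd.DataFrame(
        {
            "id": ids,
            "subgroup": [f"SG{g + 1}" for g in subgroup],
            "frailty": frailty,
        }
    )
    mets = None
    if cfg.include_mets_markers:
        mets = _mets_markers(
            cfg, latents, sex_female, prevalent_by_disease.get("hypertension", np.zeros(n, bool)), rng
        )
        mets.insert(0, "id", ids)
    return Cohort(participants, biomarkers, events, truth, mets, cfg)


# ---------------------------------------------------------------------------
# I/O


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort as CSV files (ISO-8601 dates, empty string = missing)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = cohort.participants.copy()
    for c in ("baseline_date", "followup_end_date", "death_date"):
        p[c] = pd.to_datetime(p[c]).dt.strftime("%Y-%m-%d")
    p.to_csv(out / "participants.csv", index=False)
    cohort.biomarkers.to_csv(out / "biomarkers.csv")
    ev = cohort.events.copy()
    ev["date"] = pd.to_datetime(ev["date"]).dt.strftime("%Y-%m-%d")
    ev.to_csv(out / "events.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    if cohort.mets_markers is not None:
        cohort.mets_markers.to_csv(out / "mets_markers.csv", index=False)


def read_cohort(indir: str | Path) -> Cohort:
    ind = Path(indir)
    participants = pd.read_csv(ind / "participants.csv")
    for c in ("baseline_date", "followup_end_date", "death_date"):
        participants[c] = pd.to_datetime(participants[c])
    biomarkers = pd.read_csv(ind / "biomarkers.csv", index_col="id")
    events = pd.read_csv(ind / "events.csv")
    events["date"] = pd.to_datetime(events["date"])
    truth_path = ind / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    mets_path = ind / "mets_markers.csv"
    mets = pd.read_csv(mets_path) if mets_path.exists() else None
    return Cohort(participants, biomarkers, events, truth, mets, None)


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from YAML/JSON. Unknown keys raise ConfigurationError."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return sim_config_from_dict(raw)


def sim_config_from_dict(raw: dict) -> SimConfig:
    raw = dict(raw)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown SimConfig keys: {sorted(unknown)}")
    if "biomarker_blocks" in raw:
        raw["biomarker_blocks"] = [
            BiomarkerBlock(**b) if isinstance(b, dict) else BiomarkerBlock(*b)
            for b in raw["biomarker_blocks"]
        ]
    if "disease_models" in raw:
        models = []
        for d in raw["disease_models"]:
            d = dict(d)
            d["subgroup_log_or"] = tuple(d["subgroup_log_or"])
            d["subgroup_log_hr"] = tuple(d["subgroup_log_hr"])
            models.append(DiseaseModel(**d))
        raw["disease_models"] = models
    if "subgroup_effects" in raw:
        raw["subgroup_effects"] = np.asarray(raw["subgroup_effects"], dtype=float)
    for key in ("age_bounds", "followup_years_range", "subgroup_probs"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg
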