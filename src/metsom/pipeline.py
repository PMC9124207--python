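"""Run configuration and stage orchestration.

A run is a fixed sequence of stages — simulate -> reduce -> train -> label
-> associate -> enrich — exchanging CSV artifacts (headers, ISO-8601 dates,
empty string for missing) in a working directory. Every stage draws its
randomness from a seed derived deterministically from (global seed, stage
name), so stages can be re-run independently and a whole run is exactly
reproducible. A JSON manifest records per-stage input/output hashes, seeds
and wall times; with ``resume=True`` a stage whose inputs and outputs still
match the manifest is skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import outcomes as oc
from . import preprocess as pp
from . import som as sm
from . import subgroups as sg
from . import synthetic_data as sd
from . import multimorbidity as mm

logger = logging.getLogger("metsom")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "stage_seed"]

_FLOAT_FMT = "%.10g"  # fixed formatting keeps artifacts byte-stable


@dataclass
class RunConfig:
    out: str
    seed: int = 1
    # simulate
    simulate: bool = True
    n_participants: int = 20_000
    sim_config: str | None = None    # optional YAML overriding the default generator
    input_dir: str | None = None     # pre-existing cohort when simulate=False
    # reduce
    r2_threshold: float = 0.5
    # train
    radius: int = 5
    smoothness: float = 2.0
    epochs: int = 50
    # label
    n_subgroups: int = 6
    labels_file: str | None = None   # expert labeling TSV; None -> k-medoids proposal
    reference: str = "auto"
    # associate
    definitions_file: str | None = None
    censor_date: str | None = None
    # enrich
    n_perm: int = 10_000
    n_boot: int = 1_000
    n_perm_inner: int = 1_000
    min_stratum_size: int = 50
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must be in (0, 1)")
        for key in ("n_perm", "n_boot", "n_perm_inner"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be >= 0")
        if not self.simulate and self.input_dir is None:
            raise ValueError("input_dir is required when simulate is disabled")
        for key in ("sim_config", "labels_file", "definitions_file", "input_dir"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ValueError(f"{key} does not exist: {path}")
        return self


def validate_config(source: str | Path | dict) -> RunConfig:
    """Load and fully resolve a run configuration (YAML/JSON file or dict).

    Missing optional keys take their defaults; unknown keys are rejected."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if raw is None:
        raise ValueError("empty configuration")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {unknown}")
    if "out" not in raw:
        raise ValueError("missing required configuration key: out")
    return RunConfig(**raw).validate()


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.stages: dict[str, dict] = {}
        if path.exists():
            self.stages = json.loads(path.read_text())

    def record(self, stage: str, inputs: list[Path], outputs: list[Path],
               seed: int, wall: float) -> None:
        self.stages[stage] = {
            "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
            "outputs": {p.name: _hash_file(p) for p in outputs if p.exists()},
            "seed": seed,
            "wall_seconds": round(wall, 3),
        }
        self.path.write_text(json.dumps(self.stages, indent=2, sort_keys=True))

    def up_to_date(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        rec = self.stages.get(stage)
        if rec is None:
            return False
        for p in inputs:
            if not p.exists() or rec["inputs"].get(p.name) != _hash_file(p):
                return False
        for p in outputs:
            if not p.exists() or rec["outputs"].get(p.name) != _hash_file(p):
                return False
        return True


# ---------------------------------------------------------------------------
# Stages


def run_simulate(cfg: RunConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    if cfg.sim_config:
        sim_cfg = sd.load_sim_config(cfg.sim_config)
        sim_cfg.seed = seed
    else:
        sim_cfg = sd.default_config(n_participants=cfg.n_participants, seed=seed)
    cohort = sd.generate_cohort(sim_cfg)
    sd.write_cohort(cohort, out)


def run_reduce(cfg: RunConfig, indir: Path, out: Path) -> None:
    biomarkers = pd.read_csv(indir / "biomarkers.csv", index_col="id")
    participants = pd.read_csv(indir / "participants.csv")
    tm = pp.make_training_matrix(biomarkers, participants, r2_threshold=cfg.r2_threshold)
    _write_csv(tm.Z, out / "training_matrix.csv", index=True)
    _write_csv(tm.Z.corr(min_periods=3).round(6), out / "correlations.csv", index=True)
    modules = {
        "r2_threshold": cfg.r2_threshold,
        "modules": [
            {
                "name": info.name,
                "members": info.members,
                "anchor": info.anchor,
                "loadings": [round(float(v), 10) for v in info.loadings],
                "explained_variance": round(info.explained_variance, 10),
            }
            for info in tm.loadings
        ],
        "singletons": tm.partition.singletons,
    }
    (out / "modules.json").write_text(json.dumps(modules, indent=2, sort_keys=True))


def run_train(cfg: RunConfig, indir: Path, out: Path, plot: bool = False) -> None:
    seed = stage_seed(cfg.seed, "train")
    Z = pd.read_csv(indir / "training_matrix.csv", index_col="id")
    topo = sm.create_map_topology(cfg.radius)
    model = sm.train_som(Z, topo, smoothness=cfg.smoothness, epochs=cfg.epochs,
                         seed=seed, radius=cfg.radius)
    assignment = sm.map_participants(model, Z)
    payload = {
        "radius": cfg.radius,
        "smoothness": cfg.smoothness,
        "epochs": cfg.epochs,
        "seed": seed,
        "columns": model.columns,
        "coords": [[round(float(x), 10) for x in xy] for xy in topo.coords],
        "prototypes": [[round(float(v), 10) for v in row] for row in model.prototypes],
        "training_log": [round(float(q), 10) for q in model.training_log],
    }
    (out / "som_model.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    adf = pd.DataFrame(
        {
            "district": assignment.district_of,
            "residual": assignment.residual,
            "coverage": assignment.coverage,
        }
    )
    adf.index.name = "id"
    _write_csv(adf, out / "assignments.csv", index=True)
    _write_csv(sm.qc_map(model, assignment), out / "map_qc.csv")
    cdir = out / "colorings"
    cdir.mkdir(exist_ok=True)
    for col in Z.columns:
        coloring = sm.district_coloring(assignment, Z[col], topo, cfg.smoothness, name=col)
        df = pd.DataFrame(
            {"district": topo.districts, "value": coloring.district_value}
        )
        _write_csv(df, cdir / f"{col}.csv")
        if plot:
            from .viz import plot_coloring

            plot_coloring(topo, coloring, cdir / f"{col}.png")


def run_label(cfg: RunConfig, simdir: Path, traindir: Path, out: Path) -> None:
    seed = stage_seed(cfg.seed, "label")
    Z = pd.read_csv(traindir / "training_matrix.csv", index_col="id")
    adf = pd.read_csv(traindir / "assignments.csv", index_col="id")
    assignment = sm.MapAssignment(
        district_of=adf["district"], residual=adf["residual"], coverage=adf["coverage"]
    )
    if cfg.labels_file:
        ref = cfg.reference if cfg.reference != "auto" else "I"
        labeling = sg.read_labels_tsv(cfg.labels_file, reference=ref)
    else:
        model_json = json.loads((traindir / "som_model.json").read_text())
        topo = sm.create_map_topology(model_json["radius"])
        model = sm.SomModel(
            topology=topo,
            prototypes=np.array(model_json["prototypes"]),
            columns=model_json["columns"],
            smoothness=model_json["smoothness"],
            epochs=model_json["epochs"],
            seed=model_json["seed"],
        )
        labeling = sg.propose_labeling(model, n_subgroups=cfg.n_subgroups, seed=seed)
    sg.write_labels_tsv(labeling, out / "labels.tsv")
    subgroup_of = sg.assign_subgroups(assignment, labeling)
    sdf = subgroup_of.to_frame()
    sdf.index.name = "id"
    _write_csv(sdf, out / "subgroups.csv", index=True)
    raw = pd.read_csv(simdir / "biomarkers.csv", index_col="id")
    profile = sg.subgroup_profile_matrix(Z, raw, subgroup_of)
    prof = pd.concat(
        [profile.counts.rename("n"), profile.z_profile, profile.raw_profile], axis=1
    )
    prof.index.name = "subgroup"
    _write_csv(prof, out / "profiles.csv", index=True)


def _choose_reference(disease_table: pd.DataFrame, subgroup_of: pd.Series) -> str:
    """Auto reference = subgroup with the lowest summed crude prevalence of
    the four cardiometabolic conditions (the least-burdened subgroup)."""
    sub = disease_table[disease_table["disease"].isin(oc.CARDIOMETABOLIC)].copy()
    sub["subgroup"] = sub["id"].map(subgroup_of)
    burden = sub.groupby("subgroup")["prevalent"].mean().sort_index()
    return str(burden.idxmin())


def run_associate(cfg: RunConfig, simdir: Path, labeldir: Path, out: Path) -> str:
    events = pd.read_csv(simdir / "events.csv", parse_dates=["date"])
    participants = pd.read_csv(
        simdir / "participants.csv",
        parse_dates=["baseline_date", "followup_end_date", "death_date"],
    )
    defs = (
        oc.load_definitions(cfg.definitions_file)
        if cfg.definitions_file
        else oc.default_definitions()
    )
    dt = oc.derive_disease_status(events, participants, defs, censor_date=cfg.censor_date)
    _write_csv(dt, out / "disease_table.csv")
    subgroup_of = pd.read_csv(labeldir / "subgroups.csv", index_col="id")["subgroup"]
    reference = cfg.reference
    if reference == "auto":
        reference = _choose_reference(dt, subgroup_of)
        logger.info("auto-selected reference subgroup: %s", reference)
    covars = participants.set_index("id")[["age", "sex", "center"]]
    _write_csv(
        oc.prevalence_odds_ratios(dt, subgroup_of, covars, reference),
        out / "contrasts_prevalent.csv",
    )
    _write_csv(
        oc.incidence_hazard_ratios(dt, subgroup_of, covars, reference),
        out / "contrasts_incident.csv",
    )
    _write_csv(oc.incidence_rates(dt, subgroup_of), out / "rates.csv")
    (out / "reference.json").write_text(json.dumps({"reference": reference}))
    return reference


def run_enrich(cfg: RunConfig, simdir: Path, labeldir: Path, assocdir: Path, out: Path) -> None:
    seed = stage_seed(cfg.seed, "enrich")
    dt = pd.read_csv(assocdir / "disease_table.csv")
    subgroup_of = pd.read_csv(labeldir / "subgroups.csv", index_col="id")["subgroup"]
    participants = pd.read_csv(simdir / "participants.csv").set_index("id")
    age_median = participants["age"].median()
    age_stratum = pd.Series(
        np.where(participants["age"] <= age_median, f"age<={age_median:g}", f"age>{age_median:g}"),
        index=participants.index,
    )
    rows = []
    for kind in ("prevalent", "incident"):
        panel = oc.binary_panel(dt, kind)
        overall = mm.enrichment_ratio(
            panel, n_perm=cfg.n_perm, seed=stage_seed(seed, f"{kind}:overall"),
            n_boot=cfg.n_boot, n_perm_inner=cfg.n_perm_inner,
        )
        rows.append(("overall", kind, overall))
        for strata_name, strata in (("subgroup", subgroup_of), ("age", age_stratum)):
            results = mm.stratified_enrichment(
                panel, strata, n_perm=cfg.n_perm,
                seed=stage_seed(seed, f"{kind}:{strata_name}"),
                n_boot=cfg.n_boot, n_perm_inner=cfg.n_perm_inner,
                min_size=cfg.min_stratum_size,
            )
            rows.extend((label, kind, res) for label, res in sorted(results.items()))
    enr = pd.DataFrame(
        [
            {
                "stratum": label,
                "kind": kind,
                "n": r.n_rows,
                "observed_prop": r.observed_prop,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "er": r.er,
                "p_value": r.p_value,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_perm": r.n_perm,
                "n_boot": r.n_boot,
                "seed": r.seed,
            }
            for label, kind, r in rows
        ]
    )
    _write_csv(enr, out / "enrichment.csv")

    mets_path = simdir / "mets_markers.csv"
    if mets_path.exists():
        measures = pd.read_csv(mets_path, index_col="id")
        measures["sex"] = participants["sex"]
        mets = mm.mets_classify(measures)
        mets.index.name = "id"
        _write_csv(mets, out / "mets.csv", index=True)


def run_pipeline(config: RunConfig, resume: bool = False, plot: bool = False) -> Path:
    """Execute the full stage sequence; returns the artifact directory."""
    cfg = config.validate()
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")

    cohort_dir = Path(cfg.input_dir) if (not cfg.simulate and cfg.input_dir) else out
    cohort_files = [cohort_dir / f for f in ("participants.csv", "biomarkers.csv", "events.csv")]

    stages: list[tuple[str, list[Path], list[Path], callable]] = []
    if cfg.simulate:
        stages.append(("simulate", [], cohort_files + [out / "truth.csv"],
                       lambda: run_simulate(cfg, out)))
    stages.append(
        ("reduce", cohort_files,
         [out / "training_matrix.csv", out / "modules.json", out / "correlations.csv"],
         lambda: run_reduce(cfg, cohort_dir, out))
    )
    stages.append(
        ("train", [out / "training_matrix.csv"],
         [out / "som_model.json", out / "assignments.csv", out / "map_qc.csv"],
         lambda: run_train(cfg, out, out, plot=plot))
    )
    stages.append(
        ("label", [out / "assignments.csv", out / "som_model.json"],
         [out / "labels.tsv", out / "subgroups.csv", out / "profiles.csv"],
         lambda: run_label(cfg, cohort_dir, out, out))
    )
    stages.append(
        ("associate", cohort_files + [out / "subgroups.csv"],
         [out / "disease_table.csv", out / "contrasts_prevalent.csv",
          out / "contrasts_incident.csv", out / "rates.csv"],
         lambda: run_associate(cfg, cohort_dir, out, out))
    )
    stages.append(
        ("enrich", [out / "disease_table.csv", out / "subgroups.csv"],
         [out / "enrichment.csv"],
         lambda: run_enrich(cfg, cohort_dir, out, out, out))
    )

    for name, inputs, outputs, fn in stages:
        if resume and manifest.up_to_date(name, inputs, outputs):
            logger.info("stage %-9s up to date; skipped", name)
            continue
        t0 = time.time()
        logger.info("stage %-9s started", name)
        try:
            fn()
        except Exception:
            logger.error("stage %-9s FAILED; prior artifacts persist in %s", name, out)
            raise
        manifest.record(name, inputs, outputs, stage_seed(cfg.seed, name), time.time() - t0)
        logger.info("stage %-9s done in %.1fs", name, time.time() - t0)
    return out
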