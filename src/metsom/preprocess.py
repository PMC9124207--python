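"""Biomarker panel reduction.

The raw panel is reduced to the map training matrix in four steps:

1. age/sex residualization of every biomarker (linear age term plus a sex
   indicator), followed by centering and scaling to unit SD;
2. pairwise-complete Spearman correlation of the adjusted columns;
3. collinearity modules: variables whose squared rank correlation exceeds
   the threshold (default 50%) form the edges of a network, and connected
   components with at least two members become modules;
4. each module is collapsed to its first principal-component score, sign-
   oriented and rescaled for partially observed rows; module scores and
   the remaining singleton variables are standardized into the final
   training matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

__all__ = [
    "CorrelationMatrix",
    "ModulePartition",
    "ModuleLoadings",
    "TrainingMatrix",
    "spearman_matrix",
    "build_collinearity_modules",
    "collapse_module",
    "residualize_standardize",
    "make_training_matrix",
]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    rho: pd.DataFrame       # symmetric, unit diagonal; NaN where < min_periods
    n_pairs: pd.DataFrame   # pairwise-complete counts


@dataclass
class ModulePartition:
    modules: list[tuple[str, ...]]   # each sorted, >= 2 members
    singletons: list[str]


@dataclass
class ModuleLoadings:
    """First-PC loadings of one collapsed module."""

    name: str
    members: list[str]
    loadings: np.ndarray
    anchor: str                 # orientation member (largest |loading|)
    explained_variance: float
    member_means: np.ndarray    # standardization used before the PCA
    member_sds: np.ndarray


@dataclass
class TrainingMatrix:
    """Age/sex-residualized, module-collapsed, standardized map inputs."""

    columns: list[str]
    Z: pd.DataFrame                      # participants x inputs, NaN allowed
    adjustment: pd.DataFrame             # per-column residualization record
    scaling: pd.DataFrame                # per-column (mean, sd) applied last
    partition: ModulePartition | None = None
    loadings: list[ModuleLoadings] = field(default_factory=list)


def spearman_matrix(biomarkers: pd.DataFrame, min_periods: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation with average ranks for ties.

    Ranks are recomputed within each pairwise-complete subset (so missing
    values in a third column never perturb a pair's coefficient). Pairs with
    fewer than ``min_periods`` complete rows get a missing coefficient and a
    warning; the module network later ignores them.
    """
    cols = list(biomarkers.columns)
    X = biomarkers.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    p = len(cols)
    rho = np.eye(p)
    npairs = obs.T.astype(np.int64) @ obs.astype(np.int64)
    short: list[tuple[str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            m = obs[:, i] & obs[:, j]
            k = int(m.sum())
            if k < min_periods:
                rho[i, j] = rho[j, i] = np.nan
                short.append((cols[i], cols[j]))
                continue
            ri = rankdata(X[m, i])
            rj = rankdata(X[m, j])
            ri -= ri.mean()
            rj -= rj.mean()
            denom = np.sqrt((ri**2).sum() * (rj**2).sum())
            rho[i, j] = rho[j, i] = (ri @ rj) / denom if denom > 0 else np.nan
    if short:
        warnings.warn(
            f"{len(short)} variable pair(s) had fewer than {min_periods} complete "
            f"observations and were excluded from the correlation network: {short[:5]}"
        )
    return CorrelationMatrix(
        variables=cols,
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        n_pairs=pd.DataFrame(npairs, index=cols, columns=cols),
    )


def build_collinearity_modules(
    corr: CorrelationMatrix, r2_threshold: float = 0.5
) -> ModulePartition:
    """Connected components of the strict ``rho^2 > r2_threshold`` graph.

    Components with >= 2 members become collinearity modules; everything
    else is a singleton. Missing coefficients contribute no edge.
    """
    cols = corr.variables
    r = corr.rho.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        # round to 12 decimals so e.g. rho = sqrt(threshold) sits exactly on
        # the boundary and is excluded by the strict inequality
        adj = np.round(r**2, 12) > r2_threshold
    np.fill_diagonal(adj, False)
    adj &= ~np.isnan(r)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    modules: list[tuple[str, ...]] = []
    singletons: list[str] = []
    for c in range(n_comp):
        members = sorted(np.array(cols)[labels == c].tolist())
        if len(members) >= 2:
            modules.append(tuple(members))
        else:
            singletons.extend(members)
    modules.sort(key=lambda m: m[0])
    singletons.sort()
    return ModulePartition(modules=modules, singletons=singletons)


def collapse_module(
    biomarkers: pd.DataFrame, module: tuple[str, ...] | list[str]
) -> tuple[pd.Series, ModuleLoadings]:
    """Collapse a module to its first principal-component score.

    Members are column-standardized, the first eigenvector of their
    pairwise-complete correlation matrix gives the loadings, and the score
    is oriented so that it correlates positively with the member carrying
    the largest absolute loading (ties broken alphabetically). Rows with
    only some members observed are projected on the observed loadings and
    rescaled by sqrt(m / m_observed).
    """
    members = sorted(module)
    if len(members) < 2:
        raise ValueError("a module needs at least 2 members")
    sub = biomarkers[members]
    all_missing = [c for c in members if sub[c].notna().sum() == 0]
    if all_missing:
        warnings.warn(f"dropping all-missing module member(s): {all_missing}")
        members = [c for c in members if c not in all_missing]
        sub = biomarkers[members]
        if len(members) < 2:
            raise ValueError("module reduced to < 2 observed members")
    mu = sub.mean().to_numpy()
    sd = sub.std(ddof=0).to_numpy()
    if (sd == 0).any():
        bad = [m for m, s in zip(members, sd) if s == 0]
        raise ValueError(f"zero-variance module member(s): {bad}")
    Zs = (sub - mu) / sd
    C = Zs.corr(min_periods=2).to_numpy()
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    lam = evals[order]
    v = evecs[:, order[0]]
    anchor_idx = int(np.argmax(np.abs(np.round(v, 12))))  # ties -> first (alphabetical)
    if v[anchor_idx] < 0:
        v = -v
    anchor = members[anchor_idx]
    Zv = Zs.to_numpy()
    obs = ~np.isnan(Zv)
    m = len(members)
    m_obs = obs.sum(axis=1)
    proj = np.nansum(Zv * v[None, :], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = proj * np.sqrt(m / m_obs)
    score[m_obs == 0] = np.nan
    total = float(np.clip(lam, 0, None).sum())
    info = ModuleLoadings(
        name=f"mod_{anchor}",
        members=members,
        loadings=v,
        anchor=anchor,
        explained_variance=float(lam[0] / total) if total > 0 else float("nan"),
        member_means=mu,
        member_sds=sd,
    )
    return pd.Series(score, index=biomarkers.index, name=info.name), info


def _residualize_columns(
    df: pd.DataFrame, age: pd.Series, sex: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Least-squares residuals on (age, sex indicator) per column, then
    center/scale to unit SD over observed entries. Missing stays missing."""
    age_v = age.to_numpy(dtype=float)
    sex_male = (sex.astype(str).to_numpy() == "male").astype(float)
    sex_varies = len(np.unique(sex_male)) > 1
    out = {}
    adj_rows = []
    scale_rows = []
    for col in df.columns:
        y = df[col].to_numpy(dtype=float)
        m = ~np.isnan(y)
        if m.sum() == 0 or np.nanstd(y) == 0:
            raise ValueError(f"zero-variance or empty column: {col}")
        parts = [np.ones(int(m.sum())), age_v[m]]
        if sex_varies:
            parts.append(sex_male[m])
        X = np.column_stack(parts)
        beta, *_ = np.linalg.lstsq(X, y[m], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[m] = y[m] - X @ beta
        mu = float(np.nanmean(resid))
        sd = float(np.nanstd(resid))
        if sd == 0:
            raise ValueError(f"zero residual variance in column: {col}")
        out[col] = (resid - mu) / sd
        adj_rows.append(
            {
                "column": col,
                "intercept": beta[0],
                "age_slope": beta[1],
                "sex_male_contrast": beta[2] if sex_varies else 0.0,
            }
        )
        scale_rows.append({"column": col, "mean": mu, "sd": sd})
    Z = pd.DataFrame(out, index=df.index)
    return Z, pd.DataFrame(adj_rows).set_index("column"), pd.DataFrame(scale_rows).set_index("column")


def residualize_standardize(
    columns: pd.DataFrame, age: pd.Series, sex: pd.Series
) -> TrainingMatrix:
    """Adjust each column for age and sex, then center and scale to unit SD.

    Participants must have complete age and sex (exclude them upstream);
    within the biomarker columns missing entries are tolerated and stay
    missing. A constant-sex cohort drops the sex term.
    """
    if age.isna().any() or sex.isna().any():
        raise ValueError("age and sex must be complete; exclude incomplete participants upstream")
    Z, adjustment, scaling = _residualize_columns(columns, age, sex)
    return TrainingMatrix(
        columns=list(columns.columns), Z=Z, adjustment=adjustment, scaling=scaling
    )


def make_training_matrix(
    biomarkers: pd.DataFrame,
    participants: pd.DataFrame,
    r2_threshold: float = 0.5,
) -> TrainingMatrix:
    """Full reduction: residualize -> correlate -> modules -> collapse ->
    standardize. ``participants`` must carry id-indexed ``age`` and ``sex``.

    Returns the training matrix whose columns are module PC scores plus
    singleton variables, each centered and unit-scaled.
    """
    part = participants.set_index("id") if "id" in participants.columns else participants
    part = part.loc[biomarkers.index]
    complete = part["age"].notna() & part["sex"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} participant(s) lacking age or sex")
    bio = biomarkers.loc[complete[complete].index]
    age = part.loc[bio.index, "age"].astype(float)
    sex = part.loc[bio.index, "sex"]

    adjusted = residualize_standardize(bio, age, sex)
    corr = spearman_matrix(adjusted.Z)
    partition = build_collinearity_modules(corr, r2_threshold=r2_threshold)

    score_cols: dict[str, pd.Series] = {}
    loadings: list[ModuleLoadings] = []
    for module in partition.modules:
        score, info = collapse_module(adjusted.Z, module)
        score_cols[info.name] = score
        loadings.append(info)
    assembled = pd.DataFrame(score_cols, index=adjusted.Z.index)
    assembled = pd.concat([assembled, adjusted.Z[partition.singletons]], axis=1)

    mu = assembled.mean()
    sd = assembled.std(ddof=0)
    if (sd == 0).any():
        raise ValueError(f"zero-variance training column(s): {list(sd[sd == 0].index)}")
    Z = (assembled - mu) / sd
    scaling = pd.DataFrame({"mean": mu, "sd": sd})
    scaling.index.name = "column"
    return TrainingMatrix(
        columns=list(Z.columns),
        Z=Z,
        adjustment=adjusted.adjustment,
        scaling=scaling,
        partition=partition,
        loadings=loadings,
    )
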