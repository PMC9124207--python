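"""District labeling and subgroup profiles.

Map districts are grouped into mutually exclusive subgroups by an explicit
labeling artifact (district -> subgroup TSV), mirroring a human-consensus
step: the labeling is an input, not an algorithmic output. A seeded
k-medoids proposer on the district prototypes is shipped as a convenience
starting point only — it is NOT the published procedure, which relied on
expert reading of the map colorings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .som import MapAssignment, SomModel

__all__ = [
    "SubgroupLabeling",
    "SubgroupProfile",
    "assign_subgroups",
    "subgroup_profile_matrix",
    "propose_labeling",
    "read_labels_tsv",
    "write_labels_tsv",
    "ROMAN",
]

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]


@dataclass
class SubgroupLabeling:
    district_to_subgroup: dict[int, str]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in set(self.district_to_subgroup.values()):
            raise ValueError(
                f"reference subgroup {self.reference!r} does not appear in the labeling"
            )


@dataclass
class SubgroupProfile:
    z_profile: pd.DataFrame      # subgroup x training input, mean Z (SD units)
    raw_profile: pd.DataFrame    # subgroup x biomarker, mean physical value
    counts: pd.Series            # participants per subgroup


def read_labels_tsv(path: str | Path, reference: str) -> SubgroupLabeling:
    df = pd.read_csv(path, sep="\t", header=None, names=["district", "subgroup"], comment="#")
    mapping = dict(zip(df["district"].astype(int), df["subgroup"].astype(str)))
    return SubgroupLabeling(district_to_subgroup=mapping, reference=reference)


def write_labels_tsv(labeling: SubgroupLabeling, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in sorted(labeling.district_to_subgroup):
            fh.write(f"{d}\t{labeling.district_to_subgroup[d]}\n")


def assign_subgroups(assignment: MapAssignment, labeling: SubgroupLabeling) -> pd.Series:
    """Map each participant to the subgroup of their district.

    The labeling must cover every district that actually holds participants;
    unlabeled occupied districts raise an error naming them.
    """
    districts_present = set(int(d) for d in assignment.district_of.unique())
    missing = sorted(districts_present - set(labeling.district_to_subgroup))
    if missing:
        raise ValueError(f"unlabeled district(s) present in assignment: {missing}")
    return assignment.district_of.map(labeling.district_to_subgroup).rename("subgroup")


def subgroup_profile_matrix(
    Z: pd.DataFrame, raw: pd.DataFrame, subgroup_of: pd.Series
) -> SubgroupProfile:
    """Per-subgroup mean of every training input (Z, SD units) and every raw
    biomarker (physical units), over non-missing entries."""
    Zdf = Z.Z if hasattr(Z, "Z") else Z
    common = subgroup_of.index.intersection(Zdf.index)
    groups = subgroup_of.loc[common]
    counts = groups.value_counts().sort_index()
    if (counts == 0).any():
        raise ValueError("empty subgroup in labeling")
    z_profile = Zdf.loc[common].groupby(groups).mean()
    raw_common = subgroup_of.index.intersection(raw.index)
    raw_profile = raw.loc[raw_common].groupby(subgroup_of.loc[raw_common]).mean()
    return SubgroupProfile(z_profile=z_profile, raw_profile=raw_profile, counts=counts)


def propose_labeling(
    model: SomModel,
    n_subgroups: int,
    seed: int = 0,
    reference: str | None = None,
    max_iter: int = 200,
) -> SubgroupLabeling:
    """Seeded k-medoids (PAM-style) on the district prototypes.

    Convenience proposer only: the analysis this package implements treats
    subgroup boundaries as an expert decision recorded in a labels TSV; this
    merely drafts one. Clusters are named with roman numerals in order of
    their medoid's district id; the reference defaults to subgroup "I" until
    an outcome-informed choice replaces it.
    """
    P = model.prototypes
    n = P.shape[0]
    if n_subgroups < 1 or n_subgroups > n:
        raise ValueError("n_subgroups must be between 1 and the number of districts")
    rng = np.random.default_rng(seed)
    D = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
    medoids = np.sort(rng.choice(n, size=n_subgroups, replace=False))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for k in range(n_subgroups):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[k] = members[np.argmin(within)]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    labels = np.argmin(D[:, medoids], axis=1)
    names = {k: ROMAN[k] for k in range(n_subgroups)}
    mapping = {int(d): names[int(labels[i])] for i, d in enumerate(model.topology.districts)}
    ref = reference or names[0]
    return SubgroupLabeling(district_to_subgroup=mapping, reference=ref)
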