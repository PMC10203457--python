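"""Canonical data types, trait registry, and tabular I/O.

The pot trial measures each genotype ("line") under two watering
treatments — well-watered (WW) and water-stressed (WS) — with replicate
pots.  Observations are carried as a tidy :class:`pandas.DataFrame` with
one row per measured value; :class:`TraitMeanMatrix` holds the per-line,
per-treatment replicate means that every downstream stage (derived
traits, TDRI, statistics) consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phenodrought")

# ---------------------------------------------------------------------------
# Trait registry
# ---------------------------------------------------------------------------

#: Observation table columns, in canonical order.
OBS_COLUMNS = ("line_id", "treatment", "replicate", "trait", "value", "day")

TREATMENTS = ("WW", "WS")


@dataclass(frozen=True)
class Trait:
    """One entry of the trait registry.

    ``tdri_member`` marks the 17 traits whose WS/WW mean ratios sum to the
    Total Drought Response Index.  ``negative_allowed`` marks traits whose
    values may legitimately be negative: leaf osmotic potential (always
    ≤ 0 MPa), relative growth rate (shrinking canopy) and percent
    reduction in shoot dry weight (stress can exceed control).
    """

    code: str
    display_name: str
    units: str
    tdri_member: bool
    negative_allowed: bool = False


_REGISTRY_ROWS = [
    # code, display name, units, tdri_member, negative_allowed
    ("TN", "tiller number", "count", True, False),
    ("PH", "plant height", "cm", True, False),
    ("CC", "chlorophyll content", "umol m-2", True, False),
    ("LOP", "leaf osmotic potential", "MPa", True, True),
    ("LGA", "leaf green area", "cm2", True, False),
    ("RGR", "relative growth rate", "d-1", True, True),
    ("SDW", "shoot dry weight", "g", True, False),
    ("RDW", "root dry weight", "g", True, False),
    ("RSR", "root:shoot dry weight ratio", "dimensionless", True, False),
    ("RL", "root length", "cm", True, False),
    ("CRN", "crown root number", "count", True, False),
    ("CRPT", "crown roots per tiller", "dimensionless", True, False),
    ("MRL", "maximum nodal root length", "cm", True, False),
    ("RAD", "root average diameter", "mm", True, False),
    ("RTi", "root tips", "count", True, False),
    ("RF", "root forks", "count", True, False),
    ("PLR", "percent lateral roots", "%", True, False),
    ("WU", "water uptake", "kg", False, False),
    ("WUE", "water use efficiency", "g L-1", False, False),
    ("PR_SDW", "percent reduction in shoot dry weight", "%", False, True),
]

TRAITS: dict[str, Trait] = {
    code: Trait(code, name, units, member, neg)
    for code, name, units, member, neg in _REGISTRY_ROWS
}

#: The 17 traits entering the TDRI sum, in the order of the defining formula.
TDRI_TRAITS: tuple[str, ...] = tuple(t.code for t in TRAITS.values() if t.tdri_member)

#: File tokens that are not valid identifiers map onto registry codes.
TRAIT_ALIASES = {"%LR": "PLR", "%R_SDW": "PR_SDW", "%R_SDW ": "PR_SDW"}


class UnknownTraitError(ValueError):
    """A trait token does not resolve against the registry."""


class DuplicateObservationError(ValueError):
    """Two rows share the same (line, treatment, replicate, trait, day) key."""


class SchemaError(ValueError):
    """An input table cannot be mapped onto the expected columns."""


def normalize_trait(token: str) -> str:
    """Resolve a file token (e.g. ``%LR``) to a registry code."""
    token = str(token).strip()
    code = TRAIT_ALIASES.get(token, token)
    if code not in TRAITS:
        raise UnknownTraitError(f"unknown trait code {token!r}")
    return code


# ---------------------------------------------------------------------------
# Observation I/O
# ---------------------------------------------------------------------------

def _normalize_treatment(token: str) -> str:
    t = str(token).strip().upper()
    if t not in TREATMENTS:
        raise SchemaError(f"treatment token {token!r} is not WW/WS")
    return t


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an observation table in place and return it.

    Checks trait codes, treatment tokens, key uniqueness and sign
    conventions (non-negative values except for traits flagged
    ``negative_allowed``; LOP must be ≤ 0).
    """
    df = df.copy()
    df["trait"] = [normalize_trait(t) for t in df["trait"]]
    df["treatment"] = [_normalize_treatment(t) for t in df["treatment"]]

    key_cols = ["line_id", "treatment", "replicate", "trait", "day"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise DuplicateObservationError(
            f"duplicate observation keys at rows {rows}"
        )

    for code, sub in df.groupby("trait"):
        trait = TRAITS[str(code)]
        vals = sub["value"].to_numpy(dtype=float)
        if code == "LOP":
            if (vals > 0).any():
                raise SchemaError("LOP (osmotic potential) values must be <= 0")
        elif not trait.negative_allowed and (vals < 0).any():
            raise SchemaError(f"negative value for non-negative trait {code}")
    return df


def read_observations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a long-format observation CSV.

    Expected header ``line_id,treatment,replicate,trait,value[,day]``;
    ``dialect`` maps canonical names to the file's actual column names.
    Rows with an empty value cell are dropped with a logged warning
    (field tables legitimately contain missing entries).
    """
    path = Path(path)
    raw = pd.read_csv(path)
    if raw.empty:
        raise SchemaError(f"{path} contains no data rows")
    rename = {v: k for k, v in (dialect or {}).items()}
    raw = raw.rename(columns=rename)

    missing = [c for c in ("line_id", "treatment", "replicate", "trait", "value")
               if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} lacks required columns {missing}")
    if "day" not in raw.columns:
        raw["day"] = pd.NA

    blank = raw["value"].isna()
    if blank.any():
        logger.warning("%s: dropping %d rows with empty value", path, int(blank.sum()))
        raw = raw.loc[~blank]

    df = raw.loc[:, list(OBS_COLUMNS)].reset_index(drop=True)
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = df["value"].astype(float)
    return validate_observations(df)


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table as canonical long-format CSV."""
    out = df.loc[:, list(OBS_COLUMNS)]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-line treatment means
# ---------------------------------------------------------------------------

@dataclass
class TraitMeanMatrix:
    """Replicate means per (line, treatment, trait).

    ``means`` and ``counts`` are DataFrames indexed by line (first-appearance
    order preserved) with a ``(trait, treatment)`` column MultiIndex.
    Missing combinations are NaN — completeness is enforced downstream,
    never silently imputed.
    """

    means: pd.DataFrame
    counts: pd.DataFrame

    @property
    def lines(self) -> list[str]:
        return list(self.means.index)

    def get(self, line_id: str, treatment: str, trait: str) -> float:
        try:
            return float(self.means.loc[line_id, (trait, treatment)])
        except KeyError:
            return float("nan")

    def count(self, line_id: str, treatment: str, trait: str) -> int:
        try:
            n = self.counts.loc[line_id, (trait, treatment)]
        except KeyError:
            return 0
        return 0 if pd.isna(n) else int(n)

    def treatment_means(self, treatment: str, traits: Sequence[str]) -> pd.DataFrame:
        """Lines × traits frame of means under one treatment."""
        cols = [(t, treatment) for t in traits]
        sub = self.means.reindex(columns=pd.MultiIndex.from_tuples(cols))
        sub.columns = list(traits)
        return sub

    def missing_tdri_entries(self, line_id: str) -> list[tuple[str, str]]:
        """(trait, treatment) pairs absent for a line among the 17 TDRI traits."""
        out = []
        for trait in TDRI_TRAITS:
            for trt in TREATMENTS:
                if np.isnan(self.get(line_id, trt, trait)):
                    out.append((trait, trt))
        return out

    def to_wide_csv(self, path: str | Path) -> None:
        """Write the wide matrix (rows = lines, columns = ``trait:treatment``)."""
        wide = self.means.copy()
        wide.columns = [f"{t}:{trt}" for t, trt in wide.columns]
        wide.index.name = "line_id"
        wide.to_csv(path)

    @classmethod
    def from_wide_csv(cls, path: str | Path) -> "TraitMeanMatrix":
        wide = pd.read_csv(path, index_col="line_id")
        tuples = []
        for col in wide.columns:
            trait, _, trt = col.partition(":")
            tuples.append((normalize_trait(trait), _normalize_treatment(trt)))
        wide.columns = pd.MultiIndex.from_tuples(tuples)
        counts = wide.notna().astype(float)
        return cls(means=wide, counts=counts)


def aggregate_means(obs: pd.DataFrame) -> TraitMeanMatrix:
    """Arithmetic mean over replicates per (line, treatment, trait).

    Line order follows first appearance in the observation table; the
    result is invariant to row permutations within a line.
    """
    if obs.empty:
        raise SchemaError("cannot aggregate an empty observation table")
    line_order = list(dict.fromkeys(obs["line_id"]))
    grouped = obs.groupby(["line_id", "trait", "treatment"], sort=True)["value"]
    means = grouped.mean().unstack(["trait", "treatment"])
    counts = grouped.size().unstack(["trait", "treatment"]).astype(float)
    means = means.reindex(line_order)
    counts = counts.reindex(line_order)
    means = means.sort_index(axis=1)
    counts = counts.reindex(columns=means.columns)
    return TraitMeanMatrix(means=means, counts=counts)
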