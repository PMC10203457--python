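"""Total Drought Response Index: stress ratios, banding, ranking, grouping.

For each genotype the TDRI is the plain, unweighted sum over 17 traits of
the water-stressed to well-watered mean ratio:

    TDRI = Σ_t  mean_WS(t) / mean_WW(t),   t ∈ 17 shoot and root traits.

A genotype whose traits are unaffected by stress scores 17; trait
maintenance (ratios near 1) and stress-induced increases (e.g. deeper
root systems, more negative osmotic potential) raise the index.  Leaf
osmotic potential enters as the raw ratio of two negative means, which
is positive and exceeds 1 under osmotic adjustment — no absolute-value
transform is applied.

Genotypes are banded low / moderate / tolerant by fixed cut points
(defaults 15.05 and 17.05) and ranked by descending TDRI with
lexicographic tie-breaking.  The per-line trait grouping report places
each trait's stress ratio against the empirical tertiles of that trait's
ratio distribution across all lines — a documented reconstruction, since
no standard grouping rule exists for this report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import TDRI_TRAITS, TraitMeanMatrix

__all__ = [
    "StressRatioVector",
    "TDRIResult",
    "TraitGroupReport",
    "IncompleteRatioError",
    "DEFAULT_BANDS",
    "stress_ratios",
    "compute_tdri",
    "classify_tdri",
    "rank_lines",
    "group_traits",
    "tdri_table",
    "SBIR_PANEL_TDRI",
    "SBIR_PANEL_ROLES",
]

#: Band cut points (low ≤ first < moderate ≤ second < tolerant).
DEFAULT_BANDS = (15.05, 17.05)

#: Traits where a smaller value is the favourable direction (costs);
#: their ordering is reversed before tertile grouping.
COST_TRAITS = frozenset({"PR_SDW"})


class IncompleteRatioError(ValueError):
    """TDRI requested on a ratio vector with missing or invalid traits."""


@dataclass
class StressRatioVector:
    """Per-trait WS/WW mean ratios for one line.

    ``flags`` records ``ok`` / ``missing`` / ``nonpositive_denominator``
    per trait; ratios are present only where the flag is ``ok``.
    """

    line_id: str
    ratios: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(self.flags.get(t) == "ok" for t in TDRI_TRAITS)

    def blocked_traits(self) -> list[str]:
        return [t for t in TDRI_TRAITS if self.flags.get(t) != "ok"]


@dataclass(frozen=True)
class TDRIResult:
    line_id: str
    tdri: float
    rank: int
    band: str


@dataclass(frozen=True)
class TraitGroupReport:
    line_id: str
    groups: dict[str, str]


def stress_ratios(matrix: TraitMeanMatrix, line_id: str) -> StressRatioVector:
    """WS/WW mean ratio per TDRI trait for one line.

    Failures never raise here: absent means are flagged ``missing`` and a
    zero well-watered mean is flagged ``nonpositive_denominator``.
    """
    if line_id not in matrix.lines:
        raise KeyError(f"line {line_id!r} not present in the mean matrix")
    vec = StressRatioVector(line_id=line_id)
    for trait in TDRI_TRAITS:
        ww = matrix.get(line_id, "WW", trait)
        ws = matrix.get(line_id, "WS", trait)
        if math.isnan(ww) or math.isnan(ws):
            vec.flags[trait] = "missing"
        elif ww == 0:
            vec.flags[trait] = "nonpositive_denominator"
        else:
            vec.flags[trait] = "ok"
            vec.ratios[trait] = ws / ww
    return vec


def compute_tdri(vec: StressRatioVector) -> float:
    """Sum of the 17 stress ratios — no capping, weighting or rescaling."""
    if not vec.complete:
        raise IncompleteRatioError(
            f"line {vec.line_id!r}: TDRI blocked by traits {vec.blocked_traits()}"
        )
    return float(sum(vec.ratios[t] for t in TDRI_TRAITS))


def classify_tdri(tdri: float, bands: tuple[float, float] = DEFAULT_BANDS) -> str:
    """Tolerance band for a TDRI value: ``low``, ``moderate`` or ``tolerant``.

    The published bands are gapped (13.5–15, 15.1–17, >17.1); the cut
    points sit at the gap midpoints so the function is total, and values
    below the lowest published band (e.g. a drought-sensitive recurrent
    parent) fall in ``low``.
    """
    if not math.isfinite(tdri):
        raise ValueError("TDRI must be finite to classify")
    lo, hi = bands
    if not lo < hi:
        raise ValueError("band cut points must be ascending")
    if tdri <= lo:
        return "low"
    if tdri <= hi:
        return "moderate"
    return "tolerant"


def rank_lines(
    tdri_by_line: Mapping[str, float],
    bands: tuple[float, float] = DEFAULT_BANDS,
) -> list[TDRIResult]:
    """Rank lines by descending TDRI (rank 1 = highest).

    Ties break lexicographically by line id, making the ordering
    deterministic; applying the ranking to its own output is idempotent.
    """
    if not tdri_by_line:
        raise ValueError("no lines to rank")
    ordered = sorted(tdri_by_line.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        TDRIResult(line, float(t), rank, classify_tdri(t, bands))
        for rank, (line, t) in enumerate(ordered, start=1)
    ]


def group_traits(
    ratios_by_line: Mapping[str, StressRatioVector],
    line_id: str,
    extra_values: Mapping[str, Mapping[str, float]] | None = None,
) -> TraitGroupReport:
    """Place one line's trait ratios into high/medium/low peer tertiles.

    For each trait the line's ratio is compared with the empirical
    tertiles (1/3 and 2/3 quantiles) of that trait's ratios across all
    lines: strictly above the upper tertile → ``high``, strictly below
    the lower → ``low``, otherwise ``medium`` (so a degenerate, all-equal
    distribution maps everyone to ``medium``).  ``extra_values`` adds
    non-ratio columns (e.g. WUE, PR_SDW) keyed trait → line → value;
    cost traits (PR_SDW) are sign-flipped before banding so that
    ``high`` always means favourable.
    """
    if len(ratios_by_line) < 3:
        raise ValueError("trait grouping needs at least 3 lines for tertiles")
    if line_id not in ratios_by_line:
        raise KeyError(f"line {line_id!r} absent from ratio mapping")

    columns: dict[str, dict[str, float]] = {}
    for trait in TDRI_TRAITS:
        col = {
            lid: v.ratios[trait]
            for lid, v in ratios_by_line.items()
            if v.flags.get(trait) == "ok"
        }
        if len(col) >= 3 and line_id in col:
            columns[trait] = col
    for trait, col in (extra_values or {}).items():
        clean = {lid: float(x) for lid, x in col.items() if not math.isnan(float(x))}
        if len(clean) >= 3 and line_id in clean:
            columns[trait] = clean

    groups: dict[str, str] = {}
    for trait, col in columns.items():
        sign = -1.0 if trait in COST_TRAITS else 1.0
        vals = np.array([sign * v for v in col.values()])
        x = sign * col[line_id]
        q1, q2 = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0])
        if x > q2:
            groups[trait] = "high"
        elif x < q1:
            groups[trait] = "low"
        else:
            groups[trait] = "medium"
    return TraitGroupReport(line_id=line_id, groups=groups)


def tdri_table(
    matrix: TraitMeanMatrix, bands: tuple[float, float] = DEFAULT_BANDS
) -> pd.DataFrame:
    """Full TDRI report for every line in a mean matrix.

    Columns: ``ratio:<trait>`` ×17, ``tdri``, ``rank``, ``band``; rows in
    rank order.  Lines with incomplete ratio vectors raise, listing the
    blocked traits — completeness is never silently patched.
    """
    vectors = {line: stress_ratios(matrix, line) for line in matrix.lines}
    tdri_by_line = {line: compute_tdri(v) for line, v in vectors.items()}
    results = rank_lines(tdri_by_line, bands)
    rows = []
    for res in results:
        row: dict[str, object] = {"line_id": res.line_id}
        for trait in TDRI_TRAITS:
            row[f"ratio:{trait}"] = vectors[res.line_id].ratios[trait]
        row.update(tdri=res.tdri, rank=res.rank, band=res.band)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published reference panel
# ---------------------------------------------------------------------------

#: Published TDRI values for the 18-genotype Super Basmati introgression
#: panel (15 recombinant lines, donor and recurrent parents, tolerant
#: check).  These are reported index values used as classification and
#: ranking inputs; the underlying per-line trait means are unpublished.
SBIR_PANEL_TDRI: dict[str, float] = {
    "SBIR-7-18-1": 14.08513,
    "SBIR-16-21-2": 14.12541,
    "SBIR-76-83-9": 13.95742,
    "SBIR-118-104-11": 13.63789,
    "SBIR-170-258-14": 14.70197,
    "SBIR-175-369-15": 14.5022,
    "SBIR-48-56-5": 16.82162,
    "SBIR-52-60-6": 15.7308,
    "SBIR-58-60-7": 15.41342,
    "SBIR-17-21-3": 17.87805,
    "SBIR-31-43-4": 17.90453,
    "SBIR-62-79-8": 18.23459,
    "SBIR-103-98-10": 17.67977,
    "SBIR-127-105-12": 18.30323,
    "SBIR-153-146-13": 18.73186,
    "IR-554190": 16.48336,
    "Super Basmati": 12.52044,
    "Azucena": 17.6518,
}

#: Role of each non-recombinant entry in the panel.
SBIR_PANEL_ROLES: dict[str, str] = {
    "IR-554190": "donor_parent",
    "Super Basmati": "recurrent_parent",
    "Azucena": "check",
}
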