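"""Mapping sum formulas onto a compound-to-pathway annotation table and
computing coverage and intensity statistics.

Exact-mass data cannot distinguish isomers, so matching is by canonical
formula string: one formula may witness several compounds ("structure
suggestions"). Pathway intensity sums therefore follow a deduplication
rule: a formula contributes its relative intensity at most once per
pathway, no matter how many isomeric members it matches there; a formula
matching compounds in m different pathways contributes once to each.
Coverage is the fraction of a pathway's members that were detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DB_COLUMNS = ("compound_id", "formula", "pathway_id", "pathway_size")


@dataclass
class PathwayDB:
    """Compound -> pathway annotation records with per-pathway sizes.

    ``records`` has columns compound_id, formula, pathway_id,
    pathway_size; the size counts all members of the pathway, detected
    or not, and must be consistent per pathway id.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(DB_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"pathway DB missing columns {sorted(missing)}")
        sizes = self.records.groupby("pathway_id")["pathway_size"].nunique()
        if (sizes > 1).any():
            bad = sizes.index[sizes > 1].tolist()
            raise ValueError(f"inconsistent pathway sizes for {bad}")

    @property
    def pathway_sizes(self) -> pd.Series:
        return self.records.groupby("pathway_id")["pathway_size"].first()

    @classmethod
    def from_tsv(cls, path) -> "PathwayDB":
        return cls(records=pd.read_csv(path, sep="\t", dtype={"pathway_size": int}))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class MatchResult:
    """Formula -> compound matching outcome.

    ``matches`` maps each matched formula to its (deduplicated) matching
    records; ``match_rate`` is matched/assigned; ``mean_multiplicity``
    is the mean number of distinct compound hits among matched formulas
    (the "structure suggestions per matched formula" statistic).
    """

    matches: dict[str, pd.DataFrame]
    n_assigned: int
    match_rate: float
    mean_multiplicity: float

    @property
    def matched_formulas(self) -> list[str]:
        return list(self.matches)

    def pathways_of(self, formula: str) -> set[str]:
        rec = self.matches.get(formula)
        return set(rec["pathway_id"]) if rec is not None else set()


def match_formulas(formulas, db: PathwayDB) -> MatchResult:
    """Match assigned sum formulas against the annotation table."""
    formulas = list(dict.fromkeys(str(f) for f in formulas))
    n_assigned = len(formulas)
    by_formula = dict(tuple(db.records.groupby("formula"))) if len(db.records) else {}
    matches: dict[str, pd.DataFrame] = {}
    for f in formulas:
        rec = by_formula.get(f)
        if rec is not None and len(rec):
            matches[f] = rec.reset_index(drop=True)
    if matches:
        mults = [rec["compound_id"].nunique() for rec in matches.values()]
        mean_mult = float(np.mean(mults))
    else:
        mean_mult = float("nan")
    rate = len(matches) / n_assigned if n_assigned else 0.0
    return MatchResult(
        matches=matches, n_assigned=n_assigned, match_rate=rate, mean_multiplicity=mean_mult
    )


def pathway_intensity(matches: MatchResult, intensities: pd.Series) -> pd.Series:
    """Deduplicated per-pathway relative-intensity sums.

    ``intensities`` maps formula to its relative intensity (a sample or
    a group mean). Each matched formula contributes its intensity
    exactly once to every pathway it matches, regardless of how many
    isomeric compounds it matches within that pathway.
    """
    totals: dict[str, float] = {}
    for formula, rec in matches.matches.items():
        if formula not in intensities.index:
            raise ValueError(f"intensity missing for matched formula {formula!r}")
        value = float(intensities[formula])
        for pathway in set(rec["pathway_id"]):
            totals[pathway] = totals.get(pathway, 0.0) + value
    return pd.Series(totals, name="intensity", dtype=float).sort_index()


def pathway_coverage(matches: MatchResult, db: PathwayDB, count: str = "compounds") -> pd.DataFrame:
    """Coverage per pathway: detected members / pathway size, in [0, 1].

    ``count="compounds"`` counts distinct detected member compounds (one
    formula may witness several isomeric members); ``count="formulas"``
    counts distinct detected formulas instead. Pathways of size zero are
    excluded with a warning.
    """
    if count not in ("compounds", "formulas"):
        raise ValueError(f"unknown counting mode {count!r}")
    detected: dict[str, set] = {}
    n_formulas: dict[str, int] = {}
    for formula, rec in matches.matches.items():
        for pathway, sub in rec.groupby("pathway_id"):
            bucket = detected.setdefault(pathway, set())
            if count == "compounds":
                bucket.update(sub["compound_id"])
            else:
                bucket.add(formula)
            n_formulas[pathway] = n_formulas.get(pathway, 0) + 1
    sizes = db.pathway_sizes
    rows = []
    for pathway in sorted(detected):
        size = int(sizes.get(pathway, 0))
        if size <= 0:
            warnings.warn(f"pathway {pathway!r} has size 0; excluded from coverage", stacklevel=2)
            continue
        n_detected = len(detected[pathway])
        rows.append(
            {
                "pathway_id": pathway,
                "n_detected": n_detected,
                "pathway_size": size,
                "n_formulas": n_formulas[pathway],
                "coverage": min(n_detected / size, 1.0),
            }
        )
    return pd.DataFrame(rows, columns=["pathway_id", "n_detected", "pathway_size", "n_formulas", "coverage"]).set_index("pathway_id")


@dataclass
class CoverageResult:
    """Per-pathway coverage and deduplicated intensity for one dataset
    (e.g. DOM HR-MS, or an externally supplied 16S-based prediction)."""

    label: str
    table: pd.DataFrame  # index pathway_id; columns coverage, intensity, n_formulas
    match_rate: float = float("nan")
    mean_multiplicity: float = float("nan")


def coverage_result(
    label: str, matches: MatchResult, db: PathwayDB, intensities: pd.Series, count: str = "compounds"
) -> CoverageResult:
    """Bundle coverage, dedup intensity and match statistics for a dataset."""
    cov = pathway_coverage(matches, db, count=count)
    intens = pathway_intensity(matches, intensities)
    table = cov.join(intens, how="left").fillna({"intensity": 0.0})
    return CoverageResult(
        label=label,
        table=table,
        match_rate=matches.match_rate,
        mean_multiplicity=matches.mean_multiplicity,
    )


def coverage_dispersion(coverage_by_group: dict[str, pd.Series]) -> tuple[pd.DataFrame, float]:
    """Cross-group spread of per-pathway coverage.

    Takes coverage Series (pathway -> coverage) per sample group and
    returns a per-pathway mean/SD table plus the overall mean SD. The SD
    is the sample standard deviation (ddof=1) across groups; pathways
    absent from a group count as coverage 0 there.
    """
    if len(coverage_by_group) < 2:
        raise ValueError("need at least 2 groups for a coverage dispersion")
    wide = pd.DataFrame(coverage_by_group).fillna(0.0)
    out = pd.DataFrame(
        {"mean": wide.mean(axis=1), "sd": wide.std(axis=1, ddof=1)}
    )
    out.index.name = "pathway_id"
    return out, float(out["sd"].mean())


def compare_coverage(
    dom: CoverageResult,
    other: CoverageResult,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Joint per-pathway coverage table across two datasets with
    quadrant classification (both-high / dom-only / other-only /
    both-low at the given coverage threshold). Pathways present in only
    one dataset are kept and flagged, never silently dropped."""
    a = dom.table["coverage"].rename("coverage_dom")
    b = other.table["coverage"].rename(f"coverage_{other.label}")
    joint = pd.concat([a, b], axis=1)
    if joint.empty or (a.index.intersection(b.index)).empty:
        warnings.warn("the two coverage tables share no pathways", stacklevel=2)
    missing = joint.isna().any(axis=1)

    def classify(row) -> str:
        if np.isnan(row.iloc[0]) or np.isnan(row.iloc[1]):
            return "missing"
        hi_a, hi_b = row.iloc[0] >= threshold, row.iloc[1] >= threshold
        if hi_a and hi_b:
            return "both-high"
        if hi_a:
            return "dom-only"
        if hi_b:
            return "other-only"
        return "both-low"

    joint["quadrant"] = joint.apply(classify, axis=1)
    joint["missing"] = missing
    joint.index.name = "pathway_id"
    return joint.sort_index()
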