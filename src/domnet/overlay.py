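"""Pathway-on-network overlay: how the annotated molecules of each
metabolic pathway distribute across network modules.

A pathway whose molecules concentrate in one module points at a
litter- or stage-specific function; a pathway spread over many modules
(low concentration index) is ubiquitous across the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .pathways import MatchResult


@dataclass
class OverlayTable:
    """Pathway x module distribution of annotated molecules.

    ``counts``: distinct annotated formulas of each pathway per module;
    ``fractions``: counts normalised per pathway row; ``concentration``:
    each pathway's maximum module fraction; ``ubiquitous``: True when no
    module holds more than the threshold fraction. ``enrichment`` holds
    hypergeometric p-values (BH-adjusted) when requested, else None.
    """

    counts: pd.DataFrame
    fractions: pd.DataFrame
    concentration: pd.Series
    ubiquitous: pd.Series
    ubiquity_threshold: float
    enrichment: pd.DataFrame | None = None


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def overlay(
    module_labels: pd.Series,
    matches: MatchResult,
    ubiquity_threshold: float = 0.5,
    enrichment: bool = False,
) -> OverlayTable:
    """Cross-tabulate each pathway's matched formulas over modules.

    Every matched formula must carry a module label ("grey" allowed);
    formulas absent from the network are ignored, and pathways with no
    formula in the network are excluded with a note. Optional
    enrichment: per (pathway, module) hypergeometric upper-tail
    p-values, BH-corrected across the whole table.
    """
    pathway_formulas: dict[str, set[str]] = {}
    for formula, rec in matches.matches.items():
        if formula not in module_labels.index:
            continue
        for pathway in set(rec["pathway_id"]):
            pathway_formulas.setdefault(pathway, set()).add(formula)
    empty = [
        p
        for formula, rec in matches.matches.items()
        if formula not in module_labels.index
        for p in set(rec["pathway_id"])
        if p not in pathway_formulas
    ]
    if empty:
        warnings.warn(
            f"{len(set(empty))} pathway(s) have no matched formula in the network; excluded",
            stacklevel=2,
        )
    modules = sorted(module_labels.unique())
    counts = pd.DataFrame(0, index=sorted(pathway_formulas), columns=modules, dtype=int)
    for pathway, formulas in pathway_formulas.items():
        for f in formulas:
            counts.loc[pathway, module_labels[f]] += 1
    counts.index.name = "pathway_id"
    totals = counts.sum(axis=1)
    fractions = counts.div(totals, axis=0)
    concentration = fractions.max(axis=1).rename("concentration")
    ubiquitous = (concentration < ubiquity_threshold).rename("ubiquitous")
    enrich = None
    if enrichment and len(counts):
        labeled = module_labels[module_labels.index.isin(set().union(*pathway_formulas.values()))]
        population = int(len(labeled))
        module_sizes = labeled.value_counts()
        rows = []
        for pathway in counts.index:
            n_path = int(totals[pathway])
            for module in modules:
                k = int(counts.loc[pathway, module])
                big_k = int(module_sizes.get(module, 0))
                p = float(hypergeom.sf(k - 1, population, big_k, n_path)) if big_k else 1.0
                rows.append({"pathway_id": pathway, "module": module, "overlap": k, "p_value": p})
        enrich = pd.DataFrame(rows)
        enrich["p_adjusted"] = _bh_adjust(enrich["p_value"].to_numpy())
    return OverlayTable(
        counts=counts,
        fractions=fractions,
        concentration=concentration,
        ubiquitous=ubiquitous,
        ubiquity_threshold=ubiquity_threshold,
        enrichment=enrich,
    )


def highlight_table(
    overlay_table: OverlayTable, coordinates: pd.DataFrame, module_labels: pd.Series, pathway: str,
    matches: MatchResult,
) -> pd.DataFrame:
    """Join embedding coordinates with a per-pathway highlight flag, for
    plotting one pathway's molecules on the 3-D network."""
    highlighted = {
        f
        for f, rec in matches.matches.items()
        if pathway in set(rec["pathway_id"]) and f in coordinates.index
    }
    out = coordinates.copy()
    out["module"] = module_labels.reindex(out.index).fillna("grey")
    out["highlighted"] = [f in highlighted for f in out.index]
    return out
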