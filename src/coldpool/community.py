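"""Species temperature preferences, community temperature index, functional groups.

A species temperature index (STI) is the mean of a long-term gridded
temperature surface over the species' geographic range — a single preferred
temperature in degC. The community temperature index (CTI) of a plot x
stratum is the abundance-weighted mean STI of its community, with weights
equal to stem-count proportions, so communities of cold-preference species
score low and warm-preference communities score high.

The primary input path is a precomputed STI table (species_code, leaf_habit,
sti_c); the raster route (:func:`species_temperature_index`) serves
fixture-scale grids held as plain 2-D arrays. A handful of field codes need
substitution before lookup: taxa absent from the range database borrow a
congener's STI, and an indistinguishable species pair maps to the mean of
its two members' STIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PreferenceError(KeyError):
    """Raised when surveyed species codes cannot be resolved to an STI."""


def species_temperature_index(mask: np.ndarray, raster: np.ndarray) -> float:
    """Unweighted mean of raster cells inside a species' range mask.

    ``mask`` is boolean, ``raster`` numeric, both on the same grid. Cells are
    weighted equally (on a ~1-km grid at mid-latitudes, area weighting would
    change values negligibly).
    """
    mask = np.asarray(mask, dtype=bool)
    raster = np.asarray(raster, dtype=float)
    if mask.shape != raster.shape:
        raise ValueError(f"mask shape {mask.shape} != raster shape {raster.shape}")
    if not mask.any():
        raise ValueError("range mask selects no raster cells")
    return float(raster[mask].mean())


@dataclass(frozen=True)
class SubstitutionRules:
    """Code-level fixes applied before STI lookup.

    ``borrow`` maps an unresolvable code to the code whose STI it inherits
    (e.g. a birch absent from the range database borrows its widespread
    congener's value). ``hybrid_average`` maps a field designation covering
    an indistinguishable pair to the two member codes whose STIs are
    averaged (e.g. 'black/red spruce' where the two spruces hybridise).
    """

    borrow: dict[str, str] = field(default_factory=dict)
    hybrid_average: dict[str, tuple[str, str]] = field(default_factory=dict)


#: Default rules for the standard field-code situations.
DEFAULT_RULES = SubstitutionRules(
    borrow={"BECO": "BEPA"},  # Betula cordifolia -> B. papyrifera
    hybrid_average={"PIMA/PIRU": ("PIMA", "PIRU")},  # black/red spruce
)


def resolve_preference(
    species_code: str,
    table: pd.DataFrame,
    rules: SubstitutionRules = DEFAULT_RULES,
) -> dict:
    """Resolve one species code to (leaf_habit, STI, provenance).

    Direct table hits resolve as-is; otherwise the borrow and hybrid-average
    rules apply. Unresolvable codes raise :class:`PreferenceError`.
    """
    t = table.set_index("species_code")
    if species_code in t.index:
        row = t.loc[species_code]
        return {"species_code": species_code, "leaf_habit": row["leaf_habit"],
                "sti_c": float(row["sti_c"]),
                "provenance": row.get("provenance", "table")}
    if species_code in rules.borrow:
        src = rules.borrow[species_code]
        if src not in t.index:
            raise PreferenceError(f"substitution source {src!r} for {species_code!r} not in table")
        row = t.loc[src]
        return {"species_code": species_code, "leaf_habit": row["leaf_habit"],
                "sti_c": float(row["sti_c"]), "provenance": "substitution"}
    if species_code in rules.hybrid_average:
        a, b = rules.hybrid_average[species_code]
        missing = [c for c in (a, b) if c not in t.index]
        if missing:
            raise PreferenceError(f"hybrid members {missing} for {species_code!r} not in table")
        return {"species_code": species_code, "leaf_habit": t.loc[a, "leaf_habit"],
                "sti_c": float((t.loc[a, "sti_c"] + t.loc[b, "sti_c"]) / 2.0),
                "provenance": "hybrid-average"}
    raise PreferenceError(f"unresolvable species code: {species_code!r}")


def resolve_preferences(
    codes: "pd.Series | list[str]",
    table: pd.DataFrame,
    rules: SubstitutionRules = DEFAULT_RULES,
) -> pd.DataFrame:
    """Resolve every surveyed code; raise once listing all failures."""
    unique = pd.unique(pd.Series(codes))
    rows, unmatched = [], []
    for code in unique:
        try:
            rows.append(resolve_preference(code, table, rules))
        except PreferenceError:
            unmatched.append(code)
    if unmatched:
        raise PreferenceError(f"unresolvable species codes: {sorted(unmatched)}")
    return pd.DataFrame(rows)


def community_temperature_index(
    surveys: pd.DataFrame,
    preferences: pd.DataFrame,
) -> pd.DataFrame:
    """CTI per plot x stratum: stem-proportion-weighted mean STI.

    CTI = sum_s (count_s / total) * STI_s over the species present, computed
    separately for overstory and understory. Plot x stratum combinations
    with zero stems carry no CTI and are absent from the output.
    """
    prefs = preferences.set_index("species_code")["sti_c"]
    unknown = set(surveys["species_code"]) - set(prefs.index)
    if unknown:
        raise PreferenceError(f"surveys contain unresolved species codes: {sorted(unknown)}")
    df = surveys[surveys["count"] > 0].copy()
    df["sti_c"] = df["species_code"].map(prefs)
    df["weighted"] = df["count"] * df["sti_c"]
    out = (
        df.groupby(["plot_id", "stratum"], sort=False)
        .agg(total_stems=("count", "sum"), n_species=("species_code", "nunique"),
             weighted=("weighted", "sum"))
        .reset_index()
    )
    out["cti_c"] = out["weighted"] / out["total_stems"]
    return out[["plot_id", "stratum", "cti_c", "total_stems", "n_species"]]


def classify_functional_groups(preferences: pd.DataFrame) -> pd.DataFrame:
    """Split species into conifer / cold-broadleaved / warm-broadleaved.

    The conifer STI range [min, max] is the reference: broadleaves with STI
    at or below the conifer maximum are cold-broadleaved, those above it
    warm-broadleaved. Broadleaves below the conifer minimum also count as
    cold-broadleaved, keeping the partition exhaustive. At least one conifer
    is required, otherwise the range is undefined.
    """
    conifers = preferences[preferences["leaf_habit"] == "conifer"]
    if conifers.empty:
        raise ValueError("functional-group split requires at least one conifer STI")
    cmax = conifers["sti_c"].max()
    out = preferences.copy()

    def _group(row) -> str:
        if row["leaf_habit"] == "conifer":
            return "conifer"
        return "cold-broadleaved" if row["sti_c"] <= cmax else "warm-broadleaved"

    out["functional_group"] = out.apply(_group, axis=1)
    return out[["species_code", "leaf_habit", "sti_c", "functional_group"]]


def group_abundances(
    surveys: pd.DataFrame,
    groups: pd.DataFrame,
) -> pd.DataFrame:
    """Stem count and proportion per functional group per plot x stratum."""
    gmap = groups.set_index("species_code")["functional_group"]
    unknown = set(surveys["species_code"]) - set(gmap.index)
    if unknown:
        raise PreferenceError(f"surveys contain unclassified species codes: {sorted(unknown)}")
    df = surveys.copy()
    df["functional_group"] = df["species_code"].map(gmap)
    counts = (
        df.groupby(["plot_id", "stratum", "functional_group"], sort=False)["count"]
        .sum()
        .reset_index(name="stems")
    )
    # every group appears for every surveyed plot x stratum, zero-filled
    idx = pd.MultiIndex.from_product(
        [counts["plot_id"].unique(), list(pd.unique(df["stratum"])),
         ["conifer", "cold-broadleaved", "warm-broadleaved"]],
        names=["plot_id", "stratum", "functional_group"],
    )
    counts = (
        counts.set_index(["plot_id", "stratum", "functional_group"])
        .reindex(idx, fill_value=0)
        .reset_index()
    )
    totals = counts.groupby(["plot_id", "stratum"], sort=False)["stems"].transform("sum")
    counts = counts[totals > 0].copy()
    counts["proportion"] = counts["stems"] / totals[totals > 0]
    return counts
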