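"""Shared-association detection across gut locations.

A (taxon, metabolite) pair is "shared" between locations when it passes
the FDR threshold in every member location independently; no meta-
analysis is performed across locations. Sign concordance records whether
the combined Z carries the same direction everywhere (associations can
flip sign between locations). Genus- and ASV-level results are never
mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd


@dataclass
class CrossLocationReport:
    q_threshold: float
    level: str
    per_location_counts: dict[str, int]
    shared: dict[tuple[str, ...], set[tuple[str, str]]]
    sign_concordant: dict[tuple[str, ...], dict[tuple[str, str], bool]]
    annotated_only: bool = False

    def three_way(self) -> set[tuple[str, str]]:
        keys = [k for k in self.shared if len(k) == 3]
        return self.shared[keys[0]] if keys else set()

    def summary(self) -> pd.DataFrame:
        rows = [{"locations": "+".join(k), "n_shared": len(v),
                 "n_concordant": sum(self.sign_concordant[k].values())}
                for k, v in sorted(self.shared.items(), key=lambda kv: kv[0])]
        return pd.DataFrame(rows)


def shared_associations(results_by_location: dict[str, pd.DataFrame],
                        q_threshold: float = 0.05) -> CrossLocationReport:
    """Intersect significant pairs across every 2- and 3-location subset.

    ``results_by_location`` maps location name to an association scan
    table (all at the same taxonomic level).
    """
    if len(results_by_location) < 2:
        raise ValueError("need results from at least two locations")
    levels = {str(df["level"].iloc[0]) for df in results_by_location.values() if len(df)}
    if len(levels) > 1:
        raise ValueError(f"mismatched taxonomic levels across locations: {sorted(levels)}")
    level = levels.pop() if levels else "ASV"

    sig_pairs: dict[str, set[tuple[str, str]]] = {}
    signs: dict[str, dict[tuple[str, str], str]] = {}
    for loc, df in results_by_location.items():
        sig = df[df["q_value"] < q_threshold]
        pairs = set(zip(sig["taxon_id"], sig["metabolite_id"]))
        sig_pairs[loc] = pairs
        signs[loc] = dict(zip(zip(sig["taxon_id"], sig["metabolite_id"]),
                              sig["direction"]))

    shared: dict[tuple[str, ...], set[tuple[str, str]]] = {}
    concordant: dict[tuple[str, ...], dict[tuple[str, str], bool]] = {}
    locs = sorted(results_by_location)
    for r in (2, 3):
        for combo in combinations(locs, r):
            inter = set.intersection(*(sig_pairs[loc] for loc in combo))
            shared[combo] = inter
            concordant[combo] = {
                pair: len({signs[loc][pair] for loc in combo}) == 1
                for pair in inter}

    return CrossLocationReport(
        q_threshold=q_threshold, level=level,
        per_location_counts={loc: len(sig_pairs[loc]) for loc in locs},
        shared=shared, sign_concordant=concordant)


def venn_counts(sets_by_location: dict[str, set]) -> dict[str, int]:
    """Exact region counts of a 2- or 3-set Venn diagram.

    Region keys name the member locations joined by "&" (e.g. "cecum" for
    the cecum-exclusive region, "cecum&faeces" for the pairwise-exclusive
    overlap). The counts sum to the union size.
    """
    if len(sets_by_location) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets_by_location)
    universe = set().union(*sets_by_location.values())
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets_by_location[n] for n in combo))
            outside = set().union(*(sets_by_location[n] for n in names
                                    if n not in combo)) if len(combo) < len(names) else set()
            counts["&".join(combo)] = len(inside - outside)
    assert sum(counts.values()) == len(universe)
    return counts
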