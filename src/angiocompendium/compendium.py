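"""Pathway-compendium scoring of differential-expression profiles.

Each treatment's DE profile is scored against the nine angiogenic hub
pathways, split into genes upstream and downstream of the hub molecule.
Every significant member gene contributes one count to its stratum in the
state (up/down) given by its fold-change direction; the stratum's percent
activation is 100*(up+down)/|stratum| — the "percentage normalization" that
makes profiles comparable when knowledge-base strata differ in size.  The
concatenated percents over (pathway alphabetical x upstream-then-downstream)
form the 18-feature fingerprint consumed by the PLSR growth model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .knowledge import STRATA, PathwayCompendium

__all__ = [
    "CompendiumProfile",
    "feature_names",
    "score_pathways",
    "percent_normalize",
    "temporal_profile",
    "profile_to_long",
    "profiles_to_wide",
]


def feature_names(kb: PathwayCompendium) -> list[str]:
    """Feature labels in fixed order: pathway (alphabetical, case-insensitive)
    x stratum (upstream then downstream)."""
    return [f"{p}:{s}" for p in kb.pathway_names for s in STRATA]


@dataclass
class CompendiumProfile:
    """Per-treatment pathway activation fingerprint.

    ``counts`` maps (pathway, stratum) to (n_up, n_down) significant member
    genes; ``sizes`` holds the stratum memberships; ``percents`` is the
    percent-normalized feature vector aligned with ``features``.
    """

    treatment: str
    counts: Mapping[tuple[str, str], tuple[int, int]]
    sizes: Mapping[tuple[str, str], int]
    features: list[str]
    percents: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.percents, index=self.features, name=self.treatment)


def score_pathways(
    de: pd.DataFrame, kb: PathwayCompendium, treatment: str | None = None
) -> CompendiumProfile:
    """Count significant DE genes per pathway stratum, split by direction.

    A gene belonging to several pathways contributes to each of them (but
    once per stratum); significant genes outside the compendium contribute
    nowhere.
    """
    if treatment is None:
        treatment = de.attrs.get("treatment", "")
    sig = de[de["significant"]]
    up = {str(g).upper() for g in sig.index[sig["direction"] == "up"]}
    down = {str(g).upper() for g in sig.index[sig["direction"] == "down"]}
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    sizes: dict[tuple[str, str], int] = {}
    for pathway in kb.pathway_names:
        for stratum in STRATA:
            members = kb.pathways[pathway][stratum]
            counts[(pathway, stratum)] = (len(members & up), len(members & down))
            sizes[(pathway, stratum)] = len(members)
    profile = CompendiumProfile(
        treatment=treatment,
        counts=counts,
        sizes=sizes,
        features=feature_names(kb),
        percents=np.zeros(2 * len(kb.pathway_names)),
    )
    profile.percents = percent_normalize(profile)
    return profile


def percent_normalize(profile: CompendiumProfile) -> np.ndarray:
    """Percent of each stratum's membership that is significantly DE.

    Empty strata are reported as 0 with a warning rather than an error so
    that sparse knowledge bases still yield full-length feature vectors.
    """
    values = np.zeros(len(profile.features))
    empty: list[str] = []
    for i, name in enumerate(profile.features):
        pathway, stratum = name.rsplit(":", 1)
        size = profile.sizes[(pathway, stratum)]
        n_up, n_down = profile.counts[(pathway, stratum)]
        if size == 0:
            empty.append(name)
            values[i] = 0.0
        else:
            values[i] = 100.0 * (n_up + n_down) / size
    if empty:
        warnings.warn(
            f"empty compendium strata reported as 0%: {empty}", stacklevel=2
        )
    return values


def temporal_profile(
    de_tables: Sequence[pd.DataFrame], kb: PathwayCompendium
) -> pd.DataFrame:
    """Apply the compendium to an ordered series of DE tables (time course).

    All tables must share one gene universe; returns a timepoints x features
    matrix in the given order.
    """
    if len(de_tables) == 0:
        return pd.DataFrame(columns=feature_names(kb))
    universe = set(de_tables[0].index)
    for i, table in enumerate(de_tables[1:], 1):
        if set(table.index) != universe:
            raise ValueError(
                f"DE table {i} has a different gene universe than table 0"
            )
    rows = [score_pathways(t, kb).percents for t in de_tables]
    return pd.DataFrame(
        np.vstack(rows),
        index=pd.RangeIndex(len(de_tables), name="timepoint"),
        columns=feature_names(kb),
    )


def profile_to_long(profile: CompendiumProfile) -> pd.DataFrame:
    """Long-format table: one row per (pathway, stratum) with counts,
    membership size and percent."""
    records = []
    for i, name in enumerate(profile.features):
        pathway, stratum = name.rsplit(":", 1)
        n_up, n_down = profile.counts[(pathway, stratum)]
        records.append(
            {
                "treatment": profile.treatment,
                "pathway": pathway,
                "stratum": stratum,
                "up": n_up,
                "down": n_down,
                "size": profile.sizes[(pathway, stratum)],
                "percent": profile.percents[i],
            }
        )
    return pd.DataFrame.from_records(records)


def profiles_to_wide(profiles: Sequence[CompendiumProfile]) -> pd.DataFrame:
    """Wide feature matrix (treatments x features) for the PLSR model."""
    if not profiles:
        return pd.DataFrame()
    frame = pd.DataFrame([p.as_series() for p in profiles])
    frame.index.name = "treatment"
    return frame
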