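"""Upstream-regulator inference from differential-expression profiles.

A regulator's known targets are tested for enrichment among significant DE
genes with a one-tailed Fisher exact (hypergeometric) test against the
measured gene universe, and its activation state is inferred from sign
consistency: over significant targets, s_i = +1 when the observed direction
matches the direction the signed edge predicts under regulator activation
and -1 otherwise, giving the activation z-score z = sum(s_i)/sqrt(N).
z >= +threshold calls the regulator activated, z <= -threshold inactivated.
The statistic is the unweighted sign-consistency form (all edges weighted
equally); no literature-confidence weighting is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .knowledge import RegulatorNetwork

__all__ = [
    "RegulatorCall",
    "enrichment_p",
    "activation_z",
    "call_regulators",
    "overlap_table",
    "calls_to_frame",
]


@dataclass(frozen=True)
class RegulatorCall:
    regulator: str
    overlap_p: float
    z: float
    state: str  # activated | inactivated | undetermined
    n_targets_in_de: int


def enrichment_p(
    targets: Iterable[str], de_genes: Iterable[str], universe: Iterable[str]
) -> float:
    """One-tailed (greater) Fisher exact p for target/DE overlap.

    Equals the hypergeometric upper tail P(X >= k) of drawing |de_genes|
    genes from the universe and hitting k = |targets & de_genes| targets.
    """
    uni = {str(g).upper() for g in universe}
    if not uni:
        raise ValueError("empty gene universe")
    tset = {str(g).upper() for g in targets}
    dset = {str(g).upper() for g in de_genes}
    if not tset <= uni:
        raise ValueError("targets are not a subset of the universe")
    if not dset <= uni:
        raise ValueError("de_genes are not a subset of the universe")
    k = len(tset & dset)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(tset), len(dset)))
    return min(1.0, max(p, math.ulp(0.0)))


def activation_z(
    edges: Iterable[tuple], de: pd.DataFrame
) -> float:
    """Sign-consistency activation z-score for one regulator's edges.

    ``edges`` are (target, sign) pairs or (regulator, target, sign) triples.
    A +1 edge predicts its target up under regulator activation, a -1 edge
    predicts it down.  Returns 0.0 when no target is significant (state is
    undetermined; callers should check the significant-target count).
    """
    sig = de[de["significant"]]
    directions = {
        str(g).upper(): d for g, d in zip(sig.index, sig["direction"])
    }
    consistency = 0
    n = 0
    for edge in edges:
        target, sign = edge[-2], int(edge[-1])
        observed = directions.get(str(target).upper())
        if observed is None:
            continue
        predicted = "up" if sign > 0 else "down"
        n += 1
        consistency += 1 if observed == predicted else -1
    if n == 0:
        return 0.0
    return consistency / math.sqrt(n)


def call_regulators(
    net: RegulatorNetwork,
    de: pd.DataFrame,
    universe: Iterable[str],
    p_max: float = 0.01,
    z_threshold: float = 2.0,
) -> list[RegulatorCall]:
    """Score every regulator in the network against one DE profile.

    Calls are sorted by enrichment p ascending (ties by name).  A state is
    only assigned (via z thresholding) to regulators passing ``p_max`` with
    at least one significant target; all others are undetermined.
    """
    uni = {str(g).upper() for g in universe}
    sig_genes = {str(g).upper() for g in de.index[de["significant"]]}
    calls: list[RegulatorCall] = []
    for regulator in net.regulators:
        target_signs = net.targets_of(regulator)
        targets_in_uni = set(target_signs) & uni
        p = enrichment_p(targets_in_uni, sig_genes, uni)
        edges = [(t, s) for t, s in target_signs.items() if t in uni]
        n_sig = len(targets_in_uni & sig_genes)
        z = activation_z(edges, de)
        if n_sig == 0 or p >= p_max:
            state = "undetermined"
        elif z >= z_threshold:
            state = "activated"
        elif z <= -z_threshold:
            state = "inactivated"
        else:
            state = "undetermined"
        calls.append(
            RegulatorCall(
                regulator=regulator,
                overlap_p=p,
                z=z,
                state=state,
                n_targets_in_de=n_sig,
            )
        )
    calls.sort(key=lambda c: (c.overlap_p, c.regulator))
    return calls


def overlap_table(
    calls_by_treatment: Mapping[str, Sequence[RegulatorCall]], state: str
) -> pd.DataFrame:
    """Square cross-treatment overlap matrix for one activation state.

    Diagonal entries count each treatment's calls in ``state``; off-diagonal
    entries are pairwise intersection sizes (symmetric by construction).
    """
    if state not in ("activated", "inactivated"):
        raise ValueError("state must be 'activated' or 'inactivated'")
    if len(calls_by_treatment) < 2:
        raise ValueError("need at least 2 treatments")
    sets = {
        t: {c.regulator for c in calls if c.state == state}
        for t, calls in calls_by_treatment.items()
    }
    order = list(calls_by_treatment)
    matrix = np.zeros((len(order), len(order)), dtype=int)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            matrix[i, j] = len(sets[a] & sets[b])
    return pd.DataFrame(matrix, index=order, columns=order)


def calls_to_frame(calls: Sequence[RegulatorCall]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "regulator": c.regulator,
                "overlap_p": c.overlap_p,
                "z": c.z,
                "state": c.state,
                "n_targets_in_de": c.n_targets_in_de,
            }
            for c in calls
        ],
        columns=["regulator", "overlap_p", "z", "state", "n_targets_in_de"],
    )
    frame.attrs["z_statistic"] = "unweighted sign-consistency"
    return frame
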