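"""User-supplied knowledge bases: pathway compendium, signed regulator
network, and global interaction graph.

Three plain-text formats are read and written:

* extended GMT for the compendium — one line per pathway stratum,
  ``<pathway>\\t<upstream|downstream>\\t<gene>\\t<gene>...``;
* 3-column TSV for the signed regulator network (regulator, target, +1/-1);
* SIF for the undirected interaction graph (``geneA\\tpp\\tgeneB``).

Gene identifiers are case-normalized to upper case throughout.  Pathway
names are canonicalized so that unicode spellings of the nine required
angiogenic pathways (e.g. TGF-β, TNF-α) map onto their ASCII forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "REQUIRED_PATHWAYS",
    "STRATA",
    "PathwayCompendium",
    "RegulatorNetwork",
    "FocusResult",
    "canonical_pathway",
    "load_compendium",
    "write_compendium",
    "load_regulator_network",
    "write_regulator_network",
    "load_sif",
    "write_sif",
    "focus_genes",
]

#: The nine hub pathways every compendium must name (extras are allowed).
REQUIRED_PATHWAYS = (
    "Ang1",
    "bFGF",
    "CCL2",
    "NR3C1",
    "PDGF",
    "PGF",
    "TGF-beta",
    "TNF-alpha",
    "VEGF",
)

STRATA = ("upstream", "downstream")

_CANON = {p.casefold(): p for p in REQUIRED_PATHWAYS}
_CANON_NOSEP = {p.casefold().replace("-", ""): p for p in REQUIRED_PATHWAYS}


def canonical_pathway(name: str) -> str:
    """Map spelling variants of the required pathway names to canonical form.

    Greek letters are transliterated (β -> beta, α -> alpha) and matching is
    case-insensitive with separators ignored; unknown names pass through
    stripped but otherwise untouched.
    """
    s = name.strip().replace("β", "beta").replace("α", "alpha")
    key = s.casefold().replace("_", "-").replace(" ", "-")
    hit = _CANON.get(key)
    if hit is None:
        hit = _CANON_NOSEP.get(key.replace("-", ""))
    return hit if hit is not None else s


@dataclass(frozen=True)
class PathwayCompendium:
    """Pathway -> {upstream, downstream} member gene sets.

    Within each pathway the two strata are disjoint; the nine required
    pathway names must all be present.
    """

    pathways: Mapping[str, Mapping[str, frozenset[str]]]

    @classmethod
    def from_dict(cls, raw: Mapping[str, Mapping[str, Iterable[str]]]) -> "PathwayCompendium":
        cleaned: dict[str, dict[str, frozenset[str]]] = {}
        for name, strata in raw.items():
            cname = canonical_pathway(str(name))
            entry = cleaned.setdefault(cname, {s: frozenset() for s in STRATA})
            for stratum, genes in strata.items():
                s = str(stratum).strip().lower()
                if s not in STRATA:
                    raise ValueError(
                        f"pathway {cname!r}: unknown stratum {stratum!r} "
                        f"(expected one of {STRATA})"
                    )
                entry[s] = entry[s] | frozenset(str(g).upper() for g in genes)
        missing = [p for p in REQUIRED_PATHWAYS if p not in cleaned]
        if missing:
            raise ValueError(f"compendium is missing required pathways: {missing}")
        for name, strata in cleaned.items():
            overlap = strata["upstream"] & strata["downstream"]
            if overlap:
                raise ValueError(
                    f"pathway {name!r}: genes present in both strata: "
                    f"{sorted(overlap)}"
                )
        return cls(pathways=cleaned)

    def members(self, pathway: str, stratum: str) -> frozenset[str]:
        return self.pathways[canonical_pathway(pathway)][stratum]

    @property
    def pathway_names(self) -> list[str]:
        """Pathway names in the canonical (case-insensitive alphabetical) order."""
        return sorted(self.pathways, key=str.casefold)

    @property
    def all_genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for strata in self.pathways.values():
            for genes in strata.values():
                out |= genes
        return out


def load_compendium(path) -> PathwayCompendium:
    """Read an extended-GMT compendium file and validate it."""
    raw: dict[str, dict[str, set[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            name = canonical_pathway(parts[0])
            stratum = parts[1].strip().lower()
            if stratum not in STRATA:
                raise ValueError(
                    f"{path}:{lineno}: unknown stratum {parts[1]!r} "
                    f"(expected one of {STRATA})"
                )
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            raw.setdefault(name, {s: set() for s in STRATA})[stratum] |= genes
    return PathwayCompendium.from_dict(raw)


def write_compendium(compendium: PathwayCompendium, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in compendium.pathway_names:
            for stratum in STRATA:
                genes = sorted(compendium.pathways[name][stratum])
                handle.write("\t".join([name, stratum, *genes]) + "\n")


@dataclass(frozen=True)
class RegulatorNetwork:
    """Signed regulator -> target edges (+1 activating, -1 repressing)."""

    edges: tuple[tuple[str, str, int], ...] = field(default_factory=tuple)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int]]) -> "RegulatorNetwork":
        cleaned: list[tuple[str, str, int]] = []
        seen: set[tuple[str, str]] = set()
        for reg, target, sign in edges:
            reg = str(reg).upper()
            target = str(target).upper()
            sign = int(sign)
            if sign not in (1, -1):
                raise ValueError(
                    f"edge ({reg}, {target}): sign must be +1 or -1, got {sign}"
                )
            if (reg, target) in seen:
                raise ValueError(f"duplicate edge ({reg}, {target})")
            seen.add((reg, target))
            cleaned.append((reg, target, sign))
        return cls(edges=tuple(cleaned))

    @property
    def regulators(self) -> list[str]:
        return sorted({reg for reg, _, _ in self.edges})

    def targets_of(self, regulator: str) -> dict[str, int]:
        regulator = str(regulator).upper()
        return {t: s for r, t, s in self.edges if r == regulator}


def load_regulator_network(path) -> RegulatorNetwork:
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["regulator", "target", "sign"],
    )
    sign = frame["sign"].astype(str).str.replace("+", "", regex=False).astype(int)
    return RegulatorNetwork.from_edges(
        zip(frame["regulator"], frame["target"], sign)
    )


def write_regulator_network(net: RegulatorNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for reg, target, sign in sorted(net.edges):
            handle.write(f"{reg}\t{target}\t{sign:+d}\n")


def load_sif(path) -> nx.Graph:
    """Read an undirected SIF interaction graph (simple graph enforced)."""
    graph = nx.Graph()
    n_loops = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                graph.add_node(parts[0].strip().upper())
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'a<TAB>rel<TAB>b'")
            a = parts[0].strip().upper()
            for b in parts[2:]:
                b = b.strip().upper()
                if not b:
                    continue
                if a == b:
                    n_loops += 1
                    continue
                graph.add_edge(a, b)
    if n_loops:
        warnings.warn(f"{path}: dropped {n_loops} self-loop(s)", stacklevel=2)
    return graph


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            handle.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            handle.write(f"{node}\n")


@dataclass(frozen=True)
class FocusResult:
    """Significant genes eligible for network analysis."""

    genes: frozenset[str]
    eligibility_percent: float
    n_significant: int


def focus_genes(de: pd.DataFrame, graph: nx.Graph) -> FocusResult:
    """Select focus genes: significant DE genes with >= 1 interaction edge.

    The eligibility percentage is 100*|focus|/|significant| rounded to one
    decimal (0.0 when there are no significant genes).
    """
    significant = {str(g).upper() for g in de.index[de["significant"]]}
    focus = frozenset(
        g for g in significant if g in graph and graph.degree(g) > 0
    )
    if significant:
        pct = round(100.0 * len(focus) / len(significant), 1)
    else:
        pct = 0.0
    return FocusResult(
        genes=focus, eligibility_percent=pct, n_significant=len(significant)
    )
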