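"""End-to-end orchestration: simulate/load -> DE -> focus -> compendium ->
regulators -> networks -> PLSR, from a single YAML configuration.

Every run is a pure function of (config, seed): all randomness flows from
the configured seed, stage outputs are plain CSV/JSON/TSV, and a manifest
records the config hash, seed, package version and a SHA-256 content hash
of every file written, so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compendium import (
    CompendiumProfile,
    profile_to_long,
    profiles_to_wide,
    score_pathways,
)
from .knowledge import (
    FocusResult,
    PathwayCompendium,
    RegulatorNetwork,
    focus_genes,
    load_compendium,
    load_regulator_network,
    load_sif,
    write_compendium,
    write_regulator_network,
    write_sif,
)
from .networks import (
    GeneNetwork,
    annotate_regulation,
    build_networks,
    common_nodes,
    degree_ranking,
)
from .plsr import PLSRModel, PruneResult, fit, percent_error, predict, sensitivity_prune
from .preprocess import DEFAULT_THRESHOLD, ExpressionSet, quantile_normalize, select_de
from .regulators import RegulatorCall, call_regulators, calls_to_frame, overlap_table
from .synthetic import (
    SimulationConfig,
    generate_expression_set,
    generate_growth_response,
    generate_knowledge_base,
)

__all__ = [
    "ConfigError",
    "StageError",
    "InputPaths",
    "RunConfig",
    "ReportBundle",
    "run_all",
]

logger = logging.getLogger("angiocompendium")


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class InputPaths:
    """File-based inputs used instead of simulation."""

    expression: dict[str, Path]  # treatment -> TSV
    compendium: Path
    regulator_network: Path
    interaction_graph: Path
    growth: Path | None = None


@dataclass
class RunConfig:
    output_dir: Path
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: InputPaths | None = None
    de_threshold: float = DEFAULT_THRESHOLD
    z_threshold: float = 2.0
    p_max: float = 0.01
    size_cap: int = 35
    n_networks: int = 3
    n_components: int | None = None
    plsr_holdout: str | None = None
    quantile_normalization: bool = True
    write_expression: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of a simulation block or input paths must be given"
            )
        for name in ("de_threshold", "z_threshold", "p_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.size_cap < 1 or self.n_networks < 1:
            raise ConfigError("size_cap and n_networks must be positive")
        if self.n_components is not None and self.n_components < 1:
            raise ConfigError("n_components must be positive")
        if self.simulation is not None:
            try:
                self.simulation.validate()
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        out: dict = {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "thresholds": {
                "de_p": self.de_threshold,
                "z": self.z_threshold,
                "p_max": self.p_max,
                "size_cap": self.size_cap,
                "n_networks": self.n_networks,
                "n_components": self.n_components,
            },
            "plsr_holdout": self.plsr_holdout,
            "quantile_normalization": self.quantile_normalization,
            "write_expression": self.write_expression,
        }
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["planted_effects"] = {
                "|".join(key): value
                for key, value in sorted(self.simulation.planted_effects.items())
            }
            sim["pathway_sizes"] = {
                k: list(v) for k, v in sorted(self.simulation.pathway_sizes.items())
            }
            out["simulation"] = sim
        if self.inputs is not None:
            out["inputs"] = {
                "expression": {t: str(p) for t, p in self.inputs.expression.items()},
                "compendium": str(self.inputs.compendium),
                "regulator_network": str(self.inputs.regulator_network),
                "interaction_graph": str(self.inputs.interaction_graph),
                "growth": None if self.inputs.growth is None else str(self.inputs.growth),
            }
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {
            "output_dir", "seed", "simulation", "inputs", "thresholds",
            "plsr_holdout", "quantile_normalization", "write_expression",
            "log_level",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError(f"{path}: output_dir is required")
        seed = int(raw.get("seed", 0))

        simulation = None
        if "simulation" in raw and raw["simulation"] is not None:
            sim_raw = dict(raw["simulation"])
            if "treatments" in sim_raw:
                sim_raw["treatments"] = tuple(str(t) for t in sim_raw["treatments"])
            if "pathway_sizes" in sim_raw:
                sim_raw["pathway_sizes"] = {
                    str(k): (int(v[0]), int(v[1]))
                    for k, v in sim_raw["pathway_sizes"].items()
                }
            if "planted_effects" in sim_raw:
                flat: dict[tuple[str, str, str], float] = {}
                for treatment, by_pathway in sim_raw["planted_effects"].items():
                    for pathway, by_stratum in by_pathway.items():
                        for stratum, value in by_stratum.items():
                            flat[(str(treatment), str(pathway), str(stratum))] = float(value)
                sim_raw["planted_effects"] = flat
            if "growth_coefficients" in sim_raw:
                sim_raw["growth_coefficients"] = tuple(
                    float(v) for v in sim_raw["growth_coefficients"]
                )
            if "baseline_range" in sim_raw:
                sim_raw["baseline_range"] = tuple(sim_raw["baseline_range"])
            sim_raw.setdefault("seed", seed)
            try:
                simulation = SimulationConfig(**sim_raw)
            except TypeError as exc:
                raise ConfigError(f"{path}: bad simulation block: {exc}") from exc

        inputs = None
        if "inputs" in raw and raw["inputs"] is not None:
            in_raw = dict(raw["inputs"])
            try:
                inputs = InputPaths(
                    expression={
                        str(t): Path(p) for t, p in in_raw["expression"].items()
                    },
                    compendium=Path(in_raw["compendium"]),
                    regulator_network=Path(in_raw["regulator_network"]),
                    interaction_graph=Path(in_raw["interaction_graph"]),
                    growth=Path(in_raw["growth"]) if in_raw.get("growth") else None,
                )
            except KeyError as exc:
                raise ConfigError(f"{path}: inputs block missing {exc}") from exc

        thresholds = raw.get("thresholds") or {}
        config = cls(
            output_dir=Path(raw["output_dir"]),
            seed=seed,
            simulation=simulation,
            inputs=inputs,
            de_threshold=float(thresholds.get("de_p", DEFAULT_THRESHOLD)),
            z_threshold=float(thresholds.get("z", 2.0)),
            p_max=float(thresholds.get("p_max", 0.01)),
            size_cap=int(thresholds.get("size_cap", 35)),
            n_networks=int(thresholds.get("n_networks", 3)),
            n_components=(
                int(thresholds["n_components"])
                if thresholds.get("n_components") is not None
                else None
            ),
            plsr_holdout=raw.get("plsr_holdout"),
            quantile_normalization=bool(raw.get("quantile_normalization", True)),
            write_expression=bool(raw.get("write_expression", False)),
            log_level=str(raw.get("log_level", "INFO")),
        )
        config.validate()
        return config


@dataclass
class ReportBundle:
    """In-memory results plus the paths of everything written."""

    config: RunConfig
    output_dir: Path
    de_tables: dict[str, pd.DataFrame]
    focus: dict[str, FocusResult]
    profiles: list[CompendiumProfile]
    features: pd.DataFrame
    regulator_calls: dict[str, list[RegulatorCall]]
    networks: dict[str, list[GeneNetwork]]
    common_node_matrix: pd.DataFrame | None
    overlap_activated: pd.DataFrame | None
    overlap_inactivated: pd.DataFrame | None
    growth: pd.Series | None
    plsr_model: PLSRModel | None
    predictions: pd.DataFrame | None
    prune: PruneResult | None
    manifest_path: Path


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_json(payload, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _network_payload(net: GeneNetwork) -> dict:
    ranking = degree_ranking(net)
    return {
        "seed_gene": net.seed_gene,
        "score": net.score,
        "label": net.label,
        "nodes": sorted(net.nodes),
        "edges": sorted(list(e) for e in net.edges),
        "degree_ranking": ranking.to_dict(orient="records"),
    }


def _safe_name(treatment: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in treatment)


def run_all(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write one report bundle.

    Raises :class:`StageError` naming the failing stage; outputs written
    before the failure are retained.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    simulate = config.simulation is not None

    # --- knowledge base -------------------------------------------------
    try:
        if simulate:
            kb, regnet, graph = generate_knowledge_base(config.simulation)
            (out / "kb").mkdir(exist_ok=True)
            write_compendium(kb, out / "kb" / "compendium.gmt")
            write_regulator_network(regnet, out / "kb" / "regulators.tsv")
            write_sif(graph, out / "kb" / "interactions.sif")
        else:
            kb = load_compendium(config.inputs.compendium)
            regnet = load_regulator_network(config.inputs.regulator_network)
            graph = load_sif(config.inputs.interaction_graph)
        logger.info(
            "knowledge base: %d pathways, %d regulator edges, %d interaction edges",
            len(kb.pathways), len(regnet.edges), graph.number_of_edges(),
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("knowledge_base", exc) from exc

    treatments = (
        list(config.simulation.treatments)
        if simulate
        else list(config.inputs.expression)
    )

    # --- per-treatment DE / focus / compendium / regulators / networks --
    de_tables: dict[str, pd.DataFrame] = {}
    focus: dict[str, FocusResult] = {}
    profiles: list[CompendiumProfile] = []
    regulator_calls: dict[str, list[RegulatorCall]] = {}
    networks: dict[str, list[GeneNetwork]] = {}
    summary: dict[str, dict] = {}

    for treatment in treatments:
        name = _safe_name(treatment)
        try:
            if simulate:
                expr = generate_expression_set(config.simulation, kb, treatment)
                if config.write_expression:
                    (out / "expression").mkdir(exist_ok=True)
                    expr.to_tsv(out / "expression" / f"{name}.tsv")
            else:
                expr = ExpressionSet.from_tsv(
                    config.inputs.expression[treatment], treatment=treatment
                )
            if config.quantile_normalization:
                joint = np.hstack([expr.control, expr.treated])
                joint = quantile_normalize(joint)
                n_rep = expr.n_replicates
                expr = ExpressionSet(
                    gene_ids=expr.gene_ids,
                    control=joint[:, :n_rep],
                    treated=joint[:, n_rep:],
                    treatment=treatment,
                )
        except Exception as exc:
            raise StageError("expression", exc) from exc

        try:
            de = select_de(expr, threshold=config.de_threshold)
            de_tables[treatment] = de
            (out / "de").mkdir(exist_ok=True)
            de.to_csv(out / "de" / f"{name}.csv")
            n_sig = int(de["significant"].sum())
            logger.info("%s: %d/%d genes significantly DE", treatment, n_sig, len(de))
        except Exception as exc:
            raise StageError("de", exc) from exc

        try:
            res = focus_genes(de, graph)
            focus[treatment] = res
            (out / "focus").mkdir(exist_ok=True)
            with open(out / "focus" / f"{name}.txt", "w", encoding="utf-8") as fh:
                for gene in sorted(res.genes):
                    fh.write(gene + "\n")
            logger.info(
                "%s: %d focus genes (%.1f%% eligibility)",
                treatment, len(res.genes), res.eligibility_percent,
            )
        except Exception as exc:
            raise StageError("focus", exc) from exc

        try:
            profile = score_pathways(de, kb, treatment=treatment)
            profiles.append(profile)
            (out / "compendium").mkdir(exist_ok=True)
            profile_to_long(profile).to_csv(
                out / "compendium" / f"{name}.csv", index=False
            )
        except Exception as exc:
            raise StageError("compendium", exc) from exc

        try:
            calls = call_regulators(
                regnet, de, universe=expr.gene_ids,
                p_max=config.p_max, z_threshold=config.z_threshold,
            )
            regulator_calls[treatment] = calls
            (out / "regulators").mkdir(exist_ok=True)
            calls_to_frame(calls).to_csv(
                out / "regulators" / f"{name}.csv", index=False
            )
            n_act = sum(c.state == "activated" for c in calls)
            n_inact = sum(c.state == "inactivated" for c in calls)
            logger.info(
                "%s: %d activated / %d inactivated regulators",
                treatment, n_act, n_inact,
            )
        except Exception as exc:
            raise StageError("regulators", exc) from exc

        try:
            nets = build_networks(
                res.genes, graph,
                size_cap=config.size_cap, n_networks=config.n_networks,
            )
            nets = [
                annotate_regulation(net, de, label=treatment) for net in nets
            ]
            networks[treatment] = nets
            _write_json(
                [_network_payload(net) for net in nets],
                out / "networks" / f"{name}.json",
            )
        except Exception as exc:
            raise StageError("networks", exc) from exc

        summary[treatment] = {
            "n_genes": len(de),
            "n_significant": int(de["significant"].sum()),
            "n_focus": len(res.genes),
            "eligibility_percent": res.eligibility_percent,
            "network_scores": [net.score for net in networks[treatment]],
        }

    # --- cross-treatment comparisons ------------------------------------
    common = overlap_act = overlap_inact = None
    try:
        if len(treatments) >= 2:
            common = common_nodes({t: focus[t].genes for t in treatments})
            common.to_csv(out / "networks" / "common_nodes.csv")
            overlap_act = overlap_table(regulator_calls, "activated")
            overlap_inact = overlap_table(regulator_calls, "inactivated")
            overlap_act.to_csv(out / "regulators" / "overlap_activated.csv")
            overlap_inact.to_csv(out / "regulators" / "overlap_inactivated.csv")
    except Exception as exc:
        raise StageError("overlap", exc) from exc

    # --- growth + PLSR ---------------------------------------------------
    features = profiles_to_wide(profiles)
    growth = model = predictions = prune = None
    try:
        features.to_csv(out / "compendium" / "features.csv")
        if simulate:
            growth = generate_growth_response(config.simulation, profiles)
        elif config.inputs.growth is not None:
            growth = pd.read_csv(
                config.inputs.growth, sep="\t", index_col=0
            ).iloc[:, 0]
            growth.index = growth.index.astype(str)
            growth = growth.reindex(features.index)
            if growth.isna().any():
                raise ValueError("growth table does not cover every treatment")
        if growth is not None and len(features) >= 3:
            growth.to_frame().to_csv(out / "growth.tsv", sep="\t")
            holdout = config.plsr_holdout
            if holdout is not None and holdout not in features.index:
                raise ValueError(f"plsr_holdout {holdout!r} is not a treatment")
            train_idx = [t for t in features.index if t != holdout]
            x_train = features.loc[train_idx]
            y_train = growth.loc[train_idx]
            model = fit(
                x_train, y_train.to_numpy(), n_components=config.n_components
            )
            y_hat = predict(model, features)
            percents, rss = percent_error(growth.to_numpy(), y_hat)
            predictions = pd.DataFrame(
                {
                    "observed": growth.to_numpy(),
                    "predicted": y_hat,
                    "percent_error": percents,
                    "held_out": [t == holdout for t in features.index],
                },
                index=features.index,
            )
            prune = sensitivity_prune(
                x_train, y_train.to_numpy(), n_components=config.n_components
            )
            (out / "plsr").mkdir(exist_ok=True)
            model.to_json(out / "plsr" / "model.json")
            predictions.to_csv(out / "plsr" / "predictions.csv")
            prune.sensitivity.to_csv(out / "plsr" / "sensitivity.csv", index=False)
            logger.info(
                "PLSR: %d components, training RSS %.4g, pruned to %d features",
                model.n_components, rss, len(prune.kept),
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("plsr", exc) from exc

    # --- manifest ---------------------------------------------------------
    try:
        _write_json(summary, out / "summary.json")
        manifest_path = out / "manifest.json"
        files = sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p != manifest_path
        )
        config_blob = json.dumps(config.to_dict(), sort_keys=True).encode()
        manifest = {
            "config_sha256": hashlib.sha256(config_blob).hexdigest(),
            "seed": config.seed,
            "version": __version__,
            "files": {f: _sha256(out / f) for f in files},
        }
        _write_json(manifest, manifest_path)
    except Exception as exc:
        raise StageError("manifest", exc) from exc

    return ReportBundle(
        config=config,
        output_dir=out,
        de_tables=de_tables,
        focus=focus,
        profiles=profiles,
        features=features,
        regulator_calls=regulator_calls,
        networks=networks,
        common_node_matrix=common,
        overlap_activated=overlap_act,
        overlap_inactivated=overlap_inact,
        growth=growth,
        plsr_model=model,
        predictions=predictions,
        prune=prune,
        manifest_path=out / "manifest.json",
    )
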