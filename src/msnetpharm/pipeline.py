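"""End-to-end orchestration: inputs -> statistics -> profiles -> mechanism.

One :func:`run_pipeline` call reproduces the full analysis for a dataset or
a synthetic scenario: load/generate the inputs, summarize the CPI table,
apply the key-target filter, test herb-disease overlap (exact and
randomized null), run pathway over-representation, compute per-compound and
disease diffusion profiles, rank compounds by profile correlation, and
extract the mechanism subgraph for the top-ranked (or a chosen) compound.
All stage outputs and a reproducible run manifest are written to the output
directory.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assembly import (
    export_network,
    filter_key_targets,
    load_compound_targets,
    load_disease_proteins,
    summarize,
    write_summary_json,
)
from .diffusion import (
    DiffusionConfig,
    build_restart_vector,
    build_transition_matrix,
    compute_diffusion_profile,
    load_multiscale_network,
    rank_compounds,
    write_profile_tsv,
)
from .enrich import (
    hypergeom_overlap_test,
    monte_carlo_fold_enrichment,
    pathway_ora,
    read_gmt,
    write_ora_tsv,
)
from .errors import ValidationError
from .mechanism import extract_mechanism_subgraph, write_subgraph
from .synthetic import SyntheticScenario, generate_bundle, write_fixture

logger = logging.getLogger(__name__)

BACKGROUNDS = ("cpi-targets", "network-proteins")


@dataclass
class PipelineConfig:
    """Resolved configuration of one run (file inputs XOR synthetic scenario)."""

    compounds: Path | None = None
    disease: Path | None = None
    network: Path | None = None
    pathways: Path | None = None
    scenario: SyntheticScenario | None = None
    min_ingredients: int = 2
    background: str = "cpi-targets"
    correction: str = "bh"
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    n_iter: int = 10_000
    seed: int = 0
    out_dir: Path = Path("msnetpharm-run")
    mechanism_compound: str | None = None  # default: the rank-1 compound

    def __post_init__(self) -> None:
        paths = [self.compounds, self.disease, self.network, self.pathways]
        has_paths = any(p is not None for p in paths)
        if has_paths and self.scenario is not None:
            raise ValidationError("config must give input paths or a scenario, not both")
        if not has_paths and self.scenario is None:
            raise ValidationError("config must give input paths or a synthetic scenario")
        if has_paths:
            missing_fields = [
                name
                for name, p in zip(("compounds", "disease", "network", "pathways"), paths)
                if p is None
            ]
            if missing_fields:
                raise ValidationError(
                    f"config missing input path(s): {', '.join(missing_fields)}"
                )
            for p in paths:
                if not Path(p).exists():
                    raise ValidationError(f"input file does not exist: {p}")
        if self.background not in BACKGROUNDS:
            raise ValidationError(
                f"background must be one of {BACKGROUNDS}, got {self.background!r}"
            )
        if self.correction not in ("bh", "bonferroni"):
            raise ValidationError("correction must be 'bh' or 'bonferroni'")
        if self.min_ingredients < 1:
            raise ValidationError("min_ingredients must be >= 1")
        if self.n_iter < 100:
            raise ValidationError("n_iter must be >= 100")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            for key in ("targets_per_compound", "pathway_size_range", "planted_compounds"):
                if key in scenario:
                    scenario[key] = tuple(scenario[key])
            scenario = SyntheticScenario(**scenario)
        diffusion = raw.pop("diffusion", None)
        diffusion = DiffusionConfig(**diffusion) if diffusion else DiffusionConfig()
        base = Path(path).parent
        for key in ("compounds", "disease", "network", "pathways"):
            if raw.get(key) is not None:
                p = Path(raw[key])
                raw[key] = p if p.is_absolute() else base / p
        if raw.get("out_dir") is not None:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(scenario=scenario, diffusion=diffusion, **raw)


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    for key in ("compounds", "disease", "network", "pathways", "out_dir"):
        if d[key] is not None:
            d[key] = str(d[key])
    return d


@dataclass
class RunManifest:
    """Everything needed to audit and reproduce a run."""

    config: dict
    version: str
    stages: dict
    timestamps: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the whole analysis; see module docstring for the stage order."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    timestamps = {"started": datetime.datetime.now().isoformat()}
    rng = np.random.default_rng(config.seed)

    # ---- stage: inputs -------------------------------------------------
    if config.scenario is not None:
        bundle = generate_bundle(config.scenario)
        write_fixture(bundle, out / "inputs")
        table, disease = bundle.compounds, bundle.disease
        network, pathways = bundle.network, bundle.pathways
        stages["inputs"] = {"mode": "synthetic", "truth": bundle.truth}
    else:
        table = load_compound_targets(config.compounds)
        disease = load_disease_proteins(config.disease, label="disease")
        network = load_multiscale_network(config.network)
        pathways = read_gmt(config.pathways)
        stages["inputs"] = {"mode": "files"}

    # ---- stage: CPI summary and key-target filter ----------------------
    summary = summarize(table)
    write_summary_json(summary, out / "network_summary.json")
    key = filter_key_targets(table, config.min_ingredients)
    key_summary = summarize(key)
    key.to_frame().to_csv(out / "key_targets.tsv", sep="\t", index=False)
    export_network(
        key,
        graphml_path=out / "compound_target_network.graphml",
        sif_path=out / "compound_target_network.sif",
        annotations={pid: {"disease": True} for pid in disease.ids},
    )
    stages["compound_target_network"] = {
        "n_cpis": summary.n_cpis,
        "n_compounds": summary.n_compounds,
        "n_targets": summary.n_targets,
        "key_n_cpis": key_summary.n_cpis,
        "key_n_compounds": key_summary.n_compounds,
        "key_n_targets": key_summary.n_targets,
        "min_ingredients": config.min_ingredients,
    }

    # ---- stage: overlap statistics ------------------------------------
    if config.background == "cpi-targets":
        background = set(table.targets)
    else:
        background = {n for n in network.proteins}
    background |= disease.ids  # disease ids must live in the universe
    key_target_set = set(key.targets)
    overlap = hypergeom_overlap_test(
        key_target_set, disease.ids, background, name="key-targets-vs-disease"
    )
    mc = monte_carlo_fold_enrichment(
        key_target_set, disease.ids, background, n_iter=config.n_iter, rng=rng
    )
    overlap_record = {
        "overlap_k": overlap.overlap_k,
        "query_n": overlap.query_n,
        "set_K": overlap.set_K,
        "background_N": overlap.background_N,
        "p_value": overlap.p_value,
        "fold_enrichment_mc": mc.fold,
        "mean_random_overlap": mc.mean_random_overlap,
        "empirical_p": mc.empirical_p,
        "n_iter": mc.n_iter,
        "background": config.background,
    }
    with open(out / "herb_overlap.json", "w") as fh:
        json.dump(overlap_record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stages["herb_overlap"] = overlap_record

    # ---- stage: pathway over-representation ---------------------------
    ora = pathway_ora(key_target_set, pathways, background, correction=config.correction)
    write_ora_tsv(ora, out / "pathway_enrichment.tsv", correction=config.correction)
    stages["pathway_ora"] = {
        "n_sets": len(ora),
        "n_significant": sum(1 for r in ora if r.adjusted_p <= 0.05),
        "correction": config.correction,
        "top_set": ora[0].name if ora else None,
    }

    # ---- stage: diffusion profiles and ranking ------------------------
    transition = build_transition_matrix(network, config.diffusion.edge_class_weights)
    disease_restart = build_restart_vector(network, disease.ids, label="disease")
    disease_profile = compute_diffusion_profile(
        network, disease_restart, config.diffusion, transition=transition
    )
    profiles_dir = out / "profiles"
    profiles_dir.mkdir(exist_ok=True)
    write_profile_tsv(disease_profile, network, profiles_dir / "disease.tsv")
    profiles = {}
    per_compound_overlap = {}
    convergence = {"disease": {
        "iterations": disease_profile.iterations_used,
        "converged": disease_profile.converged,
    }}
    for cid in table.compounds:
        targets = table.targets_of(cid)
        restart = build_restart_vector(network, targets, label=cid)
        prof = compute_diffusion_profile(
            network, restart, config.diffusion, transition=transition
        )
        profiles[cid] = prof
        write_profile_tsv(prof, network, profiles_dir / f"{cid}.tsv")
        per_compound_overlap[cid] = hypergeom_overlap_test(
            targets, disease.ids, background, name=cid
        )
        convergence[cid] = {
            "iterations": prof.iterations_used,
            "converged": prof.converged,
        }
    ranked = rank_compounds(profiles, disease_profile, overlaps=per_compound_overlap)
    names = table.compound_names()
    ranked.insert(2, "name", [names.get(c, c) for c in ranked["compound"]])
    ranked.to_csv(out / "ranked_compounds.tsv", sep="\t", index=False, float_format="%.10g")
    stages["ranking"] = {
        "n_compounds": len(ranked),
        "top_compound": ranked["compound"].iloc[0],
        "top_correlation": float(ranked["correlation"].iloc[0]),
        "correlations": dict(zip(ranked["compound"], ranked["correlation"].map(float))),
    }
    stages["convergence"] = convergence

    # ---- stage: mechanism subgraph ------------------------------------
    chosen = config.mechanism_compound or ranked["compound"].iloc[0]
    if chosen not in profiles:
        raise ValidationError(f"mechanism compound {chosen!r} not in compound table")
    subgraph = extract_mechanism_subgraph(
        network,
        profiles[chosen],
        disease_profile,
        table.targets_of(chosen),
        disease.ids,
        k=config.diffusion.k,
    )
    write_subgraph(
        subgraph,
        graphml_path=out / "mechanism.graphml",
        sif_path=out / "mechanism.sif",
        table_path=out / "mechanism_nodes.tsv",
    )
    stages["mechanism"] = {
        "compound": chosen,
        "k": config.diffusion.k,
        "n_nodes": len(subgraph.nodes),
        "n_edges": len(subgraph.edges),
        "empty": subgraph.is_empty(),
    }

    timestamps["finished"] = datetime.datetime.now().isoformat()
    manifest = RunManifest(
        config=_config_dict(config),
        version=__version__,
        stages=stages,
        timestamps=timestamps,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
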