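"""End-to-end orchestration with a reproducibility manifest.

A pipeline run is a pure function of (inputs, config, seed): every output
file is listed in the manifest with its SHA-256 content hash, and the
per-stage seeds are derived from the single global seed by hashing
``"<seed>:<stage name>"`` — adding a stage never perturbs the randomness of
existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import yaml

from ystr import (
    amova_mantel,
    data_io,
    haplogroups,
    mj_network,
    popgen_distance,
    str_clusters,
    synthetic_data,
    tmrca,
)

log = logging.getLogger("ystr.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % 2**32


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _model_params(cfg: dict) -> tmrca.MutationModelParams:
    model = cfg.get("model", {})
    return tmrca.MutationModelParams(
        mu=float(model.get("mu", 2.1e-3)),
        generation_years=float(model.get("generation_years", 30.0)),
        n_loci=int(model.get("n_loci", 15)),
    )


def run_pipeline(cfg: dict, output_dir: str | Path) -> dict:
    """Execute all applicable stages; returns (and writes) the manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    params = _model_params(cfg)
    manifest: dict[str, Any] = {
        "config": cfg,
        "seed": seed,
        "stage_seeds": {},
        "outputs": {},
        "counts": {},
    }
    current_stage = "init"

    def emit(name: str, obj, fmt: str) -> None:
        path = out / name
        data_io.write_results(obj, path, format=fmt)
        manifest["outputs"][name] = _sha256(path)

    # referenced input files must exist before any output is produced
    for key in ("samples", "meta"):
        if key in cfg and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"input file not found: {cfg[key]}")

    try:
        if "clan" in cfg:
            current_stage = "simulate_clan"
            c = cfg["clan"]
            s = stage_seed(seed, current_stage)
            manifest["stage_seeds"][current_stage] = s
            founder = synthetic_data.EXAMPLE_FOUNDERS.get(
                c.get("founder", "alpha"), synthetic_data.DEFAULT_FOUNDER
            )
            sim_cfg = synthetic_data.ClanSimConfig(
                n_samples=int(c["n_samples"]),
                depth_generations=float(c["depth_generations"]),
                genealogy=c.get("genealogy", "star"),
                offspring_mean=float(c.get("offspring_mean", 1.2)),
                params=params,
                founder=founder,
                population_code=c.get("population_code", "SIM1"),
                seed=s,
            )
            haps, truth = synthetic_data.simulate_clan(sim_cfg)
            snp = synthetic_data._snp_calls_for_label(founder.haplogroup)
            records = synthetic_data.clan_to_records(haps, sim_cfg, snp)
            table_path = out / "clan_samples.tsv"
            data_io.write_sample_table(records, table_path)
            manifest["outputs"]["clan_samples.tsv"] = _sha256(table_path)
            emit("clan_truth.json", dataclasses.asdict(truth), "json")

            current_stage = "clan_analysis"
            records = data_io.read_sample_table(table_path)
            for rec in records:
                rec.haplogroup = haplogroups.assign_haplogroup(rec.snp_calls)
            haps2, _, excluded = data_io.records_to_haplotypes(records)
            manifest["counts"]["clan_samples"] = len(records)
            manifest["counts"]["clan_excluded_missing_loci"] = excluded
            log.info("clan: %d samples, %d excluded", len(records), excluded)

            modal_threshold = int(c.get("modal_threshold", 10))
            radius = int(c.get("related_radius", 4))
            modals = str_clusters.find_modal_haplotypes(
                haps2, threshold=modal_threshold
            )
            report = []
            if modals:
                modal = modals[0]
                related = str_clusters.related_search(modal, haps2, radius)
                net = mj_network.build_network(
                    haps2,
                    populations=[r.population_code for r in records],
                )
                emit("clan_network.graphml", net, "graphml")
                cluster = mj_network.delineate_cluster(
                    net,
                    seed_population=sim_cfg.population_code,
                    founder=modal,
                    enrichment_threshold=float(
                        c.get("enrichment_threshold", 0.5)
                    ),
                    distance_cap=int(c.get("distance_cap", radius)),
                )
                age = tmrca.date_cluster(
                    cluster, modal.haplotype, net=net, params=params
                )
                report.append({
                    "modal_count_Nstar": modal.count,
                    "related_count_Nstarstar": related.n,
                    "cluster_count_Nstarstarstar": cluster.n,
                    "rho": age.rho,
                    "age_rho_years": age.age_rho_years,
                    "sd_rho_years": age.sd_rho_years,
                    "asd": age.asd,
                    "age_asd_years": age.age_asd_years,
                    "modal_threshold": modal_threshold,
                    "related_radius": radius,
                })
            emit("cluster_report.json", report, "json")

        records_pop: Optional[list] = None
        metas: Optional[list] = None
        if "populations" in cfg:
            current_stage = "simulate_populations"
            p = cfg["populations"]
            s = stage_seed(seed, current_stage)
            manifest["stage_seeds"][current_stage] = s
            pop_cfg = synthetic_data.PopulationSimConfig(
                n_groups=int(p["n_groups"]),
                pops_per_group=int(p["pops_per_group"]),
                samples_per_pop=int(p["samples_per_pop"]),
                haplogroup_labels=list(p["haplogroup_labels"]),
                base_frequencies=[float(x) for x in p["base_frequencies"]],
                concentration=float(p.get("concentration", 10.0)),
                spatially_segregated=bool(p.get("spatially_segregated", False)),
                seed=s,
            )
            records_pop, metas, truth_pop = synthetic_data.simulate_populations(
                pop_cfg
            )
            data_io.write_sample_table(records_pop, out / "pop_samples.tsv")
            manifest["outputs"]["pop_samples.tsv"] = _sha256(
                out / "pop_samples.tsv"
            )
            data_io.write_population_meta(metas, out / "pop_meta.tsv")
            manifest["outputs"]["pop_meta.tsv"] = _sha256(out / "pop_meta.tsv")
            emit("pop_truth.json", dataclasses.asdict(truth_pop), "json")
        elif "samples" in cfg:
            current_stage = "load"
            records_pop = data_io.read_sample_table(
                cfg["samples"], schema=cfg.get("schema")
            )
            for rec in records_pop:
                rec.haplogroup = haplogroups.assign_haplogroup(rec.snp_calls)
            if "meta" in cfg:
                metas = data_io.read_population_meta(cfg["meta"])

        if records_pop is not None:
            current_stage = "frequency_analysis"
            manifest["counts"]["population_samples"] = len(records_pop)
            ft = haplogroups.frequency_table(records_pop, by="population")
            emit("frequencies.tsv", ft, "tsv")
            hd = {
                pop: haplogroups.haplogroup_diversity(ft.p[i], int(ft.n[i]))
                for i, pop in enumerate(ft.populations) if ft.n[i] >= 2
            }
            emit("haplogroup_diversity.json", hd, "json")

            current_stage = "distances_ordination"
            dm = popgen_distance.nei_distance_matrix(ft)
            emit("nei_distances.tsv", dm, "tsv")
            if len(ft.populations) > 2 and (dm.d < float("inf")).all():
                ord_mds = popgen_distance.mds(dm, k=2)
                emit("mds.json", {
                    "labels": ord_mds.labels,
                    "coordinates": ord_mds.coordinates,
                    "stress": ord_mds.stress,
                }, "json")
            ord_pca = popgen_distance.pca(ft, k=min(2, len(ft.haplogroups)))
            emit("pca.json", {
                "labels": ord_pca.labels,
                "coordinates": ord_pca.coordinates,
                "explained_variance": ord_pca.explained_variance,
            }, "json")

            if metas:
                current_stage = "amova_mantel"
                s = stage_seed(seed, current_stage)
                manifest["stage_seeds"][current_stage] = s
                n_perm = int(cfg.get("n_permutations", 999))
                schemes = sorted(
                    {name for m in metas for name in m.group_labels}
                )
                amova_out = {}
                for scheme_name in schemes:
                    scheme = amova_mantel.GroupingScheme(
                        name=scheme_name,
                        assignment={
                            m.population_code: m.group_labels[scheme_name]
                            for m in metas if scheme_name in m.group_labels
                        },
                    )
                    res = amova_mantel.amova(
                        records_pop, scheme, n_perm=n_perm, seed=s
                    )
                    amova_out[scheme_name] = dataclasses.asdict(res)
                emit("amova.json", amova_out, "json")
                if all(m.latitude is not None and m.longitude is not None
                       for m in metas):
                    geo = popgen_distance.geographic_distance(metas)
                    if geo.labels == dm.labels and (dm.d < float("inf")).all():
                        res = amova_mantel.mantel(
                            dm, geo, n_perm=n_perm, seed=s
                        )
                        emit("mantel.json", dataclasses.asdict(res), "json")
    except Exception as exc:  # noqa: BLE001 - annotate stage and abort
        (out / ".partial").write_text(
            f"pipeline aborted in stage {current_stage}\n"
        )
        raise PipelineError(current_stage, exc) from exc

    current_stage = "manifest"
    manifest_path = out / "manifest.json"
    data_io.write_results(manifest, manifest_path, "json")
    marker = out / ".partial"
    if marker.exists():
        marker.unlink()
    return manifest
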