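"""End-to-end orchestration: synthesize inputs, enrich, annotate, derive, report.

A run is described by a YAML config with one top-level seed; each stage
draws from a fixed-offset substream so stages stay independent but the whole
run is reproducible (identical config + seed => byte-identical outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .annotations import fisher_overrepresentation, identify_degs, term_gene_sets
from .assays import (
    crc_retention,
    derive_complex_activities,
    derive_resp_states,
    h2o2_slope,
    segment_phases,
)
from .enrichment import (
    EnrichmentConfig,
    EnrichmentResult,
    GeneSetCollection,
    GeneSet,
    results_to_frame,
    run_enrichment,
)
from .io import (
    read_annotation_table,
    read_de_table,
    read_gmt,
    read_schedule_yaml,
    read_traces_csv,
    write_de_table,
    write_gmt,
    write_schedule_yaml,
    write_traces_csv,
    write_yaml,
)
from .synthetic import (
    DESimConfig,
    PlantedSet,
    PulseModel,
    TraceSimConfig,
    generate_crc_trace,
    generate_de_table,
    generate_h2o2_trace,
    generate_ocr_trace,
)

logger = logging.getLogger(__name__)

Z_THRESHOLD = 1.96  # |Z| at two-sided p = 0.05

# stage-specific seed offsets so substreams never collide
STAGE_SEED_OFFSETS = {"simulate": 1000, "enrich": 2000, "assay": 3000}

__all__ = ["RunConfig", "StageError", "run_pipeline", "export_z_matrix", "Z_THRESHOLD"]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage label."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # pre-existing de/gmt/annotation/trace paths
    enrichment: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)
    assays: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, payload: dict, base_dir: Path | None = None) -> "RunConfig":
        if "out_dir" not in payload:
            raise ValueError("config requires out_dir")
        base = base_dir or Path(".")
        out_dir = Path(payload["out_dir"])
        if not out_dir.is_absolute():
            out_dir = base / out_dir
        inputs = dict(payload.get("inputs", {}))
        for key, val in inputs.items():
            p = Path(val)
            inputs[key] = str(p if p.is_absolute() else base / p)
        cfg = cls(
            out_dir=out_dir,
            seed=int(payload.get("seed", 0)),
            simulate=dict(payload.get("simulate", {})),
            inputs=inputs,
            enrichment=dict(payload.get("enrichment", {})),
            annotations=dict(payload.get("annotations", {})),
            assays=dict(payload.get("assays", {})),
            raw=payload,
        )
        for key, val in cfg.inputs.items():
            if not Path(val).exists():
                raise ValueError(f"input path for {key!r} does not exist: {val}")
        return cfg


def _config_hash(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def _stage_seed(seed: int, stage: str, index: int = 0) -> int:
    return seed + STAGE_SEED_OFFSETS[stage] + index


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, manifest: dict) -> dict:
    """Generate DE tables, a GMT (planted + decoys), and assay traces."""
    spec = config.simulate
    produced: dict = {}
    counts: dict = {}

    de_spec = spec.get("de")
    if de_spec:
        contrasts = spec.get("contrasts", ["contrast1"])
        planted = tuple(
            PlantedSet(
                name=ps["name"],
                size=int(ps.get("size", 0)),
                delta=float(ps.get("delta", 0.0)),
                direction=ps.get("direction", "up"),
                members=tuple(ps["members"]) if "members" in ps else None,
            )
            for ps in de_spec.get("planted_sets", [])
        )
        de_paths, truth_all = {}, {}
        collection = None
        for i, contrast in enumerate(contrasts):
            cfg = DESimConfig(
                n_genes=int(de_spec["n_genes"]),
                null_sd=float(de_spec.get("null_sd", 0.5)),
                planted_sets=planted,
                se_per_gene=float(de_spec.get("se_per_gene", 0.25)),
                seed=_stage_seed(config.seed, "simulate", i),
            )
            table, truth = generate_de_table(cfg)
            path = out / f"de_{contrast}.tsv"
            write_de_table(table, path)
            de_paths[contrast] = str(path)
            truth_all[contrast] = truth.sets
            if collection is None:
                collection = GeneSetCollection(
                    GeneSet.from_iterable(name, rec["members"]) for name, rec in truth.sets.items()
                )
                # keep planted membership identical across contrasts
                planted = tuple(
                    PlantedSet(
                        name=ps.name, delta=ps.delta, direction=ps.direction,
                        members=truth.sets[ps.name]["members"],
                    )
                    for ps in planted
                )
        # decoy sets drawn from the same universe pad the tested collection
        decoy = spec.get("decoy_sets")
        if decoy and collection is not None:
            rng = np.random.default_rng(_stage_seed(config.seed, "simulate", 900))
            genes = pd.read_csv(de_paths[contrasts[0]], sep="\t")["gene"].astype(str).to_numpy()
            for j in range(int(decoy.get("count", 0))):
                members = rng.choice(genes, size=int(decoy.get("size", 20)), replace=False)
                collection.add(GeneSet.from_iterable(f"decoy{j + 1:02d}", members))
        gmt_path = out / "genesets.gmt"
        write_gmt(collection, gmt_path)
        write_yaml(truth_all, out / "truth_de.yaml")
        produced["de"] = de_paths
        produced["gmt"] = str(gmt_path)
        counts["contrasts"] = len(contrasts)
        counts["gene_sets"] = len(collection)

    for kind, gen in (("ocr", "OCR_coupling"), ("eflow", "OCR_electron_flow")):
        tr_spec = spec.get(kind)
        if not tr_spec:
            continue
        cfg = TraceSimConfig(
            phase_means=tuple((str(k), float(v)) for k, v in tr_spec["phase_means"].items()),
            cycles_per_phase=int(tr_spec.get("cycles_per_phase", 6)),
            noise_sd=float(tr_spec.get("noise_sd", 0.0)),
            sample_interval=float(tr_spec.get("sample_interval", 30.0)),
            seed=_stage_seed(config.seed, "simulate", 100 if kind == "ocr" else 200),
        )
        trace, schedule, truth = generate_ocr_trace(cfg, kind=gen)
        write_traces_csv([trace], out / f"trace_{kind}.csv")
        write_schedule_yaml(schedule, out / f"schedule_{kind}.yaml")
        write_yaml({"phase_means": truth.phase_means}, out / f"truth_{kind}.yaml")
        produced[kind] = {"trace": str(out / f"trace_{kind}.csv"), "schedule": str(out / f"schedule_{kind}.yaml")}

    crc_spec = spec.get("crc")
    if crc_spec:
        cfg = TraceSimConfig(
            phase_means=(("baseline", float(crc_spec.get("baseline", 0.0))),),
            cycles_per_phase=int(crc_spec.get("cycles_per_phase", 6)),
            noise_sd=float(crc_spec.get("noise_sd", 0.0)),
            sample_interval=float(crc_spec.get("sample_interval", 10.0)),
            pulse_model=PulseModel(
                amplitude=float(crc_spec.get("amplitude", 10.0)),
                uptake_rate=float(crc_spec.get("uptake_rate", 0.05)),
                capacity=float(crc_spec.get("capacity", np.inf)),
                n_pulses=int(crc_spec.get("n_pulses", 5)),
                pulse_interval=float(crc_spec.get("pulse_interval", 180.0)),
            ),
            seed=_stage_seed(config.seed, "simulate", 300),
        )
        trace, schedule, truth = generate_crc_trace(cfg)
        write_traces_csv([trace], out / "trace_crc.csv")
        write_schedule_yaml(schedule, out / "schedule_crc.yaml")
        produced["crc"] = {"trace": str(out / "trace_crc.csv"), "schedule": str(out / "schedule_crc.yaml")}

    h_spec = spec.get("h2o2")
    if h_spec:
        trace = generate_h2o2_trace(
            slope=float(h_spec.get("slope", 2.0)),
            intercept=float(h_spec.get("intercept", 0.0)),
            noise_sd=float(h_spec.get("noise_sd", 0.0)),
            duration=float(h_spec.get("duration", 1200.0)),
            interval=float(h_spec.get("interval", 30.0)),
            seed=_stage_seed(config.seed, "simulate", 400),
        )
        write_traces_csv([trace], out / "trace_h2o2.csv")
        produced["h2o2"] = {"trace": str(out / "trace_h2o2.csv")}

    manifest["stages"]["simulate"] = {"outputs": produced, "counts": counts}
    return produced


def _stage_enrich(config: RunConfig, de_paths: dict, gmt_path: str, out: Path, manifest: dict) -> dict[str, list[EnrichmentResult]]:
    collection = read_gmt(gmt_path)
    enr_cfg = EnrichmentConfig(
        n_perm=int(config.enrichment.get("n_perm", 1000)),
        seed=_stage_seed(config.seed, "enrich"),
        convention=config.enrichment.get("convention", "balanced"),
        mode=config.enrichment.get("mode", "signed_extremum"),
        min_size=int(config.enrichment.get("min_size", 5)),
        exhaustive_threshold=int(config.enrichment.get("exhaustive_threshold", 10_000)),
        alpha=float(config.enrichment.get("alpha", 0.05)),
        fdr_cut=float(config.enrichment.get("fdr_cut", 0.1)),
    )
    results_by_contrast: dict[str, list[EnrichmentResult]] = {}
    frames = []
    for contrast, path in sorted(de_paths.items()):
        table = read_de_table(path)
        results = run_enrichment(table, collection, enr_cfg)
        results_by_contrast[contrast] = results
        frames.append(results_to_frame(results, contrast=contrast))
    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(out / "enrichment_results.tsv", sep="\t", index=False, float_format="%.10g")
    manifest["stages"]["enrich"] = {
        "counts": {
            "contrasts": len(results_by_contrast),
            "pathways_tested": int(combined.groupby("contrast").size().max()),
            "significant": int(combined["significant"].sum()),
        },
        "outputs": {"results": str(out / "enrichment_results.tsv")},
    }
    return results_by_contrast


def export_z_matrix(
    results_by_contrast: dict[str, list[EnrichmentResult]],
    out_dir: str | Path | None = None,
    z_threshold: float = Z_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway x contrast matrix of signed Z with a significance mask.

    Cells for pathways not tested in a contrast hold 0 in the Z matrix and
    False in the mask.  The mask is ``|Z| >= z_threshold`` AND the joint
    significance call; sub-threshold cells keep their Z (thresholding is a
    display rule, not censoring).
    """
    contrasts = sorted(results_by_contrast)
    pathways: list[str] = []
    for results in results_by_contrast.values():
        for r in results:
            if r.pathway not in pathways:
                pathways.append(r.pathway)
    z = pd.DataFrame(0.0, index=pathways, columns=contrasts)
    mask = pd.DataFrame(False, index=pathways, columns=contrasts)
    for contrast, results in results_by_contrast.items():
        for r in results:
            z.loc[r.pathway, contrast] = r.z
            mask.loc[r.pathway, contrast] = bool(abs(r.z) >= z_threshold and r.significant)
    z.index.name = "pathway"
    mask.index.name = "pathway"
    if out_dir is not None:
        out_dir = Path(out_dir)
        z.to_csv(out_dir / "z_matrix.tsv", sep="\t", float_format="%.10g")
        mask.to_csv(out_dir / "z_mask.tsv", sep="\t")
    return z, mask


def _stage_annot(config: RunConfig, de_paths: dict, out: Path, manifest: dict) -> None:
    ann_path = config.inputs.get("annotations")
    if not ann_path:
        return
    annotations = read_annotation_table(ann_path)
    threshold = float(config.annotations.get("deg_threshold", 0.1))
    terms = term_gene_sets(annotations)
    frames = []
    for contrast, path in sorted(de_paths.items()):
        table = read_de_table(path)
        degs = identify_degs(table, threshold=threshold)
        universe = degs["gene"]
        deg_genes = degs.loc[degs["is_deg"], "gene"]
        fisher = fisher_overrepresentation(frozenset(deg_genes), terms, universe)
        fisher.insert(0, "contrast", contrast)
        frames.append(fisher)
    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(out / "go_overrepresentation.tsv", sep="\t", index=False, float_format="%.10g")
    manifest["stages"]["annot"] = {
        "counts": {"terms": len(terms), "significant": int(combined["significant"].sum())},
        "outputs": {"results": str(out / "go_overrepresentation.tsv")},
    }


def _stage_assays(config: RunConfig, produced: dict, out: Path, manifest: dict) -> None:
    discard = int(config.assays.get("discard_first", 1))
    rows = []
    for kind in ("ocr", "eflow"):
        paths = produced.get(kind) or (
            {"trace": config.inputs.get(f"{kind}_trace"), "schedule": config.inputs.get(f"{kind}_schedule")}
            if config.inputs.get(f"{kind}_trace")
            else None
        )
        if not paths:
            continue
        schedule = read_schedule_yaml(paths["schedule"])
        for trace in read_traces_csv(paths["trace"], kind=schedule.kind):
            phases = segment_phases(trace, schedule, discard_first=discard)
            if kind == "ocr":
                states = derive_resp_states(phases)
                rows.append(
                    {
                        "assay": "ocr_coupling",
                        "well": trace.well,
                        "state_II": states.state_ii,
                        "state_III": states.state_iii,
                        "state_IIIu": states.state_iiiu,
                        "state_IVo": states.state_ivo,
                        "RCR": states.rcr,
                    }
                )
            else:
                cx = derive_complex_activities(phases)
                rows.append(
                    {
                        "assay": "electron_flow",
                        "well": trace.well,
                        "CxI": cx.cx_i,
                        "CxII": cx.cx_ii,
                        "CxIII": cx.cx_iii,
                        "CxIV": cx.cx_iv,
                    }
                )
    crc_paths = produced.get("crc")
    if crc_paths:
        schedule = read_schedule_yaml(crc_paths["schedule"])
        pulse_times = [t for lab, t in schedule.events if lab.startswith("pulse")]
        for trace in read_traces_csv(crc_paths["trace"], kind="CRC"):
            rows.append(
                {
                    "assay": "crc",
                    "well": trace.well,
                    "retention": crc_retention(trace, pulse_times, mode=config.assays.get("crc_mode", "uptake")),
                }
            )
    h_paths = produced.get("h2o2")
    if h_paths:
        for trace in read_traces_csv(h_paths["trace"], kind="H2O2"):
            fit = h2o2_slope(trace)
            rows.append(
                {
                    "assay": "h2o2",
                    "well": trace.well,
                    "slope_per_min": fit.slope_per_min,
                    "slope_se": fit.stderr,
                    "r_squared": fit.r_squared,
                }
            )
    if rows:
        pd.DataFrame(rows).to_csv(out / "assay_derived.tsv", sep="\t", index=False, float_format="%.10g")
        manifest["stages"]["assay"] = {
            "counts": {"wells": len(rows)},
            "outputs": {"derived": str(out / "assay_derived.tsv")},
        }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a deterministic run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": _config_hash(config.raw),
        "seed": config.seed,
        "versions": {
            "mitopath": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "stages": {},
    }

    produced: dict = {}
    try:
        if config.simulate:
            logger.info("[simulate] generating synthetic inputs")
            produced = _stage_simulate(config, out, manifest)
    except StageError:
        raise
    except Exception as err:
        raise StageError("simulate", str(err)) from err

    de_paths = produced.get("de") or (
        {"contrast1": config.inputs["de"]} if "de" in config.inputs else {}
    )
    gmt_path = produced.get("gmt") or config.inputs.get("gmt")

    if de_paths and gmt_path:
        try:
            logger.info("[enrich] running pathway enrichment")
            results_by_contrast = _stage_enrich(config, de_paths, gmt_path, out, manifest)
            export_z_matrix(results_by_contrast, out_dir=out)
            manifest["stages"]["enrich"]["outputs"]["z_matrix"] = str(out / "z_matrix.tsv")
        except StageError:
            raise
        except Exception as err:
            raise StageError("enrich", str(err)) from err
    elif de_paths and not gmt_path:
        raise StageError("enrich", "no gene-set GMT available (missing inputs.gmt)")

    try:
        if de_paths:
            _stage_annot(config, de_paths, out, manifest)
    except StageError:
        raise
    except Exception as err:
        raise StageError("annot", str(err)) from err

    try:
        _stage_assays(config, produced, out, manifest)
    except Exception as err:
        raise StageError("assay", str(err)) from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
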