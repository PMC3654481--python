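"""Pipeline orchestration: run configuration, stage execution, manifests.

A run executes any subset of simulate -> associate -> contacts -> kinetics
and writes a manifest (config hash, seed, input hashes, package versions)
that makes re-runs exactly reproducible: the manifest hash changes iff any
input byte or config value changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import AssociationConfig, associate, area_ratio_from_stacks, monte_carlo_null
from .contacts import ContactConfig, compute_contacts, summarize_contacts
from .kinetics import frequency_profile, resolution_time
from .synthetic import SimulationConfig, generate_scene, generate_tip_tracks, render_label_stack
from . import io as eio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "config_hash"]

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "stages",
    "simulation",
    "association",
    "contacts",
    "kinetics",
    "inputs",
    "log_level",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected by name."""

    seed: int = 0
    outdir: str = "results"
    stages: tuple = ("simulate", "associate", "kinetics")
    simulation: SimulationConfig = None
    association: AssociationConfig = field(default_factory=AssociationConfig)
    contacts: ContactConfig = field(default_factory=ContactConfig)
    kinetics: dict = field(
        default_factory=lambda: {
            "separation_nm": 500.0,
            "persistence_frames": 2,
            "bins_s": [0.0, 15.0, 60.0, 210.0],
            "n_tracks": 29,
        }
    )
    inputs: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        if "simulation" in kw and isinstance(kw["simulation"], dict):
            sim = dict(kw["simulation"])
            if "network_extent_nm" in sim:
                sim["network_extent_nm"] = tuple(sim["network_extent_nm"])
            if "resolution_time_distribution" in sim:
                fam, params = sim["resolution_time_distribution"]
                sim["resolution_time_distribution"] = (fam, tuple(params))
            kw["simulation"] = SimulationConfig(**sim)
        if "association" in kw and isinstance(kw["association"], dict):
            kw["association"] = AssociationConfig(**kw["association"])
        if "contacts" in kw and isinstance(kw["contacts"], dict):
            kw["contacts"] = ContactConfig(**kw["contacts"])
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _canonical_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))

    return json.dumps(obj, sort_keys=True, default=default, separators=(",", ":"))


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(_canonical_json(config.to_dict()).encode()).hexdigest()


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns a result bundle (also written to
    ``outdir``). Any stage error aborts with the stage name; partial outputs
    already written are preserved."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    scene = None
    tracks = None

    input_hashes = {}
    for key, p in sorted(config.inputs.items()):
        path = Path(p)
        if not path.exists():
            raise FileNotFoundError(f"input {key!r}: {p} does not exist")
        input_hashes[key] = _file_hash(path)

    if "simulate" in config.stages:
        try:
            scene = generate_scene(config.simulation, with_nucleoids=True)
            tracks, track_truth = generate_tip_tracks(
                config.simulation, config.kinetics.get("n_tracks", 29)
            )
            eio.write_points(scene.foci, outdir / "foci.csv")
            eio.write_events(scene.divisions, outdir / "divisions.csv")
            if scene.nucleoids is not None:
                eio.write_points(scene.nucleoids, outdir / "nucleoids.csv")
            eio.write_tracks(tracks, outdir / "tracks.csv")
            for i, m in enumerate(scene.mito_meshes):
                eio.write_mesh(m, outdir / f"mito_{i}.ply")
            truth = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in scene.truth.items()
            }
            (outdir / "truth.json").write_text(_canonical_json(truth))
            results["simulate"] = {
                "n_foci": len(scene.foci),
                "n_divisions": len(scene.divisions),
                "achieved_coverage": scene.truth["achieved_coverage"],
            }
        except Exception as exc:
            raise PipelineError("simulate", exc) from exc

    if "associate" in config.stages:
        try:
            if scene is None:
                events = eio.read_events(config.inputs["events"])
                foci = eio.read_points(config.inputs["foci"], "foci", label="focus")
            else:
                events, foci = scene.divisions, scene.foci
            area_ratio = None
            if scene is not None:
                mito_stack, focus_stack = render_label_stack(scene)
                area_ratio = area_ratio_from_stacks(focus_stack, mito_stack)
            res = associate(events, foci, config.association, area_ratio=area_ratio)
            results["associate"] = {
                "n_events": res.n_events,
                "n_linked": res.n_linked,
                "observed_fraction": res.observed_fraction,
                "null_fraction_analytic": res.null_fraction_analytic,
                "p_enrichment": res.p_enrichment,
            }
            (outdir / "association.json").write_text(
                _canonical_json(results["associate"])
            )
        except Exception as exc:
            raise PipelineError("associate", exc) from exc

    if "contacts" in config.stages:
        try:
            mito = eio.read_mesh(config.inputs["mito"])
            er = eio.read_mesh(config.inputs["er"])
            ribosomes = (
                eio.read_points(config.inputs["ribosomes"], "ribosomes", "ribosome")
                if "ribosomes" in config.inputs
                else None
            )
            patches = compute_contacts(mito, er, ribosomes, config.contacts)
            summary = summarize_contacts(patches, mito, config.contacts)
            eio.write_patches(patches, outdir / "patches.csv")
            results["contacts"] = {
                "n_patches": summary.n_patches,
                "total_contact_area_um2": summary.total_contact_area_um2,
                "total_surface_area_um2": summary.total_surface_area_um2,
                "percent_in_contact": summary.percent_in_contact,
            }
            (outdir / "contacts.json").write_text(
                _canonical_json(results["contacts"])
            )
        except Exception as exc:
            raise PipelineError("contacts", exc) from exc

    if "kinetics" in config.stages:
        try:
            if tracks is None:
                tracks = eio.read_tracks(config.inputs["tracks"])
            kcfg = config.kinetics
            outcomes = [
                resolution_time(
                    t,
                    separation_nm=kcfg.get("separation_nm", 500.0),
                    persistence_frames=kcfg.get("persistence_frames", 2),
                )
                for t in tracks
            ]
            profile = frequency_profile(outcomes, kcfg.get("bins_s", []))
            rows = pd.DataFrame(
                {
                    "track_id": [o.track_id for o in outcomes],
                    "status": [o.status for o in outcomes],
                    "resolution_time_s": [
                        o.resolution_time_s if o.resolution_time_s is not None else np.nan
                        for o in outcomes
                    ],
                }
            )
            eio.write_table(rows, outdir / "outcomes.csv")
            results["kinetics"] = {
                "labels": profile.labels(),
                "counts": profile.counts.tolist() + [profile.never],
                "n": profile.n,
            }
            (outdir / "kinetics.json").write_text(
                _canonical_json(results["kinetics"])
            )
        except Exception as exc:
            raise PipelineError("kinetics", exc) from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "input_hashes": input_hashes,
        "seed": config.seed,
        "versions": {"ermdquant": __version__, "numpy": np.__version__},
    }
    (outdir / "manifest.json").write_text(_canonical_json(manifest))
    results["manifest"] = manifest
    return results
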