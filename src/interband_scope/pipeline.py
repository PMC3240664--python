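"""End-to-end orchestration: simulate/load inputs, then run every
analysis stage into an output directory with a JSON manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .colocalization import pairwise_tables, to_dissimilarity
from .embedding_clustering import ahc, nonmetric_mds
from .enrichment_null import SamplingPlan, enrichment_report
from .fragment_stats import length_table
from .io_core import (
    AnchorSet,
    BindingTrack,
    ChromatinStateMap,
    GenomeBuild,
    read_anchor_table,
    read_genome_table,
    read_state_map,
    read_track_bed,
    read_track_gff,
    write_anchor_table,
    write_bed,
    write_genome_table,
    write_state_map,
)
from .synthetic_data import ProteinSpec, SimulationConfig, generate_world
from .window_profiles import WindowSpec, bound_fraction, heatmap, state_composition

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    windows_bp: tuple[int, ...] = (10000, 4000)
    segment_bp: int = 500
    n_samples: int = 13000
    # either a simulation block ...
    simulation: SimulationConfig | None = None
    # ... or explicit input paths
    genome_path: Path | None = None
    anchors_path: Path | None = None
    track_paths: dict[str, Path] = field(default_factory=dict)
    state_map_path: Path | None = None
    state_scheme: str = "five_color"
    protein_classes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.simulation is None:
            missing = [
                name
                for name, path in (
                    ("genome", self.genome_path),
                    ("anchors", self.anchors_path),
                )
                if path is None
            ]
            if missing or not self.track_paths:
                raise ValueError(
                    "config needs either a simulation block or explicit "
                    f"inputs (missing: {', '.join(missing + ([] if self.track_paths else ['tracks']))})"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = None
        if "simulation" in raw:
            simraw = dict(raw["simulation"] or {})
            for key in ("active_proteins", "silent_pcg_proteins",
                        "silent_insulator_proteins"):
                if key in simraw:
                    simraw[key] = tuple(
                        ProteinSpec(**p) if isinstance(p, dict) else ProteinSpec(p)
                        for p in simraw[key]
                    )
            if "arms" in simraw:
                simraw["arms"] = tuple((a, int(l)) for a, l in simraw["arms"])
            sim = SimulationConfig(**simraw)
        cfg = cls(
            outdir=Path(raw.get("outdir", "out")),
            seed=int(raw.get("seed", 0)),
            windows_bp=tuple(raw.get("windows_bp", (10000, 4000))),
            segment_bp=int(raw.get("segment_bp", 500)),
            n_samples=int(raw.get("n_samples", 13000)),
            simulation=sim,
            genome_path=Path(raw["genome"]) if "genome" in raw else None,
            anchors_path=Path(raw["anchors"]) if "anchors" in raw else None,
            track_paths={k: Path(v) for k, v in raw.get("tracks", {}).items()},
            state_map_path=Path(raw["state_map"]) if "state_map" in raw else None,
            state_scheme=raw.get("state_scheme", "five_color"),
            protein_classes=dict(raw.get("protein_classes", {})),
        )
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(
    config: RunConfig,
) -> tuple[GenomeBuild, AnchorSet, list[BindingTrack], ChromatinStateMap | None, dict]:
    if config.simulation is not None:
        sim = config.simulation
        world = generate_world(sim)
        classes = dict(world.truth.protein_group)
        return world.genome, world.anchors, world.tracks, world.states, classes
    genome = read_genome_table(config.genome_path)
    anchors = read_anchor_table(config.anchors_path, genome)
    tracks = []
    for protein, path in sorted(config.track_paths.items()):
        reader = read_track_gff if path.suffix.lower() in (".gff", ".gff3") else read_track_bed
        tracks.append(reader(path, protein, genome))
    states = (
        read_state_map(config.state_map_path, config.state_scheme)
        if config.state_map_path
        else None
    )
    return genome, anchors, tracks, states, dict(config.protein_classes)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, anchors, tracks, states, classes = _load_inputs(config)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }
    if config.simulation is None:
        for protein, path in sorted(config.track_paths.items()):
            manifest["inputs"][protein] = _sha256(Path(path))

    shared: dict = {}

    def stage(name: str):
        # runs the decorated stage immediately; failures carry the stage name
        def wrap(fn):
            t0 = time.monotonic()
            try:
                outputs = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.monotonic() - t0)
            manifest["stages"][name] = [str(p.name) for p in outputs]
            return outputs

        return wrap

    @stage("simulate")
    def _simulate() -> list[Path]:
        out = []
        gpath = outdir / "genome.tsv"
        write_genome_table(genome, gpath)
        out.append(gpath)
        apath = outdir / "anchors.tsv"
        write_anchor_table(anchors, apath)
        out.append(apath)
        for track in tracks:
            tpath = outdir / f"track_{track.protein}.bed"
            write_bed(track, tpath)
            out.append(tpath)
        if states is not None:
            spath = outdir / "states.bed"
            write_state_map(states, spath)
            out.append(spath)
        return out

    @stage("profile")
    def _profile() -> list[Path]:
        out = []
        for width in config.windows_bp:
            wspec = WindowSpec(width // 2, config.segment_bp)
            hm = heatmap(tracks, anchors, wspec)
            path = outdir / f"heatmap_{width}.tsv"
            hm.round(1).to_csv(path, sep="\t")
            out.append(path)
        bf = {
            t.protein: {
                str(w): round(bound_fraction(t, anchors, w, genome), 1)
                for w in config.windows_bp
            }
            for t in tracks
        }
        path = outdir / "bound_fractions.tsv"
        with open(path, "w") as fh:
            fh.write("protein\t" + "\t".join(str(w) for w in config.windows_bp) + "\n")
            for protein, row in bf.items():
                fh.write(
                    protein
                    + "\t"
                    + "\t".join(str(row[str(w)]) for w in config.windows_bp)
                    + "\n"
                )
        out.append(path)
        if states is not None:
            comp = state_composition(
                states, anchors, [w for w in range(1000, 10001, 1000)], genome
            )
            spath = outdir / "state_composition.tsv"
            comp.round(3).to_csv(spath, sep="\t", index=False)
            out.append(spath)
        return out

    @stage("enrich")
    def _enrich() -> list[Path]:
        weights = anchors.per_arm_counts()
        plans = {
            f"genome-{w // 1000}kb": SamplingPlan(
                n_samples=config.n_samples,
                region_size_bp=w,
                arm_weights=weights,
                seed=config.seed + i,
            )
            for i, w in enumerate(config.windows_bp)
        }
        report = enrichment_report(tracks, anchors, genome, plans)
        path = outdir / "enrichment.tsv"
        report.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return [path]

    @stage("lengths")
    def _lengths() -> list[Path]:
        path = outdir / "length_classes.tsv"
        length_table(tracks).to_csv(path, sep="\t", index=False)
        return [path]

    @stage("coloc")
    def _coloc() -> list[Path]:
        sim_df, matrix, chi_df = pairwise_tables(tracks, genome)
        paths = [
            outdir / "pairwise_similarity.tsv",
            outdir / "similarity_matrix.tsv",
            outdir / "pairwise_block_test.tsv",
        ]
        sim_df.to_csv(paths[0], sep="\t", index=False, float_format="%.6g")
        matrix.to_frame().round(6).to_csv(paths[1], sep="\t")
        chi_df.to_csv(paths[2], sep="\t", index=False, float_format="%.6g")
        shared["matrix"] = matrix
        return paths

    @stage("cluster")
    def _cluster() -> list[Path]:
        matrix = shared["matrix"]
        D = to_dissimilarity(matrix)
        emb = nonmetric_mds(D, labels=matrix.proteins, seed=config.seed)
        dend = ahc(D, labels=matrix.proteins)
        paths = [outdir / "mds_coordinates.tsv", outdir / "dendrogram.nwk",
                 outdir / "cluster_labels.tsv"]
        with open(paths[0], "w") as fh:
            fh.write("protein\tdim1\tdim2\n")
            for label, (x, y) in zip(emb.labels, emb.coords):
                fh.write(f"{label}\t{x:.6g}\t{y:.6g}\n")
        paths[1].write_text(dend.to_newick() + "\n")
        labels = dend.cut(min(3, len(matrix.proteins)))
        with open(paths[2], "w") as fh:
            fh.write("protein\tcluster\n")
            for protein, lab in zip(matrix.proteins, labels):
                fh.write(f"{protein}\t{int(lab)}\n")
        return paths

    manifest_path = outdir / "manifest.json"
    manifest["outputs_sha256"] = {
        name: _sha256(outdir / fname)
        for stage_files in manifest["stages"].values()
        for fname in stage_files
        for name in [fname]
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
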