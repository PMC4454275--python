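"""YAML run configuration.

A run config describes the input libraries with their model parameters, the
graph construction, the annealing schedule and (optionally) a simulation
block.  Model-critical parameters — the per-base error rate of every
library and the insert-size distribution of every paired library — have no
defaults and must be stated explicitly; everything else falls back to the
documented package defaults.

Example::

    libraries:
      - name: frag
        reads: frag_1.fastq          # paths resolve relative to the config
        mates: frag_2.fastq
        technology_class: short-accurate
        error_rate: 0.01
        insert_mean: 2000
        insert_sd: 200
        weight: 1.0
    graph:
      kmer_size: 21
    annealing:
      max_iters: 2000
      patience: 500
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annealing import AnnealConfig
from .io_utils import read_sequences
from .model import ModelParams, ReadSet, default_noalign_scale
from .simulate import GenomeSpec, LibrarySpec, RepeatSpec

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


_LIBRARY_KEYS = {
    "name",
    "reads",
    "mates",
    "technology_class",
    "error_rate",
    "insert_mean",
    "insert_sd",
    "weight",
    "orientation",
    "conn_window",
    "penalty_alpha",
    "noalign_offset",
    "noalign_scale",
}


@dataclass
class RunConfig:
    libraries: list[dict] = field(default_factory=list)
    graph: dict = field(default_factory=dict)
    annealing: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    simulate: dict | None = None
    base_dir: Path = Path(".")

    # ------------------------------------------------------------------
    def load_readsets(self) -> list[ReadSet]:
        if not self.libraries:
            raise ConfigError("config declares no libraries")
        sets = []
        for i, lib in enumerate(self.libraries):
            sets.append(self._load_library(lib, i))
        return sets

    def _load_library(self, lib: dict, idx: int) -> ReadSet:
        unknown = set(lib) - _LIBRARY_KEYS
        if unknown:
            raise ConfigError(f"library {idx}: unknown keys {sorted(unknown)}")
        if "reads" not in lib:
            raise ConfigError(f"library {idx}: missing 'reads' path")
        if "error_rate" not in lib:
            raise ConfigError(
                f"library {idx}: 'error_rate' must be stated explicitly"
            )
        paired = "mates" in lib
        if paired and ("insert_mean" not in lib or "insert_sd" not in lib):
            raise ConfigError(
                f"library {idx}: paired libraries must state insert_mean and insert_sd"
            )
        tech = lib.get("technology_class", "short-accurate")
        if tech not in ("short-accurate", "long-noisy"):
            raise ConfigError(f"library {idx}: unknown technology_class {tech!r}")
        names, reads = read_sequences(self.base_dir / lib["reads"])
        mates = None
        if paired:
            _, mates = read_sequences(self.base_dir / lib["mates"])
            if len(mates) != len(reads):
                raise ConfigError(f"library {idx}: unequal read and mate counts")
        max_len = max(len(r) for r in reads)
        # half the read length: a window as large as the read would leave
        # single-read placements unable to connect any base at all
        default_window = max(1, max_len // 2)
        params = ModelParams(
            error_rate=float(lib["error_rate"]),
            insert_mean=float(lib["insert_mean"]) if paired else None,
            insert_sd=float(lib["insert_sd"]) if paired else None,
            weight=float(lib.get("weight", 1.0)),
            orientation=lib.get("orientation", "fr"),
            conn_window=int(lib.get("conn_window", default_window)),
            penalty_alpha=float(lib.get("penalty_alpha", 3.0)),
            noalign_offset=float(lib.get("noalign_offset", -15.0)),
            noalign_scale=float(
                lib.get(
                    "noalign_scale",
                    default_noalign_scale(float(lib["error_rate"]), tech),
                )
            ),
        )
        return ReadSet(
            reads=reads,
            mates=mates,
            paired=paired,
            params=params,
            technology_class=tech,
            name=lib.get("name", f"lib{idx}"),
            names=names,
        )

    # ------------------------------------------------------------------
    def anneal_config(self, seed: int | None = None, **overrides) -> AnnealConfig:
        kwargs = dict(self.annealing)
        kwargs.pop("seed", None)
        if seed is not None:
            kwargs["rng_seed"] = seed
        elif "seed" in self.annealing:
            kwargs["rng_seed"] = int(self.annealing["seed"])
        kwargs.update(overrides)
        cfg = AnnealConfig(**kwargs)
        cfg.validate()
        return cfg

    def graph_kwargs(self) -> dict:
        out = {"kmer_size": int(self.graph.get("kmer_size", 21))}
        if self.graph.get("min_count") is not None:
            out["min_count"] = int(self.graph["min_count"])
        return out

    # ------------------------------------------------------------------
    def simulation_specs(self) -> tuple[GenomeSpec, list[LibrarySpec]]:
        if not self.simulate:
            raise ConfigError("config has no 'simulate' section")
        sim = self.simulate
        if "genome_length" not in sim:
            raise ConfigError("simulate: missing genome_length")
        repeats = [
            RepeatSpec(
                unit_length=int(r["unit_length"]),
                copies=int(r.get("copies", 2)),
                divergence=float(r.get("divergence", 0.0)),
                placements=r.get("placements"),
            )
            for r in sim.get("repeats", [])
        ]
        genome = GenomeSpec(
            length=int(sim["genome_length"]),
            repeats=repeats,
            seed=int(sim.get("seed", 0)),
        )
        libs = []
        for i, lib in enumerate(sim.get("libraries", [])):
            if "error_rate" not in lib:
                raise ConfigError(f"simulate library {i}: error_rate is required")
            libs.append(LibrarySpec(**lib))
        if not libs:
            raise ConfigError("simulate: declares no libraries")
        return genome, libs


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    unknown = set(data) - {"libraries", "graph", "annealing", "evaluation", "simulate"}
    if unknown:
        raise ConfigError(f"unknown config sections {sorted(unknown)}")
    return RunConfig(
        libraries=data.get("libraries", []),
        graph=data.get("graph", {}) or {},
        annealing=data.get("annealing", {}) or {},
        evaluation=data.get("evaluation", {}) or {},
        simulate=data.get("simulate"),
        base_dir=path.parent,
    )
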