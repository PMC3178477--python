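"""End-to-end orchestration: simulate/load -> pool -> test -> classify.

A :class:`PipelineConfig` fully determines a run; every parameter actually
used is written to a ``manifest.yaml`` next to the outputs, and a fixed
config + seed reproduces byte-identical result tables.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .count_model import CountMatrix, read_count_matrix, write_count_matrix
from .pairwise import pairwise_differential, results_to_frame
from .pooling import DEFAULT_PSEUDOCOUNT, pool_counts
from .simulate import SyntheticConfig, generate
from .specificity import (
    G_CRIT_05,
    coordinates_to_frame,
    extract_candidates,
    triple_coordinates,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("speccount")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Parameters of one full analysis run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    simulate: SyntheticConfig | None = None
    pairs: list[tuple[str, str]] = field(default_factory=list)
    focal_group: str | None = None
    f: float = DEFAULT_PSEUDOCOUNT
    alpha: float = 0.05
    rsc_threshold: float = 1.0
    g_crit: float = G_CRIT_05
    exact: str = "none"  # none | fisher
    out_dir: str = "speccount_run"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.g_crit <= 0:
            raise ValueError(f"g_crit must be positive, got {self.g_crit}")
        if self.f < 0:
            raise ValueError(f"pseudocount must be nonnegative, got {self.f}")
        if self.exact not in ("none", "fisher"):
            raise ValueError(f"unknown exact-test option {self.exact!r}")
        if (self.counts_path is None) == (self.simulate is None):
            raise ValueError("provide exactly one of input paths or a simulate config")


def _load_matrix(config: PipelineConfig) -> CountMatrix:
    if config.simulate is not None:
        config.simulate.seed = config.seed
        matrix, _ = generate(config.simulate)
        return matrix
    for path in (config.counts_path, config.metadata_path):
        if path is None or not Path(path).exists():
            raise PipelineError(f"stage load: input file not found: {path}")
    return read_count_matrix(config.counts_path, config.metadata_path)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage; returns a name -> path map of artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    matrix = _load_matrix(config)
    log.info("loaded %d proteins x %d runs", matrix.n_proteins, matrix.n_samples)
    if config.simulate is not None:
        cpath, mpath = out / "counts.tsv", out / "samples.tsv"
        write_count_matrix(matrix, cpath, mpath)
        artifacts["counts"], artifacts["samples"] = cpath, mpath

    try:
        pooled = pool_counts(matrix, by="group")
    except ValueError as e:
        raise PipelineError(f"stage pool: {e}") from e

    pairs = config.pairs or _default_pairs(pooled.groups)
    all_results = {}
    for pair in pairs:
        try:
            res = pairwise_differential(
                pooled,
                tuple(pair),
                alpha=config.alpha,
                rsc_threshold=config.rsc_threshold,
                f=config.f,
                with_fisher=config.exact == "fisher",
            )
        except ValueError as e:
            raise PipelineError(f"stage difftest {pair}: {e}") from e
        all_results[tuple(pair)] = res
        path = out / f"difftest_{pair[0]}_vs_{pair[1]}.tsv"
        results_to_frame(res).to_csv(path, sep="\t", index=False, float_format="%.6g")
        artifacts[f"difftest_{pair[0]}_vs_{pair[1]}"] = path
        log.info(
            "%s vs %s: %d significant", pair[0], pair[1],
            sum(r.significant for r in res),
        )

    if len(pooled.groups) == 3:
        coords = triple_coordinates(pooled, g_crit=config.g_crit)
        cpath = out / "coordinates.tsv"
        coordinates_to_frame(coords).to_csv(
            cpath, sep="\t", index=False, float_format="%.6g"
        )
        artifacts["coordinates"] = cpath
        focal = config.focal_group or pooled.groups[0]
        focal_pair = next((p for p in all_results if focal in p), None)
        if focal_pair is not None:
            cand = extract_candidates(coords, all_results[focal_pair], focal)
            kpath = out / f"candidates_{focal}.tsv"
            cand.to_csv(kpath, sep="\t", index=False, float_format="%.6g")
            artifacts["candidates"] = kpath
            log.info("%d %s-specific candidates", len(cand), focal)

    manifest = {
        "speccount_version": __version__,
        "parameters": _manifest_params(config),
        "groups": pooled.groups,
        "pairs": [list(p) for p in pairs],
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
    }
    mpath = out / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    artifacts["manifest"] = mpath
    return artifacts


def _default_pairs(groups: list[str]) -> list[tuple[str, str]]:
    if len(groups) == 3:
        g1, g2, g3 = groups
        return [(g1, g2), (g1, g3), (g3, g2)]
    return [(groups[0], g) for g in groups[1:]]


def _manifest_params(config: PipelineConfig) -> dict:
    d = asdict(config)
    if config.simulate is not None:
        d["simulate"] = asdict(config.simulate)
    return d
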