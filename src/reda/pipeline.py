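"""End-to-end pipeline: discover -> quantify -> call expressed -> screens.

Configuration is a TOML file whose keys mirror the discovery parameters,
plus a ``[[samples]]`` table per coverage track (id, bedgraph path,
library size, cell type).  All stages are deterministic given the same
configuration and inputs.
"""

from __future__ import annotations

import json
import logging
import os
import tomllib
from dataclasses import dataclass, field

import pandas as pd

from .annotation import build_exon_universe, parse_annotation
from .coverage import read_coverage, rpm_to_depth
from .discovery import DiscoveryConfig, ReClass, RNAElement, discover
from .enrichment import (
    annotate_repeat_overlap,
    compute_enrichment,
    read_repeats,
    results_to_frame,
)
from .quantify import (
    call_expressed,
    calls_to_frame,
    expressed_ids_by_cell_type,
    quantify_res,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "elements_to_frame"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SampleSpec:
    id: str
    bedgraph: str
    library_size: int
    cell_type: str = ""


@dataclass
class RunConfig:
    """Everything a pipeline run needs: inputs, parameters, output dir."""

    gtf: str
    samples: list[SampleSpec]
    outdir: str
    repeats: str | None = None
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    read_length: int = 75
    expressed_threshold: float = 25.0
    alpha: float = 0.05
    min_diff: float = 10.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def _resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base, p)

        disc_keys = {
            "mu",
            "bin_size",
            "merge_gap",
            "near_exon_distance",
            "extension_gap",
            "extension_max_coverage_diff",
            "strict_threshold",
        }
        disc = DiscoveryConfig(**{k: raw[k] for k in disc_keys if k in raw})
        samples = [
            SampleSpec(
                id=s["id"],
                bedgraph=_resolve(s["bedgraph"]),
                library_size=int(s["library_size"]),
                cell_type=s.get("cell_type", s["id"]),
            )
            for s in raw.get("samples", [])
        ]
        return cls(
            gtf=_resolve(raw["gtf"]),
            samples=samples,
            outdir=_resolve(raw.get("outdir", "reda_out")),
            repeats=_resolve(raw["repeats"]) if raw.get("repeats") else None,
            discovery=disc,
            read_length=int(raw.get("read_length", 75)),
            expressed_threshold=float(raw.get("expressed_threshold", 25.0)),
            alpha=float(raw.get("alpha", 0.05)),
            min_diff=float(raw.get("min_diff", 10.0)),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


def elements_to_frame(res: list[RNAElement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [el.id for el in res],
            "chrom": [el.interval.chrom for el in res],
            "start": [el.interval.start for el in res],
            "end": [el.interval.end for el in res],
            "class": [str(el.re_class) for el in res],
            "gene_names": [",".join(sorted(el.gene_names)) for el in res],
            "n_source_samples": [len(el.source_samples) for el in res],
        }
    )


def write_elements_bed(res: list[RNAElement], path: str) -> None:
    with open(path, "w") as fh:
        for el in res:
            name = f"{el.id}|{el.re_class}|{','.join(sorted(el.gene_names))}"
            fh.write(
                f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}"
                f"\t{name}\t0\t.\n"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the output manifest.

    Stages: annotation parsing, per-sample discovery and cross-sample
    merging, RPKM quantification, expressed-element calling, and (when a
    repeat annotation is configured) the repeat-enrichment screen.  Any
    stage failure raises :class:`PipelineError` naming the stage; the
    manifest lists every output file with its row count.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for p in [config.gtf, config.repeats] + [s.bedgraph for s in config.samples]:
        if p and not os.path.exists(p):
            raise PipelineError(f"input path does not exist: {p}")
    if not config.samples:
        raise PipelineError("configuration lists no samples")
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {"outputs": {}, "stages": []}

    def _stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    def _write_tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = os.path.join(config.outdir, name)
        df.to_csv(path, sep="\t", index=index, lineterminator="\n")
        manifest["outputs"][name] = {"path": path, "rows": int(df.shape[0])}

    try:
        _stage("annotation")
        universe = build_exon_universe(parse_annotation(config.gtf))
    except Exception as exc:
        raise PipelineError(f"annotation stage failed: {exc}") from exc

    try:
        _stage("discover")
        tracks = [
            read_coverage(s.bedgraph, s.library_size, s.id) for s in config.samples
        ]
        for t in tracks:
            thr = rpm_to_depth(config.discovery.mu, t.library_size)
            logger.info(
                "sample %s: mu=%g RPM -> absolute depth %.3f",
                t.sample_id,
                thr.mu,
                thr.absolute_depth,
            )
        res = discover(tracks, universe, config.discovery)
        _write_tsv(elements_to_frame(res), "elements.tsv")
        bed_path = os.path.join(config.outdir, "elements.bed")
        write_elements_bed(res, bed_path)
        manifest["outputs"]["elements.bed"] = {"path": bed_path, "rows": len(res)}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"discover stage failed: {exc}") from exc

    try:
        _stage("quantify")
        groups = {s.id: s.cell_type or s.id for s in config.samples}
        matrix = quantify_res(res, tracks, groups, config.read_length)
        mat = matrix.values.copy()
        mat.index.name = "re_id"
        _write_tsv(mat, "rpkm.tsv", index=True)
    except Exception as exc:
        raise PipelineError(f"quantify stage failed: {exc}") from exc

    try:
        _stage("call_expressed")
        calls = call_expressed(matrix, config.expressed_threshold)
        _write_tsv(calls_to_frame(calls), "expressed.tsv")
    except Exception as exc:
        raise PipelineError(f"call_expressed stage failed: {exc}") from exc

    if config.repeats:
        try:
            _stage("enrich")
            repeats = read_repeats(config.repeats)
            overlap = annotate_repeat_overlap(res, repeats)
            results = compute_enrichment(
                res,
                overlap,
                expressed_ids_by_cell_type(calls),
                alpha=config.alpha,
                min_diff=config.min_diff,
            )
            _write_tsv(results_to_frame(results), "enrichment.tsv")
        except Exception as exc:
            raise PipelineError(f"enrich stage failed: {exc}") from exc

    manifest["n_elements"] = len(res)
    manifest["n_novel"] = sum(1 for el in res if el.re_class is not ReClass.EXONIC)
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
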