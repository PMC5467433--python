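"""End-to-end pipeline driver: screen -> pairwise integration -> null
models -> merge -> topology and hubs, with a full output bundle on disk.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import PairwiseNetwork, build_pairwise_network
from .blocks import OmicsBlock, read_block
from .io import (
    write_edge_list,
    write_merged_edge_list,
    write_node_attributes,
    write_screen_report,
    write_sif,
    write_topology_report,
)
from .netops import filter_min_membership, find_hubs, merge_networks, topology
from .nullmodel import compare_to_null, null_threshold_distribution
from .screen import log_transform, screen_block
from .spls import SplsConfig

__all__ = ["BlockConfig", "PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class BlockConfig:
    path: str
    data_type: str
    fdr_threshold: float = 0.05
    log_offset: float = 0.0


@dataclass
class PipelineConfig:
    blocks: list[BlockConfig]
    groups_path: str
    reference_group: str
    out_dir: str = "omicnet_out"
    ncomp: int = 5
    keep_x: int | None = None
    keep_y: int | None = None
    scale: bool = True
    fraction: float = 0.05
    run_null: bool = False
    n_iterations: int = 200
    min_networks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError("need at least two blocks")
        labels = [b.data_type for b in self.blocks]
        if len(set(labels)) != len(labels):
            raise ValueError("block data_type labels must be unique")
        if not (0 < self.fraction <= 0.5):
            raise ValueError("fraction must be in (0, 0.5]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        blocks = [BlockConfig(**b) for b in raw.pop("blocks")]
        return cls(blocks=blocks, **raw)

    def spls_config(self) -> SplsConfig:
        return SplsConfig(
            ncomp=self.ncomp, keep_x=self.keep_x, keep_y=self.keep_y, scale=self.scale
        )


@dataclass
class PipelineResult:
    screens: dict
    networks: list[PairwiseNetwork]
    null_comparisons: dict
    merged: object
    filtered: object
    report: object
    hubs: object
    pair_summary: pd.DataFrame = field(default=None)


def run_pipeline(
    config: PipelineConfig, blocks: list[OmicsBlock] | None = None
) -> PipelineResult:
    """Execute the whole analysis and write the output bundle.

    ``blocks`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are read from the configured paths.  Any stage failure
    aborts with the stage and block pair named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if blocks is None:
        blocks = [
            read_block(
                b.path,
                data_type=b.data_type,
                groups_path=config.groups_path,
                reference_group=config.reference_group,
            )
            for b in config.blocks
        ]
    by_type = {b.data_type: b for b in blocks}

    # stage 1: differential screening; integration then runs on the
    # log-transformed values of the selected features
    screens = {}
    screened_blocks: list[OmicsBlock] = []
    for bc in config.blocks:
        block = by_type[bc.data_type]
        try:
            logged = log_transform(block, offset=bc.log_offset)
            res = screen_block(
                logged, fdr_threshold=bc.fdr_threshold, already_log=True
            )
        except ValueError as exc:
            raise RuntimeError(f"screen failed for block {bc.data_type!r}: {exc}")
        if not res.selected_features:
            raise RuntimeError(
                f"screen selected no features in block {bc.data_type!r}; "
                "it cannot enter integration"
            )
        screens[bc.data_type] = res
        write_screen_report(res, out / f"screen_{bc.data_type}.tsv")
        screened_blocks.append(logged.subset_features(sorted(res.selected_features)))
        logger.info(
            "screen %s: %d/%d features selected at FDR %.3g",
            bc.data_type,
            len(res.selected_features),
            block.n_features,
            bc.fdr_threshold,
        )

    # stage 2: all pairwise integrations (+ optional null models)
    spls_cfg = config.spls_config()
    pairs = list(itertools.combinations(screened_blocks, 2))
    seeds = np.random.SeedSequence(config.seed).spawn(len(pairs))
    networks: list[PairwiseNetwork] = []
    null_comparisons = {}
    pair_rows = []
    for k, (bx, by) in enumerate(pairs):
        label = f"{bx.data_type}&{by.data_type}"
        try:
            assoc, net = build_pairwise_network(
                bx, by, spls_config=spls_cfg, fraction=config.fraction
            )
        except ValueError as exc:
            raise RuntimeError(f"integration failed for pair {label}: {exc}")
        networks.append(net)
        write_edge_list(net, out / f"edges_{bx.data_type}_{by.data_type}.tsv")
        row = {
            "pair": label,
            "th_l": assoc.th_l,
            "th_h": assoc.th_h,
            "n_nodes_a": len(net.nodes_x),
            "n_nodes_b": len(net.nodes_y),
            "n_edges": len(net.edges),
            "connected_components": net.n_components,
        }
        if config.run_null:
            null = null_threshold_distribution(
                bx,
                by,
                spls_config=spls_cfg,
                fraction=config.fraction,
                n_iterations=config.n_iterations,
                seed=int(seeds[k].generate_state(1)[0] % (2**31)),
            )
            cmp = compare_to_null((assoc.th_l, assoc.th_h), assoc.m, null)
            null_comparisons[label] = cmp
            pd.DataFrame(
                {
                    "iteration": np.arange(1, null.n_iterations + 1),
                    "th_l": null.th_lk,
                    "th_h": null.th_hk,
                }
            ).to_csv(
                out / f"null_{bx.data_type}_{by.data_type}.tsv",
                sep="\t",
                index=False,
                float_format="%.10g",
            )
            row.update(
                {
                    "null_p_high": cmp.p_high,
                    "null_p_low": cmp.p_low,
                    "null_overlap": int(cmp.overlap),
                }
            )
        pair_rows.append(row)
        logger.info("pair %s: %d edges, thresholds (%.3g, %.3g)",
                    label, len(net.edges), assoc.th_l, assoc.th_h)
    pair_summary = pd.DataFrame(pair_rows)
    pair_summary.to_csv(
        out / "pairwise_summary.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # stage 3: merge, filter, topology, hubs
    try:
        merged = merge_networks(networks)
        filtered = filter_min_membership(merged, k=config.min_networks)
        report = topology(filtered)
        hubs = find_hubs(filtered)
    except ValueError as exc:
        raise RuntimeError(f"network merging/topology failed: {exc}")
    write_merged_edge_list(filtered, out / "merged_edges.tsv")
    write_node_attributes(filtered, hubs, out / "merged_nodes.tsv")
    write_sif(filtered, out / "merged.sif")
    write_topology_report(report, hubs, out / "merged_report.json")

    manifest = {
        "omicnet_version": __version__,
        "seed": config.seed,
        "reference_group": config.reference_group,
        "fraction": config.fraction,
        "ncomp": config.ncomp,
        "keep_x": config.keep_x,
        "keep_y": config.keep_y,
        "scale": config.scale,
        "min_networks": config.min_networks,
        "run_null": config.run_null,
        "n_iterations": config.n_iterations,
        "blocks": [
            {
                "data_type": bc.data_type,
                "path": bc.path,
                "fdr_threshold": bc.fdr_threshold,
                "log_offset": bc.log_offset,
                "n_selected": len(screens[bc.data_type].selected_features),
            }
            for bc in config.blocks
        ],
        "n_pairwise_networks": len(networks),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return PipelineResult(
        screens=screens,
        networks=networks,
        null_comparisons=null_comparisons,
        merged=merged,
        filtered=filtered,
        report=report,
        hubs=hubs,
        pair_summary=pair_summary,
    )
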