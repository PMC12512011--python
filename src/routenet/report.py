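"""Pathway visualization and run-artifact export.

Each pathway renders as a bipartite graph: molecules as boxes, reactions as
small labeled nodes (a reaction node is the hyperedge joining its reactants
to its products). Graphviz dot text is the canonical output — it is
bit-stable and diffable — with optional SVG/PDF rendering delegated to a
``dot`` executable when one is available; otherwise the dot text is written
with a warning. Reactions reported in the reference database are highlighted
(blue by default).
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from routenet.model import Network
from routenet.pathways import Pathway
from routenet.ranking import RankingTable

log = logging.getLogger(__name__)

ANNOTATIONS = {
    "rank", "total_score", "atom_economy", "byproduct_number", "pi",
    "reaction_names", "dh_per_step", "reported_flag",
}


@dataclass
class ReportConfig:
    format: str = "dot"  # {"dot", "svg", "pdf"}
    top_n: int = 10
    highlight_reported: str = "blue"
    annotations: set[str] = field(default_factory=lambda: set(ANNOTATIONS))

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.format not in ("dot", "svg", "pdf"):
            raise ValueError(f"unknown format {self.format!r}")


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def pathway_dot(
    pathway: Pathway,
    network: Network,
    rank: int | None = None,
    total: float | None = None,
    raw: dict | None = None,
    rule_names: dict[str, str] | None = None,
    reported: dict[str, bool] | None = None,
    config: ReportConfig | None = None,
) -> str:
    """Deterministic dot text for one pathway graph."""
    config = config or ReportConfig()
    ann = config.annotations
    raw = raw or {}
    rule_names = rule_names or {}
    reported = reported or {}

    header = []
    if rank is not None and "rank" in ann:
        header.append(f"rank {rank}")
    if total is not None and "total_score" in ann:
        header.append(f"score {total:.3f}")
    if "atom_economy" in ann and pathway.atom_economy is not None:
        header.append(f"AE {pathway.atom_economy:.3f}")
    if "byproduct_number" in ann and raw.get("pathway_byproducts") is not None:
        header.append(f"by-products {raw['pathway_byproducts']:.0f}")
    if "pi" in ann and raw.get("profitability_index") is not None:
        header.append(f"PI {raw['profitability_index']:.2f}")

    lines = ["digraph pathway {"]
    lines.append("  rankdir=LR;")
    lines.append(f"  label={_quote('; '.join(header))};")
    lines.append("  labelloc=t;")
    lines.append('  node [fontsize=10];')

    mols = sorted({m for k in pathway.reactions for m in
                   network.reactions[k].reactants + network.reactions[k].products})
    for m in mols:
        shape = "box"
        style = ', style=bold' if m == pathway.target else ""
        lines.append(f"  {_quote('mol:' + m)} [label={_quote(m)}, shape={shape}{style}];")

    for k in pathway.reactions:
        rxn = network.reactions[k]
        label_parts = []
        if "reaction_names" in ann:
            label_parts.append(rule_names.get(rxn.rule_id, rxn.rule_id))
        if "dh_per_step" in ann and rxn.dh_rxn is not None:
            label_parts.append(f"dH {rxn.dh_rxn:+.1f}")
        is_reported = reported.get(k, rxn.reported_flag)
        if "reported_flag" in ann and is_reported:
            label_parts.append("reported")
        node_color = (
            f", color={config.highlight_reported}, fontcolor={config.highlight_reported}"
            if is_reported else ""
        )
        edge_attr = f" [color={config.highlight_reported}]" if is_reported else ""
        lines.append(
            f"  {_quote('rxn:' + k)} [label={_quote(chr(10).join(label_parts))}, shape=ellipse{node_color}];"
        )
        for m in sorted(set(rxn.reactants)):
            lines.append(f"  {_quote('mol:' + m)} -> {_quote('rxn:' + k)}{edge_attr};")
        for m in sorted(set(rxn.products)):
            lines.append(f"  {_quote('rxn:' + k)} -> {_quote('mol:' + m)}{edge_attr};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def render_pathways(
    ranking: RankingTable,
    pathways: list[Pathway],
    network: Network,
    out_dir: str | Path,
    config: ReportConfig | None = None,
    rule_names: dict[str, str] | None = None,
    reported: dict[str, bool] | None = None,
) -> list[Path]:
    """Render the top-N ranked pathways, one graph per pathway, rank order.

    Dot files are always written; for svg/pdf formats a ``dot`` renderer is
    invoked when present, otherwise the dot text stands with a warning.
    """
    config = config or ReportConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_key = {p.key: p for p in pathways}
    written: list[Path] = []
    renderer = shutil.which("dot")
    if config.format != "dot" and renderer is None:
        log.warning("no 'dot' renderer on PATH; emitting dot text instead of %s", config.format)

    for row in ranking.rows[: config.top_n]:
        pw = by_key.get(row.pathway_key)
        if pw is None:
            continue
        dot = pathway_dot(
            pw, network, rank=row.rank, total=row.total, raw=row.raw,
            rule_names=rule_names, reported=reported, config=config,
        )
        path = out_dir / f"pathway_rank{row.rank:03d}.dot"
        path.write_text(dot)
        written.append(path)
        if config.format != "dot" and renderer is not None:
            target = path.with_suffix("." + config.format)
            subprocess.run(
                [renderer, f"-T{config.format}", str(path), "-o", str(target)],
                check=True,
            )
            written.append(target)
    return written


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def export_run(
    network: Network,
    pathways: list[Pathway],
    ranking: RankingTable | None,
    directory: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    report_config: ReportConfig | None = None,
    rule_names: dict[str, str] | None = None,
) -> dict:
    """Write net.json, paths.json, ranking.json, report files, and a manifest.

    The manifest records the config hash, seed, and per-generation counts so
    a run is identifiable and comparable after the fact. Returns the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    network.write_json(directory / "net.json")
    (directory / "paths.json").write_text(
        json.dumps([p.to_dict() for p in pathways], indent=1, sort_keys=True)
    )
    report_files: list[str] = []
    if ranking is not None:
        (directory / "ranking.json").write_text(
            json.dumps(ranking.to_dict(), indent=1, sort_keys=True)
        )
        files = render_pathways(
            ranking, pathways, network, directory / "report",
            config=report_config, rule_names=rule_names,
        )
        report_files = [str(f.relative_to(directory)) for f in files]

    per_generation = []
    for entry in network.provenance:
        per_generation.extend(entry.get("per_generation", []))
    manifest = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "molecules": len(network.molecules),
        "reactions": len(network.reactions),
        "pathways": len(pathways),
        "per_generation": per_generation,
        "files": ["net.json", "paths.json"]
        + (["ranking.json"] if ranking is not None else [])
        + report_files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
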