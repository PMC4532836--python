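"""End-to-end orchestration: simulate -> analyze -> predict -> report.

These functions are the programmatic counterparts of the CLI subcommands;
each writes plain-text outputs (TSV traces, JSON event tables and
summaries) stamped with provenance metadata (package version, seed, config
hash).  Analysis decisions — trace rejections, flagged events — are logged
at INFO level on the ``cuproforce`` logger.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from cuproforce._version import __version__
from cuproforce.analysis import (
    CLASSIFICATION_WINDOWS,
    EventTable,
    detect_intermediates,
    detect_ruptures,
    fingerprint_filter,
    fit_events,
)
from cuproforce.config import RunConfig
from cuproforce.schemes import CONSTRUCTS, InstrumentConfig, i27, load_schemes
from cuproforce.simulate import simulate_constant_velocity, simulate_force_clamp
from cuproforce.stats import dip_pvalue, partition_fractions, summarize_modes
from cuproforce.structure import (
    find_disulfides,
    metal_site_geometry,
    parse_structure,
    predict_increment,
)
from cuproforce.traces import read_trace, write_trace

logger = logging.getLogger("cuproforce")

__all__ = ["cmd_simulate", "cmd_analyze", "cmd_predict", "cmd_report"]


def _polyprotein(config: RunConfig):
    if config.scheme_file is not None:
        schemes = load_schemes(config.scheme_file)
        if config.construct not in schemes:
            raise ValueError(
                f"construct {config.construct!r} not in scheme file "
                f"{config.scheme_file} (has {sorted(schemes)})"
            )
        protein = schemes[config.construct]
        fingerprint = schemes.get("I27", i27())
        mods = []
        for _ in range(config.n_repeats):
            mods.extend([protein, fingerprint])
        return mods
    mods = []
    for _ in range(config.n_repeats):
        mods.extend([CONSTRUCTS[config.construct](), i27()])
    return mods


def _provenance(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
    }


def cmd_simulate(config: RunConfig, mode: str = "constant_velocity",
                 clamp_force: float = 20.0, duration: float = 10.0) -> list[Path]:
    """Simulate ``config.n_traces`` traces; write TSVs and ground-truth JSONs.

    Trace ``i`` uses seed ``config.seed + i``, so runs are deterministic
    given the config.  Returns the written trace paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    polyprotein = _polyprotein(config)
    paths = []
    for i in range(config.n_traces):
        inst = InstrumentConfig(
            pulling_velocity=config.instrument.pulling_velocity,
            spring_constant=config.instrument.spring_constant,
            sampling_rate=config.instrument.sampling_rate,
            force_noise_sd=config.instrument.force_noise_sd,
            rng_seed=config.seed + i,
        )
        if mode == "constant_velocity":
            trace, truth = simulate_constant_velocity(
                polyprotein, inst, temperature=config.analysis.temperature,
                persistence_length=config.analysis.persistence_length,
                tether_contour=config.tether_contour,
            )
        elif mode == "force_clamp":
            trace, truth = simulate_force_clamp(
                polyprotein, clamp_force, duration, inst,
                temperature=config.analysis.temperature,
                persistence_length=config.analysis.persistence_length,
                tether_contour=config.tether_contour,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        trace.metadata.update(_provenance(config))
        stem = f"{config.construct}_{mode}_{i:04d}"
        trace_path = out / f"{stem}.tsv"
        write_trace(trace, trace_path)
        truth["provenance"] = _provenance(config)
        (out / f"{stem}.truth.json").write_text(json.dumps(truth, indent=1))
        paths.append(trace_path)
        logger.info("wrote %s (%d samples, %d events)", trace_path,
                    len(trace), len(truth["events"]))
    return paths


def analyze_trace(trace, config: RunConfig) -> EventTable:
    """Run the full detection/fitting/classification chain on one trace."""
    ruptures = detect_ruptures(
        trace, min_drop=config.analysis.min_drop,
        min_spacing=config.analysis.min_spacing,
    )
    table = fit_events(
        trace, ruptures,
        persistence_length=config.analysis.persistence_length,
        temperature=config.analysis.temperature,
        force_floor=config.analysis.force_floor,
    )
    table = fingerprint_filter(table)
    if config.construct in CLASSIFICATION_WINDOWS:
        table = detect_intermediates(table, config.construct)
    return table


def cmd_analyze(config: RunConfig, trace_paths: list) -> dict:
    """Analyze traces; write per-trace event tables and a summary.

    Unreadable traces are skipped with a logged warning and counted in the
    summary.  Returns the summary dict (also written as JSON).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels: list[str] = []
    positions: list[float] = []
    n_rejected = 0
    n_failed = 0
    rejects: list[dict] = []
    tables = 0
    event_rows: list[dict] = []
    for path in trace_paths:
        path = Path(path)
        try:
            trace = read_trace(path)
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable trace %s: %s", path, exc)
            n_failed += 1
            continue
        table = analyze_trace(trace, config)
        tables += 1
        table_json = table.as_dict()
        table_json["provenance"] = _provenance(config)
        table_json["source_trace"] = str(path)
        (out / (path.stem + ".events.json")).write_text(
            json.dumps(table_json, indent=1)
        )
        for e in table.events:
            event_rows.append(
                {
                    "trace": path.stem,
                    "index": e.index,
                    "extension_nm": e.extension,
                    "force_pN": e.rupture_force,
                    "Lc_nm": e.contour_length,
                    "delta_Lc_nm": e.delta_Lc,
                    "label": e.label,
                    "flagged": e.flagged,
                }
            )
        if not table.accepted:
            n_rejected += 1
            rejects.append({"trace": str(path), "reason": table.reject_reason})
            logger.info("rejected %s: %s", path, table.reject_reason)
            continue
        labels.extend(table.pathway_labels)
        positions.extend(d["position_nm"] for d in table.intermediates)

    # flat TSV mirror of all events
    if event_rows:
        cols = list(event_rows[0])
        lines = ["\t".join(cols)]
        for row in event_rows:
            lines.append("\t".join(str(row[c]) for c in cols))
        (out / "events.tsv").write_text("\n".join(lines) + "\n")

    summary: dict = {
        "provenance": _provenance(config),
        "construct": config.construct,
        "n_traces": len(trace_paths),
        "n_analyzed": tables,
        "n_rejected": n_rejected,
        "n_unreadable": n_failed,
        "rejects": rejects,
        "n_pathways": len(labels),
        "n_intermediates": len(positions),
    }
    if labels:
        summary["partition"] = partition_fractions(labels).as_dict()
    windows = CLASSIFICATION_WINDOWS.get(config.construct)
    if positions and windows:
        summary["modes"] = summarize_modes(positions, windows)
        if len(positions) >= 4:
            dip = dip_pvalue(positions, n_null=config.stats.n_null,
                             seed=config.seed)
            summary["dip_test"] = {
                "dip": dip.dip, "pvalue": dip.pvalue, "n": dip.n,
                "n_null": dip.n_null, "certainty_percent": dip.certainty,
            }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def cmd_predict(pdb_path, chain_id: str = "A", anchors: list[int] | None = None,
                L_res: float = 0.38) -> dict:
    """Structure-derived contour-length report for one PDB file.

    Predicts ΔL from both termini to every metal-ligand anchor (or the
    given anchor residues), with detected disulfides intact and removed,
    plus the metal-site geometry.
    """
    content = Path(pdb_path).read_text()
    model = parse_structure(content, chain_id)
    disulfides = find_disulfides(model)
    try:
        site = metal_site_geometry(model)
        site_info = {
            "element": site.element,
            "ligands": site.ligands,
        }
        default_anchors = sorted({lig["residue"] for lig in site.ligands})
    except ValueError:
        site_info = None
        default_anchors = []
    anchors = anchors if anchors else default_anchors
    rows = []
    for terminus in ("N", "C"):
        for anchor in [None] + list(anchors):
            for ss_on in ([True, False] if disulfides else [True]):
                pred = predict_increment(
                    model, terminus, anchor,
                    disulfides=disulfides if ss_on else [],
                    L_res=L_res,
                )
                rows.append(
                    {
                        "pulled_terminus": terminus,
                        "anchor": anchor if anchor is not None else "full",
                        "disulfides": "intact" if (ss_on and disulfides) else "none",
                        "released": pred.released,
                        "trapped": pred.trapped,
                        "native_span_nm": round(pred.native_span_nm, 2),
                        "delta_L_nm": round(pred.delta_L_nm, 2),
                    }
                )
    return {
        "pdb": str(pdb_path),
        "chain": chain_id,
        "n_residues": len(model),
        "disulfides": [
            {"residues": list(b.residues), "distance_A": round(b.distance, 2)}
            for b in disulfides
        ],
        "metal_site": site_info,
        "predictions": rows,
        "L_res_nm": L_res,
        "package_version": __version__,
    }


def cmd_report(summary: dict) -> str:
    """Plain-text report mirroring figure-caption statistics style."""
    lines = [f"Construct: {summary.get('construct', '?')}"]
    lines.append(
        f"Traces: {summary.get('n_analyzed', 0)} analyzed, "
        f"{summary.get('n_rejected', 0)} rejected "
        f"(fingerprint filter), {summary.get('n_unreadable', 0)} unreadable"
    )
    part = summary.get("partition")
    if part:
        lines.append("Pathway partition:")
        for label, frac in part["fractions"].items():
            n = part["counts"][label]
            lo, hi = part["wilson_95"][label]
            lines.append(
                f"  {label:>10s}: {frac * 100:5.1f}% (n={n}, "
                f"95% CI {lo * 100:.1f}-{hi * 100:.1f}%)"
            )
    modes = summary.get("modes")
    if modes:
        lines.append("Intermediate positions:")
        for label, m in modes.items():
            if label == "unassigned":
                lines.append(f"  unassigned: n={m['n']}")
            elif m["n"]:
                lines.append(
                    f"  {label}: dL = {m['mean']:.1f} +/- {m['sd']:.1f} nm, n={m['n']}"
                )
    dip = summary.get("dip_test")
    if dip:
        lines.append(
            f"Hartigan dip test (vs uniform, {dip['n_null']} null draws): "
            f"D = {dip['dip']:.4f}, P = {dip['pvalue']:.4f} "
            f"({dip['certainty_percent']:.1f}% certainty), n = {dip['n']}"
        )
    return "\n".join(lines)
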