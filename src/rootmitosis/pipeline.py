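"""Pipeline orchestration: simulate -> analyse -> compare.

Each stage writes a self-contained bundle directory of delimited-text and
JSON files that the package's own readers can re-read.  Run metadata always
records the effective parameters (epsilon, min_samples, pooling scope, SD
convention, spectral options) because those conventions are choices the
analysis depends on; timestamps live only in metadata so all data outputs
are byte-deterministic for a given seed and configuration.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import ComparisonReport, run_comparisons
from .events_io import EventTable, read_events, write_events
from .spatial import ClusterParams, cluster_table, pairwise_centre_distances
from .synthetic import SynthConfig, intact_defaults, regenerating_defaults, simulate_table_with_truth
from .temporal import (
    average_periodograms,
    burst_threshold,
    detect_bursts,
    frame_series_by_root,
    periodogram,
    top_periods,
)

__all__ = [
    "AnalysisParams",
    "cmd_analyse",
    "cmd_compare",
    "cmd_simulate",
    "load_synth_configs",
]

log = logging.getLogger("rootmitosis")

_SYNTH_FIELDS = {f.name for f in dataclasses.fields(SynthConfig)}


@dataclasses.dataclass(frozen=True)
class AnalysisParams:
    """Effective knobs of the analyse stage."""

    cluster: ClusterParams = ClusterParams()
    pooling: str = "per-condition"
    top_k_periods: int = 3


def load_synth_configs(config: dict | str | Path | None, seed: int | None = None
                       ) -> tuple[SynthConfig, SynthConfig]:
    """Build the (intact, regenerating) config pair from a flat mapping.

    Keys matching SynthConfig fields apply to both conditions; optional
    ``intact`` / ``regenerating`` sub-mappings override per condition.
    ``None`` yields the study defaults.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config or {})
    per_cond = {c: dict(config.pop(c, {}) or {}) for c in ("intact", "regenerating")}
    unknown = set(config) - _SYNTH_FIELDS
    if unknown:
        raise ValueError(f"unknown synthetic-config keys: {sorted(unknown)}")
    base_i = dataclasses.asdict(intact_defaults())
    base_r = dataclasses.asdict(regenerating_defaults())
    for base, cond in ((base_i, "intact"), (base_r, "regenerating")):
        base.update(config)
        bad = set(per_cond[cond]) - _SYNTH_FIELDS
        if bad:
            raise ValueError(f"unknown keys under '{cond}': {sorted(bad)}")
        base.update(per_cond[cond])
        if seed is not None:
            base["seed"] = seed
        base["domain_um"] = tuple(base["domain_um"])
    return SynthConfig(**base_i), SynthConfig(**base_r)


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _run_meta(stage: str, params: dict) -> dict:
    return {
        "stage": stage,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": params,
    }


def cmd_simulate(
    config: dict | str | Path | None,
    seed: int,
    out_dir: str | Path,
    n_roots_per_condition: int = 4,
) -> Path:
    """Simulate a two-condition study; write events, truth and metadata.

    Writes ``events.csv`` (the standard event table), ``truth.json``
    (per-root burst frames, injected period, parents per frame — the ground
    truth recovery tests need) and ``run_meta.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_i, cfg_r = load_synth_configs(config, seed=seed)
    table, truth = simulate_table_with_truth(cfg_i, cfg_r, n_roots_per_condition)
    write_events(table, out / "events.csv")
    _write_json(out / "truth.json", truth.to_jsonable())
    _write_json(
        out / "run_meta.json",
        _run_meta(
            "simulate",
            {
                "seed": seed,
                "n_roots_per_condition": n_roots_per_condition,
                "intact": dataclasses.asdict(cfg_i),
                "regenerating": dataclasses.asdict(cfg_r),
            },
        ),
    )
    log.info("simulate: %d events, %d roots -> %s", len(table), len(table.root_ids), out)
    return out


def cmd_analyse(
    events: str | Path | EventTable,
    out_dir: str | Path,
    delta_t_h: float = 0.25,
    params: AnalysisParams = AnalysisParams(),
) -> Path:
    """Run every analysis stage on an event table and write a result bundle.

    Outputs: ``counts.csv``, ``bursts.csv``, ``periodogram.csv`` (per-root
    PSDs averaged per condition), ``clusters.csv``, ``cluster_summary.csv``,
    ``distances.csv``, ``summary.json`` and ``run_meta.json``.  When both
    conditions are present a comparison report is included; otherwise the
    summary notes the comparison was skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(events, EventTable):
        table = events
    else:
        table = read_events(events, delta_t_h=delta_t_h)
    if len(table) == 0:
        raise ValueError("empty event table: nothing to analyse")
    write_events(table, out / "events.csv")

    # temporal stage
    count_rows, burst_rows, pg_rows = [], [], []
    summary: dict[str, Any] = {"n_events": len(table), "conditions": {}}
    for cond in table.conditions:
        series = frame_series_by_root(table, cond)
        thr = burst_threshold(series)
        sizes_all = []
        for s in series:
            count_rows.append(
                pd.DataFrame(
                    {
                        "root_id": s.root_id,
                        "condition": cond,
                        "frame_index": np.arange(len(s.counts)),
                        "count": s.counts,
                    }
                )
            )
            burst = detect_bursts(s, thr)
            sizes_all.extend(burst.sizes)
            if len(burst):
                burst_rows.append(
                    pd.DataFrame(
                        {
                            "root_id": s.root_id,
                            "condition": cond,
                            "frame_index": burst.frames,
                            "size": burst.sizes,
                        }
                    )
                )
        pgs = [periodogram(s) for s in series if len(s) >= 4]
        cond_summary: dict[str, Any] = {
            "n_roots": len(series),
            "burst_threshold": thr,
            "n_bursts": len(sizes_all),
            "mean_burst_size": float(np.mean(sizes_all)) if sizes_all else None,
        }
        if pgs:
            pg = average_periodograms(pgs)
            pg_rows.append(
                pd.DataFrame({"condition": cond, "period_h": pg.period_h, "psd": pg.psd})
            )
            cond_summary["top_periods_h"] = top_periods(pg, params.top_k_periods)
            cond_summary["periodogram_convention"] = "per-root PSDs averaged within condition"
        summary["conditions"][cond] = cond_summary
        log.info("analyse[%s]: threshold %.2f, %d bursts", cond, thr, len(sizes_all))

    pd.concat(count_rows, ignore_index=True).to_csv(out / "counts.csv", index=False)
    burst_df = (
        pd.concat(burst_rows, ignore_index=True)
        if burst_rows
        else pd.DataFrame(columns=["root_id", "condition", "frame_index", "size"])
    )
    burst_df.to_csv(out / "bursts.csv", index=False)
    if pg_rows:
        pd.concat(pg_rows, ignore_index=True).to_csv(out / "periodogram.csv", index=False)

    # spatial stage
    labels_df, summaries = cluster_table(table, params.cluster)
    labels_df.to_csv(out / "clusters.csv", index=False)
    srows, drows = [], []
    for s in summaries:
        for label, (size, centre) in enumerate(zip(s.sizes, s.centres)):
            srows.append((s.root_id, s.frame_index, label, int(size), *centre))
        d = pairwise_centre_distances(s)
        drows.extend((s.root_id, s.frame_index, float(v)) for v in d)
    pd.DataFrame(
        srows, columns=["root_id", "frame_index", "label", "size", "cx_um", "cy_um", "cz_um"]
    ).to_csv(out / "cluster_summary.csv", index=False)
    pd.DataFrame(drows, columns=["root_id", "frame_index", "dist_um"]).to_csv(
        out / "distances.csv", index=False
    )
    n_clustered = int((labels_df["label"] >= 0).sum())
    summary["n_clustered_events"] = n_clustered
    summary["n_noise_events"] = len(table) - n_clustered
    log.info("analyse: %d/%d events in clusters", n_clustered, len(table))

    # comparison stage (only meaningful with two conditions)
    if len(table.conditions) == 2:
        report = run_comparisons(table, params.cluster, pooling=params.pooling)
        _write_json(out / "comparison.json", report.to_jsonable())
        (out / "comparison.txt").write_text(report.to_text() + "\n", encoding="utf-8")
        summary["comparison"] = "written to comparison.json"
    else:
        summary["comparison"] = (
            f"skipped: requires two conditions, found {table.conditions}"
        )

    _write_json(out / "summary.json", summary)
    _write_json(
        out / "run_meta.json",
        _run_meta(
            "analyse",
            {
                "delta_t_h": table.delta_t_h,
                "epsilon_um": params.cluster.epsilon_um,
                "min_samples": params.cluster.min_samples,
                "pooling": params.pooling,
                "sd_convention": "sample standard deviation (ddof=1)",
                "spectral": "plain FFT periodogram, mean removed, no window",
            },
        ),
    )
    return out


def cmd_compare(
    bundle_a: str | Path,
    bundle_b: str | Path | None = None,
    out_dir: str | Path | None = None,
    params: AnalysisParams = AnalysisParams(),
) -> ComparisonReport:
    """Compare conditions from one two-condition bundle or two bundles.

    Each bundle is a directory produced by `cmd_simulate` or `cmd_analyse`
    containing ``events.csv``.  With two bundles, their event tables are
    concatenated (a differing sampling interval is a configuration error).
    """
    table_a = read_events(Path(bundle_a) / "events.csv")
    if bundle_b is not None:
        meta_a = _bundle_delta_t(bundle_a)
        meta_b = _bundle_delta_t(bundle_b)
        if meta_a is not None and meta_b is not None and meta_a != meta_b:
            raise ValueError(f"mismatched delta_t_h between bundles: {meta_a} vs {meta_b}")
        table_b = read_events(Path(bundle_b) / "events.csv")
        ev = pd.concat([table_a.events, table_b.events], ignore_index=True)
        ev["event_id"] = [f"{i}-{e}" for i, e in enumerate(ev["event_id"])]
        table = EventTable(ev, delta_t_h=table_a.delta_t_h)
    else:
        table = table_a
    report = run_comparisons(table, params.cluster, pooling=params.pooling)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(out / "comparison.json", report.to_jsonable())
        (out / "comparison.txt").write_text(report.to_text() + "\n", encoding="utf-8")
    return report


def _bundle_delta_t(bundle: str | Path) -> float | None:
    meta = Path(bundle) / "run_meta.json"
    if not meta.exists():
        return None
    params = json.loads(meta.read_text(encoding="utf-8")).get("parameters", {})
    if "delta_t_h" in params:
        return float(params["delta_t_h"])
    if "intact" in params:
        return float(params["intact"].get("delta_t_h"))
    return None
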