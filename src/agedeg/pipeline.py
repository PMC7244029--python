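"""End-to-end orchestration: simulate (or load), test, classify, compare.

:func:`run_full` drives the whole analysis from a single JSON-style config
dict and returns a self-describing report: every threshold (alpha, fold
cutoffs, the 0.22 mm/sec velocity split), permutation count, cluster count
and seed that influenced the result is recorded, so two runs from the same
config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as adio
from .concordance import DirectionalGeneSet, overlap_table
from .containers import ExpressionSet
from .synthetic import (
    MV_THRESHOLD,
    TimeSeriesConfig,
    TwoGroupConfig,
    generate_timeseries,
    generate_two_group,
)
from .timeseries import run_timeseries_pipeline
from .twogroup import DEGConfig, run_two_group_pipeline

__all__ = ["run_full", "directional_set_from_calls", "directional_set_from_truth"]

logger = logging.getLogger(__name__)


def directional_set_from_calls(name: str, records: pd.DataFrame) -> DirectionalGeneSet:
    """Directional gene set from a two-group DEG table (``call`` column)."""
    return DirectionalGeneSet(
        name=name,
        up=set(records.index[records["call"] == "up"]),
        down=set(records.index[records["call"] == "down"]),
    )


def directional_set_from_truth(name: str, truth: pd.DataFrame) -> DirectionalGeneSet:
    """Directional gene set from a planted-truth table (``direction`` column)."""
    return DirectionalGeneSet(
        name=name,
        up=set(truth.index[truth["direction"] > 0]),
        down=set(truth.index[truth["direction"] < 0]),
    )


def _ts_set_from_calls(name: str, calls: pd.DataFrame) -> DirectionalGeneSet:
    return DirectionalGeneSet(
        name=name,
        up=set(calls.index[calls["class"] == "up"]),
        down=set(calls.index[calls["class"] == "down"]),
    )


def run_full(config: dict | None = None, out_dir=None) -> dict:
    """Run simulate -> two-group pipeline -> time-series pipeline -> concordance.

    ``config`` keys (all optional): ``seed``, ``two_group`` (fields of
    :class:`TwoGroupConfig`), ``deg`` (fields of :class:`DEGConfig`),
    ``timeseries`` (fields of :class:`TimeSeriesConfig`, or ``false`` to
    skip), ``ts_fc_cutoff`` (linear; ``null`` to recompute by permutation),
    ``ts_k``, ``expression``/``metadata`` (paths; load instead of
    simulating the two-group stage).  When ``out_dir`` is given, the DEG
    table, time-series calls and the JSON report are written there.

    The report's concordance section cross-tabulates each called DEG set
    against its planted truth (recovered vs planted directions).
    """
    cfg = dict(config or {})
    seed = int(cfg.get("seed", 0))

    deg_cfg = DEGConfig(**{"seed": seed, **cfg.get("deg", {})})

    if "expression" in cfg:
        eset = adio.read_expression_set(cfg["expression"], cfg["metadata"])
        truth = None
        logger.info("loaded %d probes x %d samples", eset.n_probes, eset.n_samples)
    else:
        tg_cfg = TwoGroupConfig(**{"seed": seed, **cfg.get("two_group", {})})
        eset, truth = generate_two_group(tg_cfg)
        logger.info("simulated %d probes x %d samples", eset.n_probes, eset.n_samples)

    records, summary = run_two_group_pipeline(eset, deg_cfg)
    report: dict = {
        "mv_threshold": MV_THRESHOLD,
        "seed": seed,
        "two_group": summary,
        "n_up": summary["n_up"],
        "n_down": summary["n_down"],
        "percent_deg": summary["percent_deg"],
    }

    concordance: dict = {}
    if truth is not None:
        table = overlap_table(
            directional_set_from_calls("called", records),
            directional_set_from_truth("planted", truth),
        )
        concordance["two_group_called_vs_planted"] = table.to_dict()

    ts_spec = cfg.get("timeseries", {})
    ts_calls = None
    if ts_spec is not False:
        ts_cfg = TimeSeriesConfig(**{"seed": seed, **(ts_spec or {})})
        ts_matrix, ts_truth = generate_timeseries(ts_cfg)
        ts_calls, ts_summary = run_timeseries_pipeline(
            ts_matrix,
            fc_cutoff=cfg.get("ts_fc_cutoff", 2.5),
            k=int(cfg.get("ts_k", 40)),
            seed=seed,
        )
        report["timeseries"] = ts_summary
        table = overlap_table(
            _ts_set_from_calls("called", ts_calls),
            directional_set_from_truth("planted", ts_truth),
        )
        concordance["timeseries_called_vs_planted"] = table.to_dict()

    report["concordance"] = concordance

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "deg_table.tsv", sep="\t", lineterminator="\n")
        if ts_calls is not None:
            ts_calls.to_csv(out / "timeseries_calls.tsv", sep="\t", lineterminator="\n")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
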