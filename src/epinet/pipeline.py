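"""End-to-end orchestration: metrics, null tests, comparison, summary.

Stages mirror a comparative network study: (1) compute NODF, wNODF, H2' and
Q for every network in a manifest, plus species-level d' and c tables;
(2) run fixed-fixed null tests per network (defaults: 1000 randomizations
for NODF, 100 for Q, Q optimized with 10 restarts); (3) fit the mixed-model
comparison across interaction types; (4) per-type summary statistics.

Outputs are TSV/JSON with floats fixed at 6 significant digits, so identical
configs and fixtures reproduce byte-identical files.  Every seed, null count
and skipped network is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative_stats as cs
from .modularity import all_participation_coefficients, optimize_modules
from .nestedness import nodf, wnodf
from .network_model import (
    BipartiteNetwork, NetworkError, load_manifest_networks, network_size,
    prune_empty, read_manifest,
)
from .null_models import null_test
from .specialization import d_prime, h2_prime

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    manifest: str | Path | None = None
    out_dir: str | Path = "epinet_out"
    n_null_nodf: int = 1000
    n_null_q: int = 100
    n_restarts_q: int = 10
    seed: int = 0
    network_format: str = "matrix_csv"


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "na"
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.6g}"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(
                _fmt(v) if isinstance(v, (int, float, np.floating, np.integer, bool, np.bool_))
                else ("na" if pd.isna(v) else str(v))
                for v in row
            ) + "\n")


def network_metrics(
    net: BipartiteNetwork, network_id: str, seed: int, n_restarts_q: int = 10
) -> tuple[dict, pd.DataFrame]:
    """All network-level metrics plus the per-species d'/c table."""
    net = prune_empty(net)
    mod = optimize_modules(net, n_restarts=n_restarts_q, seed=seed)
    sp = h2_prime(net)
    row = {
        "network_id": network_id,
        "interaction_type": net.meta.interaction_type,
        "locality": net.meta.locality,
        "network_size": network_size(net),
        "NODF": nodf(net).value,
        "wNODF": wnodf(net).value,
        "H2prime": sp.H2prime,
        "Q": mod.Q,
        "n_modules": mod.partition.n_modules,
        "seed": seed,
    }
    roles = {(r.axis, r.species): r.c_value
             for r in all_participation_coefficients(net, mod.partition)}
    sp_rows = []
    for axis, labels in (("row", net.row_labels), ("col", net.col_labels)):
        for lab in labels:
            sp_rows.append({
                "network_id": network_id,
                "interaction_type": net.meta.interaction_type,
                "locality": net.meta.locality,
                "species": lab,
                "axis": axis,
                "d_prime": d_prime(net, lab, axis).d_prime,
                "c_value": roles[(axis, lab)],
            })
    return row, pd.DataFrame(sp_rows)


def run_metrics(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage 1: one metrics row per manifest network, plus the species table.

    Unreadable networks are skipped with a logged reason and appear with
    missing metric values, mirroring surveys where a matrix was never
    published.
    """
    manifest = read_manifest(config.manifest)
    base = Path(config.manifest).parent
    master = np.random.SeedSequence(config.seed)
    subs = master.spawn(len(manifest))
    rows, sp_tables = [], []
    for (nid, net, err), ss in zip(
        load_manifest_networks(manifest, base, config.network_format), subs
    ):
        if net is None:
            logger.warning("skipping network %s: %s", nid, err)
            rows.append({"network_id": nid, "interaction_type": "na",
                         "locality": "na", "network_size": np.nan,
                         "NODF": np.nan, "wNODF": np.nan, "H2prime": np.nan,
                         "Q": np.nan, "n_modules": np.nan, "seed": np.nan})
            continue
        seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        try:
            row, sp = network_metrics(net, nid, seed, config.n_restarts_q)
        except NetworkError as exc:
            logger.warning("skipping network %s: %s", nid, exc)
            continue
        rows.append(row)
        sp_tables.append(sp)
    if not rows:
        raise NetworkError("no networks could be analysed")
    metrics = pd.DataFrame(rows)
    species = pd.concat(sp_tables, ignore_index=True) if sp_tables else pd.DataFrame()
    return metrics, species


def run_nulltests(config: RunConfig) -> pd.DataFrame:
    """Stage 2: fixed-fixed NODF and Q significance per network."""
    manifest = read_manifest(config.manifest)
    base = Path(config.manifest).parent
    master = np.random.SeedSequence((config.seed, 1))
    subs = master.spawn(len(manifest))
    rows = []
    for (nid, net, err), ss in zip(
        load_manifest_networks(manifest, base, config.network_format), subs
    ):
        if net is None:
            logger.warning("null tests: skipping %s: %s", nid, err)
            continue
        net = prune_empty(net)
        seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        for metric, n_null in (("NODF", config.n_null_nodf), ("Q", config.n_null_q)):
            res = null_test(net, metric, n_null=n_null, seed=seed,
                            n_restarts_q=config.n_restarts_q)
            rows.append({
                "network_id": nid, "metric": metric,
                "observed": res.observed, "null_mean": res.null_mean,
                "null_sd": res.null_sd, "n_null": res.n_null,
                "z": res.z, "p": res.p, "p_empirical": res.p_empirical,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)


def run_compare(
    metrics: pd.DataFrame,
    responses: tuple[str, ...] = ("NODF", "H2prime", "Q"),
    groups: str = "locality",
) -> dict:
    """Stage 3: mixed-model comparison report for each response metric."""
    if metrics.empty:
        raise cs.ComparisonError("metrics table is empty")
    usable = metrics[metrics["interaction_type"].isin(cs.INTERACTION_TYPES)]
    if usable["interaction_type"].nunique() < 2:
        raise cs.ComparisonError(
            "comparison needs at least 2 interaction types; "
            "use run_summary for single-type tables"
        )
    report = {}
    for resp in responses:
        if resp not in usable.columns:
            continue
        report[resp] = cs.compare_metric(usable, resp, groups=groups).to_dict()
    return report


def run_summary(metrics: pd.DataFrame,
                responses: tuple[str, ...] = ("NODF", "wNODF", "H2prime", "Q"),
                ) -> pd.DataFrame:
    """Stage 4: per-type mean and sample SD per metric, ignoring missing."""
    if metrics.empty:
        raise NetworkError("metrics table is empty")
    rows = []
    for itype, grp in metrics.groupby("interaction_type"):
        for resp in responses:
            if resp not in grp.columns:
                continue
            col = grp[resp].dropna()
            rows.append({
                "interaction_type": itype, "metric": resp, "n": len(col),
                "mean": col.mean() if len(col) else np.nan,
                "sd": col.std(ddof=1) if len(col) > 1 else 0.0 if len(col) else np.nan,
            })
    return pd.DataFrame(rows)


def nodf_wnodf_correlation(metrics: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation between NODF and wNODF across networks."""
    sub = metrics.dropna(subset=["NODF", "wNODF"])
    if len(sub) < 3:
        return float("nan"), len(sub)
    return float(np.corrcoef(sub["NODF"], sub["wNODF"])[0, 1]), len(sub)


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write TSV/JSON outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run_all: seed=%d n_null_nodf=%d n_null_q=%d restarts=%d",
                config.seed, config.n_null_nodf, config.n_null_q,
                config.n_restarts_q)
    metrics, species = run_metrics(config)
    _write_tsv(metrics, out / "metrics.tsv")
    if not species.empty:
        _write_tsv(species, out / "species_metrics.tsv")
    nulls = run_nulltests(config)
    if not nulls.empty:
        _write_tsv(nulls, out / "null_tests.tsv")
    summary = run_summary(metrics)
    _write_tsv(summary, out / "summary.tsv")
    paths = {"metrics": out / "metrics.tsv", "summary": out / "summary.tsv",
             "null_tests": out / "null_tests.tsv",
             "species_metrics": out / "species_metrics.tsv"}
    try:
        report = run_compare(metrics)
        (out / "comparison.json").write_text(json.dumps(report, indent=2))
        paths["comparison"] = out / "comparison.json"
    except cs.ComparisonError as exc:
        logger.warning("comparison stage skipped: %s", exc)
    return paths
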