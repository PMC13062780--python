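"""Sample reporting, founder/clone prioritization and study-level statistics."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .characterize import SampleCallSet

REPORT_SCHEMA_VERSION = 1


class ReportError(ValueError):
    pass


def prioritization_rank(callset: SampleCallSet) -> int:
    """Founder/clone priority class (1 best, 4 worst).

    Animals carrying a precise KI with no vector-ITR signal and no random
    integration come first; precise-KI carriers with any ITR or RI finding
    second; samples with only imprecise/partial product third; negatives last.
    """
    fractions = callset.genotype.fractions
    ki_positive = fractions.get("precise_ki", 0.0) > 0.0
    itr_or_ri = any(e.itr_detected for e in callset.ri_events) or bool(callset.ri_events)
    if ki_positive and not itr_or_ri:
        return 1
    if ki_positive:
        return 2
    if fractions.get("partial_ki", 0.0) > 0 or fractions.get("imprecise_ki", 0.0) > 0:
        return 3
    return 4


def prioritize_samples(callsets: Sequence[SampleCallSet]) -> list[SampleCallSet]:
    """Rank call sets for founder/clone selection.

    Within a priority class, ties resolve by precise-KI allele fraction,
    descending.
    """
    return sorted(callsets,
                  key=lambda cs: (prioritization_rank(cs),
                                  -cs.genotype.fractions.get("precise_ki", 0.0)))


def ki_efficiency_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of insert/total-homology ratio vs founder efficiency.

    ``table`` needs columns ``insert_length``, ``total_homology`` and
    ``efficiency``; at least three rows; returns (R, two-sided p-value from
    the t transform).
    """
    required = {"insert_length", "total_homology", "efficiency"}
    if not required <= set(table.columns):
        raise ReportError(f"model table needs columns {sorted(required)}")
    if len(table) < 3:
        raise ReportError("need at least three models for a correlation")
    if (table["total_homology"] <= 0).any():
        raise ReportError("total homology must be positive")
    ratio = table["insert_length"] / table["total_homology"]
    eff = table["efficiency"]
    if np.ptp(ratio.to_numpy()) == 0 or np.ptp(eff.to_numpy()) == 0:
        raise ReportError("correlation undefined for a constant column")
    r, p = stats.pearsonr(ratio, eff)
    return float(r), float(p)


def synthetic_ki_model_table(n: int = 108, target_r: float = -0.28,
                             seed: int = 0) -> pd.DataFrame:
    """SYNTHETIC stand-in for a multi-project knock-in efficiency table.

    Generates ``n`` single-donor model rows (insert length, total homology,
    founder efficiency) whose empirical Pearson correlation between the
    insert/homology ratio and efficiency equals ``target_r`` exactly by
    construction (residuals are orthogonalized against the ratio before
    mixing). This is simulated data for exercising the correlation utility,
    not a published project table.
    """
    rng = np.random.default_rng(seed)
    insert = rng.integers(400, 3500, size=n)
    homology = 2 * rng.integers(400, 1200, size=n)
    ratio = insert / homology
    x = (ratio - ratio.mean()) / ratio.std()
    e = rng.normal(size=n)
    e = e - (e @ x) / (x @ x) * x       # orthogonalize noise against the ratio
    e = (e - e.mean()) / e.std()
    y = target_r * x + np.sqrt(1 - target_r ** 2) * e
    lo, hi = y.min(), y.max()
    efficiency = 0.01 + (y - lo) / (hi - lo) * 0.79   # affine: preserves R
    return pd.DataFrame({"insert_length": insert,
                         "total_homology": homology,
                         "efficiency": efficiency})


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def callset_to_dict(callset: SampleCallSet) -> dict:
    d = _to_jsonable(callset)
    d["schema_version"] = REPORT_SCHEMA_VERSION
    d["prioritization_rank"] = prioritization_rank(callset)
    return d


def write_report(callset: SampleCallSet, outdir: str | Path,
                 depth_tracks: dict | None = None) -> dict[str, Path]:
    """Emit the per-sample report: JSON (machine), TSV (events) and bedGraph.

    Output is byte-stable for fixed inputs (sorted keys, fixed float
    formatting).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ReportError(f"cannot create report directory {outdir}: {exc}")
    paths: dict[str, Path] = {}
    json_path = outdir / f"{callset.sample}.report.json"
    json_path.write_text(json.dumps(callset_to_dict(callset), sort_keys=True,
                                    indent=2) + "\n")
    paths["json"] = json_path

    rows = []
    for e in callset.ri_events:
        rows.append({"type": "random_integration", "locus": f"{e.chrom}:{e.position}",
                     "support": e.support, "spread": e.spread,
                     "itr": e.itr_detected, "detail": ""})
    for e in callset.concatemer_events:
        rows.append({"type": "concatemer", "locus": "target",
                     "support": len(e.support_reads), "spread": 0,
                     "itr": False,
                     "detail": f"topology={e.topology};copies={e.copies};"
                               f"evidence={e.evidence}"})
    for a in callset.artifacts:
        rows.append({"type": "putative_artifact",
                     "locus": f"{a.genome_chrom}:{a.genome_pos}",
                     "support": a.support, "spread": a.spread, "itr": False,
                     "detail": ""})
    events_path = outdir / f"{callset.sample}.events.tsv"
    pd.DataFrame(rows, columns=["type", "locus", "support", "spread", "itr",
                                "detail"]).to_csv(events_path, sep="\t", index=False)
    paths["events"] = events_path

    if depth_tracks:
        for name, track in depth_tracks.items():
            p = outdir / f"{callset.sample}.{name}.bedgraph"
            track.to_bedgraph(p)
            paths[f"depth:{name}"] = p
    return paths


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
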