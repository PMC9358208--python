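"""End-to-end report generation mirroring the pilot study's result tables.

``run_report`` loads a cohort CSV, computes the three correlation tables
(radiological inter-correlations, neutrophil markers vs severity, and the
combinatorial composites against 90-day mRS) and writes a deterministic
JSON bundle with a provenance block.  Timestamps are deliberately
excluded so re-running an identical config yields byte-identical output.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohort import CohortTable, derive_fields, load_cohort
from .errors import SichPipeError
from .stats import (COMPOSITE_DEFINITIONS, CorrelationResult,
                    composite_report, correlation_report)

#: Severity columns correlated against the radiological volumes.
TABLE2_SEVERITY = ["ich_score", "gcs", "mrs_90d", "mgs"]
#: Neutrophil markers and the severity measures they are correlated with.
TABLE3_MARKERS = ["rogue_n_count", "net_n_count", "nlr"]
TABLE3_SEVERITY = ["gcs", "ich_score", "mrs_90d", "iph_vol", "phe_vol"]


@dataclass
class RunConfig:
    """Configuration of a report run."""

    cohort_csv: str | Path
    out_dir: str | Path = "."
    alpha: float = 0.05
    bonferroni_m: int = 1
    precision: int = 3
    seed: int = 0
    composites: dict[str, list[str]] = field(
        default_factory=lambda: dict(COMPOSITE_DEFINITIONS))


def _entry(res: CorrelationResult, precision: int) -> dict:
    return {
        "x": res.x, "y": res.y,
        "r": round(res.r, precision),
        "n": res.n,
        "p_raw": float(f"{res.p_raw:.3g}"),
        "p_bonf": float(f"{res.p_bonf:.3g}"),
        "power": round(res.power, precision),
        "class": res.strength_class,
    }


def build_tables(cohort: CohortTable, alpha: float = 0.05, m: int = 1,
                 precision: int = 3,
                 composites: dict[str, list[str]] | None = None) -> dict:
    """Compute the three result tables from a validated cohort."""
    pairs2 = [("iph_vol", "phe_vol")]
    pairs2 += [(v, s) for v in ("iph_vol", "phe_vol")
               for s in TABLE2_SEVERITY]
    pairs3 = [(mk, s) for mk in TABLE3_MARKERS for s in TABLE3_SEVERITY]
    table2 = correlation_report(cohort, pairs2, m=m, alpha=alpha)
    table3 = correlation_report(cohort, pairs3, m=m, alpha=alpha)
    table4 = composite_report(cohort, outcome="mrs_90d",
                              definitions=composites, m=m, alpha=alpha)
    return {
        "table2": [_entry(r, precision) for r in table2],
        "table3": [_entry(r, precision) for r in table3],
        "table4": {name: _entry(r, precision)
                   for name, r in table4.items()},
    }


def run_report(config: RunConfig) -> dict:
    """Execute the statistics stage and write ``report.json``.

    The provenance block records the config hash, seed and package
    version; no wall-clock fields are included, keeping regeneration
    idempotent.
    """
    path = Path(config.cohort_csv)
    if not path.exists():
        raise SichPipeError(f"cohort file not found: {path}")
    cohort = derive_fields(load_cohort(path))
    tables = build_tables(cohort, alpha=config.alpha, m=config.bonferroni_m,
                          precision=config.precision,
                          composites=config.composites)
    cfg_repr = json.dumps({
        "cohort_csv": str(config.cohort_csv), "alpha": config.alpha,
        "bonferroni_m": config.bonferroni_m, "precision": config.precision,
        "seed": config.seed, "composites": config.composites,
    }, sort_keys=True)
    bundle = {
        "provenance": {
            "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
            "seed": config.seed,
            "package_version": __version__,
            "n_patients": cohort.n,
        },
        **tables,
        "summary": {
            "ivh_prevalence_pct": round(
                100.0 * cohort.column("ivh").mean(), 1),
            "survivors": int(cohort.column("survivor").sum()),
            "cmo": int(cohort.column("cmo").sum()),
        },
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / "report.json"
    out_path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    return bundle
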