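"""Batch driver: run both risk models over a disease catalog.

A catalog row carries a disease name, the familial relationship the FRRs were
estimated for, FRR_1, optionally FRR_2, and optionally the lifetime risk.
For each row the driver

* inverts the two-group model for (IRR, q) when FRR_2 is present, and
* fits the beta risk model and its inequality summaries (Gini, top-10% and
  top-1% shares) when a lifetime risk is present,

collecting per-row warnings instead of aborting the batch.  A packaged
catalog of published estimates for common cancers and other diseases ships
with the library (``example_catalog()``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import inequality
from .continuous import BetaRiskModel, beta_from_mean_frr
from .dichotomous import DichotomousRiskModel, FrrPair, forward_residuals, solve_dichotomous
from .errors import DomainError, FamineqError

__all__ = [
    "DiseaseSpec",
    "DiseaseReport",
    "read_catalog",
    "example_catalog",
    "run_catalog",
    "render_report",
]

log = logging.getLogger("famineq.catalog")

_COLUMNS = ["name", "relationship", "frr1", "frr2", "lifetime_risk"]


@dataclass(frozen=True)
class DiseaseSpec:
    """One catalog row of published familial relative risks."""

    name: str
    relationship: str
    frr1: float
    frr2: float | None = None
    lifetime_risk: float | None = None

    def __post_init__(self) -> None:
        if self.frr1 < 1.0:
            raise DomainError(f"{self.name}: frr1 must be >= 1, got {self.frr1}")
        if self.lifetime_risk is not None and not 0.0 < self.lifetime_risk < 1.0:
            raise DomainError(
                f"{self.name}: lifetime_risk must be a proportion in (0, 1), got "
                f"{self.lifetime_risk} (write 0.12, not 12)"
            )


@dataclass(frozen=True)
class DichotomousResult:
    irr: float
    q: float
    residual_frr1: float
    residual_frr2: float


@dataclass(frozen=True)
class ContinuousResult:
    alpha: float
    beta: float
    gini: float
    top10_share: float
    top1_share: float


@dataclass(frozen=True)
class DiseaseReport:
    """Everything both models say about one catalog row."""

    spec: DiseaseSpec
    dichotomous: DichotomousResult | None = None
    continuous: ContinuousResult | None = None
    warnings: tuple[str, ...] = ()


def read_catalog(path: str | Path) -> list[DiseaseSpec]:
    """Read a disease catalog CSV with header name,relationship,frr1,frr2,lifetime_risk.

    Empty cells mean "missing" for frr2 and lifetime_risk.  Risks are
    proportions (0.12, not 12%); values above 1 are rejected with a hint.
    """
    df = pd.read_csv(path, dtype={"name": str, "relationship": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"catalog {path} is missing columns: {', '.join(missing)}")
    specs: list[DiseaseSpec] = []
    for i, row in df.iterrows():
        try:
            frr1 = float(row["frr1"])
        except (TypeError, ValueError) as exc:
            raise DomainError(f"catalog row {i}: non-numeric frr1 {row['frr1']!r}") from exc
        frr2 = None if pd.isna(row["frr2"]) else float(row["frr2"])
        lr = None if pd.isna(row["lifetime_risk"]) else float(row["lifetime_risk"])
        specs.append(
            DiseaseSpec(
                name=str(row["name"]),
                relationship=str(row["relationship"]),
                frr1=frr1,
                frr2=frr2,
                lifetime_risk=lr,
            )
        )
    if not specs:
        raise DomainError(f"catalog {path} has no data rows")
    return specs


def example_catalog() -> list[DiseaseSpec]:
    """The packaged catalog of published FRR estimates."""
    with resources.as_file(resources.files("famineq.data") / "diseases.csv") as p:
        return read_catalog(p)


def _analyze(spec: DiseaseSpec) -> DiseaseReport:
    warnings: list[str] = []
    dich = None
    cont = None
    if spec.frr2 is not None:
        try:
            pair = FrrPair(frr1=spec.frr1, frr2=spec.frr2)
            model = solve_dichotomous(pair)
            r1, r2 = forward_residuals(model, pair)
            dich = DichotomousResult(
                irr=model.irr, q=model.q, residual_frr1=r1, residual_frr2=r2
            )
        except FamineqError as exc:
            warnings.append(f"dichotomous model: {exc}")
    if spec.lifetime_risk is not None:
        try:
            beta = beta_from_mean_frr(spec.lifetime_risk, spec.frr1)
            cont = ContinuousResult(
                alpha=beta.alpha,
                beta=beta.beta,
                gini=inequality.gini(beta),
                top10_share=inequality.top_share(beta, 0.10),
                top1_share=inequality.top_share(beta, 0.01),
            )
        except FamineqError as exc:
            warnings.append(f"continuous model: {exc}")
    return DiseaseReport(
        spec=spec, dichotomous=dich, continuous=cont, warnings=tuple(warnings)
    )


def run_catalog(catalog: list[DiseaseSpec]) -> list[DiseaseReport]:
    """Analyze every catalog row in input order; infeasible rows warn, never abort."""
    if not catalog:
        raise DomainError("catalog is empty")
    reports = []
    for spec in catalog:
        log.info("analyzing %s (%s)", spec.name, spec.relationship)
        report = _analyze(spec)
        for w in report.warnings:
            log.warning("%s: %s", spec.name, w)
        reports.append(report)
    return reports


# Rendering -----------------------------------------------------------------


def _report_record(r: DiseaseReport) -> dict:
    rec: dict = {
        "name": r.spec.name,
        "relationship": r.spec.relationship,
        "frr1": r.spec.frr1,
        "frr2": r.spec.frr2,
        "lifetime_risk": r.spec.lifetime_risk,
    }
    if r.dichotomous is not None:
        rec.update(
            irr=r.dichotomous.irr,
            q=r.dichotomous.q,
            residual_frr1=r.dichotomous.residual_frr1,
            residual_frr2=r.dichotomous.residual_frr2,
        )
    else:
        rec.update(irr=None, q=None, residual_frr1=None, residual_frr2=None)
    if r.continuous is not None:
        rec.update(
            alpha=r.continuous.alpha,
            beta=r.continuous.beta,
            gini=r.continuous.gini,
            top10_share=r.continuous.top10_share,
            top1_share=r.continuous.top1_share,
        )
    else:
        rec.update(alpha=None, beta=None, gini=None, top10_share=None, top1_share=None)
    rec["warnings"] = "; ".join(r.warnings)
    return rec


def _fmt3(v) -> str:
    if v is None:
        return ""
    return f"{v:.3g}"


def render_report(reports: list[DiseaseReport], format: str = "text") -> str:
    """Serialize reports as aligned text (3 significant figures), CSV or JSON.

    CSV and JSON are lossless (full double precision); all three formats are
    deterministic byte-for-byte for a fixed input.
    """
    if not reports:
        raise DomainError("no reports to render")
    records = [_report_record(r) for r in reports]
    if format == "json":
        return json.dumps(records, indent=2)
    if format == "csv":
        return pd.DataFrame(records).to_csv(index=False, float_format="%.17g")
    if format == "text":
        cols = [
            "name", "relationship", "frr1", "frr2", "lifetime_risk",
            "irr", "q", "alpha", "beta", "gini", "top10_share", "top1_share",
        ]
        if any(r.warnings for r in reports):
            cols.append("warnings")
        rows = [
            {
                c: (rec[c] if c in ("name", "relationship", "warnings") else _fmt3(rec[c]))
                for c in cols
            }
            for rec in records
        ]
        widths = {c: max(len(c), *(len(str(row[c])) for row in rows)) for c in cols}
        lines = ["  ".join(c.ljust(widths[c]) for c in cols)]
        for row in rows:
            lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in cols))
        return "\n".join(line.rstrip() for line in lines) + "\n"
    raise DomainError(f"unknown report format {format!r} (use text, csv or json)")
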