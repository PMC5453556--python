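"""Compound-library triage: rule of 5 (400 g/mol cutoff) and structural alerts.

Virtual-screening libraries are filtered before docking: drug-likeness by
Lipinski's rule of 5 — here with a tightened molecular-weight cutoff of
400 g/mol instead of 500 — and a purge of compounds matching reactive /
promiscuous or aggregation-prone structural alerts.  Descriptors are
computed from SMILES with RDKit when not supplied; the shipped alert
lists are small illustrative SMARTS sets, and full published lists can be
loaded from ``name<TAB>SMARTS`` text files.

All cutoffs are inclusive (mw ≤ 400, logP ≤ 5, HBD ≤ 5, HBA ≤ 10) and a
compound passes only when every rule holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .errors import ConfigError, ParseError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")


@dataclass
class CompoundRecord:
    """One library compound: identity, optional SMILES, rule-of-5 descriptors."""

    compound_id: str
    smiles: str | None = None
    mw: float | None = None
    logp: float | None = None
    hbd: int | None = None
    hba: int | None = None
    alerts: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class FilterResult:
    compound_id: str
    status: str  # 'pass' | 'fail' | 'unevaluable'
    reasons: tuple[str, ...] = ()


def compute_descriptors(record: CompoundRecord) -> CompoundRecord:
    """Fill missing mw/logp/hbd/hba from SMILES (RDKit); no-op when complete."""
    if all(v is not None for v in (record.mw, record.logp, record.hbd, record.hba)):
        return record
    if not record.smiles:
        return record
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        logger.warning("unparseable SMILES for %s: %r", record.compound_id, record.smiles)
        return record
    return replace(
        record,
        mw=record.mw if record.mw is not None else Descriptors.MolWt(mol),
        logp=record.logp if record.logp is not None else Crippen.MolLogP(mol),
        hbd=record.hbd if record.hbd is not None else Lipinski.NumHDonors(mol),
        hba=record.hba if record.hba is not None else Lipinski.NumHAcceptors(mol),
    )


def apply_ro5(record: CompoundRecord, mw_cutoff: float = 400.0) -> FilterResult:
    """Rule-of-5 check with a configurable weight cutoff (default 400 g/mol).

    Pass requires mw ≤ mw_cutoff, logP ≤ 5, HBD ≤ 5 and HBA ≤ 10; a fail
    lists every violated rule.  A record with neither descriptors nor a
    parseable SMILES is 'unevaluable', distinct from a fail.
    """
    record = compute_descriptors(record)
    if any(v is None for v in (record.mw, record.logp, record.hbd, record.hba)):
        return FilterResult(record.compound_id, "unevaluable", ("missing descriptors",))
    reasons = []
    if record.mw > mw_cutoff:
        reasons.append(f"mw > {mw_cutoff:g}")
    if record.logp > 5:
        reasons.append("logp > 5")
    if record.hbd > 5:
        reasons.append("hbd > 5")
    if record.hba > 10:
        reasons.append("hba > 10")
    if reasons:
        return FilterResult(record.compound_id, "fail", tuple(reasons))
    return FilterResult(record.compound_id, "pass")


# ---------------------------------------------------------------------------
# Structural alerts


def load_alert_set(path: str | Path) -> dict[str, str]:
    """Load a ``name<TAB>SMARTS`` alert file into an ordered dict."""
    patterns: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                name, smarts = line.split("\t")
            except ValueError:
                raise ParseError(f"{path}:{lineno}: expected 'name<TAB>SMARTS'") from None
            if Chem.MolFromSmarts(smarts) is None:
                raise ParseError(f"{path}:{lineno}: invalid SMARTS {smarts!r}")
            patterns[name] = smarts
    if not patterns:
        raise ParseError(f"{path}: empty alert file")
    return patterns


def builtin_alert_sets() -> dict[str, dict[str, str]]:
    """The shipped illustrative alert lists: 'reactive' and 'aggregators'."""
    out = {}
    for name in ("reactive", "aggregators"):
        ref = resources.files("crypticscreen.data").joinpath(f"{name}.smarts")
        with resources.as_file(ref) as p:
            out[name] = load_alert_set(p)
    return out


def apply_alerts(
    record: CompoundRecord, alert_sets: Mapping[str, Mapping[str, str]]
) -> CompoundRecord | None:
    """Annotate a record with every alert-set name whose any SMARTS matches.

    Returns the annotated record, or None (unevaluable) when the SMILES is
    missing or unparseable.  The purge decision downstream is simply
    "any flag set".
    """
    if not record.smiles:
        return None
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        logger.warning("unparseable SMILES for %s: %r", record.compound_id, record.smiles)
        return None
    flags = set(record.alerts)
    for set_name, patterns in alert_sets.items():
        for smarts in patterns.values():
            if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts)):
                flags.add(set_name)
                break
    return replace(record, alerts=flags)


# ---------------------------------------------------------------------------
# Library-level pipeline


def read_library(path: str | Path) -> list[CompoundRecord]:
    """Read a library: ``.smi`` (id<TAB>smiles) or descriptor CSV."""
    path = Path(path)
    if path.suffix.lower() in (".smi", ".smiles", ".tsv", ".txt"):
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: expected 'id<TAB>smiles'")
                records.append(CompoundRecord(compound_id=parts[0], smiles=parts[1]))
        return records
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing compound_id column")
    records = []
    for _, row in df.iterrows():
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                smiles=row.get("smiles") if isinstance(row.get("smiles"), str) else None,
                mw=float(row["mw"]) if "mw" in df.columns and pd.notna(row["mw"]) else None,
                logp=float(row["logp"]) if "logp" in df.columns and pd.notna(row["logp"]) else None,
                hbd=int(row["hbd"]) if "hbd" in df.columns and pd.notna(row["hbd"]) else None,
                hba=int(row["hba"]) if "hba" in df.columns and pd.notna(row["hba"]) else None,
            )
        )
    return records


def filter_library(
    records: Iterable[CompoundRecord],
    mw_cutoff: float = 400.0,
    alert_sets: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Run rule-of-5 and alert triage over a library.

    Returns a per-compound table with columns compound_id, ro5_status,
    ro5_reasons, alerts, purged, final ('pass' / 'fail' / 'unevaluable').
    Conservation holds: every input compound appears in exactly one final
    category.
    """
    alert_sets = alert_sets if alert_sets is not None else {}
    rows = []
    for rec in records:
        rec = compute_descriptors(rec)
        ro5 = apply_ro5(rec, mw_cutoff=mw_cutoff)
        alerts: set[str] = set()
        alerts_evaluable = True
        # alert screening only applies to records carrying a SMILES; a
        # descriptor-only record is still fully evaluable under the rule of 5
        if alert_sets and rec.smiles:
            annotated = apply_alerts(rec, alert_sets)
            if annotated is None:
                alerts_evaluable = False
            else:
                alerts = annotated.alerts
        if ro5.status == "unevaluable" or not alerts_evaluable:
            final = "unevaluable"
        elif ro5.status == "fail" or alerts:
            final = "fail"
        else:
            final = "pass"
        rows.append(
            {
                "compound_id": rec.compound_id,
                "ro5_status": ro5.status,
                "ro5_reasons": ";".join(ro5.reasons),
                "alerts": ";".join(sorted(alerts)),
                "purged": bool(alerts),
                "final": final,
            }
        )
    return pd.DataFrame(rows)
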