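"""Curation of ChEMBL-style activity exports into a labeled hERG dataset.

The curation chain mirrors standard QSAR data-preparation practice: keep only
human, direct-binding (assay type ``B``) IC50 entries free of validity
warnings; standardize structures to a salt-free, charge-neutral,
stereochemistry-free canonical SMILES; convert IC50 to pIC50 = -log10(M);
aggregate replicate measurements per structure and discard compounds whose
replicate spread exceeds sigma = 2 log units; and label each compound at the
two potency thresholds in common use (pIC50 >= 6, i.e. IC50 <= 1 uM, and
pIC50 >= 5, i.e. IC50 <= 10 uM).

Entries that carry no numeric value but are annotated as "not active" in the
activity comment are retained as label-only inactives (INA at both
thresholds); when a structure has both numeric records and a not-active
comment, the numeric values win.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Elements admissible in a QSAR-ready organic structure.
ALLOWED_ELEMENTS = frozenset({"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"})

#: A fragment with more than this many heavy atoms is not a mere counterion.
_COUNTERION_MAX_HEAVY = 6

SIGMA_MAX = 2.0

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
}

#: Default ChEMBL export field names.
DEFAULT_COLUMNS = {
    "smiles": "canonical_smiles",
    "standard_type": "standard_type",
    "standard_value": "standard_value",
    "standard_units": "standard_units",
    "target_organism": "target_organism",
    "assay_type": "assay_type",
    "data_validity_comment": "data_validity_comment",
    "activity_comment": "activity_comment",
}


class CurationError(ValueError):
    pass


class EmptyDatasetError(CurationError):
    """All records were rejected; there is nothing to curate."""


class StructureRejected(CurationError):
    """A structure failed standardization; ``reason`` is a short code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class ActivityRecord:
    """One raw assay entry from an activity export."""

    smiles: str
    standard_type: str = ""
    standard_value: Optional[float] = None
    standard_units: str = ""
    target_organism: str = ""
    assay_type: str = ""
    data_validity_comment: str = ""
    activity_comment: str = ""

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("ActivityRecord requires a non-empty SMILES")
        if self.standard_value is not None and self.standard_value < 0:
            raise ValueError("standard_value must be >= 0 or missing")

    @property
    def is_comment_inactive(self) -> bool:
        """True for label-only 'not active' entries without a numeric value."""
        if self.standard_value is not None:
            return False
        comment = self.activity_comment.strip().lower()
        return comment in {"not active", "inactive"} or "not active" in comment


@dataclass
class CuratedCompound:
    """A unique standardized structure with aggregated activity and labels.

    ``pic50`` is None only for comment-labeled inactives.  ``sigma`` is the
    sample standard deviation of replicate pIC50 values (0 for a single
    measurement); compounds with sigma > 2 are excluded upstream and never
    stored.
    """

    canonical_smiles: str
    pic50: Optional[float]
    sigma: float
    n_records: int
    label_t6: str
    label_t5: str

    def __post_init__(self) -> None:
        if self.pic50 is not None and self.sigma > SIGMA_MAX:
            raise ValueError("outlier compounds (sigma > 2) must not be stored")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")


def filter_activity_entries(
    records: Sequence[ActivityRecord],
) -> tuple[list[ActivityRecord], list[tuple[int, str]]]:
    """Apply the four entry filters, preserving order.

    Returns the retained records and a log of (input index, first failing
    rule) pairs.  Raises :class:`EmptyDatasetError` when nothing survives.
    """
    kept: list[ActivityRecord] = []
    rejections: list[tuple[int, str]] = []
    for i, rec in enumerate(records):
        reason = _first_failing_rule(rec)
        if reason is None:
            kept.append(rec)
        else:
            rejections.append((i, reason))
    if not kept:
        raise EmptyDatasetError(f"all {len(records)} records rejected by the entry filters")
    return kept, rejections


def _first_failing_rule(rec: ActivityRecord) -> Optional[str]:
    if rec.standard_type.strip().upper() != "IC50" and not rec.is_comment_inactive:
        return "standard_type"
    if rec.target_organism.strip() != "Homo sapiens":
        return "target_organism"
    if rec.assay_type.strip() != "B":
        return "assay_type"
    if rec.data_validity_comment.strip():
        return "data_validity_comment"
    return None


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str) -> str:
    """Return the QSAR-ready canonical SMILES, or raise :class:`StructureRejected`.

    Steps: parse; keep the largest organic fragment (stripping common
    counterions); reject inorganics, organometallics / unusual elements and
    true multi-component mixtures; neutralize charges; drop stereochemistry;
    canonicalize.  Idempotent by construction.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureRejected("unparseable", smiles)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        raise StructureRejected("inorganic", smiles)
    large = [f for f in frags if f.GetNumHeavyAtoms() > _COUNTERION_MAX_HEAVY]
    if len(large) > 1:
        raise StructureRejected("mixture", smiles)

    keep = max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    bad = {a.GetSymbol() for a in keep.GetAtoms()} - ALLOWED_ELEMENTS
    if bad:
        raise StructureRejected("element", f"{smiles} contains {sorted(bad)}")

    keep = _UNCHARGER.uncharge(keep)
    Chem.RemoveStereochemistry(keep)
    try:
        Chem.SanitizeMol(keep)
    except Exception as exc:  # pragma: no cover - defensive
        raise StructureRejected("unparseable", f"{smiles}: {exc}")
    return Chem.MolToSmiles(keep)


def to_pic50(ic50: float, units: str) -> float:
    """Convert an IC50 with units to pIC50 = -log10(IC50 in molar)."""
    if units not in _UNIT_TO_MOLAR:
        raise CurationError(f"unknown units {units!r}; supported: {sorted(_UNIT_TO_MOLAR)}")
    if not ic50 > 0:
        raise CurationError(f"IC50 must be positive, got {ic50!r}")
    return -math.log10(ic50 * _UNIT_TO_MOLAR[units])


def aggregate_duplicates(values: Sequence[float]) -> tuple[float, float, bool]:
    """Aggregate replicate pIC50 values for one structure.

    Returns (mean, sigma, kept) where sigma is the sample standard deviation
    (n-1 denominator; 0 for a single value) and kept is sigma <= 2.
    """
    if len(values) == 0:
        raise ValueError("need at least one value")
    mean = float(np.mean(values))
    sigma = float(statistics.stdev(values)) if len(values) > 1 else 0.0
    return mean, sigma, sigma <= SIGMA_MAX


def assign_label(pic50: Optional[float], threshold: float) -> str:
    """ACT iff pIC50 >= threshold; comment-only inactives (None) are INA."""
    if threshold not in (5, 6):
        raise ValueError("threshold must be 5 or 6")
    if pic50 is None:
        return "INA"
    return "ACT" if pic50 >= threshold else "INA"


def curate(
    records: Sequence[ActivityRecord],
) -> tuple[list[CuratedCompound], pd.DataFrame]:
    """Run the full curation chain on raw records.

    Returns the curated compounds (unique canonical SMILES, sigma <= 2) and a
    rejection log with columns (stage, reason, detail, n).
    """
    kept, filter_log = filter_activity_entries(records)
    log_rows = [
        {"stage": "filter", "reason": reason, "detail": f"record {idx}"}
        for idx, reason in filter_log
    ]

    numeric: dict[str, list[float]] = {}
    comment_only: dict[str, int] = {}
    n_by_smiles: dict[str, int] = {}
    for rec in kept:
        try:
            can = standardize_structure(rec.smiles)
        except StructureRejected as exc:
            log_rows.append({"stage": "standardize", "reason": exc.reason, "detail": rec.smiles})
            continue
        n_by_smiles[can] = n_by_smiles.get(can, 0) + 1
        if rec.standard_value is None:
            comment_only[can] = comment_only.get(can, 0) + 1
            continue
        try:
            p = to_pic50(rec.standard_value, rec.standard_units)
        except CurationError as exc:
            log_rows.append({"stage": "pic50", "reason": "conversion", "detail": str(exc)})
            continue
        numeric.setdefault(can, []).append(p)

    compounds: list[CuratedCompound] = []
    for can in sorted(set(numeric) | set(comment_only)):
        if can in numeric:  # numeric values win over a not-active comment
            mean, sigma, ok = aggregate_duplicates(numeric[can])
            if not ok:
                log_rows.append(
                    {"stage": "aggregate", "reason": "sigma>2", "detail": f"{can} sigma={sigma:.3f}"}
                )
                continue
            compounds.append(
                CuratedCompound(
                    canonical_smiles=can,
                    pic50=mean,
                    sigma=sigma,
                    n_records=n_by_smiles[can],
                    label_t6=assign_label(mean, 6),
                    label_t5=assign_label(mean, 5),
                )
            )
        else:
            compounds.append(
                CuratedCompound(
                    canonical_smiles=can,
                    pic50=None,
                    sigma=0.0,
                    n_records=comment_only[can],
                    label_t6="INA",
                    label_t5="INA",
                )
            )
    if not compounds:
        raise EmptyDatasetError("no compounds survived curation")
    log = pd.DataFrame(log_rows, columns=["stage", "reason", "detail"])
    return compounds, log


def compounds_to_frame(compounds: Iterable[CuratedCompound]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "canonical_smiles": c.canonical_smiles,
                "pIC50": c.pic50,
                "sigma": c.sigma,
                "n_records": c.n_records,
                "label_t6": c.label_t6,
                "label_t5": c.label_t5,
            }
            for c in compounds
        ]
    )


def read_activity_table(
    path,
    column_map: Optional[dict[str, str]] = None,
    delimiter: Optional[str] = None,
) -> tuple[list[ActivityRecord], int]:
    """Read a TSV/CSV activity export into records.

    ``column_map`` maps the canonical field names (keys of
    :data:`DEFAULT_COLUMNS`) to the export's column names.  Unparseable rows
    are skipped with a warning; the skip count is returned alongside.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing = [v for v in (cols["smiles"],) if v not in df.columns]
    if missing:
        raise CurationError(f"export is missing required column(s) {missing}")

    def get(row, key, default=""):
        name = cols[key]
        if name not in df.columns:
            return default
        v = row[name]
        return default if pd.isna(v) else v

    records: list[ActivityRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            raw_value = get(row, "standard_value", None)
            records.append(
                ActivityRecord(
                    smiles=str(get(row, "smiles")),
                    standard_type=str(get(row, "standard_type")),
                    standard_value=None if raw_value is None else float(raw_value),
                    standard_units=str(get(row, "standard_units")),
                    target_organism=str(get(row, "target_organism")),
                    assay_type=str(get(row, "assay_type")),
                    data_validity_comment=str(get(row, "data_validity_comment")),
                    activity_comment=str(get(row, "activity_comment")),
                )
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("skipping unparseable row: %s", exc)
    if n_skipped:
        logger.warning("skipped %d unparseable rows", n_skipped)
    return records, n_skipped
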