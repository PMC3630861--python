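"""Plate-level quantification statistics for interaction and reporter assays.

Three closed-form fold statistics, each normalized to an in-plate control so
they are invariant to instrument gain:

* LUMIER fold-binding: eluate/lysate luciferase ratio of a protein pair
  divided by the same ratio for the empty-vector control.
* Dual-luciferase reporter fold-induction: firefly/renilla per well, each
  condition's replicate ratios divided by the mean control ratio.
* ChIP-qPCR fold-enrichment over IgG: ``efficiency ** (control_Ct -
  antibody_Ct)`` with amplification efficiency defaulting to 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InputError


@dataclass(frozen=True)
class LumierRecord:
    pair_id: str
    eluate_lum: float
    lysate_lum: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.eluate_lum <= 0 or self.lysate_lum <= 0:
            raise InputError(
                f"luminescence readings must be > 0 for pair {self.pair_id!r}"
            )


@dataclass(frozen=True)
class ReporterRecord:
    condition: str
    firefly: float
    renilla: float
    replicate: int = 1
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.firefly <= 0 or self.renilla <= 0:
            raise InputError(
                f"luciferase readings must be > 0 for condition {self.condition!r}"
            )


@dataclass(frozen=True)
class ChipRecord:
    target_region: str
    antibody_ct: float
    control_ct: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise InputError(
                f"qPCR efficiency must be in (1, 2], got {self.efficiency}"
            )


def lumier_fold_binding(records: list[LumierRecord]) -> dict[str, float]:
    """Fold-binding per pair: (eluate/lysate) over the control's ratio."""
    controls = [r for r in records if r.is_control]
    if not controls:
        raise InputError("no control record (empty vector) present")
    if len(controls) > 1:
        raise InputError(f"expected exactly one control record, got {len(controls)}")
    control_ratio = controls[0].eluate_lum / controls[0].lysate_lum
    return {
        r.pair_id: (r.eluate_lum / r.lysate_lum) / control_ratio for r in records
    }


def reporter_fold_induction(records: list[ReporterRecord]) -> pd.DataFrame:
    """Per-condition mean +/- SD fold-induction over the control.

    Each well's ratio is firefly/renilla; per-replicate folds are the ratios
    divided by the mean control ratio, and the SD is computed on the fold
    scale across a condition's replicates (0 for a single replicate).
    """
    controls = [r for r in records if r.is_control]
    if not controls:
        raise InputError("no control replicates (empty vector) present")
    control_mean = float(np.mean([r.firefly / r.renilla for r in controls]))
    rows = []
    conditions: dict[str, list[float]] = {}
    for r in records:
        conditions.setdefault(r.condition, []).append(
            (r.firefly / r.renilla) / control_mean
        )
    for condition, folds in conditions.items():
        arr = np.asarray(folds)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        rows.append(
            {
                "condition": condition,
                "fold_mean": float(arr.mean()),
                "fold_sd": sd,
                "n_replicates": len(arr),
            }
        )
    return pd.DataFrame(rows)


def chip_fold_enrichment(record: ChipRecord) -> float:
    """Fold-enrichment over the IgG control: efficiency ** (IgG Ct - Ab Ct)."""
    return float(record.efficiency ** (record.control_ct - record.antibody_ct))


# ---------------------------------------------------------------------------
# TSV readers mirroring the record types
# ---------------------------------------------------------------------------

def _read_table(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    raise DataError(f"cannot interpret {value!r} as a boolean")


def read_lumier_table(path) -> list[LumierRecord]:
    df = _read_table(path, {"pair_id", "eluate_lum", "lysate_lum", "is_control"})
    return [
        LumierRecord(
            pair_id=str(r.pair_id),
            eluate_lum=float(r.eluate_lum),
            lysate_lum=float(r.lysate_lum),
            is_control=_parse_bool(r.is_control),
        )
        for r in df.itertuples(index=False)
    ]


def read_reporter_table(path) -> list[ReporterRecord]:
    df = _read_table(path, {"condition", "firefly", "renilla", "replicate", "is_control"})
    return [
        ReporterRecord(
            condition=str(r.condition),
            firefly=float(r.firefly),
            renilla=float(r.renilla),
            replicate=int(r.replicate),
            is_control=_parse_bool(r.is_control),
        )
        for r in df.itertuples(index=False)
    ]


def read_chip_table(path) -> list[ChipRecord]:
    df = _read_table(path, {"target_region", "antibody_ct", "control_ct"})
    records = []
    for r in df.itertuples(index=False):
        eff = float(getattr(r, "efficiency", 2.0)) if "efficiency" in df.columns else 2.0
        records.append(
            ChipRecord(
                target_region=str(r.target_region),
                antibody_ct=float(r.antibody_ct),
                control_ct=float(r.control_ct),
                efficiency=eff,
            )
        )
    return records
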