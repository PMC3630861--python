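"""Two-channel normalization and array z-scoring.

The chain is: Cy5/Cy3 ratio per feature row -> log2 transform -> median over
technical replicates (pooling flank variants by default) per probe core ->
z-score across the array, ``z = (log2 value - median of array) / SD of
array`` with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InputError, ParseError
from .probe_design import ProbeDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingProfile:
    """Per-core z-scores of one protein; the unit of all comparisons."""

    protein: str
    entries: pd.Series  # index: core/probe id -> z-score

    @property
    def n_probes(self) -> int:
        return len(self.entries)

    @property
    def zscores(self) -> np.ndarray:
        return self.entries.to_numpy(dtype=float)


def normalize_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Per (feature, protein, replicate): value = Cy5 / Cy3.

    Raises :class:`DataError` when a channel partner is missing or a Cy3
    reading is non-positive.
    """
    required = {"feature_id", "protein", "channel", "replicate", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"intensity table missing column(s) {sorted(missing)}")
    wide = table.pivot_table(
        index=["feature_id", "protein", "replicate"],
        columns="channel",
        values="intensity",
        aggfunc="first",
    )
    for ch in ("Cy3", "Cy5"):
        if ch not in wide.columns:
            raise DataError(f"intensity table has no {ch} rows")
    bad = wide.index[wide[["Cy3", "Cy5"]].isna().any(axis=1)]
    if len(bad):
        listing = ", ".join(str(t) for t in bad[:10])
        raise DataError(
            f"{len(bad)} (feature, protein, replicate) row(s) lack a channel "
            f"partner: {listing}"
        )
    if (wide["Cy3"] <= 0).any():
        bad = wide.index[wide["Cy3"] <= 0]
        raise DataError(f"non-positive Cy3 reading for {list(bad[:10])}")
    out = wide.reset_index()
    out["value"] = out["Cy5"] / out["Cy3"]
    return out[["feature_id", "protein", "replicate", "value"]]


def summarize_replicates(
    normalized: pd.DataFrame,
    design: ProbeDesign,
    pool_flanks: bool = True,
) -> pd.DataFrame:
    """Median of log2(normalized value) per probe core (and protein).

    Technical replicates are always pooled; flank variants are pooled into
    the same median by default (``pool_flanks=False`` keeps one summary per
    core x flank).  Even-sized medians use the mean-of-middle convention.
    Raises :class:`DataError` when a declared core has no rows.
    """
    meta = design.to_frame()[["feature_id", "core_id", "flank_id"]]
    merged = normalized.merge(meta, on="feature_id", how="left")
    if merged["core_id"].isna().any():
        unknown = merged.loc[merged["core_id"].isna(), "feature_id"].unique()
        raise DataError(f"rows reference features absent from the design: {list(unknown[:10])}")
    merged["log2_value"] = np.log2(merged["value"])
    keys = ["protein", "core_id"] + ([] if pool_flanks else ["flank_id"])
    summary = merged.groupby(keys, sort=True)["log2_value"].median().reset_index()
    present = set(summary["core_id"])
    missing = [c for c in design.core_ids if c not in present]
    if missing:
        raise DataError(f"no intensity rows for declared core(s) {missing[:10]}")
    return summary


def zscore_profile(summaries: pd.Series | dict, protein: str) -> BindingProfile:
    """Standardize per-core log2 summaries into an array z-score profile.

    ``z_i = (x_i - median(x)) / sd(x)`` with the sample (n-1) standard
    deviation, so median(z) = 0 exactly and sd(z) = 1.
    """
    x = pd.Series(summaries, dtype=float)
    if len(x) < 3:
        raise InputError(f"need >= 3 cores to z-score, got {len(x)}")
    sd = float(x.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DataError(f"degenerate array for {protein!r}: zero standard deviation")
    z = (x - float(x.median())) / sd
    return BindingProfile(protein=protein, entries=z)


def profiles_from_intensities(
    table: pd.DataFrame,
    design: ProbeDesign,
    pool_flanks: bool = True,
) -> list[BindingProfile]:
    """Run the full chain ratio -> log2 -> replicate median -> z-score."""
    summary = summarize_replicates(normalize_channels(table), design, pool_flanks)
    profiles = []
    for protein, sub in summary.groupby("protein", sort=True):
        series = sub.set_index("core_id")["log2_value"]
        profiles.append(zscore_profile(series, str(protein)))
    return profiles


# ---------------------------------------------------------------------------
# z-score table I/O (supplementary-table layout: probe rows x protein columns)
# ---------------------------------------------------------------------------

def write_zscore_table(profiles: list[BindingProfile], path) -> None:
    df = pd.DataFrame({p.protein: p.entries for p in profiles})
    df.index.name = "probe"
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def _sniff_delimiter(sample_lines: list[str]) -> str:
    counts = {d: [line.count(d) for line in sample_lines] for d in ("\t", ",")}
    for delim in ("\t", ","):
        c = counts[delim]
        if c and c[0] > 0 and all(x == c[0] for x in c):
            logger.info("z-score table delimiter detected: %r", delim)
            return delim
    raise ParseError("could not detect a consistent delimiter (tab or comma)")


def load_zscore_table(path) -> list[BindingProfile]:
    """Load a probe x protein z-score table (TSV or CSV, auto-detected).

    The first column is the probe identifier; every remaining column becomes
    one :class:`BindingProfile` with probe order preserved.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [line for line in (fh.readline() for _ in range(5)) if line]
    if not lines:
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(lines)
    df = pd.read_csv(path, sep=delim, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a probe column plus >=1 protein column")
    probe_col = df.columns[0]
    profiles = []
    for col in df.columns[1:]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r}"
            )
        series = pd.Series(numeric.to_numpy(), index=df[probe_col].to_numpy(), name=col)
        profiles.append(BindingProfile(protein=str(col), entries=series))
    return profiles
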