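"""TMT reporter-ion quantitation: filter, group, normalize and merge glycoPSMs.

The two-stage normalization scheme ties multiplexed batches together:

1. **Reference normalization** — every channel of a feature is divided by
   the pooled-reference (126) channel of the same plex, making ratios
   comparable across TMT batches. Features with a zero/missing reference in
   a plex are excluded from that plex and logged, never silently zeroed.
2. **Within-channel normalization** — each sample column is divided by its
   median ratio (computed over the features quantified in that column),
   correcting channel-specific labeling/mixing variation. The statistic is
   configurable (median/mean/total).

Grouping sums glycoPSM reporter intensities over (accession, site,
composition, plex) keys, conserving per-channel totals exactly. Missing
data stay missing; nothing is imputed. For within-sample isoenzyme
comparisons (e.g. HEXA vs HEXB levels in the same channel) reference
normalization can be skipped via ``quantify(..., reference=False)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import TMT10_CHANNELS

__all__ = [
    "PSM_KEY_COLUMNS",
    "filter_psms",
    "group_glycopsms",
    "normalize_to_reference",
    "to_sample_matrix",
    "normalize_within_channel",
    "merge_plexes",
    "quantify",
]

logger = logging.getLogger(__name__)

PSM_KEY_COLUMNS = ("accession", "site", "composition", "plex")


def _channel_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in TMT10_CHANNELS if c in df.columns]
    if not cols:
        raise ValueError("no TMT reporter channel columns found")
    return cols


def filter_psms(
    psms: pd.DataFrame, pep2d_max: float = 0.001
) -> tuple[pd.DataFrame, int]:
    """Retain PSMs with PEP2D strictly below the threshold.

    Returns (filtered frame, number removed). The strict inequality matters:
    a PSM scoring exactly at the threshold is rejected.
    """
    if psms.empty:
        return psms.copy(), 0
    keep = psms["pep2d"] < pep2d_max
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_psms: removed %d of %d PSMs at PEP2D >= %g",
                    removed, len(psms), pep2d_max)
    return psms.loc[keep].reset_index(drop=True), removed


def group_glycopsms(psms: pd.DataFrame) -> pd.DataFrame:
    """Sum reporter intensities over (accession, site, composition, plex).

    Output is one row per glycopeptide feature per plex, sorted by key for
    deterministic ordering. Per-channel totals are conserved exactly.
    """
    channels = _channel_columns(psms)
    grouped = (
        psms.groupby(list(PSM_KEY_COLUMNS), sort=True)[channels].sum().reset_index()
    )
    grouped.insert(len(PSM_KEY_COLUMNS), "n_psms",
                   psms.groupby(list(PSM_KEY_COLUMNS), sort=True).size().values)
    return grouped


def normalize_to_reference(
    features: pd.DataFrame, ref_channel: str = "126"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide each channel by the same-plex reference channel of the feature.

    The reference column maps to exactly 1.0. Features whose reference
    intensity is zero or missing are excluded from the output and returned
    in a log frame (second element) rather than raising.
    """
    channels = _channel_columns(features)
    if ref_channel not in channels:
        raise ValueError(f"reference channel {ref_channel!r} not in table")
    ref = features[ref_channel].to_numpy(dtype=float)
    bad = ~np.isfinite(ref) | (ref <= 0)
    excluded = features.loc[bad].copy()
    if len(excluded):
        logger.warning("normalize_to_reference: %d features unquantifiable (ref <= 0)",
                       len(excluded))
    ok = features.loc[~bad].copy()
    ok[channels] = ok[channels].to_numpy(dtype=float) / ref[~bad, None]
    return ok, excluded


def to_sample_matrix(
    ratios: pd.DataFrame, sample_table: pd.DataFrame, ref_channel: str = "126"
) -> pd.DataFrame:
    """Pivot per-plex channel ratios into a features x samples matrix.

    ``sample_table`` maps (plex, channel) -> sample_id (as produced by
    :meth:`CohortDesign.sample_table`). Features absent from a plex are
    missing (NaN) for that plex's samples.
    """
    key_cols = [c for c in PSM_KEY_COLUMNS if c != "plex"]
    chan_map = {(r["plex"], r["channel"]): r["sample_id"] for _, r in sample_table.iterrows()}
    long = ratios.melt(
        id_vars=list(PSM_KEY_COLUMNS),
        value_vars=[c for c in _channel_columns(ratios) if c != ref_channel],
        var_name="channel",
        value_name="ratio",
    )
    long["sample_id"] = [
        chan_map.get((p, c)) for p, c in zip(long["plex"], long["channel"])
    ]
    long = long.dropna(subset=["sample_id"])
    matrix = long.pivot_table(
        index=key_cols, columns="sample_id", values="ratio", aggfunc="mean"
    )
    matrix.columns.name = None
    return matrix


def normalize_within_channel(matrix: pd.DataFrame, stat: str = "median") -> pd.DataFrame:
    """Divide each sample column by its location statistic over quantified features.

    After median normalization the per-column median log-ratio is 0 (for
    columns with at least one quantified feature). A column with no
    quantified features raises, naming the sample.
    """
    out = matrix.copy()
    for col in out.columns:
        vals = out[col].dropna()
        if vals.empty:
            raise ValueError(f"sample {col!r} has no quantified features")
        if stat == "median":
            scale = float(vals.median())
        elif stat == "mean":
            scale = float(vals.mean())
        elif stat == "total":
            scale = float(vals.sum())
        else:
            raise ValueError(f"unknown normalization statistic {stat!r}")
        if scale <= 0:
            raise ValueError(f"non-positive normalization scale for sample {col!r}")
        out[col] = out[col] / scale
    return out


def merge_plexes(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-plex sample matrices on the feature key.

    Samples are concatenated; features absent from a plex are missing for
    that plex's samples. Duplicate sample ids across plexes are an error.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    all_cols = [c for m in matrices for c in m.columns]
    dupes = {c for c in all_cols if all_cols.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicate sample ids across plexes: {sorted(dupes)}")
    return pd.concat(matrices, axis=1, join="outer").sort_index()


def quantify(
    psms: pd.DataFrame,
    sample_table: pd.DataFrame,
    pep2d_max: float = 0.001,
    ref_channel: str = "126",
    within_stat: str = "median",
    reference: bool = True,
) -> pd.DataFrame:
    """Full PSM -> normalized abundance-matrix pipeline.

    filter -> group -> reference-normalize (per plex) -> pivot to samples ->
    within-channel normalize -> merge plexes. With ``reference=False`` the
    reference-normalization stage is skipped (within-sample comparison
    mode); raw channel intensities are pivoted directly.
    """
    filtered, _ = filter_psms(psms, pep2d_max)
    if filtered.empty:
        raise ValueError("no PSMs pass the PEP2D filter; nothing to quantify")
    features = group_glycopsms(filtered)
    per_plex = []
    for plex, feats in features.groupby("plex"):
        if reference:
            ratios, _ = normalize_to_reference(feats, ref_channel)
        else:
            ratios = feats
        sub = sample_table[sample_table["plex"] == plex]
        per_plex.append(to_sample_matrix(ratios, sub, ref_channel))
    merged = merge_plexes(per_plex)
    return normalize_within_channel(merged, stat=within_stat)
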