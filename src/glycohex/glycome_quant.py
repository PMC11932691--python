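"""Glycome summarization: class shares, pathway usage, paired ratios, tests.

Operates on glycome tables (rows = glycan species with a ``composition``
column, columns = samples, values = relative extracted-ion-chromatogram
abundance, i.e. fraction of the sample total). Species are classified
through :mod:`glycohex.glycan_model`; class shares are expressed in percent
of the sample glycome and therefore sum to 100 per sample. Summaries are
linear in the input shares, so dispersion-0 synthetic glycomes round-trip
their generating profile exactly.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats_survival
from .glycan_model import (
    GlycanClass,
    PathwayLabel,
    classify_glycan,
    parse_composition,
    pathway_of,
)

__all__ = [
    "classify_table",
    "type_summary",
    "species_share_within_class",
    "pathway_usage",
    "paired_ratio",
    "compare_groups",
]

logger = logging.getLogger(__name__)


_META_COLUMNS = ("species", "composition", "label", "glycan_class")


def _sample_columns(g: pd.DataFrame) -> list[str]:
    return [
        c for c in g.columns
        if c not in _META_COLUMNS and pd.api.types.is_numeric_dtype(g[c])
    ]


def classify_table(g: pd.DataFrame) -> pd.Series:
    """Glycan class per species row, parsed from the ``composition`` column.

    Unparseable compositions fall back to class ``other`` with a warning.
    """
    classes = []
    for idx, text in g["composition"].items():
        try:
            classes.append(classify_glycan(parse_composition(text)).value)
        except ValueError as exc:
            logger.warning("species %r unclassifiable (%s); assigned 'other'", idx, exc)
            classes.append(GlycanClass.OTHER.value)
    return pd.Series(classes, index=g.index, name="glycan_class")


def type_summary(g: pd.DataFrame) -> pd.DataFrame:
    """Sum species shares per structural class, in percent of the glycome.

    Returns a classes x samples frame; columns sum to 100 (when the input
    columns sum to 1).
    """
    classes = classify_table(g)
    samples = _sample_columns(g)
    out = g[samples].groupby(classes).sum() * 100.0
    out = out.reindex([c.value for c in GlycanClass], fill_value=0.0)
    out.index.name = "glycan_class"
    return out.loc[(out != 0).any(axis=1) | (out.index == GlycanClass.OTHER.value)]


def species_share_within_class(g: pd.DataFrame, glycan_class: GlycanClass | str) -> pd.DataFrame:
    """Per-species percentage of the class total, per sample.

    Species of the requested class only; within each sample the shares sum
    to 100. Samples where the class is absent get missing values (the
    marker is undefined, not zero).
    """
    want = GlycanClass(glycan_class).value
    classes = classify_table(g)
    sub = g.loc[classes == want, _sample_columns(g)]
    if sub.empty:
        raise ValueError(f"no species of class {want!r} in table")
    totals = sub.sum(axis=0)
    out = sub.divide(totals.where(totals > 0), axis=1) * 100.0
    return out


def pathway_usage(class_shares: pd.DataFrame) -> pd.DataFrame:
    """Aggregate class shares into truncation/elongation/precursor usage (%).

    Input is the classes x samples percent table from :func:`type_summary`;
    output rows are the three pathway labels and columns sum to 100.
    """
    mapping = {c: pathway_of(GlycanClass(c)).value for c in class_shares.index}
    out = class_shares.groupby(pd.Series(mapping)).sum()
    out = out.reindex([p.value for p in PathwayLabel], fill_value=0.0)
    out.index.name = "pathway"
    return out


def paired_ratio(g: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Per-species relative-abundance ratio a/b (e.g. TUM/NAT).

    Species with zero share in ``b`` are flagged undefined (NaN ratio,
    ``defined`` False) rather than infinite.
    """
    num = g[a].astype(float)
    den = g[b].astype(float)
    ratio = num / den.where(den > 0)
    out = pd.DataFrame({"composition": g["composition"], "ratio": ratio})
    out["defined"] = den > 0
    return out


def compare_groups(
    class_shares: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    test: str = "ttest",
    reference_group: Optional[str] = "control",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-class group comparisons on the class-share table.

    ``groups`` maps sample id -> group label. With ``test="ttest"`` each
    non-reference group is tested against ``reference_group`` (unpaired
    two-sided); with ``test="anova_tukey"`` a one-way ANOVA with Tukey HSD
    covers all pairwise contrasts. Returns a tidy frame with one row per
    (class, contrast): mean difference, statistic and p value.
    """
    groups = pd.Series(dict(groups))
    labels = groups.loc[[c for c in class_shares.columns if c in groups.index]]
    rows = []
    for cls in class_shares.index:
        by_group = {
            lab: class_shares.loc[cls, labels.index[labels == lab]].to_numpy(dtype=float)
            for lab in labels.unique()
        }
        for lab, vals in by_group.items():
            if len(vals) < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 samples")
        if test == "ttest":
            if reference_group not in by_group:
                raise ValueError(f"reference group {reference_group!r} not present")
            for lab, vals in by_group.items():
                if lab == reference_group:
                    continue
                res = stats_survival.ttest(vals, by_group[reference_group], welch=welch)
                rows.append(
                    {"glycan_class": cls, "group_a": lab, "group_b": reference_group,
                     "mean_diff": res.mean_diff, "statistic": res.t, "p": res.p}
                )
        elif test == "anova_tukey":
            res = stats_survival.anova_tukey(by_group)
            for _, r in res.tukey.iterrows():
                rows.append(
                    {"glycan_class": cls, "group_a": r["group_a"], "group_b": r["group_b"],
                     "mean_diff": r["mean_diff"], "statistic": res.f, "p": r["p_adj"]}
                )
        else:
            raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(rows)
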