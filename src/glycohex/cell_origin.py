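"""Cell-of-origin annotation and marker-score/glycan-class correlation.

Proteins detected in the abundance matrix are mapped to curated annotation
sets (HPA-style: bone-marrow tissue annotation; blood NK/B/T/monocyte
lineages). A per-sample marker score aggregates the normalized abundances of
a set's detected members (sum by default, mean or log-space configurable),
and the scores are correlated against per-sample glycan-class shares with
the t-tested Pearson coefficient, pairwise-complete over missing values.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats_survival import pearson

__all__ = [
    "map_proteins",
    "marker_score",
    "correlate_origin_glycotype",
    "overlap_percentages",
]


def map_proteins(
    proteins: Iterable[str], sets: Mapping[str, Iterable[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate proteins against the sets and summarize overlaps.

    Returns ``(membership, overlap)``: membership has one row per protein
    with a boolean column per set plus ``annotated``; overlap is the
    sets x sets matrix of pairwise shared *detected* proteins (diagonal =
    per-set detected counts).
    """
    proteins = list(dict.fromkeys(proteins))
    set_members = {name: frozenset(m) for name, m in sets.items()}
    membership = pd.DataFrame(
        {name: [p in members for p in proteins] for name, members in set_members.items()},
        index=pd.Index(proteins, name="accession"),
    )
    membership["annotated"] = membership.any(axis=1)
    names = list(set_members)
    overlap = pd.DataFrame(
        [
            [int((membership[a] & membership[b]).sum()) for b in names]
            for a in names
        ],
        index=names,
        columns=names,
    )
    return membership, overlap


def marker_score(
    matrix: pd.DataFrame, annotation_set: Iterable[str], aggregate: str = "sum"
) -> pd.Series:
    """Per-sample aggregate abundance over the set's detected members.

    ``matrix`` is features(or proteins) x samples; rows whose accession (the
    first index level, or the index itself) belongs to the set contribute.
    Raises if no member is detected. Missing values are ignored within the
    aggregate; the number of contributing proteins is recorded in
    ``result.attrs["n_proteins"]``.
    """
    members = frozenset(annotation_set)
    if isinstance(matrix.index, pd.MultiIndex):
        accessions = matrix.index.get_level_values(0)
    else:
        accessions = matrix.index
    mask = accessions.isin(members)
    if not mask.any():
        raise ValueError("no member of the annotation set detected in the matrix")
    sub = matrix.loc[mask]
    if aggregate == "sum":
        score = sub.sum(axis=0, skipna=True)
    elif aggregate == "mean":
        score = sub.mean(axis=0, skipna=True)
    elif aggregate == "log_mean":
        score = np.log2(sub.where(sub > 0)).mean(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    score.name = "marker_score"
    score.attrs["n_proteins"] = int(len(np.unique(accessions[mask])))
    return score


def correlate_origin_glycotype(
    scores: Mapping[str, pd.Series], class_shares: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Pearson correlation of every marker score against every class share.

    Returns a tidy frame (set, glycan_class, r, p, n); cells with fewer
    than ``min_n`` paired samples are reported with missing r/p and
    ``computable`` False rather than raising.
    """
    rows = []
    for set_name, score in scores.items():
        for cls in class_shares.index:
            share = class_shares.loc[cls]
            common = score.index.intersection(share.index)
            x = score.loc[common].to_numpy(dtype=float)
            y = share.loc[common].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_n:
                rows.append(
                    {"set": set_name, "glycan_class": cls, "r": np.nan, "p": np.nan,
                     "n": n, "computable": False}
                )
                continue
            try:
                res = pearson(x[ok], y[ok])
            except ValueError:  # zero-variance cell (e.g. a class absent everywhere)
                rows.append(
                    {"set": set_name, "glycan_class": cls, "r": np.nan, "p": np.nan,
                     "n": n, "computable": False}
                )
                continue
            rows.append(
                {"set": set_name, "glycan_class": cls, "r": res.r, "p": res.p,
                 "n": res.n, "computable": True}
            )
    return pd.DataFrame(rows)


def overlap_percentages(reference_size: int, shared_count: int) -> float:
    """Percentage of a reference set covered by an overlap, to one decimal.

    e.g. 7 of 51 paucimannosidic proteins -> 13.7.
    """
    if reference_size <= 0:
        raise ValueError("reference set size must be positive")
    if not 0 <= shared_count <= reference_size:
        raise ValueError("shared count must lie in [0, reference size]")
    return round(100.0 * shared_count / reference_size, 1)
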