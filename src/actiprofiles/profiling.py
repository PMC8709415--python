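"""Characterising a cluster solution against participant metadata.

Three table families describe a fitted partition: per-cluster average
weekly profiles (the visual signature of each activity pattern), per-row
percentage composition tables of binary characteristics with extreme
markers (which cluster is most/least female, most/least employed, ...),
and outcome cross-tabulations that show, for each outcome category, how
its members distribute across clusters relative to the overall cluster
shares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import round_half_up

__all__ = [
    "CompositionTable",
    "OutcomeDifferenceTable",
    "cluster_mean_profiles",
    "composition_table",
    "group_shares",
    "outcome_difference_table",
    "covid_outcome_table",
]


def cluster_mean_profiles(
    X: np.ndarray,
    labels: Sequence,
    expected_labels: Sequence | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Arithmetic mean 168-hour profile per cluster, with cluster sizes.

    Returns a (cluster x hour) frame and a size series. Passing
    ``expected_labels`` raises if any expected cluster is empty.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one label required per profile")
    present = pd.unique(labels)
    if expected_labels is not None:
        missing = [l for l in expected_labels if l not in set(present.tolist())]
        if missing:
            raise ValueError(f"empty cluster(s): {missing}")
        order = list(expected_labels)
    else:
        order = sorted(present.tolist())
    means = {}
    sizes = {}
    for lab in order:
        mask = labels == lab
        means[lab] = X[mask].mean(axis=0)
        sizes[lab] = int(mask.sum())
    frame = pd.DataFrame(means).T
    frame.columns = [f"hour_{h:03d}" for h in range(X.shape[1])]
    return frame, pd.Series(sizes, name="n")


def group_shares(sizes: Mapping | pd.Series, ndigits: int | None = 1) -> pd.Series:
    """Percentage share of each group in the pooled total."""
    sizes = pd.Series(sizes, dtype=float)
    if (sizes < 0).any() or sizes.sum() <= 0:
        raise ValueError("group sizes must be non-negative with a positive total")
    shares = 100.0 * sizes / sizes.sum()
    if ndigits is not None:
        shares = shares.map(lambda v: round_half_up(v, ndigits))
    return shares


@dataclass
class CompositionTable:
    """Characteristics-by-group percentage table with row extreme markers.

    ``table`` rows are characteristics, columns the groups plus an overall
    column; ``extreme_markers`` lists, per row, the group(s) attaining the
    row maximum and minimum (ties all marked); ``denominators`` records the
    per-cell count of non-missing responses.
    """

    table: pd.DataFrame
    overall_column: str
    extreme_markers: dict
    denominators: pd.DataFrame
    notes: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "table": json.loads(self.table.to_json(orient="index")),
            "overall_column": self.overall_column,
            "extreme_markers": self.extreme_markers,
            "denominators": json.loads(self.denominators.to_json(orient="index")),
            "notes": self.notes,
        }, indent=2)


def composition_table(
    groups: Sequence,
    characteristics: pd.DataFrame,
    overall_label: str = "Overall",
    group_order: Sequence | None = None,
    ndigits: int = 1,
) -> CompositionTable:
    """Percentage of participants with each characteristic, by group.

    ``groups`` is a per-participant group label (cluster assignment or
    sample membership); ``characteristics`` holds one boolean column per
    characteristic, aligned by position, with missing values excluded from
    both numerator and denominator of their cell. The overall column pools
    all participants. Row extremes are computed over the group columns
    (excluding the overall column) on unrounded values.
    """
    groups = np.asarray(groups)
    if len(groups) != len(characteristics):
        raise ValueError("one group label required per participant")
    order = list(group_order) if group_order is not None \
        else sorted(pd.unique(groups).tolist())
    for g in order:
        if (groups == g).sum() == 0:
            raise ValueError(f"empty group: {g!r}")

    raw = pd.DataFrame(index=characteristics.columns,
                       columns=order + [overall_label], dtype=float)
    denom = raw.copy()
    for col in characteristics.columns:
        vals = characteristics[col]
        notna = vals.notna().to_numpy()
        truth = np.zeros(len(vals), dtype=bool)
        truth[notna] = np.asarray(vals[vals.notna()],
                                  dtype=object).astype(bool)
        for g in order:
            mask = (groups == g) & notna
            if mask.sum() == 0:
                raise ValueError(
                    f"group {g!r} has no non-missing values for {col!r}")
            raw.loc[col, g] = 100.0 * truth[mask].sum() / mask.sum()
            denom.loc[col, g] = mask.sum()
        raw.loc[col, overall_label] = 100.0 * truth[notna].sum() / notna.sum()
        denom.loc[col, overall_label] = notna.sum()

    markers = {}
    for col in raw.index:
        row = raw.loc[col, order].astype(float)
        markers[col] = {
            "max": [g for g in order if np.isclose(row[g], row.max())],
            "min": [g for g in order if np.isclose(row[g], row.min())],
        }
    rounded = raw.map(lambda v: round_half_up(float(v), ndigits))
    return CompositionTable(
        table=rounded,
        overall_column=overall_label,
        extreme_markers=markers,
        denominators=denom.astype(int),
        notes="missing responses excluded per cell from numerator and denominator",
    )


@dataclass
class OutcomeDifferenceTable:
    """Within-outcome cluster distribution versus the overall cluster shares.

    Each row of ``percentages`` sums to 100; ``differences`` subtracts the
    all-participants share of each cluster, so each row sums to ~0.
    """

    percentages: pd.DataFrame
    differences: pd.DataFrame
    overall_shares: pd.Series

    def formatted(self) -> pd.DataFrame:
        def cell(p, d):
            return f"{p:.1f}% ({d:+.1f}%)"
        return pd.DataFrame(
            {c: [cell(self.percentages.loc[r, c], self.differences.loc[r, c])
                 for r in self.percentages.index]
             for c in self.percentages.columns},
            index=self.percentages.index)

    def to_json(self) -> str:
        return json.dumps({
            "percentages": json.loads(self.percentages.to_json(orient="index")),
            "differences": json.loads(self.differences.to_json(orient="index")),
            "overall_shares": json.loads(self.overall_shares.to_json()),
        }, indent=2)


def outcome_difference_table(
    outcomes: Sequence,
    clusters: Sequence,
    outcome_order: Sequence | None = None,
    cluster_order: Sequence | None = None,
    ndigits: int = 1,
) -> OutcomeDifferenceTable:
    """Distribution of each outcome category across clusters, vs overall.

    Cell (o, c) is the percentage of outcome-o participants assigned to
    cluster c; the paired difference is that percentage minus the share of
    cluster c among all participants. Differences are computed on unrounded
    percentages and rounded afterwards.
    """
    outcomes = np.asarray(outcomes)
    clusters = np.asarray(clusters)
    if outcomes.shape[0] != clusters.shape[0]:
        raise ValueError("outcome and cluster labels must align")
    o_order = list(outcome_order) if outcome_order is not None \
        else sorted(pd.unique(outcomes).tolist())
    c_order = list(cluster_order) if cluster_order is not None \
        else sorted(pd.unique(clusters).tolist())

    overall = pd.Series(
        {c: 100.0 * (clusters == c).sum() / clusters.size for c in c_order})
    pct = pd.DataFrame(index=o_order, columns=c_order, dtype=float)
    for o in o_order:
        mask = outcomes == o
        n = mask.sum()
        if n == 0:
            raise ValueError(f"no participants with outcome {o!r}")
        for c in c_order:
            pct.loc[o, c] = 100.0 * (mask & (clusters == c)).sum() / n
    diff = pct.sub(overall, axis=1)
    rnd = lambda frame: frame.map(lambda v: round_half_up(float(v), ndigits))
    return OutcomeDifferenceTable(
        percentages=rnd(pct),
        differences=rnd(diff),
        overall_shares=overall.map(lambda v: round_half_up(v, ndigits)),
    )


def covid_outcome_table(
    clusters: Sequence,
    status: pd.DataFrame,
    cluster_order: Sequence | None = None,
    ndigits: int = 1,
) -> pd.DataFrame:
    """Per-cluster survival/testing outcome summary.

    ``status`` must hold boolean columns ``alive``, ``tested`` and
    ``positive`` (a positive test implies a test). Denominators follow the
    reporting convention: the alive percentage is over the cluster size,
    the tested and positive percentages over those alive, and the
    positivity rate over those tested; a cluster with no tests reports an
    undefined (NaN) positivity rather than zero.
    """
    clusters = np.asarray(clusters)
    for col in ("alive", "tested", "positive"):
        if col not in status.columns:
            raise ValueError(f"status table must include a {col!r} column")
    alive = status["alive"].astype(bool).to_numpy()
    tested = status["tested"].astype(bool).to_numpy()
    positive = status["positive"].astype(bool).to_numpy()
    if np.any(positive & ~tested):
        raise ValueError("a positive result implies having been tested")
    order = list(cluster_order) if cluster_order is not None \
        else sorted(pd.unique(clusters).tolist())

    rows = {}
    for c in order + ["Overall"]:
        mask = np.ones(clusters.size, dtype=bool) if c == "Overall" \
            else clusters == c
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty cluster: {c!r}")
        n_alive = int((mask & alive).sum())
        n_tested = int((mask & alive & tested).sum())
        n_positive = int((mask & alive & positive).sum())
        rows[c] = {
            "n": n,
            "n_alive": n_alive,
            "pct_alive": round_half_up(100.0 * n_alive / n, ndigits),
            "pct_alive_tested": round_half_up(
                100.0 * n_tested / n_alive, ndigits) if n_alive else np.nan,
            "pct_alive_positive": round_half_up(
                100.0 * n_positive / n_alive, ndigits) if n_alive else np.nan,
            "positivity_rate": round_half_up(
                100.0 * n_positive / n_tested, ndigits) if n_tested else np.nan,
        }
    return pd.DataFrame(rows).T
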