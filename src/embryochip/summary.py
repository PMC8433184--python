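"""Cohort-level phenotype aggregation and the clustergram matrix.

A cohort (one condition) is summarised by:

* ``dead_fraction``  = Dead / all embryos, with empty incubators excluded
  from the denominator (they contain no embryo);
* ``normal_over_alive`` = Normal / (Normal + LateHatching + Unclear),
  the viability phenotype over the alive population;
* mean +/- SEM of the bean-to-twitch and twitch-to-hatch intervals in
  minutes, over Normal embryos only (the only state with all three
  transitions observed).

Conditions are compared through a clustergram: each phenotype row is
z-scored across conditions (constant rows map to zeros and sort last)
and rows/columns are ordered by average-linkage hierarchical clustering
under correlation distance, with a deterministic tie-break by label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .phenotype import EmbryoRecord, EmbryoState

__all__ = ["CohortSummary", "ClustergramMatrix", "summarize_cohort", "build_clustergram"]


@dataclass
class CohortSummary:
    """Phenotype summary of one condition."""

    condition: str
    n_total: int  # embryos (Empty excluded)
    n_per_state: dict
    dead_fraction: Optional[float]
    normal_over_alive: Optional[float]
    bean_to_twitch_mean: Optional[float]
    bean_to_twitch_sem: Optional[float]
    twitch_to_hatch_mean: Optional[float]
    twitch_to_hatch_sem: Optional[float]
    bean_to_twitch_values: list = field(default_factory=list)
    twitch_to_hatch_values: list = field(default_factory=list)
    empty_cohort: bool = False


def _mean_sem(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return None, None
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem


def summarize_cohort(records: Sequence[EmbryoRecord], condition: str = "") -> CohortSummary:
    """Tally one cohort of embryo records into a :class:`CohortSummary`.

    An all-Empty cohort yields a summary flagged ``empty_cohort`` rather
    than an error.  The raw per-embryo interval vectors are kept on the
    summary so downstream significance testing (e.g. one-way ANOVA) can
    run on them directly.
    """
    counts = {s: 0 for s in EmbryoState}
    for r in records:
        counts[r.state] += 1
    n_embryos = sum(c for s, c in counts.items() if s is not EmbryoState.EMPTY)
    alive = (
        counts[EmbryoState.NORMAL]
        + counts[EmbryoState.LATE_HATCHING]
        + counts[EmbryoState.UNCLEAR]
    )
    normals = [r for r in records if r.state is EmbryoState.NORMAL]
    b2t = [r.bean_to_twitch_min for r in normals if r.bean_to_twitch_min is not None]
    t2h = [r.twitch_to_hatch_min for r in normals if r.twitch_to_hatch_min is not None]
    b2t_mean, b2t_sem = _mean_sem(b2t)
    t2h_mean, t2h_sem = _mean_sem(t2h)
    return CohortSummary(
        condition=condition,
        n_total=n_embryos,
        n_per_state={s.value: c for s, c in counts.items()},
        dead_fraction=(counts[EmbryoState.DEAD] / n_embryos) if n_embryos else None,
        normal_over_alive=(counts[EmbryoState.NORMAL] / alive) if alive else None,
        bean_to_twitch_mean=b2t_mean,
        bean_to_twitch_sem=b2t_sem,
        twitch_to_hatch_mean=t2h_mean,
        twitch_to_hatch_sem=t2h_sem,
        bean_to_twitch_values=list(b2t),
        twitch_to_hatch_values=list(t2h),
        empty_cohort=n_embryos == 0,
    )


DEFAULT_PHENOTYPES = (
    "dead_fraction",
    "normal_over_alive",
    "bean_to_twitch_mean",
    "twitch_to_hatch_mean",
)


@dataclass
class ClustergramMatrix:
    """Z-scored phenotype-by-condition matrix with dendrogram orderings."""

    matrix: pd.DataFrame  # rows = phenotypes, cols = conditions, z-scored
    row_order: list
    col_order: list

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def _cluster_order(data: np.ndarray, labels: list[str]) -> list[str]:
    """Average-linkage / correlation-distance leaf order; label tie-break."""
    order = np.argsort(np.asarray(labels), kind="stable")
    data = data[order]
    labels = [labels[i] for i in order]
    if len(labels) < 3:
        return labels
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(data, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)
    z = linkage(d, method="average")
    return [labels[i] for i in leaves_list(z)]


def build_clustergram(
    summaries: Sequence[CohortSummary],
    phenotypes: Sequence[str] = DEFAULT_PHENOTYPES,
) -> ClustergramMatrix:
    """Normalised-mean phenotype matrix across conditions.

    Each phenotype row is z-scored across conditions with the population
    standard deviation; a constant (zero-variance) row is defined as all
    zeros and sorted after the clustered rows.  Column ordering does not
    depend on the input order of the conditions.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("clustergram needs at least two conditions")
    conditions = [s.condition for s in summaries]
    if len(set(conditions)) != len(conditions):
        raise ValueError("condition labels must be unique")

    raw = pd.DataFrame(
        {s.condition: [getattr(s, p) for p in phenotypes] for s in summaries},
        index=list(phenotypes),
        dtype=float,
    )
    # canonical column order: float reductions are evaluation-order
    # dependent, so normalise over a label-sorted frame for exact
    # permutation invariance
    raw = raw[sorted(raw.columns)]
    mu = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=0)
    z = raw.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)

    constant = sd == 0.0
    variable_rows = [p for p in phenotypes if not constant[p]]
    constant_rows = [p for p in phenotypes if constant[p]]
    if variable_rows:
        row_order = _cluster_order(z.loc[variable_rows].to_numpy(), variable_rows)
    else:
        row_order = []
    row_order = row_order + sorted(constant_rows)

    basis = z.loc[variable_rows] if variable_rows else z
    col_order = _cluster_order(basis.to_numpy().T, list(z.columns))
    return ClustergramMatrix(matrix=z, row_order=row_order, col_order=col_order)
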