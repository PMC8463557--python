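"""Diagonal-discriminant t-score feature ranking.

Each (group g, feature j) gets a centroid-versus-grand-mean t-score

    tau_gj = (mean_gj - mean_j) / (m_g * (s_j + s0)),   m_g = sqrt(1/n_g - 1/n)

with s_j the pooled within-group standard deviation and s0 the median of
the s_j (a variance-stabilising floor). Features are ranked by the sum of
squared scores over groups, descending.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = ["FeatureRanking", "dda_rank"]


@dataclass
class FeatureRanking:
    """Per-group t-scores and the derived overall feature ranking."""

    tau: pd.DataFrame  # groups x features
    scores: pd.Series  # per feature, sum over groups of tau^2
    order: list[str]  # feature names, best first

    def to_csv(self, path: str | Path) -> None:
        df = self.tau.T
        df.insert(0, "score", self.scores)
        df.insert(1, "rank", np.argsort(np.argsort(-self.scores.values)) + 1)
        df.index.name = "feature"
        df.loc[self.order].to_csv(path)


def dda_rank(m: FeatureMatrix, labels: list[str] | None = None) -> FeatureRanking:
    """Rank features by group-discriminative t-scores.

    Raises ``ValueError`` with fewer than two groups. Features whose
    denominator vanishes (all features constant within groups and zero
    median sd) get a score of 0 where the numerator is also 0.
    """
    labels = list(labels if labels is not None else m.labels)
    if len(labels) != m.shape[0]:
        raise ValueError("labels length must match the number of rows")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("feature ranking needs at least 2 groups")
    x = m.values
    n, p = x.shape
    g = len(groups)
    grand = x.mean(axis=0)

    ss_within = np.zeros(p)
    group_means = np.empty((g, p))
    m_g = np.empty(g)
    for gi, lab in enumerate(groups):
        idx = [i for i, l in enumerate(labels) if l == lab]
        n_g = len(idx)
        sub = x[idx]
        group_means[gi] = sub.mean(axis=0)
        ss_within += ((sub - group_means[gi]) ** 2).sum(axis=0)
        m_g[gi] = np.sqrt(1.0 / n_g - 1.0 / n)
    if n - g <= 0:
        raise ValueError("need more observations than groups for a pooled variance")
    s_j = np.sqrt(ss_within / (n - g))
    s0 = float(np.median(s_j))

    denom = m_g[:, None] * (s_j + s0)[None, :]
    numer = group_means - grand[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    tau[np.abs(numer) == 0] = 0.0

    feature_names = [f"{mass:.2f}" for mass in m.bin_masses]
    tau_df = pd.DataFrame(tau, index=groups, columns=feature_names)
    scores = pd.Series((tau**2).sum(axis=0), index=feature_names, name="score")
    order = list(scores.sort_values(ascending=False, kind="stable").index)
    return FeatureRanking(tau_df, scores, order)
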